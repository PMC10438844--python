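"""Readers and writers for the plain-text formats used by the pipeline.

Internally all intervals are half-open and 0-based; VCF and HGVS positions
are 1-based closed and converted at this layer only. Every reader checks
the header against the documented schema and names the deviation.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genmap import GENOTYPE_CODES, GENOTYPE_LABELS, BackcrossCohort, GeneticMap
from .lof import VariantSpec
from .popgen import PopAlleleCounts

ASE_COLUMNS = ["line", "replicate_kind", "replicate_id", "material", "ref_count", "alt_count"]
COHORT_FIXED_COLUMNS = ["individual_id", "survived", "phenotype"]
MAP_COLUMNS = ["marker", "chromosome", "cM"]


class SchemaError(ValueError):
    """An input file does not match the documented schema."""


def _require_columns(df: pd.DataFrame, required, path, label):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{label} file {path}: missing column(s) {missing}; "
            f"expected header to include {required}"
        )


# --- genetic map ------------------------------------------------------------


def write_map_tsv(genetic_map: GeneticMap, path):
    df = pd.DataFrame(
        {
            "marker": genetic_map.names,
            "chromosome": genetic_map.chromosome,
            "cM": genetic_map.positions,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_map_tsv(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, MAP_COLUMNS, path, "genetic map")
    chroms = df["chromosome"].unique()
    if len(chroms) != 1:
        raise SchemaError(f"genetic map file {path}: expected a single chromosome, got {list(chroms)}")
    return GeneticMap(str(chroms[0]), tuple(zip(df["marker"].astype(str), df["cM"].astype(float))))


# --- backcross cohort -------------------------------------------------------


def write_cohort_csv(cohort: BackcrossCohort, path):
    data = {
        "individual_id": [f"ind{i + 1}" for i in range(cohort.n)],
        "survived": cohort.survived.astype(int),
        "phenotype": cohort.phenotype.astype(int),
    }
    for j, name in enumerate(cohort.map.names):
        data[name] = [GENOTYPE_LABELS[g] for g in cohort.genotypes[:, j]]
    pd.DataFrame(data).to_csv(path, index=False)


def read_cohort_csv(path, genetic_map: GeneticMap) -> BackcrossCohort:
    df = pd.read_csv(path, dtype={"survived": int, "phenotype": int})
    _require_columns(df, COHORT_FIXED_COLUMNS, path, "cohort")
    missing_markers = [m for m in genetic_map.names if m not in df.columns]
    if missing_markers:
        raise SchemaError(
            f"cohort file {path}: missing genotype column(s) for marker(s) {missing_markers}"
        )
    geno = np.empty((len(df), genetic_map.n_markers), dtype=np.int8)
    for j, name in enumerate(genetic_map.names):
        col = df[name].fillna("NA").astype(str)
        bad = ~col.isin(GENOTYPE_CODES)
        if bad.any():
            raise SchemaError(
                f"cohort file {path}: column {name!r} holds invalid genotype "
                f"value(s) {sorted(col[bad].unique())}; expected HET/HOM_S/NA"
            )
        geno[:, j] = [GENOTYPE_CODES[v] for v in col]
    return BackcrossCohort(
        genetic_map, geno, df["phenotype"].to_numpy(bool), df["survived"].to_numpy(bool)
    )


# --- population allele counts (summary VCF + sites TSV) ---------------------


def write_pop_counts_vcf(pop_counts: PopAlleleCounts, vcf_path, sites_tsv_path=None):
    """Minimal biallelic VCF with per-population AC_<pop>/AN_<pop> INFO
    fields, plus an optional sites TSV carrying the site class."""
    pops = pop_counts.populations
    lines = ["##fileformat=VCFv4.2"]
    for chrom in pop_counts.sites["chromosome"].unique():
        lines.append(f"##contig=<ID={chrom}>")
    for pop in pops:
        lines.append(
            f'##INFO=<ID=AC_{pop},Number=1,Type=Integer,Description="Derived allele count in {pop}">'
        )
        lines.append(
            f'##INFO=<ID=AN_{pop},Number=1,Type=Integer,Description="Called haploid samples in {pop}">'
        )
    lines.append('##INFO=<ID=SITECLASS,Number=1,Type=String,Description="Site class">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for i, row in pop_counts.sites.reset_index(drop=True).iterrows():
        info = ";".join(
            f"AC_{pop}={pop_counts.counts[i, j]};AN_{pop}={pop_counts.called[i, j]}"
            for j, pop in enumerate(pops)
        )
        info += f";SITECLASS={row['site_class']}"
        lines.append(
            f"{row['chromosome']}\t{row['position']}\t.\t{row['ref']}\t{row['alt']}\t.\tPASS\t{info}"
        )
    Path(vcf_path).write_text("\n".join(lines) + "\n")
    if sites_tsv_path is not None:
        pop_counts.sites.to_csv(sites_tsv_path, sep="\t", index=False)


def read_pop_counts_vcf(vcf_path) -> PopAlleleCounts:
    """Read the AC/AN summary VCF written by :func:`write_pop_counts_vcf`."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    pops = []
    for line in vcf.raw_header.splitlines():
        if line.startswith("##INFO=<ID=AC_"):
            pops.append(line.split("ID=AC_", 1)[1].split(",", 1)[0])
    if len(pops) < 2:
        raise SchemaError(f"VCF {vcf_path}: expected AC_<pop> INFO fields for >=2 populations")
    sites = []
    counts = []
    called = []
    for var in vcf:
        sites.append(
            {
                "chromosome": var.CHROM,
                "position": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
                "site_class": var.INFO.get("SITECLASS", "other"),
            }
        )
        counts.append([var.INFO.get(f"AC_{p}", 0) for p in pops])
        called.append([var.INFO.get(f"AN_{p}", 0) for p in pops])
    if not sites:
        raise SchemaError(f"VCF {vcf_path}: no variant records")
    return PopAlleleCounts(pd.DataFrame(sites), np.array(counts), np.array(called), pops)


def read_populations_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["sample", "population"], path, "populations")
    return df


def parse_region(region: str):
    """Parse "chrom:start-end" (1-based closed, as printed in genome
    browsers) into (chrom, start0, end) half-open 0-based."""
    chrom, span = region.split(":")
    start, end = span.replace(",", "").split("-")
    return chrom, int(start) - 1, int(end)


def read_vcf_genotypes(vcf_path, populations: pd.DataFrame, region: str | None = None,
                       site_classes: dict | None = None) -> PopAlleleCounts:
    """Aggregate per-sample GT calls from a VCF into population allele counts.

    Biallelic sites only. Every called allele is counted as one haploid
    call, so a diploid genotype contributes two (inbred fly genomes carry
    one haplotype each; diploid records are treated as two). ``site_classes``
    optionally maps (chromosome, position) to a class label; the default
    class is "other".
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = vcf.samples
    pop_of = dict(zip(populations["sample"].astype(str), populations["population"].astype(str)))
    unknown = [s for s in samples if s not in pop_of]
    if unknown:
        warnings.warn(f"samples without a population assignment ignored: {unknown}")
    pops = list(dict.fromkeys(populations["population"].astype(str)))
    pop_idx = {p: j for j, p in enumerate(pops)}
    col_of_sample = np.array([pop_idx.get(pop_of.get(s, ""), -1) for s in samples])

    want = parse_region(region) if region else None
    sites = []
    counts = []
    called = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        if want is not None:
            chrom, start0, end = want
            if var.CHROM != chrom or not (start0 < var.POS <= end):
                continue
        row_counts = np.zeros(len(pops), dtype=np.int64)
        row_called = np.zeros(len(pops), dtype=np.int64)
        for s_idx, gt in enumerate(var.genotypes):
            j = col_of_sample[s_idx]
            if j < 0:
                continue
            alleles = [a for a in gt[:-1] if a >= 0]
            row_called[j] += len(alleles)
            row_counts[j] += sum(1 for a in alleles if a == 1)
        cls = "other"
        if site_classes is not None:
            cls = site_classes.get((var.CHROM, var.POS), "other")
        sites.append(
            {
                "chromosome": var.CHROM,
                "position": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
                "site_class": cls,
            }
        )
        counts.append(row_counts)
        called.append(row_called)
    if not sites:
        raise SchemaError(f"VCF {vcf_path}: no usable biallelic records")
    return PopAlleleCounts(pd.DataFrame(sites), np.array(counts), np.array(called), pops)


# --- allele-specific expression ---------------------------------------------


def write_ase_csv(table: pd.DataFrame, path):
    table[ASE_COLUMNS].to_csv(path, index=False)


def read_ase_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ASE_COLUMNS, path, "ASE counts")
    for col in ("ref_count", "alt_count"):
        if (df[col] < 0).any():
            raise SchemaError(f"ASE counts file {path}: negative values in {col}")
    bad = ~df["material"].isin(["cDNA", "gDNA"])
    if bad.any():
        raise SchemaError(
            f"ASE counts file {path}: material must be cDNA or gDNA, "
            f"got {sorted(df.loc[bad, 'material'].unique())}"
        )
    return df


def read_lines_tsv(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["line", "haplotype_code"], path, "lines")
    return dict(zip(df["line"].astype(str), df["haplotype_code"].astype(str)))


# --- gene reference and variants --------------------------------------------


def read_gene_fasta(path) -> tuple:
    """Reference FASTA with two records named ``CDS`` and ``upstream``."""
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    for needed in ("CDS", "upstream"):
        if needed not in records:
            raise SchemaError(f"gene FASTA {path}: missing record {needed!r} (found {list(records)})")
    return records["CDS"], records["upstream"]


def write_gene_fasta(cds: str, upstream: str, path):
    with open(path, "w") as fh:
        fh.write(f">CDS\n{cds}\n>upstream\n{upstream}\n")


def read_variants_tsv(path) -> dict:
    """Per-genome variant lists from a TSV with columns
    genome_id, region, position, ref, alt (empty allele = '-').

    The variant kind is inferred from the allele lengths. Returns
    {genome_id: [VariantSpec, ...]}.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["genome_id", "region", "position", "ref", "alt"], path, "variants")
    out: dict = {}
    for _, row in df.iterrows():
        ref = "" if row["ref"] in ("-", "") else row["ref"]
        alt = "" if row["alt"] in ("-", "") else row["alt"]
        if ref and alt and len(ref) == 1 and len(alt) == 1:
            kind = "SNV"
        elif not ref:
            kind = "insertion"
        elif not alt:
            kind = "deletion"
        else:
            raise SchemaError(
                f"variants file {path}: genome {row['genome_id']} has an allele pair "
                f"({row['ref']!r}, {row['alt']!r}) that is neither SNV, insertion nor deletion"
            )
        out.setdefault(row["genome_id"], []).append(
            VariantSpec(kind, int(row["position"]), ref, alt, row["region"])
        )
    return out


def write_variants_tsv(genomes, path):
    """Write per-genome variants (``SimulatedGenome`` objects or
    (genome_id, variants) pairs) in the TSV schema of read_variants_tsv."""
    rows = []
    for g in genomes:
        gid, variants = (g.genome_id, g.variants) if hasattr(g, "genome_id") else g
        for v in variants:
            rows.append(
                {
                    "genome_id": gid,
                    "region": v.region,
                    "position": v.position,
                    "ref": v.ref or "-",
                    "alt": v.alt or "-",
                }
            )
    pd.DataFrame(rows, columns=["genome_id", "region", "position", "ref", "alt"]).to_csv(
        path, sep="\t", index=False
    )
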