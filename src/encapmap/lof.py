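"""Loss-of-function annotation for a single immune gene.

Classifies gene alleles as functional or loss-of-function from sequence
variants: premature stop codons (point mutations or frameshifts in the
coding sequence) and an expression-abolishing 21-bp deletion in the
upstream cis-regulatory region. Also codes the three upstream indels into
D/I haplotypes whose expression classes were established experimentally.

Coordinate conventions (HGVS-like): CDS positions are 1-based from the A
of the ATG start codon; upstream positions are negative c.-N counts of
bases before the start codon, so c.-1 is the base immediately 5' of ATG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 21-bp upstream sequence (c.-171_-151) required for induction of the
#: gene after infection; its deletion abolishes expression.
MOTIF_21BP = "AAATAAGGCTATCTGGGATCA"

STOP_CODONS = {"TAA", "TAG", "TGA"}

LOF_CLASSES = ("functional", "expression_null", "premature_stop", "multiple", "unscorable")

#: Upstream indel order for the haplotype code:
#: c.-439_-433del, c.-334_-333insACATTCAT, c.-171_-151del
HAPLOTYPE_EXPRESSION_CLASS = {
    "DDD": "low_expression",
    "DDI": "low_expression",
    "DII": "expressing",
    "IDI": "expressing",
    "III": "expressing",
}


@dataclass(frozen=True)
class VariantSpec:
    """A single variant on the gene's CDS or upstream coordinate system.

    ``kind`` is "SNV", "insertion" or "deletion". ``position`` is 1-based
    on the CDS (positive) or c.-N upstream (negative). For SNVs and
    deletions ``ref`` is the reference base(s) starting at ``position``;
    for insertions ``ref`` is empty and ``alt`` is inserted immediately
    after ``position``.
    """

    kind: str
    position: int
    ref: str
    alt: str
    region: str  # "CDS" or "upstream"

    def __post_init__(self):
        if self.kind not in ("SNV", "insertion", "deletion"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.region not in ("CDS", "upstream"):
            raise ValueError(f"unknown region {self.region!r}")
        if self.kind == "insertion" and not self.alt:
            raise ValueError("insertion needs a non-empty alt allele")
        if self.kind == "deletion" and not self.ref:
            raise ValueError("deletion needs a non-empty ref allele")
        if self.kind == "SNV" and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError("SNV needs single-base ref and alt")


@dataclass
class VariantEffectRecord:
    """Predicted functional class of one genome's gene allele."""

    genome_id: str
    lof_class: str
    evidence: list  # of (VariantSpec, consequence string)
    genotyped_fraction: float


def _index0(position: int, seq_len: int, region: str) -> int:
    """0-based index of a 1-based CDS or c.-N upstream position."""
    if region == "upstream":
        if position >= 0:
            raise ValueError("upstream positions use negative c.-N coordinates")
        idx = seq_len + position
    else:
        if position < 1:
            raise ValueError("CDS positions are 1-based and positive")
        idx = position - 1
    if not (0 <= idx < seq_len):
        raise ValueError(f"position {position} outside the {region} sequence")
    return idx


def apply_variants(reference: str, variants) -> str:
    """Apply variants to a reference sequence, right to left.

    All variants must target the same region (the region whose sequence is
    passed). Right-to-left application keeps earlier positions valid.
    Overlapping variants or ref-allele mismatches raise a ValueError naming
    the offending variant.
    """
    if not variants:
        return reference
    regions = {v.region for v in variants}
    if len(regions) > 1:
        raise ValueError("apply_variants takes variants from a single region")
    L = len(reference)
    spans = []
    for v in variants:
        idx = _index0(v.position, L, v.region)
        if v.kind == "insertion":
            spans.append((v, idx + 1, idx + 1))  # insert after position
        else:
            if reference[idx : idx + len(v.ref)] != v.ref:
                raise ValueError(
                    f"ref allele mismatch for {v}: expected {v.ref!r}, "
                    f"found {reference[idx:idx + len(v.ref)]!r}"
                )
            spans.append((v, idx, idx + len(v.ref)))
    spans.sort(key=lambda t: t[1])
    for (va, _, end_a), (vb, start_b, _) in zip(spans, spans[1:]):
        if start_b < end_a:
            raise ValueError(f"overlapping variants: {va} and {vb}")
    seq = reference
    for v, start, end in reversed(spans):
        seq = seq[:start] + v.alt + seq[end:]
    return seq


def find_premature_stop(cds: str, reference_length: int | None = None):
    """First in-frame premature stop codon in a (possibly mutated) CDS.

    Scans codons from the start; a stop strictly before the reference
    terminal codon is premature. Returns ``(codon_number | None,
    frameshift_flag, start_warning)``. The frameshift flag is set when the
    length difference to the reference is not a multiple of 3; a non-ATG
    start sets the warning flag but the scan proceeds.
    """
    if len(cds) < 3:
        raise ValueError("CDS must be at least one codon long")
    ref_len = len(cds) if reference_length is None else reference_length
    terminal_codon = ref_len // 3
    frameshift = (len(cds) - ref_len) % 3 != 0
    start_warning = not cds.upper().startswith("ATG")
    seq = cds.upper()
    # str(Seq.translate) would also work; a direct scan keeps partial codons simple
    for codon_number in range(1, len(seq) // 3 + 1):
        codon = seq[(codon_number - 1) * 3 : codon_number * 3]
        if codon in STOP_CODONS:
            if codon_number < terminal_codon:
                return codon_number, frameshift, start_warning
            return None, frameshift, start_warning
    return None, frameshift, start_warning


def detect_regulatory_deletion(upstream: str, motif: str = MOTIF_21BP, max_mismatch: int = 0) -> bool:
    """True when the regulatory motif is PRESENT in the upstream sequence
    (the expression-competent state); False when absent (expression-null).

    Matching is exact by default; ``max_mismatch`` allows that many
    substitutions in a sliding-window comparison.
    """
    if not upstream:
        raise ValueError("upstream sequence is empty")
    up = upstream.upper()
    motif = motif.upper()
    if max_mismatch == 0:
        return motif in up
    m = len(motif)
    motif_arr = np.frombuffer(motif.encode(), dtype="S1")
    for i in range(len(up) - m + 1):
        window = np.frombuffer(up[i : i + m].encode(), dtype="S1")
        if int((window != motif_arr).sum()) <= max_mismatch:
            return True
    return False


def indel_haplotype_code(states) -> tuple:
    """Three-letter D/I haplotype code for the upstream indels.

    ``states`` are the deletion/insertion states, in the fixed order
    c.-439_-433del, c.-334_-333insACATTCAT, c.-171_-151del; each state is
    "D", "I" or missing (None / "missing" / "."). Returns
    ``(code, expression_class)`` where missing states render as the middle
    dot and make the class "undetermined". Complete codes map to
    "low_expression" (DDD, DDI), "expressing" (DII, IDI, III) or
    "unobserved" for combinations without an established class.
    """
    if len(states) != 3:
        raise ValueError("expected states for exactly three indels")
    letters = []
    for s in states:
        if s is None or s in ("missing", ".", "·"):
            letters.append("·")
        elif s in ("D", "I"):
            letters.append(s)
        else:
            raise ValueError(f"invalid indel state {s!r}")
    code = "".join(letters)
    if "·" in code:
        return code, "undetermined"
    return code, HAPLOTYPE_EXPRESSION_CLASS.get(code, "unobserved")


def _lof_consequence(variant: VariantSpec, cds: str, upstream: str) -> str | None:
    """Consequence of a single variant applied alone, or None if benign."""
    if variant.region == "upstream":
        mutated = apply_variants(upstream, [variant])
        if detect_regulatory_deletion(upstream) and not detect_regulatory_deletion(mutated):
            return "regulatory_deletion"
        return None
    mutated = apply_variants(cds, [variant])
    stop, frameshift, _ = find_premature_stop(mutated, reference_length=len(cds))
    if stop is not None:
        return f"premature_stop@codon{stop}" + ("+frameshift" if frameshift else "")
    return None


def classify_genome(
    variants,
    cds: str,
    upstream: str,
    genotyped_fraction: float,
    genome_id: str = "genome",
    min_genotyped: float = 0.5,
) -> VariantEffectRecord:
    """Classify one genome's gene allele from its variants.

    A genome genotyped for no more than ``min_genotyped`` of the gene is
    "unscorable". Otherwise each variant is scored alone: upstream variants
    that remove the 21-bp motif are expression-null, coding variants whose
    applied sequence translates to a premature stop (directly or through a
    frameshift) are premature-stop. Two or more distinct loss-of-function
    variants give "multiple" (the co-occurrence rule); one gives its own
    class; none gives "functional". Variants that are only jointly
    disruptive (e.g. two indels whose combined length shifts the frame)
    are caught by a final joint evaluation.
    """
    if genotyped_fraction <= min_genotyped:
        return VariantEffectRecord(genome_id, "unscorable", [], genotyped_fraction)
    evidence = []
    for v in variants:
        consequence = _lof_consequence(v, cds, upstream)
        if consequence is not None:
            evidence.append((v, consequence))
    if not evidence and variants:
        cds_vars = [v for v in variants if v.region == "CDS"]
        if cds_vars:
            mutated = apply_variants(cds, cds_vars)
            stop, frameshift, _ = find_premature_stop(mutated, reference_length=len(cds))
            if stop is not None:
                tag = f"premature_stop@codon{stop}" + ("+frameshift" if frameshift else "")
                evidence = [(v, tag + " (joint)") for v in cds_vars]
    if len(evidence) >= 2:
        lof_class = "multiple"
    elif len(evidence) == 1:
        lof_class = (
            "expression_null" if evidence[0][1] == "regulatory_deletion" else "premature_stop"
        )
    else:
        lof_class = "functional"
    return VariantEffectRecord(genome_id, lof_class, evidence, genotyped_fraction)


def population_lof_frequencies(records, populations) -> pd.DataFrame:
    """Per-population frequencies of the functional classes.

    ``records`` are VariantEffectRecords, ``populations`` the matching
    population label per record. Frequencies are over scorable genomes and
    sum to 1 per population; populations with no scorable genome are
    omitted with a warning.
    """
    records = list(records)
    populations = list(populations)
    if len(records) != len(populations):
        raise ValueError("one population label per record required")
    classes = [c for c in LOF_CLASSES if c != "unscorable"]
    rows = {}
    for pop in dict.fromkeys(populations):
        recs = [r for r, p in zip(records, populations) if p == pop and r.lof_class != "unscorable"]
        if not recs:
            warnings.warn(f"population {pop!r} has no scorable genomes; omitted")
            continue
        n = len(recs)
        rows[pop] = {c: sum(r.lof_class == c for r in recs) / n for c in classes}
    if not rows:
        raise ValueError("no population has scorable genomes")
    return pd.DataFrame.from_dict(rows, orient="index")[classes]
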