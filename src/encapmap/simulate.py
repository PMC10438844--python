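"""Synthetic-data generators for every stage of the pipeline.

Each generator emulates the statistical structure the downstream analyses
assume:

* backcross cohorts in which genotypes form a two-state Markov chain along
  the chromosome (Haldane recombination) and survival of parasitoid
  infection depends on the genotype at a single causal locus;
* multi-population allele frequencies under the Balding-Nichols drift
  model, with optional deterministic frequency shifts at locally selected
  sites;
* overdispersed (beta-binomial) allele-specific read counts with a
  genomic-DNA control at a 50:50 allele ratio;
* toy gene panels carrying premature-stop, frameshift and cis-regulatory
  deletion variants with known truth classes.

Every generator takes an explicit seed and uses its own ``numpy`` Generator;
there is no global random state, so results are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import HET, HOM_S, MISSING, BackcrossCohort, GeneticMap, haldane_recomb
from .lof import MOTIF_21BP, VariantSpec
from .popgen import PopAlleleCounts

ASE_COLUMNS = ["line", "replicate_kind", "replicate_id", "material", "ref_count", "alt_count"]


def _simulate_states(rng, n: int, positions: np.ndarray) -> np.ndarray:
    """Markov-chain genotypes (1=HET, 0=HOM_S) for n individuals at loci
    with the given cM positions."""
    L = len(positions)
    states = np.empty((n, L), dtype=np.int8)
    states[:, 0] = rng.random(n) < 0.5
    if L > 1:
        r = haldane_recomb(np.diff(positions))
        flips = rng.random((n, L - 1)) < r[None, :]
        for j in range(1, L):
            states[:, j] = states[:, j - 1] ^ flips[:, j - 1]
    return states


def simulate_backcross(
    genetic_map: GeneticMap,
    causal_position: float,
    p_het: float,
    p_hom: float,
    n: int,
    seed: int,
    background_survival: float = 1.0,
    missing_rate: float = 0.0,
) -> BackcrossCohort:
    """Simulate a backcross cohort with a single causal resistance locus.

    Genotypes at the markers and the (untyped) causal locus are generated
    jointly as a Markov chain with Haldane transition probabilities, so the
    marginal HET frequency is 0.5 everywhere. The melanization phenotype is
    Bernoulli with probability ``p_het`` for heterozygotes at the causal
    locus and ``p_hom`` for homozygous-susceptible individuals. Survival
    equals the phenotype (susceptible flies are killed by the parasitoid),
    optionally thinned by an independent ``background_survival`` rate.

    Parameters
    ----------
    genetic_map : GeneticMap
    causal_position : float
        cM position of the causal locus; must lie within the map span.
    p_het, p_hom : float
        Penetrances (probability of melanizing / surviving) for the two
        backcross genotypes; ``0 <= p_hom <= p_het <= 1``.
    n : int
        Number of individuals.
    seed : int
    background_survival : float
        Genotype-independent survival probability applied on top of the
        phenotype; default 1 (survival == melanization).
    missing_rate : float
        Per-genotype missingness applied to the marker matrix.
    """
    if not (0.0 <= p_hom <= p_het <= 1.0):
        raise ValueError("need 0 <= p_hom <= p_het <= 1")
    if not genetic_map.contains(causal_position):
        raise ValueError("causal position lies outside the map span")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    positions = genetic_map.positions
    # insert the causal locus into the position order (reuse a coincident marker)
    exact = np.where(np.isclose(positions, causal_position))[0]
    if len(exact):
        all_pos = positions
        causal_idx = int(exact[0])
        marker_cols = np.arange(len(positions))
    else:
        insert_at = int(np.searchsorted(positions, causal_position))
        all_pos = np.insert(positions, insert_at, causal_position)
        causal_idx = insert_at
        marker_cols = np.delete(np.arange(len(all_pos)), insert_at)

    states = _simulate_states(rng, n, all_pos)
    causal_het = states[:, causal_idx] == HET
    pen = np.where(causal_het, p_het, p_hom)
    phenotype = rng.random(n) < pen
    survived = phenotype
    if background_survival < 1.0:
        survived = survived & (rng.random(n) < background_survival)

    genotypes = states[:, marker_cols].copy()
    if missing_rate > 0.0:
        genotypes[rng.random(genotypes.shape) < missing_rate] = MISSING
    return BackcrossCohort(genetic_map, genotypes, phenotype, survived, float(causal_position))


def simulate_survivor_cohort(
    genetic_map: GeneticMap,
    causal_position: float,
    p_het: float,
    p_hom: float,
    n_survivors: int,
    seed: int,
) -> BackcrossCohort:
    """Simulate a cohort conditioned on survival, retaining exactly
    ``n_survivors`` surviving individuals (the selective-genotyping design:
    only flies that melanized the parasitoid are genotyped)."""
    rng = np.random.default_rng(seed)
    p_surv = 0.5 * (p_het + p_hom)
    if p_surv <= 0:
        raise ValueError("survival probability is zero; no survivors possible")
    keep_geno = []
    collected = 0
    positions = genetic_map.positions
    exact = np.where(np.isclose(positions, causal_position))[0]
    if len(exact):
        all_pos = positions
        causal_idx = int(exact[0])
        marker_cols = np.arange(len(positions))
    else:
        insert_at = int(np.searchsorted(positions, causal_position))
        all_pos = np.insert(positions, insert_at, causal_position)
        causal_idx = insert_at
        marker_cols = np.delete(np.arange(len(all_pos)), insert_at)
    while collected < n_survivors:
        batch = max(64, int((n_survivors - collected) / p_surv * 1.2))
        states = _simulate_states(rng, batch, all_pos)
        pen = np.where(states[:, causal_idx] == HET, p_het, p_hom)
        alive = rng.random(batch) < pen
        surv = states[alive][:, marker_cols]
        keep_geno.append(surv)
        collected += surv.shape[0]
    genotypes = np.concatenate(keep_geno)[:n_survivors]
    ones = np.ones(n_survivors, dtype=bool)
    return BackcrossCohort(genetic_map, genotypes, ones, ones, float(causal_position))


def simulate_population_counts(
    n_pops: int,
    n_sites: int,
    divergence_f,
    sample_sizes,
    ancestral_freqs=(0.05, 0.95),
    selected_sites=(),
    site_classes=None,
    missing_rate: float = 0.0,
    seed: int = 0,
    chromosome: str = "2L",
    start_position: int = 1,
    spacing: int = 100,
) -> PopAlleleCounts:
    """Multi-population allele counts under the Balding-Nichols drift model.

    Each site has an ancestral frequency p; population i draws its frequency
    from Beta(p (1-F_i)/F_i, (1-p)(1-F_i)/F_i), i.e. mean p and variance
    F_i p (1-p). Counts are binomial given the frequency and haploid sample
    size. Selected sites receive a deterministic frequency shift (clamped to
    [0, 1]) in the stated population before sampling, emulating local
    adaptation; their site_class defaults to "focal".

    Parameters
    ----------
    divergence_f : float or sequence
        Per-population drift parameter F in (0, 1).
    sample_sizes : int or sequence
        Haploid samples per population.
    ancestral_freqs : float, sequence, or (lo, hi) tuple
        Fixed value(s) or a uniform range to draw from.
    selected_sites : iterable of (site_index, pop_index, shift)
    site_classes : sequence of str or None
        Per-site class labels; default "short_intron" everywhere except
        selected sites, which become "focal".
    missing_rate : float
        Per-(site, population, haplotype) missingness rate.
    """
    if n_pops < 2:
        raise ValueError("need at least two populations")
    f = np.broadcast_to(np.asarray(divergence_f, dtype=float), (n_pops,)).copy()
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("divergence F must lie in (0, 1)")
    sizes = np.broadcast_to(np.asarray(sample_sizes, dtype=np.int64), (n_pops,)).copy()
    if np.any(sizes <= 0):
        raise ValueError("sample sizes must be positive")
    rng = np.random.default_rng(seed)

    if isinstance(ancestral_freqs, tuple) and len(ancestral_freqs) == 2:
        p0 = rng.uniform(ancestral_freqs[0], ancestral_freqs[1], n_sites)
    else:
        p0 = np.broadcast_to(np.asarray(ancestral_freqs, dtype=float), (n_sites,)).copy()

    lam = (1.0 - f) / f  # per-population Beta concentration
    freqs = rng.beta(
        np.outer(p0, lam),
        np.outer(1.0 - p0, lam),
    )
    for site_idx, pop_idx, shift in selected_sites:
        freqs[site_idx, pop_idx] = min(1.0, max(0.0, freqs[site_idx, pop_idx] + shift))

    called = rng.binomial(sizes[None, :], 1.0 - missing_rate, size=(n_sites, n_pops))
    counts = rng.binomial(called, freqs)

    if site_classes is None:
        classes = np.array(["short_intron"] * n_sites, dtype=object)
        for site_idx, _, _ in selected_sites:
            classes[site_idx] = "focal"
    else:
        classes = np.asarray(site_classes, dtype=object)
    sites = pd.DataFrame(
        {
            "chromosome": chromosome,
            "position": start_position + spacing * np.arange(n_sites),
            "ref": "A",
            "alt": "T",
            "site_class": classes,
        }
    )
    pops = [f"pop{i + 1}" for i in range(n_pops)]
    return PopAlleleCounts(sites, counts, called, pops, sample_sizes=sizes)


def simulate_ase_counts(
    true_fraction: float,
    depth: int,
    n_bio: int = 2,
    n_tech: int = 2,
    overdispersion: float = 0.005,
    seed: int = 0,
    line: str = "line1",
) -> pd.DataFrame:
    """Allele-specific read counts for one line crossed to the reference.

    cDNA counts are beta-binomial: each biological replicate draws a latent
    reference-allele fraction from a Beta with mean ``true_fraction`` and
    correlation parameter rho = ``overdispersion`` (rho = 0 collapses to
    binomial), and each technical replicate is binomial at that fraction.
    gDNA counts are binomial with the fraction fixed at 0.5 — the no-bias
    control: in genomic DNA the two alleles are present in equal copy.

    Returns a DataFrame with columns
    ``line, replicate_kind, replicate_id, material, ref_count, alt_count``;
    ``replicate_id`` is ``b<bio>.t<tech>`` so technical replicates of one
    biological replicate share the ``b<bio>`` prefix.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not (0.0 <= true_fraction <= 1.0):
        raise ValueError("true_fraction must lie in [0, 1]")
    if overdispersion < 0:
        raise ValueError("overdispersion must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    kind = "technical" if n_tech > 1 else "biological"
    for material, frac, rho in (("cDNA", true_fraction, overdispersion), ("gDNA", 0.5, 0.0)):
        for b in range(1, n_bio + 1):
            if rho > 0 and 0.0 < frac < 1.0:
                p = rng.beta(frac * (1 - rho) / rho, (1 - frac) * (1 - rho) / rho)
            else:
                p = frac
            for t in range(1, n_tech + 1):
                ref = int(rng.binomial(depth, p))
                rows.append((line, kind, f"b{b}.t{t}", material, ref, depth - ref))
    return pd.DataFrame(rows, columns=ASE_COLUMNS)


# ---------------------------------------------------------------------------
# toy gene panel for the loss-of-function annotator


def toy_gene(seed: int = 12345, n_codons: int = 60, upstream_length: int = 200):
    """Deterministic toy gene: a CDS of ``n_codons`` codons (ATG ... TAA,
    no internal stops) and an upstream region carrying the 21-bp regulatory
    motif at c.-171..-151.

    The CDS is constructed so that the default variant menu works: codon 11
    is TAC (one substitution from a TAA stop) and a 4-bp insertion at
    position 129 shifts the frame onto a premature stop.
    """
    from .lof import find_premature_stop

    non_stop = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in ("TAA", "TAG", "TGA")
    ]
    bases = np.array(list("ACGT"))
    for attempt in range(100):
        rng = np.random.default_rng(seed + attempt)
        body = [non_stop[i] for i in rng.integers(len(non_stop), size=n_codons - 2)]
        body[9] = "TAC"  # codon 11 of the CDS; TAC -> TAA by one SNV
        cds = "ATG" + "".join(body) + "TAA"
        shifted = cds[:129] + "ACGT" + cds[129:]
        stop, _, _ = find_premature_stop(shifted, reference_length=len(cds))
        if stop is not None:
            break
    else:  # pragma: no cover - 100 failures is astronomically unlikely
        raise RuntimeError("could not construct a frameshift-sensitive toy CDS")
    up = list(rng.choice(bases, upstream_length))
    # c.-N maps to index upstream_length - N; motif spans c.-171 .. c.-151
    start = upstream_length - 171
    up[start : start + len(MOTIF_21BP)] = list(MOTIF_21BP)
    return cds, "".join(up)


DEFAULT_CLASS_FREQUENCIES = {
    "functional": 0.55,
    "expression_null": 0.25,
    "premature_stop": 0.15,
    "multiple": 0.05,
}


@dataclass
class SimulatedGenome:
    """One simulated genome for the annotation panel."""

    genome_id: str
    truth_class: str
    variants: list
    genotyped_fraction: float
    population: str = "pop1"


def default_variant_menu(cds: str, upstream: str):
    """LoF variant options consistent with the toy gene: the 21-bp
    regulatory deletion, a stop-gain SNV, and a 4-bp frameshift insertion."""
    del21 = VariantSpec("deletion", -171, MOTIF_21BP, "", "upstream")
    # codon 11 (positions 31-33) is TAC in the toy gene; C>A gives a TAA stop
    if cds[30:33] != "TAC":
        raise ValueError("variant menu expects codon 11 of the CDS to be TAC")
    stop_snv = VariantSpec("SNV", 33, "C", "A", "CDS")
    frameshift = VariantSpec("insertion", 129, "", "ACGT", "CDS")
    return {
        "expression_null": [del21],
        "premature_stop": [stop_snv, frameshift],
        "multiple": [[del21, stop_snv]],
        "functional": [[]],
    }


def simulate_gene_panel(
    cds: str,
    upstream: str,
    variant_menu=None,
    genome_count: int = 100,
    class_frequencies=None,
    missing_rate: float = 0.0,
    seed: int = 0,
    populations=("pop1",),
):
    """Simulate genomes carrying LoF variants with known truth classes.

    Each genome draws a truth class from ``class_frequencies`` and receives
    variants from the menu consistent with that class. ``genotyped_fraction``
    is the binomial fraction of gene positions called at rate
    1 - ``missing_rate``. Returns a list of :class:`SimulatedGenome`.
    """
    from .lof import apply_variants  # deferred: validates ref alleles

    freqs = dict(DEFAULT_CLASS_FREQUENCIES if class_frequencies is None else class_frequencies)
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("class frequencies must sum to 1")
    menu = default_variant_menu(cds, upstream) if variant_menu is None else variant_menu
    # validate menu variants against the reference sequences
    for options in menu.values():
        for opt in options:
            variants = opt if isinstance(opt, (list, tuple)) else [opt]
            for v in variants:
                ref = upstream if v.region == "upstream" else cds
                apply_variants(ref, [v])

    rng = np.random.default_rng(seed)
    classes = list(freqs)
    probs = np.array([freqs[c] for c in classes])
    draws = rng.choice(len(classes), size=genome_count, p=probs)
    gene_length = len(cds) + len(upstream)
    genomes = []
    for g, ci in enumerate(draws):
        cls = classes[ci]
        options = menu.get(cls, [[]])
        opt = options[rng.integers(len(options))]
        variants = list(opt) if isinstance(opt, (list, tuple)) else [opt]
        if cls == "functional":
            variants = []
        called = rng.binomial(gene_length, 1.0 - missing_rate)
        genomes.append(
            SimulatedGenome(
                genome_id=f"g{g + 1}",
                truth_class=cls,
                variants=variants,
                genotyped_fraction=called / gene_length,
                population=populations[rng.integers(len(populations))],
            )
        )
    return genomes
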