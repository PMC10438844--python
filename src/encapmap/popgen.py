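"""Selection-scan statistics: Weir-Cockerham F_ST, the population branch
statistic (PBS), and empirical null distributions from short-intron variants.

All estimators work on haploid allele counts. Inbred Drosophila genomes
contribute a single haplotype each; a diploid genotype call in an input VCF
is counted as two haploid calls. F_ST uses the Weir & Cockerham (1984)
ANOVA estimator specialised to haploid samples: with r populations of sizes
n_i and derived-allele frequencies p_i,

    MSP = sum n_i (p_i - p_bar)^2 / (r - 1)          (among populations)
    MSG = sum n_i p_i (1 - p_i) / sum (n_i - 1)      (within populations)
    n_c = (N - sum n_i^2 / N) / (r - 1),  N = sum n_i
    theta = (MSP - MSG) / (MSP + (n_c - 1) MSG)

theta may be negative by sampling. The PBS for three populations a, b, c is
PBS_a = (T_ab + T_ac - T_bc) / 2 with T = -ln(1 - F_ST); negative F_ST is
clamped to 0 inside the log so estimator noise cannot produce negative
branch lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITE_CLASSES = ("focal", "short_intron", "other")


@dataclass
class PopAlleleCounts:
    """Per-site, per-population derived-allele counts.

    Attributes
    ----------
    sites : DataFrame
        Columns ``chromosome, position, ref, alt, site_class`` with
        ``position`` 1-based; rows unique by (chromosome, position, alt).
    counts : ndarray, shape (n_sites, n_pops)
        Derived-allele counts.
    called : ndarray, shape (n_sites, n_pops)
        Called haploid sample sizes; ``counts <= called`` element-wise.
    populations : list of str
    sample_sizes : ndarray or None
        Total haploid samples per population (used for the "fraction of
        samples typed" filter); inferred as the column max of ``called``
        when absent.
    """

    sites: pd.DataFrame
    counts: np.ndarray
    called: np.ndarray
    populations: list
    sample_sizes: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.called = np.asarray(self.called, dtype=np.int64)
        if len(self.populations) < 2:
            raise ValueError("need at least two populations")
        if self.counts.shape != self.called.shape:
            raise ValueError("counts and called must have the same shape")
        if self.counts.shape != (len(self.sites), len(self.populations)):
            raise ValueError("matrix shape must be n_sites x n_populations")
        if np.any(self.counts < 0) or np.any(self.counts > self.called):
            raise ValueError("need 0 <= count <= called at every site")
        key = self.sites[["chromosome", "position", "alt"]]
        if key.duplicated().any():
            raise ValueError("sites must be unique by (chromosome, position, alt)")
        if self.sample_sizes is not None:
            self.sample_sizes = np.asarray(self.sample_sizes, dtype=np.int64)

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    def totals(self) -> np.ndarray:
        """Per-population haploid totals, inferred when not supplied."""
        if self.sample_sizes is not None:
            return self.sample_sizes
        return self.called.max(axis=0)


@dataclass
class FstResult:
    """Variance components and theta for one site."""

    a: float  # among-population component (MSP - MSG) / n_c
    within: float  # within-population mean square (MSG)
    theta: float  # F_ST estimate; nan when undefined
    n_pops_used: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.theta)


@dataclass
class PbsResult:
    """Branch lengths and PBS for three populations."""

    t_ab: float
    t_ac: float
    t_bc: float
    pbs: tuple  # (PBS_a, PBS_b, PBS_c)
    focal_labels: tuple = ("a", "b", "c")
    infinite: bool = False


def wc_fst_per_site(counts, called) -> FstResult:
    """Weir-Cockerham F_ST at one biallelic site from haploid counts.

    Populations with ``called == 0`` are dropped for the site. A site
    monomorphic across all used populations gives ``theta = nan`` (flagged
    undefined) rather than a 0/0 error.
    """
    counts = np.asarray(counts, dtype=float)
    called = np.asarray(called, dtype=float)
    use = called > 0
    if use.sum() < 2:
        return FstResult(np.nan, np.nan, np.nan, int(use.sum()))
    c = counts[use]
    n = called[use]
    r = len(n)
    p = c / n
    ntot = n.sum()
    pbar = (n * p).sum() / ntot
    msp = (n * (p - pbar) ** 2).sum() / (r - 1)
    msg = (n * p * (1.0 - p)).sum() / (n - 1.0).sum()
    nc = (ntot - (n**2).sum() / ntot) / (r - 1)
    denom = msp + (nc - 1.0) * msg
    a = (msp - msg) / nc
    if denom == 0.0:
        return FstResult(a, msg, np.nan, r)
    return FstResult(a, msg, (msp - msg) / denom, r)


def wc_fst_sites(counts, called) -> np.ndarray:
    """Per-site Weir-Cockerham theta for a sites x populations matrix.

    Vectorised version of :func:`wc_fst_per_site`; sites where fewer than
    two populations are called, or monomorphic sites, are nan.
    """
    counts = np.asarray(counts, dtype=float)
    called = np.asarray(called, dtype=float)
    use = called > 0
    r = use.sum(axis=1)
    n = np.where(use, called, 0.0)
    c = np.where(use, counts, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(use, c / np.where(n > 0, n, 1.0), 0.0)
        ntot = n.sum(axis=1)
        pbar = (n * p).sum(axis=1) / ntot
        msp = (n * (p - pbar[:, None]) ** 2).sum(axis=1) / (r - 1)
        msg = (n * p * (1.0 - p)).sum(axis=1) / np.where(use, n - 1.0, 0.0).sum(axis=1)
        nc = (ntot - (n**2).sum(axis=1) / ntot) / (r - 1)
        denom = msp + (nc - 1.0) * msg
        theta = np.where(denom != 0.0, (msp - msg) / np.where(denom != 0, denom, 1.0), np.nan)
    theta = np.where(r >= 2, theta, np.nan)
    return theta


def _wc_components(counts, called):
    """Per-site (a, a + within) for ratio-of-sums combination (two or more pops)."""
    counts = np.asarray(counts, dtype=float)
    called = np.asarray(called, dtype=float)
    use = called > 0
    r = use.sum(axis=1)
    n = np.where(use, called, 0.0)
    c = np.where(use, counts, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(use, c / np.where(n > 0, n, 1.0), 0.0)
        ntot = n.sum(axis=1)
        pbar = (n * p).sum(axis=1) / ntot
        msp = (n * (p - pbar[:, None]) ** 2).sum(axis=1) / (r - 1)
        msg = (n * p * (1.0 - p)).sum(axis=1) / np.where(use, n - 1.0, 0.0).sum(axis=1)
        nc = (ntot - (n**2).sum(axis=1) / ntot) / (r - 1)
        a = (msp - msg) / nc
        tot = a + msg
    ok = r >= 2
    return np.where(ok, a, np.nan), np.where(ok, tot, np.nan)


def pairwise_fst(counts, called, pop_a: int, pop_b: int, mode: str = "ratio_of_sums"):
    """F_ST between two populations over a set of sites.

    ``mode="per_site"`` returns the per-site theta array;
    ``mode="ratio_of_sums"`` returns the multi-locus estimate
    sum(a) / sum(a + within), the standard combination across loci.
    """
    counts = np.asarray(counts)
    called = np.asarray(called)
    if counts.ndim == 1:
        counts = counts[None, :]
        called = called[None, :]
    sub_counts = counts[:, [pop_a, pop_b]]
    sub_called = called[:, [pop_a, pop_b]]
    if mode == "per_site":
        return wc_fst_sites(sub_counts, sub_called)
    if mode != "ratio_of_sums":
        raise ValueError("mode must be 'per_site' or 'ratio_of_sums'")
    a, tot = _wc_components(sub_counts, sub_called)
    ok = ~np.isnan(tot)
    denom = np.nansum(tot[ok])
    if denom == 0.0:
        return float("nan")
    return float(np.nansum(a[ok]) / denom)


def _branch_length(fst: float) -> float:
    f = max(float(fst), 0.0)
    if f >= 1.0:
        return float("inf")
    return -math.log(1.0 - f)


def pbs(fst_ab: float, fst_ac: float, fst_bc: float, labels=("a", "b", "c")) -> PbsResult:
    """Population branch statistic for three populations.

    T_xy = -ln(1 - F_ST) with negative F_ST clamped to 0;
    PBS_a = (T_ab + T_ac - T_bc)/2 and cyclic permutations. An input
    F_ST of 1 gives an infinite branch, flagged rather than raised.
    """
    t_ab = _branch_length(fst_ab)
    t_ac = _branch_length(fst_ac)
    t_bc = _branch_length(fst_bc)
    pbs_a = (t_ab + t_ac - t_bc) / 2.0
    pbs_b = (t_ab + t_bc - t_ac) / 2.0
    pbs_c = (t_ac + t_bc - t_ab) / 2.0
    infinite = any(math.isinf(t) for t in (t_ab, t_ac, t_bc))
    return PbsResult(t_ab, t_ac, t_bc, (pbs_a, pbs_b, pbs_c), tuple(labels), infinite)


def pbs_sites(counts, called, pop_a: int, pop_b: int, pop_c: int) -> np.ndarray:
    """Per-site PBS on the branch leading to ``pop_a``."""
    f_ab = wc_fst_sites(np.asarray(counts)[:, [pop_a, pop_b]], np.asarray(called)[:, [pop_a, pop_b]])
    f_ac = wc_fst_sites(np.asarray(counts)[:, [pop_a, pop_c]], np.asarray(called)[:, [pop_a, pop_c]])
    f_bc = wc_fst_sites(np.asarray(counts)[:, [pop_b, pop_c]], np.asarray(called)[:, [pop_b, pop_c]])
    out = np.full(len(f_ab), np.nan)
    for i in range(len(out)):
        if np.isnan(f_ab[i]) or np.isnan(f_ac[i]) or np.isnan(f_bc[i]):
            # monomorphic in a pair: treat that pair's F_ST as 0 divergence
            fab = 0.0 if np.isnan(f_ab[i]) else f_ab[i]
            fac = 0.0 if np.isnan(f_ac[i]) else f_ac[i]
            fbc = 0.0 if np.isnan(f_bc[i]) else f_bc[i]
        else:
            fab, fac, fbc = f_ab[i], f_ac[i], f_bc[i]
        out[i] = pbs(fab, fac, fbc).pbs[0]
    return out


def build_empirical_null(
    pop_counts: PopAlleleCounts,
    site_class: str = "short_intron",
    maf_min: float = 0.05,
    typed_min_fraction: float = 0.40,
    statistic: str = "fst",
    focal=None,
):
    """Empirical null distribution of a statistic over putatively neutral sites.

    Filters, in order: ``site_class`` match; pooled minor-allele frequency
    >= ``maf_min`` (over all called haplotypes); fraction of samples typed
    > ``typed_min_fraction`` in every population used. ``statistic`` is
    ``"fst"`` (multi-population per-site theta) or ``"pbs"`` (per-site PBS on
    the first of three ``focal`` population indices).

    Returns
    -------
    (ndarray, int)
        Sorted finite statistic values and the retained-site count.
    """
    cls = pop_counts.sites["site_class"].to_numpy()
    in_class = cls == site_class
    n_class = int(in_class.sum())

    totals = pop_counts.totals().astype(float)
    if statistic == "pbs":
        if focal is None or len(focal) != 3:
            raise ValueError("statistic='pbs' needs three focal population indices")
        cols = list(focal)
    else:
        cols = list(focal) if focal is not None else list(range(len(pop_counts.populations)))

    counts = pop_counts.counts[:, cols]
    called = pop_counts.called[:, cols]

    pooled_called = called.sum(axis=1).astype(float)
    pooled_count = counts.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(pooled_called > 0, pooled_count / np.where(pooled_called > 0, pooled_called, 1), np.nan)
    maf = np.minimum(p, 1.0 - p)
    pass_maf = in_class & (maf >= maf_min)
    n_maf = int(pass_maf.sum())

    with np.errstate(invalid="ignore", divide="ignore"):
        typed_frac = called / totals[cols][None, :]
    pass_typed = pass_maf & np.all(typed_frac > typed_min_fraction, axis=1)
    n_typed = int(pass_typed.sum())

    if n_typed == 0:
        raise ValueError(
            "no sites survive the null filters "
            f"(site_class={site_class}: {n_class}; +MAF>={maf_min}: {n_maf}; "
            f"+typed>{typed_min_fraction}: {n_typed})"
        )

    if statistic == "fst":
        values = wc_fst_sites(counts[pass_typed], called[pass_typed])
    elif statistic == "pbs":
        values = pbs_sites(counts[pass_typed], called[pass_typed], 0, 1, 2)
    else:
        raise ValueError("statistic must be 'fst' or 'pbs'")
    values = values[np.isfinite(values)]
    return np.sort(values), n_typed


def null_quantile(null: np.ndarray, q: float) -> float:
    """Threshold at quantile ``q`` of the null, linear (type 7) interpolation."""
    return float(np.quantile(np.asarray(null, dtype=float), q))


def empirical_outlier(stat_value: float, null: np.ndarray):
    """Empirical percentile and upper-tail p-value of a statistic in a null.

    The percentile inverts the type-7 (linear interpolation) quantile
    function; the p-value uses the add-one rule
    p = (1 + #{null >= stat}) / (1 + N) so p is never exactly 0.
    """
    null = np.sort(np.asarray(null, dtype=float))
    n = len(null)
    if n == 0:
        raise ValueError("null distribution is empty")
    grid = np.linspace(0.0, 100.0, n)
    if stat_value <= null[0]:
        percentile = 0.0
    elif stat_value >= null[-1]:
        percentile = 100.0
    else:
        percentile = float(np.interp(stat_value, null, grid))
    p = (1 + int((null >= stat_value).sum())) / (1 + n)
    return percentile, p
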