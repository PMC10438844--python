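"""Binary-trait QTL mapping in a backcross.

Interval mapping maximises, at each grid position, the likelihood of a
two-penetrance model: the phenotype is Bernoulli(p_het) for heterozygotes
and Bernoulli(p_hom) for homozygous-susceptible individuals at the tested
position, with the hidden genotype distributed according to the flanking
markers (Haldane recombination, Markov property). The likelihood is
maximised by EM over the hidden genotype, which is monotone and has an
analytic M-step. LOD = log10 L1 - log10 L0 against the genotype-free
binomial fit.

Composite interval mapping adds selected marker cofactors as additive
covariates in a logistic model, excluding cofactors within a window around
the test position, so that linked QTL elsewhere on the chromosome are
absorbed by the cofactors rather than inflating the local score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .genmap import HET, MISSING, BackcrossCohort, haldane_recomb

_EPS = 1e-9


@dataclass
class QTLScan:
    """A genome-scan curve with its support interval.

    ``positions`` is the strictly increasing cM grid, ``score`` the
    per-position LOD (or chi-square, for survivor profiles rendered on a
    grid), ``method`` one of {"IM", "CIM", "CHISQ"}.
    """

    positions: np.ndarray
    score: np.ndarray
    method: str
    support_interval: tuple | None = None
    flat: bool = False

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.score = np.asarray(self.score, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.score.shape:
            raise ValueError("positions and score must be matching 1-d arrays")
        if len(self.positions) > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("scan grid must be strictly increasing")

    @property
    def peak_position(self) -> float:
        # ties broken toward the smaller cM value (argmax returns first max)
        return float(self.positions[int(np.argmax(self.score))])

    @property
    def peak_score(self) -> float:
        return float(self.score.max())


def genotype_probabilities(cohort: BackcrossCohort, position: float) -> np.ndarray:
    """P(HET at ``position``) per individual given flanking marker genotypes.

    Uses the Markov property of backcross genotypes: conditioning on the
    nearest non-missing marker on each side is exact. At a typed,
    non-missing marker the probability equals the genotype indicator;
    missing flanking markers are marginalised by skipping to the next
    informative marker, and individuals with no informative marker get 0.5.
    """
    lo, hi = cohort.map.span
    if not (lo <= position <= hi):
        raise ValueError("position outside the map span")
    pos = cohort.map.positions
    G = cohort.genotypes
    n, m = G.shape
    typed = G != MISSING

    left_mask = typed & (pos <= position)[None, :]
    has_left = left_mask.any(axis=1)
    li = np.where(has_left, m - 1 - np.argmax(left_mask[:, ::-1], axis=1), 0)
    right_mask = typed & (pos >= position)[None, :]
    has_right = right_mask.any(axis=1)
    ri = np.where(has_right, np.argmax(right_mask, axis=1), 0)

    out = np.full(n, 0.5)

    both = has_left & has_right
    if np.any(both):
        gl = G[both, li[both]].astype(float)
        gr = G[both, ri[both]].astype(float)
        rl = haldane_recomb(position - pos[li[both]])
        rr = haldane_recomb(pos[ri[both]] - position)
        rl = np.atleast_1d(rl)
        rr = np.atleast_1d(rr)
        # transition probabilities to HET state
        t_l = np.where(gl == HET, 1.0 - rl, rl)  # P(pos=HET | left)
        t_r = np.where(gr == HET, 1.0 - rr, rr)  # P(right | pos=HET)
        num = t_l * t_r
        den = num + (1.0 - t_l) * (1.0 - t_r)
        out[both] = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)

    only_left = has_left & ~has_right
    if np.any(only_left):
        gl = G[only_left, li[only_left]].astype(float)
        rl = np.atleast_1d(haldane_recomb(position - pos[li[only_left]]))
        out[only_left] = np.where(gl == HET, 1.0 - rl, rl)

    only_right = has_right & ~has_left
    if np.any(only_right):
        gr = G[only_right, ri[only_right]].astype(float)
        rr = np.atleast_1d(haldane_recomb(pos[ri[only_right]] - position))
        out[only_right] = np.where(gr == HET, 1.0 - rr, rr)

    return out


def _binary_em(w: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 500):
    """Maximise the mixture likelihood over (p_het, p_hom) by EM.

    ``w`` is the prior P(HET) per individual, ``y`` the binary phenotype.
    Returns (loglik, p_het, p_hom).
    """
    y = y.astype(float)
    sw = w.sum()
    sv = (1.0 - w).sum()
    p_het = (w * y).sum() / sw if sw > 0 else y.mean()
    p_hom = ((1.0 - w) * y).sum() / sv if sv > 0 else y.mean()
    if abs(p_het - p_hom) < 1e-12:
        p_het = min(1.0, p_het + 1e-6)  # break the symmetric stationary point
    ll_old = -np.inf
    for _ in range(max_iter):
        ph = np.clip(p_het, _EPS, 1.0 - _EPS)
        pm = np.clip(p_hom, _EPS, 1.0 - _EPS)
        f_het = np.where(y == 1.0, ph, 1.0 - ph)
        f_hom = np.where(y == 1.0, pm, 1.0 - pm)
        mix = w * f_het + (1.0 - w) * f_hom
        ll = float(np.log(mix).sum())
        z = np.where(mix > 0, w * f_het / np.where(mix > 0, mix, 1.0), w)
        sz = z.sum()
        so = (1.0 - z).sum()
        p_het = (z * y).sum() / sz if sz > 0 else p_het
        p_hom = ((1.0 - z) * y).sum() / so if so > 0 else p_hom
        if ll - ll_old < tol:
            break
        ll_old = ll
    return ll, p_het, p_hom


def _null_loglik(y: np.ndarray) -> float:
    p = np.clip(y.mean(), _EPS, 1.0 - _EPS)
    k = y.sum()
    n = len(y)
    return float(k * math.log(p) + (n - k) * math.log(1.0 - p))


def _scan_grid(cohort: BackcrossCohort, step: float) -> np.ndarray:
    lo, hi = cohort.map.span
    grid = np.arange(lo, hi + step / 2.0, step)
    grid = np.union1d(np.round(grid, 10), np.round(cohort.map.positions, 10))
    return grid[(grid >= lo) & (grid <= hi)]


def interval_mapping_binary(cohort: BackcrossCohort, step: float = 0.5, drop: float = 1.5) -> QTLScan:
    """Interval mapping of a binary trait; returns the full LOD curve.

    The grid is the union of an equally spaced grid (``step`` cM) and the
    marker positions. A 1.5-LOD-drop support interval is attached.
    """
    y = cohort.phenotype.astype(float)
    if y.min() == y.max():
        raise ValueError("phenotype is monomorphic; LOD is undefined")
    grid = _scan_grid(cohort, step)
    ll0 = _null_loglik(y)
    lods = np.empty(len(grid))
    for i, pos in enumerate(grid):
        w = genotype_probabilities(cohort, pos)
        ll1, _, _ = _binary_em(w, y)
        lods[i] = max((ll1 - ll0) / math.log(10.0), 0.0)
    scan = QTLScan(grid, lods, "IM")
    scan.support_interval = lod_support_interval(scan, drop=drop)
    return scan


def _marker_prob_matrix(cohort: BackcrossCohort) -> np.ndarray:
    """n x m matrix of P(HET) at each marker (observed or marginalised)."""
    cols = [genotype_probabilities(cohort, p) for p in cohort.map.positions]
    return np.column_stack(cols)


def select_cofactors(cohort: BackcrossCohort, max_cofactors: int = 3) -> list:
    """Forward selection of marker cofactors by AIC on logistic fits.

    Markers enter one at a time while they reduce the AIC of the logistic
    regression of phenotype on the selected marker set; at most
    ``max_cofactors`` are kept.
    """
    y = cohort.phenotype.astype(float)
    X_all = _marker_prob_matrix(cohort)
    m = X_all.shape[1]
    chosen: list = []
    current_aic = 2.0 - 2.0 * _null_loglik(y)
    while len(chosen) < max_cofactors:
        best = None
        for j in range(m):
            if j in chosen:
                continue
            X = sm.add_constant(X_all[:, chosen + [j]])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
                aic = fit.aic
            except Exception:
                continue
            if best is None or aic < best[0]:
                best = (aic, j)
        if best is None or best[0] >= current_aic - 1e-9:
            break
        current_aic = best[0]
        chosen.append(best[1])
    return [cohort.map.names[j] for j in chosen]


def composite_interval_mapping(
    cohort: BackcrossCohort,
    step: float = 0.5,
    cofactors="auto",
    window: float = 10.0,
    drop: float = 1.5,
) -> QTLScan:
    """Composite interval mapping: interval scan with marker cofactors.

    At each grid position the phenotype is regressed (logistic link) on the
    HET probability at that position plus the cofactor markers lying
    outside ``window`` cM of the position; the LOD compares this fit to the
    same model without the position term. ``cofactors="auto"`` uses
    :func:`select_cofactors`.
    """
    y = cohort.phenotype.astype(float)
    if y.min() == y.max():
        raise ValueError("phenotype is monomorphic; LOD is undefined")
    lo, hi = cohort.map.span
    if window > hi - lo:
        raise ValueError("cofactor window exceeds the chromosome span")
    if cofactors == "auto":
        cofactors = select_cofactors(cohort)
    cof_idx = [cohort.map.index_of(name) for name in cofactors]
    cof_pos = cohort.map.positions[cof_idx] if cof_idx else np.array([])
    X_markers = _marker_prob_matrix(cohort)

    grid = _scan_grid(cohort, step)
    lods = np.empty(len(grid))
    for i, pos in enumerate(grid):
        keep = [j for j, p in zip(cof_idx, cof_pos) if abs(p - pos) > window]
        w = genotype_probabilities(cohort, pos)
        if keep:
            X_cof = X_markers[:, keep]
            X0 = sm.add_constant(X_cof)
            X1 = sm.add_constant(np.column_stack([w, X_cof]))
        else:
            X0 = np.ones((len(y), 1))
            X1 = sm.add_constant(w)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ll0 = sm.GLM(y, X0, family=sm.families.Binomial()).fit().llf
            ll1 = sm.GLM(y, X1, family=sm.families.Binomial()).fit().llf
        lods[i] = max((ll1 - ll0) / math.log(10.0), 0.0)
    scan = QTLScan(grid, lods, "CIM")
    scan.support_interval = lod_support_interval(scan, drop=drop)
    return scan


def lod_support_interval(scan: QTLScan, drop: float = 1.5) -> tuple:
    """LOD-drop support interval around the scan peak.

    Returns the widest contiguous interval containing the peak in which the
    score stays at or above (peak - drop), extended to the crossing points
    by linear interpolation between grid points. A flat scan returns the
    full span and sets the scan's ``flat`` warning flag.
    """
    if len(scan.positions) == 0:
        raise ValueError("empty scan")
    score = scan.score
    pos = scan.positions
    peak = int(np.argmax(score))
    thresh = score[peak] - drop
    if np.ptp(score) < 1e-12:
        scan.flat = True
        return float(pos[0]), float(pos[-1])

    left = peak
    while left > 0 and score[left - 1] >= thresh:
        left -= 1
    if left == 0 or score[left] == thresh:
        low = float(pos[left])
    else:
        x0, x1 = pos[left - 1], pos[left]
        y0, y1 = score[left - 1], score[left]
        low = float(x0 + (thresh - y0) / (y1 - y0) * (x1 - x0))

    right = peak
    n = len(pos)
    while right < n - 1 and score[right + 1] >= thresh:
        right += 1
    if right == n - 1 or score[right] == thresh:
        high = float(pos[right])
    else:
        x0, x1 = pos[right], pos[right + 1]
        y0, y1 = score[right], score[right + 1]
        high = float(x0 + (thresh - y0) / (y1 - y0) * (x1 - x0))
    return low, high
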