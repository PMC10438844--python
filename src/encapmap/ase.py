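"""Allele-specific expression from SNP-assigned read counts.

Reads from heterozygous F1 flies are assigned to the two parental alleles
using diagnostic SNPs. Because both alleles share one trans-regulatory
environment, an allelic imbalance in cDNA demonstrates cis-regulation; the
genomic-DNA (gDNA) control, where the alleles are at exact 50:50 copy
number, guards against technical mapping bias. Fold-difference is the odds
transform of the allele fraction, fold = f / (1 - f).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

REQUIRED_COLUMNS = ["line", "replicate_kind", "replicate_id", "material", "ref_count", "alt_count"]


@dataclass
class AseEstimate:
    """Allele-fraction estimate for one line and material."""

    line: str
    material: str
    fraction: float
    ci: tuple
    fold_difference: float
    n_replicates: dict
    ci_method: str


@dataclass
class BiasCheck:
    """gDNA technical-bias control result."""

    passed: bool
    fraction: float
    deviation: float
    pvalue: float


def _biological_pools(rows: pd.DataFrame) -> pd.DataFrame:
    """Pool technical replicates within each biological replicate.

    Technical replicates share the ``b<k>`` prefix of ``replicate_id``
    (before the first '.'); rows flagged biological are their own pool.
    """
    pool = rows["replicate_id"].astype(str).str.split(".").str[0]
    return rows.groupby(pool, sort=True)[["ref_count", "alt_count"]].sum()


def allele_fraction(table: pd.DataFrame, line: str, material: str) -> AseEstimate:
    """Reference-allele read fraction with a 95% CI.

    The point estimate pools all reads: ref / (ref + alt). With >= 3
    biological replicates the CI is a t-interval around the pooled estimate
    using the between-replicate standard deviation of the per-replicate
    fractions; with fewer, it is the exact (Clopper-Pearson) binomial
    interval on the pooled counts.
    """
    rows = table[(table["line"] == line) & (table["material"] == material)]
    if rows.empty:
        raise ValueError(f"no rows for line={line!r}, material={material!r}")
    ref = int(rows["ref_count"].sum())
    alt = int(rows["alt_count"].sum())
    total = ref + alt
    if total == 0:
        raise ValueError("zero total depth")
    frac = ref / total

    pools = _biological_pools(rows)
    pool_tot = pools["ref_count"] + pools["alt_count"]
    pool_frac = (pools["ref_count"] / pool_tot).to_numpy(dtype=float)
    k = len(pool_frac)
    if k >= 3 and np.std(pool_frac) > 0:
        sd = float(np.std(pool_frac, ddof=1))
        half = stats.t.ppf(0.975, k - 1) * sd / math.sqrt(k)
        ci = (max(0.0, frac - half), min(1.0, frac + half))
        method = "t"
    else:
        bt = stats.binomtest(ref, total)
        ci_obj = bt.proportion_ci(confidence_level=0.95, method="exact")
        ci = (ci_obj.low, ci_obj.high)
        method = "exact_binomial"
    fold = frac / (1.0 - frac) if frac < 1.0 else math.inf
    n_reps = {
        "rows": len(rows),
        "biological": k,
    }
    return AseEstimate(line, material, frac, ci, fold, n_reps, method)


def gdna_bias_check(
    table: pd.DataFrame, line: str, alpha: float = 0.01, margin: float = 0.05
) -> BiasCheck:
    """Technical-bias control on pooled genomic-DNA counts.

    In gDNA the two alleles are at exact 50:50 copy number, so any
    deviation reflects mapping or assignment bias. The check passes when
    the exact binomial test against 0.5 is non-significant (p >= alpha) or
    the absolute deviation is inside the equivalence margin.
    """
    rows = table[(table["line"] == line) & (table["material"] == "gDNA")]
    if rows.empty:
        raise ValueError(f"no gDNA rows for line {line!r}")
    ref = int(rows["ref_count"].sum())
    alt = int(rows["alt_count"].sum())
    if ref + alt == 0:
        raise ValueError("zero gDNA depth")
    frac = ref / (ref + alt)
    p = stats.binomtest(ref, ref + alt, 0.5).pvalue
    deviation = abs(frac - 0.5)
    return BiasCheck(bool(p >= alpha or deviation < margin), frac, deviation, float(p))


def welch_t_two_groups(values_a, values_b) -> tuple:
    """Welch two-sample t test; returns (t, Satterthwaite df, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("both groups have zero variance; the t statistic is degenerate")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass
class QuasibinomialResult:
    """Group contrast from a quasibinomial logistic fit."""

    coefficient: float
    tstat: float
    pvalue: float
    dispersion: float
    df_resid: float
    separated: bool = False


def quasibinomial_group_test(
    table: pd.DataFrame,
    line_codes: dict,
    group_a,
    group_b,
    material: str = "cDNA",
) -> QuasibinomialResult:
    """Compare allele fractions between two haplotype groups of lines.

    Per-replicate (ref, alt) counts from lines whose haplotype code is in
    ``group_a`` or ``group_b`` enter a logistic regression on the group
    indicator (1 for group_b), fitted by IRLS. The dispersion is estimated
    from Pearson residuals (floored at 1, the binomial value) and scales
    the standard error; the reported statistic is coefficient / scaled SE
    with a t reference on the residual degrees of freedom. Perfect
    separation is flagged and the statistic reported as infinite.
    """
    group_a = set(group_a) if not isinstance(group_a, str) else {group_a}
    group_b = set(group_b) if not isinstance(group_b, str) else {group_b}
    rows = table[table["material"] == material].copy()
    rows["code"] = rows["line"].map(line_codes)
    rows = rows[rows["code"].isin(group_a | group_b)]
    lines_a = set(rows.loc[rows["code"].isin(group_a), "line"])
    lines_b = set(rows.loc[rows["code"].isin(group_b), "line"])
    if len(lines_a) < 1 or len(lines_b) < 1:
        raise ValueError("both groups need lines with counts")
    endog = rows[["ref_count", "alt_count"]].to_numpy(dtype=float)
    indicator = rows["code"].isin(group_b).to_numpy(dtype=float)
    exog = sm.add_constant(indicator)
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit()
    df_resid = fit.df_resid
    dispersion = max(1.0, float(fit.pearson_chi2 / df_resid)) if df_resid > 0 else 1.0
    coef = float(fit.params[1])
    se = float(fit.bse[1]) * math.sqrt(dispersion)
    # near-zero SE with a huge coefficient indicates separation
    if not math.isfinite(coef) or abs(coef) > 30:
        warnings.warn("perfect separation between groups; statistic is infinite")
        return QuasibinomialResult(coef, math.inf, 0.0, dispersion, df_resid, separated=True)
    t = coef / se
    p = 2.0 * stats.t.sf(abs(t), df_resid)
    return QuasibinomialResult(coef, t, p, dispersion, df_resid)
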