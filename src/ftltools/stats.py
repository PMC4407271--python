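"""Shared statistical machinery for crossover-count comparisons.

Binomial GLM with logit link for recombinant-fraction contrasts, an F-test
on per-individual cM variances, chi-square tests on count tables (with
tail-inward category merging for sparse chiasmata distributions and the
Yates continuity correction for 2x2 marker tables), Benjamini-Hochberg FDR,
and windowed Spearman correlation for paired genomic tracks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


__all__ = [
    "TestResult",
    "GlmFit",
    "fit_binomial_glm",
    "variance_f_test",
    "merged_chisq",
    "yates_chisq_2x2",
    "bh_fdr",
    "windowed_spearman",
    "rebin_track",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of range: {self.p_value}")


@dataclass
class GlmFit:
    """Result of a binomial GLM fit on grouped recombinant counts."""

    coefficients: pd.Series
    deviance: float
    df_resid: int
    genotype_test: TestResult
    separation_flag: bool = False

    @property
    def pearson_dispersion(self) -> float | None:
        """Pearson chi2 / residual df; a diagnostic for overdispersion."""
        return self._dispersion

    _dispersion: float | None = None


# separated fits drift to huge logits; clamp there for a finite report
_SEPARATION_LOGIT = 15.0


def _design(df: pd.DataFrame, with_genotype: bool) -> tuple[pd.DataFrame, list[str]]:
    parts = [pd.Series(1.0, index=df.index, name="intercept")]
    if with_genotype:
        dums = pd.get_dummies(df["genotype"].astype(str), prefix="genotype",
                              drop_first=True, dtype=float)
        parts.append(dums)
    if "replicate" in df.columns and df["replicate"].nunique() > 1:
        dums = pd.get_dummies(df["replicate"].astype(str), prefix="replicate",
                              drop_first=True, dtype=float)
        parts.append(dums)
    X = pd.concat(parts, axis=1)
    return X, list(X.columns)


def fit_binomial_glm(observations: pd.DataFrame) -> GlmFit:
    """Binomial GLM (logit link) testing a genotype effect on recombination.

    ``observations`` needs columns ``recombinant`` (successes Y_i), ``total``
    (n_i) and ``genotype``; an optional ``replicate`` column is entered as an
    additional factor.  The model is Y_i ~ Binomial(n_i, p_i) with
    logit(p_i) = X beta, fitted by iteratively reweighted least squares.
    The genotype effect is tested by a likelihood-ratio test against the
    model without the genotype factor (chi-square reference with df equal to
    the number of dropped columns).

    Complete separation is reported with a warning and clamped, finite
    coefficients; a rank-deficient design raises an error naming the
    aliased columns.
    """
    df = observations.reset_index(drop=True)
    y = np.asarray(df["recombinant"], dtype=float)
    n = np.asarray(df["total"], dtype=float)
    if np.any(y < 0) or np.any(y > n):
        raise ValueError("need 0 <= recombinant <= total for every row")
    if df["genotype"].nunique() < 2:
        raise ValueError("genotype test needs at least two genotype levels")

    X_full, cols = _design(df, with_genotype=True)
    rank = np.linalg.matrix_rank(X_full.to_numpy())
    if rank < X_full.shape[1]:
        # name columns not in a maximal independent subset
        aliased: list[str] = []
        kept: list[np.ndarray] = []
        for name in cols:
            cand = kept + [X_full[name].to_numpy()]
            if np.linalg.matrix_rank(np.column_stack(cand)) == len(cand):
                kept.append(X_full[name].to_numpy())
            else:
                aliased.append(name)
        raise ValueError(f"design matrix is rank deficient; aliased columns: "
                         f"{', '.join(aliased)}")

    endog = np.column_stack([y, n - y])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels separation chatter
        full = sm.GLM(endog, X_full.to_numpy(), family=sm.families.Binomial()).fit(
            maxiter=200)
        X_null, _ = _design(df, with_genotype=False)
        null = sm.GLM(endog, X_null.to_numpy(), family=sm.families.Binomial()).fit(
            maxiter=200)

    params = pd.Series(full.params, index=cols)
    separated = bool((params.abs() > _SEPARATION_LOGIT).any())
    if separated:
        warnings.warn(
            "complete or quasi-complete separation detected; coefficients "
            "clamped to +/-15 on the logit scale", stacklevel=2)
        params = params.clip(-_SEPARATION_LOGIT, _SEPARATION_LOGIT)

    lrt = max(null.deviance - full.deviance, 0.0)
    df_test = X_full.shape[1] - X_null.shape[1]
    p = float(sps.chi2.sf(lrt, df_test)) if df_test > 0 else 1.0
    fit = GlmFit(
        coefficients=params,
        deviance=float(full.deviance),
        df_resid=int(full.df_resid),
        genotype_test=TestResult(float(lrt), df_test, p, "binomial GLM LRT"),
        separation_flag=separated,
    )
    fit._dispersion = (float(full.pearson_chi2 / full.df_resid)
                       if full.df_resid > 0 else None)
    return fit


def variance_f_test(group_a, group_b) -> TestResult:
    """Two-sided F-test comparing per-individual cM variances.

    F = var(A)/var(B) on (nA-1, nB-1) degrees of freedom; the two-sided
    p-value doubles the smaller tail.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("variance_f_test needs >= 2 values per group")
    var_b = b.var(ddof=1)
    if var_b == 0.0:
        raise ValueError("zero variance in denominator group")
    f = a.var(ddof=1) / var_b
    dfn, dfd = a.size - 1, b.size - 1
    p = 2.0 * min(sps.f.sf(f, dfn, dfd), sps.f.cdf(f, dfn, dfd))
    return TestResult(float(f), float(dfn), float(min(p, 1.0)), "variance F-test")


def merged_chisq(counts, min_expected: float = 5.0) -> TestResult:
    """Chi-square homogeneity test with tail-inward category merging.

    ``counts`` is a groups x categories table (e.g. chiasmata-count
    distributions per genotype, categories ordered by chiasmata number).
    Adjacent categories are pooled from the distribution tails inward until
    every expected cell is at least ``min_expected``, then a standard
    chi-square test of homogeneity is run on the merged table with
    (groups - 1) x (merged categories - 1) degrees of freedom.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2:
        raise ValueError("merged_chisq needs a 2-D table with >= 2 groups")

    def expected(tab: np.ndarray) -> np.ndarray:
        return np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()

    while table.shape[1] > 1:
        exp = expected(table)
        bad = np.nonzero(exp.min(axis=0) < min_expected)[0]
        if bad.size == 0:
            break
        centre = (table.shape[1] - 1) / 2.0
        j = bad[np.argmax(np.abs(bad - centre))]  # outermost offender first
        k = j + 1 if j < centre else j - 1
        lo, hi = min(j, k), max(j, k)
        table = np.concatenate(
            [table[:, :lo], (table[:, lo] + table[:, hi])[:, None],
             table[:, hi + 1:]], axis=1)
    if table.shape[1] < 2:
        raise ValueError("category merging collapsed the table to one column")
    exp = expected(table)
    chi2 = float(((table - exp) ** 2 / exp).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return TestResult(chi2, float(df), float(sps.chi2.sf(chi2, df)),
                      "merged-category chi-square")


def yates_chisq_2x2(table) -> TestResult:
    """Chi-square test on a 2x2 table with Yates continuity correction."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("yates_chisq_2x2 needs a 2x2 table")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in 2x2 table")
    chi2, p, df, _ = sps.chi2_contingency(tab, correction=True)
    return TestResult(float(chi2), float(df), float(p),
                      "Yates-corrected chi-square")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotone in the input ranks, never below the raw p, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rebin_track(values, factor: int) -> np.ndarray:
    """Average a fine per-window track into windows ``factor`` times coarser.

    Trailing windows that do not fill a coarse bin are dropped; NaNs are
    ignored within each bin (a bin of all-NaN stays NaN).
    """
    v = np.asarray(values, dtype=float)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    m = (v.size // factor) * factor
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(v[:m].reshape(-1, factor), axis=1)


def windowed_spearman(track_a, track_b, rebin: int = 1) -> float:
    """Spearman rank correlation between two aligned per-window tracks.

    Windows where either track is missing are dropped pairwise; ``rebin``
    optionally averages each track into coarser windows first, supporting
    correlation at multiple physical scales from one fine-grained pair of
    tracks.
    """
    a = rebin_track(track_a, rebin)
    b = rebin_track(track_b, rebin)
    if a.size != b.size:
        raise ValueError("tracks must have equal numbers of windows")
    mask = ~(np.isnan(a) | np.isnan(b))
    if mask.sum() < 3:
        raise ValueError("need >= 3 non-missing window pairs")
    rho = sps.spearmanr(a[mask], b[mask]).statistic
    return float(rho)
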