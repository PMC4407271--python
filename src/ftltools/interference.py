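"""Crossover-interference statistics.

Crossover interference is the tendency of crossovers in adjacent intervals
to occur less often together than expected under independence.  Two
complementary measurements are implemented:

* gamete-level: the coefficient of coincidence (CoC) from the eight classes
  of a three-colour pollen experiment, with interference = 1 - CoC;
* tetrad-level: the ratio of Perkins map distances in a focal interval
  between tetrads without and with a crossover in the adjacent interval.

Fisher's combined probability test aggregates per-interval contrasts, and
``compare_interference`` tests two groups of three-colour replicates for a
difference in double-crossover incidence via a binomial GLM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.api as sm

from .estimators import (CrossoverEstimate, TetradCounts,
                         ThreeColourPollenCounts, tetrad_cm, threecolour_cms)
from .stats import TestResult


__all__ = [
    "InterferenceResult",
    "AdjacentInterferenceResult",
    "coc_threecolour",
    "tetrad_adjacent_interference",
    "adjacent_interference_from_estimates",
    "fisher_combined",
    "fisher_critical_value",
    "compare_interference",
]


@dataclass(frozen=True)
class InterferenceResult:
    observed_dco: int
    expected_dco: float
    coc: float
    interference: float
    p_value: float

    def __post_init__(self) -> None:
        if self.expected_dco < 0:
            raise ValueError("expected_dco must be non-negative")


@dataclass(frozen=True)
class AdjacentInterferenceResult:
    """Map distances of a focal interval stratified by adjacent-interval COs.

    Positive interference makes ``cm_without`` exceed ``cm_with``; ``ratio``
    (without/with) grows with interference strength.
    """

    cm_without: CrossoverEstimate
    cm_with: CrossoverEstimate
    ratio: float
    p_value: float


def coc_threecolour(counts: ThreeColourPollenCounts) -> InterferenceResult:
    """Coefficient of coincidence from three-colour pollen class counts.

    Observed DCOs are the two classes recombinant in both intervals
    (N_-Y- + N_B-R); the expectation under independence is
    (cM_b/100) * (cM_c/100) * N_total.  Significance of the departure is a
    binomial test of the observed DCO count against the expected DCO
    fraction.
    """
    est_b, est_c = threecolour_cms(counts)
    if est_b.cm <= 0.0 or est_c.cm <= 0.0:
        raise ValueError("CoC undefined: zero genetic distance in one interval")
    n = counts.N_total
    observed = counts.N_mYm + counts.N_BmR
    expected = (est_b.cm / 100.0) * (est_c.cm / 100.0) * n
    coc = observed / expected
    p = sps.binomtest(observed, n, expected / n).pvalue
    return InterferenceResult(
        observed_dco=observed, expected_dco=expected, coc=coc,
        interference=1.0 - coc, p_value=float(p),
    )


def adjacent_interference_from_estimates(
    cm_without: CrossoverEstimate, cm_with: CrossoverEstimate,
) -> AdjacentInterferenceResult:
    """Combine two stratum estimates into an adjacent-CO interference ratio.

    The significance of the contrast is a two-sided z-test on the cM
    difference using the delta-method standard errors.  When the
    with-adjacent-CO stratum has zero cM the ratio is undefined (NaN) and
    only the z-test is informative.
    """
    se = math.hypot(cm_without.se, cm_with.se)
    if se > 0:
        z = (cm_without.cm - cm_with.cm) / se
        p = 2.0 * sps.norm.sf(abs(z))
    else:
        p = 1.0
    ratio = cm_without.cm / cm_with.cm if cm_with.cm > 0 else float("nan")
    return AdjacentInterferenceResult(cm_without, cm_with, ratio, float(p))


def tetrad_adjacent_interference(calls: pd.DataFrame) -> AdjacentInterferenceResult:
    """Tetrad-based interference for a focal interval.

    ``calls`` has one row per tetrad with columns ``adjacent_co`` (0/1 or
    bool: any crossover in the adjacent interval) and ``focal_class``
    (``PD``/``NPD``/``T`` for the focal interval).  Perkins map distances
    are computed separately for the tetrads without and with an adjacent
    crossover; strong interference depresses the with-adjacent-CO estimate.
    """
    adj = calls["adjacent_co"].astype(bool)
    strata = []
    for mask in (~adj, adj):
        sub = calls.loc[mask, "focal_class"].value_counts()
        if sub.sum() == 0:
            raise ValueError("empty stratum: every tetrad falls on one side "
                             "of the adjacent-CO split")
        counts = TetradCounts(PD=int(sub.get("PD", 0)),
                              NPD=int(sub.get("NPD", 0)),
                              T=int(sub.get("T", 0)))
        strata.append(tetrad_cm(counts))
    return adjacent_interference_from_estimates(*strata)


def fisher_combined(p_values) -> TestResult:
    """Fisher's combined probability test: chi2 = -2 sum(ln p), df = 2k."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return TestResult(chi2, float(df), float(sps.chi2.sf(chi2, df)),
                      "Fisher combined probability")


def fisher_critical_value(alpha: float, df: int) -> float:
    """Upper-tail chi-square critical value for the combined test."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return float(sps.chi2.isf(alpha, df))


def _dco_frame(replicates, group_label: str) -> pd.DataFrame:
    rows = []
    for i, counts in enumerate(replicates):
        est_b, est_c = threecolour_cms(counts)
        expected = (est_b.cm / 100.0) * (est_c.cm / 100.0) * counts.N_total
        rows.append({
            "genotype": group_label,
            "replicate": f"{group_label}_{i}",
            "recombinant": counts.N_mYm + counts.N_BmR,
            "total": counts.N_total,
            "expected_dco": expected,
        })
    return pd.DataFrame(rows)


def compare_interference(group_a, group_b) -> float:
    """Test two groups of three-colour replicates for different interference.

    Interference is expressed through double-crossover incidence, so the
    comparison models per-replicate DCO counts (successes) out of total
    pollen with a binomial GLM including an offset for each replicate's
    expected DCO proportion under independence; the returned p-value is the
    likelihood-ratio test of the group effect.  Modelling counts rather
    than 1 - CoC keeps the inference in the binomial framework (CoC itself
    is a ratio of estimates with awkward error propagation).
    """
    frames = [_dco_frame(group_a, "A"), _dco_frame(group_b, "B")]
    df = pd.concat(frames, ignore_index=True)
    if (df["recombinant"] == 0).all():
        raise ValueError("no double crossovers observed in either group")
    # fold the independence expectation in as a per-observation offset:
    # logit(p_i) = offset_i + beta * group
    y = df["recombinant"].to_numpy(dtype=float)
    n = df["total"].to_numpy(dtype=float)
    expected_prop = np.clip(df["expected_dco"].to_numpy() / n, 1e-12, 1 - 1e-12)
    offset = np.log(expected_prop / (1.0 - expected_prop))
    endog = np.column_stack([y, n - y])
    group = (df["genotype"] == "B").to_numpy(dtype=float)
    X_full = np.column_stack([np.ones_like(group), group])
    X_null = X_full[:, :1]
    import warnings

    fam = sm.families.Binomial()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels separation chatter
        full = sm.GLM(endog, X_full, family=fam, offset=offset).fit(maxiter=200)
        null = sm.GLM(endog, X_null, family=fam, offset=offset).fit(maxiter=200)
    lrt = max(null.deviance - full.deviance, 0.0)
    return float(sps.chi2.sf(lrt, 1))
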