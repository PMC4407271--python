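"""Genetic-distance estimators for fluorescent tagged line (FTL) crossover assays.

Fluorescent tagged lines carry linked transgenes expressing fluorescent
proteins in pollen or seed. After meiosis in a hemizygous plant, the
fluorescence pattern of each gamete (or selfed seed) reveals whether a
crossover occurred between the transgenes, so class counts from flow
cytometry or seed imaging translate directly into genetic distance.

Each scoring modality has its own estimator:

* two-colour pollen  -- ``pollen2_cm``  (conditions on green fluorescence to
  avoid the non-hydrated-pollen artifact that inflates red-alone counts)
* selfed seed        -- ``seed_cm``     (inverts the diploid segregation model)
* pollen tetrads     -- ``tetrad_cm``   (Perkins PD/NPD/T formula)
* three-colour pollen -- ``threecolour_cms`` (two adjacent intervals at once)

All estimators return a :class:`CrossoverEstimate` carrying the map distance
in centimorgans, a standard error, and the informative count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal


__all__ = [
    "TwoColourPollenCounts",
    "SeedClassCounts",
    "TetradCounts",
    "ThreeColourPollenCounts",
    "CrossoverEstimate",
    "pollen2_cm",
    "seed_cm",
    "tetrad_cm",
    "threecolour_cms",
    "classify_seed_objects",
    "call_configuration",
    "interval_heterozygosity",
    "THREECOLOUR_CLASSES",
]

#: Eight fluorescence classes of a three-reporter pollen experiment, named by
#: presence (letter) or absence (dash) of Blue, Yellow and Red fluorescence.
THREECOLOUR_CLASSES = (
    "N_BYR", "N_BY-", "N_B-R", "N_B--", "N_-YR", "N_-Y-", "N_--R", "N_---",
)


def _check_nonneg(**counts: int) -> None:
    for name, value in counts.items():
        if value < 0:
            raise ValueError(f"count {name} must be non-negative, got {value}")


@dataclass(frozen=True)
class TwoColourPollenCounts:
    """Class counts from a two-colour (green/red) pollen flow-cytometry run.

    ``R3`` is the green+red (parental) gate and ``R5`` the green-alone
    (recombinant) gate.  ``red_alone`` and ``none`` are retained for
    completeness but are not informative for estimation because the
    red-alone gate is contaminated by non-hydrated pollen.
    """

    R3: int
    R5: int
    red_alone: int = 0
    none: int = 0

    def __post_init__(self) -> None:
        _check_nonneg(R3=self.R3, R5=self.R5, red_alone=self.red_alone,
                      none=self.none)

    @property
    def total(self) -> int:
        return self.R3 + self.R5 + self.red_alone + self.none


@dataclass(frozen=True)
class SeedClassCounts:
    """Four fluorescence categories of selfed-seed scoring."""

    N_GR: int  # both green and red
    N_G: int   # green alone
    N_R: int   # red alone
    N_N: int   # non-fluorescent

    def __post_init__(self) -> None:
        _check_nonneg(N_GR=self.N_GR, N_G=self.N_G, N_R=self.N_R, N_N=self.N_N)

    @property
    def N_T(self) -> int:
        return self.N_GR + self.N_G + self.N_R + self.N_N


@dataclass(frozen=True)
class TetradCounts:
    """Parental ditype / non-parental ditype / tetratype tetrad counts."""

    PD: int
    NPD: int
    T: int

    def __post_init__(self) -> None:
        _check_nonneg(PD=self.PD, NPD=self.NPD, T=self.T)

    @property
    def n(self) -> int:
        return self.PD + self.NPD + self.T

    def __add__(self, other: "TetradCounts") -> "TetradCounts":
        return TetradCounts(self.PD + other.PD, self.NPD + other.NPD,
                            self.T + other.T)


@dataclass(frozen=True)
class ThreeColourPollenCounts:
    """The eight fluorescence classes of a three-reporter pollen experiment.

    Field names follow presence/absence of Blue, Yellow and Red: ``N_BYR`` is
    triple-positive (parental), ``N_mYm`` is yellow-alone (a double
    crossover), etc., with ``m`` standing in for the dash of the gate label.
    """

    N_BYR: int
    N_BYm: int
    N_BmR: int
    N_Bmm: int
    N_mYR: int
    N_mYm: int
    N_mmR: int
    N_mmm: int

    def __post_init__(self) -> None:
        _check_nonneg(**{k: getattr(self, k) for k in self.__dataclass_fields__})

    @property
    def N_total(self) -> int:
        return (self.N_BYR + self.N_BYm + self.N_BmR + self.N_Bmm
                + self.N_mYR + self.N_mYm + self.N_mmR + self.N_mmm)

    def as_series(self) -> pd.Series:
        return pd.Series(
            [self.N_BYR, self.N_BYm, self.N_BmR, self.N_Bmm,
             self.N_mYR, self.N_mYm, self.N_mmR, self.N_mmm],
            index=list(THREECOLOUR_CLASSES),
        )


@dataclass(frozen=True)
class CrossoverEstimate:
    """A genetic-distance point estimate with its standard error.

    ``cm`` and ``se`` are in centimorgans, ``n`` is the informative count
    the estimate is based on, and ``method`` tags the scoring modality.
    ``extra`` carries modality-specific ancillary values (e.g. the estimated
    recombinant pollen total for the two-colour assay).
    """

    cm: float
    se: float
    n: int
    method: str
    extra: dict = field(default_factory=dict)

    def rounded(self, ndigits: int = 2) -> tuple[float, float]:
        """(cM, SE) rounded for display, matching 2-dp table conventions."""
        return round(self.cm, ndigits), round(self.se, ndigits)


# ---------------------------------------------------------------------------
# estimators


def pollen2_cm(counts: TwoColourPollenCounts) -> CrossoverEstimate:
    """Two-colour pollen estimator: cM = 100 * R5 / (R3 + R5).

    Only green-positive gates enter the estimate, so the excess of red-alone
    objects from non-hydrated pollen cannot bias it.  Because green-alone
    pollen represent half of all recombinants, the estimated recombinant
    total (reported in ``extra``) is twice the green-alone count.
    """
    informative = counts.R3 + counts.R5
    if informative <= 0:
        raise ValueError("pollen2_cm requires R3 + R5 > 0")
    p = counts.R5 / informative
    se = 100.0 * math.sqrt(p * (1.0 - p) / informative)
    return CrossoverEstimate(
        cm=100.0 * p, se=se, n=informative, method="pollen2",
        extra={"recombinant_total": 2 * counts.R5},
    )


def seed_cm(counts: SeedClassCounts) -> CrossoverEstimate:
    """Selfed-seed estimator: cM = 100 * (1 - sqrt(1 - 2(N_G+N_R)/N_T)).

    A selfed RG/++ plant produces single-colour seed only when exactly one
    of the two uniting gametes is recombinant; the square root inverts that
    two-gamete convolution.  The standard error comes from first-order
    propagation of the binomial variance of the single-colour fraction:
    with q = (N_G+N_R)/N_T, cM = 100(1-sqrt(1-2q)) and
    d(cM)/dq = 100/sqrt(1-2q).
    """
    n_t = counts.N_T
    if n_t <= 0:
        raise ValueError("seed_cm requires at least one scored seed")
    q = (counts.N_G + counts.N_R) / n_t
    radicand = 1.0 - 2.0 * q
    if radicand < 0.0:
        raise ValueError(
            "seed_cm domain error: 2(N_G + N_R) exceeds N_T "
            f"(N_G={counts.N_G}, N_R={counts.N_R}, N_T={n_t})"
        )
    cm = 100.0 * (1.0 - math.sqrt(radicand))
    if cm > 50.0:
        warnings.warn(
            "seed_cm above 50 cM: single-interval scoring saturates under "
            "double crossovers; treat with caution", stacklevel=2,
        )
    if radicand > 0.0:
        se = (100.0 / math.sqrt(radicand)) * math.sqrt(q * (1.0 - q) / n_t)
    else:
        se = float("inf")
    return CrossoverEstimate(cm=cm, se=se, n=n_t, method="seed")


def tetrad_cm(counts: TetradCounts) -> CrossoverEstimate:
    """Perkins tetrad estimator: cM = 100 * (T/2 + 3 NPD) / n.

    Tetratypes carry a single crossover (two of four chromatids recombinant)
    and non-parental ditypes arise from four-strand double crossovers, hence
    the factor 3 correcting for the unobserved double-crossover classes.
    The standard error is the multinomial delta method applied to the
    proportions t = T/n and d = NPD/n:

        se = (100/sqrt(n)) * sqrt(t(1-t)/4 + 9 d(1-d) - 3 t d)
    """
    n = counts.n
    if n <= 0:
        raise ValueError("tetrad_cm requires PD + NPD + T > 0")
    t = counts.T / n
    d = counts.NPD / n
    cm = 100.0 * (t / 2.0 + 3.0 * d)
    var = 0.25 * t * (1.0 - t) + 9.0 * d * (1.0 - d) - 3.0 * t * d
    se = (100.0 / math.sqrt(n)) * math.sqrt(max(var, 0.0))
    return CrossoverEstimate(cm=cm, se=se, n=n, method="tetrad")


def threecolour_cms(
    counts: ThreeColourPollenCounts,
) -> tuple[CrossoverEstimate, CrossoverEstimate]:
    """Genetic distances of the two adjacent intervals of a B-Y-R reporter.

    Interval b lies between the blue and yellow transgenes, interval c
    between yellow and red.  A pollen grain is recombinant for an interval
    when the presence of the two flanking colours differs, so

        cM_b = 100 * (N_-Y- + N_B-R + N_-YR + N_B--) / N_total
        cM_c = 100 * (N_-Y- + N_B-R + N_BY- + N_--R) / N_total

    with a binomial standard error for each.
    """
    n = counts.N_total
    if n <= 0:
        raise ValueError("threecolour_cms requires N_total > 0")

    def _est(recomb: int) -> CrossoverEstimate:
        p = recomb / n
        return CrossoverEstimate(
            cm=100.0 * p, se=100.0 * math.sqrt(p * (1.0 - p) / n),
            n=n, method="pollen3",
        )

    rec_b = counts.N_mYm + counts.N_BmR + counts.N_mYR + counts.N_Bmm
    rec_c = counts.N_mYm + counts.N_BmR + counts.N_BYm + counts.N_mmR
    return _est(rec_b), _est(rec_c)


# ---------------------------------------------------------------------------
# seed-object classification


def _valley_threshold(values: np.ndarray, bins: int = 64,
                      smooth_sigma: float = 2.0) -> float:
    """Deepest interior valley of a smoothed log-intensity histogram.

    Raises if the smoothed histogram has no interior local minimum between
    local maxima (unimodal), in which case explicit thresholds are needed.
    """
    logv = np.log10(np.asarray(values, dtype=float) + 1.0)
    hist, edges = np.histogram(logv, bins=bins)
    smooth = ndimage.gaussian_filter1d(hist.astype(float), smooth_sigma)
    # modes must be substantial relative to the dominant one, otherwise
    # histogram noise would masquerade as bimodality
    peaks, _ = signal.find_peaks(smooth, prominence=0.15 * smooth.max())
    if peaks.size < 2:
        raise ValueError(
            "intensity histogram looks unimodal; automatic thresholding "
            "failed -- pass explicit (red, green) thresholds"
        )
    top_two = np.sort(peaks[np.argsort(smooth[peaks])[-2:]])
    lo, hi = top_two
    best = lo + int(np.argmin(smooth[lo:hi + 1]))
    centre = 0.5 * (edges[best] + edges[best + 1])
    return 10.0 ** centre - 1.0


def classify_seed_objects(
    table: pd.DataFrame,
    thresholds: tuple[float, float] | None = None,
) -> SeedClassCounts:
    """Assign each seed object to a fluorescence category.

    ``table`` must have ``red`` and ``green`` intensity columns (arbitrary
    units, >= 0), one row per seed.  A seed is positive for a channel when
    its intensity exceeds the channel threshold.  With ``thresholds=None``
    each per-channel cut is placed at the deepest valley of a smoothed
    log-intensity histogram, mirroring the manual gating of seed-image
    fluorescence histograms.
    """
    if len(table) == 0:
        raise ValueError("classify_seed_objects requires at least one seed")
    red = np.asarray(table["red"], dtype=float)
    green = np.asarray(table["green"], dtype=float)
    if (red < 0).any() or (green < 0).any():
        raise ValueError("intensities must be non-negative")
    if thresholds is None:
        red_cut = _valley_threshold(red)
        green_cut = _valley_threshold(green)
    else:
        red_cut, green_cut = thresholds
    has_r = red > red_cut
    has_g = green > green_cut
    return SeedClassCounts(
        N_GR=int(np.sum(has_g & has_r)),
        N_G=int(np.sum(has_g & ~has_r)),
        N_R=int(np.sum(~has_g & has_r)),
        N_N=int(np.sum(~has_g & ~has_r)),
    )


# ---------------------------------------------------------------------------
# cis/trans transgene configuration


def _cis_class_probs(r: float) -> np.ndarray:
    """Seed-category probabilities (GR, G, R, N) for a cis RG/++ parent.

    Gametes: RG and ++ parental at (1-r)/2 each, G+ and +R recombinant at
    r/2 each; a seed is the union of two independent gametes.
    """
    no_g = 0.5        # gamete lacks green: ++ or +R
    only_pp = (1.0 - r) / 2.0
    p_none = only_pp ** 2
    p_single = no_g ** 2 - p_none     # lacks one colour but not both
    p_both = 1.0 - p_none - 2.0 * p_single
    return np.array([p_both, p_single, p_single, p_none])


def call_configuration(
    counts: SeedClassCounts,
    reference_r: float = 0.15,
    margin: float = 2.0,
) -> str:
    """Call the transgene phase of a two-colour seed line: cis or trans.

    A fluorescence-selected F2 can carry the two transgenes on one
    chromosome (cis, RG/++) or on opposite homologues (trans, R+/+G).  The
    two phases swap the parental and crossover seed classes, so the
    four-category counts are compared under the cis model at ``reference_r``
    and under the trans model (algebraically the cis model at 1 - r).
    Returns ``"cis"``, ``"trans"`` or ``"ambiguous"`` when the
    log-likelihood difference is below ``margin``.
    """
    if counts.N_T <= 0:
        raise ValueError("call_configuration requires scored seed")
    obs = np.array([counts.N_GR, counts.N_G, counts.N_R, counts.N_N])
    with np.errstate(divide="ignore"):
        ll_cis = float(obs @ np.log(_cis_class_probs(reference_r)))
        ll_trans = float(obs @ np.log(_cis_class_probs(1.0 - reference_r)))
    delta = ll_cis - ll_trans
    if abs(delta) < margin:
        return "ambiguous"
    return "cis" if delta > 0 else "trans"


# ---------------------------------------------------------------------------
# ancillary metrics


def interval_heterozygosity(
    variants,
    region: tuple[int, int],
) -> float:
    """Per-kilobase heterozygosity of a region.

    ``variants`` is an iterable of ``(position, type, indel_length)`` with
    type ``"SNP"`` or ``"indel"``; SNPs contribute 1 each and indels their
    length in bp.  The sum over variants inside ``region`` (1-based
    inclusive coordinates) is divided by the region length in kb.
    """
    start, end = region
    if end <= start:
        raise ValueError(f"inverted or empty region ({start}, {end})")
    total = 0.0
    for pos, vtype, length in variants:
        if not (start <= pos <= end):
            continue
        if vtype == "SNP":
            total += 1.0
        elif vtype == "indel":
            total += float(length)
        else:
            raise ValueError(f"unknown variant type {vtype!r}")
    return total / ((end - start + 1) / 1000.0)
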