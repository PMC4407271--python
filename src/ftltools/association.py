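"""Marker-genotype association with crossover rate in F2 populations.

Selfing a hybrid that carries a fluorescent crossover reporter yields an F2
population in which every individual has its own measured recombination
rate (cM) for the reporter interval and a genome-wide marker genotype.
Two scans for markers whose genotype predicts that rate are provided:

* ``quartile_association`` -- the hot/cold-quartile contingency procedure:
  rank individuals by cM, take the hottest and coldest quarters, and test
  each marker's heterozygous-vs-homozygous counts between the two quartiles
  with a Yates-corrected chi-square followed by Benjamini-Hochberg FDR;
* ``lod_scan`` -- a single-marker regression LOD scan with a genome-wide
  significance threshold from phenotype permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import bh_fdr, yates_chisq_2x2


__all__ = [
    "F2Individual",
    "MarkerAssociationResult",
    "quartile_association",
    "association_from_tables",
    "lod_scan",
]

MISSING = "NA"
_HOM = {"HOM_REF", "HOM_ALT"}


@dataclass(frozen=True)
class F2Individual:
    """One F2 plant: marker genotypes plus its reporter-interval phenotype.

    ``genotypes`` maps marker bp position (1-based) to one of ``HET``,
    ``HOM_REF``, ``HOM_ALT`` or ``NA``; ``cm`` is the individual's measured
    genetic distance and ``counts`` the underlying class counts.
    """

    id: str
    genotypes: dict
    cm: float
    counts: object = None

    def __post_init__(self) -> None:
        if self.cm < 0:
            raise ValueError("cM must be non-negative")


@dataclass(frozen=True)
class MarkerAssociationResult:
    marker_bp: int
    hot_het: int
    hot_hom: int
    cold_het: int
    cold_hom: int
    chi2: float
    p_raw: float
    p_adj: float = field(default=float("nan"))

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.hot_het, self.hot_hom],
                         [self.cold_het, self.cold_hom]], dtype=float)


def _test_table(marker_bp: int, table: np.ndarray) -> MarkerAssociationResult:
    tab = np.asarray(table, dtype=float)
    degenerate = (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any()
    if degenerate:
        chi2, p = 0.0, 1.0  # e.g. every individual heterozygous
    else:
        res = yates_chisq_2x2(tab)
        chi2, p = res.statistic, res.p_value
    return MarkerAssociationResult(
        marker_bp=int(marker_bp),
        hot_het=int(tab[0, 0]), hot_hom=int(tab[0, 1]),
        cold_het=int(tab[1, 0]), cold_hom=int(tab[1, 1]),
        chi2=chi2, p_raw=p,
    )


def _adjust(results: list[MarkerAssociationResult]) -> list[MarkerAssociationResult]:
    adj = bh_fdr([r.p_raw for r in results])
    return [MarkerAssociationResult(
        r.marker_bp, r.hot_het, r.hot_hom, r.cold_het, r.cold_hom,
        r.chi2, r.p_raw, float(q)) for r, q in zip(results, adj)]


def association_from_tables(tables: dict) -> list[MarkerAssociationResult]:
    """Run the chi-square + FDR step on fixed per-marker 2x2 quartile tables.

    ``tables`` maps marker bp to ``[[hot_het, hot_hom], [cold_het,
    cold_hom]]``.  FDR adjustment uses all supplied markers, so published
    quartile count tables can be fed straight through the same machinery
    the full pipeline uses.
    """
    results = [_test_table(bp, tab) for bp, tab in tables.items()]
    return _adjust(results)


def quartile_association(population: list[F2Individual],
                         markers=None,
                         quartile_size: int | None = None,
                         ) -> list[MarkerAssociationResult]:
    """Hot/cold-quartile marker association scan.

    Individuals are ranked by cM (ties broken by id for determinism); the
    hottest and coldest ``quartile_size`` individuals (default
    ``floor(n/4)``) form the two strata.  For each marker a 2x2 table of
    heterozygous vs homozygous counts (both homozygous classes pooled) in
    hot vs cold is tested with the Yates-corrected chi-square, and the
    resulting p-values are Benjamini-Hochberg adjusted across markers.
    Missing genotypes are dropped per marker; a marker with no genotyped
    individual in the two quartiles raises.
    """
    n = len(population)
    if n < 8:
        raise ValueError("need a population of at least 8 individuals")
    q = quartile_size if quartile_size is not None else n // 4
    if q < 1:
        raise ValueError("quartile size is zero")
    ranked = sorted(population, key=lambda ind: (ind.cm, ind.id))
    cold, hot = ranked[:q], ranked[-q:]
    if markers is None:
        markers = sorted({m for ind in population for m in ind.genotypes})

    results = []
    for marker in markers:
        tab = np.zeros((2, 2))
        informative = 0
        for row, stratum in enumerate((hot, cold)):
            for ind in stratum:
                g = ind.genotypes.get(marker, MISSING)
                if g == "HET":
                    tab[row, 0] += 1
                elif g in _HOM:
                    tab[row, 1] += 1
                elif g == MISSING or (isinstance(g, float) and np.isnan(g)):
                    continue
                else:
                    raise ValueError(f"unknown genotype {g!r} at {marker}")
                informative += 1
        if informative == 0:
            raise ValueError(f"marker {marker} has no genotyped individuals "
                             "in the hot/cold quartiles")
        results.append(_test_table(marker, tab))
    return _adjust(results)


def _marker_lod(y: np.ndarray, genotypes: np.ndarray) -> float | None:
    """LOD of a single-marker regression of phenotype on genotype class.

    Returns None when fewer than two genotype classes are present among
    non-missing individuals.
    """
    ok = genotypes != MISSING
    yy = y[ok]
    gg = genotypes[ok]
    classes = np.unique(gg)
    if classes.size < 2 or yy.size < 3:
        return None
    n = yy.size
    rss0 = float(((yy - yy.mean()) ** 2).sum())
    rss1 = 0.0
    for c in classes:
        sub = yy[gg == c]
        rss1 += float(((sub - sub.mean()) ** 2).sum())
    if rss1 <= 0.0:
        rss1 = np.finfo(float).tiny
    return (n / 2.0) * np.log10(rss0 / rss1)


def lod_scan(population: list[F2Individual],
             markers=None,
             n_permutations: int = 1000,
             alpha: float = 0.05,
             seed: int | None = None,
             ) -> tuple[pd.DataFrame, float]:
    """Single-marker LOD scan with a permutation genome-wide threshold.

    For each marker the phenotype (per-individual cM) is regressed on the
    genotype classes and LOD = (n/2) log10(RSS0/RSS1) recorded.  The
    genome-wide threshold is the (1 - alpha) quantile of the maximum LOD
    over ``n_permutations`` random permutations of the phenotype vector,
    seeded for reproducibility.  Markers with fewer than two genotype
    classes are skipped.  Returns ``(per-marker table, threshold)``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    y = np.array([ind.cm for ind in population], dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 phenotyped individuals")
    if np.allclose(y, y[0]):
        raise ValueError("constant phenotype: LOD scan undefined")
    if markers is None:
        markers = sorted({m for ind in population for m in ind.genotypes})
    geno = {m: np.array([str(ind.genotypes.get(m, MISSING))
                         for ind in population]) for m in markers}

    rows = []
    usable = []
    for m in markers:
        lod = _marker_lod(y, geno[m])
        if lod is not None:
            rows.append({"marker_bp": int(m), "lod": lod})
            usable.append(m)
    if not rows:
        raise ValueError("no marker with >= 2 genotype classes")
    scan = pd.DataFrame(rows)

    rng = np.random.default_rng(seed)
    max_lods = np.empty(n_permutations)
    for i in range(n_permutations):
        yp = rng.permutation(y)
        max_lods[i] = max(_marker_lod(yp, geno[m]) for m in usable)
    threshold = float(np.quantile(max_lods, 1.0 - alpha, method="higher"))
    return scan, threshold
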