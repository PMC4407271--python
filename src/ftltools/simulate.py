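"""Synthetic four-strand meiosis with tunable crossover interference.

The generator produces every count modality the estimators consume
(two- and three-colour pollen, selfed seed, pollen tetrads, F2 marker
populations) from a single mechanistic layer:

* chiasmata are placed on the bivalent along the genetic scale by a
  stationary gamma-renewal process (shape ``nu``; ``nu = 1`` is Poisson,
  i.e. no interference; larger ``nu`` spaces events more evenly), with mean
  inter-event distance 0.5 Morgan so that the recombinant fraction of a
  single chromatid equals the map distance;
* a fraction ``escape_fraction`` of events instead comes from an
  interference-free Poisson pathway, mimicking the non-interfering
  (FANCM-dependent) crossover route;
* each chiasma involves one chromatid from each homologue chosen uniformly
  and independently (no chromatid interference), and pollen are sampled one
  chromatid per meiosis.

Physical (bp) coordinates are connected to the genetic scale by a monotone
piecewise-linear map; regional rate modifiers rescale the map density on bp
windows, which is how heterozygosity-driven rate changes are emulated
(a descriptive stand-in, not a mechanism).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import F2Individual
from .estimators import (SeedClassCounts, TetradCounts, ThreeColourPollenCounts,
                         TwoColourPollenCounts, _cis_class_probs, seed_cm)


__all__ = [
    "GeneticMap",
    "SimulationModel",
    "ReporterLayout",
    "SeedIntensityModel",
    "simulate_meioses",
    "simulate_tetrad_counts",
    "simulate_pollen_two_colour",
    "simulate_pollen_three_colour",
    "simulate_selfed_seed",
    "simulate_f2_population",
]


@dataclass(frozen=True)
class GeneticMap:
    """Monotone piecewise-linear map from bp position to Morgans."""

    bp: np.ndarray       # strictly increasing breakpoints, bp[0] = map start
    morgans: np.ndarray  # non-decreasing cumulative genetic position

    def __post_init__(self) -> None:
        bp = np.asarray(self.bp, dtype=float)
        mg = np.asarray(self.morgans, dtype=float)
        if bp.ndim != 1 or bp.shape != mg.shape or bp.size < 2:
            raise ValueError("map needs matching 1-D bp/morgan arrays (>= 2)")
        if not np.all(np.diff(bp) > 0):
            raise ValueError("bp breakpoints must be strictly increasing")
        if not np.all(np.isfinite(mg)) or np.any(np.diff(mg) < 0):
            raise ValueError("genetic map must be finite and non-decreasing")
        object.__setattr__(self, "bp", bp)
        object.__setattr__(self, "morgans", mg)

    @property
    def length_morgans(self) -> float:
        return float(self.morgans[-1] - self.morgans[0])

    def morgans_at(self, bp_pos) -> np.ndarray:
        return np.interp(np.asarray(bp_pos, dtype=float), self.bp, self.morgans)


@dataclass(frozen=True)
class SimulationModel:
    """Chromosome layout and crossover-placement parameters.

    ``region_modifiers`` is a list of ``(start_bp, end_bp, factor)`` windows
    whose map density is multiplied by ``factor`` (>= 0); the effective map
    used for simulation is rebuilt with those factors applied.
    """

    chromosome_length_bp: int
    genetic_map: GeneticMap
    nu: float = 1.0
    escape_fraction: float = 0.0
    region_modifiers: list = field(default_factory=list)
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.chromosome_length_bp < 2:
            raise ValueError("chromosome_length_bp must be >= 2")
        if not (self.nu > 0 and math.isfinite(self.nu)):
            raise ValueError("nu must be a positive finite number")
        if not 0.0 <= self.escape_fraction <= 1.0:
            raise ValueError("escape_fraction must be in [0, 1]")
        for start, end, factor in self.region_modifiers:
            if end <= start:
                raise ValueError(f"inverted modifier region ({start}, {end})")
            if factor < 0:
                raise ValueError("rate factors must be >= 0")

    @classmethod
    def uniform(cls, chromosome_length_bp: int, total_cm: float,
                **kwargs) -> "SimulationModel":
        """Model with a uniform recombination density along the chromosome."""
        gmap = GeneticMap(np.array([1.0, float(chromosome_length_bp)]),
                          np.array([0.0, total_cm / 100.0]))
        return cls(chromosome_length_bp=chromosome_length_bp,
                   genetic_map=gmap, **kwargs)

    def effective_map(self) -> GeneticMap:
        """Genetic map with the regional rate modifiers folded in."""
        if not self.region_modifiers:
            return self.genetic_map
        cuts = set(self.genetic_map.bp.tolist())
        for start, end, _ in self.region_modifiers:
            cuts.add(float(start))
            cuts.add(float(end))
        lo, hi = self.genetic_map.bp[0], self.genetic_map.bp[-1]
        bp = np.array(sorted(c for c in cuts if lo <= c <= hi))
        base = self.genetic_map.morgans_at(bp)
        seg = np.diff(base)
        mid = 0.5 * (bp[:-1] + bp[1:])
        for start, end, factor in self.region_modifiers:
            inside = (mid >= start) & (mid <= end)
            seg[inside] *= factor
        return GeneticMap(bp, np.concatenate([[base[0]],
                                              base[0] + np.cumsum(seg)]))

    def rng(self, rng: np.random.Generator | None = None) -> np.random.Generator:
        return rng if rng is not None else np.random.default_rng(self.rng_seed)


@dataclass(frozen=True)
class ReporterLayout:
    """Ordered fluorescent-transgene markers and the scoring modality."""

    markers: list  # of (name, bp_position, colour in {G,R,Y,B,C})
    modality: str  # pollen2 | pollen3 | seed | tetrad

    _REQUIRED = {"pollen2": 2, "seed": 2, "tetrad": 2, "pollen3": 3}

    def __post_init__(self) -> None:
        if self.modality not in self._REQUIRED:
            raise ValueError(f"unknown modality {self.modality!r}")
        need = self._REQUIRED[self.modality]
        if len(self.markers) != need:
            raise ValueError(
                f"modality {self.modality!r} needs {need} markers, "
                f"got {len(self.markers)}")
        positions = [m[1] for m in self.markers]
        if not all(x < y for x, y in zip(positions, positions[1:])):
            raise ValueError("marker positions must be strictly increasing")
        for _, _, colour in self.markers:
            if colour not in {"G", "R", "Y", "B", "C"}:
                raise ValueError(f"unknown colour label {colour!r}")

    @property
    def positions_bp(self) -> np.ndarray:
        return np.array([m[1] for m in self.markers], dtype=float)


# ---------------------------------------------------------------------------
# event placement


def _stationary_gamma_points(rng: np.random.Generator, n: int, length: float,
                             nu: float, mean_spacing: float) -> np.ndarray:
    """Stationary gamma-renewal points on [0, length) for n processes.

    Returns an (n, k) array padded with +inf.  The first event is drawn from
    the equilibrium (forward-recurrence) distribution, sampled via the
    size-bias identity: the excess time of a stationary renewal process is
    U * X_size_biased, and the size-biased version of Gamma(nu, theta) is
    Gamma(nu + 1, theta).
    """
    theta = mean_spacing / nu
    cols = []
    pos = rng.uniform(size=n) * rng.gamma(nu + 1.0, theta, size=n)
    while True:
        active = pos < length
        if not active.any():
            break
        cols.append(np.where(active, pos, np.inf))
        step = rng.gamma(nu, theta, size=n)
        pos = pos + step
    if not cols:
        return np.empty((n, 0))
    return np.column_stack(cols)


def _poisson_points(rng: np.random.Generator, n: int, length: float,
                    rate: float) -> np.ndarray:
    counts = rng.poisson(rate * length, size=n)
    k = int(counts.max()) if n else 0
    if k == 0:
        return np.empty((n, 0))
    out = np.full((n, k), np.inf)
    u = rng.uniform(0.0, length, size=(n, k))
    mask = np.arange(k)[None, :] < counts[:, None]
    out[mask] = u[mask]
    return np.sort(out, axis=1)


#: chiasma intensity on the bivalent per Morgan; two chiasmata per Morgan
#: make the single-chromatid recombinant fraction equal the map distance.
_CHIASMA_RATE = 2.0


def _simulate_events(model: SimulationModel, n: int,
                     rng: np.random.Generator):
    """Padded (positions, chromatid_a, chromatid_b) arrays for n meioses.

    Positions are on the genetic scale (Morgans from the map start) of the
    effective map, sorted ascending per meiosis with +inf padding.
    Chromatids 0/1 belong to homologue 0, chromatids 2/3 to homologue 1;
    each chiasma picks one of each uniformly.
    """
    if n <= 0:
        raise ValueError("number of meioses must be >= 1")
    length = model.effective_map().length_morgans
    if not math.isfinite(length):
        raise ValueError("genetic map is not finite")
    interfering_weight = 1.0 - model.escape_fraction
    parts = []
    if interfering_weight > 0.0 and length > 0.0:
        spacing = 1.0 / (_CHIASMA_RATE * interfering_weight)
        parts.append(_stationary_gamma_points(rng, n, length, model.nu, spacing))
    if model.escape_fraction > 0.0 and length > 0.0:
        parts.append(_poisson_points(rng, n, length,
                                     _CHIASMA_RATE * model.escape_fraction))
    if parts:
        pos = np.sort(np.concatenate(parts, axis=1), axis=1)
    else:
        pos = np.empty((n, 0))
    a = rng.integers(0, 2, size=pos.shape)
    b = 2 + rng.integers(0, 2, size=pos.shape)
    return pos, a, b


def simulate_meioses(model: SimulationModel, n: int,
                     rng: np.random.Generator | None = None) -> list:
    """Simulate n meioses; returns one list of crossover records per meiosis.

    Each record is ``(genetic_position_morgans, chromatid_i, chromatid_j)``
    with positions measured on the effective map's genetic scale.
    """
    rng = model.rng(rng)
    pos, a, b = _simulate_events(model, n, rng)
    out = []
    for i in range(pos.shape[0]):
        valid = np.isfinite(pos[i])
        out.append([(float(p), int(x), int(y)) for p, x, y
                    in zip(pos[i, valid], a[i, valid], b[i, valid])])
    return out


def _chromatid_labels(pos, a, b, marker_morgans):
    """Homologue-of-origin label of each meiotic product at each marker.

    Returns an (n_markers, n_meioses, 4) uint8 array; label 0 means the
    product carries homologue-0 (reporter) sequence at that position.

    Each exchange joins the proximal part of one original strand to the
    distal part of the other, so a meiotic product is the path that starts
    at one centromere and jumps to the partner strand at every exchange
    involving the strand it is currently travelling on.  The four paths'
    current strands are propagated left to right, applying each exchange
    before reading any marker to its right; a path's homologue label is the
    homologue of its current strand (strands 0/1 vs 2/3), so every
    encountered exchange toggles it.
    """
    n, k = pos.shape
    strand = np.tile(np.arange(4, dtype=np.int8), (n, 1))
    order = np.argsort(marker_morgans, kind="stable")
    out = np.empty((len(marker_morgans), n, 4), dtype=np.uint8)
    prev = -np.inf
    for m in order:
        g = marker_morgans[m]
        for j in range(k):
            mask = (pos[:, j] >= prev) & (pos[:, j] < g)
            if not mask.any():
                continue
            ridx = np.nonzero(mask)[0]
            sub = strand[ridx]
            on_a = sub == a[ridx, j][:, None]
            on_b = sub == b[ridx, j][:, None]
            sub[on_a] = np.broadcast_to(b[ridx, j][:, None], sub.shape)[on_a]
            sub[on_b] = np.broadcast_to(a[ridx, j][:, None], sub.shape)[on_b]
            strand[ridx] = sub
        out[m] = (strand >= 2).astype(np.uint8)
        prev = g
    return out


def _marker_morgans(model: SimulationModel, layout: ReporterLayout) -> np.ndarray:
    return model.effective_map().morgans_at(layout.positions_bp)


def simulate_tetrad_counts(model: SimulationModel, layout: ReporterLayout,
                           n: int, rng: np.random.Generator | None = None,
                           ) -> TetradCounts:
    """Classify n simulated meioses into PD/NPD/T tetrad classes."""
    if layout.modality != "tetrad" or len(layout.markers) != 2:
        raise ValueError("tetrad simulation needs a two-marker tetrad layout")
    rng = model.rng(rng)
    pos, a, b = _simulate_events(model, n, rng)
    lab = _chromatid_labels(pos, a, b, _marker_morgans(model, layout))
    recombinant = (lab[0] != lab[1]).sum(axis=1)  # 0, 2 or 4 chromatids
    return TetradCounts(PD=int((recombinant == 0).sum()),
                        NPD=int((recombinant == 4).sum()),
                        T=int((recombinant == 2).sum()))


def simulate_per_tetrad_calls(model: SimulationModel,
                              layout_b: ReporterLayout,
                              layout_c: ReporterLayout,
                              n: int,
                              rng: np.random.Generator | None = None,
                              ) -> pd.DataFrame:
    """Per-tetrad calls for two adjacent intervals sharing a middle marker.

    Returns a DataFrame with ``adjacent_co`` (crossover in the second
    interval) and ``focal_class`` (PD/NPD/T of the first), the input shape
    for tetrad-based interference estimation.
    """
    rng = model.rng(rng)
    pos, a, b = _simulate_events(model, n, rng)
    g = np.concatenate([_marker_morgans(model, layout_b),
                        _marker_morgans(model, layout_c)])
    # layouts share the middle marker; unique positions in order
    morgans = np.unique(g)
    if morgans.size != 3:
        raise ValueError("adjacent layouts must span three distinct markers")
    lab = _chromatid_labels(pos, a, b, morgans)
    rec_b = (lab[0] != lab[1]).sum(axis=1)
    rec_c = (lab[1] != lab[2]).sum(axis=1)
    cls = np.where(rec_b == 0, "PD", np.where(rec_b == 2, "T", "NPD"))
    return pd.DataFrame({"tetrad_id": np.arange(n),
                         "adjacent_co": rec_c > 0,
                         "focal_class": cls})


def simulate_pollen_two_colour(model: SimulationModel, layout: ReporterLayout,
                               n: int, artifact_fraction: float = 0.0,
                               rng: np.random.Generator | None = None,
                               ) -> TwoColourPollenCounts:
    """Two-colour pollen class counts from n meioses (one gamete each).

    ``artifact_fraction`` adds spurious red-alone objects (non-hydrated
    pollen debris); the artifact count is Poisson with mean
    ``n * f / (1 - f)`` so artifacts make up fraction ``f`` of all scored
    objects in expectation.
    """
    if not 0.0 <= artifact_fraction < 1.0:
        raise ValueError("artifact_fraction must be in [0, 1)")
    if layout.modality != "pollen2" or len(layout.markers) != 2:
        raise ValueError("two-colour simulation needs a pollen2 layout")
    rng = model.rng(rng)
    pos, a, b = _simulate_events(model, n, rng)
    lab = _chromatid_labels(pos, a, b, _marker_morgans(model, layout))
    chromatid = rng.integers(0, 4, size=n)
    rows = np.arange(n)
    has_g = lab[0][rows, chromatid] == 0
    has_r = lab[1][rows, chromatid] == 0
    artifacts = 0
    if artifact_fraction > 0.0:
        artifacts = int(rng.poisson(n * artifact_fraction
                                    / (1.0 - artifact_fraction)))
    return TwoColourPollenCounts(
        R3=int((has_g & has_r).sum()),
        R5=int((has_g & ~has_r).sum()),
        red_alone=int((~has_g & has_r).sum()) + artifacts,
        none=int((~has_g & ~has_r).sum()),
    )


def simulate_pollen_three_colour(model: SimulationModel,
                                 layout: ReporterLayout, n: int,
                                 rng: np.random.Generator | None = None,
                                 ) -> ThreeColourPollenCounts:
    """Eight-class three-colour pollen counts from n meioses."""
    if layout.modality != "pollen3" or len(layout.markers) != 3:
        raise ValueError("three-colour simulation needs a pollen3 layout")
    rng = model.rng(rng)
    pos, a, b = _simulate_events(model, n, rng)
    lab = _chromatid_labels(pos, a, b, _marker_morgans(model, layout))
    chromatid = rng.integers(0, 4, size=n)
    rows = np.arange(n)
    present = [lab[m][rows, chromatid] == 0 for m in range(3)]  # B, Y, R
    code = present[0].astype(int) * 4 + present[1] * 2 + present[2] * 1
    c = np.bincount(code, minlength=8)
    return ThreeColourPollenCounts(
        N_BYR=int(c[0b111]), N_BYm=int(c[0b110]), N_BmR=int(c[0b101]),
        N_Bmm=int(c[0b100]), N_mYR=int(c[0b011]), N_mYm=int(c[0b010]),
        N_mmR=int(c[0b001]), N_mmm=int(c[0b000]),
    )


# ---------------------------------------------------------------------------
# selfed seed


@dataclass(frozen=True)
class SeedIntensityModel:
    """Lognormal per-channel intensity model for simulated seed objects.

    Mean intensity grows with transgene copy number (0, 1 or 2 copies per
    diploid seed); ``sigma`` is the lognormal shape on the natural-log
    scale.
    """

    background: float = 30.0
    per_copy: float = 600.0
    sigma: float = 0.35


def simulate_selfed_seed(r: float, n: int,
                         intensity_params: SeedIntensityModel | None = None,
                         rng: np.random.Generator | None = None,
                         seed: int | None = None):
    """Seed class counts from selfing a cis RG/++ plant.

    Gametes are parental (RG or ++) with probability (1-r)/2 each and
    recombinant (G+ or +R) with probability r/2 each; a seed unites two
    independent gametes and its fluorescence category follows transgene
    presence.  Returns ``SeedClassCounts``; with ``intensity_params`` also
    returns a per-seed intensity table (columns ``red``, ``green``) drawn
    from the copy-number-dependent lognormal model.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("recombinant fraction r must be in [0, 1]")
    if n <= 0:
        raise ValueError("need n >= 1 seeds")
    rng = rng if rng is not None else np.random.default_rng(seed)
    # gamete types: 0 = RG, 1 = ++, 2 = G+, 3 = +R
    probs = np.array([(1 - r) / 2, (1 - r) / 2, r / 2, r / 2])
    g1 = rng.choice(4, size=n, p=probs)
    g2 = rng.choice(4, size=n, p=probs)
    g_copies = np.isin(g1, (0, 2)).astype(int) + np.isin(g2, (0, 2)).astype(int)
    r_copies = np.isin(g1, (0, 3)).astype(int) + np.isin(g2, (0, 3)).astype(int)
    counts = SeedClassCounts(
        N_GR=int(((g_copies > 0) & (r_copies > 0)).sum()),
        N_G=int(((g_copies > 0) & (r_copies == 0)).sum()),
        N_R=int(((g_copies == 0) & (r_copies > 0)).sum()),
        N_N=int(((g_copies == 0) & (r_copies == 0)).sum()),
    )
    if intensity_params is None:
        return counts
    ip = intensity_params
    def _channel(copies):
        mu = np.log(ip.background + ip.per_copy * copies)
        return rng.lognormal(mean=mu, sigma=ip.sigma)
    table = pd.DataFrame({"red": _channel(r_copies),
                          "green": _channel(g_copies)})
    return counts, table


def expected_seed_class_probs(r: float) -> np.ndarray:
    """(both, green-alone, red-alone, none) seed-class probabilities."""
    return _cis_class_probs(r)


# ---------------------------------------------------------------------------
# F2 population


def simulate_unlinked_marker_genotypes(model: SimulationModel,
                                       marker_positions,
                                       n_individuals: int,
                                       rng: np.random.Generator | None = None,
                                       ) -> list[dict]:
    """Marker genotypes for a chromosome carrying no reporter.

    Each individual unites two independent gametes (no selection applies to
    a non-reporter chromosome), so markers segregate 1 HOM_REF : 2 HET :
    1 HOM_ALT.  Returns one ``{marker_bp: genotype}`` dict per individual,
    for augmenting F2 populations with unlinked chromosomes.
    """
    markers = [int(m) for m in marker_positions]
    if not markers:
        raise ValueError("empty marker list")
    if n_individuals <= 0:
        raise ValueError("n_individuals must be >= 1")
    rng = model.rng(rng)
    marker_g = model.effective_map().morgans_at(np.array(markers, dtype=float))
    pos, a, b = _simulate_events(model, 2 * n_individuals, rng)
    lab = _chromatid_labels(pos, a, b, marker_g)
    chromatid = rng.integers(0, 4, size=2 * n_individuals)
    rows = np.arange(2 * n_individuals)
    alleles = np.stack([lab[m][rows, chromatid] for m in range(len(markers))])
    gam1, gam2 = alleles[:, :n_individuals], alleles[:, n_individuals:]
    out = []
    for i in range(n_individuals):
        out.append({marker: ("HOM_REF", "HET", "HOM_ALT")[
            int(gam1[j, i]) + int(gam2[j, i])]
            for j, marker in enumerate(markers)})
    return out


def simulate_f2_population(model: SimulationModel,
                           marker_positions,
                           cis_effect,
                           n_individuals: int,
                           seeds_per_individual: int = 2000,
                           reporter: tuple[int, int] | None = None,
                           rng: np.random.Generator | None = None,
                           ) -> list[F2Individual]:
    """F2 individuals with marker genotypes and reporter-interval seed counts.

    Selfing an F1 that carries the two linked reporter transgenes on one
    homologue produces F2s; only individuals that inherit one intact
    reporter chromosome over a non-transgenic one (RG/++, the configuration
    retained experimentally) are kept.  Each retained individual's marker
    genotypes come from its two simulated gametes, and its reporter-interval
    crossover rate is the map distance of ``reporter`` multiplied by
    ``cis_effect(genotypes)`` -- a user-supplied function encoding how the
    individual's heterozygosity pattern modifies local recombination.  Seed
    class counts are then drawn at that effective rate and summarised as a
    per-individual cM.
    """
    markers = [int(m) for m in marker_positions]
    if not markers:
        raise ValueError("empty marker list")
    if n_individuals <= 0:
        raise ValueError("n_individuals must be >= 1")
    rng = model.rng(rng)
    emap = model.effective_map()
    if reporter is None:
        reporter = (markers[0], markers[-1])
    rep_g = emap.morgans_at(np.array(reporter, dtype=float))
    base_cm = 100.0 * float(rep_g[1] - rep_g[0])
    if base_cm <= 0.0:
        raise ValueError("reporter interval has zero genetic length; pass "
                         "an explicit (start_bp, end_bp) reporter")
    marker_g = emap.morgans_at(np.array(markers, dtype=float))
    all_g = np.concatenate([marker_g, rep_g])

    individuals: list[F2Individual] = []
    batch = max(4 * n_individuals, 64)
    next_id = 0
    while len(individuals) < n_individuals:
        pos, a, b = _simulate_events(model, 2 * batch, rng)
        lab = _chromatid_labels(pos, a, b, all_g)
        chromatid = rng.integers(0, 4, size=2 * batch)
        rows = np.arange(2 * batch)
        # gamete allele at each queried position: 0 = reporter homologue
        alleles = np.stack([lab[m][rows, chromatid]
                            for m in range(all_g.size)])  # (M+2, 2*batch)
        gam1, gam2 = alleles[:, :batch], alleles[:, batch:]
        m = len(markers)
        t1 = (gam1[m] == 0) & (gam1[m + 1] == 0)      # gamete 1 carries both
        n1 = (gam1[m] == 1) & (gam1[m + 1] == 1)      # gamete 1 carries none
        t2 = (gam2[m] == 0) & (gam2[m + 1] == 0)
        n2 = (gam2[m] == 1) & (gam2[m + 1] == 1)
        keep = np.nonzero((t1 & n2) | (n1 & t2))[0]
        for idx in keep:
            if len(individuals) >= n_individuals:
                break
            genotypes = {}
            for j, marker in enumerate(markers):
                pair = int(gam1[j, idx]) + int(gam2[j, idx])
                genotypes[marker] = ("HOM_REF", "HET", "HOM_ALT")[pair]
            factor = float(cis_effect(genotypes)) if cis_effect else 1.0
            if factor < 0:
                raise ValueError("cis_effect must return factors >= 0")
            eff_r = min(base_cm * factor / 100.0, 0.5)
            seed_counts = simulate_selfed_seed(eff_r, seeds_per_individual,
                                               rng=rng)
            individuals.append(F2Individual(
                id=f"F2_{next_id:04d}", genotypes=genotypes,
                counts=seed_counts, cm=seed_cm(seed_counts).cm,
            ))
            next_id += 1
    return individuals
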