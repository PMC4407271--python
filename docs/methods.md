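# Methods

This note documents the statistical models behind `ftltools`, the
assumptions they make, the defaults and why, and what the synthetic-data
generator does and does not emulate.

## Estimators

**Two-colour pollen.** A plant hemizygous for two linked pollen-expressed
fluorescent transgenes (green proximal, red distal) produces four gamete
classes. The estimator conditions on green fluorescence:
`cM = 100·R5/(R3+R5)` with a binomial standard error on that conditional
fraction. Conditioning matters because flow cytometry of pollen
over-counts the red-alone gate (non-hydrated pollen fall there), so the
red-alone class is treated as uninformative; the estimated total number of
recombinant pollen is reported as twice the green-alone count, using the
symmetry of the two recombinant classes.

**Selfed seed.** Selfing a plant carrying both seed-expressed transgenes
on one homologue (cis) gives seed whose fluorescence reflects the union of
two independent gametes. With gamete recombinant fraction r the
single-colour seed fraction is `2(N_G+N_R)/N_T = 1-(1-r)²`, so
`cM = 100·(1-√(1-2(N_G+N_R)/N_T))` inverts the model exactly — a property
the tests verify over the whole r ∈ (0, 0.5] range. The standard error is
first-order propagation of the binomial variance of the single-colour
fraction. Estimates above 50 cM trigger a warning rather than an error:
the formula saturates there and only a negative radicand is a hard domain
failure.

**Tetrads.** When the four products of one meiosis stay attached, a
two-reporter interval classifies each tetrad as parental ditype,
non-parental ditype or tetratype, and the Perkins estimator
`cM = 100·(T/2 + 3·NPD)/n` corrects for double crossovers (an NPD is a
four-strand double). Its standard error is the multinomial delta method,
`se = (100/√n)·√(t(1-t)/4 + 9d(1-d) - 3td)` with t = T/n, d = NPD/n. The
estimator is exactly unbiased through two chiasmata; with k ≥ 3 chiasmata
in one interval it undercorrects (the exact class distribution follows a
three-state Markov chain over PD/NPD/T), which is ~0.1 cM at a 10 cM
interval and ~0.01 cM at 5 cM under no interference. Validation against
the bundled published tetrad table reproduces every printed cM at 2 dp and
every printed SE except the interval-1c rows, where the published ±0.04 is
inconsistent with any multinomial error at those counts (an apparent
typographical slip; the delta method gives ±0.40).

**Three-colour pollen.** Three linked reporters (blue–yellow–red) define
two adjacent intervals scored simultaneously in each pollen grain; a grain
is recombinant for an interval when the flanking colours disagree. The
printed class-sum formulas are applied with a ×100 factor so the values
are in centimorgans, consistent with how the quantities are plotted and
tabulated.

**Seed-object classification.** Upstream image analysis reduces each seed
to a (red, green) intensity pair. Classification thresholds each channel;
in automatic mode the cut sits at the deepest valley of a
Gaussian-smoothed log₁₀-intensity histogram between the two most prominent
modes (peaks with prominence ≥ 15% of the largest, 64 bins, σ = 2 bins).
A histogram without two such modes raises and asks for explicit
thresholds — a deliberate refusal to guess on unimodal data. The exact
thresholding rule inside the original imaging pipeline is not public;
this valley heuristic is this package's choice and is validated on
simulated copy-number lognormal mixtures (≥99% agreement).

**Cis/trans configuration.** A fluorescence-selected F2 can carry the two
transgenes in cis (RG/++) or trans (R+/+G); the seed-class expectations of
the trans phase equal the cis model evaluated at 1−r, so the call is a
two-model multinomial likelihood comparison at a reference r (default
0.15, typical of the surveyed intervals), returning "ambiguous" inside a
configurable log-likelihood margin (default 2).

## Interference statistics

The coefficient of coincidence from three-colour counts is
`CoC = observed DCO / expected DCO` with
`expected = (cM_b/100)(cM_c/100)·N_total`; interference is 1−CoC and its
significance a binomial test of the DCO count against the independence
expectation. The tetrad-based measure stratifies a focal interval's
Perkins cM by the presence of a crossover in the adjacent interval; the
without/with ratio grows with interference, and the contrast is tested by
a two-sided z-test on the cM difference with delta-method SEs (the
original analyses mark significance without naming a test; a z-test on
asymptotically normal estimates is the natural choice). Group differences
in interference are tested by a binomial GLM on DCO counts with an offset
for each replicate's expected DCO proportion — modelling counts rather
than 1−CoC keeps inference in the binomial framework instead of
propagating a ratio of estimates. Fisher's combined probability test
(χ² = −2Σln p, df = 2k) aggregates per-interval contrasts; its helper
returns scipy's exact critical value (39.25 at α = 0.001, df = 16 — older
printed tables round this to 39.26).

## Shared statistics

The recombinant-fraction GLM is Y_i ~ Binomial(n_i, p_i) with
logit(p_i) = Xβ, genotype and optionally replicate as factors, fitted by
IRLS (statsmodels). The genotype effect is a likelihood-ratio test —
preferred over Wald for small replicate groups — with binomial dispersion
fixed at 1 and the Pearson dispersion reported as a diagnostic only.
Separation is reported with a warning and clamped finite coefficients
(|logit| ≤ 15); rank-deficient designs raise with the aliased columns
named. Null calibration was checked by simulation: the empirical type-I
error at α = 0.05 over 10⁴ grouped-binomial null datasets is 0.050.

Chiasmata-count distributions are compared by a chi-square test after
pooling adjacent categories from the distribution tails inward until every
expected cell reaches 5 (merging never joins non-adjacent categories);
marker contingency tables use the Yates-corrected 2×2 chi-square followed
by Benjamini–Hochberg adjustment across the tested markers. This
Yates+BH combination numerically reproduces the published FDR-adjusted
p-values from the printed hot/cold-quartile count tables at the anchor
markers. Track correlation is Spearman's rank over aligned windows with
pairwise deletion of missing windows and optional re-binning (averaging)
to coarser physical scales.

## Association scans

`quartile_association` ranks F2 individuals by measured cM (ties broken by
id for determinism), takes the hottest and coldest ⌊n/4⌋ individuals
(the original quartile rounding rule is unstated; the floor is this
package's choice and is overridable), pools the two homozygous classes,
and tests each marker's HET/HOM split between quartiles. `lod_scan` is a
deliberately simple single-marker regression: LOD = (n/2)·log₁₀(RSS₀/RSS₁)
per marker, with a genome-wide 5% threshold from the (1−α) quantile of the
max-LOD over seeded phenotype permutations. Full interval mapping is out
of scope; marker densities in these designs make single-marker scans
adequate for localisation claims.

## The simulator

Chiasmata are placed on the bivalent along the genetic scale by a
stationary gamma-renewal process: shape ν (ν = 1 is Poisson; larger ν
spaces events more regularly, emulating interference), mean spacing 0.5
Morgan so intensity is 2 chiasmata per Morgan and a chromatid's expected
crossover count across d Morgans is d. The first event comes from the
equilibrium forward-recurrence distribution, sampled by the size-bias
identity (U·Gamma(ν+1, θ)), so interval statistics are
translation-invariant. A fraction `escape_fraction` of events instead
comes from an independent Poisson pathway, emulating the non-interfering
crossover route (so wild-type-like ≈ 0.15 escape, fancm-like ≈ high
escape, and a pure-Poisson ν = 1 control all fit one parameterisation);
defaults are ν = 1 and escape 0 — the neutral, assumption-free setting.
Each chiasma involves one chromatid of each homologue chosen uniformly
and independently (no chromatid interference), and pollen are sampled one
chromatid per meiosis.

Meiotic products are path-traced: each exchange joins the proximal part of
one original strand to the distal part of the other, so a product's
homologue-of-origin toggles at every exchange on its current strand. This
reproduces the classical results exactly: single-chromatid recombinant
fractions follow Haldane's (1−e^(−2d))/2 under ν = 1, tetrad classes
follow the standard PD/NPD/T strand-choice distribution, and gamete-level
CoC equals 1 under Poisson placement.

Physical coordinates map to the genetic scale through a monotone
piecewise-linear map; regional rate modifiers multiply the map density on
bp windows. That is how heterozygosity-dependent rate changes are
emulated in F2 simulations — a descriptive stand-in controlled by the
user-supplied `cis_effect` function, not a mechanistic model of how
polymorphism remodels recombination. No obligate crossover is enforced
and double-strand-break dynamics are not modelled.

`simulate_f2_population` mirrors the experimental design: selfed-F1
gametes, retention only of individuals inheriting an intact reporter
chromosome over a non-transgenic one, marker genotypes from the two
gametes, and per-individual seed counts drawn at the individual's
effective rate (base interval cM × cis_effect of its genotype pattern,
capped at a recombinant fraction of 0.5). Unlinked chromosomes are
simulated without selection and segregate 1:2:1.

**What the generator does not emulate:** obligate crossovers and
chromosome-number constraints, chromatid interference, gene conversion,
segregation distortion, genotyping error, between-plant biological
variance beyond counting noise, and any mechanistic coupling between
polymorphism and recombination (the cis effect is imposed, not emergent).
Passing tests therefore demonstrate that the estimators and scans recover
what this generative model encodes at realistic counts — not that real
data are free of those additional effects.

## Problem sizes and numerical choices

Simulation-based checks use 10⁵ gametes/tetrads per round-trip (matching
the per-plant scale of flow-cytometry scoring), F2 populations of n = 139
with 2,000 seeds per individual (the scale of the largest published F2),
10⁴ null datasets for GLM calibration, and 300–500 phenotype permutations
per LOD threshold with 10–15 replicate populations for
localisation/calibration rates. Null-calibration pass bounds are set from
the binomial distribution of false-positive counts at the nominal level
(flake probability < 1%). All randomness flows from explicit integer
seeds; identical seeds give bit-identical outputs. Reported tables round
cM and SE to 2 dp (matching field conventions) while full precision is
kept internally.

## Known limitations

Gamete-modality estimators report recombinant fractions, which understate
map distance by O(d²) for large intervals (no mapping-function correction
is applied, by design — the published values being matched are likewise
uncorrected); the Perkins estimator undercorrects k ≥ 3 chiasmata; the
seed estimator saturates above 50 cM; `merged_chisq` assumes ordered
categories; the LOD scan is single-marker and does not model interval
positions between markers; and `call_configuration` assumes the reference
r is close to the interval's true rate.
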