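# Methods

## Gaussian ΦID with MMI redundancy

For a region pair (x, y) at lag τ the package estimates the 4×4 sample
covariance of the stacked vector (x<sub>t−τ</sub>, y<sub>t−τ</sub>,
x<sub>t</sub>, y<sub>t</sub>). Under a joint-Gaussian model the mutual
information between coordinate blocks A and B is
½·log(det Σ<sub>A</sub>·det Σ<sub>B</sub>/det Σ<sub>AB</sub>) (nats).

The 16 ΦID atoms live on the product of two redundancy lattices with nodes
{1}{2} ⪯ {1},{2} ⪯ {12} (refinement order: α ⪯ β iff every collection of β
contains some collection of α). Each product node (α→β) is assigned the
cumulative value min over collections a∈α, b∈β of I(a<sub>past</sub>;
b<sub>present</sub>) — the MMI double-redundancy function, with joint MIs
for multi-channel collections. Atoms are recovered by Möbius inversion
(one fixed 16×16 solve). These 16 cumulative values are exactly the nine
pairwise block MIs, the three forward MMI redundancies, the three backward
redundancies, and the double redundancy, so the construction coincides with
the constraint system of the standard Gaussian MMI-ΦID solver. Because the
top node's cumulative value is the TDMI and its down-set is the whole
lattice, the atoms sum to the TDMI identically; the test suite checks this
to 1e−8 relative tolerance and checks all 16 atoms against an independent
brute-force lattice enumeration.

Numerical choices:

- **Lag τ = 1 sample.** A conventional single-TR delay; configurable.
- **Per-window z-scoring** of each series before covariance estimation
  makes atoms invariant to channel scale; configurable off.
- **Regularization.** When the 4×4 covariance has condition number above
  1e12 (e.g. duplicated channels), ε·I is added with ε = 1e−9·trace/4.
  The jitter largely cancels inside MI differences.
- **Clamping.** MIs are clamped at 0 (tiny negative rounding); an MI below
  −1e−7 raises. Negative atoms beyond 1e−6·TDMI are logged, not fatal —
  MMI-ΦID atoms other than rtr are not guaranteed nonnegative.
- Pairs containing a constant (zero-variance) series within a window are
  set to 0 with a warning rather than failing the whole window.

The all-pairs path (`pairwise_phiid`) batches covariance estimation and the
log-determinants across all R(R−1)/2 pairs and is tested for numerical
agreement with the per-pair path.

## Sliding-window rank gradient

Windows of 500 samples with 99% overlap (step = round(500·0.01) = 5).
The window count is n = max(1, ⌊(T − L)/step⌋); with T = 800 this yields
60 windows, matching the session arithmetic the analysis is designed
around (3 runs → 180 columns per subject; 3 subjects → 540 per condition).
The alternative convention ⌊(T−L)/step⌋+1 would give 61; the chosen rule
drops the final 5 samples.

Per window, region strength is the row mean of the rtr (or sts) matrix
excluding the diagonal; strengths are ranked ascending (average ranks on
ties, preserving the exact zero column sum of the gradient), and the
gradient is synergy rank minus redundancy rank, in [−(R−1), R−1].

## Condition statistics

Per region, control and condition gradient samples (windows pooled across
runs and, at group level, subjects) are compared with a two-sided Wilcoxon
rank-sum test. Bonferroni correction multiplies by the number of regions
tested; significance additionally requires |effect size| > 0.8. The effect
size is Cohen's d with pooled SD (sign = condition mean − control mean;
negative = shift toward redundancy); a rank-biserial alternative is
available. α = 0.05. Windows are treated as exchangeable observations
despite the 99% overlap — their strong autocorrelation means nominal p
values are anti-conservative in absolute terms; the Bonferroni + effect
size gate is the operative filter, and the family-wise error measured
under a global null is effectively zero. At the individual level a region
is only reported if it also belongs to the group-level significance mask.

## Structure–function coupling

Redundancy matrices are compared against the structural connectome (SC)
with Spearman's ρ over upper-triangle entries restricted to the SC's
nonzero support (absent tracts carry no comparable weight); synergy is
compared against the Euclidean distance between centroids over the full
upper triangle. Correlations are computed per window, giving coupling
distributions per condition; contrasts reuse the rank-sum machinery with
Bonferroni over the number of contrasts. A time-averaged mode is not the
default because the per-window distributions are what the condition
contrasts consume.

## High-order topology

Redundancy slices are summarized by weighted modularity:
Q = 1/(2m) Σ<sub>ij</sub> [a<sub>ij</sub> − γ·k<sub>i</sub>k<sub>j</sub>/(2m)]·δ(m<sub>i</sub>, m<sub>j</sub>).
Communities come from Louvain optimization (networkx) at resolution γ
(default 1, with a sweep utility over e.g. {0.8, 1.0, 1.2}); the best of
n_restarts = 20 seeded restarts by the γ-quality is kept and Q is evaluated
on that partition by the formula above, so γ = 1 reports plain Newman Q.
Synergy slices are summarized by weighted global efficiency on the
connection-length matrix L = 1/W: E is the mean over nodes of the mean
inverse shortest-path length to the other nodes, with unreachable pairs
contributing zero. Tiny negative matrix entries (MMI numerics) are clamped
to zero with a logged count. Inside the pipeline, topology is evaluated on
every 6th window by default (`topology_stride`): at 99% overlap adjacent
windows are near-duplicates, and community detection is the one step whose
cost is not amortized by vectorization.

## Synthetic data

**Sinusoid toy.** X(t) = sin(10t) + s<sub>x</sub>η, Y(t) = sin(10t + ct²) +
s<sub>y</sub>η on a uniform 1000-point grid over [0, 2π] (the sampling
density is a package choice). c = 0 gives a redundancy-dominated pair,
c = 0.3 a synergy-dominated one, and raising s<sub>y</sub> to 1 drowns both
(the noise-dominated regime keeps s<sub>x</sub> = 0.05).

**Connectome.** Module centers spread in 3D (spacing 40 mm), centroids
scattered around them (SD 8 mm), weights = planted block structure
(between-module base 0.15) × exponential distance decay (length scale
60 mm) × symmetric lognormal variability, thinned to 30% density. This
emulates the modular, distance-dependent, sparse character of
streamline-count connectomes; it does not emulate hemispheric symmetry,
hubs, or realistic degree distributions.

**Hopf whole-brain model.** dz<sub>j</sub> = [(a<sub>j</sub> + iω<sub>j</sub>
− |z<sub>j</sub>|²)z<sub>j</sub> + G Σ<sub>k</sub> C<sub>jk</sub>(z<sub>k</sub>
− z<sub>j</sub>)]dt + β dW<sub>j</sub>, Euler–Maruyama at dt = 0.01, C
max-normalized, 20 steps per output sample, 25% transient discarded, signal
= Re z. Defaults: a = −0.02 (just subcritical, noise-driven oscillations),
ω ~ U(0.4, 0.6) rad/unit-time drawn once per subject (a stable subject
trait, so condition contrasts are within-subject), G = 0.7, β = 0.04 —
a partially synchronized regime: the Kuramoto order parameter
R(t) = |mean e<sup>iθ</sup>| rises monotonically with G while its temporal
SD (metastability) peaks at intermediate coupling. The model generates
oscillatory SC-coupled signals; it does not include hemodynamic
convolution, measurement noise structure, or empirical spectra.

**Stimulation injector.** A condition perturbs k target regions (default:
5 regions of one module for a 140-region study) by shifting their
bifurcation parameter (+0.4: autonomous limit cycle, emulating focal
hyperexcitability) and scaling their structural coupling (×0.3, optionally
restricted to a neighborhood set such as the target's own community).
Designed signatures: the targets' rank-gradient distributions shift,
SC–redundancy coupling drops, and the redundancy network's community
structure weakens.

## What the tests show (and don't)

Passing end-to-end tests show the pipeline recovers a perturbation whose
ground truth is known, under dynamics with the statistical structure the
analysis assumes (SC-coupled Gaussian-ish oscillations). They do not show
sensitivity at empirical effect sizes, robustness to hemodynamics or head
motion, or that real stimulation behaves like the injector.

Scale of the shipped experiments: target-flagging recovery runs at full
study scale (140 regions, 3 subjects × 3 runs × 60 windows = 540 windows
per arm); there it is highly reliable. The *direction* of the global
modularity and coupling changes, however, is only identified when the
perturbed regions are a substantial fraction of their community: a
5-of-140 perturbation alters ~2% of pairwise interactions, and the sign of
the resulting global Q shift depends on the subject/noise realization (an
instability consistent with the per-animal inconsistencies such analyses
report on real data). Direction recovery is therefore demonstrated on a
40-region study where the 5 targets are half of their community; both the
SC–redundancy coupling and redundancy modularity decreases are then
sign-stable across seeds with |d| > 2.

## Known limitations

- MMI is the only redundancy function; discrete-alphabet ΦID and other
  redundancy measures (CCS and relatives) are out of scope.
- Overlapping windows violate the independence assumed by the rank-sum
  test; inference is calibrated by the conservative correction and effect
  size gate, not by an autocorrelation-aware model.
- Louvain is a heuristic; Q values are best-of-restarts lower bounds on
  the optimum. Results are deterministic given the seed.
- The synthetic connectome and Hopf parameterization are plausible, not
  fitted to any empirical dataset.
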