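# synred

Synergy–redundancy rank-gradient analysis of multi-region brain time series,
built on Gaussian integrated information decomposition (ΦID) with the
minimum-mutual-information (MMI) redundancy function.

## The problem

Pairwise correlation summarizes how strongly two brain regions co-fluctuate,
but not *what kind* of information they carry together. Partial information
decomposition splits the mutual information two sources hold about a target
into **redundant** (available from either source alone), **unique**, and
**synergistic** (available only jointly) parts. ΦID applies this forward and
backward in time to the time-delayed mutual information (TDMI) of a bivariate
process X<sub>t</sub> = (X<sup>i</sup><sub>t</sub>, X<sup>j</sup><sub>t</sub>),

I(X<sub>t−τ</sub>; X<sub>t</sub>) = Σ<sub>α→β</sub> atom(α→β),

yielding 16 atoms on the product of two four-node redundancy lattices
𝒜 = {{12}, {1}, {2}, {1}{2}}. Two atoms are the workhorses here:

- **rtr** — persistent redundancy: information redundantly available in the
  past that stays redundant;
- **sts** — persistent synergy: information only the joint past carries
  about the joint present.

Under a joint-Gaussian assumption with MMI redundancy every lattice value is
a closed-form log-determinant expression, so the decomposition of a
time-series pair costs one 4×4 covariance and a fixed 16×16 linear solve.

On parcellated BOLD-like recordings (regions × timepoints), the package:

1. computes rtr and sts for every region pair over sliding windows
   (500 samples, 99% overlap → 60 windows for an 800-sample run);
2. reduces each window's matrices to per-region strengths (row means),
   ranks them, and forms the **synergy-minus-redundancy rank gradient**
   (positive = relatively more synergistic);
3. compares per-region gradient distributions between a control condition
   and each stimulation condition (Wilcoxon rank-sum, Bonferroni over
   regions, |Cohen's d| > 0.8 gate), at group and individual level;
4. quantifies structure–function coupling (Spearman ρ of redundancy vs the
   structural connectome on its nonzero support, and of synergy vs
   Euclidean distance) per window;
5. characterizes high-order topology: weighted modularity Q of the
   redundancy network (Louvain at resolution γ, Q by the Newman formula)
   and weighted global efficiency E of the synergy network.

A Hopf (Stuart–Landau) whole-brain simulator on a modular synthetic
connectome generates every input the pipeline needs, including
stimulation-like focal perturbations and Kuramoto order-parameter
diagnostics, so the full chain is testable end to end.

## Worked example

Two noisy sinusoids, X(t) = sin(10t) + 0.05η and
Y(t) = sin(10t + ct²) + 0.05η sampled on [0, 2π]: at c = 0 the signals are
duplicates (pure redundancy), and increasing the chirp c slides the pair
toward pure synergy.

```python
from synred import SinusoidToyConfig, sinusoid_pair, lagged_covariance, phiid_decompose

for chirp in (0.0, 0.02, 0.3):
    x, y = sinusoid_pair(SinusoidToyConfig(chirp=chirp, seed=0))
    atoms = phiid_decompose(lagged_covariance(x, y, lag=1))
    shares = atoms.normalized()
    print(f"chirp={chirp:<5} TDMI={atoms.tdmi:.3f} nats   "
          f"rtr/TDMI={shares['rtr']:.3f}   sts/TDMI={shares['sts']:.3f}")
```

```
chirp=0.0   TDMI=2.347 nats   rtr/TDMI=0.903   sts/TDMI=0.006
chirp=0.02  TDMI=3.448 nats   rtr/TDMI=0.263   sts/TDMI=0.590
chirp=0.3   TDMI=4.223 nats   rtr/TDMI=0.003   sts/TDMI=0.973
```

TDMI is the pair's total temporal information; the shares show it is almost
entirely persistent redundancy for duplicated signals, mixed at a small
chirp, and almost entirely persistent synergy once the chirp has decohered
the pair.

The full pipeline runs from the shell:

```bash
synred generate --out-dir study/ --regions 140 --samples 800 --seed 0
synred run-all study/manifest.csv --out-dir results/ \
    --sc-weights study/sc_weights.csv --sc-coords study/sc_coords.csv
```

which writes per-condition gradient matrices (140 × 540 at group level),
region comparison tables, coupling and topology window series and
contrasts, and a `run_log.yaml` capturing the full configuration.

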