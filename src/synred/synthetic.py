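"""Synthetic inputs: noisy-sinusoid toy pairs, a modular structural
connectome, a Hopf (Stuart-Landau) whole-brain simulator with Kuramoto
diagnostics, and a stimulation-effect injector.

The Hopf model places each region near a supercritical Hopf bifurcation:

    dz_j = [(a_j + i w_j - |z_j|^2) z_j + G sum_k C_jk (z_k - z_j)] dt
           + beta dW_j

with complex state z_j, bifurcation parameter a_j (a < 0: noise-driven
damped oscillations; a > 0: limit cycle of amplitude sqrt(a)), natural
frequency w_j, global coupling G over the structural connectome C, and
complex white noise of amplitude beta.  The real part of z, downsampled
after a discarded transient, is the BOLD-like signal.  Global synchrony is
tracked by the Kuramoto order parameter R(t) = |mean_j exp(i theta_j)|;
metastability is the temporal standard deviation of R(t).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .coupling import StructuralConnectome

__all__ = [
    "SinusoidToyConfig",
    "HopfConfig",
    "KopSummary",
    "sinusoid_pair",
    "synthetic_connectome",
    "simulate_hopf",
    "inject_condition_effect",
    "generate_study",
]


# --------------------------------------------------------------------------- #
# Sinusoid toy
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class SinusoidToyConfig:
    """Two noisy sinusoids X(t) = sin(10t) + s_x eta, Y(t) = sin(10t + c t^2) + s_y eta.

    The chirp rate c morphs the pair from duplicated (c = 0, redundancy-
    dominated) through partial phase slippage to fully decohered (c = 0.3,
    synergy-dominated); raising the noise SD on Y to 1 drowns both kinds of
    shared information.
    """

    chirp: float = 0.0
    noise_sd_x: float = 0.05
    noise_sd_y: float = 0.05
    n_samples: int = 1000
    t_max: float = 2.0 * np.pi
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 100:
            raise ValueError("n_samples must be >= 100")
        if self.noise_sd_x < 0 or self.noise_sd_y < 0:
            raise ValueError("noise SDs must be nonnegative")


def sinusoid_pair(config: SinusoidToyConfig) -> tuple[np.ndarray, np.ndarray]:
    """Sample the toy pair on a uniform grid over [0, t_max]."""
    rng = np.random.default_rng(config.seed)
    t = np.linspace(0.0, config.t_max, config.n_samples)
    x = np.sin(10.0 * t) + config.noise_sd_x * rng.standard_normal(config.n_samples)
    y = (
        np.sin(10.0 * t + config.chirp * t**2)
        + config.noise_sd_y * rng.standard_normal(config.n_samples)
    )
    return x, y


# --------------------------------------------------------------------------- #
# Synthetic connectome
# --------------------------------------------------------------------------- #


def synthetic_connectome(
    n_regions: int = 140,
    n_modules: int = 4,
    seed: int = 0,
    density: float = 0.3,
    module_spacing: float = 40.0,
    scatter: float = 8.0,
    length_scale: float = 60.0,
    between_weight: float = 0.15,
) -> StructuralConnectome:
    """Modular, distance-dependent streamline-like connectome with centroids.

    Module centers are spread in 3D; region centroids scatter around their
    module center, so within-module Euclidean distances are shorter.
    Weights combine a planted block structure (within-module base 1, between
    ``between_weight``) with exponential distance decay and lognormal
    streamline-count variability, then the weakest entries are removed to
    reach the requested density.
    """
    if n_regions < 2 * n_modules:
        raise ValueError("need at least 2 regions per module")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((n_modules, 3))
    centers *= module_spacing / np.maximum(
        np.linalg.norm(centers, axis=1, keepdims=True), 1e-9
    )
    membership = np.arange(n_regions) % n_modules
    coords = centers[membership] + scatter * rng.standard_normal((n_regions, 3))
    dist = squareform(pdist(coords))
    base = np.where(
        membership[:, None] == membership[None, :], 1.0, between_weight
    )
    noise = rng.lognormal(mean=0.0, sigma=0.5, size=(n_regions, n_regions))
    noise = np.sqrt(noise * noise.T)  # symmetric variability
    w = base * np.exp(-dist / length_scale) * noise
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    if density < 1:
        iu = np.triu_indices(n_regions, k=1)
        vals = w[iu]
        keep = int(round(density * vals.size))
        thresh = np.sort(vals)[::-1][max(keep - 1, 0)]
        w[w < thresh] = 0.0
        np.fill_diagonal(w, 0.0)
    return StructuralConnectome(weights=w, coords=coords)


# --------------------------------------------------------------------------- #
# Hopf whole-brain model
# --------------------------------------------------------------------------- #


@dataclass
class KopSummary:
    """Kuramoto order parameter diagnostics of one simulation."""

    mean_kop: float
    metastability: float


@dataclass
class HopfConfig:
    """Parameters of one Hopf whole-brain simulation.

    a : bifurcation parameter per region (scalar broadcast); default -0.02
        keeps regions just below the bifurcation, producing noise-driven
        oscillations as in resting-state models.
    omega : natural frequencies (rad per unit time); drawn from a narrow
        band around 0.5 when omitted.
    coupling : global coupling G scaling the (max-normalized) connectome.
    noise : additive complex noise amplitude beta.
    dt, steps_per_sample : Euler-Maruyama step and downsampling factor; one
        output sample spans dt * steps_per_sample time units (a TR analogue).
    n_samples : output samples per run after discarding the transient
        (default 800); transient_samples defaults to 25% of n_samples.
    """

    n_regions: int = 140
    sc: StructuralConnectome | None = None
    a: float | np.ndarray = -0.02
    omega: np.ndarray | None = None
    omega_band: tuple[float, float] = (0.4, 0.6)
    coupling: float = 0.7
    noise: float = 0.04
    dt: float = 0.01
    steps_per_sample: int = 20
    n_samples: int = 800
    transient_samples: int | None = None
    seed: int = 0
    blowup_bound: float = 1e6

    def resolved(self) -> "HopfConfig":
        """Fill in SC, frequencies and array-valued a from the seed."""
        cfg = replace(self)
        rng = np.random.default_rng(cfg.seed)
        if cfg.sc is None:
            cfg.sc = synthetic_connectome(cfg.n_regions, seed=cfg.seed)
        if cfg.sc.n_regions != cfg.n_regions:
            raise ValueError("connectome size does not match n_regions")
        if cfg.omega is None:
            lo, hi = cfg.omega_band
            cfg.omega = rng.uniform(lo, hi, size=cfg.n_regions)
        cfg.a = np.broadcast_to(np.asarray(cfg.a, dtype=float), (cfg.n_regions,)).copy()
        if cfg.transient_samples is None:
            cfg.transient_samples = cfg.n_samples // 4
        return cfg


def simulate_hopf(config: HopfConfig) -> tuple[np.ndarray, KopSummary]:
    """Integrate the coupled Stuart-Landau network; return signals and KOP.

    Returns ``(data, kop)`` with data of shape (n_regions, n_samples) — the
    real part of z downsampled after the transient — and Kuramoto
    diagnostics computed from the sampled instantaneous phases.
    """
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)
    N = cfg.n_regions
    C = cfg.sc.weights.copy()
    if C.max() > 0:
        C = C / C.max()
    row_sum = C.sum(axis=1)
    a = np.asarray(cfg.a, dtype=float)
    omega = np.asarray(cfg.omega, dtype=float)
    G = cfg.coupling
    dt = cfg.dt
    sq_dt = np.sqrt(dt)
    total = cfg.n_samples + cfg.transient_samples
    z = 0.1 * (rng.standard_normal(N) + 1j * rng.standard_normal(N))
    out = np.empty((N, total), dtype=complex)
    lin = a + 1j * omega
    with np.errstate(over="ignore", invalid="ignore"):
        for s in range(total):
            for _ in range(cfg.steps_per_sample):
                coupling_term = G * (C @ z - row_sum * z)
                drift = (lin - np.abs(z) ** 2) * z + coupling_term
                noise = cfg.noise * (
                    rng.standard_normal(N) + 1j * rng.standard_normal(N)
                )
                z = z + drift * dt + noise * sq_dt
            zmax = np.max(np.abs(z))
            if not np.isfinite(zmax) or zmax > cfg.blowup_bound:
                raise FloatingPointError(
                    "Hopf integration blew up; use a smaller dt or coupling"
                )
            out[:, s] = z
    kept = out[:, cfg.transient_samples:]
    kop_t = np.abs(np.exp(1j * np.angle(kept)).mean(axis=0))
    kop = KopSummary(
        mean_kop=float(kop_t.mean()), metastability=float(kop_t.std())
    )
    return kept.real.copy(), kop


def inject_condition_effect(
    config: HopfConfig,
    target_regions: np.ndarray | list[int],
    a_shift: float = 0.0,
    coupling_scale: float = 1.0,
    neighborhood: np.ndarray | list[int] | None = None,
) -> HopfConfig:
    """Return a config with a region-localized dynamical perturbation.

    ``a_shift`` is added to the bifurcation parameter of the targets
    (pushing them onto or away from the limit cycle).  ``coupling_scale``
    multiplies the effective coupling of the targets: all their links when
    ``neighborhood`` is None, or only their links into the given region set
    (e.g. the targets' own structural community, emulating a stimulation
    that decouples the target from its community while long-range links
    persist).  Zero shift and unit scale return an equivalent config.
    """
    cfg = config.resolved()
    targets = np.asarray(target_regions, dtype=int)
    if targets.size and (targets.min() < 0 or targets.max() >= cfg.n_regions):
        raise ValueError("target region index out of range")
    a = np.asarray(cfg.a, dtype=float).copy()
    a[targets] += a_shift
    cfg.a = a
    if coupling_scale != 1.0:
        w = cfg.sc.weights.copy()
        if neighborhood is None:
            nb = np.arange(cfg.n_regions)
        else:
            nb = np.asarray(neighborhood, dtype=int)
            if nb.size and (nb.min() < 0 or nb.max() >= cfg.n_regions):
                raise ValueError("neighborhood region index out of range")
        mask = np.zeros((cfg.n_regions, cfg.n_regions), dtype=bool)
        mask[np.ix_(targets, nb)] = True
        mask |= mask.T
        w[mask] *= coupling_scale
        cfg.sc = StructuralConnectome(
            weights=w, coords=cfg.sc.coords, region_labels=cfg.sc.region_labels
        )
    return cfg


# --------------------------------------------------------------------------- #
# Study generation
# --------------------------------------------------------------------------- #


@dataclass
class StudySpec:
    """Layout of a full synthetic study (subjects x conditions x runs).

    Each stimulation condition pushes its target regions onto an autonomous
    limit cycle (``a_shift`` on the bifurcation parameter) while weakening
    their structural coupling (``coupling_scale`` on their links, optionally
    restricted per condition via ``neighborhoods``) — a focal perturbation
    whose designed signatures are a rank-gradient shift at the targets,
    reduced structure-function coupling, and weakened community structure
    in the redundancy network.
    """

    n_subjects: int = 3
    n_runs: int = 3
    conditions: tuple[str, ...] = ("control", "stimA", "stimB")
    targets: dict = field(default_factory=dict)
    neighborhoods: dict = field(default_factory=dict)
    a_shift: float = 0.4
    coupling_scale: float = 0.3


def generate_study(
    base: HopfConfig,
    spec: StudySpec | None = None,
    seed: int = 0,
) -> tuple[dict[tuple[str, str, str], np.ndarray], StructuralConnectome]:
    """Simulate every (subject, condition, run) of a study design.

    All runs share one structural connectome (the empirical analogue uses an
    average connectome); subjects and runs differ in their noise and
    frequency realizations.  Non-control conditions perturb their target
    regions with the spec's a-shift and coupling scale.  Returns a dict
    keyed by (subject, condition, run) plus the connectome.
    """
    spec = spec or StudySpec()
    base = replace(base, seed=seed)
    base = base.resolved()
    if not spec.targets:
        # default: k regions from a single module of the default 4-module
        # connectome (module membership cycles with period 4), emulating a
        # focal stimulation confined to one anatomical community
        per = max(1, base.n_regions // 28)
        stim_conditions = [c for c in spec.conditions if c != "control"]
        spec.targets = {
            c: [i + 4 * j for j in range(per) if i + 4 * j < base.n_regions]
            for i, c in enumerate(stim_conditions)
        }
    runs: dict[tuple[str, str, str], np.ndarray] = {}
    ss = np.random.SeedSequence(seed)
    child = iter(ss.spawn(spec.n_subjects * (1 + len(spec.conditions) * spec.n_runs)))
    for s in range(spec.n_subjects):
        subject = f"m{s + 1}"
        # intrinsic regional frequencies are a stable subject trait: drawn
        # once per subject and shared across that subject's conditions/runs,
        # so condition contrasts are within-subject
        subj_rng = np.random.default_rng(next(child))
        lo, hi = base.omega_band
        subj_omega = subj_rng.uniform(lo, hi, size=base.n_regions)
        for condition in spec.conditions:
            if condition == "control":
                cond_cfg = base
            else:
                cond_cfg = inject_condition_effect(
                    base,
                    spec.targets[condition],
                    a_shift=spec.a_shift,
                    coupling_scale=spec.coupling_scale,
                    neighborhood=spec.neighborhoods.get(condition),
                )
            for r in range(spec.n_runs):
                run_seed = int(next(child).generate_state(1)[0] % (2**31))
                cfg = replace(cond_cfg, seed=run_seed, omega=subj_omega.copy())
                data, _ = simulate_hopf(cfg)
                runs[(subject, condition, f"r{r + 1}")] = data
    return runs, base.sc
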