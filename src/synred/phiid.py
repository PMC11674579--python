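"""Gaussian integrated information decomposition (PhiID) with MMI redundancy.

The time-delayed mutual information (TDMI) of a bivariate stochastic process
``(X^i, X^j)`` — the information the pair's past carries about its present —
is decomposed into 16 "atoms" on the product of two partial-information
lattices, one for the past sources and one for the present targets.  Each
lattice has four nodes: redundancy ``{1}{2}``, the two unique nodes ``{1}``
and ``{2}``, and synergy ``{12}``.  Under the minimum-mutual-information
(MMI) redundancy function and a joint-Gaussian assumption every lattice
value has a closed form, so the decomposition reduces to a handful of log
determinants and one fixed 16x16 linear solve (Moebius inversion).

Two atoms are of primary scientific interest downstream:

* ``rtr`` — persistent redundancy: information carried redundantly by either
  channel in the past that remains redundant in the present.
* ``sts`` — persistent synergy: information only the joint past carries
  about the joint present.

All quantities are in nats.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PidLattice",
    "LaggedGaussianModel",
    "PhiIDAtoms",
    "DegenerateInputError",
    "ATOM_NAMES",
    "lagged_covariance",
    "gaussian_mi",
    "double_redundancy_mmi",
    "phiid_decompose",
    "pairwise_phiid",
]

# Condition number above which a small diagonal jitter is applied.
_COND_LIMIT = 1e12
# Relative jitter magnitude: eps = _JITTER_SCALE * trace / 4.
_JITTER_SCALE = 1e-9
# Moebius-inversion residual tolerance (relative to TDMI).
_RESIDUAL_RTOL = 1e-8


class DegenerateInputError(ValueError):
    """Raised when an input is too degenerate to analyse (e.g. constant series)."""


# --------------------------------------------------------------------------- #
# Lattice machinery
# --------------------------------------------------------------------------- #

# Source collections are frozensets of channel indices; a lattice node is a
# tuple of collections (an antichain under set inclusion).
_C1 = frozenset({0})
_C2 = frozenset({1})
_C12 = frozenset({0, 1})

_RED = (_C1, _C2)   # {1}{2}
_UN1 = (_C1,)       # {1}
_UN2 = (_C2,)       # {2}
_SYN = (_C12,)      # {12}

_NODE_CHARS = {_RED: "r", _UN1: "x", _UN2: "y", _SYN: "s"}


def _node_below(alpha, beta) -> bool:
    """Single-lattice order: alpha <= beta iff every collection of beta
    contains some collection of alpha (redundancy at the bottom)."""
    return all(any(a <= b for a in alpha) for b in beta)


@dataclass(frozen=True)
class PidLattice:
    """The four-node redundancy lattice of two sources.

    Nodes are ordered bottom-up: ``{1}{2}`` (Red), ``{1}``, ``{2}``, ``{12}``
    (Syn).  ``below(a, b)`` evaluates the refinement partial order.
    """

    nodes: tuple = (_RED, _UN1, _UN2, _SYN)
    labels: tuple = ("Red", "Unique1", "Unique2", "Syn")

    def below(self, alpha, beta) -> bool:
        return _node_below(alpha, beta)

    @property
    def bottom(self):
        return self.nodes[0]

    @property
    def top(self):
        return self.nodes[-1]


_LATTICE = PidLattice()

# Product-lattice nodes in a fixed order; names follow the 'AtB' convention
# (r = redundancy, x/y = unique, s = synergy), e.g. 'rts' = redundancy in the
# past that becomes synergy in the present.
_PRODUCT_NODES = tuple(itertools.product(_LATTICE.nodes, _LATTICE.nodes))
ATOM_NAMES = tuple(
    f"{_NODE_CHARS[a]}t{_NODE_CHARS[b]}" for a, b in _PRODUCT_NODES
)


def _build_zeta() -> np.ndarray:
    """Zeta matrix of the product order: Z[i, j] = 1 iff node_j <= node_i."""
    n = len(_PRODUCT_NODES)
    z = np.zeros((n, n))
    for i, (a2, b2) in enumerate(_PRODUCT_NODES):
        for j, (a1, b1) in enumerate(_PRODUCT_NODES):
            if _node_below(a1, a2) and _node_below(b1, b2):
                z[i, j] = 1.0
    return z


_ZETA = _build_zeta()
_ZETA_INV = np.linalg.inv(_ZETA)

# For each product node, the list of (past-index-tuple, present-index-tuple)
# over which the MMI minimum is taken.  Stacked-coordinate convention:
# 0 = x_{t-lag}, 1 = y_{t-lag}, 2 = x_t, 3 = y_t.
_PAST_IDX = {_C1: (0,), _C2: (1,), _C12: (0, 1)}
_PRES_IDX = {_C1: (2,), _C2: (3,), _C12: (2, 3)}

_MIN_TERMS = tuple(
    tuple((_PAST_IDX[a], _PRES_IDX[b]) for a in alpha for b in beta)
    for alpha, beta in _PRODUCT_NODES
)


# --------------------------------------------------------------------------- #
# Covariance estimation
# --------------------------------------------------------------------------- #


@dataclass
class LaggedGaussianModel:
    """Sample second moments of ``(x_{t-lag}, y_{t-lag}, x_t, y_t)``.

    Attributes
    ----------
    lag : int
        Delay in samples between past and present.
    cov : (4, 4) ndarray
        Symmetric covariance of the stacked vector, regularized if needed.
    n_samples : int
        Number of lagged observations the covariance was estimated from.
    condition_number : float
        Condition number of the raw covariance before any regularization.
    """

    lag: int
    cov: np.ndarray
    n_samples: int
    condition_number: float = np.nan

    def __post_init__(self):
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (4, 4):
            raise ValueError(f"cov must be 4x4, got {self.cov.shape}")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("cov must be symmetric")


def _regularize(cov: np.ndarray) -> tuple[np.ndarray, float]:
    """Add diagonal jitter when the covariance is numerically singular."""
    eig = np.linalg.eigvalsh(cov)
    lo, hi = eig[0], eig[-1]
    cond = np.inf if lo <= 0 else hi / lo
    if cond > _COND_LIMIT:
        eps = _JITTER_SCALE * np.trace(cov) / 4.0
        cov = cov + eps * np.eye(cov.shape[0])
        logger.debug("covariance jittered (cond=%.3g, eps=%.3g)", cond, eps)
    return cov, cond


def lagged_covariance(
    x: np.ndarray,
    y: np.ndarray,
    lag: int = 1,
    standardize: bool = True,
) -> LaggedGaussianModel:
    """Estimate the 4x4 covariance of ``(x_{t-lag}, y_{t-lag}, x_t, y_t)``.

    Parameters
    ----------
    x, y : 1-d arrays of equal length T > 4 * lag.
    lag : positive delay in samples.
    standardize : z-score each series before estimation, making downstream
        information atoms invariant to channel scale.

    Raises
    ------
    DegenerateInputError
        If either series is constant.
    ValueError
        On length mismatch, non-finite values, or too-short series.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"series length mismatch: {x.size} vs {y.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("series contain non-finite values")
    if lag < 1:
        raise ValueError("lag must be >= 1")
    T = x.size
    if T <= 4 * lag:
        raise ValueError(f"need T > 4*lag, got T={T}, lag={lag}")
    for name, s in (("x", x), ("y", y)):
        if np.std(s) == 0:
            raise DegenerateInputError(f"series {name!r} is constant")
    if standardize:
        x = (x - x.mean()) / x.std()
        y = (y - y.mean()) / y.std()
    stacked = np.vstack([x[:-lag], y[:-lag], x[lag:], y[lag:]])
    cov = np.cov(stacked)
    cov, cond = _regularize(cov)
    return LaggedGaussianModel(
        lag=lag, cov=cov, n_samples=T - lag, condition_number=cond
    )


# --------------------------------------------------------------------------- #
# Gaussian mutual information and MMI redundancy
# --------------------------------------------------------------------------- #


def _logdet(cov: np.ndarray, idx) -> float:
    sub = cov[np.ix_(idx, idx)]
    sign, ld = np.linalg.slogdet(sub)
    if sign <= 0:
        raise np.linalg.LinAlgError(
            f"covariance block {tuple(idx)} is not positive definite"
        )
    return ld


def gaussian_mi(model: LaggedGaussianModel | np.ndarray, source_idx, target_idx) -> float:
    """Closed-form Gaussian mutual information between two coordinate blocks.

    ``I(A; B) = 0.5 * log(det S_A * det S_B / det S_AB)`` in nats.  Small
    negative rounding errors are clamped to zero.
    """
    cov = model.cov if isinstance(model, LaggedGaussianModel) else np.asarray(model)
    a = tuple(source_idx)
    b = tuple(target_idx)
    if set(a) & set(b):
        raise ValueError("source and target index sets must be disjoint")
    try:
        mi = 0.5 * (_logdet(cov, a) + _logdet(cov, b) - _logdet(cov, a + b))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular block for MI({a}; {b}): {exc}"
        ) from exc
    if mi < -1e-7:
        raise np.linalg.LinAlgError(
            f"negative MI {mi:.3g} for blocks ({a}; {b}) — covariance invalid"
        )
    return max(mi, 0.0)


def double_redundancy_mmi(model: LaggedGaussianModel) -> float:
    """MMI double redundancy: the minimum over the four single-channel
    past-to-present mutual informations."""
    mis = [
        gaussian_mi(model, (a,), (b,))
        for a in (0, 1)
        for b in (2, 3)
    ]
    return min(mis)


# --------------------------------------------------------------------------- #
# Full decomposition
# --------------------------------------------------------------------------- #


@dataclass
class PhiIDAtoms:
    """The 16 PhiID atoms of one ordered region pair at one lag.

    ``atoms`` maps atom names ('rtr', 'rtx', ..., 'sts') to values in nats.
    ``tdmi`` is the time-delayed mutual information the atoms sum to.
    """

    atoms: dict = field(default_factory=dict)
    tdmi: float = 0.0

    @property
    def rtr(self) -> float:
        """Persistent redundancy."""
        return self.atoms["rtr"]

    @property
    def sts(self) -> float:
        """Persistent synergy."""
        return self.atoms["sts"]

    def normalized(self) -> dict:
        """Atoms divided by TDMI (dimensionless shares), or zeros if TDMI ~ 0."""
        if self.tdmi < 1e-12:
            return {k: 0.0 for k in self.atoms}
        return {k: v / self.tdmi for k, v in self.atoms.items()}


def phiid_decompose(
    model: LaggedGaussianModel, lattice: PidLattice = _LATTICE
) -> PhiIDAtoms:
    """Decompose the pair's TDMI into the 16 PhiID atoms (MMI redundancy).

    Each product-lattice node ``alpha -> beta`` receives the cumulative value
    ``min I(a_past; b_present)`` over collections ``a`` in alpha, ``b`` in
    beta (joint Gaussian MIs for multi-channel collections); atoms are then
    recovered by Moebius inversion over the product partial order.  The atoms
    sum to the TDMI exactly by construction of the zeta matrix.
    """
    cums = np.empty(len(_PRODUCT_NODES))
    mi_cache: dict = {}
    for k, terms in enumerate(_MIN_TERMS):
        vals = []
        for a_idx, b_idx in terms:
            key = (a_idx, b_idx)
            if key not in mi_cache:
                mi_cache[key] = gaussian_mi(model, a_idx, b_idx)
            vals.append(mi_cache[key])
        cums[k] = min(vals)
    atoms = _ZETA_INV @ cums
    tdmi = mi_cache[((0, 1), (2, 3))]
    residual = np.max(np.abs(_ZETA @ atoms - cums))
    if residual > _RESIDUAL_RTOL * max(tdmi, 1.0):
        raise np.linalg.LinAlgError(
            f"Moebius inversion residual {residual:.3g} exceeds tolerance"
        )
    neg = atoms.min()
    if neg < -1e-6 * max(tdmi, 1e-12):
        logger.info("negative PhiID atom of magnitude %.3g (tdmi=%.3g)", -neg, tdmi)
    return PhiIDAtoms(atoms=dict(zip(ATOM_NAMES, atoms)), tdmi=tdmi)


# --------------------------------------------------------------------------- #
# Vectorized all-pairs decomposition
# --------------------------------------------------------------------------- #

# Index blocks whose log-determinants feed the nine past->present MIs.
_BLOCKS = [
    (0,), (1,), (2,), (3,),
    (0, 1), (2, 3),
    (0, 2), (0, 3), (1, 2), (1, 3),
    (0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3),
    (0, 1, 2, 3),
]
_BLOCK_POS = {b: i for i, b in enumerate(_BLOCKS)}


def _batch_logdet(cov: np.ndarray, idx: tuple) -> np.ndarray:
    sub = cov[:, idx, :][:, :, idx]
    sign, ld = np.linalg.slogdet(sub)
    bad = sign <= 0
    if bad.any():
        ld = np.where(bad, -np.inf, ld)
    return ld


def pairwise_phiid(
    data: np.ndarray,
    lag: int = 1,
    standardize: bool = True,
) -> dict[str, np.ndarray]:
    """PhiID atoms for every unordered region pair of a (R, T) data matrix.

    Returns a dict with symmetric zero-diagonal (R, R) matrices under keys
    ``'rtr'``, ``'sts'`` and ``'tdmi'``.  rtr and sts are symmetric in the
    channel order by the MMI construction, so each unordered pair is computed
    once.  Pairs involving a constant (zero-variance) region are set to 0
    with a warning.

    This is numerically equivalent to calling :func:`lagged_covariance` +
    :func:`phiid_decompose` per pair, but batches the covariance estimation
    and log-determinants across all R*(R-1)/2 pairs.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be (regions, timepoints)")
    R, T = data.shape
    if R < 2:
        raise ValueError("need at least 2 regions")
    if T <= 4 * lag:
        raise ValueError(f"need T > 4*lag, got T={T}, lag={lag}")

    sd = data.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant region(s); their pairs set to 0",
            RuntimeWarning,
        )
    if standardize:
        safe_sd = np.where(degenerate, 1.0, sd)
        data = (data - data.mean(axis=1, keepdims=True)) / safe_sd[:, None]

    past = data[:, :-lag]
    pres = data[:, lag:]
    n = T - lag
    past = past - past.mean(axis=1, keepdims=True)
    pres = pres - pres.mean(axis=1, keepdims=True)
    denom = n - 1
    c_mm = past @ past.T / denom
    c_mp = past @ pres.T / denom
    c_pp = pres @ pres.T / denom

    iu, ju = np.triu_indices(R, k=1)
    P = iu.size
    cov = np.empty((P, 4, 4))
    # Stacked order: (x_i past, x_j past, x_i present, x_j present).
    cov[:, 0, 0] = c_mm[iu, iu]
    cov[:, 1, 1] = c_mm[ju, ju]
    cov[:, 2, 2] = c_pp[iu, iu]
    cov[:, 3, 3] = c_pp[ju, ju]
    cov[:, 0, 1] = cov[:, 1, 0] = c_mm[iu, ju]
    cov[:, 2, 3] = cov[:, 3, 2] = c_pp[iu, ju]
    cov[:, 0, 2] = cov[:, 2, 0] = c_mp[iu, iu]
    cov[:, 0, 3] = cov[:, 3, 0] = c_mp[iu, ju]
    cov[:, 1, 2] = cov[:, 2, 1] = c_mp[ju, iu]
    cov[:, 1, 3] = cov[:, 3, 1] = c_mp[ju, ju]

    # Jitter ill-conditioned pair covariances (duplicated or collinear series).
    eig = np.linalg.eigvalsh(cov)
    cond = np.where(eig[:, 0] > 0, eig[:, -1] / np.maximum(eig[:, 0], 1e-300), np.inf)
    ill = cond > _COND_LIMIT
    if ill.any():
        eps = _JITTER_SCALE * np.trace(cov[ill], axis1=1, axis2=2) / 4.0
        cov[ill] += eps[:, None, None] * np.eye(4)

    logdets = np.stack([_batch_logdet(cov, b) for b in _BLOCKS], axis=1)

    def mi(a: tuple, b: tuple) -> np.ndarray:
        v = 0.5 * (
            logdets[:, _BLOCK_POS[a]]
            + logdets[:, _BLOCK_POS[b]]
            - logdets[:, _BLOCK_POS[tuple(sorted(a + b))]]
        )
        return np.maximum(v, 0.0)

    mis = {
        (a, b): mi(a, b)
        for a in ((0,), (1,), (0, 1))
        for b in ((2,), (3,), (2, 3))
    }
    cums = np.empty((P, len(_PRODUCT_NODES)))
    for k, terms in enumerate(_MIN_TERMS):
        cums[:, k] = np.min(np.stack([mis[t] for t in terms], axis=1), axis=1)
    atoms = cums @ _ZETA_INV.T
    tdmi = mis[((0, 1), (2, 3))]

    bad = ~np.isfinite(atoms).all(axis=1)
    pair_degenerate = degenerate[iu] | degenerate[ju] | bad

    out = {}
    for key, vec in (
        ("rtr", atoms[:, ATOM_NAMES.index("rtr")]),
        ("sts", atoms[:, ATOM_NAMES.index("sts")]),
        ("tdmi", tdmi),
    ):
        vec = np.where(pair_degenerate, 0.0, vec)
        m = np.zeros((R, R))
        m[iu, ju] = vec
        m[ju, iu] = vec
        out[key] = m
    return out
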