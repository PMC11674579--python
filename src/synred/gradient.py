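"""Sliding-window synergy-minus-redundancy rank gradient.

For each window of a run, persistent redundancy (rtr) and persistent synergy
(sts) are computed for every region pair, reduced to per-region strengths
(row means), ranked, and differenced: positive gradient values mark regions
that are relatively more synergistic than redundant in that window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .phiid import pairwise_phiid

__all__ = [
    "WindowSpec",
    "WindowedHighOrderMatrices",
    "RankGradientMatrix",
    "make_windows",
    "window_matrices",
    "rank_gradient",
    "concatenate_gradients",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry.

    length : window size in samples (default 500)
    overlap_fraction : fractional overlap of consecutive windows (default 0.99)
    """

    length: int = 500
    overlap_fraction: float = 0.99

    def __post_init__(self):
        if self.length < 2:
            raise ValueError("window length must be >= 2")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.step < 1:
            raise ValueError("window step must be >= 1")

    @property
    def step(self) -> int:
        return int(round(self.length * (1.0 - self.overlap_fraction)))

    def n_windows(self, T: int) -> int:
        if T < self.length:
            raise ValueError(f"run length {T} shorter than window length {self.length}")
        return max(1, (T - self.length) // self.step)


def make_windows(T: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open [start, end) window bounds: starts 0, step, 2*step, ...

    The window count is ``max(1, floor((T - length) / step))``; with an
    800-sample run, 500-sample windows and 99% overlap (step 5) this yields
    60 windows, the count used throughout the analysis.
    """
    n = spec.n_windows(T)
    return [(k * spec.step, k * spec.step + spec.length) for k in range(n)]


@dataclass
class WindowedHighOrderMatrices:
    """Per-window pairwise redundancy and synergy matrices for one run.

    redundancy, synergy : (n_windows, R, R) symmetric, zero diagonal.
    """

    redundancy: np.ndarray
    synergy: np.ndarray
    region_labels: list[str]
    windows: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.redundancy.shape != self.synergy.shape:
            raise ValueError("redundancy/synergy shape mismatch")
        if self.redundancy.shape[1] != len(self.region_labels):
            raise ValueError("region label count does not match matrices")

    @property
    def n_windows(self) -> int:
        return self.redundancy.shape[0]

    @property
    def n_regions(self) -> int:
        return self.redundancy.shape[1]


def window_matrices(
    data: np.ndarray,
    spec: WindowSpec,
    region_labels: list[str] | None = None,
    lag: int = 1,
    standardize: bool = True,
) -> WindowedHighOrderMatrices:
    """Pairwise PhiID matrices over every sliding window of a (R, T) run.

    Each window's series are truncated to the window and (by default)
    z-scored within it before covariance estimation.  rtr and sts are
    symmetric in channel order, so the matrices are symmetric by
    construction; constant-region pairs inside a window are zeroed with a
    warning (see :func:`synred.phiid.pairwise_phiid`).
    """
    data = np.asarray(data, dtype=float)
    R, T = data.shape
    if R < 2:
        raise ValueError("need at least 2 regions")
    if region_labels is None:
        region_labels = [f"R{i:03d}" for i in range(R)]
    wins = make_windows(T, spec)
    red = np.empty((len(wins), R, R))
    syn = np.empty((len(wins), R, R))
    for w, (a, b) in enumerate(wins):
        mats = pairwise_phiid(data[:, a:b], lag=lag, standardize=standardize)
        red[w] = mats["rtr"]
        syn[w] = mats["sts"]
    return WindowedHighOrderMatrices(
        redundancy=red, synergy=syn, region_labels=list(region_labels), windows=wins
    )


@dataclass
class RankGradientMatrix:
    """Regions x windows matrix of synergy-rank minus redundancy-rank.

    Every column is the difference of two rank permutations of 1..R
    (average ranks on ties), so each column sums to zero and entries lie in
    [-(R-1), R-1].  ``provenance`` carries one (subject, condition, run,
    window) row per column.
    """

    values: np.ndarray
    region_labels: list[str]
    provenance: pd.DataFrame

    def __post_init__(self):
        if self.values.shape[0] != len(self.region_labels):
            raise ValueError("row count does not match region labels")
        if self.values.shape[1] != len(self.provenance):
            raise ValueError("column count does not match provenance rows")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [
            f"{r.subject}|{r.condition}|{r.run}|w{r.window}"
            for r in self.provenance.itertuples()
        ]
        return pd.DataFrame(self.values, index=self.region_labels, columns=cols)


def _strengths(mats: np.ndarray) -> np.ndarray:
    """Row means excluding the diagonal: (W, R, R) -> (W, R)."""
    R = mats.shape[1]
    return (mats.sum(axis=2) - np.diagonal(mats, axis1=1, axis2=2)) / (R - 1)


def rank_gradient(
    matrices: WindowedHighOrderMatrices,
    subject: str = "s1",
    condition: str = "cond",
    run: str = "r1",
) -> RankGradientMatrix:
    """Synergy-rank minus redundancy-rank per region, one column per window.

    Strengths are ranked ascending (1 = weakest participation); ties receive
    average ranks, which preserves the zero column sum exactly.
    """
    red_s = _strengths(matrices.redundancy)
    syn_s = _strengths(matrices.synergy)
    red_rank = rankdata(red_s, axis=1)
    syn_rank = rankdata(syn_s, axis=1)
    values = (syn_rank - red_rank).T  # regions x windows
    prov = pd.DataFrame(
        {
            "subject": subject,
            "condition": condition,
            "run": run,
            "window": np.arange(values.shape[1]),
        }
    )
    return RankGradientMatrix(
        values=values, region_labels=matrices.region_labels, provenance=prov
    )


def concatenate_gradients(gradients: list[RankGradientMatrix]) -> RankGradientMatrix:
    """Stack gradient columns run-major across runs (and subjects).

    All inputs must share region labels in the same order.  For one subject
    and condition, 3 runs x 60 windows gives a regions x 180 matrix; pooling
    3 subjects gives regions x 540.
    """
    if not gradients:
        raise ValueError("no gradients to concatenate")
    labels = gradients[0].region_labels
    for g in gradients[1:]:
        if g.region_labels != labels:
            bad = sorted(set(g.region_labels) ^ set(labels))
            raise ValueError(f"region label mismatch: {bad[:10]}")
    values = np.concatenate([g.values for g in gradients], axis=1)
    prov = pd.concat([g.provenance for g in gradients], ignore_index=True)
    return RankGradientMatrix(values=values, region_labels=list(labels), provenance=prov)
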