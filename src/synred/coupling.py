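"""Structure-function coupling of high-order interaction matrices.

Redundancy matrices are compared with the structural connectome (SC) over
the SC's nonzero entries, and synergy matrices with the Euclidean distance
(ED) between region centroids over the full upper triangle, using
Spearman's rank correlation per window.  Coupling distributions across
windows are contrasted between conditions with the same rank-sum /
Bonferroni / effect-size machinery used for the rank gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy.stats import spearmanr

from .gradient import WindowedHighOrderMatrices
from .stats import (
    DEFAULT_ALPHA,
    DEFAULT_ES_THRESHOLD,
    RegionComparison,
    compare_region,
)

__all__ = [
    "StructuralConnectome",
    "CouplingSeries",
    "coupling_correlation",
    "coupling_series",
    "coupling_by_condition",
]


@dataclass
class StructuralConnectome:
    """Nonnegative symmetric streamline-weight matrix plus region centroids."""

    weights: np.ndarray
    coords: np.ndarray
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        np.fill_diagonal(w, 0.0)
        self.weights = w
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (w.shape[0], 3):
            raise ValueError(f"coords must be ({w.shape[0]}, 3), got {c.shape}")
        self.coords = c
        if not self.region_labels:
            self.region_labels = [f"R{i:03d}" for i in range(w.shape[0])]

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def euclidean_distance(self) -> np.ndarray:
        return squareform(pdist(self.coords))


@dataclass
class CouplingSeries:
    """Per-window Spearman rho for one (structure, function) pair."""

    rho: np.ndarray
    structure: str  # 'SC' | 'ED'
    function: str   # 'redundancy' | 'synergy'
    condition: str = ""
    subject: str = ""


def coupling_correlation(
    func_matrix: np.ndarray,
    structure: StructuralConnectome,
    structure_kind: str = "SC",
) -> float:
    """Spearman correlation between a functional matrix and structure.

    For SC the correlation is restricted to upper-triangle positions with a
    nonzero structural weight (the SC is sparse; absent tracts carry no
    comparable weight).  For ED the full upper triangle is used.
    """
    func_matrix = np.asarray(func_matrix, dtype=float)
    R = structure.n_regions
    if func_matrix.shape != (R, R):
        raise ValueError("functional matrix size does not match connectome")
    iu = np.triu_indices(R, k=1)
    if structure_kind == "SC":
        sv = structure.weights[iu]
        keep = sv > 0
        sv = sv[keep]
        fv = func_matrix[iu][keep]
    elif structure_kind == "ED":
        sv = structure.euclidean_distance[iu]
        fv = func_matrix[iu]
    else:
        raise ValueError("structure_kind must be 'SC' or 'ED'")
    if sv.size < 3:
        raise ValueError(f"fewer than 3 valid entries for {structure_kind} coupling")
    return float(spearmanr(sv, fv).statistic)


def coupling_series(
    matrices: WindowedHighOrderMatrices,
    structure: StructuralConnectome,
    structure_kind: str = "SC",
    function: str = "redundancy",
    condition: str = "",
    subject: str = "",
) -> CouplingSeries:
    """Per-window coupling correlations for one run's windowed matrices."""
    stack = matrices.redundancy if function == "redundancy" else matrices.synergy
    rho = np.array(
        [coupling_correlation(stack[w], structure, structure_kind)
         for w in range(matrices.n_windows)]
    )
    return CouplingSeries(
        rho=rho, structure=structure_kind, function=function,
        condition=condition, subject=subject,
    )


def coupling_by_condition(
    per_condition: dict[str, list[WindowedHighOrderMatrices]],
    structure: StructuralConnectome,
    control: str,
    pairs: tuple[tuple[str, str], ...] = (("SC", "redundancy"), ("ED", "synergy")),
    alpha: float = DEFAULT_ALPHA,
    es_threshold: float = DEFAULT_ES_THRESHOLD,
) -> tuple[pd.DataFrame, list[RegionComparison]]:
    """Coupling distributions per condition plus condition-vs-control contrasts.

    Returns a long-format table of per-window rho values and one rank-sum
    contrast per (pair, condition) against the control, Bonferroni-corrected
    over the number of contrasts performed.
    """
    if control not in per_condition:
        raise ValueError(f"control condition {control!r} missing")
    rows = []
    pooled: dict[tuple[str, str, str], list[np.ndarray]] = {}
    for cond, runs in per_condition.items():
        for run_idx, whm in enumerate(runs):
            for structure_kind, function in pairs:
                cs = coupling_series(whm, structure, structure_kind, function, cond)
                pooled.setdefault((structure_kind, function, cond), []).append(cs.rho)
                for w, r in enumerate(cs.rho):
                    rows.append(
                        {
                            "condition": cond,
                            "run": run_idx,
                            "window": w,
                            "structure": structure_kind,
                            "function": function,
                            "rho": r,
                        }
                    )
    table = pd.DataFrame(rows)
    conditions = [c for c in per_condition if c != control]
    n_contrasts = len(conditions) * len(pairs)
    contrasts = []
    for structure_kind, function in pairs:
        ctrl = np.concatenate(pooled[(structure_kind, function, control)])
        if ctrl.size < 2:
            raise ValueError("need at least 2 control windows for a contrast")
        for cond in conditions:
            sample = np.concatenate(pooled[(structure_kind, function, cond)])
            if sample.size < 2:
                raise ValueError(f"need at least 2 windows in {cond!r} for a contrast")
            cmp = compare_region(
                ctrl,
                sample,
                region=f"{structure_kind}-{function}:{cond}",
                n_tests=n_contrasts,
                alpha=alpha,
                es_threshold=es_threshold,
            )
            contrasts.append(cmp)
    return table, contrasts
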