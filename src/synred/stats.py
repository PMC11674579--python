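"""Per-region condition-versus-control comparisons of rank-gradient values.

Each region's distribution of gradient values over windows is compared
between control and a stimulation condition with a two-sided Wilcoxon
rank-sum test, Bonferroni-corrected over regions, and gated by an absolute
effect size (Cohen's d with pooled SD) above a threshold.  Negative effect
sizes mark a shift toward redundancy, positive toward synergy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .phiid import DegenerateInputError

__all__ = ["RegionComparison", "compare_region", "compare_all", "comparisons_frame"]

DEFAULT_ALPHA = 0.05
DEFAULT_ES_THRESHOLD = 0.8


@dataclass
class RegionComparison:
    """Outcome of one region's condition-vs-control comparison."""

    region: str
    statistic: float
    p_raw: float
    p_bonferroni: float
    effect_size: float
    significant: bool
    direction: str  # 'synergistic-shift' | 'redundant-shift' | 'none'


def cohens_d(control: np.ndarray, condition: np.ndarray) -> float:
    """Cohen's d with pooled SD; sign is mean(condition) - mean(control)."""
    n1, n2 = control.size, condition.size
    v1 = control.var(ddof=1) if n1 > 1 else 0.0
    v2 = condition.var(ddof=1) if n2 > 1 else 0.0
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if pooled <= 0:
        raise DegenerateInputError("zero pooled variance: effect size undefined")
    return (condition.mean() - control.mean()) / np.sqrt(pooled)


def rank_biserial(control: np.ndarray, condition: np.ndarray) -> float:
    """Rank-biserial correlation, an ordinal alternative effect size."""
    u = sps.mannwhitneyu(condition, control, alternative="two-sided").statistic
    return 2.0 * u / (control.size * condition.size) - 1.0


def compare_region(
    control: np.ndarray,
    condition: np.ndarray,
    region: str = "",
    n_tests: int = 1,
    alpha: float = DEFAULT_ALPHA,
    es_threshold: float = DEFAULT_ES_THRESHOLD,
    effect: str = "cohen_d",
) -> RegionComparison:
    """Wilcoxon rank-sum comparison of one region's two gradient samples.

    ``n_tests`` is the Bonferroni family size (number of regions tested).
    Significance requires both the corrected p below ``alpha`` and the
    absolute effect size above ``es_threshold``.
    """
    control = np.asarray(control, dtype=float).ravel()
    condition = np.asarray(condition, dtype=float).ravel()
    if control.size < 2 or condition.size < 2:
        raise ValueError("need at least 2 observations per sample")
    res = sps.ranksums(condition, control)
    if effect == "cohen_d":
        es = cohens_d(control, condition)
    elif effect == "rank_biserial":
        es = rank_biserial(control, condition)
    else:
        raise ValueError(f"unknown effect size estimator {effect!r}")
    p_bonf = min(1.0, res.pvalue * n_tests)
    significant = bool(p_bonf < alpha and abs(es) > es_threshold)
    if not significant or es == 0:
        direction = "none"
    else:
        direction = "synergistic-shift" if es > 0 else "redundant-shift"
    return RegionComparison(
        region=region,
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        p_bonferroni=float(p_bonf),
        effect_size=float(es),
        significant=significant,
        direction=direction,
    )


def compare_all(
    control: np.ndarray,
    condition: np.ndarray,
    region_labels: list[str],
    level: str = "group",
    group_mask: set[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    es_threshold: float = DEFAULT_ES_THRESHOLD,
    effect: str = "cohen_d",
) -> list[RegionComparison]:
    """Region-wise comparisons of two regions x windows gradient matrices.

    At ``level='individual'`` a region is significant only if it also
    belongs to ``group_mask``, the set of regions flagged at group level —
    individual results are read as confirmations of the group finding.
    The Bonferroni family size is the number of regions tested.
    """
    control = np.asarray(control, dtype=float)
    condition = np.asarray(condition, dtype=float)
    R = len(region_labels)
    if control.shape[0] != R or condition.shape[0] != R:
        raise ValueError("matrix row count does not match region labels")
    if level not in ("group", "individual"):
        raise ValueError("level must be 'group' or 'individual'")
    if level == "individual":
        if group_mask is None:
            raise ValueError("individual-level comparison requires a group mask")
        unknown = set(group_mask) - set(region_labels)
        if unknown:
            raise ValueError(f"group mask references unknown regions: {sorted(unknown)}")
    out = []
    for i, label in enumerate(region_labels):
        cmp = compare_region(
            control[i],
            condition[i],
            region=label,
            n_tests=R,
            alpha=alpha,
            es_threshold=es_threshold,
            effect=effect,
        )
        if level == "individual" and label not in group_mask:
            cmp.significant = False
            cmp.direction = "none"
        out.append(cmp)
    return out


def comparisons_frame(comparisons: list[RegionComparison]) -> pd.DataFrame:
    """Tabulate comparisons as a DataFrame ready for delimited-text export."""
    return pd.DataFrame(
        {
            "region": [c.region for c in comparisons],
            "statistic": [c.statistic for c in comparisons],
            "p_raw": [c.p_raw for c in comparisons],
            "p_bonferroni": [c.p_bonferroni for c in comparisons],
            "effect_size": [c.effect_size for c in comparisons],
            "significant": [c.significant for c in comparisons],
            "direction": [c.direction for c in comparisons],
        }
    )
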