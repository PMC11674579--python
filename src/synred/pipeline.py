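"""End-to-end orchestration: generate/load runs, decompose, rank, compare.

A :class:`StudyLayout` names every (subject, condition, run) time-series
file plus the structural connectome and analysis configuration;
:func:`run_pipeline` executes the full chain — windowed PhiID matrices,
rank gradients, region-wise condition statistics, structure-function
coupling and high-order topology — and writes delimited-text outputs plus
a YAML run log capturing the configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .coupling import StructuralConnectome, coupling_by_condition
from .gradient import (
    RankGradientMatrix,
    WindowSpec,
    WindowedHighOrderMatrices,
    concatenate_gradients,
    rank_gradient,
    window_matrices,
)
from .stats import comparisons_frame, compare_all
from .topology import topology_by_condition

logger = logging.getLogger(__name__)

__all__ = ["StudyLayout", "PipelineResult", "run_pipeline"]


@dataclass
class StudyLayout:
    """Manifest of a study: one row per (subject, condition, run) file.

    manifest : DataFrame with columns subject, condition, run, path.
    control : name of the control condition (must appear in the manifest).
    config : analysis parameters (window length/overlap, lag, alpha,
        effect-size threshold, gamma, topology stride and restarts, seed).
    """

    manifest: pd.DataFrame
    control: str = "control"
    sc: StructuralConnectome | None = None
    config: dict = field(default_factory=dict)

    def validate(self) -> None:
        need = {"subject", "condition", "run", "path"}
        missing = need - set(self.manifest.columns)
        if missing:
            raise ValueError(f"manifest missing columns {sorted(missing)}")
        keys = self.manifest[["subject", "condition", "run"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate manifest entry {dup}")
        if self.control not in set(self.manifest["condition"]):
            raise ValueError(f"control condition {self.control!r} not in manifest")
        counts = self.manifest.groupby(["subject", "condition"]).size()
        if counts.nunique() > 1:
            bad = counts[counts != counts.max()]
            raise ValueError(
                "incomplete layout; missing runs for "
                + ", ".join(f"(subject={s!r}, condition={c!r})" for s, c in bad.index)
            )
        for p in self.manifest["path"]:
            if not Path(p).exists():
                raise FileNotFoundError(p)


_DEFAULT_CONFIG = {
    "window_length": 500,
    "overlap_fraction": 0.99,
    "lag": 1,
    "standardize": True,
    "alpha": 0.05,
    "es_threshold": 0.8,
    "gamma": 1.0,
    "topology_stride": 6,
    "topology_restarts": 5,
    "seed": 0,
}


@dataclass
class PipelineResult:
    """In-memory bundle of everything the pipeline computed."""

    gradients: dict[str, RankGradientMatrix]
    group_comparisons: dict[str, pd.DataFrame]
    individual_comparisons: dict[tuple[str, str], pd.DataFrame]
    coupling_table: pd.DataFrame | None
    coupling_contrasts: pd.DataFrame | None
    topology_contrasts: pd.DataFrame | None
    topology_series: dict | None
    config: dict


def _stride_windows(whm: WindowedHighOrderMatrices, stride: int) -> WindowedHighOrderMatrices:
    return WindowedHighOrderMatrices(
        redundancy=whm.redundancy[::stride],
        synergy=whm.synergy[::stride],
        region_labels=whm.region_labels,
        windows=whm.windows[::stride],
    )


def run_pipeline(layout: StudyLayout, out_dir=None) -> PipelineResult:
    """Execute the full analysis over a validated study layout.

    Outputs (when ``out_dir`` is given): per-condition group gradient
    matrices, group and individual comparison tables, coupling and topology
    series/contrast tables, and ``run_log.yaml`` with the full configuration.
    Deterministic given fixed seeds in the config.
    """
    layout.validate()
    cfg = {**_DEFAULT_CONFIG, **layout.config}
    spec = WindowSpec(cfg["window_length"], cfg["overlap_fraction"])
    manifest = layout.manifest.sort_values(["condition", "subject", "run"])

    per_run_whm: dict[tuple[str, str, str], WindowedHighOrderMatrices] = {}
    per_run_grad: dict[tuple[str, str, str], RankGradientMatrix] = {}
    labels = None
    for row in manifest.itertuples():
        data, run_labels = sio.read_timeseries(row.path)
        if labels is None:
            labels = run_labels
        elif run_labels != labels:
            bad = sorted(set(run_labels) ^ set(labels))
            raise ValueError(f"region labels differ across runs: {bad[:10]}")
        whm = window_matrices(
            data, spec, run_labels, lag=cfg["lag"], standardize=cfg["standardize"]
        )
        key = (row.subject, row.condition, row.run)
        per_run_whm[key] = whm
        per_run_grad[key] = rank_gradient(whm, row.subject, row.condition, row.run)
        logger.info("decomposed %s (%d windows)", key, whm.n_windows)

    conditions = list(dict.fromkeys(manifest["condition"]))
    subjects = list(dict.fromkeys(manifest["subject"]))

    gradients = {
        cond: concatenate_gradients(
            [g for (s, c, r), g in per_run_grad.items() if c == cond]
        )
        for cond in conditions
    }

    # Group-level statistics and the per-condition group mask.
    group_comparisons: dict[str, pd.DataFrame] = {}
    group_masks: dict[str, set] = {}
    for cond in conditions:
        if cond == layout.control:
            continue
        cmps = compare_all(
            gradients[layout.control].values,
            gradients[cond].values,
            labels,
            level="group",
            alpha=cfg["alpha"],
            es_threshold=cfg["es_threshold"],
        )
        group_comparisons[cond] = comparisons_frame(cmps)
        group_masks[cond] = {c.region for c in cmps if c.significant}

    # Individual-level statistics constrained to the group mask.
    individual_comparisons: dict[tuple[str, str], pd.DataFrame] = {}
    for cond in group_comparisons:
        for subj in subjects:
            ctrl = concatenate_gradients(
                [g for (s, c, r), g in per_run_grad.items()
                 if c == layout.control and s == subj]
            )
            stim = concatenate_gradients(
                [g for (s, c, r), g in per_run_grad.items()
                 if c == cond and s == subj]
            )
            cmps = compare_all(
                ctrl.values,
                stim.values,
                labels,
                level="individual",
                group_mask=group_masks[cond],
                alpha=cfg["alpha"],
                es_threshold=cfg["es_threshold"],
            )
            individual_comparisons[(cond, subj)] = comparisons_frame(cmps)

    # Structure-function coupling and topology need the connectome / stride.
    coupling_table = coupling_contrasts = None
    topology_contrasts = None
    topology_series = None
    per_condition = {
        cond: [whm for (s, c, r), whm in per_run_whm.items() if c == cond]
        for cond in conditions
    }
    if layout.sc is not None:
        coupling_table, ccmps = coupling_by_condition(
            per_condition,
            layout.sc,
            control=layout.control,
            alpha=cfg["alpha"],
            es_threshold=cfg["es_threshold"],
        )
        coupling_contrasts = comparisons_frame(ccmps)

    stride = max(1, int(cfg["topology_stride"]))
    strided = {
        cond: [_stride_windows(whm, stride) for whm in whms]
        for cond, whms in per_condition.items()
    }
    topology_series, tcmps, _ = topology_by_condition(
        strided,
        control=layout.control,
        gamma=cfg["gamma"],
        seed=cfg["seed"],
        n_restarts=cfg["topology_restarts"],
        alpha=cfg["alpha"],
        es_threshold=cfg["es_threshold"],
    )
    topology_contrasts = comparisons_frame(tcmps)

    result = PipelineResult(
        gradients=gradients,
        group_comparisons=group_comparisons,
        individual_comparisons=individual_comparisons,
        coupling_table=coupling_table,
        coupling_contrasts=coupling_contrasts,
        topology_contrasts=topology_contrasts,
        topology_series=topology_series,
        config=cfg,
    )
    if out_dir is not None:
        _write_outputs(result, layout, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, layout: StudyLayout, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for cond, grad in result.gradients.items():
        grad.to_frame().to_csv(out / f"gradient_{cond}.csv")
    for cond, df in result.group_comparisons.items():
        df.to_csv(out / f"comparison_group_{cond}.csv", index=False)
    for (cond, subj), df in result.individual_comparisons.items():
        df.to_csv(out / f"comparison_{subj}_{cond}.csv", index=False)
    if result.coupling_table is not None:
        result.coupling_table.to_csv(out / "coupling_windows.csv", index=False)
        result.coupling_contrasts.to_csv(out / "coupling_contrasts.csv", index=False)
    if result.topology_contrasts is not None:
        result.topology_contrasts.to_csv(out / "topology_contrasts.csv", index=False)
        rows = []
        for cond, ts in result.topology_series.items():
            for w, (q, e) in enumerate(zip(ts.modularity_q, ts.efficiency)):
                rows.append(
                    {"condition": cond, "window": w, "modularity_q": q, "efficiency": e}
                )
        pd.DataFrame(rows).to_csv(out / "topology_windows.csv", index=False)
    log = {
        "control": layout.control,
        "config": {
            k: (v.item() if isinstance(v, np.generic) else v)
            for k, v in result.config.items()
        },
        "manifest": layout.manifest.to_dict(orient="records"),
    }
    (out / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=False))
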