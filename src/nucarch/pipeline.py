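"""Cohort orchestration and group statistics.

``quantify_cell`` composes segmentation, morphometry, territory analysis,
polarity scoring and mark–territory co-localization into one per-cell
record; a failing measurement is logged and recorded as missing rather than
aborting the cohort.  ``compare_groups`` reproduces the reporting style of
the source experiments: per-group mean + 1 SEM with the biological repeat
as the unit of replication, paired t for two groups, one-way ANOVA for
three or more, and Bonferroni-adjusted pairwise tests computed only when
the overall p-value is below 0.05.  ``run_cohort`` renders a synthetic
cohort (or loads stacks from a directory), quantifies every cell and
writes deterministic CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as nio
from .core import MultiChannelVolume
from .morphometry import (
    classify_invaginated,
    nuclear_shape_factor,
    nuclear_volume,
    peripherality_index,
    channel_volume,
    solidity,
)
from .polarity import epipolarity_score
from .segmentation import detect_territories, segment_nucleus
from .synthetic import CohortConfig, render_scene, sample_scene_config
from .territories import analyze_homolog_pair, colocalization_volume

logger = logging.getLogger("nucarch")

__all__ = ["AnalysisConfig", "CellRecord", "GroupComparison", "quantify_cell",
           "compare_groups", "run_cohort"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Channel mapping and measurement knobs for cohort quantification."""

    dapi_channel: str = "dapi"
    mark_channels: tuple[str, ...] = ("mark",)
    paint_channels: tuple[str, ...] = ("paint",)
    lamin_channel: str | None = None
    smoothing_sigma_um: float = 0.3
    nucleus_min_volume_um3: float = 20.0
    territory_min_volume_um3: float = 0.5
    tau: float = 0.7
    d_prox_um: float = 2.0
    shell_depth_um: float = 0.5
    solidity_cutoff: float = 0.92
    n_directions: int = 200

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("mark_channels", "paint_channels"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class CellRecord:
    """Flat per-cell measurement record; None marks a contained failure."""

    cell_id: str
    group: str = ""
    repeat_id: str = ""
    volume_um3: float | None = None
    nsf: float | None = None
    solidity: float | None = None
    invaginated: bool | None = None
    lamin_volume_um3: float | None = None
    peripherality: float | None = None
    polarity: dict = field(default_factory=dict)  # mark -> (score, polar)
    homologs: dict = field(default_factory=dict)  # paint -> HomologPairResult
    colocalization: dict = field(default_factory=dict)  # (mark, paint) -> result
    errors: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        row: dict = {
            "cell_id": self.cell_id,
            "group": self.group,
            "repeat": self.repeat_id,
            "volume_um3": self.volume_um3,
            "nsf": self.nsf,
            "solidity": self.solidity,
            "invaginated": self.invaginated,
            "lamin_volume_um3": self.lamin_volume_um3,
            "peripherality": self.peripherality,
        }
        for mark, res in self.polarity.items():
            row[f"polarity_score_{mark}"] = res.score
            row[f"polar_{mark}"] = res.polar
        for paint, res in self.homologs.items():
            row[f"n_objects_{paint}"] = res.n_objects
            row[f"distance_um_{paint}"] = res.distance_um
            row[f"proximal_{paint}"] = res.proximal
        for (mark, paint), res in self.colocalization.items():
            row[f"overlap_um3_{mark}_{paint}"] = res.overlap_um3
            row[f"overlap_fraction_{mark}_{paint}"] = (
                res.overlap_fraction_of_territory
            )
        row["errors"] = ";".join(self.errors)
        return row


def _attempt(record: CellRecord, label: str, fn):
    try:
        return fn()
    except Exception as exc:  # noqa: BLE001 - containment is the contract
        logger.warning("cell %s: %s failed: %s", record.cell_id, label, exc)
        record.errors.append(f"{label}: {exc}")
        return None


def quantify_cell(
    stack: MultiChannelVolume,
    config: AnalysisConfig = AnalysisConfig(),
    cell_id: str = "cell",
    group: str = "",
    repeat_id: str = "",
) -> CellRecord:
    """Measure one cell end to end; partial failures are contained."""
    if config.dapi_channel not in stack.channels:
        raise ValueError(
            f"missing DAPI channel {config.dapi_channel!r}; "
            f"stack has {stack.channel_names}"
        )
    rec = CellRecord(cell_id=cell_id, group=group, repeat_id=repeat_id)

    nucleus = _attempt(
        rec,
        "segmentation",
        lambda: segment_nucleus(
            stack.channel(config.dapi_channel),
            stack.grid,
            smoothing_sigma_um=config.smoothing_sigma_um,
            min_volume_um3=config.nucleus_min_volume_um3,
            cell_id=cell_id,
        ),
    )
    if nucleus is None:
        return rec

    rec.volume_um3 = _attempt(rec, "volume", lambda: nuclear_volume(nucleus))
    rec.nsf = _attempt(rec, "nsf", lambda: nuclear_shape_factor(nucleus))
    sol = _attempt(rec, "solidity", lambda: solidity(nucleus))
    rec.solidity = sol
    if sol is not None:
        rec.invaginated = classify_invaginated(sol, config.solidity_cutoff)
    if config.lamin_channel and config.lamin_channel in stack.channels:
        rec.lamin_volume_um3 = _attempt(
            rec,
            "lamin volume",
            lambda: channel_volume(stack.channel(config.lamin_channel), nucleus),
        )
        rec.peripherality = _attempt(
            rec,
            "peripherality",
            lambda: peripherality_index(
                stack.channel(config.lamin_channel), nucleus,
                config.shell_depth_um,
            ),
        )

    for mark in config.mark_channels:
        if mark not in stack.channels:
            continue
        res = _attempt(
            rec,
            f"polarity[{mark}]",
            lambda m=mark: epipolarity_score(
                stack.channel(m), nucleus,
                n_directions=config.n_directions, tau=config.tau,
            ),
        )
        if res is not None:
            rec.polarity[mark] = res

    for paint in config.paint_channels:
        if paint not in stack.channels:
            continue
        terrs = _attempt(
            rec,
            f"territories[{paint}]",
            lambda p=paint: detect_territories(
                stack.channel(p), nucleus,
                min_volume_um3=config.territory_min_volume_um3,
                channel_name=p,
            ),
        )
        if terrs is None:
            continue
        rec.homologs[paint] = analyze_homolog_pair(terrs, config.d_prox_um)
        for mark in config.mark_channels:
            if mark not in stack.channels or not terrs:
                continue
            res = _attempt(
                rec,
                f"colocalization[{mark},{paint}]",
                lambda m=mark, t=terrs[0]: colocalization_volume(
                    stack.channel(m), t, nucleus
                ),
            )
            if res is not None:
                rec.colocalization[(mark, paint)] = res
    return rec


# ---------------------------------------------------------------------------
# Group statistics


@dataclass
class GroupComparison:
    """Mean + SEM per group with the appropriate omnibus test and
    Bonferroni-gated pairwise post-tests."""

    metric: str
    group_means: dict[str, float]
    group_sems: dict[str, float]
    test: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame  # empty unless overall p < 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _repeat_means(values: pd.DataFrame) -> pd.DataFrame:
    return (
        values.dropna(subset=["value"])
        .groupby(["group", "repeat"], sort=True)["value"]
        .mean()
        .reset_index()
    )


def compare_groups(
    values: pd.DataFrame,
    metric: str = "value",
    design: str = "auto",
    unit: str = "repeat",
) -> GroupComparison:
    """Compare a metric across groups.

    ``values`` has columns (group, repeat, value).  With ``unit='repeat'``
    the per-repeat means are the observations (biological repeat = unit of
    replication); ``unit='cell'`` pools cells.  Two groups use a paired t
    test when the repeat structure matches (``design='two-group paired'``
    or 'auto'), otherwise Welch's t; three or more groups use one-way
    ANOVA.  Pairwise Bonferroni-adjusted t tests are computed only when
    the overall p is < 0.05.
    """
    df = values.dropna(subset=["value"]).copy()
    obs = _repeat_means(df) if unit == "repeat" else df
    groups = sorted(obs["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = {g: obs.loc[obs["group"] == g, "value"].to_numpy() for g in groups}
    for g, v in samples.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")

    means = {g: float(v.mean()) for g, v in samples.items()}
    sems = {g: float(stats.sem(v)) for g, v in samples.items()}

    if len(groups) == 2:
        a, b = (samples[g] for g in groups)
        paired = design in ("two-group paired", "auto") and len(a) == len(b)
        if design == "two-group paired" and len(a) != len(b):
            raise ValueError("paired design requires equal repeat structure")
        if paired:
            stat, p = stats.ttest_rel(a, b)
            test = "paired-t"
        else:
            stat, p = stats.ttest_ind(a, b, equal_var=False)
            test = "welch-t"
    else:
        stat, p = stats.f_oneway(*(samples[g] for g in groups))
        test = "one-way ANOVA"

    pairs = []
    if p < 0.05 and len(groups) > 2:
        m = len(list(combinations(groups, 2)))
        for g1, g2 in combinations(groups, 2):
            t, praw = stats.ttest_ind(samples[g1], samples[g2], equal_var=False)
            pairs.append(
                {
                    "group_a": g1,
                    "group_b": g2,
                    "p_raw": float(praw),
                    "p_bonferroni": min(1.0, m * float(praw)),
                }
            )
    pairwise = pd.DataFrame(
        pairs, columns=["group_a", "group_b", "p_raw", "p_bonferroni"]
    )
    return GroupComparison(
        metric=metric,
        group_means=means,
        group_sems=sems,
        test=test,
        statistic=float(stat),
        p_value=float(p),
        pairwise=pairwise,
    )


# ---------------------------------------------------------------------------
# Cohort runner


#: Metrics summarised per group in the cohort report.
_SUMMARY_METRICS = [
    "volume_um3",
    "nsf",
    "solidity",
    "polarity_score_mark",
    "distance_um_paint",
]


def run_cohort(
    cohort: CohortConfig,
    config: AnalysisConfig = AnalysisConfig(),
    out_dir=None,
    write_stacks: bool = False,
) -> dict:
    """Simulate, quantify and summarise a synthetic cohort.

    Returns a dict with the per-cell DataFrame (``cells``), the group
    summary (``groups``) and the comparison table (``comparisons``); when
    ``out_dir`` is given the three are also written as CSV (byte-identical
    across reruns with the same config and seed) together with a JSON log.
    """
    if not cohort.groups:
        raise ValueError("empty cohort")
    root = np.random.SeedSequence(cohort.seed)
    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    for gi, group in enumerate(cohort.groups):
        g_ss = np.random.SeedSequence(cohort.seed, spawn_key=(gi,))
        cell_seeds = g_ss.spawn(cohort.n_cells)
        for ci in range(cohort.n_cells):
            repeat = f"rep{ci % cohort.n_repeats + 1}"
            cell_id = f"{group.name}_{ci:03d}"
            rng = np.random.default_rng(cell_seeds[ci])
            scene = sample_scene_config(group, rng)
            seed = int(rng.integers(0, 2**31 - 1))
            stack, truth = render_scene(scene, seed=seed)
            if write_stacks and out_dir is not None:
                nio.write_stack(stack, out_dir / f"{cell_id}.tif")
            rec = quantify_cell(
                stack, config, cell_id=cell_id, group=group.name,
                repeat_id=repeat,
            )
            row = rec.to_row()
            row["true_radius_um"] = scene.nucleus.radius
            row["true_kappa"] = scene.mark_polarity_kappa
            row["true_separation_um"] = scene.homolog_separation
            rows.append(row)
            logger.info("quantified %s", cell_id)

    cells = pd.DataFrame(rows)
    summaries = []
    comparisons = []
    for metric in _SUMMARY_METRICS:
        if metric not in cells.columns:
            continue
        sub = cells[["group", "repeat", metric]].rename(columns={metric: "value"})
        summary = (
            sub.dropna()
            .groupby("group")["value"]
            .agg(["mean", "sem", "count"])
            .reset_index()
        )
        summary.insert(0, "metric", metric)
        summaries.append(summary)
        if sub["group"].nunique() >= 2:
            try:
                cmp_res = compare_groups(sub, metric=metric)
            except ValueError:
                continue
            comparisons.append(
                {
                    "metric": metric,
                    "test": cmp_res.test,
                    "statistic": cmp_res.statistic,
                    "p_value": cmp_res.p_value,
                    **{f"mean_{g}": m for g, m in cmp_res.group_means.items()},
                }
            )
    groups_df = (
        pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    )
    comparisons_df = pd.DataFrame(comparisons)

    result = {"cells": cells, "groups": groups_df, "comparisons": comparisons_df}
    if out_dir is not None:
        cells.to_csv(out_dir / "cells.csv", index=False, float_format="%.6g")
        groups_df.to_csv(out_dir / "groups.csv", index=False, float_format="%.6g")
        comparisons_df.to_csv(
            out_dir / "comparisons.csv", index=False, float_format="%.6g"
        )
        cfg_repr = repr((cohort, config)).encode()
        log = {
            "seed": cohort.seed,
            "n_cells": cohort.n_cells,
            "groups": [g.name for g in cohort.groups],
            "config_sha1": hashlib.sha1(cfg_repr).hexdigest(),
            "cells_with_errors": int((cells["errors"] != "").sum()),
        }
        (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    return result
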