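"""Null predictors that anchor each subchallenge's leaderboard.

* shuffle — predict each cell by a uniformly chosen cell of the same
  condition (a pure random permutation of cell ids; self-assignment
  allowed, an O(1/n) bias that is documented rather than removed).
* EGF-copy — predict an inhibitor condition by resampling the same line's
  EGF arm at the same time, i.e. assume the inhibitor has no effect.
* average line — predict every test line by the mean over training lines
  of their per-condition medians.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import (
    CONDITION_COLUMNS,
    TREATMENT_EGF,
    CoverageError,
    PredictionSet,
    SingleCellTable,
)
from .scoring import condition_medians


def shuffle_baseline(truth: SingleCellTable, targets: list[str] | None = None,
                     seed: int = 0) -> PredictionSet:
    """Random within-condition prediction: permute cell ids per condition
    and use the permuted cell's target-marker values."""
    targets = list(targets if targets is not None else truth.panel.sc1_targets)
    rng = np.random.default_rng(seed)
    frames = []
    for _, g in truth.data.groupby(CONDITION_COLUMNS, sort=True):
        perm = rng.permutation(len(g))
        pred = g[["cell_line", "treatment", "time", "cellID"]].reset_index(drop=True)
        vals = g[targets].to_numpy()[perm]
        for j, marker in enumerate(targets):
            out = pred.copy()
            out["marker"] = marker
            out["value"] = vals[:, j]
            frames.append(out)
    return PredictionSet("SC1", pd.concat(frames, ignore_index=True),
                         truth.panel)


def egf_copy_baseline(context: SingleCellTable,
                      target_conditions: pd.DataFrame,
                      n: int = 10000, seed: int = 0) -> PredictionSet:
    """No-inhibitor-effect null: for each target (cell line, treatment,
    time), resample n cells with replacement from the line's EGF arm at the
    same time."""
    rng = np.random.default_rng(seed)
    egf = context.data[context.data["treatment"] == TREATMENT_EGF]
    groups = {(cl, t): g for (cl, t), g in egf.groupby(["cell_line", "time"])}
    frames = []
    conds = (target_conditions[CONDITION_COLUMNS].drop_duplicates()
             .sort_values(CONDITION_COLUMNS))
    for _, row in conds.iterrows():
        key = (row["cell_line"], row["time"])
        if key not in groups:
            raise CoverageError(
                f"no EGF condition for line {row['cell_line']!r} "
                f"at time {row['time']}")
        g = groups[key]
        take = rng.integers(0, len(g), size=n)
        out = g.iloc[take][list(context.panel.names)].reset_index(drop=True)
        out.insert(0, "cell_line", row["cell_line"])
        out.insert(1, "treatment", row["treatment"])
        out.insert(2, "time", row["time"])
        out.insert(3, "cellID", np.arange(n))
        out.insert(4, "fileID", f"{row['cell_line']}_{row['treatment']}_egfcopy")
        frames.append(out)
    return PredictionSet("SC2", pd.concat(frames, ignore_index=True),
                         context.panel)


def average_line_baseline(train: SingleCellTable,
                          test_design: pd.DataFrame) -> PredictionSet:
    """Average-cell-line null for the time-course task: per (treatment,
    time, marker), the mean over training lines of their per-line medians,
    replicated identically for every test line."""
    med = condition_medians(train)
    med = med[med["treatment"] != "full"]
    avg = (med.groupby(["treatment", "time", "marker"])["value"]
           .mean().rename("value").reset_index())
    design = (test_design[CONDITION_COLUMNS].drop_duplicates()
              .sort_values(CONDITION_COLUMNS))
    out = design.merge(avg, on=["treatment", "time"], how="left")
    if out["value"].isna().any():
        bad = out[out["value"].isna()].iloc[0]
        raise CoverageError(
            f"train lacks condition ({bad['treatment']}, {bad['time']})")
    return PredictionSet("SC4", out[["cell_line", "treatment", "time",
                                     "marker", "value"]], train.panel)
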