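"""Subchallenge scores, bootstrap resampling, and Bayes-factor ranking.

Four scores, all "lower is better":

* SC1 — per-condition single-cell RMSE of the withheld markers, averaged
  with equal weight over every (cell line, treatment, time, marker) entry.
* SC2/SC3 — per condition, squared error of the predicted mean vector plus
  squared error of the predicted covariance over unordered marker pairs
  (diagonal included), the two parts added with equal weight; averaged over
  conditions.
* SC4 — RMSE of the predicted median time course per (cell line, treatment,
  marker), averaged over curves.

Robust ranking resamples the scoring units with replacement (1000 draws) and
compares teams by the ratio of bootstrap win counts (the challenge's "Bayes
factor").
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    CONDITION_COLUMNS,
    CoverageError,
    ConditionStats,
    PredictionSet,
    ScoreReport,
    SingleCellTable,
)

#: bootstrap resampling units per subchallenge (groups of per-condition
#: table columns; each group's unique values are drawn with replacement)
BOOTSTRAP_AXES: dict[str, list[tuple[str, ...]]] = {
    "SC1": [("cell_line", "treatment", "time")],
    "SC2": [("cell_line",), ("treatment", "time")],
    "SC3": [("cell_line",), ("treatment", "time")],
    "SC4": [("cell_line",), ("treatment",)],
}


def _check_no_nan(arr: np.ndarray, what: str) -> None:
    if np.isnan(arr).any():
        raise ValueError(f"NaN in {what}; scoring rejects missing values")


# ---------------------------------------------------------------------------
# SC1: single-cell RMSE of withheld markers
# ---------------------------------------------------------------------------

def _sc1_merge(pred: PredictionSet, truth: SingleCellTable,
               targets: Sequence[str]) -> pd.DataFrame:
    truth_long = truth.data.melt(
        id_vars=["cell_line", "treatment", "time", "cellID"],
        value_vars=list(targets), var_name="marker", value_name="y")
    merged = truth_long.merge(
        pred.data.rename(columns={"value": "yhat"}),
        on=["cell_line", "treatment", "time", "cellID", "marker"],
        how="left", indicator=True)
    missing = merged["_merge"] == "left_only"
    if missing.any():
        first = merged[missing].iloc[0]
        raise CoverageError(
            "prediction missing for truth cell "
            f"({first['cell_line']}, {first['treatment']}, {first['time']}, "
            f"cellID={first['cellID']}, marker={first['marker']})")
    _check_no_nan(merged["y"].to_numpy(), "truth values")
    _check_no_nan(merged["yhat"].to_numpy(), "predicted values")
    return merged.drop(columns="_merge")


def score_sc1(pred: PredictionSet, truth: SingleCellTable,
              targets: Sequence[str] | None = None) -> ScoreReport:
    """Root-mean-square error per (cell line, treatment, time, marker)
    condition; the final score is the unweighted mean of all entries."""
    targets = list(targets if targets is not None else truth.panel.sc1_targets)
    merged = _sc1_merge(pred, truth, targets)
    sq = (merged["y"] - merged["yhat"]) ** 2
    per = (sq.groupby([merged[c] for c in CONDITION_COLUMNS + ["marker"]])
           .mean().pow(0.5).rename("score").reset_index())
    return ScoreReport(per_condition=per, final=float(per["score"].mean()))


def sc1_diagnostics(pred: PredictionSet, truth: SingleCellTable,
                    targets: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-condition Pearson correlation and explained variance R^2.

    R^2 = 1 - SSE/SST over the cells of the condition; it is negative when
    the prediction is worse than the condition mean.  Correlation is NaN
    where the truth has zero variance.
    """
    targets = list(targets if targets is not None else truth.panel.sc1_targets)
    merged = _sc1_merge(pred, truth, targets)

    def per_group(g: pd.DataFrame) -> pd.Series:
        y = g["y"].to_numpy()
        yhat = g["yhat"].to_numpy()
        sst = float(((y - y.mean()) ** 2).sum())
        sse = float(((y - yhat) ** 2).sum())
        if sst == 0 or np.std(yhat) == 0:
            corr = np.nan
        else:
            corr = float(np.corrcoef(y, yhat)[0, 1])
        r2 = np.nan if sst == 0 else 1.0 - sse / sst
        return pd.Series({"correlation": corr, "r2": r2})

    out = (merged.groupby(CONDITION_COLUMNS + ["marker"])
           .apply(per_group, include_groups=False).reset_index())
    return out


def basal_means(table: SingleCellTable, markers: Sequence[str],
                time: float = 0.0) -> pd.DataFrame:
    """Per-(cell line, marker) mean of the time-0 cells, across all arms
    present (at time 0, before stimulation, arms are exchangeable)."""
    sub = table.data[table.data["time"] == time]
    long = sub.melt(id_vars=["cell_line"], value_vars=list(markers),
                    var_name="marker", value_name="value")
    return (long.groupby(["cell_line", "marker"])["value"].mean()
            .rename("mean").reset_index())


def prediction_basal_means(pred: PredictionSet, time: float = 0.0) -> pd.DataFrame:
    """Per-(cell line, marker) mean of an SC1 prediction's time-0 values."""
    sub = pred.data[pred.data["time"] == time]
    return (sub.groupby(["cell_line", "marker"])["value"].mean()
            .rename("mean").reset_index())


def basal_correction(pred: PredictionSet, truth_basal_means: pd.DataFrame,
                     pred_basal_means: pd.DataFrame) -> PredictionSet:
    """Shift every predicted value of (cell line, marker) by the measured
    minus predicted mean basal (time-0) activity of that pair."""
    offsets = truth_basal_means.merge(
        pred_basal_means, on=["cell_line", "marker"],
        suffixes=("_true", "_pred"))
    offsets["offset"] = offsets["mean_true"] - offsets["mean_pred"]

    need = pred.data[["cell_line", "marker"]].drop_duplicates()
    have = offsets[["cell_line", "marker"]]
    gap = need.merge(have, on=["cell_line", "marker"], how="left",
                     indicator=True)
    if (gap["_merge"] == "left_only").any():
        first = gap[gap["_merge"] == "left_only"].iloc[0]
        raise CoverageError(
            f"no basal means for ({first['cell_line']}, {first['marker']})")

    corrected = pred.data.merge(
        offsets[["cell_line", "marker", "offset"]],
        on=["cell_line", "marker"], how="left")
    corrected["value"] = corrected["value"] + corrected["offset"]
    return PredictionSet(pred.subchallenge,
                         corrected.drop(columns="offset"), pred.panel)


# ---------------------------------------------------------------------------
# SC2/SC3: population statistics score
# ---------------------------------------------------------------------------

def compute_condition_stats(cells: SingleCellTable,
                            key: tuple[str, str, float]) -> ConditionStats:
    """Sample mean and covariance (n-1 denominator) of one condition."""
    cl, tr, t = key
    sub = cells.data[(cells.data["cell_line"] == cl)
                     & (cells.data["treatment"] == tr)
                     & (cells.data["time"] == t)]
    if len(sub) < 2:
        raise ValueError(f"condition {key} has fewer than 2 cells")
    markers = list(cells.panel.names)
    x = sub[markers].to_numpy(dtype=float)
    _check_no_nan(x, f"condition {key}")
    mean = pd.Series(x.mean(axis=0), index=markers)
    cov = pd.DataFrame(np.cov(x, rowvar=False, ddof=1),
                       index=markers, columns=markers)
    return ConditionStats(mean=mean, cov=cov, n_cells=len(sub))


def score_sc23(pred: PredictionSet, truth: SingleCellTable) -> ScoreReport:
    """Squared-error score on per-condition means and covariances.

    Per condition i: ``S_i = sum_j (mu_ij - muhat_ij)^2
    + sum_{j<=k} (cov_ijk - covhat_ijk)^2``; the final score is the mean of
    S_i over conditions.
    """
    markers = list(truth.panel.names)
    m = len(markers)
    iu = np.triu_indices(m)

    pred_groups = {k: v for k, v in pred.data.groupby(CONDITION_COLUMNS)}
    rows = []
    for key, tsub in truth.data.groupby(CONDITION_COLUMNS):
        if key not in pred_groups:
            raise CoverageError(f"prediction missing condition {key}")
        ty = tsub[markers].to_numpy(dtype=float)
        py = pred_groups[key][markers].to_numpy(dtype=float)
        _check_no_nan(ty, f"truth condition {key}")
        _check_no_nan(py, f"predicted condition {key}")
        if len(ty) < 2 or len(py) < 2:
            raise ValueError(f"condition {key} needs >= 2 cells on both sides")
        dmu = ty.mean(axis=0) - py.mean(axis=0)
        dcov = (np.cov(ty, rowvar=False, ddof=1)
                - np.cov(py, rowvar=False, ddof=1))
        s_mu = float((dmu ** 2).sum())
        s_sigma = float((dcov[iu] ** 2).sum())
        rows.append({"cell_line": key[0], "treatment": key[1], "time": key[2],
                     "s_mu": s_mu, "s_sigma": s_sigma,
                     "score": s_mu + s_sigma})
    per = pd.DataFrame(rows)
    return ScoreReport(per_condition=per, final=float(per["score"].mean()))


def n_statistics(n_markers: int, n_conditions: int) -> int:
    """Number of scored statistics: per condition, n_markers means plus
    n_markers(n_markers+1)/2 covariance entries."""
    return n_conditions * (n_markers + n_markers * (n_markers + 1) // 2)


def normalize_per_statistic(report: ScoreReport, n_stats: int) -> float:
    """Total squared error divided by the number of predicted statistics,
    enabling comparison across designs of different size."""
    if n_stats <= 0:
        raise ValueError("n_stats must be positive")
    return float(report.per_condition["score"].sum()) / n_stats


# ---------------------------------------------------------------------------
# SC4: median time-course RMSE
# ---------------------------------------------------------------------------

def condition_medians(table: SingleCellTable) -> pd.DataFrame:
    """Per-condition per-marker medians in SC4 long layout."""
    med = (table.data.groupby(CONDITION_COLUMNS)[list(table.panel.names)]
           .median().reset_index())
    return med.melt(id_vars=CONDITION_COLUMNS, var_name="marker",
                    value_name="value")


def score_sc4(pred: PredictionSet, truth_medians: pd.DataFrame) -> ScoreReport:
    """RMSE across time per (cell line, treatment, marker) curve; final
    score is the mean over curves."""
    merged = truth_medians.rename(columns={"value": "y"}).merge(
        pred.data.rename(columns={"value": "yhat"}),
        on=["cell_line", "treatment", "time", "marker"],
        how="left", indicator=True)
    missing = merged["_merge"] == "left_only"
    if missing.any():
        first = merged[missing].iloc[0]
        raise CoverageError(
            "prediction missing for "
            f"({first['cell_line']}, {first['treatment']}, {first['time']}, "
            f"{first['marker']})")
    _check_no_nan(merged["y"].to_numpy(), "truth medians")
    _check_no_nan(merged["yhat"].to_numpy(), "predicted medians")
    sq = (merged["y"] - merged["yhat"]) ** 2
    per = (sq.groupby([merged[c] for c in ["cell_line", "treatment", "marker"]])
           .mean().pow(0.5).rename("score").reset_index())
    return ScoreReport(per_condition=per, final=float(per["score"].mean()))


# ---------------------------------------------------------------------------
# Bootstrap resampling and Bayes factors
# ---------------------------------------------------------------------------

def bootstrap_scores(per_condition: Mapping[str, pd.DataFrame] | pd.DataFrame,
                     axes: Sequence[tuple[str, ...]] | str,
                     n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Bootstrap final scores by resampling scoring units with replacement.

    ``axes`` names the resampling units as groups of per-condition table
    columns (or a subchallenge name to use its convention): each replicate
    independently draws every axis's unique values with replacement and
    averages the per-condition scores over the resulting cross, so teams are
    compared on identical resamples.
    """
    if isinstance(axes, str):
        axes = BOOTSTRAP_AXES[axes]
    teams = ({"team": per_condition} if isinstance(per_condition, pd.DataFrame)
             else dict(per_condition))
    axis_cols = [list(a) for a in axes]
    flat_cols = [c for a in axis_cols for c in a]

    def keyframe(df: pd.DataFrame) -> pd.DataFrame:
        return df[flat_cols].drop_duplicates().sort_values(flat_cols) \
            .reset_index(drop=True)

    ref = None
    cubes = {}
    levels: list[list] = []
    for name, df in teams.items():
        kf = keyframe(df)
        if ref is None:
            ref = kf
            for a in axis_cols:
                levels.append(sorted(map(tuple, df[a].drop_duplicates()
                                         .to_numpy().tolist())))
        elif not kf.equals(ref):
            raise ValueError(f"team {name!r} scored on a different condition set")
        # mean score per cross-cell of the axes
        grouped = df.groupby(flat_cols)["score"].mean()
        shape = tuple(len(lv) for lv in levels)
        cube = np.full(shape, np.nan)
        lookup = [{v: i for i, v in enumerate(lv)} for lv in levels]
        for key, val in grouped.items():
            key = (key,) if not isinstance(key, tuple) else key
            pos = []
            off = 0
            for a, lk in zip(axis_cols, lookup):
                sub = tuple(key[off:off + len(a)])
                pos.append(lk[sub])
                off += len(a)
            cube[tuple(pos)] = val
        cubes[name] = cube

    rng = np.random.default_rng(seed)
    out = np.empty((n_boot, len(teams)))
    sizes = [len(lv) for lv in levels]
    for b in range(n_boot):
        draws = [rng.integers(0, s, size=s) for s in sizes]
        for t, name in enumerate(teams):
            cube = cubes[name]
            sub = cube[np.ix_(*draws)] if len(sizes) > 1 else cube[draws[0]]
            out[b, t] = np.nanmean(sub)
    return pd.DataFrame(out, columns=list(teams))


def bayes_factor(boot_x: np.ndarray, boot_y: np.ndarray) -> float:
    """Ratio of strict bootstrap win counts (lower score wins).

    Ties are excluded from both counts; all-ties gives 1; an undefeated
    x gives +inf.
    """
    x = np.asarray(boot_x, dtype=float)
    y = np.asarray(boot_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("bootstrap vectors must be paired and equal length")
    wins = int((x < y).sum())
    losses = int((x > y).sum())
    if wins == 0 and losses == 0:
        return 1.0
    if losses == 0:
        return np.inf
    return wins / losses


def bayes_factor_matrix(boot: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bayes factors between all teams (diagonal fixed at 1)."""
    teams = list(boot.columns)
    out = pd.DataFrame(1.0, index=teams, columns=teams)
    for i, a in enumerate(teams):
        for j, b in enumerate(teams):
            if i != j:
                out.loc[a, b] = bayes_factor(boot[a].to_numpy(),
                                             boot[b].to_numpy())
    return out
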