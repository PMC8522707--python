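"""Combining multiple submissions into ensemble predictions.

Per-value median (SC1/SC4), per-condition cell subsampling and
statistics-averaging (SC2/SC3), a stacked random forest trained with
leave-cell-lines-out folds, and the random-ensemble evaluation harness that
scores ensembles of increasing size.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .datamodel import (
    CONDITION_COLUMNS,
    SC1_COLUMNS,
    SC4_COLUMNS,
    TREATMENT_EGF,
    TREATMENTS,
    CoverageError,
    PredictionSet,
    SingleCellTable,
)
from .predictors import (
    condition_stats_frame,
    gaussian_sampler,
    stats_to_condition,
)
from .scoring import condition_medians, score_sc1, score_sc23, score_sc4


def _value_keys(subchallenge: str) -> list[str]:
    if subchallenge == "SC1":
        return [c for c in SC1_COLUMNS if c != "value"]
    if subchallenge == "SC4":
        return [c for c in SC4_COLUMNS if c != "value"]
    raise ValueError("median combination applies to SC1/SC4 predictions")


def combine_median(members: Sequence[PredictionSet]) -> PredictionSet:
    """Elementwise median of aligned per-value predictions (mean of the
    central pair for an even member count)."""
    if not members:
        raise ValueError("need at least one member")
    sub = members[0].subchallenge
    keys = _value_keys(sub)
    merged = members[0].data[keys].copy()
    for i, m in enumerate(members):
        if m.subchallenge != sub:
            raise ValueError("members must share a subchallenge")
        part = m.data.rename(columns={"value": f"v{i}"})
        merged = merged.merge(part, on=keys, how="inner")
    if len(merged) != len(members[0].data):
        raise ValueError("members are not aligned on identical keys")
    vals = merged[[f"v{i}" for i in range(len(members))]].to_numpy()
    out = merged[keys].copy()
    out["value"] = np.median(vals, axis=1)
    return PredictionSet(sub, out, members[0].panel)


def combine_subsample(members: Sequence[PredictionSet], n: int,
                      seed: int = 0) -> PredictionSet:
    """Per condition, draw an equal share of cells from every member
    (balanced within one cell; without replacement, falling back to with
    replacement when a member runs short) and pool them to n cells."""
    if not members:
        raise ValueError("need at least one member")
    panel = members[0].panel
    rng = np.random.default_rng(seed)
    k = len(members)
    quotas = np.full(k, n // k)
    extras = rng.permutation(k)[: n % k]
    quotas[extras] += 1

    member_groups = [dict(tuple(m.data.groupby(CONDITION_COLUMNS)))
                     for m in members]
    conditions = sorted(member_groups[0])
    frames = []
    for cond in conditions:
        parts = []
        for mi, groups in enumerate(member_groups):
            if cond not in groups:
                raise CoverageError(f"member {mi} lacks condition {cond}")
            g = groups[cond]
            q = int(quotas[mi])
            replace = q > len(g)
            take = rng.choice(len(g), size=q, replace=replace)
            parts.append(g.iloc[take])
        pooled = pd.concat(parts, ignore_index=True)
        pooled = pooled.iloc[rng.permutation(len(pooled))].reset_index(drop=True)
        pooled["cellID"] = np.arange(len(pooled))
        frames.append(pooled)
    return PredictionSet(members[0].subchallenge,
                         pd.concat(frames, ignore_index=True), panel)


def combine_stats_average(members: Sequence[PredictionSet], n: int,
                          seed: int = 0) -> PredictionSet:
    """Average members' per-condition means and covariances elementwise,
    then sample n cells per condition from the averaged statistics."""
    if not members:
        raise ValueError("need at least one member")
    panel = members[0].panel
    markers = list(panel.names)
    rng = np.random.default_rng(seed)
    stats = [condition_stats_frame(m.cells()) for m in members]
    index = stats[0].index
    for s in stats[1:]:
        if not s.index.equals(index):
            raise ValueError("members are not aligned on identical conditions")
    avg = sum(s.to_numpy() for s in stats) / len(stats)
    avg = pd.DataFrame(avg, index=index, columns=stats[0].columns)
    frames = []
    for key in index:
        cs = stats_to_condition(avg.loc[key], markers)
        frames.append(gaussian_sampler(
            cs, n=n, seed=int(rng.integers(2 ** 31)), condition=key,
            fileID=f"{key[0]}_{key[1]}_statsavg"))
    return PredictionSet(members[0].subchallenge,
                         pd.concat(frames, ignore_index=True), panel)


# ---------------------------------------------------------------------------
# Stacked random forest with leave-cell-lines-out folds
# ---------------------------------------------------------------------------

def _fold_assignment(lines: list[str], n_folds: int,
                     seed: int) -> pd.DataFrame:
    if n_folds > len(lines):
        raise ValueError(f"n_folds={n_folds} exceeds {len(lines)} test lines")
    rng = np.random.default_rng(seed)
    order = rng.permutation(sorted(lines))
    folds = np.array_split(order, n_folds)
    rows = [{"cell_line": ln, "fold": fi}
            for fi, fold in enumerate(folds) for ln in fold]
    return pd.DataFrame(rows).sort_values("cell_line").reset_index(drop=True)


def stacked_rf_combine(members: Sequence[PredictionSet],
                       truth: SingleCellTable, subchallenge: str,
                       n_folds: int = 6, seed: int = 0, n_trees: int = 50,
                       max_depth: int | None = None,
                       egf_context: SingleCellTable | None = None,
                       n_cells: int | None = None
                       ) -> tuple[PredictionSet, pd.DataFrame]:
    """Learn to combine submissions with out-of-fold forests.

    Folds partition the test cell lines, so every line is predicted by a
    model never trained on it — mirroring the subchallenge setup.  SC1
    stacks per-cell member predictions (plus time, one-hot treatment,
    one-hot predicted marker, and the non-target markers; cell line is
    deliberately not a feature).  SC2 stacks per-condition member
    statistics plus the line's EGF-arm marker medians, and samples cells
    from the forest-predicted statistics.
    """
    lines = truth.cell_lines
    folds = _fold_assignment(lines, n_folds, seed)
    fold_of = dict(zip(folds["cell_line"], folds["fold"]))

    if subchallenge == "SC1":
        pred, panel = _stacked_sc1(members, truth, fold_of, n_folds, seed,
                                   n_trees, max_depth)
    elif subchallenge in {"SC2", "SC3"}:
        if egf_context is None:
            raise ValueError("SC2 stacking needs egf_context for EGF medians")
        pred, panel = _stacked_sc2(members, truth, fold_of, n_folds, seed,
                                   n_trees, max_depth, egf_context, n_cells)
    else:
        raise ValueError(f"no stacker for {subchallenge}")
    return PredictionSet(subchallenge, pred, panel), folds


def _stacked_sc1(members, truth, fold_of, n_folds, seed, n_trees, max_depth):
    panel = truth.panel
    targets = [m for m in members[0].data["marker"].unique()]
    keys = ["cell_line", "treatment", "time", "cellID", "marker"]
    base = members[0].data[keys].copy()
    for i, m in enumerate(members):
        base = base.merge(m.data.rename(columns={"value": f"member{i}"}),
                          on=keys, how="inner")
    truth_long = truth.data.melt(
        id_vars=["cell_line", "treatment", "time", "cellID"],
        value_vars=targets, var_name="marker", value_name="y")
    nontargets = [m for m in panel.names if m not in targets]
    feats = truth.data[["cell_line", "treatment", "time", "cellID"]
                       + nontargets]
    df = base.merge(truth_long, on=keys[:4] + ["marker"]) \
             .merge(feats, on=keys[:4])
    for tr in TREATMENTS:
        df[f"treatment_{tr}"] = (df["treatment"] == tr).astype(float)
    member_cols = [f"member{i}" for i in range(len(members))]
    marker_cols = []
    for mk in targets:
        col = f"marker_{mk}"
        df[col] = (df["marker"] == mk).astype(float)
        marker_cols.append(col)
    feat_cols = (member_cols + ["time"]
                 + [f"treatment_{tr}" for tr in TREATMENTS]
                 + marker_cols + nontargets)
    df["fold"] = df["cell_line"].map(fold_of)

    outs = []
    for mi, marker in enumerate(targets):
        dmk = df[df["marker"] == marker]
        for fold in range(n_folds):
            tr_rows = dmk[dmk["fold"] != fold]
            te_rows = dmk[dmk["fold"] == fold]
            if te_rows.empty:
                continue
            rf = RandomForestRegressor(
                n_estimators=n_trees, max_depth=max_depth,
                random_state=seed + 13 * fold + 997 * mi, n_jobs=1)
            rf.fit(tr_rows[feat_cols].to_numpy(dtype=float),
                   tr_rows["y"].to_numpy(dtype=float))
            out = te_rows[keys].copy()
            out["value"] = rf.predict(te_rows[feat_cols].to_numpy(dtype=float))
            outs.append(out)
    return pd.concat(outs, ignore_index=True), panel


def _stacked_sc2(members, truth, fold_of, n_folds, seed, n_trees, max_depth,
                 egf_context, n_cells):
    panel = truth.panel
    markers = list(panel.names)
    member_stats = [condition_stats_frame(m.cells()) for m in members]
    truth_stats = condition_stats_frame(truth)
    index = member_stats[0].index
    egf = egf_context.data[egf_context.data["treatment"] == TREATMENT_EGF]
    egf_medians = egf.groupby("cell_line")[markers].median()
    if n_cells is None:
        n_cells = int(members[0].data.groupby(CONDITION_COLUMNS).size().iloc[0])

    cols = list(truth_stats.columns)
    rows = index.to_frame(index=False)
    rows["fold"] = rows["cell_line"].map(fold_of)
    rng = np.random.default_rng(seed)

    pred_stats = pd.DataFrame(index=index, columns=cols, dtype=float)
    for fold in range(n_folds):
        tr_keys = rows[rows["fold"] != fold]
        te_keys = rows[rows["fold"] == fold]
        if te_keys.empty:
            continue
        tr_idx = pd.MultiIndex.from_frame(tr_keys[CONDITION_COLUMNS])
        te_idx = pd.MultiIndex.from_frame(te_keys[CONDITION_COLUMNS])
        egf_tr = egf_medians.loc[tr_keys["cell_line"]].to_numpy()
        egf_te = egf_medians.loc[te_keys["cell_line"]].to_numpy()
        for ci, stat in enumerate(cols):
            X_tr = np.column_stack(
                [ms.loc[tr_idx, stat].to_numpy() for ms in member_stats]
                + [egf_tr])
            X_te = np.column_stack(
                [ms.loc[te_idx, stat].to_numpy() for ms in member_stats]
                + [egf_te])
            rf = RandomForestRegressor(
                n_estimators=n_trees, max_depth=max_depth,
                random_state=seed + 31 * fold + 613 * ci, n_jobs=1)
            rf.fit(X_tr, truth_stats.loc[tr_idx, stat].to_numpy())
            pred_stats.loc[te_idx, stat] = rf.predict(X_te)

    frames = []
    for key in index:
        cs = stats_to_condition(pred_stats.loc[key], markers)
        frames.append(gaussian_sampler(
            cs, n=n_cells, seed=int(rng.integers(2 ** 31)), condition=key,
            fileID=f"{key[0]}_{key[1]}_stacked"))
    return pd.concat(frames, ignore_index=True), panel


# ---------------------------------------------------------------------------
# Random-ensemble evaluation harness
# ---------------------------------------------------------------------------

def random_ensemble_curve(members: Sequence[PredictionSet], truth,
                          sizes: Sequence[int], repeats: int = 100,
                          seed: int = 0, subchallenge: str | None = None,
                          n_cells: int | None = None) -> pd.DataFrame:
    """Score random ensembles of each size, `repeats` times.

    Members are combined by median (SC1/SC4) or cell subsampling (SC2/SC3)
    and scored like any submission; the full (size, repeat, score)
    distribution is returned, trend left to the caller.
    """
    sub = subchallenge or members[0].subchallenge
    if max(sizes) > len(members):
        raise ValueError("ensemble size exceeds the number of members")
    if sub in {"SC2", "SC3"} and n_cells is None:
        n_cells = int(members[0].data.groupby(CONDITION_COLUMNS).size().iloc[0])
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        for rep in range(repeats):
            chosen = [members[i] for i in
                      rng.choice(len(members), size=size, replace=False)]
            if sub in {"SC1", "SC4"}:
                combined = combine_median(chosen)
            else:
                combined = combine_subsample(chosen, n=n_cells,
                                             seed=int(rng.integers(2 ** 31)))
            if sub == "SC1":
                score = score_sc1(combined, truth).final
            elif sub in {"SC2", "SC3"}:
                score = score_sc23(combined, truth).final
            else:
                score = score_sc4(combined, truth).final
            rows.append({"size": size, "repeat": rep, "score": score})
    return pd.DataFrame(rows)
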