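"""Organizers' reference predictors for the three modeled subchallenges.

* SC1 — one random forest per withheld marker, trained across all
  conditions of a random subset of training cell lines on per-cell features
  (the non-target markers, time, one-hot treatment, starvation and
  stimulation flags).
* SC2 — per-statistic forecasting: for every (time, statistic) an
  independent random forest predicts the statistic's value in a missing
  treatment from its values in the available treatments, with training cell
  lines as samples; predicted means/covariances feed a multivariate-normal
  sampler that emits representative single cells.
* SC4 — superposition: the predicted median time course is the average
  training-cell-line response plus a learned cell-line-specific deviation
  (one forest per marker, driven by the line's basal "full"-condition
  marker medians).

There is no reference predictor for SC3; the imTOR split is scored with the
same statistics score using SC2-style machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .datamodel import (
    CONDITION_COLUMNS,
    KNOWN_INHIBITORS,
    TREATMENT_EGF,
    TREATMENT_FULL,
    TREATMENTS,
    CoverageError,
    ConditionStats,
    FormatError,
    MarkerPanel,
    PredictionSet,
    SingleCellTable,
)
from .scoring import condition_medians

DEFAULT_N_TREES = 100


def _rf(n_trees: int, max_depth: int | None, seed: int,
        max_samples: float | None = None) -> RandomForestRegressor:
    return RandomForestRegressor(n_estimators=n_trees, max_depth=max_depth,
                                 max_samples=max_samples, random_state=seed,
                                 n_jobs=1)


# ---------------------------------------------------------------------------
# SC1: per-marker random forest on single cells
# ---------------------------------------------------------------------------

def sc1_feature_frame(df: pd.DataFrame, feature_markers: list[str]) -> pd.DataFrame:
    """Per-cell design matrix: non-target markers, time, one-hot treatment,
    starvation flag (off only in "full"), stimulation flag (off at time 0
    and in "full")."""
    missing = [m for m in feature_markers if m not in df.columns]
    if missing:
        raise FormatError(f"feature column(s) missing: {missing}")
    x = df[feature_markers].copy()
    if x.isna().any().any():
        raise ValueError("NaN in feature markers")
    x["time"] = df["time"].to_numpy(dtype=float)
    for tr in TREATMENTS:
        x[f"treatment_{tr}"] = (df["treatment"] == tr).astype(float)
    x["starved"] = (df["treatment"] != TREATMENT_FULL).astype(float)
    x["stimulated"] = ((df["treatment"] != TREATMENT_FULL)
                       & (df["time"] > 0)).astype(float)
    return x


@dataclass
class Sc1Model:
    targets: list[str]
    feature_markers: list[str]
    models: dict[str, RandomForestRegressor]
    selected_lines: list[str]


def sc1_fit(train: SingleCellTable, targets: list[str] | None = None,
            n_train_lines: int = 7, cells_per_condition: int = 500,
            seed: int = 0, n_trees: int = DEFAULT_N_TREES,
            max_depth: int | None = None,
            max_samples: float | None = None) -> Sc1Model:
    """Fit the SC1 reference model on a random subset of training lines
    (default 7 lines, 500 cells per condition, mirroring the challenge's
    reference)."""
    panel = train.panel
    targets = list(targets if targets is not None else panel.sc1_targets)
    feature_markers = [m for m in panel.names if m not in targets]
    rng = np.random.default_rng(seed)

    # usable training lines: target markers observed (not withheld as NaN)
    has_targets = (train.data.groupby("cell_line")[targets]
                   .apply(lambda g: g.notna().all().all()))
    lines = sorted(has_targets[has_targets].index)
    if len(lines) < n_train_lines:
        warnings.warn(f"only {len(lines)} training lines available, "
                      f"requested {n_train_lines}; using all")
        selected = lines
    else:
        selected = sorted(rng.choice(lines, size=n_train_lines,
                                     replace=False).tolist())

    sub = train.data[train.data["cell_line"].isin(selected)]
    # at most `cells_per_condition` cells per (line, treatment, time)
    keep_idx = []
    for _, g in sub.groupby(CONDITION_COLUMNS, sort=True):
        idx = g.index.to_numpy()
        if len(idx) > cells_per_condition:
            idx = rng.choice(idx, size=cells_per_condition, replace=False)
        keep_idx.append(np.sort(idx))
    sub = sub.loc[np.concatenate(keep_idx)]

    X = sc1_feature_frame(sub, feature_markers)
    models = {}
    for i, marker in enumerate(targets):
        rf = _rf(n_trees, max_depth, seed + 101 * (i + 1), max_samples)
        rf.fit(X.to_numpy(), sub[marker].to_numpy(dtype=float))
        models[marker] = rf
    return Sc1Model(targets=targets, feature_markers=feature_markers,
                    models=models, selected_lines=list(selected))


def sc1_predict(model: Sc1Model, test: SingleCellTable) -> PredictionSet:
    """Predict each withheld marker for every test cell."""
    X = sc1_feature_frame(test.data, model.feature_markers).to_numpy()
    keys = test.data[["cell_line", "treatment", "time", "cellID"]]
    frames = []
    for marker in model.targets:
        out = keys.copy()
        out["marker"] = marker
        out["value"] = model.models[marker].predict(X)
        frames.append(out)
    return PredictionSet("SC1", pd.concat(frames, ignore_index=True),
                         test.panel)


# ---------------------------------------------------------------------------
# SC2: per-statistic forecasting + Gaussian sampler
# ---------------------------------------------------------------------------

def stat_names(markers: list[str]) -> list[str]:
    names = [f"mean:{m}" for m in markers]
    for i, a in enumerate(markers):
        for b in markers[i:]:
            names.append(f"cov:{a}|{b}")
    return names


def condition_stats_frame(cells: SingleCellTable) -> pd.DataFrame:
    """Flat per-condition statistics table: one row per (cell line,
    treatment, time), one column per statistic (marker means and the upper
    covariance triangle including the diagonal)."""
    markers = list(cells.panel.names)
    m = len(markers)
    iu = np.triu_indices(m)
    cols = stat_names(markers)
    rows = {}
    for key, g in cells.data.groupby(CONDITION_COLUMNS):
        x = g[markers].to_numpy(dtype=float)
        if len(x) < 2:
            raise ValueError(f"condition {key} has fewer than 2 cells")
        cov = np.cov(x, rowvar=False, ddof=1)
        rows[key] = np.concatenate([x.mean(axis=0), cov[iu]])
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    frame.index = pd.MultiIndex.from_tuples(frame.index,
                                            names=CONDITION_COLUMNS)
    return frame


def stats_to_condition(stats_row: pd.Series, markers: list[str]) -> ConditionStats:
    """Rebuild a mean vector and (symmetrized) covariance from a flat
    statistics row."""
    m = len(markers)
    mean = pd.Series([stats_row[f"mean:{mk}"] for mk in markers], index=markers)
    cov = np.zeros((m, m))
    for i, a in enumerate(markers):
        for j in range(i, m):
            v = stats_row[f"cov:{a}|{markers[j]}"]
            cov[i, j] = cov[j, i] = v
    return ConditionStats(mean=mean,
                          cov=pd.DataFrame(cov, index=markers, columns=markers))


def repair_psd(cov: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues to zero (forecast covariances need not be
    positive semidefinite)."""
    cov = (cov + cov.T) / 2.0
    w, v = np.linalg.eigh(cov)
    if w.min() >= 0:
        return cov
    w = np.clip(w, 0.0, None)
    return (v * w) @ v.T


def gaussian_sampler(stats: ConditionStats, n: int = 10000, seed: int = 0,
                     condition: tuple[str, str, float] = ("NA", TREATMENT_EGF, 0.0),
                     fileID: str = "sampled") -> pd.DataFrame:
    """Draw representative single cells from a multivariate normal with the
    given mean and (PSD-repaired) covariance, in single-cell-table layout."""
    cov = np.asarray(stats.cov, dtype=float)
    if cov.shape != (len(stats.mean), len(stats.mean)):
        raise FormatError("covariance must be square and match the mean length")
    rng = np.random.default_rng(seed)
    x = rng.multivariate_normal(stats.mean.to_numpy(), repair_psd(cov),
                                size=n, method="eigh")
    out = pd.DataFrame(x, columns=stats.markers)
    cl, tr, t = condition
    out.insert(0, "cell_line", cl)
    out.insert(1, "treatment", tr)
    out.insert(2, "time", float(t))
    out.insert(3, "cellID", np.arange(n))
    out.insert(4, "fileID", fileID)
    return out


@dataclass
class Sc2Model:
    """One random forest per (target treatment, time, statistic), mapping
    the statistic's values in the feature treatments to its value in the
    target treatment; training cell lines are the samples."""

    panel: MarkerPanel
    target_treatments: list[str]
    feature_treatments: dict[str, list[str]]   # per target treatment
    times: list[float]
    models: dict[tuple[str, float, str], RandomForestRegressor]
    training_lines: list[str]


def sc2_fit(train: SingleCellTable,
            target_treatments: list[str] | None = None,
            feature_treatments: list[str] | None = None,
            n_train_lines: int | None = 7,
            seed: int = 0, n_trees: int = 25,
            max_depth: int | None = None) -> Sc2Model:
    """Fit per-statistic forecasting forests.

    By default each target treatment is predicted from EGF plus the other
    known inhibitor arms (leave-one-treatment-out).  When the available
    context is narrower — e.g. test lines carry only their EGF arm — pass
    ``feature_treatments`` explicitly.  Statistics are aligned on the
    intersection of the treatments' time grids; unshared times fall back to
    the nearest shared time at prediction.
    """
    targets = list(target_treatments if target_treatments is not None
                   else KNOWN_INHIBITORS)
    stats = condition_stats_frame(train)
    feat_map: dict[str, list[str]] = {}
    for tr in targets:
        if feature_treatments is not None:
            feats = [f for f in feature_treatments if f != tr]
        else:
            feats = [TREATMENT_EGF] + [k for k in KNOWN_INHIBITORS if k != tr]
        if not feats:
            raise ValueError(f"no feature treatments for target {tr}")
        feat_map[tr] = feats

    # training lines must carry every involved treatment
    needed = set(targets) | {f for fs in feat_map.values() for f in fs}
    by_line = stats.reset_index().groupby("cell_line")["treatment"] \
        .agg(lambda s: set(s))
    lines = sorted(ln for ln, trs in by_line.items() if needed <= trs)
    if not lines:
        raise ValueError("no training line carries all involved treatments")
    rng = np.random.default_rng(seed)
    if n_train_lines is not None and len(lines) > n_train_lines:
        lines = sorted(rng.choice(lines, size=n_train_lines,
                                  replace=False).tolist())

    # shared time grid across involved treatments
    times_by_tr = stats.reset_index().groupby("treatment")["time"] \
        .agg(lambda s: set(s))
    shared = set.intersection(*(times_by_tr[tr] for tr in sorted(needed)))
    times = sorted(shared)
    if not times:
        raise ValueError("no shared time points across treatments")

    cols = list(stats.columns)
    models: dict[tuple[str, float, str], RandomForestRegressor] = {}
    i = 0
    for tr in targets:
        feats = feat_map[tr]
        for t in times:
            # (lines x stats) blocks per treatment, assembled once
            ymat = stats.loc[[(ln, tr, t) for ln in lines]].to_numpy()
            xmats = np.stack([
                stats.loc[[(ln, f, t) for ln in lines]].to_numpy()
                for f in feats], axis=2)
            for ci, stat in enumerate(cols):
                rf = _rf(n_trees, max_depth, seed + 7919 * (i + 1))
                rf.fit(xmats[:, ci, :], ymat[:, ci])
                models[(tr, t, stat)] = rf
                i += 1
    return Sc2Model(panel=train.panel, target_treatments=targets,
                    feature_treatments=feat_map, times=times,
                    models=models, training_lines=lines)


def _nearest(value: float, options: list[float]) -> float:
    return min(options, key=lambda o: (abs(o - value), o))


def sc2_forecast_stats(model: Sc2Model, context: SingleCellTable,
                       cell_line: str, treatment: str, time: float,
                       _stats: pd.DataFrame | None = None) -> ConditionStats:
    """Forecast the full statistics vector of one missing condition from a
    test line's available arms."""
    stats = _stats if _stats is not None else condition_stats_frame(
        context.subset(cell_lines=[cell_line]))
    feats = model.feature_treatments[treatment]
    t_model = _nearest(time, model.times)
    cols = list(stats.columns)
    xrow = np.empty((len(cols), len(feats)))
    for fi, f in enumerate(feats):
        avail = [t for (_, tr2, t) in stats.index if tr2 == f]
        if not avail:
            raise CoverageError(
                f"line {cell_line!r} lacks feature treatment {f!r}")
        t_feat = _nearest(t_model, sorted(set(avail)))
        xrow[:, fi] = stats.loc[(cell_line, f, t_feat)].to_numpy()
    pred = pd.Series(index=cols, dtype=float)
    for ci, stat in enumerate(cols):
        pred[stat] = model.models[(treatment, t_model, stat)] \
            .predict(xrow[ci][None, :])[0]
    return stats_to_condition(pred, list(model.panel.names))


def sc2_predict(model: Sc2Model, context: SingleCellTable,
                test_lines: list[str],
                times: list[float] | None = None,
                n: int = 10000, seed: int = 0) -> PredictionSet:
    """Forecast statistics for every (test line, target treatment, time)
    and sample n representative cells per condition."""
    times = list(times if times is not None else model.times)
    rng = np.random.default_rng(seed)
    frames = []
    for cl in sorted(test_lines):
        if cl not in set(context.data["cell_line"]):
            raise CoverageError(f"unknown cell line {cl!r}")
        line_stats = condition_stats_frame(context.subset(cell_lines=[cl]))
        for tr in model.target_treatments:
            for t in times:
                stats = sc2_forecast_stats(model, context, cl, tr, t,
                                           _stats=line_stats)
                frames.append(gaussian_sampler(
                    stats, n=n, seed=int(rng.integers(2 ** 31)),
                    condition=(cl, tr, t), fileID=f"{cl}_{tr}_pred"))
    return PredictionSet("SC2", pd.concat(frames, ignore_index=True),
                         model.panel)


# ---------------------------------------------------------------------------
# SC4: superposition of average response and line-specific deviation
# ---------------------------------------------------------------------------

def basal_feature_table(table: SingleCellTable) -> pd.DataFrame:
    """Per-line medians of the unperturbed "full" condition (wide), the
    stand-in for basal omics features."""
    sub = table.data[table.data["treatment"] == TREATMENT_FULL]
    if sub.empty:
        raise CoverageError("no 'full' condition rows to derive basal features")
    return sub.groupby("cell_line")[list(table.panel.names)].median()


@dataclass
class Sc4Model:
    panel: MarkerPanel
    average_response: pd.DataFrame     # (treatment, time, marker, value) long
    deviation_models: dict[str, RandomForestRegressor]
    feature_columns: list[str]
    training_lines: list[str]


def _sc4_features(basal: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Rows of `design` (cell_line, treatment, time) joined with basal
    features, one-hot treatment, time, and stimulation flag."""
    x = design.merge(basal, left_on="cell_line", right_index=True, how="left")
    if x[basal.columns].isna().any().any():
        missing = sorted(set(design["cell_line"]) - set(basal.index))
        raise CoverageError(f"basal features missing for line(s): {missing}")
    for tr in TREATMENTS:
        x[f"treatment_{tr}"] = (x["treatment"] == tr).astype(float)
    x["stimulated"] = (x["time"] > 0).astype(float)
    return x


def sc4_fit(train: SingleCellTable, basal_features: pd.DataFrame | None = None,
            seed: int = 0, n_trees: int = DEFAULT_N_TREES,
            max_depth: int | None = None) -> Sc4Model:
    """Fit the superposition model ``y = y_average + d`` on training lines.

    ``y_average`` is the per-(treatment, time, marker) mean of the training
    lines' per-condition medians; one forest per marker learns the deviation
    ``d`` from basal "full"-condition medians plus treatment/time features.
    """
    med = condition_medians(train)
    perturbed = med[med["treatment"] != TREATMENT_FULL]
    # training lines are those observed beyond their basal state
    train_lines = sorted(perturbed["cell_line"].unique())
    med_train = med[med["cell_line"].isin(train_lines)]

    avg = (med_train.groupby(["treatment", "time", "marker"])["value"]
           .mean().rename("value").reset_index())

    dev = med_train.merge(avg, on=["treatment", "time", "marker"],
                          suffixes=("", "_avg"))
    dev["d"] = dev["value"] - dev["value_avg"]

    basal = basal_features if basal_features is not None \
        else basal_feature_table(train)
    missing = set(train_lines) - set(basal.index)
    if missing:
        raise CoverageError(f"basal features missing for line(s): {sorted(missing)}")

    wide = dev.pivot_table(index=["cell_line", "treatment", "time"],
                           columns="marker", values="d").reset_index()
    X = _sc4_features(basal, wide[["cell_line", "treatment", "time"]])
    feat_cols = [c for c in X.columns
                 if c not in ("cell_line", "treatment")]
    markers = list(train.panel.names)
    models = {}
    for i, marker in enumerate(markers):
        rf = _rf(n_trees, max_depth, seed + 211 * (i + 1))
        rf.fit(X[feat_cols].to_numpy(dtype=float),
               wide[marker].to_numpy(dtype=float))
        models[marker] = rf
    return Sc4Model(panel=train.panel, average_response=avg,
                    deviation_models=models, feature_columns=feat_cols,
                    training_lines=train_lines)


def sc4_predict(model: Sc4Model, test_lines: list[str],
                basal_features: pd.DataFrame,
                include_deviation: bool = True) -> PredictionSet:
    """Median time-course predictions for every perturbed condition of the
    test design; with ``include_deviation=False`` the prediction is the
    bare average-response term."""
    missing = set(test_lines) - set(basal_features.index)
    if missing:
        raise CoverageError(f"basal features missing for line(s): {sorted(missing)}")
    design = model.average_response[["treatment", "time"]].drop_duplicates()
    frames = []
    for cl in sorted(test_lines):
        d = design.copy()
        d.insert(0, "cell_line", cl)
        base = d.merge(model.average_response, on=["treatment", "time"])
        if include_deviation:
            X = _sc4_features(basal_features, d)
            if list(X.columns.drop(["cell_line", "treatment"])) != \
                    model.feature_columns:
                raise FormatError("basal feature columns do not match the "
                                  "fitted model")
            xmat = X[model.feature_columns].to_numpy(dtype=float)
            dev = pd.DataFrame(
                {m: model.deviation_models[m].predict(xmat)
                 for m in model.panel.names})
            dev = pd.concat([d.reset_index(drop=True), dev], axis=1) \
                .melt(id_vars=["cell_line", "treatment", "time"],
                      var_name="marker", value_name="d")
            base = base.merge(dev, on=["cell_line", "treatment", "time",
                                       "marker"])
            base["value"] = base["value"] + base["d"]
            base = base.drop(columns="d")
        frames.append(base)
    return PredictionSet("SC4", pd.concat(frames, ignore_index=True),
                         model.panel)
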