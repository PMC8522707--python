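"""Core domain types and I/O for long-format single-cell perturbation tables.

The data layout mirrors mass-cytometry perturbation screens: one row per
cell, keyed by (cell_line, treatment, time, cellID, fileID), followed by one
column per marker.  Values are assumed to arrive already variance-stabilized
(arcsinh-transformed upstream); no transform is applied here.

Missing values are encoded as NaN.  Scoring rejects NaN; predictors that
declare imputation may accept them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Treatments
# ---------------------------------------------------------------------------

TREATMENT_FULL = "full"
TREATMENT_EGF = "EGF"
INHIBITORS = ("iEGFR", "iMEK", "iPI3K", "iPKC", "imTOR")
KNOWN_INHIBITORS = ("iEGFR", "iMEK", "iPI3K", "iPKC")  # imTOR is held out
TREATMENTS = (TREATMENT_FULL, TREATMENT_EGF) + INHIBITORS

KEY_COLUMNS = ["cell_line", "treatment", "time", "cellID", "fileID"]
CONDITION_COLUMNS = ["cell_line", "treatment", "time"]


class FormatError(ValueError):
    """A table or file does not conform to the expected layout."""


class CoverageError(ValueError):
    """A prediction or lookup table does not cover a required key."""


# ---------------------------------------------------------------------------
# Marker panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerPanel:
    """An ordered antibody panel of phospho and cellular markers.

    Parameters
    ----------
    phospho, cellular
        Disjoint marker name lists; their concatenation defines the panel
        order used throughout (readers validate against it, the synthetic
        network is lower-triangular in it).
    sc1_targets
        The five phospho markers withheld in the missing-marker task.
    cycle_markers
        Mapping of cell-cycle roles {"IdU", "p.H3", "cyclinB", "p.RB",
        "cleavedCas"} to panel names.
    """

    phospho: tuple[str, ...]
    cellular: tuple[str, ...]
    sc1_targets: tuple[str, ...]
    cycle_markers: Mapping[str, str]

    def __post_init__(self) -> None:
        names = self.names
        if len(set(names)) != len(names):
            raise FormatError("marker names must be unique")
        if set(self.phospho) & set(self.cellular):
            raise FormatError("phospho and cellular markers must be disjoint")
        missing = set(self.sc1_targets) - set(names)
        if missing:
            raise FormatError(f"sc1_targets not in panel: {sorted(missing)}")
        bad = set(self.cycle_markers.values()) - set(names)
        if bad:
            raise FormatError(f"cycle markers not in panel: {sorted(bad)}")

    @property
    def names(self) -> tuple[str, ...]:
        return self.phospho + self.cellular

    @property
    def n_markers(self) -> int:
        return len(self.names)

    def index_of(self, marker: str) -> int:
        return self.names.index(marker)


# Default panel: 31 phospho + 5 cellular markers, ordered topologically for
# the synthetic signaling network (receptors first, terminal nodes last).
_DEFAULT_PHOSPHO = (
    "p.EGFR", "p.HER2", "p.MEK", "p.PDPK1", "p.PLCg2", "p.SRC",
    "p.ERK", "p.AKT.S473", "p.PKC", "p.p90RSK", "p.GSK3b", "p.S6K",
    "p.MKK3.MKK6", "p.MKK4", "p.FAK", "p.STAT1", "p.STAT3", "p.STAT5",
    "p.p38", "p.JNK", "p.NFkB", "p.S6", "p.4EBP1", "p.CREB",
    "p.MAPKAPK2", "p.cJUN", "p.AMPK", "p.SMAD23", "p.p53", "p.RB", "p.H3",
)
_DEFAULT_CELLULAR = ("IdU", "cyclinB", "cleavedCas", "Ki.67", "GAPDH")

DEFAULT_PANEL = MarkerPanel(
    phospho=_DEFAULT_PHOSPHO,
    cellular=_DEFAULT_CELLULAR,
    sc1_targets=("p.ERK", "p.AKT.S473", "p.PLCg2", "p.HER2", "p.S6"),
    cycle_markers={
        "IdU": "IdU",
        "p.H3": "p.H3",
        "cyclinB": "cyclinB",
        "p.RB": "p.RB",
        "cleavedCas": "cleavedCas",
    },
)

assert len(DEFAULT_PANEL.phospho) == 31 and len(DEFAULT_PANEL.cellular) == 5


# ---------------------------------------------------------------------------
# Single-cell table
# ---------------------------------------------------------------------------

@dataclass
class SingleCellTable:
    """A validated long-format single-cell table.

    ``data`` holds columns (cell_line, treatment, time, cellID, fileID)
    followed by one column per panel marker.  cellID is unique within each
    (cell_line, treatment, time) condition.
    """

    data: pd.DataFrame
    panel: MarkerPanel

    def __post_init__(self) -> None:
        missing = [c for c in KEY_COLUMNS + list(self.panel.names)
                   if c not in self.data.columns]
        if missing:
            raise FormatError(f"missing required column(s): {missing}")
        # canonical column order
        self.data = self.data[KEY_COLUMNS + list(self.panel.names)].reset_index(drop=True)
        bad = set(self.data["treatment"].unique()) - set(TREATMENTS)
        if bad:
            raise FormatError(f"unknown treatment(s): {sorted(bad)}")
        if len(self.data) and self.data.duplicated(
                subset=["cell_line", "treatment", "time", "cellID"]).any():
            raise FormatError("duplicate (condition, cellID) rows")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.data["cell_line"].unique())

    def conditions(self) -> pd.DataFrame:
        """Unique (cell_line, treatment, time) combinations, sorted."""
        return (self.data[CONDITION_COLUMNS].drop_duplicates()
                .sort_values(CONDITION_COLUMNS).reset_index(drop=True))

    def values_matrix(self) -> np.ndarray:
        """Marker values as an (n_cells, n_markers) array in panel order."""
        return self.data[list(self.panel.names)].to_numpy(dtype=float)

    def subset(self, *, cell_lines: Iterable[str] | None = None,
               treatments: Iterable[str] | None = None,
               times: Iterable[float] | None = None) -> "SingleCellTable":
        mask = pd.Series(True, index=self.data.index)
        if cell_lines is not None:
            mask &= self.data["cell_line"].isin(list(cell_lines))
        if treatments is not None:
            mask &= self.data["treatment"].isin(list(treatments))
        if times is not None:
            mask &= self.data["time"].isin(list(times))
        return SingleCellTable(self.data[mask].copy(), self.panel)


# ---------------------------------------------------------------------------
# Prediction sets and score reports
# ---------------------------------------------------------------------------

#: long per-cell layout used by SC1 predictions
SC1_COLUMNS = ["cell_line", "treatment", "time", "cellID", "marker", "value"]
#: per-condition median layout used by SC4 predictions
SC4_COLUMNS = ["cell_line", "treatment", "time", "marker", "value"]


@dataclass
class PredictionSet:
    """A submission for one subchallenge.

    * SC1 — long table (cell_line, treatment, time, cellID, marker, value),
      one row per truth cell per target marker.
    * SC2/SC3 — a :class:`SingleCellTable`-shaped frame with a constant
      number of sampled cells per predicted condition.
    * SC4 — per-condition median table (cell_line, treatment, time, marker,
      value).
    """

    subchallenge: str
    data: pd.DataFrame
    panel: MarkerPanel | None = None

    def __post_init__(self) -> None:
        if self.subchallenge not in {"SC1", "SC2", "SC3", "SC4"}:
            raise FormatError(f"unknown subchallenge {self.subchallenge!r}")
        expected = {"SC1": SC1_COLUMNS, "SC4": SC4_COLUMNS}.get(self.subchallenge)
        if expected is not None:
            missing = [c for c in expected if c not in self.data.columns]
            if missing:
                raise FormatError(
                    f"{self.subchallenge} prediction missing column(s): {missing}")
            self.data = self.data[expected].reset_index(drop=True)
        else:
            if self.panel is None:
                raise FormatError("SC2/SC3 predictions require a panel")
            missing = [c for c in KEY_COLUMNS + list(self.panel.names)
                       if c not in self.data.columns]
            if missing:
                raise FormatError(
                    f"{self.subchallenge} prediction missing column(s): {missing}")
            counts = self.data.groupby(CONDITION_COLUMNS, sort=False).size()
            if len(counts) and counts.nunique() != 1:
                raise FormatError(
                    "SC2/SC3 predictions must have a constant per-condition cell count")

    def cells(self) -> SingleCellTable:
        if self.subchallenge not in {"SC2", "SC3"}:
            raise FormatError("only SC2/SC3 predictions are cell tables")
        return SingleCellTable(self.data.copy(), self.panel)


@dataclass
class ConditionStats:
    """Per-condition mean vector and covariance matrix over markers."""

    mean: pd.Series          # index: marker names
    cov: pd.DataFrame        # index/columns: marker names
    n_cells: int | None = None

    def __post_init__(self) -> None:
        if list(self.mean.index) != list(self.cov.index) or \
                list(self.cov.index) != list(self.cov.columns):
            raise FormatError("mean and covariance marker labels must align")

    @property
    def markers(self) -> list[str]:
        return list(self.mean.index)


@dataclass
class ScoreReport:
    """Per-condition scores plus the final (mean) score of a submission."""

    per_condition: pd.DataFrame   # grouping columns + a "score" column
    final: float
    bootstrap: np.ndarray | None = None
    diagnostics: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if "score" not in self.per_condition.columns:
            raise FormatError("per_condition must contain a 'score' column")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_cells(path, panel: MarkerPanel = DEFAULT_PANEL) -> SingleCellTable:
    """Read a long-format single-cell CSV into a validated table."""
    df = pd.read_csv(path)
    missing = [c for c in KEY_COLUMNS + list(panel.names) if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    for m in panel.names:
        try:
            df[m] = pd.to_numeric(df[m])
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[m], errors="coerce").isna() & df[m].notna()
            row = int(np.flatnonzero(bad.to_numpy())[0]) if bad.any() else -1
            raise FormatError(
                f"{path}: non-numeric value in column {m!r} at row {row}") from exc
    df["time"] = pd.to_numeric(df["time"])
    return SingleCellTable(df, panel)


def write_cells(table: SingleCellTable, path) -> None:
    """Write a table in the canonical long CSV layout."""
    table.data.to_csv(path, index=False)


def read_predictions(path, subchallenge: str,
                     panel: MarkerPanel = DEFAULT_PANEL) -> PredictionSet:
    df = pd.read_csv(path)
    if subchallenge in {"SC2", "SC3"}:
        df["time"] = pd.to_numeric(df["time"])
        return PredictionSet(subchallenge, df, panel)
    df["time"] = pd.to_numeric(df["time"])
    df["value"] = pd.to_numeric(df["value"])
    return PredictionSet(subchallenge, df, panel)


def write_predictions(pred: PredictionSet, path) -> None:
    pred.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Challenge splits
# ---------------------------------------------------------------------------

@dataclass
class Split:
    train: SingleCellTable
    test: SingleCellTable
    withheld: str


@dataclass
class SplitDesign:
    """Which cell lines (or treatment) each subchallenge withholds.

    Defaults mirror the challenge: 6 test lines for SC1, 12 for SC2, the
    imTOR arm for SC3, 5 test lines for SC4.  Lines may be named explicitly;
    otherwise they are drawn at random with the split seed.
    """

    sc1_test_lines: tuple[str, ...] | int = 6
    sc2_test_lines: tuple[str, ...] | int = 12
    sc3_treatment: str = "imTOR"
    sc4_test_lines: tuple[str, ...] | int = 5


def _resolve_lines(requested, all_lines: Sequence[str],
                   rng: np.random.Generator, label: str) -> list[str]:
    if isinstance(requested, int):
        if requested > len(all_lines):
            raise FormatError(f"{label}: requested {requested} test lines, "
                              f"only {len(all_lines)} present")
        return sorted(rng.choice(all_lines, size=requested,
                                 replace=False).tolist())
    missing = set(requested) - set(all_lines)
    if missing:
        raise FormatError(f"{label}: test cell line(s) absent: {sorted(missing)}")
    return sorted(requested)


def split_challenge(table: SingleCellTable,
                    design: SplitDesign | None = None,
                    seed: int = 0,
                    subchallenges: Sequence[str] | None = None
                    ) -> dict[str, Split]:
    """Partition a dataset into the subchallenge train/test splits.

    SC1 withholds the five target-marker *columns* of the test lines (their
    rows stay in train with those columns set to NaN); SC2 withholds the
    known-inhibitor arms of its test lines; SC3 withholds the imTOR arm of
    every line; SC4 withholds everything but the unperturbed "full" rows of
    its test lines.  Test lines for the different subchallenges are drawn
    independently (each draw consumes the seeded stream in the fixed order
    SC1, SC2, SC4), so requesting a subset still reproduces the full run's
    assignment for the subchallenges it contains only when the subset is a
    prefix of that order.
    """
    design = design or SplitDesign()
    wanted = set(subchallenges or ("SC1", "SC2", "SC3", "SC4"))
    rng = np.random.default_rng(seed)
    df = table.data
    lines = table.cell_lines
    panel = table.panel

    splits: dict[str, Split] = {}

    if "SC1" in wanted:
        # SC1: column split for the target markers of the test lines
        sc1_lines = _resolve_lines(design.sc1_test_lines, lines, rng, "SC1")
        in_test = df["cell_line"].isin(sc1_lines)
        train1 = df.copy()
        train1.loc[in_test, list(panel.sc1_targets)] = np.nan
        test1 = df[in_test].copy()
        splits["SC1"] = Split(
            SingleCellTable(train1, panel), SingleCellTable(test1, panel),
            f"target markers {list(panel.sc1_targets)} of test lines {sc1_lines}")

    if "SC2" in wanted:
        # SC2: known-inhibitor rows of the test lines; imTOR rows stay in train
        sc2_lines = _resolve_lines(design.sc2_test_lines, lines, rng, "SC2")
        mask2 = df["cell_line"].isin(sc2_lines) \
            & df["treatment"].isin(KNOWN_INHIBITORS)
        splits["SC2"] = Split(
            SingleCellTable(df[~mask2].copy(), panel),
            SingleCellTable(df[mask2].copy(), panel),
            f"treatments {list(KNOWN_INHIBITORS)} of test lines {sc2_lines}")

    if "SC3" in wanted:
        # SC3: the withheld treatment everywhere
        mask3 = df["treatment"] == design.sc3_treatment
        splits["SC3"] = Split(
            SingleCellTable(df[~mask3].copy(), panel),
            SingleCellTable(df[mask3].copy(), panel),
            f"treatment {design.sc3_treatment} of all lines")

    if "SC4" in wanted:
        # SC4: everything but basal ("full") rows of the test lines
        sc4_lines = _resolve_lines(design.sc4_test_lines, lines, rng, "SC4")
        mask4 = df["cell_line"].isin(sc4_lines) \
            & (df["treatment"] != TREATMENT_FULL)
        splits["SC4"] = Split(
            SingleCellTable(df[~mask4].copy(), panel),
            SingleCellTable(df[mask4].copy(), panel),
            f"all perturbed conditions of test lines {sc4_lines}")

    return splits
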