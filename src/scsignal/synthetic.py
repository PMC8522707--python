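"""Synthetic single-cell perturbation-response generator.

Emulates the statistical structure of a mass-cytometry kinase-inhibitor
screen: cell-line-specific basal offsets, stimulus responses that rise and
saturate as ``s(t) = 1 - exp(-t/tau)``, inhibitors that silence their target
kinase's *outgoing* signaling (the target's own phosphorylation persists,
its substrates stop responding), a rare subset of "non-canonical" cell lines
in which one substrate ignores an upstream inhibitor, and a cell-cycle
mixture that shifts IdU / p.H3 / cyclinB / p.RB / cleavedCas per phase.

Signal propagation is linear over an acyclic network (strictly
lower-triangular weight matrix in panel order), which keeps every
per-condition mean and covariance available in closed form
(:func:`true_condition_stats`) as an exact oracle for tests.

Two further structural features mirror what mass-cytometry perturbation
data look like.  First, cell lines modulate the *size* of their response:
a per-(line, marker) amplitude multiplies the canonical propagated response
once, driven by a per-line latent factor that also shifts the line's basal
offsets — so a line's basal state is informative about its response, the
premise of the basal-omics prediction task.  Second, single cells within a
condition co-fluctuate: a per-cell latent activity factor loads on all
phospho markers, producing the within-condition marker covariance that
missing-marker imputation exploits and the covariance score measures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    DEFAULT_PANEL,
    INHIBITORS,
    TREATMENT_EGF,
    TREATMENT_FULL,
    MarkerPanel,
    SingleCellTable,
)

PHASES = ("G0G1", "S", "G2", "M", "apoptotic")
DEFAULT_PHASE_PROPORTIONS = (0.60, 0.15, 0.12, 0.08, 0.05)

# Backbone signaling edges (parent -> child) used by the default network.
_BACKBONE_EDGES = [
    ("p.EGFR", "p.MEK"), ("p.EGFR", "p.PLCg2"), ("p.EGFR", "p.PDPK1"),
    ("p.EGFR", "p.SRC"),
    ("p.HER2", "p.MEK"), ("p.HER2", "p.PDPK1"),
    ("p.MEK", "p.ERK"),
    ("p.ERK", "p.p90RSK"),
    ("p.p90RSK", "p.S6"), ("p.p90RSK", "p.CREB"),
    ("p.PDPK1", "p.AKT.S473"), ("p.PDPK1", "p.PKC"),
    ("p.AKT.S473", "p.GSK3b"), ("p.AKT.S473", "p.S6K"),
    ("p.S6K", "p.S6"), ("p.S6K", "p.4EBP1"),
    ("p.PLCg2", "p.PKC"),
    ("p.PKC", "p.MKK3.MKK6"), ("p.PKC", "p.NFkB"), ("p.PKC", "p.MKK4"),
    ("p.MKK3.MKK6", "p.p38"),
    ("p.p38", "p.MAPKAPK2"),
    ("p.MKK4", "p.JNK"),
    ("p.JNK", "p.cJUN"),
    ("p.SRC", "p.FAK"), ("p.SRC", "p.STAT1"), ("p.SRC", "p.STAT3"),
    ("p.SRC", "p.STAT5"),
]

DEFAULT_STIMULUS_INPUT = ("p.EGFR", "p.HER2")
DEFAULT_INHIBITOR_TARGETS = {
    "iEGFR": "p.EGFR",
    "iMEK": "p.MEK",
    "iPI3K": "p.PDPK1",
    "iPKC": "p.PKC",
    "imTOR": "p.S6K",
}
# In non-canonical lines this substrate keeps responding under the inhibitor.
DEFAULT_NONCANONICAL_EDGE = ("iMEK", "p.MEK", "p.ERK")


@dataclass
class SyntheticConfig:
    """Study design of the synthetic challenge.

    Defaults are the package's default study conditions: 20 cell lines with
    500 cells per condition, one basal time point, a 10-point one-hour grid
    for the EGF arm and a 7-point subset for inhibitor arms, and a 7.5%
    rare fraction of non-canonical lines.
    """

    n_cell_lines: int = 20
    cells_per_condition: int = 500
    basal_times: tuple[float, ...] = (0.0,)
    stimulated_times: tuple[float, ...] = (0.0, 5.5, 7.0, 9.0, 13.0, 17.0,
                                           23.0, 30.0, 40.0, 60.0)
    inhibitor_times: tuple[float, ...] = (0.0, 7.0, 13.0, 23.0, 30.0, 40.0, 60.0)
    rare_fraction: float = 5 / 67
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_lines <= 0 or self.cells_per_condition <= 0:
            raise ValueError("counts must be positive")
        if not (0 <= self.rare_fraction < 1):
            raise ValueError("rare_fraction must be in [0, 1)")

    def design(self) -> list[tuple[str, float]]:
        """All (treatment, time) pairs of the design, in canonical order."""
        pairs = [(TREATMENT_FULL, t) for t in self.basal_times]
        pairs += [(TREATMENT_EGF, t) for t in self.stimulated_times]
        for inh in INHIBITORS:
            pairs += [(inh, t) for t in self.inhibitor_times]
        return pairs


@dataclass
class SyntheticModel:
    """Latent parameters of one synthetic challenge instance."""

    panel: MarkerPanel
    cell_lines: tuple[str, ...]
    network: np.ndarray                  # (m, m) strictly lower-triangular
    stimulus_input: tuple[str, ...]
    inhibitor_targets: dict[str, str]
    basal_offsets: pd.DataFrame          # lines x markers
    response_amplitude: pd.DataFrame     # lines x markers
    tau: float
    noise_sd: pd.Series                  # per marker
    cell_factor_loading: pd.Series       # per marker (0 for cellular)
    phase_proportions: pd.Series         # per phase
    phase_shifts: pd.DataFrame           # phases x markers (0 off-cycle)
    noncanonical_lines: tuple[str, ...]
    noncanonical_edge: tuple[str, str, str] = DEFAULT_NONCANONICAL_EDGE
    inhibition_factor: float = 0.0

    def __post_init__(self) -> None:
        m = self.panel.n_markers
        if self.network.shape != (m, m):
            raise ValueError("network shape must match panel size")
        if np.any(np.triu(self.network) != 0):
            raise ValueError("network must be strictly lower-triangular")
        if not np.isclose(self.phase_proportions.sum(), 1.0):
            raise ValueError("phase proportions must sum to 1")
        if (self.noise_sd <= 0).any():
            raise ValueError("noise_sd must be positive")

    # -- closed-form mean response ------------------------------------------

    def stimulus(self, time: float) -> float:
        return 1.0 - float(np.exp(-time / self.tau))

    def canonical_response(self, cell_line: str, treatment: str,
                           time: float) -> np.ndarray:
        """Line-independent propagated response (the non-canonical escape
        still depends on the line, hence the argument): stimulus pushed
        through the network in topological order with the treatment's
        inhibition applied to the target's outgoing edges."""
        names = self.panel.names
        m = len(names)
        idx = {n: i for i, n in enumerate(names)}
        s = 0.0 if treatment == TREATMENT_FULL else self.stimulus(time)
        target = self.inhibitor_targets.get(treatment)
        t_idx = idx[target] if target is not None else -1
        nc_tr, nc_parent, nc_child = self.noncanonical_edge
        nc_active = (treatment == nc_tr and cell_line in self.noncanonical_lines)

        r = np.zeros(m)
        src = set(self.stimulus_input)
        for j in range(m):
            inc = 0.0
            row = self.network[j]
            for k in np.flatnonzero(row):
                g = self.inhibition_factor if k == t_idx else 1.0
                if (nc_active and names[k] == nc_parent and names[j] == nc_child):
                    g = 1.0
                inc += row[k] * g * r[k]
            drive = s if names[j] in src else 0.0
            r[j] = drive + inc
        return r

    def mean_response(self, cell_line: str, treatment: str,
                      time: float) -> pd.Series:
        """Deterministic signaling component of the mean, before the basal
        offset and cell-cycle shift: the canonical propagated response
        scaled once by the line's per-marker amplitude."""
        amp = self.response_amplitude.loc[cell_line].to_numpy()
        r = self.canonical_response(cell_line, treatment, time)
        return pd.Series(amp * r, index=list(self.panel.names))

    def condition_mean_components(self, cell_line: str, treatment: str,
                                  time: float) -> pd.Series:
        """Basal offset + propagated response (no cell-cycle shift)."""
        return self.basal_offsets.loc[cell_line] + \
            self.mean_response(cell_line, treatment, time)


def make_model(config: SyntheticConfig, seed: int | None = None,
               panel: MarkerPanel = DEFAULT_PANEL,
               tau: float = 10.0, gate_shift: float = 3.0) -> SyntheticModel:
    """Draw a reproducible model instance for the given design.

    Cell lines share one signaling network; a per-line latent factor z links
    basal offsets and response amplitudes, so a line's basal state carries
    information about its perturbation response (the premise of the
    time-course prediction task).
    """
    if not (0 <= config.rare_fraction < 1):
        raise ValueError("rare_fraction must be in [0, 1)")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    names = list(panel.names)
    m = len(names)
    idx = {n: i for i, n in enumerate(names)}

    network = np.zeros((m, m))
    for parent, child in _BACKBONE_EDGES:
        i, j = idx[child], idx[parent]
        if j >= i:
            raise ValueError(f"edge {parent}->{child} violates panel order")
        network[i, j] = rng.normal(1.0, 0.1)

    lines = tuple(f"CL{i + 1:02d}" for i in range(config.n_cell_lines))
    z = rng.normal(0.0, 1.0, size=config.n_cell_lines)

    base = rng.uniform(2.0, 4.0, size=m)
    beta = rng.normal(0.0, 0.4, size=m)
    basal = (base[None, :] + np.outer(z, beta)
             + rng.normal(0.0, 0.1, size=(config.n_cell_lines, m)))
    basal_offsets = pd.DataFrame(basal, index=list(lines), columns=names)

    amp = 1.0 + 0.25 * z[:, None] + rng.normal(0.0, 0.05,
                                               size=(config.n_cell_lines, m))
    response_amplitude = pd.DataFrame(np.clip(amp, 0.2, None),
                                      index=list(lines), columns=names)

    noise_sd = pd.Series(rng.uniform(0.25, 0.35, size=m), index=names)

    # per-cell activity factor loads on phospho markers only, so single
    # cells co-fluctuate within a condition (cellular markers stay clean
    # for gating)
    loading = pd.Series(0.0, index=names)
    loading[list(panel.phospho)] = rng.uniform(0.2, 0.4, size=len(panel.phospho))

    shifts = pd.DataFrame(0.0, index=list(PHASES), columns=names)
    cm = panel.cycle_markers
    shifts.loc["S", cm["IdU"]] = gate_shift
    shifts.loc["G2", cm["cyclinB"]] = gate_shift
    shifts.loc["M", cm["p.H3"]] = gate_shift
    shifts.loc["M", cm["cyclinB"]] = gate_shift
    shifts.loc["apoptotic", cm["cleavedCas"]] = gate_shift
    # p.RB rises through S/G2/M but is deliberately not separable by itself
    shifts.loc[["S", "G2", "M"], cm["p.RB"]] = 0.3 * gate_shift

    n_rare = int(round(config.rare_fraction * config.n_cell_lines))
    noncanonical = tuple(sorted(map(str, rng.choice(
        lines, size=n_rare, replace=False)))) if n_rare else ()

    return SyntheticModel(
        panel=panel,
        cell_lines=lines,
        network=network,
        stimulus_input=DEFAULT_STIMULUS_INPUT,
        inhibitor_targets=dict(DEFAULT_INHIBITOR_TARGETS),
        basal_offsets=basal_offsets,
        response_amplitude=response_amplitude,
        tau=tau,
        noise_sd=noise_sd,
        cell_factor_loading=loading,
        phase_proportions=pd.Series(DEFAULT_PHASE_PROPORTIONS, index=list(PHASES)),
        phase_shifts=shifts,
        noncanonical_lines=noncanonical,
    )


def simulate_dataset(model: SyntheticModel, config: SyntheticConfig,
                     seed: int | None = None,
                     return_phases: bool = False):
    """Draw a full single-cell dataset from the model.

    Per cell: a latent cycle phase from the mixture and a latent activity
    factor eta ~ N(0,1), then ``value = basal + propagated response
    + phase shift + eta * loading + N(0, noise_sd)``.  Deterministic given
    the seed; with ``return_phases`` the latent phase labels are returned
    alongside (for gating oracles).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    names = list(model.panel.names)
    n = config.cells_per_condition
    props = model.phase_proportions.to_numpy()
    shifts = model.phase_shifts.to_numpy()
    sds = model.noise_sd.to_numpy()
    loading = model.cell_factor_loading.to_numpy()

    frames = []
    phase_rows = []
    for cl in model.cell_lines:
        for treatment, time in config.design():
            mu = model.condition_mean_components(cl, treatment, time).to_numpy()
            phase_idx = rng.choice(len(PHASES), size=n, p=props)
            eta = rng.normal(0.0, 1.0, size=n)
            values = (mu[None, :] + shifts[phase_idx]
                      + eta[:, None] * loading[None, :]
                      + rng.normal(0.0, sds, size=(n, len(names))))
            frame = pd.DataFrame(values, columns=names)
            frame.insert(0, "cell_line", cl)
            frame.insert(1, "treatment", treatment)
            frame.insert(2, "time", time)
            frame.insert(3, "cellID", np.arange(n))
            frame.insert(4, "fileID", f"{cl}_{treatment}")
            frames.append(frame)
            if return_phases:
                ph = frame[["cell_line", "treatment", "time", "cellID"]].copy()
                ph["phase"] = [PHASES[i] for i in phase_idx]
                phase_rows.append(ph)

    table = SingleCellTable(pd.concat(frames, ignore_index=True), model.panel)
    if return_phases:
        return table, pd.concat(phase_rows, ignore_index=True)
    return table


def true_condition_stats(model: SyntheticModel, cell_line: str,
                         treatment: str, time: float):
    """Exact mean vector and covariance of one condition.

    Mean adds the mixture-average phase shift; covariance is the diagonal
    noise, plus the rank-one contribution of the per-cell activity factor
    (loading outer product), plus the between-phase covariance of the
    shifts (law of total variance) on the cycle-marker block.
    """
    from .datamodel import ConditionStats

    if cell_line not in model.cell_lines:
        raise KeyError(f"unknown cell line {cell_line!r}")
    names = list(model.panel.names)
    props = model.phase_proportions.to_numpy()
    shifts = model.phase_shifts.to_numpy()
    loading = model.cell_factor_loading.to_numpy()

    mu = model.condition_mean_components(cell_line, treatment, time).to_numpy()
    mean_shift = props @ shifts
    mean = mu + mean_shift

    centered = shifts - mean_shift[None, :]
    between = (centered * props[:, None]).T @ centered
    cov = (np.diag(model.noise_sd.to_numpy() ** 2)
           + np.outer(loading, loading) + between)

    return ConditionStats(
        mean=pd.Series(mean, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
    )


# ---------------------------------------------------------------------------
# Serialization (model reuse as an oracle across CLI steps)
# ---------------------------------------------------------------------------

def model_to_json(model: SyntheticModel, path) -> None:
    payload = {
        "phospho": list(model.panel.phospho),
        "cellular": list(model.panel.cellular),
        "sc1_targets": list(model.panel.sc1_targets),
        "cycle_markers": dict(model.panel.cycle_markers),
        "cell_lines": list(model.cell_lines),
        "network": model.network.tolist(),
        "stimulus_input": list(model.stimulus_input),
        "inhibitor_targets": model.inhibitor_targets,
        "basal_offsets": model.basal_offsets.to_dict(orient="split"),
        "response_amplitude": model.response_amplitude.to_dict(orient="split"),
        "tau": model.tau,
        "noise_sd": model.noise_sd.to_dict(),
        "cell_factor_loading": model.cell_factor_loading.to_dict(),
        "phase_proportions": model.phase_proportions.to_dict(),
        "phase_shifts": model.phase_shifts.to_dict(orient="split"),
        "noncanonical_lines": list(model.noncanonical_lines),
        "noncanonical_edge": list(model.noncanonical_edge),
        "inhibition_factor": model.inhibition_factor,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def model_from_json(path) -> SyntheticModel:
    with open(path) as fh:
        p = json.load(fh)
    panel = MarkerPanel(
        phospho=tuple(p["phospho"]), cellular=tuple(p["cellular"]),
        sc1_targets=tuple(p["sc1_targets"]), cycle_markers=p["cycle_markers"])

    def frame(d):
        return pd.DataFrame(d["data"], index=d["index"], columns=d["columns"])

    names = list(panel.names)
    return SyntheticModel(
        panel=panel,
        cell_lines=tuple(p["cell_lines"]),
        network=np.asarray(p["network"]),
        stimulus_input=tuple(p["stimulus_input"]),
        inhibitor_targets=p["inhibitor_targets"],
        basal_offsets=frame(p["basal_offsets"]),
        response_amplitude=frame(p["response_amplitude"]),
        tau=p["tau"],
        noise_sd=pd.Series(p["noise_sd"]).reindex(names),
        cell_factor_loading=pd.Series(p["cell_factor_loading"]).reindex(names),
        phase_proportions=pd.Series(p["phase_proportions"]).reindex(list(PHASES)),
        phase_shifts=frame(p["phase_shifts"]),
        noncanonical_lines=tuple(p["noncanonical_lines"]),
        noncanonical_edge=tuple(p["noncanonical_edge"]),
        inhibition_factor=p["inhibition_factor"],
    )
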