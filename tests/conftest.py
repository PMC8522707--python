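import numpy as np
import pandas as pd
import pytest

from scsignal import MarkerPanel, SingleCellTable


@pytest.fixture(scope="session")
def mini_panel():
    """Five-marker panel (2 phospho + 3 cellular) for fast scoring tests."""
    return MarkerPanel(
        phospho=("m1", "m2"),
        cellular=("IdU", "cyclinB", "cleavedCas"),
        sc1_targets=("m1",),
        cycle_markers={"IdU": "IdU", "p.H3": "m1", "cyclinB": "cyclinB",
                       "p.RB": "m2", "cleavedCas": "cleavedCas"},
    )


def make_cells(panel, conditions, n_cells, rng, mean=0.0, sd=1.0):
    """Gaussian cells for the given (cell_line, treatment, time) keys."""
    frames = []
    for cl, tr, t in conditions:
        vals = rng.normal(mean, sd, size=(n_cells, panel.n_markers))
        df = pd.DataFrame(vals, columns=list(panel.names))
        df.insert(0, "cell_line", cl)
        df.insert(1, "treatment", tr)
        df.insert(2, "time", float(t))
        df.insert(3, "cellID", np.arange(n_cells))
        df.insert(4, "fileID", f"{cl}_{tr}")
        frames.append(df)
    return SingleCellTable(pd.concat(frames, ignore_index=True), panel)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
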