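import numpy as np
import pytest

from understory.data import CensusedPlot, Experiment, IndividualRecord, RectWindow


@pytest.fixture
def window():
    return RectWindow(1.1, 0.9)


def make_plot(species_xy, plot_id="p1", block_id="b1", treatment="no", census="t1",
              window=RectWindow(1.1, 0.9)):
    individuals = [IndividualRecord(s, x, y) for s, x, y in species_xy]
    return CensusedPlot(plot_id, block_id, treatment, census, window, individuals)


@pytest.fixture
def tiny_experiment(window):
    """Two plots, two censuses, hand-placed individuals."""
    plots = [
        make_plot([("A", 0.1, 0.1), ("A", 0.5, 0.5), ("B", 0.9, 0.7)],
                  "p1", "b1", "no", "t1", window),
        make_plot([("A", 0.1, 0.1), ("B", 0.9, 0.7)], "p1", "b1", "no", "t2", window),
        make_plot([("A", 0.2, 0.2), ("C", 0.6, 0.3)], "p2", "b1", "strong", "t1", window),
        make_plot([("C", 0.6, 0.3)], "p2", "b1", "strong", "t2", window),
    ]
    return Experiment(plots=plots)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
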