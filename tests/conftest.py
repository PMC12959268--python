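import numpy as np
import pytest

from hamascreen import DEFAULT_PANEL, SubstratePanel, WellMeasurement


@pytest.fixture
def panel() -> SubstratePanel:
    return DEFAULT_PANEL


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def make_well(panel):
    """Factory for wells with concentrations given as a substrate->µM dict."""

    def _make(
        variant_label="WT",
        conc=None,
        plate_id="P01",
        well="A1",
        batch_id=None,
        replicate=1,
    ):
        vec = np.zeros(len(panel))
        if conc:
            for sub, value in conc.items():
                vec[panel.index(sub)] = value
        return WellMeasurement(
            plate_id=plate_id,
            well=well,
            variant_label=variant_label,
            batch_id=batch_id if batch_id is not None else plate_id,
            replicate=replicate,
            conc=vec,
            panel=panel,
        )

    return _make


def random_probability_vector(rng, n=19):
    p = rng.dirichlet(np.ones(n))
    return p / p.sum()
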