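import numpy as np
import pytest

from tcrshare.vdj import RecombinationModel, Segment, default_model, pgen_aa


def _uniform4():
    return np.full(4, 0.25)


@pytest.fixture(scope="session")
def m1():
    """Degenerate model: single V suffix TGT, single J prefix TTT, no dels/ins."""
    return RecombinationModel(
        [Segment("V1", "TGT", 1.0)], [Segment("J1", "TTT", 1.0)],
        [1.0], [1.0], [1.0], _uniform4(), name="M1",
    )


@pytest.fixture(scope="session")
def m2():
    """M1 plus insertion length ∈ {0,1} each 0.5, uniform inserted nucleotide."""
    return RecombinationModel(
        [Segment("V1", "TGT", 1.0)], [Segment("J1", "TTT", 1.0)],
        [1.0], [1.0], [0.5, 0.5], _uniform4(), name="M2",
    )


@pytest.fixture(scope="session")
def m3():
    """M2 plus V deletion ∈ {0,1} each 0.5."""
    return RecombinationModel(
        [Segment("V1", "TGT", 1.0)], [Segment("J1", "TTT", 1.0)],
        [0.5, 0.5], [1.0], [0.5, 0.5], _uniform4(), name="M3",
    )


@pytest.fixture(scope="session")
def toy_models(m1, m2, m3):
    """Enumerable toy models spanning multi-segment, skewed and biased cases."""
    m4 = RecombinationModel(
        [Segment("V1", "TGTGCA", 0.6), Segment("V2", "TGCAGT", 0.4)],
        [Segment("J1", "GAATTT", 0.7), Segment("J2", "TACTTC", 0.3)],
        [0.5, 0.3, 0.2], [0.6, 0.4], [0.4, 0.3, 0.3], _uniform4(), name="M4",
    )
    m5 = RecombinationModel(
        [Segment("V1", "TGTGCAAGC", 0.5), Segment("V2", "TGCAGTGTA", 0.3), Segment("V3", "TGTGCC", 0.2)],
        [Segment("J1", "GCTTTCTTT", 0.5), Segment("J2", "CAGTACTTT", 0.5)],
        [0.4, 0.3, 0.2, 0.1], [0.5, 0.5], [0.3, 0.3, 0.2, 0.2],
        np.array([0.1, 0.4, 0.4, 0.1]), name="M5",
    )
    return [m1, m2, m3, m4, m5]


@pytest.fixture(scope="session")
def trb_model():
    """The packaged toy TRB-like model, with the p_gen kernel warmed."""
    model = default_model()
    pgen_aa(model, "CASSL")  # trigger numba compilation once per session
    return model
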