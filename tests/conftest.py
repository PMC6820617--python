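import numpy as np
import pytest

from ritfit import RITAssay, RITObservation


def make_exact_assay(
    A: float = 20.0,
    b: float = 0.1,
    times=None,
    initial_count: int = 20,
    genotype: str = "g",
    replicate_id: str = "r1",
) -> RITAssay:
    """Assay whose counts lie exactly on A*exp(-b*t) (counts kept as floats)."""
    if times is None:
        times = np.arange(0.0, 72.0, 8.0)
    obs = [RITObservation(float(t), A * np.exp(-b * t)) for t in times]
    return RITAssay(
        genotype=genotype,
        replicate_id=replicate_id,
        observations=obs,
        initial_count=initial_count,
        interval_s=float(times[1] - times[0]) if len(times) > 1 else 8.0,
    )


@pytest.fixture
def exact_assay():
    return make_exact_assay()
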