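import numpy as np
import pytest

from epdd import DepthDoseCurve, PrimaryTailParams, fixture_curve


@pytest.fixture(scope="session")
def table1b_12mev():
    """Measured (standard) 12 MeV scan at the 10 cm cone, 5 mm grid."""
    return fixture_curve("table1b/12MeV/standard")


@pytest.fixture(scope="session")
def triangle_curve():
    """Piecewise-linear falloff with exact closed-form crossings."""
    return DepthDoseCurve(depths=[0.0, 10.0, 20.0], values=[100.0, 50.0, 0.0])


@pytest.fixture(scope="session")
def reference_params():
    """Mid-range (12 MeV-like) classic parameters."""
    return PrimaryTailParams(N=8.9, n=290.0, mu=0.0005, t=0.02)


@pytest.fixture(scope="session")
def sigmoid_scan():
    """Fine-grid noiseless scan with a genuine distal falloff and plateau."""
    from epdd import synth_scan

    params = PrimaryTailParams(N=8.9, n=48.0 ** 2, mu=1e-3, t=0.0, tail_exponent=9.0)
    return synth_scan(params, (0.5, 90.0, 0.5), noise_sd=0.0, xray_floor=2.0, seed=0)


def linear_crossing_oracle(depths, values, threshold):
    """Independent closed-form solver: first distal crossing of ``threshold``
    on a piecewise-linear curve, scanning segments after the argmax."""
    imax = int(np.argmax(values))
    for i in range(imax, len(depths) - 1):
        y0, y1 = values[i], values[i + 1]
        if y0 >= threshold > y1:
            # solve y0 + (y1-y0) * s = threshold on the segment
            s = (y0 - threshold) / (y0 - y1)
            return depths[i] + s * (depths[i + 1] - depths[i])
    return None
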