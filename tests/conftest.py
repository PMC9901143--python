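import numpy as np
import pytest

from ascertain.illness_death import HazardSet
from ascertain.interpolation import AGE_GRID
from ascertain.tables import AgeBand, Measure, RateTable


def make_table(values, measure=Measure.incidence, width=5, open_tail=False, **kw):
    """Banded table over consecutive bands of the given width."""
    values = np.asarray(values, dtype=float)
    bands = [AgeBand(k * width, (k + 1) * width) for k in range(len(values))]
    if open_tail:
        bands[-1] = AgeBand(bands[-1].lo, open_ended=True)
    defaults = dict(disease="synthetic", sex="male", year=2015)
    defaults.update(kw)
    return RateTable(measure=measure, bands=bands, values=values, **defaults)


@pytest.fixture
def smooth_hazards():
    """A smooth, non-degenerate hazard set: exponential-in-age incidence and
    case fatality, constant remission, Gompertz other-cause mortality."""
    a = AGE_GRID.astype(float)
    return HazardSet(
        i=1.5e-3 * np.exp(0.05 * (a - 50.0)),
        r=np.full(100, 0.1),
        f=8e-3 * np.exp(0.04 * (a - 50.0)),
        m=np.minimum(2e-4 * np.exp(0.085 * a), 0.5),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
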