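import hypothesis
import numpy as np
import pandas as pd
import pytest

from domoptics import EEM, SampleTable
from domoptics.synthetic import FluorComponent, synth_eem

hypothesis.settings.register_profile("default", derandomize=True, deadline=None)
hypothesis.settings.load_profile("default")


@pytest.fixture
def two_component_eem():
    """The two-Gaussian fixture whose ARIX has the closed form 1.5998.

    Long component: amplitude 2, emission mean 510 nm, sd 60; short:
    amplitude 1, mean 400 nm, sd 40.  Huge excitation sds make both fully
    excited at 320 nm, so the emission profile is the plain Gaussian sum.
    """
    comps = (
        FluorComponent(2.0, 320.0, 1e6, 510.0, 60.0),
        FluorComponent(1.0, 320.0, 1e6, 400.0, 40.0),
    )
    eem, truth = synth_eem(comps, ex_grid=np.arange(250.0, 501.0, 2.0),
                           em_grid=np.arange(300.0, 601.0, 2.0))
    return eem, truth


@pytest.fixture
def uniform_eem():
    ex = np.arange(250.0, 501.0, 5.0)
    em = np.arange(300.0, 601.0, 5.0)
    return EEM("uniform", ex, em, np.full((em.size, ex.size), 3.7))


@pytest.fixture
def linear_emission_eem():
    """I(em) = em / 1000 at every excitation."""
    ex = np.arange(250.0, 501.0, 5.0)
    em = np.arange(300.0, 601.0, 1.0)
    intens = np.tile((em / 1000.0)[:, None], (1, ex.size))
    return EEM("linear", ex, em, intens)


@pytest.fixture
def small_table():
    return SampleTable(pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "dataset_label": ["river", "river", "estuary", "lake"],
        "doc": [10.0, 4.0, 125.0, 2.0],
        "a254": [30.0, 30.0, 100.0, 4.0],
    }))
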