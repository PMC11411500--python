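import pytest

from xtalshift.datasets import load_verinurad
from xtalshift.pipeline import AssignOptions, assign_dataset


@pytest.fixture(scope="session")
def verinurad():
    return load_verinurad()


@pytest.fixture(scope="session")
def verinurad_options():
    # exact marginalization: the aromatic ambiguity component of verinurad
    # has 25 sites, well beyond the default enumeration cap
    return AssignOptions(method="enumerate", max_enum=40)


@pytest.fixture(scope="session")
def verinurad_result(verinurad, verinurad_options):
    fx = verinurad
    return assign_dataset(
        fx.sites, fx.bdm, fx.peaklists, fx.correlations, fx.priors,
        verinurad_options,
    )


def peak_shift_of(fx, result, site):
    """Shift of the peak mapped to a site."""
    return fx.peak_shift(result.map[site])
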