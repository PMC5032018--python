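import numpy as np
import pytest

import neutronrbe as nr


@pytest.fixture(scope="session")
def outer_table():
    """Default synthetic composition table, outer scoring region."""
    return nr.generate_composition_table(nr.FieldGeneratorConfig())


@pytest.fixture(scope="session")
def cluster_curves():
    """Default fitted DSB-cluster curves (10% multiplicative noise)."""
    return nr.default_damage_curves("dsb_clusters", noise_cv=0.10)


@pytest.fixture(scope="session")
def fragment_curves():
    return nr.default_damage_curves("short_fragments", noise_cv=0.10)


@pytest.fixture
def rng():
    return np.random.default_rng(nr.DEFAULT_SEED)


def constant_curve(species, value, endpoint="dsb_clusters",
                   let_range=(0.1, 1e4)):
    """A damage curve returning `value` at every LET (exponent 0)."""
    return nr.DamageCurve(
        species=species, endpoint=endpoint, form="power_law",
        params=(value, 0.0), let_range=let_range,
    )
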