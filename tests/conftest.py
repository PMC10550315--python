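import numpy as np
import pytest

from adscan import PlantSpec, ProteinRecord, SyntheticSpec, generate_proteome


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_proteome():
    """Three short background-only proteins with fixed sequences."""
    return [
        ProteinRecord("P0001", "MSTAGQSPQNGSATPQGSTANQPSGTAQSPNGTSAQPGSTN"),
        ProteinRecord("P0002", "GSTAQPNGSTAQPGSNTAQPSGTANQPGSTAQPNGSATQPG" * 2),
        ProteinRecord("P0003", "AQSPTGNSAQPTGNSAQPTGSNAQPTGSNAPQTGSNAQPTG" * 3),
    ]


@pytest.fixture
def planted():
    """Seeded proteome with 6 plants that pass the original model
    (charge -10, WFYL 9 sits on the diagonal boundary itself)."""
    spec = SyntheticSpec(
        n_proteins=12,
        length_range=(200, 320),
        plants=(PlantSpec(net_charge=-10, hydro_count=9, length=39, count=6),),
        seed=424242,
    )
    return generate_proteome(spec)
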