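import pytest
from hypothesis import HealthCheck, settings

from invexpect.checklist import Checklist, SpeciesRecord
from invexpect.invasion_model import ModelParams, Port

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_record(
    name: str,
    regions,
    presence,
    kingdom: str = "Animalia",
    phylum: str = "Arthropoda",
    klass: str = "Malacostraca",
) -> SpeciesRecord:
    return SpeciesRecord(
        name=name,
        kingdom=kingdom,
        phylum=phylum,
        klass=klass,
        native_regions=frozenset(regions),
        presence=dict(presence),
    )


def make_checklist(records, subregions=("north_sea", "baltic_sea"), recipient="north_baltic"):
    return Checklist(
        recipient_region=recipient, subregion_ids=list(subregions), records=list(records)
    )


@pytest.fixture
def unit_params() -> ModelParams:
    """Neutral constants: alpha=1, sigmoid midpoint at 1 km, no mortality decay scale tricks."""
    return ModelParams(
        alpha=1.0, beta=1.0, gamma=1.0, lam=1.0, mu=0.0, sigma_t=1.0, sigma_s=1.0
    )


@pytest.fixture
def port_factory():
    def factory(pid, lon=0.0, lat=0.0, region="north_baltic", temperature=10.0, salinity=20.0):
        return Port(
            id=pid,
            name=pid,
            region=region,
            lon=lon,
            lat=lat,
            temperature=temperature,
            salinity=salinity,
        )

    return factory
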