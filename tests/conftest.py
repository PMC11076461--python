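import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eegmst import (
    BandSpec,
    CohortSpec,
    CouplingSpec,
    RegionSpec,
    band_by_name,
    make_tree_topology,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def alpha() -> BandSpec:
    return band_by_name("alpha")


@pytest.fixture
def small_montage() -> tuple[str, ...]:
    return tuple(f"CH{i}" for i in range(6))


def make_cohort(
    montage,
    topology_kind="star",
    band_name="alpha",
    n_subjects=2,
    seed=0,
    **coupling,
):
    """A small single-group cohort with one coupling spec, for unit tests."""
    topo = make_tree_topology(topology_kind, len(montage), seed=seed)
    spec = CouplingSpec(topology=topo, band=band_by_name(band_name), **coupling)
    return CohortSpec(
        n_subjects=n_subjects,
        groups=(("g", spec),),
        montage=tuple(montage),
        seed=seed,
    )


@pytest.fixture
def small_region(small_montage) -> RegionSpec:
    return RegionSpec(anterior=frozenset(small_montage[:3]),
                      posterior=frozenset(small_montage[3:5]))
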