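import itertools

import numpy as np
import pytest

from palaeodiv.binning import build_equal_length_scheme, load_default_stages
from palaeodiv.occurrences import (
    Determinacy,
    Environment,
    Material,
    OccurrenceDataset,
    OccurrenceRecord,
)

_COUNTER = itertools.count(1)


def make_record(**kwargs) -> OccurrenceRecord:
    """An occurrence record with sensible defaults, overridable per test."""
    genus = kwargs.pop("genus", "Elonichthys")
    species = kwargs.pop("species", "robisoni")
    if "determinacy" not in kwargs:
        if genus is None:
            kwargs["determinacy"] = Determinacy.INDETERMINATE
        elif species is None:
            kwargs["determinacy"] = Determinacy.GENUS
        else:
            kwargs["determinacy"] = Determinacy.SPECIES
    defaults = dict(
        occurrence_id=f"t{next(_COUNTER):05d}",
        genus=genus,
        species=species,
        material=Material.BODY,
        locality_id="loc1",
        locality_name="Locality One",
        modern_lat=55.0,
        modern_lon=-3.0,
        palaeo_lat=-5.0,
        palaeo_lon=10.0,
        environment=Environment.MARINE,
        earliest_stage="Serpukhovian",
        latest_stage="Serpukhovian",
    )
    defaults.update(kwargs)
    return OccurrenceRecord(**defaults)


def make_dataset(records, **kwargs) -> OccurrenceDataset:
    return OccurrenceDataset(records=list(records), **kwargs)


@pytest.fixture(scope="session")
def stages():
    return load_default_stages()


@pytest.fixture(scope="session")
def scheme(stages):
    return build_equal_length_scheme(stages)


def random_incidence_matrix(rng: np.random.Generator, t_max: int = 6):
    """A random locality-by-taxon presence matrix with every taxon present
    somewhere; returns (matrix, T)."""
    T = int(rng.integers(2, t_max + 1))
    S = int(rng.integers(1, 9))
    fill = rng.uniform(0.15, 0.9, size=S)
    M = (rng.random((T, S)) < fill).astype(int)
    for j in range(S):
        if M[:, j].sum() == 0:
            M[int(rng.integers(T)), j] = 1
    return M, T
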