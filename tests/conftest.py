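import numpy as np
import pytest

from caripheno.clusters import default_cluster_map
from caripheno.dentition import (
    SubjectRecord,
    SurfaceStatus,
    enumerate_index_surfaces,
    make_uniform_record,
)


@pytest.fixture(scope="session")
def universe():
    return enumerate_index_surfaces()


@pytest.fixture(scope="session")
def default_map():
    return default_cluster_map()


@pytest.fixture
def all_sound():
    return make_uniform_record("sound", SurfaceStatus.SOUND, age=30, sex="female")


@pytest.fixture
def edentulous():
    return make_uniform_record("edent", SurfaceStatus.MISSING_TOOTH, age=80, sex="male")


def random_record(rng: np.random.Generator, subject_id: str = "r") -> SubjectRecord:
    """A random but invariant-respecting record: whole teeth go missing,
    remaining surfaces draw independently among the non-missing statuses."""
    surfaces = {}
    missing = set()
    from caripheno.dentition import INDEX_TEETH

    for tooth in INDEX_TEETH:
        if rng.random() < 0.1:
            missing.add(tooth)
    choices = [
        SurfaceStatus.SOUND, SurfaceStatus.DECAYED,
        SurfaceStatus.FILLED, SurfaceStatus.EXCLUDED,
    ]
    probs = [0.6, 0.15, 0.2, 0.05]
    for tooth, surf in enumerate_index_surfaces():
        if tooth in missing:
            surfaces[(tooth, surf)] = SurfaceStatus.MISSING_TOOTH
        else:
            surfaces[(tooth, surf)] = choices[rng.choice(4, p=probs)]
    return SubjectRecord(subject_id, float(rng.uniform(18, 90)), "unknown", surfaces)
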