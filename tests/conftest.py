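import numpy as np
import pytest
import skimage.measure as skm

import nucleoquant as nq


@pytest.fixture(scope="session")
def nucleolar_scene():
    """Default 12-nucleus scene with noise, shared across read-only tests."""
    return nq.gen_nucleolar_scene(nq.NucleolarSceneSpec(seed=7))


@pytest.fixture(scope="session")
def aggregation_scene():
    """Three cells with 0 / 3 / 7 foci (diffuse, moderate, aggregated)."""
    return nq.gen_aggregation_scene(nq.AggregationSceneSpec(seed=3))


@pytest.fixture(scope="session")
def standard_trace():
    """Canonical trace at true P/M ratio 2 with mild noise."""
    return nq.gen_polysome_trace(nq.standard_polysome_spec(2.0, seed=5))


def match_to_truth(measured_labels: np.ndarray, scene) -> dict[int, int]:
    """Map measured nucleus labels to ground-truth ids by centroid lookup."""
    mapping = {}
    for region in skm.regionprops(measured_labels):
        cy, cx = (int(round(c)) for c in region.centroid)
        tid = int(scene.nuclei.labels[cy, cx])
        if tid > 0:
            mapping[region.label] = tid
    return mapping
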