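import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from featrack.features import FeatureSpec, FeatureTable
from featrack.tracker import LinkSet

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def linear_spec():
    """Four linear features on a periodic 100x100 domain."""
    return FeatureSpec(names=("x", "y", "length", "intensity"),
                       kinds=("linear",) * 4, circular_period=(None,) * 4,
                       domain_size=(100.0, 100.0), periodic=True)


@pytest.fixture
def open_spec():
    """Positions plus a nematic orientation on an unbounded domain."""
    return FeatureSpec(names=("x", "y", "orientation"),
                       kinds=("linear", "linear", "circular"),
                       circular_period=(None, None, math.pi))


def make_links(frame, ids_from, ids_to, scores=None, kind="training"):
    n = len(ids_from)
    return LinkSet(pd.DataFrame({
        "frame_from": frame, "id_from": ids_from,
        "frame_to": frame + 1, "id_to": ids_to,
        "score": scores if scores is not None else np.zeros(n),
        "kind": kind,
    }))


def static_scene(spec, n_objects, n_frames, rng, jitter=0.0, spacing=25.0):
    """Well-separated motionless objects; ground truth is the identity."""
    side = spec.domain_size[0] if spec.periodic else 100.0
    grid = math.ceil(math.sqrt(n_objects))
    pos = np.column_stack([(np.arange(n_objects) % grid + 0.5) * side / grid,
                           (np.arange(n_objects) // grid + 0.5) * side / grid])
    extra = rng.uniform(1, 10, (n_objects, len(spec.names) - 2))
    tables = []
    for f in range(n_frames):
        X = np.column_stack([pos, extra])
        if jitter:
            X = X + rng.normal(0, jitter, X.shape)
        tables.append(FeatureTable(f, np.arange(n_objects), X))
    gt = pd.concat([
        pd.DataFrame({"frame_from": f, "id_from": np.arange(n_objects),
                      "frame_to": f + 1, "id_to": np.arange(n_objects),
                      "score": 0.0, "kind": "primary"})
        for f in range(n_frames - 1)], ignore_index=True)
    return tables, LinkSet(gt)
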