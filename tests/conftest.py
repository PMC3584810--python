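import numpy as np
import pytest
from hypothesis import settings

from rootvec import ArchitectureParams, Root, RootNode, RootSystem

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def sparse_params(seed: int) -> ArchitectureParams:
    """A lighter architecture for oracle-heavy tests (fewer laterals)."""
    return ArchitectureParams(
        seed=seed,
        lateral_density={1: 0.3, 2: 0.1},
        length_range={1: (15.0, 25.0), 2: (3.0, 6.0), 3: (0.5, 2.0)},
        extent=(30.0, 30.0),
    )


@pytest.fixture
def toy_system() -> RootSystem:
    """Vertical main axis (10 cm, d=0.1) with one lateral (5 cm, d=0.05) at 5 cm.

    Closed forms: main surface = pi*0.1*10 = pi, lateral surface = 0.25*pi.
    """
    system = RootSystem(label="toy", extent=(20.0, 20.0))
    system.add(
        Root(
            id="main",
            polyline=[RootNode(5.0, 0.0, 0.1), RootNode(5.0, 10.0, 0.1)],
            order=1,
        )
    )
    system.add(
        Root(
            id="lat",
            polyline=[RootNode(5.0, 5.0, 0.05), RootNode(10.0, 5.0, 0.05)],
            order=2,
            parent_id="main",
            insertion_position=5.0,
        )
    )
    return system


def brute_force_point_segment(p, a, b) -> float:
    """Independent scalar point-to-segment distance (law-of-cosines clamp)."""
    p, a, b = (np.asarray(v, float) for v in (p, a, b))
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return float(np.linalg.norm(p - a))
    t = float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab)))


def enumerate_segments(system: RootSystem):
    """(root_id, a_node, b_node) for every polyline segment in the system."""
    for r in system:
        for a, b in zip(r.polyline[:-1], r.polyline[1:]):
            yield r.id, a, b
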