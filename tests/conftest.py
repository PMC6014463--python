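from collections import Counter

import pytest

from icpkit import (
    CallerConfig,
    CellPattern,
    Color,
    SimulationConfig,
    build_acrocentric_panel,
    build_full_panel,
    build_standard_panel,
)
from icpkit.spotcall import SpotCluster


@pytest.fixture(scope="session")
def standard_panel():
    return build_standard_panel()


@pytest.fixture(scope="session")
def acro_panel():
    return build_acrocentric_panel()


@pytest.fixture(scope="session")
def full_panel():
    return build_full_panel()


@pytest.fixture(scope="session")
def caller_config():
    return CallerConfig()


@pytest.fixture
def noise_free_config():
    return SimulationConfig(seed=0)


def make_pattern(
    cell_id: int,
    counts: dict[Color, int],
    fusions: list[frozenset] | None = None,
    attached: dict[Color, Color] | None = None,
) -> CellPattern:
    """Construct a CellPattern with plausible geometry.

    Each signal gets its own cluster.  ``attached`` maps a terminal color to
    its anchor color: the i-th terminal cluster is placed near the i-th
    anchor cluster (0.2 apart); unanchored signals land far from everything.
    """
    attached = attached or {}
    clusters: list[SpotCluster] = []
    anchor_pos: dict[Color, list[tuple[float, float]]] = {}
    # anchors first, spread widely on a line
    for color, n in counts.items():
        if color in attached.values():
            anchor_pos[color] = [(2.0 * i, 0.0) for i in range(n)]
            clusters.extend(
                SpotCluster((color,), pos, 1) for pos in anchor_pos[color]
            )
    for color, n in counts.items():
        if color in attached.values():
            continue
        anchor = attached.get(color)
        positions = anchor_pos.get(anchor, []) if anchor else []
        for i in range(n):
            if i < len(positions):
                x, y = positions[i]
                clusters.append(SpotCluster((color,), (x + 0.2, y), 1))
            else:
                clusters.append(SpotCluster((color,), (50.0 + 2.0 * i, 50.0), 1))
    return CellPattern(
        cell_id=cell_id,
        color_counts=dict(counts),
        fusions=Counter(fusions or []),
        clusters=clusters,
    )


def make_patterns(counts, n=20, **kwargs):
    return [make_pattern(i + 1, counts, **kwargs) for i in range(n)]
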