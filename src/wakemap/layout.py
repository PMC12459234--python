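"""Scalp channel layouts for the toy spherical head.

A layout places ``n_channels`` scalp electrodes quasi-uniformly on the
upper unit hemisphere (Fibonacci lattice with a small seeded jitter),
appends two mastoid reference channels below the equator and two EMG
(muscle) channels, and derives:

* ``ap_coord`` — anterior–posterior coordinate in [0, 1] per scalp
  channel (0 = most posterior, 1 = most anterior), monotone in the
  y-axis of the electrode position;
* ``adjacency`` — a symmetric, irreflexive neighbor relation from the
  Delaunay triangulation of the stereographic projection;
* ``innermost`` — the subset of scalp channels whose polar angle from
  the vertex is below a threshold (default 74°), the desk-scale
  analogue of the innermost-channel subset of a high-density net.

Mastoid and EMG channels never take part in scalp analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

#: polar-angle threshold (degrees) below which a scalp channel counts as innermost
INNERMOST_POLAR_DEG = 74.0


@dataclass
class ChannelLayout:
    channel_id: list[str]
    position: np.ndarray            # (n_total, 3) unit-sphere coordinates
    ap_coord: np.ndarray            # (n_scalp,) in [0, 1]
    adjacency: np.ndarray           # (n_scalp, n_scalp) boolean, symmetric, irreflexive
    innermost: np.ndarray           # (n_scalp,) boolean
    mastoid_ids: list[str]
    emg_ids: list[str]

    @property
    def n_scalp(self) -> int:
        return self.ap_coord.shape[0]

    @property
    def scalp_ids(self) -> list[str]:
        return self.channel_id[: self.n_scalp]

    @property
    def mastoid_index(self) -> np.ndarray:
        return np.array([self.channel_id.index(c) for c in self.mastoid_ids])

    @property
    def emg_index(self) -> np.ndarray:
        return np.array([self.channel_id.index(c) for c in self.emg_ids])

    def validate(self) -> None:
        adj = self.adjacency
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(adj)):
            raise ValueError("adjacency must be irreflexive")
        if np.any(adj.sum(axis=1) < 2):
            raise ValueError("every scalp channel needs at least 2 neighbors")


def _fibonacci_hemisphere(n: int, rng: np.random.Generator) -> np.ndarray:
    """Quasi-uniform points on the upper unit hemisphere with tiny jitter."""
    i = np.arange(n)
    # z uniform in (0, 1] gives area-uniform coverage of the hemisphere
    z = 1.0 - (i + 0.5) / n
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i + rng.uniform(-0.02, 0.02, size=n)
    z = np.clip(z + rng.uniform(-0.005, 0.005, size=n), 1e-3, 1.0)
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_layout(n_channels: int, seed: int = 0) -> ChannelLayout:
    """Build a scalp layout with ``n_channels`` scalp electrodes.

    Two mastoids (below the equator, left/right) and two EMG channels
    are appended after the scalp block.  Deterministic given the seed.
    """
    if n_channels < 16:
        raise ValueError("n_channels must be >= 16 to form a usable adjacency")
    rng = np.random.default_rng(seed)
    pos = _fibonacci_hemisphere(n_channels, rng)

    # anterior-posterior coordinate: +y is anterior
    y = pos[:, 1]
    ap = (y - y.min()) / (y.max() - y.min())

    # adjacency from Delaunay triangulation of the stereographic projection
    # (project from the south pole so the upper hemisphere maps to a disk)
    px = pos[:, 0] / (1.0 + pos[:, 2])
    py = pos[:, 1] / (1.0 + pos[:, 2])
    tri = Delaunay(np.column_stack([px, py]))
    adj = np.zeros((n_channels, n_channels), dtype=bool)
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                adj[simplex[a], simplex[b]] = True
                adj[simplex[b], simplex[a]] = True

    polar = np.degrees(np.arccos(np.clip(pos[:, 2], -1, 1)))
    innermost = polar < INNERMOST_POLAR_DEG

    mastoid_pos = np.array([[-0.95, -0.25, -0.15], [0.95, -0.25, -0.15]])
    mastoid_pos /= np.linalg.norm(mastoid_pos, axis=1, keepdims=True)
    emg_pos = np.array([[-0.5, 0.6, -0.6], [0.5, 0.6, -0.6]])
    emg_pos /= np.linalg.norm(emg_pos, axis=1, keepdims=True)

    ids = [f"E{i + 1}" for i in range(n_channels)]
    mastoid_ids = ["M1", "M2"]
    emg_ids = ["EMG1", "EMG2"]

    layout = ChannelLayout(
        channel_id=ids + mastoid_ids + emg_ids,
        position=np.vstack([pos, mastoid_pos, emg_pos]),
        ap_coord=ap,
        adjacency=adj,
        innermost=innermost,
        mastoid_ids=mastoid_ids,
        emg_ids=emg_ids,
    )
    layout.validate()
    return layout
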