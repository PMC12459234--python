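"""Toy spherical forward model.

Sources are radial current dipoles on a quasi-regular grid inside the
upper half of a unit sphere (a desk-scale stand-in for a cortical voxel
grid).  Gains are quasi-static infinite-medium dipole potentials sampled
at the scalp electrodes — deliberately simple head physics: the inverse
machinery downstream only requires a full-column-rank, geometrically
plausible gain matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layout import ChannelLayout

#: radial shell limits for the source grid (fractions of scalp radius)
R_MIN, R_MAX = 0.25, 0.85


@dataclass
class LeadField:
    gain: np.ndarray        # (n_channels_scalp, n_sources)
    source_pos: np.ndarray  # (n_sources, 3)

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]

    @property
    def source_ap_coord(self) -> np.ndarray:
        """Anterior-posterior coordinate in [0,1] per source (+y anterior)."""
        y = self.source_pos[:, 1]
        return (y - y.min()) / (y.max() - y.min())


def _ball_fibonacci(n: int, rng: np.random.Generator) -> np.ndarray:
    """n quasi-uniform points in the upper half-ball shell R_MIN..R_MAX."""
    pts = []
    i = 0
    golden = np.pi * (3.0 - np.sqrt(5.0))
    # draw from a 2n-point full-ball lattice, keep upper-hemisphere points
    m = 4 * n
    radii = R_MIN + (R_MAX - R_MIN) * ((np.arange(m) + 0.5) / m) ** (1.0 / 3.0)
    z = 1.0 - 2.0 * ((np.arange(m) + 0.5) / m)
    phi = golden * np.arange(m)
    order = rng.permutation(m)
    for k in order:
        if z[k] <= 0.05:
            continue
        r = np.sqrt(1 - z[k] ** 2)
        pts.append(radii[k] * np.array([r * np.cos(phi[k]), r * np.sin(phi[k]), z[k]]))
        i += 1
        if i == n:
            break
    if i < n:
        raise ValueError(f"could not place {n} sources in the grid")
    return np.array(pts)


def make_leadfield(layout: ChannelLayout, n_sources: int, seed: int = 0) -> LeadField:
    """Radial-dipole gains from an interior grid to the scalp electrodes.

    The grid excludes a central core (a radial dipole at the sphere
    center has no preferred direction, hence near-zero gain) and the
    lower hemisphere.  Deterministic given the seed.
    """
    if n_sources > 1000:
        raise ValueError("n_sources > 1000 exceeds the desk-scale grid")
    if n_sources < 2:
        raise ValueError("need at least 2 sources")
    rng = np.random.default_rng(seed)
    src = _ball_fibonacci(n_sources, rng)

    elec = layout.position[: layout.n_scalp]           # (C, 3)
    diff = elec[:, None, :] - src[None, :, :]           # (C, S, 3)
    dist = np.linalg.norm(diff, axis=2)                 # (C, S)
    moment = src / np.linalg.norm(src, axis=1, keepdims=True)  # radial unit moments
    # infinite-medium dipole potential: q . (e - r0) / |e - r0|^3
    gain = np.einsum("csk,sk->cs", diff, moment) / dist**3
    norms = np.linalg.norm(gain, axis=0)
    if np.any(~np.isfinite(gain)) or np.any(norms == 0):
        raise ValueError("degenerate lead field column")
    return LeadField(gain=gain, source_pos=src)
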