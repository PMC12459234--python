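"""Standardized minimum-norm (sLORETA) inverse on the toy head.

The kernel is the Tikhonov-regularized minimum-norm operator
``K = Gᵀ (G Gᵀ + λ c I)⁻¹`` with ``c = trace(G Gᵀ)/n_channels`` so the
regularization parameter λ (default 1e-2) is dimensionless.  sLORETA
standardization divides each source estimate by the square root of the
corresponding diagonal entry of the resolution matrix ``R = K G`` —
for radial single-orientation sources a per-source scalar.  The
defining property, zero localization error for noiseless point
sources, holds for any λ > 0 because ``R`` is positive semidefinite:
``R_ij² ≤ R_ii R_jj`` with equality only at i = j.

An average-reference projector is applied to the gains, matching the
average-referenced scalp data the kernel is applied to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bands import DEFAULT_BANDS
from .forward import LeadField
from .simulate import Trial


@dataclass
class InverseOperator:
    kernel: np.ndarray             # (n_sources, n_channels)
    lam: float
    standardization: np.ndarray    # (n_sources,) sqrt of resolution diagonal
    source_pos: np.ndarray

    @property
    def n_sources(self) -> int:
        return self.kernel.shape[0]

    def apply(self, data: np.ndarray) -> np.ndarray:
        """Standardized source estimate for channel data (n_channels, n_samples)."""
        return (self.kernel @ data) / self.standardization[:, None]


@dataclass
class SourceTimecourse:
    power: np.ndarray              # (n_sources, n_bands, n_epochs), >= 0
    epoch_times: np.ndarray
    grid: np.ndarray               # source positions
    band_names: tuple
    subject_id: str = ""


def build_inverse(leadfield: LeadField, lam: float = 1e-2) -> InverseOperator:
    """Tikhonov-regularized sLORETA operator for the given lead field."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    g = leadfield.gain
    n_ch = g.shape[0]
    # average-reference projector on the channel side
    p = np.eye(n_ch) - np.full((n_ch, n_ch), 1.0 / n_ch)
    g = p @ g
    gram = g @ g.T
    scale = np.trace(gram) / n_ch
    reg = gram + lam * scale * np.eye(n_ch)
    try:
        kernel = np.linalg.solve(reg, g).T     # Gᵀ reg⁻¹
    except np.linalg.LinAlgError as e:
        raise ArithmeticError(f"singular regularized Gram matrix: {e}") from e
    resolution_diag = np.einsum("sc,cs->s", kernel, g)
    if np.any(resolution_diag <= 0):
        raise ArithmeticError("non-positive resolution diagonal")
    return InverseOperator(kernel=kernel, lam=lam,
                           standardization=np.sqrt(resolution_diag),
                           source_pos=leadfield.source_pos)


def source_band_power(trial: Trial, inv: InverseOperator,
                      bands=DEFAULT_BANDS) -> SourceTimecourse:
    """Project scalp data through the kernel, then 1-s-epoch band power
    per source with the same FFT rule as the channel-level pipeline."""
    from .spectral import epoch_band_power

    n_scalp = trial.layout.n_scalp
    if inv.kernel.shape[1] != n_scalp:
        raise ValueError("kernel channel count does not match the trial layout")
    src = inv.apply(np.asarray(trial.data[:n_scalp], dtype=np.float64))
    power = epoch_band_power(src, trial.fs, bands)
    n_epochs = power.shape[-1]
    times = -trial.t0_index / trial.fs + 0.5 + np.arange(n_epochs)
    return SourceTimecourse(power=power, epoch_times=times, grid=inv.source_pos,
                            band_names=tuple(b.name for b in bands),
                            subject_id=trial.subject_id)
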