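"""Frequency-band definitions used throughout the pipeline.

The five canonical sleep-EEG bands (Hz): delta 1–4, theta 5–7,
alpha 8–11.5, sigma 12–16, beta 18–29.5.  Band power is computed on
1-s epochs with 1-Hz bin spacing, so these edges fall exactly on FFT
bin centers; a bin contributes to a band when its center frequency
lies in [lo, hi] inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"invalid band edges for {self.name!r}: {self.lo}, {self.hi}")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 5.0, 7.0),
    BandDefinition("alpha", 8.0, 11.5),
    BandDefinition("sigma", 12.0, 16.0),
    BandDefinition("beta", 18.0, 29.5),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)


def band_by_name(name: str, bands=DEFAULT_BANDS) -> BandDefinition:
    for b in bands:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}")
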