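"""Canonical EEG frequency-band definitions.

The five classical resting-state bands used throughout the package:
delta 1-4, theta 4-8, alpha 8-12, beta 13-30 and gamma 30-45 Hz. Note the
12-13 Hz gap between alpha and beta: the bands do not tile the broadband
range, so per-band quantities (power, connectivity) never double-count but
also do not sum to the broadband total.

Gamma is defined as 30-45 Hz by default. Recordings low-passed at 40 Hz
carry no energy above the filter edge, so users of such data may prefer a
30-40 Hz gamma; pass a custom :class:`BandSpec` anywhere a band is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got "
                f"({self.f_lo}, {self.f_hi})"
            )

    def validate_for_fs(self, fs: float) -> None:
        """Reject bands whose upper edge reaches the Nyquist frequency."""
        if self.f_hi >= fs / 2:
            raise ValueError(
                f"band {self.name!r} upper edge {self.f_hi} Hz is at or above "
                f"Nyquist ({fs / 2} Hz) for fs={fs}"
            )


DELTA = BandSpec("delta", 1.0, 4.0)
THETA = BandSpec("theta", 4.0, 8.0)
ALPHA = BandSpec("alpha", 8.0, 12.0)
BETA = BandSpec("beta", 13.0, 30.0)
GAMMA = BandSpec("gamma", 30.0, 45.0)

DEFAULT_BANDS: tuple[BandSpec, ...] = (DELTA, THETA, ALPHA, BETA, GAMMA)

#: Broadband reference range (Hz) used as the relative-power denominator.
BROADBAND = (1.0, 45.0)


def band_by_name(name: str, bands: Iterable[BandSpec] = DEFAULT_BANDS) -> BandSpec:
    for b in bands:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}")


def check_unique_names(bands: Iterable[BandSpec]) -> None:
    names = [b.name for b in bands]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate band names in {names}")
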