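"""Welch spectral power per ROI: absolute and relative band power, group tests.

The power spectral density is estimated with Welch's method (Hann-tapered
4-s segments, 50% overlap, density scaling, so the PSD integrates to the
signal variance).  Absolute band power is the mean PSD over the in-band
frequency bins; relative band power is the in-band power as a fraction of
broadband (1-45 Hz) power, i.e. the ratio of the in-band PSD integral to
the broadband integral.  Band bins are half-open [f_lo, f_hi) so adjacent
bands never double-count a bin.

Group comparisons are per-ROI independent two-tailed t tests, by default on
log10 absolute power (variance stabilization; configurable), with
Benjamini-Hochberg FDR correction across ROIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from statsmodels.stats.multitest import multipletests

from .bands import BandSpec, BROADBAND
from .timeseries import TimeSeriesBlock

__all__ = [
    "PowerSpectrum",
    "BandPowerMap",
    "PowerTestResult",
    "welch_psd",
    "band_power",
    "power_group_test",
]


@dataclass
class PowerSpectrum:
    """Per-channel Welch PSD on a common frequency grid."""

    freqs: np.ndarray
    psd: np.ndarray  # channels x freqs, signal-units^2 / Hz
    window_len: float
    overlap: float
    labels: list[str]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if np.any(self.psd < 0):
            raise ValueError("PSD must be nonnegative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class BandPowerMap:
    """Per-channel absolute (mean in-band PSD) and relative band power."""

    band: str
    absolute: np.ndarray
    relative: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.absolute = np.asarray(self.absolute, dtype=float)
        self.relative = np.asarray(self.relative, dtype=float)
        if np.any((self.relative < 0) | (self.relative > 1 + 1e-9)):
            raise ValueError("relative power must lie in [0, 1]")


@dataclass
class PowerTestResult:
    """Per-ROI two-sample t map with FDR significance mask."""

    t: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    q: float
    labels: list[str]


def welch_psd(
    ts: TimeSeriesBlock, window: float = 4.0, overlap: float = 0.5
) -> PowerSpectrum:
    """Hann-tapered Welch PSD; integrates to signal variance (Parseval)."""
    nperseg = int(round(window * ts.fs))
    if ts.n_samples < nperseg:
        raise ValueError(
            f"record of {ts.n_samples} samples shorter than one {window}-s window"
        )
    if not (0 <= overlap < 1):
        raise ValueError(f"overlap fraction must be in [0,1), got {overlap}")
    freqs, psd = signal.welch(
        ts.data,
        fs=ts.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    return PowerSpectrum(
        freqs=freqs, psd=psd, window_len=window, overlap=overlap, labels=list(ts.labels)
    )


def _band_bins(ps: PowerSpectrum, f_lo: float, f_hi: float) -> np.ndarray:
    return (ps.freqs >= f_lo) & (ps.freqs < f_hi)


def band_power(ps: PowerSpectrum, band: BandSpec, mode: str = "both") -> BandPowerMap:
    """Absolute and relative power of one band for every channel.

    Absolute = mean PSD over bins with f_lo <= f < f_hi.  Relative =
    in-band PSD integral / broadband [1, 45) Hz integral (the fraction of
    broadband power carried by the band); the five default bands therefore
    sum to at most 1 (they leave a 12-13 Hz gap).
    """
    if mode not in ("absolute", "relative", "both"):
        raise ValueError(f"bad mode {mode!r}")
    in_band = _band_bins(ps, band.f_lo, band.f_hi)
    if not in_band.any():
        raise ValueError(
            f"band {band.name!r} ({band.f_lo}-{band.f_hi} Hz) has no bins on the "
            f"frequency grid (df={ps.df} Hz, max={ps.freqs[-1]} Hz)"
        )
    broad = _band_bins(ps, *BROADBAND)
    if not broad.any():
        raise ValueError("broadband range has no bins on the frequency grid")
    absolute = ps.psd[:, in_band].mean(axis=1)
    broad_total = ps.psd[:, broad].sum(axis=1)
    band_total = ps.psd[:, in_band & broad].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        relative = np.where(broad_total > 0, band_total / np.where(broad_total > 0, broad_total, 1.0), 0.0)
    return BandPowerMap(band=band.name, absolute=absolute, relative=np.clip(relative, 0, 1),
                        labels=list(ps.labels))


def power_group_test(
    patients: list[BandPowerMap] | np.ndarray,
    controls: list[BandPowerMap] | np.ndarray,
    q: float = 0.05,
    mode: str = "absolute",
    log_transform: bool = True,
) -> PowerTestResult:
    """Per-ROI independent two-tailed t with Benjamini-Hochberg FDR mask.

    ``mode`` picks the absolute or relative values from the input maps;
    ``log_transform`` applies log10 before testing (absolute power only —
    relative power is already bounded).
    """
    a, labels = _power_stack(patients, mode)
    b, labels_b = _power_stack(controls, mode)
    if labels and labels_b and labels != labels_b:
        raise ValueError("ROI labels differ between groups")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if log_transform and mode == "absolute":
        floor = np.finfo(float).tiny
        a = np.log10(np.maximum(a, floor))
        b = np.log10(np.maximum(b, floor))
    n1, n2 = a.shape[0], b.shape[0]
    sp2 = ((n1 - 1) * a.var(axis=0, ddof=1) + (n2 - 1) * b.var(axis=0, ddof=1)) / (
        n1 + n2 - 2
    )
    denom = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    diff = a.mean(axis=0) - b.mean(axis=0)
    zero = denom == 0
    if zero.any():
        warnings.warn("ROIs with zero pooled variance: t set to 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(~zero, diff / np.where(zero, 1.0, denom), 0.0)
    from scipy import stats as _st

    p = 2 * _st.t.sf(np.abs(t), n1 + n2 - 2)
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return PowerTestResult(t=t, p=p, mask=reject, q=q, labels=labels or labels_b)


def _power_stack(maps, mode: str) -> tuple[np.ndarray, list[str]]:
    if isinstance(maps, np.ndarray):
        return np.asarray(maps, dtype=float), []
    key = "absolute" if mode == "absolute" else "relative"
    arr = np.stack([getattr(m, key) for m in maps])
    labels = list(maps[0].labels)
    for m in maps:
        if list(m.labels) != labels:
            raise ValueError("ROI labels differ within stack")
    return arr, labels
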