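"""Standardized minimum-norm (sLORETA-style) source estimation and ROI averaging.

Given a lead field L (sensors x sources, fixed orientation), the
minimum-norm estimate of the sources from sensor data m is

    j_hat = L^T (L L^T + alpha I)^(-1) m

and the standardized estimate divides each source by the square root of the
corresponding diagonal element of the resolution-like matrix
R = L^T (L L^T + alpha I)^(-1) L.  This standardization yields zero
localization error for noiseless single-dipole data in the limit alpha -> 0,
and makes the estimates invariant to a global rescaling of the lead field.

Source time courses are then arithmetically averaged within each region of
a cortical parcellation (default: the 68-label Desikan-Killiany atlas, 34
regions per hemisphere).  Note that averaging raw signed traces can cancel
sources of opposite polarity within a region; this is the standard hazard
of sign-ambiguous source estimates and is documented rather than hidden.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .synthetic import LeadField
from .timeseries import TimeSeriesBlock

__all__ = [
    "InverseKernel",
    "Parcellation",
    "default_parcellation",
    "common_average_reference",
    "compute_inverse_kernel",
    "apply_inverse",
    "roi_average",
]


@dataclass
class InverseKernel:
    """Precomputed inverse operator: standardized sources x sensors matrix."""

    kernel: np.ndarray          # raw minimum-norm kernel, sources x sensors
    scale: np.ndarray           # per-source standardization sqrt(R_ii)
    alpha: float

    @property
    def n_sources(self) -> int:
        return self.kernel.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.kernel.shape[1]

    @property
    def standardized_kernel(self) -> np.ndarray:
        return self.kernel / self.scale[:, None]


@dataclass
class Parcellation:
    """Ordered cortical ROI labels with hemisphere membership."""

    roi_labels: list[str]
    hemispheres: list[str]

    def __post_init__(self) -> None:
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("ROI labels must be unique")
        if len(self.hemispheres) != len(self.roi_labels):
            raise ValueError("hemisphere list length mismatch")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)


def default_parcellation() -> Parcellation:
    """The packaged 68-region Desikan-Killiany cortical parcellation."""
    text = (
        importlib.resources.files("oscinet.data")
        .joinpath("desikan_killiany_68.txt")
        .read_text()
    )
    labels = [ln.strip() for ln in text.splitlines() if ln.strip()]
    hemis = ["left" if lb.startswith("lh-") else "right" for lb in labels]
    return Parcellation(roi_labels=labels, hemispheres=hemis)


def common_average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous mean across rows (channels)."""
    return data - data.mean(axis=0, keepdims=True)


def compute_inverse_kernel(
    lf: LeadField, alpha: float | None = None, car: bool = False
) -> InverseKernel:
    """Build the standardized minimum-norm inverse for a lead field.

    ``alpha`` is the Tikhonov regularization of the sensor-space Gram
    matrix; the default is the SNR-agnostic heuristic
    ``0.05 * trace(L L^T) / n_sensors``.  ``alpha=0`` uses a pseudoinverse
    of the Gram matrix, valid only when the lead field has full row rank.
    With ``car=True`` the lead-field rows are common-average referenced
    first (sensor data must then be referenced the same way); this is the
    usual convention for average-referenced EEG but leaves the Gram matrix
    rank-deficient, which the pseudoinverse path handles.
    """
    L = np.asarray(lf.matrix, dtype=float)
    if car:
        L = L - L.mean(axis=0, keepdims=True)
    gram = L @ L.T
    if alpha is None:
        alpha = 0.05 * np.trace(gram) / gram.shape[0]
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    if alpha == 0:
        if not car and np.linalg.matrix_rank(gram) < gram.shape[0]:
            raise np.linalg.LinAlgError(
                "lead field is rank deficient; set alpha > 0 to regularize"
            )
        gram_inv = linalg.pinvh(gram)
    else:
        gram_inv = linalg.inv(gram + alpha * np.eye(gram.shape[0]))
    kernel = L.T @ gram_inv                      # sources x sensors
    res_diag = np.einsum("ij,ji->i", kernel, L)  # diag of K L = L^T G^-1 L
    scale = np.sqrt(np.clip(res_diag, 0.0, None))
    dead = scale <= 0
    if dead.any():
        # sources with zero gain: leave unscaled (their estimate is 0 anyway)
        scale = scale.copy()
        scale[dead] = 1.0
    return InverseKernel(kernel=kernel, scale=scale, alpha=float(alpha))


def apply_inverse(
    k: InverseKernel, sensor_ts: TimeSeriesBlock, car: bool = False
) -> TimeSeriesBlock:
    """Apply the standardized kernel samplewise to sensor data."""
    if sensor_ts.n_channels != k.n_sensors:
        raise ValueError(
            f"{sensor_ts.n_channels} sensor channels but kernel expects {k.n_sensors}"
        )
    data = sensor_ts.data
    if car:
        data = common_average_reference(data)
    src = k.standardized_kernel @ data
    labels = [f"src{i:04d}" for i in range(k.n_sources)]
    return TimeSeriesBlock(data=src, fs=sensor_ts.fs, labels=labels, kind="source")


def roi_average(
    source_ts: TimeSeriesBlock,
    parcellation: Parcellation,
    source_to_roi: np.ndarray,
) -> TimeSeriesBlock:
    """Average source time courses within each parcellation region.

    Every source must be assigned to a region and every region must own at
    least one source; an empty region is reported by name.
    """
    src_map = np.asarray(source_to_roi, dtype=int)
    if src_map.shape != (source_ts.n_channels,):
        raise ValueError("source_to_roi must assign every source row exactly once")
    n_rois = parcellation.n_rois
    if src_map.min() < 0 or src_map.max() >= n_rois:
        raise ValueError("source_to_roi indices outside parcellation range")
    counts = np.bincount(src_map, minlength=n_rois)
    empty = np.nonzero(counts == 0)[0]
    if empty.size:
        names = [parcellation.roi_labels[i] for i in empty]
        raise ValueError(f"regions with no assigned sources: {names}")
    out = np.zeros((n_rois, source_ts.n_samples))
    np.add.at(out, src_map, source_ts.data)
    out /= counts[:, None]
    return TimeSeriesBlock(
        data=out, fs=source_ts.fs, labels=list(parcellation.roi_labels), kind="roi"
    )
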