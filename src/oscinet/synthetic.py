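"""Synthetic resting-state cohorts with known envelope-coupling structure.

Real patient EEG for this kind of study is rarely shareable, so the package
ships a generator that emulates the statistical structure the analysis is
built to detect:

* band-limited oscillations whose slow amplitude envelopes carry *planted*
  pairwise correlations (log-normal envelopes driven by correlated Gaussian
  modulators, multiplying independent band-limited carriers);
* group effects: designated edges whose envelope coupling differs between
  patients and controls by a configurable additive amount;
* brain-behavior coupling: edges whose coupling scales linearly with a
  per-patient severity score, which also drives simulated clinical scores
  (cancellation-test omissions and line-bisection deviation);
* an optional toy lead field for exercising the sensor-to-source inverse.

The modulator-correlation -> realized envelope-correlation mapping is
monotone but not the identity (the positivity transform and the carrier
both attenuate it); the package documents it empirically rather than
assuming it.

Simulated clinical scores follow a 35-target cancellation sheet (15 targets
left, 15 right, 5 central) with left/right omission probabilities increasing
with severity, and a line-bisection deviation in percent.  Clinical cutoffs:
left-minus-right omissions >= 4 of 15 flags cancellation neglect; rightward
bisection deviation > 11% flags bisection neglect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .bands import BandSpec, DEFAULT_BANDS
from .timeseries import TimeSeriesBlock

logger = logging.getLogger(__name__)

__all__ = [
    "CouplingPlan",
    "BehaviorScores",
    "SubjectRecord",
    "LeadField",
    "repair_psd",
    "generate_band_signals",
    "make_behavior",
    "make_cohort",
    "make_connectivity_cohort",
    "make_toy_leadfield",
    "project_to_sensors",
]

# Correlations are clamped here so planted coupling matrices stay comfortably
# positive definite and envelopes never become deterministic copies.
MAX_EDGE_CORR = 0.95

# Cancellation-sheet layout: 7 virtual columns of 5 targets each.
N_TARGETS_LEFT = 15
N_TARGETS_RIGHT = 15
N_TARGETS_CENTER = 5
N_TARGETS_TOTAL = N_TARGETS_LEFT + N_TARGETS_RIGHT + N_TARGETS_CENTER

CANCELLATION_CUTOFF = 4  # left-minus-right omissions, out of 15
BISECTION_CUTOFF_PCT = 11.0  # rightward deviation, percent


@dataclass
class CouplingPlan:
    """Planted envelope coupling for one band.

    ``edges`` are unordered 0-based node pairs (i < j).  For each edge the
    effective modulator correlation of a subject is::

        base + group_delta * [subject is patient] + behavior_slope * severity

    clamped to [0, MAX_EDGE_CORR].
    """

    band: str
    edges: list[tuple[int, int]]
    base_corr: dict[tuple[int, int], float] = field(default_factory=dict)
    group_delta: dict[tuple[int, int], float] = field(default_factory=dict)
    behavior_slope: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = [self._norm(e) for e in self.edges]
        for d in (self.base_corr, self.group_delta, self.behavior_slope):
            for k in list(d):
                d[self._norm(k)] = d.pop(k)
        for e, r in self.base_corr.items():
            if not (0 <= r < 1):
                raise ValueError(f"base correlation {r} for edge {e} outside [0, 1)")

    @staticmethod
    def _norm(e) -> tuple[int, int]:
        i, j = int(e[0]), int(e[1])
        if i == j:
            raise ValueError(f"self-edge ({i},{j}) not allowed")
        return (i, j) if i < j else (j, i)

    def effective_corr(self, edge: tuple[int, int], is_patient: bool, severity: float) -> float:
        e = self._norm(edge)
        r = self.base_corr.get(e, 0.0)
        if is_patient:
            r += self.group_delta.get(e, 0.0)
        r += self.behavior_slope.get(e, 0.0) * severity
        clamped = float(np.clip(r, 0.0, MAX_EDGE_CORR))
        if clamped != r:
            logger.warning("edge %s effective correlation %.3f clamped to %.3f", e, r, clamped)
        return clamped


@dataclass
class BehaviorScores:
    """Simulated clinical battery outcome for one subject."""

    omissions_left: int
    omissions_right: int
    omissions_center: int
    bisection_dev_pct: float
    total_targets: int = N_TARGETS_TOTAL
    neglect_cancellation_flag: bool = False
    neglect_bisection_flag: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.omissions_left <= N_TARGETS_LEFT):
            raise ValueError(f"omissions_left {self.omissions_left} outside 0..{N_TARGETS_LEFT}")
        if not (0 <= self.omissions_right <= N_TARGETS_RIGHT):
            raise ValueError(f"omissions_right {self.omissions_right} outside 0..{N_TARGETS_RIGHT}")
        if not (0 <= self.omissions_center <= N_TARGETS_CENTER):
            raise ValueError(
                f"omissions_center {self.omissions_center} outside 0..{N_TARGETS_CENTER}"
            )
        self.neglect_cancellation_flag = (
            self.omissions_left - self.omissions_right >= CANCELLATION_CUTOFF
        )
        self.neglect_bisection_flag = self.bisection_dev_pct > BISECTION_CUTOFF_PCT

    @property
    def omissions_total(self) -> int:
        return self.omissions_left + self.omissions_right + self.omissions_center

    def to_dict(self) -> dict:
        return {
            "omissions_left": self.omissions_left,
            "omissions_right": self.omissions_right,
            "omissions_center": self.omissions_center,
            "total_targets": self.total_targets,
            "bisection_dev_pct": round(self.bisection_dev_pct, 4),
            "neglect_cancellation_flag": self.neglect_cancellation_flag,
            "neglect_bisection_flag": self.neglect_bisection_flag,
        }


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # patient | control
    severity: float
    timeseries: TimeSeriesBlock
    behavior: BehaviorScores

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"group must be patient|control, got {self.group!r}")
        if not (0 <= self.severity <= 1):
            raise ValueError(f"severity {self.severity} outside [0, 1]")


@dataclass
class LeadField:
    """Fixed-orientation forward operator: sensors x sources gain matrix."""

    matrix: np.ndarray
    sensor_labels: list[str]
    source_to_roi_map: np.ndarray  # source index -> ROI index

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.source_to_roi_map = np.asarray(self.source_to_roi_map, dtype=int)
        if self.matrix.ndim != 2:
            raise ValueError("lead field must be 2-D")
        if len(self.sensor_labels) != self.matrix.shape[0]:
            raise ValueError("sensor label count mismatch")
        if self.source_to_roi_map.shape != (self.matrix.shape[1],):
            raise ValueError("source_to_roi_map must have one entry per source")

    @property
    def n_sensors(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_rois(self) -> int:
        return int(self.source_to_roi_map.max()) + 1


def repair_psd(corr: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone and restore a unit diagonal.

    Eigenvalues below zero are clipped; the result is re-normalized to a
    correlation matrix.  The repair is logged when it actually changes the
    input.  Raises if the input is so far from PSD that clipping removes
    more than half its trace.
    """
    corr = np.asarray(corr, dtype=float)
    sym = 0.5 * (corr + corr.T)
    w, v = np.linalg.eigh(sym)
    if w.min() >= -tol:
        return sym
    clipped = np.clip(w, 0.0, None)
    if clipped.sum() < 0.5 * np.abs(w).sum():
        raise ValueError("coupling matrix too far from positive semidefinite to repair")
    fixed = (v * clipped) @ v.T
    d = np.sqrt(np.clip(np.diag(fixed), 1e-12, None))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    logger.warning(
        "coupling matrix repaired: min eigenvalue %.3g clipped to 0", w.min()
    )
    return fixed


def _spectral_shape(
    white: np.ndarray, gain: np.ndarray, n_samples: int
) -> np.ndarray:
    """Shape white Gaussian rows by a real spectral gain (rfft grid).

    Frequency-domain shaping of stationary Gaussian noise is exact and has
    no filter startup transients, which matters here: time-domain IIR
    filtering at sub-hertz cutoffs rings at the record edges, and the
    log-normal envelope transform amplifies any such excursion explosively.
    """
    spec = np.fft.rfft(white, axis=-1)
    out = np.fft.irfft(spec * gain[None, :], n=n_samples, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _correlated_modulators(
    corr: np.ndarray, n_samples: int, f_lo: float, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Slow correlated Gaussian modulators with unit variance per node."""
    n = corr.shape[0]
    white = rng.standard_normal((n, n_samples))
    # factorize the (repaired) correlation matrix; eigh is robust to PSD rank loss
    w, v = np.linalg.eigh(corr)
    root = v * np.sqrt(np.clip(w, 0.0, None))
    mixed = root @ white
    # slow modulation: low-pass well below the carrier band (2nd-order
    # Butterworth magnitude response)
    cutoff = min(f_lo / 2.0, 2.0)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    gain = 1.0 / np.sqrt(1.0 + (freqs / cutoff) ** 4)
    return _spectral_shape(mixed, gain, n_samples)


def _band_carrier(
    n_nodes: int, band: BandSpec, n_samples: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Independent unit-variance band-limited Gaussian carriers.

    Band limitation by a 4th-order Butterworth magnitude response applied
    spectrally (exact for stationary Gaussian synthesis).
    """
    white = rng.standard_normal((n_nodes, n_samples))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    f0 = np.sqrt(band.f_lo * band.f_hi)
    bw = band.f_hi - band.f_lo
    with np.errstate(divide="ignore"):
        # analog band-pass prototype |H| for a 4th-order Butterworth
        x = np.where(freqs > 0, (freqs**2 - f0**2) / (np.maximum(freqs, 1e-12) * bw), np.inf)
    gain = 1.0 / np.sqrt(1.0 + x**8)
    gain[0] = 0.0
    return _spectral_shape(white, gain, n_samples)


def generate_band_signals(
    n_nodes: int,
    band: BandSpec,
    modulator_corr: np.ndarray,
    duration: float = 180.0,
    fs: float = 250.0,
    seed: int = 0,
    modulator_sigma: float = 1.0,
) -> TimeSeriesBlock:
    """Band-limited signals with planted pairwise envelope correlations.

    Each node's signal is ``envelope * carrier`` where the carrier is an
    independent unit-variance band-limited Gaussian and the envelope is
    ``exp(sigma * g / 2)`` for slow correlated Gaussian modulators ``g``
    (log-normal envelopes, guaranteed positive).  The realized envelope
    correlation increases monotonically with the planted modulator
    correlation; the mapping is attenuated, not the identity.
    """
    band.validate_for_fs(fs)
    n_samples = int(round(duration * fs))
    if n_samples < 10 * fs:
        raise ValueError(f"duration {duration}s too short; need >= 10 s")
    corr = np.asarray(modulator_corr, dtype=float)
    if corr.shape != (n_nodes, n_nodes):
        raise ValueError(f"modulator_corr shape {corr.shape} != ({n_nodes},{n_nodes})")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("modulator_corr must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValueError("modulator_corr must have unit diagonal")
    corr = repair_psd(corr)

    rng = np.random.default_rng(seed)
    g = _correlated_modulators(corr, n_samples, band.f_lo, fs, rng)
    envelope = np.exp(modulator_sigma * g / 2.0)
    carrier = _band_carrier(n_nodes, band, n_samples, fs, rng)
    data = envelope * carrier
    labels = [f"node{i:02d}" for i in range(n_nodes)]
    return TimeSeriesBlock(data=data, fs=fs, labels=labels, kind="roi")


def make_behavior(
    severity: float,
    seed: int,
    p_left_base: float = 0.05,
    p_left_slope: float = 0.9,
    p_right_base: float = 0.05,
    p_right_slope: float = 0.25,
    bisection_slope: float = 40.0,
    bisection_noise_sd: float = 5.0,
) -> BehaviorScores:
    """Simulate the clinical battery for one subject at a given severity.

    Omission counts are binomial over the cancellation-sheet targets with
    miss probabilities rising linearly in severity; severe subjects miss
    left-side targets far more often than right-side ones (left hemineglect).
    Line-bisection deviation drifts rightward with severity plus Gaussian
    noise.  Neglect flags follow the clinical cutoffs.
    """
    if not (0 <= severity <= 1):
        raise ValueError(f"severity {severity} outside [0, 1]")
    rng = np.random.default_rng(seed)
    p_l = float(np.clip(p_left_base + p_left_slope * severity, 0, 1))
    p_r = float(np.clip(p_right_base + p_right_slope * severity, 0, 1))
    return BehaviorScores(
        omissions_left=int(rng.binomial(N_TARGETS_LEFT, p_l)),
        omissions_right=int(rng.binomial(N_TARGETS_RIGHT, p_r)),
        omissions_center=int(rng.binomial(N_TARGETS_CENTER, p_r)),
        bisection_dev_pct=float(bisection_slope * severity + rng.normal(0, bisection_noise_sd)),
    )


def _one_over_f_noise(shape: tuple[int, int], fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance pink (1/f amplitude) background noise."""
    n_ch, n_samples = shape
    white = rng.standard_normal((n_ch, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale[None, :], n=n_samples, axis=-1)
    sd = pink.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def make_cohort(
    n_patients: int = 15,
    n_controls: int = 27,
    n_nodes: int = 68,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    plan: list[CouplingPlan] | None = None,
    duration: float = 180.0,
    fs: float = 250.0,
    seed: int = 0,
    snr_db: float = 10.0,
) -> list[SubjectRecord]:
    """Generate a full synthetic cohort of ROI time series plus behavior.

    Defaults mirror the study design this generator emulates: 15 patients
    vs 27 controls, 68 cortical ROIs, 3-minute recordings at 250 Hz.  Each
    subject's broadband trace is the sum of the per-band envelope-modulated
    signals plus 1/f background noise at ``snr_db`` (total band-signal power
    over noise power).  Patient severities are drawn uniform(0, 1);
    controls have severity 0.
    """
    if n_patients < 2 or n_controls < 2:
        raise ValueError("need at least 2 subjects per group")
    plan = plan or []
    plan_by_band = {p.band: p for p in plan}
    unknown = set(plan_by_band) - {b.name for b in bands}
    if unknown:
        raise ValueError(f"coupling plan refers to unknown bands: {sorted(unknown)}")

    master = np.random.default_rng(seed)
    records: list[SubjectRecord] = []
    groups = ["patient"] * n_patients + ["control"] * n_controls
    severities = [float(master.uniform(0, 1)) for _ in range(n_patients)] + [0.0] * n_controls

    for idx, (group, sev) in enumerate(zip(groups, severities)):
        sub_seed = int(master.integers(0, 2**31 - 1))
        sub_rng = np.random.default_rng(sub_seed)
        n_samples = int(round(duration * fs))
        total = np.zeros((n_nodes, n_samples))
        for band in bands:
            corr = np.eye(n_nodes)
            p = plan_by_band.get(band.name)
            if p is not None:
                for e in p.edges:
                    i, j = e
                    if not (0 <= i < n_nodes and 0 <= j < n_nodes):
                        raise ValueError(f"edge {e} outside node range 0..{n_nodes - 1}")
                    r = p.effective_corr(e, group == "patient", sev)
                    corr[i, j] = corr[j, i] = r
            band_ts = generate_band_signals(
                n_nodes, band, corr, duration, fs,
                seed=int(sub_rng.integers(0, 2**31 - 1)),
            )
            total += band_ts.data
        sig_power = float(np.mean(total**2))
        noise = _one_over_f_noise((n_nodes, n_samples), fs, sub_rng)
        noise_power = sig_power / (10 ** (snr_db / 10)) if sig_power > 0 else 1.0
        total += noise * np.sqrt(noise_power)

        behavior = make_behavior(sev, seed=int(sub_rng.integers(0, 2**31 - 1)))
        ts = TimeSeriesBlock(
            data=total, fs=fs,
            labels=[f"node{i:02d}" for i in range(n_nodes)], kind="roi",
        )
        records.append(
            SubjectRecord(
                subject_id=f"{'P' if group == 'patient' else 'C'}{idx:03d}",
                group=group, severity=sev, timeseries=ts, behavior=behavior,
            )
        )
    return records


def make_connectivity_cohort(
    n_a: int,
    n_b: int,
    n_nodes: int,
    seed: int,
    base_corr: float = 0.2,
    edge_sd: float = 0.15,
    effect_edges: list[tuple[int, int]] | None = None,
    effect_size: float = 0.0,
    slope_edges: list[tuple[int, int]] | None = None,
    slope: float = 0.0,
    covariate: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cohorts of per-subject connectivity matrices drawn directly.

    A fast complement to :func:`make_cohort` for statistics-level studies
    (permutation-test calibration, power analyses) that only consume the
    subject-by-subject adjacency matrices: each subject's edge value is
    ``base_corr`` plus independent Gaussian between-subject noise
    (``edge_sd``, a realistic spread of resting envelope correlations),
    plus ``effect_size`` on ``effect_edges`` for group-A subjects, plus
    ``slope * covariate`` on ``slope_edges``.

    Returns ``(stack_a, stack_b)`` of shapes (n_a, N, N) and (n_b, N, N),
    symmetric with zero diagonal, values clipped to [-0.95, 0.95].
    """
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n_nodes, k=1)
    n_edges = len(iu[0])

    def _edge_index(edges):
        lut = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(*iu))}
        return [lut[(min(i, j), max(i, j))] for i, j in edges]

    def _stack(n_sub, group_a: bool, cov):
        vals = base_corr + edge_sd * rng.standard_normal((n_sub, n_edges))
        if group_a and effect_edges and effect_size:
            vals[:, _edge_index(effect_edges)] += effect_size
        if slope_edges and slope and cov is not None:
            idx = _edge_index(slope_edges)
            vals[:, idx] += slope * np.asarray(cov, dtype=float)[:, None]
        vals = np.clip(vals, -MAX_EDGE_CORR, MAX_EDGE_CORR)
        out = np.zeros((n_sub, n_nodes, n_nodes))
        out[:, iu[0], iu[1]] = vals
        out += out.transpose(0, 2, 1)
        return out

    cov_a = covariate[:n_a] if covariate is not None else None
    cov_b = covariate[n_a:] if covariate is not None else None
    return _stack(n_a, True, cov_a), _stack(n_b, False, cov_b)


def make_toy_leadfield(
    n_sensors: int = 19,
    n_sources: int = 60,
    n_rois: int = 12,
    seed: int = 0,
    smoothness: float = 0.2,
    max_redraws: int = 10,
) -> LeadField:
    """Smooth random gain matrix standing in for a BEM forward model.

    Sensors sit on a ring; each ROI is a spatially contiguous patch of
    sources jittered around its own center inside the unit disc (parcels of
    a cortical atlas are contiguous, and contiguity is what makes them
    resolvable at all).  A source's gain profile is a spatial Gaussian of
    its distance to each sensor times a random dipole amplitude — dipoles
    within a patch share an orientation sign, emulating locally aligned
    cortical columns — giving spatially correlated columns like a real
    volume-conduction operator.  Sources are split into contiguous balanced
    index blocks, one block per ROI.  Rank-deficient draws are redrawn with
    an incremented seed (logged).
    """
    if not (n_sources >= n_rois >= 1):
        raise ValueError("need n_sources >= n_rois >= 1")
    if n_sensors < 2:
        raise ValueError("need at least 2 sensors")
    for attempt in range(max_redraws):
        rng = np.random.default_rng(seed + attempt)
        theta = np.linspace(0, 2 * np.pi, n_sensors, endpoint=False)
        sensors = np.column_stack([np.cos(theta), np.sin(theta)])
        blocks = np.array_split(np.arange(n_sources), n_rois)
        phi = np.linspace(0, 2 * np.pi, n_rois, endpoint=False) + rng.uniform(0, 2 * np.pi)
        centers = 0.85 * np.column_stack([np.cos(phi), np.sin(phi)])
        sources = np.empty((n_sources, 2))
        signs = np.empty(n_sources)
        for r, block in enumerate(blocks):
            sources[block] = centers[r] + 0.05 * rng.standard_normal((len(block), 2))
            signs[block] = rng.choice([-1.0, 1.0])
        d2 = ((sensors[:, None, :] - sources[None, :, :]) ** 2).sum(-1)
        amp = rng.normal(1.0, 0.3, n_sources) * signs
        gain = np.exp(-d2 / (2 * smoothness**2)) * amp[None, :]
        gain += 0.01 * rng.standard_normal(gain.shape)  # break exact symmetries
        if np.linalg.matrix_rank(gain) == n_sensors:
            cond = np.linalg.cond(gain @ gain.T)
            logger.info("toy lead field: %dx%d, cond(LL^T)=%.3g (seed %d)",
                        n_sensors, n_sources, cond, seed + attempt)
            if attempt:
                logger.warning("lead field redrawn %d time(s) for rank deficiency", attempt)
            labels = [f"S{i:02d}" for i in range(n_sensors)]
            src_map = np.concatenate([
                np.full(len(block), r)
                for r, block in enumerate(np.array_split(np.arange(n_sources), n_rois))
            ])
            return LeadField(matrix=gain, sensor_labels=labels, source_to_roi_map=src_map)
    raise RuntimeError(f"could not draw a full-row-rank lead field in {max_redraws} tries")


def project_to_sensors(
    source_ts: TimeSeriesBlock,
    lf: LeadField,
    snr_db: float = np.inf,
    seed: int = 0,
) -> TimeSeriesBlock:
    """Forward-project source traces through the lead field with sensor noise.

    White Gaussian sensor noise is rescaled so the realized noise power over
    the whole record matches the requested SNR exactly; ``snr_db=inf`` gives
    a noiseless projection.
    """
    if source_ts.n_channels != lf.n_sources:
        raise ValueError(
            f"{source_ts.n_channels} source rows but lead field has {lf.n_sources} sources"
        )
    clean = lf.matrix @ source_ts.data
    if np.isinf(snr_db):
        data = clean
    else:
        rng = np.random.default_rng(seed)
        sig_power = float(np.mean(clean**2))
        if sig_power == 0:
            warnings.warn("zero source input: sensor output is pure unit-variance noise")
            target_noise_power = 1.0
        else:
            target_noise_power = sig_power / (10 ** (snr_db / 10))
        noise = rng.standard_normal(clean.shape)
        noise *= np.sqrt(target_noise_power / np.mean(noise**2))
        data = clean + noise
    return TimeSeriesBlock(data=data, fs=source_ts.fs, labels=list(lf.sensor_labels),
                           kind="sensor")
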