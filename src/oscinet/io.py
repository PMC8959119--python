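"""File formats, cohort manifests, and pipeline configuration.

Time-series TSV dialect (bit-exact spec): an optional leading comment line
``# fs=<Hz> kind=<sensor|source|roi>``, then one row per channel, tab
separated, first field the channel label, remaining fields the samples
printed with ``%.17g`` (lossless round-trip for IEEE doubles), ``.`` decimal
separator, no quoting.

Connectivity matrices and power tables are TSVs with a labeled header row
and label index column.  Cohort manifests are JSON.  EDF recordings (e.g. a
19-channel 10-20 montage) are read through MNE; channel order is preserved.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bands import BandSpec, DEFAULT_BANDS
from .connectivity import ConnectivityMatrix
from .synthetic import BehaviorScores, SubjectRecord
from .timeseries import TimeSeriesBlock

__all__ = [
    "read_timeseries",
    "write_timeseries_tsv",
    "read_timeseries_tsv",
    "read_timeseries_edf",
    "write_connectivity_tsv",
    "read_connectivity_tsv",
    "write_cohort",
    "load_cohort",
    "PipelineConfig",
]


def write_timeseries_tsv(ts: TimeSeriesBlock, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={ts.fs:.17g} kind={ts.kind}\n")
        for label, row in zip(ts.labels, ts.data):
            fh.write(label + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_timeseries_tsv(path, fs: float | None = None) -> TimeSeriesBlock:
    path = Path(path)
    labels, rows = [], []
    kind = "sensor"
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    k, _, v = tok.partition("=")
                    if k == "fs":
                        fs = float(v)
                    elif k == "kind":
                        kind = v
                continue
            parts = line.split("\t")
            labels.append(parts[0])
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field ({exc})")
    if not rows:
        raise ValueError(f"{path}: no data rows")
    if fs is None:
        raise ValueError(f"{path}: sampling rate not in file header; pass fs=")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"{path}: rows have differing lengths {sorted(lengths)}")
    return TimeSeriesBlock(data=np.array(rows), fs=fs, labels=labels, kind=kind)


def read_timeseries_edf(path) -> TimeSeriesBlock:
    """Load an EDF recording via MNE, preserving channel order."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return TimeSeriesBlock(
        data=raw.get_data(), fs=float(raw.info["sfreq"]),
        labels=list(raw.ch_names), kind="sensor",
    )


def read_timeseries(path, format: str | None = None, fs: float | None = None) -> TimeSeriesBlock:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "tsv")
    if fmt == "edf":
        return read_timeseries_edf(path)
    if fmt == "tsv":
        return read_timeseries_tsv(path, fs=fs)
    raise ValueError(f"unknown format {fmt!r}")


def write_connectivity_tsv(cm: ConnectivityMatrix, path) -> None:
    df = pd.DataFrame(cm.values, index=cm.node_labels, columns=cm.node_labels)
    df.to_csv(path, sep="\t", float_format="%.17g", index_label=f"band:{cm.band}")


def read_connectivity_tsv(path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    band = str(df.index.name or "")
    band = band.removeprefix("band:")
    return ConnectivityMatrix(band=band, values=df.to_numpy(),
                              node_labels=[str(c) for c in df.columns])


def write_cohort(records: list[SubjectRecord], outdir, seed: int | None = None) -> Path:
    """Write one TSV per subject plus a JSON manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in records:
        fname = f"{rec.subject_id}.tsv"
        write_timeseries_tsv(rec.timeseries, outdir / fname)
        entries.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "severity": rec.severity,
                "behavior": rec.behavior.to_dict(),
                "file": fname,
                "fs": rec.timeseries.fs,
            }
        )
    manifest = {"seed": seed, "subjects": entries}
    mpath = outdir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return mpath


def load_cohort(manifest_path) -> list[SubjectRecord]:
    mpath = Path(manifest_path)
    with open(mpath) as fh:
        manifest = json.load(fh)
    ids = [e["subject_id"] for e in manifest["subjects"]]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in manifest")
    records = []
    for e in manifest["subjects"]:
        fpath = mpath.parent / e["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"manifest refers to missing file {fpath}")
        ts = read_timeseries_tsv(fpath, fs=e.get("fs"))
        beh = e["behavior"]
        records.append(
            SubjectRecord(
                subject_id=e["subject_id"],
                group=e["group"],
                severity=float(e["severity"]),
                timeseries=ts,
                behavior=BehaviorScores(
                    omissions_left=beh["omissions_left"],
                    omissions_right=beh["omissions_right"],
                    omissions_center=beh["omissions_center"],
                    bisection_dev_pct=beh["bisection_dev_pct"],
                ),
            )
        )
    return records


_KNOWN_KEYS = {
    "bands", "epoch_len", "z_thresh", "broadband_lo", "broadband_hi",
    "welch_window", "welch_overlap", "env_fs", "nbs_nperm", "nbs_alpha",
    "nbs_threshold_p", "regress_covariates", "seed", "manifest", "outdir",
    "leadfield", "inverse_alpha",
}


@dataclass
class PipelineConfig:
    """Validated end-to-end pipeline configuration.

    ``regress_covariates`` names behavior fields (e.g. ``omissions_left``)
    regressed against patient edge strengths; regressions use patients only.
    """

    manifest: str
    outdir: str
    bands: list[BandSpec] = field(default_factory=lambda: list(DEFAULT_BANDS))
    epoch_len: float = 1.0
    z_thresh: float = 1.5
    broadband_lo: float = 0.5
    broadband_hi: float = 40.0
    welch_window: float = 4.0
    welch_overlap: float = 0.5
    env_fs: float | None = None
    nbs_nperm: int = 5000
    nbs_alpha: float = 0.05
    nbs_threshold_p: float = 0.01
    regress_covariates: list[str] = field(default_factory=lambda: ["omissions_left"])
    seed: int = 0
    leadfield: str | None = None
    inverse_alpha: float | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "bands" in raw:
            raw["bands"] = [BandSpec(b["name"], b["f_lo"], b["f_hi"]) for b in raw["bands"]]
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
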