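"""End-to-end orchestration: cohort in, networks / power / statistics out.

``run_pipeline`` executes preprocessing -> (optional inverse projection) ->
per-band connectivity and power -> NBS group contrast per band -> NBS
behavioral regressions (patients only) -> conjunction of group and
regression results, writing every artifact under the output directory
tagged with the configuration hash and master seed.  Every source of
randomness derives from the single master seed via spawned child seeds so
single stages can be re-run reproducibly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as _io
from .connectivity import ConnectivityMatrix, aec_matrix, group_effect
from .inverse import apply_inverse, compute_inverse_kernel, default_parcellation, roi_average
from .nbs import DesignSpec, NbsResult, conjunction, nbs
from .preprocessing import preprocess
from .spectral import band_power, power_group_test, welch_psd
from .synthetic import LeadField, SubjectRecord
from scipy import stats as _stats

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Handles to everything the pipeline computed and where it was written."""

    outdir: Path
    config_hash: str
    connectivity: dict[str, list[ConnectivityMatrix]] = field(default_factory=dict)
    group_nbs: dict[str, NbsResult] = field(default_factory=dict)
    regression_nbs: dict[tuple[str, str], NbsResult] = field(default_factory=dict)
    conjunction_edges: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    rejected_epochs: dict[str, int] = field(default_factory=dict)


def _spawn_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_pipeline(config: _io.PipelineConfig) -> PipelineResult:
    cfg_hash = config.config_hash()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: config hash %s, seed %d", cfg_hash, config.seed)

    records = _io.load_cohort(config.manifest)
    logger.info("loaded %d subjects", len(records))

    lf = None
    kernel = None
    parc = None
    if config.leadfield:
        lf_ts = _io.read_timeseries_tsv(config.leadfield, fs=1.0)
        # lead-field TSV: rows = sensors; ROI map file alongside (.roimap.tsv)
        roimap_path = Path(config.leadfield).with_suffix(".roimap.tsv")
        src_map = np.loadtxt(roimap_path, dtype=int)
        lf = LeadField(matrix=lf_ts.data, sensor_labels=lf_ts.labels,
                       source_to_roi_map=src_map)
        kernel = compute_inverse_kernel(lf, alpha=config.inverse_alpha, car=True)
        parc = default_parcellation()
        if lf.n_rois != parc.n_rois:
            from .inverse import Parcellation

            parc = Parcellation(
                roi_labels=[f"roi{i:02d}" for i in range(lf.n_rois)],
                hemispheres=["unknown"] * lf.n_rois,
            )

    stage_seed = _spawn_seeds(config.seed, 4)
    result = PipelineResult(outdir=outdir, config_hash=cfg_hash)

    # --- per-subject preprocessing, optional inverse, connectivity, power ---
    conn: dict[str, list[ConnectivityMatrix]] = {b.name: [] for b in config.bands}
    power_abs: dict[str, list[np.ndarray]] = {b.name: [] for b in config.bands}
    groups: list[str] = []
    behaviors: list[dict] = []
    for rec in records:
        clean, es = preprocess(
            rec.timeseries,
            f_lo=config.broadband_lo,
            f_hi=config.broadband_hi,
            epoch_len=config.epoch_len,
            z_thresh=config.z_thresh,
        )
        n_rej = es.n_epochs - es.n_kept
        result.rejected_epochs[rec.subject_id] = n_rej
        logger.info(
            "%s: %s -> kept %d/%d epochs, clean shape %s",
            rec.subject_id, rec.timeseries.data.shape, es.n_kept, es.n_epochs,
            clean.data.shape,
        )
        if kernel is not None and clean.kind == "sensor":
            src = apply_inverse(kernel, clean, car=True)
            clean = roi_average(src, parc, lf.source_to_roi_map)
        ps = welch_psd(clean, window=config.welch_window, overlap=config.welch_overlap)
        for band in config.bands:
            cm = aec_matrix(clean, band, env_fs=config.env_fs)
            conn[band.name].append(cm)
            power_abs[band.name].append(band_power(ps, band).absolute)
        groups.append(rec.group)
        behaviors.append(rec.behavior.to_dict())
    result.connectivity = conn

    pat = np.array([g == "patient" for g in groups])
    n_pat = int(pat.sum())

    # --- per-band artifacts: connectivity tensors, power tables, NBS ---
    for bi, band in enumerate(config.bands):
        stack = conn[band.name]
        for rec, cm in zip(records, stack):
            _io.write_connectivity_tsv(cm, outdir / f"conn_{band.name}_{rec.subject_id}.tsv")
        eff = group_effect([m for m, p in zip(stack, pat) if p],
                           [m for m, p in zip(stack, pat) if not p])
        np.savetxt(outdir / f"effect_d_{band.name}.tsv", eff.d, delimiter="\t")

        pw = np.stack(power_abs[band.name])
        ptest = power_group_test(pw[pat], pw[~pat])
        with open(outdir / f"power_test_{band.name}.json", "w") as fh:
            json.dump(
                {"band": band.name, "t": ptest.t.tolist(), "p": ptest.p.tolist(),
                 "fdr_mask": ptest.mask.tolist(), "q": ptest.q},
                fh, indent=2,
            )

        thresh = float(
            _stats.t.ppf(1 - config.nbs_threshold_p / 2, len(records) - 2)
        )
        design = DesignSpec(
            kind="two_group",
            group_labels=["patient" if p else "control" for p in pat],
            primary_threshold=thresh,
            nperm=config.nbs_nperm,
            alpha=config.nbs_alpha,
            seed=stage_seed[0] + bi,
        )
        res = nbs(stack, design)
        res.to_json(outdir / f"nbs_group_{band.name}.json")
        result.group_nbs[band.name] = res

        pat_stack = [m for m, p in zip(stack, pat) if p]
        if n_pat < 4:
            if bi == 0:
                logger.warning(
                    "only %d patients: behavioral regressions skipped", n_pat
                )
            continue
        for cov_name in config.regress_covariates:
            cov = np.array([b[cov_name] for b, p in zip(behaviors, pat) if p], dtype=float)
            if cov.std() == 0:
                logger.warning("covariate %s constant among patients; skipped", cov_name)
                continue
            rdesign = DesignSpec(
                kind="regression",
                covariate=cov,
                primary_threshold=float(_stats.t.ppf(1 - config.nbs_threshold_p / 2, n_pat - 2)),
                nperm=config.nbs_nperm,
                alpha=config.nbs_alpha,
                seed=stage_seed[1] + bi,
            )
            rres = nbs(pat_stack, rdesign)
            rres.to_json(outdir / f"nbs_regress_{cov_name}_{band.name}.json")
            result.regression_nbs[(band.name, cov_name)] = rres

            conj = conjunction([res, rres], alpha=config.nbs_alpha)
            result.conjunction_edges[f"{band.name}:{cov_name}"] = sorted(conj)

    with open(outdir / "run_info.json", "w") as fh:
        json.dump(
            {
                "config_hash": cfg_hash,
                "seed": config.seed,
                "n_subjects": len(records),
                "n_patients": n_pat,
                "rejected_epochs": result.rejected_epochs,
                "conjunction": {
                    k: [[int(i), int(j)] for i, j in v]
                    for k, v in result.conjunction_edges.items()
                },
            },
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    logger.info("pipeline done: artifacts in %s", outdir)
    return result
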