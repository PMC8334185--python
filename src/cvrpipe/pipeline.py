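"""End-to-end orchestration: physiology -> maps -> group statistics.

Two entry points are provided.  :func:`run_pipeline` consumes a study
directory on disk (physio CSVs, BOLD NIfTIs, motion text files, a
parcellation and a metadata table, as written by ``cvrpipe simulate`` or
assembled by hand) and writes per-subject maps plus the group tables.
:func:`run_synthetic_study` runs the identical computation fully in
memory on generator output — the form used by the recovery experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .config import ParcellationVolume, PipelineConfig
from .cvr import CvrMap, attach_voxel_p, map_cvr
from .exceptions import ConfigError
from .group import (GroupResult, build_region_table, fisher_z,
                    fit_region_models, partial_spearman, regional_average)
from .paradigm import Paradigm, ParadigmSpec, build_paradigm
from .physio import (GasTrace, _shift_samples, correct_technical_delay,
                     detect_breaths, extract_end_tidal, resample_to_tr_grid)
from .preprocess import BoldSeries, NuisanceSet, build_mask, preprocess_bold
from .synthetic import (EffectProfile, GroundTruth, cohort_metadata,
                        make_bold, make_cohort, make_parcellation,
                        make_physio)

log = logging.getLogger(__name__)


@dataclass
class SubjectResult:
    subject_id: str
    cvr: CvrMap
    technical_delay: float
    regional_z: pd.Series


@dataclass
class StudyResult:
    group_result: GroupResult
    region_table: pd.DataFrame
    spearman: pd.DataFrame
    subjects: list[SubjectResult] = field(default_factory=list)


# ---------------------------------------------------------------------------
# per-subject processing
# ---------------------------------------------------------------------------

def process_subject(subject_id: str, pco2, po2, flow, bold: BoldSeries,
                    motion: np.ndarray | None, mask: np.ndarray,
                    config: PipelineConfig, paradigm_f0: float,
                    p_rng: np.random.Generator | None = None,
                    attach_p: bool = False) -> SubjectResult:
    """Run one subject from raw traces + raw BOLD to a coupling map."""
    pco2c, lag = correct_technical_delay(pco2, flow, config.max_technical_lag)
    # O2 shares the sampling line, hence the same technical delay
    po2c = GasTrace(_shift_samples(po2.values, -int(round(lag * po2.rate))),
                    po2.rate, po2.start_time, "O2")
    breaths = detect_breaths(pco2c, flow,
                             min_breath_duration=config.min_breath_duration)
    et_co2, _ = extract_end_tidal(pco2c, po2c, breaths)

    n_ret = bold.n_volumes - config.n_discard_volumes
    t0 = config.n_discard_volumes * config.tr
    ref = resample_to_tr_grid(et_co2, config.tr, n_ret, t0)

    delta = preprocess_bold(bold, NuisanceSet(motion, config.detrend_order)
                            if motion is not None else None,
                            config, mask=mask)
    fs = 1.0 / config.tr
    cvr = map_cvr(delta.data, ref.values, delta.mask, fs=fs, f0=paradigm_f0,
                  band=config.band, delay_band=config.delay_band,
                  lag_window=config.lag_search_window, r_at=config.r_at)
    if attach_p:
        attach_voxel_p(cvr, ref.values, fs=fs, band=config.band,
                       rng=p_rng)
    return SubjectResult(subject_id, cvr, lag, pd.Series(dtype=float))


def _group_stage(subjects: list[SubjectResult],
                 parcellation: ParcellationVolume,
                 meta: pd.DataFrame) -> StudyResult:
    rows = {}
    for sub in subjects:
        zmap = fisher_z(np.clip(sub.cvr.r, -1 + 1e-9, 1 - 1e-9))
        sub.regional_z = regional_average(zmap, parcellation)
        rows[sub.subject_id] = sub.regional_z
    table = build_region_table(rows)
    if "ventricle" in table.columns:
        table = table.drop(columns="ventricle")
    result = fit_region_models(table, meta)

    meta_idx = meta.set_index("subject_id")
    sp_rows = []
    if "tfc" in meta_idx.columns:
        tfc = meta_idx.loc[table.index, "tfc"].to_numpy(dtype=float)
        age = meta_idx.loc[table.index, "age"].to_numpy(dtype=float)
        enough = np.isfinite(tfc).sum() >= 5
        for region in table.columns:
            if not enough:
                sp_rows.append({"region": region, "rho": np.nan,
                                "p": np.nan})
                continue
            rho, p = partial_spearman(table[region].to_numpy(), tfc, age)
            sp_rows.append({"region": region, "rho": rho, "p": p})
    spearman = pd.DataFrame(sp_rows)
    return StudyResult(result, table, spearman, subjects)


# ---------------------------------------------------------------------------
# file-based study
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, study_dir, out_dir,
                 paradigm_spec: ParadigmSpec | None = None) -> StudyResult:
    """Run the complete pipeline on a study directory.

    Expects ``metadata.csv``, ``parcellation.nii.gz`` + ``regions.tsv`` and
    per subject ``<id>_physio.csv``, ``<id>_bold.nii.gz`` and optional
    ``<id>_motion.txt``.  Writes per-subject r/delay maps, the subject x
    region z table and the group-statistics table into ``out_dir``.
    """
    study_dir, out_dir = Path(study_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = paradigm_spec or ParadigmSpec()
    f0 = spec.fundamental_frequency

    meta_path = study_dir / "metadata.csv"
    if not meta_path.exists():
        raise ConfigError(f"missing metadata table {meta_path}")
    meta = pd.read_csv(meta_path)
    for col in ("subject_id", "group", "age"):
        if col not in meta.columns:
            raise ConfigError(f"metadata is missing the '{col}' column")
    parcellation = cio.read_parcellation(study_dir / "parcellation.nii.gz",
                                         study_dir / "regions.tsv")
    exclude = [0] + [lab for lab, name in parcellation.lookup.items()
                     if name == "ventricle"]
    mask = build_mask(parcellation, exclude)
    rng = np.random.default_rng(config.rng_seed)

    subjects = []
    for sid in meta["subject_id"]:
        log.info("processing %s", sid)
        pco2, po2, flow = cio.read_physio_csv(
            study_dir / f"{sid}_physio.csv", config)
        bold = cio.read_bold_nifti(study_dir / f"{sid}_bold.nii.gz")
        if bold.data.shape[:3] != parcellation.labels.shape:
            raise ConfigError(f"{sid}: BOLD grid {bold.data.shape[:3]} does "
                              f"not match parcellation "
                              f"{parcellation.labels.shape}")
        motion_path = study_dir / f"{sid}_motion.txt"
        motion = cio.read_motion_regressors(motion_path) \
            if motion_path.exists() else None
        sub = process_subject(sid, pco2, po2, flow, bold, motion, mask,
                              config, f0, p_rng=rng)
        cio.write_map_nifti(sub.cvr.r, parcellation.voxel_dims,
                            out_dir / f"{sid}_cvr_r.nii.gz")
        cio.write_map_nifti(sub.cvr.delay, parcellation.voxel_dims,
                            out_dir / f"{sid}_cvr_delay.nii.gz")
        subjects.append(sub)

    study = _group_stage(subjects, parcellation, meta)
    study.region_table.to_csv(out_dir / "region_z.csv",
                              index_label="subject_id")
    study.group_result.to_csv(out_dir / "group_stats.csv")
    study.spearman.to_csv(out_dir / "tfc_spearman.csv", index=False)
    log.info("pipeline complete: %d subjects, %d regions",
             len(subjects), study.region_table.shape[1])
    return study


# ---------------------------------------------------------------------------
# in-memory synthetic study
# ---------------------------------------------------------------------------

def run_synthetic_study(n_hd: int = 12, n_control: int = 11,
                        effect: EffectProfile | None = None,
                        grid_shape: tuple[int, int, int] = (24, 24, 12),
                        n_regions: int = 48, seed: int = 0,
                        config: PipelineConfig | None = None,
                        paradigm_spec: ParadigmSpec | None = None,
                        n_volumes: int = 480,
                        physio_rate: float = 100.0
                        ) -> tuple[StudyResult, list[GroundTruth],
                                   np.ndarray]:
    """Generate a synthetic cohort and run the full pipeline in memory.

    Returns the study result, the cohort ground truth and the affected
    region indices.
    """
    config = config or PipelineConfig(rng_seed=seed)
    spec = paradigm_spec or ParadigmSpec()
    paradigm = build_paradigm(spec, physio_rate, seed=seed)
    parcellation = make_parcellation(grid_shape, n_regions, seed=seed)
    cohort, affected = make_cohort(n_hd, n_control, effect, n_regions,
                                   seed=seed)
    exclude = [0] + [lab for lab, name in parcellation.lookup.items()
                     if name == "ventricle"]
    mask = build_mask(parcellation, exclude)

    subjects = []
    for truth in cohort:
        pco2, po2, flow = make_physio(truth, paradigm, physio_rate)
        bold, motion = make_bold(truth, paradigm, parcellation,
                                 tr=config.tr, n_volumes=n_volumes,
                                 n_dummy=config.n_discard_volumes,
                                 band=config.band)
        sub = process_subject(truth.subject_id, pco2, po2, flow, bold,
                              motion, mask, config,
                              spec.fundamental_frequency)
        subjects.append(sub)

    meta = cohort_metadata(cohort)
    study = _group_stage(subjects, parcellation, meta)
    return study, cohort, affected


def detection_rates(study: StudyResult, affected: np.ndarray,
                    alpha: float = 0.05) -> tuple[float, float]:
    """(sensitivity, false-flag rate) of the FDR-significant region calls.

    A region is flagged when its FDR-adjusted p falls below ``alpha``.
    ``affected`` holds 0-based indices into the generator's region list
    (region ``region_{i+1:03d}``).
    """
    table = study.group_result.table
    flagged = set(table.index[table["p_fdr"] < alpha])
    aff_names = {f"region_{i + 1:03d}" for i in affected}
    unaff_names = set(table.index) - aff_names
    sens = len(flagged & aff_names) / max(len(aff_names), 1)
    false = len(flagged & unaff_names) / max(len(unaff_names), 1)
    return sens, false
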