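"""Write a complete synthetic study to disk.

Produces a self-contained directory the file-based pipeline can consume:
per-subject physio CSVs, BOLD NIfTIs and motion text files, the
parcellation NIfTI with its lookup table, the subject metadata CSV and a
ground-truth YAML for later comparison.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from .config import PipelineConfig
from .paradigm import ParadigmSpec, build_paradigm
from .synthetic import (EffectProfile, cohort_metadata, make_bold,
                        make_cohort, make_parcellation, make_physio)


def simulate_study(out_dir, n_hd: int = 12, n_control: int = 11,
                   effect: EffectProfile | None = None,
                   grid_shape=(24, 24, 12), n_regions: int = 48,
                   seed: int = 0, config: PipelineConfig | None = None,
                   paradigm_spec: ParadigmSpec | None = None,
                   n_volumes: int = 480,
                   physio_rate: float = 100.0) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or PipelineConfig(rng_seed=seed)
    spec = paradigm_spec or ParadigmSpec()
    paradigm = build_paradigm(spec, physio_rate, seed=seed)
    parcellation = make_parcellation(grid_shape, n_regions, seed=seed)
    cohort, affected = make_cohort(n_hd, n_control, effect, n_regions,
                                   seed=seed)

    cio.write_parcellation(parcellation, out / "parcellation.nii.gz",
                           out / "regions.tsv")
    cohort_metadata(cohort).to_csv(out / "metadata.csv", index=False)

    truth_dump = {"affected_regions": [int(i) for i in affected],
                  "subjects": {}}
    for truth in cohort:
        pco2, po2, flow = make_physio(truth, paradigm, physio_rate)
        bold, motion = make_bold(truth, paradigm, parcellation,
                                 tr=config.tr, n_volumes=n_volumes,
                                 n_dummy=config.n_discard_volumes,
                                 band=config.band)
        sid = truth.subject_id
        cio.write_physio_csv(out / f"{sid}_physio.csv", pco2, po2, flow)
        cio.write_bold_nifti(bold, out / f"{sid}_bold.nii.gz")
        np.savetxt(out / f"{sid}_motion.txt", motion, fmt="%.6f")
        truth_dump["subjects"][sid] = {
            "group": truth.group, "age": float(truth.age),
            "technical_delay": float(truth.technical_delay),
            "resting_petco2": float(truth.resting_petco2),
            "z_true": [float(z) for z in truth.z_true],
            "delays": [float(d) for d in truth.delays],
        }
    with open(out / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(truth_dump, fh, sort_keys=False)
    config.to_yaml(out / "config.yaml")
    return out
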