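"""End-to-end orchestration: simulate -> extract -> QC -> associate.

The pipeline mirrors a memory-clinic imaging workflow operating on
preprocessed maps: dementia-informed IDP extraction (with segmentation
corrections), staged automated QC flagging, and the hierarchical-FDR
association screen against age, cognition and ordered diagnosis.  Run with
no external inputs it exercises every stage on synthetic data with known
ground truth; each stage can also consume user-supplied tables/maps in the
same formats (TSV tables, gzipped NIfTI maps with a JSON role manifest).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import idp, qc, stats, synthetic
from .synthetic import CORTICAL_ROI_NAMES, LOBE_NAMES, STRUCTURE_NAMES, CohortTruth

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "default_idp_modalities", "default_cohort_truth", "run_pipeline"]


def default_idp_modalities() -> dict[str, str]:
    """Name -> modality map of the default 110-IDP set, mirroring extraction."""
    out: dict[str, str] = {}
    for lobe in LOBE_NAMES:
        out[f"lobar_gm_{lobe}"] = idp.MODALITY_T1
    for i in range(synthetic.N_WM_TRACTS):
        out[f"wmh_wm_tract_{i + 1:02d}"] = idp.MODALITY_FLAIR
    for side in ("nbm_l", "nbm_r"):
        out[f"{side}_volume"] = idp.MODALITY_T1
    out["psmd"] = idp.MODALITY_DMRI
    for i in range(synthetic.N_TRACTOGRAPHY_TRACTS):
        out[f"tract_volume_tractography_tract_{i + 1:02d}"] = idp.MODALITY_DMRI
    regions = list(STRUCTURE_NAMES) + [
        f"{base}_{side}" for base in CORTICAL_ROI_NAMES for side in ("l", "r")
    ]
    for region in regions:
        out[f"regional_md_{region}"] = idp.MODALITY_DMRI
        out[f"regional_mo_{region}"] = idp.MODALITY_DMRI
    return out


def default_cohort_truth(seed: int = 0) -> CohortTruth:
    """Planted effects for the demo cohort.

    A handful of IDPs carry moderate standardised effects on age, cognition
    and the diagnosis latent — lesion load and PSMD worsening with age,
    hippocampal diffusivity and basal-forebrain volume tracking diagnosis —
    while every other IDP is null.  Effect sizes are configurable at the
    call site; these defaults give the screen something detectable at a
    ~200-subject clinic cohort without being trivial.
    """
    planted = {
        "lobar_gm_temporal": {"age": -0.35, "ace": 0.30},
        "wmh_wm_tract_05": {"age": 0.35},
        "psmd": {"age": 0.30, "diagnosis": 0.50},
        "nbm_l_volume": {"diagnosis": -0.45},
        "regional_md_hippocampus_l": {"ace": -0.30, "diagnosis": 0.60},
    }
    modalities = default_idp_modalities()
    nulls = [name for name in modalities if name not in planted]
    return CohortTruth(planted_beta=planted, null_idp_names=nulls, seed=seed)


@dataclass
class PipelineConfig:
    """All knobs of the synthetic end-to-end run.

    QC: ``iqr_k`` fence multiplier, ``svar_threshold`` slow-variance
    percentage.  Statistics: FDR level ``q``.  ``excluded_scans`` is the
    human exclusion list (scan ids); excluded subjects are dropped before
    the association stage.
    """

    n_subjects: int = 213
    seed: int = 0
    out_dir: str = "clinidp_output"
    # phantom
    phantom_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    wmh_burden: float = 0.02
    atrophy: float = 0.1
    write_imagery: bool = False
    # QC
    iqr_k: float = 1.5
    svar_threshold: float = 75.0
    n_iqm_metrics: int = 10
    n_planted_outliers: int = 5
    excluded_scans: list[str] = field(default_factory=list)
    bold_T: int = 60
    # statistics
    q: float = 0.05
    min_n: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.q < 1):
            raise ValueError(f"q must be in (0,1), got {self.q}")
        if self.iqr_k <= 0:
            raise ValueError("iqr_k must be positive")
        if not (0 <= self.svar_threshold <= 100):
            raise ValueError("svar_threshold is a percentage")
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be >= 10")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        for key in ("phantom_shape", "voxel_size"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig, truth: Optional[CohortTruth] = None) -> dict:
    """Execute all stages; returns the run manifest (also written to disk).

    Stages: (1) phantom simulation + IDP extraction for one subject; (2)
    cohort simulation with planted effects; (3) IQM flagging, DSE
    decomposition and the slow-variance criterion; (4) exclusion of flagged-
    and-excluded subjects; (5) the hierarchical-FDR association screen.
    Outputs land in ``config.out_dir`` as TSV/JSON; the manifest records the
    seed and subject counts at every stage boundary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seeds = np.random.SeedSequence(config.seed).generate_state(4)
    manifest: dict = {"seed": config.seed, "config": asdict(config), "stages": {}}

    # --- stage 1: phantom + extraction -------------------------------------
    subject, atlas, truth_map = synthetic.make_phantom(
        seed=int(rng_seeds[0] % 2**31),
        shape=config.phantom_shape,
        voxel_size=config.voxel_size,
        wmh_burden=config.wmh_burden,
        atrophy=config.atrophy,
    )
    if config.write_imagery:
        synthetic.save_subject(subject, atlas, out / "phantom", seed=config.seed)
    phantom_idps = idp.extract_all(subject, atlas, subject_id="phantom-0001")
    _write_tsv(phantom_idps, out / "phantom_idps.tsv")
    manifest["stages"]["extract"] = {
        "n_idps": int(phantom_idps["idp_name"].nunique()),
        "mislocalised_structures": phantom_idps.attrs.get("mislocalised_structures", []),
    }

    # --- stage 2: cohort -----------------------------------------------------
    truth = truth or default_cohort_truth(seed=int(rng_seeds[1] % 2**31))
    idp_table, phen = synthetic.make_cohort(
        config.n_subjects, truth, default_idp_modalities()
    )
    _write_tsv(idp_table, out / "cohort_idps.tsv")
    _write_tsv(phen, out / "cohort_phenotypes.tsv")
    manifest["stages"]["cohort"] = {
        "n_subjects": int(phen.shape[0]),
        "n_idps": int(idp_table["idp_name"].nunique()),
    }

    # --- stage 3: QC ---------------------------------------------------------
    iqm_rng = np.random.default_rng(int(rng_seeds[2] % 2**31))
    outlier_ids = sorted(
        iqm_rng.choice(config.n_subjects, size=min(config.n_planted_outliers, config.n_subjects), replace=False).tolist()
    )
    iqm = synthetic.make_iqm_table(
        n_scans=config.n_subjects,
        n_metrics=config.n_iqm_metrics,
        outlier_ids=outlier_ids,
        seed=int(rng_seeds[2] % 2**31),
        modality="T1",
    )
    _write_tsv(iqm, out / "iqm.tsv")
    reports = qc.iqr_flags(iqm, k=config.iqr_k)
    flags = qc.reports_to_frame(reports)
    flags["excluded"] = flags["scan_id"].isin(config.excluded_scans)
    _write_tsv(flags, out / "qc_flags.tsv")
    summary = qc.summarize_flags(reports, exclusions=config.excluded_scans)
    _write_tsv(summary, out / "qc_summary.tsv")

    bold = synthetic.make_bold(
        seed=int(rng_seeds[3] % 2**31),
        shape=(12, 12, 12),
        T=config.bold_T,
        spike_timepoints=[config.bold_T // 2],
    )
    dse = qc.dse_decompose(bold)
    svar_times, svar_flag = qc.svar_criterion(dse, config.svar_threshold)
    manifest["stages"]["qc"] = {
        "n_scans": int(config.n_subjects),
        "n_flagged": int(flags["flagged"].sum()),
        "pct_flagged": float(100.0 * flags["flagged"].mean()),
        "n_excluded": int(flags["excluded"].sum()),
        "planted_outlier_scans": [f"scan-{i + 1:04d}" for i in outlier_ids],
        "dse_pct_dvar": dse.pct_dvar,
        "dse_pct_svar": dse.pct_svar,
        "svar_flagged_timepoints": svar_times,
        "svar_scan_flag": bool(svar_flag),
    }

    # --- stage 4: exclusions before association -------------------------------
    excluded_subjects = {s.replace("scan-", "sub-") for s in config.excluded_scans}
    phen_used = phen[~phen["subject_id"].isin(excluded_subjects)]
    idp_used = idp_table[idp_table["subject_id"].isin(phen_used["subject_id"])]
    manifest["stages"]["exclusion"] = {
        "n_subjects_in": int(phen.shape[0]),
        "n_excluded": int(phen.shape[0] - phen_used.shape[0]),
        "n_subjects_out": int(phen_used.shape[0]),
    }

    # --- stage 5: association screen ------------------------------------------
    try:
        screen = stats.run_association_screen(
            idp_used, phen_used, q=config.q, min_n=config.min_n
        )
    except Exception as exc:  # pragma: no cover - stage failure context
        raise RuntimeError(f"association stage failed: {exc}") from exc
    hierarchy_report = {}
    for outcome, res in screen.items():
        _write_tsv(res.table, out / f"associations_{outcome}.tsv")
        hierarchy_report[outcome] = {
            "simes_p": {k: float(v) for k, v in res.hier.family_simes_p.items()},
            "selected_families": res.hier.selected_families,
            "m_families": res.hier.m_families,
            "r_selected": res.hier.r_selected,
            "adjusted_level": res.hier.adjusted_level,
            "n_rejected": res.hier.n_rejected,
            "skipped_idps": res.skipped,
        }
    (out / "hierarchy_report.json").write_text(json.dumps(hierarchy_report, indent=2))
    manifest["stages"]["association"] = {
        outcome: {
            "n_fits": int(res.table.shape[0]),
            "n_rejected": int(res.table["rejected"].sum()),
            "n_subjects": int(phen_used.shape[0]),
        }
        for outcome, res in screen.items()
    }

    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
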