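"""Synthetic phantoms, cohorts, quality-metric tables and BOLD series.

Everything downstream of image preprocessing can be exercised without scan
data: this module builds (a) geometric phantoms whose regional volumes and
overlaps are exact voxel-count arithmetic, (b) tabular cohorts with planted
IDP-phenotype effects (linear for age/cognition, proportional-odds for the
ordered diagnosis), (c) image-quality-metric tables with planted outliers
guaranteed to breach the interquartile fences of the remaining scans, and
(d) 4D time series with planted global-intensity spikes.

Phantom regions are axis-aligned boxes, deliberately non-anatomical: the
point is that every true volume, overlap and weighted mean is known by
counting voxels, so the extraction operators can be tested exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .grids import AtlasBundle, SubjectImagery, VolumeGrid

__all__ = [
    "CohortTruth",
    "LOBE_NAMES",
    "STRUCTURE_NAMES",
    "CORTICAL_ROI_NAMES",
    "make_phantom",
    "make_cohort",
    "make_iqm_table",
    "make_bold",
    "save_subject",
    "load_subject",
]

LOBE_NAMES = ("frontal", "parietal", "temporal", "occipital")
STRUCTURE_NAMES = (
    "hippocampus_l",
    "hippocampus_r",
    "amygdala_l",
    "amygdala_r",
)
# Cortical grey-matter ROIs measured bilaterally for regional diffusion.
CORTICAL_ROI_NAMES = (
    "parahippocampal_gyrus",
    "precuneus",
    "superior_frontal",
    "superior_parietal",
    "supramarginal",
)
N_WM_TRACTS = 48
N_TRACTOGRAPHY_TRACTS = 27
DIAGNOSIS_LEVELS = ("no_drd", "mci", "dementia")

# Fixed cutpoints of the proportional-odds latent scale; with standard
# logistic noise and a unit-variance linear predictor these give all three
# diagnosis levels comfortably nonzero mass.
_DIAGNOSIS_CUTPOINTS = (-1.0, 0.2)


@dataclass
class CohortTruth:
    """Ground truth for a simulated cohort.

    ``planted_beta`` maps IDP name -> {phenotype -> standardised effect};
    phenotypes are ``age``, ``ace`` (linear outcomes) and ``diagnosis``
    (coefficient on the proportional-odds latent scale).  ``noise_sd``
    of ``None`` auto-calibrates the residual so each planted IDP has unit
    variance, making the planted betas exact standardised partial effects.
    """

    planted_beta: dict[str, dict[str, float]]
    null_idp_names: list[str]
    noise_sd: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.planted_beta) & set(self.null_idp_names)
        if overlap:
            raise ValueError(f"IDPs both planted and null: {sorted(overlap)}")

    @property
    def idp_names(self) -> list[str]:
        return list(self.planted_beta) + list(self.null_idp_names)


# ---------------------------------------------------------------------------
# Phantom imagery
# ---------------------------------------------------------------------------


def _scaled_box(shape: Sequence[int], lo: Sequence[float], hi: Sequence[float]) -> tuple[slice, slice, slice]:
    """Axis-aligned box from fractional coordinates, at least 1 voxel thick."""
    out = []
    for n, a, b in zip(shape, lo, hi):
        i = int(round(a * n))
        j = int(round(b * n))
        j = max(j, i + 1)
        out.append(slice(min(i, n - 1), min(j, n)))
    return tuple(out)  # type: ignore[return-value]


def _box_mask(shape: Sequence[int], lo: Sequence[float], hi: Sequence[float]) -> np.ndarray:
    m = np.zeros(shape, dtype=float)
    m[_scaled_box(shape, lo, hi)] = 1.0
    return m


def make_phantom(
    seed: int,
    shape: tuple[int, int, int] = (32, 32, 32),
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
    wmh_burden: float = 0.01,
    atrophy: float = 0.0,
) -> tuple[SubjectImagery, AtlasBundle, dict[str, float]]:
    """Build one synthetic subject plus a matching atlas and its ground truth.

    Parameters
    ----------
    seed:
        Seeds all random map values; identical seeds give bit-identical output.
    shape:
        Grid dimensions, each at least 16.
    voxel_size:
        Voxel edge lengths in mm.
    wmh_burden:
        Fraction of candidate white/grey-matter voxels receiving a lesion,
        in [0, 1].  Lesions are placed so they straddle WM tract masks and
        cortical grey matter, exercising both the tract-overlap and the
        lesion-masking corrections.
    atrophy:
        Global downscaling of the grey-matter partial volume, in [0, 1].

    Returns
    -------
    (subject, atlas, ground_truth) where ``ground_truth`` maps region/IDP
    names to true volumes in mm^3 and true regional weighted MD/MO means,
    all computed by explicit voxel-count arithmetic on the generated maps.
    """
    shape = tuple(int(s) for s in shape)  # type: ignore[assignment]
    if len(shape) != 3 or any(s < 16 for s in shape):
        raise ValueError(f"phantom shape must be >= (16,16,16), got {shape}")
    if not (0.0 <= wmh_burden <= 1.0 and 0.0 <= atrophy <= 1.0):
        raise ValueError("wmh_burden and atrophy must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    voxvol = float(np.prod(voxel_size))

    brain = np.zeros(shape, dtype=float)
    brain[1:-1, 1:-1, 1:-1] = 1.0

    # --- atlas geometry (deterministic, independent of seed) ---------------
    lobar = {
        "frontal": _box_mask(shape, (0.08, 0.08, 0.52), (0.45, 0.45, 0.88)),
        "parietal": _box_mask(shape, (0.55, 0.08, 0.52), (0.92, 0.45, 0.88)),
        "temporal": _box_mask(shape, (0.08, 0.55, 0.52), (0.45, 0.92, 0.88)),
        "occipital": _box_mask(shape, (0.55, 0.55, 0.52), (0.92, 0.92, 0.88)),
    }

    # 48 tract masks: an 8 x 6 grid of small boxes in a deep white-matter slab.
    wm_tracts: dict[str, np.ndarray] = {}
    for idx in range(N_WM_TRACTS):
        col, row = idx % 8, idx // 8
        x0 = 0.08 + 0.84 * col / 8
        y0 = 0.08 + 0.84 * row / 6
        wm_tracts[f"wm_tract_{idx + 1:02d}"] = _box_mask(
            shape, (x0, y0, 0.20), (x0 + 0.84 / 8, y0 + 0.84 / 6, 0.42)
        )

    nbm = {
        "nbm_l": _box_mask(shape, (0.30, 0.42, 0.44), (0.42, 0.55, 0.50)),
        "nbm_r": _box_mask(shape, (0.58, 0.42, 0.44), (0.70, 0.55, 0.50)),
    }

    # Subcortical structures (subject space in reality; shared grid here).
    structure_arrays = {
        "hippocampus_l": _box_mask(shape, (0.20, 0.30, 0.08), (0.38, 0.48, 0.18)),
        "hippocampus_r": _box_mask(shape, (0.62, 0.30, 0.08), (0.80, 0.48, 0.18)),
        "amygdala_l": _box_mask(shape, (0.20, 0.55, 0.08), (0.34, 0.70, 0.18)),
        "amygdala_r": _box_mask(shape, (0.66, 0.55, 0.08), (0.80, 0.70, 0.18)),
    }

    gm_rois: dict[str, np.ndarray] = {}
    for i, base in enumerate(CORTICAL_ROI_NAMES):
        x0 = 0.10 + 0.16 * i
        gm_rois[f"{base}_l"] = _box_mask(shape, (x0, 0.12, 0.90), (x0 + 0.10, 0.26, 0.96))
        gm_rois[f"{base}_r"] = _box_mask(shape, (x0, 0.70, 0.90), (x0 + 0.10, 0.84, 0.96))

    tract_names = [f"tractography_tract_{i + 1:02d}" for i in range(N_TRACTOGRAPHY_TRACTS)]

    # --- subject maps (seeded) ---------------------------------------------
    gm_pve = rng.uniform(0.2, 0.95, size=shape) * brain * (1.0 - atrophy)

    # Lesions straddle deep WM tract boxes and cortical GM so both the
    # tract-overlap IDPs and lesion-masking are exercised.
    any_tract = np.zeros(shape, dtype=bool)
    for m in wm_tracts.values():
        any_tract |= m.astype(bool)
    any_lobe = np.zeros(shape, dtype=bool)
    for m in lobar.values():
        any_lobe |= m.astype(bool)
    candidates = np.flatnonzero((any_tract | any_lobe) & (brain > 0))
    wmh = np.zeros(shape, dtype=float)
    n_lesion = int(round(wmh_burden * candidates.size))
    if n_lesion > 0:
        chosen = rng.choice(candidates, size=n_lesion, replace=False)
        wmh.ravel()[chosen] = 1.0

    # CSF: low inside the brain with a pocket flooding part of the left
    # hippocampus, so CSF-masking removes a known voxel set.
    csf = rng.uniform(0.0, 0.3, size=shape) * brain
    pocket = _scaled_box(shape, (0.20, 0.30, 0.08), (0.29, 0.48, 0.18))
    csf[pocket] = rng.uniform(0.75, 1.0, size=csf[pocket].shape)

    # MD around cortical values with an x-gradient on the skeleton so the
    # skeleton percentile width is nonzero; units mm^2/s.
    md = 7e-4 + 1e-4 * rng.standard_normal(shape)
    grad = np.linspace(0.0, 3e-4, shape[0])[:, None, None]
    md = np.abs(md + grad)
    mo = rng.uniform(-0.6, 0.6, size=shape)

    skeleton = _box_mask(shape, (0.12, 0.12, 0.30), (0.88, 0.88, 0.34))

    # Tractography densities: supra-threshold core inside a box, plus a
    # shell sitting below the binarisation threshold.
    tract_density: dict[str, VolumeGrid] = {}
    tract_truth: dict[str, float] = {}
    for i, name in enumerate(tract_names):
        col, row = i % 7, i // 7
        x0 = 0.10 + 0.80 * col / 7
        y0 = 0.10 + 0.80 * row / 4
        core = _scaled_box(shape, (x0, y0, 0.22), (x0 + 0.80 / 7, y0 + 0.80 / 4, 0.40))
        dens = np.zeros(shape, dtype=float)
        dens[core] = rng.uniform(0.01, 0.6, size=dens[core].shape)
        shell = _scaled_box(shape, (x0, y0, 0.40), (x0 + 0.80 / 7, y0 + 0.80 / 4, 0.46))
        dens[shell] = 0.003
        tract_density[name] = VolumeGrid(dens, voxel_size)
        tract_truth[f"tract_volume_{name}"] = float((dens > 0.005).sum()) * voxvol

    subject = SubjectImagery(
        gm_pve=VolumeGrid(gm_pve, voxel_size),
        wmh_mask=VolumeGrid(wmh, voxel_size),
        csf_map=VolumeGrid(csf, voxel_size),
        structure_masks={k: VolumeGrid(v, voxel_size) for k, v in structure_arrays.items()},
        md_map=VolumeGrid(md, voxel_size),
        mo_map=VolumeGrid(mo, voxel_size),
        skeleton_mask=VolumeGrid(skeleton, voxel_size),
        tract_density=tract_density,
    )
    atlas = AtlasBundle(
        lobar_masks={k: VolumeGrid(v, voxel_size) for k, v in lobar.items()},
        wm_tract_masks={k: VolumeGrid(v, voxel_size) for k, v in wm_tracts.items()},
        nbm_masks={k: VolumeGrid(v, voxel_size) for k, v in nbm.items()},
        gm_roi_masks={k: VolumeGrid(v, voxel_size) for k, v in gm_rois.items()},
        tractography_tract_names=tract_names,
    )

    # --- ground truth by explicit arithmetic on the generated arrays -------
    truth: dict[str, float] = dict(tract_truth)
    gm_corr = gm_pve * (1.0 - wmh)
    for name, m in lobar.items():
        truth[f"lobar_gm_{name}"] = float((gm_corr * m).sum()) * voxvol
    for name, m in wm_tracts.items():
        truth[f"wmh_{name}"] = float((wmh * m).sum()) * voxvol
    for name, m in nbm.items():
        truth[f"{name}_volume"] = float((gm_corr * m).sum()) * voxvol

    csf_binary = (csf > 0.5).astype(float)
    corrected_structures = {
        name: arr * (1.0 - csf_binary) for name, arr in structure_arrays.items()
    }
    for name, arr in corrected_structures.items():
        truth[f"structure_{name}_volume"] = float(arr.sum()) * voxvol

    roi_arrays = dict(corrected_structures)
    roi_arrays.update(gm_rois)
    for name, m in roi_arrays.items():
        w = gm_corr * m
        tot = float(w.sum())
        if tot > 0:
            truth[f"regional_md_{name}"] = float((md * w).sum()) / tot
            truth[f"regional_mo_{name}"] = float((mo * w).sum()) / tot
        else:
            truth[f"regional_md_{name}"] = float("nan")
            truth[f"regional_mo_{name}"] = float("nan")

    sk = md[skeleton.astype(bool)]
    truth["psmd"] = float(np.percentile(sk, 95) - np.percentile(sk, 5))

    return subject, atlas, truth


# ---------------------------------------------------------------------------
# Tabular cohort with planted effects
# ---------------------------------------------------------------------------

_VALID_PHENOTYPES = {"age", "ace", "diagnosis"}


def make_cohort(
    n: int,
    truth: CohortTruth,
    modality_labels: Mapping[str, str],
    ace_age_corr: float = 0.0,
    diagnosis_age_effect: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an IDP table and phenotype table with planted effects.

    Covariates (age, sex, head size, cognition) are sampled independently
    by default so planted coefficients are exact standardised partial
    effects; ``ace_age_corr`` injects an age-cognition correlation when
    realism matters more than clean parameter recovery.  The ordered
    diagnosis is generated from a proportional-odds latent: a linear
    predictor in the planted IDPs (plus an age term) plus standard logistic
    noise, cut at fixed thresholds, so all three levels (no dementia-related
    diagnosis < MCI < dementia) have nonzero mass.

    Returns ``(idp_table, phenotype_table)``: the IDP table is long-format
    (subject_id, idp_name, modality, value); phenotypes carry age in years,
    a binary sex indicator, a unitless head-size factor, ACE-III total
    (0-100) and the ordered diagnosis label.
    """
    if n < 10:
        raise ValueError(f"cohort size must be >= 10, got {n}")
    unknown = set(truth.planted_beta) - set(modality_labels)
    unknown |= set(truth.null_idp_names) - set(modality_labels)
    if unknown:
        raise ValueError(f"effect or null declared for unknown IDPs: {sorted(unknown)}")
    for idp, betas in truth.planted_beta.items():
        bad = set(betas) - _VALID_PHENOTYPES
        if bad:
            raise ValueError(f"unknown phenotypes {sorted(bad)} for IDP {idp!r}")

    rng = np.random.default_rng(truth.seed)
    age_z = rng.standard_normal(n)
    sex = rng.integers(0, 2, size=n).astype(float)
    head_z = rng.standard_normal(n)
    ace_z = ace_age_corr * (-age_z) + np.sqrt(max(0.0, 1 - ace_age_corr**2)) * rng.standard_normal(n)

    pheno_z = {"age": age_z, "ace": ace_z}

    idp_values: dict[str, np.ndarray] = {}
    for idp in truth.idp_names:
        betas = truth.planted_beta.get(idp, {})
        signal = np.zeros(n)
        ss = 0.0
        for pheno, b in betas.items():
            if pheno == "diagnosis":
                continue  # diagnosis is generated FROM the IDP below
            signal = signal + b * pheno_z[pheno]
            ss += b * b
        if truth.noise_sd is not None:
            resid_sd = truth.noise_sd
        else:
            if ss >= 1.0:
                raise ValueError(
                    f"planted effects for {idp!r} imply variance >= 1; "
                    "set noise_sd explicitly"
                )
            resid_sd = float(np.sqrt(1.0 - ss))
        idp_values[idp] = signal + resid_sd * rng.standard_normal(n)

    # Proportional-odds diagnosis from the planted latent.
    latent = diagnosis_age_effect * age_z
    for idp, betas in truth.planted_beta.items():
        b = betas.get("diagnosis", 0.0)
        if b:
            latent = latent + b * idp_values[idp]
    latent = latent + rng.logistic(size=n)
    c1, c2 = _DIAGNOSIS_CUTPOINTS
    diag_idx = np.digitize(latent, [c1, c2])
    diagnosis = pd.Categorical.from_codes(
        diag_idx, categories=list(DIAGNOSIS_LEVELS), ordered=True
    )

    phen = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:04d}" for i in range(n)],
            "age": 78.0 + 6.2 * age_z,
            "sex": sex.astype(int),
            "head_size": 1.0 + 0.1 * head_z,
            "ace_total": np.clip(np.round(74.0 + 17.0 * ace_z), 0, 100).astype(int),
            "diagnosis": diagnosis,
        }
    )

    rows = []
    for idp in truth.idp_names:
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": phen["subject_id"],
                    "idp_name": idp,
                    "modality": modality_labels[idp],
                    "value": idp_values[idp],
                }
            )
        )
    idp_table = pd.concat(rows, ignore_index=True)
    return idp_table, phen


# ---------------------------------------------------------------------------
# IQM tables with planted outliers
# ---------------------------------------------------------------------------


def make_iqm_table(
    n_scans: int,
    n_metrics: int,
    outlier_ids: Sequence[int],
    seed: int,
    modality: str = "T1",
) -> pd.DataFrame:
    """Image-quality-metric table with guaranteed planted outliers.

    Ordinary scans draw every metric from one Gaussian per metric; each
    scan in ``outlier_ids`` (integer indices into 0..n_scans-1) has one
    metric pushed far beyond the 1.5-IQR fences computed from the
    remaining scans, so the interquartile flagging rule must pick it up.
    """
    if n_scans < 5:
        raise ValueError("need at least 5 scans for meaningful quartiles")
    outlier_ids = list(outlier_ids)
    if any(i < 0 or i >= n_scans for i in outlier_ids):
        raise ValueError("outlier_ids must be valid scan indices")

    rng = np.random.default_rng(seed)
    mu = rng.uniform(-5, 5, size=n_metrics)
    sd = rng.uniform(0.5, 2.0, size=n_metrics)
    values = mu + sd * rng.standard_normal((n_scans, n_metrics))

    for sid in outlier_ids:
        m = int(rng.integers(0, n_metrics))
        rest = np.delete(values[:, m], outlier_ids)
        q1, q3 = np.percentile(rest, [25, 75])
        iqr = q3 - q1
        values[sid, m] = q3 + 1.5 * iqr + max(3 * iqr, 3 * sd[m])

    records = []
    for i in range(n_scans):
        for m in range(n_metrics):
            records.append(
                (f"scan-{i + 1:04d}", modality, f"metric_{m + 1:02d}", values[i, m])
            )
    return pd.DataFrame(records, columns=["scan_id", "modality", "metric_name", "value"])


# ---------------------------------------------------------------------------
# 4D BOLD with planted spikes
# ---------------------------------------------------------------------------


def make_bold(
    seed: int,
    shape: tuple[int, int, int],
    T: int,
    spike_timepoints: Sequence[int] = (),
    spike_amplitude: float = 4.0,
) -> np.ndarray:
    """i.i.d.-noise 4D series with global-intensity spikes at given timepoints.

    Spike timepoints are 0-based and must be interior (1 <= t <= T-2) so
    that both the transition into and out of the spike exist.
    """
    if T < 10:
        raise ValueError(f"need T >= 10 timepoints, got {T}")
    for t in spike_timepoints:
        if not (1 <= t <= T - 2):
            raise ValueError(f"spike timepoint {t} outside [1, {T - 2}]")
    rng = np.random.default_rng(seed)
    bold = rng.standard_normal((*shape, T))
    for t in spike_timepoints:
        bold[..., t] += spike_amplitude
    return bold


# ---------------------------------------------------------------------------
# On-disk layout: gzipped NIfTI per map + JSON manifest
# ---------------------------------------------------------------------------


def save_subject(
    subject: SubjectImagery,
    atlas: AtlasBundle,
    out_dir: str | Path,
    seed: Optional[int] = None,
    params: Optional[dict] = None,
) -> Path:
    """Write one subject + atlas as .nii.gz files with a role manifest.

    Returns the manifest path.  The manifest maps each role (e.g.
    ``gm_pve``, ``lobar_masks/frontal``) to its filename and echoes the
    generation seed and parameters for provenance.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"roles": {}, "seed": seed, "params": params or {}}

    def _write(role: str, grid: VolumeGrid) -> None:
        fname = role.replace("/", "_") + ".nii.gz"
        grid.save(out / fname)
        manifest["roles"][role] = fname

    _write("gm_pve", subject.gm_pve)
    _write("wmh_mask", subject.wmh_mask)
    _write("csf_map", subject.csf_map)
    _write("md_map", subject.md_map)
    _write("mo_map", subject.mo_map)
    _write("skeleton_mask", subject.skeleton_mask)
    for name, g in subject.structure_masks.items():
        _write(f"structure_masks/{name}", g)
    for name, g in subject.tract_density.items():
        _write(f"tract_density/{name}", g)
    for group, masks in (
        ("lobar_masks", atlas.lobar_masks),
        ("wm_tract_masks", atlas.wm_tract_masks),
        ("nbm_masks", atlas.nbm_masks),
        ("gm_roi_masks", atlas.gm_roi_masks),
    ):
        for name, g in masks.items():
            _write(f"{group}/{name}", g)
    manifest["tractography_tract_names"] = list(atlas.tractography_tract_names)

    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_subject(manifest_path: str | Path) -> tuple[SubjectImagery, AtlasBundle]:
    """Load a subject + atlas from a manifest written by :func:`save_subject`."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    roles: dict[str, str] = manifest["roles"]

    def _load(role: str) -> VolumeGrid:
        return VolumeGrid.load(base / roles[role])

    def _load_group(prefix: str) -> dict[str, VolumeGrid]:
        out = {}
        for role in roles:
            if role.startswith(prefix + "/"):
                out[role.split("/", 1)[1]] = _load(role)
        return out

    subject = SubjectImagery(
        gm_pve=_load("gm_pve"),
        wmh_mask=_load("wmh_mask"),
        csf_map=_load("csf_map"),
        structure_masks=_load_group("structure_masks"),
        md_map=_load("md_map"),
        mo_map=_load("mo_map"),
        skeleton_mask=_load("skeleton_mask"),
        tract_density=_load_group("tract_density"),
    )
    atlas = AtlasBundle(
        lobar_masks=_load_group("lobar_masks"),
        wm_tract_masks=_load_group("wm_tract_masks"),
        nbm_masks=_load_group("nbm_masks"),
        gm_roi_masks=_load_group("gm_roi_masks"),
        tractography_tract_names=manifest.get("tractography_tract_names", []),
    )
    return subject, atlas
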