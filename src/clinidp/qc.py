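"""Staged quality control: IQR outlier flagging and DSE variance decomposition.

Automated QC here marks scans for human inspection; it never excludes them
by itself.  Per metric, within modality, a scan is flagged when its value
falls more than ``k`` interquartile ranges outside the first/third quartile
(k = 1.5 by default); a scan is flagged overall when at least one metric
flags it.  Exclusion decisions arrive as a separate list (the
human-in-the-loop visual stage) and are merged into the report.

For resting-state series the DSE decomposition splits the whole-series
variance into a fast component D (half-differences of adjacent volumes), a
slow component S (half-sums) and an edge term E (endpoints), satisfying
A = D + S + E exactly.  Timepoints where the slow share exceeds a threshold
(75% by default; white noise sits near 50%) indicate residual structured
noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .grids import VolumeGrid

__all__ = [
    "FlagReport",
    "DSEResult",
    "iqr_flags",
    "dse_decompose",
    "svar_criterion",
    "summarize_flags",
]


@dataclass
class FlagReport:
    """Per-scan QC decision: flagged metrics plus the exclusion verdict."""

    scan_id: str
    modality: str
    flagged_metrics: list[str] = field(default_factory=list)
    excluded: bool = False
    reason: str = ""

    @property
    def flagged(self) -> bool:
        return len(self.flagged_metrics) > 0


def iqr_flags(iqm: pd.DataFrame, k: float = 1.5) -> list[FlagReport]:
    """Flag scans whose value breaches the Tukey fences on any metric.

    ``iqm`` is long-format with columns scan_id, modality, metric_name,
    value.  Quartiles are computed per (modality, metric) with linear
    interpolation between order statistics (quantile type 7); a scan is
    flagged on a metric iff value < Q1 - k*IQR or value > Q3 + k*IQR.
    A metric with zero spread (IQR = 0) flags only values differing from
    the common quartile band.
    """
    required = {"scan_id", "modality", "metric_name", "value"}
    missing = required - set(iqm.columns)
    if missing:
        raise ValueError(f"IQM table missing columns: {sorted(missing)}")
    if not np.isfinite(iqm["value"]).all():
        raise ValueError("IQM values must be finite")
    dup = iqm.duplicated(subset=["scan_id", "modality", "metric_name"])
    if dup.any():
        raise ValueError("duplicate (scan, modality, metric) entries")

    flagged: dict[tuple[str, str], list[str]] = {}
    for (modality, metric), grp in iqm.groupby(["modality", "metric_name"], sort=False):
        if len(grp) < 5:
            raise ValueError(
                f"metric {metric!r} in modality {modality!r} has {len(grp)} scans; "
                "need >= 5 for quartiles"
            )
        q1, q3 = np.percentile(grp["value"], [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        out = grp[(grp["value"] < lo) | (grp["value"] > hi)]
        for sid in out["scan_id"]:
            flagged.setdefault((sid, modality), []).append(metric)

    reports = []
    for (sid, modality), grp in iqm.groupby(["scan_id", "modality"], sort=False):
        reports.append(
            FlagReport(
                scan_id=sid,
                modality=modality,
                flagged_metrics=sorted(flagged.get((sid, modality), [])),
            )
        )
    return reports


# ---------------------------------------------------------------------------
# DSE decomposition
# ---------------------------------------------------------------------------


@dataclass
class DSEResult:
    """Fast/slow/edge variance split of a 4D series.

    ``avar_t`` has one entry per timepoint; ``dvar_t`` and ``svar_t`` one per
    transition between adjacent timepoints (length T-1); ``evar_t`` the two
    endpoint terms.  ``pct_*`` express each term as a percentage of the mean
    per-timepoint variance, so a white-noise series hovers near 50% for both
    D and S.  Globally %D + %S + %E = 100 exactly.
    """

    avar_t: np.ndarray
    dvar_t: np.ndarray
    svar_t: np.ndarray
    evar_t: np.ndarray
    pct_dvar_t: np.ndarray
    pct_svar_t: np.ndarray
    pct_dvar: float
    pct_svar: float
    pct_evar: float

    @property
    def total_variance(self) -> float:
        return float(self.avar_t.sum())


def dse_decompose(bold: np.ndarray, brain_mask: Optional[VolumeGrid] = None) -> DSEResult:
    """Decompose a (x, y, z, t) series into fast, slow and edge variance.

    Each voxel's time series is mean-centred; then with y_t the centred
    values, the per-transition fast and slow terms are the voxel-averaged
    squares of (y_{t+1} - y_t)/2 and (y_{t+1} + y_t)/2, and the edge term
    is (y_1^2 + y_T^2)/2 averaged over voxels.  These satisfy
    sum(A) = sum(D) + sum(S) + sum(E) identically.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 4:
        raise ValueError(f"bold must be 4D, got ndim={bold.ndim}")
    T = bold.shape[-1]
    if T < 3:
        raise ValueError(f"need at least 3 timepoints, got {T}")
    if brain_mask is not None:
        sel = brain_mask.data.astype(bool)
        if brain_mask.shape != bold.shape[:3]:
            raise ValueError("brain mask incompatible with bold grid")
        if not sel.any():
            raise ValueError("brain mask is empty")
        series = bold[sel]  # (voxels, T)
    else:
        series = bold.reshape(-1, T)

    y = series - series.mean(axis=1, keepdims=True)
    avar_t = (y**2).mean(axis=0)
    d = (y[:, 1:] - y[:, :-1]) / 2.0
    s = (y[:, 1:] + y[:, :-1]) / 2.0
    dvar_t = (d**2).mean(axis=0)
    svar_t = (s**2).mean(axis=0)
    evar_t = np.array([(y[:, 0] ** 2).mean() / 2.0, (y[:, -1] ** 2).mean() / 2.0])

    total = float(avar_t.sum())
    mean_a = total / T
    # a constant series leaves only float residue from the mean-centring
    if total <= (series**2).mean() * T * np.finfo(float).eps:
        zeros = np.zeros(T)
        zero_trans = np.zeros(T - 1)
        return DSEResult(zeros, zero_trans, zero_trans.copy(), np.zeros(2),
                         zero_trans.copy(), zero_trans.copy(), 0.0, 0.0, 0.0)

    return DSEResult(
        avar_t=avar_t,
        dvar_t=dvar_t,
        svar_t=svar_t,
        evar_t=evar_t,
        pct_dvar_t=100.0 * dvar_t / mean_a,
        pct_svar_t=100.0 * svar_t / mean_a,
        pct_dvar=100.0 * float(dvar_t.sum()) / total,
        pct_svar=100.0 * float(svar_t.sum()) / total,
        pct_evar=100.0 * float(evar_t.sum()) / total,
    )


def svar_criterion(dse: DSEResult, threshold_pct: float = 75.0) -> tuple[list[int], bool]:
    """Transitions whose slow-variance share exceeds the threshold.

    Returns (indices, flagged): 0-based transition indices where
    %S-var > threshold, and whether any did.  White noise sits near 50%,
    so sustained excursions above 75% mark residual structured noise.
    """
    idx = np.flatnonzero(dse.pct_svar_t > threshold_pct)
    return list(int(i) for i in idx), bool(idx.size > 0)


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------


def summarize_flags(
    reports: Sequence[FlagReport], exclusions: Sequence[str] = ()
) -> pd.DataFrame:
    """Per-modality flag/exclusion percentages.

    ``exclusions`` lists scan ids excluded after visual inspection; these
    are merged into the reports (an excluded scan need not have been
    auto-flagged — visual inspection can also catch what the metrics miss).
    Returns one row per modality: n_total, n_flagged, n_excluded,
    pct_flagged, pct_excluded.
    """
    excl = set(exclusions)
    rows: dict[str, dict[str, float]] = {}
    for r in reports:
        d = rows.setdefault(
            r.modality, {"n_total": 0, "n_flagged": 0, "n_excluded": 0}
        )
        d["n_total"] += 1
        if r.flagged:
            d["n_flagged"] += 1
        if r.excluded or r.scan_id in excl:
            d["n_excluded"] += 1
    if not rows:
        warnings.warn("no reports to summarise; returning empty table")
        return pd.DataFrame(
            columns=["modality", "n_total", "n_flagged", "n_excluded", "pct_flagged", "pct_excluded"]
        )
    out = []
    for modality, d in rows.items():
        out.append(
            {
                "modality": modality,
                "n_total": int(d["n_total"]),
                "n_flagged": int(d["n_flagged"]),
                "n_excluded": int(d["n_excluded"]),
                "pct_flagged": 100.0 * d["n_flagged"] / d["n_total"],
                "pct_excluded": 100.0 * d["n_excluded"] / d["n_total"],
            }
        )
    return pd.DataFrame(out)


def reports_to_frame(reports: Sequence[FlagReport]) -> pd.DataFrame:
    """Flatten flag reports for TSV/JSON output."""
    return pd.DataFrame(
        {
            "scan_id": [r.scan_id for r in reports],
            "modality": [r.modality for r in reports],
            "flagged": [r.flagged for r in reports],
            "flagged_metrics": [";".join(r.flagged_metrics) for r in reports],
            "excluded": [r.excluded for r in reports],
            "reason": [r.reason for r in reports],
        }
    )
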