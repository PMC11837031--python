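"""Mass-univariate association screen with hierarchical FDR control.

The screen regresses each imaging-derived phenotype (IDP) against three
clinical outcomes: age and cognition (ACE-III total) by ordinary least
squares, and the ordered diagnosis (no dementia-related diagnosis < MCI <
dementia) by proportional-odds logistic regression.  All numeric variables
(IDPs, age, head size, cognition) are rank-based normalised to Gaussian
scores first, so the IDP coefficient reads as "1 SD of IDP corresponds to
beta SD of outcome" (or beta log-odds for diagnosis).

Multiplicity is handled hierarchically per outcome: IDP p-values are
grouped into families by acquisition modality; a Simes omnibus p-value per
family enters a Benjamini-Hochberg (BH) pass across the m families at
level q; the R selected families then have their member IDPs BH-tested at
the stricter level q*R/m.  This controls the within-family false discovery
rate while spending error budget only on modalities that show any signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.api import OLS
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "HierFDRResult",
    "ModelSpec",
    "quantile_normalise",
    "fit_linear_assoc",
    "fit_ordinal_assoc",
    "simes_p",
    "bh_reject",
    "hierarchical_fdr",
    "run_association_screen",
    "default_model_specs",
    "simulate_hierarchical_fdr",
]


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------


def quantile_normalise(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform to Gaussian scores.

    Non-missing values are mapped monotonically to Phi^{-1}((r - 0.5)/n)
    with average ranks for ties; missing values stay missing.  The result
    depends only on ranks, so any strictly monotone transform of the input
    yields identical output.
    """
    arr = np.asarray(values, dtype=float)
    out = np.full(arr.shape, np.nan)
    present = ~np.isnan(arr)
    x = arr[present]
    if x.size < 3:
        raise ValueError(f"need >= 3 non-missing values, got {x.size}")
    if np.all(x == x[0]):
        raise ValueError("all values identical; normal scores undefined")
    ranks = sps.rankdata(x, method="average")
    out[present] = sps.norm.ppf((ranks - 0.5) / x.size)
    return out


# ---------------------------------------------------------------------------
# Per-IDP model fits
# ---------------------------------------------------------------------------


@dataclass
class AssociationResult:
    """One IDP-outcome fit: standardised effect, Wald statistic, raw p."""

    idp_name: str
    modality: str
    beta: float
    se: float
    statistic: float
    p_raw: float
    n_used: int


def _design(idp: np.ndarray, covariates: Optional[np.ndarray]) -> np.ndarray:
    cols = [np.ones_like(idp), idp]
    if covariates is not None and covariates.size:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != idp.size:
            cov = cov.T
        cols.extend(cov.T)
    return np.column_stack(cols)


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy elimination
        bad = []
        keep: list[int] = []
        for j in range(X.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(X[:, trial]) < len(trial):
                bad.append(names[j] if j < len(names) else f"col{j}")
            else:
                keep.append(j)
        raise ValueError(f"design matrix rank-deficient; collinear columns: {bad}")


def fit_linear_assoc(
    outcome: np.ndarray,
    idp: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    idp_name: str = "idp",
    modality: str = "",
    covariate_names: Sequence[str] = (),
) -> AssociationResult:
    """OLS of outcome on (intercept, IDP, covariates); two-sided t-test p."""
    outcome = np.asarray(outcome, dtype=float)
    idp = np.asarray(idp, dtype=float)
    X = _design(idp, covariates)
    if outcome.size <= X.shape[1] + 2:
        raise ValueError(f"n={outcome.size} too small for {X.shape[1]} parameters")
    _check_rank(X, ["intercept", idp_name, *covariate_names])
    fit = OLS(outcome, X).fit()
    return AssociationResult(
        idp_name=idp_name,
        modality=modality,
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        statistic=float(fit.tvalues[1]),
        p_raw=float(fit.pvalues[1]),
        n_used=int(outcome.size),
    )


def fit_ordinal_assoc(
    diagnosis: np.ndarray,
    idp: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    idp_name: str = "idp",
    modality: str = "",
    use_lr_pvalue: bool = False,
) -> AssociationResult:
    """Proportional-odds logistic fit of the ordered diagnosis.

    ``diagnosis`` holds ordered integer codes (0 < 1 < 2 ...).  The
    returned beta is the IDP log-odds coefficient (exp(beta) is the odds
    ratio of a higher diagnostic category per SD of IDP); p is Wald-based
    unless ``use_lr_pvalue`` requests a likelihood-ratio test.
    """
    codes = np.asarray(diagnosis)
    levels = np.unique(codes)
    if levels.size < 2:
        raise ValueError("diagnosis must have >= 2 observed levels")
    idp = np.asarray(idp, dtype=float)
    exog_cols = [idp]
    if covariates is not None and np.asarray(covariates).size:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != idp.size:
            cov = cov.T
        exog_cols.extend(cov.T)
    exog = np.column_stack(exog_cols)
    _check_rank(np.column_stack([np.ones(len(idp)), exog]), ["intercept", idp_name])

    model = OrderedModel(codes, exog, distr="logit")
    fit = model.fit(method="bfgs", disp=False, maxiter=200)
    beta = float(fit.params[0])
    se = float(fit.bse[0])
    if not np.isfinite(se) or se > 50:
        raise ValueError(
            f"ordinal fit for {idp_name!r} unstable (se={se:.3g}); "
            "likely complete or quasi-complete separation"
        )
    z = beta / se
    p = 2.0 * sps.norm.sf(abs(z))
    if use_lr_pvalue:
        null_exog = exog[:, 1:] if exog.shape[1] > 1 else None
        if null_exog is None:
            null_llf = OrderedModel(codes, np.zeros((len(codes), 0)), distr="logit").fit(
                method="bfgs", disp=False
            ).llf
        else:
            null_llf = OrderedModel(codes, null_exog, distr="logit").fit(
                method="bfgs", disp=False
            ).llf
        lr = 2.0 * (fit.llf - null_llf)
        p = float(sps.chi2.sf(max(lr, 0.0), df=1))
    return AssociationResult(
        idp_name=idp_name,
        modality=modality,
        beta=beta,
        se=se,
        statistic=float(z),
        p_raw=float(p),
        n_used=int(len(codes)),
    )


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def simes_p(pvec: Sequence[float] | np.ndarray) -> float:
    """Simes omnibus p-value: min over i of m * p_(i) / i, capped at 1."""
    p = np.asarray(pvec, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    p_sorted = np.sort(p)
    ranks = np.arange(1, m + 1)
    return float(min(1.0, np.min(m * p_sorted / ranks)))


def bh_reject(pvec: Sequence[float] | np.ndarray, level: float) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection flags, adjusted p-values)."""
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0,1), got {level}")
    p = np.asarray(pvec, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=level, method="fdr_bh")
    return reject, p_adj


@dataclass
class HierFDRResult:
    """Bookkeeping of the two-stage (family then member) FDR procedure."""

    q: float
    family_simes_p: dict[str, float]
    selected_families: list[str]
    m_families: int
    r_selected: int
    adjusted_level: float
    member_p_adjusted: dict[str, np.ndarray] = field(default_factory=dict)
    member_rejected: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_rejected(self) -> int:
        return int(sum(r.sum() for r in self.member_rejected.values()))


def hierarchical_fdr(
    p_by_family: Mapping[str, Sequence[float] | np.ndarray], q: float = 0.05
) -> HierFDRResult:
    """Two-stage FDR: Simes per family, BH across families, BH within selected.

    Stage 1 computes a Simes omnibus p per family and runs BH over those m
    p-values at level q, selecting R families.  Stage 2 runs BH within each
    selected family at the proportionally stricter level q*R/m; unselected
    families reject nothing.  Member adjusted p-values are the within-family
    BH-adjusted values scaled by m/R (capped at 1), so rejection is
    equivalent to adjusted p <= q.
    """
    if not p_by_family:
        raise ValueError("need at least one family")
    families = list(p_by_family)
    simes = {f: simes_p(p_by_family[f]) for f in families}
    m = len(families)
    sel_flags, _ = bh_reject([simes[f] for f in families], q)
    selected = [f for f, s in zip(families, sel_flags) if s]
    r = len(selected)
    adj_level = q * r / m if r else q

    member_adj: dict[str, np.ndarray] = {}
    member_rej: dict[str, np.ndarray] = {}
    for f in families:
        p = np.asarray(p_by_family[f], dtype=float)
        if f in selected:
            rej, p_adj = bh_reject(p, adj_level)
            member_adj[f] = np.minimum(1.0, p_adj * m / r)
            member_rej[f] = rej
        else:
            member_adj[f] = np.full(p.shape, np.nan)
            member_rej[f] = np.zeros(p.shape, dtype=bool)

    return HierFDRResult(
        q=q,
        family_simes_p=simes,
        selected_families=selected,
        m_families=m,
        r_selected=r,
        adjusted_level=adj_level,
        member_p_adjusted=member_adj,
        member_rejected=member_rej,
    )


# ---------------------------------------------------------------------------
# End-to-end screen
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """One outcome model of the screen.

    ``covariates`` are phenotype columns entered alongside the IDP;
    ``extra_covariates`` optionally maps IDP name -> list of other IDP
    names (e.g. the matched tract volume) added to that IDP's model only —
    the volume-controlled sensitivity variant.
    """

    outcome: str
    covariates: list[str]
    model_family: str = "linear"
    extra_covariates: Optional[dict[str, list[str]]] = None

    def __post_init__(self) -> None:
        if self.outcome in self.covariates:
            raise ValueError(f"outcome {self.outcome!r} cannot be a covariate")
        if self.outcome == "diagnosis" and self.model_family != "ordinal":
            raise ValueError("diagnosis outcome requires the ordinal family")
        if self.model_family not in ("linear", "ordinal"):
            raise ValueError(f"unknown model family {self.model_family!r}")


def default_model_specs() -> list[ModelSpec]:
    """The three standard outcome models of the screen."""
    return [
        ModelSpec("age", ["sex", "head_size", "ace_total"], "linear"),
        ModelSpec("ace_total", ["age", "sex", "head_size"], "linear"),
        ModelSpec("diagnosis", ["age", "sex", "head_size"], "ordinal"),
    ]


# phenotype columns normalised to Gaussian scores; sex stays a raw indicator
_NORMALISED_PHENO = ("age", "head_size", "ace_total")


@dataclass
class ScreenResult:
    """Association table plus FDR bookkeeping for one outcome."""

    outcome: str
    table: pd.DataFrame
    hier: HierFDRResult
    skipped: list[str] = field(default_factory=list)


def run_association_screen(
    idps: pd.DataFrame,
    phen: pd.DataFrame,
    specs: Optional[Sequence[ModelSpec]] = None,
    q: float = 0.05,
    min_n: int = 20,
) -> dict[str, ScreenResult]:
    """Fit every IDP against every outcome and correct hierarchically.

    ``idps`` is long-format (subject_id, idp_name, modality, value); ``phen``
    has subject_id, age, sex, head_size, ace_total, diagnosis.  Each outcome
    gets its own hierarchy over modality families.  Complete-case per IDP:
    rows missing the IDP, outcome or any covariate are dropped for that fit;
    IDPs with fewer than ``min_n`` usable rows (or unstable fits) are
    skipped and logged.
    """
    specs = list(specs) if specs is not None else default_model_specs()
    wide = idps.pivot(index="subject_id", columns="idp_name", values="value")
    modality_of = (
        idps.drop_duplicates("idp_name").set_index("idp_name")["modality"].to_dict()
    )
    phen = phen.set_index("subject_id").loc[wide.index]

    # normalise IDPs and numeric phenotypes once
    norm = {}
    for col in wide.columns:
        norm[col] = quantile_normalise(wide[col].to_numpy())
    covars: dict[str, np.ndarray] = {"sex": phen["sex"].to_numpy(dtype=float)}
    for col in _NORMALISED_PHENO:
        covars[col] = quantile_normalise(phen[col].to_numpy(dtype=float))
    diag_codes = (
        phen["diagnosis"].cat.codes.to_numpy()
        if isinstance(phen["diagnosis"].dtype, pd.CategoricalDtype)
        else pd.Categorical(phen["diagnosis"], ordered=True).codes
    ).astype(float)
    diag_codes[diag_codes < 0] = np.nan

    out: dict[str, ScreenResult] = {}
    for spec in specs:
        results: list[AssociationResult] = []
        skipped: list[str] = []
        y_full = diag_codes if spec.outcome == "diagnosis" else covars[spec.outcome]
        for idp_name in wide.columns:
            x_full = norm[idp_name]
            extra = (spec.extra_covariates or {}).get(idp_name, [])
            cov_cols = [covars[c] for c in spec.covariates] + [norm[e] for e in extra]
            stack = np.column_stack([y_full, x_full, *cov_cols])
            ok = ~np.isnan(stack).any(axis=1)
            if ok.sum() < min_n:
                logger.warning("skipping %s for %s: n=%d < %d", idp_name, spec.outcome, ok.sum(), min_n)
                skipped.append(idp_name)
                continue
            y, x = y_full[ok], x_full[ok]
            cov = np.column_stack([c[ok] for c in cov_cols]) if cov_cols else None
            try:
                if spec.model_family == "ordinal":
                    res = fit_ordinal_assoc(
                        y.astype(int), x, cov, idp_name=idp_name,
                        modality=modality_of.get(idp_name, ""),
                    )
                else:
                    res = fit_linear_assoc(
                        y, x, cov, idp_name=idp_name,
                        modality=modality_of.get(idp_name, ""),
                        covariate_names=list(spec.covariates) + list(extra),
                    )
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("skipping %s for %s: %s", idp_name, spec.outcome, exc)
                skipped.append(idp_name)
                continue
            results.append(res)

        table = pd.DataFrame(
            {
                "idp_name": [r.idp_name for r in results],
                "modality": [r.modality for r in results],
                "beta": [r.beta for r in results],
                "se": [r.se for r in results],
                "statistic": [r.statistic for r in results],
                "p_raw": [r.p_raw for r in results],
                "n_used": [r.n_used for r in results],
            }
        )
        p_by_family = {
            fam: grp["p_raw"].to_numpy() for fam, grp in table.groupby("modality", sort=False)
        }
        hier = hierarchical_fdr(p_by_family, q=q)
        table["p_corrected"] = np.nan
        table["rejected"] = False
        for fam, grp in table.groupby("modality", sort=False):
            table.loc[grp.index, "p_corrected"] = hier.member_p_adjusted[fam]
            table.loc[grp.index, "rejected"] = hier.member_rejected[fam]
        out[spec.outcome] = ScreenResult(spec.outcome, table, hier, skipped)
    return out


# ---------------------------------------------------------------------------
# FDR-control simulation
# ---------------------------------------------------------------------------


def simulate_hierarchical_fdr(
    n_reps: int = 2000,
    seed: int = 0,
    m_families: int = 6,
    tests_per_family: int = 50,
    n_signal_families: int = 2,
    n_signal_per_family: int = 10,
    effect: float = 2.8,
    q: float = 0.05,
) -> dict[str, float]:
    """Empirical within-family FDR of the two-stage procedure.

    Each replicate draws two-sided z-test p-values: nulls from N(0,1),
    non-nulls from N(effect, 1) (effect = 2.8 gives roughly 50% power at
    the operating thresholds); non-nulls occupy the first
    ``n_signal_per_family`` slots of the first ``n_signal_families``
    families.  The per-replicate false discovery proportion pools
    rejections across families (0 when nothing is rejected); the return
    value reports its mean as a percentage plus the Monte-Carlo SE.
    """
    rng = np.random.default_rng(seed)
    fdp = np.zeros(n_reps)
    power = np.zeros(n_reps)
    n_signal_total = n_signal_families * n_signal_per_family
    for rep in range(n_reps):
        p_by_family: dict[str, np.ndarray] = {}
        is_null: dict[str, np.ndarray] = {}
        for f in range(m_families):
            z = rng.standard_normal(tests_per_family)
            null_mask = np.ones(tests_per_family, dtype=bool)
            if f < n_signal_families:
                z[:n_signal_per_family] += effect
                null_mask[:n_signal_per_family] = False
            name = f"family_{f}"
            p_by_family[name] = 2.0 * sps.norm.sf(np.abs(z))
            is_null[name] = null_mask
        res = hierarchical_fdr(p_by_family, q=q)
        false = sum(int((res.member_rejected[f] & is_null[f]).sum()) for f in p_by_family)
        true = sum(int((res.member_rejected[f] & ~is_null[f]).sum()) for f in p_by_family)
        total = false + true
        fdp[rep] = false / total if total else 0.0
        power[rep] = true / n_signal_total if n_signal_total else math.nan
    return {
        "empirical_fdr_pct": 100.0 * float(fdp.mean()),
        "mc_se_pct": 100.0 * float(fdp.std(ddof=1) / np.sqrt(n_reps)),
        "mean_power": float(power.mean()),
        "n_reps": float(n_reps),
    }
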