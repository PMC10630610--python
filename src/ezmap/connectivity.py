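"""Structural connectome abnormality mapping.

Turns FA-weighted connectivity matrices into per-connection and
per-region abnormality z-scores against a normative control model.  The
pipeline order is fixed: harmonize across scanner batches, adjust for
age and sex with a robust linear model fitted on healthy controls, then
z-score each patient connection against the control mean and SD:

    A_ij = (C_ij - mu_i) / sigma_i

Regional abnormality R_kj is the mean of A over the n_k connections
incident to region k.  The ranking score is -R_kj, so FA *reductions*
(negative z) rank as large abnormalities; an optional clamp at zero
discards positive-z regions instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .combat import CombatModel, apply_combat, fit_combat

__all__ = [
    "ConnectivityMatrix",
    "ConnectomeNormativeModel",
    "ConnectionAbnormalityMap",
    "RegionalConnectivityAbnormality",
    "combat_harmonize",
    "fit_normative_connectome",
    "connection_abnormalities",
    "regional_abnormality",
]

DEGENERATE_SD = 1e-12
HUBER_T = 1.345  # robust-regression tuning constant


@dataclass
class ConnectivityMatrix:
    """One subject's symmetric region-by-region FA connectome + covariates."""

    subject_id: str
    region_ids: list[str]
    weights: np.ndarray  # (n, n) FA in [0, 1]
    present_mask: np.ndarray  # (n, n) bool, atlas-present connections
    age: float
    sex: int  # 0/1 binary code
    batch: str

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        m = np.asarray(self.present_mask, dtype=bool)
        n = len(self.region_ids)
        if len(set(self.region_ids)) != n:
            raise ValueError("duplicate region ids")
        if w.shape != (n, n) or m.shape != (n, n):
            raise ValueError("weights/mask shape does not match region count")
        if not np.all(np.isfinite(w)):
            raise ValueError("non-finite connection weight")
        if not np.allclose(w, w.T):
            i, j = np.argwhere(~np.isclose(w, w.T))[0]
            raise ValueError(f"asymmetric weights at ({self.region_ids[i]}, {self.region_ids[j]})")
        if not np.array_equal(m, m.T):
            raise ValueError("asymmetric presence mask")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        self.weights = w
        self.present_mask = m

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)


def _edge_index(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle (i, j) indices of present connections."""
    iu, ju = np.triu_indices(mask.shape[0], k=1)
    keep = mask[iu, ju]
    return iu[keep], ju[keep]


def _edge_vector(cm: ConnectivityMatrix, iu: np.ndarray, ju: np.ndarray) -> np.ndarray:
    return cm.weights[iu, ju]


def _check_cohort(cohort: list[ConnectivityMatrix]) -> tuple[np.ndarray, np.ndarray]:
    ref = cohort[0]
    for cm in cohort[1:]:
        if cm.region_ids != ref.region_ids:
            raise ValueError("cohort region ids differ")
        if not np.array_equal(cm.present_mask, ref.present_mask):
            raise ValueError("cohort presence masks differ")
    return _edge_index(ref.present_mask)


@dataclass
class ConnectomeNormativeModel:
    """Control-derived reference for z-scoring patient connectomes."""

    region_ids: list[str]
    present_mask: np.ndarray
    beta_age: np.ndarray  # per-edge FA/year
    beta_sex: np.ndarray  # per-edge FA
    mu: np.ndarray  # per-edge mean of adjusted control weights
    sigma: np.ndarray  # per-edge SD (ddof=1) of adjusted control weights
    age_ref: float
    sex_ref: float
    combat: CombatModel | None = None

    @property
    def degenerate(self) -> np.ndarray:
        return self.sigma < DEGENERATE_SD

    @property
    def edge_index(self) -> tuple[np.ndarray, np.ndarray]:
        return _edge_index(self.present_mask)


@dataclass
class ConnectionAbnormalityMap:
    """Per-connection z-scores for one subject (NaN where undefined)."""

    subject_id: str
    region_ids: list[str]
    z: np.ndarray  # (n, n) symmetric, NaN off-mask and on degenerate edges
    present_mask: np.ndarray
    n_degenerate: int = 0


@dataclass
class RegionalConnectivityAbnormality:
    """Mean connection abnormality per region, with the ranking score."""

    subject_id: str
    region_ids: list[str]
    r: np.ndarray  # R_k, NaN where no scored connections
    n_connections: np.ndarray
    clamp_positive: bool = False
    score: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        s = -np.asarray(self.r, dtype=float)
        if self.clamp_positive:
            s = np.where(np.isnan(s), np.nan, np.clip(s, 0.0, None))
        self.score = s

    def score_by_region(self) -> dict[str, float]:
        return {
            rid: float(s)
            for rid, s in zip(self.region_ids, self.score)
            if not np.isnan(s)
        }


# ---------------------------------------------------------------------------
# operations


def combat_harmonize(
    cohort: list[ConnectivityMatrix],
    fit_cohort: list[ConnectivityMatrix] | None = None,
) -> list[ConnectivityMatrix]:
    """Harmonize connection weights across scanner batches.

    Batch location/scale parameters are estimated per connection with
    empirical-Bayes shrinkage, protecting age and sex as biological
    covariates, then removed.  With ``fit_cohort`` given (typically the
    healthy controls), parameters are estimated there and applied to
    ``cohort``; by default the cohort is its own reference.  A
    single-batch cohort is returned unchanged.
    """
    if not cohort:
        return []
    fit_on = fit_cohort if fit_cohort is not None else cohort
    iu, ju = _check_cohort(list(fit_on) + list(cohort))
    batches = {cm.batch for cm in fit_on}
    if len(batches) < 2:
        return [_replace_weights(cm, cm.weights[iu, ju], iu, ju) for cm in cohort]
    y_fit = np.stack([_edge_vector(cm, iu, ju) for cm in fit_on])
    cov_fit = np.array([[cm.age, cm.sex] for cm in fit_on], dtype=float)
    model = fit_combat(y_fit, np.array([cm.batch for cm in fit_on]), cov_fit)
    y = np.stack([_edge_vector(cm, iu, ju) for cm in cohort])
    cov = np.array([[cm.age, cm.sex] for cm in cohort], dtype=float)
    y_adj = apply_combat(model, y, np.array([cm.batch for cm in cohort]), cov)
    np.clip(y_adj, 0.0, 1.0, out=y_adj)
    return [_replace_weights(cm, y_adj[j], iu, ju) for j, cm in enumerate(cohort)]


def _replace_weights(
    cm: ConnectivityMatrix, edges: np.ndarray, iu: np.ndarray, ju: np.ndarray
) -> ConnectivityMatrix:
    w = np.zeros_like(cm.weights)
    w[iu, ju] = edges
    w[ju, iu] = edges
    return ConnectivityMatrix(
        subject_id=cm.subject_id,
        region_ids=list(cm.region_ids),
        weights=w,
        present_mask=cm.present_mask.copy(),
        age=cm.age,
        sex=cm.sex,
        batch=cm.batch,
    )


def fit_normative_connectome(
    controls: list[ConnectivityMatrix], min_controls: int = 10
) -> ConnectomeNormativeModel:
    """Fit the normative control model per masked connection.

    Each connection weight is regressed on age and sex with a Huber
    M-estimator (tuning constant 1.345) over the (already harmonized)
    controls; mu_i and sigma_i are the mean and SD (n-1 denominator) of
    the covariate-adjusted control weights.  Connections with sigma_i
    below 1e-12 are flagged degenerate rather than raising.
    """
    if len(controls) < min_controls:
        raise ValueError(
            f"need at least {min_controls} controls to fit a normative model, got {len(controls)}"
        )
    iu, ju = _check_cohort(controls)
    y = np.stack([_edge_vector(cm, iu, ju) for cm in controls])  # (n_subj, n_edges)
    ages = np.array([cm.age for cm in controls], dtype=float)
    sexes = np.array([cm.sex for cm in controls], dtype=float)
    age_ref, sex_ref = float(ages.mean()), float(sexes.mean())
    X = sm.add_constant(np.column_stack([ages - age_ref, sexes - sex_ref]))
    n_edges = y.shape[1]
    beta_age = np.zeros(n_edges)
    beta_sex = np.zeros(n_edges)
    mu = np.empty(n_edges)
    for e in range(n_edges):
        col = y[:, e]
        if np.ptp(col) < DEGENERATE_SD:
            mu[e] = col.mean()  # constant weight: slopes 0, sigma flags it
            continue
        fit = sm.RLM(col, X, M=sm.robust.norms.HuberT(t=HUBER_T)).fit()
        # covariates are centred, so the intercept is the robust location
        # at the reference age/sex (outlier-resistant, unlike a plain mean)
        mu[e] = fit.params[0]
        beta_age[e] = fit.params[1]
        beta_sex[e] = fit.params[2]
    adjusted = y - np.outer(ages - age_ref, beta_age) - np.outer(sexes - sex_ref, beta_sex)
    sigma = adjusted.std(axis=0, ddof=1)
    ref = controls[0]
    return ConnectomeNormativeModel(
        region_ids=list(ref.region_ids),
        present_mask=ref.present_mask.copy(),
        beta_age=beta_age,
        beta_sex=beta_sex,
        mu=mu,
        sigma=sigma,
        age_ref=age_ref,
        sex_ref=sex_ref,
    )


def connection_abnormalities(
    patient: ConnectivityMatrix, model: ConnectomeNormativeModel
) -> ConnectionAbnormalityMap:
    """z-score a subject's connections against the normative model.

    The subject's weights are covariate-adjusted with the control-fitted
    age/sex coefficients (patients never influence the model), then
    A_ij = (adjusted C_ij - mu_i) / sigma_i on each masked,
    non-degenerate connection.  Degenerate connections come back NaN and
    are counted.
    """
    if patient.region_ids != model.region_ids:
        raise ValueError("patient/model region ids differ")
    if not np.array_equal(patient.present_mask, model.present_mask):
        raise ValueError("patient/model presence masks differ")
    if patient.age is None or patient.sex is None:
        raise ValueError("patient covariates missing")
    iu, ju = model.edge_index
    w = patient.weights[iu, ju]
    adjusted = (
        w
        - (patient.age - model.age_ref) * model.beta_age
        - (patient.sex - model.sex_ref) * model.beta_sex
    )
    degen = model.degenerate
    a = np.full_like(w, np.nan)
    ok = ~degen
    a[ok] = (adjusted[ok] - model.mu[ok]) / model.sigma[ok]
    z = np.full(patient.weights.shape, np.nan)
    z[iu, ju] = a
    z[ju, iu] = a
    return ConnectionAbnormalityMap(
        subject_id=patient.subject_id,
        region_ids=list(patient.region_ids),
        z=z,
        present_mask=model.present_mask.copy(),
        n_degenerate=int(degen.sum()),
    )


def regional_abnormality(
    a_map: ConnectionAbnormalityMap, clamp_positive: bool = False
) -> RegionalConnectivityAbnormality:
    """Mean connection abnormality per region.

    R_k averages the z-scores of all scored connections incident to
    region k; regions without any scored connection are NaN (missing,
    not zero).  The ranking score is -R_k (optionally clamped at 0).
    """
    z = a_map.z
    n = z.shape[0]
    r = np.full(n, np.nan)
    counts = np.zeros(n, dtype=int)
    for k in range(n):
        row = z[k]
        vals = row[a_map.present_mask[k] & ~np.isnan(row)]
        counts[k] = vals.size
        if vals.size:
            r[k] = vals.mean()
    return RegionalConnectivityAbnormality(
        subject_id=a_map.subject_id,
        region_ids=list(a_map.region_ids),
        r=r,
        n_connections=counts,
        clamp_positive=clamp_positive,
    )
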