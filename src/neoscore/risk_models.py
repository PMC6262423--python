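"""Clinical and composite logistic risk models.

Three model specifications are used for the severe-impairment outcome:

* ``full`` — eight clinical covariates chosen for biological plausibility
  and univariate association (gestational age, birth weight, antenatal
  steroids, 5-minute Apgar, postnatal steroids, ventilator days, inotropes,
  severe ROP);
* ``slim`` — the parsimonious set retained by backwards stepwise selection
  on AIC (ventilator days, delivery mode, antenatal steroids, severe ROP);
* ``composite`` — the slim clinical set plus the weighted MRI injury score.

Fitting is maximum likelihood via iteratively reweighted least squares
(Newton-Raphson with step halving, so the log-likelihood is monotonically
non-decreasing across iterations); the covariance of the estimates is the
inverse observed information. Collinearity is screened with variance
inflation factors (VIF > 5 flags excessive collinearity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cohort import Cohort, SubjectRecord
from .scoring import WeightTable, final_weights, score_injury

FULL_COVARIATES = (
    "gestational_age",
    "birth_weight",
    "antenatal_steroids_any",
    "apgar5",
    "postnatal_steroids",
    "ventilator_days",
    "inotropes",
    "severe_rop",
)

SLIM_COVARIATES = (
    "ventilator_days",
    "vaginal_delivery",
    "antenatal_steroids_any",
    "severe_rop",
)

IMAGING_SCORE = "imaging_score"

CONVERGENCE_TOL = 1e-8
MAX_ITER = 100
VIF_FLAG = 5.0


class SeparationError(RuntimeError):
    """Perfect (or quasi-perfect) separation: the MLE does not exist."""


class RankDeficiencyError(ValueError):
    """The design matrix is not full column rank."""


@dataclass(frozen=True)
class ModelSpec:
    """Named logistic model: ordered covariates on the severe outcome."""

    name: str
    covariates: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("covariates must be unique")
        if self.name == "composite" and self.covariates.count(IMAGING_SCORE) != 1:
            raise ValueError("a composite model must include imaging_score exactly once")

    @classmethod
    def full(cls) -> "ModelSpec":
        return cls("full", FULL_COVARIATES)

    @classmethod
    def slim(cls) -> "ModelSpec":
        return cls("slim", SLIM_COVARIATES)

    @classmethod
    def composite(cls) -> "ModelSpec":
        return cls("composite", SLIM_COVARIATES + (IMAGING_SCORE,))


@dataclass(frozen=True)
class RiskPrediction:
    probability: float
    se: float
    linear_predictor: float


@dataclass
class FittedModel:
    spec: ModelSpec
    params: np.ndarray  # intercept first, then spec.covariates order
    cov_params: np.ndarray
    loglik: float
    loglik_null: float
    n_used: int
    vif: dict[str, float]
    ll_trajectory: list[float]
    score_weights: Optional[WeightTable] = None

    @property
    def names(self) -> tuple[str, ...]:
        return ("intercept",) + self.spec.covariates

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    @property
    def pseudo_r2(self) -> dict[str, float]:
        n = self.n_used
        mcfadden = 1.0 - self.loglik / self.loglik_null if self.loglik_null != 0 else 0.0
        cox_snell = 1.0 - np.exp(2.0 * (self.loglik_null - self.loglik) / n)
        max_cs = 1.0 - np.exp(2.0 * self.loglik_null / n)
        return {"mcfadden": float(mcfadden), "nagelkerke": float(cox_snell / max_cs)}

    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.names, (float(b) for b in self.params)))

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": 1,
                "spec": {"name": self.spec.name, "covariates": list(self.spec.covariates)},
                "params": self.params.tolist(),
                "cov_params": self.cov_params.tolist(),
                "loglik": self.loglik,
                "loglik_null": self.loglik_null,
                "aic": self.aic,
                "pseudo_r2": self.pseudo_r2,
                "vif": self.vif,
                "n_used": self.n_used,
                "score_weights": self.score_weights.as_dict() if self.score_weights else None,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FittedModel":
        data = json.loads(text)
        weights = data.get("score_weights")
        return cls(
            spec=ModelSpec(data["spec"]["name"], tuple(data["spec"]["covariates"])),
            params=np.asarray(data["params"], dtype=float),
            cov_params=np.asarray(data["cov_params"], dtype=float),
            loglik=float(data["loglik"]),
            loglik_null=float(data["loglik_null"]),
            n_used=int(data["n_used"]),
            vif={k: float(v) for k, v in data["vif"].items()},
            ll_trajectory=[],
            score_weights=WeightTable(**weights) if weights else None,
        )


def _logistic_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # numerically stable: log(1+exp(eta)) via logaddexp
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _irls(X: np.ndarray, y: np.ndarray, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Newton-Raphson/IRLS with step halving; log-likelihood never decreases."""
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise RankDeficiencyError("design matrix is rank deficient")
    beta = np.zeros(p)
    ll = _logistic_loglik(X, y, beta)
    trajectory = [ll]
    for _ in range(MAX_ITER):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(_separation_message(X, beta, names)) from exc
        # step halving guarantees monotone log-likelihood
        scale = 1.0
        for _ in range(30):
            candidate = beta + scale * step
            ll_new = _logistic_loglik(X, y, candidate)
            if ll_new >= ll:
                break
            scale *= 0.5
        else:
            candidate, ll_new = beta, ll
        beta, delta, ll = candidate, ll_new - ll, ll_new
        trajectory.append(ll)
        if np.abs(beta).max() > 1e4:
            raise SeparationError(_separation_message(X, beta, names))
        if abs(delta) < CONVERGENCE_TOL:
            break
    else:
        mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
        if np.minimum(mu, 1 - mu).max() < 1e-6 or np.abs(beta).max() > 50:
            raise SeparationError(_separation_message(X, beta, names))
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    # every fitted probability at 0/1 means the classes are separable and
    # the MLE ran off to infinity before the step size underflowed
    if len(beta) > 1 and np.minimum(mu, 1.0 - mu).max() < 1e-7:
        raise SeparationError(_separation_message(X, beta, names))
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.inv(info)
    return beta, cov, trajectory


def _separation_message(X: np.ndarray, beta: np.ndarray, names: Sequence[str]) -> str:
    scaled = np.abs(beta) * (X.std(axis=0) + (X.std(axis=0) == 0))
    worst = int(np.argmax(scaled[1:]) + 1) if len(beta) > 1 else 0
    return (
        f"perfect separation detected; covariate {names[worst]!r} drives the "
        "fitted probabilities to 0/1"
    )


def fit_logistic_xy(
    X: np.ndarray, y: np.ndarray, covariate_names: Sequence[str], spec_name: str = "custom"
) -> FittedModel:
    """Fit a logistic model on an explicit design matrix (no intercept column).

    ``X`` has one column per covariate; an intercept is prepended
    automatically. This is the computational core behind
    :func:`fit_logistic` and is convenient for simulation studies.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both outcome classes must be present")
    names = ("intercept",) + tuple(covariate_names)
    design = np.column_stack([np.ones(len(y)), X])
    vifs = vif_from_matrix(X, covariate_names)
    bad = [name for name, value in vifs.items() if np.isinf(value)]
    if bad:
        raise RankDeficiencyError(
            f"covariate(s) {bad} are exact linear combinations of the others (infinite VIF)"
        )
    beta, cov, trajectory = _irls(design, y, names)
    p_bar = y.mean()
    ll_null = float(len(y) * (p_bar * np.log(p_bar) + (1 - p_bar) * np.log(1 - p_bar)))
    return FittedModel(
        spec=ModelSpec(spec_name, tuple(covariate_names)),
        params=beta,
        cov_params=cov,
        loglik=trajectory[-1],
        loglik_null=ll_null,
        n_used=len(y),
        vif=vifs,
        ll_trajectory=trajectory,
    )


def covariate_value(
    record: SubjectRecord, name: str, weights: Optional[WeightTable] = None
) -> Optional[float]:
    """Numeric value of one model covariate for one subject."""
    if name == IMAGING_SCORE:
        return float(score_injury(record.injury, weights or final_weights()))
    value = getattr(record.covariates, name)
    return None if value is None else float(value)


def design_matrix(
    cohort: Cohort,
    covariates: Sequence[str],
    weights: Optional[WeightTable] = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Complete-case design matrix (no intercept), labels, and subject ids."""
    rows, labels, ids = [], [], []
    for record in cohort.labeled():
        values = [covariate_value(record, name, weights) for name in covariates]
        if any(v is None for v in values):
            continue
        rows.append(values)
        labels.append(float(record.severe))
        ids.append(record.id)
    if not rows:
        raise ValueError("no complete-case records for this covariate set")
    return np.asarray(rows, dtype=float), np.asarray(labels), ids


def fit_logistic(
    cohort: Cohort, spec: ModelSpec, weights: Optional[WeightTable] = None
) -> FittedModel:
    """Fit a named model specification on the labeled, complete-case cohort."""
    X, y, _ = design_matrix(cohort, spec.covariates, weights)
    model = fit_logistic_xy(X, y, spec.covariates, spec_name=spec.name)
    model.spec = spec
    if IMAGING_SCORE in spec.covariates:
        model.score_weights = weights or final_weights()
    return model


def vif_from_matrix(X: np.ndarray, names: Sequence[str]) -> dict[str, float]:
    """Variance inflation factors: 1/(1-R²) of each column on the others.

    Exact linear dependence is reported as ``inf``. A single covariate has
    VIF 1 by convention.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    out: dict[str, float] = {}
    for j in range(p):
        target = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        ss_tot = float(((target - target.mean()) ** 2).sum())
        ss_res = float((resid**2).sum())
        if ss_tot == 0.0:
            out[names[j]] = float("inf")  # constant column
        elif ss_res / ss_tot < 1e-12:
            out[names[j]] = float("inf")
        else:
            out[names[j]] = 1.0 / (ss_res / ss_tot)
    return out


def vif(cohort: Cohort, covariates: Sequence[str], weights: Optional[WeightTable] = None) -> dict[str, float]:
    X, _, _ = design_matrix(cohort, covariates, weights)
    return vif_from_matrix(X, covariates)


def backward_stepwise_aic(
    cohort: "Cohort | tuple[np.ndarray, np.ndarray]",
    candidates: Sequence[str],
    weights: Optional[WeightTable] = None,
) -> FittedModel:
    """Backwards stepwise selection: drop the covariate whose removal most
    lowers AIC, until no single removal improves it.

    Ties (equal AIC improvements) break toward dropping the covariate that
    appears latest in ``candidates``, making the procedure deterministic.
    Accepts a cohort or an ``(X, y)`` pair aligned with ``candidates``.
    """
    if isinstance(cohort, Cohort):
        X_all, y, _ = design_matrix(cohort, candidates, weights)
    else:
        X_all, y = np.asarray(cohort[0], dtype=float), np.asarray(cohort[1], dtype=float)
    remaining = list(range(len(candidates)))
    names = list(candidates)

    def fit_subset(idx: list[int]) -> FittedModel:
        if not idx:
            return fit_logistic_xy(np.empty((len(y), 0)), y, (), spec_name="stepwise")
        return fit_logistic_xy(X_all[:, idx], y, tuple(names[i] for i in idx), spec_name="stepwise")

    current = fit_subset(remaining)
    while remaining:
        best_idx, best_fit = None, None
        for position in range(len(remaining) - 1, -1, -1):
            subset = remaining[:position] + remaining[position + 1 :]
            candidate_fit = fit_subset(subset)
            if candidate_fit.aic < current.aic and (
                best_fit is None or candidate_fit.aic < best_fit.aic
            ):
                best_idx, best_fit = position, candidate_fit
        if best_fit is None:
            break
        del remaining[best_idx]
        current = best_fit
    return current


def predict_risk(
    model: FittedModel,
    subject: "SubjectRecord | dict[str, float]",
    imaging_score: Optional[int] = None,
) -> RiskPrediction:
    """Per-subject probability of severe impairment with a delta-method SE.

    SE(p) = p(1-p) * sqrt(x' Σ x) where Σ is the coefficient covariance.
    ``imaging_score`` overrides the score computed from the subject's injury
    profile (useful for what-if predictions).
    """
    x = [1.0]
    for name in model.spec.covariates:
        if name == IMAGING_SCORE and imaging_score is not None:
            x.append(float(imaging_score))
            continue
        if isinstance(subject, dict):
            if name not in subject:
                raise ValueError(f"missing covariate {name!r}")
            value = float(subject[name])
        else:
            value = covariate_value(subject, name, model.score_weights)
            if value is None:
                raise ValueError(f"missing covariate {name!r}")
        x.append(value)
    xv = np.asarray(x)
    eta = float(xv @ model.params)
    p = 1.0 / (1.0 + np.exp(-eta))
    se = float(p * (1 - p) * np.sqrt(xv @ model.cov_params @ xv))
    return RiskPrediction(probability=p, se=se, linear_predictor=eta)
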