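"""Per-subject inversion of the effort-choice model.

Parameters are estimated by MAP under independent Gaussian priors on
latent parameters, with a Laplace (Gaussian) approximation of the
posterior around the mode — the same approximation variational-Bayes
schemes reach at convergence.  The six sensitivity parameters are
positive by construction and live on a log latent scale (natural value =
exp(latent)); the bias is identity-mapped.

Because fatigue and learning are rolled forward from the *observed*
choices, the subjective value is linear in the natural parameters given
the data: SV = X @ beta for a fixed per-dataset design matrix X.  This
makes the likelihood a sign-constrained logistic regression and allows
exact gradients and Hessians, which the optimizer and the Laplace
evidence use throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, log_expit

from .choice_model import (
    MAX_CUMULATIVE_EFFORT,
    N_MENTAL_TRIALS,
    N_PARAMS,
    PARAM_NAMES,
    BehavioralParameters,
    ChoiceDataset,
)

P_FLOOR = 1e-10  # per-trial likelihood floor against saturated parameters
LATENT_BOUND = 15.0


@dataclass(frozen=True)
class PriorSpec:
    """Independent Gaussian priors on the latent parameters."""

    latent_mean: np.ndarray = field(default_factory=lambda: np.zeros(N_PARAMS))
    latent_sd: np.ndarray = field(default_factory=lambda: np.ones(N_PARAMS))

    def __post_init__(self) -> None:
        object.__setattr__(self, "latent_mean", np.asarray(self.latent_mean, float))
        object.__setattr__(self, "latent_sd", np.asarray(self.latent_sd, float))
        if self.latent_mean.shape != (N_PARAMS,) or self.latent_sd.shape != (N_PARAMS,):
            raise ValueError(f"prior vectors must have length {N_PARAMS}")
        if np.any(self.latent_sd <= 0):
            raise ValueError("latent_sd must be strictly positive")


@dataclass(frozen=True)
class ModelVariant:
    """A nested variant: the named parameters are free, the rest clamped to 0."""

    name: str
    free: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.free) == 0:
            raise ValueError("variant must free at least one parameter")
        unknown = set(self.free) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters: {unknown}")

    @property
    def free_idx(self) -> np.ndarray:
        return np.array([PARAM_NAMES.index(n) for n in self.free], dtype=int)


FULL_MODEL = ModelVariant("full", PARAM_NAMES)


@dataclass
class FitResult:
    map_latent: np.ndarray  # length 7, NaN where clamped
    map_params: BehavioralParameters
    posterior_cov: np.ndarray  # k x k over the free parameters
    log_lik: float
    free_energy: float
    aic: float
    bic: float
    fit_quality: dict
    variant: ModelVariant
    hessian_regularized: bool = False
    n_trials: int = 0


def to_natural(latent: np.ndarray) -> np.ndarray:
    """Map latent vector to natural parameters (exp for k's, identity bias)."""
    natural = np.array(latent, dtype=float)
    natural[:6] = np.exp(natural[:6])
    return natural


def to_latent(params: BehavioralParameters) -> np.ndarray:
    vals = params.as_array()
    latent = vals.copy()
    with np.errstate(divide="ignore"):
        latent[:6] = np.log(vals[:6])
    return latent


def design_matrix(ds: ChoiceDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial regressors X and 0/1 choices y with SV = X @ natural.

    States (fatigue, learning) are rolled forward from the observed
    choices, exactly as the generative model accrues them.
    """
    f = ds.frame
    n = len(f)
    phys = (f["effort_type"] == "physical").to_numpy()
    ment = ~phys
    gain = (f["valence"] == "gain").to_numpy()
    inc = f["incentive_level"].to_numpy(float)
    eff = f["effort_level"].to_numpy(float)
    y = (f["choice"] == "high").to_numpy().astype(float)

    exerted = np.where(phys, eff * y, 0.0)
    fatigue = np.concatenate([[0.0], np.cumsum(exerted)[:-1]]) / MAX_CUMULATIVE_EFFORT
    done_mental = np.concatenate([[0.0], np.cumsum(ment.astype(float))[:-1]])
    learning = done_mental / N_MENTAL_TRIALS

    X = np.zeros((n, N_PARAMS))
    X[:, 0] = np.where(gain, inc, 0.0)  # kR
    X[:, 1] = np.where(~gain, inc, 0.0)  # kP
    X[:, 2] = np.where(phys, -eff, 0.0)  # kEp
    X[:, 3] = np.where(ment, -eff, 0.0)  # kEm
    X[:, 4] = np.where(phys, -fatigue * eff, 0.0)  # kFp
    X[:, 5] = np.where(ment, learning * eff, 0.0)  # kLm
    X[:, 6] = 1.0  # bias
    return X, y


def log_likelihood(params: BehavioralParameters, ds: ChoiceDataset) -> float:
    """Bernoulli log-likelihood of the observed choices."""
    X, y = design_matrix(ds)
    sv = X @ params.as_array()
    p = expit(sv)
    p_choice = np.where(y == 1.0, p, 1.0 - p)
    small = p_choice < P_FLOOR
    if np.any(small):
        warnings.warn("per-trial likelihood clamped at floor", RuntimeWarning)
        p_choice = np.maximum(p_choice, P_FLOOR)
    return float(np.sum(np.log(p_choice)))


def _neg_log_post(z, X, y, mu, sd, is_k):
    """Value and gradient of the negative log-posterior in latent space."""
    beta = np.where(is_k, np.exp(z), z)
    sv = X @ beta
    # log p(choice): log sigma(sv) when y=1, log sigma(-sv) when y=0
    ll = np.sum(np.where(y == 1.0, log_expit(sv), log_expit(-sv)))
    resid = y - expit(sv)  # dLL/dsv
    g_nat = X.T @ resid
    d = np.where(is_k, beta, 1.0)  # dbeta/dz
    grad_ll = g_nat * d
    prior = -0.5 * np.sum(((z - mu) / sd) ** 2)
    grad_prior = -(z - mu) / sd**2
    return -(ll + prior), -(grad_ll + grad_prior)


def _hessian(z, X, y, mu, sd, is_k):
    """Exact Hessian of the negative log-posterior at z."""
    beta = np.where(is_k, np.exp(z), z)
    sv = X @ beta
    w = expit(sv) * (1.0 - expit(sv))
    d = np.where(is_k, beta, 1.0)
    Xd = X * d
    H = Xd.T @ (Xd * w[:, None])
    g_nat = X.T @ (y - expit(sv))
    curv = np.where(is_k, -g_nat * beta, 0.0)  # from d2(beta)/dz2 = beta
    H[np.diag_indices_from(H)] += curv + 1.0 / sd**2
    return H


def fit_map(
    ds: ChoiceDataset,
    prior: PriorSpec | None = None,
    variant: ModelVariant = FULL_MODEL,
    n_starts: int = 5,
    tol: float = 1e-6,
    seed: int = 0,
) -> FitResult:
    """Multi-start quasi-Newton MAP fit with a Laplace posterior.

    Starts are the prior mean plus ``n_starts - 1`` prior draws; the best
    optimum is kept.  The posterior covariance is the inverse Hessian of
    the negative log-posterior at the mode (ridge-regularized and flagged
    if indefinite), and the Laplace free energy is
    log-posterior(mode) + 0.5*logdet(2*pi*cov).
    """
    prior = prior or PriorSpec()
    idx = variant.free_idx
    X_full, y = design_matrix(ds)
    if "kEp" in variant.free or "kFp" in variant.free:
        if not (ds.frame["effort_type"] == "physical").any():
            raise ValueError("variant frees physical parameters but data has no physical trials")
    if "kEm" in variant.free or "kLm" in variant.free:
        if not (ds.frame["effort_type"] == "mental").any():
            raise ValueError("variant frees mental parameters but data has no mental trials")
    X = X_full[:, idx]
    mu, sd = prior.latent_mean[idx], prior.latent_sd[idx]
    is_k = idx < 6

    rng = np.random.default_rng(seed)
    starts = [mu.copy()]
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.normal(mu, sd))

    best = None
    for z0 in starts:
        res = optimize.minimize(
            _neg_log_post,
            z0,
            args=(X, y, mu, sd, is_k),
            jac=True,
            method="L-BFGS-B",
            bounds=[(-LATENT_BOUND, LATENT_BOUND)] * len(idx),
            options={"ftol": tol, "gtol": 1e-8, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):  # pragma: no cover
        raise RuntimeError("MAP optimization failed on all starts")

    z_free = best.x
    H = _hessian(z_free, X, y, mu, sd, is_k)
    H = 0.5 * (H + H.T)
    regularized = False
    eigvals = np.linalg.eigvalsh(H)
    if eigvals.min() <= 1e-10:
        H = H + (1e-6 + abs(eigvals.min())) * np.eye(len(idx))
        regularized = True
    cov = np.linalg.inv(H)
    cov = 0.5 * (cov + cov.T)

    map_latent = np.full(N_PARAMS, np.nan)
    map_latent[idx] = z_free
    natural = np.zeros(N_PARAMS)
    natural[idx] = np.where(is_k, np.exp(z_free), z_free)
    params = BehavioralParameters.from_array(natural)

    ll = log_likelihood(params, ds)
    log_prior = float(np.sum(stats.norm.logpdf(z_free, mu, sd)))
    sign, logdet = np.linalg.slogdet(2.0 * np.pi * cov)
    free_energy = ll + log_prior + 0.5 * logdet
    k = len(idx)
    n = len(ds.frame)
    p_pred = expit(X_full @ natural)
    y_obs = y
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(p_pred, y_obs)[0, 1] if np.std(p_pred) > 0 else 0.0
    fit_quality = {
        "median_abs_error": float(np.median(np.abs(p_pred - y_obs))),
        "r2": float(r**2) if np.isfinite(r) else 0.0,
    }
    return FitResult(
        map_latent=map_latent,
        map_params=params,
        posterior_cov=cov,
        log_lik=ll,
        free_energy=float(free_energy),
        aic=2 * k - 2 * ll,
        bic=k * np.log(n) - 2 * ll,
        fit_quality=fit_quality,
        variant=variant,
        hessian_regularized=regularized,
        n_trials=n,
    )


def compare_models(
    ds: ChoiceDataset,
    variants: list[ModelVariant],
    prior: PriorSpec | None = None,
    seed: int = 0,
    n_starts: int = 5,
) -> pd.DataFrame:
    """Fit each variant and rank by Laplace free energy (AIC/BIC reported)."""
    if len(variants) < 2:
        raise ValueError("need at least 2 variants to compare")
    rows = []
    for v in variants:
        try:
            fit = fit_map(ds, prior=prior, variant=v, seed=seed, n_starts=n_starts)
            rows.append(
                {
                    "name": v.name,
                    "k": len(v.free),
                    "log_lik": fit.log_lik,
                    "free_energy": fit.free_energy,
                    "aic": fit.aic,
                    "bic": fit.bic,
                    "failed": False,
                }
            )
        except Exception as exc:  # fit failure: exclude from ranking
            warnings.warn(f"variant {v.name} failed: {exc}", RuntimeWarning)
            rows.append(
                {
                    "name": v.name,
                    "k": len(v.free),
                    "log_lik": np.nan,
                    "free_energy": np.nan,
                    "aic": np.nan,
                    "bic": np.nan,
                    "failed": True,
                }
            )
    table = pd.DataFrame(rows).sort_values("free_energy", ascending=False).reset_index(drop=True)
    ok = table[~table["failed"]]
    table["wins_free_energy"] = table["name"] == ok.loc[ok["free_energy"].idxmax(), "name"]
    table["wins_aic"] = table["name"] == ok.loc[ok["aic"].idxmin(), "name"]
    table["wins_bic"] = table["name"] == ok.loc[ok["bic"].idxmin(), "name"]
    return table


@dataclass
class TransformedParameters:
    values: pd.DataFrame
    lambdas: dict[str, float]
    shifts: dict[str, float]


def boxcox_transform(values, lmbda: float | None = None, shift: float | None = None):
    """Box-Cox power transform y = (x^l - 1)/l (log x at l = 0).

    ``lmbda`` is estimated by profile maximum likelihood when omitted.
    Zeros are shifted by +1e-6 when no shift is supplied; negative inputs
    raise, naming the offending positions.
    """
    x = np.asarray(values, dtype=float)
    if shift is None:
        shift = 1e-6 if np.any(x == 0) else 0.0
    x = x + shift
    if np.any(x <= 0):
        bad = np.where(x <= 0)[0].tolist()
        raise ValueError(f"non-positive values after shift at positions {bad}")
    if lmbda is None:
        if len(x) < 3:
            raise ValueError("need n >= 3 to estimate lambda")
        y, lmbda = stats.boxcox(x)
    else:
        y = stats.boxcox(x, lmbda=lmbda)
    return np.asarray(y), float(lmbda), float(shift)


def transform_parameter_table(table: pd.DataFrame) -> TransformedParameters:
    """Box-Cox every sensitivity column; the bias column passes through."""
    out = {}
    lambdas: dict[str, float] = {}
    shifts: dict[str, float] = {}
    for name in PARAM_NAMES:
        col = table[name].to_numpy(float)
        if name == "bias":
            out[name] = col
            continue
        y, lam, sh = boxcox_transform(col)
        out[name] = y
        lambdas[name] = lam
        shifts[name] = sh
    frame = pd.DataFrame(out, index=table.index)
    return TransformedParameters(values=frame, lambdas=lambdas, shifts=shifts)
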