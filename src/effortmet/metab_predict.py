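"""Metabolite-to-behavior prediction pipeline.

Subjects' brain metabolite features (concentrations and ratios from a
single MRS voxel) predict a behavioral read-out — the proportion of
high-effort choices or a fitted model parameter — through:

1. a random train/test split (80/20 or 75/25),
2. stage-1 screening: drop features with |Pearson r| < 0.1 against the
   target on the training rows,
3. stage-2 selection: rank surviving features by boosted-ensemble
   importance (AdaBoost) and keep the importance-ranked nested subset
   with the smallest leave-one-out cross-validation (CVLOO) error,
4. gradient-boosted regression (XGBoost) with hyperparameters tuned by
   Bayesian (Gaussian-process expected-improvement) search over CVLOO
   RMSE,
5. holdout evaluation (RMSE, one-tailed Pearson r),
6. a label-permutation null: training labels are shuffled, the model is
   retrained with frozen hyperparameters, and the observed test RMSE is
   compared with the 5th percentile of the permuted RMSE distribution
   (equivalently, the model must beat the 95th percentile of null
   performance),
7. Shapley (exact TreeSHAP) per-feature attribution.

Everything upstream of evaluation reads only training rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import xgboost as xgb
from scipy import stats
from sklearn.ensemble import AdaBoostRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

TARGET_CHOICES = ("HME", "HPE", "kEm", "kR", "kP", "kLm", "bias")


@dataclass
class FeatureTable:
    """Subjects x features with a single regression target."""

    frame: pd.DataFrame
    feature_cols: list[str]
    target_col: str
    region: str = "dmPFC/dACC"

    def __post_init__(self) -> None:
        missing = [c for c in self.feature_cols + [self.target_col] if c not in self.frame]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if self.frame[self.target_col].isna().any():
            raise ValueError("missing target values")

    @property
    def n(self) -> int:
        return len(self.frame)

    def rows(self, ids) -> "FeatureTable":
        return FeatureTable(
            frame=self.frame.loc[ids],
            feature_cols=list(self.feature_cols),
            target_col=self.target_col,
            region=self.region,
        )


@dataclass(frozen=True)
class SplitSpec:
    train_ids: tuple
    test_ids: tuple
    ratio: float
    seed: int


@dataclass
class SelectionResult:
    stage1_kept: list[str]
    stage2_kept: list[str]
    selection_trace: pd.DataFrame  # subset size, features, CVLOO RMSE


@dataclass
class HyperparameterSpace:
    """Search bounds for the six tuned XGBoost hyperparameters."""

    eta: tuple[float, float] = (0.01, 0.5)
    max_depth: tuple[int, int] = (2, 6)
    min_child_weight: tuple[float, float] = (1.0, 10.0)
    gamma: tuple[float, float] = (0.0, 5.0)
    reg_lambda: tuple[float, float] = (0.5, 10.0)
    reg_alpha: tuple[float, float] = (0.0, 5.0)
    n_evals: int = 40
    n_estimators: int = 100

    def __post_init__(self) -> None:
        for name in ("eta", "max_depth", "min_child_weight", "gamma", "reg_lambda", "reg_alpha"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"invalid bounds for {name}")
        if self.max_depth[0] < 1:
            raise ValueError("max_depth must be >= 1")
        if self.n_evals < 1:
            raise ValueError("empty search budget")


@dataclass
class PredictionReport:
    train_rmse: float
    validation_rmse: float
    test_rmse: float
    test_pearson_r: float
    test_p: float  # one-tailed
    variance_explained: float
    hyperparameters: dict
    features: list[str]
    n_train: int
    n_test: int


@dataclass
class PermutationResult:
    n_perm: int
    permuted_rmse: np.ndarray
    threshold: float  # 5th-percentile permuted RMSE (k-th order statistic)
    observed_rmse: float
    significant: bool
    seed: int


@dataclass
class ShapleyReport:
    values: pd.DataFrame  # rows x features
    base_value: float
    ranking: pd.Series  # mean |attribution| per feature, descending


@dataclass
class CurvatureComparison:
    linear: dict  # r, p, aic, bic
    quadratic: dict
    winner_aic: str
    winner_bic: str


# ---------------------------------------------------------------------------
# splitting and feature selection


def split_train_test(table: FeatureTable, ratio: float, seed: int) -> SplitSpec:
    """Random disjoint split with |train| = floor(ratio * N)."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    if table.n < 10:
        raise ValueError("need at least 10 subjects")
    rng = np.random.default_rng(seed)
    ids = np.array(table.frame.index)
    perm = rng.permutation(len(ids))
    n_train = int(np.floor(ratio * len(ids)))
    train = tuple(ids[perm[:n_train]])
    test = tuple(ids[perm[n_train:]])
    return SplitSpec(train_ids=train, test_ids=test, ratio=ratio, seed=seed)


def stage1_filter(train: FeatureTable, threshold: float = 0.1) -> list[str]:
    """Keep features with |Pearson r| >= threshold against the target."""
    y = train.frame[train.target_col].to_numpy(float)
    kept = []
    for col in train.feature_cols:
        x = train.frame[col].to_numpy(float)
        if np.std(x) == 0:
            warnings.warn(f"constant feature {col} treated as r=0, removed", RuntimeWarning)
            continue
        r = np.corrcoef(x, y)[0, 1]
        if abs(r) >= threshold:
            kept.append(col)
    return kept


def _loo_rmse(model_factory, X: np.ndarray, y: np.ndarray, max_skip_frac: float = 0.2) -> float:
    """Leave-one-out CV RMSE; failed folds are skipped and counted."""
    n = len(y)
    errs, skipped = [], 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            m = model_factory()
            m.fit(X[mask], y[mask])
            pred = m.predict(X[~mask])[0]
            errs.append((pred - y[i]) ** 2)
        except Exception:
            skipped += 1
    if skipped > max_skip_frac * n:
        raise RuntimeError(f"{skipped}/{n} LOO folds failed")
    return float(np.sqrt(np.mean(errs)))


def stage2_select(
    train: FeatureTable,
    stage1_features: list[str],
    seed: int = 0,
    n_estimators: int = 50,
) -> SelectionResult:
    """CVLOO-scored nested-subset search over importance-ranked features."""
    if len(stage1_features) == 0:
        raise ValueError("stage-1 produced no features")
    y = train.frame[train.target_col].to_numpy(float)
    X_all = train.frame[stage1_features].to_numpy(float)
    if len(stage1_features) == 1:
        trace = pd.DataFrame(
            [{"k": 1, "features": tuple(stage1_features), "cvloo_rmse": np.nan}]
        )
        return SelectionResult(list(stage1_features), list(stage1_features), trace)

    ranker = AdaBoostRegressor(n_estimators=n_estimators, random_state=seed)
    ranker.fit(X_all, y)
    order = np.argsort(ranker.feature_importances_)[::-1]
    ranked = [stage1_features[i] for i in order]

    rows = []
    best_k, best_err = 1, np.inf
    for k in range(1, len(ranked) + 1):
        subset = ranked[:k]
        X = train.frame[subset].to_numpy(float)
        err = _loo_rmse(
            lambda: AdaBoostRegressor(n_estimators=n_estimators, random_state=seed), X, y
        )
        rows.append({"k": k, "features": tuple(subset), "cvloo_rmse": err})
        if err < best_err:
            best_k, best_err = k, err
    trace = pd.DataFrame(rows)
    return SelectionResult(list(stage1_features), ranked[:best_k], trace)


# ---------------------------------------------------------------------------
# Bayesian hyperparameter tuning


_LOG_DIMS = {"eta", "reg_lambda"}
_DIM_NAMES = ("eta", "max_depth", "min_child_weight", "gamma", "reg_lambda", "reg_alpha")


def _unit_to_params(u: np.ndarray, space: HyperparameterSpace) -> dict:
    params = {}
    for j, name in enumerate(_DIM_NAMES):
        lo, hi = getattr(space, name)
        if name in _LOG_DIMS:
            val = float(np.exp(np.log(lo) + u[j] * (np.log(hi) - np.log(lo))))
        else:
            val = float(lo + u[j] * (hi - lo))
        if name == "max_depth":
            val = int(round(val))
        params[name] = val
    return params


def _xgb_factory(params: dict, space: HyperparameterSpace, seed: int):
    def factory():
        return xgb.XGBRegressor(
            n_estimators=space.n_estimators,
            learning_rate=params["eta"],
            max_depth=params["max_depth"],
            min_child_weight=params["min_child_weight"],
            gamma=params["gamma"],
            reg_lambda=params["reg_lambda"],
            reg_alpha=params["reg_alpha"],
            objective="reg:squarederror",
            n_jobs=1,
            random_state=seed,
            verbosity=0,
        )

    return factory


def tune_and_fit(
    train: FeatureTable,
    features: list[str],
    space: HyperparameterSpace | None = None,
    seed: int = 0,
):
    """GP expected-improvement search over CVLOO RMSE, refit on all train.

    Returns (fitted XGBRegressor, chosen hyperparameters, CVLOO RMSE at
    the optimum).  Deterministic under ``seed``.
    """
    if len(features) == 0:
        raise ValueError("no features to fit")
    space = space or HyperparameterSpace()
    rng = np.random.default_rng(seed)
    X = train.frame[features].to_numpy(float)
    y = train.frame[train.target_col].to_numpy(float)

    n_init = min(max(5, space.n_evals // 3), space.n_evals)
    U, scores = [], []

    def evaluate(u):
        params = _unit_to_params(u, space)
        return _loo_rmse(_xgb_factory(params, space, seed), X, y)

    for _ in range(n_init):
        u = rng.random(len(_DIM_NAMES))
        U.append(u)
        scores.append(evaluate(u))

    while len(U) < space.n_evals:
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5, length_scale=np.full(len(_DIM_NAMES), 0.3)),
            alpha=1e-6,
            normalize_y=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(np.array(U), np.array(scores))
        cand = rng.random((256, len(_DIM_NAMES)))
        mean, sd = gp.predict(cand, return_std=True)
        best = np.min(scores)
        with np.errstate(divide="ignore", invalid="ignore"):
            zz = (best - mean) / np.maximum(sd, 1e-12)
            ei = (best - mean) * stats.norm.cdf(zz) + sd * stats.norm.pdf(zz)
        u = cand[int(np.argmax(ei))]
        U.append(u)
        scores.append(evaluate(u))

    i_best = int(np.argmin(scores))
    best_params = _unit_to_params(U[i_best], space)
    model = _xgb_factory(best_params, space, seed)()
    model.fit(X, y)
    model.feature_names_used_ = list(features)
    return model, best_params, float(scores[i_best])


# ---------------------------------------------------------------------------
# evaluation, permutation null, attribution


def evaluate(model, test: FeatureTable, features: list[str]) -> PredictionReport:
    """Holdout RMSE, one-tailed Pearson r, and variance explained."""
    if test.n < 3:
        raise ValueError("need at least 3 test subjects")
    X = test.frame[features].to_numpy(float)
    y = test.frame[test.target_col].to_numpy(float)
    pred = model.predict(X)
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    if np.std(pred) == 0 or np.std(y) == 0:
        r, p = 0.0, 1.0
    else:
        r, p = stats.pearsonr(pred, y, alternative="greater")
    return PredictionReport(
        train_rmse=np.nan,
        validation_rmse=np.nan,
        test_rmse=rmse,
        test_pearson_r=float(r),
        test_p=float(p),
        variance_explained=float(r**2),
        hyperparameters={},
        features=list(features),
        n_train=0,
        n_test=test.n,
    )


def permutation_threshold(permuted_rmse: np.ndarray, alpha: float = 0.05) -> float:
    """The k-th smallest permuted RMSE with k = floor(alpha * n_perm).

    Beating this value means outperforming 95% of null models — the
    "95th-percentile performance threshold".
    """
    n = len(permuted_rmse)
    k = int(np.floor(alpha * n))
    if k < 1:
        raise ValueError("n_perm too small for the requested alpha")
    return float(np.sort(permuted_rmse)[k - 1])


def permutation_test(
    model_factory,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    observed_rmse: float | None = None,
) -> PermutationResult:
    """Label-permutation null for test RMSE with frozen hyperparameters."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    if observed_rmse is None:
        m = model_factory()
        m.fit(X_train, y_train)
        observed_rmse = float(np.sqrt(np.mean((m.predict(X_test) - y_test) ** 2)))
    rmses = np.empty(n_perm)
    i = 0
    while i < n_perm:
        y_perm = rng.permutation(y_train)
        try:
            m = model_factory()
            m.fit(X_train, y_perm)
            pred = m.predict(X_test)
        except Exception as exc:  # redraw on a failed fit
            warnings.warn(f"permutation fit failed, redrawn: {exc}", RuntimeWarning)
            continue
        rmses[i] = np.sqrt(np.mean((pred - y_test) ** 2))
        i += 1
    thr = permutation_threshold(rmses)
    return PermutationResult(
        n_perm=n_perm,
        permuted_rmse=rmses,
        threshold=thr,
        observed_rmse=float(observed_rmse),
        significant=bool(observed_rmse < thr),
        seed=seed,
    )


def shapley_attribution(model, rows: pd.DataFrame) -> ShapleyReport:
    """Exact tree-path Shapley attributions for a fitted tree ensemble.

    Local accuracy holds per row: attributions + base value equal the
    model's (margin) prediction.
    """
    if not isinstance(model, (xgb.XGBRegressor, xgb.Booster)):
        raise TypeError("shapley_attribution supports xgboost tree models only")
    booster = model.get_booster() if isinstance(model, xgb.XGBRegressor) else model
    features = getattr(model, "feature_names_used_", None) or list(rows.columns)
    dmat = xgb.DMatrix(rows[features].to_numpy(float), feature_names=[str(f) for f in features])
    contribs = booster.predict(dmat, pred_contribs=True)
    values = pd.DataFrame(contribs[:, :-1], columns=features, index=rows.index)
    base = float(contribs[0, -1])
    ranking = values.abs().mean(axis=0).sort_values(ascending=False)
    return ShapleyReport(values=values, base_value=base, ranking=ranking)


def curvature_comparison(x, y) -> CurvatureComparison:
    """Linear vs inverted-U: y ~ x against y ~ (x - mean(x))^2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 10:
        raise ValueError("need n >= 10")
    if np.std(x) == 0:
        raise ValueError("zero-variance predictor")

    def _fit(reg):
        X = sm.add_constant(reg)
        fit = sm.OLS(y, X).fit()
        r, p = stats.pearsonr(reg, y)
        return {"r": float(r), "p": float(p), "aic": float(fit.aic), "bic": float(fit.bic)}

    lin = _fit(x)
    quad = _fit((x - x.mean()) ** 2)
    winner_aic = "quadratic" if quad["aic"] < lin["aic"] else "linear"
    winner_bic = "quadratic" if quad["bic"] < lin["bic"] else "linear"
    return CurvatureComparison(linear=lin, quadratic=quad, winner_aic=winner_aic, winner_bic=winner_bic)


def plasma_brain_correlation(
    plasma: pd.DataFrame, brain: pd.DataFrame, metabolites: list[str], region: str = "dmPFC/dACC"
) -> pd.DataFrame:
    """Pearson r (two-tailed) between matched plasma and brain levels."""
    rows = []
    joined = plasma.join(brain, lsuffix="_plasma", rsuffix="_brain", how="inner")
    for met in metabolites:
        a = joined.get(f"{met}_plasma", joined.get(met))
        b = joined.get(f"{met}_brain")
        if a is None or b is None:
            raise KeyError(f"metabolite {met} missing from one table")
        pair = pd.concat([a, b], axis=1).dropna()
        if len(pair) < 3:
            raise ValueError(f"fewer than 3 complete pairs for {met}")
        r, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
        rows.append({"metabolite": met, "region": region, "n": len(pair), "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class PipelineReport:
    split: SplitSpec
    selection: SelectionResult
    prediction: PredictionReport
    permutation: PermutationResult
    shapley: ShapleyReport


def run_pipeline(
    table: FeatureTable,
    ratio: float = 0.8,
    n_perm: int = 5000,
    seed: int = 0,
    space: HyperparameterSpace | None = None,
    stage2_estimators: int = 50,
) -> PipelineReport:
    """Full split -> select -> tune -> evaluate -> permute -> attribute run.

    One master seed fans out to independent streams for the split, the
    selection/tuning, and the permutation null.  Selection and tuning see
    only training rows.
    """
    ss = np.random.SeedSequence(seed)
    s_split, s_sel, s_tune, s_perm = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)]

    split = split_train_test(table, ratio=ratio, seed=s_split)
    train = table.rows(list(split.train_ids))
    test = table.rows(list(split.test_ids))

    stage1 = stage1_filter(train)
    if not stage1:
        raise RuntimeError("stage-1 filter removed all features")
    selection = stage2_select(train, stage1, seed=s_sel, n_estimators=stage2_estimators)
    feats = selection.stage2_kept

    model, hyper, val_rmse = tune_and_fit(train, feats, space=space, seed=s_tune)
    X_train = train.frame[feats].to_numpy(float)
    y_train = train.frame[train.target_col].to_numpy(float)
    train_rmse = float(np.sqrt(np.mean((model.predict(X_train) - y_train) ** 2)))

    report = evaluate(model, test, feats)
    report.train_rmse = train_rmse
    report.validation_rmse = val_rmse
    report.hyperparameters = hyper
    report.n_train = train.n

    space_used = space or HyperparameterSpace()
    perm = permutation_test(
        _xgb_factory(hyper, space_used, s_tune),
        X_train,
        y_train,
        test.frame[feats].to_numpy(float),
        test.frame[test.target_col].to_numpy(float),
        n_perm=n_perm,
        seed=s_perm,
        observed_rmse=report.test_rmse,
    )
    shap = shapley_attribution(model, table.frame[feats])
    return PipelineReport(split=split, selection=selection, prediction=report, permutation=perm, shapley=shap)
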