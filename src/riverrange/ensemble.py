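"""Five-algorithm presence/background ensemble with spatial cross-validation.

The Maxent-style learner is a maxnet-equivalent L1-penalized logistic
regression on an expanded feature space (linear, quadratic, hinge, product,
threshold columns), tuned over an 8 x 6 regularization/feature-class grid by
AICc. Evaluation uses AUC (Mann-Whitney form) and the maximum true skill
statistic; members passing an AUC gate are combined by AUC-weighted
averaging.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler

from .grid import Grid
from .predictors import PredictorStack

__all__ = [
    "FEATURE_CLASS_GRID",
    "REG_MULT_GRID",
    "ALGORITHMS",
    "LearnerConfig",
    "FittedModel",
    "EnsembleModel",
    "FeatureExpander",
    "expand_features",
    "fit_maxent_like",
    "aicc",
    "tune_maxent",
    "auc",
    "tss_max",
    "fit_all",
    "build_ensemble",
    "classify_performance",
    "variable_importance",
    "predict_grid",
]

REG_MULT_GRID: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)
FEATURE_CLASS_GRID: tuple[str, ...] = ("L", "LQ", "H", "LQH", "LQHP", "LQHPT")
ALGORITHMS: tuple[str, ...] = ("GLM", "GAM", "GBM", "RF", "MAXENT")

DEFAULT_KNOTS_PER_VAR = 10
DEFAULT_MIN_AUC = 0.70
_VALID_LETTERS = set("LQHPT")

#: Relative regularization strength per feature type (hinge/threshold
#: features are penalized harder, mirroring the reference defaults).
PENALTY_SCALE_BY_TYPE = {"L": 1.0, "Q": 1.0, "P": 1.0, "H": 6.0, "T": 6.0}


@dataclass(frozen=True)
class LearnerConfig:
    """Algorithm name plus hyperparameters (Maxent: reg_mult + classes)."""

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.algorithm == "MAXENT":
            rm = self.hyperparameters.get("reg_mult")
            fc = self.hyperparameters.get("feature_classes")
            if rm is not None and rm not in REG_MULT_GRID:
                raise ValueError(f"reg_mult {rm} not in {REG_MULT_GRID}")
            if fc is not None and fc not in FEATURE_CLASS_GRID:
                raise ValueError(f"feature_classes {fc!r} not in {FEATURE_CLASS_GRID}")


# ---------------------------------------------------------------------------
# Feature expansion
# ---------------------------------------------------------------------------


class FeatureExpander:
    """Expand raw variables into the requested feature-class columns.

    Knots for hinge (H) and threshold (T) columns are placed at
    ``knots_per_var`` evenly spaced interior positions over each variable's
    *training* range, so transform of new data reuses the fitted knots.
    """

    def __init__(self, classes: str, knots_per_var: int = DEFAULT_KNOTS_PER_VAR):
        letters = set(classes)
        unknown = letters - _VALID_LETTERS
        if classes not in FEATURE_CLASS_GRID or unknown:
            raise ValueError(
                f"feature classes {classes!r} must be one of {FEATURE_CLASS_GRID}"
            )
        self.classes = classes
        self.knots_per_var = knots_per_var
        self.knots_: np.ndarray | None = None  # (n_vars, knots_per_var)

    def fit(self, X: np.ndarray) -> "FeatureExpander":
        X = np.asarray(X, float)
        if set(self.classes) & {"H", "T"}:
            lo, hi = X.min(axis=0), X.max(axis=0)
            # interior knots: endpoints excluded so hinges are non-degenerate
            grid = np.linspace(0, 1, self.knots_per_var + 2)[1:-1]
            self.knots_ = lo[:, None] + (hi - lo)[:, None] * grid[None, :]
        else:
            self.knots_ = np.empty((X.shape[1], 0))
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.knots_ is None:
            raise RuntimeError("FeatureExpander must be fitted before transform")
        X = np.asarray(X, float)
        cols: list[np.ndarray] = []
        types: list[str] = []
        if "L" in self.classes:
            cols.append(X)
            types += ["L"] * X.shape[1]
        if "Q" in self.classes:
            cols.append(X**2)
            types += ["Q"] * X.shape[1]
        if "H" in self.classes:
            for j in range(X.shape[1]):
                for k in self.knots_[j]:
                    cols.append(np.maximum(0.0, X[:, j] - k)[:, None])
                    cols.append(np.maximum(0.0, k - X[:, j])[:, None])
                    types += ["H", "H"]
        if "P" in self.classes:
            for j, k in itertools.combinations(range(X.shape[1]), 2):
                cols.append((X[:, j] * X[:, k])[:, None])
                types.append("P")
        if "T" in self.classes:
            for j in range(X.shape[1]):
                for k in self.knots_[j]:
                    cols.append((X[:, j] > k).astype(float)[:, None])
                    types.append("T")
        self.column_types_ = types
        return np.hstack([c if c.ndim == 2 else c for c in cols])

    def penalty_scales(self) -> np.ndarray:
        """Per-column penalty multipliers in the convention of the reference
        implementation: hinge and threshold features are regularized harder
        than linear/quadratic/product ones."""
        if not hasattr(self, "column_types_"):
            raise RuntimeError("transform must run before penalty_scales")
        return np.array(
            [PENALTY_SCALE_BY_TYPE[t] for t in self.column_types_]
        )

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def expand_features(
    X: np.ndarray, classes: str, knots_per_var: int = DEFAULT_KNOTS_PER_VAR
) -> np.ndarray:
    """One-shot design matrix for ``classes`` with knots from X's own range."""
    return FeatureExpander(classes, knots_per_var).fit_transform(X)


# ---------------------------------------------------------------------------
# Maxent-style penalized logistic
# ---------------------------------------------------------------------------


@dataclass
class MaxentFit:
    """L1-penalized presence/background logistic fit on a design matrix."""

    coef: np.ndarray
    intercept: float
    means: np.ndarray
    sds: np.ndarray
    keep: np.ndarray  # non-constant column mask
    reg_mult: float
    k: int  # non-zero coefficient count
    loglik: float  # binomial log-likelihood of the penalized fit
    loglik_refit: float  # log-likelihood of an unpenalized refit on the
    # selected support; the shrinkage-free quantity AICc should compare
    n: int

    def predict(self, design: np.ndarray) -> np.ndarray:
        Z = (np.asarray(design, float)[:, self.keep] - self.means) / self.sds
        eta = Z @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-eta))


def _refit_intercept(
    eta0: np.ndarray, y: np.ndarray, start: float = 0.0, n_iter: int = 50
) -> float:
    """1-D Newton refit of the (unpenalized) intercept with coefficients held
    fixed; converges to the MLE of the binomial log-likelihood in b."""
    b = start
    for _ in range(n_iter):
        p = 1.0 / (1.0 + np.exp(-(eta0 + b)))
        grad = float(np.sum(y - p))
        hess = float(np.sum(p * (1.0 - p)))
        if hess <= 0:
            break
        step = grad / hess
        b += step
        if abs(step) < 1e-10:
            break
    return float(b)


def fit_maxent_like(
    design: np.ndarray,
    labels: np.ndarray,
    reg_mult: float,
    base_penalty: float | None = None,
    penalty_scale: np.ndarray | None = None,
) -> MaxentFit:
    """Fit the penalized presence/background logistic model.

    Columns are standardized, which makes the uniform L1 penalty equivalent
    to a per-column penalty proportional to each column's training standard
    deviation. The effective penalty is ``reg_mult * base_penalty`` on the
    summed log-loss; ``base_penalty`` defaults to sqrt(n) so regularization
    strength is comparable across sample sizes. ``penalty_scale`` applies an
    extra per-column multiplier (used to regularize hinge/threshold columns
    harder). The intercept is never penalized.
    """
    design = np.asarray(design, float)
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise ValueError("need both presence and background labels")
    n = len(y)
    sds = design.std(axis=0)
    keep = sds > 0
    Z = design[:, keep]
    means = Z.mean(axis=0)
    sds = sds[keep]
    if penalty_scale is not None:
        # folding the multiplier into the column scale turns the uniform L1
        # penalty into a per-column one
        sds = sds * np.asarray(penalty_scale, float)[keep]
    Z = (Z - means) / sds

    if base_penalty is None:
        base_penalty = float(np.sqrt(n))
    lam = reg_mult * base_penalty
    clf = LogisticRegression(
        penalty="l1",
        C=1.0 / lam,
        solver="liblinear",
        intercept_scaling=10.0,
        max_iter=1000,
        tol=1e-5,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Z, y)
    coef = clf.coef_.ravel()
    # liblinear penalizes the intercept; recalibrate it unpenalized so the
    # all-zero-coefficient limit predicts exactly the observed prevalence
    intercept = _refit_intercept(Z @ coef, y, start=float(clf.intercept_[0]))
    eta = Z @ coef + intercept
    loglik = _binom_loglik(eta, y)
    support = np.flatnonzero(coef)
    if support.size:
        refit = LogisticRegression(penalty=None, max_iter=300)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            refit.fit(Z[:, support], y)
        eta_r = Z[:, support] @ refit.coef_.ravel() + float(refit.intercept_[0])
        loglik_refit = _binom_loglik(eta_r, y)
    else:
        pbar = y.mean()
        loglik_refit = _binom_loglik(
            np.full(n, np.log(pbar / (1 - pbar))) if 0 < pbar < 1 else
            np.zeros(n), y
        )
    return MaxentFit(
        coef=coef,
        intercept=intercept,
        means=means,
        sds=sds,
        keep=keep,
        reg_mult=reg_mult,
        k=int(np.count_nonzero(coef)),
        loglik=loglik,
        loglik_refit=loglik_refit,
        n=n,
    )


def _binom_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    p = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    return float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def tune_maxent(
    table: pd.DataFrame,
    feature_cols: list[str] | None = None,
    reg_mults: tuple[float, ...] = REG_MULT_GRID,
    feature_classes: tuple[str, ...] = FEATURE_CLASS_GRID,
    knots_per_var: int = DEFAULT_KNOTS_PER_VAR,
) -> tuple[LearnerConfig, pd.DataFrame]:
    """Fit every (reg_mult, feature_classes) combination on the full training
    table and pick the lowest-AICc configuration.

    Ties break toward fewer non-zero features, then lower reg_mult. Returns
    the winning config plus the full tuning table (one row per combination;
    failed fits recorded with status and excluded from selection).
    """
    feature_cols = _feature_cols(table, feature_cols)
    X = table[feature_cols].to_numpy(float)
    y = table["label"].to_numpy(int)
    rows = []
    for fc, rm in itertools.product(feature_classes, reg_mults):
        row: dict = {"feature_classes": fc, "reg_mult": rm}
        try:
            expander = FeatureExpander(fc, knots_per_var)
            design = expander.fit_transform(X)
            fit = fit_maxent_like(
                design, y, rm, penalty_scale=expander.penalty_scales()
            )
            row.update(
                loglik=fit.loglik_refit,
                k=fit.k,
                n=fit.n,
                aicc=aicc(fit.loglik_refit, fit.k, fit.n),
                status="ok",
            )
        except Exception as exc:  # keep tuning alive across single failures
            row.update(loglik=np.nan, k=-1, n=len(y), aicc=np.nan, status=str(exc))
        rows.append(row)
    tuning = pd.DataFrame(rows)
    ok = tuning[tuning["status"] == "ok"]
    if ok.empty:
        raise RuntimeError("all tuning configurations failed")
    best = ok.sort_values(["aicc", "k", "reg_mult"], kind="stable").iloc[0]
    config = LearnerConfig(
        "MAXENT",
        {
            "reg_mult": float(best["reg_mult"]),
            "feature_classes": str(best["feature_classes"]),
            "knots_per_var": knots_per_var,
        },
    )
    return config, tuning


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------


def _check_two_class(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(int)
    pos = labels == 1
    if not pos.any() or pos.all():
        raise ValueError("need both presence (1) and background (0) labels")
    return pos, ~pos


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability that a random presence outscores a random background
    point, ties counted 1/2 (Mann-Whitney / rank form)."""
    scores = np.asarray(scores, float)
    pos, neg = _check_two_class(labels)
    ranks = stats.rankdata(scores)
    n1, n0 = int(pos.sum()), int(neg.sum())
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _threshold_candidates(scores: np.ndarray) -> np.ndarray:
    u = np.unique(scores)
    if len(u) < 2:
        return u.astype(float)
    return (u[:-1] + u[1:]) / 2.0


def _confusion_curve(
    scores: np.ndarray, pos: np.ndarray, neg: np.ndarray, thresholds: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sensitivity and specificity at each threshold (predict 1 iff score >= t)."""
    s_pos = np.sort(scores[pos])
    s_neg = np.sort(scores[neg])
    # counts of scores >= t via searchsorted on sorted arrays
    sens = 1.0 - np.searchsorted(s_pos, thresholds, side="left") / len(s_pos)
    spec = np.searchsorted(s_neg, thresholds, side="left") / len(s_neg)
    return sens, spec


def tss_max(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Maximum of sensitivity + specificity - 1 over candidate thresholds
    (midpoints of sorted unique scores); returns (max TSS, lowest argmax)."""
    scores = np.asarray(scores, float)
    pos, neg = _check_two_class(labels)
    thresholds = _threshold_candidates(scores)
    if len(thresholds) == 0:
        return 0.0, float("nan")
    sens, spec = _confusion_curve(scores, pos, neg, thresholds)
    tss = sens + spec - 1.0
    best = int(np.argmax(tss))  # argmax returns the first (lowest) maximizer
    return float(tss[best]), float(thresholds[best])


def classify_performance(auc_value: float, tss_value: float) -> tuple[str, str]:
    """Map AUC and TSS to the conventional verbal accuracy classes.

    The AUC scale as printed leaves [0.60, 0.70] without a class; such values
    are labelled ``"unclassified (scale gap)"`` rather than silently binned.
    """
    if not 0.0 <= auc_value <= 1.0:
        raise ValueError(f"AUC out of range: {auc_value}")
    if not -1.0 <= tss_value <= 1.0:
        raise ValueError(f"TSS out of range: {tss_value}")
    if auc_value > 0.90:
        auc_class = "excellent"
    elif auc_value > 0.80:
        auc_class = "good"
    elif auc_value > 0.70:
        auc_class = "fair"
    elif auc_value < 0.60:
        auc_class = "poor"
    else:
        auc_class = "unclassified (scale gap)"
    if tss_value > 0.75:
        tss_class = "excellent"
    elif tss_value > 0.40:
        tss_class = "good"
    else:
        tss_class = "poor"
    return auc_class, tss_class


# ---------------------------------------------------------------------------
# Learners
# ---------------------------------------------------------------------------


class _SklearnLearner:
    """Raw-feature learner backed by an sklearn classifier pipeline."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_SklearnLearner":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.estimator.fit(X, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict_proba(X)[:, 1]


class _QuadraticGLM(_SklearnLearner):
    """Logistic regression with linear + quadratic terms."""

    def __init__(self, seed=None):
        super().__init__(
            make_pipeline(
                StandardScaler(),
                LogisticRegression(C=100.0, max_iter=1000),
            )
        )

    def fit(self, X, y):
        return super().fit(self._quad(X), y)

    def predict(self, X):
        return super().predict(self._quad(X))

    @staticmethod
    def _quad(X):
        X = np.asarray(X, float)
        return np.hstack([X, X**2])


class _SplineGAM(_SklearnLearner):
    """Additive smooth of each variable (B-spline basis) with a logistic link."""

    def __init__(self, seed=None, n_knots: int = 5):
        super().__init__(
            make_pipeline(
                SplineTransformer(n_knots=n_knots, degree=3),
                LogisticRegression(C=10.0, max_iter=1000),
            )
        )


class _ShallowGBM(_SklearnLearner):
    def __init__(self, seed=None):
        super().__init__(
            GradientBoostingClassifier(
                n_estimators=100,
                learning_rate=0.05,
                max_depth=3,
                subsample=0.8,
                validation_fraction=0.2,
                n_iter_no_change=10,
                random_state=seed,
            )
        )


class _BalancedRF(_SklearnLearner):
    def __init__(self, seed=None):
        super().__init__(
            RandomForestClassifier(
                n_estimators=200,
                min_samples_leaf=2,
                class_weight="balanced",
                random_state=seed,
                n_jobs=1,
            )
        )


class _MaxentLearner:
    def __init__(self, config: LearnerConfig):
        hp = config.hyperparameters
        self.reg_mult = float(hp.get("reg_mult", 1.0))
        self.classes = str(hp.get("feature_classes", "LQH"))
        self.knots = int(hp.get("knots_per_var", DEFAULT_KNOTS_PER_VAR))
        self.expander: FeatureExpander | None = None
        self.fit_: MaxentFit | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_MaxentLearner":
        self.expander = FeatureExpander(self.classes, self.knots).fit(X)
        design = self.expander.transform(X)
        self.fit_ = fit_maxent_like(
            design, y, self.reg_mult,
            penalty_scale=self.expander.penalty_scales(),
        )
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        assert self.expander is not None and self.fit_ is not None
        return self.fit_.predict(self.expander.transform(X))


def _make_learner(config: LearnerConfig, seed: int | None):
    if config.algorithm == "GLM":
        return _QuadraticGLM(seed)
    if config.algorithm == "GAM":
        return _SplineGAM(seed)
    if config.algorithm == "GBM":
        return _ShallowGBM(seed)
    if config.algorithm == "RF":
        return _BalancedRF(seed)
    if config.algorithm == "MAXENT":
        return _MaxentLearner(config)
    raise ValueError(f"unknown algorithm {config.algorithm!r}")


# ---------------------------------------------------------------------------
# Cross-validated fitting and the ensemble
# ---------------------------------------------------------------------------


@dataclass
class FittedModel:
    config: LearnerConfig
    learner: object
    feature_cols: list[str]
    fold_scores: pd.DataFrame  # columns: fold, auc, tss

    @property
    def algorithm(self) -> str:
        return self.config.algorithm

    @property
    def mean_auc(self) -> float:
        return float(self.fold_scores["auc"].mean())

    @property
    def mean_tss(self) -> float:
        return float(self.fold_scores["tss"].mean())

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.clip(self.learner.predict(np.asarray(X, float)), 0.0, 1.0)

    def predict_table(self, table: pd.DataFrame) -> np.ndarray:
        return self.predict(table[self.feature_cols].to_numpy(float))


def _feature_cols(table: pd.DataFrame, feature_cols) -> list[str]:
    if feature_cols is None:
        return [c for c in table.columns if c not in ("record_id", "label")]
    return list(feature_cols)


def fit_all(
    table: pd.DataFrame,
    folds: pd.Series,
    feature_cols: list[str] | None = None,
    algorithms: tuple[str, ...] = ALGORITHMS,
    maxent_config: LearnerConfig | None = None,
    knots_per_var: int = DEFAULT_KNOTS_PER_VAR,
    seed: int | None = 0,
) -> list[FittedModel]:
    """Four-fold spatially blocked cross-validation of every algorithm.

    Each algorithm is scored (AUC, max TSS) on each held-out fold, then refit
    on the full table. The Maxent learner uses ``maxent_config`` if given and
    is otherwise tuned by AICc on the full table first. Folds lacking either
    class are skipped with a warning; a model with no usable fold is dropped.
    """
    feature_cols = _feature_cols(table, feature_cols)
    X = table[feature_cols].to_numpy(float)
    y = table["label"].to_numpy(int)
    fold_of = folds.reindex(table["record_id"]).to_numpy()
    if np.isnan(np.asarray(fold_of, float)).any():
        raise ValueError("every record needs a fold assignment")
    fold_of = fold_of.astype(int)
    fold_ids = np.unique(fold_of)

    models: list[FittedModel] = []
    for name in algorithms:
        if name == "MAXENT":
            if maxent_config is None:
                config, _ = tune_maxent(
                    table, feature_cols, knots_per_var=knots_per_var
                )
            else:
                config = maxent_config
        else:
            config = LearnerConfig(name)
        scores = []
        for f in fold_ids:
            test = fold_of == f
            train = ~test
            if len(set(y[train])) < 2 or len(set(y[test])) < 2:
                warnings.warn(
                    f"fit_all: fold {f} lacks a class for {name}; skipped",
                    stacklevel=2,
                )
                continue
            learner = _make_learner(config, seed)
            learner.fit(X[train], y[train])
            preds = learner.predict(X[test])
            t, _ = tss_max(preds, y[test])
            scores.append({"fold": int(f), "auc": auc(preds, y[test]), "tss": t})
        if not scores:
            warnings.warn(f"fit_all: no usable folds for {name}; model dropped",
                          stacklevel=2)
            continue
        final = _make_learner(config, seed)
        final.fit(X, y)
        models.append(
            FittedModel(
                config=config,
                learner=final,
                feature_cols=feature_cols,
                fold_scores=pd.DataFrame(scores),
            )
        )
    return models


@dataclass
class EnsembleModel:
    """AUC-weighted average of the member models passing the AUC gate."""

    members: list[FittedModel]
    weights: np.ndarray

    @property
    def feature_cols(self) -> list[str]:
        return self.members[0].feature_cols

    def predict(self, X: np.ndarray) -> np.ndarray:
        preds = np.stack([m.predict(X) for m in self.members])
        return np.average(preds, axis=0, weights=self.weights)

    def predict_table(self, table: pd.DataFrame) -> np.ndarray:
        return self.predict(table[self.feature_cols].to_numpy(float))

    def evaluation_table(self) -> pd.DataFrame:
        rows = []
        for m in self.members:
            for _, r in m.fold_scores.iterrows():
                rows.append(
                    {
                        "algorithm": m.algorithm,
                        "fold": int(r["fold"]),
                        "auc": r["auc"],
                        "tss": r["tss"],
                    }
                )
        return pd.DataFrame(rows)


def build_ensemble(
    models: list[FittedModel], min_auc: float = DEFAULT_MIN_AUC
) -> EnsembleModel:
    """Keep models whose cross-validated mean AUC passes the gate and weight
    them by that mean AUC."""
    passing = [m for m in models if m.mean_auc >= min_auc]
    if not passing:
        scores = {m.algorithm: round(m.mean_auc, 3) for m in models}
        raise ValueError(
            f"no model passed the AUC >= {min_auc} gate (mean AUCs: {scores})"
        )
    weights = np.array([m.mean_auc for m in passing])
    return EnsembleModel(members=passing, weights=weights)


def variable_importance(
    model: EnsembleModel | FittedModel,
    table: pd.DataFrame,
    permutations: int = 5,
    seed: int | None = None,
) -> pd.Series:
    """Permutation importance: 1 - Pearson r between predictions on the
    original table and on the table with one variable shuffled (mean over
    permutations, clipped at zero)."""
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    rng = np.random.default_rng(seed)
    cols = model.feature_cols
    X = table[cols].to_numpy(float)
    base = model.predict(X)
    if np.std(base) == 0:
        warnings.warn("variable_importance: constant predictions; importances 0",
                      stacklevel=2)
        return pd.Series(0.0, index=cols, name="importance")
    out = {}
    for j, name in enumerate(cols):
        vals = []
        for _ in range(permutations):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            perm = model.predict(Xp)
            if np.std(perm) == 0:
                vals.append(1.0)
                continue
            r = float(np.corrcoef(base, perm)[0, 1])
            vals.append(1.0 - r)
        out[name] = max(0.0, float(np.mean(vals)))
    return pd.Series(out, name="importance")


def predict_grid(
    model: EnsembleModel | FittedModel, stack: PredictorStack
) -> Grid:
    """Evaluate a fitted model over every masked cell of a predictor stack."""
    mask = np.asarray(stack.mask.values) == 1
    rows, cols = np.nonzero(mask)
    X = np.column_stack(
        [np.asarray(stack.layers[c].values, float)[rows, cols]
         for c in model.feature_cols]
    )
    preds = model.predict(X)
    out = np.full(stack.mask.shape, np.nan)
    out[rows, cols] = preds
    return stack.mask.like(out, nodata=np.nan)
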