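"""Elastic-net derivation of the healthy-lifestyle metabolite signature.

The protocol: predictors are the preprocessed metabolites, the response is
the HL score (continuous, linear family) or its low/high dichotomization
(logistic family). The penalty mixing parameter alpha can be trained by
leave-group-out cross-validation over the grid 0, 0.1, ..., 1; the penalty
strength lambda is tuned by K-fold cross-validation and fixed at the
"minimum error + 1 SE" value (the parsimony-favouring ``lambda.1se`` rule).
The whole-data fit at that lambda is replicated R times with fresh fold
splits; reported coefficients are averages over replicates (zeros included)
and the signature is the set of metabolites selected in all R replicates.

The penalized objective is

    L(b0, b) + lambda * [ (1 - alpha)/2 * ||b||_2^2 + alpha * ||b||_1 ]

with L the mean squared error / 2 (linear) or the mean negative
log-likelihood of the logit model (logistic). Solvers are scikit-learn's
coordinate descent / SAGA with the penalty reparameterized accordingly;
predictors are standardized to unit variance internally and coefficients
are reported on the input scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, LogisticRegression, Ridge, enet_path
from sklearn.metrics import log_loss
from sklearn.model_selection import KFold

from ._containers import DimensionError, ValidationError

ALPHA_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))

#: floor on alpha in the lambda_max formula (pure ridge has no finite
#: all-zero lambda; the conventional glmnet workaround)
_ALPHA_FLOOR = 1e-3


@dataclass(frozen=True)
class ElasticNetSpec:
    """Family, mixing parameter and penalty strength of one fit."""

    family: str = "linear"  # 'linear' or 'logistic'
    alpha: float = 0.1
    lam: float = 0.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.family not in ("linear", "logistic"):
            raise ValidationError(f"unknown family {self.family!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha must be in [0,1], got {self.alpha}")
        if self.lam < 0:
            raise ValidationError(f"lambda must be >= 0, got {self.lam}")


@dataclass
class CVResult:
    """K-fold cross-validation curve over a lambda path."""

    lambda_path: np.ndarray
    cv_error_mean: np.ndarray
    cv_error_se: np.ndarray
    lambda_min: float
    lambda_1se: float


@dataclass
class SignatureModel:
    """Averaged elastic-net signature over R replicates."""

    metabolites: list[str]
    coef_avg: np.ndarray
    intercept_avg: float
    selection_count: np.ndarray
    family: str
    alpha: float
    R: int
    K: int
    seed: int
    lambdas: list[float] = field(default_factory=list)
    selection_threshold: int | None = None

    @property
    def signature_metabolites(self) -> list[str]:
        thr = self.R if self.selection_threshold is None else self.selection_threshold
        return [m for m, c in zip(self.metabolites, self.selection_count) if c >= thr]

    @property
    def signature_size(self) -> int:
        return len(self.signature_metabolites)

    def to_csv(self, path, header_path=None) -> None:
        pd.DataFrame({
            "metabolite": self.metabolites,
            "coef_avg": self.coef_avg,
            "selection_count": self.selection_count,
        }).to_csv(path, index=False)
        if header_path is not None:
            with open(header_path, "w") as fh:
                json.dump({
                    "family": self.family, "alpha": self.alpha,
                    "intercept_avg": self.intercept_avg, "R": self.R,
                    "K": self.K, "seed": self.seed, "lambdas": self.lambdas,
                }, fh, indent=2)


def _as_xy(X, y):
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float).ravel()
    if Xa.ndim != 2 or len(ya) != Xa.shape[0]:
        raise DimensionError(
            f"X has shape {Xa.shape} but y has length {len(ya)}"
        )
    if not (np.isfinite(Xa).all() and np.isfinite(ya).all()):
        raise ValidationError("X and y must be finite with no missing values")
    return Xa, ya, names


def _standardize(X):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd, glmnet-style
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


def elastic_net_objective(beta0, beta, X, y, spec: ElasticNetSpec) -> float:
    """Penalized objective evaluated at (beta0, beta) on the given scale."""
    Xa, ya, _ = _as_xy(X, y)
    beta = np.asarray(beta, dtype=float).ravel()
    if len(beta) != Xa.shape[1]:
        raise DimensionError(
            f"beta has {len(beta)} entries for {Xa.shape[1]} predictors"
        )
    eta = beta0 + Xa @ beta
    if spec.family == "linear":
        loss = 0.5 * float(np.mean((ya - eta) ** 2))
    else:
        # mean negative log-likelihood of the logit model
        loss = float(np.mean(np.logaddexp(0.0, eta) - ya * eta))
    penalty = spec.lam * (
        (1.0 - spec.alpha) / 2.0 * float(beta @ beta)
        + spec.alpha * float(np.abs(beta).sum())
    )
    return loss + penalty


def fit_elastic_net(X, y, spec: ElasticNetSpec) -> tuple[float, np.ndarray]:
    """Fit one elastic net; returns (intercept, coefficients) on the input
    scale (predictors are standardized internally when ``spec.standardize``).
    """
    Xa, ya, _ = _as_xy(X, y)
    n = len(ya)
    if spec.standardize:
        Xs, mean, sd = _standardize(Xa)
    else:
        Xs, mean, sd = Xa, np.zeros(Xa.shape[1]), np.ones(Xa.shape[1])

    if spec.family == "linear":
        if spec.lam == 0.0:
            A = np.column_stack([np.ones(n), Xs])
            sol, *_ = np.linalg.lstsq(A, ya, rcond=None)
            b0, bs = sol[0], sol[1:]
        elif spec.alpha == 0.0:
            model = Ridge(alpha=n * spec.lam, fit_intercept=True)
            model.fit(Xs, ya)
            b0, bs = float(model.intercept_), model.coef_
        else:
            model = ElasticNet(alpha=spec.lam, l1_ratio=spec.alpha,
                               fit_intercept=True, max_iter=50000, tol=1e-8)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(Xs, ya)
            b0, bs = float(model.intercept_), model.coef_
    else:
        if len(np.unique(ya)) < 2:
            raise ValidationError("logistic fit needs both classes present")
        if spec.lam == 0.0:
            model = LogisticRegression(C=np.inf, max_iter=5000)
        else:
            model = LogisticRegression(
                solver="saga", l1_ratio=spec.alpha,
                C=1.0 / (n * spec.lam), max_iter=5000, tol=1e-7,
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(Xs, ya)
        b0, bs = float(model.intercept_[0]), model.coef_[0]
        # SAGA's step size shrinks with the penalty and can leave the
        # (unpenalized) intercept short of its score equation; polish it
        # with 1-D Newton at fixed coefficients.
        eta_x = Xs @ bs
        for _ in range(100):
            p = 1.0 / (1.0 + np.exp(-(b0 + eta_x)))
            g = float(np.mean(ya - p))
            h = float(np.mean(p * (1.0 - p)))
            if h < 1e-12 or abs(g) < 1e-12:
                break
            b0 += g / h

    coef = bs / sd
    intercept = b0 - float((bs * mean / sd).sum())
    return intercept, coef


def lambda_max(Xs: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest lambda at which all coefficients are zero, for standardized
    predictors (alpha floored at 0.001 so pure ridge gets a finite path)."""
    n = len(y)
    r = y - y.mean()
    g = np.abs(Xs.T @ r) / n
    return float(g.max() / max(alpha, _ALPHA_FLOOR))


def _fold_error_path_linear(Xtr, ytr, Xva, yva, alpha, path):
    Xs, mean, sd = _standardize(Xtr)
    yc = ytr - ytr.mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, coefs, _ = enet_path(Xs, yc, l1_ratio=max(alpha, _ALPHA_FLOOR),
                                alphas=path, max_iter=5000)
    Xva_s = (Xva - mean) / sd
    preds = Xva_s @ coefs + ytr.mean()  # (n_va, n_lambda)
    return np.mean((yva[:, None] - preds) ** 2, axis=0)


def _fold_error_path_logistic(Xtr, ytr, Xva, yva, alpha, path):
    Xs, mean, sd = _standardize(Xtr)
    Xva_s = (Xva - mean) / sd
    n = len(ytr)
    errs = np.empty(len(path))
    model = LogisticRegression(
        solver="saga", l1_ratio=alpha,
        warm_start=True, max_iter=2000, tol=1e-6,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for k, lam in enumerate(path):
            model.C = 1.0 / (n * lam)
            model.fit(Xs, ytr)
            p = model.predict_proba(Xva_s)[:, 1]
            errs[k] = 2.0 * log_loss(yva, p, labels=[0, 1])  # mean deviance
    return errs


def cv_lambda_path(
    X, y, family: str = "linear", alpha: float = 0.1,
    K: int = 10, seed: int = 0, n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
) -> CVResult:
    """K-fold cross-validation over a 100-point geometric lambda path.

    The path runs from lambda_max (all-zero fit) down to
    ``lambda_min_ratio * lambda_max``. The CV loss is MSE (linear) or mean
    binomial deviance (logistic); the per-lambda SE is the SD over folds
    divided by sqrt(K). ``lambda_1se`` is the largest lambda whose mean CV
    error is within one SE of the minimum.
    """
    Xa, ya, _ = _as_xy(X, y)
    if K < 2:
        raise ValidationError("K must be >= 2")
    if np.ptp(ya) == 0:
        raise ValidationError("y is constant; cross-validation is undefined")
    Xs_all, _, _ = _standardize(Xa)
    lmax = lambda_max(Xs_all, ya, alpha)
    path = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)

    folds = KFold(n_splits=K, shuffle=True, random_state=seed % (2**32))
    fold_err = np.empty((K, n_lambda))
    fn = _fold_error_path_linear if family == "linear" else _fold_error_path_logistic
    for i, (tr, va) in enumerate(folds.split(Xa)):
        fold_err[i] = fn(Xa[tr], ya[tr], Xa[va], ya[va], alpha, path)

    mean = fold_err.mean(axis=0)
    se = fold_err.std(axis=0, ddof=1) / np.sqrt(K)
    i_min = int(np.argmin(mean))
    cutoff = mean[i_min] + se[i_min]
    i_1se = int(np.flatnonzero(mean <= cutoff)[0])  # path is decreasing in lambda
    return CVResult(
        lambda_path=path, cv_error_mean=mean, cv_error_se=se,
        lambda_min=float(path[i_min]), lambda_1se=float(path[i_1se]),
    )


def select_alpha(
    X, y, family: str = "linear", grid=ALPHA_GRID,
    n_groups: int = 10, seed: int = 0, K: int = 10,
) -> float:
    """Train the mixing parameter alpha by leave-group-out cross-validation.

    Participants are split into ``n_groups`` random subsets; for each alpha
    on the grid, the model is fit on all-but-one subset (with lambda fixed
    at that training set's lambda_1se) and evaluated on the held-out subset
    (MSE for linear, classification accuracy for logistic). Returns the
    best alpha; ties break toward the smaller alpha.
    """
    Xa, ya, _ = _as_xy(X, y)
    grid = list(grid)
    if not grid:
        raise ValidationError("alpha grid is empty")
    n = len(ya)
    if n_groups > n:
        raise ValidationError(f"n_groups={n_groups} exceeds n={n}")
    rng = np.random.default_rng(seed)
    groups = np.array_split(rng.permutation(n), n_groups)

    perf = []
    for a in grid:
        scores = []
        for g, hold in enumerate(groups):
            tr = np.setdiff1d(np.arange(n), hold)
            cv = cv_lambda_path(Xa[tr], ya[tr], family=family, alpha=a,
                                K=K, seed=seed * 1000 + g)
            spec = ElasticNetSpec(family=family, alpha=a, lam=cv.lambda_1se)
            b0, b = fit_elastic_net(Xa[tr], ya[tr], spec)
            eta = b0 + Xa[hold] @ b
            if family == "linear":
                scores.append(float(np.mean((ya[hold] - eta) ** 2)))
            else:
                acc = float(np.mean((eta > 0) == (ya[hold] > 0.5)))
                scores.append(-acc)  # lower is better, uniformly
        perf.append(float(np.mean(scores)))
    best = int(np.argmin(perf))  # argmin returns the first (smallest alpha) tie
    return float(grid[best])


def derive_signature(
    X, y, family: str = "linear", alpha: float = 0.1,
    R: int = 10, K: int = 10, seed: int = 0,
    selection_threshold: int | None = None,
) -> SignatureModel:
    """Replicated cross-validated elastic net with averaged coefficients.

    For each of R replicates: a fresh random K-fold split yields
    lambda_1se; the model is then refit on *all* participants at that
    lambda and its coefficients recorded. ``coef_avg`` is the mean over
    replicates (zeros included); ``selection_count[j]`` counts replicates
    with a nonzero coefficient; the signature is the set selected in all R
    replicates (threshold configurable).
    """
    Xa, ya, names = _as_xy(X, y)
    names = names or [f"x{j}" for j in range(Xa.shape[1])]
    coefs = np.zeros((R, Xa.shape[1]))
    intercepts = np.zeros(R)
    lambdas = []
    for r in range(R):
        rep_seed = int(np.random.default_rng([seed, r]).integers(0, 2**31 - 1))
        try:
            cv = cv_lambda_path(Xa, ya, family=family, alpha=alpha, K=K, seed=rep_seed)
            spec = ElasticNetSpec(family=family, alpha=alpha, lam=cv.lambda_1se)
            intercepts[r], coefs[r] = fit_elastic_net(Xa, ya, spec)
            lambdas.append(cv.lambda_1se)
        except Exception as exc:  # noqa: BLE001 - annotate replicate index
            raise RuntimeError(f"replicate {r + 1}/{R} failed: {exc}") from exc
    return SignatureModel(
        metabolites=names,
        coef_avg=coefs.mean(axis=0),
        intercept_avg=float(intercepts.mean()),
        selection_count=(coefs != 0).sum(axis=0),
        family=family, alpha=alpha, R=R, K=K, seed=seed,
        lambdas=lambdas, selection_threshold=selection_threshold,
    )


def score_signature(model: SignatureModel, X) -> np.ndarray:
    """Linear predictor of the signature for new data (log-odds scale for
    the logistic family). Columns must align with the model's metabolites."""
    if isinstance(X, pd.DataFrame):
        cols = list(X.columns)
        if cols != model.metabolites:
            for got, want in zip(cols, model.metabolites):
                if got != want:
                    raise DimensionError(
                        f"column mismatch: expected {want!r}, got {got!r}"
                    )
            raise DimensionError(
                f"X has {len(cols)} columns, model expects {len(model.metabolites)}"
            )
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        if Xa.shape[1] != len(model.metabolites):
            raise DimensionError(
                f"X has {Xa.shape[1]} columns, model expects {len(model.metabolites)}"
            )
    return model.intercept_avg + Xa @ model.coef_avg
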