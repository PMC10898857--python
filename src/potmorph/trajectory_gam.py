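"""Hierarchical smooth-trajectory models for shape-space coordinates.

Each principal component is modeled separately as a penalized-spline function
of percent time (0 = start of shaping, 100 = final form):

* model G  — one global smoother for all observations;
* model S  — one smoother per community, sharing a single smoothing
  parameter, plus community intercepts;
* model SI — model S plus potter-level deviation smoothers and potter
  intercepts, all shrunk by a second shared smoothing parameter (the
  factor-smoother construction: the ridge component penalizes the potter
  terms all the way to zero, so SI collapses to S in the strong-penalty
  limit).

Smoothers use cubic B-splines (default 10 basis functions on [0, 100]) with a
second-order difference penalty and a sum-to-zero constraint against the
intercepts.  Smoothing parameters minimize a restricted-likelihood (REML)
criterion on a deterministic coarse grid with two local refinement passes, so
identical data and spec give bitwise-identical fits.  Model comparison uses
conditional AIC (effective degrees of freedom + 1 for the scale) and
out-of-sample Gaussian deviance on the held-out even trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, null_space

from .errors import DesignError, DomainError, ValidationError

__all__ = [
    "SmoothModelSpec",
    "SmoothFit",
    "OOSReport",
    "split_trials",
    "fit_smooth_model",
    "aic_compare",
    "oos_deviance",
    "oos_report",
    "compare_models",
]

MODELS = ("G", "S", "SI")
TRAIN_TRIALS = (1, 3, 5)
TEST_TRIALS = (2, 4)
T_LO, T_HI = 0.0, 100.0


@dataclass
class SmoothModelSpec:
    model: str
    basis_dim: int = 10
    penalty_order: int = 2

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise DomainError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.basis_dim < self.penalty_order + 2:
            raise DomainError("basis_dim too small for the penalty order")


def split_trials(trials):
    """Odd trials (1, 3, 5) train; even trials (2, 4) test.

    Accepts any sequence of objects with a ``trial_number`` attribute
    (TrialRecords or Trajectories).  Potters with incomplete trial sets are
    tolerated with a warning.
    """
    numbers = {t.trial_number for t in trials}
    bad = numbers - set(range(1, 6))
    if bad:
        raise ValidationError(f"trial numbers outside 1..5: {sorted(bad)}")
    by_potter: dict = {}
    for t in trials:
        by_potter.setdefault(t.potter_id, set()).add(t.trial_number)
    incomplete = [p for p, nums in sorted(by_potter.items())
                  if nums != set(range(1, 6))]
    if incomplete:
        warnings.warn(f"potters with incomplete trial sets: {incomplete}",
                      UserWarning, stacklevel=2)
    train = [t for t in trials if t.trial_number in TRAIN_TRIALS]
    test = [t for t in trials if t.trial_number in TEST_TRIALS]
    return train, test


# ---------------------------------------------------------------------------
# design construction


def _bspline_basis(t: np.ndarray, k: int) -> np.ndarray:
    """Cubic B-spline design matrix with k columns on [0, 100] (clamped,
    uniform interior knots)."""
    degree = 3
    n_interior = k - degree - 1
    interior = np.linspace(T_LO, T_HI, n_interior + 2)[1:-1]
    knots = np.concatenate([[T_LO] * (degree + 1), interior, [T_HI] * (degree + 1)])
    tc = np.clip(np.asarray(t, float), T_LO, T_HI)
    return BSpline.design_matrix(tc, knots, degree).toarray()


def _greville(k: int) -> np.ndarray:
    """Greville abscissae of the clamped cubic basis with k columns."""
    degree = 3
    n_interior = k - degree - 1
    interior = np.linspace(T_LO, T_HI, n_interior + 2)[1:-1]
    knots = np.concatenate([[T_LO] * (degree + 1), interior, [T_HI] * (degree + 1)])
    return np.array([knots[i + 1:i + 1 + degree].mean() for i in range(k)])


def _divided_difference_penalty(k: int, order: int) -> np.ndarray:
    """Difference-penalty matrix using divided differences at the Greville
    abscissae, so the penalty null space consists of coefficient vectors
    whose spline is exactly a polynomial of degree < order in t (a straight
    line for order 2), including near the clamped ends."""
    xi = _greville(k)
    D = np.eye(k)
    for _ in range(order):
        m = D.shape[0]
        step = xi[-m + 1:] - xi[:m - 1] if m > 1 else np.ones(0)
        D = np.diff(D, axis=0) / step[:, None]
        xi = (xi[1:] + xi[:-1]) / 2.0  # midpoints for the next level
    return D


@dataclass
class _Block:
    name: str
    start: int
    stop: int
    penalty: np.ndarray | None   # penalty on this block's coefficients
    lam_group: int | None        # which smoothing parameter scales it
    null_dim: int


class _DesignBuilder:
    """Builds model design matrices and penalty blocks; reusable on new rows
    for prediction."""

    def __init__(self, spec: SmoothModelSpec, train: pd.DataFrame):
        self.spec = spec
        k = spec.basis_dim
        self.communities = sorted(train["community"].unique())
        self.potters = sorted(train["potter"].unique())
        if spec.model in ("S", "SI") and len(self.communities) < 2:
            raise DesignError("models S/SI need >= 2 communities")

        B = _bspline_basis(train["percent_time"].to_numpy(), k)
        c = B.sum(axis=0, keepdims=True)  # sum-to-zero constraint over training rows
        self.Z = null_space(c)            # (k, k-1)
        D = _divided_difference_penalty(k, spec.penalty_order)
        S_full = D.T @ D
        self.S_smooth = self.Z.T @ S_full @ self.Z
        self.S_potter = self.S_smooth + np.eye(k - 1)  # diff + ridge: no null space
        ev = np.linalg.eigvalsh(self.S_smooth)
        self.smooth_null_dim = int(np.sum(ev < ev[-1] * 1e-10))

        self.blocks: list[_Block] = []
        self.n_columns = 0
        self._layout()

    def _add(self, name, width, penalty, lam_group, null_dim):
        b = _Block(name, self.n_columns, self.n_columns + width, penalty,
                   lam_group, null_dim)
        self.blocks.append(b)
        self.n_columns += width
        return b

    def _layout(self):
        km1 = self.spec.basis_dim - 1
        m = self.spec.model
        if m == "G":
            self._add("intercept", 1, None, None, 1)
            self._add("smooth:global", km1, self.S_smooth, 0, self.smooth_null_dim)
        else:
            self._add("intercept:community", len(self.communities), None, None,
                      len(self.communities))
            for c in self.communities:
                self._add(f"smooth:{c}", km1, self.S_smooth, 0,
                          self.smooth_null_dim)
            if m == "SI":
                self._add("intercept:potter", len(self.potters),
                          np.eye(len(self.potters)), 1, 0)
                for p in self.potters:
                    self._add(f"smooth:potter:{p}", km1, self.S_potter, 1, 0)

    @property
    def n_lambda(self) -> int:
        groups = {b.lam_group for b in self.blocks if b.lam_group is not None}
        return len(groups)

    @property
    def null_dim_total(self) -> int:
        return sum(b.null_dim for b in self.blocks)

    def build(self, df: pd.DataFrame) -> np.ndarray:
        m = self.spec.model
        n = len(df)
        X = np.zeros((n, self.n_columns))
        B = _bspline_basis(df["percent_time"].to_numpy(), self.spec.basis_dim)
        BZ = B @ self.Z
        comm = df["community"].to_numpy()
        if m == "S" or m == "SI":
            unseen = set(comm) - set(self.communities)
            if unseen:
                raise DesignError(f"community level(s) not in the training design: "
                                  f"{sorted(unseen)}")
        for b in self.blocks:
            if b.name == "intercept":
                X[:, b.start] = 1.0
            elif b.name == "intercept:community":
                for i, c in enumerate(self.communities):
                    X[comm == c, b.start + i] = 1.0
            elif b.name == "intercept:potter":
                pot = df["potter"].to_numpy()
                for i, p in enumerate(self.potters):
                    X[pot == p, b.start + i] = 1.0
            elif b.name == "smooth:global":
                X[:, b.start:b.stop] = BZ
            elif b.name.startswith("smooth:potter:"):
                p = b.name.split("smooth:potter:")[1]
                mrows = df["potter"].to_numpy() == p
                X[mrows, b.start:b.stop] = BZ[mrows]
            elif b.name.startswith("smooth:"):
                c = b.name.split("smooth:")[1]
                mrows = comm == c
                X[mrows, b.start:b.stop] = BZ[mrows]
        return X

    def penalty_total(self, lambdas: np.ndarray) -> np.ndarray:
        S = np.zeros((self.n_columns, self.n_columns))
        for b in self.blocks:
            if b.penalty is not None:
                S[b.start:b.stop, b.start:b.stop] += lambdas[b.lam_group] * b.penalty
        return S

    def log_det_penalty(self, lambdas: np.ndarray) -> float:
        """log pseudo-determinant of the lambda-weighted penalty."""
        total = 0.0
        for b in self.blocks:
            if b.penalty is None:
                continue
            ev = np.linalg.eigvalsh(b.penalty)
            pos = ev[ev > max(ev[-1], 0) * 1e-10]
            total += len(pos) * np.log(lambdas[b.lam_group]) + np.sum(np.log(pos))
        return total


@dataclass
class SmoothFit:
    """A fitted penalized-spline model for one response dimension."""

    spec: SmoothModelSpec
    response: str
    beta: np.ndarray
    lambdas: np.ndarray
    edf: float
    loglik: float
    aic: float
    scale: float
    rss: float
    n_obs: int
    builder: _DesignBuilder = field(repr=False)
    train_fingerprint: tuple = field(default=(), repr=False)

    @property
    def model(self) -> str:
        return self.spec.model

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return self.builder.build(df) @ self.beta


@dataclass
class OOSReport:
    model: str
    per_pc: dict
    total: float


def _reml_score(builder, XtX, Xty, yty, n, lambdas):
    S = builder.penalty_total(lambdas)
    H = XtX + S
    try:
        cf = cho_factor(H)
    except np.linalg.LinAlgError:
        return np.inf, None
    beta = cho_solve(cf, Xty)
    rss = float(yty - 2 * beta @ Xty + beta @ XtX @ beta)
    rss = max(rss, 1e-300)
    pen = float(beta @ S @ beta)
    M = builder.null_dim_total
    sigma2 = max((rss + pen) / (n - M), 1e-300)
    logdet_H = 2.0 * np.sum(np.log(np.diag(cf[0])))
    score = ((n - M) * (np.log(sigma2) + 1.0) + logdet_H
             - builder.log_det_penalty(lambdas))
    return score, (beta, rss, pen, cf)


def _optimize_lambdas(builder, XtX, Xty, yty, n):
    """Deterministic grid + refinement REML minimization over log10 lambda."""
    n_lam = builder.n_lambda
    if n_lam == 0:
        return np.zeros(0)

    def score_of(loglams):
        s, _ = _reml_score(builder, XtX, Xty, yty, n, 10.0 ** np.asarray(loglams))
        return s

    grids = [np.arange(-3.0, 7.5, 1.5) for _ in range(n_lam)]
    if n_lam == 1:
        best = min(grids[0], key=lambda g: score_of([g]))
        step = 1.5
        for _ in range(3):
            step /= 3.0
            cand = [best - step, best, best + step]
            best = min(cand, key=lambda g: score_of([g]))
        return 10.0 ** np.array([best])
    # two smoothing parameters: coarse 2-D grid then local refinement
    best = None
    best_score = np.inf
    for g1 in grids[0]:
        for g2 in grids[1]:
            s = score_of([g1, g2])
            if s < best_score:
                best_score, best = s, (g1, g2)
    step = 1.5
    for _ in range(3):
        step /= 3.0
        for d1 in (-step, 0.0, step):
            for d2 in (-step, 0.0, step):
                cand = (best[0] + d1, best[1] + d2)
                s = score_of(cand)
                if s < best_score:
                    best_score, best = s, cand
    return 10.0 ** np.array(best)


def fit_smooth_model(data: pd.DataFrame, spec: SmoothModelSpec,
                     response: str = "value",
                     lambdas=None) -> SmoothFit:
    """Fit one penalized-spline model to (percent_time, value, community,
    potter) rows.  Deterministic given data and spec.

    ``lambdas`` pins the smoothing parameter(s) instead of optimizing the
    REML criterion (used for penalty-limit diagnostics)."""
    required = {"percent_time", response, "community", "potter"}
    missing = required - set(data.columns)
    if missing:
        raise ValidationError(f"data missing columns: {sorted(missing)}")
    t = data["percent_time"].to_numpy(float)
    if np.any(t < T_LO - 1e-9) or np.any(t > T_HI + 1e-9):
        raise ValidationError("percent_time must lie in [0, 100]")
    n = len(data)
    if n < spec.basis_dim + 2:
        raise ValidationError(
            f"need >= {spec.basis_dim + 2} observations, got {n}")

    builder = _DesignBuilder(spec, data)
    X = builder.build(data)
    y = data[response].to_numpy(float)
    XtX, Xty, yty = X.T @ X, X.T @ y, float(y @ y)

    if lambdas is None:
        lambdas = _optimize_lambdas(builder, XtX, Xty, yty, n)
    else:
        lambdas = np.asarray(lambdas, float)
        if len(lambdas) != builder.n_lambda:
            raise ValidationError(
                f"model {spec.model} has {builder.n_lambda} smoothing "
                f"parameter(s), got {len(lambdas)}")
    score, payload = _reml_score(builder, XtX, Xty, yty, n, lambdas
                                 if len(lambdas) else np.zeros(0))
    if payload is None:
        raise DesignError("design matrix is rank deficient even under penalty")
    beta, rss, pen, cf = payload
    edf = float(np.trace(cho_solve(cf, XtX)))
    sigma2_ml = rss / n
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2_ml) + 1.0)
    aic = -2.0 * loglik + 2.0 * (edf + 1.0)
    scale = rss / max(n - edf, 1.0)
    fingerprint = (n, round(float(y.sum()), 9), round(float(t.sum()), 9))
    return SmoothFit(spec=spec, response=response, beta=beta, lambdas=lambdas,
                     edf=edf, loglik=loglik, aic=aic, scale=scale, rss=rss,
                     n_obs=n, builder=builder, train_fingerprint=fingerprint)


def aic_compare(fits: dict) -> pd.DataFrame:
    """AIC ranking table from ``fits[model][response] -> SmoothFit``.

    All models must be fitted to identical training data (checked via a
    fingerprint of the training rows).
    """
    responses = None
    for model, per_pc in fits.items():
        if responses is None:
            responses = sorted(per_pc)
        elif sorted(per_pc) != responses:
            raise ValidationError("models were fitted to different responses")
    for r in responses:
        fps = {fits[m][r].train_fingerprint for m in fits}
        if len(fps) != 1:
            raise ValidationError(
                f"models for {r} were fitted on different training sets")
    rows = []
    for model, per_pc in fits.items():
        for r, fit in per_pc.items():
            rows.append({"model": model, "response": r, "aic": fit.aic,
                         "edf": fit.edf, "loglik": fit.loglik})
    df = pd.DataFrame(rows)
    df["delta_aic"] = df.groupby("response")["aic"].transform(lambda a: a - a.min())
    total = df.groupby("model", as_index=False)["aic"].sum()
    total["response"] = "total"
    total["delta_aic"] = total["aic"] - total["aic"].min()
    return pd.concat([df, total], ignore_index=True)


def oos_deviance(fit: SmoothFit, test: pd.DataFrame) -> float:
    """Gaussian deviance of held-out rows: 2 * (saturated - model
    log-likelihood), which for a Gaussian response is the sum of squared
    prediction errors (unit dispersion, the usual GAM deviance convention).
    Dividing by each model's own training scale would make deviances
    incomparable across models of different flexibility, so the scale is
    not applied here."""
    if len(test) == 0:
        raise ValidationError("empty test set")
    mu = fit.predict(test)
    y = test[fit.response].to_numpy(float)
    return float(np.sum((y - mu) ** 2))


def oos_report(per_pc_fits: dict, test: pd.DataFrame) -> OOSReport:
    """Out-of-sample deviance per response and total for one model."""
    per = {r: oos_deviance(f, test) for r, f in per_pc_fits.items()}
    models = {f.model for f in per_pc_fits.values()}
    return OOSReport(model=models.pop() if len(models) == 1 else "mixed",
                     per_pc=per, total=float(sum(per.values())))


def compare_models(train: pd.DataFrame, test: pd.DataFrame | None = None,
                   responses=("pc1", "pc2", "pc3"), models=MODELS,
                   basis_dim: int = 10) -> pd.DataFrame:
    """Fit every requested model to every response; return the AIC table,
    with out-of-sample deviance appended when a test set is given."""
    fits = {m: {r: fit_smooth_model(train, SmoothModelSpec(m, basis_dim=basis_dim),
                                    response=r)
                for r in responses}
            for m in models}
    table = aic_compare(fits)
    if test is not None and len(test):
        oos = {m: oos_report(fits[m], test) for m in models}
        def lookup(row):
            if row["response"] == "total":
                return oos[row["model"]].total
            return oos[row["model"]].per_pc[row["response"]]
        table["oos_deviance"] = table.apply(lookup, axis=1)
    return table
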