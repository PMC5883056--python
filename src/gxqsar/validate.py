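"""The statistical validation battery for linear QSAR models.

Covers goodness of fit (r², F, standard errors), internal predictivity
(leave-one-out q² via the hat matrix), external predictivity (pred_r²
referenced to the training-set activity mean), the rm² metrics (both axis
orders, average and delta), Y-randomization (best random r²/q², Z-scores and
an empirical permutation alpha), and the range-based applicability-domain
outlier count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .dataset import ActivityTable, DataSplit
from .errors import InfluentialPointError, UndefinedStatisticError
from .qsar import LinearQSARModel, applicability_flag, fit_mlr, predict_table, stepwise_forward


def r_squared(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Coefficient of determination 1 - SSres/SStot."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if len(y) < 3:
        raise UndefinedStatisticError("r2 needs at least 3 points")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise UndefinedStatisticError("r2 undefined: zero variance in y")
    sse = float(((y - yhat) ** 2).sum())
    return 1.0 - sse / sst


def _design(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(len(X)), X])


def q2_loo(X, y) -> tuple[float, float]:
    """Leave-one-out q² and PRESS via the hat matrix.

    PRESS = sum_i (e_i / (1 - h_ii))²; q² = 1 - PRESS / SStot. Algebraically
    identical to n explicit refits (checked against that oracle in the test
    suite at 1e-10).
    """
    A = _design(X)
    yv = np.asarray(y, dtype=float)
    n, p = A.shape
    if n <= p + 1:
        raise UndefinedStatisticError(f"q2_loo needs n > k + 2 (n={n}, k={p - 1})")
    sst = float(((yv - yv.mean()) ** 2).sum())
    if sst == 0:
        raise UndefinedStatisticError("q2 undefined: zero variance in y")
    Q, _ = np.linalg.qr(A)
    h = (Q**2).sum(axis=1)
    near_one = np.where(h >= 1.0 - 1e-10)[0]
    if near_one.size:
        raise InfluentialPointError(
            f"leverage 1 at row(s) {near_one.tolist()}: LOO residual undefined"
        )
    beta, *_ = np.linalg.lstsq(A, yv, rcond=None)
    e = yv - A @ beta
    press = float(((e / (1.0 - h)) ** 2).sum())
    return 1.0 - press / sst, press


def pred_r2(
    y_test: Sequence[float], yhat_test: Sequence[float], y_train_mean: float
) -> float:
    """External predictivity: 1 - SS(test residuals) / SS(test about the
    training-set activity mean)."""
    y_test = np.asarray(y_test, dtype=float)
    yhat_test = np.asarray(yhat_test, dtype=float)
    if y_test.size == 0:
        raise UndefinedStatisticError("empty test set")
    denom = float(((y_test - y_train_mean) ** 2).sum())
    if denom == 0:
        raise UndefinedStatisticError("pred_r2 undefined: test activities all equal train mean")
    return 1.0 - float(((y_test - yhat_test) ** 2).sum()) / denom


def _rm2_one_direction(x: np.ndarray, y: np.ndarray) -> float:
    """rm² with x as the predictor axis: r² from the with-intercept fit and
    r0² from the through-origin (slope-only) fit of y on x."""
    sst = float(((y - y.mean()) ** 2).sum())
    r = np.corrcoef(x, y)[0, 1]
    r2 = float(r**2)
    k = float((x @ y) / (x @ x))
    r02 = 1.0 - float(((y - k * x) ** 2).sum()) / sst
    return r2 * (1.0 - np.sqrt(abs(r2 - r02)))


def rm2_battery(y_obs: Sequence[float], y_pred: Sequence[float]) -> dict[str, float]:
    """Roy's rm² metrics over (observed, predicted) pairs, both axis orders.

    Returns ``rm2``, ``rm2_reverse``, ``rm2_avg`` and ``rm2_delta``.
    """
    obs = np.asarray(y_obs, dtype=float)
    pred = np.asarray(y_pred, dtype=float)
    if obs.size < 3:
        raise UndefinedStatisticError("rm2 needs at least 3 pairs")
    if obs.std() == 0 or pred.std() == 0:
        raise UndefinedStatisticError("rm2 undefined: zero variance input")
    rm2 = _rm2_one_direction(pred, obs)
    rm2_rev = _rm2_one_direction(obs, pred)
    return {
        "rm2": rm2,
        "rm2_reverse": rm2_rev,
        "rm2_avg": 0.5 * (rm2 + rm2_rev),
        "rm2_delta": abs(rm2 - rm2_rev),
    }


def f_statistic(y: Sequence[float], yhat: Sequence[float], k: int) -> tuple[float, int]:
    """Regression F = (SSreg/k) / (SSres/(n-k-1)) and residual df.

    A perfect fit (SSres = 0) reports +inf.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    n = len(y)
    dof = n - k - 1
    if dof <= 0 or k < 1:
        raise UndefinedStatisticError(f"invalid dof for F (n={n}, k={k})")
    sst = float(((y - y.mean()) ** 2).sum())
    sse = float(((y - yhat) ** 2).sum())
    ssr = sst - sse
    if sse <= 0:
        return float("inf"), dof
    return (ssr / k) / (sse / dof), dof


def standard_errors(
    y_train,
    yhat_train,
    k: int,
    press: Optional[float] = None,
    y_test=None,
    yhat_test=None,
) -> dict[str, float]:
    """RMSE-style standard errors for the fitted, LOO and external residual
    sets (denominators n-k-1, n and n_test respectively)."""
    y_train = np.asarray(y_train, dtype=float)
    yhat_train = np.asarray(yhat_train, dtype=float)
    n = len(y_train)
    out = {"r2_se": float(np.sqrt(((y_train - yhat_train) ** 2).sum() / (n - k - 1)))}
    if press is not None:
        out["q2_se"] = float(np.sqrt(press / n))
    if y_test is not None and yhat_test is not None and len(y_test):
        y_test = np.asarray(y_test, dtype=float)
        yhat_test = np.asarray(yhat_test, dtype=float)
        out["pred_r2_se"] = float(np.sqrt(((y_test - yhat_test) ** 2).sum() / len(y_test)))
    return out


ModelBuilder = Callable[[pd.DataFrame, np.ndarray], tuple[float, float]]


def mlr_builder(X: pd.DataFrame, y: np.ndarray) -> tuple[float, float]:
    """Default Y-randomization builder: plain MLR on all columns; returns
    (r², hat-matrix LOO q²)."""
    model = fit_mlr(X, y)
    A = _design(np.asarray(X, dtype=float))
    beta = np.array([model.intercept] + [model.coefficients[n] for n in model.descriptor_names])
    r2 = r_squared(y, A @ beta)
    q2, _ = q2_loo(X, y)
    return r2, q2


def stepwise_builder(
    f_to_enter: float = 4.0,
    max_terms: Optional[int] = None,
    corr_cutoff: float = 0.7,
) -> ModelBuilder:
    """Y-randomization builder that reruns the full stepwise pipeline."""

    def build(X: pd.DataFrame, y: np.ndarray) -> tuple[float, float]:
        table = ActivityTable.from_dataframe(
            X.assign(log_ic50=y).reset_index(drop=True).rename_axis("compound_id").reset_index()
        )
        model = stepwise_forward(table, f_to_enter, max_terms, corr_cutoff)
        if not model.descriptor_names:
            return 0.0, 0.0
        preds = predict_table(model, table)
        r2 = r_squared(y, preds["pred_log_ic50"].to_numpy())
        q2, _ = q2_loo(table.X(model.descriptor_names), y)
        return r2, q2

    return build


def y_randomization(
    X: pd.DataFrame,
    y: Sequence[float],
    model_builder: ModelBuilder = mlr_builder,
    n_trials: int = 100,
    seed: int = 0,
) -> dict[str, float]:
    """Activity-scrambling test: rebuild the model on permuted activities.

    The full model-building pipeline (``model_builder``) reruns on each
    permuted response. Reports the best random r²/q², Z-scores for both, and
    the add-one-smoothed empirical p-value
    alpha = (#{random r² >= actual r²} + 1) / (n_trials + 1).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    yv = np.asarray(y, dtype=float)
    if yv.std() == 0:
        raise UndefinedStatisticError("y-randomization undefined: constant y")
    X = pd.DataFrame(X).reset_index(drop=True)
    actual_r2, actual_q2 = model_builder(X, yv)
    rng = np.random.default_rng(seed)
    rand_r2 = np.empty(n_trials)
    rand_q2 = np.empty(n_trials)
    for t in range(n_trials):
        perm = rng.permutation(len(yv))
        rand_r2[t], rand_q2[t] = model_builder(X, yv[perm])

    def zscore(actual, sample):
        sd = sample.std(ddof=1) if len(sample) > 1 else 0.0
        return float((actual - sample.mean()) / sd) if sd > 0 else float("inf")

    alpha = (int((rand_r2 >= actual_r2).sum()) + 1) / (n_trials + 1)
    return {
        "actual_r2": float(actual_r2),
        "actual_q2": float(actual_q2),
        "best_ran_r2": float(rand_r2.max()),
        "best_ran_q2": float(rand_q2.max()),
        "zscore_r2": zscore(actual_r2, rand_r2),
        "zscore_q2": zscore(actual_q2, rand_q2),
        "alpha": float(alpha),
        "n_trials": n_trials,
    }


@dataclass
class ValidationReport:
    """The assembled validation battery for one model."""

    r2: float
    q2_loo: float
    pred_r2: Optional[float]
    rm2_avg: float
    rm2_delta: float
    df: int
    f_stat: float
    r2_se: float
    q2_se: float
    pred_r2_se: Optional[float]
    best_ran_r2: float
    best_ran_q2: float
    zscore_r2: float
    zscore_q2: float
    alpha: float
    n_random_trials: int
    ad_outlier_count: Union[int, str]
    residuals: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    #: human-readable row labels for the report table
    _LABELS = [
        ("r2", "r2"),
        ("(LOOcv) q2", "q2_loo"),
        ("pred_r2", "pred_r2"),
        ("Avg rm2", "rm2_avg"),
        ("Delta rm2", "rm2_delta"),
        ("Df", "df"),
        ("F test", "f_stat"),
        ("best_ran_r2", "best_ran_r2"),
        ("best_ran_q2", "best_ran_q2"),
        ("alpha_test", "alpha"),
        ("r2 se", "r2_se"),
        ("q2 se", "q2_se"),
        ("pred_r2 se", "pred_r2_se"),
        ("ZScore (q2)", "zscore_q2"),
        ("ZScore (r2)", "zscore_r2"),
        ("Applicability domain", "ad_outlier_count"),
    ]

    def to_dict(self) -> dict:
        d = {attr: getattr(self, attr) for _, attr in self._LABELS}
        d["n_random_trials"] = self.n_random_trials
        d["warnings"] = list(self.warnings)
        return d

    def to_table(self) -> str:
        lines = []
        for label, attr in self._LABELS:
            v = getattr(self, attr)
            if isinstance(v, float):
                v = f"{v:.4f}"
            lines.append(f"{label:<22} {v}")
        return "\n".join(lines)


def validate_model(
    table: ActivityTable,
    split: DataSplit,
    model: Optional[LinearQSARModel] = None,
    builder_kwargs: Optional[dict] = None,
    n_random_trials: int = 100,
    seed: int = 0,
) -> tuple[LinearQSARModel, ValidationReport]:
    """Fit (unless given) and fully validate a model on a train/test split.

    Y-randomization reruns the same stepwise pipeline used for the real fit
    (or plain MLR over the model's descriptors when ``model`` was supplied).
    """
    builder_kwargs = builder_kwargs or {}
    train = table.subset(split.train_ids)
    if model is None:
        model = stepwise_forward(train, **builder_kwargs)
        randomization_builder: ModelBuilder = stepwise_builder(**builder_kwargs)
        rand_X = train.X()
    else:
        randomization_builder = mlr_builder
        rand_X = train.X(model.descriptor_names)
    if not model.descriptor_names:
        raise UndefinedStatisticError("cannot validate an intercept-only model")

    y_train = train.y().to_numpy(dtype=float)
    yhat_train = predict_table(model, train)["pred_log_ic50"].to_numpy()
    k = len(model.descriptor_names)

    r2 = r_squared(y_train, yhat_train)
    q2, press = q2_loo(train.X(model.descriptor_names), y_train)
    rm2 = rm2_battery(y_train, yhat_train)
    f, dof = f_statistic(y_train, yhat_train, k)

    warnings = []
    if q2 > r2:
        warnings.append("q2 exceeds r2 (numerical warning)")

    pr2 = pr2_se = None
    y_test = yhat_test = None
    ad_count: Union[int, str] = "unavailable"
    if split.test_ids:
        test = table.subset(split.test_ids)
        y_test = test.y().to_numpy(dtype=float)
        yhat_test = predict_table(model, test)["pred_log_ic50"].to_numpy()
        pr2 = pred_r2(y_test, yhat_test, float(y_train.mean()))
        flags = [
            applicability_flag(model, test.df.loc[cid, model.descriptor_names])
            for cid in test.ids
        ]
        if all(isinstance(fl, int) for fl in flags):
            ad_count = int(sum(flags))

    ses = standard_errors(y_train, yhat_train, k, press, y_test, yhat_test)
    rand = y_randomization(rand_X, y_train, randomization_builder, n_random_trials, seed)

    report = ValidationReport(
        r2=r2,
        q2_loo=q2,
        pred_r2=pr2,
        rm2_avg=rm2["rm2_avg"],
        rm2_delta=rm2["rm2_delta"],
        df=dof,
        f_stat=f,
        r2_se=ses["r2_se"],
        q2_se=ses["q2_se"],
        pred_r2_se=ses.get("pred_r2_se"),
        best_ran_r2=rand["best_ran_r2"],
        best_ran_q2=rand["best_ran_q2"],
        zscore_r2=rand["zscore_r2"],
        zscore_q2=rand["zscore_q2"],
        alpha=rand["alpha"],
        n_random_trials=n_random_trials,
        ad_outlier_count=ad_count,
        residuals={
            "train": dict(zip(split.train_ids, (y_train - yhat_train).tolist())),
            "test": dict(zip(split.test_ids, (y_test - yhat_test).tolist()))
            if y_test is not None
            else {},
        },
        warnings=warnings,
    )
    return model, report
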