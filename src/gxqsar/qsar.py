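"""Linear QSAR models: ordinary least squares, stepwise-forward selection,
the three frozen published cell-line models, prediction, and the
range-based applicability domain flag.

The response throughout is log10 IC50 in µM; a predicted IC50 in µM is
``10**log`` exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .dataset import ActivityTable
from .errors import (
    DegreesOfFreedomError,
    MissingDescriptorError,
    SingularMatrixError,
)

PUBLISHED_MODELS = ("model1", "model2", "model3")

RESPONSE = "Log10 IC50 (uM)"

AD_UNAVAILABLE = "unavailable"


@dataclass
class LinearQSARModel:
    """An affine scorer: predicted log10 IC50 = intercept + sum(coef * x).

    ``train_ranges`` (per-descriptor min/max over the training set) power the
    applicability-domain flag; published models ship without them, so their
    flag is reported as ``unavailable`` rather than a silent 0.
    """

    name: str
    descriptor_names: list[str]
    coefficients: dict[str, float]
    intercept: float
    response: str = RESPONSE
    provenance: str = "built"
    training_ids: list = field(default_factory=list)
    train_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    fit_stats: dict = field(default_factory=dict)
    version: int = 1

    def __post_init__(self):
        if set(self.coefficients) != set(self.descriptor_names):
            raise ValueError("coefficients and descriptor_names disagree")
        vals = [*self.coefficients.values(), self.intercept]
        if not all(np.isfinite(vals)):
            raise ValueError("non-finite model coefficients")

    def to_json_dict(self) -> dict:
        return {
            "name": self.name,
            "response": self.response,
            "descriptors": [
                {
                    "name": n,
                    "coefficient": self.coefficients[n],
                    **(
                        {
                            "train_min": self.train_ranges[n][0],
                            "train_max": self.train_ranges[n][1],
                        }
                        if n in self.train_ranges
                        else {}
                    ),
                }
                for n in self.descriptor_names
            ],
            "intercept": self.intercept,
            "provenance": self.provenance,
            "version": self.version,
            "training_ids": list(self.training_ids),
            "fit_stats": self.fit_stats,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)

    @classmethod
    def from_json_dict(cls, d: dict) -> "LinearQSARModel":
        names = [e["name"] for e in d["descriptors"]]
        coeffs = {e["name"]: float(e["coefficient"]) for e in d["descriptors"]}
        ranges = {
            e["name"]: (float(e["train_min"]), float(e["train_max"]))
            for e in d["descriptors"]
            if "train_min" in e and "train_max" in e
        }
        return cls(
            name=d.get("name", "model"),
            descriptor_names=names,
            coefficients=coeffs,
            intercept=float(d["intercept"]),
            response=d.get("response", RESPONSE),
            provenance=d.get("provenance", "built"),
            training_ids=d.get("training_ids", []),
            train_ranges=ranges,
            fit_stats=d.get("fit_stats", {}),
            version=d.get("version", 1),
        )

    @classmethod
    def load(cls, path) -> "LinearQSARModel":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


@dataclass(frozen=True)
class Prediction:
    log_ic50: float
    ic50_uM: float


def published_model(which: str) -> LinearQSARModel:
    """Load one of the frozen published models (``model1`` A549, ``model2``
    HepG2, ``model3`` U251) from packaged JSON."""
    if which not in PUBLISHED_MODELS:
        raise KeyError(f"unknown model {which!r}; valid ids: {list(PUBLISHED_MODELS)}")
    text = resources.files("gxqsar.data.models").joinpath(f"{which}.json").read_text()
    return LinearQSARModel.from_json_dict(json.loads(text))


def _as_matrix(
    X: Union[pd.DataFrame, np.ndarray], names: Optional[Sequence[str]]
) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    return X, list(names)


def fit_mlr(
    X: Union[pd.DataFrame, np.ndarray],
    y: Sequence[float],
    names: Optional[Sequence[str]] = None,
    model_name: str = "mlr",
    training_ids: Optional[Sequence] = None,
) -> LinearQSARModel:
    """Ordinary least squares with intercept.

    Raises a degrees-of-freedom error when n <= k + 1 and a singularity error
    naming the collinear columns when the design matrix is rank deficient.
    """
    Xm, names = _as_matrix(X, names)
    yv = np.asarray(y, dtype=float)
    n, k = Xm.shape
    if n <= k + 1:
        raise DegreesOfFreedomError(f"need n > k + 1 (got n={n}, k={k})")
    A = np.column_stack([np.ones(n), Xm])
    # QR with column pivoting both solves and localizes collinearity
    _, R, piv = sla.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < k + 1:
        bad = sorted(piv[rank:])
        bad_names = ["intercept" if j == 0 else names[j - 1] for j in bad]
        raise SingularMatrixError(bad_names)
    beta, *_ = np.linalg.lstsq(A, yv, rcond=None)
    yhat = A @ beta
    resid = yv - yhat
    sse = float(resid @ resid)
    sst = float(((yv - yv.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    dof = n - k - 1
    se = float(np.sqrt(sse / dof))
    ssr = sst - sse
    f = float((ssr / k) / (sse / dof)) if k > 0 and sse > 0 else float("inf")
    ranges = {nm: (float(Xm[:, j].min()), float(Xm[:, j].max())) for j, nm in enumerate(names)}
    return LinearQSARModel(
        name=model_name,
        descriptor_names=list(names),
        coefficients={nm: float(b) for nm, b in zip(names, beta[1:])},
        intercept=float(beta[0]),
        provenance="built",
        training_ids=list(training_ids) if training_ids is not None else [],
        train_ranges=ranges,
        fit_stats={"n": n, "k": k, "r2": r2, "se": se, "F": f, "df": dof},
    )


def _sse(Xm: np.ndarray, yv: np.ndarray) -> float:
    A = np.column_stack([np.ones(len(yv)), Xm]) if Xm.size else np.ones((len(yv), 1))
    beta, *_ = np.linalg.lstsq(A, yv, rcond=None)
    r = yv - A @ beta
    return float(r @ r)


def stepwise_forward(
    table: ActivityTable,
    f_to_enter: float = 4.0,
    max_terms: Optional[int] = None,
    corr_cutoff: float = 0.7,
    model_name: str = "stepwise",
) -> LinearQSARModel:
    """Stepwise-forward descriptor selection over an activity table.

    Starting from the empty model, each round adds the descriptor with the
    largest partial F, provided that F >= ``f_to_enter`` and its |Pearson r|
    with every already-selected descriptor is <= ``corr_cutoff``. Stops at
    ``max_terms`` (default n // 6) or when no candidate qualifies; ties go to
    the lowest column index. If nothing qualifies in round one an
    intercept-only model is returned (with a warning in fit_stats).
    """
    if f_to_enter <= 0:
        raise ValueError("f_to_enter must be > 0")
    X = table.X().astype(float)
    yv = table.y().to_numpy(dtype=float)
    n = len(yv)
    if max_terms is None:
        max_terms = n // 6
    names = list(table.descriptor_names)
    corr = X.corr().abs()

    selected: list[str] = []
    sse_current = _sse(np.empty((n, 0)), yv)
    while len(selected) < max_terms:
        best = None  # (F, column index, name, sse)
        p = len(selected)
        dof = n - p - 2  # residual dof after adding one more term
        if dof <= 0:
            break
        for j, cand in enumerate(names):
            if cand in selected:
                continue
            if selected and corr.loc[cand, selected].max() > corr_cutoff:
                continue
            Xm = X[selected + [cand]].to_numpy()
            try:
                sse_new = _sse(Xm, yv)
            except np.linalg.LinAlgError:  # pragma: no cover
                continue
            if sse_new <= 0:
                f_partial = float("inf")
            else:
                f_partial = (sse_current - sse_new) / (sse_new / dof)
            if f_partial >= f_to_enter and (best is None or f_partial > best[0]):
                best = (f_partial, j, cand, sse_new)
        if best is None:
            break
        _, _, name, sse_current = best
        selected.append(name)

    if not selected:
        sst = float(((yv - yv.mean()) ** 2).sum())
        return LinearQSARModel(
            name=model_name,
            descriptor_names=[],
            coefficients={},
            intercept=float(yv.mean()),
            provenance="built",
            training_ids=table.ids,
            train_ranges={},
            fit_stats={
                "n": n,
                "k": 0,
                "r2": 0.0 if sst > 0 else float("nan"),
                "se": float(np.sqrt(sst / (n - 1))) if n > 1 else float("nan"),
                "F": float("nan"),
                "df": n - 1,
                "warning": "no descriptor met the entry criterion; intercept-only model",
            },
        )
    model = fit_mlr(X[selected], yv, model_name=model_name, training_ids=table.ids)
    return model


def _vector_values(model: LinearQSARModel, vector) -> dict[str, float]:
    if isinstance(vector, pd.Series):
        vector = vector.to_dict()
    elif hasattr(vector, "values") and not isinstance(vector, Mapping):
        vector = vector.values  # DescriptorVector
    missing = [n for n in model.descriptor_names if n not in vector or vector[n] is None]
    if missing:
        raise MissingDescriptorError(missing)
    return {n: float(vector[n]) for n in model.descriptor_names}


def predict(model: LinearQSARModel, vector) -> Prediction:
    """Evaluate the affine scorer on a named descriptor vector.

    Missing descriptors raise (no silent zero-fill). Returns both the
    predicted log10 IC50 (µM) and IC50 in µM (= 10**log).
    """
    vals = _vector_values(model, vector)
    log = model.intercept + sum(model.coefficients[n] * vals[n] for n in model.descriptor_names)
    return Prediction(log_ic50=float(log), ic50_uM=float(10.0**log))


def predict_table(model: LinearQSARModel, table: ActivityTable) -> pd.DataFrame:
    """Predictions for every row of a table (columns: pred_log_ic50, pred_ic50_uM)."""
    rows = {}
    for cid in table.ids:
        p = predict(model, table.df.loc[cid, table.descriptor_names])
        rows[cid] = (p.log_ic50, p.ic50_uM)
    return pd.DataFrame.from_dict(rows, orient="index", columns=["pred_log_ic50", "pred_ic50_uM"])


def applicability_flag(model: LinearQSARModel, vector) -> Union[int, str]:
    """Range-based applicability domain: 0 when every descriptor lies within
    the training [min, max] (inclusive), 1 otherwise; ``"unavailable"`` for
    models shipped without training ranges (the published equations)."""
    if not model.train_ranges or set(model.train_ranges) != set(model.descriptor_names):
        return AD_UNAVAILABLE
    vals = _vector_values(model, vector)
    for n in model.descriptor_names:
        lo, hi = model.train_ranges[n]
        if not (lo <= vals[n] <= hi):
            return 1
    return 0
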