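"""Two-marker logistic risk model for cirrhosis-only versus HCC.

The model regresses the diagnosis (event = cirrhosis-only, coded 1) on the
two receptor H-scores:

    Risk = intercept + beta1 * (TGFBR1 H-score) + beta2 * (TGFBR2 H-score)
    Prob(Cirrhosis) = exp(Risk) / (1 + exp(Risk))

Fitting is by Newton-Raphson / iteratively reweighted least squares with
the coefficient covariance taken as the inverse observed information.  The
published coefficient set (-2.4106, 0.00619, 0.00543) ships as the frozen
:data:`PUBLISHED_MODEL` so new samples can be scored without refitting.
Also here: adjusted odds ratios per H-score unit, the rank-based AUROC, and
quintile calibration of predicted probability against observed incidence.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .diagnostics import CIRRHOSIS

_MAX_ITER = 50
_TOL = 1e-8


@dataclass
class LogisticModel:
    """Intercept and per-unit slopes of the two-marker logistic model.

    ``cov`` is the 3x3 coefficient covariance (None for models quoted
    without one, such as the published set).
    """

    intercept: float
    beta1: float
    beta2: float
    cov: np.ndarray | None = None
    converged: bool = True
    n_iter: int = 0
    note: str = ""

    @property
    def coef(self) -> np.ndarray:
        return np.array([self.intercept, self.beta1, self.beta2])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "intercept": self.intercept,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "cov": None if self.cov is None else self.cov.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "note": self.note,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LogisticModel":
        payload = json.loads(Path(path).read_text())
        cov = payload.pop("cov")
        return cls(cov=None if cov is None else np.asarray(cov), **payload)


#: The published final model, frozen: scores samples without refitting.
PUBLISHED_MODEL = LogisticModel(
    intercept=-2.4106, beta1=0.00619, beta2=0.00543, cov=None, note="published final model"
)


def fit_logistic(r1: Sequence[float], r2: Sequence[float], event: Sequence[int]) -> LogisticModel:
    """Maximum-likelihood fit by Newton/IRLS.

    ``event`` is 1 for cirrhosis-only, 0 for HCC; both H-scores must be
    present for every record.  Convergence when the largest coefficient
    update falls below 1e-8, capped at 50 iterations; quasi-separated data
    are returned flagged ``converged=False`` with a diagnostic note.
    Raises on constant outcomes or a rank-deficient design.
    """
    r1 = np.asarray(r1, float)
    r2 = np.asarray(r2, float)
    y = np.asarray(event, float)
    if not (len(r1) == len(r2) == len(y)):
        raise ValueError("r1, r2 and event must align")
    if np.isnan(r1).any() or np.isnan(r2).any():
        raise ValueError("both H-scores must be present for every record")
    if len(np.unique(y)) < 2:
        raise ValueError("event indicator is constant; need both classes")
    X = np.column_stack([np.ones_like(r1), r1, r2])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates)")

    beta = np.zeros(3)
    converged, note, iteration = False, "", 0
    info = np.eye(3)
    for iteration in range(1, _MAX_ITER + 1):
        p = expit(X @ beta)
        w = p * (1.0 - p)
        info = X.T @ (X * w[:, None])
        score = X.T @ (y - p)
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            note = "information matrix singular (possible separation)"
            break
        beta += delta
        if np.max(np.abs(delta)) < _TOL:
            converged = True
            break
    if not converged and not note:
        note = "no convergence in 50 iterations (possible separation)"
    p = expit(X @ beta)
    if converged and (p.min() < 1e-10 or p.max() > 1 - 1e-10):
        converged, note = False, "fitted probabilities at machine 0/1 (separation)"
    cov = np.linalg.pinv(info)
    return LogisticModel(
        intercept=float(beta[0]),
        beta1=float(beta[1]),
        beta2=float(beta[2]),
        cov=cov,
        converged=converged,
        n_iter=iteration,
        note=note,
    )


def predict_prob(model: LogisticModel, r1, r2) -> np.ndarray | float:
    """Prob(cirrhosis-only) from the linear predictor; vectorised."""
    risk = model.intercept + model.beta1 * np.asarray(r1, float) + model.beta2 * np.asarray(r2, float)
    prob = expit(risk)
    return float(prob) if np.ndim(prob) == 0 else prob


def adjusted_odds_ratios(model: LogisticModel, z: float = 1.96) -> pd.DataFrame:
    """Adjusted odds ratio per one H-score unit for each marker.

    aOR = exp(beta); the Wald interval exp(beta +/- z*SE) needs the fitted
    covariance and is NaN for models quoted without one.
    """
    if not model.converged:
        raise ValueError(f"model did not converge: {model.note}")
    rows = []
    for idx, (name, beta) in enumerate((("TGFBR1", model.beta1), ("TGFBR2", model.beta2)), start=1):
        if model.cov is not None:
            se = math.sqrt(float(model.cov[idx, idx]))
            lo, hi = math.exp(beta - z * se), math.exp(beta + z * se)
        else:
            lo = hi = float("nan")
        rows.append({"marker": name, "aOR": math.exp(beta), "ci_lower": lo, "ci_upper": hi})
    return pd.DataFrame(rows)


def auroc(scores: Sequence[float], labels: Sequence[str], event: str = CIRRHOSIS) -> float:
    """Area under the ROC curve, rank-based (Mann-Whitney) with midranks.

    Orientation: 1.0 means every event (cirrhosis-only) sample scores above
    every non-event (HCC) sample; all-tied scores give 0.5.  Invariant to
    strictly monotone transforms, so the linear risk and the probability
    give identical values.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, dtype=object)
    is_event = labels == event
    n1, n0 = int(is_event.sum()), int((~is_event).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)  # midranks for ties
    rank_sum = float(ranks[is_event].sum())
    return (rank_sum - n1 * (n1 + 1) / 2.0) / (n1 * n0)


@dataclass(frozen=True)
class CalibrationResult:
    """Quintile calibration: per-bin mean prediction vs observed incidence,
    plus the least-squares line through the five points.

    ``slope``/``intercept`` are NaN for degenerate (zero x-variance) bins;
    perfect calibration has slope 1, intercept 0.
    """

    table: pd.DataFrame  # columns: bin, n, mean_predicted, observed_rate
    slope: float
    intercept: float
    r_squared: float


def calibrate_quintiles(probs: Sequence[float], labels: Sequence[str], event: str = CIRRHOSIS) -> CalibrationResult:
    """Split samples into 5 near-equal bins of ascending predicted
    probability (stable sort; ties stay with the lower bin) and regress
    observed incidence on mean prediction across bins."""
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, dtype=object)
    if len(probs) < 5:
        raise ValueError("need at least 5 samples for quintile calibration")
    order = np.argsort(probs, kind="stable")
    bins = np.array_split(order, 5)
    rows = []
    for i, idx in enumerate(bins, start=1):
        rows.append(
            {
                "bin": i,
                "n": len(idx),
                "mean_predicted": float(probs[idx].mean()),
                "observed_rate": float((labels[idx] == event).mean()),
            }
        )
    table = pd.DataFrame(rows)
    x = table["mean_predicted"].to_numpy()
    y = table["observed_rate"].to_numpy()
    if np.ptp(x) == 0:
        return CalibrationResult(table, float("nan"), float("nan"), float("nan"))
    slope, intercept = np.polyfit(x, y, 1)
    residual = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = float("nan") if ss_tot == 0 else 1.0 - float((residual**2).sum()) / ss_tot
    return CalibrationResult(table, float(slope), float(intercept), r2)
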