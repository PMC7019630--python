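"""From-scratch PLS-DA: autoscaling, NIPALS, prediction, classification, VIP.

Partial least squares discriminant analysis treats a binary class label
(case = 1, control = 0) as a continuous response and regresses it on the
predictor panel through a small number of latent variables (LVs) —
directions of maximal covariance between the autoscaled predictors and the
centred response.  With a single dummy-coded response the NIPALS weight
update has a closed form per component (w ∝ Xᵀy), making the algorithm a
short deflation loop.

The decision rule assigns class 1 when the predicted response exceeds a
threshold (default 0.5, the midpoint of the label coding); a score exactly
at the threshold goes to class 0, deterministically.

Variable importance in projection (VIP) summarises each predictor's
contribution across components, weighted by the response variance each
component explains; predictors with VIP > 1 form the discriminant set.
The scores are normalised so that the mean squared VIP over predictors is
exactly 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_EPS = 1e-12


class ZeroVarianceError(ValueError):
    """A predictor column has zero variance and cannot be autoscaled."""


class DegenerateResponseError(ValueError):
    """The (deflated) response is orthogonal to the predictors."""


@dataclass
class Scaler:
    """Per-column autoscaling parameters learned from a training matrix."""

    means: np.ndarray
    sds: np.ndarray

    @property
    def n_features(self) -> int:
        return len(self.means)


def autoscale_fit(X: np.ndarray, column_names: list[str] | None = None) -> Scaler:
    """Learn per-column mean and sample SD (n−1 denominator).

    Raises :class:`ZeroVarianceError` naming the offending column if any
    column is constant.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("autoscale_fit needs a 2-D matrix with >= 2 rows")
    if np.isnan(X).any():
        raise ValueError("autoscale_fit does not accept missing values")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = np.nonzero(sds <= _EPS)[0]
    if zero.size:
        j = int(zero[0])
        name = column_names[j] if column_names else f"column {j}"
        raise ZeroVarianceError(f"zero-variance predictor: {name}")
    return Scaler(means=means, sds=sds)


def apply_scaler(scaler: Scaler, X: np.ndarray) -> np.ndarray:
    """Autoscale ``X`` with (training) statistics stored in ``scaler``."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != scaler.n_features:
        raise ValueError(
            f"dimension mismatch: scaler has {scaler.n_features} columns, "
            f"matrix has {X.shape[1]}"
        )
    return (X - scaler.means) / scaler.sds


@dataclass
class PLSModel:
    """Fitted PLS-DA state.

    Attributes
    ----------
    n_components : number of latent variables A.
    weights : W, p × A, unit-norm weight vector per component.
    scores : T, n × A, training scores (columns mutually orthogonal).
    x_loadings : P, p × A.
    y_loadings : q, length A, response loading per component.
    scaler : training autoscaling parameters.
    y_mean : training response mean (case fraction).
    threshold : decision cut on the predicted response.
    """

    n_components: int
    weights: np.ndarray
    scores: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scaler: Scaler
    y_mean: float
    threshold: float = 0.5
    analyte_names: list[str] | None = None

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "weights": self.weights.tolist(),
            "scores": self.scores.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "scaler_means": self.scaler.means.tolist(),
            "scaler_sds": self.scaler.sds.tolist(),
            "y_mean": self.y_mean,
            "threshold": self.threshold,
            "analyte_names": self.analyte_names,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PLSModel":
        return cls(
            n_components=int(payload["n_components"]),
            weights=np.asarray(payload["weights"], dtype=float),
            scores=np.asarray(payload["scores"], dtype=float),
            x_loadings=np.asarray(payload["x_loadings"], dtype=float),
            y_loadings=np.asarray(payload["y_loadings"], dtype=float),
            scaler=Scaler(
                means=np.asarray(payload["scaler_means"], dtype=float),
                sds=np.asarray(payload["scaler_sds"], dtype=float),
            ),
            y_mean=float(payload["y_mean"]),
            threshold=float(payload["threshold"]),
            analyte_names=payload.get("analyte_names"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "PLSModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _validate_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be coded 0 (control) / 1 (case)")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y.astype(float)


def pls_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    *,
    threshold: float = 0.5,
    analyte_names: list[str] | None = None,
) -> PLSModel:
    """Fit a PLS-DA model by NIPALS on the autoscaled predictor matrix.

    Parameters are learned from ``X`` alone (autoscaling) and from the
    centred dummy response; with ``n_components`` equal to the rank of the
    scaled matrix the fit coincides with ordinary least squares.
    """
    X = np.asarray(X, dtype=float)
    yf = _validate_labels(y)
    n, p = X.shape
    max_a = min(n - 1, p)
    if not 1 <= n_components <= max_a:
        raise ValueError(
            f"n_components must be in [1, {max_a}] for an {n} x {p} matrix, "
            f"got {n_components}"
        )
    scaler = autoscale_fit(X, analyte_names)
    Xd = apply_scaler(scaler, X)
    y_mean = float(yf.mean())
    yd = yf - y_mean

    W = np.empty((p, n_components))
    T = np.empty((n, n_components))
    P = np.empty((p, n_components))
    q = np.empty(n_components)
    for a in range(n_components):
        w = Xd.T @ yd
        w_norm = np.linalg.norm(w)
        if w_norm < _EPS:
            raise DegenerateResponseError(
                f"response orthogonal to predictors at component {a + 1}"
            )
        w /= w_norm
        t = Xd @ w
        tt = float(t @ t)
        if tt < _EPS:
            raise DegenerateResponseError(
                f"degenerate score vector at component {a + 1}"
            )
        q_a = float(t @ yd) / tt
        p_a = (Xd.T @ t) / tt
        Xd -= np.outer(t, p_a)
        yd -= q_a * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, p_a, q_a

    return PLSModel(
        n_components=n_components,
        weights=W,
        scores=T,
        x_loadings=P,
        y_loadings=q,
        scaler=scaler,
        y_mean=y_mean,
        threshold=threshold,
        analyte_names=list(analyte_names) if analyte_names else None,
    )


def pls_transform(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Project new samples onto the model's latent variables (n × A scores)."""
    Xd = apply_scaler(model.scaler, np.asarray(X_new, dtype=float))
    A = model.n_components
    T = np.empty((Xd.shape[0], A))
    for a in range(A):
        t = Xd @ model.weights[:, a]
        Xd -= np.outer(t, model.x_loadings[:, a])
        T[:, a] = t
    return T


def pls_predict_components(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted responses after 1..A components (n × A matrix).

    Column a−1 holds the prediction of the truncated a-component model;
    useful for scanning model complexity without refitting.
    """
    T = pls_transform(model, X_new)
    return model.y_mean + np.cumsum(T * model.y_loadings, axis=1)


def pls_predict(
    model: PLSModel, X_new: np.ndarray, n_components: int | None = None
) -> np.ndarray:
    """Continuous decision scores for new samples (training scaler applied)."""
    preds = pls_predict_components(model, X_new)
    a = model.n_components if n_components is None else n_components
    if not 1 <= a <= model.n_components:
        raise ValueError(f"n_components must be in [1, {model.n_components}]")
    return preds[:, a - 1]


def classify(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Assign class 1 iff score > threshold; a tie goes to class 0."""
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    return (scores > threshold).astype(int)


@dataclass
class VIPResult:
    """VIP scores per analyte and the VIP > 1 discriminant set."""

    vip: np.ndarray
    analyte_names: list[str]
    discriminant_set: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.discriminant_set = [
            name for name, v in zip(self.analyte_names, self.vip) if v > 1.0
        ]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"analyte": self.analyte_names, "vip": self.vip}
        ).sort_values("vip", ascending=False, ignore_index=True)


def vip(model: PLSModel, analyte_names: list[str] | None = None) -> VIPResult:
    """Variable importance in projection for a fitted model.

    VIP_j = sqrt( p · Σ_a SSY_a w_ja² / Σ_a SSY_a ) with
    SSY_a = q_a² tᵀ_a t_a, the response sum of squares captured by
    component a.  Σ_j VIP_j² = p holds exactly because each w_a has unit
    norm.
    """
    names = analyte_names or model.analyte_names
    if names is None:
        names = [f"x{j}" for j in range(model.weights.shape[0])]
    p = model.weights.shape[0]
    ssy = model.y_loadings**2 * np.einsum("ia,ia->a", model.scores, model.scores)
    contributions = (model.weights**2) @ ssy
    scores = np.sqrt(p * contributions / ssy.sum())
    return VIPResult(vip=scores, analyte_names=list(names))
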