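"""Two-block PLS regression (NIPALS PLS2) on vectorized features.

The model decomposes centered predictors and responses around shared latent
scores::

    X = sum_r t_r p_r^T + E        Y = sum_r t_r c_r^T + F

Components are extracted sequentially by the NIPALS iteration, each score
maximizing covariance between an X-direction and the current Y residual;
X (and by default Y) are deflated after every component.  Scores are stored
unit-norm.  Columns of X are mean-centered but NOT variance-scaled: the
response variables are normalized upstream, the features keep their natural
scales (``scale_x=True`` opts into autoscaling).

Prediction uses the standard identity ``B = W (P^T W)^{-1} C^T`` so that
``Y_hat = (X_new - x_mean) B + y_mean``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import solve_triangular

from .io_core import DegenerateDataError, ParameterError, ShapeMismatchError
from .feature_tensor import FeatureMatrix

_TOL = 1e-10
_MAX_ITER = 500


def _sign_fix(v: np.ndarray, eps: float = 1e-12) -> float:
    """Sign making the first non-negligible element of v positive."""
    nz = np.flatnonzero(np.abs(v) > eps)
    if nz.size == 0:
        return 1.0
    return 1.0 if v[nz[0]] > 0 else -1.0


@dataclass
class PLSModel:
    """Fitted NIPALS PLS2 model (scores unit-norm, X- and Y-deflation)."""

    n_components: int
    weights: np.ndarray        # (I, R)
    x_loadings: np.ndarray     # (I, R)
    y_loadings: np.ndarray     # (J, R)
    scores: np.ndarray         # (N, R), training diagnostics
    x_mean: np.ndarray         # (I,)
    y_mean: np.ndarray         # (J,)
    x_scale: np.ndarray        # (I,) ones unless scale_x
    deflate_y: bool
    x_residual_norms: np.ndarray = field(default=None)  # length R+1
    y_residual_norms: np.ndarray = field(default=None)

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]

    @property
    def n_responses(self) -> int:
        return self.y_loadings.shape[0]

    def coefficients(self, n_components: int | None = None) -> np.ndarray:
        return pls_coefficients(self, n_components)

    def predict(self, x_new, n_components: int | None = None) -> np.ndarray:
        return predict_pls(self, x_new, n_components)


def _as_array(x) -> np.ndarray:
    if isinstance(x, FeatureMatrix):
        return x.values
    return np.asarray(x, dtype=float)


def fit_pls(
    x,
    y: np.ndarray,
    n_components: int,
    *,
    scale_x: bool = False,
    deflate_y: bool = True,
    tol: float = _TOL,
    max_iter: int = _MAX_ITER,
) -> PLSModel:
    """Fit a PLS2 model with ``n_components`` latent components.

    ``n_components = 0`` yields the mean-only baseline model.  Raises
    :class:`ParameterError` when the component count exceeds ``min(N-1, I)``
    and :class:`DegenerateDataError` when X has no variance after centering.
    """
    x = _as_array(x)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n, i = x.shape
    if y.shape[0] != n:
        raise ShapeMismatchError(f"X has {n} rows but Y has {y.shape[0]}")
    max_r = min(n - 1, i)
    if not (0 <= n_components <= max_r):
        raise ParameterError(
            f"n_components={n_components} must lie in [0, min(N-1, I)] = [0, {max_r}]"
        )
    x_mean = x.mean(axis=0)
    y_mean = y.mean(axis=0)
    xr = x - x_mean
    if scale_x:
        x_scale = xr.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
        xr = xr / x_scale
    else:
        x_scale = np.ones(i)
    if n_components > 0 and not np.any(xr):
        raise DegenerateDataError("X has zero variance after centering")
    yr = y - y_mean

    j = y.shape[1]
    ws, ps, cs, ts = [], [], [], []
    x_norms = [np.linalg.norm(xr)]
    y_norms = [np.linalg.norm(yr)]
    achieved = 0
    for _ in range(n_components):
        if np.linalg.norm(xr) < 1e-12 * max(x_norms[0], 1e-300) or (
            np.linalg.norm(yr) < 1e-12 * max(y_norms[0], 1e-300)
        ):
            warnings.warn(
                f"residual exhausted after {achieved} components; stopping early",
                stacklevel=2,
            )
            break
        u = yr[:, int(np.argmax(yr.var(axis=0)))].copy()
        degenerate = False
        for _ in range(max_iter):
            w = xr.T @ u
            w_norm = np.linalg.norm(w)
            if w_norm == 0:
                degenerate = True
                break
            w /= w_norm
            t = xr @ w
            t /= np.linalg.norm(t)
            c = yr.T @ t
            if j == 1:
                break
            u_new = yr @ c / (c @ c)
            if np.linalg.norm(u_new - u) < tol * max(np.linalg.norm(u_new), 1e-300):
                u = u_new
                break
            u = u_new
        if degenerate:
            warnings.warn(
                f"X carries no covariance with Y after {achieved} components",
                stacklevel=2,
            )
            break
        s = _sign_fix(w)
        w, t, c = s * w, s * t, s * c
        p = xr.T @ t
        xr = xr - np.outer(t, p)
        if deflate_y:
            yr = yr - np.outer(t, c)
        ws.append(w)
        ps.append(p)
        cs.append(c)
        ts.append(t)
        x_norms.append(np.linalg.norm(xr))
        y_norms.append(np.linalg.norm(yr if deflate_y else yr - np.outer(t, c)))
        achieved += 1

    return PLSModel(
        n_components=achieved,
        weights=np.array(ws).T.reshape(i, achieved),
        x_loadings=np.array(ps).T.reshape(i, achieved),
        y_loadings=np.array(cs).T.reshape(j, achieved),
        scores=np.array(ts).T.reshape(n, achieved),
        x_mean=x_mean,
        y_mean=y_mean,
        x_scale=x_scale,
        deflate_y=deflate_y,
        x_residual_norms=np.array(x_norms),
        y_residual_norms=np.array(y_norms),
    )


def pls_coefficients(model: PLSModel, n_components: int | None = None) -> np.ndarray:
    """Coefficient matrix B (I x J) on centered scale: Y_hat = Xc B + y_mean."""
    r = model.n_components if n_components is None else n_components
    if not (0 <= r <= model.n_components):
        raise ParameterError(f"n_components={r} exceeds fitted {model.n_components}")
    if r == 0:
        return np.zeros((model.n_features, model.n_responses))
    w = model.weights[:, :r]
    p = model.x_loadings[:, :r]
    c = model.y_loadings[:, :r]
    ptw = p.T @ w  # upper triangular by construction
    rot = solve_triangular(ptw, c.T, lower=False)  # (R, J)
    b = w @ rot
    return b / model.x_scale[:, None]


def predict_pls(model: PLSModel, x_new, n_components: int | None = None) -> np.ndarray:
    """Predict responses (rows x J) for new feature rows."""
    x_new = _as_array(x_new)
    single = x_new.ndim == 1
    if single:
        x_new = x_new[None, :]
    if x_new.shape[1] != model.n_features:
        raise ShapeMismatchError(
            f"X_new has {x_new.shape[1]} columns; model expects {model.n_features}"
        )
    b = pls_coefficients(model, n_components)
    out = (x_new - model.x_mean) @ b + model.y_mean
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_pls(model: PLSModel, path: str | Path) -> None:
    meta = {"kind": "pls", "n_components": model.n_components,
            "deflate_y": model.deflate_y}
    np.savez(
        path,
        meta=json.dumps(meta),
        weights=model.weights,
        x_loadings=model.x_loadings,
        y_loadings=model.y_loadings,
        scores=model.scores,
        x_mean=model.x_mean,
        y_mean=model.y_mean,
        x_scale=model.x_scale,
        x_residual_norms=model.x_residual_norms,
        y_residual_norms=model.y_residual_norms,
    )


def load_pls(path: str | Path) -> PLSModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        return PLSModel(
            n_components=int(meta["n_components"]),
            weights=z["weights"],
            x_loadings=z["x_loadings"],
            y_loadings=z["y_loadings"],
            scores=z["scores"],
            x_mean=z["x_mean"],
            y_mean=z["y_mean"],
            x_scale=z["x_scale"],
            deflate_y=bool(meta["deflate_y"]),
            x_residual_norms=z["x_residual_norms"],
            y_residual_norms=z["y_residual_norms"],
        )
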