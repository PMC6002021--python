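"""Higher-Order PLS regression on the 4-mode feature tensor.

The predictor tensor ``X`` (trials x channel-1 x channel-2 x band) and the
response matrix ``Y`` are decomposed around shared latent scores::

    X = sum_r G_r x1 t_r x2 P_r^(1) x3 P_r^(2) x4 P_r^(3) + E
    Y = sum_r d_r t_r q_r^T + V

with unit-norm scores ``t_r``, column-orthonormal loading matrices
``P_r^(1) (M x L1)``, ``P_r^(2) (M x L2)``, ``P_r^(3) (F x L3)`` and a small
core tensor ``G_r`` of shape ``(1, L1, L2, L3)``.  Per component the
algorithm:

1. forms the cross-covariance tensor ``C[j, m1, m2, f] = sum_n Y[n,j] X[n,...]``
   on the current residuals;
2. computes its best rank-``(1, L1, L2, L3)`` orthogonal Tucker approximation
   by alternating orthogonal iteration (HOOI), giving the loadings and a core
   ``D_r``;
3. projects ``X`` onto the loadings and contracts with the normalized core,
   ``t_r `` proportional to`` Z_(1) vec(D_r)`` -- the multilinear analogue of the
   PLS weight step.  With full loading ranks this reduces exactly to PLS2 on
   the vectorized tensor;
4. sets ``q_r = Y^T t_r / d_r`` with ``d_r = ||Y^T t_r||`` and deflates both
   blocks by their rank-one reconstructions.

Tensor primitives (unfolding, mode-n product, HOOI) are implemented here on
plain numpy.  Tensors are centered trial-wise (the mean tensor is subtracted),
mirroring PLS column centering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_core import DegenerateDataError, ParameterError, ShapeMismatchError
from .feature_tensor import FeatureTensor

# ---------------------------------------------------------------------------
# Tensor primitives
# ---------------------------------------------------------------------------


def unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` unfolding: rows index the chosen mode."""
    return np.moveaxis(tensor, mode, 0).reshape(tensor.shape[mode], -1)


def fold(matrix: np.ndarray, mode: int, shape: tuple[int, ...]) -> np.ndarray:
    """Inverse of :func:`unfold` for a tensor of the given full shape."""
    moved = [shape[mode]] + [s for i, s in enumerate(shape) if i != mode]
    return np.moveaxis(matrix.reshape(moved), 0, mode)


def mode_dot(tensor: np.ndarray, matrix: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n product: multiply ``matrix`` (rows replace the mode) along ``mode``."""
    moved = np.moveaxis(tensor, mode, -1)
    return np.moveaxis(moved @ matrix.T, -1, mode)


def multi_mode_dot(tensor, matrices, modes):
    for mat, mode in zip(matrices, modes):
        tensor = mode_dot(tensor, mat, mode)
    return tensor


def _leading_singular_vectors(mat: np.ndarray, k: int) -> np.ndarray:
    """Leading k left singular vectors via the (small) Gram matrix.

    Unfolding rows index a single tensor mode, so the Gram matrix is at most
    M x M here -- far cheaper than an SVD of the wide unfolding, and the
    same route the batched leave-one-out engine uses.
    """
    gram = mat @ mat.T
    _, vecs = np.linalg.eigh(gram)  # ascending order
    return vecs[:, ::-1][:, :k]


def tucker_hooi(
    tensor: np.ndarray,
    ranks: tuple[int, ...],
    max_iter: int = 100,
    tol: float = 1e-9,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Best rank-``ranks`` orthogonal Tucker approximation via HOOI.

    Initialized by truncated SVD of each unfolding (HOSVD); alternates
    orthogonal iteration over the modes until the core norm stabilizes.
    Returns ``(factors, core)`` with column-orthonormal factors.
    """
    ndim = tensor.ndim
    if len(ranks) != ndim:
        raise ParameterError(f"need {ndim} ranks, got {len(ranks)}")
    for k, (r, s) in enumerate(zip(ranks, tensor.shape)):
        if not (1 <= r <= s):
            raise ParameterError(f"rank {r} invalid for mode {k} of size {s}")
    factors = [
        _leading_singular_vectors(unfold(tensor, k), r) for k, r in enumerate(ranks)
    ]
    prev = -1.0
    for _ in range(max_iter):
        for k in range(ndim):
            # project every other mode; later modes shrink the working tensor
            # fastest, so process them first
            partial = tensor
            order = sorted((j for j in range(ndim) if j != k),
                           key=lambda j: -(tensor.shape[j] - ranks[j]))
            for j in order:
                partial = mode_dot(partial, factors[j].T, j)
            factors[k] = _leading_singular_vectors(unfold(partial, k), ranks[k])
        core = multi_mode_dot(tensor, [f.T for f in factors], range(ndim))
        norm = np.linalg.norm(core)
        if abs(norm - prev) <= tol * max(norm, 1e-300):
            break
        prev = norm
    # deterministic sign convention: first sizable element of each column >= 0
    for k, f in enumerate(factors):
        for c in range(f.shape[1]):
            nz = np.flatnonzero(np.abs(f[:, c]) > 1e-12)
            if nz.size and f[nz[0], c] < 0:
                f[:, c] = -f[:, c]
    core = multi_mode_dot(tensor, [f.T for f in factors], range(ndim))
    return factors, core


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


@dataclass
class HOPLSComponent:
    loadings: tuple[np.ndarray, np.ndarray, np.ndarray]  # P^(1), P^(2), P^(3)
    core: np.ndarray          # (1, L1, L2, L3)
    weight: np.ndarray        # vec of normalized cross-covariance core
    alpha: float              # vec(core) . weight, score normalizer
    score: np.ndarray         # t_r, training scores, unit norm
    d: float                  # response strength
    q: np.ndarray             # (J,), unit norm
    reconstruction: np.ndarray  # (M, M, F): core x2 P1 x3 P2 x4 P3


@dataclass
class HOPLSModel:
    """Fitted HOPLS model with per-component loadings, cores and scores."""

    n_components: int
    ranks: tuple[int, int, int]
    components: list[HOPLSComponent]
    x_mean: np.ndarray        # (M, M, F)
    y_mean: np.ndarray        # (J,)
    x_residual_norms: np.ndarray = field(default=None)
    y_residual_norms: np.ndarray = field(default=None)

    @property
    def tensor_shape(self) -> tuple[int, int, int]:
        return self.x_mean.shape

    @property
    def n_responses(self) -> int:
        return self.y_mean.shape[0]

    def predict(self, x_new) -> np.ndarray:
        return predict_hopls(self, x_new)

    def coefficients(self) -> np.ndarray:
        return hopls_coefficients(self)


def _as_tensor(x) -> np.ndarray:
    if isinstance(x, FeatureTensor):
        return x.values
    return np.asarray(x, dtype=float)


def fit_hopls(
    x,
    y: np.ndarray,
    n_components: int,
    l1: int,
    l2: int,
    l3: int,
    *,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> HOPLSModel:
    """Fit a HOPLS model with ``n_components`` and loading ranks (L1, L2, L3).

    Stops early (with a warning) when the residual is exhausted before the
    requested component count; the model records the achieved count.
    """
    x = _as_tensor(x)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if x.ndim != 4:
        raise ShapeMismatchError(f"X must be 4-mode (N, M, M, F); got {x.shape}")
    n, m1_dim, m2_dim, f_dim = x.shape
    if y.shape[0] != n:
        raise ShapeMismatchError(f"X has {n} trials but Y has {y.shape[0]} rows")
    if not (1 <= l1 <= m1_dim and 1 <= l2 <= m2_dim):
        raise ParameterError(
            f"loading ranks L1={l1}, L2={l2} must lie in [1, M={m1_dim}]"
        )
    if not (1 <= l3 <= f_dim):
        raise ParameterError(f"L3={l3} must lie in [1, F={f_dim}]")
    if n_components < 1:
        raise ParameterError("n_components must be >= 1")

    x_mean = x.mean(axis=0)
    y_mean = y.mean(axis=0)
    xr = x - x_mean
    yr = y - y_mean
    if not np.any(xr):
        raise DegenerateDataError("X has zero variance after centering")

    x0 = np.linalg.norm(xr)
    y0 = np.linalg.norm(yr)
    x_norms = [x0]
    y_norms = [y0]
    comps: list[HOPLSComponent] = []
    for r in range(n_components):
        if np.linalg.norm(xr) < 1e-12 * max(x0, 1e-300) or (
            np.linalg.norm(yr) < 1e-12 * max(y0, 1e-300)
        ):
            warnings.warn(
                f"residual exhausted after {len(comps)} components; stopping early",
                stacklevel=2,
            )
            break
        # (a) cross-covariance tensor on current residuals
        c = np.tensordot(yr, xr, axes=(0, 0))  # (J, M, M, F)
        # (b) rank-(1, L1, L2, L3) orthogonal Tucker approximation
        factors, d_core = tucker_hooi(c, (1, l1, l2, l3), max_iter=max_iter, tol=tol)
        loadings = tuple(factors[1:])
        # (c) latent scores: project X onto the loadings, contract with the
        # normalized core (the multilinear PLS weight)
        w = unfold(d_core, 0).ravel()
        w_norm = np.linalg.norm(w)
        if w_norm == 0:
            warnings.warn(
                f"cross-covariance vanished after {len(comps)} components",
                stacklevel=2,
            )
            break
        w = w / w_norm
        z = multi_mode_dot(xr, [p.T for p in loadings], (1, 2, 3))
        s = unfold(z, 0) @ w
        s_norm = np.linalg.norm(s)
        if s_norm == 0:
            break
        t = s / s_norm
        sign = 1.0
        nz = np.flatnonzero(np.abs(t) > 1e-12)
        if nz.size and t[nz[0]] < 0:
            sign = -1.0
        t = sign * t
        # (d) core, response loading and strength
        g = multi_mode_dot(xr, [t[None, :]] + [p.T for p in loadings], (0, 1, 2, 3))
        g_vec = unfold(g, 0).ravel()
        alpha = float(g_vec @ w)
        qt = yr.T @ t
        d = float(np.linalg.norm(qt))
        q = qt / d if d > 0 else qt
        # (e) deflation by the rank-one reconstructions
        recon = multi_mode_dot(g, loadings, (1, 2, 3))[0]
        xr = xr - t[:, None, None, None] * recon
        yr = yr - d * np.outer(t, q)
        x_norms.append(np.linalg.norm(xr))
        y_norms.append(np.linalg.norm(yr))
        comps.append(
            HOPLSComponent(loadings, g, w, alpha, t, d, q, recon)
        )

    return HOPLSModel(
        n_components=len(comps),
        ranks=(l1, l2, l3),
        components=comps,
        x_mean=x_mean,
        y_mean=y_mean,
        x_residual_norms=np.array(x_norms),
        y_residual_norms=np.array(y_norms),
    )


def _predict_centered(
    model: HOPLSModel, xc: np.ndarray, n_components: int | None = None
) -> np.ndarray:
    """Predict on already-centered tensors, without adding back y_mean."""
    r = model.n_components if n_components is None else n_components
    if not (0 <= r <= model.n_components):
        raise ParameterError(f"n_components={r} exceeds fitted {model.n_components}")
    pred = np.zeros((xc.shape[0], model.n_responses))
    xc = xc.copy()
    for comp in model.components[:r]:
        z = multi_mode_dot(xc, [p.T for p in comp.loadings], (1, 2, 3))
        t_new = unfold(z, 0) @ comp.weight / comp.alpha
        pred += comp.d * np.outer(t_new, comp.q)
        xc -= t_new[:, None, None, None] * comp.reconstruction
    return pred


def predict_hopls(
    model: HOPLSModel, x_new, n_components: int | None = None
) -> np.ndarray:
    """Predict responses for new trials (rows x M x M x F).

    ``n_components`` truncates the fitted model to its first components
    (extraction is sequential, so this equals a smaller-R2 fit).
    """
    x_new = _as_tensor(x_new)
    single = x_new.ndim == 3
    if single:
        x_new = x_new[None]
    if x_new.shape[1:] != model.tensor_shape:
        raise ShapeMismatchError(
            f"tensor slices {x_new.shape[1:]} do not match model "
            f"{model.tensor_shape}"
        )
    out = _predict_centered(model, x_new - model.x_mean, n_components) + model.y_mean
    return out[0] if single else out


def hopls_coefficients(model: HOPLSModel) -> np.ndarray:
    """Coefficient tensor W (M, M, F, J): prediction = <X_centered, W> + y_mean.

    The prediction rule is linear in the centered input, so W is obtained
    exactly by pushing the canonical basis tensors through it.
    """
    m1, m2, f = model.tensor_shape
    basis = np.eye(m1 * m2 * f).reshape(-1, m1, m2, f)
    w = _predict_centered(model, basis)  # (M*M*F, J)
    return w.reshape(m1, m2, f, model.n_responses)


# ---------------------------------------------------------------------------
# Batched leave-one-out engine
# ---------------------------------------------------------------------------
#
# Grid searches fit one HOPLS model per LOOCV fold; doing that fold by fold
# spends most of the time in Python call overhead on small arrays.  The
# engine below runs every fold simultaneously through batched linear algebra
# while reproducing the per-fold algorithm exactly: factor updates use the
# same Gram-eigendecomposition route, sweep order and convergence rule, and
# folds that converge (or exhaust their residual) are frozen individually.


def _batched_mode_dot(tensor: np.ndarray, factor: np.ndarray, mode: int) -> np.ndarray:
    """Contract batched tensor (B, ...) along ``mode`` (1-based within the
    per-fold tensor) with batched factor (B, dim, L), giving L on that mode."""
    moved = np.moveaxis(tensor, mode, -1)
    lead = moved.shape[:-1]
    b = tensor.shape[0]
    out = np.matmul(moved.reshape(b, -1, moved.shape[-1]), factor)
    return np.moveaxis(out.reshape(lead + (factor.shape[-1],)), -1, mode)


def _batched_leading_eig(tensor: np.ndarray, mode: int, k: int) -> np.ndarray:
    """Leading k left singular vectors of each fold's mode unfolding."""
    moved = np.moveaxis(tensor, mode, 1)
    b, dim = moved.shape[:2]
    flat = moved.reshape(b, dim, -1)
    gram = flat @ np.swapaxes(flat, 1, 2)
    _, vecs = np.linalg.eigh(gram)
    return vecs[..., ::-1][..., :k]


def _batched_sign_fix(vectors: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Per (batch of) column(s): sign of the first non-negligible element."""
    big = np.abs(vectors) > eps
    first = np.argmax(big, axis=-2)
    lead = np.take_along_axis(vectors, first[..., None, :], axis=-2)[..., 0, :]
    sign = np.where(lead < 0, -1.0, 1.0)
    sign = np.where(big.any(axis=-2), sign, 1.0)
    return sign


def _batched_hooi(c: np.ndarray, ranks: tuple[int, ...], max_iter: int, tol: float):
    """HOOI on a batch of tensors (B, d0, d1, ...), per-batch convergence."""
    b = c.shape[0]
    ndim = c.ndim - 1
    shape = c.shape[1:]
    factors = [
        _batched_leading_eig(c, k + 1, r) for k, r in enumerate(ranks)
    ]
    prev = np.full(b, -1.0)
    active = np.arange(b)
    order_cache = {
        k: sorted((j for j in range(ndim) if j != k),
                  key=lambda j: -(shape[j] - ranks[j]))
        for k in range(ndim)
    }
    for _ in range(max_iter):
        if active.size == 0:
            break
        c_act = c[active]
        for k in range(ndim):
            partial = c_act
            for j in order_cache[k]:
                partial = _batched_mode_dot(partial, factors[j][active], j + 1)
            factors[k][active] = _batched_leading_eig(partial, k + 1, ranks[k])
        core = c_act
        for j in range(ndim):
            core = _batched_mode_dot(core, factors[j][active], j + 1)
        norm = np.linalg.norm(core.reshape(active.size, -1), axis=1)
        converged = np.abs(norm - prev[active]) <= tol * np.maximum(norm, 1e-300)
        prev[active] = norm
        active = active[~converged]
    for k in range(ndim):
        sign = _batched_sign_fix(factors[k])
        factors[k] = factors[k] * sign[:, None, :]
    core = c
    for j in range(ndim):
        core = _batched_mode_dot(core, factors[j], j + 1)
    return factors, core


def loo_fit_predict_hopls(
    x: np.ndarray,
    y_folds: np.ndarray,
    n_components: int,
    l1: int,
    l2: int,
    l3: int,
    *,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> dict[int, np.ndarray]:
    """Leave-one-out HOPLS: fit every fold at once, predict its held-out trial.

    ``x`` is the full (N, M, M, F) tensor; ``y_folds`` (N, N-1, J) holds each
    fold's (already normalized) training responses in ``np.delete`` order.
    Returns ``{r: predictions (N, J)}`` for every component count
    ``r = 1 .. n_components``, identical to fitting :func:`fit_hopls` per
    fold and predicting with ``n_components=r``.
    """
    n, m1_dim, m2_dim, f_dim = x.shape
    idx = np.arange(n)
    train = np.stack([np.delete(idx, i) for i in range(n)])
    xb = x[train]                                 # (N, N-1, M, M, F)
    x_mean = xb.mean(axis=1)
    xc = xb - x_mean[:, None]
    x_test = x - x_mean                           # centered held-out trials
    y_mean = y_folds.mean(axis=1)
    yc = y_folds - y_mean[:, None]

    j_dim = y_folds.shape[-1]
    x0 = np.linalg.norm(xc.reshape(n, -1), axis=1)
    y0 = np.linalg.norm(yc.reshape(n, -1), axis=1)
    alive = np.ones(n, dtype=bool)

    pred = np.broadcast_to(y_mean, (n, j_dim)).copy()
    out: dict[int, np.ndarray] = {}
    for _ in range(n_components):
        x_norm = np.linalg.norm(xc.reshape(n, -1), axis=1)
        y_norm = np.linalg.norm(yc.reshape(n, -1), axis=1)
        alive = alive & (x_norm >= 1e-12 * np.maximum(x0, 1e-300)) & (
            y_norm >= 1e-12 * np.maximum(y0, 1e-300)
        )
        c = np.einsum("bnj,bnmkf->bjmkf", yc, xc, optimize=True)
        factors, core = _batched_hooi(c, (1, l1, l2, l3), max_iter, tol)
        loadings = factors[1:]
        w = core.reshape(n, -1)
        w_norm = np.linalg.norm(w, axis=1)
        alive = alive & (w_norm > 0)
        w = np.where(alive[:, None], w / np.where(w_norm > 0, w_norm, 1.0)[:, None], 0.0)
        z = xc
        for k, p in enumerate(loadings):
            z = _batched_mode_dot(z, p, k + 2)
        z_flat = z.reshape(n, n - 1, -1)
        s = np.einsum("bnl,bl->bn", z_flat, w)
        s_norm = np.linalg.norm(s, axis=1)
        alive = alive & (s_norm > 0)
        t = np.where(alive[:, None], s / np.where(s_norm > 0, s_norm, 1.0)[:, None], 0.0)
        sign = _batched_sign_fix(t[..., None])[:, 0]
        t = t * sign[:, None]
        g = np.einsum("bn,bnl->bl", t, z_flat)
        alpha = np.einsum("bl,bl->b", g, w)
        qt = np.einsum("bnj,bn->bj", yc, t)
        d = np.linalg.norm(qt, axis=1)
        q = np.where(d[:, None] > 0, qt / np.where(d > 0, d, 1.0)[:, None], qt)
        # rank-one reconstructions and deflation
        recon = g.reshape((n, 1, l1, l2, l3))
        for k, p in enumerate(loadings):
            recon = _batched_mode_dot(recon, np.swapaxes(p, 1, 2), k + 2)
        recon = recon[:, 0]
        xc = xc - t[:, :, None, None, None] * recon[:, None]
        yc = yc - d[:, None, None] * t[:, :, None] * q[:, None, :]
        # held-out prediction: project the single test tensor of each fold
        zt = x_test[:, None]
        for k, p in enumerate(loadings):
            zt = _batched_mode_dot(zt, p, k + 2)
        t_new = np.einsum("bl,bl->b", zt.reshape(n, -1), w)
        denom = np.where(np.abs(alpha) > 0, alpha, 1.0)
        t_new = np.where(alive, t_new / denom, 0.0)
        pred = pred + (d * t_new)[:, None] * q
        x_test = x_test - t_new[:, None, None, None] * recon
        out[len(out) + 1] = pred.copy()
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_hopls(model: HOPLSModel, path: str | Path) -> None:
    meta = {
        "kind": "hopls",
        "n_components": model.n_components,
        "ranks": list(model.ranks),
        "d": [c.d for c in model.components],
        "alpha": [c.alpha for c in model.components],
    }
    arrays = {"x_mean": model.x_mean, "y_mean": model.y_mean,
              "x_residual_norms": model.x_residual_norms,
              "y_residual_norms": model.y_residual_norms}
    for r, c in enumerate(model.components):
        arrays[f"p1_{r}"] = c.loadings[0]
        arrays[f"p2_{r}"] = c.loadings[1]
        arrays[f"p3_{r}"] = c.loadings[2]
        arrays[f"core_{r}"] = c.core
        arrays[f"weight_{r}"] = c.weight
        arrays[f"score_{r}"] = c.score
        arrays[f"q_{r}"] = c.q
        arrays[f"recon_{r}"] = c.reconstruction
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_hopls(path: str | Path) -> HOPLSModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        comps = []
        for r in range(int(meta["n_components"])):
            comps.append(
                HOPLSComponent(
                    loadings=(z[f"p1_{r}"], z[f"p2_{r}"], z[f"p3_{r}"]),
                    core=z[f"core_{r}"],
                    weight=z[f"weight_{r}"],
                    alpha=float(meta["alpha"][r]),
                    score=z[f"score_{r}"],
                    d=float(meta["d"][r]),
                    q=z[f"q_{r}"],
                    reconstruction=z[f"recon_{r}"],
                )
            )
        return HOPLSModel(
            n_components=int(meta["n_components"]),
            ranks=tuple(meta["ranks"]),
            components=comps,
            x_mean=z["x_mean"],
            y_mean=z["y_mean"],
            x_residual_norms=z["x_residual_norms"],
            y_residual_norms=z["y_residual_norms"],
        )
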