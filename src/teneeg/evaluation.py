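"""Response normalization, LOOCV, hyperparameter grids, RMSE and contributions.

The evaluation protocol is per-subject leave-one-out cross-validation: every
trial is predicted by a model trained on the remaining trials, and prediction
quality is the RMSE per rating scale on the normalized response scale.
Response variables (MOS, VAL, ARL) are normalized to zero mean and unit
variance; by default the normalization parameters are estimated inside each
training fold (no leakage into the held-out trial), ``global_normalize=True``
normalizes once before splitting.

Hyperparameters are selected by the LOOCV error itself over a grid (the
small-N protocol; ``nested_loocv`` offers the honest nested variant).  The
default grids are R1 in 1..43 for PLS and L1, L2 in 1..7, L3, R2 in 1..5 for
HOPLS, and the selection objective is the mean RMSE across the three scales
(ties broken toward the smallest model).

Feature attribution ranks features by the magnitude of the regression
coefficients: top-K lists per scale, counts by feature kind (PSD/PWD/PHD) and
by band among the top K, and the top channel pairs by summed magnitude.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import (
    SCALES,
    DegenerateDataError,
    ParameterError,
    ShapeMismatchError,
)
from .feature_tensor import (
    FeatureDescriptor,
    FeatureMatrix,
    FeatureTensor,
    feature_count,
    flat_coefficients_from_tensor,
    _layout_cells,
    cell_descriptor,
)
from . import pls as _pls
from . import hopls as _hopls

# ---------------------------------------------------------------------------
# Response normalization and RMSE
# ---------------------------------------------------------------------------


@dataclass
class ResponseNormalization:
    """Column-wise standardization parameters (sample sd, divisor N-1)."""

    mean: np.ndarray
    std: np.ndarray

    def transform(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.mean) / self.std

    def inverse(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, dtype=float) * self.std + self.mean


def normalize_responses(y: np.ndarray) -> tuple[np.ndarray, ResponseNormalization]:
    """Standardize each response column to zero mean, unit variance (ddof=1)."""
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    mean = y.mean(axis=0)
    std = y.std(axis=0, ddof=1)
    if np.any(std == 0):
        j = int(np.flatnonzero(std == 0)[0])
        raise DegenerateDataError(f"response column {j} is constant")
    params = ResponseNormalization(mean, std)
    return params.transform(y), params


def rmse(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Root mean squared error between two equal-length vectors."""
    predicted = np.asarray(predicted, dtype=float).ravel()
    actual = np.asarray(actual, dtype=float).ravel()
    if predicted.shape != actual.shape or predicted.size == 0:
        raise ShapeMismatchError(
            f"rmse needs equal non-empty lengths, got {predicted.shape} "
            f"vs {actual.shape}"
        )
    return float(np.sqrt(np.mean((predicted - actual) ** 2)))


# ---------------------------------------------------------------------------
# Model specification and LOOCV
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Which regression to run and with which fixed hyperparameters.

    ``kind`` is ``"pls"`` (params: ``r1``; ``r1=0`` is the mean-only
    baseline) or ``"hopls"`` (params: ``l1, l2, l3, r2``).
    """

    kind: str
    params: tuple[tuple[str, int], ...]

    @staticmethod
    def pls(r1: int) -> "ModelSpec":
        return ModelSpec("pls", (("r1", int(r1)),))

    @staticmethod
    def hopls(l1: int, l2: int, l3: int, r2: int) -> "ModelSpec":
        return ModelSpec(
            "hopls",
            (("l1", int(l1)), ("l2", int(l2)), ("l3", int(l3)), ("r2", int(r2))),
        )

    def as_dict(self) -> dict:
        return dict(self.params)


@dataclass
class EvaluationResult:
    """Per-scale LOOCV RMSE with the hyperparameters and per-fold values."""

    model_kind: str
    hyperparams: dict
    rmse_per_scale: dict
    predictions: np.ndarray   # (N, J), normalized scale
    actuals: np.ndarray       # (N, J), normalized scale
    n_folds: int
    scale_names: tuple = SCALES

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(list(self.rmse_per_scale.values())))


def _feature_values(features):
    if isinstance(features, FeatureMatrix):
        return features.values
    if isinstance(features, FeatureTensor):
        return features.values
    return np.asarray(features, dtype=float)


def _check_feasible(spec: ModelSpec, n_train: int, shape) -> None:
    p = spec.as_dict()
    if spec.kind == "pls":
        i = int(np.prod(shape[1:]))
        if p["r1"] > min(n_train - 1, i):
            raise ParameterError(
                f"R1={p['r1']} infeasible for training folds of {n_train} "
                f"trials (max {min(n_train - 1, i)})"
            )
    elif spec.kind == "hopls":
        _, m1, m2, f = shape
        if not (1 <= p["l1"] <= m1 and 1 <= p["l2"] <= m2 and 1 <= p["l3"] <= f):
            raise ParameterError(
                f"loading ranks {p} infeasible for tensor modes ({m1}, {m2}, {f})"
            )
    else:
        raise ParameterError(f"unknown model kind {spec.kind!r}")


def _fit_predict(spec: ModelSpec, x_train, y_train, x_test) -> np.ndarray:
    p = spec.as_dict()
    if spec.kind == "pls":
        x2 = x_train.reshape(x_train.shape[0], -1)
        model = _pls.fit_pls(x2, y_train, p["r1"])
        return _pls.predict_pls(model, x_test.reshape(x_test.shape[0], -1))
    model = _hopls.fit_hopls(x_train, y_train, p["r2"], p["l1"], p["l2"], p["l3"])
    return _hopls.predict_hopls(model, x_test)


def loocv(
    features,
    y: np.ndarray,
    spec: ModelSpec,
    *,
    global_normalize: bool = False,
) -> EvaluationResult:
    """Leave-one-out cross-validation with per-fold response normalization."""
    x = _feature_values(features)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = x.shape[0]
    if y.shape[0] != n:
        raise ShapeMismatchError(f"{n} trials but {y.shape[0]} rating rows")
    if n < 3:
        raise ParameterError("LOOCV needs at least 3 trials")
    _check_feasible(spec, n - 1, x.shape if x.ndim == 4 else (n, x.reshape(n, -1).shape[1]))
    if global_normalize:
        y_all, _ = normalize_responses(y)
    preds = np.empty_like(y, dtype=float)
    actuals = np.empty_like(y, dtype=float)
    for i in range(n):
        train = np.arange(n) != i
        if global_normalize:
            yn_train, yn_test = y_all[train], y_all[i]
        else:
            yn_train, params = normalize_responses(y[train])
            yn_test = params.transform(y[i])
        preds[i] = _fit_predict(spec, x[train], yn_train, x[i : i + 1])[0]
        actuals[i] = yn_test
    scores = {
        s: rmse(preds[:, j], actuals[:, j]) for j, s in enumerate(SCALES[: y.shape[1]])
    }
    return EvaluationResult(spec.kind, spec.as_dict(), scores, preds, actuals, n)


def _loocv_pls_path(x2, y, r1_values, global_normalize=False):
    """LOOCV for many R1 values with one NIPALS fit per fold.

    NIPALS components are nested, so predictions at every component count come
    from prefixes of a single fit at the largest requested R1.  Identical to
    calling :func:`loocv` per value, only faster.
    """
    n = x2.shape[0]
    r_max = max(r1_values)
    preds = {r: np.empty_like(y, dtype=float) for r in r1_values}
    actuals = np.empty_like(y, dtype=float)
    if global_normalize:
        y_all, _ = normalize_responses(y)
    for i in range(n):
        train = np.arange(n) != i
        if global_normalize:
            yn_train, yn_test = y_all[train], y_all[i]
        else:
            yn_train, params = normalize_responses(y[train])
            yn_test = params.transform(y[i])
        model = _pls.fit_pls(x2[train], yn_train, r_max)
        for r in r1_values:
            preds[r][i] = _pls.predict_pls(model, x2[i : i + 1], min(r, model.n_components))[0]
        actuals[i] = yn_test
    out = {}
    for r in r1_values:
        scores = {s: rmse(preds[r][:, j], actuals[:, j]) for j, s in enumerate(SCALES)}
        out[r] = EvaluationResult("pls", {"r1": r}, scores, preds[r], actuals, n)
    return out


def _loocv_hopls_path(x, y, l1, l2, l3, r2_values, global_normalize=False):
    """LOOCV for several R2 values through the batched fold engine.

    Identical to fitting :func:`teneeg.hopls.fit_hopls` per fold; all folds
    are fitted simultaneously and every prefix component count is read off
    one pass.
    """
    n = x.shape[0]
    r_max = max(r2_values)
    actuals = np.empty_like(y, dtype=float)
    y_folds = np.empty((n, n - 1, y.shape[1]))
    if global_normalize:
        y_all, _ = normalize_responses(y)
    for i in range(n):
        train = np.arange(n) != i
        if global_normalize:
            y_folds[i], actuals[i] = y_all[train], y_all[i]
        else:
            y_folds[i], params = normalize_responses(y[train])
            actuals[i] = params.transform(y[i])
    path = _hopls.loo_fit_predict_hopls(x, y_folds, r_max, l1, l2, l3)
    preds = {r: path[r] for r in r2_values}
    out = []
    for r in r2_values:
        scores = {s: rmse(preds[r][:, j], actuals[:, j]) for j, s in enumerate(SCALES)}
        out.append(
            EvaluationResult(
                "hopls",
                {"l1": l1, "l2": l2, "l3": l3, "r2": r},
                scores,
                preds[r],
                actuals,
                n,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------


def default_pls_grid() -> list[int]:
    """R1 from 1 to 43."""
    return list(range(1, 44))


def default_hopls_grid() -> list[tuple[int, int, int, int]]:
    """(L1, L2, L3, R2) with L1, L2 in 1..7 and L3, R2 in 1..5 (1225 points)."""
    return [
        (l1, l2, l3, r2)
        for l1 in range(1, 8)
        for l2 in range(1, 8)
        for l3 in range(1, 6)
        for r2 in range(1, 6)
    ]


def _model_size(spec_dict: dict) -> tuple:
    if "r1" in spec_dict:
        return (spec_dict["r1"],)
    return (spec_dict["r2"], spec_dict["l1"] + spec_dict["l2"] + spec_dict["l3"])


def grid_search(
    features,
    y: np.ndarray,
    model_kind: str,
    grid=None,
    *,
    global_normalize: bool = False,
) -> tuple[EvaluationResult, pd.DataFrame]:
    """LOOCV over a hyperparameter grid; best point by mean RMSE across scales.

    Ties are broken toward the smaller model (fewer components, then smaller
    total loading rank).  Grid points that are infeasible for the fold size or
    tensor dimensions are skipped with a warning.  Returns the winning
    :class:`EvaluationResult` and the full grid table.
    """
    if model_kind not in ("pls", "hopls"):
        raise ParameterError(f"unknown model kind {model_kind!r}")
    if grid is None:
        grid = default_pls_grid() if model_kind == "pls" else default_hopls_grid()
    grid = list(grid)
    if not grid:
        raise ParameterError("empty hyperparameter grid")

    results: list[EvaluationResult] = []
    skipped = []
    if model_kind == "pls":
        x2 = _feature_values(features)
        x2 = x2.reshape(x2.shape[0], -1)
        n = x2.shape[0]
        feasible = [r for r in grid if 0 <= r <= min(n - 2, x2.shape[1])]
        skipped = sorted(set(grid) - set(feasible))
        path = _loocv_pls_path(x2, y, [r for r in feasible if r > 0],
                               global_normalize=global_normalize)
        for r in feasible:
            if r == 0:
                results.append(loocv(x2, y, ModelSpec.pls(0),
                                     global_normalize=global_normalize))
            else:
                results.append(path[r])
    else:
        x = _feature_values(features)
        n = x.shape[0]
        if n < 3:
            raise ParameterError("LOOCV needs at least 3 trials")
        _, m1, m2, f = x.shape
        by_loadings: dict[tuple[int, int, int], list[int]] = {}
        for l1, l2, l3, r2 in grid:
            if not (1 <= l1 <= m1 and 1 <= l2 <= m2 and 1 <= l3 <= f and r2 >= 1):
                skipped.append((l1, l2, l3, r2))
                continue
            by_loadings.setdefault((l1, l2, l3), []).append(r2)
        # HOPLS extraction is sequential, so every R2 on the grid comes from
        # prefixes of one fit per fold at the largest R2 (identical results,
        # one fit instead of len(r2_values))
        for (l1, l2, l3), r2_values in by_loadings.items():
            results.extend(
                _loocv_hopls_path(x, y, l1, l2, l3, sorted(set(r2_values)),
                                  global_normalize=global_normalize)
            )
    if skipped:
        warnings.warn(f"skipped infeasible grid points: {skipped}", stacklevel=2)
    if not results:
        raise ParameterError("no feasible grid point")

    rows = []
    for res in results:
        row = dict(res.hyperparams)
        for s in SCALES:
            row[f"rmse_{s}"] = res.rmse_per_scale[s]
        row["rmse_mean"] = res.mean_rmse
        rows.append(row)
    table = pd.DataFrame(rows)
    best = min(results, key=lambda r: (r.mean_rmse,) + _model_size(r.hyperparams))
    return best, table


def nested_loocv(
    features,
    y: np.ndarray,
    model_kind: str,
    grid=None,
) -> EvaluationResult:
    """Nested LOOCV: hyperparameters chosen per outer fold on inner folds only."""
    x = _feature_values(features)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    preds = np.empty_like(y, dtype=float)
    actuals = np.empty_like(y, dtype=float)
    chosen = []
    for i in range(n):
        train = np.arange(n) != i
        inner_best, _ = grid_search(x[train], y[train], model_kind, grid)
        spec = (
            ModelSpec.pls(inner_best.hyperparams["r1"])
            if model_kind == "pls"
            else ModelSpec.hopls(**inner_best.hyperparams)
        )
        yn_train, params = normalize_responses(y[train])
        preds[i] = _fit_predict(spec, x[train], yn_train, x[i : i + 1])[0]
        actuals[i] = params.transform(y[i])
        chosen.append(inner_best.hyperparams)
    scores = {s: rmse(preds[:, j], actuals[:, j]) for j, s in enumerate(SCALES)}
    return EvaluationResult(
        model_kind, {"per_fold": chosen}, scores, preds, actuals, n
    )


def evaluation_summary(
    pls_result: EvaluationResult, hopls_result: EvaluationResult
) -> pd.DataFrame:
    """One row per rating scale: vector and tensor RMSE plus R1, L1, L2, L3, R2."""
    rows = []
    for s in SCALES:
        rows.append(
            {
                "scale": s,
                "rmse_vector": pls_result.rmse_per_scale[s],
                "rmse_tensor": hopls_result.rmse_per_scale[s],
                "R1": pls_result.hyperparams.get("r1"),
                "L1": hopls_result.hyperparams.get("l1"),
                "L2": hopls_result.hyperparams.get("l2"),
                "L3": hopls_result.hyperparams.get("l3"),
                "R2": hopls_result.hyperparams.get("r2"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Contribution analysis
# ---------------------------------------------------------------------------


@dataclass
class ContributionReport:
    """Coefficient-magnitude attribution per rating scale."""

    top_features: dict          # scale -> DataFrame(rank, kind, ch1, ch2, band, magnitude)
    kind_counts: pd.DataFrame   # rows: scale, columns: PSD, PWD, PHD
    band_counts: pd.DataFrame   # rows: scale, columns: band names
    top_pairs: dict             # scale -> DataFrame(channel1, channel2, magnitude)
    k: int

    def to_csv(self, prefix: str | Path) -> list[Path]:
        prefix = Path(prefix)
        written = []
        for scale, df in self.top_features.items():
            p = prefix.with_name(prefix.name + f"_top_{scale}.csv")
            df.to_csv(p, index=False)
            written.append(p)
        p = prefix.with_name(prefix.name + "_kind_counts.csv")
        self.kind_counts.to_csv(p)
        written.append(p)
        p = prefix.with_name(prefix.name + "_band_counts.csv")
        self.band_counts.to_csv(p)
        written.append(p)
        for scale, df in self.top_pairs.items():
            p = prefix.with_name(prefix.name + f"_pairs_{scale}.csv")
            df.to_csv(p, index=False)
            written.append(p)
        return written


def contributions(
    coef: np.ndarray,
    index_map: list[FeatureDescriptor] | None = None,
    *,
    channel_labels: list[str] | None = None,
    band_names: list[str] | None = None,
    k: int = 100,
    n_pairs: int = 10,
    scale_names=SCALES,
) -> ContributionReport:
    """Rank features by absolute regression coefficient.

    ``coef`` is either an ``(I, J)`` matrix together with its ``index_map`` or
    an ``(M, M, F, J)`` coefficient tensor together with channel labels and
    band names.  Ties are broken deterministically by column order.
    """
    coef = np.asarray(coef, dtype=float)
    if coef.ndim == 4:
        if channel_labels is None or band_names is None:
            raise ParameterError(
                "tensor coefficients need channel_labels and band_names"
            )
        index_map = [
            cell_descriptor(a, b, c, channel_labels, band_names)
            for a, b, c in _layout_cells(len(channel_labels), len(band_names))
        ]
        coef = flat_coefficients_from_tensor(coef, channel_labels, band_names)
    if index_map is None:
        raise ParameterError("matrix coefficients need an index_map")
    if coef.ndim == 1:
        coef = coef[:, None]
    i, j = coef.shape
    if len(index_map) != i:
        raise ShapeMismatchError(f"{i} coefficients but {len(index_map)} descriptors")
    if k > i:
        warnings.warn(f"K={k} exceeds {i} features; clipping", stacklevel=2)
        k = i
    bands = list(dict.fromkeys(d.band for d in index_map))
    scales = list(scale_names)[:j]

    top_features, top_pairs = {}, {}
    kind_rows, band_rows = [], []
    for jj, scale in enumerate(scales):
        mag = np.abs(coef[:, jj])
        order = np.argsort(-mag, kind="stable")[:k]
        rows = [
            {
                "rank": rank + 1,
                "kind": index_map[c].kind,
                "channel1": index_map[c].channel1,
                "channel2": index_map[c].channel2 or "",
                "band": index_map[c].band,
                "magnitude": mag[c],
            }
            for rank, c in enumerate(order)
        ]
        df = pd.DataFrame(rows)
        top_features[scale] = df
        kind_rows.append(
            {"scale": scale, **{kd: int((df["kind"] == kd).sum()) for kd in ("PSD", "PWD", "PHD")}}
        )
        band_rows.append(
            {"scale": scale, **{b: int((df["band"] == b).sum()) for b in bands}}
        )
        pair_mag: dict[tuple[str, str], float] = {}
        for c in range(i):
            d = index_map[c]
            if d.channel2 is None:
                continue
            key = tuple(sorted((d.channel1, d.channel2)))
            pair_mag[key] = pair_mag.get(key, 0.0) + mag[c]
        pairs = sorted(pair_mag.items(), key=lambda kv: (-kv[1], kv[0]))[:n_pairs]
        top_pairs[scale] = pd.DataFrame(
            [{"channel1": a, "channel2": b, "magnitude": v} for (a, b), v in pairs]
        )
    return ContributionReport(
        top_features,
        pd.DataFrame(kind_rows).set_index("scale"),
        pd.DataFrame(band_rows).set_index("scale"),
        top_pairs,
        k,
    )
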