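"""Vectorized feature matrix and 4-mode feature tensor with index bookkeeping.

The same per-trial features are laid out two ways:

* **matrix** ``X`` of shape ``(N, I)`` with ``I = F * (M*(M-1) + M)`` columns:
  band-major, then kind (PSD, PWD, PHD), then channel / pair lexicographic;
* **tensor** ``X`` of shape ``(N, M, M, F)`` whose cell ``(n, m1, m2, f)`` is
  PWD when ``m1 > m2``, PHD when ``m1 < m2`` and PSD of channel ``m1`` on the
  diagonal.

Each off-diagonal tensor cell holds exactly one feature (the lower triangle
carries the power differences, the upper triangle the phase differences), so
both layouts contain the same multiset of values.  ``index_map`` records the
matrix column order so every coefficient can be mapped back to
``(kind, channels, band)`` for the contribution analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .io_core import FormatError, ParameterError, TeneegError
from .spectral import FeatureSet


class FeatureDescriptor(NamedTuple):
    """Human-readable identity of one feature column / tensor cell."""

    kind: str               # "PSD" | "PWD" | "PHD"
    channel1: str
    channel2: str | None    # None for PSD
    band: str


class FeatureIndexError(TeneegError, IndexError):
    """A feature index lies outside the layout."""


def feature_count(n_channels: int, n_bands: int) -> int:
    """I = F * (M*(M-1) + M)."""
    return n_bands * (n_channels * (n_channels - 1) + n_channels)


def _layout_cells(m: int, f: int):
    """Yield tensor cells (m1, m2, band) in matrix column order."""
    for fi in range(f):
        for ch in range(m):
            yield ch, ch, fi                    # PSD
        for m1 in range(m):
            for m2 in range(m1):
                yield m1, m2, fi                # PWD (m1 > m2)
        for m1 in range(m):
            for m2 in range(m1 + 1, m):
                yield m1, m2, fi                # PHD (m1 < m2)


def cell_descriptor(
    m1: int, m2: int, band_index: int, channel_labels: list[str], band_names: list[str]
) -> FeatureDescriptor:
    """Descriptor of a tensor cell, applying the m1>m2 / m1<m2 / diagonal rule."""
    m = len(channel_labels)
    if not (0 <= m1 < m and 0 <= m2 < m and 0 <= band_index < len(band_names)):
        raise FeatureIndexError(f"cell ({m1}, {m2}, {band_index}) out of range")
    band = band_names[band_index]
    if m1 == m2:
        return FeatureDescriptor("PSD", channel_labels[m1], None, band)
    kind = "PWD" if m1 > m2 else "PHD"
    return FeatureDescriptor(kind, channel_labels[m1], channel_labels[m2], band)


@dataclass
class FeatureMatrix:
    """``(N, I)`` vectorized features plus the column order in ``index_map``."""

    values: np.ndarray
    index_map: list[FeatureDescriptor]
    channel_labels: list[str]
    band_names: list[str]

    def __post_init__(self) -> None:
        i = feature_count(len(self.channel_labels), len(self.band_names))
        if self.values.shape[1] != i or len(self.index_map) != i:
            raise FormatError(
                f"feature matrix has {self.values.shape[1]} columns; layout "
                f"demands I = {i}"
            )
        self._column_lookup = {d: j for j, d in enumerate(self.index_map)}

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def describe(self, column: int) -> FeatureDescriptor:
        if not (0 <= column < self.n_features):
            raise FeatureIndexError(f"column {column} out of range")
        return self.index_map[column]

    def column_of(self, descriptor: FeatureDescriptor) -> int:
        try:
            return self._column_lookup[descriptor]
        except KeyError:
            raise FeatureIndexError(f"{descriptor} is not in the layout") from None


@dataclass
class FeatureTensor:
    """``(N, M, M, F)`` structured features (trials, channel-1, channel-2, band)."""

    values: np.ndarray
    channel_labels: list[str]
    band_names: list[str]

    def __post_init__(self) -> None:
        m, f = len(self.channel_labels), len(self.band_names)
        if self.values.shape[1:] != (m, m, f):
            raise FormatError(
                f"tensor shape {self.values.shape} does not match "
                f"(N, {m}, {m}, {f})"
            )

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def describe(self, m1: int, m2: int, band_index: int) -> FeatureDescriptor:
        return cell_descriptor(
            m1, m2, band_index, self.channel_labels, self.band_names
        )


def _require_full(features: FeatureSet) -> None:
    if features.psd is None or features.pwd is None or features.phd is None:
        raise ParameterError(
            "feature assembly needs PSD, PWD and PHD; run the spectral steps first"
        )


def build_feature_tensor(features: FeatureSet) -> FeatureTensor:
    """Assemble the structured 4-mode tensor from a full FeatureSet."""
    _require_full(features)
    n, m, f = features.n_trials, features.n_channels, features.n_bands
    values = np.empty((n, m, m, f))
    lower = np.tril(np.ones((m, m), dtype=bool), -1)
    upper = np.triu(np.ones((m, m), dtype=bool), 1)
    diag = np.eye(m, dtype=bool)
    values[:, lower, :] = features.pwd[:, lower, :]
    values[:, upper, :] = features.phd[:, upper, :]
    values[:, diag, :] = features.psd
    return FeatureTensor(values, list(features.channel_labels), list(features.band_names))


def build_feature_matrix(features: FeatureSet) -> FeatureMatrix:
    """Assemble the vectorized (N, I) feature matrix from a full FeatureSet."""
    tensor = build_feature_tensor(features)
    return matrix_from_tensor(tensor)


def matrix_from_tensor(tensor: FeatureTensor) -> FeatureMatrix:
    """Reorder tensor cells into the canonical matrix column layout."""
    m, f = len(tensor.channel_labels), len(tensor.band_names)
    cells = list(_layout_cells(m, f))
    m1s = np.array([c[0] for c in cells])
    m2s = np.array([c[1] for c in cells])
    fis = np.array([c[2] for c in cells])
    values = tensor.values[:, m1s, m2s, fis]
    index_map = [
        cell_descriptor(a, b, c, tensor.channel_labels, tensor.band_names)
        for a, b, c in cells
    ]
    return FeatureMatrix(values, index_map, list(tensor.channel_labels),
                         list(tensor.band_names))


def tensor_cell_of(
    descriptor: FeatureDescriptor, channel_labels: list[str], band_names: list[str]
) -> tuple[int, int, int]:
    """Inverse of :func:`cell_descriptor`: descriptor -> (m1, m2, band index)."""
    try:
        fi = band_names.index(descriptor.band)
        m1 = channel_labels.index(descriptor.channel1)
    except ValueError:
        raise FeatureIndexError(f"{descriptor} not addressable in this layout") from None
    if descriptor.kind == "PSD":
        if descriptor.channel2 is not None:
            raise FeatureIndexError("PSD descriptors carry a single channel")
        return m1, m1, fi
    try:
        m2 = channel_labels.index(descriptor.channel2)
    except ValueError:
        raise FeatureIndexError(f"{descriptor} not addressable in this layout") from None
    ok = (descriptor.kind == "PWD" and m1 > m2) or (descriptor.kind == "PHD" and m1 < m2)
    if not ok:
        raise FeatureIndexError(
            f"{descriptor}: {descriptor.kind} requires "
            f"{'m1 > m2' if descriptor.kind == 'PWD' else 'm1 < m2'}"
        )
    return m1, m2, fi


def describe_index(
    index: int | tuple[int, int, int],
    channel_labels: list[str],
    band_names: list[str],
) -> FeatureDescriptor:
    """Describe either a flat matrix column or a tensor cell ``(m1, m2, f)``."""
    m, f = len(channel_labels), len(band_names)
    if isinstance(index, tuple):
        return cell_descriptor(*index, channel_labels, band_names)
    i = feature_count(m, f)
    if not (0 <= index < i):
        raise FeatureIndexError(f"column {index} out of range for I={i}")
    for j, cell in enumerate(_layout_cells(m, f)):
        if j == index:
            return cell_descriptor(*cell, channel_labels, band_names)
    raise AssertionError("unreachable")


def flat_coefficients_from_tensor(
    coef: np.ndarray, channel_labels: list[str], band_names: list[str]
) -> np.ndarray:
    """Reorder an (M, M, F, ...) coefficient array into matrix column order."""
    m, f = len(channel_labels), len(band_names)
    cells = list(_layout_cells(m, f))
    m1s = np.array([c[0] for c in cells])
    m2s = np.array([c[1] for c in cells])
    fis = np.array([c[2] for c in cells])
    return coef[m1s, m2s, fis]


# ---------------------------------------------------------------------------
# Serialization: .npy payload + JSON sidecar with the index map
# ---------------------------------------------------------------------------


def save_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    path = Path(path)
    np.save(path, matrix.values)
    sidecar = {
        "channel_labels": matrix.channel_labels,
        "band_names": matrix.band_names,
        "index_map": [list(d) for d in matrix.index_map],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    index_map = [
        FeatureDescriptor(k, c1, c2 if c2 is not None else None, b)
        for k, c1, c2, b in meta["index_map"]
    ]
    return FeatureMatrix(values, index_map, meta["channel_labels"], meta["band_names"])


def save_feature_tensor(tensor: FeatureTensor, path: str | Path) -> None:
    path = Path(path)
    np.save(path, tensor.values)
    sidecar = {"channel_labels": tensor.channel_labels, "band_names": tensor.band_names}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_feature_tensor(path: str | Path) -> FeatureTensor:
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return FeatureTensor(values, meta["channel_labels"], meta["band_names"])
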