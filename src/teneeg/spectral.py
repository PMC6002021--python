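"""Per-trial spectra and the PSD / PWD / PHD feature families.

Every trial is transformed with a single unwindowed full-length DFT (the raw
periodogram: ``p(f_k) = |x(f_k)|^2 / T``) and its phase spectrum
``h(f_k) = angle x(f_k)``.  Three feature families are then computed at the
five canonical EEG bands (delta 1-4, theta 4-8, alpha 8-12, beta 12-30,
gamma 30-45 Hz):

* ``PSD(m, f)`` -- periodogram averaged over the band's bins, per channel;
* ``PWD(m1, m2, f) = PSD(m1, f) - PSD(m2, f)`` -- band-power difference of a
  channel pair;
* ``PHD(m1, m2, f)`` -- mean phase difference of a channel pair over the
  band's bins, each per-bin difference wrapped to ``(-pi, pi]``.

Raw angle subtraction is ambiguous modulo 2*pi; wrapping per bin keeps the
feature bounded and exactly antisymmetric.  ``wrap_phase=False`` reproduces
the literal unwrapped subtraction.

Trials may have different lengths: each trial gets its own frequency grid
``f_k = k * rate / T_n`` and band averaging makes the features comparable
across trials.  Band membership is the half-open interval ``[low, high)``
over the positive-frequency bins ``k = 1 .. floor(T/2)`` so touching band
edges are counted exactly once and DC is never included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import DegenerateDataError, EpochSet, FormatError, ParameterError

# ---------------------------------------------------------------------------
# Frequency bands
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Band:
    """A named frequency band ``[low_hz, high_hz)``."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ParameterError(
                f"band {self.name!r}: need 0 < low < high, got "
                f"({self.low_hz}, {self.high_hz})"
            )


DEFAULT_BANDS: tuple[Band, ...] = (
    Band("delta", 1.0, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 12.0),
    Band("beta", 12.0, 30.0),
    Band("gamma", 30.0, 45.0),
)


def validate_bands(bands: Sequence[Band]) -> tuple[Band, ...]:
    """Check that bands are ordered and non-overlapping."""
    bands = tuple(bands)
    if not bands:
        raise ParameterError("at least one band is required")
    for a, b in zip(bands, bands[1:]):
        if b.low_hz < a.high_hz:
            raise ParameterError(
                f"bands {a.name!r} and {b.name!r} overlap or are out of order"
            )
    return bands


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------


@dataclass
class SpectrumSet:
    """Full-trial DFT products for every trial and channel.

    ``coefficients[n]`` is the complex ``(M, T_n)`` DFT array of trial ``n``;
    ``power[n]`` the periodogram ``|x|^2 / T_n``; ``phase[n]`` the angles in
    ``(-pi, pi]``; ``frequencies[n]`` the grid ``k * rate / T_n`` for
    ``k = 0 .. T_n - 1``.
    """

    coefficients: list[np.ndarray]
    power: list[np.ndarray]
    phase: list[np.ndarray]
    frequencies: list[np.ndarray]
    channel_labels: list[str]
    sampling_rate: float

    @property
    def n_trials(self) -> int:
        return len(self.coefficients)

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)


def compute_spectrum(epochs: EpochSet) -> SpectrumSet:
    """Unwindowed full-trial DFT, periodogram and phase per trial/channel."""
    coeffs, power, phase, freqs = [], [], [], []
    for n, trial in enumerate(epochs.trials):
        t_n = trial.shape[1]
        if t_n < 2:
            raise FormatError(f"trial {n}: too short for a spectrum ({t_n} samples)")
        x = np.fft.fft(trial, axis=-1)
        p = (np.abs(x) ** 2) / t_n
        h = np.angle(x)
        # np.angle returns [-pi, pi]; fold the closed lower edge onto +pi
        h = np.where(h <= -np.pi, h + 2 * np.pi, h)
        coeffs.append(x)
        power.append(p)
        phase.append(h)
        freqs.append(np.arange(t_n) * (epochs.sampling_rate / t_n))
    return SpectrumSet(
        coeffs, power, phase, freqs, list(epochs.channel_labels), epochs.sampling_rate
    )


def band_bin_indices(frequencies: np.ndarray, band: Band) -> np.ndarray:
    """Positive-frequency bin indices whose frequency lies in [low, high)."""
    t = frequencies.size
    k = np.arange(1, t // 2 + 1)
    f = frequencies[k]
    return k[(f >= band.low_hz) & (f < band.high_hz)]


def wrap_phase(delta: np.ndarray) -> np.ndarray:
    """Wrap phase differences into ``(-pi, pi]``."""
    w = np.mod(delta, 2 * np.pi)
    return np.where(w > np.pi, w - 2 * np.pi, w)


# ---------------------------------------------------------------------------
# Feature families
# ---------------------------------------------------------------------------


@dataclass
class FeatureSet:
    """Band-level features for N trials: PSD (N,M,F), PWD/PHD (N,M,M,F).

    PWD and PHD are exactly antisymmetric in the channel indices and zero on
    the diagonal.  Any of the three blocks may be ``None`` until the
    corresponding compute step has run.
    """

    psd: np.ndarray | None
    pwd: np.ndarray | None
    phd: np.ndarray | None
    channel_labels: list[str]
    band_names: list[str]

    @property
    def n_trials(self) -> int:
        for block in (self.psd, self.pwd, self.phd):
            if block is not None:
                return block.shape[0]
        return 0

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    @property
    def n_bands(self) -> int:
        return len(self.band_names)


def _band_indices_checked(spectra: SpectrumSet, bands: Sequence[Band]):
    per_trial = []
    for n, freqs in enumerate(spectra.frequencies):
        idx = []
        for band in bands:
            k = band_bin_indices(freqs, band)
            if k.size == 0:
                raise DegenerateDataError(
                    f"band {band.name!r} has no frequency bins on trial {n} "
                    f"(T={freqs.size})"
                )
            idx.append(k)
        per_trial.append(idx)
    return per_trial


def band_average_psd(
    spectra: SpectrumSet, bands: Sequence[Band] = DEFAULT_BANDS
) -> FeatureSet:
    """Average the periodogram over each band's bins: PSD(m, f)."""
    bands = validate_bands(bands)
    indices = _band_indices_checked(spectra, bands)
    n, m, f = spectra.n_trials, spectra.n_channels, len(bands)
    psd = np.empty((n, m, f))
    for i, (p, idx) in enumerate(zip(spectra.power, indices)):
        for j, k in enumerate(idx):
            psd[i, :, j] = p[:, k].mean(axis=1)
    return FeatureSet(psd, None, None, list(spectra.channel_labels), [b.name for b in bands])


def compute_pwd(features: FeatureSet) -> FeatureSet:
    """Pairwise band-power differences PWD(m1, m2, f) = PSD(m1,f) - PSD(m2,f)."""
    if features.psd is None:
        raise ParameterError("compute_pwd needs the PSD block; run band_average_psd")
    psd = features.psd
    pwd = psd[:, :, None, :] - psd[:, None, :, :]
    return FeatureSet(psd, pwd, features.phd, features.channel_labels, features.band_names)


def compute_phd(
    spectra: SpectrumSet,
    bands: Sequence[Band] = DEFAULT_BANDS,
    wrap: bool = True,
) -> FeatureSet:
    """Mean pairwise phase difference per band, per-bin wrapped by default."""
    bands = validate_bands(bands)
    indices = _band_indices_checked(spectra, bands)
    n, m, f = spectra.n_trials, spectra.n_channels, len(bands)
    phd = np.empty((n, m, m, f))
    for i, (h, idx) in enumerate(zip(spectra.phase, indices)):
        for j, k in enumerate(idx):
            hb = h[:, k]  # (M, |D_f|)
            diff = hb[:, None, :] - hb[None, :, :]
            if wrap:
                diff = wrap_phase(diff)
            phd[i, :, :, j] = diff.mean(axis=2)
    return FeatureSet(
        None, None, phd, list(spectra.channel_labels), [b.name for b in bands]
    )


def extract_features(
    epochs: EpochSet,
    bands: Sequence[Band] = DEFAULT_BANDS,
    wrap_phase_differences: bool = True,
) -> FeatureSet:
    """Full feature extraction: spectrum -> PSD -> PWD, PHD in one call."""
    spectra = compute_spectrum(epochs)
    feats = compute_pwd(band_average_psd(spectra, bands))
    phd = compute_phd(spectra, bands, wrap=wrap_phase_differences)
    feats.phd = phd.phd
    return feats


def features_to_frame(features: FeatureSet) -> pd.DataFrame:
    """Long-format dump: trial, kind, channel1, channel2, band, value."""
    rows = []
    labels = features.channel_labels
    for n in range(features.n_trials):
        for fi, band in enumerate(features.band_names):
            if features.psd is not None:
                for m, lab in enumerate(labels):
                    rows.append((n, "PSD", lab, "", band, features.psd[n, m, fi]))
            if features.pwd is not None:
                for m1 in range(len(labels)):
                    for m2 in range(m1):
                        rows.append(
                            (n, "PWD", labels[m1], labels[m2], band,
                             features.pwd[n, m1, m2, fi])
                        )
            if features.phd is not None:
                for m1 in range(len(labels)):
                    for m2 in range(m1 + 1, len(labels)):
                        rows.append(
                            (n, "PHD", labels[m1], labels[m2], band,
                             features.phd[n, m1, m2, fi])
                        )
    return pd.DataFrame(
        rows, columns=["trial", "kind", "channel1", "channel2", "band", "value"]
    )
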