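"""Synthetic EEG-like epochs and coupled ratings with known ground truth.

The generator emulates the structure of a per-subject speech-listening
recording: 44 ragged trials of 13-22 s at 256 Hz, each channel a sum of one
sinusoid per canonical band (random in-band frequency per trial, per-channel
amplitudes, stable inter-channel phase offsets plus per-trial jitter) over
white Gaussian sensor noise.  Ratings are built from a known coefficient
tensor: the centered feature-tensor slice of each trial is contracted with a
ground-truth tensor per rating scale, standardized, noised and affinely
rescaled into the printed ranges (MOS 1-5, VAL/ARL 1-9) -- so every pipeline
stage can be tested against the truth without any real recordings.

Everything is driven by a single integer seed; the same seed reproduces the
epoch sets and ratings bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import SCALES, RATING_BOUNDS, EpochSet, ParameterError, RatingsTable
from .spectral import DEFAULT_BANDS, Band, extract_features, validate_bands
from .feature_tensor import FeatureTensor, build_feature_tensor
from .contribution_viz import STANDARD_64_LABELS

DEFAULT_BAND_AMPLITUDES: dict[str, tuple[float, float]] = {
    # rough resting-EEG ordering: alpha prominent, gamma weak (arbitrary units)
    "delta": (1.0, 2.0),
    "theta": (0.5, 1.5),
    "alpha": (1.0, 3.0),
    "beta": (0.3, 1.0),
    "gamma": (0.1, 0.5),
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic recording.

    ``phase_lags`` maps ordered label pairs to a phase lead in radians
    (channel1 leads channel2); channels not covered get a random stable
    offset when the map is ``None`` and zero otherwise.  ``amplitude_rank``
    gives band amplitudes a low-rank spatial structure through shared source
    profiles (see :func:`draw_source_profiles`).  ``noise_sd`` is the
    sensor-noise standard deviation in signal units; ``rating_noise_sd`` is
    added to the standardized (unit-variance) latent rating signal, so the
    rating SNR is ``1 / rating_noise_sd**2``.
    """

    n_subjects: int = 1
    n_trials: int = 44
    n_channels: int = 16
    sampling_rate: float = 256.0
    duration_range: tuple[float, float] = (13.0, 22.0)
    band_amplitudes: dict = field(default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES))
    phase_lags: dict | None = None
    amplitude_rank: int | None = 3
    phase_jitter_sd: float = 0.3
    noise_sd: float = 1.0
    rating_noise_sd: float = 0.5
    bands: tuple[Band, ...] = DEFAULT_BANDS
    fixed_band_freqs: dict | None = None
    channel_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_trials, self.n_channels) < 1:
            raise ParameterError("counts must be positive")
        lo, hi = self.duration_range
        if not (0 < lo <= hi):
            raise ParameterError(f"bad duration range {self.duration_range}")
        if self.n_channels > len(STANDARD_64_LABELS) and self.channel_labels is None:
            raise ParameterError(
                f"at most {len(STANDARD_64_LABELS)} channels without explicit labels"
            )
        self.bands = validate_bands(self.bands)

    @property
    def labels(self) -> list[str]:
        if self.channel_labels is not None:
            if len(self.channel_labels) != self.n_channels:
                raise ParameterError("channel_labels length != n_channels")
            return list(self.channel_labels)
        return list(STANDARD_64_LABELS[: self.n_channels])


def _channel_offsets(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    labels = config.labels
    index = {lab: i for i, lab in enumerate(labels)}
    if config.phase_lags is None:
        return rng.uniform(-np.pi, np.pi, size=len(labels))
    offsets = np.zeros(len(labels))
    for (a, b), lag in config.phase_lags.items():
        if a not in index or b not in index:
            raise ParameterError(f"phase lag references unknown channel in ({a}, {b})")
        offsets[index[a]] = offsets[index[b]] + lag
    return offsets


def draw_source_profiles(
    config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray | None:
    """Fixed non-negative spatial mixing profiles (M x amplitude_rank).

    A few latent sources project smoothly into all channels, the way cortical
    generators spread across the scalp; the same spatial profiles drive every
    band, so the amplitude covariance is separable across the channel and
    band modes.  ``amplitude_rank=None`` disables the structure (independent
    channel amplitudes).
    """
    if not config.amplitude_rank:
        return None
    return np.abs(rng.standard_normal((len(config.labels), config.amplitude_rank)))


def generate_epochs(
    config: SimulationConfig,
    seed: int | np.random.Generator,
    subject_id: str = "s01",
    source_profiles: np.ndarray | None = None,
) -> EpochSet:
    """Generate one subject's EpochSet of band-limited oscillations + noise."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = config.sampling_rate
    labels = config.labels
    m = len(labels)
    offsets = _channel_offsets(config, rng)
    nyq = fs / 2
    if source_profiles is None:
        source_profiles = draw_source_profiles(config, rng)
    mixing = source_profiles
    trials = []
    for _ in range(config.n_trials):
        dur = rng.uniform(*config.duration_range)
        t_n = int(round(dur * fs))
        t = np.arange(t_n) / fs
        x = np.zeros((m, t_n))
        for band in config.bands:
            lo, hi = config.band_amplitudes.get(band.name, (0.0, 0.0))
            if hi <= 0:
                continue
            if config.fixed_band_freqs and band.name in config.fixed_band_freqs:
                freq = float(config.fixed_band_freqs[band.name])
            else:
                freq = rng.uniform(band.low_hz, min(band.high_hz, 0.9 * nyq))
            phi = rng.uniform(-np.pi, np.pi)
            if mixing is not None:
                raw = mixing @ rng.uniform(0.0, 1.0, size=mixing.shape[1])
                span = raw.max() - raw.min()
                if span > 0:
                    amps = lo + (hi - lo) * (raw - raw.min()) / span
                else:
                    amps = np.full(m, (lo + hi) / 2)
            else:
                amps = rng.uniform(lo, hi, size=m)
            jitter = (
                rng.normal(0.0, config.phase_jitter_sd, size=m)
                if config.phase_jitter_sd > 0
                else np.zeros(m)
            )
            phases = phi + offsets + jitter
            x += amps[:, None] * np.sin(2 * np.pi * freq * t[None, :] + phases[:, None])
        if config.noise_sd > 0:
            x += rng.normal(0.0, config.noise_sd, size=(m, t_n))
        trials.append(x)
    return EpochSet(subject_id, trials, labels, fs)


# ---------------------------------------------------------------------------
# Ground-truth coefficient tensors
# ---------------------------------------------------------------------------


def make_truth(
    kind: str,
    config: SimulationConfig,
    seed: int | np.random.Generator,
    *,
    n_nonzero: int = 3,
    rank: int = 2,
    cells: list[tuple[int, int, int]] | None = None,
    band_indices: list[int] | None = None,
    pairwise_only: bool = False,
    spatial_basis: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Draw a coefficient tensor (M, M, F) per rating scale.

    ``sparse``: ``n_nonzero`` random cells (or the explicit ``cells``) with
    random-signed weights.  ``low_rank``: a sum of ``rank`` outer products of
    random unit channel/band factors, antisymmetrized over the off-diagonal
    (pairwise) region.  ``band_indices`` restricts support to those bands and
    ``pairwise_only`` zeroes the diagonal (PSD) cells.  ``spatial_basis``
    (M x K) draws the channel factors inside that subspace -- used to place
    the rating-relevant spatial patterns in the span of the simulated source
    projections, as when the predictive cortical activity comes from the
    same generators that dominate the recording.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m, f = config.n_channels, len(config.bands)

    def channel_factor() -> np.ndarray:
        if spatial_basis is not None:
            u = spatial_basis @ rng.standard_normal(spatial_basis.shape[1])
        else:
            u = rng.standard_normal(m)
        return u / np.linalg.norm(u)
    truth = {}
    for scale in SCALES:
        if kind == "sparse":
            w = np.zeros((m, m, f))
            if cells is None:
                pool = [
                    (a, b, c)
                    for a in range(m)
                    for b in range(m)
                    for c in (band_indices if band_indices is not None else range(f))
                    if not (pairwise_only and a == b)
                ]
                chosen = [pool[i] for i in rng.choice(len(pool), n_nonzero, replace=False)]
            else:
                chosen = cells
            for a, b, c in chosen:
                w[a, b, c] = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5)
        elif kind == "low_rank":
            w = np.zeros((m, m, f))
            for _ in range(rank):
                u = channel_factor()
                v = channel_factor()
                wb = np.zeros(f)
                idx = band_indices if band_indices is not None else list(range(f))
                wb[idx] = rng.standard_normal(len(idx))
                wb /= np.linalg.norm(wb)
                w += np.einsum("a,b,c->abc", u, v, wb)
            # off-diagonal cells are the pairwise (PWD/PHD) features; impose the
            # antisymmetry those features carry, keep the PSD diagonal as drawn
            off = ~np.eye(m, dtype=bool)
            anti = 0.5 * (w - np.transpose(w, (1, 0, 2)))
            w[off, :] = anti[off, :]
            if pairwise_only:
                w[np.eye(m, dtype=bool), :] = 0.0
        else:
            raise ParameterError(f"unknown truth kind {kind!r}")
        truth[scale] = w
    return truth


@dataclass
class GroundTruth:
    """Everything needed to assert against the generator downstream."""

    truth: dict                       # scale -> (M, M, F)
    latent: dict                      # scale -> standardized noise-free signal (N,)
    noise: dict                       # scale -> noise draws (N,)
    scaling: dict                     # scale -> (a, b): rating = a * y + b
    noise_sd: float


def generate_ratings(
    epochs: EpochSet,
    truth: dict[str, np.ndarray],
    noise_sd: float,
    seed: int | np.random.Generator,
    bands: tuple[Band, ...] = DEFAULT_BANDS,
) -> tuple[RatingsTable, GroundTruth]:
    """Ratings linearly coupled to the centered feature tensor plus noise.

    The latent signal ``s_n = <Xc_n, W_scale>`` is standardized to unit
    variance (when non-constant) before noise is added, then affinely mapped
    into the scale's printed range.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tensor = build_feature_tensor(extract_features(epochs, bands))
    return ratings_from_tensor(tensor, epochs.subject_id, truth, noise_sd, rng)


def ratings_from_tensor(
    tensor: FeatureTensor,
    subject_id: str,
    truth: dict[str, np.ndarray],
    noise_sd: float,
    rng: np.random.Generator,
) -> tuple[RatingsTable, GroundTruth]:
    values = tensor.values
    xc = values - values.mean(axis=0)
    n = values.shape[0]
    latent, noise, scaling = {}, {}, {}
    columns = {}
    for scale in SCALES:
        w = np.asarray(truth[scale], dtype=float)
        if w.shape != values.shape[1:]:
            raise ParameterError(
                f"truth tensor {w.shape} does not match features {values.shape[1:]}"
            )
        s = np.tensordot(xc, w, axes=3)
        sd = s.std()
        if sd > 0:
            s = (s - s.mean()) / sd
        eps = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
        y = s + eps
        lo, hi = RATING_BOUNDS[scale]
        span = y.max() - y.min()
        if span > 0:
            a = (hi - lo) / span
            b = lo - a * y.min()
        else:
            a, b = 0.0, (lo + hi) / 2
        columns[scale] = np.clip(a * y + b, lo, hi)  # guard fp rounding at the edges
        latent[scale] = s
        noise[scale] = eps
        scaling[scale] = (a, b)
    frame = pd.DataFrame(
        {
            "subject": subject_id,
            "trial": np.arange(n),
            "MOS": columns["MOS"],
            "VAL": columns["VAL"],
            "ARL": columns["ARL"],
        }
    )
    return RatingsTable(frame), GroundTruth(truth, latent, noise, scaling, noise_sd)


@dataclass
class SimulatedDataset:
    epoch_sets: list[EpochSet]
    ratings: RatingsTable
    truth: dict
    ground_truths: dict               # subject_id -> GroundTruth


def simulate_dataset(
    config: SimulationConfig,
    seed: int,
    truth_kind: str = "low_rank",
    align_truth: bool = True,
    **truth_kwargs,
) -> SimulatedDataset:
    """Full simulate step: epochs + coupled ratings for every subject.

    With ``align_truth`` (default) a low-rank truth draws its spatial factors
    inside the span of the simulated source profiles, so the rating-relevant
    patterns live where the data actually vary.  The truth tensor is shared
    across subjects; each subject gets its own source profiles and epochs.
    """
    rng = np.random.default_rng(seed)
    profiles = draw_source_profiles(config, rng)
    basis = None
    if align_truth and truth_kind == "low_rank" and profiles is not None:
        basis, _ = np.linalg.qr(profiles)
    truth = make_truth(truth_kind, config, rng, spatial_basis=basis, **truth_kwargs)
    epoch_sets, frames, gts = [], [], {}
    for s in range(config.n_subjects):
        sid = f"s{s + 1:02d}"
        if s > 0:  # first subject reuses the profiles the truth was aligned to
            profiles = draw_source_profiles(config, rng)
        epochs = generate_epochs(config, rng, subject_id=sid, source_profiles=profiles)
        ratings, gt = generate_ratings(
            epochs, truth, config.rating_noise_sd, rng, config.bands
        )
        epoch_sets.append(epochs)
        frames.append(ratings.frame)
        gts[sid] = gt
    table = RatingsTable(pd.concat(frames, ignore_index=True))
    return SimulatedDataset(epoch_sets, table, truth, gts)
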