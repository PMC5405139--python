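"""Time-varying iPLV connectivity with surrogate-based statistical masking.

Multichannel signals are band-pass filtered (3rd-order zero-phase
Butterworth), converted to instantaneous phases via the Hilbert transform,
and pairwise phase coupling is quantified inside sliding windows by the
phase-locking value

    PLV  = | (1/T) Σ_t exp(i(φ_k(t) − φ_l(t))) |

and its imaginary part

    iPLV = | Im( (1/T) Σ_t exp(i(φ_k(t) − φ_l(t))) ) |

which discards zero-lag (volume-conduction-like) coupling.  Statistical
masking compares each observed windowed iPLV against an ensemble of
time-rotated surrogates of the whole recording (single random cut inside a
central window, segments exchanged) with one-sided p-values and
Benjamini–Hochberg FDR across sensor pairs per band and window; values that
do not survive are set to 0 in the (band × window × node × node) tensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BandSpec",
    "DEFAULT_BANDS",
    "SlidingWindowSpec",
    "TVGraphTensor",
    "bandpass",
    "analytic_phase",
    "plv_iplv",
    "sliding_iplv",
    "make_surrogate",
    "surrogate_pvalues",
    "fdr_bh",
    "build_tv_tensor",
]


class SignalError(ValueError):
    """Raised on invalid signals, bands or window specifications."""


@dataclass(frozen=True)
class BandSpec:
    """A frequency band with its centre frequency (mean of the edges)."""

    name: str
    low: float
    high: float

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)


#: the eight canonical electrophysiological rhythms
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 0.5, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha1", 8.0, 10.0),
    BandSpec("alpha2", 10.0, 13.0),
    BandSpec("beta1", 13.0, 20.0),
    BandSpec("beta2", 20.0, 30.0),
    BandSpec("gamma1", 30.0, 48.0),
    BandSpec("gamma2", 52.0, 70.0),
)


@dataclass
class SlidingWindowSpec:
    """Sliding-window geometry: width in cycles of the band centre frequency."""

    cycles: int = 10
    step_ms: float = 20.0

    def window_samples(self, fs: float, band: BandSpec) -> int:
        return int(round(self.cycles * fs / band.center))

    def step_samples(self, fs: float) -> int:
        return max(1, int(round(self.step_ms * fs / 1000.0)))

    def n_windows(self, T: int, fs: float, band: BandSpec) -> int:
        w = self.window_samples(fs, band)
        if T < w:
            return 0
        return (T - w) // self.step_samples(fs) + 1


@dataclass
class TVGraphTensor:
    """Masked time-varying iPLV tensor (band × window × node × node).

    Window counts differ per band (the window width is band-dependent while
    the step is fixed), so slices past each band's own ``n_windows`` are
    NaN-padded.  Surviving entries are the unmodified iPLV values; 0 marks a
    non-significant estimate.
    """

    values: np.ndarray
    window_times: np.ndarray
    n_windows: np.ndarray
    bands: tuple[BandSpec, ...]
    fs: float

    @property
    def n_nodes(self) -> int:
        return self.values.shape[-1]

    def band_slices(self, b: int) -> np.ndarray:
        """The valid (window × node × node) block of band ``b``."""
        return self.values[b, : self.n_windows[b]]


def bandpass(signals: np.ndarray, band: BandSpec, fs: float) -> np.ndarray:
    """Zero-phase 3rd-order Butterworth band-pass along the first axis."""
    if fs <= 2.0 * band.high:
        raise SignalError(
            f"band {band.name} ({band.high} Hz) exceeds Nyquist for fs={fs}"
        )
    sos = butter(3, [band.low, band.high], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(signals, dtype=float), axis=0)


def analytic_phase(filtered: np.ndarray) -> np.ndarray:
    """Instantaneous phase of the analytic signal, in (−π, π]."""
    return np.angle(hilbert(np.asarray(filtered, dtype=float), axis=0))


def plv_iplv(
    phase_k: np.ndarray, phase_l: np.ndarray, window: slice | None = None
) -> tuple[float, float]:
    """PLV and iPLV of one channel pair over one window.

    Both lie in [0, 1] and iPLV ≤ PLV; a constant zero or π phase lag gives
    iPLV = 0 while a constant π/2 lag gives iPLV = 1.
    """
    pk = np.asarray(phase_k, float)
    pl = np.asarray(phase_l, float)
    if pk.shape != pl.shape:
        raise SignalError("phase series have different lengths")
    if window is not None:
        pk, pl = pk[window], pl[window]
    if pk.size == 0:
        raise SignalError("empty window")
    z = np.exp(1j * (pk - pl)).mean()
    return float(np.abs(z)), float(np.abs(z.imag))


def _windowed_mean_phasor(
    phases: np.ndarray,
    window_samples: int,
    step_samples: int,
    phases_other: np.ndarray | None = None,
) -> np.ndarray:
    """Mean coupling phasor per (window, pair) for all channel pairs.

    Uses a cumulative sum over ``exp(i(φ_k − φ_l))`` so the cost is linear in
    the series length.  Returns (n_windows, N, N) complex with zero diagonal.
    ``phases_other`` substitutes the second channel of every pair (used to
    pit original against surrogate series).
    """
    T, n = phases.shape
    if T < window_samples:
        raise SignalError(
            f"signal of {T} samples shorter than window of {window_samples}"
        )
    z = np.exp(1j * phases)  # Δφ phasor = z_k * conj(z_l)
    z2 = z if phases_other is None else np.exp(1j * phases_other)
    n_win = (T - window_samples) // step_samples + 1
    starts = np.arange(n_win) * step_samples
    cs = np.concatenate(
        [np.zeros((1, n, n), complex), np.cumsum(z[:, :, None] * z2.conj()[:, None, :], axis=0)]
    )
    sums = cs[starts + window_samples] - cs[starts]
    out = sums / window_samples
    idx = np.arange(n)
    out[:, idx, idx] = 0.0
    return out


def sliding_iplv(
    signals: np.ndarray,
    band: BandSpec,
    fs: float,
    spec: SlidingWindowSpec | None = None,
    *,
    phases: np.ndarray | None = None,
) -> np.ndarray:
    """Windowed iPLV matrices for all channel pairs of a recording.

    ``signals`` is (samples × channels); band-pass filtering and phase
    extraction are applied unless precomputed ``phases`` are given.  Returns
    an (n_windows × N × N) array of symmetric zero-diagonal iPLV matrices,
    with ``n_windows = (T − window)//step + 1``.
    """
    spec = spec or SlidingWindowSpec()
    w = spec.window_samples(fs, band)
    s = spec.step_samples(fs)
    T = (signals if phases is None else phases).shape[0]
    if T < w:
        raise SignalError(f"signal of {T} samples shorter than window of {w}")
    if phases is None:
        phases = analytic_phase(bandpass(signals, band, fs))
    phasors = _windowed_mean_phasor(phases, w, s)
    return np.abs(phasors.imag)


def make_surrogate(
    signal: np.ndarray,
    cut_window: tuple[float, float],
    rng: np.random.Generator | int,
    fs: float = 1.0,
) -> np.ndarray:
    """Time-rotation surrogate: cut once at a random point, swap the halves.

    The cut index is drawn uniformly inside ``cut_window`` (seconds, relative
    to the recording start); the output is ``[x[cut:], x[:cut]]`` — the same
    multiset of samples with phase dynamics minimally distorted.
    """
    x = np.asarray(signal, dtype=float)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lo = int(round(cut_window[0] * fs))
    hi = int(round(cut_window[1] * fs))
    if not (0 <= lo < hi <= x.shape[0]):
        raise SignalError(f"degenerate cut window {cut_window} for {x.shape[0]} samples")
    cut = int(rng.integers(lo, hi))
    return np.concatenate([x[cut:], x[:cut]], axis=0)


def surrogate_pvalues(observed: np.ndarray, surrogate: np.ndarray) -> np.ndarray:
    """One-sided permutation p-values with the (+1)/(S+1) correction.

    ``surrogate`` stacks the ensemble along its first axis; broadcasting
    handles scalar or array ``observed``.
    """
    surrogate = np.asarray(surrogate, dtype=float)
    if surrogate.shape[0] == 0:
        raise SignalError("empty surrogate ensemble")
    n = surrogate.shape[0]
    count = (surrogate >= np.asarray(observed, float)[None, ...]).sum(axis=0)
    return (1.0 + count) / (1.0 + n)


def fdr_bh(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection mask at FDR level ``q``."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(p.shape, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise SignalError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise SignalError(f"q must be in (0, 1), got {q}")
    reject, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)


def build_tv_tensor(
    signals: np.ndarray,
    fs: float,
    bands: Sequence[BandSpec] = DEFAULT_BANDS,
    spec: SlidingWindowSpec | None = None,
    *,
    n_surrogates: int = 1000,
    q: float = 0.01,
    cut_window: tuple[float, float] | None = None,
    seed: int | np.random.Generator = 0,
    fdr_pool_windows: bool = False,
) -> TVGraphTensor:
    """Statistically masked time-varying iPLV tensor of a recording.

    Per band: windowed iPLV for every sensor pair; an ensemble of
    ``n_surrogates`` time-rotation surrogates of the whole recording (each
    channel cut inside ``cut_window``, default the middle 10 s) is windowed
    identically, pairing each original channel with the rotated partner so
    the surrogate pair is misaligned by at least the cut window's lower
    edge; one-sided p-values per (window, pair) are FDR-masked
    (Benjamini–Hochberg) across pairs per window (or pooled over windows) at
    level ``q``.  Non-significant entries are set to 0.
    """
    X = np.asarray(signals, dtype=float)
    if X.ndim != 2:
        raise SignalError("signals must be (samples x channels)")
    T, n_ch = X.shape
    spec = spec or SlidingWindowSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration = T / fs
    if cut_window is None:
        mid = duration / 2.0
        cut_window = (max(0.0, mid - 5.0), min(duration, mid + 5.0))

    bands = tuple(bands)
    n_wins = np.array([spec.n_windows(T, fs, b) for b in bands])
    if np.any(n_wins < 1):
        bad = bands[int(np.argmin(n_wins))]
        raise SignalError(
            f"recording too short for band {bad.name}: needs at least "
            f"{spec.window_samples(fs, bad)} samples, got {T}"
        )
    max_win = int(n_wins.max())
    values = np.full((len(bands), max_win, n_ch, n_ch), np.nan)
    times = np.full((len(bands), max_win), np.nan)
    iu, ju = np.triu_indices(n_ch, k=1)

    # one set of rotated raw recordings shared by all bands
    cuts = rng.integers(
        int(round(cut_window[0] * fs)),
        int(round(cut_window[1] * fs)),
        size=(n_surrogates, n_ch),
    )
    for b, band in enumerate(bands):
        w = spec.window_samples(fs, band)
        s = spec.step_samples(fs)
        nw = int(n_wins[b])
        phases = analytic_phase(bandpass(X, band, fs))
        obs = np.abs(_windowed_mean_phasor(phases, w, s).imag)[:, iu, ju]

        count = np.zeros_like(obs, dtype=np.int64)
        for k in range(n_surrogates):
            rot = np.empty_like(X)
            for c in range(n_ch):
                cut = int(cuts[k, c])
                rot[:, c] = np.concatenate([X[cut:, c], X[:cut, c]])
            sp = analytic_phase(bandpass(rot, band, fs))
            # original first channel against the rotated partner: the central
            # cut window guarantees the pair is misaligned by at least its
            # lower edge, well beyond the band's phase coherence time
            surr = np.abs(_windowed_mean_phasor(phases, w, s, sp).imag)[:, iu, ju]
            count += surr >= obs
        pvals = (1.0 + count) / (1.0 + n_surrogates)

        if fdr_pool_windows:
            mask = fdr_bh(pvals, q)
        else:
            mask = np.stack([fdr_bh(pvals[t], q) for t in range(nw)])
        slab = np.zeros((nw, n_ch, n_ch))
        kept = np.where(mask, obs, 0.0)
        slab[:, iu, ju] = kept
        slab[:, ju, iu] = kept
        values[b, :nw] = slab
        starts = np.arange(nw) * s
        times[b, :nw] = (starts + w / 2.0) / fs
    return TVGraphTensor(values, times, n_wins, bands, fs)
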