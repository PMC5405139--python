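"""Seeded synthetic-data generators for every layer of the toolkit.

These generators produce inputs with the statistical structure the method
assumes, so the whole pipeline is exercisable without any recorded data:

- planted-backbone weighted graphs (a union of edge-disjoint spanning trees
  with high weights buried in weak noise edges) for the filtering schemes;
- phase-coupled narrowband oscillator channels (coupling expressed purely in
  phase, which is what iPLV measures) for the dynamic layer;
- multi-subject cohorts of AR(2) network-metric time series with
  subject-specific resonance signatures for fingerprinting;
- noisy multi-scan replicates of a base graph for reliability analysis.

All generators are pure functions of (spec, seed): identical inputs give
bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .dynamics import BandSpec, bandpass
from .graph import ConnectivityMatrix, kruskal_mst, validate_weights

__all__ = [
    "SynthGraphSpec",
    "SynthSignalSpec",
    "CohortSpec",
    "gen_backbone_graph",
    "gen_coupled_signals",
    "gen_cohort_nmts",
    "gen_multiscan_graphs",
]


@dataclass
class SynthGraphSpec:
    """Planted-backbone graph: m_true edge-disjoint spanning trees + noise.

    Backbone edges draw weights from ``hi`` and all remaining pairs from
    ``lo`` (``hi`` strictly above ``lo``); Gaussian jitter of scale
    ``jitter`` is added before clipping to [0, 1] and max-normalizing.
    """

    n_nodes: int = 32
    m_true: int = 3
    hi: tuple[float, float] = (0.7, 1.0)
    lo: tuple[float, float] = (0.05, 0.3)
    jitter: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hi[0] <= self.lo[1]:
            raise ValueError("backbone weight range must lie strictly above noise range")
        e = self.n_nodes * (self.n_nodes - 1) // 2
        if self.m_true * (self.n_nodes - 1) > e:
            raise ValueError("backbone trees need more edges than the graph has")


def gen_backbone_graph(spec: SynthGraphSpec) -> tuple[ConnectivityMatrix, np.ndarray]:
    """Generate a planted-backbone graph and its ground-truth edge mask.

    The backbone is the union of ``m_true`` random edge-disjoint spanning
    trees (successive MSTs of random distances with used edges removed).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    D = rng.uniform(1.0, 2.0, size=(n, n))
    D = np.triu(D, k=1)
    D = D + D.T
    mask = np.zeros((n, n), dtype=bool)
    for _ in range(spec.m_true):
        tree = kruskal_mst(D)
        for u, v in tree.edges:
            mask[u, v] = mask[v, u] = True
            D[u, v] = D[v, u] = np.inf

    W = rng.uniform(spec.lo[0], spec.lo[1], size=(n, n))
    hi_draw = rng.uniform(spec.hi[0], spec.hi[1], size=(n, n))
    W[mask] = hi_draw[mask]
    W += rng.normal(0.0, spec.jitter, size=(n, n))
    W = np.triu(W, k=1)
    W = W + W.T
    W = np.clip(W, 0.0, 1.0)
    np.fill_diagonal(W, 0.0)
    mx = W.max()
    if mx > 0:
        W = W / mx
    return ConnectivityMatrix(validate_weights(W)), mask


@dataclass
class Coupling:
    """One directed phase-coupling: channel ``src`` drives ``dst``."""

    src: int
    dst: int
    phase_lag: float = np.pi / 2
    strength: float = 1.0
    onset: float = 0.0
    offset: float = np.inf

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("coupling strength must lie in [0, 1]")


@dataclass
class SynthSignalSpec:
    """Phase-coupled narrowband oscillator channels."""

    fs: float = 128.0
    duration: float = 20.0
    n_channels: int = 4
    band: BandSpec = field(default_factory=lambda: BandSpec("alpha", 8.0, 13.0))
    couplings: list[Coupling] = field(default_factory=list)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 2.0 * self.band.high:
            raise ValueError("sampling rate must exceed twice the band's upper edge")
        dsts = [c.dst for c in self.couplings]
        if len(dsts) != len(set(dsts)):
            raise ValueError("contradictory couplings: a channel is driven twice")


def gen_coupled_signals(spec: SynthSignalSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate (samples × channels) signals plus the coupling ground truth.

    Channels are narrowband-filtered white noise.  A coupled destination
    channel is, during [onset, offset], a mixture of the source channel
    shifted by the prescribed phase lag (via its analytic signal, so the lag
    is exact in phase) and its own independent oscillator, weighted by the
    coupling strength; white observation noise is added everywhere.

    Returns ``(signals, truth)`` where ``truth[k, l]`` is the coupling
    strength between channels k and l (symmetric, 0 = uncoupled).
    """
    rng = np.random.default_rng(spec.seed)
    T = int(round(spec.duration * spec.fs))
    base = bandpass(rng.standard_normal((T, spec.n_channels)), spec.band, spec.fs)
    base = base / base.std(axis=0, keepdims=True)
    X = base.copy()
    truth = np.zeros((spec.n_channels, spec.n_channels))
    t = np.arange(T) / spec.fs
    for c in spec.couplings:
        analytic = hilbert(base[:, c.src])
        shifted = np.real(analytic * np.exp(-1j * c.phase_lag))
        active = (t >= c.onset) & (t < c.offset)
        X[active, c.dst] = (
            c.strength * shifted[active] + (1.0 - c.strength) * base[active, c.dst]
        )
        truth[c.src, c.dst] = truth[c.dst, c.src] = c.strength
    X = X + rng.normal(0.0, spec.noise_sigma, size=X.shape)
    return X, truth


@dataclass
class CohortSpec:
    """Multi-subject cohort of AR(2) network-metric time series.

    Each subject carries an AR(2) signature
    ``x_t = c_s + 2 r cos(θ_s) x_{t−1} − r² x_{t−2} + ε_t``: the pole angle
    θ_s (spectral peak) and the process level c_s are subject-specific,
    equally spaced across the cohort so both the oscillatory dynamics and
    the running level of the metric series distinguish subjects — mirroring
    how nodal-efficiency series differ across individuals in both mean and
    temporal structure.  The AR part is normalized to unit standard
    deviation before the level offset (``level_spacing`` per subject, in sd
    units) and shared observation noise σ are added.
    ``identical_signatures`` collapses all subjects onto one (θ, level)
    pair — the chance-level control.
    """

    n_subjects: int = 20
    n_windows: int = 240
    n_features: int = 4
    pole_radius: float = 0.95
    theta_range: tuple[float, float] = (0.15 * np.pi, 0.85 * np.pi)
    level_spacing: float = 0.8
    feature_jitter: float = 0.02
    noise_sigma: float = 0.05
    identical_signatures: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.pole_radius < 1.0:
            raise ValueError("AR poles must lie inside the unit circle")


def _ar2(theta: float, r: float, length: int, rng: np.random.Generator) -> np.ndarray:
    a1, a2 = 2.0 * r * np.cos(theta), -r * r
    burn = 100
    x = np.zeros(length + burn)
    eps = rng.standard_normal(length + burn)
    for t in range(2, length + burn):
        x[t] = a1 * x[t - 1] + a2 * x[t - 2] + eps[t]
    return x[burn:]


def gen_cohort_nmts(
    spec: CohortSpec,
) -> dict[str, dict[tuple[str, int], tuple[np.ndarray, np.ndarray]]]:
    """Cohort NMTS database: subject → (band, node) → (first, second half)."""
    rng = np.random.default_rng(spec.seed)
    thetas = np.linspace(*spec.theta_range, spec.n_subjects)
    levels = spec.level_spacing * np.arange(spec.n_subjects, dtype=float)
    if spec.identical_signatures:
        thetas = np.full(spec.n_subjects, thetas.mean())
        levels = np.full(spec.n_subjects, levels.mean())
    database: dict[str, dict[tuple[str, int], tuple[np.ndarray, np.ndarray]]] = {}
    for s in range(spec.n_subjects):
        subj = f"S{s:03d}"
        feats = {}
        for f in range(spec.n_features):
            theta = thetas[s] + spec.feature_jitter * (f - spec.n_features / 2.0)
            series = _ar2(theta, spec.pole_radius, spec.n_windows, rng)
            series = series / series.std()
            series = levels[s] + series + rng.normal(0.0, spec.noise_sigma, size=series.size)
            half = (series.size + 1) // 2
            feats[("band0", f)] = (series[:half], series[half:])
        database[subj] = feats
    return database


def gen_multiscan_graphs(
    base: ConnectivityMatrix | np.ndarray,
    n_scans: int,
    sigma_scan: float,
    seed: int = 0,
) -> list[ConnectivityMatrix]:
    """Noisy scan replicates: clip(base + symmetric Gaussian noise), renormalized."""
    if sigma_scan < 0:
        raise ValueError("scan noise must be non-negative")
    W0 = base.weights if isinstance(base, ConnectivityMatrix) else validate_weights(base)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_scans):
        noise = rng.normal(0.0, sigma_scan, size=W0.shape)
        noise = np.triu(noise, k=1)
        W = np.clip(W0 + noise + noise.T, 0.0, 1.0)
        np.fill_diagonal(W, 0.0)
        mx = W.max()
        if mx > 0:
            W = W / mx
        out.append(ConnectivityMatrix(W))
    return out
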