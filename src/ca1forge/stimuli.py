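"""Stimulus generators: Poisson spike trains (homogeneous, sinusoidal,
phase-histogram driven), medial-septum disinhibition current, and tonic
depolarization relative to rheobase.

Inhomogeneous Poisson trains are generated by Lewis-Shedler thinning of a
dominating homogeneous process, which is exact for bounded rate functions.
All generators are seeded and produce sorted spike times in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np


@dataclass
class RateFunction:
    """Time-varying firing rate (Hz) with a known upper bound."""

    rate: Callable[[np.ndarray], np.ndarray]   # t in ms -> rate in Hz
    max_rate: float
    mean_rate: float
    kind: str = "constant"

    def __call__(self, t_ms):
        return self.rate(np.asarray(t_ms, dtype=float))


@dataclass
class CurrentWaveform:
    """Sampled current waveform (nA vs ms)."""

    times: np.ndarray
    samples: np.ndarray
    description: str = "tonic"

    def __post_init__(self):
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("current samples must be finite")


def constant_rate(rate_hz: float) -> RateFunction:
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    return RateFunction(lambda t: np.full_like(t, rate_hz, dtype=float),
                        rate_hz, rate_hz, "constant")


def sinusoidal_rate(cell_frequency: float,
                    signal_frequency: float) -> RateFunction:
    """Sinusoidally modulated rate m (1 + sin 2 pi f t), floored at 0.

    The individual mean rate ``cell_frequency`` (Hz) sets both the offset
    and the amplitude, so the rate touches zero at the troughs and peaks
    at 2 m; ``signal_frequency`` (Hz) is the oscillation being imposed.
    """
    if cell_frequency <= 0 or signal_frequency <= 0:
        raise ValueError("frequencies must be positive")
    m, f = cell_frequency, signal_frequency

    def rate(t_ms):
        return np.maximum(
            m * (1.0 + np.sin(2 * np.pi * f * t_ms / 1000.0)), 0.0)

    return RateFunction(rate, 2.0 * m, m, "sinusoidal")


def phase_histogram_rate(phase_probs, frequency: float,
                         mean_rate: float,
                         smoothing_sigma_bins: float = 1.0) -> RateFunction:
    """Periodic rate built from a discharge-probability-vs-phase histogram.

    The histogram (bins spanning [0, 2 pi)) is circularly smoothed with a
    Gaussian kernel, mapped from phase to time at the given frequency
    (phase 0 at t = 0), and normalized so the time-averaged rate equals
    ``mean_rate`` (Hz).
    """
    probs = np.asarray(phase_probs, dtype=float)
    if np.any(probs < 0):
        raise ValueError("probabilities must be >= 0")
    if probs.sum() <= 0:
        raise ValueError("phase histogram is all zero")
    nbins = len(probs)
    if smoothing_sigma_bins > 0:
        k = np.arange(nbins)
        k = np.minimum(k, nbins - k)
        kern = np.exp(-0.5 * (k / smoothing_sigma_bins) ** 2)
        kern /= kern.sum()
        probs = np.real(np.fft.ifft(np.fft.fft(probs) * np.fft.fft(kern)))
        probs = np.maximum(probs, 0.0)
    shape = probs / probs.mean()          # time average 1
    period_ms = 1000.0 / frequency

    def rate(t_ms):
        phase_bin = np.floor((t_ms % period_ms) / period_ms
                             * nbins).astype(int) % nbins
        return mean_rate * shape[phase_bin]

    return RateFunction(rate, mean_rate * shape.max(), mean_rate,
                        "phase-histogram")


def poisson_trains(rate: RateFunction, n_sources: int, duration_ms: float,
                   seed: int = 0) -> dict[int, np.ndarray]:
    """Independent (in)homogeneous Poisson spike trains.

    Homogeneous rates use direct exponential gaps; time-varying rates use
    thinning of a dominating homogeneous process at ``rate.max_rate``.
    Returns a dict source id -> sorted spike times (ms).
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    if rate.max_rate < 0:
        raise ValueError("negative rate")
    rng = np.random.default_rng(seed)
    out = {}
    lam = rate.max_rate / 1000.0          # spikes per ms
    for src in range(n_sources):
        if lam == 0:
            out[src] = np.empty(0)
            continue
        n_exp = rng.poisson(lam * duration_ms)
        times = np.sort(rng.uniform(0.0, duration_ms, n_exp))
        if rate.kind != "constant":
            accept = rng.random(n_exp) < rate(times) / rate.max_rate
            times = times[accept]
        out[src] = times
    return out


def ms_disinhibition_current(frequency: float = 8.0, amplitude: float = 0.2,
                             duration_ms: float = 1000.0,
                             dt_ms: float = 0.5) -> CurrentWaveform:
    """Sinusoidal hyperpolarizing drive for PV+ interneurons.

    I(t) = -A + A sin(2 pi f t): the mean is set to minus the amplitude so
    the current oscillates in [-2A, 0] and never depolarizes.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    t = np.arange(0.0, duration_ms, dt_ms)
    i = -amplitude + amplitude * np.sin(2 * np.pi * frequency * t / 1000.0)
    return CurrentWaveform(t, i, "sinusoidal-hyperpolarizing")


def tonic_depolarization(rheobase_na: float, percent: float,
                         duration_ms: float = 1000.0,
                         dt_ms: float = 0.5) -> CurrentWaveform:
    """Constant somatic current at ``percent`` % of the rheobase."""
    t = np.arange(0.0, duration_ms, dt_ms)
    level = percent / 100.0 * rheobase_na
    return CurrentWaveform(t, np.full_like(t, level), "tonic")


# --------------------------------------------------------------------------
# spike text I/O (two columns: gid, time in ms)


def write_spikes(spikes: dict[int, np.ndarray], path) -> None:
    lines = ["# gid time_ms"]
    for gid in sorted(spikes):
        for t in spikes[gid]:
            lines.append(f"{gid} {t:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_spikes(path) -> dict[int, np.ndarray]:
    out: dict[int, list] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        gid_s, t_s = line.split()
        out.setdefault(int(gid_s), []).append(float(t_s))
    return {g: np.array(sorted(ts)) for g, ts in out.items()}
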