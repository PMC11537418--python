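"""Oscillation analysis: band filtering, multitaper PSD, Morlet wavelet
spectrograms, current source density, spike-phase locking, waveform
asymmetry, spike-train correlation (STTC), and stationarity checks.

All filters are zero-phase (forward-backward 6th-order Butterworth) so
that downstream phase analysis is not biased by filter group delay.  The
raw extracellular signal (2 kHz) is split at 400 Hz into LFP and
high-frequency components; the LFP is detrended, downsampled to 400 Hz
and band-filtered into delta (1-3 Hz), theta (4-12 Hz) and gamma
(30-120 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

RAW_FS_HZ = 2000.0
LFP_FS_HZ = 400.0
BANDS_HZ = {"delta": (1.0, 3.0), "theta": (4.0, 12.0),
            "gamma": (30.0, 120.0)}
FILTER_ORDER = 6
DISCARD_MS = 1000.0    # initial transient dropped from simulations


def _butter_sos(kind, cutoff, fs):
    return sps.butter(FILTER_ORDER, cutoff, btype=kind, fs=fs,
                      output="sos")


def zero_phase_filter(x, kind, cutoff, fs):
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 3 * FILTER_ORDER * 3:
        raise ValueError("trace too short for the filter warm-up")
    return sps.sosfiltfilt(_butter_sos(kind, cutoff, fs), x, axis=-1)


def split_bands(x, fs: float = RAW_FS_HZ) -> dict[str, np.ndarray]:
    """Standard extracellular processing chain.

    Splits the raw signal at 400 Hz into 'lfp' and 'hf' components, then
    detrends the LFP, downsamples it to 400 Hz ('lfp_ds') and band-filters
    into 'delta', 'theta', 'gamma'.  Works on 1-D or (channels, time)
    arrays.
    """
    x = np.asarray(x, dtype=float)
    out = {
        "lfp": zero_phase_filter(x, "lowpass", 400.0, fs),
        "hf": zero_phase_filter(x, "highpass", 400.0, fs),
    }
    lfp = sps.detrend(out["lfp"], axis=-1)
    decim = int(round(fs / LFP_FS_HZ))
    lfp_ds = sps.resample_poly(lfp, 1, decim, axis=-1)
    out["lfp_ds"] = lfp_ds
    for band, (lo, hi) in BANDS_HZ.items():
        out[band] = zero_phase_filter(lfp_ds, "bandpass", (lo, hi),
                                      LFP_FS_HZ)
    return out


def multitaper_psd(x, fs: float = LFP_FS_HZ,
                   resolution_hz: float = 1.5):
    """Multitaper PSD with the requested frequency resolution.

    DPSS tapers with half-bandwidth W = resolution/2 (NW = T W), averaging
    the K = floor(2 NW - 1) leading tapers.  Returns (freqs, psd).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    t_sec = n / fs
    nw = t_sec * resolution_hz / 2.0
    k = max(int(2 * nw - 1), 1)
    if nw < 1:
        raise ValueError("signal too short for the requested resolution")
    tapers = sps.windows.dpss(n, nw, Kmax=k)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    psd = np.zeros(len(freqs))
    for taper in tapers:
        spec = np.fft.rfft(x * taper)
        psd += np.abs(spec) ** 2
    psd /= k
    # one-sided density normalization
    psd *= 2.0 / fs
    psd[0] /= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    return freqs, psd


def peak_frequency(freqs, psd, fmin: float = 0.5,
                   fmax: float | None = None) -> float:
    sel = freqs >= fmin
    if fmax is not None:
        sel &= freqs <= fmax
    return float(freqs[sel][np.argmax(psd[sel])])


def wavelet_spectrogram(x, fs: float = LFP_FS_HZ, n_cycles: float = 7.0,
                        fmin: float = 1.0, fmax: float = 150.0,
                        fstep: float = 0.25, db_floor: float = -300.0):
    """Complex Morlet time-frequency power in dB.

    Frequencies span ``fmin`` to ``fmax`` in ``fstep`` steps; each
    frequency uses a Gaussian-envelope complex exponential with
    ``n_cycles`` cycles (sigma_t = n_cycles / (2 pi f)).  Returns
    (freqs, power_db) with power_db shaped (n_freqs, n_times).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    freqs = np.arange(fmin, fmax + fstep / 2, fstep)
    xf = np.fft.fft(x, 2 * n)
    power = np.empty((len(freqs), n))
    t = np.arange(-n, n) / fs
    for i, f in enumerate(freqs):
        sigma_t = n_cycles / (2 * np.pi * f)
        wavelet = np.exp(2j * np.pi * f * t) * np.exp(
            -t**2 / (2 * sigma_t**2))
        wavelet /= np.sqrt(np.sum(np.abs(wavelet) ** 2))
        wf = np.fft.fft(np.fft.ifftshift(wavelet))
        conv = np.fft.ifft(xf * wf)[:n]
        power[i] = np.abs(conv) ** 2
    with np.errstate(divide="ignore"):
        power_db = 10.0 * np.log10(power)
    return freqs, np.maximum(power_db, db_floor)


def csd_1d(traces: np.ndarray, depths_um, sigma_s_per_m: float = 0.3,
           smooth_window: int = 5) -> np.ndarray:
    """One-dimensional current source density across channels.

    A regularized second spatial derivative: Savitzky-Golay (polynomial
    order 2) when at least ``smooth_window`` channels are available,
    otherwise the direct central difference.  CSD = -sigma d2V/dz2, so
    sinks (inward current) are negative.  Requires >= 3 channels with
    strictly increasing depths.
    """
    traces = np.asarray(traces, dtype=float)
    depths = np.asarray(depths_um, dtype=float)
    if traces.ndim != 2 or len(depths) != traces.shape[0]:
        raise ValueError("traces must be (channels, time)")
    if len(depths) < 3:
        raise ValueError("need at least 3 channels")
    dz = np.diff(depths)
    if np.any(dz <= 0):
        raise ValueError("depths must be strictly increasing")
    h = float(dz.mean())
    if len(depths) >= smooth_window:
        d2 = sps.savgol_filter(traces, smooth_window, polyorder=2,
                               deriv=2, delta=h, axis=0)
    else:
        d2 = np.empty_like(traces)
        d2[1:-1] = (traces[2:] - 2 * traces[1:-1] + traces[:-2]) / h**2
        d2[0] = d2[1]
        d2[-1] = d2[-2]
    return -sigma_s_per_m * d2


# --------------------------------------------------------------------------
# spike-phase analysis


@dataclass
class PhaseLockingResult:
    mean_angle_deg: float
    vector_norm: float
    rayleigh_p: float
    n_spikes: int
    angular_deviation_deg: float


def instantaneous_phase_deg(theta_signal: np.ndarray) -> np.ndarray:
    """Instantaneous phase of a band-limited signal with the trough at 0
    degrees (analytic-signal angle shifted by 180)."""
    analytic = sps.hilbert(np.asarray(theta_signal, dtype=float))
    return (np.degrees(np.angle(analytic)) + 180.0) % 360.0


def rayleigh_test(angles_rad: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity: returns (R, p).

    Uses the standard approximation
    p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n)), accurate for
    moderate n.
    """
    n = len(angles_rad)
    if n == 0:
        raise ValueError("no angles")
    c = np.cos(angles_rad).sum()
    s = np.sin(angles_rad).sum()
    rn = np.hypot(c, s)
    r = rn / n
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - rn**2)) - (1 + 2 * n))
    return float(r), float(min(max(p, 0.0), 1.0))


def phase_locking(spike_times_ms: np.ndarray, theta_signal: np.ndarray,
                  fs: float = LFP_FS_HZ, t0_ms: float = 0.0,
                  min_spikes: int = 10) -> PhaseLockingResult | None:
    """Spike-phase statistics of one cell against a theta reference.

    Spike phases are interpolated from the instantaneous phase
    (trough = 0 degrees); the resultant-vector angle gives the preferred
    phase, its norm the locking strength, and the Rayleigh test the
    significance.  Cells with fewer than ``min_spikes`` spikes are
    excluded (returns None).
    """
    spikes = np.asarray(spike_times_ms, dtype=float)
    spikes = spikes[(spikes >= t0_ms)
                    & (spikes < t0_ms + len(theta_signal) / fs * 1000.0)]
    if len(spikes) < min_spikes:
        return None
    phase = instantaneous_phase_deg(theta_signal)
    # unwrap for interpolation, then re-wrap
    unwrapped = np.unwrap(np.radians(phase))
    t_grid = t0_ms + np.arange(len(theta_signal)) / fs * 1000.0
    sp_phase = np.interp(spikes, t_grid, unwrapped) % (2 * np.pi)
    r, p = rayleigh_test(sp_phase)
    mean_angle = np.degrees(np.arctan2(np.sin(sp_phase).sum(),
                                       np.cos(sp_phase).sum())) % 360.0
    ang_dev = np.degrees(np.sqrt(2 * (1 - r)))
    return PhaseLockingResult(float(mean_angle), r, p, len(spikes),
                              float(ang_dev))


def asymmetry_index(lfp: np.ndarray, fs: float = LFP_FS_HZ,
                    band=(1.0, 80.0), z_thresh: float = 1.0):
    """Per-cycle and mean rise/decay asymmetry of an oscillation.

    The signal is band-filtered (1-80 Hz), z-scored, and peaks/troughs
    above/below ``z_thresh`` are paired into cycles
    (trough -> peak -> trough); the index per cycle is
    log(t_rise / t_decay) — negative for fast-rise/slow-decay waves.
    Returns (indices, mean) or None if fewer than 3 cycles are found.
    """
    x = zero_phase_filter(np.asarray(lfp, dtype=float), "bandpass", band,
                          fs)
    z = (x - x.mean()) / max(x.std(), 1e-12)
    peaks, _ = sps.find_peaks(z, height=z_thresh)
    troughs, _ = sps.find_peaks(-z, height=z_thresh)
    if len(peaks) < 3 or len(troughs) < 4:
        return None
    indices = []
    for i in range(len(troughs) - 1):
        t0, t1 = troughs[i], troughs[i + 1]
        between = peaks[(peaks > t0) & (peaks < t1)]
        if len(between) != 1:
            continue
        pk = between[0]
        t_rise = (pk - t0) / fs
        t_decay = (t1 - pk) / fs
        if t_rise > 0 and t_decay > 0:
            indices.append(np.log(t_rise / t_decay))
    if len(indices) < 3:
        return None
    indices = np.asarray(indices)
    return indices, float(indices.mean())


# --------------------------------------------------------------------------
# spike-train correlation


def sttc(train_a, train_b, dt_ms: float = 10.0,
         t_start: float = 0.0, t_stop: float | None = None) -> float:
    """Spike time tiling coefficient of two trains.

    STTC = 1/2 [(Pa - Tb)/(1 - Pa Tb) + (Pb - Ta)/(1 - Pb Ta)] where Ta
    is the fraction of total time within +-dt of spikes of A and Pa the
    proportion of A spikes within +-dt of a B spike.  Robust to firing
    rate differences; lies in [-1, 1].
    """
    a = np.asarray(train_a, dtype=float)
    b = np.asarray(train_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty spike train")
    if t_stop is None:
        t_stop = max(a.max(), b.max()) + dt_ms
    span = t_stop - t_start

    def tiled_fraction(train):
        lo = np.maximum(train - dt_ms, t_start)
        hi = np.minimum(train + dt_ms, t_stop)
        total = 0.0
        cur_lo, cur_hi = lo[0], hi[0]
        for x, y in zip(lo[1:], hi[1:]):
            if x <= cur_hi:
                cur_hi = max(cur_hi, y)
            else:
                total += cur_hi - cur_lo
                cur_lo, cur_hi = x, y
        total += cur_hi - cur_lo
        return total / span

    def prop_within(train, other):
        idx = np.searchsorted(other, train)
        idx_lo = np.clip(idx - 1, 0, len(other) - 1)
        idx_hi = np.clip(idx, 0, len(other) - 1)
        d = np.minimum(np.abs(train - other[idx_lo]),
                       np.abs(train - other[idx_hi]))
        return np.mean(d <= dt_ms)

    ta = tiled_fraction(a)
    tb = tiled_fraction(b)
    pa = prop_within(a, b)
    pb = prop_within(b, a)
    term1 = (pa - tb) / (1 - pa * tb) if pa * tb != 1 else 0.0
    term2 = (pb - ta) / (1 - pb * ta) if pb * ta != 1 else 0.0
    return 0.5 * (term1 + term2)


def spike_correlogram(train_a, train_b, bin_ms: float = 10.0,
                      window_ms: float = 200.0):
    """Normalized cross-correlogram of two spike trains.

    Histogram of pairwise time differences (b - a) within
    +-``window_ms``, normalized to unit sum.  Returns (lags, histogram).
    """
    a = np.asarray(train_a, dtype=float)
    b = np.asarray(train_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty spike train")
    # bins centered on zero lag
    edges = np.arange(-window_ms - bin_ms / 2,
                      window_ms + bin_ms, bin_ms)
    counts = np.zeros(len(edges) - 1)
    for t in a:
        d = b - t
        d = d[(d >= -window_ms) & (d <= window_ms)]
        counts += np.histogram(d, bins=edges)[0]
    total = counts.sum()
    if total > 0:
        counts /= total
    lags = 0.5 * (edges[:-1] + edges[1:])
    return lags, counts


def io_gain(input_spikes: dict[int, np.ndarray],
            output_spikes: dict[int, np.ndarray],
            groups: dict[str, list] | None = None) -> dict[str, float]:
    """Output/input spike-count ratio, optionally per output group."""
    n_in = sum(len(s) for s in input_spikes.values())
    if n_in == 0:
        raise ValueError("no input spikes: gain undefined")
    result = {"all": sum(len(s) for s in output_spikes.values()) / n_in}
    for name, gids in (groups or {}).items():
        result[name] = sum(len(output_spikes.get(g, ())) for g in gids) \
            / n_in
    return result


def adf_check(x, alpha: float = 0.05, detrend: bool = True):
    """Augmented Dickey-Fuller stationarity decision for one channel.

    Returns (is_stationary, statistic, p).  The signal is linearly
    detrended first (matching the processing order of the LFP chain);
    constant signals are trivially stationary.
    """
    from statsmodels.tsa.stattools import adfuller

    x = np.asarray(x, dtype=float)
    if len(x) < 100:
        raise ValueError("need at least 100 samples")
    if np.ptp(x) == 0:
        return True, -np.inf, 0.0
    if detrend:
        x = sps.detrend(x)
    stat, p = adfuller(x, autolag="AIC")[:2]
    return bool(p < alpha), float(stat), float(p)
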