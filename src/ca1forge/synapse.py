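"""Stochastic Tsodyks-Markram synapses with multivesicular release and
calcium / acetylcholine modulation.

The presynaptic state has a deterministic utilization variable u
(facilitation time constant tau_facil) and N_RRP vesicles that recover
independently (time constant tau_rec).  At each presynaptic spike every
recovered vesicle releases independently with probability u; the effective
baseline utilization U_SE is scaled multiplicatively by the extracellular
calcium concentration (Hill, normalized to 1 at 2 mM) and by the
acetylcholine dose-response factor.  ACh additionally injects a
depolarizing somatic current with its own Hill dose-response.

The module also carries the relative-error cost function and the
alternating two-step grid search used to constrain afferent synapse
parameters against experimental PSP statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

# ACh dose-response constants (current in nA, concentration in uM)
ACH_I_MAX_NA = 0.567
ACH_I_EC50_UM = 100.0
ACH_I_HILL = 0.436
ACH_U_IC50_UM = 4.541
ACH_U_HILL = 0.576

CALCIUM_REFERENCE_MM = 2.0
# Hill exponents for the U_SE calcium dependence; the half-concentration
# and the three profiles are stand-in defaults exposed as configuration
CALCIUM_HILL_EXPONENTS = {"steep": 4.0, "intermediate": 3.0, "shallow": 2.0}
CALCIUM_HILL_KD_MM = 2.3


@dataclass
class ReceptorKinetics:
    tau_rise: float      # ms
    tau_decay: float     # ms
    e_rev: float = 0.0   # mV

    def __post_init__(self):
        if self.tau_rise <= 0 or self.tau_decay <= self.tau_rise:
            raise ValueError("need 0 < tau_rise < tau_decay")


@dataclass
class TMParams:
    """Stochastic Tsodyks-Markram parameter set for one pathway."""

    u_se: float                     # baseline release probability
    tau_rec: float                  # D, ms
    tau_facil: float                # F, ms
    g_max: float                    # nS per vesicle
    n_rrp: int = 1                  # release-ready vesicles
    ampa: ReceptorKinetics = field(
        default_factory=lambda: ReceptorKinetics(0.2, 10.0, 0.0))
    nmda: ReceptorKinetics | None = None
    nmda_ratio: float = 0.0         # NMDA/AMPA peak conductance ratio
    delay_ms: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.u_se <= 1.0:
            raise ValueError("U_SE must be in [0, 1]")
        if self.tau_rec <= 0 or self.tau_facil < 0:
            raise ValueError("time constants must be positive")
        if self.n_rrp < 1:
            raise ValueError("N_RRP must be >= 1")


# --------------------------------------------------------------------------
# neuromodulation


def ach_current(concentration_um) -> float | np.ndarray:
    """Depolarizing somatic current (nA) evoked by ACh at the given
    concentration (uM): Hill dose-response saturating at 0.567 nA with
    half-maximum at 100 uM and exponent 0.436; zero at zero concentration
    (control condition)."""
    c = np.asarray(concentration_um, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    h = np.power(c, ACH_I_HILL, where=c > 0, out=np.zeros_like(c))
    out = ACH_I_MAX_NA * h / (ACH_I_EC50_UM**ACH_I_HILL + h)
    return float(out) if np.isscalar(concentration_um) else out


def ach_release_scaling(concentration_um) -> float | np.ndarray:
    """Multiplicative U_SE scaling by ACh, a decreasing Hill factor equal
    to 1 at zero concentration and 0.5 at 4.541 uM.  The same factor is
    applied to all pathways, afferents included."""
    c = np.asarray(concentration_um, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    # stable rearrangement of c^-h / (k^-h + c^-h) avoiding the c=0 pole
    out = 1.0 / (1.0 + np.power(c / ACH_U_IC50_UM, ACH_U_HILL,
                                where=c > 0, out=np.zeros_like(c)))
    return float(out) if np.isscalar(concentration_um) else out


def calcium_scaling(calcium_mm: float, profile: str = "intermediate") -> float:
    """U_SE scaling with extracellular calcium: Hill in calcium with a
    profile-dependent exponent, normalized to 1 at the 2 mM reference."""
    if calcium_mm <= 0:
        raise ValueError("calcium must be positive")
    if profile not in CALCIUM_HILL_EXPONENTS:
        raise ValueError(f"unknown profile {profile!r}")
    n = CALCIUM_HILL_EXPONENTS[profile]
    kd = CALCIUM_HILL_KD_MM

    def hill(c):
        return c**n / (kd**n + c**n)

    return hill(calcium_mm) / hill(CALCIUM_REFERENCE_MM)


def effective_u(params: TMParams, calcium_mm: float = 2.0,
                ach_um: float = 0.0,
                calcium_profile: str = "intermediate") -> float:
    u = params.u_se * calcium_scaling(calcium_mm, calcium_profile) \
        * ach_release_scaling(ach_um)
    return min(u, 1.0)


# --------------------------------------------------------------------------
# release dynamics


@dataclass
class ReleaseEvent:
    time: float            # ms
    vesicles: int
    conductance: float     # nS peak (g_max x vesicles x double-exp peak)


def tm_release(spike_times, params: TMParams, calcium_mm: float = 2.0,
               ach_um: float = 0.0, seed: int = 0,
               calcium_profile: str = "intermediate"):
    """Simulate stochastic release for a sorted spike train.

    Returns ``(released, events)``: per-spike released vesicle counts and
    the conductance event train.  Utilization follows the standard
    recursion u_k = U + u_{k-1} (1 - U) exp(-dt/tau_facil) (u = U at the
    first spike); each recovered vesicle releases independently with
    probability u_k and re-enters recovery (exponential with tau_rec).
    Vesicle conservation (recovered + recovering = N_RRP) holds
    throughout.
    """
    spikes = np.asarray(spike_times, dtype=float)
    if np.any(np.diff(spikes) < 0):
        raise ValueError("spike times must be sorted")
    rng = np.random.default_rng(seed)
    u_base = effective_u(params, calcium_mm, ach_um, calcium_profile)
    n = params.n_rrp
    recovered = np.ones(n, dtype=bool)
    recovery_at = np.full(n, -np.inf)     # time each busy vesicle returns
    u = 0.0
    last = None
    released = np.zeros(len(spikes), dtype=int)
    events = []
    for i, t in enumerate(spikes):
        if last is None:
            u = u_base
        else:
            decay = (np.exp(-(t - last) / params.tau_facil)
                     if params.tau_facil > 0 else 0.0)
            u = u_base + u * (1.0 - u_base) * decay
        recovered |= recovery_at <= t
        avail = np.flatnonzero(recovered)
        fire = avail[rng.random(len(avail)) < u]
        released[i] = len(fire)
        if len(fire):
            recovered[fire] = False
            recovery_at[fire] = t + rng.exponential(params.tau_rec,
                                                    len(fire))
            events.append(ReleaseEvent(
                t + params.delay_ms, len(fire),
                params.g_max * len(fire)))
        last = t
    return released, events


def tm_deterministic_mean(spike_times, params: TMParams,
                          calcium_mm: float = 2.0, ach_um: float = 0.0,
                          calcium_profile: str = "intermediate"):
    """Mean-field (deterministic) expected released fraction per spike.

    Because u is deterministic given spike times and vesicles are
    independent, the expectation obeys the classic recursion
    x-_k = 1 - (1 - x+_{k-1}) exp(-dt/tau_rec), release_k = u_k x-_k,
    x+_k = x-_k (1 - u_k); the expected released count is N_RRP u x.
    """
    spikes = np.asarray(spike_times, dtype=float)
    u_base = effective_u(params, calcium_mm, ach_um, calcium_profile)
    x = 1.0
    u = 0.0
    last = None
    out = np.zeros(len(spikes))
    for i, t in enumerate(spikes):
        if last is None:
            u = u_base
        else:
            dt = t - last
            decay = (np.exp(-dt / params.tau_facil)
                     if params.tau_facil > 0 else 0.0)
            u = u_base + u * (1.0 - u_base) * decay
            x = 1.0 - (1.0 - x) * np.exp(-dt / params.tau_rec)
        out[i] = params.n_rrp * u * x
        x = x * (1.0 - u)
        last = t
    return out


def double_exponential(t, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Normalized difference-of-exponentials conductance waveform
    (peak = 1)."""
    t = np.asarray(t, dtype=float)
    tp = (tau_rise * tau_decay / (tau_decay - tau_rise)
          * np.log(tau_decay / tau_rise))
    norm = np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise)
    out = np.where(t >= 0,
                   (np.exp(-t / tau_decay) - np.exp(-t / tau_rise)) / norm,
                   0.0)
    return out


# --------------------------------------------------------------------------
# parameter fitting


def fit_cost(targets) -> float:
    """Sum of relative errors |x_mod - x_exp| / x_exp over fit targets.

    ``targets`` is an iterable of (x_mod, x_exp) pairs or objects with
    those attributes.
    """
    total = 0.0
    for tgt in targets:
        if isinstance(tgt, tuple):
            x_mod, x_exp = tgt
        else:
            x_mod, x_exp = tgt.x_mod, tgt.x_exp
        if x_exp == 0:
            raise ValueError("experimental value must be nonzero")
        total += abs(x_mod - x_exp) / abs(x_exp)
    return total


def fit_sc_parameters(step1_grid, step2_grid, simulate, targets_step1,
                      targets_step2, max_iter: int = 10):
    """Alternating two-step grid search for afferent synapse parameters.

    Step 1 scans (g_max, n_rrp) against amplitude/CV targets; step 2 scans
    AMPA (tau_rise, tau_decay) against kinetics targets.  ``simulate``
    maps a parameter dict to a dict of model measures; targets are dicts
    measure -> experimental value.  Steps alternate until both optima are
    stable.  Returns ``(params, cost, converged)``.
    """
    if not step1_grid or not step2_grid:
        raise ValueError("grids must be non-empty")

    def step_cost(params, targets):
        measures = simulate(params)
        return fit_cost([(measures[k], v) for k, v in targets.items()])

    current = {"g_max": step1_grid[0][0], "n_rrp": step1_grid[0][1],
               "tau_rise": step2_grid[0][0], "tau_decay": step2_grid[0][1]}
    prev = None
    converged = False
    for _ in range(max_iter):
        best1 = min(step1_grid, key=lambda gn: step_cost(
            {**current, "g_max": gn[0], "n_rrp": gn[1]}, targets_step1))
        current.update(g_max=best1[0], n_rrp=best1[1])
        best2 = min(step2_grid, key=lambda tt: step_cost(
            {**current, "tau_rise": tt[0], "tau_decay": tt[1]},
            targets_step2))
        current.update(tau_rise=best2[0], tau_decay=best2[1])
        key = (best1, best2)
        if key == prev:
            converged = True
            break
        prev = key
    cost = step_cost(current, {**targets_step1, **targets_step2})
    return current, cost, converged


def psp_features(time_ms, trace_mv, baseline_window=(0.0, 5.0),
                 noise_sd_threshold: float = 5.0):
    """Amplitude, 10-90% rise time, half-width and decay tau of a PSP.

    The decay time constant comes from an exponential fit of the falling
    phase (peak to 10% of amplitude).  A trace without a deflection above
    ``noise_sd_threshold`` baseline standard deviations is flagged by
    returning None.
    """
    t = np.asarray(time_ms, dtype=float)
    v = np.asarray(trace_mv, dtype=float)
    base_sel = (t >= baseline_window[0]) & (t <= baseline_window[1])
    base = v[base_sel].mean()
    noise = max(v[base_sel].std(), 1e-12)
    dv = v - base
    sign = 1.0 if abs(dv.max()) >= abs(dv.min()) else -1.0
    dv = dv * sign
    peak_idx = int(np.argmax(dv))
    amplitude = dv[peak_idx]
    if amplitude < noise_sd_threshold * noise:
        return None
    # 10-90% rise
    rise_sel = slice(0, peak_idx + 1)
    t10 = _crossing(t[rise_sel], dv[rise_sel], 0.1 * amplitude)
    t90 = _crossing(t[rise_sel], dv[rise_sel], 0.9 * amplitude)
    rise_time = t90 - t10
    # half width
    half = 0.5 * amplitude
    t_half_up = _crossing(t[rise_sel], dv[rise_sel], half)
    fall = slice(peak_idx, len(t))
    t_half_down = _crossing(t[fall], dv[fall], half, falling=True)
    half_width = t_half_down - t_half_up
    # decay tau: exponential fit from the peak down to 10% of amplitude
    fall_t = t[fall]
    fall_v = dv[fall]
    stop = np.argmax(fall_v < 0.1 * amplitude) or len(fall_v)
    ft = fall_t[:stop] - fall_t[0]
    fv = fall_v[:stop]
    if len(ft) < 4:
        return None   # falling phase too short to characterize
    popt, _ = curve_fit(lambda x, a, tau: a * np.exp(-x / tau), ft, fv,
                        p0=(amplitude, max(half_width, 1.0)), maxfev=5000)
    decay_tau = float(popt[1])
    return {"amplitude": float(sign * amplitude),
            "rise_time": float(rise_time),
            "half_width": float(half_width),
            "decay_tau": decay_tau}


def _crossing(t, v, level, falling=False):
    if falling:
        below = np.flatnonzero(v <= level)
        i = below[0] if len(below) else len(v) - 1
    else:
        above = np.flatnonzero(v >= level)
        i = above[0] if len(above) else len(v) - 1
    if i == 0:
        return t[0]
    # linear interpolation between samples
    v0, v1 = v[i - 1], v[i]
    if v1 == v0:
        return t[i]
    frac = (level - v0) / (v1 - v0)
    return t[i - 1] + frac * (t[i] - t[i - 1])
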