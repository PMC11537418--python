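"""Surrogate point-neuron network simulator.

Neurons are adaptive exponential integrate-and-fire (AdEx) point models,
one parameter set per e-type; with delta_T = 0 the model reduces to a
leaky integrate-and-fire neuron whose rheobase has the closed form
g_L (V_th - E_L).  Synapses use the stochastic Tsodyks-Markram machinery
(per-synapse utilization and vesicle pool) driving difference-of-
exponential conductances.  Global experimental conditions (extracellular
calcium, ACh concentration) scale release probability and inject somatic
current.  The extracellular signal is a point-source proxy: channel
voltage = sum of per-cell synaptic currents weighted by 1/(4 pi sigma d).

This simulator is a deliberately simple stand-in for multicompartment
conductance-based models: it preserves network-level structure (who
connects to whom, with what dynamics) but none of the dendritic
electrotonics, so downstream claims are property-level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimuli import CurrentWaveform

log = logging.getLogger(__name__)

EXTRACELLULAR_SIGMA_S_PER_M = 0.3
LFP_DISTANCE_FLOOR_UM = 10.0


@dataclass
class PointNeuron:
    """AdEx parameter set (nF, nS, mV, ms, nA units)."""

    etype: str = "cADpyr"
    c_m: float = 0.2               # nF
    g_l: float = 10.0              # nS
    e_l: float = -70.0             # mV
    v_th: float = -50.0            # mV (threshold / exponential onset)
    v_reset: float = -60.0         # mV
    delta_t: float = 2.0           # mV; 0 -> LIF
    v_cut: float = -30.0           # spike detection cutoff
    tau_w: float = 120.0           # ms adaptation
    a: float = 2.0                 # nS subthreshold adaptation
    b: float = 0.02                # nA spike-triggered adaptation
    refractory: float = 2.0        # ms

    def __post_init__(self):
        if self.v_reset >= self.v_th:
            raise ValueError("reset must be below threshold")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")

    def lif_rheobase(self) -> float:
        """Closed-form rheobase for delta_T = 0: g_L (V_th - E_L), nA."""
        return self.g_l * (self.v_th - self.e_l) * 1e-3


ETYPE_PARAMS = {
    # excitatory, adapting
    "cADpyr": PointNeuron("cADpyr"),
    # fast-spiking basket-like
    "cNAC": PointNeuron("cNAC", c_m=0.1, g_l=10.0, v_reset=-58.0,
                        tau_w=30.0, a=0.0, b=0.0, refractory=1.5),
    # adapting interneuron
    "cAC": PointNeuron("cAC", c_m=0.12, g_l=8.0, tau_w=100.0, a=2.0,
                       b=0.01),
    # bursting-onset interneuron (approximated as low-threshold adapting)
    "bAC": PointNeuron("bAC", c_m=0.12, g_l=8.0, v_th=-52.0, tau_w=80.0,
                       a=4.0, b=0.01),
}


def _step_adex(p: PointNeuron, v, w, i_syn, i_ext, dt):
    if p.delta_t > 0:
        exp_term = p.g_l * p.delta_t * np.exp(
            np.minimum((v - p.v_th) / p.delta_t, 20.0))
    else:
        exp_term = 0.0
    # currents in nA; conductances nS, voltages mV -> g*V in pA, /1000
    dv = (-p.g_l * (v - p.e_l) * 1e-3 + exp_term * 1e-3
          - w + i_syn + i_ext) / p.c_m * dt
    dw = ((p.a * (v - p.e_l) * 1e-3 - w) / p.tau_w) * dt
    return v + dv, w + dw


def simulate_neuron(neuron: PointNeuron, current_na, duration_ms: float,
                    dt_ms: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Single-neuron run under a current (constant scalar or waveform);
    returns (spike times ms, membrane trace)."""
    n = int(round(duration_ms / dt_ms))
    if np.isscalar(current_na):
        i_ext = np.full(n, float(current_na))
    elif isinstance(current_na, CurrentWaveform):
        i_ext = np.interp(np.arange(n) * dt_ms, current_na.times,
                          current_na.samples)
    else:
        i_ext = np.asarray(current_na, dtype=float)
    v = neuron.e_l
    w = 0.0
    refr_until = -1.0
    spikes = []
    trace = np.empty(n)
    thresh = neuron.v_cut if neuron.delta_t > 0 else neuron.v_th
    for k in range(n):
        t = k * dt_ms
        if t < refr_until:
            trace[k] = neuron.v_reset
            continue
        v, w = _step_adex(neuron, v, w, 0.0, i_ext[k], dt_ms)
        if v >= thresh:
            spikes.append(t)
            v = neuron.v_reset
            w += neuron.b
            refr_until = t + neuron.refractory
        trace[k] = v
    return np.array(spikes), trace


def estimate_rheobase(neuron: PointNeuron, i_max: float = 2.0,
                      accuracy: float = 1e-3, sim_ms: float = 300.0,
                      dt_ms: float = 0.05) -> float:
    """Bisection search for the minimal spiking current (nA).

    The bracket is halved until its width is below ``accuracy``; the upper
    bound of the final bracket is returned so the cell is guaranteed to
    spike at the reported value.
    """
    lo, hi = 0.0, i_max
    spikes, _ = simulate_neuron(neuron, hi, sim_ms, dt_ms)
    if len(spikes) == 0:
        raise ValueError("neuron does not spike at the bracket maximum")
    while hi - lo > accuracy:
        mid = 0.5 * (lo + hi)
        spikes, _ = simulate_neuron(neuron, mid, sim_ms, dt_ms)
        if len(spikes):
            hi = mid
        else:
            lo = mid
    return hi


# --------------------------------------------------------------------------
# network


@dataclass
class FieldTrace:
    """Multichannel extracellular trace (uV vs ms)."""

    channel_depths: np.ndarray     # um along the radial axis, monotone
    times: np.ndarray              # ms
    samples: np.ndarray            # (n_channels, n_times) uV

    def __post_init__(self):
        d = np.asarray(self.channel_depths, dtype=float)
        if np.any(np.diff(d) <= 0):
            raise ValueError("channel depths must be strictly increasing")
        if self.samples.shape != (len(d), len(self.times)):
            raise ValueError("samples shape mismatch")

    @property
    def fs_hz(self) -> float:
        return 1000.0 / (self.times[1] - self.times[0])


@dataclass
class SimResult:
    spikes: dict[int, np.ndarray]
    times: np.ndarray
    v: dict[int, np.ndarray]
    cell_currents: np.ndarray       # (n_cells, n_rec) net synaptic nA
    field: FieldTrace | None = None


@dataclass
class Conditions:
    calcium_mm: float = 2.0
    ach_um: float = 0.0
    temperature_c: float = 32.0     # condition tag (no effect in surrogate)
    mg_mm: float = 1.0              # condition tag (NMDA block, unused here)
    calcium_profile: str = "intermediate"


def lfp_proxy(cell_currents: np.ndarray, cell_positions: np.ndarray,
              channel_positions: np.ndarray, times: np.ndarray,
              sigma_s_per_m: float = EXTRACELLULAR_SIGMA_S_PER_M,
              floor_um: float = LFP_DISTANCE_FLOOR_UM) -> FieldTrace:
    """Point-source extracellular proxy.

    V(ch, t) = sum_i I_i(t) / (4 pi sigma d_i) with d floored at
    ``floor_um``.  With currents in nA, sigma in S/m and distances in um
    the result is in microvolts: V_uV = 1e3 I_nA / (4 pi sigma d_um).
    """
    ch = np.asarray(channel_positions, dtype=float)
    pos = np.asarray(cell_positions, dtype=float)
    d = np.linalg.norm(pos[None, :, :] - ch[:, None, :], axis=-1)
    n_floored = int((d < floor_um).sum())
    if n_floored:
        log.info("lfp_proxy: %d cell-channel distances floored", n_floored)
    d = np.maximum(d, floor_um)
    weights = 1e3 / (4 * np.pi * sigma_s_per_m * d)      # uV per nA
    samples = weights @ cell_currents
    depths = ch[:, 2] if ch.ndim == 2 else ch
    return FieldTrace(depths, times, samples)


def run_network(cells: pd.DataFrame, synapses: pd.DataFrame,
                fiber_spikes: dict[int, np.ndarray] | None = None,
                currents: dict[int, object] | None = None,
                conditions: Conditions = Conditions(),
                duration_ms: float = 1000.0, dt_ms: float = 0.1,
                record_dt_ms: float = 0.5, seed: int = 0,
                record_v: tuple[int, ...] = (),
                channel_positions: np.ndarray | None = None,
                disable_inhibition: bool = False) -> SimResult:
    """Integrate the network with fixed-step Euler dynamics.

    ``cells`` needs columns gid, etype, x, y, z (and optionally
    is_inhibitory); ``synapses`` columns pre_gid, post_gid, g_max (nS),
    e_rev, tau_rise, tau_decay, u_se, tau_rec, tau_facil, n_rrp, delay_ms,
    and optionally is_fiber (presynaptic id refers to an external fiber).
    ``disable_inhibition`` zeroes conductances of synapses with
    e_rev < -40 mV (gabazine-like manipulation).
    """
    from .synapse import ach_current, ach_release_scaling, calcium_scaling

    rng = np.random.default_rng(seed)
    gids = cells["gid"].to_numpy()
    n_cells = len(gids)
    gid_index = {g: i for i, g in enumerate(gids)}
    etypes = cells["etype"].tolist()
    params = [ETYPE_PARAMS.get(e, ETYPE_PARAMS["cADpyr"]) for e in etypes]

    n_steps = int(round(duration_ms / dt_ms))
    rec_every = max(1, int(round(record_dt_ms / dt_ms)))
    n_rec = n_steps // rec_every
    rec_times = np.arange(n_rec) * record_dt_ms

    # synapse arrays
    syn = synapses.reset_index(drop=True)
    ns = len(syn)
    u_scale = (calcium_scaling(conditions.calcium_mm,
                               conditions.calcium_profile)
               * ach_release_scaling(conditions.ach_um))
    if ns:
        g_max = syn["g_max"].to_numpy(dtype=float).copy()
        e_rev = syn["e_rev"].to_numpy(dtype=float)
        if disable_inhibition:
            g_max[e_rev < -40.0] = 0.0
        tau_r = syn["tau_rise"].to_numpy(dtype=float)
        tau_d = syn["tau_decay"].to_numpy(dtype=float)
        u_se = np.minimum(syn["u_se"].to_numpy(dtype=float) * u_scale, 1.0)
        tau_rec = syn["tau_rec"].to_numpy(dtype=float)
        tau_fac = syn["tau_facil"].to_numpy(dtype=float)
        n_rrp = syn["n_rrp"].to_numpy(dtype=int)
        delay = syn["delay_ms"].to_numpy(dtype=float) \
            if "delay_ms" in syn else np.ones(ns)
        post_idx = np.array([gid_index[g] for g in syn["post_gid"]])
        is_fiber = syn["is_fiber"].to_numpy(dtype=bool) \
            if "is_fiber" in syn else np.zeros(ns, dtype=bool)
        # normalization so that a unit release peaks at g_max
        tp = tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)
        norm = 1.0 / (np.exp(-tp / tau_d) - np.exp(-tp / tau_r))
        dec_r = np.exp(-dt_ms / tau_r)
        dec_d = np.exp(-dt_ms / tau_d)
        dec_w = np.where(tau_fac > 0, np.exp(-dt_ms / tau_fac), 0.0)
        p_rec = 1.0 - np.exp(-dt_ms / tau_rec)
        a_state = np.zeros(ns)
        b_state = np.zeros(ns)
        w_state = np.zeros(ns)
        recovered = n_rrp.copy()
        pre_syn: dict[int, np.ndarray] = {}
        for key, grp in syn.groupby("pre_gid").groups.items():
            pre_syn[key] = np.asarray(grp)
    else:
        post_idx = np.zeros(0, dtype=int)
        pre_syn = {}

    # external fiber spike schedule -> per-step synapse activations
    schedule: dict[int, list] = {}
    if fiber_spikes and ns:
        for fid, times in fiber_spikes.items():
            sidx = pre_syn.get(fid)
            if sidx is None:
                continue
            fiber_sel = sidx[is_fiber[sidx]]
            if len(fiber_sel) == 0:
                continue
            for t in times:
                for si in fiber_sel:
                    step = int(round((t + delay[si]) / dt_ms))
                    if 0 <= step < n_steps:
                        schedule.setdefault(step, []).append(si)

    # external currents
    i_ext = np.zeros((n_cells, n_steps))
    i_ach = ach_current(conditions.ach_um)
    if i_ach:
        i_ext += i_ach
    if currents:
        tgrid = np.arange(n_steps) * dt_ms
        for gid, cur in currents.items():
            if gid not in gid_index:
                continue
            row = gid_index[gid]
            if np.isscalar(cur):
                i_ext[row] += float(cur)
            elif isinstance(cur, CurrentWaveform):
                i_ext[row] += np.interp(tgrid, cur.times, cur.samples)
            else:
                i_ext[row] += np.asarray(cur, dtype=float)

    v = np.array([p.e_l for p in params])
    w_adapt = np.zeros(n_cells)
    refr_until = np.full(n_cells, -1.0)
    spikes: dict[int, list] = {int(g): [] for g in gids}
    v_rec = {int(g): np.empty(n_rec) for g in record_v}
    cell_cur = np.zeros((n_cells, n_rec))

    c_m = np.array([p.c_m for p in params])
    g_l = np.array([p.g_l for p in params])
    e_l = np.array([p.e_l for p in params])
    # optional per-cell threshold override (population heterogeneity)
    if "v_th" in cells:
        v_th = cells["v_th"].to_numpy(dtype=float)
    else:
        v_th = np.array([p.v_th for p in params])
    v_reset = np.array([p.v_reset for p in params])
    delta_t = np.array([p.delta_t for p in params])
    v_cut = np.where(delta_t > 0, [p.v_cut for p in params], v_th)
    tau_w = np.array([p.tau_w for p in params])
    a_w = np.array([p.a for p in params])
    b_w = np.array([p.b for p in params])
    refr = np.array([p.refractory for p in params])

    for k in range(n_steps):
        t = k * dt_ms
        # synaptic states
        if ns:
            a_state *= dec_r
            b_state *= dec_d
            w_state *= dec_w
            busy = n_rrp - recovered
            has_busy = busy > 0
            if has_busy.any():
                rec_now = rng.binomial(busy[has_busy], p_rec[has_busy])
                recovered[has_busy] += rec_now
            acts = schedule.pop(k, None)
            if acts:
                for si in acts:
                    u = u_se[si] + w_state[si] * (1.0 - u_se[si])
                    n_rel = rng.binomial(recovered[si], u)
                    w_state[si] = u
                    if n_rel:
                        recovered[si] -= n_rel
                        inc = n_rel * norm[si]
                        a_state[si] += inc
                        b_state[si] += inc
            g_syn = g_max * (b_state - a_state)
            i_syn_per = -g_syn * (v[post_idx] - e_rev) * 1e-3   # nA
            i_syn = np.zeros(n_cells)
            np.add.at(i_syn, post_idx, i_syn_per)
        else:
            i_syn = np.zeros(n_cells)

        active = t >= refr_until
        exp_term = np.where(
            delta_t > 0,
            g_l * np.where(delta_t > 0, delta_t, 1.0) * np.exp(
                np.minimum((v - v_th) / np.where(delta_t > 0, delta_t, 1.0),
                           20.0)),
            0.0)
        dv = (-g_l * (v - e_l) * 1e-3 + exp_term * 1e-3 - w_adapt
              + i_syn + i_ext[:, k]) / c_m * dt_ms
        dw = ((a_w * (v - e_l) * 1e-3 - w_adapt) / tau_w) * dt_ms
        v = np.where(active, v + dv, v_reset)
        w_adapt += np.where(active, dw, 0.0)
        fired = active & (v >= v_cut)
        if fired.any():
            for row in np.flatnonzero(fired):
                gid = int(gids[row])
                spikes[gid].append(t)
                sidx = pre_syn.get(gid)
                if sidx is not None:
                    intrinsic = sidx[~is_fiber[sidx]]
                    for si in intrinsic:
                        step = k + int(round(delay[si] / dt_ms))
                        if step < n_steps:
                            schedule.setdefault(step, []).append(si)
            v[fired] = v_reset[fired]
            w_adapt[fired] += b_w[fired]
            refr_until[fired] = t + refr[fired]
        if np.any(~np.isfinite(v)):
            raise FloatingPointError(f"NaN membrane state at t={t} ms")

        if k % rec_every == 0:
            r = k // rec_every
            if r < n_rec:
                cell_cur[:, r] = i_syn
                for gid in record_v:
                    v_rec[gid][r] = v[gid_index[gid]]

    field_trace = None
    if channel_positions is not None:
        pos = cells[["x", "y", "z"]].to_numpy(dtype=float)
        field_trace = lfp_proxy(cell_cur, pos, channel_positions, rec_times)
    return SimResult({g: np.array(s) for g, s in spikes.items()},
                     rec_times, v_rec, cell_cur, field_trace)


# --------------------------------------------------------------------------
# input-output curve


def calibrate_sc_gain(cells: pd.DataFrame, synapses: pd.DataFrame,
                      fiber_ids: np.ndarray, sampled_gids: np.ndarray,
                      volley_ms: float = 50.0, window_ms: float = 30.0,
                      duration_ms: float = 100.0,
                      conditions: "Conditions" = None,
                      seed: int = 0, max_doublings: int = 10) -> float:
    """Scale factor on afferent conductances such that activating 100% of
    the fiber pool makes every sampled neuron spike (the 100%-input /
    100%-output calibration of the slice protocol).  Returns the factor;
    raises if it cannot be reached."""
    conditions = conditions or Conditions(calcium_mm=2.4)
    gain = 1.0
    for _ in range(max_doublings):
        syn = synapses.copy()
        is_fiber = syn["is_fiber"].to_numpy(dtype=bool)
        syn.loc[is_fiber, "g_max"] *= gain
        fiber_spikes = {int(f): np.array([volley_ms]) for f in fiber_ids}
        res = run_network(cells, syn, fiber_spikes=fiber_spikes,
                          conditions=conditions, duration_ms=duration_ms,
                          seed=seed)
        ok = all(
            np.any((res.spikes[int(g)] >= volley_ms)
                   & (res.spikes[int(g)] <= volley_ms + window_ms))
            for g in sampled_gids)
        if ok:
            return gain
        gain *= 2.0
    raise RuntimeError("full-input calibration failed: sampled neurons "
                       "do not all spike even at maximum gain")


def io_curve(cells: pd.DataFrame, synapses: pd.DataFrame,
             fiber_ids: np.ndarray, sampled_gids: np.ndarray,
             fractions, seeds, volley_ms: float = 50.0,
             window_ms: float = 30.0, duration_ms: float = 100.0,
             conditions: Conditions = Conditions(calcium_mm=2.4),
             disable_inhibition: bool = False,
             dt_ms: float = 0.1) -> np.ndarray:
    """Fraction of sampled neurons firing after a synchronous afferent
    volley, per activated-fiber fraction, averaged over seeds.

    Mirrors the slice calibration protocol: a volley on a fraction of the
    fiber pool at ``volley_ms``; a sampled neuron counts as responding if
    it spikes within ``window_ms`` after the volley.
    """
    fractions = np.asarray(fractions, dtype=float)
    out = np.zeros((len(seeds), len(fractions)))
    for si, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        perm = rng.permutation(fiber_ids)
        for fi, frac in enumerate(fractions):
            n_act = int(round(frac * len(fiber_ids)))
            active = perm[:n_act]
            fiber_spikes = {int(f): np.array([volley_ms]) for f in active}
            res = run_network(cells, synapses, fiber_spikes=fiber_spikes,
                              conditions=conditions,
                              duration_ms=duration_ms, dt_ms=dt_ms,
                              seed=seed,
                              disable_inhibition=disable_inhibition)
            n_resp = sum(
                1 for g in sampled_gids
                if np.any((res.spikes[int(g)] >= volley_ms)
                          & (res.spikes[int(g)] <= volley_ms + window_ms)))
            out[si, fi] = n_resp / len(sampled_gids)
    return out.mean(axis=0)
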