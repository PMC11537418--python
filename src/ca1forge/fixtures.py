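"""Deterministic synthetic fixtures: analytic volumes, morphology
populations, and miniature end-to-end circuits.

Every generator takes an explicit seed; analytic atlases come with
ground-truth coordinate grids so the geometric pipeline can be checked
against closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

import pandas as pd

from .atlas import (CoordinateField, RegionMask, assign_layers,
                    layer_proportions_from_thicknesses, layer_r_intervals)
from .morph import SWC_CODES, Morphology


@dataclass
class AtlasFixture:
    mask: RegionMask
    upper_shell: np.ndarray
    lower_shell: np.ndarray
    endpoints: np.ndarray            # two world points for the centerline
    analytic: CoordinateField | None = None


def _pad_grid(occ_core: np.ndarray, pad: int = 2) -> tuple[np.ndarray, tuple]:
    shape = tuple(s + 2 * pad for s in occ_core.shape)
    occ = np.zeros(shape, dtype=bool)
    sl = tuple(slice(pad, pad + s) for s in occ_core.shape)
    occ[sl] = occ_core
    return occ, sl


def make_slab(nx: int = 100, ny: int = 20, nz: int = 20,
              voxel_size: float = 10.0) -> AtlasFixture:
    """Axis-aligned slab: l along x, t along y, r along z.

    The analytic radial coordinate is the fractional depth between the
    lower (z-min) and upper (z-max) shell voxel-center planes; shells are
    the outermost in-mask voxel layers.
    """
    pad = 2
    occ, sl = _pad_grid(np.ones((nx, ny, nz), dtype=bool), pad)
    mask = RegionMask(occ, voxel_size)
    ii = np.indices(occ.shape).astype(float)

    lower = np.zeros_like(occ)
    upper = np.zeros_like(occ)
    lower[sl[0], sl[1], pad] = True
    upper[sl[0], sl[1], pad + nz - 1] = True

    l_an = np.full(occ.shape, np.nan)
    t_an = np.full(occ.shape, np.nan)
    r_an = np.full(occ.shape, np.nan)
    d_an = np.full(occ.shape + (3,), np.nan)
    x = (ii[0] - pad + 0.5) / nx
    y = (ii[1] - pad + 0.5) / ny
    z = (ii[2] - pad) / (nz - 1)           # 0 at lower shell plane
    l_an[occ], t_an[occ], r_an[occ] = x[occ], y[occ], z[occ]
    d_an[occ] = np.array([0.0, 0.0, 1.0])
    analytic = CoordinateField(l_an, t_an, r_an, d_an, mask)

    mid = voxel_size * np.array([pad + 0.5, pad + ny / 2, pad + nz / 2])
    endpoints = np.array([
        mid, mid + np.array([voxel_size * (nx - 1), 0.0, 0.0])])
    return AtlasFixture(mask, upper, lower, endpoints, analytic)


def make_quarter_annulus(inner: float = 40.0, outer: float = 60.0,
                         height: int = 24,
                         voxel_size: float = 1.0) -> AtlasFixture:
    """Quarter annulus bent in the xy-plane, thickness ``height`` along z.

    The centerline follows the mid-radius arc; analytic coordinates are
    l = angle / (pi/2), t = fractional height, and r the radial fraction
    (rho - inner) / (outer - inner).  Lower shell = inner surface.
    """
    pad = 2
    n = int(np.ceil(outer)) + 1
    ii = np.indices((n, n, height)).astype(float) + 0.5
    rho_core = np.hypot(ii[0], ii[1])
    core = (rho_core >= inner) & (rho_core <= outer)
    occ, sl = _pad_grid(core, pad)
    mask = RegionMask(occ, voxel_size)

    jj = np.indices(occ.shape).astype(float) + 0.5 - pad
    rho = np.hypot(jj[0], jj[1])
    theta = np.arctan2(jj[1], jj[0])

    lower = occ & (rho < inner + 1.0)
    upper = occ & (rho > outer - 1.0)

    l_an = np.full(occ.shape, np.nan)
    t_an = np.full(occ.shape, np.nan)
    r_an = np.full(occ.shape, np.nan)
    d_an = np.full(occ.shape + (3,), np.nan)
    l_an[occ] = theta[occ] / (np.pi / 2)
    t_an[occ] = (jj[2][occ] - 0.5) / (height - 1)
    r_an[occ] = (rho[occ] - inner) / (outer - inner)
    radial = np.stack([np.cos(theta), np.sin(theta),
                       np.zeros_like(theta)], axis=-1)
    d_an[occ] = radial[occ]
    analytic = CoordinateField(l_an, t_an, r_an, d_an, mask)

    mid_rho = 0.5 * (inner + outer)
    zc = voxel_size * (pad + height / 2)
    endpoints = np.array([
        [voxel_size * (pad + mid_rho), voxel_size * (pad + 1.0), zc],
        [voxel_size * (pad + 1.0), voxel_size * (pad + mid_rho), zc]])
    return AtlasFixture(mask, upper, lower, endpoints, analytic)


def make_bent_slab(nx: int = 80, ny: int = 16, nz: int = 16,
                   amplitude: float = 4.0,
                   voxel_size: float = 10.0) -> AtlasFixture:
    """Slab sheared sinusoidally along z as a function of x — a gentle
    'mini-CA1' volume for end-to-end demonstrations (no tight analytic
    oracle; the shear makes the true coordinates only approximately
    separable)."""
    pad = 2
    bend_max = int(np.ceil(amplitude))
    shape = (nx, ny, nz + 2 * bend_max)
    ii = np.indices(shape).astype(float)
    bend = amplitude * np.sin(np.pi * ii[0] / nx)
    zp = ii[2] - bend_max - bend
    core = (zp >= 0) & (zp < nz)
    occ, sl = _pad_grid(core, pad)
    mask = RegionMask(occ, voxel_size)

    jj = np.indices(occ.shape).astype(float) - pad
    bend_full = amplitude * np.sin(np.pi * jj[0] / nx)
    zp_full = jj[2] - bend_max - bend_full
    lower = occ & (zp_full < 1)
    upper = occ & (zp_full >= nz - 1)

    l_an = np.full(occ.shape, np.nan)
    t_an = np.full(occ.shape, np.nan)
    r_an = np.full(occ.shape, np.nan)
    d_an = np.full(occ.shape + (3,), np.nan)
    l_an[occ] = np.clip((jj[0][occ] + 0.5) / nx, 0, 1)
    t_an[occ] = np.clip((jj[1][occ] + 0.5) / ny, 0, 1)
    r_an[occ] = np.clip(zp_full[occ] / (nz - 1), 0, 1)
    d_an[occ] = np.array([0.0, 0.0, 1.0])
    analytic = CoordinateField(l_an, t_an, r_an, d_an, mask)

    z0 = voxel_size * (pad + bend_max + nz / 2)
    endpoints = np.array([
        [voxel_size * (pad + 0.5), voxel_size * (pad + ny / 2), z0],
        [voxel_size * (pad + nx - 0.5), voxel_size * (pad + ny / 2), z0]])
    return AtlasFixture(mask, upper, lower, endpoints, analytic)


def make_atlas(kind: str = "slab", **kwargs) -> AtlasFixture:
    """Dispatch on atlas fixture kind: slab | bent-slab | quarter-annulus."""
    makers = {"slab": make_slab, "bent-slab": make_bent_slab,
              "quarter-annulus": make_quarter_annulus}
    if kind not in makers:
        raise ValueError(f"unknown atlas kind {kind!r}")
    return makers[kind](**kwargs)


def _grow_neurite(nodes, parent_idx, origin, direction, depth, seg_len,
                  type_code, rng, n_seg: int = 3, branch_angle: float = 0.5):
    """Recursively grow a binary-branching neurite; returns nothing, the
    node list is extended in place.  ``depth=1`` gives an unbranched
    neurite."""
    direction = direction / np.linalg.norm(direction)
    pos = origin.copy()
    last = parent_idx
    for _ in range(n_seg):
        step = seg_len / n_seg
        wiggle = rng.normal(0.0, 0.08, 3)
        d = direction + wiggle
        d /= np.linalg.norm(d)
        pos = pos + d * step
        nodes.append((pos.copy(), 0.5, type_code, last))
        last = len(nodes) - 1
    if depth > 1:
        for sign in (-1.0, 1.0):
            perp = np.cross(direction, rng.normal(size=3))
            if np.linalg.norm(perp) < 1e-9:
                perp = np.cross(direction, [1.0, 0.0, 0.0])
            perp /= np.linalg.norm(perp)
            newdir = (np.cos(branch_angle) * direction
                      + np.sin(branch_angle) * sign * perp)
            _grow_neurite(nodes, last, pos, newdir, depth - 1,
                          seg_len * 0.8, type_code, rng, n_seg, branch_angle)


def make_morphology(kind: str = "int", depth: int = 3,
                    seg_len: float = 60.0, seed: int = 0,
                    name: str | None = None) -> Morphology:
    """Random binary-branching morphology.

    kind='int': axon and basal dendrites radiating from the soma.
    kind='pc': pyramidal-like — apical trunk along +y, basal skirt along
    -y, and a long axon running along the transverse (x) axis.
    """
    rng = np.random.default_rng(seed)
    soma_radius = 8.0 if kind == "pc" else 6.0
    nodes = [(np.zeros(3), soma_radius, SWC_CODES["soma"], -1)]
    if kind == "pc":
        _grow_neurite(nodes, 0, np.zeros(3), np.array([0.0, 1.0, 0.0]),
                      depth, seg_len * 2, SWC_CODES["apical"], rng)
        _grow_neurite(nodes, 0, np.zeros(3), np.array([0.3, -1.0, 0.1]),
                      depth, seg_len, SWC_CODES["basal"], rng)
        # long transverse axon with short collaterals
        _grow_neurite(nodes, 0, np.zeros(3), np.array([1.0, -0.15, 0.0]),
                      max(depth, 2), seg_len * 4, SWC_CODES["axon"], rng,
                      n_seg=8, branch_angle=0.25)
    elif kind == "int":
        # basket-like: dense local axon spreading laterally (perisomatic
        # targeting needs many segments near PC somata), sparser dendrites
        for vec in [(1.0, 0.3, 0.2), (-1.0, 0.2, -0.2), (0.2, -0.4, 1.0),
                    (-0.3, 0.3, -1.0), (0.7, 0.7, -0.4),
                    (-0.6, -0.7, 0.4)]:
            _grow_neurite(nodes, 0, np.zeros(3), np.array(vec),
                          depth + 1, seg_len * 2.0, SWC_CODES["axon"],
                          rng, n_seg=5, branch_angle=0.7)
        for vec in [(0.5, -1.0, 0.0), (-0.5, -0.8, 0.2)]:
            _grow_neurite(nodes, 0, np.zeros(3), np.array(vec), depth,
                          seg_len, SWC_CODES["basal"], rng)
    else:
        raise ValueError(f"unknown morphology kind {kind!r}")
    pts = np.array([n[0] for n in nodes])
    radii = np.array([n[1] for n in nodes])
    types = np.array([n[2] for n in nodes])
    parent = np.array([n[3] for n in nodes])
    m = Morphology(pts, radii, types, parent,
                   name=name or f"{kind}_{seed}")
    m.validate()
    return m


def make_morphologies(n: int = 10, kind: str = "int", depth: int = 3,
                      seg_len: float = 60.0, seed: int = 0):
    """A population of ``n`` random morphologies with per-cell seeds
    derived from ``seed``."""
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=n)
    return [make_morphology(kind, depth, seg_len, int(s),
                            name=f"{kind}_{seed}_{i}")
            for i, s in enumerate(seeds)]


def make_noisy_slab(nx: int = 40, ny: int = 12, nz: int = 12,
                    voxel_size: float = 10.0, flip_fraction: float = 0.05,
                    seed: int = 0) -> tuple[RegionMask, RegionMask]:
    """A clean slab and a salt-and-pepper corrupted copy (for smoothing
    tests).  Returns (clean, noisy)."""
    fx = make_slab(nx, ny, nz, voxel_size)
    clean = fx.mask
    rng = np.random.default_rng(seed)
    occ = clean.occupancy.copy()
    occ ^= rng.random(occ.shape) < flip_fraction
    return clean, RegionMask(occ, voxel_size)


# --------------------------------------------------------------------------
# toy circuit


# default layer thicknesses (um, ordered SO, SP, SR, SLM from r = 0) and
# the standard laminar proportions derived from them
LAYER_THICKNESSES_UM = (168.0, 59.0, 279.0, 146.0)
LAYER_PROPORTIONS = layer_proportions_from_thicknesses(LAYER_THICKNESSES_UM)

# minimal per-pathway short-term-plasticity physiology for the toy
# circuit: (u_se, tau_rec ms, tau_facil ms, g_max nS, n_rrp, e_rev mV,
# tau_rise ms, tau_decay ms)
TOY_PHYSIOLOGY = {
    "E->E": dict(u_se=0.5, tau_rec=671.0, tau_facil=17.0, g_max=1.2,
                 n_rrp=4, e_rev=0.0, tau_rise=0.2, tau_decay=10.0),
    "E->I": dict(u_se=0.09, tau_rec=138.0, tau_facil=670.0, g_max=2.0,
                 n_rrp=4, e_rev=0.0, tau_rise=0.2, tau_decay=4.0),
    # perisomatic inhibition is strong; the point neuron lumps what would
    # be several anatomical contacts into one effective conductance
    "I->E": dict(u_se=0.25, tau_rec=706.0, tau_facil=21.0, g_max=10.0,
                 n_rrp=4, e_rev=-80.0, tau_rise=0.2, tau_decay=8.0),
    "I->I": dict(u_se=0.25, tau_rec=706.0, tau_facil=21.0, g_max=5.0,
                 n_rrp=4, e_rev=-80.0, tau_rise=0.2, tau_decay=8.0),
    # afferent conductances are desk-scaled: the toy has ~500x fewer
    # afferent synapses per cell than the tissue, so single contacts are
    # kept weak and the slice calibration scales the pool as needed
    "SC->E": dict(u_se=0.5, tau_rec=671.0, tau_facil=17.0, g_max=0.05,
                  n_rrp=12, e_rev=0.0, tau_rise=0.4, tau_decay=12.0),
    "SC->I": dict(u_se=0.5, tau_rec=671.0, tau_facil=17.0, g_max=0.4,
                  n_rrp=2, e_rev=0.0, tau_rise=0.1, tau_decay=1.0),
}


@dataclass
class ToyCircuit:
    cells: pd.DataFrame                  # gid, mtype, etype, xyz, ltr
    placed: list                         # PlacedCell instances
    synapses: pd.DataFrame               # intrinsic, netsim schema
    sc_synapses: pd.DataFrame            # afferent, netsim schema
    fiber_ids: np.ndarray
    field: CoordinateField
    layer_labels: np.ndarray


def _physiology_row(pre_is_inh: bool, post_is_inh: bool,
                    pathway: str | None = None) -> dict:
    if pathway == "SC":
        return TOY_PHYSIOLOGY["SC->I" if post_is_inh else "SC->E"]
    key = f"{'I' if pre_is_inh else 'E'}->{'I' if post_is_inh else 'E'}"
    return TOY_PHYSIOLOGY[key]


def make_toy_circuit(n_pc: int = 30, n_int: int = 10,
                     n_fibers: int = 60, sc_per_pc: float = 40.0,
                     sc_per_int: float = 30.0, seed: int = 0,
                     nx: int = 20, ny: int = 8, nz: int = 30,
                     voxel_size: float = 10.0) -> ToyCircuit:
    """Miniature end-to-end circuit wired through placement, touch
    detection, pruning and afferent projection synthesis.

    Pyramidal cells sit in SP, basket cells (PVBC) in SP; afferent fibers
    form a virtual presynaptic pool.  Convergence targets are desk-scale
    stand-ins, not the full-scale experimental numbers.
    """
    from . import connectome as conn
    from . import placement as plc
    from . import projections as proj

    rng = np.random.default_rng(seed)
    fx = make_slab(nx, ny, nz, voxel_size)
    field = fx.analytic
    labels = assign_layers(field, LAYER_PROPORTIONS)

    recipe = plc.CompositionRecipe(
        counts={"SP_PC": n_pc, "SP_PVBC": n_int},
        layers={"SP_PC": "SP", "SP_PVBC": "SP"},
        etype_fractions={"SP_PC": {"cADpyr": 1.0},
                         "SP_PVBC": {"cNAC": 1.0}})
    cells = plc.place_somata(field, labels, recipe, LAYER_PROPORTIONS,
                             seed=int(rng.integers(2**31 - 1)))
    # population heterogeneity: spike thresholds jittered around the
    # e-type value so excitability varies across cells
    cells["v_th"] = -50.0 + rng.uniform(-2.5, 2.5, size=len(cells))

    placed = []
    for row in cells.itertuples():
        is_pc = row.mtype == "SP_PC"
        m = make_morphology("pc" if is_pc else "int",
                            depth=3, seg_len=50.0,
                            seed=int(rng.integers(2**31 - 1)))
        rot = plc.orient_cell(field, [(row.x, row.y, row.z)], row.mtype,
                              seed=int(rng.integers(2**31 - 1)),
                              is_pyramidal=is_pc)
        world = m.transformed(rotation=rot,
                              translation=(row.x, row.y, row.z))
        placed.append(conn.PlacedCell(row.gid, row.mtype, world,
                                      is_pyramidal=is_pc))

    appositions = conn.find_appositions(placed)
    constraints = {}
    if not appositions.empty:
        tmp = appositions.assign(
            pathway=appositions.pre_mtype + "->" + appositions.post_mtype)
        for pathway, grp in tmp.groupby("pathway"):
            app_per_conn = grp.groupby(["pre_gid", "post_gid"]).size().mean()
            pre_inh = not pathway.startswith("SP_PC")
            post_inh = not pathway.endswith("SP_PC")
            cls = "I-I" if (pre_inh and post_inh) else "other"
            target = max(
                conn.predict_synapses_per_connection(app_per_conn, cls),
                1.0)
            constraints[pathway] = conn.PruningConstraints(
                mean_syns_per_connection=target)
    pruned = conn.prune(appositions, constraints,
                        seed=int(rng.integers(2**31 - 1)))

    # netsim schema for intrinsic synapses
    inh = {row.gid: row.mtype != "SP_PC" for row in cells.itertuples()}
    syn_rows = []
    for row in pruned.itertuples():
        phys = _physiology_row(inh[row.pre_gid], inh[row.post_gid])
        syn_rows.append(dict(pre_gid=row.pre_gid, post_gid=row.post_gid,
                             delay_ms=1.0, is_fiber=False, **phys))
    synapses = pd.DataFrame(syn_rows)

    # afferent projections: dendritic segment pool per postsynaptic class
    proportions = LAYER_PROPORTIONS
    intervals = layer_r_intervals(proportions)

    def seg_pool(cells_subset):
        rows = []
        for pc in cells_subset:
            m = pc.morphology
            seg = m.segment_lengths()
            dend = np.isin(m.types, [SWC_CODES["basal"],
                                     SWC_CODES["apical"]])
            for i in np.flatnonzero(dend & (m.parent >= 0)):
                mid = 0.5 * (m.points[i] + m.points[m.parent[i]])
                rel_z = mid[2] / voxel_size
                # layer from the analytic radial coordinate of the slab
                idx = field.mask.world_to_index([mid])[0]
                idx = np.clip(idx, 0, np.array(field.r.shape) - 1)
                r_here = field.r[tuple(idx)]
                if not np.isfinite(r_here):
                    continue
                layer = next(
                    (name for name, (lo, hi) in intervals.items()
                     if lo <= r_here <= hi), "SR")
                rows.append((pc.gid, i, seg[i], layer))
        return pd.DataFrame(rows,
                            columns=["gid", "segment", "length", "layer"])

    sc_recipe = proj.ProjectionRecipe(n_fibers=n_fibers,
                                      pc_target=sc_per_pc,
                                      int_target=sc_per_int)
    sc_parts = []
    for post_class, subset in (
            ("PC", [p for p in placed if p.is_pyramidal]),
            ("INT", [p for p in placed if not p.is_pyramidal])):
        if not subset:
            continue
        pool = seg_pool(subset)
        if pool.empty:
            continue
        part = proj.build_projection(pool, pool["layer"], sc_recipe,
                                     post_class, len(subset),
                                     seed=int(rng.integers(2**31 - 1)))
        sc_parts.append(part)
    sc = pd.concat(sc_parts, ignore_index=True)
    sc_rows = []
    for row in sc.itertuples():
        phys = _physiology_row(False, inh[row.gid], pathway="SC")
        sc_rows.append(dict(pre_gid=row.fiber, post_gid=row.gid,
                            delay_ms=1.0, is_fiber=True, **phys))
    sc_synapses = pd.DataFrame(sc_rows)

    return ToyCircuit(cells, placed, synapses, sc_synapses,
                      np.arange(n_fibers), field, labels)
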