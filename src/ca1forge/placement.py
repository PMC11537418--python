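"""Cell composition, density-based soma placement, orientation, and
rule-scored morphology selection.

Composition starts from the pyramidal-cell density in stratum pyramidale
and scales interneuron counts to the excitatory/inhibitory ratio.  Somata
are placed voxel-by-voxel with multinomial allocation proportional to
density x voxel volume.  Each cell's local y-axis is aligned with the
radial direction; morphologies are then scored against placement rules —
per-rule interval-overlap scores combined as a harmonic mean over optional
rules times a minimum over strict rules — and sampled proportionally to
their score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import LAYER_NAMES, CoordinateField, layer_r_intervals

log = logging.getLogger(__name__)

OPTIONAL_ZERO_CUTOFF = 1e-3   # an optional rule score below this zeroes Î
DEFAULT_EI_RATIO = 0.11       # inhibitory fraction of all neurons


# --------------------------------------------------------------------------
# composition


@dataclass
class CompositionRecipe:
    """Per-m-type target counts, layers, and e-type fractions."""

    counts: dict[str, int]                     # m-type -> cell count
    layers: dict[str, str]                     # m-type -> layer name
    etype_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    bands: dict[str, tuple[float, float]] = field(default_factory=dict)
    # bands: optional within-layer relative-depth restriction per m-type

    def __post_init__(self):
        for mt, fr in self.etype_fractions.items():
            s = sum(fr.values())
            if abs(s - 1.0) > 1e-6:
                raise ValueError(f"e-type fractions of {mt} sum to {s}")
        for mt, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {mt}")


def derive_composition(pc_density: float, sp_volume: float,
                       interneuron_ratios: dict[str, float],
                       interneuron_layers: dict[str, str],
                       ei_ratio: float = DEFAULT_EI_RATIO,
                       etype_fractions: dict | None = None,
                       bands: dict | None = None) -> CompositionRecipe:
    """Build a composition recipe from the PC density and the E/I ratio.

    ``pc_density`` in cells/mm^3, ``sp_volume`` in mm^3.  The interneuron
    ratios give the relative abundances of the inhibitory m-types; their
    absolute counts are scaled so that the inhibitory fraction of all
    neurons equals ``ei_ratio`` (E:I = 89:11 by default).
    """
    if sp_volume <= 0 or pc_density <= 0:
        raise ValueError("density and volume must be positive")
    if not 0 < ei_ratio < 1:
        raise ValueError("ei_ratio must be in (0, 1)")
    n_pc = int(round(pc_density * sp_volume))
    total_int = n_pc * ei_ratio / (1 - ei_ratio)
    rel = np.array(list(interneuron_ratios.values()), dtype=float)
    if rel.sum() <= 0:
        raise ValueError("interneuron ratios must have positive sum")
    raw = total_int * rel / rel.sum()
    counts_int = _largest_remainder(raw, int(round(total_int)))
    counts = {"SP_PC": n_pc}
    counts.update({mt: int(c) for mt, c
                   in zip(interneuron_ratios, counts_int)})
    layers = {"SP_PC": "SP"}
    layers.update(interneuron_layers)
    return CompositionRecipe(counts, layers, etype_fractions or {},
                             bands or {})


def _largest_remainder(raw: np.ndarray, total: int) -> np.ndarray:
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    if rem > 0:
        order = np.argsort(raw - base)[::-1]
        base[order[:rem]] += 1
    elif rem < 0:
        order = np.argsort(raw - base)
        base[order[:-rem]] -= 1
    return base


# --------------------------------------------------------------------------
# soma placement


# m-types restricted to a sub-band of their layer, expressed as a
# relative-depth interval within the layer (0 at the layer's r-lower edge)
DEFAULT_BANDS = {
    "SR_SCA": (0.45, 0.55),     # middle of SR +/- 5% of the layer
    "SLM_PPA": (0.02, 0.10),    # lower part of SLM, 2% to 10%
}


def place_somata(field_: CoordinateField, layer_labels: np.ndarray,
                 recipe: CompositionRecipe, proportions,
                 seed: int = 0) -> pd.DataFrame:
    """Place somata with exact per-m-type totals.

    Every admissible voxel (inside the m-type's layer and band) receives a
    multinomially allocated share of the requested count with weight
    proportional to density x voxel volume (densities are uniform within a
    layer, so weights are uniform over admissible voxels); positions are
    uniform within each voxel.  Returns a cell table with gid, m-type,
    e-type, xyz and (l, t, r).
    """
    rng = np.random.default_rng(seed)
    mask = field_.mask
    occ = mask.occupancy
    name_to_idx = {n: i for i, n in enumerate(LAYER_NAMES)}
    intervals = layer_r_intervals(proportions)
    rows = []
    gid = 0
    bands = dict(DEFAULT_BANDS)
    bands.update(recipe.bands)
    for mtype, n in recipe.counts.items():
        if n == 0:
            continue
        layer = recipe.layers[mtype]
        admissible = occ & (layer_labels == name_to_idx[layer])
        if mtype in bands:
            r_lo, r_hi = intervals[layer]
            rel = (field_.r - r_lo) / max(r_hi - r_lo, 1e-12)
            b_lo, b_hi = bands[mtype]
            admissible &= (rel >= b_lo) & (rel <= b_hi)
        vox = np.argwhere(admissible)
        if len(vox) == 0:
            raise ValueError(f"no admissible voxels for {mtype}")
        weights = np.full(len(vox), 1.0 / len(vox))
        alloc = rng.multinomial(n, weights)
        etypes = recipe.etype_fractions.get(mtype, {"default": 1.0})
        enames = list(etypes)
        eprobs = np.array(list(etypes.values()))
        for v, k in zip(vox, alloc):
            if k == 0:
                continue
            offs = rng.random((k, 3))
            pos = mask.origin + (v + offs) * mask.voxel_size
            ii = tuple(v)
            es = rng.choice(enames, size=k, p=eprobs)
            for p, e in zip(pos, es):
                rows.append((gid, mtype, e, p[0], p[1], p[2],
                             field_.l[ii], field_.t[ii], field_.r[ii]))
                gid += 1
    return pd.DataFrame(rows, columns=[
        "gid", "mtype", "etype", "x", "y", "z", "l", "t", "r"])


# --------------------------------------------------------------------------
# orientation


def _transverse_direction(field_: CoordinateField, voxel: tuple) -> np.ndarray:
    """Unit vector of decreasing t at a voxel (toward the distal end),
    from the t-gradient projected orthogonal to the radial direction."""
    from scipy import ndimage
    occ = field_.mask.occupancy
    if not hasattr(field_, "_t_grad"):
        _, nearest = ndimage.distance_transform_edt(~occ, return_indices=True)
        t_ext = field_.t[tuple(nearest)]
        t_ext = ndimage.gaussian_filter(t_ext, 1.0)
        g = np.stack(np.gradient(t_ext, field_.mask.voxel_size), axis=-1)
        field_._t_grad = g
    g = field_._t_grad[voxel]
    rad = field_.direction[voxel]
    g = g - (g @ rad) * rad
    n = np.linalg.norm(g)
    if n < 1e-12:
        # degenerate: any vector orthogonal to the radial axis
        g = np.cross(rad, [0.0, 0.0, 1.0])
        if np.linalg.norm(g) < 1e-9:
            g = np.cross(rad, [0.0, 1.0, 0.0])
        n = np.linalg.norm(g)
    return -g / n


def orient_cell(field_: CoordinateField, position, mtype: str,
                seed: int = 0, is_pyramidal: bool | None = None) -> np.ndarray:
    """Rotation matrix (columns = local x, y, z in world frame) for a cell.

    The local y-axis follows the radial direction.  Interneurons receive a
    seeded uniform rotation about it; pyramidal cells are rotated so the
    morphology's +x (the PCA-aligned axon axis, most complex branch first)
    points along the local transverse direction toward the distal (t = 0)
    end.
    """
    mask = field_.mask
    vox = tuple(mask.world_to_index(position)[0])
    rad = np.asarray(field_.direction[vox], dtype=float)
    if not np.all(np.isfinite(rad)):
        raise ValueError("no direction vector at position")
    if is_pyramidal is None:
        is_pyramidal = mtype.endswith("PC")
    y_local = rad / np.linalg.norm(rad)
    if is_pyramidal:
        x_local = _transverse_direction(field_, vox)
    else:
        rng = np.random.default_rng(seed)
        ref = np.cross(y_local, [0.0, 0.0, 1.0])
        if np.linalg.norm(ref) < 1e-9:
            ref = np.cross(y_local, [0.0, 1.0, 0.0])
        ref /= np.linalg.norm(ref)
        ang = rng.uniform(0.0, 2 * np.pi)
        x_local = np.cos(ang) * ref + np.sin(ang) * np.cross(y_local, ref)
    x_local = x_local - (x_local @ y_local) * y_local
    x_local /= np.linalg.norm(x_local)
    z_local = np.cross(x_local, y_local)
    return np.column_stack([x_local, y_local, z_local])


# --------------------------------------------------------------------------
# rule scoring (interval overlap, harmonic-mean aggregation)


@dataclass
class PlacementRule:
    """Interval rule for one annotated morphology span.

    ``kind`` is 'optional' or 'strict'.  ``morph_interval`` (a_lo, a_hi)
    is the annotated extent in um relative to the soma along the local
    radial axis; ``target_interval`` (r_lo, r_hi) is the target region
    along the same axis in absolute um.
    """

    kind: str
    morph_interval: tuple[float, float]
    target_interval: tuple[float, float]

    def __post_init__(self):
        if self.kind not in ("optional", "strict"):
            raise ValueError("rule kind must be optional or strict")
        if self.morph_interval[1] < self.morph_interval[0] \
                or self.target_interval[1] < self.target_interval[0]:
            raise ValueError("intervals must have hi >= lo")


def interval_score(a: tuple[float, float], r: tuple[float, float]) -> float:
    """Overlap of two intervals normalized by the larger one, floored at 0.

    Equals 1 only for a perfect overlap of equal intervals; symmetric in
    its arguments.
    """
    a_lo, a_hi = a
    r_lo, r_hi = r
    widest = max(a_hi - a_lo, r_hi - r_lo)
    if widest <= 0:
        return 0.0
    return max((min(a_hi, r_hi) - max(a_lo, r_lo)) / widest, 0.0)


def score_placement(y0: float, rules: list[PlacementRule]) -> float:
    """Total placement score S = Î · L̂ at soma radial position ``y0`` um.

    Optional rules aggregate as the harmonic mean Î (zero if any optional
    score falls below 0.001 — low scores are penalized harder than by an
    arithmetic mean, but strong rules can still rescue a weak one); strict
    rules aggregate as the minimum L̂.  Empty rule groups contribute 1.
    """
    if not rules:
        raise ValueError("at least one rule required")
    opt, strict = [], []
    for rule in rules:
        a = (rule.morph_interval[0] + y0, rule.morph_interval[1] + y0)
        s = interval_score(a, rule.target_interval)
        (opt if rule.kind == "optional" else strict).append(s)
    if opt:
        if min(opt) < OPTIONAL_ZERO_CUTOFF:
            i_hat = 0.0
        else:
            i_hat = len(opt) / sum(1.0 / s for s in opt)
    else:
        i_hat = 1.0
    l_hat = min(strict) if strict else 1.0
    return i_hat * l_hat


def select_morphology(scores: dict[str, float], seed: int = 0,
                      mode: str = "proportional"):
    """Choose a morphology with probability proportional to its score.

    Returns ``(name, n_dropped_increment)``; if every candidate scores
    zero the position is dropped (returns ``(None, 1)``).
    ``mode='argmax'`` selects the best-scoring candidate deterministically
    (seeded tie break).
    """
    names = list(scores)
    vals = np.array([scores[n] for n in names], dtype=float)
    if len(names) == 0 or vals.max() <= 0:
        return None, 1
    rng = np.random.default_rng(seed)
    if mode == "argmax":
        best = vals.max()
        ties = [n for n, v in zip(names, vals) if v >= best - 1e-12]
        return ties[int(rng.integers(len(ties)))], 0
    p = vals / vals.sum()
    return names[int(rng.choice(len(names), p=p))], 0
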