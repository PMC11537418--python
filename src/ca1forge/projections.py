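"""Schaffer-collateral afferent synapse generation.

CA3 pyramidal axons are not modeled explicitly; instead, afferent synapses
are placed directly on CA1 dendrites: per-layer synapse counts follow the
experimental laminar distribution, target segments are drawn with
replacement weighted by segment length (somata excluded), each synapse
receives a uniform offset along its segment, and synapses are assigned
uniformly at random to a pool of virtual presynaptic fibers.  Convergence
targets are the midpoints of the experimentally reported per-class ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# experimentally reported afferent-synapse ranges (synapses per neuron)
PC_SYNAPSE_RANGE = (13_059, 28_697)
INT_SYNAPSE_RANGE = (7_952, 17_476)

# laminar distribution of SC synapses over (SO, SP, SR, SLM), ordered
# from r = 0 to match the layer stacking used throughout
SC_LAYER_FRACTIONS = {"SO": 0.247, "SP": 0.071, "SR": 0.679, "SLM": 0.003}


@dataclass
class ProjectionRecipe:
    """Afferent-projection parameters."""

    n_fibers: int
    pc_target: float
    int_target: float
    layer_fractions: dict[str, float] = field(
        default_factory=lambda: dict(SC_LAYER_FRACTIONS))

    def __post_init__(self):
        total = sum(self.layer_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"layer fractions sum to {total}, not 1")
        if self.pc_target <= 0 or self.int_target <= 0 or self.n_fibers < 1:
            raise ValueError("targets and fiber count must be positive")


def convergence_targets(range_pc=PC_SYNAPSE_RANGE,
                        range_int=INT_SYNAPSE_RANGE) -> tuple[float, float]:
    """Midpoints of the reported afferent-synapse ranges per post class."""
    for lo, hi in (range_pc, range_int):
        if lo > hi:
            raise ValueError("range low must be <= high")
    return (0.5 * (range_pc[0] + range_pc[1]),
            0.5 * (range_int[0] + range_int[1]))


def allocate_layer_counts(total: int, fractions) -> np.ndarray:
    """Integer per-layer counts summing exactly to ``total``
    (largest-remainder rounding)."""
    fr = np.asarray(list(fractions.values())
                    if isinstance(fractions, dict) else fractions,
                    dtype=float)
    if abs(fr.sum() - 1.0) > 1e-6:
        raise ValueError("fractions must sum to 1")
    raw = fr * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(raw - base)[::-1]
    base[order[:rem]] += 1
    return base


def sample_segments(segments: pd.DataFrame, n: int,
                    seed: int = 0) -> pd.DataFrame:
    """Draw ``n`` synapse placements from a segment pool with replacement.

    ``segments`` needs columns gid, segment, length (um); sampling weight
    is proportional to length so short segments are not oversampled, and
    each placement gets an independent uniform offset in [0, 1) along its
    segment.  Somata must already be excluded from the pool.
    """
    if n == 0:
        return pd.DataFrame(columns=["gid", "segment", "offset"])
    if segments.empty:
        raise ValueError("empty segment pool with positive synapse count")
    rng = np.random.default_rng(seed)
    lengths = segments["length"].to_numpy(dtype=float)
    if np.any(lengths < 0) or lengths.sum() <= 0:
        raise ValueError("segment lengths must be positive")
    p = lengths / lengths.sum()
    rows = rng.choice(len(segments), size=n, p=p)
    out = segments.iloc[rows][["gid", "segment"]].reset_index(drop=True)
    out["offset"] = rng.random(n)
    return out


def assign_fibers(placements: pd.DataFrame, n_fibers: int,
                  seed: int = 0) -> pd.DataFrame:
    """Attach a uniformly random presynaptic fiber id to every synapse."""
    if n_fibers < 1:
        raise ValueError("need at least one fiber")
    rng = np.random.default_rng(seed)
    out = placements.copy()
    out["fiber"] = rng.integers(0, n_fibers, size=len(out))
    return out


def build_projection(cell_segments: pd.DataFrame, layer_labels_of_segment,
                     recipe: ProjectionRecipe, post_class: str,
                     n_post: int, seed: int = 0) -> pd.DataFrame:
    """End-to-end afferent synthesis for one postsynaptic class.

    ``cell_segments`` holds the dendritic segment pool (gid, segment,
    length, layer).  Total synapses = convergence target x number of
    postsynaptic cells, split across layers by the recipe fractions; each
    layer's quota is sampled from that layer's segment pool.  Returns the
    synapse table with fiber ids and a 'pathway' label of 'SC'.
    """
    target = recipe.pc_target if post_class == "PC" else recipe.int_target
    total = int(round(target * n_post))
    # quota from layers with no reachable segments is redistributed over
    # the populated layers (small circuits may not span every stratum)
    fractions = dict(recipe.layer_fractions)
    populated = {layer: (layer_labels_of_segment == layer).any()
                 for layer in fractions}
    lost = sum(f for lay, f in fractions.items() if not populated[lay])
    if lost > 0:
        if lost == 1.0:
            raise ValueError("no layer has any target segments")
        fractions = {lay: (f / (1 - lost) if populated[lay] else 0.0)
                     for lay, f in fractions.items()}
    counts = allocate_layer_counts(total, fractions)
    rng = np.random.default_rng(seed)
    parts = []
    for (layer, frac), cnt in zip(fractions.items(), counts):
        if cnt == 0:
            continue
        pool = cell_segments[layer_labels_of_segment == layer]
        placed = sample_segments(pool, int(cnt),
                                 seed=int(rng.integers(2**31 - 1)))
        placed["layer"] = layer
        parts.append(placed)
    out = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["gid", "segment", "offset", "layer"])
    out = assign_fibers(out, recipe.n_fibers,
                        seed=int(rng.integers(2**31 - 1)))
    out["pathway"] = "SC"
    return out
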