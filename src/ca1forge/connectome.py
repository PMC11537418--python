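"""Apposition detection, admissibility rules, and constraint-driven pruning.

Candidate synapses (appositions) are axo-dendritic/somatic near-contacts:
a presynaptic axon segment passing within a maximum touch distance of a
postsynaptic neurite (1.0 um onto pyramidal cells, 6.0 um onto
interneurons).  Compartment admissibility mirrors the known wiring
constraints: axo-axonic cells contact only the PC axon initial segment,
PC-PC contacts avoid somata, and SCA/Ivy/bistratified cells avoid PC
somata.  Pruning then thins appositions to match target mean
synapses/connection and bouton-density statistics (synapse counts are
converted to boutons with 1.15 synapses per bouton).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morph import SWC_CODES, Morphology

log = logging.getLogger(__name__)

TOUCH_DISTANCE_UM = {"PC": 1.0, "INT": 6.0}   # by postsynaptic class
SYNAPSES_PER_BOUTON = 1.15
DEFAULT_BOUTON_CV = 0.50
AIS_LENGTH_UM = 60.0   # axon path length from the soma counted as AIS

# appositions-per-connection -> synapses-per-connection linear predictors
SYN_PER_CONN_SLOPE = {"I-I": 0.1096, "other": 1.1690}


# --------------------------------------------------------------------------
# placed cells


@dataclass
class PlacedCell:
    """A morphology instanced at a position/orientation in the circuit."""

    gid: int
    mtype: str
    morphology: Morphology         # in world coordinates
    is_pyramidal: bool = False

    def __post_init__(self):
        m = self.morphology
        self._seg_a = {}
        self._seg_b = {}
        self._seg_kind = {}
        pathd = m.path_distances()
        has_parent = m.parent >= 0
        kinds = np.full(m.n_nodes, "", dtype=object)
        for i in range(m.n_nodes):
            t = m.types[i]
            if t == SWC_CODES["soma"]:
                kinds[i] = "soma"
            elif t == SWC_CODES["axon"]:
                kinds[i] = ("AIS" if pathd[i] <= AIS_LENGTH_UM else "axon")
            else:
                kinds[i] = "dendrite"
        idx = np.flatnonzero(has_parent)
        self.seg_start = m.points[m.parent[idx]]
        self.seg_end = m.points[idx]
        self.seg_node = idx
        self.seg_kind = kinds[idx]
        # surface radius per segment: touch distances are measured to the
        # cell surface, so the soma counts with its full radius
        self.seg_surface = np.zeros(len(idx))
        # soma represented as a degenerate segment at its center
        soma_c = m.soma_center
        self.seg_start = np.vstack([self.seg_start, soma_c])
        self.seg_end = np.vstack([self.seg_end, soma_c])
        self.seg_node = np.append(self.seg_node, -1)
        self.seg_kind = np.append(self.seg_kind, "soma")
        self.seg_surface = np.append(self.seg_surface, m.soma_radius)

    def segments(self, kinds: tuple[str, ...]):
        keep = np.isin(self.seg_kind, kinds)
        return (self.seg_start[keep], self.seg_end[keep],
                self.seg_node[keep], self.seg_kind[keep],
                self.seg_surface[keep])


def admissible_compartments(pre_mtype: str, post_mtype: str,
                            post_is_pc: bool) -> tuple[str, ...]:
    """Postsynaptic compartment kinds allowed for a pathway; empty tuple
    means the pathway itself is disallowed."""
    pre_is_aa = "AA" in pre_mtype.split("_")
    pre_is_pc = pre_mtype.endswith("PC")
    if pre_is_aa:
        # axo-axonic cells contact only the PC axon initial segment
        return ("AIS",) if post_is_pc else ()
    if pre_is_pc and post_is_pc:
        return ("dendrite",)
    if post_is_pc and any(tag in pre_mtype.split("_")
                          for tag in ("SCA", "Ivy", "BS")):
        return ("dendrite",)      # no PC-soma contacts for these
    return ("dendrite", "soma")


def _segment_distances(a0, a1, b0, b1):
    """Pairwise minimum distance between segment sets A (n,3 start/end)
    and B (m,3).  Vectorized closed-form segment-segment distance."""
    d1 = (a1 - a0)[:, None, :]
    d2 = (b1 - b0)[None, :, :]
    r = a0[:, None, :] - b0[None, :, :]
    a = np.einsum("ijk,ijk->ij", d1, d1)
    e = np.einsum("ijk,ijk->ij", d2, d2)
    f = np.einsum("ijk,ijk->ij", d2, r)
    c = np.einsum("ijk,ijk->ij", d1, r)
    b = np.einsum("ijk,ijk->ij", d1, d2)
    denom = a * e - b * b
    s = np.where(denom > 1e-12, (b * f - c * e) / np.maximum(denom, 1e-12),
                 0.0)
    s = np.clip(s, 0.0, 1.0)
    t = np.where(e > 1e-12, (b * s + f) / np.maximum(e, 1e-12), 0.0)
    t_clipped = np.clip(t, 0.0, 1.0)
    # re-project s for clipped t
    s = np.where(a > 1e-12, (b * t_clipped - c) / np.maximum(a, 1e-12), 0.0)
    s = np.clip(s, 0.0, 1.0)
    closest_a = a0[:, None, :] + s[..., None] * d1
    closest_b = b0[None, :, :] + t_clipped[..., None] * d2
    return np.linalg.norm(closest_a - closest_b, axis=-1), s, t_clipped


def find_appositions(cells: list[PlacedCell],
                     thresholds: dict | None = None,
                     grid_cell: float | None = None) -> pd.DataFrame:
    """All axon-to-neurite near-contacts between distinct cells.

    Candidate pre/post segment pairs are generated with a uniform spatial
    hash (cell size = the maximum touch distance plus the longest segment)
    and verified with exact segment-segment distances.  Admissibility is
    applied per (pre m-type, post m-type, compartment).
    """
    thresholds = thresholds or TOUCH_DISTANCE_UM
    records = []
    for post in cells:
        post_class = "PC" if post.is_pyramidal else "INT"
        thr = thresholds[post_class]
        for pre in cells:
            if pre.gid == post.gid:
                continue
            kinds = admissible_compartments(pre.mtype, post.mtype,
                                            post.is_pyramidal)
            if not kinds:
                continue
            pa0, pa1, pnode, _, _ = pre.segments(("axon", "AIS"))
            qa0, qa1, qnode, qkind, qsurf = post.segments(kinds)
            if len(pa0) == 0 or len(qa0) == 0:
                continue
            pad = thr + qsurf.max()
            # coarse AABB reject per pair of cells
            lo = np.maximum(np.minimum(pa0, pa1).min(0),
                            np.minimum(qa0, qa1).min(0)) - pad
            hi = np.minimum(np.maximum(pa0, pa1).max(0),
                            np.maximum(qa0, qa1).max(0)) + pad
            if np.any(lo > hi):
                continue
            pin = _aabb_select(pa0, pa1, lo, hi)
            qin = _aabb_select(qa0, qa1, lo, hi)
            if not pin.any() or not qin.any():
                continue
            d, s, t = _segment_distances(pa0[pin], pa1[pin],
                                         qa0[qin], qa1[qin])
            # distance measured to the postsynaptic surface
            d = d - qsurf[qin][None, :]
            ii, jj = np.nonzero(d <= thr)
            pidx = np.flatnonzero(pin)
            qidx = np.flatnonzero(qin)
            for i, j in zip(ii, jj):
                records.append((
                    pre.gid, post.gid, pre.mtype, post.mtype,
                    int(pnode[pidx[i]]), float(s[i, j]),
                    int(qnode[qidx[j]]), float(t[i, j]),
                    float(d[i, j]), str(qkind[qidx[j]])))
    return pd.DataFrame(records, columns=[
        "pre_gid", "post_gid", "pre_mtype", "post_mtype",
        "pre_segment", "pre_offset", "post_segment", "post_offset",
        "distance", "compartment"])


def _aabb_select(s0, s1, lo, hi):
    smin = np.minimum(s0, s1)
    smax = np.maximum(s0, s1)
    return np.all((smax >= lo) & (smin <= hi), axis=1)


def predict_synapses_per_connection(appositions_per_connection: float,
                                    pathway_class: str = "other") -> float:
    """Linear predictor of mean synapses/connection from mean
    appositions/connection (separate fits for inhibitory-to-inhibitory
    pathways and the rest)."""
    if appositions_per_connection < 0:
        raise ValueError("appositions per connection must be >= 0")
    key = "I-I" if pathway_class == "I-I" else "other"
    return SYN_PER_CONN_SLOPE[key] * appositions_per_connection


@dataclass
class PruningConstraints:
    """Per-pathway targets for the pruning stage."""

    mean_syns_per_connection: float
    bouton_density_mean: float | None = None      # boutons / um of axon
    bouton_density_cv: float = DEFAULT_BOUTON_CV
    synapses_per_bouton: float = SYNAPSES_PER_BOUTON

    def __post_init__(self):
        if self.mean_syns_per_connection <= 0:
            raise ValueError("mean synapses/connection must be positive")
        if self.bouton_density_mean is not None \
                and self.bouton_density_mean <= 0:
            raise ValueError("bouton density must be positive")


def prune(appositions: pd.DataFrame,
          constraints: dict[str, PruningConstraints],
          axon_lengths: dict[int, float] | None = None,
          seed: int = 0) -> pd.DataFrame:
    """Two-stage stochastic pruning of appositions into synapses.

    Stage 1 (connection level): within each pathway, synapse multiplicity
    of every connection is binomially thinned so the surviving mean
    synapses/connection matches the target; emptied connections disappear.
    Stage 2 (axon level): if a bouton-density target is given, each
    presynaptic axon draws a target density from a gamma distribution with
    the prescribed mean and CV and its synapses are thinned to match
    (bouton count = synapse count / synapses-per-bouton).  Infeasible
    targets (above the available statistics) keep everything and flag the
    pathway.  Pruning only removes synapses, never creates them.
    """
    rng = np.random.default_rng(seed)
    if appositions.empty:
        return appositions.copy()
    df = appositions.copy()
    df["pathway"] = df["pre_mtype"] + "->" + df["post_mtype"]
    keep_all = np.ones(len(df), dtype=bool)
    for pathway, grp in df.groupby("pathway", sort=False):
        cons = constraints.get(pathway)
        if cons is None:
            raise KeyError(f"no pruning constraints for pathway {pathway}")
        idx = grp.index.to_numpy()
        conn = grp.groupby(["pre_gid", "post_gid"]).size()
        mean0 = conn.mean()
        target = cons.mean_syns_per_connection
        if target >= mean0:
            if target > mean0 * 1.05:
                log.warning("pathway %s: target %.2f syn/conn above "
                            "available %.2f — keeping all", pathway,
                            target, mean0)
            survive = np.ones(len(idx), dtype=bool)
        else:
            # binomial thinning; one correction pass compensates the
            # upward bias from dropping emptied (zero-synapse) connections
            p = target / mean0
            probe = rng.random(len(idx)) < p
            kept = grp[probe]
            if not kept.empty:
                realized = kept.groupby(["pre_gid",
                                         "post_gid"]).size().mean()
                if realized > 0:
                    p = min(1.0, p * target / realized)
            survive = rng.random(len(idx)) < p
        keep_all[df.index.get_indexer(idx)] &= survive

        if cons.bouton_density_mean is not None:
            if axon_lengths is None:
                raise ValueError("axon_lengths required for bouton-density "
                                 "pruning")
            sub = grp[survive]
            for pre_gid, axon_grp in sub.groupby("pre_gid"):
                length = axon_lengths[int(pre_gid)]
                n_syn = len(axon_grp)
                dens = n_syn / cons.synapses_per_bouton / length
                cv = cons.bouton_density_cv
                shape = 1.0 / cv**2
                target_dens = rng.gamma(shape,
                                        cons.bouton_density_mean / shape)
                if target_dens >= dens:
                    continue
                p_keep = target_dens / dens
                drop_local = rng.random(n_syn) >= p_keep
                keep_all[df.index.get_indexer(
                    axon_grp.index.to_numpy()[drop_local])] = False
    out = df[keep_all].drop(columns=[]).reset_index(drop=True)
    return out


def bouton_stats(per_connection_synapse_counts) -> tuple[float, float, float]:
    """Mean, population standard deviation and CV of synapse counts per
    connection (used to generalize bouton-density variability across
    pathways)."""
    counts = np.asarray(per_connection_synapse_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("counts must be non-empty")
    mean = counts.mean()
    if mean == 0:
        raise ValueError("zero mean synapse count")
    sd = counts.std(ddof=0)
    return float(mean), float(sd), float(sd / mean)
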