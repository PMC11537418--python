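"""Neuron morphologies: SWC I/O, curation, cloning, alignment, validation.

A morphology is a rooted tree of typed nodes (soma, axon, basal and apical
dendrite).  The module covers the library-building steps — shrinkage
correction, isotropic scale cloning with branch jitter, PCA re-alignment of
pyramidal axons — and the validation statistics: the median-over-visible-
spread (MVS) score for morphometric feature populations and the
topological persistence diagram of branch start/end radial distances
(elder rule), with Gaussian persistence images.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

SWC_TYPES = {1: "soma", 2: "axon", 3: "basal", 4: "apical"}
SWC_CODES = {v: k for k, v in SWC_TYPES.items()}
NEURITE_TYPES = ("axon", "basal", "apical")


@dataclass
class Morphology:
    """Rooted neurite tree.

    ``parent[i]`` is the array index of node i's parent (-1 for the root);
    parents always precede children.  ``types`` holds SWC integer codes.
    """

    points: np.ndarray             # (n, 3) um
    radii: np.ndarray              # (n,)
    types: np.ndarray              # (n,) int SWC codes
    parent: np.ndarray             # (n,) int, -1 for root
    name: str = "morphology"
    provenance: str = "original"   # original | repaired | clone

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.types = np.asarray(self.types, dtype=int)
        self.parent = np.asarray(self.parent, dtype=int)

    def validate(self) -> None:
        if (self.parent[0] != -1) or (self.parent[1:] < 0).any():
            raise ValueError("single root required, parents precede children")
        if np.any(self.parent >= np.arange(len(self.parent))):
            raise ValueError("parent must precede child")
        if self.types[0] != SWC_CODES["soma"]:
            raise ValueError("root must be a soma node")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")

    # -- structure helpers -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.points)

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        return ch

    def neurite_mask(self, neurite: str) -> np.ndarray:
        return self.types == SWC_CODES[neurite]

    @property
    def soma_center(self) -> np.ndarray:
        return self.points[self.types == SWC_CODES["soma"]].mean(axis=0)

    @property
    def soma_radius(self) -> float:
        soma = self.types == SWC_CODES["soma"]
        if soma.sum() == 1:
            return float(self.radii[soma][0])
        # multi-point soma: reach of the contour around the center
        d = np.linalg.norm(self.points[soma] - self.soma_center, axis=1)
        return float(max(d.max(), self.radii[soma].max()))

    def segment_lengths(self) -> np.ndarray:
        """Per-node length of the segment to the parent (0 for the root)."""
        out = np.zeros(self.n_nodes)
        has = self.parent >= 0
        out[has] = np.linalg.norm(
            self.points[has] - self.points[self.parent[has]], axis=1)
        return out

    def total_length(self, neurite: str | None = None) -> float:
        seg = self.segment_lengths()
        if neurite is None:
            keep = self.types != SWC_CODES["soma"]
        else:
            keep = self.neurite_mask(neurite)
        return float(seg[keep].sum())

    def path_distances(self) -> np.ndarray:
        """Path length from the root to each node."""
        seg = self.segment_lengths()
        out = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            out[i] = out[self.parent[i]] + seg[i]
        return out

    def transformed(self, rotation: np.ndarray | None = None,
                    translation=(0.0, 0.0, 0.0)) -> "Morphology":
        pts = self.points
        if rotation is not None:
            pts = pts @ np.asarray(rotation).T
        return replace(self, points=pts + np.asarray(translation, float))


# --------------------------------------------------------------------------
# SWC I/O


def read_swc(path: str | Path) -> Morphology:
    """Read an SWC file (ids remapped to 0-based contiguous order)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split()
        rows.append((int(f[0]), int(f[1]), float(f[2]), float(f[3]),
                     float(f[4]), float(f[5]), int(f[6])))
    if not rows:
        raise ValueError(f"no SWC records in {path}")
    ids = {r[0]: i for i, r in enumerate(rows)}
    points = np.array([r[2:5] for r in rows])
    radii = np.array([r[5] for r in rows])
    types = np.array([r[1] for r in rows])
    parent = np.array([-1 if r[6] == -1 else ids[r[6]] for r in rows])
    m = Morphology(points, radii, types, parent, name=Path(path).stem)
    m.validate()
    return m


def write_swc(m: Morphology, path: str | Path) -> None:
    lines = [f"# {m.name} ({m.provenance})"]
    for i in range(m.n_nodes):
        p = -1 if m.parent[i] < 0 else m.parent[i] + 1
        x, y, z = m.points[i]
        lines.append(
            f"{i + 1} {m.types[i]} {x:.17g} {y:.17g} {z:.17g} "
            f"{m.radii[i]:.17g} {p}")
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# curation / cloning / alignment


def curate(m: Morphology, shrink_z: float = 0.25,
           shrink_xy: float = 0.10) -> Morphology:
    """Repair and shrink-correct a reconstruction.

    Centers the soma at the origin, removes zero-length segments, and
    expands coordinates by (1 + shrink_xy) in x, y and (1 + shrink_z) in z
    to undo tissue shrinkage.  A morphology without axon nodes is flagged
    with ``ValueError`` (such cells are dropped from the library).
    """
    m.validate()
    if not m.neurite_mask("axon").any():
        raise ValueError(f"{m.name}: no axon — cell removed from library")
    pts = m.points - m.soma_center
    pts = pts * np.array([1 + shrink_xy, 1 + shrink_xy, 1 + shrink_z])
    cur = replace(m, points=pts, provenance="repaired")
    return _remove_zero_length(cur)


def _remove_zero_length(m: Morphology, atol: float = 1e-12) -> Morphology:
    seg = m.segment_lengths()
    drop = (seg <= atol) & (m.parent >= 0) \
        & (m.types == m.types[np.maximum(m.parent, 0)]) \
        & (m.types != SWC_CODES["soma"])
    if not drop.any():
        return m
    keep = ~drop
    remap = -np.ones(m.n_nodes, dtype=int)
    remap[keep] = np.arange(keep.sum())
    new_parent = []
    for i in np.flatnonzero(keep):
        p = m.parent[i]
        while p >= 0 and not keep[p]:
            p = m.parent[p]
        new_parent.append(-1 if p < 0 else remap[p])
    return replace(m, points=m.points[keep], radii=m.radii[keep],
                   types=m.types[keep], parent=np.array(new_parent))


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        return np.eye(3)
    x, y, z = axis / n
    c, s = np.cos(angle), np.sin(angle)
    cc = 1 - c
    return np.array([
        [c + x * x * cc, x * y * cc - z * s, x * z * cc + y * s],
        [y * x * cc + z * s, c + y * y * cc, y * z * cc - x * s],
        [z * x * cc - y * s, z * y * cc + x * s, c + z * z * cc]])


def scale_clone(m: Morphology, scale: float, jitter_seed: int | None = None,
                sigma_rot: float = 0.1, sigma_len: float = 0.05,
                max_scale: float = 0.15) -> Morphology:
    """Produce a clone: isotropic scaling by (1 + scale) about the soma
    plus seeded per-branch jitter.

    Each first-order subtree off a branch point is rotated by an angle
    ~ N(0, sigma_rot radians) about its parent direction, and each branch's
    offsets are scaled by ~ N(1, sigma_len).  ``jitter_seed=None`` disables
    jitter (pure scaling).
    """
    if abs(scale) > max_scale + 1e-12:
        raise ValueError(f"|scale| must be <= {max_scale}")
    m.validate()
    pts = (m.points - m.soma_center) * (1 + scale) + m.soma_center
    clone = replace(m, points=pts, radii=m.radii * (1 + scale),
                    provenance="clone", name=m.name + "_clone")
    if jitter_seed is None:
        return clone
    rng = np.random.default_rng(jitter_seed)
    children = clone.children()
    pts = clone.points.copy()
    order = [i for i in range(clone.n_nodes)
             if len(children[i]) > 1 or clone.parent[i] < 0]
    for b in order:
        for c in children[b]:
            if clone.types[c] == SWC_CODES["soma"]:
                continue
            sub = _subtree(clone, c)
            axis = pts[c] - pts[b]
            rot = _rotation_about(axis, rng.normal(0.0, sigma_rot))
            lsc = max(0.1, rng.normal(1.0, sigma_len))
            rel = (pts[sub] - pts[b]) @ rot.T * lsc
            pts[sub] = pts[b] + rel
    return replace(clone, points=pts)


def _subtree(m: Morphology, root: int) -> np.ndarray:
    children = m.children()
    out, stack = [], [root]
    while stack:
        i = stack.pop()
        out.append(i)
        stack.extend(children[i])
    return np.array(sorted(out))


def pca_align_axon(m: Morphology, original: Morphology | None = None,
                   reject_ratio: float = 3.3) -> Morphology | None:
    """Align the axon principal axis with the transverse (x) axis.

    The rotation taking the axon point cloud's first principal component
    to +x is applied to the whole morphology; the caudal side is oriented
    so that the axon centroid has non-negative x.  If ``original`` is
    given and the aligned clone's axonal z-range exceeds ``reject_ratio``
    times the original's, the clone is rejected (returns None).
    Degenerate (collinear) axons fall back to the first-to-last-point
    direction.
    """
    ax = m.neurite_mask("axon")
    if ax.sum() < 3:
        raise ValueError("axon with >= 3 points required")
    pts = m.points[ax]
    centered = pts - pts.mean(axis=0)
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    if not np.isfinite(evals[-1]) or evals[-1] < 1e-12:
        axis = pts[-1] - pts[0]
        axis = axis / np.linalg.norm(axis)
    else:
        axis = evecs[:, -1]
    target = np.array([1.0, 0.0, 0.0])
    v = np.cross(axis, target)
    c = float(axis @ target)
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]],
                       [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx / (1 + c)
    aligned = m.transformed(rotation=rot)
    if aligned.points[ax][:, 0].mean() < 0:
        aligned = aligned.transformed(rotation=np.diag([-1.0, 1.0, -1.0]))
    if original is not None:
        z_new = np.ptp(aligned.points[ax][:, 2])
        oax = original.neurite_mask("axon")
        z_orig = np.ptp(original.points[oax][:, 2])
        if z_orig > 0 and z_new > reject_ratio * z_orig:
            return None
    return aligned


# --------------------------------------------------------------------------
# validation statistics


def whisker_union_ovs(a: np.ndarray, b: np.ndarray) -> float:
    """Default overall-visible-spread: width of the union of the two
    populations' boxplot whisker intervals [Q1 - 1.5 IQR, Q3 + 1.5 IQR]."""
    los, his = [], []
    for pop in (a, b):
        q1, q3 = np.percentile(pop, [25, 75])
        iqr = q3 - q1
        los.append(q1 - 1.5 * iqr)
        his.append(q3 + 1.5 * iqr)
    return float(max(his) - min(los))


def mvs_score(a, b, ovs=whisker_union_ovs) -> float:
    """Median-over-visible-spread score between two feature populations.

    |median(a) - median(b)| / OVS(a, b).  Scores below 0.3 indicate good
    agreement.  Zero OVS with equal medians gives 0; with unequal medians,
    +inf.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("populations must be non-empty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("populations must be finite")
    num = abs(float(np.median(a)) - float(np.median(b)))
    denom = float(ovs(a, b))
    if denom == 0:
        return 0.0 if num == 0 else float("inf")
    return num / denom


MVS_GOOD_AGREEMENT = 0.3


@dataclass
class PersistenceDiagram:
    """Bars of (start, end) radial distances, one per branch component."""

    bars: np.ndarray               # (n, 2) um: (birth=tip, death=merge)
    neurite: str = "axon"

    def __post_init__(self):
        self.bars = np.asarray(self.bars, dtype=float).reshape(-1, 2)


def persistence_diagram(m: Morphology, neurite: str) -> PersistenceDiagram:
    """Topological persistence of a neurite under the radial filtration.

    The filtration function is Euclidean distance from the soma surface
    (soma radius subtracted, floored at 0).  Components are born at the
    tips and merge at branch points under the elder rule: the component
    whose tip is farther survives; each terminated component contributes
    one bar (birth = its tip distance, death = the merge distance; the
    last survivor of each stem dies at the neurite root).  The number of
    bars equals the number of leaves.
    """
    if neurite not in NEURITE_TYPES:
        raise ValueError(f"unknown neurite {neurite!r}")
    mask = m.neurite_mask(neurite)
    if not mask.any():
        return PersistenceDiagram(np.empty((0, 2)), neurite)
    center = m.soma_center
    dist = np.maximum(
        np.linalg.norm(m.points - center, axis=1) - m.soma_radius, 0.0)
    children = m.children()
    bars: list[tuple[float, float]] = []
    # farthest-tip distance of each node's neurite subtree (bottom-up)
    far = np.where(mask, dist, 0.0)
    for i in range(m.n_nodes - 1, -1, -1):
        kids = [c for c in children[i] if mask[c]]
        if kids and mask[i]:
            far[i] = max(dist[i], max(far[c] for c in kids))
    for i in range(m.n_nodes):
        if not mask[i]:
            continue
        kids = [c for c in children[i] if mask[c]]
        if len(kids) > 1:
            # elder rule: all but the farthest-reaching child die here
            far_kid = max(kids, key=lambda c: far[c])
            for c in kids:
                if c != far_kid:
                    bars.append((far[c], dist[i]))
    # the surviving component of each stem dies at the neurite root
    roots = [i for i in range(m.n_nodes)
             if mask[i] and (m.parent[i] < 0 or not mask[m.parent[i]])]
    for rt in roots:
        p = m.parent[rt]
        bars.append((far[rt], dist[p] if p >= 0 else 0.0))
    return PersistenceDiagram(np.array(bars), neurite)


def persistence_image(diagram, grid_size: int = 64,
                      bounds: tuple | None = None,
                      bandwidth: float | None = None) -> tuple:
    """Gaussian-kernel density of persistence bars on a 2-D grid.

    Accepts a single diagram or a population (bars pooled).  Returns
    ``(image, (xs, ys))``; the image integrates to 1.
    """
    diagrams = ([diagram] if isinstance(diagram, PersistenceDiagram)
                else list(diagram))
    stacks = [d.bars for d in diagrams if len(d.bars)]
    if not stacks:
        raise ValueError("no bars in diagram(s)")
    bars = np.vstack(stacks)
    if bounds is None:
        lo, hi = bars.min(), bars.max()
        pad = 0.25 * max(hi - lo, 1.0)
        bounds = (lo - pad, hi + pad)
    xs = np.linspace(bounds[0], bounds[1], grid_size)
    ys = np.linspace(bounds[0], bounds[1], grid_size)
    if bandwidth is None:
        bandwidth = (bounds[1] - bounds[0]) / 20.0
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    img = np.zeros((grid_size, grid_size))
    for bx, by in bars:
        img += np.exp(-((gx - bx) ** 2 + (gy - by) ** 2)
                      / (2 * bandwidth ** 2))
    cell = (xs[1] - xs[0]) * (ys[1] - ys[0])
    total = img.sum() * cell
    if total > 0:
        img /= total
    return img, (xs, ys)


def persistence_image_diff(pop_a, pop_b, grid_size: int = 64,
                           bounds: tuple | None = None,
                           bandwidth: float | None = None) -> np.ndarray:
    """Difference of two populations' persistence images on a shared
    grid."""
    all_bars = np.vstack([d.bars for d in list(pop_a) + list(pop_b)
                          if len(d.bars)])
    if bounds is None:
        lo, hi = all_bars.min(), all_bars.max()
        pad = 0.25 * max(hi - lo, 1.0)
        bounds = (lo - pad, hi + pad)
    img_a, _ = persistence_image(pop_a, grid_size, bounds, bandwidth)
    img_b, _ = persistence_image(pop_b, grid_size, bounds, bandwidth)
    return img_a - img_b
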