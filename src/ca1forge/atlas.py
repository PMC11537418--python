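"""Parametric (l, t, r) coordinate system on a voxelized region.

The curved CA1 volume is parameterized by three coordinates in [0, 1]:
``l`` along the longitudinal (dorso-ventral) axis, ``t`` along the
transverse (proximo-distal) axis, and ``r`` along the radial (laminar)
axis.  The pipeline is:

1. :func:`smooth_mask` regularizes a raw voxel mask (Gaussian + closing).
2. :func:`compute_centerline` follows the ridge of the distance transform
   between two seed points (Dijkstra on a distance-weighted voxel graph),
   smoothed into a spline.
3. :func:`build_coordinates` cuts the volume into cross-section planes
   perpendicular to the centerline (one plane per voxel of arc length,
   giving ``l``), resamples the upper and lower boundary shells within each
   plane into matched splines (parameter ``u`` giving ``t``), and assigns
   ``r`` as the relative position of the voxel along the segment that joins
   the lower-shell point to the upper-shell point with the same ``u``
   (r = 0 on the lower / stratum-oriens side, r = 1 on the upper / pial
   side).
4. :func:`assign_layers` slices ``r`` into the four strata by cumulative
   proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, sparse
from scipy.interpolate import interp1d, splev, splprep
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)

LAYER_NAMES = ("SO", "SP", "SR", "SLM")  # ordered from r = 0


# --------------------------------------------------------------------------
# domain types


@dataclass
class RegionMask:
    """Dense boolean occupancy grid in world micrometres."""

    occupancy: np.ndarray          # bool, shape (nx, ny, nz)
    voxel_size: float = 1.0        # um per voxel edge (isotropic)
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        self.origin = np.asarray(self.origin, dtype=float)
        if not self.occupancy.any():
            raise ValueError("empty region mask")

    @property
    def n_voxels(self) -> int:
        return int(self.occupancy.sum())

    def voxel_centers(self) -> np.ndarray:
        """World coordinates (um) of all in-mask voxel centers, (N, 3)."""
        idx = np.argwhere(self.occupancy)
        return self.origin + (idx + 0.5) * self.voxel_size

    def world_to_index(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.floor((pts - self.origin) / self.voxel_size).astype(int)

    def contains(self, points) -> np.ndarray:
        idx = self.world_to_index(points)
        ok = np.all((idx >= 0) & (idx < self.occupancy.shape), axis=1)
        out = np.zeros(len(idx), dtype=bool)
        out[ok] = self.occupancy[tuple(idx[ok].T)]
        return out


@dataclass
class Centerline:
    """Arc-length parameterized cubic spline through the volume core."""

    control_points: np.ndarray     # (n, 3) world um, ordered A -> B
    _tck: tuple = None
    _s_of_u: interp1d = None
    arc_length: float = 0.0

    @classmethod
    def from_points(cls, points: np.ndarray, smoothing: float = 0.0):
        points = np.asarray(points, dtype=float)
        if len(points) < 2:
            raise ValueError("need at least two centerline points")
        k = min(3, len(points) - 1)
        tck, _ = splprep(points.T, s=smoothing, k=k)
        dense_u = np.linspace(0, 1, 64 * len(points))
        dense = np.column_stack(splev(dense_u, tck))
        seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        total = cum[-1]
        if total <= 0:
            raise ValueError("degenerate centerline (zero arc length)")
        # map normalized arc length s in [0,1] -> spline parameter u
        s_of_u = interp1d(cum / total, dense_u, assume_sorted=True)
        return cls(points, tck, s_of_u, total)

    def point(self, s) -> np.ndarray:
        """Curve point at normalized arc length ``s`` in [0, 1]."""
        u = self._s_of_u(np.clip(s, 0.0, 1.0))
        return np.column_stack(splev(u, self._tck)) if np.ndim(s) \
            else np.array(splev(float(u), self._tck))

    def tangent(self, s) -> np.ndarray:
        u = self._s_of_u(np.clip(s, 0.0, 1.0))
        d = np.column_stack(splev(np.atleast_1d(u), self._tck, der=1))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        return d if np.ndim(s) else d[0]


@dataclass
class CoordinateField:
    """Per-voxel parametric coordinates and radial direction vectors."""

    l: np.ndarray                  # noqa: E741 - domain name
    t: np.ndarray
    r: np.ndarray
    direction: np.ndarray          # (nx, ny, nz, 3) unit vectors, NaN outside
    mask: RegionMask
    n_filled: int = 0              # voxels filled from nearest neighbor

    def validate(self, atol: float = 1e-6) -> None:
        occ = self.mask.occupancy
        for name, arr in (("l", self.l), ("t", self.t), ("r", self.r)):
            vals = arr[occ]
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"non-finite {name} inside mask")
            if vals.min() < -atol or vals.max() > 1 + atol:
                raise ValueError(f"{name} outside [0, 1]")
            if np.isfinite(arr[~occ]).any():
                raise ValueError(f"finite {name} outside mask")
        norms = np.linalg.norm(self.direction[occ], axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("direction vectors not unit norm")


# --------------------------------------------------------------------------
# operations


def smooth_mask(mask: RegionMask, sigma: float = 1.0,
                closing_radius: int = 1,
                preserve_bulk: bool = True) -> RegionMask:
    """Regularize a mask with a Gaussian filter plus morphological closing.

    ``sigma`` is in micrometres; the Gaussian-filtered occupancy is
    re-thresholded at 0.5, closed with a cubic structuring element of the
    given voxel radius, and reduced to its largest connected component
    (isolated voxels removed).  With ``preserve_bulk`` the result is
    unioned with the morphologically opened input, so smoothing removes
    noise and closes holes without eroding genuine structure such as sharp
    convex corners.  The voxel-count change is logged.
    """
    occ = mask.occupancy
    sig_vox = sigma / mask.voxel_size
    smoothed = ndimage.gaussian_filter(occ.astype(float), sig_vox) > 0.5
    if closing_radius > 0:
        struct = np.ones((2 * closing_radius + 1,) * 3, dtype=bool)
        smoothed = ndimage.binary_closing(smoothed, structure=struct)
    if preserve_bulk:
        struct = np.ones((3, 3, 3), dtype=bool)
        smoothed |= ndimage.binary_opening(occ, structure=struct)
    labels, n = ndimage.label(smoothed)
    if n == 0:
        raise ValueError("smoothing removed the entire mask")
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        smoothed = labels == (1 + np.argmax(counts))
    change = (smoothed.sum() - occ.sum()) / occ.sum()
    log.info("smooth_mask: voxel count change %+.2f%%", 100 * change)
    return replace(mask, occupancy=smoothed)


def compute_centerline(mask: RegionMask, endpoints,
                       smoothing: float | None = None,
                       subsample: int = 4) -> Centerline:
    """Trace the innermost path between two seed points.

    The path follows local maxima of the Euclidean distance transform:
    voxel-graph edges are weighted by step length divided by the squared
    interior distance, and the globally shortest weighted path is found
    with Dijkstra's algorithm, then fitted with a cubic spline.
    ``endpoints`` are two world-coordinate points inside the mask.
    """
    endpoints = np.asarray(endpoints, dtype=float)
    if endpoints.shape != (2, 3):
        raise ValueError("endpoints must be two 3-D points")
    inside = mask.contains(endpoints)
    if not inside.all():
        raise ValueError("endpoints must lie inside the mask")
    occ = mask.occupancy
    dt = ndimage.distance_transform_edt(occ) * mask.voxel_size

    idx = np.argwhere(occ)
    flat = -np.ones(occ.shape, dtype=np.int64)
    flat[tuple(idx.T)] = np.arange(len(idx))
    # 26-neighborhood edges
    offsets = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                        for k in (-1, 0, 1) if (i, j, k) > (0, 0, 0)])
    rows, cols, weights = [], [], []
    dt_flat = dt[tuple(idx.T)]
    for off in offsets:
        nbr = idx + off
        ok = np.all((nbr >= 0) & (nbr < occ.shape), axis=1)
        nbr_id = np.full(len(idx), -1, dtype=np.int64)
        nbr_id[ok] = flat[tuple(nbr[ok].T)]
        ok &= nbr_id >= 0
        step = np.linalg.norm(off) * mask.voxel_size
        mid = 0.5 * (dt_flat[ok] + dt_flat[nbr_id[ok]])
        rows.append(np.flatnonzero(ok))
        cols.append(nbr_id[ok])
        weights.append(step / (0.5 * mask.voxel_size + mid) ** 2)
    graph = sparse.csr_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(idx), len(idx)))
    graph = graph + graph.T

    ends = mask.world_to_index(endpoints)
    src, dst = flat[tuple(ends[0])], flat[tuple(ends[1])]
    dist, pred = dijkstra(graph, indices=src, return_predecessors=True)
    if not np.isfinite(dist[dst]):
        raise ValueError("endpoints are not connected within the mask")
    path = [dst]
    while path[-1] != src:
        path.append(pred[path[-1]])
    path_idx = idx[path[::-1]]
    points = mask.origin + (path_idx + 0.5) * mask.voxel_size
    if subsample > 1 and len(points) > 2 * subsample:
        keep = np.r_[np.arange(0, len(points) - 1, subsample),
                     len(points) - 1]
        points = points[keep]
    if smoothing is None:
        # allow ~1 voxel of residual per control point: the raw path is
        # quantized to the voxel grid and its jitter is not meaningful
        smoothing = len(points) * mask.voxel_size ** 2
    return Centerline.from_points(points, smoothing=smoothing)


def _plane_frames(centerline: Centerline, n_planes: int):
    s = np.linspace(0.0, 1.0, n_planes)
    anchors = centerline.point(s)
    tangents = centerline.tangent(s)
    return s, anchors, tangents


def _resample_polyline(pts2d: np.ndarray, order_axis: np.ndarray,
                       n_samples: int) -> np.ndarray:
    """Order in-plane shell points along ``order_axis`` and resample to
    ``n_samples`` points uniform in normalized chord length."""
    proj = pts2d @ order_axis
    order = np.argsort(proj, kind="stable")
    pts = pts2d[order]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] <= 0:
        return np.repeat(pts[:1], n_samples, axis=0)
    u = cum / cum[-1]
    # collapse duplicate parameters
    uu, first = np.unique(u, return_index=True)
    fx = interp1d(uu, pts[first, 0], assume_sorted=True)
    fy = interp1d(uu, pts[first, 1], assume_sorted=True)
    uq = np.linspace(0, 1, n_samples)
    return np.column_stack([fx(uq), fy(uq)])


def build_coordinates(mask: RegionMask, centerline: Centerline,
                      upper_shell: np.ndarray, lower_shell: np.ndarray,
                      n_t_samples: int = 65,
                      max_unassigned: float = 0.01) -> CoordinateField:
    """Assign (l, t, r) coordinates to every in-mask voxel.

    ``upper_shell`` and ``lower_shell`` are boolean voxel grids marking the
    two boundary surfaces (pial side and stratum-oriens side).  The
    conventions are r = 0 at the lower shell, r = 1 at the upper shell,
    l = 0 at the first centerline endpoint; the sign of the transverse
    parameterization is fixed by the orientation of (tangent, transverse,
    radial) as a right-handed frame, which makes the construction covariant
    under rigid rotation.
    """
    occ = mask.occupancy
    if (upper_shell & lower_shell).any():
        raise ValueError("upper and lower shells must be disjoint")
    n_planes = max(2, int(round(centerline.arc_length / mask.voxel_size)))
    s_vals, anchors, tangents = _plane_frames(centerline, n_planes)
    tree = cKDTree(anchors)

    def assign_planes(pts):
        # candidate planes by proximity, then choose the plane whose
        # cross-section the point actually lies in (minimal out-of-plane
        # offset); ties break toward lower l by argmin on sorted indices
        k_cand = min(12, n_planes)
        _, cand = tree.query(pts, k=k_cand)
        cand = np.atleast_2d(cand)
        cand.sort(axis=1)
        off = np.abs(np.einsum(
            "ijk,ijk->ij", pts[:, None, :] - anchors[cand], tangents[cand]))
        return cand[np.arange(len(pts)), np.argmin(off, axis=1)]

    vox_idx = np.argwhere(occ)
    vox_pts = mask.origin + (vox_idx + 0.5) * mask.voxel_size
    vox_plane = assign_planes(vox_pts)

    def shell_points(shell):
        sidx = np.argwhere(shell)
        spts = mask.origin + (sidx + 0.5) * mask.voxel_size
        return spts, assign_planes(spts)

    up_pts, up_plane = shell_points(np.asarray(upper_shell, dtype=bool))
    lo_pts, lo_plane = shell_points(np.asarray(lower_shell, dtype=bool))

    shape = occ.shape
    l_arr = np.full(shape, np.nan)
    t_arr = np.full(shape, np.nan)
    r_arr = np.full(shape, np.nan)
    dir_arr = np.full(shape + (3,), np.nan)

    assigned = np.zeros(len(vox_idx), dtype=bool)
    for k in range(n_planes):
        sel = vox_plane == k
        if not sel.any():
            continue

        def near(plane_ids, pts):
            # shells are voxelized more coarsely than the plane stack on
            # their concave side; borrow from neighboring planes as needed
            for w in (1, 2, 3):
                hit = np.abs(plane_ids - k) <= w
                if hit.sum() >= 2:
                    return pts[hit]
            return pts[:0]

        ups = near(up_plane, up_pts)
        los = near(lo_plane, lo_pts)
        if len(ups) < 2 or len(los) < 2:
            continue
        tangent = tangents[k]
        anchor = anchors[k]
        # in-plane orthonormal basis
        seed = np.array([1.0, 0.0, 0.0])
        if abs(seed @ tangent) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        e1 = seed - (seed @ tangent) * tangent
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(tangent, e1)

        def to2d(p):
            d = p - anchor
            return np.column_stack([d @ e1, d @ e2])

        up2 = to2d(ups)
        lo2 = to2d(los)
        radial_hint = up2.mean(axis=0) - lo2.mean(axis=0)

        # transverse direction: leading principal component of each shell
        # curve separately (the union would be dominated by the radial
        # separation between the shells), signs aligned
        def pc1(pts):
            c = pts - pts.mean(axis=0)
            _, evecs = np.linalg.eigh(np.cov(c.T))
            return evecs[:, -1]

        d_up, d_lo = pc1(up2), pc1(lo2)
        if d_up @ d_lo < 0:
            d_lo = -d_lo
        d_axis = d_up + d_lo
        d_axis /= np.linalg.norm(d_axis)
        # right-handed (tangent, transverse, radial) fixes the t sign
        d3 = d_axis[0] * e1 + d_axis[1] * e2
        rad3 = radial_hint[0] * e1 + radial_hint[1] * e2
        if np.dot(tangent, np.cross(d3, rad3)) < 0:
            d_axis = -d_axis

        up_line = _resample_polyline(up2, d_axis, n_t_samples)
        lo_line = _resample_polyline(lo2, d_axis, n_t_samples)

        seg_vec = up_line - lo_line                  # (M, 2), lower -> upper
        seg_len2 = np.maximum((seg_vec ** 2).sum(axis=1), 1e-12)
        q = to2d(vox_pts[sel])                       # (nv, 2)
        diff = q[:, None, :] - lo_line[None, :, :]   # (nv, M, 2)
        tau = np.clip((diff * seg_vec[None]).sum(-1) / seg_len2, 0.0, 1.0)
        closest = lo_line[None] + tau[..., None] * seg_vec[None]
        d2 = ((q[:, None, :] - closest) ** 2).sum(-1)
        j = np.argmin(d2, axis=1)
        nv = np.arange(len(q))
        uq = np.linspace(0, 1, n_t_samples)

        ii = tuple(vox_idx[sel].T)
        l_arr[ii] = s_vals[k]
        t_arr[ii] = uq[j]
        r_arr[ii] = tau[nv, j]
        seg3 = (seg_vec[j, 0, None] * e1 + seg_vec[j, 1, None] * e2)
        seg3 /= np.linalg.norm(seg3, axis=1, keepdims=True)
        dir_arr[ii] = seg3
        assigned[sel] = True

    n_un = int((~assigned).sum())
    frac = n_un / len(vox_idx)
    if frac > max_unassigned:
        raise ValueError(
            f"{n_un} voxels ({100 * frac:.1f}%) could not be assigned")
    if n_un:
        log.info("build_coordinates: filling %d unassigned voxels", n_un)
        filled = np.zeros(occ.shape, dtype=bool)
        filled[tuple(vox_idx[assigned].T)] = True
        _, nearest = ndimage.distance_transform_edt(
            ~filled, return_indices=True)
        for arr in (l_arr, t_arr, r_arr):
            src = arr[tuple(nearest)]
            arr[tuple(vox_idx[~assigned].T)] = src[tuple(vox_idx[~assigned].T)]
        srcd = dir_arr[tuple(nearest) + (slice(None),)]
        dir_arr[tuple(vox_idx[~assigned].T)] = srcd[tuple(vox_idx[~assigned].T)]

    field_ = CoordinateField(l_arr, t_arr, r_arr, dir_arr, mask,
                             n_filled=n_un)
    field_.validate()
    return field_


def direction_vectors(field_: CoordinateField,
                      presmooth_vox: float = 1.5) -> CoordinateField:
    """Recompute radial direction vectors as the normalized gradient of r.

    The unit vector at each voxel points in the direction of increasing r
    (partial derivative of position with respect to the radial coordinate).
    Zero-gradient voxels are filled from their nearest assigned neighbor.
    """
    occ = field_.mask.occupancy
    r = field_.r.copy()
    # extend r outside the mask from the nearest in-mask voxel so that
    # finite differences at the boundary stay one-sided on valid data
    _, nearest = ndimage.distance_transform_edt(~occ, return_indices=True)
    r_ext = r[tuple(nearest)]
    if presmooth_vox > 0:
        # suppress voxelization staircase before differentiating
        r_ext = ndimage.gaussian_filter(r_ext, presmooth_vox)
    gx, gy, gz = np.gradient(r_ext, field_.mask.voxel_size)
    grad = np.stack([gx, gy, gz], axis=-1)
    norm = np.linalg.norm(grad, axis=-1)
    good = occ & (norm > 1e-12)
    direction = np.full(occ.shape + (3,), np.nan)
    direction[good] = grad[good] / norm[good][..., None]
    n_zero = int((occ & ~good).sum())
    if n_zero:
        log.info("direction_vectors: %d zero-gradient voxels filled", n_zero)
        _, nn = ndimage.distance_transform_edt(~good, return_indices=True)
        bad = occ & ~good
        direction[bad] = direction[tuple(nn[:, bad])]
    return replace(field_, direction=direction, n_filled=n_zero)


def layer_proportions_from_thicknesses(thicknesses) -> np.ndarray:
    """Relative layer proportions from mean thicknesses ordered from r = 0
    (SO, SP, SR, SLM), in micrometres."""
    th = np.asarray(thicknesses, dtype=float)
    if np.any(th <= 0):
        raise ValueError("thicknesses must be positive")
    return th / th.sum()


def assign_layers(field_: CoordinateField, proportions) -> np.ndarray:
    """Label voxels with layer indices 0..3 (SO, SP, SR, SLM from r = 0).

    ``proportions`` are the per-layer fractions of the radial extent,
    ordered from r = 0; they must sum to 1.  Returns an integer grid with
    -1 outside the mask.
    """
    props = np.asarray(proportions, dtype=float)
    if np.any(props <= 0):
        raise ValueError("proportions must be positive")
    if abs(props.sum() - 1.0) > 1e-3:
        raise ValueError("proportions must sum to 1")
    props = props / props.sum()   # absorb rounding of printed fractions
    bounds = np.cumsum(props)[:-1]
    labels = np.full(field_.r.shape, -1, dtype=np.int8)
    occ = field_.mask.occupancy
    labels[occ] = np.searchsorted(bounds, field_.r[occ], side="right")
    return labels


def layer_r_intervals(proportions) -> dict:
    """Map layer name -> (r_lo, r_hi) interval, ordered from r = 0."""
    props = np.asarray(proportions, dtype=float)
    edges = np.concatenate([[0.0], np.cumsum(props)])
    edges[-1] = 1.0
    return {name: (edges[i], edges[i + 1])
            for i, name in enumerate(LAYER_NAMES)}
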