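"""Footprint extraction chain for ligament insertions on bone.

Stages, in order: Gaussian one-hot label smoothing, Sobel boundary
delineation per structure, dilation–erosion overlap detection between the
soft-tissue and bone boundaries, selection of the connected candidate
component nearest an anatomical seed (fovea for the deep insertion, styloid
for the superficial one), and RANSAC plane refinement.  The result is a
:class:`FootprintPatch`: the connected set of ligament-surface voxels in
contact with the bone, together with the fitted articular plane.

All physical parameters are in mm and converted to per-axis voxel radii, so
anisotropic grids use ellipsoidal structuring elements.  The chain is
bit-deterministic for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ExtractionError, GeometryError, SchemaError
from .label_volumes import AnatomicalFrame, LabelVolume, extract_label_mask

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class Plane:
    """A plane in world mm coordinates: a point on it and a unit normal."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > _UNIT_TOL:
            raise ValueError("plane normal must have unit norm")
        object.__setattr__(self, "point", tuple(float(x) for x in self.point))
        object.__setattr__(self, "normal", tuple(float(x) for x in n))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return (p - np.asarray(self.point)) @ np.asarray(self.normal)


@dataclass
class PipelineConfig:
    """Tunable parameters of the extraction chain.

    The RANSAC seed must be given explicitly; every other field has a
    documented default.  ``dilation_radius_mm=None`` selects the smallest
    radius that bridges two facing one-voxel boundary layers (two voxels per
    axis); explicit radii are floored at two voxels per axis so the overlap
    slab survives the one-voxel erosion.
    """

    seed: int
    smoothing_sigma: float = 1.0           # voxels
    sobel_threshold: float = 0.1           # fraction of max gradient magnitude
    dilation_radius_mm: float | None = None
    component_connectivity: int = 26       # 6 | 18 | 26
    ransac_iterations: int = 1000
    ransac_inlier_threshold_mm: float = 0.15
    min_component_voxels: int = 30

    def __post_init__(self):
        if not (0 < self.sobel_threshold <= 1):
            raise ValueError("sobel_threshold must lie in (0, 1]")
        if self.dilation_radius_mm is not None and self.dilation_radius_mm <= 0:
            raise ValueError("dilation_radius_mm must be > 0")
        if self.component_connectivity not in (6, 18, 26):
            raise ValueError("component_connectivity must be 6, 18 or 26")
        if self.ransac_iterations < 1:
            raise ValueError("ransac_iterations must be >= 1")
        if self.ransac_inlier_threshold_mm <= 0:
            raise ValueError("ransac_inlier_threshold_mm must be > 0")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class FootprintPatch:
    """An extracted contact region between a soft-tissue sheet and a bone."""

    voxel_indices: np.ndarray          # (M, 3) int grid indices
    world_points: np.ndarray           # (M, 3) mm
    plane: Plane
    inlier_flags: np.ndarray           # (M,) bool
    source_labels: tuple[int, int]     # (soft label, bone label)
    region_tag: str = "deep"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    stage_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=int)
        self.world_points = np.asarray(self.world_points, dtype=float)
        self.inlier_flags = np.asarray(self.inlier_flags, dtype=bool)
        if self.inlier_flags.sum() < 3:
            raise GeometryError("a footprint patch needs >= 3 inlier points")

    @property
    def inlier_points(self) -> np.ndarray:
        return self.world_points[self.inlier_flags]

    def to_json_dict(self) -> dict:
        return {
            "region_tag": self.region_tag,
            "source_labels": list(self.source_labels),
            "n_points": int(len(self.world_points)),
            "n_inliers": int(self.inlier_flags.sum()),
            "plane_point": list(self.plane.point),
            "plane_normal": list(self.plane.normal),
            "spacing_mm": list(self.spacing),
            "stage_counts": self.stage_counts,
        }


# ---------------------------------------------------------------------------
# individual stages

def smooth_labels(volume: LabelVolume, sigma: float) -> LabelVolume:
    """Gaussian one-hot label smoothing followed by per-voxel argmax.

    Ties break toward the lower label code; ``sigma`` is in voxels and 0 is
    the identity.  No label absent from the input can appear in the output.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return volume.copy()
    labels = np.unique(volume.voxels)
    if len(labels) == 1:
        return volume.copy()
    best_score = np.full(volume.shape, -np.inf, dtype=np.float32)
    best_label = np.zeros(volume.shape, dtype=volume.voxels.dtype)
    for lab in labels:  # ascending: strict '>' keeps the lower code on ties
        score = ndimage.gaussian_filter(
            (volume.voxels == lab).astype(np.float32), sigma)
        take = score > best_score
        best_score[take] = score[take]
        best_label[take] = lab
    out = volume.copy()
    out.voxels = best_label
    return out


def boundary_voxels(mask: np.ndarray, spacing, threshold: float = 0.1) -> np.ndarray:
    """Surface voxels of a binary mask via thresholded 3D Sobel magnitude.

    The Sobel gradient of the indicator is normalized to [0, 1] and
    thresholded; the result is restricted to the mask so it is the inner
    surface layer.  Mask voxels with a 6-connected background neighbour are
    always included (this covers flat faces and isolated voxels, where the
    centred gradient vanishes).
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return np.zeros_like(m)
    spacing = np.asarray(spacing, dtype=float)
    ind = m.astype(np.float32)
    grad_sq = np.zeros_like(ind)
    for ax in range(3):
        g = ndimage.sobel(ind, axis=ax) / spacing[ax]
        grad_sq += g * g
    mag = np.sqrt(grad_sq)
    peak = mag.max()
    sobel_part = (mag >= threshold * peak) if peak > 0 else np.zeros_like(m)
    surface = m & ~ndimage.binary_erosion(
        m, structure=ndimage.generate_binary_structure(3, 1), border_value=1)
    return m & (sobel_part | surface)


def _ellipsoid_structure(radius_vox: np.ndarray) -> np.ndarray:
    """Ellipsoidal structuring element with per-axis radii in voxels."""
    r = np.maximum(np.asarray(radius_vox, dtype=float), 1e-6)
    half = np.floor(r).astype(int)
    grids = np.ogrid[-half[0]:half[0] + 1,
                     -half[1]:half[1] + 1,
                     -half[2]:half[2] + 1]
    dist = sum((g / ri) ** 2 for g, ri in zip(grids, r))
    return dist <= 1.0 + 1e-9


def candidate_overlap(soft_boundary: np.ndarray, bone_boundary: np.ndarray,
                      dilation_radius_mm: float | None, spacing) -> np.ndarray:
    """Dilation–erosion overlap of two boundary masks: the preliminary footprint.

    Both boundaries are dilated by an ellipsoidal ball of the given physical
    radius, intersected, eroded by one voxel to suppress single-voxel bridges,
    and finally restricted to voxels within one voxel of both original
    boundaries (a symmetric guard band).
    """
    a = np.asarray(soft_boundary, dtype=bool)
    b = np.asarray(bone_boundary, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("boundary masks must share a grid")
    spacing = np.asarray(spacing, dtype=float)
    if dilation_radius_mm is None:
        radius_vox = np.full(3, 2.0)
    else:
        if dilation_radius_mm < spacing.min():
            raise ValueError(
                "dilation radius below the smallest voxel spacing is a no-op")
        # floor of 2 voxels/axis: thinner overlap slabs cannot survive erosion
        radius_vox = np.maximum(dilation_radius_mm / spacing, 2.0)
    ball = _ellipsoid_structure(radius_vox)
    if not (a.any() and b.any()):
        return np.zeros_like(a)
    inter = (ndimage.binary_dilation(a, structure=ball)
             & ndimage.binary_dilation(b, structure=ball))
    cross = ndimage.generate_binary_structure(3, 1)
    # border_value=1: the grid edge is not a set boundary, so structures that
    # touch it are not eroded from that side
    inter = ndimage.binary_erosion(inter, structure=cross, border_value=1)
    guard = ndimage.generate_binary_structure(3, 3)  # Chebyshev-1 neighbourhood
    inter &= ndimage.binary_dilation(a, structure=guard)
    inter &= ndimage.binary_dilation(b, structure=guard)
    return inter


_CONN_STRUCT = {6: 1, 18: 2, 26: 3}


def largest_component(mask: np.ndarray, connectivity: int = 26,
                      min_size: int = 1) -> np.ndarray:
    """Largest connected component, after discarding components below min_size.

    Equal-sized components tie-break to the one containing the
    lexicographically smallest voxel index.  Returns an all-false mask when no
    component reaches ``min_size`` (an empty result, not an error).
    """
    struct = ndimage.generate_binary_structure(3, _CONN_STRUCT[connectivity])
    labeled, n = ndimage.label(np.asarray(mask, dtype=bool), structure=struct)
    if n == 0:
        return np.zeros(mask.shape, dtype=bool)
    sizes = np.bincount(labeled.ravel())[1:]
    keep = np.flatnonzero(sizes >= max(min_size, 1)) + 1
    if keep.size == 0:
        return np.zeros(mask.shape, dtype=bool)
    best = keep[np.argmax(sizes[keep - 1])]
    top = sizes[best - 1]
    ties = keep[sizes[keep - 1] == top]
    if len(ties) > 1:
        # scipy labels in scan order, so the smallest first-occurrence index
        # belongs to the component whose seed voxel is lexicographically first
        firsts = {
            lab: np.argmax(labeled.ravel() == lab) for lab in ties
        }
        best = min(firsts, key=firsts.get)
    return labeled == best


def ransac_plane(points: np.ndarray, threshold_mm: float, iterations: int,
                 seed: int) -> tuple[Plane, np.ndarray]:
    """Classical 3-point RANSAC plane fit with least-squares refinement.

    Best candidate by inlier count (ties by smaller mean absolute inlier
    residual); the final plane is re-estimated from the inliers by total least
    squares (centroid + smallest-variance direction, two refinement rounds)
    and inlier flags are recomputed against it.  Deterministic for fixed seed.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise GeometryError("plane fitting needs >= 3 points")
    n_pts = len(pts)
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(pts).max())) < 2:
        raise GeometryError("points are collinear; no unique plane")

    rng = np.random.default_rng(seed)
    best_count = -1
    best_resid = np.inf
    best_plane: tuple[np.ndarray, np.ndarray] | None = None
    chunk = 256
    done = 0
    while done < iterations:
        m = min(chunk, iterations - done)
        done += m
        idx = rng.integers(0, n_pts, size=(m, 3))
        p0, p1, p2 = pts[idx[:, 0]], pts[idx[:, 1]], pts[idx[:, 2]]
        normals = np.cross(p1 - p0, p2 - p0)
        norms = np.linalg.norm(normals, axis=1)
        ok = norms > 1e-12
        if not ok.any():
            continue
        normals = normals[ok] / norms[ok, None]
        origins = p0[ok]
        # residual matrix (m_ok, n_pts)
        resid = np.abs(np.einsum("ij,kj->ki", pts, normals)
                       - np.einsum("kj,kj->k", origins, normals)[:, None])
        inl = resid <= threshold_mm
        counts = inl.sum(axis=1)
        mean_res = np.where(counts > 0,
                            np.where(inl, resid, 0.0).sum(axis=1)
                            / np.maximum(counts, 1), np.inf)
        for i in range(len(counts)):
            if counts[i] > best_count or (counts[i] == best_count
                                          and mean_res[i] < best_resid):
                best_count = int(counts[i])
                best_resid = float(mean_res[i])
                best_plane = (origins[i], normals[i])
    if best_plane is None or best_count < 3:
        raise GeometryError("RANSAC found no plane supported by 3 points")

    origin, normal = best_plane
    flags = np.abs((pts - origin) @ normal) <= threshold_mm
    for _ in range(2):  # least-squares re-estimation from the inlier set
        sel = pts[flags]
        centroid = sel.mean(axis=0)
        _, _, vt = np.linalg.svd(sel - centroid, full_matrices=False)
        normal = vt[-1]
        # canonical sign: largest-|component| positive
        k = int(np.argmax(np.abs(normal)))
        if normal[k] < 0:
            normal = -normal
        origin = centroid
        new_flags = np.abs((pts - origin) @ normal) <= threshold_mm
        if np.array_equal(new_flags, flags):
            break
        if new_flags.sum() < 3:
            break
        flags = new_flags
    normal = normal / np.linalg.norm(normal)
    return Plane(tuple(origin), tuple(normal)), flags


# ---------------------------------------------------------------------------
# full chain

def _resolve_seed_point(volume: LabelVolume, region_seed) -> np.ndarray:
    """World coordinates of the region seed (a point, or a landmark label)."""
    if isinstance(region_seed, (int, np.integer)):
        if region_seed not in volume.label_schema:
            raise SchemaError(f"landmark label {region_seed} not in schema")
        where = np.argwhere(volume.voxels == region_seed)
        if len(where) == 0:
            raise ExtractionError("seed", f"landmark label {region_seed} "
                                  "has no voxels")
        return volume.world_coordinates(where.mean(axis=0))
    p = np.asarray(region_seed, dtype=float)
    if p.shape != (3,):
        raise ValueError("region_seed must be a 3-vector or a label code")
    return p


def extract_footprint(volume: LabelVolume, soft_label: int, bone_label: int,
                      cfg: PipelineConfig, region_seed,
                      region_tag: str = "deep") -> FootprintPatch:
    """Run the full extraction chain and return the refined footprint patch.

    ``region_seed`` is a world point or a landmark label code; among the
    candidate overlap components it selects the one with the nearest centroid
    (deep = fovea, superficial = styloid).  The final patch is the largest
    connected subset of RANSAC-inlier voxels lying on the soft-tissue
    boundary — the ligament-surface voxels in contact with the bone.
    """
    for lab, what in ((soft_label, "soft"), (bone_label, "bone")):
        if lab not in volume.label_schema:
            raise SchemaError(f"{what} label {lab} not in schema")
        if not np.any(volume.voxels == lab):
            raise SchemaError(f"{what} label {lab} absent from volume")
    seed_point = _resolve_seed_point(volume, region_seed)
    counts: dict[str, int] = {}

    smoothed = smooth_labels(volume, cfg.smoothing_sigma)
    soft_mask = extract_label_mask(smoothed, soft_label)
    bone_mask = extract_label_mask(smoothed, bone_label)
    counts["soft_voxels"] = int(soft_mask.sum())
    counts["bone_voxels"] = int(bone_mask.sum())
    if not (soft_mask.any() and bone_mask.any()):
        raise ExtractionError("smoothing", "a structure vanished during "
                              "label smoothing")

    soft_b = boundary_voxels(soft_mask, volume.spacing, cfg.sobel_threshold)
    bone_b = boundary_voxels(bone_mask, volume.spacing, cfg.sobel_threshold)
    counts["soft_boundary"] = int(soft_b.sum())
    counts["bone_boundary"] = int(bone_b.sum())

    overlap = candidate_overlap(soft_b, bone_b, cfg.dilation_radius_mm,
                                volume.spacing)
    counts["overlap"] = int(overlap.sum())
    if not overlap.any():
        raise ExtractionError("overlap", "no contact between the boundaries")

    struct = ndimage.generate_binary_structure(
        3, _CONN_STRUCT[cfg.component_connectivity])
    labeled, n = ndimage.label(overlap, structure=struct)
    sizes = np.bincount(labeled.ravel())[1:]
    cand = np.flatnonzero(sizes >= cfg.min_component_voxels) + 1
    if cand.size == 0:
        raise ExtractionError("component", "no overlap component reaches "
                              f"min_component_voxels={cfg.min_component_voxels}")
    dists = []
    for lab in cand:
        idx = np.argwhere(labeled == lab)
        centroid = volume.world_coordinates(idx.mean(axis=0))
        dists.append(np.linalg.norm(centroid - seed_point))
    comp = labeled == cand[int(np.argmin(dists))]
    counts["component"] = int(comp.sum())

    # the inlier band cannot resolve below the voxel lattice: floor it at one
    # voxel so it can span the two facing boundary layers of a discrete contact
    thr = max(cfg.ransac_inlier_threshold_mm, 1.05 * max(volume.spacing))

    comp_idx = np.argwhere(comp)
    comp_pts = volume.world_coordinates(comp_idx)
    plane, flags = ransac_plane(comp_pts, thr, cfg.ransac_iterations, cfg.seed)
    counts["ransac_inliers"] = int(flags.sum())

    # footprint proper: inlier voxels on the ligament surface
    on_soft = soft_b[tuple(comp_idx.T)]
    final_mask = np.zeros(volume.shape, dtype=bool)
    keep = flags & on_soft
    if keep.sum() < 3:
        raise ExtractionError("ransac", "fewer than 3 inliers on the "
                              "soft-tissue boundary")
    final_mask[tuple(comp_idx[keep].T)] = True
    final_mask = largest_component(final_mask, cfg.component_connectivity, 1)
    counts["patch"] = int(final_mask.sum())
    if counts["patch"] < 3:
        raise ExtractionError("ransac", "final patch degenerate")

    patch_idx = np.argwhere(final_mask)
    patch_pts = volume.world_coordinates(patch_idx)
    patch_flags = np.abs(plane.signed_distance(patch_pts)) <= thr
    return FootprintPatch(patch_idx, patch_pts, plane, patch_flags,
                          (soft_label, bone_label), region_tag,
                          volume.spacing, counts)


def export_patch_ply(patch: FootprintPatch, path: str) -> None:
    """Write the patch points as an ASCII PLY point cloud (needs trimesh)."""
    import trimesh

    cloud = trimesh.PointCloud(patch.world_points)
    cloud.export(path, file_type="ply")
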