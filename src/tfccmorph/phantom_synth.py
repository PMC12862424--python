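"""Seeded synthetic wrist phantoms with analytically known footprint truth.

The phantom emulates the distal radioulnar joint region of an isotropic,
super-resolved segmentation volume: an ulna (cylindrical shaft, spherical
head truncated by a planar foveal facet, truncated-cone styloid), an offset
slab standing in for the distal radius, and a thin triangular-fibrocartilage
(TFC) sheet suspended above the head.  The sheet carries a contact boss whose
in-plane outline is a closed-form 2D template — a stadium ("ribbon"), a
convex quadrilateral, or a crescent ("semilunar") — laid flat on the foveal
facet, so the continuous contact area, maximal lengths and shape class are
known exactly before voxelization.  A second small pad rests on the flat
styloid tip as the superficial insertion.

Geometry is expressed in an :class:`AnatomicalFrame`; by default DV = +x,
RU = +y, PD = +z, with the head centre at the world origin.  For a fixed seed
generation is deterministic.  With ``geometry_jitter`` enabled (the default)
each seed perturbs the template dimensions (±5%), in-plane rotation (±10°)
and centre (±0.4 mm DV, −0.1..+0.4 mm RU), with the truth fields tracking the
perturbed geometry — so a cohort of seeds behaves like a cohort of specimens.
Boundary noise is modelled as per-voxel Gaussian jitter of the
signed-distance threshold, with magnitude ``noise_level`` voxels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import GeometryError
from .footprint_pipeline import Plane
from .label_volumes import (
    LABEL_FOVEA_LANDMARK,
    LABEL_RADIUS,
    LABEL_STYLOID_LANDMARK,
    LABEL_TFCC,
    LABEL_ULNA,
    AnatomicalFrame,
    DEFAULT_SCHEMA,
    LabelVolume,
)
from .morphometry import ShapeClass

# ---------------------------------------------------------------------------
# 2D footprint templates (closed-form geometry, local coordinates in mm)


class _Template:
    area: float

    def sdf(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def contains(self, x, y) -> np.ndarray:
        return self.sdf(np.asarray(x, float), np.asarray(y, float)) <= 0.0

    def boundary_points(self, n: int = 2000) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass
class StadiumTemplate(_Template):
    """Rectangle of length L−W capped by two half-discs of radius W/2."""

    length: float
    width: float

    def __post_init__(self):
        if self.width >= self.length:
            raise GeometryError("a stadium needs width < length")
        w = self.width
        self.area = (self.length - w) * w + np.pi * (w / 2) ** 2
        self._a = (self.length - w) / 2.0

    def sdf(self, x, y):
        qx = np.maximum(np.abs(x) - self._a, 0.0)
        return np.hypot(qx, y) - self.width / 2.0

    def boundary_points(self, n: int = 2000) -> np.ndarray:
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        r = self.width / 2.0
        cx = np.where(np.cos(t) >= 0, self._a, -self._a)
        return np.column_stack([cx + r * np.cos(t), r * np.sin(t)])


@dataclass
class QuadTemplate(_Template):
    """Convex quadrilateral: a rectangle with radially scaled corners."""

    length: float
    width: float
    corner_scales: tuple[float, float, float, float] = (0.90, 0.82, 0.95, 0.85)

    def __post_init__(self):
        hx, hy = self.length / 2.0, self.width / 2.0
        base = np.array([[-hx, -hy], [hx, -hy], [hx, hy], [-hx, hy]])
        s = np.asarray(self.corner_scales, dtype=float)
        if np.any(s <= 0) or np.any(s > 1.0):
            raise GeometryError("corner scales must lie in (0, 1]")
        self.vertices = base * s[:, None]
        e = np.roll(self.vertices, -1, axis=0) - self.vertices
        e2 = np.roll(e, -1, axis=0)
        crosses = e[:, 0] * e2[:, 1] - e[:, 1] * e2[:, 0]
        if not (np.all(crosses > 0) or np.all(crosses < 0)):
            raise GeometryError("quadrilateral is not convex")
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        self.area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        # outward edge normals for the half-plane signed distance (CCW order)
        self._normals = np.column_stack([e[:, 1], -e[:, 0]])
        self._normals /= np.linalg.norm(self._normals, axis=1, keepdims=True)

    def sdf(self, x, y):
        p = np.stack([np.asarray(x, float), np.asarray(y, float)], axis=-1)
        d = np.stack([
            (p - v) @ n for v, n in zip(self.vertices, self._normals)
        ], axis=0)
        return d.max(axis=0)

    def boundary_points(self, n: int = 2000) -> np.ndarray:
        per = max(n // 4, 2)
        pts = []
        for i in range(4):
            a, b = self.vertices[i], self.vertices[(i + 1) % 4]
            t = np.linspace(0, 1, per, endpoint=False)[:, None]
            pts.append(a + t * (b - a))
        return np.concatenate(pts)


@dataclass
class CrescentTemplate(_Template):
    """Crescent: disc of radius L/2 minus an equal disc offset by W.

    The cut disc is centred at (0, −W), so the crescent bulges toward +y with
    its tips at y = −W/2; its maximal thickness along the symmetry axis is W
    and its DV extent is the full outer diameter L.
    """

    length: float
    width: float

    def __post_init__(self):
        self.radius = self.length / 2.0
        self.offset = self.width
        if not 0 < self.offset < 2 * self.radius:
            raise GeometryError("crescent needs 0 < width < length")
        r, d = self.radius, self.offset
        lens = 2 * r * r * np.arccos(d / (2 * r)) \
            - (d / 2.0) * np.sqrt(4 * r * r - d * d)
        self.area = np.pi * r * r - lens

    def sdf(self, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        outer = np.hypot(x, y) - self.radius
        inner = self.radius - np.hypot(x, y + self.offset)
        return np.maximum(outer, inner)

    def boundary_points(self, n: int = 2000) -> np.ndarray:
        r, d = self.radius, self.offset
        # intersection angle on the outer circle (tips at y = -d/2)
        t = np.linspace(0, 2 * np.pi, n)
        outer = np.column_stack([r * np.cos(t), r * np.sin(t)])
        keep_o = np.hypot(outer[:, 0], outer[:, 1] + d) >= r
        inner = np.column_stack([r * np.cos(t), r * np.sin(t) - d])
        keep_i = np.hypot(inner[:, 0], inner[:, 1]) <= r
        return np.concatenate([outer[keep_o], inner[keep_i]])


def make_template(shape: ShapeClass | str, length: float, width: float,
                  corner_scales=None) -> _Template:
    shape = ShapeClass(shape)
    if shape is ShapeClass.RIBBON:
        return StadiumTemplate(length, width)
    if shape is ShapeClass.IRREGULAR_QUADRILATERAL:
        if corner_scales is None:
            return QuadTemplate(length, width)
        return QuadTemplate(length, width, tuple(corner_scales))
    return CrescentTemplate(length, width)


# ---------------------------------------------------------------------------
# specs and truth


@dataclass
class PhantomSpec:
    """Design parameters of a synthetic wrist phantom (mm unless noted)."""

    grid_shape: tuple[int, int, int] = (128, 154, 84)
    spacing: tuple[float, float, float] = (0.15, 0.15, 0.15)
    ulna_head_radius: float = 9.0
    styloid_height: float = 3.5
    tfc_thickness: float = 0.60
    footprint_shape: ShapeClass = ShapeClass.RIBBON
    footprint_dv_length: float = 13.40
    footprint_ru_width: float = 3.98
    superficial_patch_area: float = 10.0   # mm^2; 0 disables the pad
    frame: AnatomicalFrame = field(default_factory=AnatomicalFrame)
    noise_level: float = 0.0               # boundary jitter, voxels
    seed: int = 0
    geometry_jitter: bool = True
    landmark_labels: bool = False

    def __post_init__(self):
        self.footprint_shape = ShapeClass(self.footprint_shape)
        for name in ("ulna_head_radius", "styloid_height", "tfc_thickness",
                     "footprint_dv_length", "footprint_ru_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.superficial_patch_area < 0:
            raise ValueError("superficial_patch_area must be >= 0")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 8:
            raise ValueError("grid_shape must be a triple of >= 8 voxels")
        if len(self.spacing) != 3 or min(self.spacing) <= 0:
            raise ValueError("spacing must be a positive mm triple")


def default_spec_for_shape(shape: ShapeClass | str, seed: int = 0,
                           **overrides) -> PhantomSpec:
    """Per-class default dimensions: ribbon/semilunar use the band-like
    cohort means (13.40 × 3.98 mm); the quadrilateral uses a compact
    8.0 × 4.2 mm outline so its elongation sits below the ribbon threshold."""
    shape = ShapeClass(shape)
    dims = {
        ShapeClass.RIBBON: (13.40, 3.98),
        ShapeClass.SEMILUNAR: (13.40, 3.98),
        ShapeClass.IRREGULAR_QUADRILATERAL: (8.0, 4.2),
    }[shape]
    return PhantomSpec(footprint_shape=shape, footprint_dv_length=dims[0],
                       footprint_ru_width=dims[1], seed=seed, **overrides)


@dataclass
class PhantomTruth:
    """Closed-form ground truth paired with a generated phantom."""

    deep_area: float
    superficial_area: float
    dv_length: float
    ru_length: float
    shape: ShapeClass
    tfc_center_thickness: float
    footprint_plane: Plane
    landmark_positions: dict[str, tuple[float, float, float]]

    def to_json_dict(self) -> dict:
        return {
            "deep_area_mm2": self.deep_area,
            "superficial_area_mm2": self.superficial_area,
            "dv_length_mm": self.dv_length,
            "ru_length_mm": self.ru_length,
            "shape": self.shape.value,
            "tfc_center_thickness_mm": self.tfc_center_thickness,
            "footprint_plane": {"point": list(self.footprint_plane.point),
                                "normal": list(self.footprint_plane.normal)},
            "landmark_positions": {k: list(v)
                                   for k, v in self.landmark_positions.items()},
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def load_json(cls, path) -> "PhantomTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            deep_area=d["deep_area_mm2"],
            superficial_area=d["superficial_area_mm2"],
            dv_length=d["dv_length_mm"],
            ru_length=d["ru_length_mm"],
            shape=ShapeClass(d["shape"]),
            tfc_center_thickness=d["tfc_center_thickness_mm"],
            footprint_plane=Plane(tuple(d["footprint_plane"]["point"]),
                                  tuple(d["footprint_plane"]["normal"])),
            landmark_positions={k: tuple(v)
                                for k, v in d["landmark_positions"].items()},
        )


# ---------------------------------------------------------------------------
# generation

_JITTER_SCALE = (0.95, 1.05)
_JITTER_ROT_DEG = 10.0
_SHEET_GAP = 0.8          # mm stand-off of the sheet above the facet
_STYLOID_CLEARANCE = 0.8  # mm carve-out of the sheet around the styloid
_FIT_MARGIN = 0.3         # mm template-to-facet-edge margin


def _layout(spec: PhantomSpec) -> dict:
    rh = spec.ulna_head_radius
    z_facet = 0.45 * rh
    facet_radius = float(np.sqrt(rh * rh - z_facet * z_facet))
    r_sup = float(np.sqrt(spec.superficial_patch_area / np.pi)) \
        if spec.superficial_patch_area > 0 else 0.0
    top_r = max(2.0, r_sup + 0.4)
    base_r = top_r + 0.4
    return {
        "rh": rh,
        "z_facet": z_facet,
        "facet_radius": facet_radius,
        "shaft_radius": 0.45 * rh,
        "sty_y": -(facet_radius - base_r + 0.6),
        "sty_base_r": base_r,
        "sty_top_r": top_r,
        "z_sty_top": z_facet + spec.styloid_height,
        "r_sup": r_sup,
        "sheet_lo": z_facet + _SHEET_GAP,
        "sheet_hi": z_facet + _SHEET_GAP + spec.tfc_thickness,
        "sheet_radius": facet_radius + 0.2,
        "radius_bone": {  # (x half width, y range, z range) of the slab
            "hx": 0.67 * facet_radius,
            "y0": facet_radius + 2.0,
            "y1": facet_radius + 4.2,
            "z0": -2.5,
            "z1": z_facet,
        },
    }


def _draw_placement(spec: PhantomSpec, rng: np.random.Generator):
    sl = rng.uniform(*_JITTER_SCALE)
    sw = rng.uniform(*_JITTER_SCALE)
    theta = np.deg2rad(rng.uniform(-_JITTER_ROT_DEG, _JITTER_ROT_DEG))
    cx = rng.uniform(-0.4, 0.4)
    cy = rng.uniform(-0.1, 0.4)
    corner = tuple(rng.uniform(0.78, 1.0, size=4))
    if not spec.geometry_jitter:
        sl = sw = 1.0
        theta = cx = cy = 0.0
        corner = None
    return sl, sw, theta, cx, cy, corner


def generate_phantom(spec: PhantomSpec) -> tuple[LabelVolume, PhantomTruth]:
    """Voxelize the phantom and return it with its closed-form truth."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    sl, sw, theta, cx, cy, corner = _draw_placement(spec, rng)
    lay = _layout(spec)

    length = spec.footprint_dv_length * sl
    width = spec.footprint_ru_width * sw
    template = make_template(spec.footprint_shape, length, width, corner)

    ct, st = float(np.cos(theta)), float(np.sin(theta))
    bnd = template.boundary_points(3000)
    placed = np.column_stack([
        cx + ct * bnd[:, 0] - st * bnd[:, 1],
        cy + st * bnd[:, 0] + ct * bnd[:, 1],
    ])
    if np.hypot(placed[:, 0], placed[:, 1]).max() \
            > lay["facet_radius"] - _FIT_MARGIN:
        raise GeometryError("footprint template exceeds the foveal facet "
                            "of the ulnar head")
    if lay["r_sup"] > 0 and lay["r_sup"] + 0.2 > lay["sty_top_r"]:
        raise GeometryError("superficial patch exceeds the styloid tip")

    # frame coordinates of every voxel centre (head centre at world origin)
    shape = tuple(int(s) for s in spec.grid_shape)
    h = np.asarray(spec.spacing, dtype=float)
    origin = (
        -(shape[0] - 1) * h[0] / 2.0,
        -(lay["facet_radius"] + 1.3),
        -3.0,
    )
    ii, jj, kk = np.meshgrid(
        (origin[0] + np.arange(shape[0]) * h[0]).astype(np.float32),
        (origin[1] + np.arange(shape[1]) * h[1]).astype(np.float32),
        (origin[2] + np.arange(shape[2]) * h[2]).astype(np.float32),
        indexing="ij", copy=False)
    m = spec.frame.matrix().astype(np.float32)
    u = m[0, 0] * ii + m[0, 1] * jj + m[0, 2] * kk
    v = m[1, 0] * ii + m[1, 1] * jj + m[1, 2] * kk
    w = m[2, 0] * ii + m[2, 1] * jj + m[2, 2] * kk
    del ii, jj, kk

    need = {
        "u": lay["facet_radius"] + 0.5,
        "v_lo": -(lay["facet_radius"] + 1.2),
        "v_hi": lay["radius_bone"]["y1"] + 0.3,
        "w_lo": -1.5,
        "w_hi": lay["z_sty_top"] + spec.tfc_thickness + 0.5,
    }
    if (u.min() > -need["u"] or u.max() < need["u"]
            or v.min() > need["v_lo"] or v.max() < need["v_hi"]
            or w.min() > need["w_lo"] or w.max() < need["w_hi"]):
        raise GeometryError("phantom anatomy does not fit the grid at the "
                            "given spacing")

    rho2 = np.hypot(u, v)
    rho3 = np.sqrt(rho2 * rho2 + w * w)
    rho_sty = np.hypot(u, v - lay["sty_y"])

    sdf_shaft = np.maximum(rho2 - lay["shaft_radius"], w)
    sdf_head = np.maximum(rho3 - lay["rh"], w - lay["z_facet"])
    frac = np.clip((w - lay["z_facet"]) / spec.styloid_height, 0.0, 1.0)
    sty_radius = lay["sty_base_r"] + (lay["sty_top_r"] - lay["sty_base_r"]) * frac
    sdf_sty = np.maximum.reduce([rho_sty - sty_radius,
                                 lay["z_facet"] - w,
                                 w - lay["z_sty_top"]])
    sdf_ulna = np.minimum.reduce([sdf_shaft, sdf_head, sdf_sty])
    del sdf_shaft, sdf_head, sdf_sty, rho3

    rb = lay["radius_bone"]
    sdf_radius = np.maximum.reduce([
        np.abs(u) - rb["hx"], rb["y0"] - v, v - rb["y1"],
        rb["z0"] - w, w - rb["z1"]])

    sdf_sheet = np.maximum.reduce([
        w - lay["sheet_hi"], lay["sheet_lo"] - w, rho2 - lay["sheet_radius"]])
    # contact boss: template cross-section from facet up into the sheet
    tl = ct * (u - cx) + st * (v - cy)
    tp = -st * (u - cx) + ct * (v - cy)
    sdf_boss = np.maximum.reduce([
        template.sdf(tl, tp).astype(np.float32),
        lay["z_facet"] - w, w - lay["sheet_hi"]])
    del tl, tp
    sheet_and_boss = np.minimum(sdf_sheet, sdf_boss)
    del sdf_sheet, sdf_boss
    clearance = (sty_radius + _STYLOID_CLEARANCE) - rho_sty
    sdf_tfcc = np.maximum(sheet_and_boss, clearance)
    del sheet_and_boss, clearance
    if lay["r_sup"] > 0:
        sdf_pad = np.maximum.reduce([
            rho_sty - lay["r_sup"],
            lay["z_sty_top"] - w,
            w - (lay["z_sty_top"] + spec.tfc_thickness)])
        sdf_tfcc = np.minimum(sdf_tfcc, sdf_pad)
        del sdf_pad
    del rho2, rho_sty, sty_radius, frac

    def _inside(sdf: np.ndarray) -> np.ndarray:
        if spec.noise_level > 0:
            jit = rng.standard_normal(sdf.shape, dtype=np.float32)
            return sdf <= spec.noise_level * float(h.mean()) * jit
        return sdf <= 0.0

    vox = np.zeros(shape, dtype=np.int16)
    vox[_inside(sdf_tfcc)] = LABEL_TFCC
    vox[_inside(sdf_radius)] = LABEL_RADIUS
    vox[_inside(sdf_ulna)] = LABEL_ULNA   # bone priority over soft tissue

    schema = dict(DEFAULT_SCHEMA)
    fovea_local = np.array([cx, cy, lay["z_facet"]])
    apex_local = np.array([0.0, lay["sty_y"], lay["z_sty_top"]])
    if spec.landmark_labels:
        schema[LABEL_FOVEA_LANDMARK] = "fovea_landmark"
        schema[LABEL_STYLOID_LANDMARK] = "styloid_landmark"
        for local, lab, lift in ((fovea_local, LABEL_FOVEA_LANDMARK,
                                  lay["sheet_hi"] - lay["z_facet"] + 0.8),
                                 (apex_local, LABEL_STYLOID_LANDMARK,
                                  spec.tfc_thickness + 0.8)):
            pos = local + np.array([0.0, 0.0, lift])  # float above the tissue
            dist = np.sqrt((u - pos[0]) ** 2 + (v - pos[1]) ** 2
                           + (w - pos[2]) ** 2)
            vox[(dist <= 1.3 * float(h.max())) & (vox == 0)] = lab

    volume = LabelVolume(vox, tuple(h), origin, "LPS", schema)

    mat_t = spec.frame.matrix().T
    to_world = lambda p: tuple(float(x) for x in mat_t @ np.asarray(p))
    truth = PhantomTruth(
        deep_area=float(template.area),
        superficial_area=float(spec.superficial_patch_area),
        dv_length=float(placed[:, 0].max() - placed[:, 0].min()),
        ru_length=float(placed[:, 1].max() - placed[:, 1].min()),
        shape=spec.footprint_shape,
        tfc_center_thickness=float(spec.tfc_thickness),
        footprint_plane=Plane(to_world(fovea_local),
                              to_world((0.0, 0.0, 1.0))),
        landmark_positions={
            "fovea": to_world(fovea_local),
            "styloid_apex": to_world(apex_local),
        },
    )
    return volume, truth


# ---------------------------------------------------------------------------
# paired-measurement simulator for the agreement statistics


@dataclass
class AgreementSimSpec:
    """Variance components of a two-method paired-measurement simulation."""

    n_specimens: int = 50
    true_between_variance: float = 9.0
    true_error_variance_a: float = 1.0
    true_error_variance_b: float = 1.0
    mean_level: float = 43.39
    seed: int = 0

    def __post_init__(self):
        if self.n_specimens < 2:
            raise ValueError("n_specimens must be >= 2")
        for name in ("true_between_variance", "true_error_variance_a",
                     "true_error_variance_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def theoretical_icc(self) -> float:
        err = 0.5 * (self.true_error_variance_a + self.true_error_variance_b)
        tot = self.true_between_variance + err
        return self.true_between_variance / tot if tot > 0 else float("nan")


@dataclass
class PairedMeasurements:
    table: pd.DataFrame
    theoretical_icc: float
    spec: AgreementSimSpec


def simulate_paired_measurements(spec: AgreementSimSpec) -> PairedMeasurements:
    """Draw per-specimen latent levels plus independent method errors."""
    rng = np.random.default_rng(spec.seed)
    latent = spec.mean_level + rng.normal(
        0.0, np.sqrt(spec.true_between_variance), spec.n_specimens)
    a = latent + rng.normal(0.0, np.sqrt(spec.true_error_variance_a),
                            spec.n_specimens)
    b = latent + rng.normal(0.0, np.sqrt(spec.true_error_variance_b),
                            spec.n_specimens)
    table = pd.DataFrame({
        "specimen": np.arange(spec.n_specimens),
        "method_a": a,
        "method_b": b,
    })
    return PairedMeasurements(table, spec.theoretical_icc, spec)
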