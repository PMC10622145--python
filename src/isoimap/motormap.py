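"""Intracortical-microstimulation (ICMS) motor maps.

An ICMS motor map is a set of stimulation sites in chamber coordinates
(mm), each with the movement(s) evoked at that site and the current
threshold (uA) for evoking them.  The map is painted as Voronoi tiles
clipped to a maximum radius (0.75 mm), site classes are consolidated
into broad somatotopic categories (hand, arm, trunk, face, dual), the
M1/premotor border is drawn at the transition from low (<30 uA) to high
threshold sites 3-5 mm from the central sulcus, and the forelimb
representation (hand + arm + forelimb-dual tiles in M1 and PMd) is
rasterized into a pixel mask used to express activity-map sizes as
overlap percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Point, Polygon, box
from skimage import measure

__all__ = [
    "StimSite",
    "MotorMap",
    "ForelimbMask",
    "ImageGeometry",
    "consolidate_class",
    "consolidate_movements",
    "merge_depth_records",
    "build_voronoi_tiles",
    "delineate_m1_border",
    "rasterize_site_labels",
    "rasterize_forelimb_mask",
    "M1_THRESHOLD_UA",
]

#: Current threshold (uA) separating M1 from premotor sites.
M1_THRESHOLD_UA = 30.0

#: Joints counted as hand vs arm when consolidating site classes.
HAND_JOINTS = frozenset({"digits", "wrist"})
ARM_JOINTS = frozenset({"shoulder", "elbow"})
OTHER_JOINTS = frozenset({"trunk", "face"})
KNOWN_JOINTS = HAND_JOINTS | ARM_JOINTS | OTHER_JOINTS

FORELIMB_CLASSES = frozenset({"hand", "arm", "dual-forelimb"})


class ClassificationError(ValueError):
    """Raised for movement labels outside the known joint vocabulary."""


@dataclass
class StimSite:
    """One ICMS penetration: location, evoked movements, threshold."""

    x_mm: float
    y_mm: float
    movements: list[tuple[str, str]]  # (joint, movement type)
    threshold_uA: float
    dual: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.threshold_uA <= 300):
            raise ValueError(
                f"threshold_uA must be in (0, 300], got {self.threshold_uA}"
            )
        if not self.movements:
            raise ValueError("site needs >=1 movement label (or 'no response')")


def consolidate_movements(movements: list[tuple[str, str]]) -> str:
    """Consolidate evoked-movement labels into a broad class.

    digits/wrist -> hand; shoulder/elbow -> arm; mixed arm+hand or
    forelimb+other -> dual; trunk/face preserved.
    """
    if not movements:
        raise ClassificationError("empty movement list")
    joints = {j for j, _ in movements}
    unknown = joints - KNOWN_JOINTS
    if unknown:
        raise ClassificationError(f"unknown joint label(s): {sorted(unknown)}")
    has_hand = bool(joints & HAND_JOINTS)
    has_arm = bool(joints & ARM_JOINTS)
    has_other = bool(joints & OTHER_JOINTS)
    if (has_hand or has_arm) and has_other:
        return "dual"
    if has_hand and has_arm:
        return "dual-forelimb"
    if has_hand:
        return "hand"
    if has_arm:
        return "arm"
    # trunk/face only
    if joints == {"trunk"}:
        return "trunk"
    if joints == {"face"}:
        return "face"
    return "dual"  # trunk + face


def consolidate_class(site: StimSite) -> str:
    """Broad class for one site (see :func:`consolidate_movements`)."""
    return consolidate_movements(site.movements)


def merge_depth_records(depth_records: pd.DataFrame) -> pd.DataFrame:
    """Merge per-depth stimulation records into one record per penetration.

    The overall classification of a penetration keeps every movement
    evoked at a threshold within 30% of the lowest threshold across the
    tested depths; the penetration threshold is that minimum.

    Parameters
    ----------
    depth_records
        Columns: x_mm, y_mm, depth_um, joint, movement, threshold_uA.
    """
    required = {"x_mm", "y_mm", "depth_um", "joint", "movement", "threshold_uA"}
    missing = required - set(depth_records.columns)
    if missing:
        raise ValueError(f"depth records missing columns: {sorted(missing)}")
    rows = []
    for (x, y), grp in depth_records.groupby(["x_mm", "y_mm"], sort=True):
        tmin = grp["threshold_uA"].min()
        keep = grp[grp["threshold_uA"] <= 1.3 * tmin]
        movements = sorted({(j, m) for j, m in zip(keep["joint"], keep["movement"])})
        for j, m in movements:
            rows.append(
                {"x_mm": x, "y_mm": y, "joint": j, "movement": m,
                 "threshold_uA": tmin}
            )
    return pd.DataFrame(rows)


def _halfplane(site: np.ndarray, other: np.ndarray, extent: float) -> Polygon:
    """Half-plane (as a large polygon) on ``site``'s side of the bisector."""
    n = other - site
    n = n / np.linalg.norm(n)
    t = np.array([-n[1], n[0]])
    m = 0.5 * (site + other)
    a = m + t * extent
    b = m - t * extent
    return Polygon([a, b, b - n * 2 * extent, a - n * 2 * extent])


def build_voronoi_tiles(
    sites_xy: np.ndarray,
    max_radius_mm: float = 0.75,
    bounds: tuple[float, float, float, float] | None = None,
) -> list[Polygon]:
    """Voronoi tiles clipped to a disc of ``max_radius_mm`` per site.

    Each tile is (Voronoi cell of the site) ∩ (disc of radius
    ``max_radius_mm`` centred on the site) ∩ ``bounds``.

    Parameters
    ----------
    sites_xy
        (n, 2) array of site coordinates in mm.
    bounds
        (xmin, ymin, xmax, ymax) in mm; ``None`` leaves tiles unclipped
        by any outer boundary.
    """
    pts = np.asarray(sites_xy, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 1:
        raise ValueError("sites_xy must be a non-empty (n, 2) array")
    # duplicate coordinates make the Voronoi cell degenerate
    _, inverse, counts = np.unique(
        pts.round(9), axis=0, return_inverse=True, return_counts=True
    )
    if (counts > 1).any():
        dup = np.flatnonzero(counts[inverse] > 1)
        raise ValueError(
            f"duplicate site coordinates at indices {dup.tolist()[:4]}"
        )
    span = pts.max(axis=0) - pts.min(axis=0)
    extent = float(np.hypot(*span)) + 4 * max_radius_mm + 1.0
    clip = box(*bounds) if bounds is not None else None
    tree = cKDTree(pts)
    tiles: list[Polygon] = []
    for i, p in enumerate(pts):
        tile = Point(p).buffer(max_radius_mm, quad_segs=64)
        if clip is not None:
            tile = tile.intersection(clip)
        for j in tree.query_ball_point(p, 2 * max_radius_mm + 1e-9):
            if j == i:
                continue
            tile = tile.intersection(_halfplane(p, pts[j], extent))
        tiles.append(tile)
    return tiles


@dataclass
class ImageGeometry:
    """Pixel grid <-> chamber-mm transform (pixel centres at integers)."""

    height_px: int
    width_px: int
    px_per_mm: float
    origin_mm: tuple[float, float] = (0.0, 0.0)  # mm position of pixel (0, 0)

    def pixel_centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        ox, oy = self.origin_mm
        x = ox + np.arange(self.width_px) / self.px_per_mm
        y = oy + np.arange(self.height_px) / self.px_per_mm
        return np.meshgrid(x, y)  # (H, W) each

    def mm_to_px(self, x_mm: np.ndarray, y_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ox, oy = self.origin_mm
        return (np.asarray(x_mm) - ox) * self.px_per_mm, (np.asarray(y_mm) - oy) * self.px_per_mm


@dataclass
class MotorMap:
    """Site table plus derived tiles, consolidated classes and area labels.

    ``sites`` columns: x_mm, y_mm, threshold_uA plus one row per site;
    ``consolidated_class`` and ``area`` are per-site labels, ``tiles``
    per-site polygons.
    """

    sites: pd.DataFrame
    tiles: list[Polygon] = field(default_factory=list)
    consolidated_class: list[str] = field(default_factory=list)
    area: list[str] = field(default_factory=list)
    m1_border: np.ndarray | None = None  # (k, 2) polyline in mm
    max_radius_mm: float = 0.75
    bounds: tuple[float, float, float, float] | None = None

    @classmethod
    def from_site_table(
        cls,
        sites: pd.DataFrame,
        max_radius_mm: float = 0.75,
        bounds: tuple[float, float, float, float] | None = None,
    ) -> "MotorMap":
        """Build tiles and consolidated classes from a long site table.

        ``sites`` has one row per (site, movement) with columns x_mm,
        y_mm, joint, movement, threshold_uA.
        """
        grouped = []
        classes = []
        for (x, y), grp in sites.groupby(["x_mm", "y_mm"], sort=True):
            movements = [(j, m) for j, m in zip(grp["joint"], grp["movement"])]
            classes.append(consolidate_movements(movements))
            grouped.append(
                {"x_mm": x, "y_mm": y, "threshold_uA": float(grp["threshold_uA"].iloc[0]),
                 "n_movements": len(movements)}
            )
        df = pd.DataFrame(grouped)
        tiles = build_voronoi_tiles(
            df[["x_mm", "y_mm"]].to_numpy(), max_radius_mm, bounds
        )
        return cls(
            sites=df, tiles=tiles, consolidated_class=classes,
            max_radius_mm=max_radius_mm, bounds=bounds,
        )

    def tile_vertices(self) -> list[np.ndarray]:
        return [np.asarray(t.exterior.coords) for t in self.tiles]


def delineate_m1_border(
    mmap: MotorMap,
    cs_line: np.ndarray | LineString,
    pm_divide_y_mm: float,
    distance_band_mm: tuple[float, float] = (3.0, 5.0),
    raster_step_mm: float = 0.1,
) -> dict:
    """Label site areas (M1 / PMd / PMv) and draw the M1 rostral border.

    Sites with threshold below 30 uA on the central-sulcus side are M1;
    rostral sites are PMd (medial of ``pm_divide_y_mm``) or PMv
    (lateral).  The border polyline is the rasterized boundary between
    M1-labelled and premotor-labelled territory; its distance to the
    central sulcus is validated against ``distance_band_mm`` (3-5 mm)
    and violations are reported, not "fixed".

    Returns a dict with keys ``area`` (per-site labels, also written to
    ``mmap.area``), ``border_mm`` (polyline), and ``band_violations``.
    """
    sites = mmap.sites
    cs = cs_line if isinstance(cs_line, LineString) else LineString(np.asarray(cs_line))
    low = sites["threshold_uA"].to_numpy() < M1_THRESHOLD_UA
    if not low.any():
        raise ValueError("no sites with threshold < 30 uA: cannot place M1 border")
    if low.all():
        raise ValueError(
            "all sites have threshold < 30 uA: no low/high transition to border"
        )

    d_cs = np.array(
        [cs.distance(Point(x, y)) for x, y in zip(sites["x_mm"], sites["y_mm"])]
    )
    area = []
    for is_low, d, y in zip(low, d_cs, sites["y_mm"]):
        if is_low:
            area.append("M1")
        elif y >= pm_divide_y_mm:
            area.append("PMv")
        else:
            area.append("PMd")
    mmap.area = area

    # rasterize nearest-site labels on a fine grid and trace the M1 boundary
    pts = sites[["x_mm", "y_mm"]].to_numpy()
    if mmap.bounds is not None:
        xmin, ymin, xmax, ymax = mmap.bounds
    else:
        xmin, ymin = pts.min(axis=0) - 1
        xmax, ymax = pts.max(axis=0) + 1
    gx = np.arange(xmin, xmax + raster_step_mm, raster_step_mm)
    gy = np.arange(ymin, ymax + raster_step_mm, raster_step_mm)
    X, Y = np.meshgrid(gx, gy)
    tree = cKDTree(pts)
    _, idx = tree.query(np.column_stack([X.ravel(), Y.ravel()]))
    is_m1 = low[idx].reshape(X.shape).astype(float)
    contours = measure.find_contours(is_m1, 0.5)
    if not contours:
        border_mm = np.empty((0, 2))
    else:
        c = max(contours, key=len)  # (row=gy index, col=gx index)
        border_mm = np.column_stack(
            [xmin + c[:, 1] * raster_step_mm, ymin + c[:, 0] * raster_step_mm]
        )
    lo, hi = distance_band_mm
    violations = []
    for x, y in border_mm[:: max(1, len(border_mm) // 200)]:
        d = cs.distance(Point(x, y))
        if not (lo <= d <= hi):
            violations.append((float(x), float(y), float(d)))
    return {"area": area, "border_mm": border_mm, "band_violations": violations}


def rasterize_site_labels(
    sites_xy: np.ndarray,
    geometry: ImageGeometry,
    max_radius_mm: float = 0.75,
    bounds: tuple[float, float, float, float] | None = None,
) -> np.ndarray:
    """Label each pixel with its nearest site index within the tile radius.

    Pixels farther than ``max_radius_mm`` from every site (or outside
    ``bounds``) get -1.  This nearest-site labelling is exactly the
    rasterization of the clipped Voronoi tiles.
    """
    X, Y = geometry.pixel_centers_mm()
    tree = cKDTree(np.asarray(sites_xy, dtype=float))
    d, idx = tree.query(np.column_stack([X.ravel(), Y.ravel()]))
    labels = np.where(d <= max_radius_mm, idx, -1)
    labels = labels.reshape(X.shape)
    if bounds is not None:
        xmin, ymin, xmax, ymax = bounds
        outside = (X < xmin) | (X > xmax) | (Y < ymin) | (Y > ymax)
        labels[outside] = -1
    return labels


@dataclass
class ForelimbMask:
    """Rasterized forelimb representation per cortical area.

    ``combined`` is the union of the per-area masks; ``n_countable`` is
    the combined pixel count after vessel exclusion.
    """

    per_area: dict[str, np.ndarray]
    combined: np.ndarray
    geometry: ImageGeometry
    n_countable: int
    vessel_mask: np.ndarray | None = None

    def countable(self) -> np.ndarray:
        if self.vessel_mask is None:
            return self.combined
        return self.combined & ~self.vessel_mask


def rasterize_forelimb_mask(
    mmap: MotorMap,
    geometry: ImageGeometry,
    vessel_mask: np.ndarray | None = None,
    areas: tuple[str, ...] = ("M1", "PMd"),
) -> ForelimbMask:
    """Rasterize the forelimb representation (hand/arm/dual tiles).

    Pixels inside tiles whose consolidated class is forelimb (hand, arm
    or dual-forelimb) and whose area is in ``areas`` (default M1 and
    PMd; PMv and face/trunk territory are excluded) are set.  Vessel
    pixels are removed from the countable total.
    """
    if not mmap.area:
        raise ValueError("site areas not assigned; run delineate_m1_border first")
    if vessel_mask is not None and vessel_mask.shape != (
        geometry.height_px,
        geometry.width_px,
    ):
        raise ValueError(
            f"vessel mask shape {vessel_mask.shape} does not match geometry "
            f"({geometry.height_px}, {geometry.width_px})"
        )
    labels = rasterize_site_labels(
        mmap.sites[["x_mm", "y_mm"]].to_numpy(), geometry,
        mmap.max_radius_mm, mmap.bounds,
    )
    cls = np.asarray(mmap.consolidated_class)
    area = np.asarray(mmap.area)
    forelimb_site = np.isin(cls, list(FORELIMB_CLASSES))
    per_area: dict[str, np.ndarray] = {}
    for a in areas:
        site_ok = forelimb_site & (area == a)
        ok_idx = np.flatnonzero(site_ok)
        per_area[a] = np.isin(labels, ok_idx)
    combined = np.zeros_like(labels, dtype=bool)
    for m in per_area.values():
        combined |= m
    countable = combined if vessel_mask is None else combined & ~vessel_mask
    return ForelimbMask(
        per_area=per_area,
        combined=combined,
        geometry=geometry,
        n_countable=int(countable.sum()),
        vessel_mask=vessel_mask,
    )
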