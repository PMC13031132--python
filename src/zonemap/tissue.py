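"""Vein detection, trajectory ROIs, strategic cell selection and spatial ratios.

The workflow mirrors how hepatocytes are picked for laser microdissection
along a porto-central trajectory:

1. ``detect_veins`` finds cell-free lumens in the cell-boundary channel
   (Gaussian blur, grey dilation, histogram-minimum threshold, connected
   components).
2. ``classify_veins`` types each lumen as central or portal by comparing the
   standardized pericentral vs periportal marker intensity in a surrounding
   annulus.
3. ``pair_trajectories`` greedily pairs central with portal veins by anchor
   distance.
4. ``build_trajectory_roi`` keeps cells between the two anchors and within a
   two-sided cone (default half-angle 65 deg) around the axis.
5. ``select_cells_fft`` picks up to k=44 cells by farthest-first traversal,
   maximizing the minimum pairwise centroid distance (a 2-approximation to
   the max-min dispersion optimum).
6. ``compute_spatial_ratio`` assigns each selected cell its normalized
   position S in [0, 1] along the axis, with S=0 at the central vein.

``manual_trajectory`` reproduces the same downstream behaviour from two
user-supplied anchor points, for tissue where marker staining fails.

Coordinates are pixels, origin top-left, x right / y down.  Polygons are
stored open (last vertex != first).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon
from skimage import filters, measure, morphology

__all__ = [
    "CellContour",
    "Vein",
    "Trajectory",
    "SpatialCell",
    "NoThresholdError",
    "AmbiguousVeinError",
    "EmptyTrajectoryError",
    "detect_veins",
    "classify_veins",
    "pair_trajectories",
    "build_trajectory_roi",
    "select_cells_fft",
    "compute_spatial_ratio",
    "manual_trajectory",
    "simplify_contour",
]


class NoThresholdError(ValueError):
    """The boundary channel has no histogram valley to threshold at."""


class AmbiguousVeinError(ValueError):
    """A vein's marker scores tie; its type cannot be decided automatically."""


class EmptyTrajectoryError(ValueError):
    """No cell centroid satisfies the trajectory's cone predicate."""


@dataclass(frozen=True)
class CellContour:
    """A segmented cell polygon in pixel coordinates."""

    id: str
    vertices: np.ndarray  # (n, 2) float, open ring
    centroid: tuple[float, float]
    area: float

    @classmethod
    def from_vertices(cls, id: str, vertices: np.ndarray) -> "CellContour":
        vertices = np.asarray(vertices, dtype=float)
        if vertices.ndim != 2 or vertices.shape[1] != 2 or len(vertices) < 3:
            raise ValueError(f"contour {id!r}: need >= 3 (x, y) vertices")
        poly = Polygon(vertices)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError(f"contour {id!r}: polygon is degenerate or self-intersecting")
        c = poly.centroid
        return cls(id=id, vertices=vertices, centroid=(c.x, c.y), area=poly.area)

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class Vein:
    """A detected (or user-declared) vein lumen."""

    mask: np.ndarray | None  # boolean pixel mask; None for manual point veins
    anchor: tuple[float, float]  # (x, y)
    area: float
    type: str | None = None  # "central" | "portal"
    marker_score_central: float = float("nan")
    marker_score_portal: float = float("nan")


@dataclass
class Trajectory:
    """A central-portal vein pair with its cone ROI."""

    central: Vein
    portal: Vein
    cone_half_angle: float
    roi_cells: list[CellContour] = field(default_factory=list)

    @property
    def axis_length(self) -> float:
        (ax, ay), (bx, by) = self.central.anchor, self.portal.anchor
        return math.hypot(ax - bx, ay - by)


@dataclass(frozen=True)
class SpatialCell:
    """A selected cell with its position along the porto-central axis."""

    contour: CellContour
    d_central: float
    d_portal: float
    S: float
    patient_id: str = ""


def detect_veins(
    boundary: np.ndarray,
    min_vein_area: float = 900.0,
    blur_sigma: float = 5.0,
    dilation_radius: int = 10,
) -> list[Vein]:
    """Find cell-free lumens (vein candidates) in the boundary-stain channel.

    The image is Gaussian-blurred and grey-dilated (removing small inter-cell
    voids), thresholded at the histogram minimum, and the below-threshold
    connected components larger than ``min_vein_area`` are returned.
    """
    img = np.asarray(boundary, dtype=float)
    if img.ndim != 2:
        raise ValueError("boundary channel must be a 2-D image")
    smoothed = filters.gaussian(img, sigma=blur_sigma, preserve_range=True)
    dilated = morphology.dilation(smoothed, morphology.disk(dilation_radius))
    try:
        thresh = filters.threshold_minimum(dilated)
    except RuntimeError as exc:  # unimodal histogram: no valley
        raise NoThresholdError(
            "no histogram-minimum threshold found (image has no signal voids)"
        ) from exc
    voids = dilated < thresh
    labels = measure.label(voids)
    veins: list[Vein] = []
    for region in measure.regionprops(labels):
        if region.area < min_vein_area:
            continue
        cy, cx = region.centroid  # regionprops is (row, col)
        veins.append(
            Vein(mask=labels == region.label, anchor=(float(cx), float(cy)),
                 area=float(region.area))
        )
    return veins


def classify_veins(
    veins: list[Vein],
    pericentral: np.ndarray,
    periportal: np.ndarray,
    annulus_width: int = 20,
) -> list[Vein]:
    """Type each vein by marker expression in an annulus around its lumen.

    Both marker channels are standardized image-wide (z-scored) first; a
    vein is *central* when the mean standardized pericentral signal in the
    annulus exceeds the periportal one, *portal* otherwise.  The annulus is
    clipped at image borders.  An exact tie raises :class:`AmbiguousVeinError`.
    """

    def _standardize(img: np.ndarray) -> np.ndarray:
        img = np.asarray(img, dtype=float)
        sd = img.std()
        if sd == 0:
            raise ValueError("marker channel is constant; cannot standardize")
        return (img - img.mean()) / sd

    zc = _standardize(pericentral)
    zp = _standardize(periportal)
    footprint = morphology.disk(annulus_width)
    out: list[Vein] = []
    for i, vein in enumerate(veins):
        if vein.mask is None:
            raise ValueError("cannot classify a point vein without a mask")
        annulus = morphology.dilation(vein.mask, footprint) & ~vein.mask
        if not annulus.any():
            raise ValueError(f"vein {i}: annulus is empty")
        sc = float(zc[annulus].mean())
        sp = float(zp[annulus].mean())
        if sc == sp:
            raise AmbiguousVeinError(f"vein {i} at {vein.anchor}: marker scores tie")
        vein.marker_score_central = sc
        vein.marker_score_portal = sp
        vein.type = "central" if sc > sp else "portal"
        out.append(vein)
    return out


def pair_trajectories(veins: list[Vein]) -> list[tuple[Vein, Vein]]:
    """Greedy nearest-anchor matching of central to portal veins.

    Repeatedly takes the globally closest unmatched (central, portal) pair;
    each vein is used at most once.  Pairs are returned sorted by axis
    length.  Returns an empty list when no central/portal pair exists.
    """
    centrals = [v for v in veins if v.type == "central"]
    portals = [v for v in veins if v.type == "portal"]
    if not centrals or not portals:
        return []
    candidates = sorted(
        ((math.dist(c.anchor, p.anchor), i, j)
         for i, c in enumerate(centrals) for j, p in enumerate(portals)),
        key=lambda t: t[0],
    )
    used_c: set[int] = set()
    used_p: set[int] = set()
    pairs: list[tuple[Vein, Vein]] = []
    for d, i, j in candidates:
        if i in used_c or j in used_p:
            continue
        used_c.add(i)
        used_p.add(j)
        pairs.append((centrals[i], portals[j]))
    pairs.sort(key=lambda cp: math.dist(cp[0].anchor, cp[1].anchor))
    return pairs


def _cone_contains(
    centroid: tuple[float, float],
    a: tuple[float, float],
    b: tuple[float, float],
    half_angle_deg: float,
) -> bool:
    """Two-sided cone predicate: centroid projects onto the open segment AB
    and its angular deviation from the axis, measured at the nearer anchor,
    is at most the half-angle."""
    c = np.asarray(centroid, float)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ab = b - a
    L2 = float(ab @ ab)
    t = float((c - a) @ ab) / L2
    if not 0.0 < t < 1.0:
        return False
    anchor, axis = (a, ab) if t <= 0.5 else (b, -ab)
    v = c - anchor
    nv = float(np.hypot(*v))
    if nv == 0.0:
        return True  # centroid exactly on an anchor point
    cosang = float(v @ axis) / (nv * math.sqrt(L2))
    ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
    return ang <= half_angle_deg + 1e-12


def build_trajectory_roi(
    pair: tuple[Vein, Vein],
    contours: list[CellContour],
    cone_half_angle: float = 65.0,
) -> Trajectory:
    """Keep the cells lying between the two vein anchors inside the cone.

    Cells whose centroid falls inside either vein mask are excluded.  Raises
    :class:`EmptyTrajectoryError` when no cell qualifies.
    """
    central, portal = pair
    a, b = central.anchor, portal.anchor
    if a == b:
        raise ValueError("vein anchors must be distinct")
    roi: list[CellContour] = []
    for cell in contours:
        if not _cone_contains(cell.centroid, a, b, cone_half_angle):
            continue
        x, y = int(round(cell.centroid[0])), int(round(cell.centroid[1]))
        inside_mask = False
        for vein in (central, portal):
            m = vein.mask
            if m is not None and 0 <= y < m.shape[0] and 0 <= x < m.shape[1] and m[y, x]:
                inside_mask = True
                break
        if not inside_mask:
            roi.append(cell)
    if not roi:
        raise EmptyTrajectoryError("no cell centroid falls inside the trajectory cone")
    return Trajectory(central=central, portal=portal,
                      cone_half_angle=cone_half_angle, roi_cells=roi)


def select_cells_fft(roi_cells: list[CellContour], k: int = 44) -> list[CellContour]:
    """Farthest-first traversal: pick k cells maximizing min pairwise distance.

    Initialized with the exact diameter pair (maximum pairwise centroid
    distance, ties broken by lowest cell id); each subsequent pick maximizes
    its minimum distance to the already-selected set.  Greedy farthest-first
    traversal guarantees a min-distance of at least half the exhaustive
    max-min dispersion optimum.  Returns cells in selection order; if there
    are at most k cells, all are returned unchanged.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(roi_cells) <= k:
        return list(roi_cells)
    pts = np.array([c.centroid for c in roi_cells])
    n = len(pts)
    d = np.hypot(pts[:, 0][:, None] - pts[:, 0][None, :],
                 pts[:, 1][:, None] - pts[:, 1][None, :])
    ids = [c.id for c in roi_cells]
    # diameter pair, deterministic tie-break on sorted id pair
    best = None
    for i in range(n):
        for j in range(i + 1, n):
            key = (-d[i, j], min(ids[i], ids[j]), max(ids[i], ids[j]))
            if best is None or key < best[0]:
                best = (key, i, j)
    _, i0, j0 = best
    selected = [i0, j0]
    mind = np.minimum(d[i0], d[j0])
    mind[i0] = mind[j0] = -np.inf
    while len(selected) < k:
        m = mind.max()
        cand = np.flatnonzero(mind == m)
        nxt = min(cand, key=lambda i: ids[i])
        selected.append(nxt)
        mind = np.minimum(mind, d[nxt])
        mind[nxt] = -np.inf
    return [roi_cells[i] for i in selected]


def compute_spatial_ratio(
    centroid: tuple[float, float],
    central_anchor: tuple[float, float],
    portal_anchor: tuple[float, float],
    orientation: str = "central_zero",
) -> tuple[float, float, float]:
    """Distances to both anchors and the spatial ratio S.

    With the default orientation, S = d_central / (d_central + d_portal):
    S=0 at the central vein, S=1 at the portal vein.  ``orientation=
    "portal_zero"`` flips the convention.
    """
    if tuple(central_anchor) == tuple(portal_anchor):
        raise ValueError("anchors must be distinct")
    d_central = math.dist(centroid, central_anchor)
    d_portal = math.dist(centroid, portal_anchor)
    S = d_central / (d_central + d_portal)
    if orientation == "portal_zero":
        S = 1.0 - S
    elif orientation != "central_zero":
        raise ValueError("orientation must be 'central_zero' or 'portal_zero'")
    return d_central, d_portal, S


def manual_trajectory(
    point_a: tuple[float, float],
    point_b: tuple[float, float],
    contours: list[CellContour],
    cone_half_angle: float = 65.0,
) -> Trajectory:
    """Trajectory from two user-picked anchor points (A=central, B=portal).

    Behaves exactly like the automatic mode with degenerate point veins;
    intended for tissue whose marker staining cannot be trusted.  Anchors
    may lie outside the image (the predicate is purely geometric).
    """
    if tuple(point_a) == tuple(point_b):
        raise ValueError("anchor points A and B must be distinct")
    central = Vein(mask=None, anchor=(float(point_a[0]), float(point_a[1])),
                   area=0.0, type="central")
    portal = Vein(mask=None, anchor=(float(point_b[0]), float(point_b[1])),
                  area=0.0, type="portal")
    return build_trajectory_roi((central, portal), contours, cone_half_angle)


def simplify_contour(
    contour: CellContour,
    target_fraction: float = 0.10,
    max_area_change: float = 0.05,
) -> CellContour:
    """Decimate a contour to at most ceil(target_fraction x n) vertices.

    Uniform decimation is tried first, with the decimated polygon rescaled
    about its centroid to preserve the original area (a vertex-subset
    polygon is inscribed and systematically undersized).  If the result
    self-intersects or the symmetric area difference still exceeds
    ``max_area_change`` of the original area, a Douglas-Peucker
    simplification is refined (tolerance bisection) until both the vertex
    budget and the area tolerance hold.
    """
    verts = contour.vertices
    n = len(verts)
    budget = max(3, math.ceil(target_fraction * n))
    if n <= budget:
        return contour
    original = contour.polygon()

    def _rescale(xy: np.ndarray) -> np.ndarray | None:
        poly = Polygon(xy)
        if not poly.is_valid or poly.area <= 0:
            return None
        c = np.array([poly.centroid.x, poly.centroid.y])
        s = math.sqrt(original.area / poly.area)
        return c + (xy - c) * s

    def _ok(xy: np.ndarray) -> bool:
        if xy is None or len(xy) < 3:
            return False
        poly = Polygon(xy)
        if not poly.is_valid or poly.area <= 0:
            return False
        sym = poly.symmetric_difference(original).area
        return sym <= max_area_change * original.area

    idx = np.unique(np.round(np.linspace(0, n, budget, endpoint=False)).astype(int) % n)
    cand = _rescale(verts[np.sort(idx)])
    if cand is not None and len(cand) >= 3 and _ok(cand):
        return CellContour.from_vertices(contour.id, cand)

    # Douglas-Peucker: bisect the tolerance between "too many vertices"
    # (needs coarser) and "area drifted too far" (needs finer)
    span = float(np.ptp(verts, axis=0).max())
    lo, hi = 0.0, span
    best: np.ndarray | None = None
    for _ in range(60):
        mid = (lo + hi) / 2
        simp = original.simplify(mid, preserve_topology=True)
        xy = np.asarray(simp.exterior.coords)[:-1] if simp.geom_type == "Polygon" else None
        if xy is None or len(xy) > budget:
            lo = mid
            continue
        xy = _rescale(xy)
        if _ok(xy):
            best = xy
            break
        hi = mid
    if best is None:
        raise ValueError(
            f"contour {contour.id!r}: cannot reach {budget} vertices within "
            f"{max_area_change:.0%} area tolerance"
        )
    return CellContour.from_vertices(contour.id, best)
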