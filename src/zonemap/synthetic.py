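"""Synthetic tissue scenes and single-cell proteome matrices with known ground truth.

Two generators underpin the test surface of the whole package:

``generate_tissue``
    A two-vein liver-like scene: four image channels (pericentral marker,
    periportal marker, cell-boundary stain, nuclear stain) plus polygonal
    cell contours.  Marker channels decay exponentially with distance from
    their vein; the boundary channel is void inside vein lumens, which is
    exactly the cue the vein detector exploits.  Cells are Voronoi polygons
    of a jittered grid, so they tile the parenchyma like phalloidin-bounded
    hepatocytes without running any segmentation model.

``generate_proteome``
    Protein intensities under the random-intercept gradient model

        y_ij = beta0 + beta1 * S_ij + u_i + eps_ij

    per protein, with patient random intercepts u_i ~ N(0, sigma_u^2),
    residuals eps_ij ~ N(0, sigma_e^2), an optional "disease" condition in
    which slopes are multiplied by an attenuation factor, and logistic
    missing-not-at-random dropout acting on the standardized latent
    intensity (low-abundance entries are more likely to be missing).

Both are deterministic given their seed; all randomness flows through one
``numpy.random.Generator`` per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from scipy.special import expit
from shapely.geometry import Polygon, box

from .tissue import CellContour

__all__ = [
    "TissueSpec",
    "ProteomeSpec",
    "GroundTruth",
    "generate_tissue",
    "generate_proteome",
]


@dataclass(frozen=True)
class TissueSpec:
    """Parameters of a synthetic two-vein tissue scene (pixel units)."""

    image_shape: tuple[int, int] = (700, 360)  # (H, W)
    vein_central: tuple[float, float, float] = (180.0, 60.0, 30.0)  # (x, y, radius)
    vein_portal: tuple[float, float, float] = (180.0, 640.0, 30.0)
    cell_grid_pitch: float = 20.0
    cell_jitter: float = 5.0
    marker_decay_length: float = 150.0
    noise_sd: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        ax, ay, ar = self.vein_central
        bx, by, br = self.vein_portal
        if math.hypot(ax - bx, ay - by) <= ar + br:
            raise ValueError("vein lumens overlap; adjust anchors or radii")
        if min(ar, br) <= 0:
            raise ValueError("vein radii must be positive")
        if self.cell_grid_pitch <= 0:
            raise ValueError("cell_grid_pitch must be positive")


@dataclass(frozen=True)
class ProteomeSpec:
    """Parameters of a synthetic single-cell proteome cohort."""

    n_patients: int = 14
    n_disease_patients: int = 0
    cells_per_patient: int = 44
    n_proteins: int = 200
    frac_zonated: float = 0.5
    beta1_range: tuple[float, float] = (0.5, 2.0)  # |slope| range for zonated proteins
    beta0_mean_sd: tuple[float, float] = (12.0, 1.0)
    sigma_u: float = 0.5
    sigma_e: float = 0.3
    dropout_midpoint: float | None = -1.5  # None disables dropout entirely
    dropout_slope: float = 1.0
    attenuation: float = 1.0  # multiplies beta1 for disease-condition patients
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.frac_zonated <= 1.0:
            raise ValueError("frac_zonated must be in [0, 1]")
        if self.sigma_u < 0 or self.sigma_e < 0:
            raise ValueError("sigma_u and sigma_e must be non-negative")
        if self.n_disease_patients > self.n_patients:
            raise ValueError("n_disease_patients exceeds n_patients")
        if self.n_patients < 1 or self.cells_per_patient < 1 or self.n_proteins < 1:
            raise ValueError("counts must be positive")


@dataclass
class GroundTruth:
    """True generative parameters behind a synthetic proteome matrix."""

    beta0: np.ndarray  # (n_proteins,)
    beta1: np.ndarray  # (n_proteins,) — healthy-condition slope
    zonated: np.ndarray  # (n_proteins,) bool
    u: np.ndarray  # (n_proteins, n_patients) random intercepts
    S: np.ndarray  # (n_cells,)
    latent: np.ndarray  # (n_proteins, n_cells) pre-dropout intensities
    patient_ids: list[str] = field(default_factory=list)
    conditions: list[str] = field(default_factory=list)  # per patient


def _circle(cx: float, cy: float, r: float, n: int = 64) -> Polygon:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Polygon(np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)]))


def _voronoi_cells(seeds: np.ndarray, width: float, height: float) -> list[np.ndarray]:
    """Finite Voronoi polygons of `seeds`, clipped to the image rectangle.

    Seeds are mirrored across all four image edges so every interior region
    is bounded; the region of each original seed is then intersected with
    the image box.
    """
    mirrored = [seeds]
    for axis, bound in ((0, width), (1, height)):
        for edge in (0.0, bound):
            m = seeds.copy()
            m[:, axis] = 2 * edge - m[:, axis]
            mirrored.append(m)
    allpts = np.vstack(mirrored)
    vor = Voronoi(allpts)
    frame = box(0, 0, width, height)
    polys: list[np.ndarray] = []
    for i in range(len(seeds)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            continue
        poly = Polygon(vor.vertices[region]).intersection(frame)
        if poly.is_empty or poly.geom_type != "Polygon" or poly.area <= 0:
            continue
        xy = np.asarray(poly.exterior.coords)[:-1]  # drop closing vertex
        polys.append(xy)
    return polys


def generate_tissue(
    spec: TissueSpec,
) -> tuple[dict[str, np.ndarray], list[CellContour], dict[str, tuple[float, float]]]:
    """Generate a synthetic two-vein scene.

    Returns
    -------
    channels : dict
        ``{"pericentral", "periportal", "boundary", "nuclei"}`` → float32
        (H, W) arrays.
    contours : list of CellContour
        Jittered Voronoi cells tiling the non-vein area.
    anchors : dict
        True vein centres, ``{"central": (x, y), "portal": (x, y)}``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_shape
    cx, cy, cr = spec.vein_central
    px, py, pr = spec.vein_portal

    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    d_central = np.hypot(xx - cx, yy - cy)
    d_portal = np.hypot(xx - px, yy - py)

    in_central = d_central <= cr
    in_portal = d_portal <= pr
    lumen = in_central | in_portal

    def noisy(base: np.ndarray) -> np.ndarray:
        out = base + rng.normal(0.0, spec.noise_sd, base.shape)
        return np.clip(out, 0.0, None).astype(np.float32)

    pericentral = noisy(np.exp(-d_central / spec.marker_decay_length))
    periportal = noisy(np.exp(-d_portal / spec.marker_decay_length))
    boundary = np.where(lumen, 0.02, 0.7)
    boundary = noisy(boundary)

    # jittered grid seeds for cell polygons, kept clear of the lumens
    gx = np.arange(spec.cell_grid_pitch / 2, W, spec.cell_grid_pitch)
    gy = np.arange(spec.cell_grid_pitch / 2, H, spec.cell_grid_pitch)
    seeds = np.array([(x, y) for y in gy for x in gx], dtype=float)
    seeds += rng.uniform(-spec.cell_jitter, spec.cell_jitter, seeds.shape)
    seeds[:, 0] = np.clip(seeds[:, 0], 1.0, W - 1.0)
    seeds[:, 1] = np.clip(seeds[:, 1], 1.0, H - 1.0)
    # hepatocytes tile right up to the vein wall: keep cell centres half a
    # cell pitch clear of the lumen so polygons abut but do not cross it
    margin = spec.cell_grid_pitch / 2
    keep = (np.hypot(seeds[:, 0] - cx, seeds[:, 1] - cy) > cr + margin) & (
        np.hypot(seeds[:, 0] - px, seeds[:, 1] - py) > pr + margin
    )
    seeds = seeds[keep]

    # clip cell polygons against the lumens: cells abut but never cover a vein
    lumens = _circle(cx, cy, cr).union(_circle(px, py, pr))
    contours: list[CellContour] = []
    i = 0
    for xy in _voronoi_cells(seeds, float(W), float(H)):
        poly = Polygon(xy).difference(lumens)
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
        if poly.is_empty or poly.geom_type != "Polygon" or poly.area <= 1.0:
            continue
        contours.append(
            CellContour.from_vertices(
                f"cell_{i:04d}", np.asarray(poly.exterior.coords)[:-1]
            )
        )
        i += 1

    nuclei = np.zeros((H, W), dtype=np.float64)
    sig = 3.0
    for c in contours:
        x0, y0 = c.centroid
        xi, yi = int(round(x0)), int(round(y0))
        r = 9
        ys = slice(max(0, yi - r), min(H, yi + r + 1))
        xs = slice(max(0, xi - r), min(W, xi + r + 1))
        sub_y, sub_x = np.mgrid[ys, xs]
        nuclei[ys, xs] += np.exp(-((sub_x - x0) ** 2 + (sub_y - y0) ** 2) / (2 * sig**2))
    nuclei = noisy(nuclei)

    channels = {
        "pericentral": pericentral,
        "periportal": periportal,
        "boundary": boundary,
        "nuclei": nuclei,
    }
    anchors = {"central": (cx, cy), "portal": (px, py)}
    return channels, contours, anchors


def generate_proteome(
    spec: ProteomeSpec,
    S: np.ndarray | None = None,
) -> tuple["IntensityMatrix", GroundTruth]:
    """Generate a proteins x samples intensity matrix under the gradient model.

    Parameters
    ----------
    spec : ProteomeSpec
    S : array, optional
        Spatial ratios per cell (length n_patients * cells_per_patient).
        Drawn uniform on [0, 1] when omitted.
    """
    from .qc import IntensityMatrix  # local import to avoid a cycle

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_cells = spec.n_patients * spec.cells_per_patient
    if S is None:
        S = rng.uniform(0.0, 1.0, n_cells)
    else:
        S = np.asarray(S, dtype=float)
        if S.shape != (n_cells,):
            raise ValueError(f"S must have length {n_cells}")
        if S.min() < 0 or S.max() > 1:
            raise ValueError("S values must lie in [0, 1]")

    patients = [f"P{i + 1:02d}" for i in range(spec.n_patients)]
    conditions = ["disease" if i < spec.n_disease_patients else "healthy"
                  for i in range(spec.n_patients)]
    patient_idx = np.repeat(np.arange(spec.n_patients), spec.cells_per_patient)

    n_zon = int(round(spec.frac_zonated * spec.n_proteins))
    zonated = np.zeros(spec.n_proteins, dtype=bool)
    zonated[:n_zon] = True
    lo, hi = spec.beta1_range
    beta1 = np.zeros(spec.n_proteins)
    beta1[zonated] = rng.uniform(lo, hi, n_zon) * rng.choice([-1.0, 1.0], n_zon)
    beta0 = rng.normal(spec.beta0_mean_sd[0], spec.beta0_mean_sd[1], spec.n_proteins)
    u = rng.normal(0.0, spec.sigma_u, (spec.n_proteins, spec.n_patients))
    eps = rng.normal(0.0, spec.sigma_e, (spec.n_proteins, n_cells))

    slope_scale = np.where(np.array(conditions) == "disease", spec.attenuation, 1.0)
    cell_slope = slope_scale[patient_idx]  # (n_cells,)
    latent = (
        beta0[:, None]
        + beta1[:, None] * (cell_slope * S)[None, :]
        + u[:, patient_idx]
        + eps
    )

    if spec.dropout_midpoint is None:
        observed = np.ones_like(latent, dtype=bool)
    else:
        sd = latent.std(axis=1, ddof=0, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        z = (latent - latent.mean(axis=1, keepdims=True)) / sd
        p_obs = expit((z - spec.dropout_midpoint) * spec.dropout_slope)
        observed = rng.uniform(size=latent.shape) < p_obs

    values = np.where(observed, latent, np.nan)
    sample_ids = [
        f"{patients[patient_idx[j]]}_c{j % spec.cells_per_patient:03d}"
        for j in range(n_cells)
    ]
    protein_ids = [f"PROT{i + 1:04d}" for i in range(spec.n_proteins)]
    mat = pd.DataFrame(values, index=protein_ids, columns=sample_ids)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "patient_id": [patients[i] for i in patient_idx],
            "condition": [conditions[i] for i in patient_idx],
            "S": S,
        }
    ).set_index("sample_id")

    truth = GroundTruth(
        beta0=beta0,
        beta1=beta1,
        zonated=zonated,
        u=u,
        S=S,
        latent=latent,
        patient_ids=patients,
        conditions=conditions,
    )
    return IntensityMatrix(values=mat, meta=meta), truth
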