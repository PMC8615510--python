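"""Ground-truthed synthetic inputs for every pipeline stage.

Each generator emulates one class of raw data the pipeline consumes and
attaches a :class:`SyntheticTruth` describing exactly what was rendered:

* two-compartment H&E-like sections populated by elliptical cells of
  controlled axis ratio (hence controlled convex-hull circularity),
  rendered through the Beer-Lambert optical-density stain model;
* bright-membrane CAM-like images with dark anti-aliased vessel trees of
  known centerline polylines, total length and junction count;
* logistic viability time courses;
* sigmoid Hill dose-response tables with replicate noise.

All randomness flows from a single integer seed per spec, so a fixed
spec is bit-reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ellipe

from .doseresponse import DoseResponseTable, hill
from .growth import ViabilityTimeSeries, logistic
from .histomorphometry import DEFAULT_STAIN_MATRIX

__all__ = [
    "GenerationError",
    "SyntheticHistologySpec",
    "SyntheticVesselSpec",
    "SyntheticTruth",
    "TrueCell",
    "ellipse_circularity",
    "make_histology",
    "make_vessels",
    "make_viability",
    "make_dose_response",
    "polyline_length",
]

logger = logging.getLogger(__name__)


class GenerationError(RuntimeError):
    """Raised when a spec cannot be realized (e.g. overcrowded compartment)."""


def ellipse_circularity(axis_ratio: float) -> float:
    """Analytic hull circularity 4*pi*A/P^2 of an ellipse with a/b ratio.

    The convex hull of an ellipse is the ellipse itself; the perimeter
    uses the complete elliptic integral of the second kind.
    """
    if axis_ratio < 1:
        axis_ratio = 1.0 / axis_ratio
    a, b = axis_ratio, 1.0
    area = math.pi * a * b
    m = 1.0 - (b / a) ** 2  # eccentricity squared
    perimeter = 4.0 * a * ellipe(m)
    return 4.0 * math.pi * area / perimeter**2


def polyline_length(points: np.ndarray) -> float:
    """Euclidean arc length of a polyline given as (N, 2) rows/cols."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        return 0.0
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


@dataclass
class TrueCell:
    center_rc: tuple[float, float]
    semi_axes_px: tuple[float, float]  # (a, b), a >= b
    orientation_rad: float
    circularity: float
    compartment: str


@dataclass
class SyntheticTruth:
    seed: int
    pixel_size_um: float = 1.0
    cells: list[TrueCell] = field(default_factory=list)
    polylines_px: list[np.ndarray] = field(default_factory=list)
    total_length_um: float = 0.0
    junction_count: int = 0
    params: dict = field(default_factory=dict)

    def cell_area_fraction(self, shape: tuple[int, int]) -> float:
        """Analytic total ellipse area over image area (non-overlapping cells)."""
        total = sum(math.pi * a * b for c in self.cells for a, b in [c.semi_axes_px])
        return total / (shape[0] * shape[1])


@dataclass
class SyntheticHistologySpec:
    """Recipe for a two-compartment H&E-like section.

    The compartment layout is a vertical split: left half parenchymal
    (label 1), right half stromal (label 2), unless a custom label mask
    is supplied.  Cell shapes are ellipses with per-compartment axis
    ratio laws; the stain model renders cell, matrix and background
    optical densities through three unit stain vectors.
    """

    shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 1.0
    n_cells: dict[str, int] = field(
        default_factory=lambda: {"parenchymal": 30, "stromal": 30}
    )
    axis_ratio: dict[str, float] = field(
        default_factory=lambda: {"parenchymal": 1.1, "stromal": 4.0}
    )
    axis_ratio_sd: dict[str, float] = field(
        default_factory=lambda: {"parenchymal": 0.05, "stromal": 0.3}
    )
    cell_radius_um: float = 6.0  # geometric-mean semi-axis
    cell_radius_sd_um: float = 0.5
    stain_matrix: np.ndarray = field(default_factory=lambda: DEFAULT_STAIN_MATRIX.copy())
    cell_od: float = 0.9
    matrix_od: dict[str, float] = field(
        default_factory=lambda: {"parenchymal": 0.15, "stromal": 0.3}
    )
    background_od: float = 0.02
    noise_sd: float = 0.01
    allow_overlap: bool = False
    max_overlap_fraction: float = 0.0
    compartment_mask: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")
        if any(v < 0 for v in self.n_cells.values()):
            raise ValueError("cell counts must be >= 0")
        m = np.asarray(self.stain_matrix, dtype=float)
        if not np.allclose(np.linalg.norm(m, axis=1), 1.0, atol=1e-6):
            raise ValueError("stain vectors must be unit-norm")
        for i in range(3):
            for j in range(i + 1, 3):
                if abs(float(np.dot(m[i], m[j]))) > 1 - 1e-6:
                    raise ValueError("stain vectors must be pairwise non-collinear")


def _default_compartments(shape: tuple[int, int]) -> np.ndarray:
    mask = np.ones(shape, dtype=np.uint8)
    mask[:, shape[1] // 2 :] = 2
    return mask


def _ellipse_mask(shape, center, a, b, theta):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ct, st = math.cos(theta), math.sin(theta)
    u = dc * ct + dr * st
    v = -dc * st + dr * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def make_histology(
    spec: SyntheticHistologySpec,
) -> tuple[np.ndarray, np.ndarray, SyntheticTruth]:
    """Render a synthetic stained section.

    Returns (RGB float image in [0, 1], compartment label mask, truth).
    Cells are non-overlapping by default; if a compartment cannot host
    its requested count a :class:`GenerationError` names it.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    comp_mask = (
        _default_compartments(shape)
        if spec.compartment_mask is None
        else np.asarray(spec.compartment_mask, dtype=np.uint8)
    )

    occupied = np.zeros(shape, dtype=bool)
    cell_conc = np.zeros(shape, dtype=float)
    truth = SyntheticTruth(seed=spec.seed, pixel_size_um=spec.pixel_size_um)
    s = spec.pixel_size_um

    for comp_label, comp_name in ((1, "parenchymal"), (2, "stromal")):
        n = spec.n_cells.get(comp_name, 0)
        region = comp_mask == comp_label
        coords = np.argwhere(region)
        if n > 0 and coords.size == 0:
            raise GenerationError(f"compartment {comp_name!r} absent from the layout")
        placed = 0
        attempts = 0
        max_attempts = max(200 * n, 1000)
        while placed < n:
            attempts += 1
            if attempts > max_attempts:
                raise GenerationError(
                    f"compartment {comp_name!r} too crowded: placed {placed}/{n} cells"
                )
            ratio = max(rng.normal(spec.axis_ratio[comp_name],
                                   spec.axis_ratio_sd[comp_name]), 1.0)
            r_geo = max(rng.normal(spec.cell_radius_um, spec.cell_radius_sd_um), 1.0) / s
            a = r_geo * math.sqrt(ratio)
            b = r_geo / math.sqrt(ratio)
            theta = rng.uniform(0, math.pi)
            idx = coords[rng.integers(coords.shape[0])]
            center = (float(idx[0]), float(idx[1]))
            margin = a + 1
            if not (
                margin <= center[0] < shape[0] - margin
                and margin <= center[1] < shape[1] - margin
            ):
                continue
            mask = _ellipse_mask(shape, center, a, b, theta)
            if not spec.allow_overlap:
                # demand clear separation so segmentation sees single cells
                dilated = np.zeros(shape, dtype=bool)
                r0 = max(int(center[0] - a - 2), 0)
                r1 = min(int(center[0] + a + 3), shape[0])
                c0 = max(int(center[1] - a - 2), 0)
                c1 = min(int(center[1] + a + 3), shape[1])
                dilated[r0:r1, c0:c1] = True
                if (occupied & dilated).any():
                    continue
            if not region[int(center[0]), int(center[1])]:
                continue
            occupied |= mask
            cell_conc[mask] = spec.cell_od
            truth.cells.append(
                TrueCell(
                    center_rc=center,
                    semi_axes_px=(a, b),
                    orientation_rad=theta,
                    circularity=ellipse_circularity(a / b),
                    compartment=comp_name,
                )
            )
            placed += 1

    matrix_conc = np.zeros(shape, dtype=float)
    for comp_label, comp_name in ((1, "parenchymal"), (2, "stromal")):
        matrix_conc[comp_mask == comp_label] = spec.matrix_od[comp_name]
    matrix_conc[occupied] = 0.0
    bg_conc = np.full(shape, spec.background_od)

    m = np.asarray(spec.stain_matrix, dtype=float)
    od = (
        cell_conc[..., None] * m[0]
        + matrix_conc[..., None] * m[1]
        + bg_conc[..., None] * m[2]
    )
    rgb = 10.0 ** (-od)
    if spec.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sd, rgb.shape)
    rgb = np.clip(rgb, 0.0, 1.0)

    truth.params = {
        "n_cells": dict(spec.n_cells),
        "axis_ratio": dict(spec.axis_ratio),
        "cell_od": spec.cell_od,
        "noise_sd": spec.noise_sd,
    }
    return rgb, comp_mask, truth


@dataclass
class SyntheticVesselSpec:
    """Recipe for a CAM-like vessel-tree image.

    A branching random tree is grown from ``n_roots`` border points:
    headings random-walk with ``curvature_jitter`` per step, segments are
    drawn from a lognormal length law, and at each segment end the tree
    bifurcates with ``branch_prob`` (a junction) or terminates.  Vessels
    are rendered as dark anti-aliased strokes on a bright membrane
    background, darkest in the green channel.
    """

    shape: tuple[int, int] = (384, 384)
    pixel_size_um: float = 2.0
    n_roots: int = 3
    branch_prob: float = 0.7
    max_depth: int = 4
    segment_length_um: float = 120.0
    segment_length_sd_um: float = 30.0
    vessel_width_px: float = 3.0
    curvature_jitter_rad: float = 0.08
    border_repulsion: float = 0.25  # steering away from the canvas edge
    border_margin_px: int = 30
    background_gray: float = 0.85
    vessel_gray: float = 0.25
    noise_sd: float = 0.01
    # a CAM field is always perfused; trees below this centerline density
    # (um of vessel per um^2, ~5-10x below typical) are regrown
    min_density_per_um: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vessel_width_px < 1:
            raise ValueError("vessel width must be >= 1 px")
        if self.vessel_gray >= self.background_gray:
            raise ValueError("vessels must be darker than the background")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")


def _grow_tree(spec: SyntheticVesselSpec, rng: np.random.Generator):
    """Grow branch polylines; returns (polylines, junction points)."""
    shape = spec.shape
    step = 2.0  # px per walk step
    polylines: list[np.ndarray] = []
    junctions: list[tuple[float, float]] = []

    def in_canvas(p):
        return 1 <= p[0] < shape[0] - 1 and 1 <= p[1] < shape[1] - 1

    stack = []
    for _ in range(spec.n_roots):
        side = rng.integers(4)
        if side == 0:
            p = (1.0, float(rng.uniform(0, shape[1] - 1)))
            heading = math.pi / 2  # down
        elif side == 1:
            p = (float(shape[0] - 2), float(rng.uniform(0, shape[1] - 1)))
            heading = -math.pi / 2
        elif side == 2:
            p = (float(rng.uniform(0, shape[0] - 1)), 1.0)
            heading = 0.0
        else:
            p = (float(rng.uniform(0, shape[0] - 1)), float(shape[1] - 2))
            heading = math.pi
        stack.append((p, heading, 0))

    while stack:
        start, heading, depth = stack.pop()
        length_px = max(
            rng.normal(spec.segment_length_um, spec.segment_length_sd_um), 10.0
        ) / spec.pixel_size_um
        pts = [start]
        pos = start
        traveled = 0.0
        clipped = False
        center = (shape[0] / 2.0, shape[1] / 2.0)
        margin = spec.border_margin_px
        while traveled < length_px:
            heading += rng.normal(0.0, spec.curvature_jitter_rad)
            # a perfused membrane fills the field: walks near the canvas
            # edge are steered back inward instead of walking off
            near_border = (
                pos[0] < margin or pos[0] > shape[0] - margin
                or pos[1] < margin or pos[1] > shape[1] - margin
            )
            if near_border:
                to_center = math.atan2(center[0] - pos[0], center[1] - pos[1])
                delta = (to_center - heading + math.pi) % (2 * math.pi) - math.pi
                heading += spec.border_repulsion * delta
            nxt = (pos[0] + step * math.sin(heading), pos[1] + step * math.cos(heading))
            if not in_canvas(nxt):
                clipped = True
                logger.warning("vessel branch clipped at the canvas border")
                break
            pts.append(nxt)
            traveled += step
            pos = nxt
        if len(pts) >= 2:
            polylines.append(np.asarray(pts, dtype=float))
        if clipped or depth >= spec.max_depth:
            continue
        if rng.uniform() < spec.branch_prob:
            junctions.append(pos)
            spread = rng.uniform(0.3, 0.8)
            stack.append((pos, heading - spread, depth + 1))
            stack.append((pos, heading + spread, depth + 1))

    return polylines, junctions


def _render_strokes(shape, polylines, width_px, bg, fg):
    """Anti-aliased dark strokes via per-sample radial coverage stamps."""
    ink = np.zeros(shape, dtype=float)
    half = width_px / 2.0
    win = int(math.ceil(half + 1.5))
    for poly in polylines:
        # resample at ~0.5 px spacing along the polyline
        seglens = np.hypot(*np.diff(poly, axis=0).T)
        total = float(seglens.sum())
        n_samp = max(int(total / 0.5), 2)
        t = np.linspace(0, total, n_samp)
        cum = np.concatenate([[0], np.cumsum(seglens)])
        rs = np.interp(t, cum, poly[:, 0])
        cs = np.interp(t, cum, poly[:, 1])
        for r, c in zip(rs, cs):
            r0, c0 = int(r) - win, int(c) - win
            r1, c1 = int(r) + win + 1, int(c) + win + 1
            rr = np.arange(max(r0, 0), min(r1, shape[0]))
            cc = np.arange(max(c0, 0), min(c1, shape[1]))
            if rr.size == 0 or cc.size == 0:
                continue
            d = np.hypot(rr[:, None] - r, cc[None, :] - c)
            cover = np.clip(half + 0.5 - d, 0.0, 1.0)
            block = ink[rr[0] : rr[-1] + 1, cc[0] : cc[-1] + 1]
            np.maximum(block, cover, out=block)
    gray = bg - (bg - fg) * ink
    return gray


def _crossing_points(polylines, known, merge_radius: float):
    """Crossings between distinct branches, excluding known branch points."""
    from shapely.geometry import LineString, MultiPoint, Point

    lines = [LineString(np.c_[p[:, 1], p[:, 0]]) for p in polylines if len(p) >= 2]
    pts: list[tuple[float, float]] = [tuple(j) for j in known]

    def add(geom):
        stack = [geom]
        while stack:
            g = stack.pop()
            if isinstance(g, Point):
                cand = (g.y, g.x)  # back to (row, col)
                if all(math.hypot(cand[0] - q[0], cand[1] - q[1]) > merge_radius
                       for q in pts):
                    pts.append(cand)
            elif isinstance(g, MultiPoint):
                stack.extend(g.geoms)
            elif hasattr(g, "geoms"):
                stack.extend(g.geoms)

    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            inter = lines[i].intersection(lines[j])
            if not inter.is_empty:
                add(inter)
    return pts


def vessels_from_polylines(
    polylines_px: list[np.ndarray], spec: SyntheticVesselSpec,
    branch_points: list[tuple[float, float]] | None = None,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Render explicit centerline polylines under a vessel spec.

    Useful for constructing controlled geometries (straight lines,
    forced crossings); the truth is computed exactly as in
    :func:`make_vessels`, with crossings of distinct polylines counted
    as junctions.
    """
    rng = np.random.default_rng(spec.seed)
    polylines = [np.asarray(p, dtype=float) for p in polylines_px]
    junctions = _crossing_points(polylines, list(branch_points or []),
                                 merge_radius=spec.vessel_width_px)
    total_um = sum(polyline_length(p) for p in polylines) * spec.pixel_size_um
    gray = _render_strokes(spec.shape, polylines, spec.vessel_width_px,
                           spec.background_gray, spec.vessel_gray)
    red = spec.background_gray - 0.6 * (spec.background_gray - gray)
    blue = spec.background_gray - 0.4 * (spec.background_gray - gray)
    rgb = np.stack([red, gray, blue], axis=-1)
    if spec.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sd, rgb.shape)
    rgb = np.clip(rgb, 0.0, 1.0)
    truth = SyntheticTruth(
        seed=spec.seed, pixel_size_um=spec.pixel_size_um,
        polylines_px=polylines, total_length_um=total_um,
        junction_count=len(junctions),
        params={"junction_points": [tuple(j) for j in junctions]},
    )
    return rgb, truth


def make_vessels(spec: SyntheticVesselSpec) -> tuple[np.ndarray, SyntheticTruth]:
    """Render a synthetic vessel-tree image with analytic truth.

    Returns (RGB float image, truth with centerline polylines, total
    length in um and junction count).  The truth junction count includes
    both branch events of the growth process and incidental crossings of
    distinct branches (which the skeleton cannot tell apart); junctions
    closer than one vessel width are merged, as they are unresolvable.
    """
    rng = np.random.default_rng(spec.seed)
    area_um2 = spec.shape[0] * spec.shape[1] * spec.pixel_size_um**2
    for attempt in range(20):
        polylines, branch_points = _grow_tree(spec, rng)
        total_um = sum(polyline_length(p) for p in polylines) * spec.pixel_size_um
        if total_um >= spec.min_density_per_um * area_um2:
            break
        logger.warning("tree too sparse for a perfused membrane; regrowing")
    junctions = _crossing_points(polylines, branch_points,
                                 merge_radius=spec.vessel_width_px)

    gray = _render_strokes(
        spec.shape, polylines, spec.vessel_width_px, spec.background_gray,
        spec.vessel_gray,
    )
    # vessels are dark red-brown on CAM: green carries the most contrast
    red = spec.background_gray - 0.6 * (spec.background_gray - gray)
    blue = spec.background_gray - 0.4 * (spec.background_gray - gray)
    rgb = np.stack([red, gray, blue], axis=-1)
    if spec.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sd, rgb.shape)
    rgb = np.clip(rgb, 0.0, 1.0)

    truth = SyntheticTruth(
        seed=spec.seed,
        pixel_size_um=spec.pixel_size_um,
        polylines_px=polylines,
        total_length_um=total_um,
        junction_count=len(junctions),
        params={
            "n_roots": spec.n_roots,
            "branch_prob": spec.branch_prob,
            "vessel_width_px": spec.vessel_width_px,
            "junction_points": [tuple(j) for j in junctions],
        },
    )
    return rgb, truth


def make_viability(
    c0: float,
    cmax: float,
    d: float,
    times_days,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    culture: str = "2D",
) -> tuple[ViabilityTimeSeries, SyntheticTruth]:
    """Logistic viability time course with i.i.d. Gaussian replicate noise.

    At d = 0 the law degenerates to the constant C0.
    """
    if c0 <= 0 or cmax < c0 or d < 0:
        raise ValueError("require C0 > 0, Cmax >= C0, d >= 0")
    times = np.asarray(times_days, dtype=float)
    rng = np.random.default_rng(seed)
    values = []
    for t in times:
        mean = c0 if d == 0 else logistic(t, c0, cmax, d)
        reps = mean + rng.normal(0.0, noise_sd, n_replicates) if noise_sd > 0 else (
            np.full(n_replicates, mean)
        )
        values.append(np.maximum(reps, 0.0))
    series = ViabilityTimeSeries(times_days=times, values=values, culture=culture)
    truth = SyntheticTruth(
        seed=seed,
        params={"c0": c0, "cmax": cmax, "d": d, "noise_sd": noise_sd,
                "n_replicates": n_replicates},
    )
    return series, truth


def make_dose_response(
    emax: float,
    ec50_log10: float,
    h: float,
    doses_ug_ml,
    n_replicates: int = 4,
    noise_sd: float = 0.0,
    seed: int = 0,
    culture: str = "2D",
    formulation: str = "free",
) -> tuple[DoseResponseTable, SyntheticTruth]:
    """Hill-sigmoid dead-fraction table with per-dose replicate noise.

    The zero-dose control is generated at E = 0; replicate values are
    clipped at 0 (a dead fraction cannot be negative).  Returns the
    per-dose mean/s.d./n table plus the truth; replicate-level values are
    stored in ``truth.params['replicates']``.
    """
    if not 0 < emax <= 100:
        raise ValueError("require 0 < Emax <= 100")
    doses = np.asarray(doses_ug_ml, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be >= 0")
    if not np.any(doses == 0):
        raise ValueError("the zero-dose control must be included")
    rng = np.random.default_rng(seed)
    means, sds, reps_store = [], [], {}
    for dose in doses:
        e_true = 0.0 if dose == 0 else hill(math.log10(dose), emax, ec50_log10, h)
        reps = e_true + rng.normal(0.0, noise_sd, n_replicates) if noise_sd > 0 else (
            np.full(n_replicates, e_true)
        )
        reps = np.clip(reps, 0.0, 100.0)
        reps_store[float(dose)] = reps
        means.append(float(reps.mean()))
        sds.append(float(reps.std(ddof=1)) if n_replicates > 1 else 0.0)
    table = DoseResponseTable(
        doses_ug_ml=doses,
        e_percent=np.asarray(means),
        sigma_e=np.asarray(sds),
        n=np.full(doses.size, n_replicates),
        culture=culture,
        formulation=formulation,
    )
    truth = SyntheticTruth(
        seed=seed,
        params={
            "emax": emax,
            "ec50_log10": ec50_log10,
            "h": h,
            "noise_sd": noise_sd,
            "replicates": reps_store,
        },
    )
    return table, truth
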