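"""Quantification of CAM vascular networks from stereomicroscopy images.

The pipeline follows the standard brightfield chorioallantoic-membrane
(CAM) workflow: vessels show the strongest contrast in the green channel,
so the green plane is extracted, contrast-stretched, and curvilinear
structures are traced with a Steger-style ridge detector (second
derivatives of a Gaussian kernel, principal-curvature direction from the
local Hessian, sub-pixel line-point test, hysteresis linking).  The
resulting unit-width skeleton is converted to a graph of segments and
junctions from which branch-length density (total centerline length per
ROI area) and branching statistics are computed, averaged per egg, and
compared between experimental groups with the two-sample
Kolmogorov-Smirnov and Mann-Whitney U tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from scipy import stats
from skimage.filters import apply_hysteresis_threshold
from skimage.morphology import skeletonize

__all__ = [
    "RidgeParams",
    "VesselSkeleton",
    "RoiMetrics",
    "EggSummary",
    "green_channel",
    "stretch",
    "detect_ridges",
    "branch_length_density",
    "egg_summary",
    "ecdf",
    "ks_two_sample",
    "mann_whitney",
    "sigma_for_width",
]

# 8-connected neighbor offsets and their step lengths (px)
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_SQRT2 = float(np.sqrt(2.0))


def sigma_for_width(width_px: float) -> float:
    """Gaussian scale matched to a line of given full width.

    Uses the bar-profile relation sigma >= w / (2*sqrt(3)) at which the
    second-derivative response across the line is single-moded.
    """
    return float(width_px) / (2.0 * np.sqrt(3.0))


@dataclass
class RidgeParams:
    """Parameters of the Gaussian-derivative ridge detector."""

    sigma: float = 1.8
    low: float = 0.04
    high: float = 0.10
    min_length_px: float = 5.0
    dark_lines: bool = True

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not (self.high >= self.low >= 0):
            raise ValueError("need high >= low >= 0")


@dataclass
class RoiMetrics:
    roi: tuple
    area_um2: float
    total_length_um: float
    density_per_um: float
    junctions_per_um2: float
    mean_segment_length_um: float
    n_segments: int
    n_junctions: int


@dataclass
class EggSummary:
    egg_id: str
    group: str
    roi_metrics: list[RoiMetrics]
    mean_density_per_um: float
    junctions_per_um2: float
    mean_segment_length_um: float


class VesselSkeleton:
    """Unit-width centerline skeleton of a vessel network with its graph.

    Nodes are skeleton pixels with a number of 8-neighbors different
    from 2 (endpoints and junction pixels); edges are the pixel chains
    between them.  Each edge carries a geometric length estimated by
    polygonal resampling of its pixel chain (every few pixels plus the
    endpoints), which suppresses the systematic overestimation of the
    raw unit/sqrt(2) step metric on oblique digital lines while never
    dropping below the Euclidean endpoint distance.
    """

    def __init__(self, mask: np.ndarray, pixel_size_um: float = 1.0):
        self.mask = np.asarray(mask, dtype=bool)
        self.pixel_size_um = float(pixel_size_um)
        self.graph = _build_graph(self.mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def edges(self):
        """Iterate (chain_pixels, length_px) over all segments."""
        for _, _, data in self.graph.edges(data=True):
            yield data["pixels"], data["length_px"]

    def total_length_px(self) -> float:
        return float(sum(l for _, l in self.edges()))

    def total_length_um(self) -> float:
        return self.total_length_px() * self.pixel_size_um

    def junctions(self, merge_radius_px: float = 6.0) -> list[tuple[float, float]]:
        """Junction coordinates; junction pixels closer than the merge
        radius collapse to one point.  The default is about twice a
        typical vessel width: an X-crossing of width-w lines thins into
        two 3-way nodes up to ~2w apart, so finer separations do not
        correspond to distinct crossings."""
        jpix = [n for n in self.graph.nodes if self.graph.degree(n) >= 3]
        if not jpix:
            return []
        from scipy.spatial import cKDTree

        sub = nx.Graph()
        sub.add_nodes_from(jpix)
        tree = cKDTree(np.asarray(jpix, dtype=float))
        for i, j in tree.query_pairs(merge_radius_px):
            sub.add_edge(jpix[i], jpix[j])
        out = []
        for comp in nx.connected_components(sub):
            arr = np.array(list(comp), dtype=float)
            out.append((float(arr[:, 0].mean()), float(arr[:, 1].mean())))
        return out

    def prune_spurs(self, min_length_px: float, max_iter: int = 5) -> "VesselSkeleton":
        """Remove terminal segments shorter than ``min_length_px``.

        Pruning can expose new short spurs, so the pass iterates to a
        fixpoint (bounded by ``max_iter``); isolated short fragments are
        removed as well and the graph is rebuilt on the pruned mask.
        """
        current = self
        for _ in range(max_iter):
            mask = current.mask.copy()
            changed = False
            for u, v, data in current.graph.edges(data=True):
                du, dv = current.graph.degree(u), current.graph.degree(v)
                terminal = du == 1 or dv == 1
                if terminal and data["length_px"] < min_length_px:
                    for (r, c) in data["pixels"]:
                        keep = (r, c) in (u, v) and current.graph.degree((r, c)) >= 3
                        if not keep:
                            mask[r, c] = False
                    changed = True
            if not changed:
                return current
            current = VesselSkeleton(mask, current.pixel_size_um)
        return current


def _chain_geometric_length(chain, sample_step: int = 4) -> float:
    """Arc length of a pixel chain by polygonal resampling.

    Sampling every few pixels (plus both endpoints) averages out the
    staircase of the digital line, removing the ~5% positive bias the
    unit/sqrt(2) step metric has on oblique lines.
    """
    pts = np.asarray(chain, dtype=float)
    if pts.shape[0] < 2:
        return 0.0
    idx = list(range(0, pts.shape[0] - 1, sample_step)) + [pts.shape[0] - 1]
    sub = pts[idx]
    return float(np.sum(np.hypot(*np.diff(sub, axis=0).T)))


def _build_graph(mask: np.ndarray) -> nx.MultiGraph:
    g = nx.MultiGraph()
    pts = set(zip(*np.nonzero(mask)))
    if not pts:
        return g

    def nbrs(p):
        r, c = p
        return [(r + dr, c + dc) for dr, dc in _OFFSETS if (r + dr, c + dc) in pts]

    deg = {p: len(nbrs(p)) for p in pts}
    nodes = {p for p, d in deg.items() if d != 2}
    for p in nodes:
        g.add_node(p)

    visited_steps: set[tuple] = set()

    # trace chains outward from every node
    for start in nodes:
        for nb in nbrs(start):
            key = (start, nb)
            if key in visited_steps:
                continue
            chain = [start, nb]
            visited_steps.add((start, nb))
            visited_steps.add((nb, start))
            prev, cur = start, nb
            while cur not in nodes:
                nxt = [q for q in nbrs(cur) if q != prev]
                # drop shortcut diagonal when an axial neighbor of both exists
                if len(nxt) > 1:
                    nxt = [q for q in nxt if (q, cur) not in visited_steps]
                if not nxt:
                    break
                nq = nxt[0]
                visited_steps.add((cur, nq))
                visited_steps.add((nq, cur))
                chain.append(nq)
                prev, cur = cur, nq
            g.add_edge(chain[0], chain[-1], pixels=chain,
                       length_px=_chain_geometric_length(chain))

    # pure cycles have no degree!=2 pixel; pick an anchor per cycle
    traced = {p for _, _, d in g.edges(data=True) for p in d["pixels"]}
    remaining = pts - traced - nodes
    while remaining:
        start = next(iter(remaining))
        chain = [start]
        prev, cur = None, start
        while True:
            cand = [q for q in nbrs(cur) if q != prev]
            if not cand:
                break
            nq = cand[0]
            if nq == start:
                chain.append(nq)
                break
            chain.append(nq)
            prev, cur = cur, nq
        g.add_node(start)
        g.add_edge(chain[0], chain[-1], pixels=chain,
                   length_px=_chain_geometric_length(chain))
        remaining -= set(chain)

    # isolated single pixels contribute nothing but stay as nodes
    return g


def green_channel(rgb: np.ndarray) -> np.ndarray:
    """Extract the green plane of an RGB image, dtype unchanged."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected a 3-channel RGB image")
    return rgb[:, :, 1]


def stretch(gray: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0) -> np.ndarray:
    """Percentile histogram stretch to [0, 1] with clipping."""
    gray = np.asarray(gray, dtype=float)
    lo, hi = np.percentile(gray, [low_pct, high_pct])
    if hi <= lo:
        warnings.warn("constant image: histogram stretch is a no-op", stacklevel=2)
        return gray.copy()
    return np.clip((gray - lo) / (hi - lo), 0.0, 1.0)


def _ridge_response(gray: np.ndarray, sigma: float, dark_lines: bool):
    """Scale-normalized principal curvature and the Steger line-point test."""
    g = np.asarray(gray, dtype=float)
    if not dark_lines:
        g = -g
    rx = ndi.gaussian_filter(g, sigma, order=(0, 1), mode="reflect")
    ry = ndi.gaussian_filter(g, sigma, order=(1, 0), mode="reflect")
    rxx = ndi.gaussian_filter(g, sigma, order=(0, 2), mode="reflect")
    ryy = ndi.gaussian_filter(g, sigma, order=(2, 0), mode="reflect")
    rxy = ndi.gaussian_filter(g, sigma, order=(1, 1), mode="reflect")

    # eigenvalues of the Hessian [[ryy, rxy], [rxy, rxx]] (row=y, col=x);
    # a dark line has a strongly positive curvature across its axis
    half_tr = 0.5 * (rxx + ryy)
    root = np.sqrt(0.25 * (rxx - ryy) ** 2 + rxy**2)
    lam = half_tr + root  # largest eigenvalue
    # unit eigenvector (nx, ny) across the line
    nx_ = rxy.copy()
    ny_ = lam - rxx
    degenerate = np.hypot(nx_, ny_) < 1e-12
    nx_[degenerate] = 1.0
    ny_[degenerate] = 0.0
    norm = np.hypot(nx_, ny_)
    nx_ /= norm
    ny_ /= norm

    # sub-pixel extremum along (nx, ny): within half a pixel of center
    second = rxx * nx_**2 + 2 * rxy * nx_ * ny_ + ryy * ny_**2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = -(rx * nx_ + ry * ny_) / second
    t = np.where(np.isfinite(t), t, np.inf)
    on_line = (np.abs(t * nx_) <= 0.7) & (np.abs(t * ny_) <= 0.7) & (lam > 0)

    response = sigma**2 * lam  # gamma-normalized for scale comparability
    return response, on_line


def detect_ridges(gray: np.ndarray, params: RidgeParams | None = None,
                  pixel_size_um: float = 1.0) -> VesselSkeleton:
    """Trace curvilinear vessels and return their unit-width skeleton.

    Second-derivative Gaussian responses are computed at ``params.sigma``;
    pixels passing the line-point test are linked by hysteresis between
    the low and high response thresholds, thinned to 8-connected unit
    width, and pruned of terminal spurs shorter than ``min_length_px``.
    """
    params = params or RidgeParams()
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    if params.sigma > min(gray.shape) / 8:
        raise ValueError("sigma too large for this image (exceeds min dim / 8)")

    response, on_line = _ridge_response(gray, params.sigma, params.dark_lines)
    response = np.where(on_line, response, 0.0)
    if params.high > 0:
        mask = apply_hysteresis_threshold(response, params.low, params.high)
    else:
        mask = response > 0
    # close 1-px gaps left by the line-point test before thinning
    mask = ndi.binary_closing(mask, structure=np.ones((3, 3)))
    skel = skeletonize(mask)
    vs = VesselSkeleton(skel, pixel_size_um)
    if params.min_length_px > 0:
        vs = vs.prune_spurs(params.min_length_px)
    return vs


def _roi_mask(roi, shape) -> np.ndarray:
    """ROI -> boolean mask. Rect: (r0, c0, height, width). Polygon: (N,2) rows/cols."""
    arr = np.asarray(roi, dtype=float)
    mask = np.zeros(shape, dtype=bool)
    if arr.shape == (4,):
        r0, c0, h, w = (int(round(v)) for v in arr)
        if h <= 0 or w <= 0:
            raise ValueError("zero-area ROI")
        if r0 < 0 or c0 < 0 or r0 + h > shape[0] or c0 + w > shape[1]:
            raise ValueError("ROI outside image bounds")
        mask[r0 : r0 + h, c0 : c0 + w] = True
    elif arr.ndim == 2 and arr.shape[1] == 2:
        from skimage.draw import polygon

        rr, cc = polygon(arr[:, 0], arr[:, 1], shape)
        if rr.size == 0:
            raise ValueError("zero-area ROI")
        mask[rr, cc] = True
    else:
        raise ValueError("ROI must be (r0, c0, h, w) or an (N, 2) polygon")
    return mask


def branch_length_density(skeleton: VesselSkeleton, roi,
                          pixel_size_um: float | None = None) -> RoiMetrics:
    """Branch length per unit ROI area, plus branching statistics.

    Length is accumulated over 8-connected steps whose both pixels lie in
    the ROI; density is reported in 1/um (um of centerline per um^2).
    """
    s = pixel_size_um if pixel_size_um is not None else skeleton.pixel_size_um
    if s <= 0:
        raise ValueError("pixel size must be > 0")
    mask = _roi_mask(roi, skeleton.shape)
    area_um2 = float(mask.sum()) * s * s
    if area_um2 == 0:
        raise ValueError("zero-area ROI")

    total_px = 0.0
    seg_lengths = []
    for chain, _ in skeleton.edges():
        in_roi = 0.0
        for a, b in zip(chain[:-1], chain[1:]):
            if mask[a] and mask[b]:
                in_roi += _SQRT2 if (a[0] != b[0] and a[1] != b[1]) else 1.0
        if in_roi > 0:
            seg_lengths.append(in_roi)
            total_px += in_roi
    njunc = sum(1 for (r, c) in skeleton.junctions()
                if mask[int(round(r)), int(round(c))])
    total_um = total_px * s
    return RoiMetrics(
        roi=tuple(np.asarray(roi).ravel().tolist()) if np.asarray(roi).ndim == 1
        else ("polygon", len(np.asarray(roi))),
        area_um2=area_um2,
        total_length_um=total_um,
        density_per_um=total_um / area_um2,
        junctions_per_um2=njunc / area_um2,
        mean_segment_length_um=float(np.mean(seg_lengths) * s) if seg_lengths else 0.0,
        n_segments=len(seg_lengths),
        n_junctions=int(njunc),
    )


def egg_summary(metrics: list[RoiMetrics], egg_id: str = "", group: str = "") -> EggSummary:
    """Per-egg summary: arithmetic mean density across ROIs; junction
    density pooled as total junctions over total area."""
    if not metrics:
        raise ValueError("need >= 1 ROI")
    mean_density = float(np.mean([m.density_per_um for m in metrics]))
    pooled_junc = sum(m.n_junctions for m in metrics) / sum(m.area_um2 for m in metrics)
    with_segs = [m for m in metrics if m.n_segments > 0]
    mean_seg = (
        float(np.mean([m.mean_segment_length_um for m in with_segs])) if with_segs else 0.0
    )
    return EggSummary(
        egg_id=egg_id,
        group=group,
        roi_metrics=list(metrics),
        mean_density_per_um=mean_density,
        junctions_per_um2=float(pooled_junc),
        mean_segment_length_um=mean_seg,
    )


def ecdf(values) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF: (sorted unique support, F values)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("ecdf of empty sample")
    if not np.all(np.isfinite(v)):
        raise ValueError("ecdf requires finite values")
    support, counts = np.unique(v, return_counts=True)
    return support, np.cumsum(counts) / v.size


def ks_two_sample(x, y, exact_threshold: int = 10000) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D = sup |F_x - F_y|; the p-value is exact when n*m is at or below
    ``exact_threshold`` and asymptotic (Kolmogorov distribution) above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if x.size * y.size <= exact_threshold else "asymp"
    res = stats.ks_2samp(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(x, y, two_sided: bool = True) -> tuple[float, float]:
    """Mann-Whitney U test with tie correction.

    Exact p for small tie-free samples, normal approximation otherwise
    (scipy's automatic switch). Returns U for sample x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided" if two_sided else "greater", method="auto"
    )
    return float(res.statistic), float(res.pvalue)
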