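"""Synthetic ER phantoms and a fluorescence acquisition simulator.

The endoplasmic reticulum in a STED field of view appears as a network of
thin tubules (~100 nm wide) meeting predominantly in 3-way junctions, with
flat sheets interspersed.  This module generates such structures with exact
ground-truth class labels and a ground-truth skeleton graph, and images them
under a simple photon-budget model: Gaussian PSF blur, per-pixel Poisson
shot noise proportional to dose, plus Poisson detector dark counts.

Two acquisition regimes mirror a high-dose "ground truth" scan
(56.3 uW excitation x 6 line accumulations) and a ~70x lower-dose
"low intensity" scan (4.8 uW x 1) of the same field, so that denoising
pipelines can be exercised end to end without microscope data.

All randomness flows from a single integer seed per operation through
``numpy.random.SeedSequence`` spawning, so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError

from .structure import ClassLabelMap, BACKGROUND, TUBE, SHEET

__all__ = [
    "PhantomParams",
    "AcquisitionParams",
    "DynamicsParams",
    "Phantom",
    "GROUND_TRUTH_ACQUISITION",
    "LOW_INTENSITY_ACQUISITION",
    "generate_phantom",
    "simulate_acquisition",
    "simulate_pair",
    "simulate_timeseries",
    "simulate_dark_movie",
    "simulate_prediction",
]


@dataclass(frozen=True)
class PhantomParams:
    """Geometry of a synthetic ER field of view.

    ``tube_width_nm`` is the full width of a tubule stroke; 100 nm is a
    typical apparent ER tubule width at STED resolution.  With the default
    20 nm pixels that is a 5-px-wide ridge.
    """

    height_px: int = 256
    width_px: int = 256
    pixel_size_nm: float = 20.0
    n_seed_nodes: int = 40
    tube_width_nm: float = 100.0
    n_sheets: int = 3
    sheet_area_px_range: tuple[int, int] = (200, 1200)
    junction_target_order: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 64 or self.width_px < 64:
            raise ValueError("image must be at least 64x64 px")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.tube_width_nm < self.pixel_size_nm:
            raise ValueError("tube_width_nm must be >= pixel_size_nm")
        if self.tube_width_nm / self.pixel_size_nm >= min(self.height_px, self.width_px):
            raise ValueError("tube width exceeds image extent")
        if self.n_seed_nodes < 0 or self.n_sheets < 0:
            raise ValueError("counts must be nonnegative")
        lo, hi = self.sheet_area_px_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid sheet_area_px_range")


@dataclass(frozen=True)
class AcquisitionParams:
    """Photon-budget model for one scan.

    Expected signal photons per pixel at unit structure density is
    ``dose_per_unit_density * line_accumulations``; detector dark counts
    are Poisson with mean ``dark_count_rate`` per pixel regardless of
    structure.  ``psf_fwhm_nm`` sets the effective (post-depletion) optical
    resolution; the depletion physics itself is not modelled.
    """

    dose_per_unit_density: float = 4.8
    line_accumulations: int = 1
    dark_count_rate: float = 0.01
    psf_fwhm_nm: float = 90.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.dose_per_unit_density < 0:
            raise ValueError("dose must be nonnegative")
        if self.line_accumulations < 1:
            raise ValueError("line_accumulations must be >= 1")
        if self.dark_count_rate < 0:
            raise ValueError("dark_count_rate must be nonnegative")
        if self.psf_fwhm_nm <= 0:
            raise ValueError("psf_fwhm_nm must be positive")

    @property
    def total_dose(self) -> float:
        return self.dose_per_unit_density * self.line_accumulations


#: Table-style defaults for the two acquisition regimes: excitation power
#: (uW) times line accumulations gives relative per-pixel dose, ratio
#: (56.3 * 6) / (4.8 * 1) = 70.375.
GROUND_TRUTH_ACQUISITION = AcquisitionParams(
    dose_per_unit_density=56.3, line_accumulations=6)
LOW_INTENSITY_ACQUISITION = AcquisitionParams(
    dose_per_unit_density=4.8, line_accumulations=1)


@dataclass(frozen=True)
class DynamicsParams:
    """Frame-to-frame remodelling of the phantom.

    ``rearrangement_rate`` is the fraction of network edges whose endpoints
    are jittered per frame; it is a phenomenological knob controlling how
    much adjacent frames overlap, not a biophysical model of ER motion.
    """

    n_frames: int = 20
    frame_interval_s: float = 4.6
    rearrangement_rate: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0.0 <= self.rearrangement_rate <= 1.0:
            raise ValueError("rearrangement_rate must be in [0, 1]")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")


@dataclass
class Phantom:
    """A rendered phantom: structure density, truth labels, truth skeleton.

    ``density_map`` is the fluorophore density before imaging (0 = empty).
    ``label_map`` assigns every pixel with density > 0 a structural class.
    ``skeleton_graph_truth`` lists the generating network nodes as
    ``(row, col, degree)`` triples.
    """

    density_map: np.ndarray
    label_map: ClassLabelMap
    skeleton_graph_truth: list[tuple[float, float, int]]
    params: PhantomParams | None = None
    # internal generative state, kept so dynamics can perturb and re-render
    _graph: nx.Graph | None = field(default=None, repr=False)
    _node_pos: dict | None = field(default=None, repr=False)
    _sheets: list | None = field(default=None, repr=False)


def _prune_to_target_order(graph: nx.Graph, target: int, rng: np.random.Generator) -> nx.Graph:
    """Remove edges from high-degree nodes until degrees approach ``target``,
    never disconnecting the graph."""
    g = graph.copy()
    # deterministic order: sort candidate edges, shuffle with rng
    changed = True
    while changed:
        changed = False
        over = [n for n, d in sorted(g.degree()) if d > target]
        rng.shuffle(over)
        for n in over:
            if g.degree(n) <= target:
                continue
            nbrs = sorted(g.neighbors(n), key=lambda m: g.degree(m), reverse=True)
            for m in nbrs:
                if g.degree(n) <= target:
                    break
                g.remove_edge(n, m)
                if nx.is_connected(g):
                    changed = True
                else:
                    g.add_edge(n, m)
    return g


def _build_network(params: PhantomParams, rng: np.random.Generator) -> tuple[nx.Graph, dict]:
    """Planar tubule network: uniform random nodes, Delaunay edges, pruned."""
    n = params.n_seed_nodes
    h, w = params.height_px, params.width_px
    margin = max(4.0, params.tube_width_nm / params.pixel_size_nm)
    pos = {
        i: (margin + rng.random() * (h - 2 * margin),
            margin + rng.random() * (w - 2 * margin))
        for i in range(n)
    }
    g = nx.Graph()
    g.add_nodes_from(pos)
    if n == 2:
        g.add_edge(0, 1)
        return g, pos
    if n >= 3:
        pts = np.array([pos[i] for i in range(n)])
        try:
            tri = Delaunay(pts)
            for simplex in tri.simplices:
                for a, b in ((0, 1), (1, 2), (0, 2)):
                    g.add_edge(int(simplex[a]), int(simplex[b]))
        except QhullError:  # collinear degenerate layout: chain them
            order = np.argsort(pts[:, 0] + pts[:, 1])
            for a, b in zip(order[:-1], order[1:]):
                g.add_edge(int(a), int(b))
        if g.number_of_edges() and nx.is_connected(g):
            g = _prune_to_target_order(g, params.junction_target_order, rng)
    return g, pos


def _render_tubes(shape: tuple[int, int], graph: nx.Graph, pos: dict,
                  half_width_px: float) -> np.ndarray:
    """Anti-aliased constant-width strokes: density = clip(hw + 0.5 - d, 0, 1)
    where d is distance to the nearest segment axis."""
    h, w = shape
    density = np.zeros(shape, dtype=np.float64)
    for a, b in graph.edges():
        r0, c0 = pos[a]
        r1, c1 = pos[b]
        rmin = max(0, int(np.floor(min(r0, r1) - half_width_px - 2)))
        rmax = min(h, int(np.ceil(max(r0, r1) + half_width_px + 2)) + 1)
        cmin = max(0, int(np.floor(min(c0, c1) - half_width_px - 2)))
        cmax = min(w, int(np.ceil(max(c0, c1) + half_width_px + 2)) + 1)
        if rmin >= rmax or cmin >= cmax:
            continue
        rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
        dr, dc = r1 - r0, c1 - c0
        L2 = dr * dr + dc * dc
        if L2 == 0:
            dist = np.hypot(rr - r0, cc - c0)
        else:
            t = np.clip(((rr - r0) * dr + (cc - c0) * dc) / L2, 0.0, 1.0)
            dist = np.hypot(rr - (r0 + t * dr), cc - (c0 + t * dc))
        stroke = np.clip(half_width_px + 0.5 - dist, 0.0, 1.0)
        np.maximum(density[rmin:rmax, cmin:cmax], stroke,
                   out=density[rmin:rmax, cmin:cmax])
    return density


def _make_sheets(params: PhantomParams, pos: dict,
                 rng: np.random.Generator) -> list[tuple[float, float, float, float, float]]:
    """Sheet descriptors (center_r, center_c, semi_a, semi_b, angle):
    filled ellipses (convex blobs) anchored near network nodes."""
    sheets = []
    anchors = list(pos.values())
    for _ in range(params.n_sheets):
        lo, hi = params.sheet_area_px_range
        area = rng.uniform(lo, hi)
        ecc = rng.uniform(1.0, 2.5)
        a = np.sqrt(area * ecc / np.pi)
        b = area / (np.pi * a)
        if anchors:
            cr, cc = anchors[rng.integers(len(anchors))]
            cr += rng.normal(0, 3)
            cc += rng.normal(0, 3)
        else:
            cr = rng.uniform(0, params.height_px)
            cc = rng.uniform(0, params.width_px)
        theta = rng.uniform(0, np.pi)
        sheets.append((cr, cc, a, b, theta))
    return sheets


def _render_sheets(shape: tuple[int, int],
                   sheets: list[tuple[float, float, float, float, float]]) -> np.ndarray:
    h, w = shape
    mask = np.zeros(shape, dtype=np.float64)
    rr, cc = np.mgrid[0:h, 0:w]
    for cr, cc0, a, b, theta in sheets:
        ct, st = np.cos(theta), np.sin(theta)
        u = (rr - cr) * ct + (cc - cc0) * st
        v = -(rr - cr) * st + (cc - cc0) * ct
        r2 = (u / a) ** 2 + (v / b) ** 2
        # soft 1-px edge so the density rolls off like the tube strokes
        edge = np.clip((1.0 - r2) * max(a, b) * 0.5 + 0.5, 0.0, 1.0)
        np.maximum(mask, edge, out=mask)
    return mask


def _render_phantom(params: PhantomParams, graph: nx.Graph, pos: dict,
                    sheets: list) -> Phantom:
    shape = (params.height_px, params.width_px)
    half_width_px = 0.5 * params.tube_width_nm / params.pixel_size_nm
    tube_density = _render_tubes(shape, graph, pos, half_width_px)
    sheet_density = _render_sheets(shape, sheets)
    density = np.maximum(tube_density, sheet_density)
    labels = np.zeros(shape, dtype=np.uint8)
    labels[tube_density > 0] = TUBE
    labels[sheet_density > 0] = SHEET  # sheets override tubes where they overlap
    truth = [(float(pos[n][0]), float(pos[n][1]), int(d))
             for n, d in sorted(graph.degree())]
    return Phantom(
        density_map=density,
        label_map=ClassLabelMap(labels, params.pixel_size_nm),
        skeleton_graph_truth=truth,
        params=params,
        _graph=graph,
        _node_pos=pos,
        _sheets=sheets,
    )


def generate_phantom(params: PhantomParams) -> Phantom:
    """Generate an ER-like phantom with ground-truth labels.

    Tubules are constant-width anti-aliased strokes along the edges of a
    pruned Delaunay triangulation of uniformly placed nodes (pruning pulls
    node degrees toward ``junction_target_order``); sheets are filled
    convex blobs anchored on the network.  Deterministic given
    ``params.rng_seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.rng_seed).spawn(1)[0])
    graph, pos = _build_network(params, rng)
    sheets = _make_sheets(params, pos, rng)
    return _render_phantom(params, graph, pos, sheets)


def _fwhm_to_sigma_px(fwhm_nm: float, pixel_size_nm: float) -> float:
    return fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / pixel_size_nm


def simulate_acquisition(phantom: Phantom, acq: AcquisitionParams) -> np.ndarray:
    """Image a phantom: PSF blur, dose scaling, Poisson shot + dark noise.

    Returns a float array of photon counts (integers stored as floats).
    Deterministic given ``acq.rng_seed``.
    """
    if np.any(phantom.density_map < 0):
        raise ValueError("phantom density must be nonnegative")
    pixel_size = phantom.label_map.pixel_size_nm
    sigma = _fwhm_to_sigma_px(acq.psf_fwhm_nm, pixel_size)
    blurred = ndimage.gaussian_filter(phantom.density_map, sigma=sigma)
    expected = blurred * acq.total_dose + acq.dark_count_rate
    rng = np.random.default_rng(np.random.SeedSequence(acq.rng_seed).spawn(1)[0])
    return rng.poisson(expected).astype(np.float64)


def simulate_pair(phantom: Phantom, acq_high: AcquisitionParams,
                  acq_low: AcquisitionParams) -> tuple[np.ndarray, np.ndarray]:
    """Two acquisitions of the identical phantom with independent noise.

    The frames are pixel-aligned by construction, emulating registered
    high-dose / low-dose training pairs.
    """
    if acq_high.rng_seed == acq_low.rng_seed:
        # force independent streams even under a shared seed convention
        acq_low = replace(acq_low, rng_seed=acq_low.rng_seed + 1_000_003)
    high = simulate_acquisition(phantom, acq_high)
    low = simulate_acquisition(phantom, acq_low)
    return high, low


def _perturb(phantom: Phantom, dyn: DynamicsParams,
             rng: np.random.Generator) -> Phantom:
    """Jitter the endpoints of a fraction of edges and nudge sheets."""
    params = phantom.params
    graph, pos, sheets = phantom._graph, dict(phantom._node_pos), list(phantom._sheets)
    rate = dyn.rearrangement_rate
    if rate > 0 and graph.number_of_edges() > 0:
        edges = sorted(graph.edges())
        n_move = int(round(rate * len(edges)))
        if n_move > 0:
            idx = rng.choice(len(edges), size=n_move, replace=False)
            moved_nodes = {n for i in idx for n in edges[i]}
            jitter_px = 2.0
            h, w = params.height_px, params.width_px
            for n in sorted(moved_nodes):
                r, c = pos[n]
                pos[n] = (float(np.clip(r + rng.normal(0, jitter_px), 0, h - 1)),
                          float(np.clip(c + rng.normal(0, jitter_px), 0, w - 1)))
        sheet_shift = rate * 3.0
        sheets = [(cr + rng.normal(0, sheet_shift), cc + rng.normal(0, sheet_shift),
                   a, b, th) for cr, cc, a, b, th in sheets]
    return _render_phantom(params, graph, pos, sheets)


def simulate_timeseries(
    params: PhantomParams, dyn: DynamicsParams, acq: AcquisitionParams
) -> tuple[np.ndarray, list[ClassLabelMap]]:
    """A movie of a remodelling phantom with per-frame truth labels.

    Returns ``(stack, truth_labels)`` where ``stack`` has shape
    ``(n_frames, H, W)``.  With ``rearrangement_rate=0`` the underlying
    structure is static (all truth maps identical); higher rates reduce
    adjacent-frame structural overlap.
    """
    seq = np.random.SeedSequence(dyn.rng_seed)
    dyn_rng = np.random.default_rng(seq.spawn(1)[0])
    acq_seeds = np.random.SeedSequence(acq.rng_seed).generate_state(dyn.n_frames) % (2**31)
    phantom = generate_phantom(params)
    frames, truths = [], []
    for t in range(dyn.n_frames):
        if t > 0 and dyn.rearrangement_rate > 0:
            phantom = _perturb(phantom, dyn, dyn_rng)
        frame_acq = replace(acq, rng_seed=int(acq_seeds[t]))
        frames.append(simulate_acquisition(phantom, frame_acq))
        truths.append(phantom.label_map)
    return np.stack(frames), truths


def simulate_dark_movie(shape: tuple[int, int], n_frames: int,
                        dark_count_rate: float, rng_seed: int) -> np.ndarray:
    """Structure-free detector dark-noise movie: i.i.d. Poisson counts."""
    if dark_count_rate < 0:
        raise ValueError("dark_count_rate must be nonnegative")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed).spawn(1)[0])
    return rng.poisson(dark_count_rate, size=(n_frames,) + tuple(shape)).astype(np.float64)


def simulate_prediction(phantom: Phantom, psf_fwhm_nm: float = 90.0,
                        read_noise_sd: float = 0.01, rng_seed: int = 0) -> np.ndarray:
    """Emulate a denoised network output for a phantom.

    Denoising networks emit images on a normalized scale that must be
    rescaled before metric computation; this emulation reproduces that
    property: the blurred noiseless rendering plus low-variance Gaussian
    read noise, min-max normalized to [0, 1].
    """
    pixel_size = phantom.label_map.pixel_size_nm
    sigma = _fwhm_to_sigma_px(psf_fwhm_nm, pixel_size)
    blurred = ndimage.gaussian_filter(phantom.density_map, sigma=sigma)
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed).spawn(1)[0])
    noisy = blurred + rng.normal(0.0, read_noise_sd, size=blurred.shape)
    lo, hi = noisy.min(), noisy.max()
    if hi == lo:
        return np.zeros_like(noisy)
    return (noisy - lo) / (hi - lo)
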