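"""Synthetic inputs for every stage of the tension-gradient pipeline.

Everything the analysis consumes can be generated here with known ground
truth and seeded randomness: TCSPC photon-arrival histograms of bi-exponential
Flipper-TR-like decays convolved with a Gaussian IRF at 20 MHz repetition,
cell/micropattern geometries carrying linear and edge-localized lifetime
gradients plus a top-bottom plane offset, expanding supported-lipid-bilayer
(SLB) patches with power-law slowdown and a speed-coupled gradient, line-scan
kymographs of diffusing/flowing membrane fluorophores, FRAP recovery traces,
and MALDI-MSI-like channel stacks.

The synthetic decays use a fixed component pair ``tau_pair = (tau1, tau2)``:
the target mean lifetime of a pixel is realized by varying the intensity
fraction ``alpha1 = (tau2 - tau_bar)/(tau2 - tau1)`` of the fast component,
matching the probe's two-state photochemistry with one degree of freedom per
pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.stats import norm
from skimage.morphology import convex_hull_image

from .corrspec import Kymograph
from .flim import DecayHistogram, HistogramStack, IrfCurve

__all__ = [
    "SceneSpec",
    "SceneTruth",
    "TcspcConfig",
    "SlbMovie",
    "MigrationMovie",
    "FrapTraceSim",
    "make_scene",
    "make_irf",
    "target_tau_to_amplitudes",
    "simulate_decay",
    "simulate_tcspc_image",
    "simulate_slb_movie",
    "simulate_linescan",
    "simulate_frap",
    "simulate_line_frap",
    "simulate_migration_movie",
    "simulate_msi_stack",
]

SHAPES = ("keratocyte", "polarized", "cross", "crossbow", "ring", "disc", "slb")

#: default raster size (pixels) per scene shape, at the shape's default pixel size
_DEFAULT_SIZE = {
    "keratocyte": (224, 224),
    "polarized": (672, 672),
    "cross": (224, 224),
    "crossbow": (224, 224),
    "ring": (224, 224),
    "disc": (224, 224),
    "slb": (224, 224),
}


@dataclass
class TcspcConfig:
    """Timing configuration of the photon-counting simulation and analysis.

    ``rep_rate`` (MHz) fixes the excitation window to ``1000/rep_rate`` ns
    (50 ns at the default 20 MHz); photons arriving after the window fold back
    into it (periodic excitation).  The IRF is a Gaussian of width
    ``irf_sigma`` centered at ``irf_center``.
    """

    rep_rate: float = 20.0
    n_bins: int = 256
    irf_center: float = 2.0
    irf_sigma: float = 0.2
    tau_pair: tuple[float, float] = (1.5, 6.0)

    def __post_init__(self) -> None:
        t1, t2 = self.tau_pair
        if not (0 < t1 <= t2 < self.window):
            raise ValueError("need 0 < tau1 <= tau2 < window")
        if self.irf_sigma < 0:
            raise ValueError("irf_sigma must be >= 0")
        if self.rep_rate <= 0 or self.n_bins <= 0:
            raise ValueError("rep_rate and n_bins must be positive")

    @property
    def window(self) -> float:
        return 1000.0 / self.rep_rate

    @property
    def bin_width(self) -> float:
        return self.window / self.n_bins


@dataclass
class SceneSpec:
    """Parameters of a synthetic scene (geometry + lifetime field + counts)."""

    shape: str = "polarized"
    image_size: Optional[tuple[int, int]] = None
    pixel_size: float = 0.25
    baseline_tau: float = 4.5
    linear_slope: float = 0.0
    edge_amplitude: float = 0.0
    edge_decay_length: float = 2.0
    edge_decay_form: str = "exponential"
    plane_offset: float = 0.0
    mean_photons: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; choose from {SHAPES}")
        if self.edge_decay_form not in ("linear", "exponential"):
            raise ValueError("edge_decay_form must be 'linear' or 'exponential'")
        if self.baseline_tau <= 0:
            raise ValueError("baseline_tau must be > 0")
        if self.mean_photons <= 0:
            raise ValueError("mean_photons must be > 0")
        if self.edge_decay_length <= 0:
            raise ValueError("edge_decay_length must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.image_size is None:
            self.image_size = _DEFAULT_SIZE[self.shape]


@dataclass
class SceneTruth:
    """Ground truth for one scene: masks, true lifetime field, and its spec."""

    cell_mask: np.ndarray
    pattern_mask: Optional[np.ndarray]
    true_tau: np.ndarray
    spec: SceneSpec


@dataclass
class SlbMovie:
    """Expanding-SLB ground truth: masks, speed-coupled lifetime movie.

    ``speeds[i]`` is the area-based spreading speed over frames ``i -> i+1``
    (the observable Delta A / (dt * crop_width)); ``slopes[i]`` the gradient
    slope (ns/um) written into lifetime frame ``i``.
    """

    masks: np.ndarray
    tau: np.ndarray
    speeds: np.ndarray
    slopes: np.ndarray
    dt: float
    pixel_size: float
    crop_width: float
    baseline_tau: float
    gradient_window: float


@dataclass
class MigrationMovie:
    """Translating cell with a protrusion-side edge lifetime amplitude."""

    masks: np.ndarray
    tau: np.ndarray
    dt: float
    pixel_size: float
    edge_amplitude: float
    baseline_tau: float


@dataclass
class FrapTraceSim:
    """Raw FRAP trace plus the companion background/reference traces."""

    times: np.ndarray
    trace: np.ndarray
    background: np.ndarray
    reference: np.ndarray
    bleach_index: int
    truth: dict


# --------------------------------------------------------------------------- #
# geometry
# --------------------------------------------------------------------------- #


def _grids_um(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    h, w = spec.image_size
    y = (np.arange(h) - (h - 1) / 2.0) * spec.pixel_size
    x = (np.arange(w) - (w - 1) / 2.0) * spec.pixel_size
    return np.meshgrid(x, y)  # xx, yy in um, origin at the image center


def _shape_masks(spec: SceneSpec) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Rasterize the cell mask and, for micropatterns, the pattern mask.

    Geometries are simple parametric stand-ins for the shapes the pipeline
    meets in practice: a half-annulus crescent (fish-keratocyte-like), a large
    ellipse with a frontal lobe (well-spread polarized fibroblast, sized after
    Cos7-scale cells, ~150 um tip to tail), and cross/crossbow/ring/disc
    micropatterns with the cell spread over the pattern's convex hull.
    """
    xx, yy = _grids_um(spec)
    r = np.hypot(xx, yy)
    pattern = None
    if spec.shape == "keratocyte":
        cell = (r <= 20.0) & (r >= 10.0) & (xx >= 0)
    elif spec.shape == "polarized":
        cell = (xx / 70.0) ** 2 + (yy / 35.0) ** 2 <= 1.0
        cell |= (xx - 60.0) ** 2 + yy**2 <= 18.0**2
    elif spec.shape == "cross":
        pattern = (np.abs(xx) <= 20.0) & (np.abs(yy) <= 5.0)
        pattern |= (np.abs(yy) <= 20.0) & (np.abs(xx) <= 5.0)
        cell = convex_hull_image(pattern)
    elif spec.shape == "crossbow":
        pattern = (r >= 16.0) & (r <= 21.0) & (yy >= 0)
        pattern |= (np.abs(xx) <= 2.5) & (yy <= 0) & (yy >= -21.0)
        cell = convex_hull_image(pattern)
    elif spec.shape == "ring":
        pattern = (r >= 14.0) & (r <= 19.0)
        cell = convex_hull_image(pattern)
    elif spec.shape == "disc":
        pattern = r <= 18.0
        cell = pattern.copy()
    elif spec.shape == "slb":
        cell = r <= 40.0
    else:  # pragma: no cover - guarded by SceneSpec
        raise ValueError(spec.shape)
    return cell.astype(bool), None if pattern is None else pattern.astype(bool)


def _edge_distance_um(mask: np.ndarray, pixel_size: float) -> np.ndarray:
    """Unsigned inward distance (um) to the nearest cell-boundary pixel."""
    boundary = mask & ~ndimage.binary_erosion(mask, border_value=0)
    d = ndimage.distance_transform_edt(~boundary) * pixel_size
    return np.where(mask, d, np.nan)


def make_scene(spec: SceneSpec) -> SceneTruth:
    """Build a scene's masks and noiseless per-pixel mean-lifetime field.

    Inside the cell mask::

        true_tau = baseline + linear_slope * x + edge_term(d_edge) + plane_offset

    with ``x`` the polarity-axis coordinate (um, relative to the cell
    centroid, front toward +x), ``d_edge`` the inward distance to the cell
    edge, and the edge term either ``amp * exp(-d/L)`` or
    ``amp * max(0, 1 - d/L)``.  Deterministic given the spec.
    """
    cell, pattern = _shape_masks(spec)
    xx, _ = _grids_um(spec)
    x0 = xx[cell].mean()
    d = _edge_distance_um(cell, spec.pixel_size)
    if spec.edge_decay_form == "exponential":
        edge = spec.edge_amplitude * np.exp(-d / spec.edge_decay_length)
    else:
        edge = spec.edge_amplitude * np.clip(1.0 - d / spec.edge_decay_length, 0.0, None)
    tau = spec.baseline_tau + spec.linear_slope * (xx - x0) + edge + spec.plane_offset
    tau = np.where(cell, tau, np.nan)
    if np.any(tau[cell] <= 0):
        raise ValueError("scene parameters produce non-positive lifetimes")
    return SceneTruth(cell_mask=cell, pattern_mask=pattern, true_tau=tau, spec=spec)


# --------------------------------------------------------------------------- #
# TCSPC photon simulation
# --------------------------------------------------------------------------- #


def target_tau_to_amplitudes(tau_bar: float | np.ndarray, cfg: TcspcConfig) -> float | np.ndarray:
    """Intensity fraction alpha1 on tau1 that realizes a target mean lifetime.

    From ``tau_bar = alpha1*tau1 + alpha2*tau2`` with ``alpha1 + alpha2 = 1``:
    ``alpha1 = (tau2 - tau_bar)/(tau2 - tau1)``.  The amplitude ratio follows
    as ``A1/A2 = (alpha1/tau1)/(alpha2/tau2)``.
    """
    t1, t2 = cfg.tau_pair
    tb = np.asarray(tau_bar, dtype=float)
    if np.any(tb < t1 - 1e-12) or np.any(tb > t2 + 1e-12):
        raise ValueError(f"tau_bar must lie within [{t1}, {t2}] ns")
    if t2 == t1:
        a1 = np.ones_like(tb)
    else:
        a1 = np.clip((t2 - tb) / (t2 - t1), 0.0, 1.0)
    return float(a1) if np.isscalar(tau_bar) else a1


def make_irf(cfg: TcspcConfig) -> IrfCurve:
    """Expected (noiseless) IRF histogram on the configured bin grid.

    A Gaussian of width ``irf_sigma`` centered at ``irf_center`` integrated
    over each bin, wrapped into the excitation window; ``irf_sigma = 0``
    collapses to a delta in the containing bin.
    """
    w = cfg.window
    edges = np.arange(cfg.n_bins + 1) * cfg.bin_width
    if cfg.irf_sigma == 0:
        counts = np.zeros(cfg.n_bins)
        counts[min(int((cfg.irf_center % w) / cfg.bin_width), cfg.n_bins - 1)] = 1.0
    else:
        counts = np.zeros(cfg.n_bins)
        for wrap in (-2, -1, 0, 1, 2):
            z = (edges + wrap * w - cfg.irf_center) / cfg.irf_sigma
            counts += np.diff(norm.cdf(z))
    return IrfCurve(counts=counts, bin_width=cfg.bin_width)


def _draw_arrival_times(tau_bar: np.ndarray, cfg: TcspcConfig, rng: np.random.Generator) -> np.ndarray:
    """Arrival times (ns, folded into the window) for one photon per entry."""
    t1, t2 = cfg.tau_pair
    n = tau_bar.size
    if t2 > t1:
        a1 = (t2 - tau_bar) / (t2 - t1)
        scale = np.where(rng.random(n) < a1, np.float32(t1), np.float32(t2))
    else:
        scale = np.full(n, t1, dtype=np.float32)
    t = rng.standard_exponential(n, dtype=np.float32) * scale
    if cfg.irf_sigma > 0:
        t += rng.standard_normal(n, dtype=np.float32) * np.float32(cfg.irf_sigma)
    t += np.float32(cfg.irf_center)
    return np.mod(t, np.float32(cfg.window))


def simulate_decay(
    tau_bar: float, n_photons: int, cfg: TcspcConfig, seed: int | np.random.Generator = 0
) -> DecayHistogram:
    """Single decay histogram with exactly ``n_photons`` photons."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    target_tau_to_amplitudes(tau_bar, cfg)  # validate range
    t = _draw_arrival_times(np.full(n_photons, float(tau_bar)), cfg, rng)
    bins = np.minimum((t / cfg.bin_width).astype(np.int64), cfg.n_bins - 1)
    counts = np.bincount(bins, minlength=cfg.n_bins)
    return DecayHistogram(counts=counts, bin_width=cfg.bin_width)


def simulate_tcspc_image(
    truth: SceneTruth,
    cfg: TcspcConfig,
    seed: int,
    mean_photons: Optional[float] = None,
    chunk_rows: int = 64,
) -> HistogramStack:
    """Per-pixel TCSPC histograms for a scene.

    Photon counts are Poisson(``mean_photons``) inside the cell mask and zero
    outside; each photon's arrival time is drawn from the bi-exponential
    realizing the pixel's true mean lifetime, IRF-jittered, folded into the
    window and binned.  Bit-identical under the same seed.
    """
    t1, t2 = cfg.tau_pair
    tau = truth.true_tau
    mask = truth.cell_mask
    vals = tau[mask]
    if np.any(vals < t1) or np.any(vals > t2):
        raise ValueError("true_tau must lie within cfg.tau_pair inside the cell mask")
    mp = truth.spec.mean_photons if mean_photons is None else mean_photons
    rng = np.random.default_rng(seed)
    h, w = mask.shape
    nb = cfg.n_bins

    flat_idx = np.flatnonzero(mask.ravel())
    n_per_pix = rng.poisson(mp, flat_idx.size)
    pix_id = np.repeat(flat_idx, n_per_pix)  # ascending
    tau_ph = np.repeat(tau.ravel()[flat_idx], n_per_pix)
    t = _draw_arrival_times(tau_ph, cfg, rng)
    bins = np.minimum((t / cfg.bin_width).astype(np.int64), nb - 1)

    counts = np.zeros((h * w, nb), dtype=np.uint16)
    for r0 in range(0, h, chunk_rows):
        lo, hi = r0 * w, min(r0 + chunk_rows, h) * w
        s, e = np.searchsorted(pix_id, [lo, hi])
        if s == e:
            continue
        blk = np.bincount((pix_id[s:e] - lo) * nb + bins[s:e], minlength=(hi - lo) * nb)
        counts[lo:hi] = blk.reshape(hi - lo, nb)
    return HistogramStack(
        counts=counts.reshape(h, w, nb),
        bin_width=cfg.bin_width,
        pixel_size=truth.spec.pixel_size,
    )


# --------------------------------------------------------------------------- #
# SLB expansion
# --------------------------------------------------------------------------- #


def simulate_slb_movie(
    r0: float = 60.0,
    beta: float = 0.7,
    slope_coupling: float = 0.0015,
    frames: int = 12,
    dt: float = 0.5,
    v0: float = 10.0,
    t0: float = 1.0,
    field_size_um: tuple[float, float] = (100.0, 240.0),
    pixel_size: float = 0.5,
    baseline_tau: float = 4.0,
    gradient_window: float = 100.0,
    sign: float = 1.0,
    tilt: float = 0.1,
    seed: int = 0,
) -> SlbMovie:
    """Expanding SLB front with power-law slowdown and a speed-coupled gradient.

    The field of view is a rectangular crop of a large spreading patch, so the
    advancing front appears as a near-straight line (slightly tilted by
    ``tilt`` so rasterization phases average out across rows).  The front
    advances with speed ``v(t) = v0 (1 + t/t0)^(-beta)`` (position by its
    integral).  Each lifetime frame carries a linear gradient versus distance
    from the front, ``tau = baseline + sign * s_i * min(d, window)``, with
    ``s_i = slope_coupling * speeds[i]`` where ``speeds[i]`` is the area-based
    spreading speed measured from the rasterized masks themselves (the same
    observable the analysis reports), so the constructed coupling is exact
    frame by frame.  With ``slope_coupling = 0`` the field is flat, and as the
    spreading stalls the slope relaxes to zero.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    if frames < 2:
        raise ValueError("need at least 2 frames")
    hu, wu = field_size_um
    h, w = int(round(hu / pixel_size)), int(round(wu / pixel_size))
    yy, xx = np.meshgrid(
        (np.arange(h) + 0.5) * pixel_size, (np.arange(w) + 0.5) * pixel_size, indexing="ij"
    )
    cy = hu / 2.0

    times = np.arange(frames) * dt
    if abs(beta - 1.0) < 1e-9:
        fronts = r0 + v0 * t0 * np.log1p(times / t0)
    else:
        fronts = r0 + v0 * t0 / (1.0 - beta) * ((1.0 + times / t0) ** (1.0 - beta) - 1.0)
    if fronts[-1] + abs(tilt) * hu / 2 >= wu:
        raise ValueError("front leaves the field; enlarge field_size_um or reduce v0/frames")
    edge = xx - tilt * (yy - cy)  # front coordinate along the advance direction
    masks = edge[None] <= fronts[:, None, None]

    areas = masks.sum(axis=(1, 2)) * pixel_size**2
    speeds = np.diff(areas) / (dt * hu)
    slopes = slope_coupling * speeds
    norm = math.sqrt(1.0 + tilt**2)
    tau = np.empty((frames - 1, h, w))
    for i in range(frames - 1):
        d_front = np.clip((fronts[i] - edge) / norm, 0.0, gradient_window)
        tau[i] = np.where(masks[i], baseline_tau + sign * slopes[i] * d_front, np.nan)
    return SlbMovie(
        masks=masks,
        tau=tau,
        speeds=speeds,
        slopes=slopes,
        dt=dt,
        pixel_size=pixel_size,
        crop_width=hu,
        baseline_tau=baseline_tau,
        gradient_window=gradient_window,
    )


# --------------------------------------------------------------------------- #
# line-scan fluctuation data
# --------------------------------------------------------------------------- #


def simulate_linescan(
    n_pixels: int = 64,
    pixel_size: float = 0.16,
    line_time: float = 960e-6,
    n_lines: int = 50_000,
    D: float = 2.0,
    n_particles: int = 150,
    brightness: float = 5.0,
    drift_v: float = 0.0,
    psf_waist: float = 0.25,
    background: float = 0.05,
    domain_factor: float = 3.0,
    transverse_height: float = 3.0,
    seed: int = 0,
    return_positions: bool = False,
):
    """Line-scan kymograph of fluorophores diffusing (and optionally flowing).

    Particles perform 2D Brownian steps of per-coordinate variance
    ``2 D line_time`` per line plus a drift ``drift_v * line_time`` along the
    scan axis, on a periodic domain ``domain_factor`` times the scanned line
    (and ``transverse_height`` um across it).  Pixel intensities are Poisson
    counts of a Gaussian-PSF detection profile (1/e^2 waist ``psf_waist``)
    plus a flat background.

    Returns a :class:`~tensiongrad.corrspec.Kymograph`; with
    ``return_positions=True`` also the (n_lines, n_particles) scan-axis
    positions for trajectory-level oracles.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if min(pixel_size, line_time, psf_waist) <= 0 or D < 0:
        raise ValueError("rates and geometry must be positive")
    rng = np.random.default_rng(seed)
    line_len = n_pixels * pixel_size
    lx = domain_factor * line_len
    ly = transverse_height
    x_lo = -(lx - line_len) / 2.0  # scanned window sits at [0, line_len)

    step_sd = math.sqrt(2.0 * D * line_time)
    x0 = rng.uniform(x_lo, x_lo + lx, n_particles).astype(np.float32)
    y0 = rng.uniform(-ly / 2, ly / 2, n_particles).astype(np.float32)
    shape = (n_lines, n_particles)
    dx = rng.standard_normal(shape, dtype=np.float32) * np.float32(step_sd)
    dy = rng.standard_normal(shape, dtype=np.float32) * np.float32(step_sd)
    dx += np.float32(drift_v * line_time)
    dx[0] = 0.0
    dy[0] = 0.0
    x = np.mod(x0 + np.cumsum(dx, axis=0) - np.float32(x_lo), np.float32(lx)) + np.float32(x_lo)
    y = np.mod(y0 + np.cumsum(dy, axis=0) + np.float32(ly / 2), np.float32(ly)) - np.float32(ly / 2)

    reach = max(2, int(np.ceil(2.0 * psf_waist / pixel_size)))
    base_all = np.floor(x / np.float32(pixel_size)).astype(np.int32)
    line_idx = np.broadcast_to(np.arange(n_lines, dtype=np.int64)[:, None], shape)
    near = (base_all >= -reach) & (base_all < n_pixels + reach)
    xs = x[near]
    li = line_idx[near]
    bs = base_all[near].astype(np.int64)
    yw = np.float32(brightness) * np.exp(np.float32(-2.0 / psf_waist**2) * y[near] ** 2)
    mean = np.zeros(n_lines * n_pixels)
    inv_w2 = np.float32(-2.0 / psf_waist**2)
    for k in range(-reach, reach + 1):
        pix = bs + k
        m = (pix >= 0) & (pix < n_pixels)
        if not m.any():
            continue
        xc = (pix[m].astype(np.float32) + np.float32(0.5)) * np.float32(pixel_size)
        wgt = yw[m] * np.exp(inv_w2 * (xc - xs[m]) ** 2)
        mean += np.bincount(li[m] * n_pixels + pix[m], weights=wgt, minlength=mean.size)
    intensity = rng.poisson(mean.reshape(n_lines, n_pixels) + background).astype(np.float64)
    kymo = Kymograph(
        intensity=intensity, pixel_size=pixel_size, line_time=line_time, dwell=5.2e-6
    )
    if return_positions:
        return kymo, x
    return kymo


# --------------------------------------------------------------------------- #
# FRAP
# --------------------------------------------------------------------------- #


def simulate_frap(
    mobile: float,
    k: float,
    bleach_depth: float = 0.7,
    noise_sd: float = 0.0,
    n_pre: int = 25,
    n_post: int = 200,
    dt: float = 0.2,
    background_level: float = 50.0,
    signal_level: float = 1000.0,
    acq_bleach_rate: float = 0.0,
    seed: int = 0,
) -> FrapTraceSim:
    """Raw FRAP intensity trace with companion background and reference traces.

    The underlying normalized recovery is a pre-bleach plateau at 1 followed by
    ``f(t) = (1 - bleach_depth) + bleach_depth * mobile * (1 - exp(-k t))``.
    The raw trace adds a constant background, a signal scale, optional slow
    acquisition photobleaching (shared with the reference trace), and Gaussian
    noise of SD ``noise_sd`` (in normalized units).
    """
    if not 0.0 <= mobile <= 1.0:
        raise ValueError("mobile fraction must be in [0, 1]")
    if k <= 0:
        raise ValueError("recovery rate k must be > 0")
    rng = np.random.default_rng(seed)
    times = (np.arange(n_pre + n_post) - n_pre) * dt
    f = np.ones_like(times)
    post = times >= 0
    f[post] = (1.0 - bleach_depth) + bleach_depth * mobile * (1.0 - np.exp(-k * times[post]))
    decay = np.exp(-acq_bleach_rate * (times - times[0]))
    noisy = f + rng.normal(0.0, noise_sd, f.size) if noise_sd > 0 else f
    trace = background_level + signal_level * noisy * decay
    reference = background_level + signal_level * decay
    background = np.full_like(times, background_level)
    return FrapTraceSim(
        times=times,
        trace=trace,
        background=background,
        reference=reference,
        bleach_index=n_pre,
        truth={"mobile": mobile, "k": k, "t_half": math.log(2) / k, "bleach_depth": bleach_depth},
    )


def simulate_line_frap(
    drift_v: float = 0.3,
    D: float = 0.0,
    n_frames: int = 12,
    frame_dt: float = 0.5,
    pixel_size: float = 0.11,
    image_shape: tuple[int, int] = (100, 220),
    dip_depth: float = 0.8,
    dip_sigma: float = 0.5,
    counts: float = 400.0,
    recovery_k: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Movie of a bleached-line recovery whose intensity dip drifts and spreads.

    Frame ``i`` is a uniform field carrying a Gaussian dip across the line
    direction, centered at ``x0 + drift_v * t_i`` with variance
    ``dip_sigma^2 + 2 D t_i``, optionally refilling with rate ``recovery_k``,
    plus Poisson noise.  Returns (frames, truth dict).
    """
    rng = np.random.default_rng(seed)
    ny, nx = image_shape
    x = (np.arange(nx) + 0.5) * pixel_size
    x0 = nx * pixel_size / 2.0
    frames = np.empty((n_frames, ny, nx))
    for i in range(n_frames):
        t = i * frame_dt
        var = dip_sigma**2 + 2.0 * D * t
        depth = dip_depth * np.exp(-recovery_k * t) * dip_sigma / math.sqrt(var)
        profile = 1.0 - depth * np.exp(-((x - x0 - drift_v * t) ** 2) / (2.0 * var))
        frames[i] = rng.poisson(counts * profile[None, :].repeat(ny, axis=0))
    return frames, {"drift_v": drift_v, "x0": x0, "pixel_size": pixel_size, "frame_dt": frame_dt}


# --------------------------------------------------------------------------- #
# migration movies
# --------------------------------------------------------------------------- #


def simulate_migration_movie(
    frames: int = 2,
    dt: float = 2.0,
    speed: float = 0.6,
    radius: float = 14.0,
    image_size: tuple[int, int] = (192, 224),
    pixel_size: float = 0.25,
    baseline_tau: float = 4.4,
    edge_amplitude: float = 0.15,
    edge_decay_length: float = 3.0,
) -> MigrationMovie:
    """Disc-shaped cell translating along +x with a front-weighted edge term.

    The true lifetime field of each frame is ``baseline + amp *
    exp(-d_edge/L) * max(0, cos(bearing))``: the advancing (protruding) edge
    carries the amplitude, the retracting rear does not.  Deterministic; pair
    with :func:`simulate_tcspc_image` for photon noise.
    """
    h, w = image_size
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    xx = (xx - w / 2.0) * pixel_size
    yy = (yy - h / 2.0) * pixel_size
    masks = np.empty((frames, h, w), dtype=bool)
    tau = np.empty((frames, h, w))
    x_start = -speed * dt * (frames - 1) / 2.0
    for i in range(frames):
        cx = x_start + speed * dt * i
        masks[i] = np.hypot(xx - cx, yy) <= radius
        d = _edge_distance_um(masks[i], pixel_size)
        bearing = np.arctan2(yy, xx - cx)
        front_w = np.clip(np.cos(bearing), 0.0, None)
        tau[i] = np.where(
            masks[i],
            baseline_tau + edge_amplitude * np.exp(-d / edge_decay_length) * front_w,
            np.nan,
        )
    return MigrationMovie(
        masks=masks,
        tau=tau,
        dt=dt,
        pixel_size=pixel_size,
        edge_amplitude=edge_amplitude,
        baseline_tau=baseline_tau,
    )


# --------------------------------------------------------------------------- #
# MALDI-MSI style stacks
# --------------------------------------------------------------------------- #


def simulate_msi_stack(
    species_maps: dict[str, np.ndarray],
    peaks_per_species: int = 2,
    n_unknown: int = 5,
    total_counts: float = 200.0,
    seed: int = 0,
):
    """Channel stack + peak table emulating a processed MSI export.

    ``species_maps`` gives each species' relative abundance raster (>= 0).
    Each species is spread over ``peaks_per_species`` channels with random
    splits; ``n_unknown`` unassigned channels of background intensity are
    interleaved.  Returns ``(stack, table)`` where ``table`` is a pandas
    DataFrame with columns channel/mz/species, suitable for
    :func:`tensiongrad.msi.lipid_fractions`.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    names = list(species_maps)
    shape = next(iter(species_maps.values())).shape
    channels, rows = [], []
    mz = 400.0
    for name in names:
        split = rng.dirichlet(np.ones(peaks_per_species))
        for frac in split:
            channels.append(total_counts * frac * np.asarray(species_maps[name], dtype=float))
            rows.append({"channel": len(channels) - 1, "mz": round(mz, 3), "species": name})
            mz += rng.uniform(5, 40)
    for _ in range(n_unknown):
        channels.append(rng.uniform(0, total_counts / 10, shape))
        rows.append({"channel": len(channels) - 1, "mz": round(mz, 3), "species": "unknown"})
        mz += rng.uniform(5, 40)
    stack = rng.poisson(np.clip(np.stack(channels), 0, None)).astype(float)
    return stack, pd.DataFrame(rows)
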