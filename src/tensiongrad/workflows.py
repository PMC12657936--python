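"""End-to-end experiment compositions used for validation and reporting.

Each function runs one self-contained in-silico experiment — generate
synthetic data with known ground truth, push it through the full estimation
chain, and return measured-vs-true quantities.  They are the single source of
truth for the package's recovery checks and for the reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from . import corrspec as cs
from . import dynamics, flim, spatial
from . import synthgen as sg

__all__ = [
    "estimator_agreement",
    "recover_polarized_gradient",
    "plane_offset_recovery",
    "slb_coupling_experiment",
    "ffs_diffusion_experiment",
    "ffs_transport_experiment",
    "ffs_zero_flow_experiment",
    "frap_experiment",
    "line_frap_experiment",
]


def estimator_agreement(seed: int, n_pixels: int = 100, photons: int = 10_000,
                        tau_range: tuple[float, float] = (4.3, 5.0)) -> np.ndarray:
    """Relative |barycenter - biexponential tau_bar| per simulated pixel."""
    cfg = sg.TcspcConfig()
    irf = sg.make_irf(cfg)
    rng = np.random.default_rng(seed)
    rel = []
    for _ in range(n_pixels):
        tb = rng.uniform(*tau_range)
        h = sg.simulate_decay(tb, photons, cfg, seed=rng)
        b = flim.barycenter_lifetime(h, irf)
        f = flim.fit_biexponential(h, irf)
        rel.append(abs(b - f.tau_bar) / f.tau_bar)
    return np.asarray(rel)


def _polarity_wedge(mask: np.ndarray, half_angle: float = 30.0) -> np.ndarray:
    rr, cc = np.nonzero(mask)
    cy, cx = rr.mean(), cc.mean()
    yy, xx = np.mgrid[: mask.shape[0], : mask.shape[1]]
    bearing = np.degrees(np.arctan2(yy - cy, xx - cx))
    return mask & (np.abs((bearing + 180.0) % 360.0 - 180.0) <= half_angle)


def recover_polarized_gradient(
    seed: int,
    linear_slope: float = 0.02,
    edge_amplitude: float = 0.3,
    edge_decay_length: float = 2.0,
    mean_photons: float = 30.0,
    baseline_tau: float = 4.1,
    slope_range: tuple[float, float] = (8.0, 30.0),
) -> dict:
    """Full gradient pipeline on one polarized-cell scene.

    The chain is: simulate TCSPC photons -> barycenter lifetime image -> mask
    below 20 photons -> (for the profile) 3-px median filter -> front-wedge
    distance profile -> weighted slope fit; and in parallel 60 deg / 10 um
    front and rear sectors -> photon-weighted means (on the masked, unfiltered
    image, as ROI averages are computed on raw lifetimes).  Truth values come
    from the identical geometry applied to the noiseless lifetime field.
    """
    spec = sg.SceneSpec(shape="polarized", baseline_tau=baseline_tau,
                        linear_slope=linear_slope, edge_amplitude=edge_amplitude,
                        edge_decay_length=edge_decay_length,
                        mean_photons=mean_photons, seed=seed)
    truth = sg.make_scene(spec)
    cfg = sg.TcspcConfig()
    stack = sg.simulate_tcspc_image(truth, cfg, seed=seed)
    img = flim.mask_low_counts(flim.lifetime_image(stack, sg.make_irf(cfg)), 20)
    img_med = flim.median_filter_tau(img, 3)

    dist = spatial.inward_distance(truth.cell_mask, spec.pixel_size)
    wedge = _polarity_wedge(truth.cell_mask)
    prof = spatial.decay_profile(img_med, dist, 1.0, domain=wedge)
    slope_est = spatial.fit_slope(prof, slope_range).slope

    true_img = flim.LifetimeImage(tau=truth.true_tau,
                                  photons=np.asarray(truth.cell_mask, int),
                                  pixel_size=spec.pixel_size)
    prof_true = spatial.decay_profile(true_img, dist, 1.0, domain=wedge, weighted=False)
    slope_true = spatial.fit_slope(prof_true, slope_range).slope

    regions = spatial.front_rear_angular(truth.cell_mask, spec.pixel_size,
                                         polarity_angle=0.0, half_angle=30.0, dmax=10.0)
    delta_est = (flim.weighted_mean(img, regions["front"])
                 - flim.weighted_mean(img, regions["rear"]))
    delta_true = (np.nanmean(truth.true_tau[regions["front"]])
                  - np.nanmean(truth.true_tau[regions["rear"]]))
    front_est = flim.weighted_mean(img, regions["front"])
    rear_est = flim.weighted_mean(img, regions["rear"])
    return {
        "slope_est": slope_est, "slope_true": slope_true,
        "delta_est": delta_est, "delta_true": delta_true,
        "front_est": front_est, "rear_est": rear_est,
    }


def plane_offset_recovery(seed: int, offset: float = 0.26) -> dict:
    """Top-vs-bottom lifetime difference recovered from two simulated planes."""
    cfg = sg.TcspcConfig()
    irf = sg.make_irf(cfg)
    out = {}
    for plane, off in (("bottom", 0.0), ("top", offset)):
        spec = sg.SceneSpec(shape="ring", baseline_tau=4.6, plane_offset=off,
                            seed=seed)
        truth = sg.make_scene(spec)
        stack = sg.simulate_tcspc_image(truth, cfg, seed=seed + (0 if off == 0 else 1))
        img = flim.mask_low_counts(flim.lifetime_image(stack, irf), 20)
        out[plane] = flim.weighted_mean(img, truth.cell_mask)
    out["delta"] = out["top"] - out["bottom"]
    out["delta_true"] = offset
    return out


def slb_coupling_experiment(seed: int, slope_coupling: float = 0.0015,
                            frames: int = 12) -> dict:
    """Expanding-SLB movie: measured speed/slope pairs vs the constructed coupling."""
    movie = sg.simulate_slb_movie(slope_coupling=slope_coupling, frames=frames, seed=seed)
    cfg = sg.TcspcConfig()
    irf = sg.make_irf(cfg)
    mm = dynamics.MaskMovie(movie.masks, dt=movie.dt, pixel_size=movie.pixel_size)
    imgs = []
    for i in range(frames - 1):
        truth = sg.SceneTruth(
            cell_mask=movie.masks[i], pattern_mask=None, true_tau=movie.tau[i],
            spec=sg.SceneSpec(shape="slb", image_size=movie.tau[i].shape,
                              pixel_size=movie.pixel_size, baseline_tau=movie.baseline_tau))
        stack = sg.simulate_tcspc_image(truth, cfg, seed=seed * 1000 + i, mean_photons=30)
        imgs.append(flim.mask_low_counts(flim.lifetime_image(stack, irf), 20))
    pairs = dynamics.speed_slope_curve(mm, imgs, crop_width=movie.crop_width)
    speeds = np.array([p[0] for p in pairs])
    slopes_est = np.array([p[1].slope for p in pairs])
    stderr = np.array([p[1].stderr for p in pairs])
    rho = float(spearmanr(speeds, slopes_est).statistic)
    return {"speeds": speeds, "slopes_est": slopes_est, "stderr": stderr,
            "slopes_true": movie.slopes, "spearman": rho}


def ffs_diffusion_experiment(D: float, seed: int, n_lines: int = 50_000) -> float:
    """Line-scan FCS chain at the standard acquisition geometry; returns D0."""
    kymo = sg.simulate_linescan(D=D, n_lines=n_lines, seed=seed)
    k = cs.detrend(kymo)
    return float(np.median([cs.fit_acf(cs.acf(k, s)).D0 for s in cs.default_sections()]))


def ffs_transport_experiment(seed: int, drift_v: float = 0.8, D: float = 0.02,
                             n_lines: int = 50_000) -> dict:
    """Directed-transport scan: pCF arrival time and flow decision."""
    kymo = sg.simulate_linescan(D=D, drift_v=drift_v, n_lines=n_lines, seed=seed)
    k = cs.detrend(kymo)
    a = cs.fit_acf(cs.acf(k))
    fw = cs.fit_pcf(cs.pcf(k, 5, "forward"), a)
    detected, _ = cs.detect_flow(k)
    return {
        "tau_arrival": fw.tau_arrival,
        "tau_expected": 5 * kymo.pixel_size / drift_v,
        "transport_efficiency": fw.transport_efficiency,
        "flow_detected": detected,
    }


def ffs_zero_flow_experiment(seed: int, D: float = 2.0, n_lines: int = 50_000) -> bool:
    """Whether a pure-diffusion scan is (wrongly) flagged as flowing."""
    kymo = sg.simulate_linescan(D=D, n_lines=n_lines, seed=seed)
    detected, _ = cs.detect_flow(cs.detrend(kymo))
    return bool(detected)


def frap_experiment(seed: int, mobile: float = 0.8, k: float = 0.1,
                    noise_sd: float = 0.02, n_traces: int = 10) -> cs.FrapResult:
    """Average ``n_traces`` normalized recoveries, then fit (the standard
    protocol: individual experiments are aligned to bleach time and averaged
    before the single-exponential fit)."""
    norms, times, b = [], None, None
    for i in range(n_traces):
        sim = sg.simulate_frap(mobile=mobile, k=k, noise_sd=noise_sd, seed=seed * 100 + i)
        norms.append(cs.frap_normalize(sim.trace, sim.background, sim.reference,
                                       sim.bleach_index, sim.times))
        times, b = sim.times, sim.bleach_index
    avg = np.mean(norms, axis=0)
    t = times[b:]
    return cs.frap_fit(t - t[0], avg[b:])


def line_frap_experiment(seed: int, drift_v: float = 0.3) -> cs.LineFrapResult:
    """Drifting bleached-line movie through the minima-tracking analysis."""
    frames, truth = sg.simulate_line_frap(drift_v=drift_v, seed=seed)
    return cs.line_frap_flow(frames, truth["pixel_size"], truth["frame_dt"])
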