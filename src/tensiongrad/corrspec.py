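"""Line-scan fluctuation spectroscopy (ACF/pCF) and FRAP kinetics.

A line scan repeatedly sweeps a 64-pixel, ~10 um line across the membrane;
stacking the lines gives a kymograph (space x time).  After detrending away
slow artefacts such as photobleaching:

* the autocorrelation function (ACF, ``delta_r = 0``) of each column decays on
  the timescale a molecule needs to diffuse through the focus; fitting a
  two-component 2D-diffusion model ``G(tau) = G0 * sum_i f_i /
  (1 + tau/tau_Di) + offset`` with ``tau_Di = w^2 / (4 D_i)`` recovers the
  number of moving molecules (``G0 ~ 1/N``) and their diffusion coefficients;
* the pair correlation function (pCF, ``delta_r = 5`` pixels) correlates
  fluctuations at positions ``delta_r`` apart; its peak lag is the arrival
  time of molecules covering that distance, and the forward/reverse asymmetry
  reveals directed transport.  Peaks are fitted with a Gaussian on the
  log10(lag) axis since they span decades.

FRAP traces are normalized to 0 at the bleach and 1 at the pre-bleach plateau
and fitted with ``M (1 - exp(-k t))``; a bleached *line* whose intensity
minimum drifts during recovery reports in-plane flow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import next_fast_len, rfft, irfft
from scipy.ndimage import uniform_filter1d
from scipy.optimize import curve_fit

__all__ = [
    "Kymograph",
    "CorrelationCurve",
    "AcfFit",
    "PcfFit",
    "FrapResult",
    "LineFrapResult",
    "default_sections",
    "detrend",
    "acf",
    "fit_acf",
    "pcf",
    "fit_pcf",
    "detect_flow",
    "frap_normalize",
    "frap_fit",
    "line_frap_flow",
]


@dataclass
class Kymograph:
    """Line-scan intensity raster: rows are scan lines (time), columns pixels."""

    intensity: np.ndarray
    pixel_size: float = 0.16
    line_time: float = 960e-6
    dwell: float = 5.2e-6

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("kymograph must be 2-D (lines x pixels)")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_lines(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.intensity.shape[1]


@dataclass
class CorrelationCurve:
    lags: np.ndarray  # seconds, increasing (quasi-log multi-tau grid)
    G: np.ndarray
    kind: str = "acf"  # acf | pcf_forward | pcf_reverse
    delta_r: int = 0


@dataclass
class AcfFit:
    G0: float
    f1: float
    f2: float
    D1: float  # um^2/s, D1 <= D2
    D2: float
    D0: float  # fraction-weighted mean, the reported diffusion coefficient
    offset: float
    converged: bool = True


@dataclass
class PcfFit:
    tau_arrival: float
    amplitude: float
    transport_efficiency: float
    sigma_log: float
    ok: bool = True


@dataclass
class FrapResult:
    mobile_fraction: float
    t_half: float
    k: float
    residual: float
    ok: bool = True
    message: str = ""


@dataclass
class LineFrapResult:
    times: np.ndarray
    positions: np.ndarray  # um, dip position per frame
    velocity: float  # um/s
    truncated: bool = False


# --------------------------------------------------------------------------- #
# correlation machinery
# --------------------------------------------------------------------------- #


def default_sections(n_pixels: int = 64) -> list[tuple[int, int]]:
    """Three spatially distinct column sections as half-open 0-based ranges.

    The conventional 1-based inclusive pixel ranges 1-21, 22-42 and 43-63
    become (0, 21), (21, 42), (42, 63).
    """
    if n_pixels < 63:
        raise ValueError("sections are defined for >= 63 pixels")
    return [(0, 21), (21, 42), (42, 63)]


def _multitau_lags(n_max: int, per_octave: int = 16) -> np.ndarray:
    lags = []
    lag, step, count = 1, 1, 0
    while lag < n_max:
        lags.append(lag)
        lag += step
        count += 1
        if count % per_octave == 0:
            step *= 2
    return np.asarray(lags, dtype=np.int64)


def _cross_corr(a: np.ndarray, b: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """G(tau) = <dA(t) dB(t+tau)> / (<A><B>) at integer line lags."""
    n = a.size
    ma, mb = a.mean(), b.mean()
    if ma <= 0 or mb <= 0:
        return np.full(lags.size, np.nan)
    da, db = a - ma, b - mb
    nfft = next_fast_len(2 * n)
    c = irfft(np.conj(rfft(da, nfft)) * rfft(db, nfft), nfft)[: lags.max() + 1]
    return c[lags] / (n - lags) / (ma * mb)


def detrend(k: Kymograph, window_lines: int = 10_000) -> Kymograph:
    """Divide out each column's moving-average trend, restoring its mean.

    Removes slow-timescale artefacts (photobleaching, stage drift) while
    leaving fast fluctuations and each column's global mean intact.  The
    window must stay much longer than the diffusion correlation tail: 2D
    diffusion decays only as 1/lag, and a short window folds that tail into a
    spurious anticorrelation dip.
    """
    if window_lines < 100:
        raise ValueError("detrending window must be >= 100 lines")
    data = k.intensity
    trend = uniform_filter1d(data, size=window_lines, axis=0, mode="nearest")
    trend = np.clip(trend, 1e-12, None)
    out = data / trend
    col_mean = data.mean(axis=0)
    out *= col_mean / np.clip(out.mean(axis=0), 1e-12, None)
    return Kymograph(out, k.pixel_size, k.line_time, k.dwell)


def acf(k: Kymograph, columns: tuple[int, int] | None = None, max_lag_fraction: float = 0.25) -> CorrelationCurve:
    """Column-wise autocorrelation averaged over a section of the kymograph.

    ``columns`` is a half-open (start, stop) range; the full width by default.
    Lags follow a multi-tau (quasi-logarithmic) grid starting at one line time.
    """
    lo, hi = (0, k.n_pixels) if columns is None else columns
    if not (0 <= lo < hi <= k.n_pixels):
        raise ValueError("column section outside the kymograph")
    lags = _multitau_lags(int(k.n_lines * max_lag_fraction))
    curves = [_cross_corr(k.intensity[:, c], k.intensity[:, c], lags) for c in range(lo, hi)]
    return CorrelationCurve(lags=lags * k.line_time, G=np.nanmean(curves, axis=0), kind="acf")


def pcf(
    k: Kymograph,
    delta_r: int = 5,
    direction: str = "forward",
    max_lag_fraction: float = 0.25,
) -> CorrelationCurve:
    """Pair correlation between columns ``delta_r`` pixels apart.

    Forward correlates column ``i`` with ``i + delta_r`` (all admissible
    ``i``); reverse correlates ``i`` with ``i - delta_r``.  A molecule flowing
    toward +x produces a forward peak at the transit time
    ``delta_r * pixel_size / v`` and a suppressed reverse curve.
    """
    if not 0 < delta_r < k.n_pixels:
        raise ValueError("delta_r must be within the scanned line")
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    lags = _multitau_lags(int(k.n_lines * max_lag_fraction))
    step = delta_r if direction == "forward" else -delta_r
    cols = range(0, k.n_pixels - delta_r) if direction == "forward" else range(delta_r, k.n_pixels)
    curves = [_cross_corr(k.intensity[:, c], k.intensity[:, c + step], lags) for c in cols]
    return CorrelationCurve(
        lags=lags * k.line_time,
        G=np.nanmean(curves, axis=0),
        kind=f"pcf_{direction}",
        delta_r=delta_r,
    )


# --------------------------------------------------------------------------- #
# model fits
# --------------------------------------------------------------------------- #


def _acf_model(tau, G0, f1, td1, td2, offset):
    return G0 * (f1 / (1.0 + tau / td1) + (1.0 - f1) / (1.0 + tau / td2)) + offset


def fit_acf(curve: CorrelationCurve, psf_waist: float = 0.25) -> AcfFit:
    """Two-component 2D-diffusion fit of an ACF.

    ``tau_Di = waist^2 / (4 D_i)``; the reported ``D0`` is the
    fraction-weighted mean of the two components.  Single-component data
    yields either a vanishing fraction or two equal components.
    """
    good = np.isfinite(curve.G)
    tau, G = curve.lags[good], curve.G[good]
    if tau.size < 10:
        raise ValueError("need >= 10 lag points")
    g0 = max(float(G[0]), 1e-6)
    below = np.nonzero(G < g0 / 2)[0]
    t_half = float(tau[below[0]]) if below.size else float(tau[tau.size // 2])
    p0 = [g0, 0.5, t_half / 3.0, t_half * 3.0, 0.0]
    bounds = ([0.0, 0.0, 1e-7, 1e-7, -np.inf], [np.inf, 1.0, 1e5, 1e5, np.inf])
    try:
        popt, _ = curve_fit(_acf_model, tau, G, p0=p0, bounds=bounds, maxfev=20000)
        ok = True
    except RuntimeError:
        popt, ok = p0, False
    G0, f1, td1, td2, off = popt
    d = psf_waist**2 / (4.0 * np.array([td1, td2]))
    f = np.array([f1, 1.0 - f1])
    order = np.argsort(d)  # report D1 <= D2
    d, f = d[order], f[order]
    return AcfFit(
        G0=float(G0),
        f1=float(f[0]),
        f2=float(f[1]),
        D1=float(d[0]),
        D2=float(d[1]),
        D0=float(f @ d),
        offset=float(off),
        converged=ok,
    )


def _log_gauss(loglag, A, mu, sig):
    return A * np.exp(-((loglag - mu) ** 2) / (2.0 * sig**2))


def fit_pcf(curve: CorrelationCurve, acf_fit: AcfFit | None = None, snr: float = 3.0) -> PcfFit:
    """Gaussian (in log10 lag) fit around the pCF peak.

    Returns the arrival time (peak lag), peak amplitude, and — when the paired
    ACF fit is supplied — the transport efficiency ``G_tau / G0``.  A curve
    with no significant positive peak yields ``ok=False`` (no transport), not
    an exception.
    """
    good = np.isfinite(curve.G) & (curve.lags > 0)
    tau, G = curve.lags[good], curve.G[good]
    if tau.size < 8:
        return PcfFit(float("nan"), float("nan"), float("nan"), float("nan"), ok=False)
    Gs = uniform_filter1d(G, size=3)
    noise = float(np.std(G[-max(4, G.size // 4):]))
    ipk = int(np.argmax(Gs))
    peak = float(Gs[ipk])
    if peak <= 0 or peak < snr * noise:
        return PcfFit(float("nan"), peak, float("nan"), float("nan"), ok=False)
    L = np.log10(tau)
    # fit only near the peak: the diffusive early-arrival shoulder is strongly
    # skewed in log-lag and would otherwise drag the fitted center to early lags
    win = np.abs(L - L[ipk]) <= 0.6
    if win.sum() < 5:
        win = np.abs(L - L[ipk]) <= 1.0
    try:
        popt, _ = curve_fit(
            _log_gauss,
            L[win],
            G[win],
            p0=[peak, L[ipk], 0.3],
            bounds=([0.0, L[0] - 1.0, 0.05], [np.inf, L[-1] + 1.0, 3.0]),
            maxfev=10000,
        )
    except RuntimeError:
        return PcfFit(float("nan"), peak, float("nan"), float("nan"), ok=False)
    A, mu, sig = popt
    eff = A / acf_fit.G0 if acf_fit is not None and acf_fit.G0 > 0 else float("nan")
    return PcfFit(tau_arrival=float(10**mu), amplitude=float(A), transport_efficiency=float(eff), sigma_log=float(sig))


def detect_flow(
    k: Kymograph,
    delta_r: int = 5,
    psf_waist: float = 0.25,
    ratio_threshold: float = 3.0,
) -> tuple[bool, dict]:
    """Directed-transport decision from forward/reverse pCF asymmetry.

    Flow is declared when only one direction shows a significant pCF peak, or
    when the forward/reverse arrival times or amplitudes differ by at least
    ``ratio_threshold`` (fixed a priori).  Pure diffusion is isotropic, so
    both directions give matching curves and no flow is declared.
    """
    a = fit_acf(acf(k), psf_waist=psf_waist)
    cf = pcf(k, delta_r, "forward")
    cr = pcf(k, delta_r, "reverse")
    fw = fit_pcf(cf, a)
    rv = fit_pcf(cr, a)
    info = {"acf": a, "forward": fw, "reverse": rv}
    pk_f = float(uniform_filter1d(cf.G, 3).max())
    pk_r = float(uniform_filter1d(cr.G, 3).max())
    if (pk_f > 0) != (pk_r > 0):
        return True, info
    if pk_f <= 0 and pk_r <= 0:
        return False, info
    amp_ratio = max(pk_f / pk_r, pk_r / pk_f)
    if amp_ratio >= ratio_threshold:
        return True, info
    if fw.ok and rv.ok:
        tau_ratio = max(fw.tau_arrival / rv.tau_arrival, rv.tau_arrival / fw.tau_arrival)
        if tau_ratio >= ratio_threshold:
            return True, info
    return False, info


# --------------------------------------------------------------------------- #
# FRAP
# --------------------------------------------------------------------------- #


def frap_normalize(
    trace: np.ndarray,
    background: np.ndarray | float,
    reference: np.ndarray | float,
    bleach_index: int,
    times: np.ndarray,
    pre_seconds: float = 5.0,
) -> np.ndarray:
    """Background-subtract, bleach-correct and rescale a FRAP trace.

    The corrected signal ``(F - bg)/(ref - bg)`` is mapped to 0 at the first
    post-bleach sample and 1 at the mean of the ``pre_seconds`` of samples
    preceding the bleach.
    """
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    if bleach_index <= 0:
        raise ValueError("bleach cannot be at the trace start")
    if times[bleach_index] - times[0] < pre_seconds:
        raise ValueError(f"need >= {pre_seconds} s of pre-bleach samples")
    bg = np.asarray(background, dtype=float)
    ref = np.asarray(reference, dtype=float)
    corrected = (trace - bg) / np.clip(ref - bg, 1e-12, None)
    pre = (times < times[bleach_index]) & (times >= times[bleach_index] - pre_seconds)
    c_pre = corrected[pre].mean()
    c_bleach = corrected[bleach_index]
    if c_pre == c_bleach:
        raise ValueError("no bleach contrast in the trace")
    return (corrected - c_bleach) / (c_pre - c_bleach)


def frap_fit(times: np.ndarray, values: np.ndarray) -> FrapResult:
    """Single-exponential recovery fit ``M (1 - exp(-k t))`` of a normalized trace.

    ``times`` start at 0 at the bleach.  Returns the mobile fraction ``M`` and
    half-time ``t_half = ln2/k``; an immobile trace (M ~ 0) leaves ``k``
    unidentifiable and is flagged rather than raising.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t[0] != 0:
        raise ValueError("times must be bleach-aligned (t[0] == 0)")
    plateau = float(np.median(y[-max(3, y.size // 10):]))
    if plateau < 0.02:
        return FrapResult(max(plateau, 0.0), float("nan"), float("nan"),
                          float(np.sqrt(np.mean(y**2))), ok=False,
                          message="immobile: recovery rate unidentifiable")
    rise = np.nonzero(y > plateau * (1 - 1 / math.e))[0]
    k0 = 1.0 / max(t[rise[0]], t[1]) if rise.size and t[rise[0]] > 0 else 1.0 / max(t[-1] / 5, t[1])
    try:
        popt, _ = curve_fit(
            lambda tt, M, kk: M * (1.0 - np.exp(-kk * tt)),
            t, y, p0=[max(plateau, 0.05), k0],
            bounds=([0.0, 1e-9], [1.5, np.inf]), maxfev=10000,
        )
    except RuntimeError as err:
        return FrapResult(float("nan"), float("nan"), float("nan"), float("nan"),
                          ok=False, message=str(err))
    M, k = popt
    resid = float(np.sqrt(np.mean((y - M * (1 - np.exp(-k * t))) ** 2)))
    return FrapResult(mobile_fraction=float(M), t_half=math.log(2) / k, k=float(k), residual=resid)


def line_frap_flow(
    frames: np.ndarray,
    pixel_size: float,
    frame_dt: float,
    integration_width: int = 100,
    n_frames: int = 12,
    min_contrast: float = 0.02,
) -> LineFrapResult:
    """Track the drifting minimum of a bleached line and report flow velocity.

    Each frame of the (n_frames, ny, nx) movie is integrated over
    ``integration_width`` rows parallel to the bleach line; the dip position is
    the vertex of a parabola fitted around the profile minimum, and the flow
    velocity the slope of position versus time.  If the dip recovers below
    ``min_contrast`` the track is truncated with a warning.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be (n_frames, ny, nx)")
    ny = frames.shape[1]
    r0 = max(0, (ny - integration_width) // 2)
    rows = slice(r0, min(ny, r0 + integration_width))
    n_use = min(n_frames, frames.shape[0])
    positions, truncated = [], False
    for i in range(n_use):
        profile = frames[i, rows].sum(axis=0)
        profile = uniform_filter1d(profile, size=3)
        base = np.median(profile)
        j = int(np.argmin(profile))
        contrast = (base - profile[j]) / base if base > 0 else 0.0
        if contrast < min_contrast:
            truncated = True
            warnings.warn(f"bleach dip vanished at frame {i}; track truncated", stacklevel=2)
            break
        j0, j1 = max(0, j - 2), min(profile.size, j + 3)
        xs = np.arange(j0, j1, dtype=float)
        a, b, _ = np.polyfit(xs, profile[j0:j1], 2)
        vertex = -b / (2 * a) if a > 0 else float(j)
        positions.append(vertex * pixel_size)
    if len(positions) < 2:
        raise ValueError("no trackable dip in at least two frames")
    positions = np.asarray(positions)
    times = np.arange(positions.size) * frame_dt
    velocity = float(np.polyfit(times, positions, 1)[0])
    return LineFrapResult(times=times, positions=positions, velocity=velocity, truncated=truncated)
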