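"""Spatial statistics of lifetime images: distance fields, gradient profiles,
region systems, aligned average maps and condition-difference maps.

The central spatial descriptor is the per-pixel Euclidean distance to a named
boundary (cell edge, micropattern boundary, SLB front).  Lifetime decays are
profiled against that distance in 1-um bins (photon-weighted), gradients are
quantified as weighted least-squares slopes (ns/um), and standard region
systems (front/rear by area fraction or by angular sector, high/low lifetime
deciles of a control average map) turn maps into per-cell scalars.  Cells on
micropatterns are registered by pattern centroid plus the pattern's discrete
symmetry rotations and averaged pixel-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

from .flim import LifetimeImage

__all__ = [
    "DistanceField",
    "GradientProfile",
    "SlopeFit",
    "RegionSet",
    "ContourProfile",
    "signed_distance",
    "inward_distance",
    "decay_profile",
    "fit_slope",
    "front_rear_by_fraction",
    "front_rear_angular",
    "hist2d_mean",
    "align_and_average",
    "decile_regions",
    "difference_map",
    "contour_profile",
]


@dataclass
class DistanceField:
    """Per-pixel distance (um) to a named boundary; negative inside if signed."""

    d: np.ndarray
    reference: str = "cell_edge"
    signed: bool = True


@dataclass
class GradientProfile:
    """Lifetime vs distance: photon-weighted mean +- sd per uniform bin."""

    bin_centers: np.ndarray
    mean_tau: np.ndarray
    sd_tau: np.ndarray
    n_pixels: np.ndarray
    n_photons: np.ndarray
    bin_width: float


@dataclass
class SlopeFit:
    slope: float  # ns/um
    intercept: float  # ns
    r2: float
    fit_range: tuple[float, float]
    stderr: float = float("nan")


@dataclass
class RegionSet:
    """Named binary masks over the analysis domain (front/rear, high/low, ...)."""

    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks


@dataclass
class ContourProfile:
    arc_centers: np.ndarray  # um along the closed cell contour
    mean_tau: np.ndarray
    n_pixels: np.ndarray
    total_length: float  # um


# --------------------------------------------------------------------------- #
# distance fields
# --------------------------------------------------------------------------- #


def signed_distance(mask: np.ndarray, pixel_size: float, reference: str = "cell_edge") -> DistanceField:
    """Euclidean distance (um) to the nearest boundary pixel, negative inside.

    Boundary pixels are mask pixels with at least one 4-connected background
    neighbor; they carry distance exactly 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any() or mask.all():
        raise ValueError("mask must be non-empty and non-full")
    boundary = mask & ~ndimage.binary_erosion(mask, border_value=0)
    d = ndimage.distance_transform_edt(~boundary) * pixel_size
    d = np.where(mask, -d, d)
    return DistanceField(d=d, reference=reference, signed=True)


def inward_distance(mask: np.ndarray, pixel_size: float, reference: str = "cell_edge") -> DistanceField:
    """Unsigned distance from the boundary, defined inside the mask only (NaN out)."""
    f = signed_distance(mask, pixel_size, reference)
    d = np.where(np.asarray(mask, bool), -f.d, np.nan)
    return DistanceField(d=d, reference=reference, signed=False)


# --------------------------------------------------------------------------- #
# binned statistics (shared by decay_profile and hist2d_mean so their
# marginals agree exactly)
# --------------------------------------------------------------------------- #


def _weights(img: LifetimeImage, sel: np.ndarray, weighted: bool) -> np.ndarray:
    if weighted:
        return img.photons[sel].astype(float)
    return np.ones(int(sel.sum()))


def _accumulate(idx: np.ndarray, nb: int, w: np.ndarray, v: np.ndarray):
    sw = np.bincount(idx, weights=w, minlength=nb)
    swv = np.bincount(idx, weights=w * v, minlength=nb)
    swv2 = np.bincount(idx, weights=w * v * v, minlength=nb)
    cnt = np.bincount(idx, minlength=nb)
    return sw, swv, swv2, cnt


def decay_profile(
    img: LifetimeImage,
    fld: DistanceField,
    bin_width: float = 1.0,
    fit_range: tuple[float, float] | None = None,
    domain: np.ndarray | None = None,
    weighted: bool = True,
) -> GradientProfile:
    """Photon-weighted lifetime profile versus distance, per uniform bin.

    ``domain`` restricts the pixels considered (e.g. a front sector); bins
    with no valid pixel carry NaN means.
    """
    if img.tau.shape != fld.d.shape:
        raise ValueError("image and distance field must be congruent")
    sel = img.valid & np.isfinite(fld.d)
    if domain is not None:
        sel &= np.asarray(domain, bool)
    d = fld.d[sel]
    lo, hi = (np.floor(d.min()), np.ceil(d.max())) if fit_range is None else fit_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if edges.size < 2:
        raise ValueError("empty profile range")
    nb = edges.size - 1
    inside = (d >= edges[0]) & (d < edges[-1])
    idx = np.minimum(((d[inside] - edges[0]) / bin_width).astype(np.int64), nb - 1)
    w = _weights(img, sel, weighted)[inside]
    v = img.tau[sel][inside]
    sw, swv, swv2, cnt = _accumulate(idx, nb, w, v)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = swv / sw
        var = np.clip(swv2 / sw - mean**2, 0.0, None)
    mean[sw == 0] = np.nan
    return GradientProfile(
        bin_centers=(edges[:-1] + edges[1:]) / 2.0,
        mean_tau=mean,
        sd_tau=np.sqrt(var),
        n_pixels=cnt,
        n_photons=sw if weighted else np.bincount(idx, weights=img.photons[sel][inside].astype(float), minlength=nb),
        bin_width=bin_width,
    )


def fit_slope(profile: GradientProfile, fit_range: tuple[float, float] | None = None) -> SlopeFit:
    """Weighted least-squares line through a gradient profile.

    Weights are the per-bin pixel counts; reports the weighted R^2 and the
    standard error of the slope.
    """
    x = profile.bin_centers
    y = profile.mean_tau
    w = profile.n_pixels.astype(float)
    sel = np.isfinite(y) & (w > 0)
    if fit_range is not None:
        sel &= (x >= fit_range[0]) & (x <= fit_range[1])
    if sel.sum() < 3:
        raise ValueError("need >= 3 valid bins in the fit range")
    x, y, w = x[sel], y[sel], w[sel]
    sw = w.sum()
    xm, ym = (w * x).sum() / sw, (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    sxy = (w * (x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    ss_res = (w * resid**2).sum()
    ss_tot = (w * (y - ym) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(x.size - 2, 1)
    stderr = float(np.sqrt((ss_res / dof) / sxx * (x.size / max(x.size, 1))))
    rng_out = (float(x.min()), float(x.max()))
    return SlopeFit(slope=float(slope), intercept=float(intercept), r2=float(np.clip(r2, 0.0, 1.0)),
                    fit_range=rng_out, stderr=stderr)


# --------------------------------------------------------------------------- #
# region systems
# --------------------------------------------------------------------------- #


def front_rear_by_fraction(mask: np.ndarray, fld: DistanceField, fraction: float = 0.2) -> RegionSet:
    """Front/rear as the closest/farthest area fractions from a reference edge.

    Pixels are ranked by their distance-field value inside the mask; the front
    is the closest ``fraction`` of the area, the rear the farthest.  Rank-tie
    groups are assigned wholly (so region areas can exceed the exact fraction
    by one tie group); at ``fraction = 0.5`` ties go to the front.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    mask = np.asarray(mask, bool)
    d = fld.d
    vals = d[mask]
    n = vals.size
    k = max(1, int(round(fraction * n)))
    order = np.sort(vals)
    thr_front = order[k - 1]
    thr_rear = order[n - k]
    front = mask & (d <= thr_front)
    rear = mask & (d >= thr_rear) & ~front  # ties across the middle go to the front
    return RegionSet({"front": front, "rear": rear})


def front_rear_angular(
    mask: np.ndarray,
    pixel_size: float,
    polarity_angle: float,
    half_angle: float = 30.0,
    dmax: float = 10.0,
) -> RegionSet:
    """Front/rear as 60-degree angular sectors within ``dmax`` um of the edge.

    The polarity angle (degrees, image x-axis convention, supplied externally
    e.g. from cell morphology) defines the front bearing from the mask
    centroid; the rear is the antipodal sector.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    d = inward_distance(mask, pixel_size).d
    rr, cc = np.nonzero(mask)
    cy, cx = rr.mean(), cc.mean()
    yy, xx = np.mgrid[: mask.shape[0], : mask.shape[1]]
    bearing = np.degrees(np.arctan2(yy - cy, xx - cx))

    def sector(angle: float) -> np.ndarray:
        diff = np.abs((bearing - angle + 180.0) % 360.0 - 180.0)
        return mask & (d <= dmax) & (diff <= half_angle)

    front = sector(polarity_angle)
    rear = sector(polarity_angle + 180.0)
    if not front.any() or not rear.any():
        raise ValueError("empty front or rear sector")
    return RegionSet({"front": front, "rear": rear})


def hist2d_mean(
    img: LifetimeImage,
    field_a: DistanceField,
    field_b: DistanceField,
    bins_a: np.ndarray,
    bins_b: np.ndarray,
    weighted: bool = True,
):
    """Photon-weighted mean lifetime over a 2D grid of two spatial descriptors.

    Returns ``(mean_map, count_map, photon_map, (bins_a, bins_b))``; cells
    with no valid pixel are NaN.  Marginalizing the photon-weighted maps over
    one axis reproduces :func:`decay_profile` on the other field exactly.
    """
    if not (img.tau.shape == field_a.d.shape == field_b.d.shape):
        raise ValueError("rasters must be congruent")
    bins_a = np.asarray(bins_a, float)
    bins_b = np.asarray(bins_b, float)
    sel = img.valid & np.isfinite(field_a.d) & np.isfinite(field_b.d)
    da, db = field_a.d[sel], field_b.d[sel]
    na, nbins = bins_a.size - 1, bins_b.size - 1
    ia = np.digitize(da, bins_a) - 1
    ib = np.digitize(db, bins_b) - 1
    ok = (ia >= 0) & (ia < na) & (ib >= 0) & (ib < nbins)
    idx = ia[ok] * nbins + ib[ok]
    w = _weights(img, sel, weighted)[ok]
    v = img.tau[sel][ok]
    sw, swv, _, cnt = _accumulate(idx, na * nbins, w, v)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = (swv / sw).reshape(na, nbins)
    mean[sw.reshape(na, nbins) == 0] = np.nan
    return mean, cnt.reshape(na, nbins), sw.reshape(na, nbins), (bins_a, bins_b)


def decile_regions(avg_map: np.ndarray, k: int = 2) -> RegionSet:
    """High/low regions: the top and bottom ``k`` lifetime deciles of a map.

    Operates on the valid (finite) pixels of a control average map.  Value-tie
    groups are assigned wholly to the region, so each region covers 10k% of
    the valid area up to a tie group.  A constant map has no deciles and
    raises.
    """
    avg_map = np.asarray(avg_map, float)
    vals = avg_map[np.isfinite(avg_map)]
    if vals.size < 10:
        raise ValueError("need >= 10 valid pixels")
    if vals.min() == vals.max():
        raise ValueError("constant map: deciles undefined")
    n = vals.size
    kk = max(1, int(round(0.1 * k * n)))
    order = np.sort(vals)
    thr_low, thr_high = order[kk - 1], order[n - kk]
    high = np.isfinite(avg_map) & (avg_map >= thr_high)
    low = np.isfinite(avg_map) & (avg_map <= thr_low)
    if (high & low).any():
        raise ValueError("tie group spans both deciles: map too degenerate")
    return RegionSet({"high": high, "low": low})


# --------------------------------------------------------------------------- #
# alignment, averaging, differences
# --------------------------------------------------------------------------- #


def _int_shift(arr: np.ndarray, dy: int, dx: int, fill) -> np.ndarray:
    out = np.full_like(arr, fill)
    h, w = arr.shape
    ys = slice(max(0, dy), min(h, h + dy))
    xs = slice(max(0, dx), min(w, w + dx))
    ys_src = slice(max(0, -dy), min(h, h - dy))
    xs_src = slice(max(0, -dx), min(w, w - dx))
    out[ys, xs] = arr[ys_src, xs_src]
    return out


def _rotate(arr: np.ndarray, angle: float, fill) -> np.ndarray:
    if angle % 360 == 0:
        return arr.copy()
    if angle % 90 == 0:
        return np.rot90(arr, k=int(angle // 90) % 4)
    nan_fill = not np.issubdtype(arr.dtype, np.bool_)
    out = ndimage.rotate(
        np.nan_to_num(arr.astype(float), nan=np.nan) if nan_fill else arr.astype(np.uint8),
        angle, reshape=False, order=0, cval=np.nan if nan_fill else 0,
    )
    return out.astype(arr.dtype) if not nan_fill else out


def _centroid(mask: np.ndarray) -> tuple[float, float]:
    rr, cc = np.nonzero(mask)
    return float(rr.mean()), float(cc.mean())


def align_and_average(
    images: list[LifetimeImage],
    pattern_masks: list[np.ndarray],
    template_mask: np.ndarray,
    symmetry_angles: tuple[float, ...] = (0.0,),
    min_overlap: float = 0.5,
    weighted: bool = True,
):
    """Register cells by their micropattern and average lifetimes pixel-wise.

    Each image is rotated by the template-symmetry angle maximizing the
    Jaccard overlap of its (centroid-translated) pattern mask with the
    template, then translated so the pattern centroids coincide.  Free
    rotation/scaling is deliberately excluded: patterns are manufactured at a
    fixed size and orientation, and free registration could smear gradients.
    Images whose best overlap stays below ``min_overlap`` are dropped with a
    warning.  Returns ``(average LifetimeImage, density map, transforms)``
    where density counts the images contributing per pixel.
    """
    if len(images) < 1 or len(images) != len(pattern_masks):
        raise ValueError("need one pattern mask per image")
    template_mask = np.asarray(template_mask, bool)
    tc = _centroid(template_mask)
    sum_w = np.zeros(template_mask.shape)
    sum_wt = np.zeros(template_mask.shape)
    density = np.zeros(template_mask.shape, dtype=np.int64)
    transforms = []
    for i, (img, pat) in enumerate(zip(images, pattern_masks)):
        pat = np.asarray(pat, bool)
        best = (-1.0, 0.0, 0, 0)
        for ang in symmetry_angles:
            rp = _rotate(pat, ang, False)
            pc = _centroid(rp)
            dy, dx = int(round(tc[0] - pc[0])), int(round(tc[1] - pc[1]))
            sp = _int_shift(rp, dy, dx, False)
            inter = np.logical_and(sp, template_mask).sum()
            union = np.logical_or(sp, template_mask).sum()
            iou = inter / union if union else 0.0
            if iou > best[0]:
                best = (iou, ang, dy, dx)
        iou, ang, dy, dx = best
        if iou < min_overlap:
            warnings.warn(f"image {i}: best pattern overlap {iou:.2f} < {min_overlap}; dropped",
                          stacklevel=2)
            transforms.append({"index": i, "dropped": True, "iou": iou})
            continue
        tau = _int_shift(_rotate(img.tau, ang, np.nan), dy, dx, np.nan)
        pho = _int_shift(_rotate(img.photons.astype(float), ang, 0.0), dy, dx, 0.0)
        w = pho if weighted else np.ones_like(pho)
        ok = np.isfinite(tau) & (w > 0)
        sum_w[ok] += w[ok]
        sum_wt[ok] += w[ok] * tau[ok]
        density[ok] += 1
        transforms.append({"index": i, "dropped": False, "iou": iou, "angle": ang, "shift": (dy, dx)})
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = sum_wt / sum_w
    avg[sum_w == 0] = np.nan
    out = LifetimeImage(tau=avg, photons=sum_w, pixel_size=images[0].pixel_size,
                        meta={"n_images": len(images), "weighted": weighted})
    return out, density, transforms


def difference_map(per_cell_images: list[LifetimeImage], reference_avg: LifetimeImage):
    """Per-cell and averaged lifetime differences to a reference average map.

    Inputs must already be registered to the reference geometry (run
    :func:`align_and_average` first).  ``Delta(p) = tau_cell(p) - tau_ref(p)``
    on the common valid support; the averaged map is the pixel-wise mean of
    the per-cell differences.
    """
    ref = reference_avg.tau
    deltas = []
    for img in per_cell_images:
        if img.tau.shape != ref.shape:
            raise ValueError("images must share the reference geometry")
        deltas.append(img.tau - ref)
    stack = np.stack(deltas)
    if not np.isfinite(stack).any():
        raise ValueError("no common valid support with the reference")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        avg = np.nanmean(stack, axis=0)
    return deltas, avg


def contour_profile(
    img: LifetimeImage,
    mask: np.ndarray,
    start_anchor: tuple[int, int] | None = None,
    band: float = 1.0,
    bin_width: float = 1.0,
) -> ContourProfile:
    """Lifetime along the cell contour, sampled from a 1-um inward band.

    The boundary is traced as a closed curve; pixels within ``band`` um of the
    edge are assigned to their nearest contour vertex and averaged
    (photon-weighted) per arc-length bin.  The profile is periodic.  With
    multiple mask components the largest is used with a warning.
    """
    mask = np.asarray(mask, bool)
    lab, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("empty mask")
    if n > 1:
        warnings.warn(f"mask has {n} components; using the largest", stacklevel=2)
        sizes = ndimage.sum(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)
    if contour.shape[0] >= 15:
        # circular moving average of the vertices removes the staircase
        # inflation (~5%) of the marching-squares polygon length
        kern = 7
        pad = np.vstack([contour[-kern:], contour, contour[:kern]])
        smoothed = np.stack(
            [np.convolve(pad[:, j], np.ones(kern) / kern, mode="same") for j in (0, 1)], axis=1
        )
        contour = smoothed[kern:-kern]
    if start_anchor is not None:
        d2 = ((contour - np.asarray(start_anchor)) ** 2).sum(axis=1)
        contour = np.roll(contour, -int(np.argmin(d2)), axis=0)
    seg = np.linalg.norm(np.diff(np.vstack([contour, contour[:1]]), axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg[:-1])]) * img.pixel_size
    total = float(seg.sum() * img.pixel_size)

    dist = inward_distance(mask, img.pixel_size).d
    sel = np.isfinite(dist) & (dist <= band) & img.valid
    rr, cc = np.nonzero(sel)
    if rr.size == 0:
        raise ValueError("no valid pixels in the contour band")
    tree = cKDTree(contour)
    _, nearest = tree.query(np.column_stack([rr, cc]))
    pix_arc = arc[nearest]
    edges = np.arange(0.0, total + bin_width / 2, bin_width)
    nb = max(edges.size - 1, 1)
    idx = np.minimum((pix_arc / bin_width).astype(np.int64), nb - 1)
    w = img.photons[rr, cc].astype(float)
    v = img.tau[rr, cc]
    sw, swv, _, cnt = _accumulate(idx, nb, w, v)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = swv / sw
    mean[sw == 0] = np.nan
    centers = (edges[:-1] + edges[1:]) / 2.0
    return ContourProfile(arc_centers=centers, mean_tau=mean, n_pixels=cnt, total_length=total)
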