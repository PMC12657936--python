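"""Edge kinematics, SLB expansion analysis, and track/shape descriptors.

Cell-edge velocity is measured from segmentation-mask time series as the
frame-to-frame difference of signed distance maps evaluated at the earlier
frame's contour (positive outward).  Contour pixels above/below a symmetric
velocity threshold seed protruding/retracting sectors extending inward from
the edge, and lifetimes can be binned jointly by distance-from-edge and edge
velocity.  SLB spreading speed is the net area increase per time per crop
width, paired frame-by-frame with the fitted lifetime gradient slope near the
advancing front.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

from .flim import LifetimeImage
from .spatial import DistanceField, GradientProfile, RegionSet, SlopeFit, decay_profile, fit_slope, hist2d_mean, inward_distance

__all__ = [
    "MaskMovie",
    "EdgeVelocityField",
    "Track",
    "edge_velocity",
    "classify_edges",
    "velocity_binned_lifetime",
    "slb_speed",
    "speed_slope_curve",
    "directionality_ratio",
    "aspect_ratio",
]


@dataclass
class MaskMovie:
    """Binary segmentation rasters over frames, with frame interval in minutes."""

    masks: np.ndarray  # (frames, H, W) bool
    dt: float  # min / frame
    pixel_size: float  # um / pixel

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, bool)
        if self.masks.ndim != 3:
            raise ValueError("masks must be (frames, H, W)")
        if self.dt <= 0 or self.pixel_size <= 0:
            raise ValueError("dt and pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]


@dataclass
class EdgeVelocityField:
    """Outward edge velocity (um/min) at the contour pixels of one frame.

    ``arc_length[k]`` is the length of cell boundary (um) represented by
    contour pixel ``k`` (from the sub-pixel traced contour), so that
    ``sum(v * arc_length) * dt`` approximates the area swept by the edge.
    """

    coords: np.ndarray  # (N, 2) row/col of contour pixels of the earlier frame
    v: np.ndarray  # (N,) um/min, positive outward
    arc_length: np.ndarray  # (N,) um of boundary per contour pixel
    frame: int
    mask: np.ndarray  # the earlier frame's mask


@dataclass
class Track:
    """Time-ordered cell-centroid positions (um)."""

    times: np.ndarray
    xy: np.ndarray  # (N, 2)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.xy = np.asarray(self.xy, float)
        if self.xy.shape[0] < 2:
            raise ValueError("a track needs >= 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("track times must strictly increase")


def _signed_dist_px(mask: np.ndarray) -> np.ndarray:
    """Signed distance in pixels, positive inside the mask."""
    return ndimage.distance_transform_edt(mask) - ndimage.distance_transform_edt(~mask)


def _contour_pixels(mask: np.ndarray) -> np.ndarray:
    boundary = mask & ~ndimage.binary_erosion(mask, border_value=0)
    return np.column_stack(np.nonzero(boundary))


def edge_velocity(movie: MaskMovie, frame: int, sample_depth: float = 3.0) -> EdgeVelocityField:
    """Edge displacement rate between ``frame`` and ``frame + 1``.

    ``v(p) = [d(p, frame+1) - d(p, frame)] * pixel_size / dt`` at the contour
    pixels of the earlier frame, with ``d`` the signed distance to the cell
    exterior (positive inside), so outward motion is positive.  Sub-pixel
    velocities are kept as real numbers.

    Right at a boundary pixel the two distance maps carry different
    staircase-quantization biases (the earlier frame's distance is pinned to
    exactly one pixel), so the difference is read ``sample_depth`` pixels
    inward — where both maps are smooth and their raster biases cancel — and
    assigned to the nearest contour pixel.  Thin masks without such an
    interior ring fall back to sampling at the contour itself.
    """
    if not 0 <= frame < movie.n_frames - 1:
        raise ValueError("need frames `frame` and `frame + 1`")
    m0, m1 = movie.masks[frame], movie.masks[frame + 1]
    if not m0.any() or not m1.any():
        raise ValueError("empty mask")
    coords = _contour_pixels(m0)
    d0 = _signed_dist_px(m0)
    d1 = _signed_dist_px(m1)
    diff = d1 - d0
    e0 = ndimage.distance_transform_edt(m0)
    ring = (e0 > sample_depth - 0.5) & (e0 <= sample_depth + 0.5)
    if ring.any():
        ring_coords = np.column_stack(np.nonzero(ring))
        _, idx = cKDTree(ring_coords).query(coords)
        picked = ring_coords[idx]
        vals = diff[picked[:, 0], picked[:, 1]]
    else:
        vals = diff[coords[:, 0], coords[:, 1]]
    v = vals * movie.pixel_size / movie.dt

    # share of the sub-pixel traced boundary carried by each contour pixel
    arc = np.zeros(coords.shape[0])
    tree = cKDTree(coords)
    for contour in measure.find_contours(m0.astype(float), 0.5):
        closed = np.vstack([contour, contour[:1]])
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        mid = (closed[:-1] + closed[1:]) / 2.0
        _, nearest = tree.query(mid)
        np.add.at(arc, nearest, seg)
    return EdgeVelocityField(
        coords=coords, v=v, arc_length=arc * movie.pixel_size, frame=frame, mask=m0
    )


def classify_edges(
    field: EdgeVelocityField,
    pixel_size: float,
    threshold: float = 0.2,
    band: float = 10.0,
) -> RegionSet:
    """Protruding/retracting regions seeded by edge velocity.

    Contour pixels with ``v > +threshold`` um/min seed protruding sectors and
    ``v < -threshold`` retracting ones (symmetric threshold; the band
    ``|v| <= threshold`` stays unclassified).  Each classified region extends
    0-``band`` um inward from the edge: interior pixels inherit the class of
    their nearest contour pixel.  The two regions are disjoint by
    construction.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    mask = field.mask
    d = inward_distance(mask, pixel_size).d
    inner = np.isfinite(d) & (d <= band)
    rr, cc = np.nonzero(inner)
    tree = cKDTree(field.coords)
    _, nearest = tree.query(np.column_stack([rr, cc]))
    v_near = field.v[nearest]
    prot = np.zeros_like(mask)
    retr = np.zeros_like(mask)
    prot[rr, cc] = v_near > threshold
    retr[rr, cc] = v_near < -threshold
    return RegionSet({"protruding": prot, "retracting": retr})


def velocity_binned_lifetime(
    img: LifetimeImage,
    field: EdgeVelocityField,
    bins_distance: np.ndarray,
    bins_velocity: np.ndarray,
):
    """Photon-weighted mean lifetime over (distance-from-edge, edge-velocity) bins.

    Every interior pixel inherits the velocity of its nearest contour pixel;
    the marginal over velocity reproduces the plain distance profile.
    Returns ``(mean_map, count_map, photon_map, (bins_d, bins_v))``.
    """
    mask = field.mask
    d = inward_distance(mask, img.pixel_size)
    rr, cc = np.nonzero(mask)
    tree = cKDTree(field.coords)
    _, nearest = tree.query(np.column_stack([rr, cc]))
    vmap = np.full(mask.shape, np.nan)
    vmap[rr, cc] = field.v[nearest]
    vfield = DistanceField(d=vmap, reference="edge_velocity", signed=False)
    return hist2d_mean(img, d, vfield, bins_distance, bins_velocity)


def slb_speed(movie: MaskMovie, crop_width: float, frame: int) -> float:
    """SLB spreading speed: net area increase / (dt * crop width), um/min."""
    if crop_width <= 0:
        raise ValueError("crop width must be > 0")
    if not 0 <= frame < movie.n_frames - 1:
        raise ValueError("need frames `frame` and `frame + 1`")
    a0 = movie.masks[frame].sum() * movie.pixel_size**2
    a1 = movie.masks[frame + 1].sum() * movie.pixel_size**2
    return float((a1 - a0) / (movie.dt * crop_width))


def speed_slope_curve(
    movie: MaskMovie,
    lifetime_frames: list[LifetimeImage],
    crop_width: float,
    window: float = 100.0,
    bin_width: float = 1.0,
) -> list[tuple[float, SlopeFit]]:
    """Per-frame (spreading speed, lifetime-gradient slope) pairs for an SLB.

    For each frame interval the speed is the area-based spreading speed and
    the slope a weighted linear fit of lifetime versus distance from the
    advancing front, restricted to the ``window`` um closest to the front
    (distance measured as the Euclidean distance to the film exterior, which
    for an advancing front is the distance to the front line).
    """
    if len(lifetime_frames) < movie.n_frames - 1:
        raise ValueError("need a lifetime frame per mask interval")
    out = []
    for i in range(movie.n_frames - 1):
        speed = slb_speed(movie, crop_width, i)
        img = lifetime_frames[i]
        mask = movie.masks[i]
        d = ndimage.distance_transform_edt(mask) * movie.pixel_size
        fld = DistanceField(d=np.where(mask, d, np.nan), reference="slb_front", signed=False)
        prof = decay_profile(img, fld, bin_width=bin_width, fit_range=(0.0, window))
        out.append((speed, fit_slope(prof)))
    return out


def directionality_ratio(track: Track) -> float:
    """Net displacement over path length; 1 for a straight path, 0 for a loop."""
    seg = np.linalg.norm(np.diff(track.xy, axis=0), axis=1)
    path = seg.sum()
    if path <= 0:
        raise ValueError("zero path length")
    net = float(np.linalg.norm(track.xy[-1] - track.xy[0]))
    return net / float(path)


def aspect_ratio(mask: np.ndarray) -> float:
    """Major/minor axis ratio of the second-moment-equivalent ellipse (>= 1)."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    minor = props.axis_minor_length
    if minor <= 0:
        raise ValueError("degenerate mask: minor axis is zero")
    return float(props.axis_major_length / minor)
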