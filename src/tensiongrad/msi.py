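"""MALDI-MSI lipid-fraction maps and cross-cell normalized averages.

A processed MSI export is a multi-channel stack (one channel per m/z peak)
plus a peak table assigning channels to lipid species (or "unknown").  Per
pixel, a species' lipid fraction is the summed intensity of its peaks over
the total intensity of the *known* peaks only; pixels with zero known
intensity are invalid rather than zero (off-cell background must not dilute
pooled statistics).  Spatial heterogeneity is compared across cells by
z-scoring each species' fractions against the statistics pooled over all
cells' valid pixels, then registering cells by their micropattern and
averaging pixel-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flim import LifetimeImage
from .spatial import align_and_average

__all__ = ["FractionMap", "lipid_fractions", "zscore_fractions", "msi_average_map"]


@dataclass
class FractionMap:
    """Per-species lipid-fraction rasters plus the shared validity mask."""

    fractions: dict[str, np.ndarray]
    valid: np.ndarray

    @property
    def species(self) -> list[str]:
        return list(self.fractions)


def _check_table(peaks: pd.DataFrame, n_channels: int) -> pd.DataFrame:
    required = {"channel", "species"}
    if not required.issubset(peaks.columns):
        raise ValueError("peak table needs 'channel' and 'species' columns")
    if peaks["channel"].duplicated().any():
        raise ValueError("duplicate channel indices in peak table")
    if peaks["channel"].max() >= n_channels or peaks["channel"].min() < 0:
        raise ValueError("peak table channel outside the stack")
    known = peaks[peaks["species"] != "unknown"]
    if known.empty:
        raise ValueError("peak table assigns no known species")
    return known


def lipid_fractions(stack: np.ndarray, peaks: pd.DataFrame) -> FractionMap:
    """Per-pixel lipid fraction of each species over the known peaks.

    ``stack`` is (channels, H, W).  Unknown channels are excluded from the
    total; species present in several peaks have their relative abundances
    summed.  Valid-pixel fractions sum to 1 across species.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (channels, H, W)")
    known = _check_table(peaks, stack.shape[0])
    total = stack[known["channel"].to_numpy()].sum(axis=0)
    valid = total > 0
    fractions = {}
    for species, grp in known.groupby("species", sort=False):
        num = stack[grp["channel"].to_numpy()].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = num / total
        f[~valid] = np.nan
        fractions[str(species)] = f
    return FractionMap(fractions=fractions, valid=valid)


def zscore_fractions(maps: list[FractionMap], species: str) -> tuple[list[np.ndarray], float, float]:
    """Z-score one species' fraction maps against statistics pooled over cells.

    All valid pixels of all cells are pooled; each map becomes
    ``(f - pooled mean) / pooled SD``.  A species with zero pooled SD is
    uninformative and raises.  Returns ``(z_maps, mean, sd)``.
    """
    pooled = np.concatenate([m.fractions[species][m.valid] for m in maps])
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        raise ValueError("no valid pixels for species")
    mu, sd = float(pooled.mean()), float(pooled.std())
    if sd == 0:
        raise ValueError(f"species {species!r} has zero pooled SD (uninformative)")
    return [(m.fractions[species] - mu) / sd for m in maps], mu, sd


def msi_average_map(
    z_maps: list[np.ndarray],
    pattern_masks: list[np.ndarray],
    template_mask: np.ndarray,
    symmetry_angles: tuple[float, ...] = (0.0,),
    min_overlap: float = 0.5,
):
    """Cross-cell average of z-scored maps after micropattern registration.

    Delegates to :func:`tensiongrad.spatial.align_and_average` with equal
    pixel weights (z-scores carry no photon statistics).  The same transform
    must be applied to every species of a cell: call once per species with
    identical ``pattern_masks`` and the transforms will match because
    registration depends only on the masks.
    """
    pixel_size = 0.5  # um, MSI stage step of the processed export
    images = [
        LifetimeImage(tau=np.asarray(z, float), photons=np.ones_like(np.asarray(z, float)),
                      pixel_size=pixel_size)
        for z in z_maps
    ]
    avg, density, transforms = align_and_average(
        images, pattern_masks, template_mask,
        symmetry_angles=symmetry_angles, min_overlap=min_overlap, weighted=False,
    )
    return avg.tau, density, transforms
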