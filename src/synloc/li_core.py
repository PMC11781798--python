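"""The voxel-wise Localization Index (LI) with censoring and normalization.

The LI maps where a membrane protein sits relative to a uniform membrane
reference.  At each voxel the target signal (reconstituted GFP on the
tagged receptor) is divided by the membrane-marker signal, voxels devoid
of membrane signal are censored, and the per-voxel ratio is normalized by
its arithmetic mean over the region of interest:

    r_v  = rGFP_v / membrane_v          (valid voxels only)
    LI_v = r_v / mean_{valid}(r)

so that mean(LI) = 1 over valid voxels by construction.  A protein that
distributes exactly like the membrane reference gives LI = 1 everywhere;
LI > 1 marks local enrichment, LI < 1 local depletion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from skimage.filters import threshold_otsu

from .volume_io import RegionLabelMap, Volume

__all__ = [
    "LIMap",
    "RegionSummary",
    "SignalLevel",
    "EmptyMaskError",
    "build_membrane_mask",
    "compute_li_map",
    "region_mean_li",
    "quantify_signal_level",
]


class EmptyMaskError(ValueError):
    """No voxel survives censoring; the LI is undefined."""


@dataclass
class LIMap:
    """Per-voxel LI with its validity mask.

    ``li`` is NaN at censored voxels; ``roi_mean_ratio`` is the arithmetic
    mean of rGFP/membrane ratios over valid voxels used as the
    normalization divisor.
    """

    li: np.ndarray
    valid: np.ndarray
    roi_mean_ratio: float

    def valid_values(self) -> np.ndarray:
        return self.li[self.valid]


@dataclass
class RegionSummary:
    """Mean LI of one subcellular region in one brain sample."""

    region: str
    mean_li: float
    n_valid_voxels: int
    sample_id: str = ""


@dataclass
class SignalLevel:
    """Background-corrected signal level over a region.

    ``clipped`` flags a background estimate exceeding the region signal;
    the value is then reported as 0 rather than silently negative.
    """

    value: float
    background: float
    clipped: bool = False


MaskMethod = Literal["fixed", "otsu", "quantile"]


def build_membrane_mask(
    volume: Volume,
    membrane_channel: str = "membrane",
    method: MaskMethod = "fixed",
    threshold: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Censoring mask: True exactly where membrane intensity > threshold.

    ``method="fixed"`` uses ``threshold`` directly (the default 0 is the
    literal reading of censoring voxels *devoid* of membrane signal);
    ``"otsu"`` resolves it from the intensity histogram; ``"quantile"``
    reads ``threshold`` as a quantile in (0, 1).

    Returns ``(mask, resolved_threshold)``; raises :class:`EmptyMaskError`
    if no voxel passes.
    """
    mem = volume.channel(membrane_channel)
    if method == "fixed":
        if threshold < 0:
            raise ValueError(f"fixed threshold must be >= 0, got {threshold}")
        thr = float(threshold)
    elif method == "otsu":
        if np.ptp(mem) == 0:
            raise EmptyMaskError("membrane channel is constant; Otsu threshold undefined")
        thr = float(threshold_otsu(mem.ravel()))
    elif method == "quantile":
        if not 0 < threshold < 1:
            raise ValueError(f"quantile must be in (0, 1), got {threshold}")
        thr = float(np.quantile(mem, threshold))
    else:
        raise ValueError(f"unknown mask method {method!r}")
    mask = mem > thr
    if not mask.any():
        raise EmptyMaskError(
            f"no voxel exceeds membrane threshold {thr} ({method}); LI undefined"
        )
    return mask, thr


def compute_li_map(
    volume: Volume,
    rgfp_channel: str = "rgfp",
    membrane_channel: str = "membrane",
    mask: np.ndarray | None = None,
    roi: RegionLabelMap | np.ndarray | None = None,
    winsorize_quantile: float | None = None,
) -> LIMap:
    """Compute the censored, mean-normalized LI map.

    ``mask`` defaults to the fixed zero-threshold membrane mask.  ``roi``
    optionally restricts the normalization region: a boolean field, or a
    :class:`RegionLabelMap` whose nonzero labels define the ROI.  Note the
    ROI is part of the statistic — restricting it renormalizes the map.

    ``winsorize_quantile`` optionally caps ratios at that upper quantile
    before normalization (off by default; extreme ratios at dim membrane
    voxels are otherwise reported as-is).
    """
    rgfp = volume.channel(rgfp_channel)
    mem = volume.channel(membrane_channel)
    if mask is None:
        mask, _ = build_membrane_mask(volume, membrane_channel)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError(f"mask shape {mask.shape} does not match volume shape {volume.shape}")
    valid = mask.copy()
    if roi is not None:
        roi_mask = roi.labels > 0 if isinstance(roi, RegionLabelMap) else np.asarray(roi, bool)
        if roi_mask.shape != volume.shape:
            raise ValueError("ROI shape does not match volume shape")
        valid &= roi_mask
    if not valid.any():
        raise EmptyMaskError("no valid voxel after ROI restriction; LI undefined")
    mem_valid = mem[valid]
    if np.any(mem_valid <= 0):
        raise ValueError(
            "mask admits voxels with zero membrane signal; the ratio is undefined there"
        )
    ratio = rgfp[valid] / mem_valid
    if winsorize_quantile is not None:
        if not 0 < winsorize_quantile <= 1:
            raise ValueError("winsorize_quantile must be in (0, 1]")
        cap = np.quantile(ratio, winsorize_quantile)
        ratio = np.minimum(ratio, cap)
    roi_mean = float(np.mean(ratio))
    if roi_mean <= 0:
        raise ValueError("mean ratio is zero (target channel empty in ROI); LI undefined")
    li = np.full(volume.shape, np.nan)
    li[valid] = ratio / roi_mean
    return LIMap(li=li, valid=valid, roi_mean_ratio=roi_mean)


def region_mean_li(
    limap: LIMap,
    labels: RegionLabelMap,
    region: str,
    sample_id: str = "",
) -> RegionSummary:
    """Arithmetic mean LI over the valid voxels of one labeled region.

    One summary per brain sample: each sample is a single statistical
    unit, so voxels are never pooled across samples.
    """
    sel = labels.region_mask(region) & limap.valid
    n = int(sel.sum())
    if n == 0:
        raise EmptyMaskError(f"region {region!r} has no valid (uncensored) voxels")
    return RegionSummary(
        region=region,
        mean_li=float(np.mean(limap.li[sel])),
        n_valid_voxels=n,
        sample_id=sample_id,
    )


def quantify_signal_level(
    volume: Volume,
    channel: str,
    labels: RegionLabelMap,
    region: str,
    background: Literal["none", "constant", "roi_label"] = "none",
    background_constant: float = 0.0,
    background_region: str | None = None,
    statistic: Literal["mean", "integrated"] = "mean",
) -> SignalLevel:
    """Background-corrected signal level of one channel over one region.

    Used for raw-intensity comparisons across conditions (e.g. receptor
    levels in presynaptic terminals over starvation time).  ``statistic``
    selects mean (default) or integrated (summed) intensity; background is
    none, a constant per-voxel offset, or the mean over another labeled
    region.
    """
    sel = labels.region_mask(region)
    n = int(sel.sum())
    if n == 0:
        raise EmptyMaskError(f"region {region!r} is empty")
    data = volume.channel(channel)[sel]
    if background == "none":
        bg_per_voxel = 0.0
    elif background == "constant":
        bg_per_voxel = float(background_constant)
    elif background == "roi_label":
        if background_region is None:
            raise ValueError("background='roi_label' requires background_region")
        bg_sel = labels.region_mask(background_region)
        if not bg_sel.any():
            raise EmptyMaskError(f"background region {background_region!r} is empty")
        bg_per_voxel = float(np.mean(volume.channel(channel)[bg_sel]))
    else:
        raise ValueError(f"unknown background mode {background!r}")
    if statistic == "mean":
        value = float(np.mean(data)) - bg_per_voxel
        bg_total = bg_per_voxel
    elif statistic == "integrated":
        value = float(np.sum(data)) - bg_per_voxel * n
        bg_total = bg_per_voxel * n
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    clipped = value < 0
    if clipped:
        warnings.warn(
            f"background estimate exceeds signal in region {region!r}; clipping at 0",
            RuntimeWarning,
            stacklevel=2,
        )
        value = 0.0
    return SignalLevel(value=value, background=bg_total, clipped=clipped)
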