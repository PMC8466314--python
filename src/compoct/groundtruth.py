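"""Ground-truth mask generation: ROI contours gated by Hounsfield windows.

A trained operator (or, here, the phantom's label map standing in for
one) outlines twelve regions of interest; within each contour, pixels
are then selected automatically by tissue attenuation: muscle keeps
-29 to +150 HU, fat keeps -190 to -30 HU.  Both window bounds are
treated as inclusive; the two windows are disjoint, so muscle and fat
masks derived from the same contour can never share a pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from compoct.phantom import HUSlice, TissueLabelMap
from compoct.rois import FAT_ROIS, MUSCLE_ROIS, ROI_NAMES

__all__ = [
    "HUWindow",
    "MUSCLE_WINDOW",
    "FAT_WINDOW",
    "ROIMaskSet",
    "gate_hu",
    "make_ground_truth",
    "window_for_roi",
]


@dataclass(frozen=True)
class HUWindow:
    """A closed attenuation interval [lo, hi] selecting one tissue class."""

    lo: float
    hi: float
    tissue: str

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"window requires lo < hi, got [{self.lo}, {self.hi}]")

    def contains(self, hu: np.ndarray) -> np.ndarray:
        return (hu >= self.lo) & (hu <= self.hi)


MUSCLE_WINDOW = HUWindow(-29.0, 150.0, "muscle")
FAT_WINDOW = HUWindow(-190.0, -30.0, "fat")


def window_for_roi(name: str) -> HUWindow:
    if name in MUSCLE_ROIS or name == "muscle":
        return MUSCLE_WINDOW
    if name in FAT_ROIS:
        return FAT_WINDOW
    raise KeyError(f"unknown ROI {name!r}")


@dataclass
class ROIMaskSet:
    """Twelve aligned binary masks for one slice (m01..m10, VAT, SAT)."""

    masks: dict[str, np.ndarray]
    provenance: str = "ground_truth"  # or "predicted"
    shape: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        missing = [r for r in ROI_NAMES if r not in self.masks]
        if missing:
            raise KeyError(f"missing ROI masks: {missing}")
        shapes = {self.masks[r].shape for r in ROI_NAMES}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent mask shapes: {shapes}")
        self.masks = {r: np.asarray(self.masks[r], dtype=bool) for r in ROI_NAMES}
        self.shape = next(iter(shapes))

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    @property
    def muscle(self) -> np.ndarray:
        """Pooled muscle ROI: pixel-wise union of the ten muscle masks."""
        out = np.zeros(self.shape, dtype=bool)
        for r in MUSCLE_ROIS:
            out |= self.masks[r]
        return out

    def pixel_counts(self) -> dict[str, int]:
        counts = {r: int(self.masks[r].sum()) for r in ROI_NAMES}
        counts["muscle"] = int(self.muscle.sum())
        return counts


def gate_hu(slc: HUSlice, region: np.ndarray, window: HUWindow) -> np.ndarray:
    """Keep the region pixels whose HU lies inside the (closed) window.

    The output is always a subset of ``region``; gating is idempotent
    and monotone in the window bounds.
    """
    region = np.asarray(region, dtype=bool)
    if region.shape != slc.shape:
        raise ValueError(
            f"region shape {region.shape} does not match slice {slc.shape}"
        )
    return region & window.contains(slc.values)


def make_ground_truth(
    slc: HUSlice,
    contours: Mapping[str, np.ndarray] | TissueLabelMap,
) -> ROIMaskSet:
    """Gate twelve ROI contours into ground-truth masks.

    ``contours`` maps each ROI name to a binary region (a rasterized
    manual contour), or is a phantom :class:`TissueLabelMap` whose label
    regions are used as contours.  Muscle contours are gated with the
    muscle window, VAT/SAT with the fat window.
    """
    if isinstance(contours, TissueLabelMap):
        if contours.shape != slc.shape:
            raise ValueError("label map shape does not match slice")
        regions: Mapping[str, np.ndarray] = contours.roi_masks()
    else:
        regions = contours
    missing = [r for r in ROI_NAMES if r not in regions]
    if missing:
        raise KeyError(f"missing ROI contours: {missing}")
    masks = {
        name: gate_hu(slc, regions[name], window_for_roi(name))
        for name in ROI_NAMES
    }
    return ROIMaskSet(masks=masks, provenance="ground_truth")
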