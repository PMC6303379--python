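"""Voxel classification: pore thresholding and seeded root extraction.

Pore space is the low-attenuation (air) class: a voxel is pore when its
gray value is <= the threshold (the boundary value itself is pore). The
root, of intermediate attenuation, is grown from a user-supplied seed point
by intensity-window region growing and tidied by 3D morphological closing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball

from rhizoct.volume_io import LabelVolume, PORE, ROOT, SOLID, VoxelVolume


class SegmentationError(ValueError):
    """Invalid segmentation input."""


class RootLeakError(RuntimeError):
    """Seeded root growth escaped into the soil matrix."""


@dataclass
class PoreSegmentation:
    mask: np.ndarray
    threshold: float
    method: str


def threshold_pores(volume: VoxelVolume, method: str = "otsu", threshold: float | None = None) -> PoreSegmentation:
    """Binarize pore space: gray <= threshold is pore.

    ``method="otsu"`` picks the threshold maximizing between-class variance
    of the gray histogram; ``method="fixed"`` uses the supplied value.
    """
    data = volume.data
    if method == "otsu":
        if data.min() == data.max():
            raise SegmentationError("constant-valued volume: Otsu has no variance to split")
        t = float(threshold_otsu(data))
    elif method == "fixed":
        if threshold is None:
            raise SegmentationError("method='fixed' requires a threshold value")
        t = float(threshold)
    else:
        raise SegmentationError(f"unknown thresholding method {method!r}")
    return PoreSegmentation(mask=data <= t, threshold=t, method=method)


def extract_root(
    volume: VoxelVolume,
    seed_point: tuple[int, int, int],
    pore_mask: np.ndarray | None = None,
    window: float = 25.0,
    closing_radius: int = 2,
    opening_radius: int = 2,
    max_volume_fraction: float = 0.20,
) -> np.ndarray:
    """Extract the root as the seed's connected intensity-window component.

    The window is centred on the median gray of the seed's 3x3x3
    neighbourhood; the connected component (26-connectivity) containing the
    seed is morphologically closed (fills interior noise holes) and then
    opened (strips attached surface fuzz) with balls of the given radii.
    A grown region exceeding ``max_volume_fraction`` of the volume signals a
    segmentation leak into pore or solid and raises :class:`RootLeakError`.
    """
    data = volume.data
    seed = tuple(int(c) for c in seed_point)
    if len(seed) != 3 or any(c < 0 or c >= s for c, s in zip(seed, data.shape)):
        raise SegmentationError(f"seed point {seed_point} outside volume of shape {data.shape}")

    lo = tuple(max(c - 1, 0) for c in seed)
    hi = tuple(min(c + 2, s) for c, s in zip(seed, data.shape))
    neighbourhood = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    centre_gray = float(np.median(neighbourhood))

    in_window = np.abs(data.astype(float) - centre_gray) <= window
    in_window[seed] = True  # the seed defines the class even if its own gray is a noise outlier
    structure = np.ones((3, 3, 3), dtype=bool)
    comp_labels, _ = ndimage.label(in_window, structure=structure)
    root = comp_labels == comp_labels[seed]
    # pad so the morphology does not erode where the root meets a volume face
    for op, r in ((ndimage.binary_closing, closing_radius), (ndimage.binary_opening, opening_radius)):
        if r > 0:
            padded = np.pad(root, r, mode="edge")
            padded = op(padded, structure=ball(r))
            root = padded[r:-r, r:-r, r:-r]

    fraction = root.mean()
    if fraction > max_volume_fraction:
        raise RootLeakError(
            f"grown root region covers {fraction:.1%} of the volume "
            f"(cap {max_volume_fraction:.0%}): segmentation leak"
        )
    if pore_mask is not None and bool(pore_mask[seed]):
        warnings.warn("root seed point lies inside the pore mask; check the seed", stacklevel=2)
    return root


def make_labels(pore_mask: np.ndarray, root_mask: np.ndarray, voxel_size: float) -> LabelVolume:
    """Combine masks into an exhaustive label volume; root overrides pore."""
    if pore_mask.shape != root_mask.shape:
        raise SegmentationError(f"mask shapes differ: {pore_mask.shape} vs {root_mask.shape}")
    labels = np.full(pore_mask.shape, SOLID, dtype=np.uint8)
    labels[pore_mask] = PORE
    labels[root_mask] = ROOT
    return LabelVolume(data=labels, voxel_size=voxel_size)
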