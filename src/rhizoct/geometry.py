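"""Distance-shell porosity profiling, rhizosheath extraction and connectivity.

The core computation of the pipeline: Euclidean distance from the root
surface partitions the soil into 1 mm shells; porosity per shell across
replicates feeds a one-way ANOVA + Tukey HSD that locates the rhizosheath
boundary (the prefix of shells with significantly elevated porosity); the
rhizosheath (0..boundary) and bulk (boundary..2*boundary) regions are then
extracted for region-wise porosity and pore connectivity.

Conventions (fixed once, used everywhere):

* distance bands are half-open [d, d+1) mm from the root *surface*;
* pore connectivity is the Γ-indicator: the percentage of pore volume in
  the largest 26-connected pore cluster of the analysed window;
* "middle 100 slices" means z in [z//2 - 50, z//2 + 50).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from rhizoct.volume_io import LabelVolume, PORE, ROOT

__all__ = [
    "GeometryError",
    "NoRootError",
    "ShellProfile",
    "distance_from_root",
    "shell_masks",
    "porosity",
    "shell_profile",
    "RhizosheathDetection",
    "detect_rhizosheath",
    "extract_regions",
    "unplanted_core",
    "ConnectivityResult",
    "pore_connectivity",
]

DEFAULT_BAND_EDGES = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)


class GeometryError(ValueError):
    pass


class NoRootError(GeometryError):
    """Raised for rooted-only operations on an unplanted volume."""


@dataclass
class ShellProfile:
    """Porosity per half-open distance band from the root surface."""

    band_edges: tuple[float, ...]
    porosity_pct: np.ndarray
    pore_counts: np.ndarray
    total_counts: np.ndarray
    sample_id: str = ""

    @property
    def band_labels(self) -> list[str]:
        e = self.band_edges
        return [f"{e[i]:g}-{e[i + 1]:g}mm" for i in range(len(e) - 1)]


def distance_from_root(labels: LabelVolume) -> np.ndarray:
    """Euclidean distance (µm) from each voxel to the nearest root voxel.

    Root voxels have distance 0. Raises :class:`NoRootError` on an
    unplanted volume — use :func:`unplanted_core` for those.
    """
    root = labels.mask(ROOT)
    if not root.any():
        raise NoRootError("no root voxels: use unplanted_core() for unplanted volumes")
    return ndimage.distance_transform_edt(~root, sampling=labels.voxel_size)


def shell_masks(distance_um: np.ndarray, band_edges: tuple[float, ...] = DEFAULT_BAND_EDGES) -> list[np.ndarray]:
    """Per-band soil masks for half-open [lo, hi) mm distance bands.

    Root voxels (distance 0) are excluded; the masks partition the soil
    volume out to the outermost edge.
    """
    edges = tuple(float(e) for e in band_edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise GeometryError(f"band edges must be strictly ascending, got {band_edges}")
    masks = []
    for lo, hi in zip(edges, edges[1:]):
        m = (distance_um >= lo * 1000.0) & (distance_um < hi * 1000.0)
        if lo == 0.0:
            m &= distance_um > 0  # exclude the root itself
        masks.append(m)
    return masks


def porosity(region_mask: np.ndarray, labels: LabelVolume) -> float:
    """Percent pore voxels among non-root voxels of a region."""
    non_root = region_mask & ~labels.mask(ROOT)
    total = int(non_root.sum())
    if total == 0:
        raise GeometryError("region contains no non-root voxels")
    pore = int((labels.data[non_root] == PORE).sum())
    return 100.0 * pore / total


def shell_profile(
    labels: LabelVolume,
    band_edges: tuple[float, ...] = DEFAULT_BAND_EDGES,
    sample_id: str = "",
    distance_um: np.ndarray | None = None,
) -> ShellProfile:
    """Porosity profile over distance shells around the root."""
    if distance_um is None:
        distance_um = distance_from_root(labels)
    masks = shell_masks(distance_um, band_edges)
    pore = labels.mask(PORE)
    pore_counts, total_counts, pct = [], [], []
    for m in masks:
        total = int(m.sum())
        if total == 0:
            raise GeometryError(
                f"empty distance band within edges {band_edges}: volume too small for the outer shells"
            )
        p = int((pore & m).sum())
        pore_counts.append(p)
        total_counts.append(total)
        pct.append(100.0 * p / total)
    return ShellProfile(
        band_edges=tuple(float(e) for e in band_edges),
        porosity_pct=np.array(pct),
        pore_counts=np.array(pore_counts),
        total_counts=np.array(total_counts),
        sample_id=sample_id,
    )


@dataclass
class RhizosheathDetection:
    boundary_mm: float
    status: str
    anova: pd.DataFrame
    pairwise: pd.DataFrame
    band_means: pd.Series = field(default_factory=pd.Series)


def detect_rhizosheath(profiles: list[ShellProfile], alpha: float = 0.05) -> RhizosheathDetection:
    """Locate the rhizosheath boundary from replicate porosity profiles.

    One-way ANOVA of band porosity (one observation per replicate per band
    — voxels are not independent) followed by Tukey HSD. The rhizosheath is
    the maximal prefix of bands such that every band inside the prefix has
    significantly higher porosity than every band beyond it; the boundary
    is that prefix's outer edge in mm, 0 when no band is elevated.
    """
    from rhizoct.stats import one_way_anova, tukey_hsd  # local import to avoid a cycle

    if len(profiles) < 3:
        raise GeometryError(f"rhizosheath detection needs >= 3 replicate profiles, got {len(profiles)}")
    edges = profiles[0].band_edges
    for p in profiles[1:]:
        if p.band_edges != edges:
            raise GeometryError("replicate profiles use different band edges")

    long = pd.DataFrame(
        [
            (p.sample_id or f"rep{i}", band, float(val))
            for i, p in enumerate(profiles)
            for band, val in zip(p.band_labels, p.porosity_pct)
        ],
        columns=["sample_id", "band", "porosity_pct"],
    )
    anova = one_way_anova(long, "porosity_pct", "band")
    tukey = tukey_hsd(long, "porosity_pct", "band", alpha=alpha)
    pairwise = tukey.pairwise

    band_labels = profiles[0].band_labels
    means = long.groupby("band")["porosity_pct"].mean().reindex(band_labels)

    def significantly_higher(i: int, j: int) -> bool:
        a, b = band_labels[i], band_labels[j]
        row = pairwise[((pairwise.group1 == a) & (pairwise.group2 == b)) | ((pairwise.group1 == b) & (pairwise.group2 == a))]
        if row.empty:
            return False
        return bool(row.iloc[0]["reject"]) and means[a] > means[b]

    # maximal prefix: largest k with every band i<k significantly above every
    # band j>=k (bands inside the prefix need not differ from each other)
    n_bands = len(band_labels)
    boundary_idx = 0
    for k in range(1, n_bands):
        if all(significantly_higher(i, j) for i in range(k) for j in range(k, n_bands)):
            boundary_idx = k
    boundary_mm = float(edges[boundary_idx])
    status = "ok" if boundary_idx > 0 else "no rhizosheath detected"
    return RhizosheathDetection(
        boundary_mm=boundary_mm,
        status=status,
        anova=anova.table,
        pairwise=pairwise,
        band_means=means,
    )


def extract_regions(
    labels: LabelVolume, distance_um: np.ndarray, boundary_mm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rhizosheath (0..boundary) and bulk (boundary..2*boundary) masks."""
    if not boundary_mm > 0:
        raise GeometryError("boundary must be > 0 mm (no rhizosheath detected?)")
    rhizo, bulk = shell_masks(distance_um, (0.0, boundary_mm, 2.0 * boundary_mm))
    return rhizo, bulk


def unplanted_core(labels: LabelVolume, thickness_mm: float = 1.0, shape: str = "slab") -> np.ndarray:
    """Central 1 mm core of an unplanted stack.

    ``shape="slab"``: a full-width slab of floor(thickness/voxel) slices
    centred at mid-z. ``shape="cylinder"``: a vertical cylinder of diameter
    ``thickness_mm`` about the stack centre, full z extent.
    """
    if labels.mask(ROOT).any():
        raise GeometryError("unplanted_core requires a volume without root voxels")
    nz, ny, nx = labels.shape
    thickness_vox = int(np.floor(thickness_mm * 1000.0 / labels.voxel_size))
    if thickness_vox < 1:
        raise GeometryError(f"volume resolution too coarse for a {thickness_mm} mm core")
    mask = np.zeros(labels.shape, dtype=bool)
    if shape == "slab":
        if nz < thickness_vox:
            raise GeometryError(f"stack of {nz} slices thinner than {thickness_mm} mm ({thickness_vox} slices)")
        z0 = nz // 2 - thickness_vox // 2
        mask[z0:z0 + thickness_vox] = True
    elif shape == "cylinder":
        r_vox = thickness_vox / 2.0
        if min(ny, nx) < thickness_vox:
            raise GeometryError(f"lateral extent smaller than {thickness_mm} mm cylinder")
        yy, xx = np.meshgrid(np.arange(ny) - (ny - 1) / 2.0, np.arange(nx) - (nx - 1) / 2.0, indexing="ij")
        mask[:, yy**2 + xx**2 <= r_vox**2] = True
    else:
        raise GeometryError(f"unknown core shape {shape!r}")
    return mask


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ConnectivityResult:
    connectivity_pct: float
    n_components: int
    largest_voxels: int
    total_pore_voxels: int
    component_labels: np.ndarray | None = None


def middle_slices_window(nz: int, n_slices: int = 100) -> slice:
    """z-window of the middle ``n_slices`` slices; whole stack if shorter."""
    if nz < n_slices:
        warnings.warn(
            f"stack of {nz} slices shorter than the {n_slices}-slice window: using the whole stack",
            stacklevel=2,
        )
        return slice(0, nz)
    mid = nz // 2
    return slice(mid - n_slices // 2, mid + n_slices // 2)


def pore_connectivity(
    labels: LabelVolume | np.ndarray,
    region_mask: np.ndarray | None = None,
    window: str | slice | None = "middle100",
    connectivity: int = 26,
    keep_component_labels: bool = False,
) -> ConnectivityResult:
    """Γ-indicator pore connectivity of a (windowed) region, in percent.

    Connected-component labelling of pore voxels inside region ∩ window;
    connectivity = 100 × (largest component volume) / (total pore volume in
    the window region). 26-connectivity by default, 6 available.
    """
    if connectivity not in _STRUCTURES:
        raise GeometryError(f"connectivity must be 6 or 26, got {connectivity}")
    pore = labels.mask(PORE) if isinstance(labels, LabelVolume) else np.asarray(labels, dtype=bool)
    sel = pore.copy()
    if region_mask is not None:
        sel &= region_mask
    if window == "middle100":
        zwin = middle_slices_window(sel.shape[0])
    elif isinstance(window, slice):
        zwin = window
    elif window is None:
        zwin = slice(0, sel.shape[0])
    else:
        raise GeometryError(f"unknown window {window!r}")
    windowed = np.zeros_like(sel)
    windowed[zwin] = sel[zwin]

    total = int(windowed.sum())
    if total == 0:
        raise GeometryError("no pore voxels in the analysed window region")
    comp, n = ndimage.label(windowed, structure=_STRUCTURES[connectivity])
    sizes = np.bincount(comp.ravel())[1:]
    largest = int(sizes.max())
    return ConnectivityResult(
        connectivity_pct=100.0 * largest / total,
        n_components=int(n),
        largest_voxels=largest,
        total_pore_voxels=total,
        component_labels=comp if keep_component_labels else None,
    )
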