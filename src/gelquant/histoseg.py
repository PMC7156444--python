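"""Stain deconvolution and segmentation of stained hydrogel sections.

Bright-field colour is modelled with the Beer-Lambert law: per-pixel optical
density OD = -log10((I + 1) / 256) is additive over stains, so a pixel's OD
vector is the stain-concentration-weighted sum of fixed unit stain vectors
(hematoxylin with either eosin or DAB).  Unmixing is a per-pixel least-squares
projection onto the chosen stain pair with negative concentrations clipped to
zero.

Segmentation proceeds in three steps.  The solid-vs-hollow split thresholds
total OD with Otsu's method (hollow gel regions transmit nearly all light and
sit at OD ~ 0).  Nuclei are connected components of nuclear OD (hematoxylin,
plus DAB for IHC stains) above a fixed threshold, split by a watershed on the
smoothed distance transform.  Cell clusters are connected components of the
morphological closing of the nucleus union, restricted to solid gel.

Pore masks from SEM-like images are summarised by distribution statistics
(median, interquartile range, Fisher skewness) rather than a mean pore size,
because hydrogel pore areas are strongly right-skewed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi
from scipy import stats as sps
from skimage import measure, morphology
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .morphometry import ClusterRecord

__all__ = [
    "STAIN_VECTORS",
    "STAIN_PAIRS",
    "SectionImage",
    "ODChannels",
    "PoreStats",
    "EmptySectionWarning",
    "NoPoresError",
    "rgb_to_od",
    "od_to_rgb",
    "deconvolve_stains",
    "segment_solid",
    "segment_nuclei",
    "label_clusters",
    "pore_area_stats",
]


class EmptySectionWarning(UserWarning):
    """Raised (as a warning) when an image has no stain contrast at all."""


class NoPoresError(ValueError):
    """A pore mask contains no pore component."""


def _unit(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    return a / np.linalg.norm(a)


# Published-style RGB absorbance vectors (Ruifrok & Johnston convention),
# normalised to unit length.
STAIN_VECTORS: dict[str, np.ndarray] = {
    "hematoxylin": _unit((0.644, 0.717, 0.267)),
    "eosin": _unit((0.093, 0.954, 0.283)),
    "dab": _unit((0.268, 0.570, 0.776)),
}

STAIN_PAIRS: dict[str, tuple[str, str]] = {
    "HE": ("hematoxylin", "eosin"),
    "H-DAB": ("hematoxylin", "dab"),
}

_PAIR_ALIASES = {
    "HE": "HE",
    "H&E": "HE",
    "H-E": "HE",
    "H-DAB": "H-DAB",
    "HDAB": "H-DAB",
    "IHC": "H-DAB",
}


def normalize_stain_pair(stain_pair: str) -> str:
    key = _PAIR_ALIASES.get(str(stain_pair).upper())
    if key is None:
        raise ValueError(f"unknown stain pair {stain_pair!r}; expected one of {sorted(_PAIR_ALIASES)}")
    return key


@dataclass
class SectionImage:
    """An 8-bit RGB section raster with its physical scale (um per pixel)."""

    pixels: np.ndarray
    um_per_px: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected an HxWx3 RGB array, got shape {px.shape}")
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.floating) or px.min() < 0 or px.max() > 255:
                raise ValueError("pixels must be 8-bit intensities in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if not self.um_per_px > 0:
            raise ValueError("um_per_px must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def save(self, path) -> None:
        iio.imwrite(path, self.pixels)

    @classmethod
    def load(cls, path, um_per_px: float) -> "SectionImage":
        px = np.asarray(iio.imread(path))
        if px.ndim == 3 and px.shape[2] == 4:  # drop alpha
            px = px[:, :, :3]
        return cls(px, um_per_px)


@dataclass
class ODChannels:
    """Unmixed optical-density maps for a two-stain image."""

    hematoxylin_od: np.ndarray
    second_stain_od: np.ndarray
    second_stain: str  # "eosin" or "dab"
    um_per_px: float

    def nuclear_od(self) -> np.ndarray:
        """OD attributable to nuclear chromogens: hematoxylin plus DAB if present."""
        if self.second_stain == "dab":
            return self.hematoxylin_od + self.second_stain_od
        return self.hematoxylin_od

    def dab_od(self) -> np.ndarray:
        if self.second_stain == "dab":
            return self.second_stain_od
        return np.zeros_like(self.hematoxylin_od)


def rgb_to_od(pixels: np.ndarray) -> np.ndarray:
    """Per-channel optical density -log10((I + 1) / 256) of an 8-bit image."""
    arr = np.asarray(pixels, dtype=float)
    return -np.log10((arr + 1.0) / 256.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, rounded and clipped to 8-bit intensities."""
    intensity = 256.0 * np.power(10.0, -np.asarray(od, dtype=float)) - 1.0
    return np.clip(np.rint(intensity), 0, 255).astype(np.uint8)


def deconvolve_stains(image: SectionImage, stain_pair: str = "HE") -> ODChannels:
    """Unmix an RGB section into two per-stain OD maps.

    Least-squares projection of each pixel's OD vector onto the two unit
    stain vectors of the requested pair; negative concentrations (noise
    outside the stain plane) are clipped to zero.
    """
    key = normalize_stain_pair(stain_pair)
    names = STAIN_PAIRS[key]
    m = np.stack([STAIN_VECTORS[n] for n in names])  # 2 x 3
    od = rgb_to_od(image.pixels).reshape(-1, 3)
    conc = od @ np.linalg.pinv(m)  # N x 2
    np.clip(conc, 0.0, None, out=conc)
    h, w = image.shape
    return ODChannels(
        hematoxylin_od=conc[:, 0].reshape(h, w),
        second_stain_od=conc[:, 1].reshape(h, w),
        second_stain=names[1],
        um_per_px=image.um_per_px,
    )


def segment_solid(image: SectionImage, min_hole_um2: float = 30.0) -> np.ndarray:
    """Boolean mask of solid gel (stained material), True where solid.

    Hollow pixels are those whose total OD falls below an Otsu threshold on
    the total-OD histogram.  The histogram of a cellular section is trimodal
    (near-white hollow, stained gel, dark nuclei); when Otsu's split lands
    between gel and nuclei instead of between hollow and gel — detectable
    because the lower class is itself clearly stained — Otsu is re-applied
    below the first threshold to find the hollow/gel valley.  Hollow
    components smaller than ``min_hole_um2`` are treated as rasterisation
    debris and absorbed into solid.  A section without any stain contrast
    yields an all-hollow mask and an :class:`EmptySectionWarning`; a
    uniformly stained section (contrast too small for a meaningful split) is
    reported as all solid.
    """
    total_od = rgb_to_od(image.pixels).sum(axis=-1)
    if float(np.ptp(total_od)) < 0.02:
        if float(total_od.mean()) < 0.1:
            warnings.warn("image has no stained material; returning all-hollow mask", EmptySectionWarning)
            return np.zeros(image.shape, dtype=bool)
        return np.ones(image.shape, dtype=bool)
    # Descend the histogram: Otsu on a trimodal/tailed histogram can land
    # between gel and nuclei (or between gel and stain rims); keep
    # re-applying it below the current threshold until the lower class is
    # genuinely near-white.  If no near-white class emerges the section has
    # no hollow regions.
    thr = float(threshold_otsu(total_od))
    for _ in range(4):
        below = total_od[total_od < thr]
        if below.size == 0 or float(below.mean()) <= 0.12 or float(np.ptp(below)) <= 0.02:
            break
        thr = float(threshold_otsu(below))
    else:
        below = total_od[total_od < thr]
    if below.size and float(below.mean()) > 0.12:
        return np.ones(image.shape, dtype=bool)
    hollow = total_od < thr
    lo_mean = float(total_od[hollow].mean()) if hollow.any() else 0.0
    hi_mean = float(total_od[~hollow].mean()) if (~hollow).any() else 0.0
    if hi_mean - lo_mean < 0.12:
        # No genuine hollow/solid bimodality: Otsu split is inside one mode.
        if hi_mean < 0.1:
            warnings.warn("image has no stained material; returning all-hollow mask", EmptySectionWarning)
            return np.zeros(image.shape, dtype=bool)
        return np.ones(image.shape, dtype=bool)
    min_px = max(1, int(round(min_hole_um2 / image.um_per_px**2)))
    lab = measure.label(hollow, connectivity=2)
    if lab.max():
        sizes = np.bincount(lab.ravel())
        hollow = (sizes >= min_px)[lab] & (lab > 0)
    return ~hollow


def segment_nuclei(
    od: ODChannels,
    od_threshold: float = 0.15,
    min_nucleus_um2: float = 5.0,
    typical_nucleus_um2: float = 14.0,
) -> np.ndarray:
    """Label image of nuclei from the nuclear OD map.

    Candidate pixels exceed ``od_threshold`` in nuclear OD (hematoxylin, plus
    DAB for H-DAB stains).  Touching nuclei are split by a watershed seeded at
    the peaks of the Gaussian-smoothed distance transform; the minimum peak
    separation is the radius of a typical nucleus.  Components smaller than
    ``min_nucleus_um2`` are discarded and labels are renumbered from 1.
    """
    nuclear = od.nuclear_od()
    mask = nuclear > od_threshold
    labels_out = np.zeros(mask.shape, dtype=np.int32)
    if not mask.any():
        return labels_out
    um2 = od.um_per_px**2
    r_px = math.sqrt(typical_nucleus_um2 / math.pi) / od.um_per_px
    dist = ndi.distance_transform_edt(mask)
    # light smoothing only: heavier blur flattens the distance peaks of
    # karyorrhectic fragments attached to a nucleus, and they would lose
    # their watershed marker entirely
    dist_s = ndi.gaussian_filter(dist, sigma=0.6)
    cc = measure.label(mask, connectivity=2)
    coords = peak_local_max(
        dist_s,
        min_distance=max(2, int(round(r_px))),
        labels=cc,
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    # min_distance can suppress every peak of a small component near a
    # taller neighbour; such components would be lost, so seed them at
    # their distance maximum
    seeded = np.zeros(int(cc.max()) + 1, dtype=bool)
    seeded[cc[markers > 0]] = True
    missing = np.nonzero(~seeded[1:])[0] + 1
    if missing.size:
        next_id = int(markers.max()) + 1
        for my, mx in ndi.maximum_position(dist_s, labels=cc, index=missing):
            markers[my, mx] = next_id
            next_id += 1
    labels = watershed(-dist_s, markers, mask=mask)
    min_px = max(1, int(round(min_nucleus_um2 / um2)))
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[counts >= min_px]
    remap = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    labels_out = remap[labels]
    return labels_out


def label_clusters(
    solid_mask: np.ndarray,
    nucleus_labels: np.ndarray,
    um_per_px: float,
    min_cluster_um2: float = 20.0,
    closing_radius_um: float | None = None,
    min_member_nucleus_um2: float = 5.0,
) -> tuple[np.ndarray, list[ClusterRecord]]:
    """Group nuclei into cell clusters.

    Clusters are connected components of the morphological closing (disk of
    radius one typical nucleus diameter) of the nucleus-pixel union,
    intersected with the solid mask.  A component is retained when it
    contains at least one full nucleus (label area >=
    ``min_member_nucleus_um2``); a single isolated cell therefore counts as
    a cluster even below ``min_cluster_um2``, which only gates components
    whose nuclear material is all sub-nuclear fragments.  Returns the
    cluster label image (contiguous labels from 1) and one
    :class:`~gelquant.morphometry.ClusterRecord` per cluster, flagged when
    the component touches the image border.
    """
    solid = np.asarray(solid_mask, dtype=bool)
    nuc_labels = np.asarray(nucleus_labels)
    if solid.shape != nuc_labels.shape:
        raise ValueError("solid mask and nucleus labels must be congruent")
    um2 = float(um_per_px) ** 2
    if closing_radius_um is None:
        closing_radius_um = 2.0 * math.sqrt(14.0 / math.pi)  # one typical nucleus diameter
    r_px = max(1, int(round(closing_radius_um / um_per_px)))
    nuc = nuc_labels > 0
    closed = ndi.binary_closing(nuc, structure=morphology.disk(r_px))
    closed |= nuc
    closed &= solid
    lab = measure.label(closed, connectivity=2)
    if lab.max() == 0:
        return np.zeros(solid.shape, dtype=np.int32), []

    # nucleus membership: assign each nucleus to the cluster under its
    # centroid; full nuclei and sub-nuclear fragments are tallied separately
    full_by_comp: dict[int, int] = {}
    frag_by_comp: dict[int, int] = {}
    for p in measure.regionprops(nuc_labels):
        cy, cx = p.centroid
        comp = int(lab[int(round(cy)), int(round(cx))])
        if comp <= 0:
            continue
        if p.area * um2 >= min_member_nucleus_um2:
            full_by_comp[comp] = full_by_comp.get(comp, 0) + 1
        else:
            frag_by_comp[comp] = frag_by_comp.get(comp, 0) + 1

    h, w = lab.shape
    records: list[ClusterRecord] = []
    remap = np.zeros(int(lab.max()) + 1, dtype=np.int32)
    next_id = 1
    for p in measure.regionprops(lab):
        n_nuc = full_by_comp.get(p.label, 0)
        n_frag = frag_by_comp.get(p.label, 0)
        area_um2 = p.area * um2
        if n_nuc < 1 and (n_frag < 1 or area_um2 < min_cluster_um2):
            continue
        minr, minc, maxr, maxc = p.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        cy, cx = p.centroid
        remap[p.label] = next_id
        records.append(
            ClusterRecord(
                id=next_id,
                area_um2=float(area_um2),
                nucleus_count=max(1, n_nuc),
                touches_border=bool(touches),
                centroid_xy_px=(float(cx), float(cy)),
            )
        )
        next_id += 1
    return remap[lab], records


@dataclass(frozen=True)
class PoreStats:
    """Distribution summary of pore areas in a binary pore mask."""

    median_um2: float
    iqr_um2: float
    skewness: float
    n_pores: int
    areas_um2: np.ndarray | None = None


def pore_area_stats(mask: np.ndarray, um_per_px: float) -> PoreStats:
    """Median, IQR (q75 - q25) and Fisher skewness of pore areas.

    Pores are 8-connected components of the binary mask; areas are pixel
    counts times ``um_per_px**2``.  Quantiles use linear interpolation.  With
    a single pore the IQR is 0 and the skewness is reported as 0.
    """
    arr = np.asarray(mask)
    binary = arr > 0
    lab = measure.label(binary, connectivity=2)
    n = int(lab.max())
    if n == 0:
        raise NoPoresError("pore mask contains no pore component")
    areas = np.bincount(lab.ravel())[1:].astype(float) * float(um_per_px) ** 2
    median = float(np.median(areas))
    q25, q75 = np.percentile(areas, [25.0, 75.0])
    if n >= 3 and float(np.var(areas)) > 0:
        skewness = float(sps.skew(areas))
    else:
        skewness = 0.0
    return PoreStats(
        median_um2=median,
        iqr_um2=float(q75 - q25),
        skewness=skewness,
        n_pores=n,
        areas_um2=areas,
    )
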