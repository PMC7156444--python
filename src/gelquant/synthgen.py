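"""Seeded synthetic inputs with exact ground truth.

Three generators emulate the raw data of a bioprinted-hydrogel study:

* :func:`generate_section` renders a stained paraffin-section image (H&E or
  hematoxylin+DAB) with a controlled hollow-area fraction, cell clusters in
  the three size classes, and elliptical nuclei carrying known intensity
  classes and phases (interphase / mitotic / karyorrhectic);
* :func:`generate_pore_mask` draws a binary SEM-like pore mask whose pore
  areas are lognormal (right-skewed, as hydrogel pore areas are);
* :func:`generate_stress_strain` samples a near-linear compression curve
  stress = E*strain + toe*strain^3 + noise with a known modulus.

Every generator is a pure function of its parameter record (including the
seed) and returns a :class:`TruthBundle` with the exact per-object labels,
so downstream measurements can be tested for recovery.

Rendering uses the same Beer-Lambert stain-mixing model that
:mod:`gelquant.histoseg` inverts: per-stain optical densities are painted,
mixed through fixed unit stain vectors, lightly blurred and noised, and
exponentiated to 8-bit RGB.  The per-class DAB densities are chosen to sit
at the centres of the default intensity-calling bins so the generator's own
stain-separability contract (strong > moderate > weak > negative) holds at
the default noise level.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .histoseg import STAIN_VECTORS, SectionImage, od_to_rgb
from .morphometry import classify_cluster_size

__all__ = [
    "SectionParams",
    "CurveParams",
    "TruthBundle",
    "InfeasibleLayoutError",
    "CONDITION_PRESETS",
    "generate_section",
    "generate_pore_mask",
    "generate_stress_strain",
    "intensity_mix_for_mean_weight",
    "section_params_for_condition",
]


class InfeasibleLayoutError(RuntimeError):
    """The requested layout cannot be placed in the available area."""


# ---------------------------------------------------------------------------
# rendering constants (optical densities, dimensionless)

GEL_EOSIN_OD = 0.25        # eosin-pink solid gel in H&E
GEL_HEMA_OD_HE = 0.02
GEL_HEMA_OD_IHC = 0.10     # faint hematoxylin counterstain in IHC, kept
                           # several noise sd below the nuclear OD threshold
NUCLEUS_HEMA_OD = 0.75     # negative (blue) nucleus
POSITIVE_HEMA_OD = 0.18    # residual counterstain under DAB
MITOSIS_HEMA_OD = 1.15     # condensed chromatin
NEGATIVE_DAB_OD = 0.02
DAB_OD_BY_CLASS = {"weak": 0.30, "moderate": 0.57, "strong": 0.92}
FRAGMENT_OD_BOOST = 1.25   # condensed karyorrhectic chromatin stains denser
NUCLEUS_EOSIN_OD = 0.05
RENDER_BLUR_SIGMA_PX = 0.6
RENDER_NOISE_SD = 0.012
TEXTURE_AMP = 0.06         # low-frequency multiplicative gel texture
NUCLEUS_MEAN_AREA_UM2 = 14.0
NUCLEUS_SD_AREA_UM2 = 2.5

# per-class target-area sampling ranges (um^2), kept away from the class
# boundaries so rasterisation cannot flip the class
_CLASS_AREA_RANGES = {
    "small": (120.0, 370.0),
    "medium": (450.0, 1900.0),
    "large": (2100.0, 4800.0),
}
_CLASS_MEAN_AREA = {c: (lo + hi) / 2 for c, (lo, hi) in _CLASS_AREA_RANGES.items()}

# minimum clearance between clusters (um).  Bridging during segmentation
# happens between nucleus unions, which sit a further ~2 erosion margins
# inside their clusters, so this plus the interior margins stays above the
# cluster-closing diameter.
_CLUSTER_GAP_UM = 8.0


@dataclass(frozen=True)
class SectionParams:
    """Layout and staining parameters of one synthetic section.

    ``nuclei_density_in_cluster`` is nuclei per 1000 um^2 of cluster area;
    the default of 25 corresponds to ~40 um^2 of cluster per cell, which
    makes the size-class areas and their nominal cell counts (<10, 10-50,
    >50) mutually consistent.  ``phase_rates`` is (mitosis, karyorrhexis);
    the defaults are the across-condition hydrogel means (1.4% and 28.8%).
    """

    width_px: int = 512
    height_px: int = 512
    um_per_px: float = 0.5
    target_porosity: float = 0.15
    clusters_per_class: tuple[int, int, int] = (5, 3, 2)
    nuclei_density_in_cluster: float = 25.0
    stain_mode: str = "HE"
    positive_fraction: float = 0.0
    intensity_mix: tuple[float, float, float] = (0.25, 0.5, 0.25)
    phase_rates: tuple[float, float] = (0.014, 0.288)
    nucleus_spacing_um: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 32 or self.height_px < 32:
            raise ValueError("section must be at least 32x32 px")
        if not self.um_per_px > 0:
            raise ValueError("um_per_px must be > 0")
        if not 0.0 <= self.target_porosity <= 1.0:
            raise ValueError("target_porosity must be in [0, 1]")
        if len(self.clusters_per_class) != 3 or any(c < 0 for c in self.clusters_per_class):
            raise ValueError("clusters_per_class must be three non-negative counts")
        if not self.nuclei_density_in_cluster > 0:
            raise ValueError("nuclei_density_in_cluster must be > 0")
        if self.stain_mode not in ("HE", "IHC"):
            raise ValueError("stain_mode must be 'HE' or 'IHC'")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        if abs(sum(self.intensity_mix) - 1.0) > 1e-9:
            raise ValueError("intensity_mix must sum to 1")
        if any(f < 0 for f in self.intensity_mix):
            raise ValueError("intensity_mix fractions must be >= 0")
        if any(r < 0 for r in self.phase_rates) or sum(self.phase_rates) > 1.0:
            raise ValueError("phase_rates must be non-negative and sum to <= 1")
        frame_um2 = self.width_px * self.height_px * self.um_per_px**2
        intended_occ = (
            sum(n * _CLASS_MEAN_AREA[c] for n, c in zip(self.clusters_per_class, ("small", "medium", "large")))
            / frame_um2
        )
        if self.target_porosity + intended_occ > 1.0:
            raise InfeasibleLayoutError(
                f"target porosity {self.target_porosity:.2f} plus intended cluster occupancy "
                f"{intended_occ:.2f} exceeds the section area"
            )


@dataclass(frozen=True)
class CurveParams:
    """Parameters of one synthetic compression curve."""

    E_true_kpa: float = 1.0
    max_strain: float = 0.5
    # a 50% ramp at 20%/min lasts 150 s; at a couple of samples per second
    # that is a few hundred points
    n_points: int = 300
    toe_coeff: float = 0.0
    noise_sd_kpa: float | None = None  # None -> 1% of nominal peak stress
    preload_mn: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.E_true_kpa > 0:
            raise ValueError("E_true_kpa must be > 0")
        if not 0 < self.max_strain <= 0.5:
            raise ValueError("max_strain must be in (0, 0.5] (50% compression protocol)")
        if self.n_points < 20:
            raise ValueError("n_points must be >= 20")
        if self.noise_sd_kpa is not None and self.noise_sd_kpa < 0:
            raise ValueError("noise_sd_kpa must be >= 0")


@dataclass
class TruthBundle:
    """Exact ground truth emitted alongside every generated artifact."""

    true_porosity: float | None = None
    clusters: pd.DataFrame | None = None
    nuclei: pd.DataFrame | None = None
    pore_areas_um2: np.ndarray | None = None
    E_true_kpa: float | None = None
    hollow_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.clusters is not None and self.nuclei is not None and len(self.nuclei):
            known = set(self.clusters["id"])
            if not set(self.nuclei["cluster_id"]).issubset(known):
                raise ValueError("every nucleus must reference an existing cluster id")
        for df, col in ((self.clusters, "area_um2"), (self.nuclei, "area_um2")):
            if df is not None and len(df) and not (df[col] > 0).all():
                raise ValueError("truth areas must be positive")

    def to_json(self) -> str:
        payload: dict = {}
        if self.true_porosity is not None:
            payload["true_porosity"] = self.true_porosity
        if self.E_true_kpa is not None:
            payload["E_true_kpa"] = self.E_true_kpa
        if self.pore_areas_um2 is not None:
            payload["pore_areas_um2"] = [float(a) for a in self.pore_areas_um2]
        if self.clusters is not None:
            payload["clusters"] = self.clusters.to_dict(orient="records")
        if self.nuclei is not None:
            payload["nuclei"] = self.nuclei.to_dict(orient="records")
        return json.dumps(payload, indent=1)

    def write(self, outdir, stem: str) -> None:
        """Serialise to JSON (and CSV tables) under ``outdir``."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"{stem}_truth.json").write_text(self.to_json())
        if self.clusters is not None:
            self.clusters.to_csv(out / f"{stem}_clusters.csv", index=False)
        if self.nuclei is not None:
            self.nuclei.to_csv(out / f"{stem}_nuclei.csv", index=False)


# ---------------------------------------------------------------------------
# section generation helpers


def _place_hollow(
    rng: np.random.Generator,
    shape: tuple[int, int],
    target: float,
    dist_clusters: np.ndarray | None = None,
    clearance_px: float = 3.0,
) -> np.ndarray:
    """Boolean hollow mask whose pixel fraction is within ~0.2 pp of target.

    Hollow blobs keep ``clearance_px`` away from already-placed clusters
    (``dist_clusters`` is the distance to the nearest cluster pixel).
    """
    h, w = shape
    hollow = np.zeros(shape, dtype=bool)
    if target <= 0:
        return hollow
    total = h * w
    yy, xx = np.ogrid[:h, :w]
    guard = 0
    while hollow.sum() / total < target - 0.002:
        guard += 1
        if guard > 20000:
            raise InfeasibleLayoutError("could not reach the target porosity around the clusters")
        deficit_px = (target - hollow.sum() / total) * total
        r = math.sqrt(deficit_px / math.pi)
        r = float(np.clip(r, 3.0, min(14.0, h / 4, w / 4)))
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        if dist_clusters is not None:
            iy = min(h - 1, max(0, int(round(cy))))
            ix = min(w - 1, max(0, int(round(cx))))
            if dist_clusters[iy, ix] <= r + clearance_px:
                continue
        hollow |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return hollow


def _cluster_patch(rng: np.random.Generator, area_px: float) -> np.ndarray:
    """Bool patch: union of overlapping disks with ~``area_px`` pixels."""
    n_lobes = int(rng.integers(2, 6))
    angles = rng.uniform(0, 2 * math.pi, n_lobes)
    offs = rng.uniform(0.35, 0.85, n_lobes)
    lobe_r = rng.uniform(0.45, 0.8, n_lobes)
    centers = [(0.0, 0.0)] + [(u * math.sin(a), u * math.cos(a)) for u, a in zip(offs, angles)]
    radii = [1.0] + list(lobe_r)

    r0 = math.sqrt(area_px / (math.pi * 1.35))
    patch = None
    for _ in range(4):
        extent = int(math.ceil(max(abs(c) + r for (cy, cx), r in zip(centers, radii) for c in (cy, cx)) * r0)) + 2
        yy, xx = np.ogrid[-extent : extent + 1, -extent : extent + 1]
        patch = np.zeros((2 * extent + 1, 2 * extent + 1), dtype=bool)
        for (cy, cx), r in zip(centers, radii):
            patch |= (yy - cy * r0) ** 2 + (xx - cx * r0) ** 2 <= (r * r0) ** 2
        area = patch.sum()
        if abs(area - area_px) / area_px < 0.02:
            break
        r0 *= math.sqrt(area_px / area)
    # trim to bounding box
    rows = np.any(patch, axis=1)
    cols = np.any(patch, axis=0)
    return patch[np.ix_(rows, cols)]


def _hex_grid_points(bbox_shape: tuple[int, int], spacing: float, rng: np.random.Generator) -> np.ndarray:
    """Jittered hexagonal grid covering a bounding box, as (y, x) floats."""
    h, w = bbox_shape
    dy = spacing * math.sqrt(3) / 2
    pts = []
    row = 0
    y = spacing / 2
    while y < h:
        x0 = spacing / 2 + (spacing / 2 if row % 2 else 0.0)
        x = x0
        while x < w:
            pts.append((y, x))
            x += spacing
        y += dy
        row += 1
    pts = np.asarray(pts, dtype=float)
    if len(pts):
        pts += rng.uniform(-0.12 * spacing, 0.12 * spacing, size=pts.shape)
    return pts


def _ellipse_pixels(shape, cy, cx, a_px, b_px, theta):
    """Pixel coordinates of a filled rotated ellipse clipped to ``shape``."""
    h, w = shape
    ext = int(math.ceil(max(a_px, b_px))) + 1
    y0, y1 = max(0, int(cy) - ext), min(h, int(cy) + ext + 1)
    x0, x1 = max(0, int(cx) - ext), min(w, int(cx) + ext + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = yy - cy
    dx = xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    return yy[inside], xx[inside]


def intensity_mix_for_mean_weight(mu: float) -> tuple[float, float, float]:
    """Weak/moderate/strong mix with mean H-score weight ``mu`` in [1, 3].

    Uses the binomial parametrisation (1-t)^2, 2t(1-t), t^2 with
    t = (mu - 1) / 2, whose mean weight is exactly 1 + 2t = mu.
    """
    if not 1.0 <= mu <= 3.0:
        raise ValueError("mean intensity weight must be in [1, 3]")
    t = (mu - 1.0) / 2.0
    return ((1 - t) ** 2, 2 * t * (1 - t), t**2)


def generate_section(params: SectionParams) -> tuple[SectionImage, TruthBundle]:
    """Render a stained section and its exact truth tables.

    Hollow regions render near-white; solid gel renders eosin-pink (H&E) or
    as faint counterstain (IHC); nuclei render hematoxylin-blue (negative) or
    DAB-brown (positive, with per-class optical density).  Mitotic nuclei are
    condensed and elongated with elevated hematoxylin; karyorrhectic nuclei
    are 3-6 small fragments scattered in a halo around the parent position.
    Identical parameters (including the seed) give bit-identical output.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    h, w = p.height_px, p.width_px
    um = p.um_per_px
    um2 = um * um

    # clusters are laid out first; hollow blobs then fill the remaining gel
    cluster_gap_px = _CLUSTER_GAP_UM / um
    margin = 3

    cluster_mask = np.zeros((h, w), dtype=bool)
    dist_clusters = np.full((h, w), max(h, w), dtype=float)

    cluster_rows = []
    placed = []  # (cluster_id, patch slices, patch)
    cid = 0
    class_order = [("large", p.clusters_per_class[2]), ("medium", p.clusters_per_class[1]), ("small", p.clusters_per_class[0])]
    for cls, count in class_order:
        lo, hi = _CLASS_AREA_RANGES[cls]
        for _ in range(count):
            ok = False
            for _attempt in range(60):
                target_um2 = rng.uniform(lo, hi)
                patch = _cluster_patch(rng, target_um2 / um2)
                ph, pw = patch.shape
                if ph + 2 * margin >= h or pw + 2 * margin >= w:
                    continue
                for _try in range(250):
                    y0 = int(rng.integers(margin, h - ph - margin))
                    x0 = int(rng.integers(margin, w - pw - margin))
                    sl = (slice(y0, y0 + ph), slice(x0, x0 + pw))
                    if dist_clusters[sl][patch].min() <= cluster_gap_px:
                        continue
                    area_um2 = float(patch.sum() * um2)
                    if classify_cluster_size(area_um2) != cls:
                        break  # resample the target area
                    cid += 1
                    cluster_mask[sl] |= patch
                    dist_clusters = ndi.distance_transform_edt(~cluster_mask)
                    ys, xs = np.nonzero(patch)
                    cluster_rows.append(
                        dict(
                            id=cid,
                            area_um2=area_um2,
                            size_class=cls,
                            nucleus_count=0,
                            cx_px=float(xs.mean() + x0),
                            cy_px=float(ys.mean() + y0),
                        )
                    )
                    placed.append((cid, sl, patch))
                    ok = True
                    break
                if ok:
                    break
            if not ok:
                raise InfeasibleLayoutError(
                    f"could not place a {cls} cluster without violating cluster spacing"
                )

    dist_to_clusters = (
        ndi.distance_transform_edt(~cluster_mask) if cluster_mask.any() else None
    )
    hollow = _place_hollow(rng, (h, w), p.target_porosity, dist_to_clusters)

    # --- nuclei -----------------------------------------------------------
    mean_r_px = math.sqrt(NUCLEUS_MEAN_AREA_UM2 / math.pi) / um
    if p.nucleus_spacing_um is not None:
        spacing_px = p.nucleus_spacing_um / um
    else:
        spacing_px = math.sqrt(1000.0 / p.nuclei_density_in_cluster) / um
    mit_rate, kar_rate = p.phase_rates

    hema = np.where(hollow, 0.0, GEL_HEMA_OD_HE if p.stain_mode == "HE" else GEL_HEMA_OD_IHC)
    second = np.where(hollow, 0.0, GEL_EOSIN_OD if p.stain_mode == "HE" else 0.0)
    # low-frequency gel texture
    texture = 1.0 + TEXTURE_AMP * ndi.gaussian_filter(rng.standard_normal((h, w)), 20.0) * 20.0
    solid = ~hollow
    hema[solid] *= texture[solid]
    second[solid] *= texture[solid]

    nucleus_rows = []
    nid = 0
    for (cluster_id, sl, patch) in placed:
        area_um2 = patch.sum() * um2
        count = max(1, int(round(area_um2 * p.nuclei_density_in_cluster / 1000.0)))
        erode_iter = int(round(mean_r_px)) + 1
        interior = ndi.binary_erosion(patch, iterations=erode_iter)
        interior2 = ndi.binary_erosion(patch, iterations=2)  # fragment halos may use this band
        if not interior.any():
            interior = ndi.binary_erosion(patch, iterations=max(1, erode_iter // 2))
        if not interior.any():
            interior = patch
        pts = _hex_grid_points(patch.shape, spacing_px, rng)
        if len(pts) == 0:
            pts = np.array([[patch.shape[0] / 2.0, patch.shape[1] / 2.0]])
        iy = np.clip(np.round(pts[:, 0]).astype(int), 0, patch.shape[0] - 1)
        ix = np.clip(np.round(pts[:, 1]).astype(int), 0, patch.shape[1] - 1)
        keep = interior[iy, ix]
        pts = pts[keep]
        order = rng.permutation(len(pts))
        pts = pts[order][:count]
        y_off, x_off = sl[0].start, sl[1].start

        n_placed = 0
        for cy_loc, cx_loc in pts:
            cy, cx = cy_loc + y_off, cx_loc + x_off
            nid += 1
            n_placed += 1
            area_n = float(np.clip(rng.normal(NUCLEUS_MEAN_AREA_UM2, NUCLEUS_SD_AREA_UM2), 8.0, 20.0))
            u = rng.random()
            if u < mit_rate:
                phase = "mitosis"
            elif u < mit_rate + kar_rate:
                phase = "karyorrhexis"
            else:
                phase = "interphase"
            if p.stain_mode == "IHC" and rng.random() < p.positive_fraction:
                icls = ("weak", "moderate", "strong")[rng.choice(3, p=np.asarray(p.intensity_mix) / sum(p.intensity_mix))]
            else:
                icls = "negative"
            jit = rng.uniform(0.93, 1.07)

            if icls == "negative":
                hema_od = (MITOSIS_HEMA_OD if phase == "mitosis" else NUCLEUS_HEMA_OD) * jit
                dab_od = NEGATIVE_DAB_OD
            else:
                hema_od = (MITOSIS_HEMA_OD if phase == "mitosis" else POSITIVE_HEMA_OD) * jit
                dab_od = DAB_OD_BY_CLASS[icls] * jit
            second_od = NUCLEUS_EOSIN_OD if p.stain_mode == "HE" else dab_od

            theta = rng.uniform(0, math.pi)
            area_px = area_n / um2
            if phase == "karyorrhexis":
                # 3-5 small fragments scattered in a compact halo around the
                # parent position, each kept clear of its siblings so the
                # render blur cannot fuse them, and kept inside the cluster
                # so a dying cell's halo never detaches from its cluster
                n_frag = int(rng.integers(3, 6))
                parent_r = math.sqrt(area_px / math.pi)
                frag_spec = [(rng.uniform(0.07, 0.16) * area_px, rng.uniform(1.0, 1.4)) for _ in range(n_frag)]
                placed_frags: list[tuple[float, float, float]] = []  # (y, x, r)
                halo0 = 1.9 * parent_r
                for _round in range(8):
                    halo = halo0 * 0.95**_round
                    clearance = 2.0 if _round < 5 else 1.5
                    placed_frags = []
                    for f_area, _q in frag_spec:
                        fr = math.sqrt(f_area / math.pi)
                        for _try in range(40):
                            ang = rng.uniform(0, 2 * math.pi)
                            rad = rng.uniform(0.30, 0.65) * halo
                            fy, fx = cy + rad * math.sin(ang), cx + rad * math.cos(ang)
                            iy, ix = int(round(fy - y_off)), int(round(fx - x_off))
                            if not (0 <= iy < patch.shape[0] and 0 <= ix < patch.shape[1] and interior2[iy, ix]):
                                continue
                            if all(
                                math.hypot(fy - py, fx - px_) >= fr + pr + clearance
                                for py, px_, pr in placed_frags
                            ):
                                placed_frags.append((fy, fx, fr))
                                break
                    if len(placed_frags) >= 3:
                        break
                total_px = 0
                for (fy, fx, fr), (_f_area, q) in zip(placed_frags, frag_spec):
                    yy2, xx2 = _ellipse_pixels((h, w), fy, fx, fr * math.sqrt(q), fr / math.sqrt(q), rng.uniform(0, math.pi))
                    hema[yy2, xx2] = hema_od * FRAGMENT_OD_BOOST
                    second[yy2, xx2] = second_od * (FRAGMENT_OD_BOOST if p.stain_mode == "IHC" else 1.0)
                    total_px += len(yy2)
                true_area = total_px * um2
            else:
                # blur and thresholding fatten the minor axis, so mitotic
                # figures are rendered more elongated than the detection cutoff
                q = rng.uniform(2.4, 3.0) if phase == "mitosis" else rng.uniform(1.05, 1.45)
                b = math.sqrt(area_px / (math.pi * q))
                a = q * b
                yy2, xx2 = _ellipse_pixels((h, w), cy, cx, a, b, theta)
                hema[yy2, xx2] = hema_od
                second[yy2, xx2] = second_od
                true_area = len(yy2) * um2
            nucleus_rows.append(
                dict(
                    id=nid,
                    cluster_id=cluster_id,
                    area_um2=max(true_area, um2),
                    intensity_class=icls,
                    phase=phase,
                    n_fragments=len(placed_frags) if phase == "karyorrhexis" else 0,
                    cx_px=float(cx),
                    cy_px=float(cy),
                )
            )
        cluster_rows[cluster_id - 1]["nucleus_count"] = n_placed

    # --- render -----------------------------------------------------------
    hema = ndi.gaussian_filter(hema, RENDER_BLUR_SIGMA_PX)
    second = ndi.gaussian_filter(second, RENDER_BLUR_SIGMA_PX)
    hema += rng.normal(0.0, RENDER_NOISE_SD, (h, w))
    second += rng.normal(0.0, RENDER_NOISE_SD, (h, w))
    np.clip(hema, 0.0, None, out=hema)
    np.clip(second, 0.0, None, out=second)

    v_h = STAIN_VECTORS["hematoxylin"]
    v_s = STAIN_VECTORS["eosin" if p.stain_mode == "HE" else "dab"]
    od_rgb = hema[..., None] * v_h + second[..., None] * v_s
    image = SectionImage(od_to_rgb(od_rgb), um)

    clusters_df = pd.DataFrame(
        cluster_rows, columns=["id", "area_um2", "size_class", "nucleus_count", "cx_px", "cy_px"]
    )
    nuclei_df = pd.DataFrame(
        nucleus_rows,
        columns=["id", "cluster_id", "area_um2", "intensity_class", "phase", "n_fragments", "cx_px", "cy_px"],
    )
    truth = TruthBundle(
        true_porosity=float(hollow.sum() / hollow.size),
        clusters=clusters_df,
        nuclei=nuclei_df,
        hollow_mask=hollow,
    )
    return image, truth


def generate_pore_mask(
    n_pores: int,
    lognormal_params: tuple[float, float],
    frame_um2: float,
    seed: int,
    um_per_px: float = 0.5,
) -> tuple[np.ndarray, TruthBundle]:
    """Binary mask of non-overlapping disk pores with lognormal areas.

    Pore areas (um^2) are ``n_pores`` lognormal draws with the given (mu,
    sigma) of log-area; the truth bundle records the exact drawn areas in
    draw order.  Pores are placed largest-first by dart throwing with a
    small clearance; if a pore cannot be placed after bounded retries an
    :class:`InfeasibleLayoutError` is raised.
    """
    if n_pores < 1:
        raise ValueError("n_pores must be >= 1")
    mu, sigma = lognormal_params
    if not sigma > 0:
        raise ValueError("lognormal sigma must be > 0")
    if not frame_um2 > 0:
        raise ValueError("frame_um2 must be > 0")
    rng = np.random.default_rng(seed)
    side = int(math.ceil(math.sqrt(frame_um2) / um_per_px))
    areas = rng.lognormal(mu, sigma, n_pores)
    radii_px = np.sqrt(areas / math.pi) / um_per_px
    if float(np.sum(math.pi * np.maximum(radii_px, 1.0) ** 2)) > 0.45 * side * side:
        raise InfeasibleLayoutError("requested pores cannot fit the frame without overlap")

    mask = np.zeros((side, side), dtype=bool)
    occupied = np.zeros((side, side), dtype=bool)
    yy, xx = np.ogrid[:side, :side]
    for idx in np.argsort(radii_px)[::-1]:
        r = max(float(radii_px[idx]), 1.0)
        placed = False
        for _ in range(2000):
            cy = rng.uniform(r + 1, side - r - 1)
            cx = rng.uniform(r + 1, side - r - 1)
            guard = (yy - cy) ** 2 + (xx - cx) ** 2 <= (r + 1.5) ** 2
            if occupied[guard].any():
                continue
            mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            occupied |= guard
            placed = True
            break
        if not placed:
            raise InfeasibleLayoutError(f"could not place pore of radius {r:.1f} px without overlap")
    truth = TruthBundle(pore_areas_um2=areas)
    return mask, truth


def generate_stress_strain(params: CurveParams):
    """Sample stress = E*strain + toe*strain^3 + N(0, sd) on an even grid."""
    from .mechanics import StressStrainCurve

    p = params
    rng = np.random.default_rng(p.seed)
    strain = np.linspace(0.0, p.max_strain, p.n_points)
    stress = p.E_true_kpa * strain + p.toe_coeff * strain**3
    sd = p.noise_sd_kpa
    if sd is None:
        sd = 0.01 * p.E_true_kpa * p.max_strain
    if sd > 0:
        stress = stress + rng.normal(0.0, sd, p.n_points)
    curve = StressStrainCurve(strain, stress)
    return curve, TruthBundle(E_true_kpa=float(p.E_true_kpa))


# ---------------------------------------------------------------------------
# condition presets: the six stiffness x time study conditions
#
# Magnitudes (porosity, Ki67 positivity and H-score, MKI phase rates, moduli
# in kPa) are the reported condition means of the bioprinted-hydrogel study
# these generators emulate.  They parameterise the synthetic generator; they
# are not recoverable measurements of any real slide.

CONDITION_PRESETS: dict[tuple[str, int], dict] = {
    ("0% AlgMA", 2): dict(porosity=0.149, ki67_positive=0.255, ki67_h_score=47.98,
                          mitosis=0.024, karyorrhexis=0.196, E_acellular=0.28, E_cellular=0.33),
    ("1% AlgMA", 2): dict(porosity=0.041, ki67_positive=0.369, ki67_h_score=77.85,
                          mitosis=0.026, karyorrhexis=0.45, E_acellular=1.11, E_cellular=0.60),
    ("2% AlgMA", 2): dict(porosity=0.019, ki67_positive=0.445, ki67_h_score=89.31,
                          mitosis=0.006, karyorrhexis=0.282, E_acellular=2.43, E_cellular=1.75),
    ("0% AlgMA", 4): dict(porosity=0.238, ki67_positive=0.738, ki67_h_score=200.27,
                          mitosis=0.016, karyorrhexis=0.20, E_acellular=0.28, E_cellular=0.33),
    ("1% AlgMA", 4): dict(porosity=0.203, ki67_positive=0.598, ki67_h_score=163.98,
                          mitosis=0.002, karyorrhexis=0.128, E_acellular=1.11, E_cellular=0.60),
    ("2% AlgMA", 4): dict(porosity=0.126, ki67_positive=0.907, ki67_h_score=253.95,
                          mitosis=0.012, karyorrhexis=0.474, E_acellular=2.43, E_cellular=1.75),
}


def section_params_for_condition(
    stiffness_label: str,
    timepoint_weeks: int,
    seed: int,
    stain_mode: str = "IHC",
    **overrides,
) -> SectionParams:
    """Section parameters emulating one study condition (Ki67-style IHC)."""
    preset = CONDITION_PRESETS[(stiffness_label, int(timepoint_weeks))]
    mu = preset["ki67_h_score"] / (100.0 * preset["ki67_positive"])
    kwargs = dict(
        target_porosity=preset["porosity"],
        stain_mode=stain_mode,
        positive_fraction=preset["ki67_positive"] if stain_mode == "IHC" else 0.0,
        intensity_mix=intensity_mix_for_mean_weight(mu),
        phase_rates=(preset["mitosis"], preset["karyorrhexis"]),
        seed=seed,
    )
    kwargs.update(overrides)
    return SectionParams(**kwargs)
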