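"""IHC scoring and nucleus-phase classification.

A stained nucleus is scored by its mean DAB optical density: below the
positive threshold it is negative (blue, hematoxylin only); positives are
binned into weak / moderate / strong.  Section-level summaries are the
percent of positive cells, the intensity-weighted H-score
``H = 1*p_weak + 2*p_moderate + 3*p_strong`` (percent of all cells at each
level, hence 0-300), and the four-step categorical scale
(- / + / ++ / +++).

The mitosis-karyorrhexis index (MKI) is the percent of cells that are mitotic
or karyorrhectic, classified per the Shimada convention: low (<2%),
intermediate (2-4%, inclusive), high (>4%).  Because pathologist-level phase
calls are not reducible to published image rules, phases are assigned here by
explicit morphological criteria: a karyorrhectic cell is a halo of >= 3 small
nuclear fragments, a mitotic figure is a solid (solidity >= 0.9), elongated
(aspect ratio >= 1.8) nucleus with above-median nuclear OD, and everything
else is interphase.  These criteria are artifact definitions validated only
against the synthetic generator's phenotype encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage import measure

__all__ = [
    "INTENSITY_CLASSES",
    "DEFAULT_INTENSITY_THRESHOLDS",
    "NucleusScore",
    "IHCScore",
    "MKIResult",
    "PhaseCounts",
    "call_intensity",
    "percent_positive",
    "h_score",
    "categorize_positivity",
    "classify_phase",
    "mki",
    "mki_from_percentages",
    "analyze_phases",
    "scores_from_phases",
    "summarize_scores",
    "positivity_by_size_class",
]

INTENSITY_CLASSES = ("negative", "weak", "moderate", "strong")

#: (t_pos, t_mod, t_strong) mean-DAB-OD cutpoints, lower-inclusive.
DEFAULT_INTENSITY_THRESHOLDS = (0.15, 0.40, 0.70)

#: Standard pathology H-score weights for weak/moderate/strong.
DEFAULT_HSCORE_WEIGHTS = {"weak": 1.0, "moderate": 2.0, "strong": 3.0}

PHASES = ("interphase", "mitosis", "karyorrhexis")


@dataclass(frozen=True)
class NucleusScore:
    nucleus_id: int
    mean_dab_od: float
    intensity_class: str
    phase: str = "interphase"
    cluster_id: int = 0

    def __post_init__(self) -> None:
        if self.intensity_class not in INTENSITY_CLASSES:
            raise ValueError(f"unknown intensity class {self.intensity_class!r}")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.mean_dab_od < 0:
            raise ValueError("mean DAB OD must be >= 0")

    @property
    def positive(self) -> bool:
        return self.intensity_class != "negative"


def _check_thresholds(thresholds) -> tuple[float, float, float]:
    t_pos, t_mod, t_strong = (float(t) for t in thresholds)
    if not (0 <= t_pos < t_mod < t_strong):
        raise ValueError(f"intensity thresholds must satisfy 0 <= t_pos < t_mod < t_strong, got {thresholds!r}")
    return t_pos, t_mod, t_strong


def call_intensity(mean_dab_od: float, thresholds=DEFAULT_INTENSITY_THRESHOLDS) -> str:
    """Bin a mean DAB OD into negative/weak/moderate/strong (lower-inclusive)."""
    t_pos, t_mod, t_strong = _check_thresholds(thresholds)
    od = float(mean_dab_od)
    if od < t_pos:
        return "negative"
    if od < t_mod:
        return "weak"
    if od < t_strong:
        return "moderate"
    return "strong"


def percent_positive(scores) -> float:
    """Percent of scored nuclei that are non-negative."""
    scores = list(scores)
    if not scores:
        raise ValueError("cannot compute percent positive of an empty score list")
    return 100.0 * sum(s.positive for s in scores) / len(scores)


def h_score(scores, weights=None) -> float:
    """Intensity-weighted score sum(w_c * pct_c) over positive classes, 0-300."""
    scores = list(scores)
    if not scores:
        raise ValueError("cannot compute H-score of an empty score list")
    if weights is None:
        weights = DEFAULT_HSCORE_WEIGHTS
    n = len(scores)
    total = 0.0
    for cls, w in weights.items():
        pct = 100.0 * sum(s.intensity_class == cls for s in scores) / n
        total += w * pct
    return total


def categorize_positivity(pct_positive: float) -> str:
    """Map percent positive cells to the categorical scale -, +, ++, +++.

    Cutpoints: negative below 1%, low positive 1-20%, intermediate positive
    20-50% (50 inclusive), high positive above 50%.
    """
    pct = float(pct_positive)
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"percent positive must be in [0, 100], got {pct!r}")
    if pct < 1.0:
        return "-"
    if pct < 20.0:
        return "+"
    if pct <= 50.0:
        return "++"
    return "+++"


def classify_phase(
    solidity: float,
    aspect_ratio: float,
    od: float,
    od_median: float,
    fragments_in_halo: int = 0,
    solidity_min: float = 0.9,
    aspect_min: float = 1.8,
) -> str:
    """Assign interphase / mitosis / karyorrhexis from morphology and OD."""
    if fragments_in_halo >= 3:
        return "karyorrhexis"
    if solidity >= solidity_min and aspect_ratio >= aspect_min and od > od_median:
        return "mitosis"
    return "interphase"


@dataclass(frozen=True)
class MKIResult:
    pct_mitosis: float
    pct_karyorrhexis: float
    pct_mk: float
    classification: str


def mki(n_mitosis: float, n_karyorrhexis: float, n_total: float) -> MKIResult:
    """Mitosis-karyorrhexis index from cell counts.

    Classification thresholds on the combined percent: low < 2, intermediate
    2-4 (closed interval), high > 4.  Counts may be fractional so printed
    percentages can be passed through directly (see
    :func:`mki_from_percentages`).
    """
    if n_mitosis < 0 or n_karyorrhexis < 0:
        raise ValueError("phase counts must be >= 0")
    if not n_total >= 1:
        raise ValueError("total cell count must be >= 1")
    if n_mitosis + n_karyorrhexis > n_total + 1e-9:
        raise ValueError("mitosis + karyorrhexis counts exceed the total cell count")
    pct_m = 100.0 * n_mitosis / n_total
    pct_k = 100.0 * n_karyorrhexis / n_total
    pct_mk = pct_m + pct_k
    if pct_mk < 2.0:
        cls = "low"
    elif pct_mk <= 4.0:
        cls = "intermediate"
    else:
        cls = "high"
    return MKIResult(pct_mitosis=pct_m, pct_karyorrhexis=pct_k, pct_mk=pct_mk, classification=cls)


def mki_from_percentages(pct_mitosis: float, pct_karyorrhexis: float) -> MKIResult:
    """MKI from already-computed percentages (e.g. a published table row)."""
    return mki(float(pct_mitosis), float(pct_karyorrhexis), 100.0)


@dataclass(frozen=True)
class PhaseCounts:
    n_mitosis: int
    n_karyorrhexis: int
    n_interphase: int

    @property
    def n_total(self) -> int:
        return self.n_mitosis + self.n_karyorrhexis + self.n_interphase

    def mki(self) -> MKIResult:
        return mki(self.n_mitosis, self.n_karyorrhexis, self.n_total)


def _core_estimate(values: np.ndarray, reference: np.ndarray) -> float:
    """Median of ``values`` over the core pixels of an object.

    The core is the half of the pixels with the highest ``reference``
    (nuclear OD), which excludes the blurred rim whose boundary pixels
    dilute a plain mean; taking the median there also resists small slivers
    of a touching neighbour mis-assigned by the watershed split.
    """
    values = np.asarray(values, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if values.size == 0:
        return 0.0
    sel = reference >= np.median(reference)
    core = values[sel]
    return float(np.median(core)) if core.size else float(np.median(values))


def analyze_phases(
    nucleus_labels: np.ndarray,
    od,
    min_nucleus_um2: float = 5.0,
    min_fragment_um2: float = 0.5,
    fragment_max_um2: float | None = None,
    halo_um: float = 5.5,
    fragments_per_cell: float = 4.5,
    solidity_min: float = 0.9,
    aspect_min: float = 1.8,
) -> tuple[pd.DataFrame, PhaseCounts]:
    """Phase-classify every cell in a nucleus label image.

    Components below ``fragment_max_um2`` (default 40% of the median
    full-nucleus area) are fragment candidates; candidates whose centroids
    cluster within ``halo_um`` form fragment groups, and a group of >= 3
    fragments marks karyorrhexis.  Because the halos of adjacent
    karyorrhectic cells can chain into one connected group, each group of
    ``m`` fragments is counted as ``max(1, round(m / fragments_per_cell))``
    karyorrhectic cells.  Remaining components of at least
    ``min_nucleus_um2`` are ordinary cells, split into mitosis and
    interphase by the solidity / aspect-ratio / OD rule of
    :func:`classify_phase`.

    Returns a per-cell table (phase, area, core-mean nuclear and DAB OD,
    shape descriptors) and the aggregate :class:`PhaseCounts`.  Karyorrhectic
    rows pool the pixels of their member fragments, so they can be intensity
    scored like any other cell.
    """
    labels = np.asarray(nucleus_labels)
    um_per_px = od.um_per_px
    um2 = um_per_px**2
    nuclear = od.nuclear_od()
    dab = od.dab_od()

    props = measure.regionprops(labels)
    if not props:
        empty = pd.DataFrame(
            columns=["cell_id", "phase", "area_um2", "mean_nuclear_od", "mean_dab_od", "solidity", "aspect_ratio", "cx_px", "cy_px"]
        )
        return empty, PhaseCounts(0, 0, 0)

    areas = {p.label: p.area * um2 for p in props}
    full_areas = [a for a in areas.values() if a >= min_nucleus_um2]
    median_full = float(np.median(full_areas)) if full_areas else 14.0
    if fragment_max_um2 is None:
        fragment_max_um2 = 0.4 * median_full

    frag_props = [p for p in props if min_fragment_um2 <= areas[p.label] < fragment_max_um2]
    cell_props = [p for p in props if areas[p.label] >= max(min_nucleus_um2, fragment_max_um2)]

    # group fragments into halos: union-find over centroid pairs within halo_um
    halo_px = halo_um / um_per_px
    groups: list[list] = []
    if frag_props:
        pts = np.array([p.centroid for p in frag_props])
        parent = list(range(len(frag_props)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        tree = cKDTree(pts)
        for i, j in tree.query_pairs(halo_px):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
        by_root: dict[int, list] = {}
        for i, p in enumerate(frag_props):
            by_root.setdefault(find(i), []).append(p)
        groups = [members for members in by_root.values() if len(members) >= 3]

    def label_pixel_values(image: np.ndarray, prop_list) -> np.ndarray:
        vals = []
        for p in prop_list:
            minr, minc, maxr, maxc = p.bbox
            sub = image[minr:maxr, minc:maxc]
            vals.append(sub[p.image])
        return np.concatenate(vals) if vals else np.array([])

    rows = []
    cell_id = 1
    # ordinary cells first: need the OD median over them for the mitosis rule
    cell_nuclear = []
    for p in cell_props:
        vals = label_pixel_values(nuclear, [p])
        cell_nuclear.append(_core_estimate(vals, vals))
    od_median = float(np.median(cell_nuclear)) if cell_nuclear else 0.0

    for p, nuc_od in zip(cell_props, cell_nuclear):
        minor = p.axis_minor_length
        aspect = p.axis_major_length / minor if minor > 0 else float("inf")
        phase = classify_phase(
            solidity=float(p.solidity),
            aspect_ratio=float(aspect),
            od=nuc_od,
            od_median=od_median,
            fragments_in_halo=0,
            solidity_min=solidity_min,
            aspect_min=aspect_min,
        )
        cy, cx = p.centroid
        rows.append(
            dict(
                cell_id=cell_id,
                phase=phase,
                area_um2=float(areas[p.label]),
                mean_nuclear_od=float(nuc_od),
                mean_dab_od=_core_estimate(
                    label_pixel_values(dab, [p]), label_pixel_values(nuclear, [p])
                ),
                solidity=float(p.solidity),
                aspect_ratio=float(aspect),
                cx_px=float(cx),
                cy_px=float(cy),
            )
        )
        cell_id += 1

    for members in groups:
        n_events = max(1, int(round(len(members) / fragments_per_cell)))
        area = float(sum(areas[p.label] for p in members))
        centroids = np.array([p.centroid for p in members])
        cy, cx = centroids.mean(axis=0)
        # per-fragment core estimates, combined by median: a chained group
        # can span several dying cells, and pooling their pixels would blur
        # distinct intensity classes into one intermediate value
        frag_nuc = []
        frag_dab = []
        for m in members:
            nv = label_pixel_values(nuclear, [m])
            frag_nuc.append(_core_estimate(nv, nv))
            frag_dab.append(_core_estimate(label_pixel_values(dab, [m]), nv))
        nuc_od = float(np.median(frag_nuc))
        dab_od_val = float(np.median(frag_dab))
        for _ in range(n_events):
            rows.append(
                dict(
                    cell_id=cell_id,
                    phase="karyorrhexis",
                    area_um2=area / n_events,
                    mean_nuclear_od=nuc_od,
                    mean_dab_od=dab_od_val,
                    solidity=float("nan"),
                    aspect_ratio=float("nan"),
                    cx_px=float(cx),
                    cy_px=float(cy),
                )
            )
            cell_id += 1

    df = pd.DataFrame(rows)
    counts = PhaseCounts(
        n_mitosis=int((df["phase"] == "mitosis").sum()),
        n_karyorrhexis=int((df["phase"] == "karyorrhexis").sum()),
        n_interphase=int((df["phase"] == "interphase").sum()),
    )
    return df, counts


def scores_from_phases(
    phase_table: pd.DataFrame,
    thresholds=DEFAULT_INTENSITY_THRESHOLDS,
    cluster_labels: np.ndarray | None = None,
) -> list[NucleusScore]:
    """Turn the :func:`analyze_phases` cell table into per-cell scores."""
    scores = []
    for row in phase_table.itertuples():
        cluster_id = 0
        if cluster_labels is not None:
            h, w = cluster_labels.shape
            y = min(h - 1, max(0, int(round(row.cy_px))))
            x = min(w - 1, max(0, int(round(row.cx_px))))
            cluster_id = int(cluster_labels[y, x])
        scores.append(
            NucleusScore(
                nucleus_id=int(row.cell_id),
                mean_dab_od=float(row.mean_dab_od),
                intensity_class=call_intensity(row.mean_dab_od, thresholds),
                phase=str(row.phase),
                cluster_id=cluster_id,
            )
        )
    return scores


@dataclass(frozen=True)
class IHCScore:
    """Section-level IHC summary."""

    n_cells: int
    pct_positive: float
    h_score: float
    category: str
    pct_by_class: dict[str, float] = field(default_factory=dict)


def summarize_scores(scores, weights=None) -> IHCScore:
    scores = list(scores)
    pct_pos = percent_positive(scores)
    n = len(scores)
    pct_by_class = {
        cls: 100.0 * sum(s.intensity_class == cls for s in scores) / n for cls in INTENSITY_CLASSES
    }
    return IHCScore(
        n_cells=n,
        pct_positive=pct_pos,
        h_score=h_score(scores, weights),
        category=categorize_positivity(pct_pos),
        pct_by_class=pct_by_class,
    )


def positivity_by_size_class(scores, cluster_records) -> pd.DataFrame:
    """Percent positive cells grouped by the parent cluster's size class."""
    class_by_id = {rec.id: rec.size_class for rec in cluster_records}
    rows: dict[str, list] = {}
    for s in scores:
        cls = class_by_id.get(s.cluster_id)
        if cls is None:
            continue
        rows.setdefault(cls, []).append(s.positive)
    out = []
    for cls, flags in sorted(rows.items()):
        out.append(
            dict(size_class=cls, n_cells=len(flags), pct_positive=100.0 * sum(flags) / len(flags))
        )
    return pd.DataFrame(out, columns=["size_class", "n_cells", "pct_positive"])
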