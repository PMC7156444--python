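"""Condition-grid orchestration, aggregation and the study's statistics.

Sections and compression curves are analysed per condition (hydrogel
stiffness label x culture timepoint), replicate metrics are aggregated as
mean with either standard deviation or standard error, and the study's two
statistical conventions are applied: Welch/pooled t-tests for moduli and
Pearson chi-square (2x2, df = 1, no continuity correction by default) for
positive/negative cell counts.  Significance stars follow the caption
convention: *** p < 0.001, ** p < 0.01, * p < 0.05, ns otherwise (strict
inequalities, so p = 0.05 is ns).
"""

from __future__ import annotations

import json
import logging
import math
import pathlib
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import histoseg, ihc, mechanics, morphometry, synthgen

__all__ = [
    "ConditionKey",
    "AggregateRow",
    "aggregate",
    "delta_over_time",
    "chi_square_positivity",
    "significance_stars",
    "analyze_section",
    "run_pipeline",
    "demo_config",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConditionKey:
    """One cell of the stiffness x time condition grid."""

    stiffness_label: str
    timepoint_weeks: float

    def __post_init__(self) -> None:
        if not self.stiffness_label:
            raise ValueError("stiffness label must be nonempty")
        if not self.timepoint_weeks > 0:
            raise ValueError("timepoint must be positive (weeks)")


@dataclass(frozen=True)
class AggregateRow:
    condition: object
    metric: str
    mean: float
    dispersion: float
    dispersion_kind: str
    n_replicates: int
    single_replicate: bool = False


def significance_stars(p: float) -> str:
    """Map a p-value to the caption star convention (strict inequalities)."""
    p = float(p)
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p-value must be in (0, 1], got {p!r}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _summary(values, dispersion: str) -> tuple[float, float, int, bool]:
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 1:
        raise ValueError("need at least one replicate")
    mean = float(arr.mean())
    if arr.size == 1:
        return mean, 0.0, 1, True
    sd = float(arr.std(ddof=1))
    disp = sd if dispersion == "sd" else sd / math.sqrt(arr.size)
    return mean, disp, int(arr.size), False


def aggregate(replicates, dispersion: str = "sd") -> list[AggregateRow]:
    """Aggregate replicate metrics to mean and dispersion per condition.

    ``replicates`` is either a bare sequence of numbers (one unnamed
    condition/metric), or a mapping ``{(condition, metric): values}``.
    ``dispersion`` is ``"sd"`` (sample, n-1) or ``"sem"`` (sd / sqrt(n)).
    Single replicates report dispersion 0 with ``single_replicate=True``.
    """
    if dispersion not in ("sd", "sem"):
        raise ValueError(f"dispersion must be 'sd' or 'sem', got {dispersion!r}")
    if isinstance(replicates, dict):
        items = list(replicates.items())
    else:
        items = [((None, "value"), list(replicates))]
    rows = []
    for (condition, metric), values in items:
        mean, disp, n, single = _summary(values, dispersion)
        rows.append(
            AggregateRow(
                condition=condition,
                metric=str(metric),
                mean=mean,
                dispersion=disp,
                dispersion_kind=dispersion,
                n_replicates=n,
                single_replicate=single,
            )
        )
    return rows


def delta_over_time(row_early: AggregateRow, row_late: AggregateRow) -> float:
    """Signed change of a condition mean between two timepoints (late - early)."""
    if row_early.metric != row_late.metric:
        raise ValueError(f"metric mismatch: {row_early.metric!r} vs {row_late.metric!r}")
    a, b = row_early.condition, row_late.condition
    if isinstance(a, ConditionKey) and isinstance(b, ConditionKey) and a.stiffness_label != b.stiffness_label:
        raise ValueError("time deltas compare the same stiffness condition")
    return row_late.mean - row_early.mean


def chi_square_positivity(
    pos_a: float, neg_a: float, pos_b: float, neg_b: float, correction: bool = False
) -> tuple[float, float, str]:
    """Pearson chi-square on the 2x2 positive/negative table (df = 1).

    No continuity correction by default (cell counts in this setting are
    large); set ``correction=True`` for Yates.  Returns (chi2, p, stars).
    """
    obs = np.array([[pos_a, neg_a], [pos_b, neg_b]], dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be >= 0")
    if obs.sum(axis=1).min() < 1:
        raise ValueError("both groups need at least one cell")
    if (obs.sum(axis=0) == 0).any():
        raise ValueError("a zero marginal makes the chi-square test undefined")
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    diff = np.abs(obs - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff**2 / expected).sum())
    p = float(sps.chi2.sf(chi2, df=1))
    p = min(max(p, float(np.finfo(float).tiny)), 1.0)
    return chi2, p, significance_stars(p)


# ---------------------------------------------------------------------------
# per-section analysis


def analyze_section(
    image: histoseg.SectionImage,
    stains: str = "HE",
    intensity_thresholds=ihc.DEFAULT_INTENSITY_THRESHOLDS,
    nuclear_od_threshold: float = 0.15,
    min_nucleus_um2: float = 5.0,
    collect: bool = False,
):
    """Run the full single-section pipeline and return one metrics row.

    Deconvolution -> solid segmentation -> nucleus segmentation (fine, so
    karyorrhectic fragments survive) -> cluster labelling -> morphometry ->
    phase analysis / MKI, plus IHC scoring for H-DAB stains.  With
    ``collect=True`` the intermediate masks and tables are returned as well.
    """
    stains = histoseg.normalize_stain_pair(stains)
    odc = histoseg.deconvolve_stains(image, stains)
    solid = histoseg.segment_solid(image)
    labels = histoseg.segment_nuclei(
        odc, od_threshold=nuclear_od_threshold, min_nucleus_um2=1.0
    )
    cluster_labels, cluster_records = histoseg.label_clusters(solid, labels, image.um_per_px)
    metrics = morphometry.section_metrics(solid, cluster_records, image.um_per_px)
    row: dict = metrics.as_dict()

    phase_df, counts = ihc.analyze_phases(labels, odc, min_nucleus_um2=min_nucleus_um2)
    row["n_cells"] = counts.n_total
    if counts.n_total >= 1:
        mki_res = counts.mki()
        row.update(
            pct_mitosis=mki_res.pct_mitosis,
            pct_karyorrhexis=mki_res.pct_karyorrhexis,
            pct_mk=mki_res.pct_mk,
            mki_classification=mki_res.classification,
        )

    # nucleus morphometrics over full nuclei only
    coarse = histoseg.segment_nuclei(odc, od_threshold=nuclear_od_threshold, min_nucleus_um2=min_nucleus_um2)
    morphs = morphometry.nucleus_morphometrics(coarse, image.um_per_px)
    if morphs:
        row["nucleus_area_um2_mean"] = float(np.mean([m.area_um2 for m in morphs]))
        row["nucleus_shape_factor_mean"] = float(np.mean([m.shape_factor for m in morphs]))

    scores = None
    if stains == "H-DAB" and len(phase_df):
        scores = ihc.scores_from_phases(phase_df, intensity_thresholds, cluster_labels)
        summary = ihc.summarize_scores(scores)
        row.update(
            pct_positive=summary.pct_positive,
            h_score=summary.h_score,
            ihc_category=summary.category,
        )
    if collect:
        return row, dict(
            od=odc,
            solid_mask=solid,
            nucleus_labels=labels,
            cluster_labels=cluster_labels,
            cluster_records=cluster_records,
            phase_table=phase_df,
            phase_counts=counts,
            scores=scores,
        )
    return row


# ---------------------------------------------------------------------------
# pipeline over a condition grid


def _condition_from_cfg(entry: dict) -> ConditionKey:
    return ConditionKey(str(entry["stiffness_label"]), float(entry["timepoint_weeks"]))


def _missing_inputs(config: dict) -> list[str]:
    missing = []
    for entry in config.get("conditions", []):
        for sec in entry.get("sections", []):
            path = sec.get("image")
            if path is not None and not pathlib.Path(path).exists():
                missing.append(str(path))
        for cur in entry.get("curves", []):
            path = cur.get("csv")
            if path is not None and not pathlib.Path(path).exists():
                missing.append(str(path))
    return missing


def run_pipeline(config, out_dir=None) -> dict:
    """Run the full analysis over a condition grid described by ``config``.

    ``config`` is a dict (or path to a JSON file) listing conditions, each
    with ``sections`` (``{"image": path, "stains": ...}`` or
    ``{"synth": {...SectionParams...}}``) and ``curves`` (``{"csv": path,
    ...geometry...}`` or ``{"synth": {...CurveParams...}}``).  Missing input
    files fail fast, listing every missing path.  Writes sections.csv,
    moduli.csv, aggregates.csv, comparisons.csv and report.json to
    ``out_dir`` when given; always returns the report dict.  Output is
    deterministic for a fixed config.
    """
    if not isinstance(config, dict):
        config = json.loads(pathlib.Path(config).read_text())
    missing = _missing_inputs(config)
    if missing:
        raise FileNotFoundError("missing input files: " + ", ".join(sorted(missing)))

    um_per_px = float(config.get("um_per_px", 0.5))
    dispersion = config.get("dispersion", "sem")
    thresholds = tuple(config.get("thresholds", {}).get("intensity", ihc.DEFAULT_INTENSITY_THRESHOLDS))
    nuclear_thr = float(config.get("thresholds", {}).get("nuclear_od", 0.15))
    fit_window = tuple(config.get("fit_window", (0.05, 0.15)))

    section_rows = []
    moduli_rows = []
    for entry in config.get("conditions", []):
        key = _condition_from_cfg(entry)
        t0 = time.perf_counter()
        for i, sec in enumerate(entry.get("sections", [])):
            if "synth" in sec:
                params = synthgen.SectionParams(**sec["synth"])
                image, _truth = synthgen.generate_section(params)
                stains = "H-DAB" if params.stain_mode == "IHC" else "HE"
            else:
                stains = sec.get("stains", "HE")
                image = histoseg.SectionImage.load(sec["image"], float(sec.get("um_per_px", um_per_px)))
            row = analyze_section(
                image, stains, intensity_thresholds=thresholds, nuclear_od_threshold=nuclear_thr
            )
            row.update(
                stiffness_label=key.stiffness_label,
                timepoint_weeks=key.timepoint_weeks,
                replicate=i,
            )
            section_rows.append(row)
        for i, cur in enumerate(entry.get("curves", [])):
            if "synth" in cur:
                curve, truth = synthgen.generate_stress_strain(synthgen.CurveParams(**cur["synth"]))
            else:
                curve = mechanics.load_curve_csv(
                    cur["csv"],
                    h0_mm=cur.get("h0_mm"),
                    area0_mm2=cur.get("area0_mm2"),
                    preload_mn=float(cur.get("preload_mn", 0.1)),
                )
            fit = mechanics.fit_youngs_modulus(curve, window=fit_window)
            moduli_rows.append(
                dict(
                    stiffness_label=key.stiffness_label,
                    timepoint_weeks=key.timepoint_weeks,
                    replicate=i,
                    E_kpa=fit.E_kpa,
                    r2=fit.r2,
                    n_points_used=fit.n_points_used,
                )
            )
        log.info("condition %s/%sw analysed in %.1fs", key.stiffness_label, key.timepoint_weeks, time.perf_counter() - t0)

    sections_df = pd.DataFrame(section_rows)
    moduli_df = pd.DataFrame(moduli_rows)

    # aggregate replicate metrics per condition
    agg_map: dict = {}
    if len(sections_df):
        numeric = [
            c
            for c in sections_df.columns
            if c not in ("stiffness_label", "timepoint_weeks", "replicate", "mki_classification", "ihc_category")
            and pd.api.types.is_numeric_dtype(sections_df[c])
        ]
        for (lab, weeks), grp in sections_df.groupby(["stiffness_label", "timepoint_weeks"], sort=False):
            for metric in numeric:
                vals = grp[metric].dropna().to_list()
                if vals:
                    agg_map[(ConditionKey(lab, weeks), metric)] = vals
    if len(moduli_df):
        for (lab, weeks), grp in moduli_df.groupby(["stiffness_label", "timepoint_weeks"], sort=False):
            agg_map[(ConditionKey(lab, weeks), "E_kpa")] = grp["E_kpa"].to_list()
    agg_rows = aggregate(agg_map, dispersion=dispersion) if agg_map else []

    # comparisons: moduli t-tests between conditions differing in one axis
    comparisons = []
    if len(moduli_df):
        groups = {
            ConditionKey(lab, weeks): grp["E_kpa"].to_numpy()
            for (lab, weeks), grp in moduli_df.groupby(["stiffness_label", "timepoint_weeks"], sort=False)
        }
        keys = list(groups)
        for i, ka in enumerate(keys):
            for kb in keys[i + 1 :]:
                same_axis = (ka.stiffness_label == kb.stiffness_label) != (
                    ka.timepoint_weeks == kb.timepoint_weeks
                )
                if not same_axis or len(groups[ka]) < 2 or len(groups[kb]) < 2:
                    continue
                cmp = mechanics.compare_moduli(groups[ka], groups[kb])
                comparisons.append(
                    dict(
                        metric="E_kpa",
                        test="t_welch",
                        condition_a=f"{ka.stiffness_label}/{ka.timepoint_weeks}w",
                        condition_b=f"{kb.stiffness_label}/{kb.timepoint_weeks}w",
                        statistic=cmp.t_stat,
                        p_value=cmp.p_value,
                        stars=cmp.stars,
                    )
                )
    # chi-square on positive/negative counts across time within stiffness
    if len(sections_df) and "pct_positive" in sections_df.columns:
        pos_neg = {}
        for (lab, weeks), grp in sections_df.groupby(["stiffness_label", "timepoint_weeks"], sort=False):
            sub = grp.dropna(subset=["pct_positive", "n_cells"])
            if not len(sub):
                continue
            n = sub["n_cells"].sum()
            pos = float((sub["pct_positive"] / 100.0 * sub["n_cells"]).sum())
            pos_neg[ConditionKey(lab, weeks)] = (pos, n - pos)
        keys = list(pos_neg)
        for i, ka in enumerate(keys):
            for kb in keys[i + 1 :]:
                if ka.stiffness_label != kb.stiffness_label:
                    continue
                try:
                    chi2, p, stars = chi_square_positivity(*pos_neg[ka], *pos_neg[kb])
                except ValueError:
                    continue
                comparisons.append(
                    dict(
                        metric="pct_positive",
                        test="chi2",
                        condition_a=f"{ka.stiffness_label}/{ka.timepoint_weeks}w",
                        condition_b=f"{kb.stiffness_label}/{kb.timepoint_weeks}w",
                        statistic=chi2,
                        p_value=p,
                        stars=stars,
                    )
                )

    agg_df = pd.DataFrame(
        [
            dict(
                stiffness_label=r.condition.stiffness_label,
                timepoint_weeks=r.condition.timepoint_weeks,
                metric=r.metric,
                mean=r.mean,
                dispersion=r.dispersion,
                dispersion_kind=r.dispersion_kind,
                n_replicates=r.n_replicates,
            )
            for r in agg_rows
        ]
    )
    comparisons_df = pd.DataFrame(comparisons)
    report = dict(
        sections=sections_df.to_dict(orient="records"),
        moduli=moduli_df.to_dict(orient="records"),
        aggregates=agg_df.to_dict(orient="records"),
        comparisons=comparisons,
    )
    if out_dir is not None:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sections_df.to_csv(out / "sections.csv", index=False)
        moduli_df.to_csv(out / "moduli.csv", index=False)
        agg_df.to_csv(out / "aggregates.csv", index=False)
        comparisons_df.to_csv(out / "comparisons.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report


def demo_config(seed: int = 0, n_replicates: int = 3, n_curves: int = 5, size_px: int = 384) -> dict:
    """A fully synthetic condition grid over the six study conditions.

    Each condition gets ``n_replicates`` IHC sections generated from its
    preset (porosity, Ki67 positivity, intensity mix, phase rates) and
    ``n_curves`` compression curves at the condition's cellular modulus.
    """
    ss = np.random.SeedSequence(seed)
    conditions = []
    for (label, weeks), preset in synthgen.CONDITION_PRESETS.items():
        child = ss.spawn(1)[0]
        seeds = child.generate_state(n_replicates + n_curves) % (2**31)
        sections = [
            dict(
                synth=dict(
                    width_px=size_px,
                    height_px=size_px,
                    target_porosity=preset["porosity"],
                    stain_mode="IHC",
                    positive_fraction=preset["ki67_positive"],
                    intensity_mix=synthgen.intensity_mix_for_mean_weight(
                        preset["ki67_h_score"] / (100.0 * preset["ki67_positive"])
                    ),
                    phase_rates=(preset["mitosis"], preset["karyorrhexis"]),
                    seed=int(seeds[i]),
                )
            )
            for i in range(n_replicates)
        ]
        curves = [
            dict(synth=dict(E_true_kpa=preset["E_cellular"], seed=int(seeds[n_replicates + i])))
            for i in range(n_curves)
        ]
        conditions.append(
            dict(
                stiffness_label=label,
                timepoint_weeks=weeks,
                sections=sections,
                curves=curves,
            )
        )
    return dict(um_per_px=0.5, dispersion="sem", conditions=conditions)
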