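"""Uniaxial compression mechanics for soft hydrogels.

Raw force/displacement records are converted to engineering stress and strain
(stress = force / initial contact area, strain = compression / initial
height), with samples before the preload-contact point discarded.  Young's
modulus E is the slope of an ordinary least-squares line fitted to the linear
elastic region of the stress-strain curve, either over a fixed strain window
(default 0.05-0.15, below the toe region and well under the 50% protocol
maximum) or over the best sliding window of width 0.10 strain by r^2.  For
soft gels the convenient unit identity is 1 mN / mm^2 = 1 kPa.

Group comparisons use a two-sided two-sample t-test (Welch by default, since
equal variances between hydrogel formulations are not guaranteed; a pooled
variant is available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StressStrainCurve",
    "ElasticFit",
    "GroupComparison",
    "NoContactError",
    "InsufficientDataError",
    "to_stress_strain",
    "fit_youngs_modulus",
    "compare_moduli",
    "load_curve_csv",
]

MAX_STRAIN = 0.5  # compression protocol stops at 50% deformation


class NoContactError(ValueError):
    """No sample reached the preload force: the platen never touched the gel."""


class InsufficientDataError(ValueError):
    """Fewer than three samples available inside the candidate fit window."""


@dataclass(frozen=True)
class StressStrainCurve:
    """Paired engineering strain (dimensionless) and stress (kPa) samples."""

    strain: np.ndarray
    stress_kpa: np.ndarray

    def __post_init__(self) -> None:
        strain = np.asarray(self.strain, dtype=float)
        stress = np.asarray(self.stress_kpa, dtype=float)
        if strain.ndim != 1 or stress.ndim != 1 or strain.size != stress.size:
            raise ValueError("strain and stress must be 1-D arrays of equal length")
        if strain.size < 3:
            raise ValueError("a stress-strain curve needs at least 3 samples")
        if not np.all(np.diff(strain) > 0):
            raise ValueError("strain must be strictly increasing")
        if strain[0] < 0:
            raise ValueError("strain must start at or above 0")
        if strain[-1] > MAX_STRAIN + 1e-6:
            raise ValueError(f"strain exceeds the {MAX_STRAIN:.0%} compression protocol")
        object.__setattr__(self, "strain", strain)
        object.__setattr__(self, "stress_kpa", stress)

    def __len__(self) -> int:
        return int(self.strain.size)

    def to_csv(self, path) -> None:
        pd.DataFrame({"strain": self.strain, "stress_kpa": self.stress_kpa}).to_csv(path, index=False)


@dataclass(frozen=True)
class ElasticFit:
    """OLS line fit over the elastic region of a stress-strain curve."""

    E_kpa: float
    window: tuple[float, float]
    r2: float
    n_points_used: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.E_kpa):
            raise ValueError("fitted modulus must be finite")
        if not self.window[0] < self.window[1]:
            raise ValueError("window must satisfy lo < hi")
        if self.n_points_used < 3:
            raise ValueError("a fit needs at least 3 points")


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_stat: float
    p_value: float
    df: float
    stars: str


def to_stress_strain(
    force_mn,
    displacement_mm,
    h0_mm: float,
    area0_mm2: float,
    preload_mn: float = 0.1,
) -> StressStrainCurve:
    """Convert a force/displacement record to engineering stress-strain.

    The contact onset is the first sample whose force reaches ``preload_mn``;
    earlier samples are dropped and displacement is re-zeroed there.  Strain
    is (displacement - displacement_onset) / h0; stress is force / area0,
    which in mN and mm^2 is already kPa.  Samples compressing beyond the 50%
    protocol limit are discarded.
    """
    force = np.asarray(force_mn, dtype=float)
    disp = np.asarray(displacement_mm, dtype=float)
    if force.shape != disp.shape or force.ndim != 1:
        raise ValueError("force and displacement must be 1-D arrays of equal length")
    if not h0_mm > 0 or not area0_mm2 > 0:
        raise ValueError("initial height and contact area must be > 0")
    reached = np.nonzero(force >= preload_mn)[0]
    if reached.size == 0:
        raise NoContactError(f"no sample reached the preload force of {preload_mn} mN")
    onset = int(reached[0])
    strain = (disp[onset:] - disp[onset]) / h0_mm
    stress = force[onset:] / area0_mm2  # mN/mm^2 == kPa
    keep = strain <= MAX_STRAIN + 1e-12
    return StressStrainCurve(strain[keep], stress[keep])


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and r^2 of an OLS line with intercept.

    A residual-free fit to constant data is reported as r^2 = 1 (the line
    explains everything there is to explain).
    """
    xm = x - x.mean()
    ym = y - y.mean()
    sxx = float(xm @ xm)
    if sxx == 0:
        raise InsufficientDataError("all strains in the window are identical; cannot fit a slope")
    slope = float(xm @ ym) / sxx
    ss_tot = float(ym @ ym)
    resid = ym - slope * xm
    ss_res = float(resid @ resid)
    if ss_tot <= 0:
        r2 = 1.0 if ss_res <= 1e-24 else 0.0
    else:
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
    return slope, r2


def fit_youngs_modulus(
    curve: StressStrainCurve,
    strategy: str = "fixed_window",
    window: tuple[float, float] | None = None,
    window_width: float = 0.10,
) -> ElasticFit:
    """Fit Young's modulus (kPa) as the slope of the elastic region.

    ``fixed_window`` fits over strain in ``window`` (default (0.05, 0.15),
    inclusive).  ``best_window`` slides a window of ``window_width`` strain in
    steps of one sample and keeps the fit with the highest r^2, breaking ties
    toward lower strain.
    """
    strain, stress = curve.strain, curve.stress_kpa
    if strategy == "fixed_window":
        lo, hi = window if window is not None else (0.05, 0.15)
        sel = (strain >= lo) & (strain <= hi)
        if int(sel.sum()) < 3:
            raise InsufficientDataError(
                f"only {int(sel.sum())} samples inside the strain window [{lo}, {hi}]"
            )
        slope, r2 = _ols_line(strain[sel], stress[sel])
        return ElasticFit(E_kpa=slope, window=(float(lo), float(hi)), r2=r2, n_points_used=int(sel.sum()))
    if strategy != "best_window":
        raise ValueError(f"unknown strategy {strategy!r}")

    best: ElasticFit | None = None
    for i in range(len(curve)):
        lo = float(strain[i])
        hi = lo + window_width
        sel = (strain >= lo) & (strain <= hi + 1e-12)
        if int(sel.sum()) < 3:
            continue
        slope, r2 = _ols_line(strain[sel], stress[sel])
        if best is None or r2 > best.r2 + 1e-12:
            best = ElasticFit(E_kpa=slope, window=(lo, hi), r2=r2, n_points_used=int(sel.sum()))
    if best is None:
        raise InsufficientDataError("no sliding window holds at least 3 samples")
    return best


def compare_moduli(group_a, group_b, variant: str = "welch") -> GroupComparison:
    """Two-sided two-sample t-test between two groups of moduli (kPa).

    ``variant`` is ``"welch"`` (unequal variances, default) or ``"pooled"``.
    Degenerate zero-variance groups are handled by convention: equal means
    give p = 1, different means give a vanishing p.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    sd_a = float(a.std(ddof=1))
    sd_b = float(b.std(ddof=1))
    va, vb = sd_a**2 / a.size, sd_b**2 / b.size
    if variant == "pooled":
        df = float(a.size + b.size - 2)
    elif va + vb > 0:
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    else:
        df = float(a.size + b.size - 2)
    if sd_a == 0.0 and sd_b == 0.0:
        if mean_a == mean_b:
            t, p = 0.0, 1.0
        else:
            t = math.copysign(math.inf, mean_a - mean_b)
            p = float(np.finfo(float).tiny)
    else:
        t, p = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
        t, p = float(t), float(p)
    from .report import significance_stars  # local import; report also orchestrates this module

    return GroupComparison(
        mean_a=mean_a,
        sd_a=sd_a,
        mean_b=mean_b,
        sd_b=sd_b,
        t_stat=t,
        p_value=p,
        df=df,
        stars=significance_stars(max(p, np.finfo(float).tiny)),
    )


def load_curve_csv(
    path,
    h0_mm: float | None = None,
    area0_mm2: float | None = None,
    preload_mn: float = 0.1,
) -> StressStrainCurve:
    """Read a curve CSV with either (strain, stress_kpa) or
    (displacement_mm, force_mn) columns; the latter requires geometry."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "strain" in cols and ("stress_kpa" in cols or "stress" in cols):
        stress_col = cols.get("stress_kpa", cols.get("stress"))
        return StressStrainCurve(df[cols["strain"]].to_numpy(), df[stress_col].to_numpy())
    if "displacement_mm" in cols and ("force_mn" in cols):
        if h0_mm is None or area0_mm2 is None:
            raise ValueError("force/displacement curves need h0_mm and area0_mm2")
        return to_stress_strain(
            df[cols["force_mn"]].to_numpy(),
            df[cols["displacement_mm"]].to_numpy(),
            h0_mm=h0_mm,
            area0_mm2=area0_mm2,
            preload_mn=preload_mn,
        )
    raise ValueError(
        f"{path}: expected columns (strain, stress_kpa) or (displacement_mm, force_mn), got {list(df.columns)}"
    )
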