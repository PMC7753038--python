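"""Distance measurement, normalization and distribution-based spatial
inference.

The central idea: in a trephine section a 3-D point-process analysis is not
available, so spatial clustering of structures (vessels near bone, imHCs
near capillaries) is inferred from the *shape* of the measured distance
distribution.  Distances compatible with random placement look symmetric /
normal; an excess of short distances shows up as a right-skewed
distribution, flagged by the Shapiro-Wilk test together with a skewness
z-score (sample skewness over its exact finite-sample standard error) and
localised on a de-trended Q-Q plot.

Raw distances are measured from the structure centroid and normalized by
subtracting half of the inner caliber, flooring at zero (a raw distance
smaller than the vessel radius means contact).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .config import AnalysisConfig


def nearest_distance(
    structure_mask: np.ndarray, target_mask: np.ndarray, um_per_px: float
) -> float:
    """Minimum Euclidean distance (um) from the structure centroid to the
    target boundary, via a distance transform.  An empty target yields NaN
    (target absent from the field of view)."""
    structure_mask = np.asarray(structure_mask).astype(bool)
    target_mask = np.asarray(target_mask).astype(bool)
    if not structure_mask.any():
        raise ValueError("structure mask is empty")
    if not target_mask.any():
        return float("nan")
    r, c = ndimage.center_of_mass(structure_mask)
    edt = ndimage.distance_transform_edt(~target_mask)
    ri = min(max(int(round(r)), 0), edt.shape[0] - 1)
    ci = min(max(int(round(c)), 0), edt.shape[1] - 1)
    return float(edt[ri, ci] * um_per_px)


def normalize_distance(d_raw_um: float, ic_um: float) -> float:
    """Center-referenced distance corrected for vessel size:
    max(0, d_raw - IC/2)."""
    if d_raw_um < 0 or ic_um < 0:
        raise ValueError("distances and calibers must be >= 0")
    return max(0.0, d_raw_um - ic_um / 2.0)


def cooccurrence_test(
    flags_group: Sequence[bool], flags_rest: Sequence[bool]
) -> Tuple[float, float, float]:
    """Compare the frequency of a boolean co-occurrence flag (e.g. bone in
    the field of view) between a vessel group and the remaining vessels.

    Returns (percent_group, percent_rest, p) with percentages to one
    decimal; Pearson chi-square without continuity correction, falling back
    to Fisher's exact test when any expected count is below 5.
    """
    a = np.asarray(flags_group, dtype=bool)
    b = np.asarray(flags_rest, dtype=bool)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need n >= 1")
    table = np.array(
        [[a.sum(), a.size - a.sum()], [b.sum(), b.size - b.sum()]], dtype=float
    )
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise ValueError("degenerate margins")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 5).any():
        _, p = stats.fisher_exact(table.astype(int))
    else:
        _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return (
        round(100.0 * a.mean(), 1),
        round(100.0 * b.mean(), 1),
        float(p),
    )


def skewness_se(n: int) -> float:
    """Exact finite-sample standard error of the adjusted Fisher-Pearson
    sample skewness under normality: sqrt(6n(n-1) / ((n-2)(n+1)(n+3)))."""
    if n < 5:
        raise ValueError("need n >= 5")
    return math.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))


def skewness_z_from_g1(g1: float, n: int) -> Tuple[float, int]:
    """Skewness z-score from a known sample skewness: z = g1 / SE(g1).
    Returns (raw z, z rounded to the nearest integer)."""
    z = g1 / skewness_se(n)
    return z, int(np.round(z))


def skewness_z(values: Sequence[float]) -> Tuple[float, float, float]:
    """(g1, SE, z) for a sample: adjusted Fisher-Pearson skewness over its
    exact standard error."""
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("need n >= 5")
    if x.std() == 0:
        raise ValueError("zero variance: skewness undefined")
    g1 = float(stats.skew(x, bias=False))
    se = skewness_se(x.size)
    return g1, se, g1 / se


@dataclass
class DistributionDiagnostics:
    """Normality diagnostics of one distance series."""

    n: int
    W: float
    p_sw: float
    g1: float
    se_g1: float
    z: float
    z_rounded: int
    qq_points: np.ndarray  # (theoretical quantile, de-trended ordinate)
    window: Optional[Tuple[float, float]] = None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "W": self.W,
            "p_sw": self.p_sw,
            "g1": self.g1,
            "se_g1": self.se_g1,
            "z": self.z,
            "z_rounded": self.z_rounded,
            "window": list(self.window) if self.window else None,
        }


def _plotting_positions(n: int, method: str) -> np.ndarray:
    i = np.arange(1, n + 1)
    if method == "blom":
        return (i - 0.375) / (n + 0.25)
    return (i - 0.5) / n


def normality_diagnostics(
    values: Sequence[float],
    window: Optional[Tuple[float, float]] = None,
    plotting: str = "midpoint",
) -> DistributionDiagnostics:
    """Shapiro-Wilk, skewness z and de-trended Q-Q ordinates for a series.

    The de-trended ordinate is the sorted sample minus the normal line
    fitted by (mean, SD), evaluated at standard-normal quantiles of the
    plotting positions, so a normal sample scatters around zero.
    """
    x = np.asarray(values, dtype=float)
    if window is not None:
        lo, hi = window
        x = x[(x >= lo) & (x <= hi)]
    if x.size < 3:
        raise ValueError("need n >= 3 after windowing")
    W, p_sw = stats.shapiro(x)
    if x.size >= 5 and x.std() > 0:
        g1, se, z = skewness_z(x)
    else:
        g1, se, z = float("nan"), float("nan"), float("nan")
    xs = np.sort(x)
    q = stats.norm.ppf(_plotting_positions(x.size, plotting))
    fitted = x.mean() + x.std(ddof=1) * q
    qq = np.column_stack([q, xs - fitted])
    return DistributionDiagnostics(
        n=int(x.size),
        W=float(W),
        p_sw=float(p_sw),
        g1=g1,
        se_g1=se,
        z=z,
        z_rounded=int(np.round(z)) if np.isfinite(z) else 0,
        qq_points=qq,
        window=window,
    )


def verdict(diag: Optional[DistributionDiagnostics], cfg: AnalysisConfig) -> str:
    """Map diagnostics to a verdict string.

    ``right-skewed`` iff the Shapiro-Wilk test rejects AND the skewness z
    meets the threshold; ``normal`` iff the test does not reject; otherwise
    ``symmetric non-normal``; ``insufficient-n`` below the minimum sample.
    """
    if diag is None or diag.n < 5:
        return "insufficient-n"
    if diag.p_sw < cfg.sw_alpha and diag.z >= cfg.z_skew_threshold:
        return "right-skewed"
    if diag.p_sw >= cfg.sw_alpha:
        return "normal"
    return "symmetric non-normal"


@dataclass
class ClassSpatialSummary:
    vessel_class: str
    target_kind: str
    overall: Optional[DistributionDiagnostics]
    windowed: Optional[DistributionDiagnostics]
    below: Optional[DistributionDiagnostics]
    above: Optional[DistributionDiagnostics]
    split_um: float
    verdict: str

    def to_dict(self) -> dict:
        return {
            "class": self.vessel_class,
            "target_kind": self.target_kind,
            "overall": self.overall.to_dict() if self.overall else None,
            "windowed": self.windowed.to_dict() if self.windowed else None,
            "below": self.below.to_dict() if self.below else None,
            "above": self.above.to_dict() if self.above else None,
            "split_um": self.split_um,
            "verdict": self.verdict,
        }


def clustering_inference(
    records: pd.DataFrame, cfg: Optional[AnalysisConfig] = None
) -> Dict[Tuple[str, str], ClassSpatialSummary]:
    """Per (vessel class, target kind) spatial summary.

    Expects columns: class, target_kind, d_raw_um, ic_um (d_norm_um is
    recomputed).  For each series: overall diagnostics, diagnostics within
    [0, endosteal window], and a split below/above the perivascular
    threshold (imHC targets) or the bone-contact threshold (bone targets).
    The verdict is assigned from the overall diagnostics.
    """
    if cfg is None:
        cfg = AnalysisConfig()
    df = records.copy()
    df = df.dropna(subset=["d_raw_um"])
    df["d_norm_um"] = [
        normalize_distance(d, ic)
        for d, ic in zip(df["d_raw_um"].astype(float), df["ic_um"].astype(float))
    ]
    out: Dict[Tuple[str, str], ClassSpatialSummary] = {}
    for (cls, kind), grp in df.groupby(["class", "target_kind"], sort=True):
        x = grp["d_norm_um"].to_numpy(dtype=float)
        split = (
            cfg.bone_contact_window_um
            if kind == "bone"
            else cfg.perivascular_window_um
        )

        def diag(vals: np.ndarray, window=None) -> Optional[DistributionDiagnostics]:
            try:
                return normality_diagnostics(
                    vals, window=window, plotting=cfg.qq_plotting_positions
                )
            except ValueError:
                return None

        overall = diag(x)
        windowed = diag(x, window=(0.0, cfg.endosteal_window_um))
        below = diag(x[x <= split])
        above = diag(x[x > split])
        out[(cls, kind)] = ClassSpatialSummary(
            vessel_class=cls,
            target_kind=kind,
            overall=overall,
            windowed=windowed,
            below=below,
            above=above,
            split_um=split,
            verdict=verdict(overall, cfg),
        )
    return out


def marker_proximity_association(
    marker_flags: Sequence[bool],
    distances: Sequence[float],
    threshold_um: float,
) -> Tuple[np.ndarray, float]:
    """2x2 association between a binary marker and proximity (distance
    within vs beyond ``threshold_um``); chi-square without continuity
    correction, Fisher's exact when any expected count is below 5."""
    m = np.asarray(marker_flags, dtype=bool)
    d = np.asarray(distances, dtype=float)
    if m.size != d.size:
        raise ValueError("marker and distance lengths differ")
    if m.size < 4:
        raise ValueError("need n >= 4")
    if m.all() or not m.any():
        raise ValueError("both marker states must be present")
    near = d <= threshold_um
    table = np.array(
        [
            [(m & near).sum(), (m & ~near).sum()],
            [(~m & near).sum(), (~m & ~near).sum()],
        ],
        dtype=int,
    )
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 5).any():
        _, p = stats.fisher_exact(table)
    else:
        _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return table, float(p)
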