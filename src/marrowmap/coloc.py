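"""Pixel-intensity co-localization between two fluorescence channels.

Implements Pearson's R, the Costes automatic dual threshold, thresholded
Manders coefficients M1/M2, translated negative controls, and group
comparison (Kruskal-Wallis with Dunn's post test).

The Costes search regresses the red channel on the green channel and scans
candidate thresholds down the distinct green intensity levels; the adopted
threshold is the highest level at which the pixels below BOTH channel
thresholds are uncorrelated (Pearson <= 0).  For integer images the
correlation sign below threshold is decided in exact integer arithmetic, so
the fast prefix-sum search is bit-identical to an exhaustive per-level scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from itertools import combinations
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

MIN_ROI_PIXELS = 25


@dataclass
class ChannelPair:
    """Two same-shape non-negative intensity channels plus an optional ROI.

    ``green`` holds the cytoskeletal marker (NESTIN), ``red`` the endothelial
    surface marker (CD34 or CD31); the naming follows the conventional
    pseudocolors.
    """

    green: np.ndarray
    red: np.ndarray
    roi: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green)
        self.red = np.asarray(self.red)
        if self.green.shape != self.red.shape or self.green.ndim != 2:
            raise ValueError("channels must be 2-D arrays of equal shape")
        if not (np.isfinite(self.green).all() and np.isfinite(self.red).all()):
            raise ValueError("intensities must be finite")
        if (self.green < 0).any() or (self.red < 0).any():
            raise ValueError("intensities must be non-negative")
        if self.roi is None:
            self.roi = np.ones(self.green.shape, dtype=bool)
        else:
            self.roi = np.asarray(self.roi).astype(bool)
            if self.roi.shape != self.green.shape:
                raise ValueError("roi shape mismatch")
        if int(self.roi.sum()) < MIN_ROI_PIXELS:
            raise ValueError(f"ROI must cover >= {MIN_ROI_PIXELS} pixels")


@dataclass
class CostesThresholds:
    T_green: float
    T_red: float
    slope: float
    intercept: float
    status: str = "ok"  # "ok" | "flagged"


@dataclass
class ColocResult:
    """Coefficients of one analysis plus its translated-control twins."""

    R: float
    M1: float
    M2: float
    T_green: float
    T_red: float
    slope: float
    intercept: float
    tR: float
    tM1: float
    tM2: float
    n_pixels: int
    threshold_status: str = "ok"
    control_threshold_status: str = "ok"
    decisions: Dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def pearson(pair: ChannelPair, pixel_selector: Optional[np.ndarray] = None) -> float:
    """Product-moment correlation of paired intensities over selected pixels."""
    sel = pair.roi if pixel_selector is None else (pair.roi & pixel_selector)
    g = pair.green[sel].astype(float)
    r = pair.red[sel].astype(float)
    if g.size < 3:
        raise ValueError("selector must yield >= 3 pixels")
    if g.std() == 0 or r.std() == 0:
        raise ValueError("zero variance in a channel: correlation undefined")
    return float(np.corrcoef(g, r)[0, 1])


def costes_thresholds(pair: ChannelPair, uncorrelated_band: float = 0.02) -> CostesThresholds:
    """Costes automatic threshold for a channel pair.

    Scans the distinct green levels in descending order; at each candidate
    T_green the red threshold is taken on the regression line
    ``T_red = intercept + slope * T_green`` and the below-threshold set is
    the pixels below both.  The scan stops at the first level where the
    below-threshold pixels are uncorrelated: correlation <= 0 (status
    ``ok``), or positive but negligible - below ``uncorrelated_band`` and
    below the sampling band 2/sqrt(n) margin of signal - in which case the
    stop is ``flagged`` (the behaviour seen on independent channels, which
    stop at or near the scan start).  A below-threshold set that
    degenerates (fewer than 3 pixels or zero variance) also stops the scan,
    flagged; if no level ever stops it, the minimum level is returned,
    flagged.
    """
    g = pair.green[pair.roi]
    r = pair.red[pair.roi]
    levels = np.unique(g)
    if levels.size < 2 or np.unique(r).size < 2:
        raise ValueError("both channels need >= 2 distinct intensity levels")
    slope, intercept = np.polyfit(g.astype(float), r.astype(float), 1)
    slope, intercept = float(slope), float(intercept)

    integer_ok = (
        np.issubdtype(pair.green.dtype, np.integer)
        and np.issubdtype(pair.red.dtype, np.integer)
        and g.size * float(max(g.max(), r.max(), 1)) ** 2 * g.size < 2**62
    )

    def finish(level: float, status: str) -> CostesThresholds:
        return CostesThresholds(
            T_green=float(level),
            T_red=float(intercept + slope * level),
            slope=slope,
            intercept=intercept,
            status=status,
        )

    if slope > 0:
        # below-threshold set is a prefix of pixels ordered by
        # s = max(g, (r - intercept) / slope): vectorised exact search
        s = np.maximum(g.astype(float), (r.astype(float) - intercept) / slope)
        order = np.argsort(s, kind="stable")
        s_sorted = s[order]
        gs = g[order].astype(np.int64 if integer_ok else float)
        rs = r[order].astype(np.int64 if integer_ok else float)
        c_g = np.cumsum(gs)
        c_r = np.cumsum(rs)
        c_gg = np.cumsum(gs * gs)
        c_rr = np.cumsum(rs * rs)
        c_gr = np.cumsum(gs * rs)
        ks = np.searchsorted(s_sorted, levels[::-1], side="left")
        for level, k in zip(levels[::-1], ks):
            if k < 3:
                return finish(level, "flagged")
            n = int(k)
            cov = n * c_gr[k - 1] - c_g[k - 1] * c_r[k - 1]
            var_g = n * c_gg[k - 1] - c_g[k - 1] ** 2
            var_r = n * c_rr[k - 1] - c_r[k - 1] ** 2
            if var_g == 0 or var_r == 0:
                return finish(level, "flagged")
            if cov <= 0:
                return finish(level, "ok")
            r_below = float(cov) / math.sqrt(float(var_g) * float(var_r))
            if r_below <= max(uncorrelated_band, 2.0 / math.sqrt(n)):
                return finish(level, "flagged")
        return finish(levels[0], "flagged")

    # non-positive slope: plain descending scan
    gf = g.astype(float)
    rf = r.astype(float)
    for level in levels[::-1]:
        t_red = intercept + slope * level
        below = (gf < level) & (rf < t_red)
        if below.sum() < 3:
            return finish(level, "flagged")
        gb = g[below].astype(float)
        rb = r[below].astype(float)
        if gb.std() == 0 or rb.std() == 0:
            return finish(level, "flagged")
        r_below = float(np.corrcoef(gb, rb)[0, 1])
        if r_below <= 0:
            return finish(level, "ok")
        if r_below <= max(uncorrelated_band, 2.0 / math.sqrt(gb.size)):
            return finish(level, "flagged")
    return finish(levels[0], "flagged")


def manders(pair: ChannelPair, t_green: float, t_red: float) -> Tuple[float, float]:
    """Thresholded Manders coefficients.

    M1 = fraction of total red intensity lying on green-above-threshold
    pixels; M2 = fraction of total green intensity lying on
    red-above-threshold pixels.
    """
    g = pair.green[pair.roi].astype(float)
    r = pair.red[pair.roi].astype(float)
    tot_r, tot_g = r.sum(), g.sum()
    if tot_r == 0 or tot_g == 0:
        raise ValueError("zero total intensity: Manders undefined")
    m1 = float(r[g > t_green].sum() / tot_r)
    m2 = float(g[r > t_red].sum() / tot_g)
    return m1, m2


def translated_control(pair: ChannelPair, dx_px: int, dy_px: int) -> ChannelPair:
    """Shift the green channel by (+dx, +dy) pixels (x = columns, y = rows)
    with no wraparound; the analysis ROI is restricted to the overlap."""
    h, w = pair.green.shape
    if abs(dx_px) >= w or abs(dy_px) >= h:
        raise ValueError("offset must be smaller than the image")

    def crop(a: np.ndarray, dy: int, dx: int) -> np.ndarray:
        r0, r1 = max(dy, 0), h + min(dy, 0)
        c0, c1 = max(dx, 0), w + min(dx, 0)
        return a[r0:r1, c0:c1]

    # green pixel (r, c) lands on (r + dy, c + dx): pair shifted green
    # against the untouched red over the overlap region
    green = crop(pair.green, -dy_px, -dx_px)
    red = crop(pair.red, dy_px, dx_px)
    roi = crop(pair.roi, -dy_px, -dx_px) & crop(pair.roi, dy_px, dx_px)
    return ChannelPair(green=green, red=red, roi=roi)


def coloc_analysis(
    pair: ChannelPair,
    offsets: Tuple[int, int] = (100, 100),
    above_rule: str = "either",
    uncorrelated_band: float = 0.02,
) -> ColocResult:
    """Full analysis: Costes thresholds, R/M1/M2 on above-threshold pixels,
    then the same coefficients on the translated negative control (with its
    thresholds re-estimated on the translated pair)."""
    if above_rule not in ("either", "both"):
        raise ValueError("above_rule must be 'either' or 'both'")

    def run(p: ChannelPair) -> Tuple[float, float, float, CostesThresholds, int]:
        th = costes_thresholds(p, uncorrelated_band=uncorrelated_band)
        g = p.green.astype(float)
        r = p.red.astype(float)
        if above_rule == "either":
            above = (g > th.T_green) | (r > th.T_red)
        else:
            above = (g > th.T_green) & (r > th.T_red)
        above &= p.roi
        n = int(above.sum())
        try:
            rr = pearson(p, above)
        except ValueError:
            rr = float("nan")
        m1, m2 = manders(p, th.T_green, th.T_red)
        return rr, m1, m2, th, n

    R, M1, M2, th, n_pixels = run(pair)
    ctrl = translated_control(pair, *offsets)
    tR, tM1, tM2, tth, _ = run(ctrl)

    return ColocResult(
        R=R,
        M1=M1,
        M2=M2,
        T_green=th.T_green,
        T_red=th.T_red,
        slope=th.slope,
        intercept=th.intercept,
        tR=tR,
        tM1=tM1,
        tM2=tM2,
        n_pixels=n_pixels,
        threshold_status=th.status,
        control_threshold_status=tth.status,
        decisions={
            "above_threshold_rule": above_rule,
            "m1_channel": "red_in_green",
            "control_thresholds": "re-estimated on translated pair",
            "translation": "no wraparound, overlap-restricted ROI",
        },
    )


# ---------------------------------------------------------------------------
# group comparison


@dataclass
class GroupComparison:
    H: float
    p: float
    dunn_p: Dict[Tuple[int, int], float]
    dunn_z: Dict[Tuple[int, int], float]
    adjust: str = "bonferroni"
    degenerate: bool = False


def _dunn(groups: Sequence[np.ndarray], adjust: str = "bonferroni") -> Tuple[dict, dict]:
    """Dunn's pairwise rank tests after Kruskal-Wallis, with tie correction."""
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie = (counts**3 - counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie

    mean_ranks = []
    start = 0
    for grp in groups:
        mean_ranks.append(ranks[start : start + grp.size].mean())
        start += grp.size

    k = len(groups)
    n_pairs = k * (k - 1) // 2
    zs, ps = {}, {}
    for i, j in combinations(range(k), 2):
        se = math.sqrt(var_base * (1.0 / groups[i].size + 1.0 / groups[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * n_pairs)
        zs[(i, j)] = float(z)
        ps[(i, j)] = float(p)
    return ps, zs


def compare_groups(
    groups: Sequence[Sequence[float]], adjust: str = "bonferroni"
) -> GroupComparison:
    """Kruskal-Wallis H (tie-corrected) with Dunn's post test.

    Returns pairwise p-values keyed by group-index pairs; a degenerate flag
    is raised when every value is tied across all groups.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with n >= 2 each")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        keys = list(combinations(range(len(arrays)), 2))
        return GroupComparison(
            H=0.0,
            p=1.0,
            dunn_p={k: 1.0 for k in keys},
            dunn_z={k: 0.0 for k in keys},
            adjust=adjust,
            degenerate=True,
        )
    H, p = stats.kruskal(*arrays)
    dunn_p, dunn_z = _dunn(arrays, adjust)
    return GroupComparison(H=float(H), p=float(p), dunn_p=dunn_p, dunn_z=dunn_z, adjust=adjust)
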