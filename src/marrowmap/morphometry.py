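"""Inner-caliber morphometry and vessel classification.

NESTIN-positive structures are sorted into five categories from three
observables: the lumen inner caliber (IC, um), the presence of a
perivascular (CD146+/alpha-SMA+) cell layer, and a tubular-shape flag from
3-D reconstruction (supplied as input):

* ``NC``   - not tubular: a single cell or small cluster;
* ``NCLT`` - tubular without pericytes: capillary-like tube;
* ``cEA``  - tubular, pericytes, compressed morphology, IC at or below the
  pooled median: arteriole with an artifactually compressed lumen;
* ``EA``   - tubular, pericytes, IC between the median and upper quartile;
* ``A``    - tubular, pericytes, IC above the upper quartile.

The quartile cut-offs are estimated from the measured calibers themselves
(zero-caliber structures excluded by default, since an imperceptible lumen
is a detection floor rather than a measurement).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats
from skimage import measure

CLASSES = ("A", "EA", "cEA", "NCLT", "NC")
IC_BANDS = ("no-lumen", "<=q25", "q25-q50", "q50-q75", ">q75")
COMPLEXITY_COLUMNS = (
    "pericytes_tubular",
    "nopericytes_tubular",
    "pericytes_nontubular",
    "nopericytes_nontubular",
)


@dataclass
class QuartileCutoffs:
    q25: float
    q50: float
    q75: float

    def __post_init__(self) -> None:
        if not 0 <= self.q25 <= self.q50 <= self.q75:
            raise ValueError("quartiles must satisfy 0 <= q25 <= q50 <= q75")


@dataclass
class ContingencyTable:
    """Caliber-band x complexity counts with a list of excluded columns."""

    counts: pd.DataFrame
    excluded_columns: List[str] = field(
        default_factory=lambda: ["pericytes_nontubular"]
    )


def measure_inner_caliber(lumen_mask: np.ndarray, um_per_px: float) -> float:
    """Inner caliber (um) of a lumen mask.

    Empty mask -> 0 (imperceptible lumen).  Otherwise the minor-axis length
    of the best-fit ellipse of the largest connected lumen component, which
    is robust to the compression artifact that squeezes lumens along one
    axis.
    """
    lumen_mask = np.asarray(lumen_mask)
    vals = np.unique(lumen_mask)
    if not np.isin(vals, (0, 1, True, False)).all():
        raise ValueError("lumen mask must be binary")
    mask = lumen_mask.astype(bool)
    if not mask.any():
        return 0.0
    labels = measure.label(mask)
    props = measure.regionprops(labels)
    largest = max(props, key=lambda p: p.area)
    return float(largest.axis_minor_length * um_per_px)


def compute_quartiles(
    ic_values: Sequence[float], exclude_zero: bool = True
) -> QuartileCutoffs:
    """Empirical 25/50/75th percentile cut-offs (linear interpolation)."""
    vals = np.asarray(ic_values, dtype=float)
    if exclude_zero:
        vals = vals[vals > 0]
    if vals.size < 4:
        raise ValueError("need >= 4 caliber values to estimate quartiles")
    q25, q50, q75 = np.percentile(vals, [25, 50, 75])
    return QuartileCutoffs(float(q25), float(q50), float(q75))


def classify_structure(
    record: Mapping, cutoffs: QuartileCutoffs
) -> Tuple[str, bool]:
    """Assign a class to one structure; returns (class, warning_flag).

    Rules, in order: non-tubular -> NC; tubular without pericytes -> NCLT;
    compressed with IC <= median -> cEA; IC in (median, q75] -> EA;
    IC > q75 -> A.  A pericyte-bearing small-caliber vessel without the
    compressed flag is assigned cEA with a warning (it is morphologically
    indistinguishable from a compressed arteriole in a single section).
    """
    ic = float(record["ic_um"])
    if ic < 0:
        raise ValueError("ic_um must be >= 0")
    if not record["tubular"]:
        return "NC", False
    if not record["has_pericytes"]:
        return "NCLT", False
    compressed = bool(record.get("compressed", False))
    if compressed and ic <= cutoffs.q50:
        return "cEA", False
    if cutoffs.q50 < ic <= cutoffs.q75:
        return "EA", False
    if ic > cutoffs.q75:
        return "A", False
    return "cEA", True


def classify_table(
    table: pd.DataFrame, cutoffs: Optional[QuartileCutoffs] = None
) -> Tuple[pd.DataFrame, QuartileCutoffs]:
    """Classify every row of a vessel table; adds ``assigned_class`` and
    ``class_warning`` columns.  Cut-offs are estimated from the table when
    not supplied."""
    if cutoffs is None:
        cutoffs = compute_quartiles(table["ic_um"].to_numpy())
    out = table.copy()
    assigned, warns = [], []
    for _, row in out.iterrows():
        cls, warn = classify_structure(row, cutoffs)
        assigned.append(cls)
        warns.append(warn)
    out["assigned_class"] = assigned
    out["class_warning"] = warns
    return out, cutoffs


def class_percentages(records: pd.DataFrame, column: str = "assigned_class") -> dict:
    """Percent of tubular vessels per class, to one decimal.

    The denominator counts tubular records only (NC excluded); the
    arteriolar fraction is reported both jointly (EA+cEA) and separately.
    """
    tub = records[records["tubular"].astype(bool)]
    n = len(tub)
    if n == 0:
        raise ValueError("no tubular records")
    counts = tub[column].value_counts()
    out = {}
    for cls in ("A", "EA", "cEA", "NCLT"):
        if counts.get(cls, 0):
            out[cls] = float(round(100.0 * counts.get(cls, 0) / n, 1))
    ea_cea = counts.get("EA", 0) + counts.get("cEA", 0)
    if ea_cea:
        out["EA+cEA"] = float(round(100.0 * ea_cea / n, 1))
    return out


def _band(ic: float, cutoffs: QuartileCutoffs) -> str:
    if ic == 0:
        return "no-lumen"
    if ic <= cutoffs.q25:
        return "<=q25"
    if ic <= cutoffs.q50:
        return "q25-q50"
    if ic <= cutoffs.q75:
        return "q50-q75"
    return ">q75"


def build_contingency(
    records: pd.DataFrame, cutoffs: QuartileCutoffs
) -> ContingencyTable:
    """5 caliber bands x complexity columns; counts partition the records."""
    if len(records) == 0:
        raise ValueError("need >= 1 record")
    counts = pd.DataFrame(
        0, index=list(IC_BANDS), columns=list(COMPLEXITY_COLUMNS), dtype=int
    )
    for _, row in records.iterrows():
        band = _band(float(row["ic_um"]), cutoffs)
        peri = "pericytes" if row["has_pericytes"] else "nopericytes"
        tub = "tubular" if row["tubular"] else "nontubular"
        counts.loc[band, f"{peri}_{tub}"] += 1
    return ContingencyTable(counts=counts)


def chi_square(table: ContingencyTable) -> Tuple[float, int, float]:
    """Pearson chi-square on the table after dropping excluded columns and
    zero-marginal rows/columns; returns (statistic, df, p)."""
    counts = table.counts.drop(columns=table.excluded_columns, errors="ignore")
    counts = counts.loc[counts.sum(axis=1) > 0, counts.sum(axis=0) > 0]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("degenerate contingency table")
    chi2, p, dof, _ = sstats.chi2_contingency(counts.to_numpy(), correction=False)
    return float(chi2), int(dof), float(p)


class VesselClassifier:
    """Estimator-style wrapper: ``fit`` learns the quartile cut-offs from
    measured calibers, ``predict`` assigns classes to a vessel table."""

    def __init__(self, exclude_zero: bool = True):
        self.exclude_zero = exclude_zero

    def get_params(self, deep: bool = True) -> dict:
        return {"exclude_zero": self.exclude_zero}

    def set_params(self, **params) -> "VesselClassifier":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y: Optional[Iterable] = None) -> "VesselClassifier":
        self.cutoffs_ = compute_quartiles(
            np.asarray(X["ic_um"], dtype=float), exclude_zero=self.exclude_zero
        )
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "cutoffs_"):
            raise ValueError("classifier is not fitted")
        out, _ = classify_table(X, self.cutoffs_)
        return out["assigned_class"].to_numpy()
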