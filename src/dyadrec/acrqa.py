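"""Anisotropic CRQA: vertical vs horizontal line structure of recurrence plots.

Categorical cross-recurrence plots are dominated by rectangular blocks
rather than diagonal lines, so the classic diagonal RQA measures carry
little information.  Instead, the vertical and horizontal line structures
are quantified separately:

* **laminarity (LAM)** — proportion of recurrent points lying on lines of
  length >= lmin;
* **trapping time (TT)** — mean length of those lines;
* **maximum line (MaxL)** — length of the longest one.

With the parent on the horizontal axis and the infant on the vertical axis,
a vertical line marks an interval during which the infant dwells in a state
matching one moment of the parent, and a horizontal line the converse.
Systematic asymmetry between the two orientations therefore exposes
asymmetric dynamic attunement: longer horizontal lines mean the parent
persists in matching states longer than the infant does.

Lines are maximal runs of 1s along rows or columns, not wrapped at the
matrix border; the main diagonal is kept (between two different systems it
carries no trivial self-match).  Lengths are counted in recurrence points;
multiply by 1000/fps for milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .crqa import RecurrencePlot


class AcrqaError(ValueError):
    pass


@dataclass
class AnisotropicMeasures:
    """LAM/TT/MaxL for both line orientations of one recurrence plot."""

    lam_v: float
    lam_h: float
    tt_v: float
    tt_h: float
    maxl_v: int
    maxl_h: int
    lmin: int
    n_recurrent_points: int
    defined_v: bool = True
    defined_h: bool = True
    dyad_id: str = ""

    def to_row(self) -> dict:
        return {
            "dyad_id": self.dyad_id,
            "lam_v": self.lam_v,
            "lam_h": self.lam_h,
            "tt_v": self.tt_v,
            "tt_h": self.tt_h,
            "maxl_v": self.maxl_v,
            "maxl_h": self.maxl_h,
            "lmin": self.lmin,
            "n_recurrent_points": self.n_recurrent_points,
        }


def _run_lengths(rows: np.ndarray) -> np.ndarray:
    """Lengths of all maximal runs of True along the last axis."""
    n = rows.shape[-1]
    padded = np.zeros((rows.shape[0], n + 2), dtype=np.int8)
    padded[:, 1:-1] = rows
    d = np.diff(padded, axis=1)
    starts = np.argwhere(d == 1)
    ends = np.argwhere(d == -1)
    # argwhere returns row-major order, so starts/ends pair up within rows
    return (ends[:, 1] - starts[:, 1]).astype(np.int64)


def line_length_distribution(
    plot: RecurrencePlot, orientation: str, lmin: int = 2
) -> np.ndarray:
    """Multiset of maximal run lengths >= lmin along one orientation.

    Vertical lines run along columns (consecutive infant times at a fixed
    parent time); horizontal lines along rows.
    """
    if lmin < 2:
        raise AcrqaError("lmin must be >= 2")
    if orientation == "vertical":
        arr = plot.matrix.T  # columns become rows
    elif orientation == "horizontal":
        arr = plot.matrix
    else:
        raise AcrqaError(f"orientation must be 'vertical' or 'horizontal', got {orientation!r}")
    lengths = _run_lengths(arr.astype(np.int8))
    return np.sort(lengths[lengths >= lmin])


def acrqa_measures(plot: RecurrencePlot, lmin: int = 2, dyad_id: str = "") -> AnisotropicMeasures:
    """Compute LAM, TT and MaxL for both orientations of a recurrence plot.

    When an orientation has no qualifying line (or the plot has no
    recurrent points at all) its measures are reported as 0 with
    ``defined_* = False`` so cohort tables remain rectangular.
    """
    total = int(plot.matrix.sum())
    out = {}
    defined = {}
    for orient, key in (("vertical", "v"), ("horizontal", "h")):
        lengths = line_length_distribution(plot, orient, lmin)
        if total == 0 or lengths.size == 0:
            out[f"lam_{key}"], out[f"tt_{key}"], out[f"maxl_{key}"] = 0.0, 0.0, 0
            defined[key] = False
        else:
            out[f"lam_{key}"] = float(lengths.sum()) / total
            out[f"tt_{key}"] = float(lengths.mean())
            out[f"maxl_{key}"] = int(lengths.max())
            defined[key] = True
    return AnisotropicMeasures(
        lam_v=out["lam_v"], lam_h=out["lam_h"],
        tt_v=out["tt_v"], tt_h=out["tt_h"],
        maxl_v=out["maxl_v"], maxl_h=out["maxl_h"],
        lmin=lmin, n_recurrent_points=total,
        defined_v=defined["v"], defined_h=defined["h"],
        dyad_id=dyad_id or plot.dyad_id,
    )


def ms_from_points(points: float, fps: float) -> float:
    """Convert a line length in recurrence points to milliseconds (1000/fps per point)."""
    if fps <= 0:
        raise AcrqaError("fps must be positive")
    return 1000.0 * points / fps


def cohort_table(measures: list[AnisotropicMeasures]) -> pd.DataFrame:
    return pd.DataFrame([m.to_row() for m in measures])


def asymmetry_test(measures: list[AnisotropicMeasures]) -> pd.DataFrame:
    """Paired t-tests of vertical vs horizontal LAM, TT and MaxL across dyads.

    The test statistic is computed on per-dyad differences
    vertical - horizontal, so a negative t means horizontal lines dominate
    (the parent-side dwell times are longer).  Cohen's d for paired data is
    mean(diff) / SD(diff); a zero-variance difference yields an
    undefined-statistic flag instead of a number.
    """
    if len(measures) < 2:
        raise AcrqaError("need at least 2 dyads for a paired test")
    rows = []
    for name, v_attr, h_attr in (
        ("LAM", "lam_v", "lam_h"),
        ("TT", "tt_v", "tt_h"),
        ("MaxL", "maxl_v", "maxl_h"),
    ):
        v = np.array([getattr(m, v_attr) for m in measures], dtype=float)
        h = np.array([getattr(m, h_attr) for m in measures], dtype=float)
        diff = v - h
        sd = diff.std(ddof=1)
        if sd == 0:
            if np.allclose(diff, 0):
                rows.append({"measure": name, "t": 0.0, "df": len(diff) - 1,
                             "p": 1.0, "d": 0.0, "defined": True})
            else:
                rows.append({"measure": name, "t": np.nan, "df": len(diff) - 1,
                             "p": np.nan, "d": np.nan, "defined": False})
            continue
        res = sps.ttest_rel(v, h)
        d = diff.mean() / sd
        rows.append({"measure": name, "t": float(res.statistic), "df": int(res.df),
                     "p": float(res.pvalue), "d": float(d), "defined": True})
    return pd.DataFrame(rows)
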