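"""Spatial staging along the gonad and group statistics.

Germline nuclei progress through meiotic prophase as they move along the
gonad's long axis, so position approximates time.  The unit of staging is
the "cell row": here, a bin of nucleus-centroid x positions of fixed pitch.
Zones are defined by per-row majority rules —

* CHK-2 active zone: the longest contiguous run of rows in which the
  majority (> 50%) of nuclei are flagged (SUN-1 pS24 positive);
* early pachytene: from the first row where most nuclei have >= 1 RAD-51
  focus to the first subsequent row where most nuclei have 6 CO-site foci
  (MSH-5 or HIM-6);
* peak-accumulation window: the 10-row window maximizing the median
  per-nucleus focus count.

Group comparisons delegate to scipy (Mann-Whitney U, Welch's t, Fisher
exact), all two-sided.  Brood-viability arithmetic follows the egg-count
bookkeeping: total eggs = max(eggs at tp1, eggs at tp2, adults at tp3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from .core import NucleusROI


@dataclass
class ZoneResult:
    """A contiguous row interval [start_row, end_row], inclusive."""

    start_row: int
    end_row: int
    rule: str

    def __post_init__(self) -> None:
        if self.length_rows and self.start_row > self.end_row:
            raise ValueError("start_row must be <= end_row")

    @property
    def length_rows(self) -> int:
        if self.start_row < 0:  # empty-zone sentinel
            return 0
        return self.end_row - self.start_row + 1


EMPTY_ZONE = ZoneResult(start_row=-1, end_row=-1, rule="empty")


def assign_rows(rois: Sequence[NucleusROI], row_pitch: Optional[float] = None) -> list[NucleusROI]:
    """Bin nuclei into cell rows by centroid x: row = floor((cx - min_cx) / pitch).

    ``row_pitch`` defaults to the median nearest-neighbor centroid spacing
    along x (distinct x values).  Returns the same ROI objects with
    ``row_index`` set, in input order.
    """
    if not rois:
        return []
    cx = np.asarray([r.centroid_xy[0] for r in rois], dtype=float)
    if row_pitch is None:
        # round away float noise so nuclei of one row share a single x value
        ux = np.unique(np.round(cx, 6))
        if len(ux) < 2:
            row_pitch = 1.0
        else:
            row_pitch = float(np.median(np.diff(ux)))
    if row_pitch <= 0:
        raise ValueError("row_pitch must be > 0")
    x0 = cx.min()
    for r, x in zip(rois, cx):
        # guard against float epsilon pushing an on-boundary centroid down a row
        r.row_index = int(np.floor((x - x0) / row_pitch + 1e-9))
    return list(rois)


def _majority_rows(values_by_row: dict[int, list], predicate: Callable) -> dict[int, bool]:
    return {
        row: (sum(bool(predicate(v)) for v in vals) > 0.5 * len(vals))
        for row, vals in values_by_row.items()
        if len(vals) > 0
    }


def _group_by_row(rows: Sequence[int], values: Sequence) -> dict[int, list]:
    out: dict[int, list] = {}
    for r, v in zip(rows, values):
        out.setdefault(int(r), []).append(v)
    return out


def majority_zone(flags: Sequence[bool], rows: Sequence[int], rule: str = "majority") -> ZoneResult:
    """Longest contiguous run of rows where > 50% of nuclei are flagged.

    Ties between equally long runs go to the earliest (most distal) run.
    Rows with no nuclei break contiguity.  Returns the empty zone when no
    row is positive.
    """
    if len(flags) == 0:
        raise ValueError("no nuclei supplied")
    if len(flags) != len(rows):
        raise ValueError("flags and rows must align")
    pos = _majority_rows(_group_by_row(rows, flags), bool)
    best: tuple[int, int] | None = None
    start: int | None = None
    all_rows = range(min(pos), max(pos) + 1)
    for row in all_rows:
        if pos.get(row, False):
            if start is None:
                start = row
        else:
            if start is not None:
                if best is None or (row - 1 - start) > (best[1] - best[0]):
                    best = (start, row - 1)
                start = None
    if start is not None:
        last = max(pos)
        if best is None or (last - start) > (best[1] - best[0]):
            best = (start, last)
    if best is None:
        return EMPTY_ZONE
    return ZoneResult(start_row=best[0], end_row=best[1], rule=rule)


def boundary_by_count_rule(
    counts_start: Sequence[float],
    counts_end: Sequence[float],
    rows: Sequence[int],
    start_predicate: Callable[[float], bool],
    end_predicate: Callable[[float], bool],
    rule: str = "count-rule",
) -> ZoneResult:
    """Zone from per-row majority count rules.

    start = first row where > 50% of nuclei satisfy ``start_predicate`` on
    ``counts_start``; end = first row at or after the start where > 50%
    satisfy ``end_predicate`` on ``counts_end``.  Raises if either rule is
    never met.  The canonical early-pachytene rule is
    ``start_predicate = counts >= 1`` on RAD-51 and ``end_predicate =
    counts == 6`` on MSH-5 / HIM-6.
    """
    if len(counts_start) != len(rows) or len(counts_end) != len(rows):
        raise ValueError("counts and rows must align")
    start_pos = _majority_rows(_group_by_row(rows, counts_start), start_predicate)
    end_pos = _majority_rows(_group_by_row(rows, counts_end), end_predicate)
    start = next((r for r in sorted(start_pos) if start_pos[r]), None)
    if start is None:
        raise ValueError("start rule unmet in every row")
    end = next((r for r in sorted(end_pos) if r >= start and end_pos[r]), None)
    if end is None:
        raise ValueError("end rule unmet in every row at or after the start")
    return ZoneResult(start_row=start, end_row=end, rule=rule)


def peak_window(
    counts: Sequence[float], rows: Sequence[int], width_rows: int = 10
) -> ZoneResult:
    """The ``width_rows``-wide window maximizing the median per-nucleus count.

    The window median is taken over all nuclei whose row falls in the
    window.  Ties go to the earliest window.  Raises when fewer distinct
    row positions than the width exist.
    """
    if len(counts) != len(rows):
        raise ValueError("counts and rows must align")
    by_row = _group_by_row(rows, counts)
    lo, hi = min(by_row), max(by_row)
    n_rows = hi - lo + 1
    if width_rows > n_rows:
        raise ValueError(f"window width {width_rows} exceeds {n_rows} rows present")
    best_start, best_med = None, -np.inf
    for s in range(lo, hi - width_rows + 2):
        vals = [v for r in range(s, s + width_rows) for v in by_row.get(r, [])]
        if not vals:
            continue
        med = float(np.median(vals))
        if med > best_med:
            best_start, best_med = s, med
    if best_start is None:
        raise ValueError("no nuclei in any window")
    return ZoneResult(start_row=best_start, end_row=best_start + width_rows - 1, rule="peak-window")


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float


def compare_groups(x, y=None, test: str = "mann-whitney") -> TestResult:
    """Two-sided group comparison: ``mann-whitney``, ``welch-t`` or ``fisher-exact``.

    For Fisher's exact test pass a 2x2 count table as ``x`` (``y`` unused).
    """
    if test == "fisher-exact":
        table = np.asarray(x)
        if table.shape != (2, 2):
            raise ValueError("fisher-exact needs a 2x2 count table")
        res = stats.fisher_exact(table, alternative="two-sided")
        return TestResult(test=test, statistic=float(res[0]), p_value=float(res[1]))
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    if test == "mann-whitney":
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        return TestResult(test=test, statistic=float(res.statistic), p_value=float(res.pvalue))
    if test == "welch-t":
        res = stats.ttest_ind(x, y, equal_var=False)
        return TestResult(test=test, statistic=float(res.statistic), p_value=float(res.pvalue))
    raise ValueError(f"unknown test {test!r}")


@dataclass
class BroodViability:
    total_eggs: int
    pct_hatching: float
    pct_adulthood: float
    pct_males: float


def brood_viability(
    eggs_tp1: int, eggs_tp2: int, unhatched_tp2: int, adults_tp3: int, males_tp3: int
) -> BroodViability:
    """Brood-viability percentages from the three time-point counts.

    total eggs laid = max(eggs+larvae at tp1, eggs+larvae at tp2, adults at
    tp3) — whichever is larger, to absorb undercounting of young larvae and
    larval lethality.  Then:

    * % eggs hatching   = 100 * (1 - unhatched at tp2 / total eggs)
    * % reaching adulthood = 100 * adults / total eggs
    * % males           = 100 * males / adults
    """
    if min(eggs_tp1, eggs_tp2, unhatched_tp2, adults_tp3, males_tp3) < 0:
        raise ValueError("counts must be >= 0")
    total = max(eggs_tp1, eggs_tp2, adults_tp3)
    if total == 0:
        raise ValueError("no eggs laid")
    pct_hatch = 100.0 * (1.0 - unhatched_tp2 / total)
    pct_adult = 100.0 * adults_tp3 / total
    pct_males = 100.0 * males_tp3 / adults_tp3 if adults_tp3 else float("nan")
    return BroodViability(
        total_eggs=total,
        pct_hatching=pct_hatch,
        pct_adulthood=pct_adult,
        pct_males=pct_males,
    )
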