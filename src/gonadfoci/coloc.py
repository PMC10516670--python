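"""Object-based colocalization of focus species under resolution-limit thresholds.

Two foci of different species colocalize when the 3D Euclidean distance
between their intensity maxima (in nm, voxel-centre coordinates) is
strictly under the smallest resolvable distance of the optics,

    d_min = 0.61 * lambda / NA,

i.e. 242 nm for lambda = 555 nm and 282 nm for lambda = 647 nm at NA = 1.4.
Classification is directional: each query focus is tested against its
nearest neighbor in the reference species, so A-vs-B and B-vs-A counts need
not match.  Three-species category labels (solo / +X / +Y / +X+Y) come from
independent pairwise tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from statsmodels.stats.proportion import proportion_confint


def resolution_threshold(emission_nm: float, numerical_aperture: float) -> float:
    """Rayleigh-criterion resolution limit 0.61*lambda/NA, in nm (exact)."""
    if emission_nm <= 0 or numerical_aperture <= 0:
        raise ValueError("emission wavelength and NA must be > 0")
    return 0.61 * emission_nm / numerical_aperture


def resolution_threshold_int(emission_nm: float, numerical_aperture: float) -> int:
    """The threshold rounded to integer nm, as reported."""
    return int(round(resolution_threshold(emission_nm, numerical_aperture)))


def pair_threshold(
    emission_a_nm: float, emission_b_nm: float, numerical_aperture: float = 1.4
) -> float:
    """Threshold for a two-channel pair: set by the longer (redder) wavelength.

    The resolution limit of the pair is dictated by the worse-resolved
    channel; this is the default and can be overridden per pair.
    """
    return resolution_threshold(max(emission_a_nm, emission_b_nm), numerical_aperture)


@dataclass
class ColocRecord:
    """Nearest-neighbor result for one query focus against one or more references."""

    focus_id: str
    species: str
    neighbors: dict = field(default_factory=dict)  # other species -> (distance_nm, partner_id)
    colocalized_with: list = field(default_factory=list)  # other species labels, sorted

    @property
    def category(self) -> str:
        if not self.colocalized_with:
            return "solo"
        return "+".join([self.species] + sorted(self.colocalized_with))


def _positions_nm(foci) -> np.ndarray:
    return np.asarray([f.position_nm for f in foci], dtype=float).reshape(-1, 3)


def nearest_neighbor_classify(
    query: Sequence, reference: Sequence, threshold_nm: float, reference_species: Optional[str] = None
) -> list[ColocRecord]:
    """Classify each query focus by its nearest reference focus in 3D.

    Colocalized iff the nearest-neighbor distance is strictly under
    ``threshold_nm``.  An empty reference list yields distance +inf and no
    colocalization for every query.
    """
    ref_label = reference_species or (reference[0].species if reference else "reference")
    records = []
    if len(reference) == 0:
        for q in query:
            records.append(
                ColocRecord(
                    focus_id=q.id,
                    species=q.species,
                    neighbors={ref_label: (np.inf, None)},
                )
            )
        return records
    tree = cKDTree(_positions_nm(reference))
    dists, idx = tree.query(_positions_nm(query), k=1)
    for q, d, i in zip(query, np.atleast_1d(dists), np.atleast_1d(idx)):
        rec = ColocRecord(
            focus_id=q.id,
            species=q.species,
            neighbors={ref_label: (float(d), reference[int(i)].id)},
        )
        if d < threshold_nm:
            rec.colocalized_with.append(ref_label)
        records.append(rec)
    return records


def categorize_three_species(
    species_foci: dict, thresholds_nm: dict
) -> tuple[dict, list[ColocRecord]]:
    """Label every focus of each species solo / +X / +Y / +X+Y.

    Parameters
    ----------
    species_foci : mapping species label -> list of Focus
    thresholds_nm : mapping frozenset({a, b}) or (a, b) tuple -> threshold nm

    Returns
    -------
    (counts, records) where counts maps species -> {category: n} and
    per-species category counts sum to the per-species focus totals.
    """
    thr = {frozenset(k): v for k, v in thresholds_nm.items()}
    labels = sorted(species_foci)
    records: list[ColocRecord] = []
    counts: dict[str, dict[str, int]] = {}
    for sp in labels:
        per_focus = {f.id: ColocRecord(focus_id=f.id, species=sp) for f in species_foci[sp]}
        for other in labels:
            if other == sp:
                continue
            key = frozenset({sp, other})
            if key not in thr:
                raise KeyError(f"no threshold supplied for pair {sp}/{other}")
            for rec in nearest_neighbor_classify(
                species_foci[sp], species_foci[other], thr[key], reference_species=other
            ):
                per_focus[rec.focus_id].neighbors.update(rec.neighbors)
                per_focus[rec.focus_id].colocalized_with.extend(rec.colocalized_with)
        sp_counts: dict[str, int] = {}
        for rec in per_focus.values():
            rec.colocalized_with.sort()
            sp_counts[rec.category] = sp_counts.get(rec.category, 0) + 1
            records.append(rec)
        counts[sp] = sp_counts
    return counts, records


def proportion_ci(k: int, n: int, method: str = "wilson") -> tuple[float, float]:
    """95% confidence interval for a binomial fraction k/n.

    Wilson score by default (well behaved at extreme fractions);
    ``method="beta"`` gives Clopper-Pearson.
    """
    if n == 0:
        raise ValueError("n must be > 0")
    lo, hi = proportion_confint(k, n, alpha=0.05, method=method)
    return float(lo), float(hi)


def category_fractions(counts: dict[str, int], total: Optional[int] = None) -> pd.DataFrame:
    """Fractions (as percentages) with Wilson 95% CIs from category tallies."""
    total = total if total is not None else sum(counts.values())
    rows = []
    for cat, k in counts.items():
        if total == 0:
            rows.append({"category": cat, "count": k, "total": 0, "pct": np.nan,
                         "ci_low_pct": np.nan, "ci_high_pct": np.nan})
            continue
        lo, hi = proportion_ci(k, total)
        rows.append(
            {
                "category": cat,
                "count": k,
                "total": total,
                "pct": 100.0 * k / total,
                "ci_low_pct": 100.0 * lo,
                "ci_high_pct": 100.0 * hi,
            }
        )
    return pd.DataFrame(rows)


def coloc_report(
    records: Sequence[ColocRecord],
    rel_positions: Optional[dict] = None,
    ci_method: str = "wilson",
) -> pd.DataFrame:
    """Per-category fractions with 95% CI and median relative gonad position.

    Parameters
    ----------
    records : records from one classification run (one species)
    rel_positions : optional mapping focus_id -> rel_position_pct; medians
        are computed per category over the foci that have one.

    Returns
    -------
    DataFrame with columns category, count, total, pct, ci_low_pct,
    ci_high_pct, median_rel_position_pct.  An empty run yields an empty
    frame with total 0.
    """
    total = len(records)
    by_cat: dict[str, list[ColocRecord]] = {}
    for rec in records:
        by_cat.setdefault(rec.category, []).append(rec)
    rows = []
    for cat in sorted(by_cat):
        recs = by_cat[cat]
        k = len(recs)
        lo, hi = proportion_ci(k, total, method=ci_method)
        med = np.nan
        if rel_positions:
            vals = [rel_positions[r.focus_id] for r in recs
                    if rel_positions.get(r.focus_id) is not None]
            if vals:
                med = float(np.median(vals))
        rows.append(
            {
                "category": cat,
                "count": k,
                "total": total,
                "pct": 100.0 * k / total,
                "ci_low_pct": 100.0 * lo,
                "ci_high_pct": 100.0 * hi,
                "median_rel_position_pct": med,
            }
        )
    cols = ["category", "count", "total", "pct", "ci_low_pct", "ci_high_pct",
            "median_rel_position_pct"]
    return pd.DataFrame(rows, columns=cols)
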