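"""Phenotype scoring, cell-length measurement, detachment assays, statistics.

Injured podocytes re-seeded ex vivo are scored manually into four
categories according to where sarcomere-like structures (SLSs) appear:

* ``sls_central_peripheral`` — SLSs both centrally and in the periphery
* ``sls_peripheral``         — SLSs only in the periphery
* ``loose_striated``         — loose (widely spaced) striated pattern
* ``no_sls``                 — no SLSs

This module turns category label lists into count/fraction tables, measures
cell length (maximum Feret diameter of a mask, or traced polyline length),
summarises detachment time courses, and wraps the standard group-comparison
tests (one-way ANOVA + Tukey; two-way ANOVA + Sidak).  Classification itself
is manual or synthetic input — no image-based classifier is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from scipy import stats as sps

PHENOTYPE_CATEGORIES = (
    "sls_central_peripheral",
    "sls_peripheral",
    "loose_striated",
    "no_sls",
)


@dataclass
class PhenotypeCount:
    counts: dict
    total: int
    fractions: dict

    @property
    def any_sls_fraction(self) -> float:
        """Fraction of cells with any SLS = 1 - fraction(no_sls)."""
        return 1.0 - self.fractions["no_sls"]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "category": list(self.counts),
            "count": list(self.counts.values()),
            "fraction": [self.fractions[c] for c in self.counts],
        })


@dataclass
class DetachmentSeries:
    """Attached-cell counts over time in a detachment assay."""

    time_min: np.ndarray
    attached: np.ndarray
    initial: int

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.attached = np.asarray(self.attached, dtype=float)
        if len(self.time_min) != len(self.attached):
            raise ValueError("time and attached counts must align")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("time points must be strictly increasing")
        if np.any(self.attached < 0) or self.initial <= 0:
            raise ValueError("counts must be nonnegative, initial positive")
        if np.any(self.attached > self.initial):
            raise ValueError("attached count exceeds initial count")
        if np.any(np.diff(self.attached) > 0):
            raise ValueError("attached counts must be non-increasing in time")


def score_cells(labels) -> PhenotypeCount:
    """Count cells per phenotype category and derive fractions."""
    labels = list(labels)
    if not labels:
        raise ValueError("no cells to score")
    unknown = set(labels) - set(PHENOTYPE_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown phenotype labels: {sorted(unknown)}")
    counts = {c: 0 for c in PHENOTYPE_CATEGORIES}
    for lab in labels:
        counts[lab] += 1
    total = len(labels)
    fractions = {c: counts[c] / total for c in PHENOTYPE_CATEGORIES}
    return PhenotypeCount(counts=counts, total=total, fractions=fractions)


def cell_length(region, pixel_size: float = 1.0) -> float:
    """Cell length in microns: longest axis of the cell.

    ``region`` is either a boolean mask (2D array; length = maximum Feret
    diameter of the pixel region, pixels treated as unit squares) or a
    polyline as an (n, 2) float array of micron coordinates (length = total
    arclength of the manual trace).  A single-pixel mask reports one pixel
    size by convention.
    """
    region = np.asarray(region)
    if region.ndim == 2 and region.dtype != bool and region.shape[1] == 2:
        poly = region.astype(float)
        if len(poly) < 2:
            raise ValueError("polyline needs at least two vertices")
        return float(np.sum(np.linalg.norm(np.diff(poly, axis=0), axis=1)))
    mask = region.astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2D boolean array")
    rr, cc = np.nonzero(mask)
    if len(rr) == 0:
        raise ValueError("empty mask")
    if len(rr) == 1:
        return float(pixel_size)
    # Feret diameter of the union of pixel squares: max pairwise distance
    # over the convex hull of all pixel corners
    corners = np.concatenate([
        np.column_stack([rr + dr, cc + dc])
        for dr in (-0.5, 0.5) for dc in (-0.5, 0.5)
    ]).astype(float)
    hull_pts = corners[ConvexHull(corners).vertices]
    return float(pdist(hull_pts).max() * pixel_size)


def detachment_fraction(series: DetachmentSeries) -> pd.DataFrame:
    """Detached fraction 1 - attached/initial at each time point."""
    frac = 1.0 - series.attached / series.initial
    return pd.DataFrame({"time_min": series.time_min,
                         "detached_fraction": frac})


def compare_groups(values, labels, design: str = "one_way",
                   labels2=None, alpha: float = 0.05) -> dict:
    """Group comparison via standard ANOVA + multiple-comparison tests.

    ``one_way``: one-way ANOVA across the groups in ``labels`` followed by
    Tukey's HSD (used for sarcomeric-spacing comparisons across substrate
    stiffness conditions).  ``two_way``: two-way ANOVA on factors ``labels``
    and ``labels2`` followed by Sidak-adjusted pairwise comparisons of the
    first factor within each level of the second (used for detachment time
    courses: condition x time).  Thin wrappers over scipy/statsmodels; no
    bespoke statistics.

    Returns a dict with an ``anova`` table and a ``pairwise`` table.
    """
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    from statsmodels.stats.multitest import multipletests

    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least two values")

    if design == "one_way":
        f_stat, p = sps.f_oneway(*groups)
        tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
        pairwise = pd.DataFrame(tukey.summary().data[1:],
                                columns=tukey.summary().data[0])
        anova = pd.DataFrame({"F": [f_stat], "p": [p]},
                             index=["group"])
        return {"anova": anova, "pairwise": pairwise}

    if design == "two_way":
        if labels2 is None:
            raise ValueError("two_way design needs a second factor (labels2)")
        labels2 = np.asarray(labels2)
        df = pd.DataFrame({"value": values, "g1": labels, "g2": labels2})
        model = ols("value ~ C(g1) * C(g2)", data=df).fit()
        anova = anova_lm(model, typ=2)
        rows, raw_p = [], []
        for lvl2 in pd.unique(labels2):
            sub = df[df.g2 == lvl2]
            lvls = pd.unique(sub.g1)
            for i in range(len(lvls)):
                for j in range(i + 1, len(lvls)):
                    a = sub.value[sub.g1 == lvls[i]]
                    b = sub.value[sub.g1 == lvls[j]]
                    t, p = sps.ttest_ind(a, b)
                    rows.append((lvls[i], lvls[j], lvl2, t, p))
                    raw_p.append(p)
        adj = multipletests(raw_p, alpha=alpha, method="sidak")[1]
        pairwise = pd.DataFrame(rows, columns=["group_a", "group_b",
                                               "within", "t", "p_raw"])
        pairwise["p_adj"] = adj
        return {"anova": anova, "pairwise": pairwise}

    raise ValueError(f"unknown design {design!r}")
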