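"""Mutation-pressure versus natural-selection diagnostics.

A sequence set is summarized by:

* parity-rule-2 (PR2) coordinates, A3/(A3+U3) against G3/(G3+C3) at
  synonymous third positions — the point (0.5, 0.5) is the expectation
  under balanced mutation/selection between complementary bases;
* the neutrality plot, an OLS regression of GC12 on GC3 whose slope
  splits codon-usage variation into a mutation-pressure contribution
  (|slope| x 100 %) and a natural-selection contribution (the rest);
* a Spearman rank-correlation matrix between third-position/ENC
  variables and whole-sequence composition / protein indices;
* pairwise Mann-Whitney comparisons of CAI between groups with a
  compact letter display.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_stats import CompositionSummary

logger = logging.getLogger(__name__)

OUTLIER_METHODS = ("tukey", "sd3", "none")

#: row / column variables of the correlation matrix
CORR_ROWS = ("A3s%", "C3s%", "U3s%", "G3s%", "GC3%", "ENC")
CORR_COLS = ("A%", "C%", "U%", "G%", "GC%", "Gravy", "Aroma")


@dataclass(frozen=True)
class PR2Point:
    """AT and GC bias at synonymous third codon positions."""

    at_bias: float
    gc_bias: float
    source: str = ""
    at_defined: bool = True
    gc_defined: bool = True


def pr2_coordinates(comp: CompositionSummary, source: str = "") -> PR2Point:
    """PR2 coordinates from a composition summary.

    at_bias = A3/(A3+U3), gc_bias = G3/(G3+C3) over synonymous third
    positions.  A 0/0 coordinate is flagged undefined (NaN), never
    silently zero.
    """
    if not comp.third_positions_defined:
        return PR2Point(float("nan"), float("nan"), source, False, False)
    au = comp.a3s_pct + comp.u3s_pct
    gc = comp.g3s_pct + comp.c3s_pct
    at_ok = au > 0
    gc_ok = gc > 0
    return PR2Point(
        at_bias=comp.a3s_pct / au if at_ok else float("nan"),
        gc_bias=comp.g3s_pct / gc if gc_ok else float("nan"),
        source=source,
        at_defined=at_ok,
        gc_defined=gc_ok,
    )


def detect_outliers(
    gc3: Sequence[float],
    gc12: Sequence[float],
    method: str = "tukey",
) -> tuple[np.ndarray, np.ndarray]:
    """Partition paired GC3/GC12 points into kept/removed index arrays.

    ``tukey`` applies 1.5 x IQR fences to GC3 and GC12 marginally and
    removes a point falling outside either fence; ``sd3`` uses mean
    +/- 3 SD fences; ``none`` keeps everything.  With fewer than 8
    points nothing is removed (a warning is issued).
    """
    if method not in OUTLIER_METHODS:
        raise ValueError(f"method must be one of {OUTLIER_METHODS}, got {method!r}")
    x = np.asarray(gc3, dtype=float)
    y = np.asarray(gc12, dtype=float)
    if x.shape != y.shape:
        raise ValueError("gc3 and gc12 must be the same length")
    idx = np.arange(len(x))
    if method == "none":
        return idx, np.array([], dtype=int)
    if len(x) < 8:
        warnings.warn("fewer than 8 points: outlier screening skipped", stacklevel=2)
        return idx, np.array([], dtype=int)

    def fence_mask(v: np.ndarray) -> np.ndarray:
        if method == "tukey":
            q1, q3 = np.percentile(v, [25, 75])
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        else:  # sd3
            mu, sd = v.mean(), v.std(ddof=1)
            lo, hi = mu - 3 * sd, mu + 3 * sd
        return (v >= lo) & (v <= hi)

    keep = fence_mask(x) & fence_mask(y)
    removed = idx[~keep]
    if removed.size:
        logger.info("outlier screening removed %d of %d points", removed.size, len(x))
    return idx[keep], removed


@dataclass(frozen=True)
class NeutralityFit:
    """GC12-on-GC3 regression with the mutation/selection split.

    mutation_pct = min(|slope|, 1) x 100 and selection_pct is its
    complement, so the two always sum to exactly 100.  Both Pearson
    and Spearman correlations of the kept points are reported.
    """

    slope: float
    intercept: float
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n_used: int
    n_removed: int
    selection_pct: float
    mutation_pct: float


def selection_contribution(slope: float) -> tuple[float, float]:
    """(selection %, mutation %) from a neutrality-plot slope.

    The slope of GC12 on GC3 measures how much of the third-position
    compositional drift carries through to the first two positions:
    slope 1 means pure mutation pressure, slope 0 pure selection.
    mutation % = min(|slope|, 1) x 100; selection % is the complement.
    """
    if not math.isfinite(slope):
        raise ValueError(f"slope must be finite, got {slope}")
    mutation = min(abs(slope), 1.0) * 100.0
    return 100.0 - mutation, mutation


def neutrality_fit(
    gc12: Sequence[float],
    gc3: Sequence[float],
    outlier_method: str = "tukey",
) -> NeutralityFit:
    """Neutrality-plot regression of GC12 on GC3.

    Outliers are screened first (see :func:`detect_outliers`), then an
    ordinary least-squares line is fitted.  Requires >= 3 points after
    screening and non-constant GC3.
    """
    kept, removed = detect_outliers(gc3, gc12, method=outlier_method)
    x = np.asarray(gc3, dtype=float)[kept]
    y = np.asarray(gc12, dtype=float)[kept]
    if len(x) < 3:
        raise ValueError(f"need >= 3 points after outlier removal, have {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("GC3 is constant; neutrality regression undefined")
    ols = stats.linregress(x, y)
    rho, rho_p = stats.spearmanr(x, y)
    selection, mutation = selection_contribution(ols.slope)
    return NeutralityFit(
        slope=float(ols.slope),
        intercept=float(ols.intercept),
        pearson_r=float(ols.rvalue),
        pearson_p=float(ols.pvalue),
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        n_used=len(x),
        n_removed=int(removed.size),
        selection_pct=selection,
        mutation_pct=mutation,
    )


# ---------------------------------------------------------------------------
# correlation matrix


@dataclass(frozen=True)
class CorrelationMatrix:
    """Spearman rho, two-sided p and significance stars, 6 x 7 layout."""

    rho: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: int

    def annotated(self) -> pd.DataFrame:
        """rho rounded to 2 decimals with stars appended, report-style."""
        out = self.rho.round(2).astype(str)
        return out.where(self.stars == "", out + " " + self.stars)


def _stars(p: float) -> str:
    if math.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def spearman_matrix(metrics: pd.DataFrame) -> CorrelationMatrix:
    """Spearman correlations of (A3s..G3s, GC3, ENC) x (A..GC, Gravy, Aroma).

    ``metrics`` is the per-sequence metrics table.  Ties are handled by
    average ranks (scipy).  A constant column yields NaN rho, flagged
    by an empty star string.  Requires >= 5 sequences.
    """
    missing = [c for c in CORR_ROWS + CORR_COLS if c not in metrics.columns]
    if missing:
        raise ValueError(f"metrics table lacks columns {missing}")
    n = len(metrics)
    if n < 5:
        raise ValueError(f"need >= 5 sequences for correlations, have {n}")
    rho = pd.DataFrame(index=list(CORR_ROWS), columns=list(CORR_COLS), dtype=float)
    pval = rho.copy()
    for r in CORR_ROWS:
        for c in CORR_COLS:
            x = metrics[r].to_numpy(dtype=float)
            y = metrics[c].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rho.loc[r, c] = float("nan")
                pval.loc[r, c] = float("nan")
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                s, p = stats.spearmanr(x, y)
            rho.loc[r, c] = float(s)
            pval.loc[r, c] = float(p)
    stars = pval.map(_stars)
    return CorrelationMatrix(rho=rho, p=pval, stars=stars, n=n)


# ---------------------------------------------------------------------------
# group comparison of CAI


@dataclass(frozen=True)
class GroupComparison:
    """Pairwise Mann-Whitney results plus a compact letter display."""

    pairwise: pd.DataFrame  # columns: group1, group2, U, p, (p_adj)
    letters: dict[str, str]
    alpha: float


def _compact_letter_display(
    groups: Sequence[str],
    significant: set[tuple[str, str]],
    means: Mapping[str, float],
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different.  Letter
    sets are built by splitting on each significant pair and absorbing
    redundant subsets; groups are ordered by descending mean (ties by
    name) so letters read in effect-size order.
    """
    order = sorted(groups, key=lambda g: (-means[g], g))
    letter_sets: list[set[str]] = [set(order)]
    for g1, g2 in sorted(significant):
        for s in [s for s in letter_sets if g1 in s and g2 in s]:
            letter_sets.remove(s)
            a, b = s - {g1}, s - {g2}
            for cand in (a, b):
                if not any(cand <= other for other in letter_sets):
                    letter_sets.append(cand)
            # absorb: drop any set now contained in another
            letter_sets = [
                s1
                for s1 in letter_sets
                if not any(s1 < s2 for s2 in letter_sets)
            ]
    # stable ordering of letter sets by the best-ranked member
    letter_sets.sort(key=lambda s: min(order.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, s in enumerate(letter_sets):
        for g in s:
            out[g] += alphabet[i % len(alphabet)]
    return out


def cai_group_comparison(
    values_by_group: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    adjust: bool = False,
) -> GroupComparison:
    """All pairwise two-sided Mann-Whitney tests between groups.

    Each group needs >= 3 values.  P-values are unadjusted by default;
    ``adjust=True`` applies Benjamini-Hochberg before the letter
    display is built.  Groups sharing a letter are not significantly
    different at ``alpha``.
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in values_by_group.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 values")
    rows = []
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            u, p = stats.mannwhitneyu(
                values_by_group[g1], values_by_group[g2], alternative="two-sided"
            )
            rows.append({"group1": g1, "group2": g2, "U": float(u), "p": float(p)})
    pairwise = pd.DataFrame(rows)
    pcol = "p"
    if adjust:
        pairwise["p_adj"] = stats.false_discovery_control(pairwise["p"], method="bh")
        pcol = "p_adj"
    significant = {
        (r["group1"], r["group2"])
        for _, r in pairwise.iterrows()
        if r[pcol] < alpha
    }
    means = {g: float(np.mean(v)) for g, v in values_by_group.items()}
    letters = _compact_letter_display(groups, significant, means)
    return GroupComparison(pairwise=pairwise, letters=letters, alpha=alpha)
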