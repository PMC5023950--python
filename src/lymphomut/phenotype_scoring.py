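"""Semi-quantitative IHC scoring, FISH deletion calling and the
genotype-phenotype statistics.

IHC: the extent of staining (percentage of positive tumour cells) is
bucketed 0-4 (<10% negative; 10-25 / 26-50 / 51-75 / 76-100 scoring 1-4)
and multiplied by the intensity score (0-3) into a composite on a 0-12
scale.  The H3K36me3 / H3K36me2 score ratio normalizes trimethylation for
the available dimethylated substrate.

FISH: a nucleus is deleted for the target locus when the orange (target) /
green (control) signal ratio is <= 0.5; the sample-level cutoff is the
mean + 3 sample s.d. of per-sample deleted fractions observed in negative
controls, and a tumour is called deleted when its deleted fraction exceeds
the cutoff, requiring at least 100 evaluable nuclei.

Group comparison between entities uses a two-sample rank test by default
(a paired signed-rank mode is available), and genotype-phenotype
association uses Spearman rank correlation.
"""

from __future__ import annotations

import math
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientDataError

__all__ = [
    "extent_score",
    "ihc_composite",
    "me3_me2_ratio",
    "fish_nucleus_deleted",
    "fish_deleted_fraction",
    "fish_cutoff",
    "fish_sample_call",
    "group_compare",
    "spearman_corr",
]


def extent_score(extent_pct: float) -> int:
    """Bucket the staining extent percentage into the 0-4 extent score.

    Boundaries follow the printed integer-percent buckets; fractional
    inputs are rounded half-up to an integer percent before bucketing.
    """
    if not (0 <= extent_pct <= 100):
        raise DomainError("extent_pct must lie in [0, 100]")
    pct = int(Decimal(str(extent_pct)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    if pct < 10:
        return 0
    if pct <= 25:
        return 1
    if pct <= 50:
        return 2
    if pct <= 75:
        return 3
    return 4


def ihc_composite(extent_pct: float, intensity: int,
                  interpretable: bool = True) -> Optional[int]:
    """Extent score x intensity score, on the 0-12 composite scale.

    Returns None for non-interpretable stainings (negative with no
    internal positive control).
    """
    if intensity not in (0, 1, 2, 3):
        raise DomainError("intensity must be an integer in 0..3")
    if not interpretable:
        return None
    return extent_score(extent_pct) * intensity


def me3_me2_ratio(me3_score: Optional[float],
                  me2_score: Optional[float]) -> Optional[float]:
    """H3K36me3 / H3K36me2 composite-score ratio; missing when undefined."""
    if me3_score is None or me2_score is None:
        return None
    for s in (me3_score, me2_score):
        if not (0 <= s <= 12):
            raise DomainError("IHC composite scores lie in [0, 12]")
    if me2_score == 0:
        return None
    return me3_score / me2_score


def fish_nucleus_deleted(orange_count: int, green_count: int) -> Optional[bool]:
    """Nucleus-level deletion: orange/green signal ratio <= 0.5 (inclusive).

    Nuclei without control (green) signals are uninterpretable -> None.
    """
    if orange_count < 0 or green_count < 0:
        raise DomainError("signal counts must be >= 0")
    if green_count == 0:
        return None
    return orange_count / green_count <= 0.5


def fish_deleted_fraction(nuclei: Iterable[Tuple[int, int]]) -> Tuple[float, int]:
    """Fraction of deleted nuclei among evaluable ones; returns (fraction, n)."""
    flags = [fish_nucleus_deleted(o, g) for o, g in nuclei]
    evaluable = [f for f in flags if f is not None]
    if not evaluable:
        raise InsufficientDataError("no evaluable nuclei")
    return sum(evaluable) / len(evaluable), len(evaluable)


def fish_cutoff(control_fractions: Sequence[float]) -> float:
    """Deletion cutoff from negative controls: mean + 3 x sample s.d.

    Input is one deleted fraction per control sample (>= 2 controls).
    """
    fracs = np.asarray(control_fractions, dtype=float)
    if fracs.size < 2:
        raise InsufficientDataError("need >= 2 control samples for a cutoff")
    return float(fracs.mean() + 3.0 * fracs.std(ddof=1))


def fish_sample_call(nuclei: Sequence[Tuple[int, int]], cutoff: float,
                     min_nuclei: int = 100) -> Tuple[float, str]:
    """Sample-level deletion call from tumour nuclei.

    The deleted fraction is computed over evaluable nuclei; the sample is
    called deleted when the fraction strictly exceeds the cutoff.  Fewer
    than ``min_nuclei`` evaluable nuclei is insufficient to call.
    """
    fraction, n_evaluable = fish_deleted_fraction(nuclei)
    if n_evaluable < min_nuclei:
        raise InsufficientDataError(
            f"only {n_evaluable} evaluable nuclei; need >= {min_nuclei}")
    call = "deleted" if fraction > cutoff else "not_deleted"
    return fraction, call


def group_compare(group_a: Sequence[float], group_b: Sequence[float],
                  paired: bool = False) -> Tuple[float, float]:
    """Rank-based comparison of two score distributions (two-sided).

    Default is the two-sample rank-sum (Mann-Whitney U) test for
    independent groups; ``paired=True`` switches to the Wilcoxon
    signed-rank test on per-case differences.  Fully tied input returns
    p = 1 rather than an undefined statistic.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs >= 2 observations")
    if paired:
        if a.size != b.size:
            raise DomainError("paired comparison needs equal-length groups")
        diffs = a - b
        if np.all(diffs == 0):
            return 0.0, 1.0
        res = stats.wilcoxon(a, b)
        return float(res.statistic), float(res.pvalue)
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return float(a.size * b.size / 2.0), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def spearman_corr(x: Sequence[float], y: Sequence[float],
                  ) -> Tuple[Optional[float], Optional[float]]:
    """Spearman rank correlation with average ranks for ties.

    Pairs with a missing member are dropped; needs >= 3 complete pairs;
    a constant vector leaves rho undefined -> (None, None).
    """
    pairs = [(a, b) for a, b in zip(x, y)
             if a is not None and b is not None
             and not (isinstance(a, float) and math.isnan(a))
             and not (isinstance(b, float) and math.isnan(b))]
    if len(pairs) < 3:
        raise InsufficientDataError("need >= 3 complete pairs")
    xa = np.array([p[0] for p in pairs], dtype=float)
    ya = np.array([p[1] for p in pairs], dtype=float)
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        return None, None
    rho, p = stats.spearmanr(xa, ya)
    return float(rho), float(p)
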