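"""Copy-number segmentation and LOH detection from binned coverage.

Tumour/normal read counts in fixed-width genomic bins (100 kb by default)
are turned into library-size-normalized log2 ratios, median-smoothed to
remove single-bin outliers, and segmented per chromosome with circular
binary segmentation (CBS).  Segment calls follow fixed thresholds: a
segment is a gain when its mean smoothed ratio exceeds +0.25 (loss below
-0.25) with more than eight supporting markers.  Loss of heterozygosity is
flagged from the tumour B-allele frequency (BAF) of germline heterozygous
sites: a segment whose informative het sites show mean |BAF - 0.5| >= 0.2
is in allelic imbalance; combined with a neutral coverage call this is
copy-neutral LOH.

CBS here is the classic recursive changepoint search: on each segment the
arc (i, j] maximizing the standardized mean-difference statistic is tested
against a within-segment permutation null, the split is accepted when the
permutation p-value falls at or below ``alpha``, and the search recurses
into the resulting sub-segments.  Permutations are drawn from a seeded
generator, so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DomainError, StructuralError

__all__ = [
    "SegmentCall",
    "bin_log_ratios",
    "median_smooth",
    "remove_single_point_outliers",
    "cbs_segment",
    "segments_from_breakpoints",
    "call_segments",
    "detect_loh",
    "locus_overlap",
    "segment_genome",
]

BIN_COLUMNS = ("chrom", "bin_start", "t_count", "n_count")


@dataclass
class SegmentCall:
    """A contiguous run of coverage bins with one copy-number state."""

    chrom: str
    start: int
    end: int  # 0-based half-open, bp
    n_markers: int
    mean_ratio: float
    call: str = "neutral"  # gain | loss | neutral
    loh: Optional[bool] = None  # None = no informative het sites


def bin_log_ratios(bins: pd.DataFrame) -> pd.DataFrame:
    """Add a library-size-normalized log2(tumour/normal) ratio per bin.

    Expects columns ``chrom, bin_start, t_count, n_count`` on a shared grid.
    Ratios are log2((t/T)/(n/N)) where T, N are total counts; bins where
    either count is zero get a missing ratio (they carry no usable signal
    and are masked, not imputed).
    """
    missing = set(BIN_COLUMNS) - set(bins.columns)
    if missing:
        raise StructuralError(f"bin table lacks columns: {sorted(missing)}")
    if (bins["t_count"] < 0).any() or (bins["n_count"] < 0).any():
        raise StructuralError("bin counts must be non-negative")
    out = bins.copy()
    t_total = float(out["t_count"].sum())
    n_total = float(out["n_count"].sum())
    if t_total == 0 or n_total == 0:
        raise StructuralError("total count is zero in one sample")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (out["t_count"].to_numpy(float) / t_total) / (
            out["n_count"].to_numpy(float) / n_total
        )
        log_ratio = np.log2(ratio)
    log_ratio[(out["t_count"] == 0) | (out["n_count"] == 0)] = np.nan
    out["log_ratio"] = log_ratio
    return out


def median_smooth(values: Sequence[float], window_bins: int = 5) -> np.ndarray:
    """Running median with truncated windows at chromosome edges.

    The median pulls single-bin spikes to the local level, which is the
    point: one aberrant bin should not seed a segment.  Missing values are
    ignored within each window and stay missing in the output.
    """
    if window_bins < 1 or window_bins % 2 == 0:
        raise DomainError("window_bins must be odd and >= 1")
    x = np.asarray(values, dtype=float)
    half = window_bins // 2
    out = np.full_like(x, np.nan)
    for i in range(len(x)):
        window = x[max(0, i - half): i + half + 1]
        window = window[~np.isnan(window)]
        if np.isnan(x[i]):
            continue
        out[i] = np.median(window)
    return out


def remove_single_point_outliers(values: Sequence[float], window_bins: int = 5,
                                 k: float = 3.0) -> np.ndarray:
    """Pull isolated spikes to the local running median; leave the rest.

    A bin is an outlier when it deviates from the local median by more than
    ``k`` robust standard deviations (1.4826 x MAD of the residuals).  Unlike
    a full median filter this leaves the noise structure of ordinary bins
    untouched, which matters for the segmentation permutation test: a median-
    filtered series has autocorrelated noise and an i.i.d.-shuffle null would
    over-split it.
    """
    x = np.asarray(values, dtype=float)
    med = median_smooth(x, window_bins)
    resid = x - med
    with np.errstate(invalid="ignore"):
        scale = 1.4826 * np.nanmedian(np.abs(resid))
    if not np.isfinite(scale) or scale == 0.0:
        return x.copy()
    out = x.copy()
    spikes = np.abs(resid) > k * scale
    out[spikes & ~np.isnan(x)] = med[spikes & ~np.isnan(x)]
    return out


def _arc_pairs(n: int, min_width: int) -> Tuple[np.ndarray, np.ndarray]:
    """All arc boundaries (i, j), 0 <= i < j <= n, with interior width
    min_width <= j-i <= n-min_width."""
    i_idx, j_idx = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    width = j_idx - i_idx
    keep = (width >= min_width) & (width <= n - min_width)
    return i_idx[keep], j_idx[keep]


def _max_arc_stat(x: np.ndarray, i_idx: np.ndarray, j_idx: np.ndarray,
                  sd: float) -> Tuple[float, int, int]:
    n = len(x)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    total = cs[-1]
    k = (j_idx - i_idx).astype(float)
    s_in = cs[j_idx] - cs[i_idx]
    mean_in = s_in / k
    mean_out = (total - s_in) / (n - k)
    z = np.abs(mean_in - mean_out) / (sd * np.sqrt(1.0 / k + 1.0 / (n - k)))
    best = int(np.argmax(z))
    return float(z[best]), int(i_idx[best]), int(j_idx[best])


def cbs_segment(values: Sequence[float], alpha: float = 0.01,
                n_perm: int = 1000, rng: Optional[np.random.Generator] = None,
                min_width: int = 2) -> List[int]:
    """Circular binary segmentation of one chromosome's ratio series.

    Returns sorted interior breakpoint indices b such that segments are
    ``values[prev:b]``.  Missing values must be removed by the caller (the
    pipeline segments the non-missing subsequence and maps indices back).

    The permutation test shuffles the values within the segment under test;
    it stops early once enough permutation maxima exceed the observed
    statistic to guarantee p > alpha, which does not change the decision and
    keeps flat segments cheap.
    """
    if not (0.0 < alpha < 1.0):
        raise DomainError("alpha must lie in (0, 1)")
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise DomainError("cbs_segment requires a series without missing values")
    if rng is None:
        rng = np.random.default_rng()
    breakpoints: List[int] = []
    # Number of exceedances that already forces p = (1+count)/(1+n_perm) > alpha.
    reject_count = int(np.floor(alpha * (1 + n_perm)))

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        n = len(seg)
        if n < 2 * min_width:
            return
        sd = float(np.std(seg, ddof=1))
        if sd == 0.0:
            return
        i_idx, j_idx = _arc_pairs(n, min_width)
        obs, bi, bj = _max_arc_stat(seg, i_idx, j_idx, sd)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(seg)
            stat, _, _ = _max_arc_stat(perm, i_idx, j_idx, float(np.std(perm, ddof=1)))
            if stat >= obs:
                exceed += 1
                if exceed >= reject_count:
                    return  # p-value already above alpha
        p = (1 + exceed) / (1 + n_perm)
        if p > alpha:
            return
        cuts = sorted({bi, bj} - {0, n})
        if not cuts:
            return
        edges = [0] + cuts + [n]
        for b in cuts:
            breakpoints.append(lo + b)
        for a, b in zip(edges[:-1], edges[1:]):
            recurse(lo + a, lo + b)

    recurse(0, len(x))
    return sorted(breakpoints)


def segments_from_breakpoints(chrom: str, smoothed: np.ndarray,
                              bin_starts: np.ndarray, bin_width: int,
                              breakpoints: Sequence[int]) -> List[SegmentCall]:
    """Tile a chromosome into segments between consecutive breakpoints.

    ``smoothed`` and ``bin_starts`` cover the informative (non-missing) bins
    in order; breakpoint indices refer to positions in that sequence.
    """
    edges = [0] + list(breakpoints) + [len(smoothed)]
    segments = []
    for a, b in zip(edges[:-1], edges[1:]):
        if a == b:
            continue
        segments.append(SegmentCall(
            chrom=chrom,
            start=int(bin_starts[a]),
            end=int(bin_starts[b - 1]) + bin_width,
            n_markers=b - a,
            mean_ratio=float(np.mean(smoothed[a:b])),
        ))
    return segments


def call_segments(segments: Iterable[SegmentCall], threshold: float = 0.25,
                  min_markers: int = 8) -> List[SegmentCall]:
    """Label segments gain/loss/neutral by mean ratio and marker support.

    "More than eight supporting markers" is strict: a segment needs at
    least ``min_markers + 1`` bins to be called, whatever its amplitude.
    """
    out = []
    for seg in segments:
        call = "neutral"
        if seg.n_markers > min_markers:
            if seg.mean_ratio > threshold:
                call = "gain"
            elif seg.mean_ratio < -threshold:
                call = "loss"
        seg.call = call
        out.append(seg)
    return out


def detect_loh(het_sites: pd.DataFrame, segments: Iterable[SegmentCall],
               min_sites: int = 10, min_delta_baf: float = 0.2,
               min_normal_depth: int = 20) -> List[SegmentCall]:
    """Flag segments in allelic imbalance from tumour BAF at germline hets.

    ``het_sites`` columns: chrom, pos (1-based), n_ref, n_alt, t_ref, t_alt.
    Sites are informative when the normal VAF lies in [0.4, 0.6] at depth
    >= ``min_normal_depth`` and the tumour has coverage.  A segment with at
    least ``min_sites`` informative sites whose mean |tumour BAF - 0.5|
    reaches ``min_delta_baf`` is flagged; segments without informative
    sites keep a missing flag rather than a false one.
    """
    required = {"chrom", "pos", "n_ref", "n_alt", "t_ref", "t_alt"}
    missing = required - set(het_sites.columns)
    if missing:
        raise StructuralError(f"het-site table lacks columns: {sorted(missing)}")
    hs = het_sites.copy()
    n_depth = hs["n_ref"] + hs["n_alt"]
    t_depth = hs["t_ref"] + hs["t_alt"]
    with np.errstate(invalid="ignore"):
        n_vaf = hs["n_alt"] / n_depth.replace(0, np.nan)
    informative = (
        (n_depth >= min_normal_depth)
        & (t_depth >= 1)
        & (n_vaf >= 0.4)
        & (n_vaf <= 0.6)
    )
    hs = hs[informative]
    t_baf = hs["t_alt"] / (hs["t_ref"] + hs["t_alt"])
    out = []
    for seg in segments:
        mask = (
            (hs["chrom"] == seg.chrom)
            & (hs["pos"] - 1 >= seg.start)
            & (hs["pos"] - 1 < seg.end)
        )
        baf = t_baf[mask]
        if len(baf) == 0:
            seg.loh = None
        elif len(baf) >= min_sites:
            seg.loh = bool(np.mean(np.abs(baf - 0.5)) >= min_delta_baf)
        else:
            seg.loh = False
        out.append(seg)
    return out


def locus_overlap(segments: Iterable[SegmentCall],
                  locus: Tuple[str, int, int]) -> dict:
    """Copy-number status of a locus from the segments overlapping it.

    When several segments overlap, the one covering the larger fraction of
    the locus wins.  Returns ``{"call", "loh", "overlap_fraction"}``.
    """
    chrom, start, end = locus
    if end <= start or start < 0:
        raise DomainError(f"invalid locus {locus!r}")
    best = None
    best_cov = 0
    for seg in segments:
        if seg.chrom != chrom:
            continue
        cov = min(seg.end, end) - max(seg.start, start)
        if cov > best_cov:
            best_cov = cov
            best = seg
    if best is None:
        raise DomainError(f"locus {locus!r} overlaps no segment")
    return {
        "call": best.call,
        "loh": best.loh,
        "overlap_fraction": best_cov / (end - start),
    }


def segment_genome(bins: pd.DataFrame, bin_width: int = 100_000,
                   window_bins: int = 5, alpha: float = 0.01,
                   n_perm: int = 1000, seed: Optional[int] = None,
                   het_sites: Optional[pd.DataFrame] = None,
                   threshold: float = 0.25, min_markers: int = 8,
                   ) -> List[SegmentCall]:
    """Full pipeline: log ratios -> outlier removal -> CBS -> calls (-> LOH).

    Single-bin spikes are pulled to the local running median before
    segmentation; the series otherwise keeps its per-bin noise so the CBS
    permutation null stays valid.
    """
    with_ratio = bin_log_ratios(bins)
    rng = np.random.default_rng(seed)
    segments: List[SegmentCall] = []
    for chrom, group in with_ratio.groupby("chrom", sort=False):
        group = group.sort_values("bin_start")
        ok = group["log_ratio"].notna().to_numpy()
        if not ok.any():
            continue
        smoothed = remove_single_point_outliers(
            group["log_ratio"].to_numpy(), window_bins)
        sm = smoothed[ok]
        starts = group["bin_start"].to_numpy()[ok]
        bps = cbs_segment(sm, alpha=alpha, n_perm=n_perm, rng=rng)
        segments.extend(segments_from_breakpoints(str(chrom), sm, starts,
                                                  bin_width, bps))
    segments = call_segments(segments, threshold=threshold, min_markers=min_markers)
    if het_sites is not None:
        segments = detect_loh(het_sites, segments)
    return segments


def segments_to_frame(segments: Iterable[SegmentCall]) -> pd.DataFrame:
    """Tabular view of segment calls (one row per segment)."""
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom, "start": s.start, "end": s.end,
                "n_markers": s.n_markers, "mean_ratio": s.mean_ratio,
                "call": s.call, "loh": s.loh,
            }
            for s in segments
        ]
    )
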