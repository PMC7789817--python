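"""Copy-number analysis from methylation-array intensities.

Methylated and unmethylated intensities are summed, quantile normalized
across samples, divided by the per-probe median over control samples and
log10 transformed. The per-sample log-ratio track is median-filter
smoothed and recursively segmented: at each step the maximal
standardized mean-split statistic is compared against a permutation null
(values shuffled within the segment) and the split is accepted when the
permutation p-value falls below alpha. Neighbouring segments with close
means are merged, and segments with sufficiently negative mean log ratio
are emitted as deletion calls. Interval arithmetic over deletion calls
(intersection of signature-positive deletions minus the union of
signature-negative ones) maps the epi-signature critical region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.stats import rankdata

from .datasets import load_phmds_deletions


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} after end {self.end}")

    def length_mb(self, decimals: int = 2) -> float:
        return interval_length_mb(self, decimals)


@dataclass
class CnvSegment:
    chrom: str
    start: int
    end: int
    n_probes: int
    mean_log_ratio: float
    call: str = "neutral"  # deletion | neutral | gain


def total_intensity(meth, unmeth):
    """Elementwise sum of methylated and unmethylated intensities."""
    meth = np.asarray(meth, dtype=float)
    unmeth = np.asarray(unmeth, dtype=float)
    if meth.shape != unmeth.shape:
        raise ValueError("intensity matrices have mismatched shapes")
    return meth + unmeth


def quantile_normalize(matrix) -> np.ndarray:
    """Force every column onto the cross-column mean of sorted values.

    Ties within a column receive the average of the target values at the
    tied ranks (average-rank interpolation).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    target = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    grid = np.arange(1, X.shape[0] + 1, dtype=float)
    for j in range(X.shape[1]):
        r = rankdata(X[:, j], method="average")
        out[:, j] = np.interp(r, grid, target)
    return out


def log_ratio(sample_values, control_median) -> np.ndarray:
    """log10(sample / per-probe control median); zero-median probes are NaN
    with a warning (callers should drop them)."""
    s = np.asarray(sample_values, dtype=float)
    med = np.asarray(control_median, dtype=float)
    bad = med <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} probes with non-positive control median dropped")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(bad, np.nan, np.log10(s / np.where(bad, 1.0, med)))
    return r


def _arc_widths(n: int, ratio: float = 1.2) -> list[int]:
    """Geometric grid of arc widths 1 .. n-1 scanned by the segmentation
    statistic (both observed and permuted, so the test stays valid)."""
    widths = []
    w = 1
    while w <= n - 1:
        widths.append(w)
        w = max(w + 1, int(round(w * ratio)))
    return widths


def _max_arc(x: np.ndarray, widths: list[int]) -> tuple[int, int, float]:
    """Best arc [i, j): maximal standardized |mean(arc) - mean(rest)|.

    The circular formulation: an arc and its complement give the same
    statistic, so scanning contiguous arcs of width < n covers all
    circular splits. Returns (i, j, T)."""
    n = x.size
    s = x.std(ddof=1)
    if n < 2 or s == 0:
        return 0, n, 0.0
    cs = np.concatenate([[0.0], np.cumsum(x)])
    tot = cs[-1]
    best = (0, n, 0.0)
    for w in widths:
        if w >= n:
            break
        arc = cs[w:] - cs[:-w]
        T = np.abs(arc / w - (tot - arc) / (n - w)) / (s * np.sqrt(1.0 / w + 1.0 / (n - w)))
        i = int(np.argmax(T))
        if T[i] > best[2]:
            best = (i, i + w, float(T[i]))
    return best


def _perm_max_arc(
    x: np.ndarray,
    widths: list[int],
    n_perm: int,
    rng: np.random.Generator,
    smooth_window: int = 1,
) -> np.ndarray:
    """Null distribution of the max arc statistic: shuffle the raw values,
    re-apply the same smoothing, take the max over the width grid.
    Re-smoothing each permutation keeps the null honest about the serial
    correlation the median filter induces."""
    n = x.size
    out = np.empty(n_perm)
    chunk = max(1, int(2_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        P = np.tile(x, (m, 1))
        P = rng.permuted(P, axis=1)
        if smooth_window > 1:
            P = median_filter(P, size=(1, smooth_window), mode="nearest")
        s = P.std(axis=1, ddof=1)
        s[s == 0] = np.inf
        CS = np.concatenate([np.zeros((m, 1)), np.cumsum(P, axis=1)], axis=1)
        tot = CS[:, -1:]
        best = np.zeros(m)
        for w in widths:
            if w >= n:
                break
            arc = CS[:, w:] - CS[:, :-w]
            T = np.abs(arc / w - (tot - arc) / (n - w)) / (
                s[:, None] * np.sqrt(1.0 / w + 1.0 / (n - w))
            )
            np.maximum(best, T.max(axis=1), out=best)
        out[done : done + m] = best
        done += m
    return out


def _refine_bounds(
    r: np.ndarray, bounds: list[tuple[int, int]], radius: int = 3
) -> list[tuple[int, int]]:
    """Nudge each internal breakpoint to the raw-data split that maximises
    the standardized mean difference of the two adjacent segments; undoes
    the one-or-two-probe edge smear the median filter introduces."""
    out = [list(b) for b in bounds]
    for idx in range(len(out) - 1):
        lo, b = out[idx]
        hi = out[idx + 1][1]
        best_b, best_t = b, -np.inf
        for k in range(max(lo + 1, b - radius), min(hi - 1, b + radius) + 1):
            x1, x2 = r[lo:k], r[k:hi]
            t = abs(x1.mean() - x2.mean()) / np.sqrt(1.0 / x1.size + 1.0 / x2.size)
            if t > best_t:
                best_b, best_t = k, t
        out[idx][1] = best_b
        out[idx + 1][0] = best_b
    return [tuple(b) for b in out]


def segment(
    r,
    positions,
    alpha: float = 0.01,
    n_perm: int = 10000,
    seed: int | None = 0,
    smooth_window: int = 5,
    chrom: str = "chr?",
) -> list[CnvSegment]:
    """Median-filter smoothing then recursive permutation-tested binary
    segmentation of a log-ratio track. Returns contiguous segments that
    partition the probes, with start/end at member-probe positions."""
    r = np.asarray(r, dtype=float)
    pos = np.asarray(positions, dtype=float)
    keep = ~np.isnan(r)
    r, pos = r[keep], pos[keep]
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)

    bounds: list[tuple[int, int]] = []

    def _recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 4:
            bounds.append((lo, hi))
            return
        raw = r[lo:hi]
        x = median_filter(raw, size=smooth_window, mode="nearest") if smooth_window > 1 else raw
        widths = _arc_widths(n)
        i, j, T = _max_arc(x, widths)
        if T == 0.0:
            bounds.append((lo, hi))
            return
        null = _perm_max_arc(raw, widths, n_perm, rng, smooth_window=smooth_window)
        p = (1.0 + np.sum(null >= T)) / (n_perm + 1.0)
        if p < alpha:
            if i > 0:
                _recurse(lo, lo + i)
            _recurse(lo + i, lo + j)
            if j < n:
                _recurse(lo + j, hi)
        else:
            bounds.append((lo, hi))

    _recurse(0, r.size)
    bounds.sort()
    bounds = _refine_bounds(r, bounds)
    return [
        CnvSegment(
            chrom=chrom,
            start=int(pos[lo]),
            end=int(pos[hi - 1]),
            n_probes=hi - lo,
            mean_log_ratio=float(r[lo:hi].mean()),
        )
        for lo, hi in bounds
    ]


def merge_segments(segments: list[CnvSegment], max_diff: float = 0.05) -> list[CnvSegment]:
    """Join adjacent segments whose mean log ratios differ by less than
    ``max_diff`` (probe-count-weighted means; iterated to a fixed point)."""
    segs = list(segments)
    changed = True
    while changed and len(segs) > 1:
        changed = False
        out: list[CnvSegment] = [segs[0]]
        for seg in segs[1:]:
            prev = out[-1]
            if prev.chrom == seg.chrom and abs(prev.mean_log_ratio - seg.mean_log_ratio) < max_diff:
                n = prev.n_probes + seg.n_probes
                mean = (
                    prev.mean_log_ratio * prev.n_probes + seg.mean_log_ratio * seg.n_probes
                ) / n
                out[-1] = CnvSegment(prev.chrom, prev.start, seg.end, n, mean)
                changed = True
            else:
                out.append(seg)
        segs = out
    return segs


def call_deletions(
    segments: list[CnvSegment], del_threshold: float = -0.1, min_probes: int = 5
) -> list[GenomicInterval]:
    """Segments with mean log10 ratio at or below ``del_threshold`` and at
    least ``min_probes`` member probes, as genomic intervals.

    Symmetric to the minimum-size rule, interruptions shorter than
    ``min_probes`` between two qualifying deletion segments are absorbed:
    a sub-threshold blip too small to be called a copy-number state of its
    own cannot break one deletion into two.
    """
    deleted = []
    for seg in segments:
        if seg.mean_log_ratio <= del_threshold and seg.n_probes >= min_probes:
            seg.call = "deletion"
            deleted.append(seg)
    out: list[GenomicInterval] = []
    for seg in deleted:
        if out:
            prev = out[-1]
            between = [
                s
                for s in segments
                if s.chrom == seg.chrom and s.start > prev.end and s.end < seg.start
            ]
            gap_probes = sum(s.n_probes for s in between)
            if prev.chrom == seg.chrom and gap_probes < min_probes:
                out[-1] = GenomicInterval(prev.chrom, prev.start, seg.end, label="deletion")
                continue
        out.append(GenomicInterval(seg.chrom, seg.start, seg.end, label="deletion"))
    return out


def _subtract(piece: GenomicInterval, neg: GenomicInterval) -> list[GenomicInterval]:
    """Remove ``neg`` from ``piece``; touching endpoints count as overlap.

    Breakpoint convention: the retained flank extends up to the removed
    deletion's boundary coordinate itself (its first/last probe position),
    so a region trimmed on the right by a deletion starting at c is
    reported as ending at c.
    """
    if neg.chrom != piece.chrom or neg.end < piece.start or neg.start > piece.end:
        return [piece]
    out = []
    if neg.start > piece.start:
        out.append(GenomicInterval(piece.chrom, piece.start, neg.start, piece.label))
    if neg.end < piece.end:
        out.append(GenomicInterval(piece.chrom, neg.end, piece.end, piece.label))
    return out


def critical_region(
    positives: list[GenomicInterval], negatives: list[GenomicInterval] = ()
) -> list[GenomicInterval]:
    """Intersection of all signature-positive intervals minus the union of
    the signature-negative ones. May return several disjoint intervals or
    none. All intervals must share one chromosome."""
    if not positives:
        raise ValueError("need at least one signature-positive interval")
    chroms = {iv.chrom for iv in list(positives) + list(negatives)}
    if len(chroms) != 1:
        raise ValueError(f"intervals span multiple chromosomes: {sorted(chroms)}")
    chrom = chroms.pop()
    start = max(iv.start for iv in positives)
    end = min(iv.end for iv in positives)
    if start > end:
        warnings.warn("signature-positive intervals have empty intersection")
        return []
    pieces = [GenomicInterval(chrom, start, end, label="critical_region")]
    for neg in sorted(negatives, key=lambda iv: (iv.start, iv.end)):
        pieces = [p for piece in pieces for p in _subtract(piece, neg)]
    return pieces


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/len(a), overlap/len(b)) for two intervals (0 if disjoint
    or on different chromosomes)."""
    if a.chrom != b.chrom:
        return 0.0
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    len_a, len_b = max(a.end - a.start, 1), max(b.end - b.start, 1)
    return min(inter / len_a, inter / len_b)


def interval_length_mb(interval: GenomicInterval, decimals: int = 2) -> float:
    """(end - start) / 1e6, rounded half-up to ``decimals`` places."""
    mb = Decimal(int(interval.end) - int(interval.start)) / Decimal(10**6)
    q = Decimal(1).scaleb(-decimals)
    return float(mb.quantize(q, rounding=ROUND_HALF_UP))


def phmds_deletion_intervals() -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """The packaged 22q13 EPIC deletion coordinates as interval lists:
    (signature-positive large deletions, signature-negative small ones)."""
    df = load_phmds_deletions()
    pos = [
        GenomicInterval(r.chrom, int(r.start), int(r.end), r.sample_id)
        for r in df[df["signature"]].itertuples()
    ]
    neg = [
        GenomicInterval(r.chrom, int(r.start), int(r.end), r.sample_id)
        for r in df[~df["signature"]].itertuples()
    ]
    return pos, neg


class CopyNumberModel:
    """Array-intensity CNV model for a set of query samples vs controls.

    Parameters
    ----------
    meth, unmeth : probes x samples DataFrames (raw intensities) covering
        both query and control samples.
    manifest : probe manifest (chrom/pos per probe).
    control_ids : sample ids forming the reference panel (per-probe medians).
    sample_ids : query samples to segment (default: all non-controls).
    """

    def __init__(self, meth, unmeth, manifest, control_ids, sample_ids=None):
        self.meth = meth
        self.unmeth = unmeth
        self.manifest = manifest.reset_index(drop=True)
        self.control_ids = list(control_ids)
        if sample_ids is None:
            sample_ids = [c for c in meth.columns if c not in set(self.control_ids)]
        self.sample_ids = list(sample_ids)

    def fit(
        self,
        alpha: float = 0.01,
        n_perm: int = 10000,
        seed: int | None = 0,
        del_threshold: float = -0.1,
        min_probes: int = 5,
        max_merge_diff: float = 0.05,
        smooth_window: int = 5,
    ) -> "CnvResults":
        cols = self.sample_ids + [c for c in self.control_ids if c not in self.sample_ids]
        total = total_intensity(self.meth[cols], self.unmeth[cols])
        norm = pd.DataFrame(quantile_normalize(total), index=self.meth.index, columns=cols)
        control_median = norm[self.control_ids].median(axis=1).to_numpy()

        segments: dict[str, list[CnvSegment]] = {}
        deletions: dict[str, list[GenomicInterval]] = {}
        ss = np.random.SeedSequence(seed)
        for sid, child in zip(self.sample_ids, ss.spawn(len(self.sample_ids))):
            r_all = log_ratio(norm[sid].to_numpy(), control_median)
            segs: list[CnvSegment] = []
            sample_rng_seed = child
            for chrom in pd.unique(self.manifest["chrom"]):
                sel = (self.manifest["chrom"] == chrom).to_numpy()
                segs_c = segment(
                    r_all[sel],
                    self.manifest.loc[sel, "pos"].to_numpy(),
                    alpha=alpha,
                    n_perm=n_perm,
                    seed=sample_rng_seed,
                    smooth_window=smooth_window,
                    chrom=str(chrom),
                )
                segs.extend(merge_segments(segs_c, max_diff=max_merge_diff))
            segments[sid] = segs
            deletions[sid] = call_deletions(segs, del_threshold=del_threshold, min_probes=min_probes)
        return CnvResults(segments, deletions)


class CnvResults:
    """Per-sample segmentation and deletion calls."""

    def __init__(self, segments: dict[str, list[CnvSegment]], deletions: dict[str, list[GenomicInterval]]):
        self.segments = segments
        self.deletions = deletions

    def deletion_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": sid, "chrom": iv.chrom, "start": iv.start, "end": iv.end}
            for sid, ivs in self.deletions.items()
            for iv in ivs
        ]
        return pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end"])

    def summary(self) -> str:
        lines = ["Copy-number calls from array intensities"]
        for sid, ivs in self.deletions.items():
            if not ivs:
                lines.append(f"  {sid}: no deletions")
            for iv in ivs:
                lines.append(
                    f"  {sid}: {iv.chrom}:{iv.start:,}-{iv.end:,} "
                    f"({interval_length_mb(iv, 2):.2f} Mb)"
                )
        return "\n".join(lines)

    def plot(self, sample_id: str, ax=None):
        """Segment-mean step plot for one sample (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 2.5))
        for seg in self.segments[sample_id]:
            ax.hlines(seg.mean_log_ratio, seg.start, seg.end, lw=2)
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_xlabel("position (bp)")
        ax.set_ylabel("log10 ratio")
        ax.set_title(sample_id)
        return ax
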