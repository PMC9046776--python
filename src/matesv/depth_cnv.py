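"""Read-depth CNV detection on two windowing schemes.

The detector follows the classic low-pass read-depth recipe: read ends are
counted into (a) adjustable sliding windows (default 50 kb advanced in 5 kb
increments) for coarse segmentation and (b) non-overlapping 5 kb windows
for boundary refinement and homozygous/hemizygous-deletion calling.  Raw
counts are normalised by GC stratum median and, when available, by a
reference-panel per-window median, then rescaled so the autosomal median
copy ratio equals 1.0 (diploid expectation).

Thresholds ship as config defaults: a heterozygous deletion is expected at
ratio 0.5 and a single-copy gain at 1.5, so the gain/loss cutoffs 1.25 /
0.75 sit halfway between those states and the diploid baseline — separable
at ~4x coverage where a 50-kb window holds ~2,000 read ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .pairio import AlignedPair, GenomeMap, pairs_to_frame

# Default thresholds (all overridable through config / keyword args).
GAIN_THR = 1.25
LOSS_THR = 0.75
MIN_RUN = 3
MERGE_GAP = 1
HOMDEL_RATIO = 0.1
HOMDEL_MIN_WINDOWS = 2
REFINE_FLANK = 50_000
GC_STRATUM_MIN = 30


@dataclass(frozen=True)
class WindowScheme:
    """A genome tiling: ``sliding`` (width, step) or ``fixed`` (width)."""

    kind: str = "sliding"
    width_bp: int = 50_000
    step_bp: int = 5_000

    def __post_init__(self):
        if self.kind not in ("sliding", "fixed"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        step = self.step_bp if self.kind == "sliding" else self.width_bp
        if step > self.width_bp or step <= 0 or self.width_bp <= 0:
            raise ValueError("need 0 < step <= width")

    @property
    def step(self) -> int:
        return self.step_bp if self.kind == "sliding" else self.width_bp

    def starts(self, chrom_len: int) -> np.ndarray:
        """1-based window start positions; final partial window is dropped
        when it covers less than half the nominal width."""
        starts = np.arange(1, chrom_len + 1, self.step, dtype=np.int64)
        length = np.minimum(starts + self.width_bp - 1, chrom_len) - starts + 1
        return starts[length >= self.width_bp / 2]

    def windows(self, genome: GenomeMap) -> pd.DataFrame:
        rows = []
        for chrom, length in genome.chromosomes:
            starts = self.starts(length)
            ends = np.minimum(starts + self.width_bp - 1, length)
            rows.append(pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends}))
        if not rows:
            return pd.DataFrame(columns=["chrom", "start", "end"])
        return pd.concat(rows, ignore_index=True)


@dataclass
class CopyRatioProfile:
    """Per-window normalised copy ratios on one windowing scheme.

    ``table`` columns: chrom, start, end, raw_count, gc, ratio (NaN =
    masked/missing).  Diploid expectation is ratio 1.0.
    """

    scheme: WindowScheme
    table: pd.DataFrame

    def chrom_view(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]


@dataclass
class CnvCall:
    chrom: str
    start: int                 # 1-based inclusive
    end: int
    type: str                  # 'gain' | 'loss' | 'homdel'
    mean_ratio: float
    n_windows: int
    refined: bool = False
    notes: str = ""

    @property
    def size_bp(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_counts(pairs, scheme: WindowScheme, genome: GenomeMap) -> pd.DataFrame:
    """Count read ends per window.

    Each end increments every window containing its position: exactly one
    window for the fixed scheme, up to width/step windows for the sliding
    scheme.  Duplicate-flagged pairs are skipped; MAPQ filtering is the
    ingest step's job.  Accepts a pair table (DataFrame) or an iterable of
    :class:`AlignedPair`.
    """
    if not isinstance(pairs, pd.DataFrame):
        pairs = pairs_to_frame(pairs)
    if "duplicate" in pairs.columns and len(pairs):
        pairs = pairs[~pairs["duplicate"].astype(bool)]
    win = scheme.windows(genome)
    counts = np.zeros(len(win), dtype=np.int64)
    offsets = {}
    pos = 0
    for chrom, _ in genome.chromosomes:
        n = int((win["chrom"] == chrom).sum())
        offsets[chrom] = (pos, n)
        pos += n
    step = scheme.step
    span = scheme.width_bp // step if scheme.width_bp % step == 0 else None
    for chrom, length in genome.chromosomes:
        off, nwin = offsets[chrom]
        if nwin == 0:
            continue
        ends = np.concatenate([
            pairs.loc[pairs["chrom_a"] == chrom, "pos_a"].to_numpy(np.int64),
            pairs.loc[pairs["chrom_b"] == chrom, "pos_b"].to_numpy(np.int64),
        ])
        if ends.size == 0:
            continue
        if span is not None:
            # windows start on the step grid: window i covers step-bins
            # i .. i+span-1, so per-window counts are a forward rolling sum.
            nbins = (length + step - 1) // step
            bins = np.bincount((ends - 1) // step, minlength=nbins)
            csum = np.concatenate([[0], np.cumsum(bins)])
            idx = np.arange(nwin)
            hi = np.minimum(idx + span, nbins)
            counts[off:off + nwin] = csum[hi] - csum[idx]
        else:
            starts = win["start"].to_numpy()[off:off + nwin]
            wends = win["end"].to_numpy()[off:off + nwin]
            for i in range(nwin):
                counts[off + i] = np.count_nonzero(
                    (ends >= starts[i]) & (ends <= wends[i]))
    out = win.copy()
    out["raw_count"] = counts
    return out


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def normalize(
    counts: pd.DataFrame,
    scheme: WindowScheme,
    gc_track: Optional[pd.DataFrame] = None,
    panel: Optional[pd.DataFrame] = None,
    genome: Optional[GenomeMap] = None,
    gc_stratum_min: int = GC_STRATUM_MIN,
) -> CopyRatioProfile:
    """GC- and panel-normalise raw window counts into copy ratios.

    Per window: ratio = count / median(count over the window's 1%-GC
    stratum); strata with fewer than ``gc_stratum_min`` windows fall back
    to the global median.  A panel of per-window median counts divides the
    ratio further; panel windows with median 0 are masked (ratio NaN).
    Finally ratios are rescaled so the autosomal median equals 1.0.
    """
    df = counts.copy()
    raw = df["raw_count"].to_numpy(dtype=float)
    if len(df) == 0 or not np.any(raw > 0):
        raise ValueError("insufficient coverage: all window counts are zero")
    global_med = float(np.median(raw))
    if global_med == 0:
        global_med = float(np.mean(raw[raw > 0]))

    if gc_track is not None:
        gc = _align_track(df, gc_track, "gc")
        df["gc"] = gc
        stratum = np.round(gc * 100).astype(int)
        expected = np.full(len(df), global_med)
        for s in np.unique(stratum[~np.isnan(gc)]):
            members = stratum == s
            if members.sum() >= gc_stratum_min:
                med = float(np.median(raw[members]))
                if med > 0:
                    expected[members] = med
    else:
        df["gc"] = np.nan
        expected = np.full(len(df), global_med)

    ratio = raw / expected

    if panel is not None:
        pmed = _align_track(df, panel, "median_count")
        pscale = np.nanmedian(pmed[pmed > 0])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(pmed > 0, ratio / (pmed / pscale), np.nan)

    autosomal = df["chrom"].map(GenomeMap.is_autosome).to_numpy()
    med = np.nanmedian(ratio[autosomal]) if np.any(autosomal) else np.nanmedian(ratio)
    if not np.isfinite(med) or med == 0:
        raise ValueError("insufficient coverage: undefined autosomal median")
    df["ratio"] = ratio / med
    return CopyRatioProfile(scheme=scheme, table=df)


def _align_track(df: pd.DataFrame, track: pd.DataFrame, col: str) -> np.ndarray:
    """Join a per-window track (chrom,start,<col>) onto the count table."""
    merged = df[["chrom", "start"]].merge(
        track[["chrom", "start", col]], on=["chrom", "start"], how="left")
    return merged[col].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _flag_runs(flags: np.ndarray, merge_gap: int) -> List[tuple]:
    """Maximal runs of True, merging runs separated by <= merge_gap False."""
    runs = []
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return runs
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 <= merge_gap:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    return runs


def segment(
    profile: CopyRatioProfile,
    gain_thr: float = GAIN_THR,
    loss_thr: float = LOSS_THR,
    min_run: int = MIN_RUN,
    merge_gap: int = MERGE_GAP,
) -> List[CnvCall]:
    """Coarse CNV segmentation on the sliding-window profile.

    Maximal runs of consecutive windows with ratio >= ``gain_thr`` (gain)
    or <= ``loss_thr`` (loss) become calls; runs separated by at most
    ``merge_gap`` sub-threshold windows are merged; a merged run must
    contain at least ``min_run`` flagged windows.  Call boundaries are the
    run's outermost window edges.
    """
    calls: List[CnvCall] = []
    for chrom in profile.table["chrom"].unique():
        view = profile.chrom_view(chrom)
        ratio = view["ratio"].to_numpy(dtype=float)
        starts = view["start"].to_numpy()
        ends = view["end"].to_numpy()
        for ctype, flags in (
            ("gain", ratio >= gain_thr),
            ("loss", ratio <= loss_thr),
        ):
            flags = flags & np.isfinite(ratio)
            for lo, hi in _flag_runs(flags, merge_gap):
                flagged = flags[lo:hi + 1]
                if flagged.sum() < min_run:
                    continue
                seg_ratio = ratio[lo:hi + 1][flagged]
                calls.append(CnvCall(
                    chrom=chrom, start=int(starts[lo]), end=int(ends[hi]),
                    type=ctype, mean_ratio=float(np.mean(seg_ratio)),
                    n_windows=int(flagged.sum())))
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls


# ---------------------------------------------------------------------------
# boundary refinement
# ---------------------------------------------------------------------------

def _refine_edge(
    ratio: np.ndarray, starts: np.ndarray, width: int, coarse_pos: int,
    lo_limit: int, hi_limit: int, flank_windows: int,
) -> Optional[int]:
    """Best boundary (window-start position) by the coverage step statistic.

    Candidates are 5-kb window edges b within the allowed range; the
    statistic is |mean(ratio in the ``flank_windows`` windows right of b) −
    mean(ratio left of b)|.  Ties break toward the coarse boundary.
    """
    n = len(ratio)
    best = None
    for j in range(n + 1):
        edge = int(starts[j]) if j < n else int(starts[-1]) + width
        if edge < lo_limit or edge > hi_limit:
            continue
        left = ratio[max(0, j - flank_windows):j]
        right = ratio[j:j + flank_windows]
        left = left[np.isfinite(left)]
        right = right[np.isfinite(right)]
        if left.size == 0 or right.size == 0:
            continue
        stat = abs(float(np.mean(right)) - float(np.mean(left)))
        dist = abs(edge - coarse_pos)
        key = (-stat, dist, edge)
        if best is None or key < best[0]:
            best = (key, edge)
    return None if best is None else best[1]


def refine_boundaries(
    call: CnvCall,
    profile5k: CopyRatioProfile,
    flank: int = REFINE_FLANK,
) -> CnvCall:
    """Move both call boundaries to the 5-kb window edge maximising the
    local coverage step, searching within ±``flank`` of the coarse edge
    (clipped at the call midpoint).  If a flank is entirely masked the
    boundary is left unrefined and the call is flagged."""
    if profile5k.scheme.kind != "fixed":
        raise ValueError("refinement needs the fixed 5-kb profile")
    width = profile5k.scheme.width_bp
    view = profile5k.chrom_view(call.chrom)
    ratio = view["ratio"].to_numpy(dtype=float)
    starts = view["start"].to_numpy()
    if len(view) == 0:
        return replace(call, refined=False, notes="no 5k profile")
    mid = (call.start + call.end) // 2
    fw = max(1, flank // width)
    new_start = _refine_edge(ratio, starts, width, call.start,
                             call.start - flank, min(call.start + flank, mid), fw)
    new_end_edge = _refine_edge(ratio, starts, width, call.end + 1,
                                max(call.end + 1 - flank, mid),
                                call.end + 1 + flank, fw)
    notes = call.notes
    refined = True
    if new_start is None or new_end_edge is None:
        refined = False
        notes = (notes + "; " if notes else "") + "flank masked, boundary unrefined"
        new_start = call.start if new_start is None else new_start
        new_end_edge = call.end + 1 if new_end_edge is None else new_end_edge
    return replace(call, start=int(new_start), end=int(new_end_edge) - 1,
                   refined=refined, notes=notes)


# ---------------------------------------------------------------------------
# homozygous / hemizygous deletions
# ---------------------------------------------------------------------------

def call_homdel(
    profile5k: CopyRatioProfile,
    homdel_ratio: float = HOMDEL_RATIO,
    min_windows: int = HOMDEL_MIN_WINDOWS,
) -> List[CnvCall]:
    """Report maximal runs of >= ``min_windows`` consecutive fixed windows
    with copy ratio <= ``homdel_ratio`` (including 0).  A single isolated
    window is never reported, so the minimum reportable size is about
    two window widths (~10 kb at the 5-kb default)."""
    if profile5k.scheme.kind != "fixed":
        raise ValueError("homozygous-deletion calling needs the fixed profile")
    calls: List[CnvCall] = []
    for chrom in profile5k.table["chrom"].unique():
        view = profile5k.chrom_view(chrom)
        ratio = view["ratio"].to_numpy(dtype=float)
        starts = view["start"].to_numpy()
        ends = view["end"].to_numpy()
        flags = np.isfinite(ratio) & (ratio <= homdel_ratio)
        for lo, hi in _flag_runs(flags, merge_gap=0):
            if hi - lo + 1 < min_windows:
                continue
            calls.append(CnvCall(
                chrom=chrom, start=int(starts[lo]), end=int(ends[hi]),
                type="homdel", mean_ratio=float(np.mean(ratio[lo:hi + 1])),
                n_windows=int(hi - lo + 1)))
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls


def fine_loss_runs(
    profile5k: CopyRatioProfile,
    loss_thr: float = LOSS_THR,
    min_windows: int = 2,
) -> List[CnvCall]:
    """Fine-scale loss evidence: runs of >= ``min_windows`` fixed windows
    with ratio <= ``loss_thr``.  Used to corroborate junction-based
    deletion calls below the coarse 50-kb segmentation resolution."""
    if profile5k.scheme.kind != "fixed":
        raise ValueError("fine loss evidence needs the fixed profile")
    calls: List[CnvCall] = []
    for chrom in profile5k.table["chrom"].unique():
        view = profile5k.chrom_view(chrom)
        ratio = view["ratio"].to_numpy(dtype=float)
        starts = view["start"].to_numpy()
        ends = view["end"].to_numpy()
        flags = np.isfinite(ratio) & (ratio <= loss_thr)
        for lo, hi in _flag_runs(flags, merge_gap=0):
            if hi - lo + 1 < min_windows:
                continue
            calls.append(CnvCall(
                chrom=chrom, start=int(starts[lo]), end=int(ends[hi]),
                type="loss", mean_ratio=float(np.mean(ratio[lo:hi + 1])),
                n_windows=int(hi - lo + 1), notes="fine-scale"))
    return calls
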