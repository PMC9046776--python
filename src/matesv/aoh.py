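"""Absence-of-heterozygosity detection from shallow-sequencing pileups.

Sites with 5–20x depth and at least one alternate read are genotyped as
heterozygous or homozygous-alternate by allele fraction.  Counts of each
genotype class are tallied in fixed 100-kb windows and normalised by the
sample's autosome-wide mean, so runs of homozygosity appear as a
*simultaneous* drop in the normalised heterozygous rate and rise in the
normalised homozygous rate — the joint signature that separates true AOH
from coverage dropout (which depresses both rates).

Reference-homozygous sites (zero alternate reads) carry no information
here by construction, so "hom rate" always means homozygous-ALT rate.

Reported regions of >= 5 Mb are classified terminal/interstitial and fed
through the reporting rules used for UPD and consanguinity review:
uniparental disomy is suspected for interstitial AOH above 15 Mb or
terminal AOH above 5 Mb; AOH on three or more autosomes suggests parental
consanguinity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .pairio import GenomeMap

DEPTH_MIN = 5
DEPTH_MAX = 20
HET_AF_MIN = 0.2
HET_AF_MAX = 0.8
HOM_AF_MIN = 0.9
WINDOW_BP = 100_000
HET_THR = 0.3
HOM_THR = 1.3
MAX_GAP_WINDOWS = 5
REPORT_MIN_BP = 5_000_000
INTERSTITIAL_UPD_BP = 15_000_000
TERMINAL_UPD_BP = 5_000_000
CONSANGUINITY_MIN_AUTOSOMES = 3
#: Chromosomes carrying clinically relevant imprinted regions.
IMPRINTED_CHROMOSOMES = ("6", "7", "11", "14", "15", "20")


@dataclass
class AOHRegion:
    chrom: str
    start: int                # 1-based inclusive
    end: int
    position_class: str       # 'terminal' | 'interstitial'
    mean_het_norm: float
    mean_hom_norm: float
    n_windows: int
    upd_suspect: bool = False

    @property
    def size_bp(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# genotyping
# ---------------------------------------------------------------------------

def genotype_sites(pileup: pd.DataFrame) -> pd.DataFrame:
    """Call heterozygous / homozygous-ALT SNVs from pileup counts.

    Keeps sites with depth in [5, 20] and alt_count >= 1; het when the
    alternate-allele fraction lies in [0.2, 0.8], hom_alt when >= 0.9;
    fractions in (0.8, 0.9) are ambiguous and dropped.
    """
    if len(pileup) == 0:
        return pd.DataFrame(columns=["chrom", "pos", "genotype", "depth",
                                     "alt_fraction"])
    depth = pileup["depth"].to_numpy()
    alt = pileup["alt_count"].to_numpy()
    usable = (depth >= DEPTH_MIN) & (depth <= DEPTH_MAX) & (alt >= 1)
    df = pileup.loc[usable, ["chrom", "pos", "depth"]].copy()
    af = alt[usable] / depth[usable]
    df["alt_fraction"] = af
    genotype = np.where((af >= HET_AF_MIN) & (af <= HET_AF_MAX), "het",
                        np.where(af >= HOM_AF_MIN, "hom_alt", "ambiguous"))
    df["genotype"] = genotype
    return df[df["genotype"] != "ambiguous"].reset_index(drop=True)


# ---------------------------------------------------------------------------
# windowed rates
# ---------------------------------------------------------------------------

def window_rates(calls: pd.DataFrame, genome: GenomeMap,
                 window_bp: int = WINDOW_BP) -> pd.DataFrame:
    """Per-100-kb-window genotype counts normalised by the autosome-wide
    mean per-window count of the same class.

    Windows with no usable site are flagged missing (rates NaN) and
    excluded from the normalising means.  Raises if the sample has no
    autosomal heterozygous calls at all.
    """
    rows = []
    for chrom, length in genome.chromosomes:
        starts = np.arange(1, length + 1, window_bp, dtype=np.int64)
        ends = np.minimum(starts + window_bp - 1, length)
        sub = calls[calls["chrom"] == chrom]
        idx = (sub["pos"].to_numpy(np.int64) - 1) // window_bp
        het = np.bincount(idx[(sub["genotype"] == "het").to_numpy()],
                          minlength=len(starts)) if len(sub) else np.zeros(len(starts))
        hom = np.bincount(idx[(sub["genotype"] == "hom_alt").to_numpy()],
                          minlength=len(starts)) if len(sub) else np.zeros(len(starts))
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "het_count": het[:len(starts)], "hom_count": hom[:len(starts)]}))
    win = pd.concat(rows, ignore_index=True)
    win["n_sites"] = win["het_count"] + win["hom_count"]
    informative = win["n_sites"] > 0
    autosomal = win["chrom"].map(GenomeMap.is_autosome)
    basis = informative & autosomal
    het_total = win.loc[basis, "het_count"].sum()
    if het_total == 0:
        raise ValueError("sample unusable for AOH: no autosomal heterozygous SNVs")
    het_mean = win.loc[basis, "het_count"].mean()
    hom_mean = win.loc[basis, "hom_count"].mean()
    win["het_rate_norm"] = np.where(informative, win["het_count"] / het_mean, np.nan)
    if hom_mean > 0:
        win["hom_rate_norm"] = np.where(informative, win["hom_count"] / hom_mean,
                                        np.nan)
    else:
        win["hom_rate_norm"] = np.where(informative, 0.0, np.nan)
    return win


# ---------------------------------------------------------------------------
# region calling
# ---------------------------------------------------------------------------

def call_aoh(
    windows: pd.DataFrame,
    genome: GenomeMap,
    het_thr: float = HET_THR,
    hom_thr: float = HOM_THR,
    max_gap_windows: int = MAX_GAP_WINDOWS,
    report_min: int = REPORT_MIN_BP,
) -> List[AOHRegion]:
    """Call AOH regions from normalised window rates.

    A window is flagged when het_rate_norm < ``het_thr`` AND
    hom_rate_norm > ``hom_thr`` — the joint signature that excludes
    coverage dropout; flagged runs bridging at most ``max_gap_windows``
    unflagged or missing windows are merged.  Run edges are then extended
    across contiguous windows satisfying the het-depletion criterion
    alone: heterozygote loss is the defining (and statistically much
    stronger) AOH signal, while the hom-rate rise is Poisson-noisier, so
    requiring the joint rule at the very edge would clip true boundary
    windows.  Merged regions whose inclusive span (end − start + 1)
    reaches ``report_min`` are reported (a run of exactly fifty 100-kb
    windows counts as 5 Mb).  A region within one window of a chromosome
    end is terminal.
    """
    regions: List[AOHRegion] = []
    window_bp = int((windows["end"] - windows["start"] + 1).max()) if len(windows) else WINDOW_BP
    for chrom in windows["chrom"].unique():
        view = windows[windows["chrom"] == chrom]
        het = view["het_rate_norm"].to_numpy(dtype=float)
        hom = view["hom_rate_norm"].to_numpy(dtype=float)
        starts = view["start"].to_numpy()
        ends = view["end"].to_numpy()
        flags = np.isfinite(het) & np.isfinite(hom) & (het < het_thr) & (hom > hom_thr)
        idx = np.flatnonzero(flags)
        if idx.size == 0:
            continue
        run_start = prev = idx[0]
        runs = []
        for i in idx[1:]:
            if i - prev - 1 <= max_gap_windows:
                prev = i
            else:
                runs.append((run_start, prev))
                run_start = prev = i
        runs.append((run_start, prev))
        het_only = np.isfinite(het) & (het < het_thr)
        chrom_len = genome.length(chrom)
        for lo, hi in runs:
            while lo > 0 and het_only[lo - 1]:
                lo -= 1
            while hi < len(het_only) - 1 and het_only[hi + 1]:
                hi += 1
            start, end = int(starts[lo]), int(ends[hi])
            if end - start + 1 < report_min:
                continue
            terminal = (start - 1 <= window_bp) or (chrom_len - end <= window_bp)
            sel = slice(lo, hi + 1)
            regions.append(AOHRegion(
                chrom=chrom, start=start, end=end,
                position_class="terminal" if terminal else "interstitial",
                mean_het_norm=float(np.nanmean(het[sel])),
                mean_hom_norm=float(np.nanmean(hom[sel])),
                n_windows=int(flags[sel].sum())))
    return regions


# ---------------------------------------------------------------------------
# reporting rules
# ---------------------------------------------------------------------------

def summarize_aoh(
    regions: Sequence[AOHRegion],
    genome: GenomeMap,
    interstitial_upd_bp: int = INTERSTITIAL_UPD_BP,
    terminal_upd_bp: int = TERMINAL_UPD_BP,
    consanguinity_min_autosomes: int = CONSANGUINITY_MIN_AUTOSOMES,
    imprinted_chromosomes: Sequence[str] = IMPRINTED_CHROMOSOMES,
) -> Dict:
    """Apply UPD / consanguinity reporting rules.

    Flags each region as UPD-suspect (interstitial > 15 Mb or terminal >
    5 Mb), sums autosomal AOH (sex chromosomes excluded), counts distinct
    autosomes carrying AOH, raises the consanguinity flag at >= 3 such
    autosomes, and marks regions on imprinted chromosomes.
    """
    imprinted = {c.removeprefix("chr") for c in imprinted_chromosomes}
    per_region = []
    autosomal_total = 0
    autosomes = set()
    for r in regions:
        upd = ((r.position_class == "interstitial" and r.size_bp > interstitial_upd_bp)
               or (r.position_class == "terminal" and r.size_bp > terminal_upd_bp))
        r.upd_suspect = upd
        if genome.is_autosome(r.chrom):
            autosomal_total += r.size_bp
            autosomes.add(r.chrom)
        per_region.append({
            "chrom": r.chrom, "start": r.start, "end": r.end,
            "size_bp": r.size_bp, "position_class": r.position_class,
            "upd_suspect": upd,
            "imprinted_chromosome": r.chrom.removeprefix("chr") in imprinted,
            "mean_het_norm": r.mean_het_norm,
            "mean_hom_norm": r.mean_hom_norm,
        })
    return {
        "regions": per_region,
        "autosomal_total_bp": int(autosomal_total),
        "n_autosomes_with_aoh": len(autosomes),
        "consanguinity_suspected": len(autosomes) >= consanguinity_min_autosomes,
        "any_upd_suspect": any(r["upd_suspect"] for r in per_region),
    }


def plot_rate_tracks(windows: pd.DataFrame, regions: Sequence[AOHRegion],
                     path, chrom: Optional[str] = None) -> None:
    """Two-track per-chromosome plot: normalised het (top) and hom-ALT
    (bottom) window rates, AOH regions shaded."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = [chrom] if chrom else list(windows["chrom"].unique())
    fig, axes = plt.subplots(2 * len(chroms), 1,
                             figsize=(10, 2.2 * len(chroms)), squeeze=False)
    for i, c in enumerate(chroms):
        view = windows[windows["chrom"] == c]
        mid = (view["start"] + view["end"]) / 2e6
        for j, (col, label) in enumerate(
                (("het_rate_norm", "het rate"), ("hom_rate_norm", "hom-ALT rate"))):
            ax = axes[2 * i + j][0]
            ax.plot(mid, view[col], ".", ms=2)
            ax.axhline(1.0, color="grey", lw=0.5)
            ax.set_ylabel(f"{c} {label}")
            for r in regions:
                if r.chrom == c:
                    ax.axvspan(r.start / 1e6, r.end / 1e6, color="gold", alpha=0.3)
    axes[-1][0].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
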