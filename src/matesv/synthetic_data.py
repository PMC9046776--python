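"""Synthetic mate-pair alignment and pileup simulator.

Emulates the data-generating process of a large-insert (~5 kb) mate-pair
library sequenced to ~4x base coverage: a diploid donor genome is built
from a reference chromosome map by implanting events on one haplotype
(heterozygous) or both (homozygous); fragments are drawn uniformly along
each rearranged molecule with truncated-normal insert sizes (3–8 kb) and
100-bp reads at both ends, and both ends are mapped back to reference
coordinates.  Fragments crossing an implanted junction therefore yield
chimeric pairs with exactly the orientation the event geometry dictates —
no alignment step is involved, ends are emitted pre-mapped at MAPQ 60.
Low-copy-repeat (segmental-duplication) regions are modelled as a mask in
which read ends get MAPQ 0, so junction evidence inside them vanishes at
the default ingest filter.

SNV pileups are simulated independently at ~8x mean site depth (the 5–20x
genotyping gate would otherwise discard most sites at 4x): heterozygous
candidate sites every ~1.5 kb and homozygous-ALT sites every ~2.5 kb, with
heterozygosity suppressed to a 2% residual (genotyping error) inside
implanted AOH regions, where suppressed sites become homozygous-REF or
homozygous-ALT with equal probability.

Every draw comes from a single ``numpy`` Generator seeded by the config,
so identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .pairio import GenomeMap, PAIR_FRAME_COLUMNS, write_bed, write_pair_tsv, write_pileup_tsv

DEFAULT_GENOME = (("chr1", 30_000_000), ("chr2", 30_000_000))


@dataclass(frozen=True)
class SimEvent:
    """One implanted rearrangement.

    ``type``: ``del`` | ``dup`` (forward tandem) | ``inv`` | ``ins``
    (duplicated-segment insertion) | ``tra`` (reciprocal translocation) |
    ``cpx_dup_ins`` (tandem duplication with remote segments inserted
    between the two copies).  ``zygosity`` is ``het`` (haplotype 1 only)
    or ``hom`` (both).
    """

    type: str
    chrom: str
    start: int = 0
    end: int = 0
    zygosity: str = "het"
    # ins:
    insert_chrom: Optional[str] = None
    insert_at: Optional[int] = None
    orientation: str = "forward"
    # tra:
    partner_chrom: Optional[str] = None
    partner_pos: Optional[int] = None
    # cpx_dup_ins: segments inserted between the two copies
    inserts: Tuple[Tuple[str, int, int, str], ...] = ()


@dataclass(frozen=True)
class SimConfig:
    genome: Tuple[Tuple[str, int], ...] = DEFAULT_GENOME
    insert_mean: float = 5_000.0
    insert_sd: float = 700.0
    insert_min: int = 3_000
    insert_max: int = 8_000
    read_len: int = 100
    base_coverage: float = 4.0
    het_spacing: float = 1_500.0       # mean bp between het candidate sites
    hom_spacing: float = 2_500.0       # mean bp between hom-ALT sites
    site_depth_mean: float = 8.0
    aoh_het_retention: float = 0.02
    events: Tuple[SimEvent, ...] = ()
    aoh_regions: Tuple[Tuple[str, int, int], ...] = ()
    lcr_mask: Tuple[Tuple[str, int, int], ...] = ()
    duplicate_rate: float = 0.0
    gc_window: int = 5_000
    gc_bias: float = 0.0
    seed: int = 0

    def genome_map(self) -> GenomeMap:
        return GenomeMap(chromosomes=tuple(self.genome))

    def n_fragments(self) -> int:
        total = sum(length for _, length in self.genome)
        return math.ceil(self.base_coverage * total / (2 * self.read_len))

    def validate(self) -> None:
        lengths = dict(self.genome)
        spans: Dict[str, List[Tuple[int, int]]] = {}

        def claim(chrom, start, end, what):
            if chrom not in lengths:
                raise ValueError(f"{what}: unknown chromosome {chrom}")
            if not (1 <= start <= end <= lengths[chrom]):
                raise ValueError(f"{what}: {chrom}:{start}-{end} out of bounds")
            for s, e in spans.get(chrom, []):
                if start <= e and s <= end:
                    raise ValueError(
                        f"inconsistent event composition: {what} overlaps "
                        f"{chrom}:{s}-{e}")
            spans.setdefault(chrom, []).append((start, end))

        for ev in self.events:
            if ev.type in ("del", "dup", "inv", "cpx_dup_ins"):
                claim(ev.chrom, ev.start, ev.end, ev.type)
            elif ev.type == "ins":
                claim(ev.insert_chrom, ev.insert_at, ev.insert_at + 1, "ins site")
                if ev.chrom not in lengths or not (
                        1 <= ev.start <= ev.end <= lengths[ev.chrom]):
                    raise ValueError("ins donor segment out of bounds")
            elif ev.type == "tra":
                claim(ev.chrom, ev.start, ev.start, "tra")
                claim(ev.partner_chrom, ev.partner_pos, ev.partner_pos, "tra partner")
            else:
                raise ValueError(f"unknown event type {ev.type!r}")
        for chrom, start, end in self.aoh_regions:
            if chrom not in lengths or not (1 <= start <= end <= lengths[chrom]):
                raise ValueError(f"AOH region {chrom}:{start}-{end} out of bounds")


@dataclass
class SimResult:
    config: SimConfig
    pairs: pd.DataFrame
    pileup: pd.DataFrame
    gc_track: pd.DataFrame
    truth: Dict

    def write(self, outdir) -> Dict[str, Path]:
        """Write pair table, pileup, GC track, truth JSON (and LCR mask)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "pairs": outdir / "pairs.tsv",
            "pileup": outdir / "pileup.tsv",
            "gc": outdir / "gc_track.tsv",
            "truth": outdir / "truth.json",
            "genome": outdir / "genome.tsv",
        }
        write_pair_tsv(self.pairs[~self.pairs["duplicate"]], paths["pairs"])
        write_pileup_tsv(self.pileup, paths["pileup"])
        self.gc_track.to_csv(paths["gc"], sep="\t", header=False, index=False)
        paths["truth"].write_text(json.dumps(self.truth, indent=1))
        paths["genome"].write_text(
            "".join(f"{c}\t{l}\n" for c, l in self.config.genome))
        if self.config.lcr_mask:
            paths["lcr_mask"] = outdir / "lcr_mask.bed"
            write_bed(self.config.lcr_mask, paths["lcr_mask"])
        return paths


# ---------------------------------------------------------------------------
# donor genome construction
# ---------------------------------------------------------------------------

def _donor_side(chrom, s, e, orient, which):
    """Junction side descriptor for entering ('start') or leaving ('end')
    a donor segment of the given orientation."""
    if which == "start":
        return (chrom, s, "-") if orient == "forward" else (chrom, e, "+")
    return (chrom, e, "+") if orient == "forward" else (chrom, s, "-")


def _build_haplotype(genome: Sequence[Tuple[str, int]],
                     events: Sequence[SimEvent]):
    """Segment lists (molecules) for one haplotype, plus its junctions.

    Each molecule is a list of (chrom, start, end, strand) reference
    segments; junctions are ((sideA, sideB), event_index) with sides
    (chrom, pos, strand) canonically ordered.
    """
    order = {c: i for i, (c, _) in enumerate(genome)}
    ops_by_chrom: Dict[str, List[Tuple[int, int, SimEvent]]] = {}
    tra_events: List[Tuple[int, SimEvent]] = []
    for i, ev in enumerate(events):
        if ev.type == "tra":
            tra_events.append((i, ev))
        elif ev.type == "ins":
            ops_by_chrom.setdefault(ev.insert_chrom, []).append(
                (ev.insert_at, i, ev))
        else:
            ops_by_chrom.setdefault(ev.chrom, []).append((ev.start, i, ev))

    junctions = []

    def add_junction(side_l, side_r, ev_idx):
        a, b = sorted((side_l, side_r), key=lambda s: (order[s[0]], s[1]))
        junctions.append({"side_a": a, "side_b": b,
                          "key": (a[0], b[0], a[2], b[2]), "event": ev_idx})

    molecules = {}
    for chrom, length in genome:
        segs: List[Tuple[str, int, int, str]] = []
        cur = 1
        for _, ev_idx, ev in sorted(ops_by_chrom.get(chrom, []),
                                    key=lambda t: t[0]):
            if ev.type == "del":
                if cur <= ev.start - 1:
                    segs.append((chrom, cur, ev.start - 1, "+"))
                add_junction((chrom, ev.start - 1, "+"),
                             (chrom, ev.end + 1, "-"), ev_idx)
                cur = ev.end + 1
            elif ev.type == "dup":
                segs.append((chrom, cur, ev.end, "+"))
                segs.append((chrom, ev.start, ev.end, "+"))
                add_junction((chrom, ev.end, "+"), (chrom, ev.start, "-"),
                             ev_idx)
                cur = ev.end + 1
            elif ev.type == "inv":
                if cur <= ev.start - 1:
                    segs.append((chrom, cur, ev.start - 1, "+"))
                segs.append((chrom, ev.start, ev.end, "-"))
                add_junction((chrom, ev.start - 1, "+"), (chrom, ev.end, "+"),
                             ev_idx)
                add_junction((chrom, ev.start, "-"), (chrom, ev.end + 1, "-"),
                             ev_idx)
                cur = ev.end + 1
            elif ev.type == "ins":
                segs.append((chrom, cur, ev.insert_at, "+"))
                o = ev.orientation
                seg = ((ev.chrom, ev.start, ev.end, "+") if o == "forward"
                       else (ev.chrom, ev.start, ev.end, "-"))
                segs.append(seg)
                add_junction((chrom, ev.insert_at, "+"),
                             _donor_side(ev.chrom, ev.start, ev.end, o, "start"),
                             ev_idx)
                add_junction(_donor_side(ev.chrom, ev.start, ev.end, o, "end"),
                             (chrom, ev.insert_at + 1, "-"), ev_idx)
                cur = ev.insert_at + 1
            elif ev.type == "cpx_dup_ins":
                segs.append((chrom, cur, ev.end, "+"))
                prev_side = (chrom, ev.end, "+")
                for (dc, ds, de, do) in ev.inserts:
                    add_junction(prev_side, _donor_side(dc, ds, de, do, "start"),
                                 ev_idx)
                    segs.append((dc, ds, de, "+" if do == "forward" else "-"))
                    prev_side = _donor_side(dc, ds, de, do, "end")
                add_junction(prev_side, (chrom, ev.start, "-"), ev_idx)
                segs.append((chrom, ev.start, ev.end, "+"))
                cur = ev.end + 1
        if cur <= length:
            segs.append((chrom, cur, length, "+"))
        molecules[chrom] = segs

    # reciprocal translocations: swap molecule tails
    for ev_idx, ev in tra_events:
        a, pa = ev.chrom, ev.start
        pb = ev.partner_pos
        la = dict(genome)[a]
        lb = dict(genome)[ev.partner_chrom]
        molecules[a] = [(a, 1, pa, "+"), (ev.partner_chrom, pb + 1, lb, "+")]
        molecules[ev.partner_chrom] = [(ev.partner_chrom, 1, pb, "+"),
                                       (a, pa + 1, la, "+")]
        add_junction((a, pa, "+"), (ev.partner_chrom, pb + 1, "-"), ev_idx)
        add_junction((ev.partner_chrom, pb, "+"), (a, pa + 1, "-"), ev_idx)

    return list(molecules.values()), junctions


# ---------------------------------------------------------------------------
# fragment sampling
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi, n: int) -> np.ndarray:
    """Truncated normal by rejection (acceptance ~1 for the insert model)."""
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _sample_molecule(rng, cfg: SimConfig, segs, n: int, chrom_index,
                     id_offset: int):
    """Sample n fragments on one molecule; returns mapped end arrays."""
    seg_len = np.array([e - s + 1 for _, s, e, _ in segs], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(seg_len)])  # molecule offsets
    mol_len = int(cum[-1])
    rl = cfg.read_len
    a = (cfg.insert_min - cfg.insert_mean) / cfg.insert_sd
    b = (cfg.insert_max - cfg.insert_mean) / cfg.insert_sd
    ins = np.rint(_truncated_normal(rng, cfg.insert_mean, cfg.insert_sd,
                                    cfg.insert_min, cfg.insert_max,
                                    n)).astype(np.int64)
    ins = np.minimum(ins, mol_len)
    start = np.floor(rng.random(n) * (mol_len - ins + 1)).astype(np.int64)

    seg_chrom = np.array([chrom_index[c] for c, _, _, _ in segs])
    seg_start = np.array([s for _, s, _, _ in segs], dtype=np.int64)
    seg_end = np.array([e for _, _, e, _ in segs], dtype=np.int64)
    seg_fwd = np.array([st == "+" for _, _, _, st in segs])

    def map_read(off_lo, off_hi, hap_strand_plus):
        """Map a read spanning molecule offsets [off_lo, off_hi] (0-based)."""
        idx = np.searchsorted(cum, off_lo, side="right") - 1
        ok = off_hi < cum[np.minimum(idx + 1, len(cum) - 1)]
        ok &= idx < len(segs)
        idx = np.minimum(idx, len(segs) - 1)
        fwd = seg_fwd[idx]
        rel_lo = off_lo - cum[idx]
        rel_hi = off_hi - cum[idx]
        pos = np.where(fwd, seg_start[idx] + rel_lo, seg_end[idx] - rel_hi)
        if hap_strand_plus:
            strand = np.where(fwd, "+", "-")
        else:
            strand = np.where(fwd, "-", "+")
        return idx, ok, pos, strand

    l_lo, l_hi = start, start + rl - 1
    r_lo, r_hi = start + ins - rl, start + ins - 1
    li, lok, lpos, lstrand = map_read(l_lo, l_hi, True)
    ri, rok, rpos, rstrand = map_read(r_lo, r_hi, False)
    keep = lok & rok
    names = np.array([c for c, *_ in segs])
    nkeep = int(keep.sum())
    return {
        "pair_id": id_offset + np.arange(nkeep, dtype=np.int64),
        "chrom_a": names[li[keep]],
        "pos_a": lpos[keep],
        "strand_a": lstrand[keep],
        "chrom_b": names[ri[keep]],
        "pos_b": rpos[keep],
        "strand_b": rstrand[keep],
    }


def _apply_mask(df: pd.DataFrame, mask) -> pd.DataFrame:
    for chrom, start, end in mask:
        for side in ("a", "b"):
            hit = ((df[f"chrom_{side}"] == chrom)
                   & (df[f"pos_{side}"] >= start) & (df[f"pos_{side}"] <= end))
            df.loc[hit, f"mapq_{side}"] = 0
    return df


def _canonical(df: pd.DataFrame, genome: GenomeMap) -> pd.DataFrame:
    rank = {c: i for i, c in enumerate(genome.names)}
    ra = df["chrom_a"].map(rank).to_numpy()
    rb = df["chrom_b"].map(rank).to_numpy()
    swap = (ra > rb) | ((ra == rb) & (df["pos_a"].to_numpy() > df["pos_b"].to_numpy()))
    for col in ("chrom", "pos", "strand", "mapq"):
        a, b = f"{col}_a", f"{col}_b"
        tmp = df.loc[swap, a].to_numpy()
        df.loc[swap, a] = df.loc[swap, b].to_numpy()
        df.loc[swap, b] = tmp
    return df


# ---------------------------------------------------------------------------
# pileup simulation
# ---------------------------------------------------------------------------

def _site_positions(rng, length: int, spacing: float) -> np.ndarray:
    n_guess = int(length / spacing * 1.35) + 20
    gaps = rng.exponential(spacing, size=n_guess)
    pos = np.cumsum(gaps).astype(np.int64) + 1
    while pos.size and pos[-1] <= length:
        more = np.cumsum(rng.exponential(spacing, size=50)).astype(np.int64)
        pos = np.concatenate([pos, pos[-1] + more])
    return np.unique(pos[pos <= length])


def _simulate_pileup(rng, cfg: SimConfig) -> pd.DataFrame:
    homdel = [(ev.chrom, ev.start, ev.end) for ev in cfg.events
              if ev.type == "del" and ev.zygosity == "hom"]
    frames = []
    for chrom, length in cfg.genome:
        het_pos = _site_positions(rng, length, cfg.het_spacing)
        hom_pos = _site_positions(rng, length, cfg.hom_spacing)
        in_aoh = np.zeros(het_pos.size, dtype=bool)
        for c, s, e in cfg.aoh_regions:
            if c == chrom:
                in_aoh |= (het_pos >= s) & (het_pos <= e)
        u = rng.random(het_pos.size)
        # inside AOH: a residual 2% of candidate sites remain het
        # (genotyping error); the rest are homozygous, half of them ALT.
        stays_het = ~in_aoh | (u < cfg.aoh_het_retention)
        to_hom_alt = in_aoh & ~stays_het & (rng.random(het_pos.size) < 0.5)

        pos = np.concatenate([het_pos, hom_pos])
        kind = np.concatenate([
            np.where(stays_het, 0, np.where(to_hom_alt, 1, 2)),
            np.full(hom_pos.size, 1),
        ])  # 0 het, 1 hom_alt, 2 hom_ref
        order_idx = np.argsort(pos, kind="stable")
        pos, kind = pos[order_idx], kind[order_idx]
        pos, uniq_idx = np.unique(pos, return_index=True)
        kind = kind[uniq_idx]
        for c, s, e in homdel:
            if c == chrom:
                drop = (pos >= s) & (pos <= e)
                pos, kind = pos[~drop], kind[~drop]
        depth = rng.poisson(cfg.site_depth_mean, size=pos.size)
        ok = depth > 0
        pos, kind, depth = pos[ok], kind[ok], depth[ok]
        alt = np.where(
            kind == 0, rng.binomial(depth, 0.5),
            np.where(kind == 1, depth - rng.binomial(depth, 0.02),
                     rng.binomial(depth, 0.01)))
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "depth": depth,
            "ref_count": depth - alt, "alt_count": alt}))
    return pd.concat(frames, ignore_index=True)


def _gc_track(rng, cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for chrom, length in cfg.genome:
        starts = np.arange(1, length + 1, cfg.gc_window, dtype=np.int64)
        ends = np.minimum(starts + cfg.gc_window - 1, length)
        gc = (0.45 + 0.05 * np.sin(2 * np.pi * starts / 3_000_000)
              + rng.normal(0, 0.01, size=starts.size))
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "gc": np.clip(gc, 0.3, 0.6).round(4)}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# top-level simulation
# ---------------------------------------------------------------------------

def simulate(config: SimConfig, pairs_only: bool = False,
             pileup_only: bool = False) -> SimResult:
    """Generate aligned pairs, pileup, GC track and the truth set.

    All randomness flows from ``config.seed``; the same config is
    guaranteed to reproduce byte-identical outputs.  ``pairs_only`` skips
    the pileup, ``pileup_only`` skips fragment sampling (for AOH-only
    studies on large genomes).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome = config.genome_map()
    chrom_index = {c: i for i, c in enumerate(genome.names)}

    het_events = [ev for ev in config.events if ev.zygosity == "het"]
    hom_events = [ev for ev in config.events if ev.zygosity == "hom"]
    hap_defs = [hom_events + het_events, hom_events]

    molecules, junctions = [], []
    for hap_events in hap_defs:
        mols, juncs = _build_haplotype(config.genome, hap_events)
        molecules.append(mols)
        junctions.append(juncs)

    # truth junctions deduplicated across haplotypes
    seen, truth_junctions = set(), []
    ev_index = {id(ev): i for i, ev in enumerate(config.events)}
    for hap_events, juncs in zip(hap_defs, junctions):
        for j in juncs:
            tup = (j["side_a"], j["side_b"])
            if tup in seen:
                continue
            seen.add(tup)
            truth_junctions.append({
                "side_a": list(j["side_a"]), "side_b": list(j["side_b"]),
                "key": list(j["key"]),
                "event": ev_index[id(hap_events[j["event"]])],
            })

    n_total = config.n_fragments()
    mol_list = [(h, m) for h in range(2) for m in molecules[h]]
    weights = np.array([sum(e - s + 1 for _, s, e, _ in m)
                        for _, m in mol_list], dtype=float)
    chunks = []
    if not pileup_only:
        counts = rng.multinomial(n_total, weights / weights.sum())
        id_offset = 0
        for (hap, segs), n in zip(mol_list, counts):
            if n == 0:
                continue
            chunks.append(_sample_molecule(rng, config, segs, int(n),
                                           chrom_index, id_offset))
            id_offset += int(n)
    if chunks:
        cols = {k: np.concatenate([c[k] for c in chunks]) for k in chunks[0]}
        n_all = len(cols["pair_id"])
        chrom_cats = genome.names
        pairs = pd.DataFrame({
            "pair_id": cols["pair_id"],
            "chrom_a": pd.Categorical(cols["chrom_a"], categories=chrom_cats),
            "pos_a": cols["pos_a"],
            "strand_a": pd.Categorical(cols["strand_a"], categories=["+", "-"]),
            "mapq_a": np.full(n_all, 60),
            "chrom_b": pd.Categorical(cols["chrom_b"], categories=chrom_cats),
            "pos_b": cols["pos_b"],
            "strand_b": pd.Categorical(cols["strand_b"], categories=["+", "-"]),
            "mapq_b": np.full(n_all, 60),
            "duplicate": np.zeros(n_all, dtype=bool),
        })
        pairs["pair_id"] = "p" + pairs["pair_id"].astype(str)
    else:
        pairs = pd.DataFrame(columns=list(PAIR_FRAME_COLUMNS))
    if config.gc_bias:
        gc_tmp = _gc_track(np.random.default_rng(config.seed + 1), config)
        pairs = _thin_by_gc(rng, pairs, gc_tmp, config)
    pairs = _apply_mask(pairs, config.lcr_mask)
    pairs = _canonical(pairs, genome)
    if config.duplicate_rate > 0 and len(pairs):
        k = rng.binomial(len(pairs), config.duplicate_rate)
        dup = pairs.sample(n=int(k), random_state=int(rng.integers(2**31)))
        dup = dup.assign(duplicate=True)
        pairs = pd.concat([pairs, dup], ignore_index=True)
    pairs = pairs.reset_index(drop=True)

    gc_track = _gc_track(rng, config)
    pileup = (pd.DataFrame(columns=["chrom", "pos", "depth", "ref_count",
                                    "alt_count"])
              if pairs_only else _simulate_pileup(rng, config))

    truth = {
        "seed": config.seed,
        "genome": [[c, l] for c, l in config.genome],
        "n_fragments": n_total,
        "events": [
            {**{k: v for k, v in asdict(ev).items() if v not in (None, ())},
             "index": i,
             "junctions": [j for j in truth_junctions if j["event"] == i]}
            for i, ev in enumerate(config.events)],
        "junctions": truth_junctions,
        "aoh_regions": [list(r) for r in config.aoh_regions],
        "lcr_mask": [list(r) for r in config.lcr_mask],
    }
    return SimResult(config=config, pairs=pairs, gc_track=gc_track,
                     pileup=pileup, truth=truth)


def _thin_by_gc(rng, pairs: pd.DataFrame, gc_track: pd.DataFrame,
                cfg: SimConfig) -> pd.DataFrame:
    """Optional GC bias: fragments kept with probability linear in the GC
    of the window holding their first end."""
    gc_map = {(r.chrom, (r.start - 1) // cfg.gc_window): r.gc
              for r in gc_track.itertuples()}
    gc = np.array([gc_map.get((c, (p - 1) // cfg.gc_window), 0.45)
                   for c, p in zip(pairs["chrom_a"], pairs["pos_a"])])
    p_keep = np.clip(1.0 + cfg.gc_bias * (gc - 0.45) / 0.15, 0.05, 1.0)
    return pairs[rng.random(len(pairs)) < p_keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------

def make_panel(config: SimConfig, seeds: Sequence[int], scheme,
               genome: Optional[GenomeMap] = None) -> pd.DataFrame:
    """Per-window median raw counts across >= 10 event-free replicates.

    Stand-in for a population reference panel: robust to an event present
    in a minority of replicates (median).  Returns (chrom, start, end,
    median_count) aligned to ``scheme``.
    """
    from .depth_cnv import bin_counts

    if len(seeds) < 10:
        raise ValueError("panel needs at least 10 replicates")
    genome = genome or config.genome_map()
    stack = None
    base = None
    for i, s in enumerate(seeds):
        rep = simulate(replace(config, seed=int(s)), pairs_only=True)
        counts = bin_counts(rep.pairs, scheme, genome)
        if stack is None:
            base = counts[["chrom", "start", "end"]]
            stack = np.empty((len(seeds), len(counts)))
        stack[i] = counts["raw_count"].to_numpy()
    out = base.copy()
    out["median_count"] = np.median(stack, axis=0)
    return out
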