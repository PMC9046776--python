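"""Read-pair, pileup and interval I/O plus genome context.

Coordinate conventions used across the package:

* Internally and in every report, positions are **1-based inclusive**.
* BED files are written/read 0-based half-open (the only place the
  convention changes).
* Read-pair ends are stored in canonical order: ``end_a`` <= ``end_b``
  under the genome's chromosome order, so a junction between two loci has
  exactly one key no matter how the aligner emitted the pair.
* All internal logic assumes FR (forward/reverse, inward-facing) read
  pairs.  Mate-pair chemistry natively produces outward-facing (RF) pairs;
  passing ``library_type="rf"`` to the readers flips both strands on
  ingest so downstream orientation logic sees a single grammar.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd

#: Default minimum mapping quality for an end to count as uniquely aligned.
DEFAULT_MIN_MAPQ = 20

#: Column order of the ``pair_tsv`` dialect.
PAIR_TSV_COLUMNS = (
    "pair_id",
    "chrom_a", "pos_a", "strand_a",
    "chrom_b", "pos_b", "strand_b",
    "mapq_a", "mapq_b",
)

#: Columns of the in-memory pair table (canonical bulk representation).
PAIR_FRAME_COLUMNS = (
    "pair_id",
    "chrom_a", "pos_a", "strand_a", "mapq_a",
    "chrom_b", "pos_b", "strand_b", "mapq_b",
    "duplicate",
)


class PairEnd(NamedTuple):
    chrom: str
    pos: int          # 1-based leftmost mapped base
    strand: str       # '+' or '-'
    mapq: int


class AlignedPair(NamedTuple):
    """One aligned read pair — the atom of depth and junction evidence."""

    pair_id: str
    end_a: PairEnd
    end_b: PairEnd
    duplicate: bool = False


class PileupSite(NamedTuple):
    chrom: str
    pos: int
    depth: int
    ref_count: int
    alt_count: int


class PairIOError(ValueError):
    """Malformed record or coordinate-convention violation."""


@dataclass(frozen=True)
class GenomeMap:
    """Ordered chromosome map with optional cytobands.

    ``chromosomes`` is an ordered sequence of ``(name, length_bp)``;
    ``cytobands`` are 1-based inclusive ``(chrom, start, end, band)``.
    """

    chromosomes: tuple = ()
    cytobands: Optional[tuple] = None

    def __post_init__(self):
        seen = set()
        for name, length in self.chromosomes:
            if length <= 0:
                raise PairIOError(f"chromosome {name}: non-positive length {length}")
            if name in seen:
                raise PairIOError(f"duplicate chromosome {name}")
            seen.add(name)
        if self.cytobands is not None:
            by_chrom: dict = {}
            for chrom, start, end, band in self.cytobands:
                if chrom not in seen:
                    raise PairIOError(f"cytoband on unknown chromosome {chrom}")
                if not (1 <= start <= end <= self.length(chrom)):
                    raise PairIOError(
                        f"cytoband {chrom}:{start}-{end} outside chromosome bounds")
                by_chrom.setdefault(chrom, []).append((start, end, band))
            for chrom, bands in by_chrom.items():
                bands.sort()
                for (s1, e1, _), (s2, _, _) in zip(bands, bands[1:]):
                    if s2 <= e1:
                        raise PairIOError(f"overlapping cytobands on {chrom}")

    @property
    def names(self):
        return [name for name, _ in self.chromosomes]

    def order(self, chrom: str) -> int:
        for i, (name, _) in enumerate(self.chromosomes):
            if name == chrom:
                return i
        raise PairIOError(f"unknown chromosome {chrom!r}")

    def length(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]

    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    @staticmethod
    def is_autosome(chrom: str) -> bool:
        return chrom.removeprefix("chr") not in {"X", "Y"}

    def autosome_names(self):
        return [c for c in self.names if self.is_autosome(c)]

    def band_at(self, chrom: str, pos: int) -> str:
        """Cytoband name (e.g. ``'q14.3'``) containing a 1-based position."""
        if self.cytobands is None:
            raise PairIOError("no cytobands loaded")
        for c, start, end, band in self.cytobands:
            if c == chrom and start <= pos <= end:
                return band
        raise PairIOError(f"position {chrom}:{pos} outside cytoband map")

    @classmethod
    def from_tsv(cls, path, cytoband_path=None) -> "GenomeMap":
        """Load ``chrom<TAB>length`` rows, optionally plus a UCSC cytoBand file."""
        rows = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            name, length = line.split()[:2]
            rows.append((name, int(length)))
        cyto = read_cytoband(cytoband_path) if cytoband_path else None
        return cls(chromosomes=tuple(rows), cytobands=cyto)


def read_cytoband(path) -> tuple:
    """Read a UCSC cytoBand file (0-based half-open) into 1-based tuples."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 4:
            raise PairIOError(f"{path}:{i}: cytoband line needs >=4 columns")
        chrom, start, end, band = fields[:4]
        out.append((chrom, int(start) + 1, int(end), band))
    return tuple(out)


# ---------------------------------------------------------------------------
# read pairs
# ---------------------------------------------------------------------------

def _canonicalize_frame(df: pd.DataFrame, genome: GenomeMap) -> pd.DataFrame:
    """Swap ends so (chrom, pos) of end_a <= end_b under genome order."""
    rank = {name: i for i, name in enumerate(genome.names)}
    unknown = set(df["chrom_a"]) | set(df["chrom_b"])
    unknown -= set(rank)
    if unknown:
        raise PairIOError(f"unknown chromosome(s): {sorted(unknown)}")
    ra = df["chrom_a"].map(rank).to_numpy()
    rb = df["chrom_b"].map(rank).to_numpy()
    swap = (ra > rb) | ((ra == rb) & (df["pos_a"].to_numpy() > df["pos_b"].to_numpy()))
    if swap.any():
        df = df.copy()
        for col in ("chrom", "pos", "strand", "mapq"):
            a, b = f"{col}_a", f"{col}_b"
            tmp = df.loc[swap, a].to_numpy()
            df.loc[swap, a] = df.loc[swap, b].to_numpy()
            df.loc[swap, b] = tmp
    return df


def _flip_strands(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    flip = {"+": "-", "-": "+"}
    df["strand_a"] = df["strand_a"].map(flip)
    df["strand_b"] = df["strand_b"].map(flip)
    return df


def read_pair_frame(
    path,
    genome: GenomeMap,
    dialect: str = "pair_tsv",
    library_type: str = "fr",
    min_mapq: Optional[int] = DEFAULT_MIN_MAPQ,
) -> pd.DataFrame:
    """Read aligned pairs into the canonical pair table.

    ``library_type="rf"`` flips both strands on ingest (outward-facing
    mate-pair chemistry normalised to FR).  Pairs with either end below
    ``min_mapq`` are dropped; duplicate-flagged pairs are kept with the
    flag set — removing them is the caller's choice.
    """
    if library_type not in ("fr", "rf"):
        raise PairIOError(f"unknown library_type {library_type!r}")
    if dialect == "pair_tsv":
        df = _read_pair_tsv(path)
    elif dialect == "sam_bam":
        df = _read_pair_sam(path)
    else:
        raise PairIOError(f"unknown dialect {dialect!r}")
    if (df["pos_a"] < 1).any() or (df["pos_b"] < 1).any():
        bad = df.index[(df["pos_a"] < 1) | (df["pos_b"] < 1)][0]
        raise PairIOError(f"record {bad}: position < 1")
    if library_type == "rf":
        df = _flip_strands(df)
    df = _canonicalize_frame(df, genome)
    if min_mapq is not None:
        keep = (df["mapq_a"] >= min_mapq) & (df["mapq_b"] >= min_mapq)
        df = df.loc[keep].reset_index(drop=True)
    return df


def _read_pair_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#",
            names=list(PAIR_TSV_COLUMNS),
            dtype={"pair_id": str, "chrom_a": str, "chrom_b": str,
                   "strand_a": str, "strand_b": str},
        )
    except Exception as exc:  # pandas raises several parser error types
        raise PairIOError(f"{path}: malformed pair_tsv ({exc})") from exc
    if df.empty:
        df = pd.DataFrame(columns=list(PAIR_TSV_COLUMNS))
    for col in ("pos_a", "pos_b", "mapq_a", "mapq_b"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.index[vals.isna()][0]) + 1
            raise PairIOError(f"{path}: line {line}: non-numeric {col}")
        df[col] = vals.astype(np.int64)
    bad_strand = ~df["strand_a"].isin(["+", "-"]) | ~df["strand_b"].isin(["+", "-"])
    if bad_strand.any():
        line = int(df.index[bad_strand][0]) + 1
        raise PairIOError(f"{path}: line {line}: strand must be '+' or '-'")
    df["duplicate"] = False
    return df[list(PAIR_FRAME_COLUMNS)]


def _read_pair_sam(path) -> pd.DataFrame:
    import pysam

    rows = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            end = (fh.get_reference_name(rec.reference_id),
                   rec.reference_start + 1,
                   "-" if rec.is_reverse else "+",
                   rec.mapping_quality)
            entry = rows.setdefault(rec.query_name, [None, None, False])
            if rec.is_read1:
                slot = 0
            elif rec.is_read2:
                slot = 1
            else:
                slot = 0 if entry[0] is None else 1
            entry[slot] = end
            entry[2] = entry[2] or rec.is_duplicate
    data = []
    for name, (e1, e2, dup) in rows.items():
        if e1 is None or e2 is None:
            raise PairIOError(f"unpaired or half-mapped read {name!r}")
        data.append((name, *e1[:3], e1[3], *e2[:3], e2[3], dup))
    df = pd.DataFrame(data, columns=[
        "pair_id", "chrom_a", "pos_a", "strand_a", "mapq_a",
        "chrom_b", "pos_b", "strand_b", "mapq_b", "duplicate"])
    return df


def read_pairs(path, genome: GenomeMap, dialect: str = "pair_tsv",
               library_type: str = "fr",
               min_mapq: Optional[int] = DEFAULT_MIN_MAPQ) -> Iterator[AlignedPair]:
    """Stream :class:`AlignedPair` records (thin wrapper over the frame reader)."""
    df = read_pair_frame(path, genome, dialect=dialect,
                         library_type=library_type, min_mapq=min_mapq)
    yield from frame_to_pairs(df)


def frame_to_pairs(df: pd.DataFrame) -> Iterator[AlignedPair]:
    for row in df.itertuples(index=False):
        yield AlignedPair(
            row.pair_id,
            PairEnd(row.chrom_a, int(row.pos_a), row.strand_a, int(row.mapq_a)),
            PairEnd(row.chrom_b, int(row.pos_b), row.strand_b, int(row.mapq_b)),
            bool(row.duplicate),
        )


def pairs_to_frame(pairs: Iterable[AlignedPair]) -> pd.DataFrame:
    rows = [
        (p.pair_id, p.end_a.chrom, p.end_a.pos, p.end_a.strand, p.end_a.mapq,
         p.end_b.chrom, p.end_b.pos, p.end_b.strand, p.end_b.mapq, p.duplicate)
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=list(PAIR_FRAME_COLUMNS))


def write_pair_tsv(df: pd.DataFrame, path) -> None:
    out = df[list(PAIR_TSV_COLUMNS)]
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

def read_pileup(path, genome: Optional[GenomeMap] = None) -> pd.DataFrame:
    """Read a 5-column pileup table ``chrom pos depth ref_count alt_count``.

    Returns sites position-sorted within each chromosome.  Count
    invariants (all >= 0, ref+alt <= depth) are enforced with the
    offending line reported.
    """
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                         names=["chrom", "pos", "depth", "ref_count", "alt_count"],
                         dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "pos", "depth", "ref_count", "alt_count"])
    for col in ("pos", "depth", "ref_count", "alt_count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.index[vals.isna()][0]) + 1
            raise PairIOError(f"{path}: line {line}: non-numeric {col}")
        df[col] = vals.astype(np.int64)
    neg = (df[["pos", "depth", "ref_count", "alt_count"]] < 0).any(axis=1)
    if neg.any():
        raise PairIOError(f"{path}: line {int(df.index[neg][0]) + 1}: negative count")
    over = df["ref_count"] + df["alt_count"] > df["depth"]
    if over.any():
        line = int(df.index[over][0]) + 1
        raise PairIOError(f"{path}: line {line}: ref_count + alt_count > depth")
    if genome is not None:
        unknown = set(df["chrom"]) - set(genome.names)
        if unknown:
            raise PairIOError(f"unknown chromosome(s) in pileup: {sorted(unknown)}")
        rank = {name: i for i, name in enumerate(genome.names)}
        df = df.sort_values(["chrom", "pos"],
                            key=lambda s: s.map(rank) if s.name == "chrom" else s)
    else:
        df = df.sort_values(["chrom", "pos"], kind="mergesort")
    return df.reset_index(drop=True)


def write_pileup_tsv(df: pd.DataFrame, path) -> None:
    df[["chrom", "pos", "depth", "ref_count", "alt_count"]].to_csv(
        path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(intervals, path, genome: Optional[GenomeMap] = None) -> None:
    """Write 1-based inclusive intervals as BED (0-based half-open).

    Intervals are ``(chrom, start, end)`` or ``(chrom, start, end, name)``.
    """
    lines = []
    for iv in intervals:
        chrom, start, end = iv[0], int(iv[1]), int(iv[2])
        if start < 1 or end < start:
            raise PairIOError(f"bad interval {chrom}:{start}-{end}")
        if genome is not None and end > genome.length(chrom):
            raise PairIOError(
                f"interval {chrom}:{start}-{end} exceeds chromosome length")
        fields = [chrom, str(start - 1), str(end)]
        if len(iv) > 3:
            fields.append(str(iv[3]))
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed(path):
    """Read BED3/BED4 into 1-based inclusive tuples."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise PairIOError(f"{path}:{i}: BED line needs >=3 columns")
        chrom, start, end = fields[0], int(fields[1]) + 1, int(fields[2])
        if len(fields) >= 4:
            out.append((chrom, start, end, fields[3]))
        else:
            out.append((chrom, start, end))
    return out


# ---------------------------------------------------------------------------
# VCF with breakends
# ---------------------------------------------------------------------------

def bnd_alt(mate_chrom: str, mate_pos: int, side_dir: str, mate_dir: str) -> str:
    """VCF 4.2 breakend ALT string for one side of a junction.

    ``side_dir``/``mate_dir`` are ``'tail'`` (sequence up to the breakpoint
    joins, i.e. the + / right-facing side) or ``'head'`` (sequence from the
    breakpoint onward joins, the − / left-facing side).
    """
    anchor = f"{mate_chrom}:{mate_pos}"
    if side_dir == "tail":
        # REF base then the joined piece
        return f"N[{anchor}[" if mate_dir == "head" else f"N]{anchor}]"
    # joined piece then REF base
    return f"]{anchor}]N" if mate_dir == "tail" else f"[{anchor}[N"


def write_sv_vcf(events, path, genome: GenomeMap) -> None:
    """Write SV events as VCF 4.2: symbolic records for intra-chromosomal
    events, mated BND records for inter-chromosomal junctions."""
    header = ["##fileformat=VCFv4.2", "##source=matesv"]
    for name, length in genome.chromosomes:
        header.append(f"##contig=<ID={name},length={length}>")
    header += [
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=DUP,Description="Duplication">',
        '##ALT=<ID=INV,Description="Inversion">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting pairs">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend">',
        '##INFO=<ID=EVENT,Number=1,Type=String,Description="Event id">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    lines = list(header)
    # INS/COMPLEX/TRA always go out as mated breakends (their junctions do
    # not reduce to a single symbolic interval).
    symbolic = {"DEL": "DEL", "DUP_TANDEM_FWD": "DUP", "DUP_REV_OR_INS": "DUP",
                "INV": "INV", "UNRESOLVED_LCR": "DUP"}
    for i, ev in enumerate(events):
        chroms = {bp[0] for bp in ev.breakpoints}
        support = max((c.support for c in ev.clusters), default=0)
        if len(chroms) == 1 and ev.type in symbolic:
            chrom = next(iter(chroms))
            start = min(bp[1] for bp in ev.breakpoints)
            end = max(bp[1] for bp in ev.breakpoints)
            info = (f"SVTYPE={symbolic[ev.type]};END={end};"
                    f"SVLEN={end - start};SUPPORT={support};EVENT=ev{i}")
            lines.append(f"{chrom}\t{start}\tev{i}\tN\t<{symbolic[ev.type]}>"
                         f"\t.\tPASS\t{info}")
        else:
            for j, cl in enumerate(ev.clusters):
                a, b = cl.side_a, cl.side_b
                id_a, id_b = f"ev{i}_j{j}a", f"ev{i}_j{j}b"
                alt_a = bnd_alt(b.chrom, b.breakpoint, a.direction, b.direction)
                alt_b = bnd_alt(a.chrom, a.breakpoint, b.direction, a.direction)
                common = f"SVTYPE=BND;SUPPORT={cl.support};EVENT=ev{i}"
                lines.append(f"{a.chrom}\t{a.breakpoint}\t{id_a}\tN\t{alt_a}"
                             f"\t.\tPASS\t{common};MATEID={id_b}")
                lines.append(f"{b.chrom}\t{b.breakpoint}\t{id_b}\tN\t{alt_b}"
                             f"\t.\tPASS\t{common};MATEID={id_a}")
    Path(path).write_text("\n".join(lines) + "\n")


_BND_RE = re.compile(r"([\[\]])([^\[\]:]+):(\d+)([\[\]])")


def read_sv_vcf(path):
    """Minimal reader for files produced by :func:`write_sv_vcf`.

    Returns a list of dicts (one per record) with 1-based coordinates
    restored exactly; used for round-trip verification.
    """
    records = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            continue
        chrom, pos, vid, ref, alt, qual, flt, info = line.split("\t")[:8]
        rec = {"chrom": chrom, "pos": int(pos), "id": vid, "alt": alt}
        for kv in info.split(";"):
            if "=" in kv:
                k, v = kv.split("=", 1)
                rec[k.lower()] = int(v) if v.lstrip("-").isdigit() else v
        m = _BND_RE.search(alt)
        if m:
            rec["mate_chrom"], rec["mate_pos"] = m.group(2), int(m.group(3))
        records.append(rec)
    return records
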