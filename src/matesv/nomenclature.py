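"""ISCN-like ``seq[GRCh37]`` rearrangement strings, event sizes and
breakpoint annotation.

Two string families are produced and parsed back:

* genomic-coordinate form for dosage events —
  ``seq[GRCh37] del(5)(q14.3) chr5:g.90028949_90237360del``
* junction form for rearrangements —
  ``dup(13)(q13.3)(pter->q13.3(+)(37430811)::q13.3(+)(37267951)->qter)``
  with ``::`` marking junctions and ``->`` / ``<-`` the reading direction
  of each segment (``<-`` = traversed in reverse, as in inversions).

Sizes use the convention size = end − start (no +1): that is the
convention the printed tables of this analysis style follow, verified
against every printed deletion, inversion and duplicated-segment size.
Insertion events get no single "size" — the duplicated-segment length and
the junction coordinates are reported separately, because a single number
is ambiguous for an insertion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .chimeric_sv import SVEvent
from .depth_cnv import CnvCall
from .pairio import GenomeMap, PairIOError, read_bed

DEFAULT_ASSEMBLY = "GRCh37"


@dataclass
class JunctionToken:
    band: str
    strand: str     # '+' or '-'
    pos: int


@dataclass
class ParsedNomenclature:
    op: str                                  # del | dup | inv | ins
    chroms: List[str]
    bands: List[str]
    assembly: Optional[str] = None
    g_start: Optional[int] = None            # coordinate form
    g_end: Optional[int] = None
    tokens: List[JunctionToken] = field(default_factory=list)
    connectors: List[str] = field(default_factory=list)   # between tokens


def _chrom_label(chrom: str) -> str:
    return chrom.removeprefix("chr")


def _band_range(genome: GenomeMap, chrom: str, start: int, end: int) -> str:
    b1 = genome.band_at(chrom, start)
    b2 = genome.band_at(chrom, end)
    return b1 if b1 == b2 else f"{b1}{b2}"


# ---------------------------------------------------------------------------
# sizes
# ---------------------------------------------------------------------------

def event_size(event: SVEvent) -> int:
    """Size of an intra-chromosomal event: max(pos) − min(pos).

    The difference convention (no +1) matches the printed sizes of the
    reference tables exactly.  Inter-chromosomal events have no size.
    """
    if len(event.chroms) != 1:
        raise ValueError("size undefined for inter-chromosomal event")
    if len(event.breakpoints) < 2:
        raise ValueError("size needs at least two breakpoints")
    pos = [bp[1] for bp in event.breakpoints]
    return max(pos) - min(pos)


# ---------------------------------------------------------------------------
# formatting
# ---------------------------------------------------------------------------

def format_cnv(call: CnvCall, genome: GenomeMap,
               assembly: str = DEFAULT_ASSEMBLY) -> str:
    """Dosage call in genomic-coordinate form, e.g.
    ``seq[GRCh37] del(5)(q14.3) chr5:g.90028949_90237360del``."""
    op = "del" if call.type in ("loss", "homdel") else "dup"
    label = _chrom_label(call.chrom)
    bands = _band_range(genome, call.chrom, call.start, call.end)
    chrom = call.chrom if call.chrom.startswith("chr") else f"chr{call.chrom}"
    prefix = f"seq[{assembly}] " if assembly else ""
    return (f"{prefix}{op}({label})({bands}) "
            f"{chrom}:g.{call.start}_{call.end}{op}")


def format_sv(event: SVEvent, genome: GenomeMap,
              assembly: Optional[str] = DEFAULT_ASSEMBLY) -> str:
    """Render an SV event as its nomenclature string.

    DEL uses the genomic-coordinate form; DUP_TANDEM_FWD, INV and INS use
    the junction form.  Pass ``assembly=None`` to omit the ``seq[...]``
    prefix.
    """
    prefix = f"seq[{assembly}] " if assembly else ""
    chrom = event.breakpoints[0][0]
    label = _chrom_label(chrom)
    pos = sorted(bp[1] for bp in event.breakpoints)

    if event.type == "DEL":
        lo, hi = pos[0], pos[-1]
        bands = _band_range(genome, chrom, lo, hi)
        cname = chrom if chrom.startswith("chr") else f"chr{chrom}"
        return f"{prefix}del({label})({bands}) {cname}:g.{lo}_{hi}del"

    if event.type == "DUP_TANDEM_FWD":
        lo, hi = pos[0], pos[-1]
        bands = _band_range(genome, chrom, lo, hi)
        b_lo = genome.band_at(chrom, lo)
        b_hi = genome.band_at(chrom, hi)
        return (f"{prefix}dup({label})({bands})"
                f"(pter->{b_hi}(+)({hi})::{b_lo}(+)({lo})->qter)")

    if event.type == "INV" and len(event.breakpoints) == 4:
        # breakpoints as built by the classifier:
        # (outer-left +, inner-right +, inner-left -, outer-right -)
        p1, p2, p3, p4 = [bp[1] for bp in event.breakpoints]
        bands = _band_range(genome, chrom, p1, p4)
        b = lambda p: genome.band_at(chrom, p)
        return (f"{prefix}inv({label})({bands})"
                f"(pter->{b(p1)}(+)({p1})::{b(p2)}(-)({p2})"
                f"<-{b(p3)}(-)({p3})::{b(p4)}(+)({p4})->qter)")

    if event.type == "INS" and len(event.breakpoints) == 4:
        (pc, p_lo, _), (sc, s_lo, _), (_, s_hi, _), (_, p_hi, _) = event.breakpoints
        orient = "inverted" if "inverted" in event.notes else "forward"
        lp, ls = _chrom_label(pc), _chrom_label(sc)
        bp_site = _band_range(genome, pc, p_lo, p_hi)
        bs = _band_range(genome, sc, s_lo, s_hi)
        b = lambda c, p: genome.band_at(c, p)
        if orient == "inverted":
            middle = (f"{b(sc, s_hi)}(-)({s_hi})<-{b(sc, s_lo)}(-)({s_lo})")
        else:
            middle = (f"{b(sc, s_lo)}(+)({s_lo})->{b(sc, s_hi)}(+)({s_hi})")
        return (f"{prefix}ins({lp};{ls})({bp_site};{bs})"
                f"(pter->{b(pc, p_lo)}(+)({p_lo})::{middle}"
                f"::{b(pc, p_hi)}(+)({p_hi})->qter)")

    raise ValueError(f"no nomenclature form for event type {event.type!r}")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"([pq][\d.]+|pter|qter)(?:\(([+-])\)\((\d+)\))?")
_G_FORM_RE = re.compile(
    r"^(?:seq\[(?P<asm>[^\]]+)\]\s*)?"
    r"(?P<op>del|dup|inv|ins)\((?P<chrom>[^)]+)\)\((?P<bands>[^)]+)\)\s*"
    r"chr(?P<gchrom>[^:]+):g\.(?P<start>\d+)_(?P<end>\d+)(?P<op2>del|dup)$")
_J_FORM_RE = re.compile(
    r"^(?:seq\[(?P<asm>[^\]]+)\]\s*)?"
    r"(?P<op>del|dup|inv|ins)\((?P<chrom>[^)]+)\)\((?P<bands>[^)]+)\)"
    r"\((?P<junction>pter.*qter)\)$")


def normalize_string(s: str) -> str:
    """Normalise typeset quirks: ``- >`` → ``->``, ``< -`` → ``<-``,
    thousands separators inside coordinates removed."""
    s = s.strip()
    s = re.sub(r"-\s*>\s*", "->", s)
    s = re.sub(r"<\s*-\s*(?=[pq\d])", "<-", s)
    s = re.sub(r"(?<=\d),\s*(?=\d)", "", s)
    s = re.sub(r"(?<=\d)\s+(?=\d)", "", s)
    s = re.sub(r"_\s+", "_", s)
    return s


def parse(s: str) -> ParsedNomenclature:
    """Parse a nomenclature string (either form) after normalisation."""
    s = normalize_string(s)
    m = _G_FORM_RE.match(s)
    if m:
        return ParsedNomenclature(
            op=m.group("op"), chroms=[m.group("chrom")],
            bands=m.group("bands").split(";"), assembly=m.group("asm"),
            g_start=int(m.group("start")), g_end=int(m.group("end")))
    m = _J_FORM_RE.match(s)
    if m:
        junction = m.group("junction")
        tokens: List[JunctionToken] = []
        connectors: List[str] = []
        pieces = re.split(r"(::|->|<-)", junction)
        for piece in pieces:
            piece = piece.strip()
            if piece in ("::", "->", "<-"):
                connectors.append(piece)
                continue
            if piece in ("pter", "qter", ""):
                continue
            tm = _TOKEN_RE.fullmatch(piece)
            if tm is None or tm.group(2) is None:
                raise PairIOError(f"unparseable junction token {piece!r}")
            tokens.append(JunctionToken(
                band=tm.group(1), strand=tm.group(2), pos=int(tm.group(3))))
        return ParsedNomenclature(
            op=m.group("op"), chroms=m.group("chrom").split(";"),
            bands=m.group("bands").split(";"), assembly=m.group("asm"),
            tokens=tokens, connectors=connectors)
    raise PairIOError(f"unparseable nomenclature string {s!r}")


# ---------------------------------------------------------------------------
# breakpoint annotation
# ---------------------------------------------------------------------------

def read_gene_intervals(path):
    """Load gene intervals from BED4 or GFF3 into 1-based tuples
    (chrom, start, end, name)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".gff", ".gff3") or text.startswith("##gff"):
        out = []
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9 or f[2] not in ("gene", "pseudogene"):
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            name = attrs.get("Name") or attrs.get("gene_name") or attrs.get("ID", "?")
            out.append((f[0], int(f[3]), int(f[4]), name))
        return out
    return [iv if len(iv) == 4 else (*iv, "?") for iv in read_bed(path)]


def annotate_breakpoints(event: SVEvent, genes=None, tads=None) -> Dict:
    """Annotate each breakpoint with containing genes and disrupted TADs.

    ``genes``/``tads`` are 1-based interval lists (chrom, start, end[,
    name]).  A TAD is *disrupted* when it contains some but not all of the
    event's breakpoints; an event with every breakpoint inside a single
    TAD is flagged intra-TAD.
    """
    from intervaltree import IntervalTree

    def build(intervals):
        trees: Dict[str, IntervalTree] = {}
        for iv in intervals or []:
            chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            name = iv[3] if len(iv) > 3 else f"{chrom}:{start}-{end}"
            trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, name)
        return trees

    gene_idx = build(genes)
    tad_idx = build(tads)
    bps = [(c, p) for c, p, *_ in event.breakpoints]
    records = []
    tad_membership: Dict[str, set] = {}
    for i, (chrom, pos) in enumerate(bps):
        hit_genes = sorted({iv.data for iv in gene_idx.get(chrom, IntervalTree())[pos]})
        hit_tads = sorted({iv.data for iv in tad_idx.get(chrom, IntervalTree())[pos]})
        for t in hit_tads:
            tad_membership.setdefault(t, set()).add(i)
        records.append({"chrom": chrom, "pos": pos, "genes": hit_genes,
                        "tads": hit_tads})
    n = len(bps)
    disrupted = sorted(t for t, members in tad_membership.items()
                       if len(members) < n)
    intra_tad = any(len(members) == n for members in tad_membership.values())
    for rec in records:
        rec["tads_disrupted"] = [t for t in rec.pop("tads") if t in disrupted]
    return {
        "breakpoints": records,
        "genes": sorted({g for rec in records for g in rec["genes"]}),
        "tads_disrupted": disrupted,
        "intra_tad": bool(intra_tad),
    }
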