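"""Transcript models and alternative-splicing event enumeration.

An alternative-splicing *event* is a local, binary splicing choice within a
gene, described by two disjoint sets of transcripts: the *inclusion* form
(the transcripts supporting the variant with more exonic sequence in the
variable region) and the remaining *exclusion* form. Five classical binary
event types are enumerated from an exon-level annotation:

``SE``
    Cassette (skipped) exon: an internal exon present in some transcripts
    and absent in others that directly join the flanking exons. Cassette
    exons shorter than 28 nt are flagged as microexons.
``A5`` / ``A3``
    Alternative 5'/3' splice site: two transcripts share one boundary of an
    intron but differ at the donor (A5) or acceptor (A3) side. The labels
    are strand-aware: a variation at the genomic start of an intron is a
    donor-site (A5) variation on the plus strand but an acceptor-site (A3)
    variation on the minus strand.
``MX``
    Mutually exclusive exons: two internal exons sharing flanking junctions,
    each present in a distinct subset of transcripts, never together.
``RI``
    Retained intron: one transcript's exon spans another transcript's
    exon-intron-exon block with identical outer boundaries; the inclusion
    form is the intron-retaining transcript.

All coordinates are 1-based inclusive (GTF convention). Event identifiers
follow the ``<gene>;<type>:<chrom>:<coordinate block>:<strand>`` convention
and parse back losslessly to the event geometry.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

EVENT_TYPES: tuple[str, ...] = ("SE", "A5", "A3", "MX", "RI")

#: cassette exons strictly shorter than this many nucleotides are microexons
MICROEXON_MAX_NT = 28

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: an ordered, non-overlapping exon chain on one strand."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.transcript_id}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ValueError(
                    f"exon ({start},{end}) of {self.transcript_id} has start > end"
                )
            if start <= prev_end:
                raise ValueError(
                    f"exons of {self.transcript_id} overlap or are unsorted at ({start},{end})"
                )
            prev_end = end

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        """Introns as (last base of upstream exon, first base of downstream exon)."""
        ex = self.exons
        return tuple((ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1))


@dataclass(frozen=True)
class SpliceEvent:
    """A binary splicing event with its inclusion/total transcript sets."""

    event_id: str
    event_type: str
    gene_id: str
    chrom: str
    strand: str
    inclusion_transcripts: frozenset[str]
    total_transcripts: frozenset[str]
    variant_span: tuple[int, int]
    is_microexon: bool

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if not self.inclusion_transcripts:
            raise ValueError(f"{self.event_id}: empty inclusion set")
        if not self.inclusion_transcripts < self.total_transcripts:
            raise ValueError(
                f"{self.event_id}: inclusion transcripts must be a strict subset of total"
            )
        if self.is_microexon and self.event_type != "SE":
            raise ValueError(f"{self.event_id}: only SE events can be microexons")

    @property
    def exclusion_transcripts(self) -> frozenset[str]:
        return self.total_transcripts - self.inclusion_transcripts


def parse_gtf(path) -> list[TranscriptModel]:
    """Parse exon features of a GTF file into transcript models.

    Only ``exon`` features are considered; exons are merged (overlaps
    collapsed) and sorted per transcript. Raises ``ValueError`` naming the
    offending line for malformed rows, missing ``transcript_id``/``gene_id``
    attributes, or a transcript spread over several strands or chromosomes.
    """
    acc: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(
                    f"malformed GTF line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if fields[2] != "exon":
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"malformed GTF line {lineno}: {exc}") from None
            attrs = dict(_ATTR_RE.findall(fields[8]))
            tid = attrs.get("transcript_id")
            if not tid:
                raise ValueError(f"GTF line {lineno}: exon without transcript_id")
            gid = attrs.get("gene_id")
            if not gid:
                raise ValueError(f"GTF line {lineno}: exon without gene_id")
            rec = acc.setdefault(
                tid, {"gene": gid, "chrom": fields[0], "strand": fields[6], "exons": []}
            )
            if rec["strand"] != fields[6]:
                raise ValueError(
                    f"GTF line {lineno}: transcript {tid} has exons on mixed strands"
                )
            if rec["chrom"] != fields[0]:
                raise ValueError(
                    f"GTF line {lineno}: transcript {tid} spans multiple chromosomes"
                )
            rec["exons"].append((start, end))

    models = []
    for tid, rec in acc.items():
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=_merge_exons(rec["exons"]),
            )
        )
    models.sort(key=lambda t: (t.gene_id, t.transcript_id))
    return models


def _merge_exons(exons: Sequence[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    merged: list[list[int]] = []
    for start, end in sorted(exons):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((s, e) for s, e in merged)


def group_by_gene(
    transcripts: Iterable[TranscriptModel],
) -> dict[str, list[TranscriptModel]]:
    genes: dict[str, list[TranscriptModel]] = defaultdict(list)
    for t in transcripts:
        genes[t.gene_id].append(t)
    return dict(genes)


def enumerate_events(
    transcripts: Iterable[TranscriptModel] | Mapping[str, Sequence[TranscriptModel]],
    event_types: Sequence[str] = EVENT_TYPES,
) -> list[SpliceEvent]:
    """Enumerate binary splicing events for every gene.

    Each event requires at least one transcript supporting each form; the
    total transcript set pools the transcripts carrying either form's
    defining junction structure. Output is sorted by ``event_id`` and is
    therefore invariant to transcript input order. Genes with one transcript
    yield no events.
    """
    unknown = set(event_types) - set(EVENT_TYPES)
    if unknown:
        raise ValueError(f"unknown event types: {sorted(unknown)}")
    genes = (
        dict(transcripts)
        if isinstance(transcripts, Mapping)
        else group_by_gene(transcripts)
    )
    events: dict[str, SpliceEvent] = {}
    for gene_id in sorted(genes):
        for ev in _gene_events(gene_id, list(genes[gene_id]), set(event_types)):
            events[ev.event_id] = ev
    return sorted(events.values(), key=lambda e: e.event_id)


def _gene_events(
    gene_id: str, ts: list[TranscriptModel], wanted: set[str]
) -> Iterable[SpliceEvent]:
    strands = {t.strand for t in ts}
    chroms = {t.chrom for t in ts}
    if len(strands) > 1 or len(chroms) > 1:
        raise ValueError(
            f"gene {gene_id}: transcripts on mixed strands or chromosomes"
        )
    strand, chrom = ts[0].strand, ts[0].chrom

    junc_tids: dict[tuple[int, int], set[str]] = defaultdict(set)
    exon_tids: dict[tuple[int, int], set[str]] = defaultdict(set)
    up_starts: dict[tuple[int, int], set[int]] = defaultdict(set)
    down_ends: dict[tuple[int, int], set[int]] = defaultdict(set)
    # internal exons keyed with their flanking junction boundaries
    mids: dict[tuple[int, int, int, int], set[str]] = defaultdict(set)
    # spliced exon-intron-exon blocks, for retained-intron detection
    blocks: dict[tuple[int, int, int, int], set[str]] = defaultdict(set)

    for t in ts:
        ex = t.exons
        for e in ex:
            exon_tids[e].add(t.transcript_id)
        for i, j in enumerate(t.junctions):
            junc_tids[j].add(t.transcript_id)
            up_starts[j].add(ex[i][0])
            down_ends[j].add(ex[i + 1][1])
            blocks[(ex[i][0], j[0], j[1], ex[i + 1][1])].add(t.transcript_id)
        for i in range(1, len(ex) - 1):
            mids[(ex[i - 1][1], ex[i][0], ex[i][1], ex[i + 1][0])].add(t.transcript_id)

    if "SE" in wanted:
        for (f1, ms, me, f2), inc in mids.items():
            exc = junc_tids.get((f1, f2), set())
            if exc:
                yield SpliceEvent(
                    event_id=f"{gene_id};SE:{chrom}:{f1}-{ms}:{me}-{f2}:{strand}",
                    event_type="SE",
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    inclusion_transcripts=frozenset(inc),
                    total_transcripts=frozenset(inc | exc),
                    variant_span=(ms, me),
                    is_microexon=(me - ms + 1) < MICROEXON_MAX_NT,
                )

    if "MX" in wanted:
        by_flanks: dict[tuple[int, int], list] = defaultdict(list)
        for (f1, ms, me, f2), tids in mids.items():
            by_flanks[(f1, f2)].append((ms, me, tids))
        for (f1, f2), recs in by_flanks.items():
            recs.sort(key=lambda r: (r[0], r[1]))
            for (ms1, me1, inc), (ms2, me2, exc) in combinations(recs, 2):
                if me1 >= ms2 or (inc & exc):
                    continue  # overlapping exons are A5/A3 territory
                yield SpliceEvent(
                    event_id=(
                        f"{gene_id};MX:{chrom}:{f1}-{ms1}:{me1}-{f2}:"
                        f"{f1}-{ms2}:{me2}-{f2}:{strand}"
                    ),
                    event_type="MX",
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    inclusion_transcripts=frozenset(inc),
                    total_transcripts=frozenset(inc | exc),
                    variant_span=(ms1, me2),
                    is_microexon=False,
                )

    if "A5" in wanted or "A3" in wanted:
        share_end: dict[int, list[int]] = defaultdict(list)
        share_start: dict[int, list[int]] = defaultdict(list)
        for d, a in junc_tids:
            share_end[a].append(d)
            share_start[d].append(a)
        # variation at the genomic start of the intron (upstream exon end)
        for a, donors in share_end.items():
            for d1, d2 in combinations(sorted(donors), 2):
                if min(up_starts[(d2, a)]) > d1:
                    continue  # alternative exons do not overlap
                etype = "A5" if strand == "+" else "A3"
                if etype not in wanted:
                    continue
                inc = junc_tids[(d2, a)]
                exc = junc_tids[(d1, a)]
                yield SpliceEvent(
                    event_id=f"{gene_id};{etype}:{chrom}:{d2}-{a}:{d1}-{a}:{strand}",
                    event_type=etype,
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    inclusion_transcripts=frozenset(inc),
                    total_transcripts=frozenset(inc | exc),
                    variant_span=(d1 + 1, d2),
                    is_microexon=False,
                )
        # variation at the genomic end of the intron (downstream exon start)
        for d, acceptors in share_start.items():
            for a1, a2 in combinations(sorted(acceptors), 2):
                if max(down_ends[(d, a1)]) < a2:
                    continue
                etype = "A3" if strand == "+" else "A5"
                if etype not in wanted:
                    continue
                inc = junc_tids[(d, a1)]
                exc = junc_tids[(d, a2)]
                yield SpliceEvent(
                    event_id=f"{gene_id};{etype}:{chrom}:{d}-{a1}:{d}-{a2}:{strand}",
                    event_type=etype,
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    inclusion_transcripts=frozenset(inc),
                    total_transcripts=frozenset(inc | exc),
                    variant_span=(a1, a2 - 1),
                    is_microexon=False,
                )

    if "RI" in wanted:
        for (s1, d, a, e2), exc in blocks.items():
            inc = exon_tids.get((s1, e2), set())
            if inc:
                yield SpliceEvent(
                    event_id=f"{gene_id};RI:{chrom}:{s1}:{d}-{a}:{e2}:{strand}",
                    event_type="RI",
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    inclusion_transcripts=frozenset(inc),
                    total_transcripts=frozenset(inc | exc),
                    variant_span=(d + 1, a - 1),
                    is_microexon=False,
                )


def parse_event_id(event_id: str):
    """Split an event identifier into (gene, type, chrom, coordinate tuples, strand)."""
    try:
        gene_id, rest = event_id.split(";", 1)
        parts = rest.split(":")
        etype, chrom, strand = parts[0], parts[1], parts[-1]
        blocks = parts[2:-1]
    except (ValueError, IndexError):
        raise ValueError(f"unparseable event id {event_id!r}") from None
    if etype not in EVENT_TYPES:
        raise ValueError(f"unknown event type token {etype!r} in {event_id!r}")
    if strand not in ("+", "-"):
        raise ValueError(f"invalid strand in event id {event_id!r}")
    coords: list[tuple[int, ...]] = []
    for block in blocks:
        coords.append(tuple(int(x) for x in block.split("-")))
    return gene_id, etype, chrom, tuple(coords), strand


def _span_from_coords(etype: str, coords) -> tuple[int, int]:
    if etype == "SE":
        (f1, ms), (me, f2) = coords
        return (ms, me)
    if etype in ("A5", "A3"):
        (x1, y1), (x2, y2) = coords
        if y1 == y2:  # shared intron end, variable start
            return (min(x1, x2) + 1, max(x1, x2))
        return (min(y1, y2), max(y1, y2) - 1)
    if etype == "MX":
        (f1, ms1), (me1, f2), (_, ms2), (me2, _) = coords
        return (ms1, me2)
    # RI
    (s1,), (d, a), (e2,) = coords
    return (d + 1, a - 1)


IOE_COLUMNS = ("seqname", "gene_id", "event_id", "alternative_transcripts", "total_transcripts")


def write_ioe(events: Iterable[SpliceEvent], path) -> None:
    """Write events as a tab-separated ioe table (sorted, stable byte output)."""
    with open(path, "w") as fh:
        fh.write("\t".join(IOE_COLUMNS) + "\n")
        for ev in sorted(events, key=lambda e: e.event_id):
            fh.write(
                "\t".join(
                    (
                        ev.chrom,
                        ev.gene_id,
                        ev.event_id,
                        ",".join(sorted(ev.inclusion_transcripts)),
                        ",".join(sorted(ev.total_transcripts)),
                    )
                )
                + "\n"
            )


def read_ioe(path) -> list[SpliceEvent]:
    """Read an ioe table back into :class:`SpliceEvent` objects."""
    events = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != IOE_COLUMNS:
            raise ValueError(f"{path}: unexpected ioe header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path} line {lineno}: expected 5 columns")
            chrom, gene_id, event_id, alt, total = fields
            gid, etype, echrom, coords, strand = parse_event_id(event_id)
            if gid != gene_id or echrom != chrom:
                raise ValueError(
                    f"{path} line {lineno}: event id does not match gene/seqname columns"
                )
            span = _span_from_coords(etype, coords)
            events.append(
                SpliceEvent(
                    event_id=event_id,
                    event_type=etype,
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    inclusion_transcripts=frozenset(alt.split(",")),
                    total_transcripts=frozenset(total.split(",")),
                    variant_span=span,
                    is_microexon=(
                        etype == "SE" and span[1] - span[0] + 1 < MICROEXON_MAX_NT
                    ),
                )
            )
    return events
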