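"""Alternative-splicing event enumeration from multi-isoform gene models.

Five event classes are detected from every unordered transcript pair of a
gene, following the standard transcript-pair (SUPPA-style) definitions:

* SE   — skipped exon: one isoform includes an internal exon, the other
         joins its flanking exons directly.
* RI   — retained intron: one isoform splices an intron that the other
         retains inside a single exon (outer boundaries shared exactly).
* A5SS — alternative 5' (donor) splice site: two junctions share the
         acceptor-side boundary, differ at the donor side, and the two
         donor-side exons overlap.
* A3SS — symmetric at the acceptor side.
* MXE  — mutually exclusive exons: two non-overlapping internal exons,
         each isoform splicing in exactly one, with shared flanks.

Events are deduplicated across transcript pairs by their coordinate tuple;
output order is canonical (sorted by event_id).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .genome_model import Gene, Transcript

EVENT_TYPES = ("SE", "RI", "MXE", "A3SS", "A5SS")


@dataclass(frozen=True)
class SpliceEvent:
    """One enumerated AS event.

    ``coords`` is the type-specific tuple, genomically ordered:
      SE   (e1_end, s2, e2, s3)
      RI   (s1, e1, s2, e2)
      A5SS/A3SS (shared_boundary, alt_1, alt_2) with alt_1 < alt_2
      MXE  (e1_end, s2, e2, s3, e3, s4)
    ``splice_sites`` holds the genomic boundary positions that define the
    event (for RI only the two retained-intron junctions).
    """

    event_type: str
    gene_id: str
    contig: str
    strand: str
    coords: tuple[int, ...]
    splice_sites: frozenset[int]

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.event_type in ("SE", "RI", "MXE"):
            if any(a >= b for a, b in zip(self.coords, self.coords[1:])):
                raise ValueError(
                    f"{self.event_type} coords not strictly increasing: {self.coords}"
                )
        else:  # A3SS/A5SS: only the two alternative boundaries are ordered
            if self.coords[1] >= self.coords[2]:
                raise ValueError(f"alt boundaries not ordered: {self.coords}")

    @property
    def event_id(self) -> str:
        coord_str = "-".join(str(c) for c in self.coords)
        return f"{self.event_type}:{self.contig}:{self.strand}:{coord_str}"

    @property
    def span(self) -> tuple[int, int]:
        return min(self.coords), max(self.coords)


def _exons_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _se_events(a: Transcript, b: Transcript, gene: Gene) -> Iterable[SpliceEvent]:
    """Exons internal to `a` that `b` skips with a direct junction."""
    b_junctions = set(b.junctions())
    for i in range(1, len(a.exons) - 1):
        s2, e2 = a.exons[i]
        e1_end = a.exons[i - 1][1]
        s3 = a.exons[i + 1][0]
        if (e1_end, s3) in b_junctions and not any(
            _exons_overlap((s2, e2), ex) for ex in b.exons
        ):
            yield SpliceEvent(
                "SE", gene.gene_id, gene.contig, gene.strand,
                (e1_end, s2, e2, s3), frozenset((e1_end, s2, e2, s3)),
            )


def _ri_events(a: Transcript, b: Transcript, gene: Gene) -> Iterable[SpliceEvent]:
    """Junctions of `b` whose outer exon boundaries `a` spans in one exon."""
    a_exons = set(a.exons)
    for i, (e1, s2) in enumerate(b.junctions()):
        s1 = b.exons[i][0]
        e2 = b.exons[i + 1][1]
        if (s1, e2) in a_exons:
            yield SpliceEvent(
                "RI", gene.gene_id, gene.contig, gene.strand,
                (s1, e1, s2, e2), frozenset((e1, s2)),
            )


def _ass_events(a: Transcript, b: Transcript, gene: Gene) -> Iterable[SpliceEvent]:
    """Alternative donor/acceptor events between the junction sets of a pair.

    Genomic-left side of a junction is the donor on '+' and the acceptor on
    '-'. The two exons on the alternative side must overlap (this excludes
    the junction pairs every SE/MXE already generates).
    """
    # exon lookup by junction side
    def left_exon(t: Transcript, j_idx: int) -> tuple[int, int]:
        return t.exons[j_idx]

    def right_exon(t: Transcript, j_idx: int) -> tuple[int, int]:
        return t.exons[j_idx + 1]

    ja, jb = a.junctions(), b.junctions()
    for ia, (la, ra) in enumerate(ja):
        for ib, (lb, rb) in enumerate(jb):
            if (la, ra) == (lb, rb):
                continue
            if ra == rb and la != lb:
                # alternative genomic-left boundary; left exons must overlap
                if _exons_overlap(left_exon(a, ia), left_exon(b, ib)):
                    etype = "A5SS" if gene.strand == "+" else "A3SS"
                    alt = tuple(sorted((la, lb)))
                    yield SpliceEvent(
                        etype, gene.gene_id, gene.contig, gene.strand,
                        (ra, alt[0], alt[1]), frozenset((ra, alt[0], alt[1])),
                    )
            elif la == lb and ra != rb:
                if _exons_overlap(right_exon(a, ia), right_exon(b, ib)):
                    etype = "A3SS" if gene.strand == "+" else "A5SS"
                    alt = tuple(sorted((ra, rb)))
                    yield SpliceEvent(
                        etype, gene.gene_id, gene.contig, gene.strand,
                        (la, alt[0], alt[1]), frozenset((la, alt[0], alt[1])),
                    )


def _mxe_events(a: Transcript, b: Transcript, gene: Gene) -> Iterable[SpliceEvent]:
    a_exons, b_exons = set(a.exons), set(b.exons)
    for i in range(1, len(a.exons) - 1):
        x = a.exons[i]
        flank_l = a.exons[i - 1][1]
        flank_r = a.exons[i + 1][0]
        for j in range(1, len(b.exons) - 1):
            y = b.exons[j]
            if b.exons[j - 1][1] != flank_l or b.exons[j + 1][0] != flank_r:
                continue
            if x == y or _exons_overlap(x, y):
                continue
            if y in a_exons or x in b_exons:
                continue  # some isoform contains both — not mutually exclusive
            first, second = (x, y) if x[0] < y[0] else (y, x)
            if first[1] >= second[0]:
                continue  # abutting exons: no intervening intron
            coords = (flank_l, first[0], first[1], second[0], second[1], flank_r)
            yield SpliceEvent(
                "MXE", gene.gene_id, gene.contig, gene.strand,
                coords, frozenset(coords),
            )


def enumerate_events(gene: Gene) -> list[SpliceEvent]:
    """All AS events of a gene, deduplicated, sorted by event_id.

    Genes with fewer than two transcripts yield no events.
    """
    events: dict[str, SpliceEvent] = {}
    txs = gene.transcripts
    for i in range(len(txs)):
        for j in range(i + 1, len(txs)):
            a, b = txs[i], txs[j]
            for ev in _se_events(a, b, gene):
                events[ev.event_id] = ev
            for ev in _se_events(b, a, gene):
                events[ev.event_id] = ev
            for ev in _ri_events(a, b, gene):
                events[ev.event_id] = ev
            for ev in _ri_events(b, a, gene):
                events[ev.event_id] = ev
            for ev in _ass_events(a, b, gene):
                events[ev.event_id] = ev
            for ev in _mxe_events(a, b, gene):
                events[ev.event_id] = ev
    return [events[k] for k in sorted(events)]


def enumerate_all_events(genes: Iterable[Gene]) -> list[SpliceEvent]:
    out: list[SpliceEvent] = []
    for gene in genes:
        out.extend(enumerate_events(gene))
    return out


def count_events_by_type(events: Iterable[SpliceEvent]) -> dict[str, int]:
    """Counts per event class; duplicated event_ids are counted once."""
    seen: dict[str, str] = {}
    for ev in events:
        seen[ev.event_id] = ev.event_type
    counts = Counter(seen.values())
    return {t: counts.get(t, 0) for t in EVENT_TYPES}


def events_to_frame(events: Iterable[SpliceEvent]) -> pd.DataFrame:
    rows = [
        {
            "event_id": ev.event_id,
            "event_type": ev.event_type,
            "gene_id": ev.gene_id,
            "contig": ev.contig,
            "strand": ev.strand,
            "coords": ",".join(str(c) for c in ev.coords),
            "splice_sites": ",".join(str(s) for s in sorted(ev.splice_sites)),
        }
        for ev in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "event_id", "event_type", "gene_id", "contig", "strand",
            "coords", "splice_sites",
        ],
    )


def write_events_tsv(events: Iterable[SpliceEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> list[SpliceEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"coords": str, "splice_sites": str})
    return [
        SpliceEvent(
            row.event_type, row.gene_id, row.contig, row.strand,
            tuple(int(c) for c in row.coords.split(",")),
            frozenset(int(s) for s in row.splice_sites.split(",")),
        )
        for row in df.itertuples()
    ]


def write_events_bed(events: Iterable[SpliceEvent], path: str | Path) -> None:
    """BED6-like intervals (event span) for genome-browser inspection."""
    with open(path, "w") as fh:
        for ev in events:
            s, e = ev.span
            fh.write(f"{ev.contig}\t{s}\t{e}\t{ev.event_id}\t0\t{ev.strand}\n")
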