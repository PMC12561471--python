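"""Genome sequences and gene models with uniform 0-based half-open coordinates.

FASTA and GTF files are converted at the boundary: GTF coordinates are
1-based inclusive on disk and become 0-based half-open ``(start, end)``
intervals in memory. Introns are a derived layer: the gaps between
consecutive exons of a transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

logger = logging.getLogger(__name__)

_ALLOWED = set("ACGTN")

MIN_INTRON_NT = 30  # shorter introns are kept but logged


class GenomeModelError(ValueError):
    """Raised on malformed FASTA/GTF input."""


@dataclass(frozen=True)
class GenomeSequence:
    """A single contig: name plus uppercased DNA over {A,C,G,T,N}."""

    contig_name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise GenomeModelError(f"empty sequence for contig {self.contig_name!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Intron:
    contig: str
    strand: str
    start: int
    end: int
    parent_transcript: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise GenomeModelError(
                f"intron end must exceed start: ({self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    """An exon chain on one contig/strand; exons sorted, non-overlapping."""

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeModelError(f"bad strand {self.strand!r} for {self.transcript_id}")
        if not self.exons:
            raise GenomeModelError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise GenomeModelError(
                    f"transcript {self.transcript_id}: exon ({s}, {e}) has end <= start"
                )
            if prev_end is not None and s < prev_end:
                raise GenomeModelError(
                    f"transcript {self.transcript_id}: overlapping exons at ({s}, {e})"
                )
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def junctions(self) -> list[tuple[int, int]]:
        """Introns as (donor-side-genomic-left, acceptor-side-genomic-right) pairs,
        i.e. (exon_i end, exon_{i+1} start) in genomic order."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class Gene:
    gene_id: str
    contig: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise GenomeModelError(f"gene {self.gene_id} has no transcripts")
        for t in self.transcripts:
            if t.contig != self.contig or t.strand != self.strand:
                raise GenomeModelError(
                    f"gene {self.gene_id}: transcript {t.transcript_id} on a "
                    "different contig/strand"
                )

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )

    def splice_sites(self) -> set[int]:
        """All exon/intron boundary positions across transcripts."""
        sites: set[int] = set()
        for t in self.transcripts:
            for d, a in t.junctions():
                sites.add(d)
                sites.add(a)
        return sites

    def donor_sites(self) -> set[int]:
        """Exon→intron boundaries in transcription direction."""
        sites: set[int] = set()
        for t in self.transcripts:
            for left, right in t.junctions():
                sites.add(left if self.strand == "+" else right)
        return sites

    def acceptor_sites(self) -> set[int]:
        """Intron→exon boundaries in transcription direction.

        A position can be both donor and acceptor (e.g. shared boundaries in
        different transcripts); such sites appear in both sets.
        """
        sites: set[int] = set()
        for t in self.transcripts:
            for left, right in t.junctions():
                sites.add(right if self.strand == "+" else left)
        return sites


def to_gtf_coords(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def from_gtf_coords(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def read_fasta(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a multi-record FASTA into {contig_name: GenomeSequence}.

    Sequences are uppercased; U is converted to T with a warning. Characters
    outside {A,C,G,T,N} raise, naming the offending position.
    """
    genome: dict[str, GenomeSequence] = {}
    n = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n += 1
        name = record.id
        if name in genome:
            raise GenomeModelError(f"duplicate contig name {name!r} in {path}")
        seq = str(record.seq).upper()
        if not seq:
            raise GenomeModelError(f"empty record {name!r} in {path}")
        if "U" in seq:
            logger.warning("contig %s: converting U to T (RNA-style input)", name)
            seq = seq.replace("U", "T")
        bad = next((i for i, c in enumerate(seq) if c not in _ALLOWED), None)
        if bad is not None:
            raise GenomeModelError(
                f"contig {name!r}: non-IUPAC character {seq[bad]!r} at position {bad}"
            )
        genome[name] = GenomeSequence(name, seq)
    if n == 0:
        raise GenomeModelError(f"no FASTA records in {path}")
    return genome


def write_fasta(genome: dict[str, GenomeSequence], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for gs in genome.values():
            fh.write(f">{gs.contig_name}\n")
            for i in range(0, len(gs.sequence), width):
                fh.write(gs.sequence[i : i + width] + "\n")


def _parse_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> list[Gene]:
    """Assemble genes from the exon lines of a GTF file.

    Only ``exon`` features are consumed; other feature types are ignored.
    Coordinates on disk are 1-based inclusive and converted to 0-based
    half-open. Transcripts are grouped under genes; mixed strands within a
    gene, exon end < start, and overlapping exons within a transcript are
    hard errors.
    """
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, contig, strand)
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GenomeModelError(f"{path}:{lineno}: expected 9 GTF columns")
            contig, _, feature, start_s, end_s, _, strand, _, attr_field = fields
            n_lines += 1
            if feature != "exon":
                continue
            start, end = int(start_s), int(end_s)
            if end < start:
                raise GenomeModelError(
                    f"{path}:{lineno}: exon end {end} < start {start}"
                )
            attrs = _parse_attributes(attr_field)
            try:
                gid, tid = attrs["gene_id"], attrs["transcript_id"]
            except KeyError as exc:
                raise GenomeModelError(
                    f"{path}:{lineno}: missing {exc} attribute"
                ) from None
            meta = (gid, contig, strand)
            if tid in tx_meta and tx_meta[tid] != meta:
                raise GenomeModelError(
                    f"{path}:{lineno}: transcript {tid} has inconsistent "
                    "gene/contig/strand across lines"
                )
            tx_meta[tid] = meta
            tx_exons.setdefault(tid, []).append(from_gtf_coords(start, end))

    if not tx_exons:
        logger.warning("no exon features in %s; empty gene collection", path)
        return []

    genes: dict[str, Gene] = {}
    grouped: dict[str, list[Transcript]] = {}
    for tid in sorted(tx_exons):
        gid, contig, strand = tx_meta[tid]
        tx = Transcript(tid, gid, contig, strand, tx_exons[tid])
        grouped.setdefault(gid, []).append(tx)
    for gid in sorted(grouped):
        txs = grouped[gid]
        strands = {t.strand for t in txs}
        if len(strands) > 1:
            raise GenomeModelError(f"gene {gid}: transcripts on mixed strands")
        genes[gid] = Gene(gid, txs[0].contig, txs[0].strand, txs)
    del n_lines
    return list(genes.values())


def write_gtf(genes: Iterable[Gene], path: str | Path) -> None:
    """Write exon lines in the same GTF dialect read_gtf consumes."""
    with open(path, "w") as fh:
        for gene in genes:
            for tx in gene.transcripts:
                for s, e in tx.exons:
                    gs, ge = to_gtf_coords(s, e)
                    fh.write(
                        f"{gene.contig}\tsplicescan\texon\t{gs}\t{ge}\t.\t"
                        f"{gene.strand}\t.\t"
                        f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}";\n'
                    )


def derive_introns(transcript: Transcript) -> list[Intron]:
    """Gaps between consecutive exons; empty for single-exon transcripts."""
    introns = []
    for d, a in transcript.junctions():
        intron = Intron(transcript.contig, transcript.strand, d, a,
                        transcript.transcript_id)
        if intron.length < MIN_INTRON_NT:
            logger.info(
                "transcript %s: intron (%d, %d) shorter than %d nt",
                transcript.transcript_id, d, a, MIN_INTRON_NT,
            )
        introns.append(intron)
    return introns


def model_summary(genome: dict[str, GenomeSequence] | None, genes: list[Gene]) -> dict:
    """Validation-report counts for the parse stage."""
    n_tx = sum(len(g.transcripts) for g in genes)
    exon_intervals = {
        (g.contig, s, e) for g in genes for t in g.transcripts for s, e in t.exons
    }
    intron_intervals = {
        (g.contig, i.start, i.end)
        for g in genes
        for t in g.transcripts
        for i in derive_introns(t)
    }
    return {
        "n_contigs": len(genome) if genome is not None else None,
        "genome_bp": sum(len(s) for s in genome.values()) if genome else None,
        "n_genes": len(genes),
        "n_transcripts": n_tx,
        "n_unique_exons": len(exon_intervals),
        "n_unique_introns": len(intron_intervals),
        "n_exons_per_transcript_total": sum(
            len(t.exons) for g in genes for t in g.transcripts
        ),
    }
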