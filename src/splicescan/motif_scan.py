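"""Exact motif scanning on both genomic strands and hit annotation.

The SELEX-derived Zc3h12c motifs are printed 3'→5' in the source figures
(primary GCAGGUAAGUGCG, secondary ACGAUGGCUGACC). Read 5'→3' *as printed*,
the primary motif contains AG|GUAAGU — the canonical 5' splice-donor
consensus — so the default query orientation treats the printed string as
the 5'→3' scanning query; ``orientation_mode="reversed"`` is kept as an
explicit switch and both modes log the resulting DNA query.

Hits are classified per overlapping gene as junction (an exon/intron
boundary strictly inside the hit), exon (fully inside an exon), or intron;
hits outside every gene span are intergenic. Signed distances to the
nearest splice site are measured from the hit's 5'-most base in
transcription orientation, positive downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .genome_model import Gene, GenomeSequence

logger = logging.getLogger(__name__)

_RNA = set("ACGU")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

Anchor = Literal["five_prime", "three_prime", "midpoint"]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSpec:
    name: str
    printed_rna: str
    dna_query: str
    orientation_mode: str  # "as_printed" | "reversed"

    def __post_init__(self) -> None:
        if len(self.dna_query) < 4:
            raise ValueError("motif query shorter than 4 nt")
        if not set(self.dna_query) <= set("ACGT"):
            raise ValueError(f"non-DNA character in query {self.dna_query!r}")


def build_query(
    printed_rna: str,
    orientation_mode: str = "as_printed",
    name: str = "motif",
) -> MotifSpec:
    """Turn an RNA motif string into a DNA scanning query.

    ``as_printed`` takes the string 5'→3' as given (U→T only);
    ``reversed`` additionally reverses it.
    """
    printed_rna = printed_rna.upper()
    bad = set(printed_rna) - _RNA
    if bad:
        raise ValueError(f"non-RNA characters {sorted(bad)} in motif {printed_rna!r}")
    if orientation_mode not in ("as_printed", "reversed"):
        raise ValueError(f"unknown orientation_mode {orientation_mode!r}")
    query = printed_rna.replace("U", "T")
    if orientation_mode == "reversed":
        query = query[::-1]
    logger.info("motif %s (%s): DNA query %s", name, orientation_mode, query)
    return MotifSpec(name, printed_rna, query, orientation_mode)


@dataclass(frozen=True, order=True)
class MotifHit:
    contig: str
    start: int
    end: int
    strand: str
    motif_name: str


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (overlapping) match start positions."""
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def scan(
    genome: dict[str, GenomeSequence] | Iterable[GenomeSequence],
    motif: MotifSpec,
) -> list[MotifHit]:
    """All exact occurrences of the query on '+' and of its reverse
    complement on '-', sorted by (contig, start, strand). Overlapping
    occurrences are all reported; N never matches."""
    if isinstance(genome, dict):
        contigs = list(genome.values())
    else:
        contigs = list(genome)
    q = motif.dna_query
    rc = reverse_complement(q)
    hits: list[MotifHit] = []
    m = len(q)
    for gs in contigs:
        seq = gs.sequence
        for pos in _find_all(seq, q):
            hits.append(MotifHit(gs.contig_name, pos, pos + m, "+", motif.name))
        for pos in _find_all(seq, rc):
            hits.append(MotifHit(gs.contig_name, pos, pos + m, "-", motif.name))
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return hits


@dataclass(frozen=True)
class HitAnnotation:
    hit: MotifHit
    gene_id: str | None
    feature_class: str  # exon | intron | junction | intergenic
    sense_match: bool | None
    nearest_splice_site: int | None
    nearest_site_role: str | None  # donor | acceptor
    signed_distance: int | None
    transcript_ids: tuple[str, ...] = ()


def signed_site_distance(anchor_pos: int, site: int, strand: str) -> int:
    """Signed bp from boundary ``site`` to the base at ``anchor_pos``.

    A boundary at coordinate p lies between bases p-1 and p. Positive means
    the base is downstream of the boundary in transcription direction: on
    '+' the first downstream base is p (distance 0 at base p); on '-' it is
    p-1.
    """
    if strand == "+":
        return anchor_pos - site
    return (site - 1) - anchor_pos


def hit_anchor(hit: MotifHit, gene_strand: str, anchor: Anchor = "five_prime") -> int:
    """Anchor base of a hit in the gene's transcription orientation."""
    if anchor == "midpoint":
        return (hit.start + hit.end - 1) // 2
    five = hit.start if gene_strand == "+" else hit.end - 1
    three = hit.end - 1 if gene_strand == "+" else hit.start
    return five if anchor == "five_prime" else three


def annotate_hits(
    hits: Sequence[MotifHit],
    genes: Sequence[Gene],
    anchor: Anchor = "five_prime",
) -> list[HitAnnotation]:
    """One HitAnnotation per hit×overlapping-gene; intergenic hits get one
    annotation with gene_id None."""
    by_contig: dict[str, list[Gene]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)

    # precompute per-gene geometry
    geom: dict[str, tuple] = {}
    for g in genes:
        donors = g.donor_sites()
        acceptors = g.acceptor_sites()
        sites = sorted(donors | acceptors)
        exons = sorted({ex for t in g.transcripts for ex in t.exons})
        tx_spans = [(t.span, t.transcript_id) for t in g.transcripts]
        geom[g.gene_id] = (g.span, donors, acceptors, sites, exons, tx_spans)

    annotations: list[HitAnnotation] = []
    for hit in hits:
        overlapped = False
        for g in by_contig.get(hit.contig, ()):
            span, donors, acceptors, sites, exons, tx_spans = geom[g.gene_id]
            if not (hit.start < span[1] and hit.end > span[0]):
                continue
            overlapped = True
            inside = [s for s in sites if hit.start < s < hit.end]
            if inside:
                fclass = "junction"
            elif any(s <= hit.start and hit.end <= e for s, e in exons):
                fclass = "exon"
            else:
                fclass = "intron"
            anchor_pos = hit_anchor(hit, g.strand, anchor)
            nearest = None
            role = None
            dist = None
            if sites:
                nearest = min(
                    sites,
                    key=lambda s: (abs(signed_site_distance(anchor_pos, s, g.strand)), s),
                )
                dist = signed_site_distance(anchor_pos, nearest, g.strand)
                role = "donor" if nearest in donors else "acceptor"
            tids = tuple(
                tid for (ts, te), tid in tx_spans if hit.start < te and hit.end > ts
            )
            annotations.append(
                HitAnnotation(
                    hit, g.gene_id, fclass, hit.strand == g.strand,
                    nearest, role, dist, tids,
                )
            )
        if not overlapped:
            annotations.append(
                HitAnnotation(hit, None, "intergenic", None, None, None, None)
            )
    return annotations


def summarize_hits(annotations: Sequence[HitAnnotation]) -> dict:
    """Unique-interval counts per feature class plus gene/transcript reach.

    ``n_*_hits`` count unique genomic hit intervals assigned to the class by
    at least one gene (a multi-gene hit can contribute to several classes);
    ``n_annotations_*`` count annotation rows (per transcript context, one
    per hit×gene). sense_fraction is over all gene-overlapping annotations,
    None when there are none.
    """
    def interval(h: MotifHit) -> tuple:
        return (h.contig, h.start, h.end, h.strand)

    per_class_intervals: dict[str, set] = {"exon": set(), "intron": set(), "junction": set()}
    class_rows = {"exon": 0, "intron": 0, "junction": 0}
    genes: set[str] = set()
    transcripts: set[str] = set()
    n_genic = 0
    n_sense = 0
    for ann in annotations:
        if ann.feature_class == "intergenic":
            continue
        per_class_intervals[ann.feature_class].add(interval(ann.hit))
        class_rows[ann.feature_class] += 1
        genes.add(ann.gene_id)
        transcripts.update(ann.transcript_ids)
        n_genic += 1
        n_sense += bool(ann.sense_match)
    return {
        "n_exon_hits": len(per_class_intervals["exon"]),
        "n_intron_hits": len(per_class_intervals["intron"]),
        "n_junction_hits": len(per_class_intervals["junction"]),
        "n_annotations_exon": class_rows["exon"],
        "n_annotations_intron": class_rows["intron"],
        "n_annotations_junction": class_rows["junction"],
        "n_genes_hit": len(genes),
        "n_transcripts_hit": len(transcripts),
        "sense_fraction": (n_sense / n_genic) if n_genic else None,
    }


def distance_density(
    annotations: Sequence[HitAnnotation],
    max_distance: int,
    bin_width: int = 1,
) -> pd.DataFrame:
    """Histogram of signed hit-to-splice-site distances, split donor vs
    acceptor. Bins are closed-left; rows cover [-max_distance, max_distance].
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    edges = np.arange(-max_distance, max_distance + bin_width, bin_width)
    donor = np.zeros(len(edges) - 1, dtype=int)
    acceptor = np.zeros(len(edges) - 1, dtype=int)
    for ann in annotations:
        if ann.signed_distance is None:
            continue
        d = ann.signed_distance
        if d < -max_distance or d >= max_distance:
            continue
        idx = int((d + max_distance) // bin_width)
        if ann.nearest_site_role == "donor":
            donor[idx] += 1
        else:
            acceptor[idx] += 1
    return pd.DataFrame(
        {"bin_start": edges[:-1], "donor_count": donor, "acceptor_count": acceptor}
    )


def write_hits_bed(hits: Sequence[MotifHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.contig}\t{h.start}\t{h.end}\t{h.motif_name}\t0\t{h.strand}\n")


def read_hits_bed(path: str | Path) -> list[MotifHit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            contig, start, end, name, _, strand = line.rstrip("\n").split("\t")
            hits.append(MotifHit(contig, int(start), int(end), strand, name))
    return hits


PRIMARY_MOTIF_RNA = "GCAGGUAAGUGCG"
SECONDARY_MOTIF_RNA = "ACGAUGGCUGACC"
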