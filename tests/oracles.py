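"""Independent brute-force oracles used to validate the implementation.

These deliberately stay naive — flat loops over every candidate, literal
definitions — and share no code with the package's algorithms.
"""

from __future__ import annotations

from math import comb

import numpy as np

from splicescan.genome_model import Gene, Transcript

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def brute_force_events(gene: Gene) -> set[tuple[str, tuple[int, ...]]]:
    """Every AS event of a gene as (type, coords), by literal definition."""
    found: set[tuple[str, tuple[int, ...]]] = set()
    for A in gene.transcripts:
        for B in gene.transcripts:
            if A is B:
                continue
            ea, eb = A.exons, B.exons
            # SE: A includes exon (s2,e2) between flanks; B joins the flanks
            # directly and no exon of B intersects the skipped exon.
            for i in range(len(ea) - 2):
                e1_end = ea[i][1]
                s2, e2 = ea[i + 1]
                s3 = ea[i + 2][0]
                for j in range(len(eb) - 1):
                    if eb[j][1] == e1_end and eb[j + 1][0] == s3:
                        if not any(_overlap((s2, e2), x) for x in eb):
                            found.add(("SE", (e1_end, s2, e2, s3)))
            # RI: A has one exon spanning both of B's consecutive exons.
            for ex in ea:
                for j in range(len(eb) - 1):
                    (s1, e1), (s2b, e2b) = eb[j], eb[j + 1]
                    if ex == (s1, e2b) and e1 < s2b:
                        found.add(("RI", (s1, e1, s2b, e2b)))
            # A5SS/A3SS: junctions sharing one boundary, differing at the
            # other, with the alternative-side exons overlapping.
            for i in range(len(ea) - 1):
                la, ra = ea[i][1], ea[i + 1][0]
                for j in range(len(eb) - 1):
                    lb, rb = eb[j][1], eb[j + 1][0]
                    if (la, ra) == (lb, rb):
                        continue
                    if ra == rb and la != lb and _overlap(ea[i], eb[j]):
                        t = "A5SS" if gene.strand == "+" else "A3SS"
                        found.add((t, (ra, min(la, lb), max(la, lb))))
                    if la == lb and ra != rb and _overlap(ea[i + 1], eb[j + 1]):
                        t = "A3SS" if gene.strand == "+" else "A5SS"
                        found.add((t, (la, min(ra, rb), max(ra, rb))))
            # MXE: internal exons with shared flanking junction partners,
            # mutually exclusive and non-overlapping.
            for i in range(1, len(ea) - 1):
                for j in range(1, len(eb) - 1):
                    x, y = ea[i], eb[j]
                    if x == y or _overlap(x, y):
                        continue
                    if ea[i - 1][1] != eb[j - 1][1] or ea[i + 1][0] != eb[j + 1][0]:
                        continue
                    if y in ea or x in eb:
                        continue
                    first, second = (x, y) if x[0] < y[0] else (y, x)
                    if first[1] >= second[0]:
                        continue
                    found.add(
                        ("MXE", (ea[i - 1][1], first[0], first[1],
                                 second[0], second[1], ea[i + 1][0]))
                    )
    return found


def naive_scan(sequence: str, query: str) -> set[tuple[int, str]]:
    """Position-by-position comparison on both strands."""
    rc = revcomp(query)
    m = len(query)
    hits: set[tuple[int, str]] = set()
    for i in range(len(sequence) - m + 1):
        window = sequence[i : i + m]
        if all(a == b for a, b in zip(window, query)):
            hits.add((i, "+"))
        if all(a == b for a, b in zip(window, rc)):
            hits.add((i, "-"))
    return hits


def fisher_two_sided(table: list[list[int]]) -> float:
    """Two-sided Fisher p by hypergeometric enumeration (sum of tables with
    probability <= the observed one)."""
    (a, b), (c, d) = table
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    denom = comb(n, row1)

    def pmf(x: int) -> float:
        return comb(col1, x) * comb(n - col1, row1 - x) / denom

    p_obs = pmf(a)
    lo = max(0, row1 - (n - col1))
    hi = min(col1, row1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-9))


def random_gene(rng: np.random.Generator, gene_id: str = "g") -> Gene:
    """A random gene: 2-6 transcripts, 1-10 exons each, boundaries drawn
    from a coarse shared grid so transcripts share junctions often."""
    strand = "+" if rng.random() < 0.5 else "-"
    n_tx = int(rng.integers(2, 7))
    grid = np.arange(0, 620, 20)
    transcripts = []
    for ti in range(n_tx):
        n_ex = int(rng.integers(1, 11))
        bounds = np.sort(rng.choice(grid, size=2 * n_ex, replace=False))
        exons = [(int(bounds[2 * k]), int(bounds[2 * k + 1])) for k in range(n_ex)]
        transcripts.append(Transcript(f"{gene_id}.t{ti}", gene_id, "chrR", strand, exons))
    return Gene(gene_id, "chrR", strand, transcripts)


def mirror_gene(gene: Gene, length: int = 10_000) -> Gene:
    """Reverse-complement the coordinate frame: mirror positions, flip strand."""
    strand = "-" if gene.strand == "+" else "+"
    transcripts = []
    for t in gene.transcripts:
        exons = sorted((length - e, length - s) for s, e in t.exons)
        transcripts.append(
            Transcript(t.transcript_id, t.gene_id, t.contig, strand, exons)
        )
    return Gene(gene.gene_id, gene.contig, strand, transcripts)
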