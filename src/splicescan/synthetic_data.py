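"""Seeded synthetic genomes, annotations and junction counts with ground truth.

The generator emulates the study conditions every downstream stage is tested
against: multi-isoform genes each realizing exactly one AS event of a known
class, exact motif copies planted on the sense strand straddling event
splice sites at controlled per-class probabilities (defaults 0.40 for
A3SS/A5SS and 0.20 for SE/RI/MXE), uniform-composition background sequence
scrubbed of chance motif matches, and beta-binomially dispersed junction
counts with condition-specific true PSI.

Every random draw flows from a single seed; rerunning with the same config
reproduces byte-identical FASTA/GTF/count tables, and the truth manifest
records everything needed to verify recovery.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .as_events import SpliceEvent
from .genome_model import Gene, GenomeSequence, Transcript, write_fasta, write_gtf
from .motif_scan import PRIMARY_MOTIF_RNA, build_query, reverse_complement
from .splice_quant import FIELD_COUNTS

logger = logging.getLogger(__name__)

CONTIG = "chrS"
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 250
    event_mix: dict[str, float] = field(
        default_factory=lambda: {
            "SE": 0.2, "RI": 0.2, "MXE": 0.2, "A3SS": 0.2, "A5SS": 0.2
        }
    )
    exon_length_range: tuple[int, int] = (80, 200)
    intron_length_range: tuple[int, int] = (150, 400)
    p_plant: dict[str, float] = field(
        default_factory=lambda: {
            "A3SS": 0.40, "A5SS": 0.40, "SE": 0.20, "RI": 0.20, "MXE": 0.20
        }
    )
    background_rate: float = 0.0  # expected chance motif copies per kb
    motif_rna: str = PRIMARY_MOTIF_RNA
    orientation_mode: str = "as_printed"
    conditions: tuple[str, str] = ("WT", "cKO")
    depth: float = 100.0
    dispersion: float = 0.01  # beta-binomial intra-class correlation rho
    n_samples: int = 3
    n_events_up: int = 0  # events with psi(B) = psi(A) + delta_psi
    n_events_down: int = 0
    delta_psi: float = 0.3
    intergenic_gap: int = 200

    def __post_init__(self) -> None:
        motif_len = len(self.motif_rna)
        for lo, hi in (self.exon_length_range, self.intron_length_range):
            if lo < motif_len + 2:
                raise ValueError(
                    f"length range ({lo}, {hi}) below motif length + 2"
                )
        for p in self.p_plant.values():
            if not 0 <= p <= 1:
                raise ValueError("planting probabilities must be in [0, 1]")
        if not 0 <= self.dispersion < 1:
            raise ValueError("dispersion must be in [0, 1)")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


@dataclass
class SyntheticTruth:
    """Planted ground truth: fully determines regeneration given the seed."""

    config: SimulationConfig
    events: list[SpliceEvent]
    planted: dict[str, tuple[int, int] | None]  # event_id -> motif interval
    plant_sites: dict[str, int | None]  # event_id -> straddled splice site
    background_plants: list[tuple[int, int, str]]
    psi_true: dict[str, dict[str, float]]  # event_id -> condition -> psi
    regulation: dict[str, str]  # event_id -> up | down | null

    @property
    def checksum(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    def to_json(self) -> str:
        payload = {
            "config": _config_dict(self.config),
            "events": [
                {
                    "event_id": ev.event_id,
                    "event_type": ev.event_type,
                    "gene_id": ev.gene_id,
                    "strand": ev.strand,
                    "coords": list(ev.coords),
                    "splice_sites": sorted(ev.splice_sites),
                    "planted": self.planted[ev.event_id],
                    "plant_site": self.plant_sites[ev.event_id],
                    "psi_true": self.psi_true[ev.event_id],
                    "regulation": self.regulation[ev.event_id],
                }
                for ev in self.events
            ],
            "background_plants": self.background_plants,
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":"))


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["conditions"] = list(config.conditions)
    d["exon_length_range"] = list(config.exon_length_range)
    d["intron_length_range"] = list(config.intron_length_range)
    return d


def _class_assignment(config: SimulationConfig) -> list[str]:
    """Exact per-class gene counts from the mix proportions."""
    classes = sorted(config.event_mix)
    total = sum(config.event_mix.values())
    raw = {c: config.event_mix[c] / total * config.n_genes for c in classes}
    counts = {c: int(raw[c]) for c in classes}
    remainder = config.n_genes - sum(counts.values())
    for c in sorted(classes, key=lambda c: (raw[c] - counts[c], c), reverse=True):
        if remainder <= 0:
            break
        counts[c] += 1
        remainder -= 1
    out: list[str] = []
    for c in classes:
        out.extend([c] * counts[c])
    return out


def _gene_geometry(
    etype: str, strand: str, rng: np.random.Generator, config: SimulationConfig
) -> tuple[list[list[tuple[int, int]]], tuple[int, ...], frozenset[int]]:
    """Exon chains (gene-local coords) of two transcripts realizing exactly
    one event of `etype` on `strand`, plus the event coords/splice sites."""
    ex = lambda: int(rng.integers(*config.exon_length_range, endpoint=True))
    inx = lambda: int(rng.integers(*config.intron_length_range, endpoint=True))

    if etype == "SE":
        a, b, c = ex(), ex(), ex()
        i1, i2 = inx(), inx()
        e_a = (0, a)
        e_b = (a + i1, a + i1 + b)
        e_c = (e_b[1] + i2, e_b[1] + i2 + c)
        tx = [[e_a, e_b, e_c], [e_a, e_c]]
        coords = (a, e_b[0], e_b[1], e_c[0])
        sites = frozenset(coords)
    elif etype == "RI":
        l1, l2, i = ex(), ex(), inx()
        e1 = (0, l1)
        e2 = (l1 + i, l1 + i + l2)
        tx = [[e1, e2], [(0, e2[1])]]
        coords = (0, l1, l1 + i, e2[1])
        sites = frozenset((l1, l1 + i))
    elif etype == "MXE":
        a, x1, x2, d = ex(), ex(), ex(), ex()
        i1, i2, i3 = inx(), inx(), inx()
        e_a = (0, a)
        e_x1 = (a + i1, a + i1 + x1)
        e_x2 = (e_x1[1] + i2, e_x1[1] + i2 + x2)
        e_d = (e_x2[1] + i3, e_x2[1] + i3 + d)
        tx = [[e_a, e_x1, e_d], [e_a, e_x2, e_d]]
        coords = (a, e_x1[0], e_x1[1], e_x2[0], e_x2[1], e_d[0])
        sites = frozenset(coords)
    else:
        # genomically: either alternative left-exon ends (alt5-like layout)
        # or alternative right-exon starts (alt3-like). The layout that
        # realizes the requested class depends on strand.
        want_alt_left = (etype == "A5SS") == (strand == "+")
        if want_alt_left:
            a1 = ex()
            a2 = a1 + int(rng.integers(20, 80))
            i = inx()
            c = ex()
            c0 = a2 + i
            tx = [[(0, a1), (c0, c0 + c)], [(0, a2), (c0, c0 + c)]]
            coords = (c0, a1, a2)
            sites = frozenset((c0, a1, a2))
        else:
            e1 = ex()
            i = inx()
            b1 = e1 + i
            b2 = b1 + int(rng.integers(20, 80))
            c1 = b2 + ex()
            tx = [[(0, e1), (b1, c1)], [(0, e1), (b2, c1)]]
            coords = (e1, b1, b2)
            sites = frozenset((e1, b1, b2))
    return tx, coords, sites


def make_genome(
    config: SimulationConfig,
) -> tuple[dict[str, GenomeSequence], list[Gene], SyntheticTruth]:
    """Emit a synthetic genome, gene models, and the planted truth.

    Each gene carries two transcripts realizing exactly one AS event of its
    assigned class. With probability ``p_plant[class]`` one motif copy is
    written on the gene's sense strand straddling a uniformly chosen event
    splice site (boundary strictly inside the motif interval). Chance motif
    matches in the background are scrubbed by resampling, so recovered
    enrichment is attributable to planting alone.
    """
    rng = np.random.default_rng([config.seed, 0])
    motif = build_query(config.motif_rna, config.orientation_mode, name="motif")
    q = motif.dna_query
    m = len(q)

    classes = _class_assignment(config)
    genes: list[Gene] = []
    events: list[SpliceEvent] = []
    planted: dict[str, tuple[int, int] | None] = {}
    plant_sites: dict[str, int | None] = {}
    plant_intervals: list[tuple[int, int, str]] = []

    offset = config.intergenic_gap
    for gi, etype in enumerate(classes):
        strand = "+" if rng.random() < 0.5 else "-"
        tx_local, coords_local, sites_local = _gene_geometry(
            etype, strand, rng, config
        )
        gene_id = f"g{gi:05d}"
        transcripts = [
            Transcript(
                f"{gene_id}.t{ti + 1}", gene_id, CONTIG, strand,
                [(s + offset, e + offset) for s, e in exons],
            )
            for ti, exons in enumerate(tx_local)
        ]
        gene = Gene(gene_id, CONTIG, strand, transcripts)
        genes.append(gene)
        coords = tuple(c + offset for c in coords_local)
        sites = frozenset(s + offset for s in sites_local)
        ev = SpliceEvent(etype, gene_id, CONTIG, strand, coords, sites)
        events.append(ev)

        if rng.random() < config.p_plant.get(etype, 0.0):
            site = int(rng.choice(sorted(sites)))
            o = int(rng.integers(1, m))  # 1..m-1: boundary strictly inside
            start = site - o
            planted[ev.event_id] = (start, start + m)
            plant_sites[ev.event_id] = site
            plant_intervals.append((start, start + m, strand))
        else:
            planted[ev.event_id] = None
            plant_sites[ev.event_id] = None

        offset = gene.span[1] + config.intergenic_gap + int(rng.integers(0, 100))

    total_len = offset + config.intergenic_gap
    seq = _BASES[rng.integers(0, 4, size=total_len)]
    planted_mask = np.zeros(total_len, dtype=bool)
    for start, end, strand in plant_intervals:
        word = q if strand == "+" else reverse_complement(q)
        seq[start:end] = np.frombuffer(word.encode(), dtype=np.uint8)
        planted_mask[start:end] = True

    background_plants: list[tuple[int, int, str]] = []
    if config.background_rate > 0:
        n_bg = rng.poisson(config.background_rate * total_len / 1000)
        all_sites = sorted({s for ev in events for s in ev.splice_sites})
        attempts = 0
        while len(background_plants) < n_bg and attempts < 50 * max(n_bg, 1):
            attempts += 1
            start = int(rng.integers(0, total_len - m))
            if planted_mask[start : start + m].any():
                continue
            if any(start < s < start + m for s in all_sites):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            word = q if strand == "+" else reverse_complement(q)
            seq[start : start + m] = np.frombuffer(word.encode(), dtype=np.uint8)
            planted_mask[start : start + m] = True
            background_plants.append((start, start + m, strand))

    _scrub_chance_matches(seq, planted_mask, q, rng)

    genome = {CONTIG: GenomeSequence(CONTIG, seq.tobytes().decode())}
    psi_true, regulation = _assign_psi(events, config, rng)
    truth = SyntheticTruth(
        config, events, planted, plant_sites, background_plants, psi_true, regulation
    )
    logger.info(
        "synthetic genome: %d bp, %d genes, %d planted motifs, %d background",
        total_len, len(genes),
        sum(v is not None for v in planted.values()), len(background_plants),
    )
    return genome, genes, truth


def _scrub_chance_matches(
    seq: np.ndarray, planted_mask: np.ndarray, q: str, rng: np.random.Generator,
    max_rounds: int = 20,
) -> None:
    """Resample non-planted bases of chance motif matches until none remain."""
    rc = reverse_complement(q)
    m = len(q)
    # a match counts as planted iff every one of its bases is masked
    for _ in range(max_rounds):
        text = seq.tobytes()
        dirty: list[int] = []
        for word in (q.encode(), rc.encode()):
            i = text.find(word)
            while i != -1:
                if not planted_mask[i : i + m].all():
                    dirty.append(i)
                i = text.find(word, i + 1)
        if not dirty:
            return
        for start in dirty:
            for pos in range(start, start + m):
                if not planted_mask[pos]:
                    seq[pos] = _BASES[rng.integers(0, 4)]
    logger.warning("chance motif matches remained after %d scrub rounds", max_rounds)


def _assign_psi(
    events: list[SpliceEvent], config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, dict[str, float]], dict[str, str]]:
    cond_a, cond_b = config.conditions
    n = len(events)
    n_up, n_down = config.n_events_up, config.n_events_down
    if n_up + n_down > n:
        raise ValueError("more regulated events requested than events simulated")
    order = rng.permutation(n)
    labels = np.array(["null"] * n, dtype=object)
    labels[order[:n_up]] = "up"
    labels[order[n_up : n_up + n_down]] = "down"
    d = config.delta_psi
    psi_true: dict[str, dict[str, float]] = {}
    regulation: dict[str, str] = {}
    for ev, lab in zip(events, labels):
        if lab == "up":
            base = rng.uniform(0.15, 0.95 - d)
            pa, pb = base, base + d
        elif lab == "down":
            base = rng.uniform(0.05 + d, 0.85)
            pa, pb = base, base - d
        else:
            base = rng.uniform(0.15, 0.85)
            pa, pb = base, base
        psi_true[ev.event_id] = {cond_a: float(pa), cond_b: float(pb)}
        regulation[ev.event_id] = str(lab)
    return psi_true, regulation


def simulate_counts(truth: SyntheticTruth, config: SimulationConfig | None = None) -> pd.DataFrame:
    """Beta-binomial junction counts per event × condition × sample.

    Total informative reads per event/sample are Poisson(depth); inclusion
    reads are BetaBinomial(total, psi_true, rho) (binomial at rho = 0).
    Junction columns are realized at the per-junction scale — each of a
    type's inclusion junctions sees the inclusion isoform once — so the
    averaged inclusion/exclusion counts used by the PSI estimator equal the
    drawn totals in expectation.
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 1])
    rho = config.dispersion
    rows = []
    for ev in truth.events:
        n_inc, n_exc = FIELD_COUNTS[ev.event_type]
        for condition in config.conditions:
            psi = truth.psi_true[ev.event_id][condition]
            for si in range(config.n_samples):
                total = int(rng.poisson(config.depth))
                if total == 0:
                    inc_total = 0
                elif psi <= 0:
                    inc_total = 0
                elif psi >= 1:
                    inc_total = total
                elif rho > 0:
                    a = psi * (1 - rho) / rho
                    b = (1 - psi) * (1 - rho) / rho
                    inc_total = int(stats.betabinom.rvs(total, a, b, random_state=rng))
                else:
                    inc_total = int(rng.binomial(total, psi))
                exc_total = total - inc_total
                # realize per-junction columns at the per-junction scale so
                # that the column average equals the drawn count: a type with
                # two inclusion junctions carries 2*inc_total junction reads
                if n_inc == 2:
                    inc1 = int(rng.binomial(2 * inc_total, 0.5))
                    inc2 = 2 * inc_total - inc1
                else:
                    inc1, inc2 = inc_total, 0
                if n_exc == 2:
                    exc1 = int(rng.binomial(2 * exc_total, 0.5))
                    exc2 = 2 * exc_total - exc1
                else:
                    exc1, exc2 = exc_total, 0
                rows.append(
                    {
                        "event_id": ev.event_id,
                        "event_type": ev.event_type,
                        "sample_id": f"{condition}_{si + 1}",
                        "condition": condition,
                        "inc1": inc1,
                        "inc2": inc2,
                        "exc1": exc1,
                        "exc2": exc2,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id", "event_type", "sample_id", "condition",
            "inc1", "inc2", "exc1", "exc2",
        ],
    )


def write_simulation(
    config: SimulationConfig, outdir: str | Path
) -> tuple[dict[str, GenomeSequence], list[Gene], SyntheticTruth, pd.DataFrame]:
    """Run the generator and write FASTA, GTF, counts TSV and truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, truth = make_genome(config)
    counts = simulate_counts(truth, config)
    write_fasta(genome, outdir / "genome.fa")
    write_gtf(genes, outdir / "annotation.gtf")
    counts.to_csv(outdir / "junction_counts.tsv", sep="\t", index=False)
    manifest = json.loads(truth.to_json())
    manifest["checksum"] = truth.checksum
    (outdir / "truth.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return genome, genes, truth, counts
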