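# Methods

## Coordinate model

All internal coordinates are 0-based half-open on the forward genomic
strand; conversion to/from the GTF's 1-based inclusive convention happens
only at file boundaries. A splice-site *boundary* at coordinate p lies
between bases p−1 and p. Introns are derived as the gaps between
consecutive exons of a transcript; introns shorter than 30 nt are kept but
logged, since they usually indicate annotation artifacts. Only `exon` GTF
features are consumed — event enumeration needs exon structure alone, and
sub-exonic regions (e.g. a 5′ UTR slice for coverage quantification) enter
as user-supplied intervals.

## Event definitions

Events are defined from annotation structure (transcript pairs), not read
evidence, in the standard SUPPA-style formulation; read-level filters are
applied downstream at quantification time. For a pair (A, B) of isoforms:

* **SE** — A contains an internal exon whose flanking junctions' partners
  are joined directly in B, and no exon of B intersects the skipped exon.
* **RI** — B splices a junction whose two outer exon boundaries A spans
  within a single exon (boundaries shared exactly).
* **A5SS / A3SS** — two junctions share one boundary and differ at the
  other; the differing side is the donor side (exon 3′ end in
  transcription direction) for A5SS, the acceptor side for A3SS. The two
  exons on the differing side must overlap each other. Without this
  overlap requirement every SE and MXE pair would additionally emit a
  spurious alternative-splice-site event (the skip junction and the
  inclusion junction always share one boundary), which both inflates
  counts and makes the event classes non-disjoint.
* **MXE** — two non-overlapping internal exons with identical flanking
  junction partners, separated by a positive gap, where no isoform of the
  pair contains both.

Events are deduplicated across transcript pairs by their coordinate tuple
and emitted in a canonical order (sorted by `event_id`), so repeated runs
are byte-identical. Two symmetry properties pin the strand logic down:
reverse-complementing the coordinate frame leaves all class counts
unchanged (the locus encodes the same transcripts), while relabelling a
gene to the opposite strand at fixed coordinates swaps A5SS and A3SS.

## Motif orientation

The Zc3h12c motifs are printed 3′→5′. Read 5′→3′ *as printed*, the primary
motif contains `AG|GUAAGU`, the canonical 5′ splice-donor consensus, which
is exactly the sequence context a junction-targeting factor would sit on;
read reversed it does not. The default therefore treats the printed string
as the 5′→3′ query (`orientation_mode="as_printed"`), the reversal is kept
as an explicit switch, and both modes log the resulting DNA query so the
choice is never silent. Matching is exact (the motifs are reported as
single sequences, not weight matrices); scanning covers both strands via
the reverse complement, reports overlapping occurrences, and never matches
through N.

## Hit classification and distances

A hit is *junction-spanning* for a gene when some exon/intron boundary of
that gene lies strictly inside the hit interval; hits that merely abut a
boundary belong to the flanking feature. Otherwise the hit is *exonic* if
fully contained in some exon, else *intronic*; hits outside every gene
span are intergenic. A hit overlapping several genes gets one annotation
per gene; interval-level summaries count unique genomic intervals per
class, and annotation-level (per transcript-context) counts are reported
alongside, since public annotations do not state which convention a given
genome-wide tally used.

Distances are signed in transcription orientation from the hit's 5′-most
base (configurable to 3′ end or midpoint): positive downstream of the
boundary, with the first downstream base at distance 0. Donor sites are
exon→intron boundaries in transcription direction, acceptors the reverse;
a position can be both in different transcripts.

## Targeting

An event is targeted when a hit on the gene's sense strand (configurable)
intersects `[site − W, site + W + 1)` for one of its defining splice
sites. W is not derivable from first principles, so it is an explicit,
logged parameter on every summary; the default W = 50 bp focuses on the
near-junction region where donor/acceptor context lives. A whole-event-span
secondary flag is reported alongside, since "event has a motif" is
sometimes meant span-wide. Per-class fractions carry Clopper–Pearson 95%
intervals; class and condition contrasts use Fisher's exact test with
Benjamini–Hochberg correction across the five classes.

## PSI and differential inclusion

Counts arrive per event × sample with fixed columns `inc1, inc2, exc1,
exc2`; how many columns a type uses is fixed (SE and RI: two inclusion
junctions, one exclusion; A5SS/A3SS: one and one; MXE: two and two). PSI
is the averaged-inclusion share, `Ī/(Ī + Ē)`, undefined below `min_reads`
(default 10) informative reads. Junction counts rather than intron-body
coverage quantify RI, which keeps the estimate independent of intron
length and matches the junction-centric motif analysis.

Differential inclusion defaults to a replicate-aware beta-binomial
likelihood-ratio test: a single intra-class correlation ρ is estimated
globally across events by the method of moments (solving
E[(x − tp)²] = tp(1−p)(1+(t−1)ρ) over all replicate groups, with a
k/(k−1) small-sample correction), then each event is tested by maximizing
the beta-binomial likelihood under separate vs common PSI, with p-values
from χ²(1). The simpler alternative — pooling counts within condition and
applying Fisher's exact test to the 2×2 table — is retained as
`method="pooled_fisher"` and validated against an independent
hypergeometric-tail computation, but it assumes binomial sampling: under
replicate overdispersion as mild as ρ = 0.01 at depth 100 its pooled
counts carry roughly twice the nominal variance (design effect
1 + (m−1)ρ ≈ 2), its p-values are anticonservative, and measured false
discovery proportions exceed the nominal level by 1.5–3×, which is why it
is not the default. Direction calls require q ≤ `q_max` (default 0.05)
and |ΔPSI| ≥ `dpsi_min` (default 0.1), with ΔPSI taken from pooled
counts. Events with zero informative reads in either condition are
excluded and logged. Exon-level coverage uses the standard RPKM identity,
`reads / (length/1000) / (library/10⁶)`, over user-supplied intervals.

## Synthetic data

The generator stands in for a real genome/annotation/RNA-seq triple. Each
gene gets two transcripts engineered to realize exactly one event of its
assigned class (class counts follow the mix proportions exactly);
exon lengths default to 80–200 bp and introns to 150–400 bp, compact but
long enough that a 13-nt motif fits strictly inside any feature. With
probability `p_plant[class]` one motif copy is written on the sense strand
straddling a uniformly chosen event splice site, boundary strictly inside
the motif. Defaults are 0.40 for A3SS/A5SS and 0.20 for SE/RI/MXE — the
targeted-proportion structure the pipeline is designed to detect. The
background is uniform over ACGT (composition realism is irrelevant to
exact matching) and chance motif matches are resampled away, so recovered
junction enrichment is attributable to planting alone; an optional
background rate plants additional copies away from splice-site windows.

Counts: per event × sample, total informative reads ~ Poisson(depth,
default 100); inclusion ~ beta-binomial with the condition's true PSI and
ρ (default 0.01, a typical mild replicate overdispersion); junction
columns are realized at the per-junction scale so the estimator's averaged
counts equal the drawn totals in expectation. True PSI is uniform on
(0.15, 0.85) for null events; regulated events get ΔPSI = ±0.3 (default)
with base values drawn so both conditions stay inside (0, 1). Defaults of
3 samples per condition match small-cohort RNA-seq designs.

What the generator does not emulate: realistic isoform complexity (>2
isoforms; a complexity knob exists only through the random-gene test
oracles), GC/composition structure, sequencing error, read-level
alignment, and correlated events sharing junctions. Passing tests
therefore demonstrate correctness of the event logic, scanning geometry,
targeting statistics and count-model inference — not robustness to
alignment artifacts or annotation error in real data.

## Numerical and design choices

* Exact binomial machinery throughout (Clopper–Pearson, Fisher,
  hypergeometric oracles); BH for multiplicity.
* Beta-binomial likelihood maximized by bounded scalar search on
  (10⁻⁶, 1−10⁻⁶) with xatol 10⁻⁵; LRT statistics clipped at 0; ρ clipped
  to [0, 0.5]; degenerate PSI (0 or 1) handled outside the likelihood.
* Zero-event classes report fraction 0 with NaN CIs and a warning;
  zero-read events are excluded from testing, not imputed.
* Determinism: one `numpy` Generator seeded per stream (sequence vs
  counts), canonical sort orders everywhere, and run manifests that echo
  every threshold; two runs with the same config are byte-identical.
* Problem sizes used by the test suite and acceptance script — 500 events
  per class for targeting, 1000 events for PSI/differential recovery, ten
  to twenty 500-event null replicates — are the package's chosen
  simulation scale: large enough that binomial noise sits well inside the
  tolerances being asserted, small enough to iterate on quickly.

## Known limitations

* Exact matching only; no PWM scoring or mismatch tolerance beyond the
  (default-off) sensitivity parameter.
* Alternative first/last exons and tandem UTRs are not enumerated.
* The global-dispersion assumption shares one ρ across events; strongly
  event-specific dispersion would call for per-event shrinkage (as in
  DRIMSeq/edgeR-style moderation), which is out of scope.
* Annotation-scale tallies (how many introns/exons/genes a motif hits)
  depend entirely on the annotation build supplied; the pipeline reports
  both unique-interval and per-transcript conventions rather than
  privileging either.
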