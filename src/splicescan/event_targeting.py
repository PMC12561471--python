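"""Motif-hit × AS-event intersection: targeted fractions per event class.

An event is *targeted* when at least one motif hit intersects the window
``[site - W, site + W + 1)`` around any of its defining splice sites, with
the hit on the gene's sense strand by default. The window half-width W is an
explicit, logged parameter (default 50 bp). Per-class summaries carry exact
(Clopper–Pearson) binomial confidence intervals, and two conditions are
compared per class with Fisher's exact test under Benjamini–Hochberg
correction.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .as_events import EVENT_TYPES, SpliceEvent
from .motif_scan import MotifHit, signed_site_distance

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 50


@dataclass(frozen=True)
class TargetingConfig:
    window_bp: int = DEFAULT_WINDOW_BP
    sense_only: bool = True
    anchor: str = "five_prime"

    def __post_init__(self) -> None:
        if self.window_bp < 0:
            raise ValueError("window_bp must be >= 0")


class _HitIndex:
    """Per-(contig, strand) sorted hit starts for window queries."""

    def __init__(self, hits: Sequence[MotifHit]):
        self._starts: dict[tuple[str, str], list[int]] = {}
        self._hits: dict[tuple[str, str], list[MotifHit]] = {}
        self.max_len = max((h.end - h.start for h in hits), default=0)
        for h in sorted(hits, key=lambda h: h.start):
            key = (h.contig, h.strand)
            self._starts.setdefault(key, []).append(h.start)
            self._hits.setdefault(key, []).append(h)

    def overlapping(
        self, contig: str, lo: int, hi: int, strand: str | None
    ) -> list[MotifHit]:
        """Hits intersecting [lo, hi); strand None means both strands."""
        strands = (strand,) if strand else ("+", "-")
        out = []
        for s in strands:
            key = (contig, s)
            starts = self._starts.get(key)
            if not starts:
                continue
            i0 = bisect_left(starts, lo - self.max_len)
            i1 = bisect_right(starts, hi - 1)
            for h in self._hits[key][i0:i1]:
                if h.start < hi and h.end > lo:
                    out.append(h)
        return out


def targeted_events(
    events: Sequence[SpliceEvent],
    hits: Sequence[MotifHit],
    config: TargetingConfig = TargetingConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-event targeting flags and a per-class summary.

    Returns ``(flags, summary)``: ``flags`` has one row per event with a
    splice-site-window ``targeted`` flag and a whole-span ``targeted_span``
    secondary flag; ``summary`` has one row per event class with counts,
    fraction and the exact binomial 95% CI.
    """
    w = config.window_bp
    logger.info("targeting window W=%d bp, sense_only=%s", w, config.sense_only)
    index = _HitIndex(hits)
    rows = []
    for ev in events:
        strand = ev.strand if config.sense_only else None
        hit_window = any(
            index.overlapping(ev.contig, site - w, site + w + 1, strand)
            for site in ev.splice_sites
        )
        lo, hi = ev.span
        hit_span = bool(index.overlapping(ev.contig, lo, hi, strand))
        rows.append(
            {
                "event_id": ev.event_id,
                "event_type": ev.event_type,
                "gene_id": ev.gene_id,
                "targeted": hit_window,
                "targeted_span": hit_span,
            }
        )
    flags = pd.DataFrame(
        rows, columns=["event_id", "event_type", "gene_id", "targeted", "targeted_span"]
    )

    summary_rows = []
    for etype in EVENT_TYPES:
        sub = flags[flags.event_type == etype] if len(flags) else flags
        n = len(sub)
        k = int(sub.targeted.sum()) if n else 0
        if n == 0:
            logger.warning("no events of class %s; fraction reported as 0", etype)
            frac, lo_ci, hi_ci = 0.0, float("nan"), float("nan")
        else:
            frac = k / n
            lo_ci, hi_ci = proportion_confint(k, n, alpha=0.05, method="beta")
        summary_rows.append(
            {
                "event_type": etype,
                "n_events": n,
                "n_targeted": k,
                "fraction_targeted": frac,
                "ci_low": lo_ci,
                "ci_high": hi_ci,
                "n_targeted_span": int(sub.targeted_span.sum()) if n else 0,
                "window_bp": w,
            }
        )
    return flags, pd.DataFrame(summary_rows)


# site-role labels per event class, in transcription order
_ROLES = {
    "SE": [
        "upstream_exon_donor", "skipped_exon_acceptor",
        "skipped_exon_donor", "downstream_exon_acceptor",
    ],
    "RI": ["ri_donor", "ri_acceptor"],
    "MXE": [
        "upstream_exon_donor", "exon1_acceptor", "exon1_donor",
        "exon2_acceptor", "exon2_donor", "downstream_exon_acceptor",
    ],
    "A5SS": ["alt_donor_1", "alt_donor_2", "shared_acceptor"],
    "A3SS": ["shared_donor", "alt_acceptor_1", "alt_acceptor_2"],
}


def event_site_roles(event: SpliceEvent) -> list[tuple[int, str]]:
    """(genomic position, role label) for each defining splice site.

    Role labels follow transcription orientation: on '-' the genomic order
    of sites is reversed before labels are assigned.
    """
    sites = sorted(event.splice_sites)
    ordered = sites if event.strand == "+" else sites[::-1]
    labels = _ROLES[event.event_type]
    return list(zip(ordered, labels))


def event_site_distance_profile(
    events: Sequence[SpliceEvent],
    hits: Sequence[MotifHit],
    max_distance: int,
    sense_only: bool = True,
) -> pd.DataFrame:
    """Signed distance of the nearest hit to each event splice site, binned
    per event class and site role.

    Distances use the hit's 5'-most base in transcription orientation,
    positive downstream. Returns a tidy frame (event_type, site_role,
    distance, count); classes without events are absent with a warning.
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    index = _HitIndex(hits)
    counter: dict[tuple[str, str, int], int] = {}
    present = {ev.event_type for ev in events}
    for etype in EVENT_TYPES:
        if etype not in present:
            logger.warning("no events of class %s; histogram absent", etype)
    for ev in events:
        strand = ev.strand if sense_only else None
        for site, role in event_site_roles(ev):
            cand = index.overlapping(
                ev.contig, site - max_distance, site + max_distance + 1, strand
            )
            if not cand:
                continue
            dists = []
            for h in cand:
                anchor = h.start if ev.strand == "+" else h.end - 1
                dists.append(signed_site_distance(anchor, site, ev.strand))
            d = min(dists, key=abs)
            if -max_distance <= d <= max_distance:
                key = (ev.event_type, role, d)
                counter[key] = counter.get(key, 0) + 1
    rows = [
        {"event_type": t, "site_role": r, "distance": d, "count": c}
        for (t, r, d), c in sorted(counter.items())
    ]
    return pd.DataFrame(rows, columns=["event_type", "site_role", "distance", "count"])


def compare_targeting(
    summary_a: pd.DataFrame, summary_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-class two-proportion exact (Fisher) test between two targeting
    summaries, BH-corrected across classes."""
    a = summary_a.set_index("event_type")
    b = summary_b.set_index("event_type")
    rows = []
    for etype in EVENT_TYPES:
        if etype not in a.index or etype not in b.index:
            logger.warning("class %s missing from one summary; skipped", etype)
            continue
        ra, rb = a.loc[etype], b.loc[etype]
        na, nb = int(ra.n_events), int(rb.n_events)
        if na == 0 or nb == 0:
            logger.warning("class %s has zero events in one summary; skipped", etype)
            continue
        ka, kb = int(ra.n_targeted), int(rb.n_targeted)
        table = [[ka, na - ka], [kb, nb - kb]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "event_type": etype,
                "fraction_a": ka / na,
                "fraction_b": kb / nb,
                "difference": kb / nb - ka / na,
                "p_value": p,
            }
        )
    out = pd.DataFrame(
        rows, columns=["event_type", "fraction_a", "fraction_b", "difference", "p_value"]
    )
    if len(out):
        out["q_value"] = multipletests(out.p_value.values, method="fdr_bh")[1]
    else:
        out["q_value"] = np.array([], dtype=float)
    return out
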