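"""PSI quantification from junction counts and differential inclusion.

Counts arrive as a tidy table with one row per event × sample and fixed
columns ``inc1, inc2, exc1, exc2``; how many of those columns an event type
actually uses is fixed per class:

====  ===========================  =========================
type  inclusion columns            exclusion columns
====  ===========================  =========================
SE    inc1=I_up, inc2=I_down       exc1=S (skip junction)
RI    inc1=R_5', inc2=R_3'         exc1=J (spliced junction)
A3SS  inc1=proximal junction       exc1=distal junction
A5SS  inc1=proximal junction       exc1=distal junction
MXE   inc1, inc2 = exon-1 juncs    exc1, exc2 = exon-2 juncs
====  ===========================  =========================

PSI = mean(inclusion columns) / (mean(inclusion) + mean(exclusion)),
undefined below ``min_reads`` informative reads. Differential inclusion
tests each event with a replicate-aware beta-binomial likelihood-ratio test
(globally estimated dispersion) by default, or with Fisher's exact test on
condition-pooled 2×2 tables; Benjamini–Hochberg correction runs across
events and direction calls additionally require |ΔPSI| ≥ dpsi_min.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: (number of inclusion columns, number of exclusion columns) per event type
FIELD_COUNTS: dict[str, tuple[int, int]] = {
    "SE": (2, 1),
    "RI": (2, 1),
    "A3SS": (1, 1),
    "A5SS": (1, 1),
    "MXE": (2, 2),
}

COUNT_COLUMNS = ["inc1", "inc2", "exc1", "exc2"]

DEFAULT_MIN_READS = 10
DEFAULT_DPSI_MIN = 0.1
DEFAULT_Q_MAX = 0.05


@dataclass(frozen=True)
class PsiEstimate:
    event_id: str
    sample_id: str
    psi: float | None
    total_informative_reads: int


def compute_psi(
    event_type: str,
    inclusion_counts: tuple[int, ...],
    exclusion_counts: tuple[int, ...],
    min_reads: int = DEFAULT_MIN_READS,
) -> tuple[float | None, float]:
    """PSI for one event/sample; returns (psi or None, informative reads).

    Inclusion/exclusion tuples must have the lengths FIELD_COUNTS assigns to
    the event type. Negative counts are a hard error.
    """
    n_inc, n_exc = FIELD_COUNTS[event_type]
    if len(inclusion_counts) != n_inc or len(exclusion_counts) != n_exc:
        raise ValueError(
            f"{event_type} expects {n_inc} inclusion / {n_exc} exclusion counts"
        )
    if any(c < 0 for c in inclusion_counts) or any(c < 0 for c in exclusion_counts):
        raise ValueError("negative junction count")
    inc = sum(inclusion_counts) / n_inc
    exc = sum(exclusion_counts) / n_exc
    denom = inc + exc
    if denom < min_reads:
        return None, denom
    return inc / denom, denom


def _avg_counts(df: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Vectorised per-row averaged inclusion/exclusion counts."""
    n_inc = df.event_type.map(lambda t: FIELD_COUNTS[t][0])
    n_exc = df.event_type.map(lambda t: FIELD_COUNTS[t][1])
    inc = (df.inc1 + np.where(n_inc == 2, df.inc2, 0)) / n_inc
    exc = (df.exc1 + np.where(n_exc == 2, df.exc2, 0)) / n_exc
    return pd.Series(inc, index=df.index), pd.Series(exc, index=df.index)


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    required = ["event_id", "event_type", "sample_id", "condition", *COUNT_COLUMNS]
    missing = [c for c in required if c not in counts.columns]
    if missing:
        raise ValueError(f"count table missing columns {missing}")
    if (counts[COUNT_COLUMNS].values < 0).any():
        raise ValueError("negative junction count in table")
    return counts


def psi_table(counts: pd.DataFrame, min_reads: int = DEFAULT_MIN_READS) -> pd.DataFrame:
    """Per event × sample PSI; rows below min_reads get psi = NaN."""
    counts = validate_counts(counts)
    inc, exc = _avg_counts(counts)
    denom = inc + exc
    psi = np.where(denom > 0, inc / np.where(denom > 0, denom, 1), np.nan)
    psi = np.where(denom >= min_reads, psi, np.nan)
    out = counts[["event_id", "event_type", "sample_id", "condition"]].copy()
    out["psi"] = psi
    out["total_informative_reads"] = denom.round().astype(int)
    return out


def count_expressed_events(
    psi: pd.DataFrame, condition: str, min_reads: int = DEFAULT_MIN_READS
) -> dict[str, int]:
    """Per-class counts of events with >= min_reads informative reads in at
    least half of the condition's samples."""
    sub = psi[psi.condition == condition]
    counts: dict[str, int] = {}
    for etype, grp in sub.groupby("event_type"):
        n = 0
        for _, ev in grp.groupby("event_id"):
            need = ceil(len(ev) / 2)
            if (ev.total_informative_reads >= min_reads).sum() >= need:
                n += 1
        counts[str(etype)] = n
    return counts


def _betabinom_nll(inc: np.ndarray, tot: np.ndarray, psi: float, rho: float) -> float:
    """Negative beta-binomial log-likelihood (binomial at rho -> 0),
    dropping psi-free combinatorial terms."""
    if rho <= 1e-9:
        p = min(max(psi, 1e-9), 1 - 1e-9)
        return float(-np.sum(inc * np.log(p) + (tot - inc) * np.log(1 - p)))
    a = psi * (1 - rho) / rho
    b = (1 - psi) * (1 - rho) / rho
    return float(
        -np.sum(
            gammaln(inc + a) + gammaln(tot - inc + b) - gammaln(tot + a + b)
            + gammaln(a + b) - gammaln(a) - gammaln(b)
        )
    )


def _psi_mle(inc: np.ndarray, tot: np.ndarray, rho: float) -> tuple[float, float]:
    res = minimize_scalar(
        lambda p: _betabinom_nll(inc, tot, p, rho),
        bounds=(1e-6, 1 - 1e-6), method="bounded", options={"xatol": 1e-5},
    )
    return float(res.x), float(res.fun)


def estimate_dispersion(groups: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Global method-of-moments intra-class correlation rho.

    ``groups`` are (inclusion, total) replicate vectors, one per
    event × condition. Solves the estimating equation
    E[(x - t p)^2] = t p (1-p) (1 + (t-1) rho) pooled across groups, with a
    k/(k-1) small-sample correction for the plug-in p; clipped to [0, 0.5].
    """
    num = den = 0.0
    for inc, tot in groups:
        inc = np.asarray(inc, dtype=float)
        tot = np.asarray(tot, dtype=float)
        ok = tot > 0
        inc, tot = inc[ok], tot[ok]
        k = len(tot)
        if k < 2:
            continue
        p = inc.sum() / tot.sum()
        if p <= 0 or p >= 1:
            continue
        resid = (inc - tot * p) ** 2 * k / (k - 1)
        num += float(np.sum(resid - tot * p * (1 - p)))
        den += float(np.sum(tot * p * (1 - p) * (tot - 1)))
    if den <= 0:
        return 0.0
    return float(np.clip(num / den, 0.0, 0.5))


def differential_inclusion(
    counts: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    dpsi_min: float = DEFAULT_DPSI_MIN,
    q_max: float = DEFAULT_Q_MAX,
    min_reads: int = DEFAULT_MIN_READS,
    method: str = "betabinom",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential inclusion between two conditions.

    Two tests are available per event:

    * ``betabinom`` (default) — replicate-aware beta-binomial likelihood-
      ratio test with a single dispersion rho estimated globally across
      events by the method of moments; p from chi-square(1). Overdispersed
      replicates inflate pooled-count tests, so this is the calibrated
      default.
    * ``pooled_fisher`` — counts summed across samples per condition,
      averaged over the type's junction columns, and the two rounded
      (inclusion, exclusion) pairs tested as a 2×2 table with Fisher's
      exact test (two-sided).

    delta_psi is PSI(condition_b) − PSI(condition_a) from pooled counts.
    BH correction runs across all tested events; direction calls require
    q ≤ q_max and |delta_psi| ≥ dpsi_min. Events with zero informative
    reads in either condition are excluded and logged. Returns
    ``(results, tally)`` with a per-class (increased, decreased) tally.
    """
    if method not in ("betabinom", "pooled_fisher"):
        raise ValueError(f"unknown method {method!r}")
    counts = validate_counts(counts)
    sub = counts[counts.condition.isin([condition_a, condition_b])].copy()
    inc, exc = _avg_counts(sub)
    sub["inc"] = inc
    sub["tot"] = inc + exc

    per_event: dict[tuple[str, str], dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for (eid, etype, cond), g in sub.groupby(
        ["event_id", "event_type", "condition"], sort=True
    ):
        per_event.setdefault((eid, etype), {})[cond] = (
            g["inc"].to_numpy(), g["tot"].to_numpy()
        )

    rho = 0.0
    if method == "betabinom":
        groups = [
            arrs for conds in per_event.values() for arrs in conds.values()
        ]
        rho = estimate_dispersion(groups)
        logger.info("global dispersion estimate rho=%.4g", rho)

    rows = []
    n_excluded = 0
    for (event_id, etype), conds in per_event.items():
        ia, ta = conds.get(condition_a, (np.zeros(0), np.zeros(0)))
        ib, tb = conds.get(condition_b, (np.zeros(0), np.zeros(0)))
        if ta.sum() == 0 or tb.sum() == 0:
            n_excluded += 1
            continue
        psi_a = float(ia.sum() / ta.sum())
        psi_b = float(ib.sum() / tb.sum())
        if method == "pooled_fisher":
            table = np.rint(
                [[ia.sum(), ta.sum() - ia.sum()], [ib.sum(), tb.sum() - ib.sum()]]
            ).astype(int)
            _, p = stats.fisher_exact(table, alternative="two-sided")
        else:
            _, nll_a = _psi_mle(ia, ta, rho)
            _, nll_b = _psi_mle(ib, tb, rho)
            _, nll_0 = _psi_mle(
                np.concatenate([ia, ib]), np.concatenate([ta, tb]), rho
            )
            lrt = max(2.0 * (nll_0 - nll_a - nll_b), 0.0)
            p = float(stats.chi2.sf(lrt, df=1))
        rows.append(
            {
                "event_id": event_id,
                "event_type": etype,
                "psi_a": psi_a,
                "psi_b": psi_b,
                "delta_psi": psi_b - psi_a,
                "reads_a": float(ta.sum()),
                "reads_b": float(tb.sum()),
                "p_value": p,
            }
        )
    if n_excluded:
        logger.info(
            "%d events excluded (zero informative reads in one condition)", n_excluded
        )
    results = pd.DataFrame(
        rows,
        columns=[
            "event_id", "event_type", "psi_a", "psi_b", "delta_psi",
            "reads_a", "reads_b", "p_value",
        ],
    )
    if len(results):
        results["q_value"] = multipletests(results.p_value.values, method="fdr_bh")[1]
    else:
        results["q_value"] = np.array([], dtype=float)
    sig = results.q_value <= q_max if len(results) else pd.Series(dtype=bool)
    direction = np.where(
        sig & (results.delta_psi >= dpsi_min),
        "increased",
        np.where(sig & (results.delta_psi <= -dpsi_min), "decreased", "unchanged"),
    )
    results["direction"] = direction

    tally_rows = []
    for etype in sorted(results.event_type.unique()) if len(results) else []:
        r = results[results.event_type == etype]
        tally_rows.append(
            {
                "event_type": etype,
                "increased": int((r.direction == "increased").sum()),
                "decreased": int((r.direction == "decreased").sum()),
                "n_tested": len(r),
            }
        )
    tally = pd.DataFrame(
        tally_rows, columns=["event_type", "increased", "decreased", "n_tested"]
    )
    return results, tally


@dataclass(frozen=True)
class ExonCoverage:
    region_id: str
    region: tuple[int, int]
    read_count: int
    region_length: int
    library_size: int
    rpkm: float


def exon_rpkm(
    read_count: int,
    region_length: int,
    library_size: int,
    region_id: str = "",
    region: tuple[int, int] = (0, 0),
) -> ExonCoverage:
    """Reads per kilobase of region per million mapped reads."""
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if read_count < 0:
        raise ValueError("read_count must be non-negative")
    rpkm = read_count / (region_length / 1000) / (library_size / 1_000_000)
    return ExonCoverage(region_id, region, read_count, region_length, library_size, rpkm)


def read_counts_tsv(path) -> pd.DataFrame:
    return validate_counts(pd.read_csv(path, sep="\t"))


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)
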