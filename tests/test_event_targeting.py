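import numpy as np
import pandas as pd
import pytest

from oracles import fisher_two_sided
from splicescan import as_events, event_targeting as et, motif_scan as ms
from splicescan.synthetic_data import SimulationConfig, make_genome


def hits_for(truth, planted_only=True):
    out = []
    for ev in truth.events:
        interval = truth.planted[ev.event_id]
        if interval:
            out.append(ms.MotifHit(ev.contig, interval[0], interval[1], ev.strand, "m"))
    return out


class TestTargetedEvents:
    def test_all_planted_gives_fraction_one(self):
        cfg = SimulationConfig(
            seed=2, n_genes=50,
            p_plant={t: 1.0 for t in ("SE", "RI", "MXE", "A3SS", "A5SS")},
        )
        genome, genes, truth = make_genome(cfg)
        events = as_events.enumerate_all_events(genes)
        hits = ms.scan(genome, ms.build_query(cfg.motif_rna))
        _, summary = et.targeted_events(events, hits, et.TargetingConfig(window_bp=0))
        assert (summary.fraction_targeted == 1.0).all()

    def test_zero_hits_gives_zero(self, small_sim):
        _, _, genes, _ = small_sim
        events = as_events.enumerate_all_events(genes)
        flags, summary = et.targeted_events(events, [])
        assert not flags.targeted.any()
        assert (summary.fraction_targeted == 0.0).all()

    def test_recovery_matches_planted_truth_exactly(self, small_sim):
        cfg, genome, genes, truth = small_sim
        events = as_events.enumerate_all_events(genes)
        hits = ms.scan(genome, ms.build_query(cfg.motif_rna))
        flags, _ = et.targeted_events(events, hits)
        planted = {e.event_id for e in truth.events if truth.planted[e.event_id]}
        assert set(flags[flags.targeted].event_id) == planted

    def test_antisense_hits_ignored_by_default(self, small_sim):
        cfg, genome, genes, truth = small_sim
        events = as_events.enumerate_all_events(genes)
        flipped = [
            ms.MotifHit(h.contig, h.start, h.end, "-" if h.strand == "+" else "+", h.motif_name)
            for h in ms.scan(genome, ms.build_query(cfg.motif_rna))
        ]
        _, summary = et.targeted_events(events, flipped)
        assert summary.n_targeted.sum() == 0
        _, summary_any = et.targeted_events(
            events, flipped, et.TargetingConfig(sense_only=False)
        )
        assert summary_any.n_targeted.sum() > 0

    def test_fraction_monotone_in_window(self, small_sim):
        cfg, genome, genes, _ = small_sim
        events = as_events.enumerate_all_events(genes)
        rng = np.random.default_rng(5)
        n = len(genome["chrS"].sequence)
        hits = [
            ms.MotifHit("chrS", int(s), int(s) + 13, "+" if rng.random() < 0.5 else "-", "m")
            for s in rng.integers(0, n - 13, size=200)
        ]
        prev = -1.0
        for w in (0, 10, 50, 200, 1000):
            _, summary = et.targeted_events(events, hits, et.TargetingConfig(window_bp=w))
            frac = summary.n_targeted.sum() / summary.n_events.sum()
            assert frac >= prev
            prev = frac

    def test_window_bp_validated(self):
        with pytest.raises(ValueError):
            et.TargetingConfig(window_bp=-1)


class TestCalibration:
    def test_estimated_fraction_tracks_planting_probability(self):
        """Mean recovered fraction over seeds stays within 2 binomial SEs."""
        p = {"SE": 0.2, "RI": 0.2, "MXE": 0.2, "A3SS": 0.4, "A5SS": 0.4}
        n_seeds, n_genes = 15, 100
        totals = {t: 0 for t in p}
        counts = {t: 0 for t in p}
        for seed in range(n_seeds):
            cfg = SimulationConfig(seed=seed, n_genes=n_genes, p_plant=p)
            genome, genes, truth = make_genome(cfg)
            events = as_events.enumerate_all_events(genes)
            hits = ms.scan(genome, ms.build_query(cfg.motif_rna))
            _, summary = et.targeted_events(events, hits)
            for row in summary.itertuples():
                totals[row.event_type] += row.n_events
                counts[row.event_type] += row.n_targeted
        for t, prob in p.items():
            se = (prob * (1 - prob) / totals[t]) ** 0.5
            assert abs(counts[t] / totals[t] - prob) < 2 * se


class TestDistanceProfile:
    def test_hit_crossing_upstream_exon_end(self):
        ev = as_events.SpliceEvent(
            "SE", "g", "c", "+", (100, 200, 300, 400),
            frozenset((100, 200, 300, 400)),
        )
        hits = [ms.MotifHit("c", 100, 113, "+", "m")]
        df = et.event_site_distance_profile([ev], hits, max_distance=50)
        row = df[(df.site_role == "upstream_exon_donor") & (df.distance == 0)]
        assert row["count"].item() == 1

    def test_ri_only_planting_populates_ri_only(self):
        cfg = SimulationConfig(
            seed=4, n_genes=60,
            p_plant={"SE": 0.0, "RI": 1.0, "MXE": 0.0, "A3SS": 0.0, "A5SS": 0.0},
        )
        genome, genes, _ = make_genome(cfg)
        events = as_events.enumerate_all_events(genes)
        hits = ms.scan(genome, ms.build_query(cfg.motif_rna))
        df = et.event_site_distance_profile(events, hits, max_distance=50)
        assert set(df.event_type) == {"RI"}
        assert df["count"].sum() > 0

    def test_site_roles_cover_every_splice_site(self, small_sim):
        _, _, genes, truth = small_sim
        for ev in truth.events:
            roles = et.event_site_roles(ev)
            assert {pos for pos, _ in roles} == set(ev.splice_sites)
            assert len({r for _, r in roles}) == len(roles)

    def test_bad_max_distance(self):
        with pytest.raises(ValueError):
            et.event_site_distance_profile([], [], 0)


def summary_frame(pairs):
    rows = []
    for etype, (k, n) in pairs.items():
        rows.append(
            {"event_type": etype, "n_events": n, "n_targeted": k,
             "fraction_targeted": k / n if n else 0.0}
        )
    return pd.DataFrame(rows)


class TestCompareTargeting:
    def test_identical_summaries(self):
        s = summary_frame({t: (10, 50) for t in ("SE", "RI", "MXE", "A3SS", "A5SS")})
        out = et.compare_targeting(s, s)
        assert (out.difference == 0).all()
        assert (out.p_value == 1.0).all()

    def test_two_proportion_against_hypergeometric_oracle(self):
        s_a = summary_frame({"SE": (40, 100)})
        s_b = summary_frame({"SE": (20, 100)})
        out = et.compare_targeting(s_a, s_b)
        expected = fisher_two_sided([[40, 60], [20, 80]])
        assert out.difference.item() == pytest.approx(-0.20)
        assert out.p_value.item() == pytest.approx(expected, rel=1e-9)

    def test_empty_class_skipped(self):
        s_a = summary_frame({"SE": (40, 100), "RI": (0, 0)})
        s_b = summary_frame({"SE": (20, 100), "RI": (5, 10)})
        out = et.compare_targeting(s_a, s_b)
        assert list(out.event_type) == ["SE"]


def test_equal_planting_rates_erase_class_contrast():
    """When every class is planted at the same junction rate, the alternative-
    splice-site vs other-class contrast is a null and should rarely reach
    significance."""
    from scipy.stats import fisher_exact

    n_sig = 0
    n_reps = 10
    for seed in range(n_reps):
        cfg = SimulationConfig(
            seed=seed, n_genes=150,
            p_plant={t: 0.2 for t in ("SE", "RI", "MXE", "A3SS", "A5SS")},
        )
        genome, genes, _ = make_genome(cfg)
        events = as_events.enumerate_all_events(genes)
        hits = ms.scan(genome, ms.build_query(cfg.motif_rna))
        _, summary = et.targeted_events(events, hits)
        ass = summary[summary.event_type.isin(["A3SS", "A5SS"])]
        rest = summary[~summary.event_type.isin(["A3SS", "A5SS"])]
        k1, n1 = ass.n_targeted.sum(), ass.n_events.sum()
        k2, n2 = rest.n_targeted.sum(), rest.n_events.sum()
        _, p = fisher_exact([[k1, n1 - k1], [k2, n2 - k2]])
        n_sig += p < 0.05
    assert n_sig <= 2
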