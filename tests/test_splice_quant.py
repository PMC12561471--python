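import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import fisher_two_sided
from splicescan import splice_quant as sq
from splicescan.synthetic_data import SimulationConfig, make_genome, simulate_counts


class TestComputePsi:
    @pytest.mark.parametrize(
        "etype,inc,exc,expected",
        [
            ("SE", (10, 10), (0,), 1.0),
            ("RI", (0, 0), (20,), 0.0),
            ("SE", (6, 4), (5,), 0.5),
            ("A3SS", (30,), (10,), 0.75),
            ("MXE", (10, 10), (30, 30), 0.25),
        ],
    )
    def test_formula_cases(self, etype, inc, exc, expected):
        psi, _ = sq.compute_psi(etype, inc, exc, min_reads=1)
        assert psi == pytest.approx(expected)

    def test_undefined_below_min_reads(self):
        psi, total = sq.compute_psi("SE", (2, 2), (1,), min_reads=10)
        assert psi is None and total == 3

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            sq.compute_psi("SE", (-1, 2), (3,))

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError, match="inclusion"):
            sq.compute_psi("SE", (1,), (3,))

    @given(
        inc=st.integers(0, 500), exc=st.integers(1, 500), extra=st.integers(1, 100)
    )
    @settings(max_examples=60, derandomize=True)
    def test_psi_strictly_increases_with_inclusion(self, inc, exc, extra):
        p1, _ = sq.compute_psi("A3SS", (inc,), (exc,), min_reads=0)
        p2, _ = sq.compute_psi("A3SS", (inc + extra,), (exc,), min_reads=0)
        assert p2 > p1


def counts_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "event_id", "event_type", "sample_id", "condition",
            "inc1", "inc2", "exc1", "exc2",
        ],
    )


class TestPsiTable:
    def test_min_reads_masks_psi(self):
        df = counts_frame(
            [
                ("e1", "SE", "s1", "WT", 10, 10, 0, 0),
                ("e2", "SE", "s1", "WT", 2, 2, 1, 0),
            ]
        )
        out = sq.psi_table(df, min_reads=10)
        assert out.loc[out.event_id == "e1", "psi"].item() == 1.0
        assert np.isnan(out.loc[out.event_id == "e2", "psi"].item())

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            sq.psi_table(pd.DataFrame({"event_id": []}))


class TestCountExpressed:
    def base(self, depth):
        rows = []
        for s in ("s1", "s2"):
            rows.append(("e1", "RI", s, "WT", depth, depth, depth, 0))
        return counts_frame(rows)

    def test_deep_coverage_counts_all(self):
        psi = sq.psi_table(self.base(50), min_reads=10)
        assert sq.count_expressed_events(psi, "WT", min_reads=10) == {"RI": 1}

    def test_threshold_above_depth_counts_none(self):
        psi = sq.psi_table(self.base(2), min_reads=0)
        assert sq.count_expressed_events(psi, "WT", min_reads=1000) == {"RI": 0}

    def test_monotone_in_min_reads(self):
        cfg = SimulationConfig(seed=8, n_genes=40, depth=30)
        _, _, truth = make_genome(cfg)
        counts = simulate_counts(truth, cfg)
        psi = sq.psi_table(counts, min_reads=0)
        prev = None
        for mr in (1, 10, 20, 40, 80):
            n = sum(sq.count_expressed_events(psi, "WT", min_reads=mr).values())
            if prev is not None:
                assert n <= prev
            prev = n


class TestDifferential:
    def test_identical_conditions_call_nothing(self):
        rows = []
        for cond in ("WT", "cKO"):
            for s in range(3):
                rows.append((f"e1", "RI", f"{cond}{s}", cond, 50, 50, 50, 0))
                rows.append((f"e2", "SE", f"{cond}{s}", cond, 30, 30, 70, 0))
        res, tally = sq.differential_inclusion(counts_frame(rows), "WT", "cKO")
        assert (res.direction == "unchanged").all()
        assert tally.increased.sum() == 0 and tally.decreased.sum() == 0

    def test_pooled_fisher_matches_hypergeometric_oracle(self):
        rows = [
            ("e1", "RI", "a1", "WT", 90, 90, 10, 0),
            ("e1", "RI", "b1", "cKO", 10, 10, 90, 0),
        ]
        res, _ = sq.differential_inclusion(
            counts_frame(rows), "WT", "cKO", method="pooled_fisher"
        )
        assert res.delta_psi.item() == pytest.approx(-0.8)
        expected = fisher_two_sided([[90, 10], [10, 90]])
        assert res.p_value.item() == pytest.approx(expected, rel=1e-9)

    def test_zero_read_events_excluded(self):
        rows = [
            ("e1", "RI", "a1", "WT", 0, 0, 0, 0),
            ("e1", "RI", "b1", "cKO", 10, 10, 90, 0),
            ("e2", "RI", "a1", "WT", 50, 50, 50, 0),
            ("e2", "RI", "b1", "cKO", 50, 50, 50, 0),
        ]
        res, _ = sq.differential_inclusion(counts_frame(rows), "WT", "cKO")
        assert list(res.event_id) == ["e2"]

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            sq.differential_inclusion(counts_frame([]), "a", "b", method="bogus")

    def test_recovers_planted_direction_asymmetry(self):
        cfg = SimulationConfig(
            seed=21, n_genes=300, event_mix={"RI": 1.0},
            n_events_up=30, n_events_down=10,
        )
        _, _, truth = make_genome(cfg)
        counts = simulate_counts(truth, cfg)
        res, tally = sq.differential_inclusion(counts, "WT", "cKO")
        up, down = int(tally.increased.sum()), int(tally.decreased.sum())
        assert 20 <= up <= 40
        assert 5 <= down <= 18
        assert up > down  # the planted asymmetry survives


class TestDispersionEstimate:
    def test_recovers_simulated_rho(self):
        cfg = SimulationConfig(seed=13, n_genes=400, event_mix={"RI": 1.0})
        _, _, truth = make_genome(cfg)
        counts = simulate_counts(truth, cfg)
        inc = (counts.inc1 + counts.inc2) / 2
        tot = inc + counts.exc1
        groups = [
            (g["inc"].to_numpy(), g["tot"].to_numpy())
            for _, g in pd.DataFrame(
                {"inc": inc, "tot": tot, "k": counts.event_id + counts.condition}
            ).groupby("k")
        ]
        rho = sq.estimate_dispersion(groups)
        assert 0.005 < rho < 0.02

    def test_binomial_data_gives_near_zero(self):
        rng = np.random.default_rng(0)
        groups = []
        for _ in range(300):
            tot = rng.poisson(100, size=3).astype(float)
            inc = rng.binomial(tot.astype(int), 0.4).astype(float)
            groups.append((inc, tot))
        assert sq.estimate_dispersion(groups) < 0.004


class TestExonRpkm:
    @pytest.mark.parametrize(
        "reads,length,lib,expected",
        [
            (100, 1000, 1_000_000, 100.0),
            (0, 500, 2_000_000, 0.0),
            (250, 500, 10_000_000, 50.0),
        ],
    )
    def test_hand_computed_values(self, reads, length, lib, expected):
        assert sq.exon_rpkm(reads, length, lib).rpkm == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sq.exon_rpkm(10, 0, 1000)
        with pytest.raises(ValueError):
            sq.exon_rpkm(10, 100, 0)
        with pytest.raises(ValueError):
            sq.exon_rpkm(-1, 100, 1000)

    def test_scaling_relations_on_grid(self):
        base = sq.exon_rpkm(100, 1000, 1_000_000).rpkm
        for f in (2, 3, 5, 10):
            assert sq.exon_rpkm(100 * f, 1000, 1_000_000).rpkm == pytest.approx(base * f)
            assert sq.exon_rpkm(100, 1000 * f, 1_000_000).rpkm == pytest.approx(base / f)
            assert sq.exon_rpkm(100, 1000, 1_000_000 * f).rpkm == pytest.approx(base / f)
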