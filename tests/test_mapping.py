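"""Read assignment, coverage estimation, binning, and rate statistics."""

import random

import numpy as np
import pandas as pd
import pytest

from mixcat.catalogue import Catalogue
from mixcat.mapping import (
    MappingConfig,
    MappingResult,
    assign_and_count,
    bin_coverage,
    estimate_coverage,
    mapping_rate_curves,
    paired_rate_test,
    subsample_reads,
)
from mixcat.normalize import reverse_complement
from mixcat.records import GeneRecord, Read, ReadSet


def _random_nt(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def _catalogue(genes: dict[str, str], codes: dict[str, str] | None = None):
    return Catalogue(
        name="test",
        representatives=[
            GeneRecord(gene_id=gid, nt_seq=seq,
                       partial_code=(codes or {}).get(gid, "00"))
            for gid, seq in genes.items()
        ],
    )


class TestSubsample:
    def _readset(self, n):
        rng = random.Random(0)
        return ReadSet(
            "s", [Read(f"r{i}", _random_nt(rng, 50), 1) for i in range(n)]
        )

    def test_identity_when_enough_requested(self):
        rs = self._readset(50)
        out = subsample_reads(rs, MappingConfig(n_subsample=100))
        assert [r.read_id for r in out.reads] == [r.read_id for r in rs.reads]

    def test_same_seed_same_subset(self):
        rs = self._readset(1000)
        cfg = MappingConfig(n_subsample=100, seed=7)
        a = subsample_reads(rs, cfg)
        b = subsample_reads(rs, cfg)
        assert [r.read_id for r in a.reads] == [r.read_id for r in b.reads]

    def test_different_seeds_differ(self):
        rs = self._readset(1000)
        a = subsample_reads(rs, MappingConfig(n_subsample=100, seed=1))
        b = subsample_reads(rs, MappingConfig(n_subsample=100, seed=2))
        assert {r.read_id for r in a.reads} != {r.read_id for r in b.reads}

    def test_only_forward_reads_sampled(self):
        rs = ReadSet(
            "s",
            [Read("r1", "ACGT" * 20, 1), Read("r1", "TTTT" * 20, 2)],
        )
        out = subsample_reads(rs, MappingConfig(n_subsample=10))
        assert all(r.mate == 1 for r in out.reads)


class TestAssignAndCount:
    @pytest.fixture
    def genes(self):
        rng = random.Random(42)
        return {f"g{i}": _random_nt(rng, 600) for i in range(5)}

    @pytest.mark.parametrize("exhaustive", [False, True])
    def test_exact_substring_read_counted(self, genes, exhaustive):
        cat = _catalogue(genes)
        reads = [Read("r0", genes["g2"][100:200], 1)]
        res = assign_and_count(reads, cat, MappingConfig(exhaustive=exhaustive))
        assert res.counts == {"g2": 1}
        assert res.n_unmapped == 0

    def test_reverse_complement_read_counted(self, genes):
        cat = _catalogue(genes)
        reads = [Read("r0", reverse_complement(genes["g1"][50:150]), 1)]
        res = assign_and_count(reads, cat, MappingConfig())
        assert res.counts == {"g1": 1}

    def test_random_read_unmapped(self, genes):
        rng = random.Random(9)
        cat = _catalogue(genes)
        reads = [Read("r0", _random_nt(rng, 100), 1)]
        res = assign_and_count(reads, cat, MappingConfig())
        assert res.n_unmapped == 1 and not res.counts

    @pytest.mark.parametrize("exhaustive", [False, True])
    def test_duplicate_genes_make_reads_ambiguous(self, genes, exhaustive):
        """A read matching two identical genes with the same best score is
        tallied as ambiguous and counted to neither."""
        dup = dict(genes)
        dup["g_copy"] = genes["g0"]
        cat = _catalogue(dup)
        reads = [Read("r0", genes["g0"][200:300], 1)]
        res = assign_and_count(reads, cat, MappingConfig(exhaustive=exhaustive))
        assert res.n_ambiguous == 1
        assert not res.counts

    def test_accounting_invariant(self, genes):
        rng = random.Random(5)
        cat = _catalogue(genes)
        reads = [
            Read(f"e{i}", genes[f"g{i % 5}"][i : i + 100], 1) for i in range(10)
        ] + [Read(f"u{i}", _random_nt(rng, 100), 1) for i in range(5)]
        res = assign_and_count(reads, cat, MappingConfig())
        assert res.n_assigned + res.n_ambiguous + res.n_unmapped == res.n_total
        assert res.n_total == 15

    def test_empty_catalogue_rejected(self):
        cat = Catalogue(name="x", representatives=[])
        with pytest.raises(ValueError):
            assign_and_count([Read("r", "ACGT" * 30, 1)], cat)

    def test_noisy_read_below_identity_threshold_unmapped(self, genes):
        seq = list(genes["g3"][100:200])
        rng = random.Random(11)
        for pos in rng.sample(range(100), 15):  # 85% identity < 90% cutoff
            seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
        res = assign_and_count(
            [Read("r", "".join(seq), 1)], _catalogue(genes), MappingConfig()
        )
        assert res.n_unmapped == 1


class TestCoverageEstimate:
    def test_zero_count_zero_estimate(self):
        out = estimate_coverage({}, {"g": 500}, 200.0, 10_000, 100)
        assert out["g"].estimate == 0.0
        assert out["g"].bin == "low"

    def test_methods_formula_arithmetic(self):
        # 10 counted reads, 200 bp pairs, 1 kb gene, 1e6 total pairs, 1e4 sampled
        out = estimate_coverage({"g": 10}, {"g": 1000}, 200.0, 10**6, 10**4)
        assert out["g"].estimate == pytest.approx(200.0)
        assert out["g"].bin == "median"

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_coverage({}, {"g": 0}, 200.0, 10, 10)
        with pytest.raises(ValueError):
            estimate_coverage({}, {"g": 10}, 200.0, 10, 0)

    def test_estimator_recovers_simulated_coverage(self):
        """Uniform reads at a known depth: the scale-up formula recovers the
        true coverage from a subsample."""
        rng = random.Random(3)
        genes = {f"g{i}": _random_nt(rng, 800) for i in range(5)}
        true_cov = 60.0
        read_len = 100
        all_reads = []
        for gid, seq in genes.items():
            n = int(true_cov * len(seq) / (2 * read_len))  # forward mate only
            for i in range(n):
                pos = rng.randint(0, len(seq) - read_len)
                all_reads.append(Read(f"{gid}_{i}", seq[pos : pos + read_len], 1))
        rng.shuffle(all_reads)
        total_pairs = len(all_reads)
        cfg = MappingConfig(n_subsample=400, seed=1)
        sub = subsample_reads(ReadSet("s", all_reads), cfg)
        res = assign_and_count(sub, _catalogue(genes), cfg)
        est = estimate_coverage(
            res.counts,
            {g: len(s) for g, s in genes.items()},
            2.0 * read_len,
            total_pairs,
            len(sub),
        )
        mean_est = np.mean([e.estimate for e in est.values()])
        assert mean_est == pytest.approx(true_cov, rel=0.15)


class TestBinCoverage:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.0, "low"),
            (25.0, "low"),
            (50.0, "median"),  # half-open left edge
            (499.9, "median"),
            (600.0, "high"),
            (5000.0, "very_high"),
            (250000.0, "very_high"),
        ],
    )
    def test_edges(self, value, expected):
        assert bin_coverage(value) == expected

    def test_above_top_edge_warns(self):
        with pytest.warns(UserWarning):
            assert bin_coverage(300000.0) == "very_high"

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bin_coverage(-1.0)


class TestRateCurves:
    def test_single_gene_step_function(self):
        cat = _catalogue({"g": "ACGT" * 100})
        res = MappingResult("s", {"g": 8}, 10, 8, 0, 2)
        df = mapping_rate_curves(res, cat)
        at_zero = df.loc[df["length_cutoff"] == 0, "all"].iloc[0]
        assert at_zero == pytest.approx(0.8)
        beyond = df.loc[df["length_cutoff"] > 400, "all"]
        assert (beyond == 0).all()

    def test_hand_computed_three_gene_curve(self):
        genes = {"a": "A" * 100, "b": "A" * 200, "c": "A" * 300}
        cat = _catalogue(genes, codes={"a": "00", "b": "01", "c": "11"})
        res = MappingResult("s", {"a": 2, "b": 3, "c": 5}, 20, 10, 0, 10)
        df = mapping_rate_curves(res, cat).set_index("length_cutoff")
        assert df.loc[0, "all"] == pytest.approx(0.5)
        assert df.loc[200, "all"] == pytest.approx(8 / 20)
        assert df.loc[300, "all"] == pytest.approx(5 / 20)
        assert df.loc[301, "all"] == 0.0
        assert df.loc[100, "complete"] == pytest.approx(2 / 20)
        # monotone non-increasing
        assert (np.diff(df["all"].to_numpy()) <= 1e-12).all()


class TestPairedRateTest:
    def test_identical_rates_degenerate(self):
        out = paired_rate_test([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert out.degenerate
        assert out.p_value == 1.0

    def test_constant_shift_is_significant(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0.5, 0.9, size=30)
        b = a + 0.05
        out = paired_rate_test(b, a)
        assert out.p_value < 0.01

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_rate_test([0.1, 0.2], [0.1])
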