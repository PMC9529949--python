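import itertools

import numpy as np
import pandas as pd
import pytest

from _oracles import fisher_exact_p
from errg.group_contrast import (
    MutationRecord,
    call_dmps,
    cooccurrence,
    differential_mutation,
    fisher_exact,
    group_burden_comparison,
    mutation_matrix,
    read_maf,
    snv_class,
)


def beta_groups(n_high=20, n_low=20):
    samples = [f"h{i}" for i in range(n_high)] + [f"l{i}" for i in range(n_low)]
    groups = pd.Series(["high"] * n_high + ["low"] * n_low, index=samples)
    return samples, groups


class TestCallDmps:
    def test_delta_beta_sign_and_magnitude_cutoffs(self):
        samples, groups = beta_groups()
        rng = np.random.default_rng(0)
        rows = {
            "p_big": np.r_[rng.normal(0.80, 0.02, 20), rng.normal(0.60, 0.02, 20)],
            "p_small": np.r_[rng.normal(0.70, 0.02, 20), rng.normal(0.60, 0.02, 20)],
            "p_hypo": np.r_[rng.normal(0.30, 0.02, 20), rng.normal(0.62, 0.02, 20)],
        }
        beta = pd.DataFrame(rows, index=samples).T.clip(0, 1)
        out = call_dmps(beta, groups)
        assert out.loc["p_big", "delta_beta"] == pytest.approx(0.20, abs=0.02)
        assert out.loc["p_big", "call"] == "hyper"
        # |delta| ~0.10 fails the strict 0.15 magnitude cutoff despite tiny p
        assert out.loc["p_small", "call"] == "ns"
        assert out.loc["p_hypo", "call"] == "hypo"  # hypomethylated in high-risk
        assert set(out["call"].unique()) <= {"hyper", "hypo", "ns"}

    def test_rejects_out_of_range_and_missing(self):
        samples, groups = beta_groups(2, 2)
        bad = pd.DataFrame([[0.5, 0.5, 0.5, 1.2]], index=["p"], columns=samples)
        with pytest.raises(ValueError):
            call_dmps(bad, groups)
        nan = pd.DataFrame([[0.5, np.nan, 0.5, 0.5]], index=["p"], columns=samples)
        with pytest.raises(ValueError):
            call_dmps(nan, groups)

    def test_planted_sensitivity_and_null_false_calls(self):
        """Delta-beta 0.3 at sd 0.05, n=50/50: near-perfect recovery, clean nulls."""
        samples, groups = beta_groups(50, 50)
        rng = np.random.default_rng(4)
        n_probes, n_planted = 300, 30
        base = rng.uniform(0.35, 0.65, n_probes)
        means = np.tile(base[:, None], (1, 100))
        means[:n_planted, :50] -= 0.3
        beta = pd.DataFrame(
            np.clip(rng.normal(means, 0.05), 0, 1),
            index=[f"p{i}" for i in range(n_probes)],
            columns=samples,
        )
        out = call_dmps(beta, groups)
        sens = (out["call"].iloc[:n_planted] == "hypo").mean()
        false_rate = (out["call"].iloc[n_planted:] != "ns").mean()
        assert sens >= 0.95
        assert false_rate <= 0.05
        counts = out["call"].value_counts()
        assert counts.sum() == n_probes  # hyper + hypo + ns partition the probes


class TestSnvClass:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [
            ("C", "T", "C>T"),
            ("G", "A", "C>T"),  # reverse-complement collapse
            ("A", "C", "T>G"),
            ("T", "A", "T>A"),
            ("AT", "A", None),  # not a single-base substitution
            ("-", "A", None),
        ],
    )
    def test_pyrimidine_collapse(self, ref, alt, expected):
        assert snv_class(ref, alt) == expected


def rec(sample, gene, cls="Missense_Mutation", vtype="SNP", ref="C", alt="T", pos=100, vaf=0.3):
    return MutationRecord(sample, gene, "chr1", pos, ref, alt, cls, vtype, vaf)


class TestMutationMatrix:
    def test_binarization_and_silent_filter(self):
        records = [
            rec("s1", "gA"),
            rec("s1", "gA", pos=200),  # second hit does not make the entry 2
            rec("s2", "gA", cls="Silent"),
            rec("s2", "gB", cls="Frame_Shift_Del", vtype="DEL", ref="CA", alt="-"),
        ]
        tables = mutation_matrix(records, ["s1", "s2"])
        m = tables.gene_sample
        assert m.loc["gA", "s1"] == 1
        assert m.loc["gA", "s2"] == 0  # silent-only does not qualify
        assert m.loc["gB", "s2"] == 1
        with_silent = mutation_matrix(records, ["s1", "s2"], include_silent=True)
        assert with_silent.gene_sample.loc["gA", "s2"] == 1

    def test_invariant_to_order_and_duplication(self):
        records = [rec("s1", "gA"), rec("s2", "gB"), rec("s1", "gB", pos=5)]
        a = mutation_matrix(records, ["s1", "s2"]).gene_sample
        b = mutation_matrix(records[::-1] + records, ["s1", "s2"]).gene_sample
        assert a.equals(b)

    def test_burden_summaries(self):
        records = [
            rec("s1", "gA", ref="G", alt="A"),  # collapses to C>T
            rec("s1", "gB", ref="C", alt="A"),
            rec("s2", "gA", cls="Frame_Shift_Ins", vtype="INS", ref="-", alt="TT"),
        ]
        t = mutation_matrix(records, ["s1", "s2"])
        assert t.snv_counts.loc["s1", "C>T"] == 1
        assert t.snv_counts.loc["s1", "C>A"] == 1
        assert t.type_counts.loc["s2", "INS"] == 1
        assert t.class_counts.loc["s1", "Missense_Mutation"] == 2
        assert t.vaf_mean["s1"] == pytest.approx(0.3)

    def test_unknown_sample_rejected_unknown_class_warns(self, caplog):
        with pytest.raises(ValueError):
            mutation_matrix([rec("ghost", "gA")], ["s1"])
        with caplog.at_level("WARNING", logger="errg.group_contrast"):
            t = mutation_matrix([rec("s1", "gA", cls="Weird_Class")], ["s1"])
        assert t.gene_sample.loc["gA", "s1"] == 1  # qualifies, with warning
        assert any("unknown" in r.message.lower() for r in caplog.records)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected_p",
        [
            ([[3, 1], [1, 3]], 34 / 70),
            ([[0, 5], [5, 0]], 2 / 252),
            ([[2, 2], [2, 2]], 1.0),
            ([[10, 0], [0, 10]], 2 / 184_756),
        ],
    )
    def test_enumerated_examples(self, table, expected_p):
        _, p = fisher_exact(table)
        assert p == pytest.approx(expected_p, rel=1e-9)

    def test_odds_ratio_conventions(self):
        odds, _ = fisher_exact([[3, 1], [1, 3]])
        assert odds == 9.0
        odds, _ = fisher_exact([[5, 0], [0, 5]])
        assert odds == np.inf
        odds, _ = fisher_exact([[0, 5], [0, 5]])
        assert np.isnan(odds)

    def test_matches_enumeration_for_all_small_tables(self):
        """Every 2x2 table with total <= 40 matches hypergeometric enumeration."""
        rng = np.random.default_rng(0)
        checked = 0
        for total in range(1, 41):
            for _ in range(6):
                cuts = sorted(rng.integers(0, total + 1, size=3))
                a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
                d = total - a - b - c
                _, p = fisher_exact([[a, b], [c, d]])
                assert p == pytest.approx(fisher_exact_p(a, b, c, d), rel=1e-9, abs=1e-12)
                checked += 1
        assert checked == 240

    def test_rejects_negative_or_fractional(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [0, 2]])
        with pytest.raises(ValueError):
            fisher_exact([[0.5, 1], [1, 1]])


class TestDifferentialMutation:
    @staticmethod
    def _matrix(high_mut, low_mut, n_high=10, n_low=10, gene="gA"):
        samples = [f"h{i}" for i in range(n_high)] + [f"l{i}" for i in range(n_low)]
        groups = pd.Series(["high"] * n_high + ["low"] * n_low, index=samples)
        row = [1] * high_mut + [0] * (n_high - high_mut) + [1] * low_mut + [0] * (n_low - low_mut)
        return pd.DataFrame([row], index=[gene], columns=samples), groups

    def test_fully_separated_gene(self):
        matrix, groups = self._matrix(10, 0)
        out = differential_mutation(matrix, groups, min_mutated=5)
        assert out.loc["gA", "pvalue"] == pytest.approx(2 / 184_756, rel=1e-9)
        assert out.loc["gA", "call"] == "diff"

    def test_min_mutated_floor_excludes(self):
        matrix, groups = self._matrix(2, 1)
        out = differential_mutation(matrix, groups, min_mutated=5)
        assert len(out) == 0

    def test_identical_patterns_give_p_one(self):
        matrix, groups = self._matrix(4, 4)
        out = differential_mutation(matrix, groups, min_mutated=5)
        assert out.loc["gA", "pvalue"] == pytest.approx(1.0)

    def test_planted_rate_difference_detected(self):
        rng = np.random.default_rng(1)
        n = 100
        samples = [f"h{i}" for i in range(n)] + [f"l{i}" for i in range(n)]
        groups = pd.Series(["high"] * n + ["low"] * n, index=samples)
        planted = np.r_[rng.random(n) < 0.4, rng.random(n) < 0.05].astype(int)
        nulls = rng.random((30, 2 * n)) < 0.3
        matrix = pd.DataFrame(
            np.vstack([planted, nulls.astype(int)]),
            index=["planted"] + [f"null{i}" for i in range(30)],
            columns=samples,
        )
        out = differential_mutation(matrix, groups)
        assert out.loc["planted", "call"] == "diff"
        assert out.loc["planted", "odds_ratio"] > 1


class TestCooccurrence:
    def test_identical_mutation_sets_cooccur(self):
        samples = [f"s{i}" for i in range(20)]
        row = [1] * 5 + [0] * 15
        matrix = pd.DataFrame([row, row], index=["gA", "gB"], columns=samples)
        out = cooccurrence(matrix, top_k=2)
        assert len(out) == 1
        pair = out.iloc[0]
        assert pair["label"] == "co-occurring"
        assert pair["odds_ratio"] == np.inf
        _, expected_p = fisher_exact([[5, 0], [0, 15]])
        assert pair["pvalue"] == pytest.approx(expected_p)

    def test_disjoint_sets_are_exclusive(self):
        samples = [f"s{i}" for i in range(10)]
        matrix = pd.DataFrame(
            [[1] * 5 + [0] * 5, [0] * 5 + [1] * 5], index=["gA", "gB"], columns=samples
        )
        out = cooccurrence(matrix, top_k=2)
        assert out.iloc[0]["label"] == "exclusive"
        assert out.iloc[0]["odds_ratio"] == 0.0

    def test_independent_mutations_near_nominal_significance(self):
        rng = np.random.default_rng(2)
        matrix = pd.DataFrame(
            (rng.random((12, 400)) < 0.4).astype(int),
            index=[f"g{i}" for i in range(12)],
            columns=[f"s{i}" for i in range(400)],
        )
        out = cooccurrence(matrix, top_k=12)
        assert len(out) == 66
        # exact test: significant fraction at or below ~nominal
        assert (out["pvalue"] < 0.05).mean() <= 0.10


class TestMafRoundtrip:
    def test_read_maf_and_burden_comparison(self, demo_bundle, tmp_path):
        path = tmp_path / "muts.tsv"
        demo_bundle.mutations.to_csv(path, sep="\t", index=False)
        records = read_maf(path)
        assert len(records) == len(demo_bundle.mutations)
        assert all(r.vaf is not None and 0 <= r.vaf <= 1 for r in records)
        tables = mutation_matrix(records, list(demo_bundle.risk_groups.index))
        burden = group_burden_comparison(tables, demo_bundle.risk_groups)
        assert "snv:C>T" in burden.index
        assert ((burden["pvalue"] >= 0) & (burden["pvalue"] <= 1)).all()
        # configured mix makes C>T the most common substitution
        assert tables.snv_counts.sum(axis=0).idxmax() == "C>T"
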