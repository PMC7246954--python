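"""Composition-bias statistics: exact tests, FDR, power flags, stratification."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_record, random_protein
from oracles import bh_stepup, binom_two_sided, fisher_two_sided
from termbias.bias import (
    abundance_bins,
    dipeptide_bias,
    flag_underpowered,
    pair_epistasis,
    partition_regions,
    position_bias,
    sample_odds_ratio,
    stop_context_bias,
    stratified_bias,
    third_base_comparison,
)
from termbias.proteome import detect_downstream_start_overlap
from termbias.simulate import AMINO_ACIDS, ProteomeConfig, gen_proteome


class TestPartitionRegions:
    def test_50mer_splits_20_10_20(self):
        part = partition_regions("A" * 20 + "B" * 10 + "C" * 20)
        assert (len(part.nterm), len(part.bulk), len(part.cterm)) == (20, 10, 20)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            partition_regions("A" * 41)

    def test_100mer_bulk_is_middle(self):
        seq = "".join(AMINO_ACIDS[i % 20] for i in range(100))
        part = partition_regions(seq)
        assert part.bulk == seq[20:80]
        assert part.nterm + part.bulk + part.cterm == seq


class TestPositionBias:
    def test_published_cog_example_odds_ratio(self):
        # terminal frequency 16.2% vs bulk 6.01% gives odds ratio 3.02
        a, n_term = 162, 1000
        c, n_bulk = 601, 10000
        orr = sample_odds_ratio(a, n_term - a, c, n_bulk - c)
        assert round(orr, 2) == 3.02

    def test_fisher_p_matches_enumeration(self):
        rng = np.random.default_rng(0)
        seqs = [random_protein(rng, 45) for _ in range(25)]
        df = position_bias(seqs, positions=[-1], underpowered=False)
        # obs margins are small here; check each cell against the oracle
        for row in df.itertuples(index=False):
            expected = fisher_two_sided(
                row.obs_count,
                row.obs_total - row.obs_count,
                row.bulk_count,
                row.bulk_total - row.bulk_count,
            )
            assert row.p_value == pytest.approx(expected, rel=1e-8)

    def test_small_table_against_bruteforce(self):
        # 2x2 table [[3,7],[10,90]]
        from scipy.stats import fisher_exact

        _, p = fisher_exact([[3, 7], [10, 90]])
        assert p == pytest.approx(fisher_two_sided(3, 7, 10, 90), rel=1e-10)

    def test_null_proteome_calibration(self, null_proteome):
        table, _ = null_proteome
        df = position_bias(table.records, positions=list(range(-5, 0)), underpowered=False)
        assert df["significant"].mean() <= 0.05

    def test_null_calibration_across_seeds(self):
        fractions = []
        for seed in range(6):
            table, _ = gen_proteome(ProteomeConfig(n_genes=600, seed=100 + seed))
            df = position_bias(table.records, positions=[-2, -1], underpowered=False)
            fractions.append(df["significant"].mean())
        ncells = 40
        assert np.mean(fractions) <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / (ncells * len(fractions)))

    def test_bh_matches_stepup_rule(self, null_proteome):
        table, _ = null_proteome
        df = position_bias(table.records, positions=[-3, -2, -1], underpowered=False)
        expected = bh_stepup(df["p_value"].tolist(), alpha=0.05)
        assert df["significant"].tolist() == expected

    def test_counts_sum_to_contributing_sequences(self, null_proteome):
        table, _ = null_proteome
        df = position_bias(table.records, positions=[-2, -1], underpowered=False)
        for _, sub in df.groupby("position"):
            assert sub["obs_count"].sum() == sub["obs_total"].iloc[0]
        assert df.groupby("position")["bulk_count"].sum().nunique() == 1

    def test_injected_multiplier_recovered_as_odds_ratio(self):
        # under the i.i.d. generator the sample odds ratio estimates mu exactly
        mu = 2.0
        table, _ = gen_proteome(
            ProteomeConfig(n_genes=20000, mu={"K": {-1: mu}}, seed=21)
        )
        df = position_bias(table.records, positions=[-1], underpowered=False)
        est = df.loc[df["symbol"] == "K", "odds_ratio"].iloc[0]
        assert abs(est - mu) / mu < 0.10

    def test_codon_alphabet(self, null_proteome):
        table, _ = null_proteome
        df = position_bias(table.records, alphabet="codon", positions=[-1], underpowered=False)
        assert df["symbol"].str.len().eq(3).all()
        assert df.loc[df["position"] == -1, "obs_count"].sum() == df["obs_total"].iloc[0]


class TestFlagUnderpowered:
    def test_large_counts_not_flagged(self):
        assert flag_underpowered(bulk_count=500, bulk_total=10000, obs_total=10000) is False

    def test_tiny_expected_count_flagged(self):
        # N=20, f=0.01: expected 0.2 terminal observations
        assert flag_underpowered(bulk_count=10, bulk_total=1000, obs_total=20) is True

    def test_zero_bulk_frequency_flagged(self):
        assert flag_underpowered(bulk_count=0, bulk_total=1000, obs_total=100) is True

    def test_single_sequence_group_all_flagged(self):
        rng = np.random.default_rng(5)
        df = position_bias([random_protein(rng, 60)], positions=[-1])
        assert df["underpowered"].all()


class TestDipeptideBias:
    def test_terminal_pair_and_bulk_window_counts(self):
        # constructed set where cell counts can be enumerated by hand
        seqs = []
        rng = np.random.default_rng(6)
        for i in range(30):
            body = random_protein(rng, 43)
            seqs.append(body + ("KK" if i < 12 else "AD"))
        df = dipeptide_bias(seqs)
        kk = df[df["symbol"] == "KK"].iloc[0]
        assert kk["obs_count"] == 12
        assert kk["obs_total"] == 30
        # bulk windows: each 45-mer has bulk 20..25 (5 residues, 4 windows)
        assert df["bulk_total"].iloc[0] == 30 * 4
        bulk_kk = sum(
            s[20:25].count("KK") + sum(s[i : i + 2] == "KK" for i in range(20, 24))
            for s in [q[:45] for q in seqs]
        )
        # count via an independent sliding scan
        expect = sum(1 for s in seqs for i in range(20, 24) if s[i : i + 2] == "KK")
        assert kk["bulk_count"] == expect

    def test_absent_bulk_pair_gives_inf_sentinel(self):
        rng = np.random.default_rng(7)
        seqs = [random_protein(rng, 43).replace("W", "A") + "WW" for _ in range(10)]
        df = dipeptide_bias(seqs)
        ww = df[df["symbol"] == "WW"].iloc[0]
        assert math.isinf(ww["odds_ratio"])
        assert 0 <= ww["p_value"] <= 1


class TestPairEpistasis:
    def test_binomial_p_matches_enumeration(self):
        rng = np.random.default_rng(8)
        seqs = [random_protein(rng, 10) for _ in range(60)]
        df = pair_epistasis(seqs)
        n = 60
        for row in df.head(25).itertuples(index=False):
            assert row.p_value == pytest.approx(
                binom_two_sided(row.obs_count, n, row.expected_freq), rel=1e-8
            )

    def test_independent_construction_ratio_near_one(self):
        rng = np.random.default_rng(9)
        aas = list(AMINO_ACIDS)
        seqs = [
            "M" * 8 + str(rng.choice(aas)) + str(rng.choice(aas)) for _ in range(30000)
        ]
        df = pair_epistasis(seqs)
        big = df[df["obs_count"] >= 50]
        assert (np.abs(np.log(big["ratio"])) < np.log(1.5)).mean() > 0.95

    def test_injected_pair_excess_recovered(self):
        from termbias.simulate import gen_pair_biased_termini

        seqs = gen_pair_biased_termini(50000, pair=("K", "K"), excess=1.8, seed=10)
        df = pair_epistasis(seqs)
        est = df.loc[df["pair"] == "KK", "ratio"].iloc[0]
        assert abs(est - 1.8) / 1.8 < 0.15

    def test_pair_generator_marginals_unshifted(self):
        from termbias.simulate import gen_pair_biased_termini

        seqs = gen_pair_biased_termini(50000, pair=("K", "K"), excess=1.8, seed=11)
        fk1 = np.mean([s[-1] == "K" for s in seqs])
        fk2 = np.mean([s[-2] == "K" for s in seqs])
        assert abs(fk1 - 0.05) < 0.005
        assert abs(fk2 - 0.05) < 0.005


class TestStratifiedBias:
    def test_single_group_equals_position_bias(self, null_proteome):
        table, _ = null_proteome
        grouping = {r.protein_id: "all" for r in table}
        strat = stratified_bias(table.records, grouping, positions=[-1])
        direct = position_bias(table.records, positions=[-1])
        pd.testing.assert_frame_equal(
            strat["all"].reset_index(drop=True), direct.reset_index(drop=True)
        )

    def test_per_group_injection_recovered(self):
        t1, _ = gen_proteome(ProteomeConfig(n_genes=8000, mu={"K": {-1: 2.5}}, seed=31))
        t2, _ = gen_proteome(ProteomeConfig(n_genes=8000, mu={"K": {-1: 1.0}}, seed=32, genome_id="s2"))
        records = t1.records + t2.records
        grouping = {r.protein_id: r.genome_id for r in records}
        # ids collide between the two synthetic genomes; relabel
        for i, r in enumerate(records):
            r.protein_id = f"r{i}"
        grouping = {r.protein_id: r.genome_id for r in records}
        strat = stratified_bias(records, grouping, positions=[-1])
        or1 = strat["synth"].query("symbol == 'K'")["odds_ratio"].iloc[0]
        or2 = strat["s2"].query("symbol == 'K'")["odds_ratio"].iloc[0]
        assert abs(or1 - 2.5) / 2.5 < 0.15
        assert abs(or2 - 1.0) < 0.15


class TestAbundanceBins:
    def test_decile_labels(self):
        recs = [make_record("A" * 60, protein_id=f"p{i}", genome_id="sp") for i in range(10)]
        ppm = {f"p{i}": float(i + 1) for i in range(10)}
        labels = abundance_bins(recs, ppm)
        assert {p for p, l in labels.items() if l == "low"} == {"p0", "p1"}
        assert {p for p, l in labels.items() if l == "high"} == {"p8", "p9"}

    def test_low_coverage_species_excluded(self):
        recs = [make_record("A" * 60, protein_id=f"p{i}", genome_id="sp") for i in range(10)]
        ppm = {f"p{i}": 1.0 * i for i in range(3)}  # 30% coverage
        assert abundance_bins(recs, ppm) == {}

    def test_multiple_matches_averaged(self):
        recs = [make_record("A" * 60, protein_id=f"p{i}", genome_id="sp") for i in range(5)]
        ppm = {"p0": [1.0, 3.0], "p1": 4.0, "p2": 5.0, "p3": 6.0, "p4": 10.0}
        labels = abundance_bins(recs, ppm)
        assert labels["p0"] == "low"  # mean 2.0 is the minimum


class TestStopContext:
    def test_all_same_stop_equals_position_bias(self, null_proteome):
        table, _ = null_proteome
        recs = [r for r in table if r.stop_codon == "TAA"]
        tables = stop_context_bias(recs)
        assert set(tables) == {"TAA"}
        direct = position_bias(recs, alphabet="codon", positions=[-1])
        pd.testing.assert_frame_equal(
            tables["TAA"].reset_index(drop=True), direct.reset_index(drop=True)
        )

    def test_empty_class_absent(self, null_proteome):
        table, _ = null_proteome
        recs = [r for r in table if r.stop_codon != "TGA"]
        assert "TGA" not in stop_context_bias(recs)

    def test_overlap_driven_nna_preference_vanishes_on_exclusion(self):
        table, truth = gen_proteome(
            ProteomeConfig(n_genes=6000, overlap_fraction=0.12, seed=41)
        )
        flags = detect_downstream_start_overlap(table)
        assert {p for p, f in flags.items() if f} >= set(truth["overlap_ids"])
        with_overlap = stop_context_bias(table.records)["TGA"]
        without = stop_context_bias(
            table.records, exclude_overlap=True, overlap_flags=flags
        )["TGA"]
        before = third_base_comparison(with_overlap)
        after = third_base_comparison(without)
        assert before["nna_vs_others"]["p"] < 1e-4
        assert before["mean_log2_or"]["A"] > after["mean_log2_or"]["A"]
        assert after["nna_vs_others"]["p"] > 0.01


class TestThirdBase:
    def _table(self, ors):
        return pd.DataFrame(
            {"symbol": list(ors), "position": -1, "odds_ratio": list(ors.values())}
        )

    def test_equal_ors_give_null_contrast(self):
        ors = {c: 1.7 for c in ("AAA", "AAG", "CCA", "CCG", "GGA", "GGG")}
        res = third_base_comparison(self._table(ors))
        assert res["nna_vs_others"] == {"t": 0.0, "p": 1.0, "n_a": 3, "n_b": 3}

    def test_shifted_nna_detected(self):
        rng = np.random.default_rng(12)
        symbols = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
        ors = {}
        for s in symbols:
            shift = 0.5 if s.endswith("A") else 0.0
            ors[s] = 2 ** (rng.normal(0, 0.1) + shift)
        res = third_base_comparison(self._table(ors))
        assert res["nna_vs_others"]["p"] < 1e-6
        assert res["nna_vs_others"]["t"] > 0

    def test_small_partition_reported_missing(self):
        res = third_base_comparison(self._table({"AAA": 1.2, "CCG": 0.8}))
        assert math.isnan(res["nna_vs_others"]["t"])
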