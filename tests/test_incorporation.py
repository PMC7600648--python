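"""PSM filtering, incorporation shares, pairing, Top3 and enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cansilac.incorporation import (
    filter_quantifiable,
    incorporation_summary,
    labeled_set_abundance_test,
    pair_effect_stats,
    pair_variants,
    parse_site_states,
    set_enrichment,
    site_inventory,
    top3_quant,
)

from conftest import make_record, records_frame


class TestFilterQuantifiable:
    def test_toy_table(self):
        rows = [
            make_record(sequence="GASDK", site_states=()),  # no Arg
            make_record(sequence="TTTLK", site_states=()),  # no Arg
            make_record(sequence="AADRK", site_states=("H",), pep=0.05),  # bad PEP
            make_record(sequence="AADRK", site_states=("H",)),
            make_record(sequence="AAERK", site_states=("CAV",)),
            make_record(sequence="ARDRK", site_states=("H", "L")),
        ]
        kept = filter_quantifiable(records_frame(rows))
        assert len(kept) == 3
        assert (kept["pep"] <= 0.01).all()

    def test_threshold_is_inclusive(self):
        rows = [make_record(pep=0.01), make_record(pep=0.0100001)]
        assert len(filter_quantifiable(records_frame(rows))) == 1

    def test_parses_string_site_states(self):
        df = records_frame([make_record(sequence="ARDRK")])
        df["site_states"] = ["H,CAV"]
        kept = filter_quantifiable(df)
        assert kept["site_states"].iloc[0] == ("H", "CAV")

    def test_rejects_unknown_state(self):
        with pytest.raises(ValueError, match="unknown label state"):
            parse_site_states("H,X")


class TestIncorporationSummary:
    def test_hand_computed_shares(self, single_run_hl_records):
        summary = incorporation_summary(single_run_hl_records)
        t = summary.table.set_index("state")
        assert t.loc["H", "id_share"] == pytest.approx(50.0)
        assert t.loc["CAV", "id_share"] == pytest.approx(50.0)
        assert t.loc["H", "intensity_share"] == pytest.approx(90.0)
        assert t.loc["CAV", "intensity_share"] == pytest.approx(10.0)

    def test_all_heavy_input(self):
        rows = [make_record(site_states=("H",)) for _ in range(5)]
        t = incorporation_summary(records_frame(rows)).table.set_index("state")
        assert t.loc["H", "id_share"] == pytest.approx(100.0)
        assert t.loc["L", "id_share"] == 0.0
        assert t.loc["CAV", "intensity_share"] == 0.0

    def test_shares_sum_to_hundred_both_conventions(self):
        rng = np.random.default_rng(3)
        rows = []
        for run in ("r1", "r2", "r3"):
            for _ in range(30):
                state = rng.choice(["H", "L", "CAV"])
                rows.append(
                    make_record(
                        run=run,
                        site_states=(state, state),
                        sequence="ARDRK",
                        intensity=float(rng.lognormal(10, 1)),
                    )
                )
        for convention in ("site", "peptide"):
            t = incorporation_summary(records_frame(rows), convention).table
            for cond, g in t.groupby("condition"):
                assert g["id_share"].sum() == pytest.approx(100.0, abs=1e-6)
                assert g["intensity_share"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_invariant_under_global_rescaling(self, single_run_hl_records):
        base = incorporation_summary(single_run_hl_records).table
        scaled = single_run_hl_records.copy()
        scaled["intensity"] *= 37.5
        rescaled = incorporation_summary(scaled).table
        pd.testing.assert_frame_equal(base, rescaled)

    def test_per_state_rescaling_moves_intensity_share_only(
        self, single_run_hl_records
    ):
        base = incorporation_summary(single_run_hl_records).table.set_index("state")
        scaled = single_run_hl_records.copy()
        is_cav = scaled["site_states"].map(lambda s: "CAV" in s)
        scaled.loc[is_cav, "intensity"] *= 9.0
        t = incorporation_summary(scaled).table.set_index("state")
        assert t["id_share"].equals(base["id_share"])
        assert t.loc["CAV", "intensity_share"] == pytest.approx(50.0)

    def test_single_run_sd_absent_not_zero(self, single_run_hl_records):
        t = incorporation_summary(single_run_hl_records).table
        assert t["id_sd"].isna().all()
        assert t["intensity_sd"].isna().all()

    def test_replicate_sd_from_across_run_spread(self):
        rows = [
            make_record(run="r1", site_states=("H",), intensity=90.0),
            make_record(run="r1", site_states=("CAV",), intensity=10.0),
            make_record(run="r2", site_states=("H",), intensity=80.0),
            make_record(run="r2", site_states=("CAV",), intensity=20.0),
        ]
        t = incorporation_summary(records_frame(rows)).table.set_index("state")
        assert t.loc["CAV", "intensity_share"] == pytest.approx(15.0)
        assert t.loc["CAV", "intensity_sd"] == pytest.approx(
            np.std([10.0, 20.0], ddof=1)
        )

    def test_zero_observation_condition_errors(self):
        df = records_frame([make_record(sequence="GASDK", site_states=())])
        with pytest.raises(ValueError, match="no Arg/canavanine"):
            incorporation_summary(df)

    def test_peptide_convention_rejects_mixed_records(self):
        df = records_frame([make_record(sequence="ARDRK", site_states=("H", "CAV"))])
        with pytest.raises(ValueError, match="mixed-state"):
            incorporation_summary(df, convention="peptide")


class TestSiteInventory:
    def test_toy_counts(self):
        rows = [
            make_record(run="r1", sequence="AARTK", site_states=("CAV",),
                        proteins="P1", start=10),
            make_record(run="r2", sequence="AARTK", site_states=("CAV",),
                        proteins="P1", start=10),
            make_record(run="r1", sequence="RRTTK", site_states=("CAV", "CAV"),
                        proteins="P1", start=1),
            make_record(run="r1", sequence="TTRK", site_states=("CAV",),
                        proteins="P2", start=5),
            make_record(run="r2", sequence="TTRK", site_states=("CAV",),
                        proteins="P2", start=5),
        ]
        inv = site_inventory(records_frame(rows))
        assert inv["n_cav_sequences"] == 3
        assert inv["n_cav_sites"] == 4
        assert inv["unmapped_sequences"] == []

    def test_unmappable_peptide_flagged(self):
        rows = [
            make_record(sequence="AARTK", site_states=("CAV",),
                        proteins="P1;P2", start=np.nan)
        ]
        inv = site_inventory(records_frame(rows))
        assert inv["n_cav_sequences"] == 1
        assert inv["n_cav_sites"] == 0
        assert inv["unmapped_sequences"] == ["AARTK"]


class TestPairVariants:
    def test_toy_enumeration(self, pairing_records):
        pairs = pair_variants(pairing_records)
        assert len(pairs) == 4
        assert set(pairs["sequence"]) == {"AADRK", "ARDRK"}

    def test_ratio_definition(self, pairing_records):
        pairs = pair_variants(pairing_records)
        one = pairs[(pairs["sequence"] == "AADRK") & (pairs["run"] == "r1")]
        assert one["intensity_ratio"].iloc[0] == pytest.approx(7.0)

    def test_cav_only_group_yields_no_pair(self):
        df = records_frame([make_record(site_states=("CAV",))])
        assert len(pair_variants(df)) == 0

    def test_permutation_invariance(self, pairing_records):
        shuffled = pairing_records.sample(frac=1.0, random_state=5).reset_index(
            drop=True
        )
        a = pair_variants(pairing_records).reset_index(drop=True)
        b = pair_variants(shuffled).reset_index(drop=True)
        key = ["sequence", "run", "cav_intensity"]
        pd.testing.assert_frame_equal(
            a.sort_values(key).reset_index(drop=True),
            b.sort_values(key).reset_index(drop=True),
        )


class TestPairEffectStats:
    def test_identical_variants_null_summaries(self):
        rows = []
        for i in range(10):
            rows.append(make_record(run="r1", sequence=f"AAD{'G'*i}RK",
                                    site_states=("H",), intensity=50.0, rt_min=30.0))
            rows.append(make_record(run="r1", sequence=f"AAD{'G'*i}RK",
                                    site_states=("CAV",), intensity=50.0, rt_min=30.0))
        stats_out = pair_effect_stats(pair_variants(records_frame(rows)))
        assert stats_out["median_intensity_ratio"] == pytest.approx(1.0)
        assert stats_out["median_rt_delta_min"] == 0.0
        assert stats_out["rt_wilcoxon_p"] == 1.0
        assert not stats_out["rt_significant"]

    def test_planted_rt_shift_detected(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(200):
            rt = float(rng.uniform(20, 80))
            seq = f"AAD{'G' * (i % 7)}R{'A' * (i // 7)}K"
            rows.append(make_record(run="r1", sequence=seq, site_states=("H",),
                                    intensity=100.0, rt_min=rt))
            rows.append(make_record(run="r1", sequence=seq, site_states=("CAV",),
                                    intensity=20.0,
                                    rt_min=rt + 0.5 + float(rng.normal(0, 0.2))))
        out = pair_effect_stats(pair_variants(records_frame(rows)))
        assert out["n_pairs"] == 200
        assert out["rt_wilcoxon_p"] < 0.05
        assert out["rt_significant"]

    def test_few_pairs_skips_tests(self, pairing_records):
        out = pair_effect_stats(pair_variants(pairing_records))
        assert out["tests"].startswith("skipped")

    def test_zero_cav_intensity_excluded_with_warning(self):
        rows = []
        for i in range(6):
            seq = f"AAD{'G'*i}RK"
            rows.append(make_record(sequence=seq, site_states=("H",), intensity=50.0))
            rows.append(make_record(sequence=seq, site_states=("CAV",),
                                    intensity=0.0 if i == 0 else 10.0))
        with pytest.warns(UserWarning, match="zero canavanine"):
            out = pair_effect_stats(pair_variants(records_frame(rows)))
        assert out["median_intensity_ratio"] == pytest.approx(5.0)


def brute_force_top3(peptide_intensities):
    ordered = sorted(peptide_intensities, reverse=True)
    top = ordered[: min(3, len(ordered))]
    return sum(top) / len(top)


class TestTop3:
    def test_hand_examples(self):
        assert brute_force_top3([40, 30, 20, 10]) == 30
        assert brute_force_top3([10, 20]) == 15

    def test_mean_of_top_three(self):
        rows = [
            make_record(sequence=s, site_states=("H",), proteins="P1",
                        proteotypic=True, intensity=v)
            for s, v in [("AAARK", 40.0), ("CCCRK", 30.0), ("DDDRK", 20.0),
                         ("EEERK", 10.0)]
        ]
        out = top3_quant(records_frame(rows))
        assert out["top3_abundance"].iloc[0] == pytest.approx(30.0)
        assert out["n_proteotypic_peptides"].iloc[0] == 4

    def test_two_peptides_mean_of_two(self):
        rows = [
            make_record(sequence="AAARK", proteins="P1", intensity=10.0),
            make_record(sequence="CCCRK", proteins="P1", intensity=20.0),
        ]
        out = top3_quant(records_frame(rows))
        assert out["top3_abundance"].iloc[0] == pytest.approx(15.0)

    def test_single_peptide_protein_excluded(self):
        rows = [make_record(sequence="AAARK", proteins="P1", intensity=10.0)]
        assert len(top3_quant(records_frame(rows))) == 0

    def test_peptide_intensity_is_max_over_features(self):
        rows = [
            make_record(sequence="AAARK", proteins="P1", intensity=10.0, charge=2),
            make_record(sequence="AAARK", proteins="P1", intensity=30.0, charge=3),
            make_record(sequence="CCCRK", proteins="P1", intensity=20.0),
        ]
        out = top3_quant(records_frame(rows))
        assert out["top3_abundance"].iloc[0] == pytest.approx(25.0)

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(12)
        sequences = [f"AA{aa}{bb}RK" for aa in "ACDEFGHILM" for bb in "ACDEFGHILM"]
        for _ in range(100):
            rows = []
            expected = {}
            for p in range(rng.integers(1, 6)):
                protein = f"P{p}"
                n_pep = int(rng.integers(1, 8))
                peps = rng.choice(len(sequences), size=n_pep, replace=False)
                intensities = rng.lognormal(10, 2, size=n_pep)
                for s, v in zip(peps, intensities):
                    rows.append(
                        make_record(sequence=sequences[s], proteins=protein,
                                    proteotypic=True, intensity=float(v))
                    )
                if n_pep >= 2:
                    expected[protein] = brute_force_top3(list(intensities))
            out = top3_quant(records_frame(rows)).set_index("protein")
            assert set(out.index) == set(expected)
            for protein, value in expected.items():
                assert out.loc[protein, "top3_abundance"] == pytest.approx(value)


class TestLabeledSetTest:
    @staticmethod
    def abundance_frame(labeled, unlabeled):
        rows = [{"protein": f"L{i}", "top3_abundance": v,
                 "n_proteotypic_peptides": 2, "cav_labeled": True}
                for i, v in enumerate(labeled)]
        rows += [{"protein": f"U{i}", "top3_abundance": v,
                  "n_proteotypic_peptides": 2, "cav_labeled": False}
                 for i, v in enumerate(unlabeled)]
        return pd.DataFrame(rows)

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(1)
        values = rng.lognormal(10, 1, size=100)
        out = labeled_set_abundance_test(self.abundance_frame(values, values))
        assert out["p_value"] > 0.9
        assert out["direction"] == "none"

    def test_shifted_group_detected_positive(self):
        rng = np.random.default_rng(2)
        base = rng.lognormal(10, 1, size=200)
        shifted = rng.lognormal(11, 1, size=200)
        out = labeled_set_abundance_test(self.abundance_frame(shifted, base))
        assert out["p_value"] < 1e-6
        assert out["direction"] == "positive"

    def test_u_statistic_matches_exhaustive_enumeration(self):
        labeled = [3.1, 9.4, 1.2, 7.7]
        unlabeled = [2.2, 5.5, 8.8, 0.4]
        out = labeled_set_abundance_test(self.abundance_frame(labeled, unlabeled))
        u_brute = sum(
            1.0 if x > y else (0.5 if x == y else 0.0)
            for x in labeled
            for y in unlabeled
        )
        assert out["U"] == u_brute
        # exact two-sided p by enumerating all 4-vs-4 group assignments
        pooled = labeled + unlabeled
        n1 = len(labeled)
        u_obs = max(u_brute, n1 * len(unlabeled) - u_brute)
        count = total = 0
        for idx in itertools.combinations(range(len(pooled)), n1):
            g1 = [pooled[i] for i in idx]
            g2 = [pooled[i] for i in range(len(pooled)) if i not in idx]
            u = sum(1.0 if x > y else (0.5 if x == y else 0.0)
                    for x in g1 for y in g2)
            total += 1
            if max(u, n1 * len(g2) - u) >= u_obs:
                count += 1
        assert out["p_value"] == pytest.approx(count / total, abs=1e-12)

    def test_small_group_skips_test(self):
        out = labeled_set_abundance_test(
            self.abundance_frame([1.0, 2.0], [3.0, 4.0, 5.0])
        )
        assert out["test"].startswith("skipped")


def brute_force_hypergeom_tail(k, N, K, n):
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
    ) / total


class TestSetEnrichment:
    def test_foreground_equals_background_nothing_enriched(self):
        proteins = [f"P{i}" for i in range(50)]
        annotation = {"T1": proteins[:10], "T2": proteins[5:30]}
        out = set_enrichment(proteins, proteins, annotation)
        assert len(out) == 0

    def test_planted_term_enriched(self):
        bg = [f"P{i}" for i in range(2000)]
        fg = bg[:100]
        term = fg[:50] + bg[1000:1050]  # 50% of fg, 5% of bg
        out = set_enrichment(fg, bg, {"planted": term, "null": bg[500:600]})
        assert list(out["term"]) == ["planted"]
        assert out["fold_enrichment"].iloc[0] == pytest.approx(10.0)

    def test_p_matches_brute_force_tail(self):
        bg = [f"P{i}" for i in range(100)]
        fg = bg[:20]
        term = bg[:10] + bg[50:60]  # K=20 overall, k=10 in fg
        out = set_enrichment(fg, bg, {"T": term}, fdr=1.0)
        expected = brute_force_hypergeom_tail(10, 100, 20, 20)
        assert out["p"].iloc[0] == pytest.approx(expected, rel=1e-10)

    def test_scipy_tail_matches_brute_force_on_random_configs(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            N = int(rng.integers(20, 200))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(0, min(K, n) + 1))
            assert stats.hypergeom.sf(k - 1, N, K, n) == pytest.approx(
                brute_force_hypergeom_tail(k, N, K, n), rel=1e-9, abs=1e-300
            )

    def test_foreground_outside_background_rejected(self):
        with pytest.raises(ValueError, match="not a subset"):
            set_enrichment(["X"], ["A", "B"], {"T": ["A"]})
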