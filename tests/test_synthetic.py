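"""Synthetic cohort generator: templates, determinism, planted effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from til_subtyper.features import cell_density
from til_subtyper.gating import gate_events
from til_subtyper.synthetic_data import (
    PROFILES,
    default_cohort_spec,
    expected_clone_entropy,
    profile_population_specs,
    simulate_clinical,
    simulate_cohort,
    simulate_expression,
    simulate_fcm_sample,
    simulate_tcr,
)
from til_subtyper.tcr import shannon_entropy


class TestTemplates:
    def test_study_luad_counts(self):
        spec = default_cohort_spec("study_luad")
        by_subtype = {s: n for _, s, n in spec.groups}
        assert by_subtype == {"Cold": 19, "Myeloid": 36, "CD8": 30}
        assert spec.n_samples == 85

    def test_study_lusq_total(self):
        assert default_cohort_spec("study_lusq").n_samples == 50

    def test_study_full_adds_nats(self):
        spec = default_cohort_spec("study_full")
        nat = sum(n for h, _, n in spec.groups if h == "NAT")
        assert nat == 157
        assert spec.n_samples == 85 + 50 + 157

    def test_mini_is_small_with_all_subtypes(self):
        spec = default_cohort_spec("mini")
        assert spec.n_samples <= 30
        assert {s for _, s, _ in spec.groups} >= {"Cold", "Myeloid", "CD8"}

    def test_unknown_template_lists_alternatives(self):
        with pytest.raises(ValueError, match="study_luad"):
            default_cohort_spec("bogus")


class TestFcmSample:
    def test_zero_events_rejected(self, tree):
        specs, _ = profile_population_specs(PROFILES["CD8"], tree)
        with pytest.raises(ValueError, match="n_events"):
            simulate_fcm_sample(specs, 0, 1.0, seed=0, tree=tree)

    def test_fractions_must_sum_to_one(self, tree):
        import dataclasses

        specs, _ = profile_population_specs(PROFILES["CD8"], tree)
        bad = [dataclasses.replace(specs[0], expected_fraction_of_events=0.5)]
        with pytest.raises(ValueError, match="sum"):
            simulate_fcm_sample(bad, 100, 1.0, seed=0, tree=tree)

    def test_unknown_marker_rejected(self, tree):
        import dataclasses

        specs, _ = profile_population_specs(PROFILES["CD8"], tree)
        means = dict(specs[0].mean_log_intensity)
        means["CD999"] = 1.0
        bad = [dataclasses.replace(
            specs[0], mean_log_intensity=means, expected_fraction_of_events=1.0)]
        with pytest.raises(ValueError, match="panel"):
            simulate_fcm_sample(bad, 100, 1.0, seed=0, tree=tree)

    def test_degenerate_single_population_gets_every_event(self, tree):
        import dataclasses

        specs, _ = profile_population_specs(PROFILES["CD8"], tree)
        one = [dataclasses.replace(specs[0], expected_fraction_of_events=1.0)]
        _, truth = simulate_fcm_sample(one, 1000, 1.0, seed=0, tree=tree)
        assert truth[one[0].population_id] == 1000

    def test_true_counts_within_multinomial_envelope(self, tree):
        # 0.3/0.7 at n=10000: 99% envelope is p +/- 2.576*sqrt(p(1-p)/n)
        import dataclasses

        specs, _ = profile_population_specs(PROFILES["CD8"], tree)
        two = [
            dataclasses.replace(specs[0], expected_fraction_of_events=0.3),
            dataclasses.replace(specs[1], expected_fraction_of_events=0.7),
        ]
        _, truth = simulate_fcm_sample(two, 10_000, 1.0, seed=11, tree=tree)
        margin = 2.576 * np.sqrt(0.3 * 0.7 / 10_000) * 10_000
        assert abs(truth[two[0].population_id] - 3000) < margin

    def test_contaminants_only_add_events(self, tree):
        import dataclasses

        specs, _ = profile_population_specs(PROFILES["CD8"], tree)
        one = [dataclasses.replace(specs[0], expected_fraction_of_events=1.0)]
        events, truth = simulate_fcm_sample(
            one, 1000, 1.0, seed=0, dead_fraction=0.1, epithelial_fraction=0.2,
            tree=tree)
        assert len(events) == 1000
        assert truth[one[0].population_id] == 700


class TestCohort:
    def test_same_seed_reproduces_byte_identical_events(self, tree):
        spec = default_cohort_spec("mini")
        spec.seed = 3
        c1, t1 = simulate_cohort(spec, tree)
        c2, t2 = simulate_cohort(spec, tree)
        sid = c1.sample_ids[0]
        pd.testing.assert_frame_equal(c1.events(sid), c2.events(sid))
        pd.testing.assert_frame_equal(t1.population_counts, t2.population_counts)

    def test_cold_samples_have_lowest_total_density(self, mini_cohort):
        _, truth = mini_cohort
        dens = pd.Series({
            sid: cell_density(int(row["total_cd45"]), truth.masses[sid])
            for sid, row in truth.population_counts.iterrows()
        })
        by = dens.groupby(truth.labels["subtype"]).mean()
        assert by["Cold"] < by[["Myeloid", "CD8"]].min()

    def test_gating_recovers_planted_fractions_within_3_points(
        self, tree, mini_cohort, mini_counts
    ):
        _, truth = mini_cohort
        pct = mini_counts.div(mini_counts["total_cd45"], axis=0) * 100
        planted = truth.expected_fractions * 100
        tops = ["cd4_t", "cd8_t", "macrophage", "mmdsc", "cd14_monocyte",
                "b_cells", "nk_cells", "nkt"]
        err = (pct[tops] - planted[tops]).abs()
        assert err.to_numpy().max() < 3.0

    def test_truth_counts_match_gated_counts(self, tree, mini_cohort, mini_counts):
        # gates are >= 3 sd from every planted mode, so event misassignment
        # should be essentially absent at mini depth
        _, truth = mini_cohort
        diff = (mini_counts - truth.population_counts).abs()
        assert diff.to_numpy().max() <= 2


class TestExpression:
    def test_matrix_shape_and_nonnegativity(self):
        labels = pd.Series({"s1": "CD8", "s2": "Myeloid", "s3": "Cold"})
        tpm = simulate_expression(labels, seed=0)
        assert tpm.shape[1] == 3
        assert (tpm.to_numpy() >= 0).all()

    def test_unknown_subtype_rejected(self):
        with pytest.raises(ValueError, match="Hot"):
            simulate_expression(pd.Series({"s1": "Hot"}), seed=0)

    def test_null_config_gives_nominal_rejection_rate(self):
        # no planted effects: rank-sum test rejects at ~alpha
        labels = pd.Series(
            {f"a{i}": "CD8" for i in range(20)} | {f"b{i}": "Myeloid" for i in range(20)}
        )
        config = {f"G{i}": {} for i in range(60)}
        rej = 0
        tpm = simulate_expression(labels, gene_config=config, seed=1, n_background=0)
        for g in tpm.index:
            a = tpm.loc[g, labels == "CD8"]
            b = tpm.loc[g, labels == "Myeloid"]
            rej += stats.mannwhitneyu(a, b).pvalue < 0.05
        assert rej / len(tpm.index) < 0.15

    def test_ccl5_higher_in_cd8_across_replicates(self):
        labels = pd.Series(
            {f"c{i}": "CD8" for i in range(25)} | {f"m{i}": "Myeloid" for i in range(25)}
        )
        wins = 0
        for rep in range(20):
            tpm = simulate_expression(labels, seed=rep)
            wins += (
                tpm.loc["CCL5", labels == "CD8"].median()
                > tpm.loc["CCL5", labels == "Myeloid"].median()
            )
        assert wins >= 19


class TestTcr:
    def test_richness_one_puts_all_umis_in_one_clonotype(self):
        labels = pd.Series({"s1": "CD8"})
        t = simulate_tcr(labels, {"CD8": (1, 1.0)}, umi_depth=500, seed=0)
        tra = t[t.chain == "TRA"]
        assert len(tra) == 1
        assert tra.umi_count.iloc[0] == 500

    def test_equal_richness_centers_entropy_gap_at_zero(self):
        labels = pd.Series(
            {f"c{i}": "CD8" for i in range(12)} | {f"m{i}": "Myeloid" for i in range(12)}
        )
        cfg = {"CD8": (200, 0.5), "Myeloid": (200, 0.5)}
        gaps = []
        for rep in range(10):
            t = simulate_tcr(labels, cfg, umi_depth=3000, seed=rep)
            h = shannon_entropy(t)
            h = h[h.chain == "TRB"].set_index("sample_id")["entropy"]
            gaps.append(h[labels == "CD8"].mean() - h[labels == "Myeloid"].mean())
        assert abs(np.mean(gaps)) < 0.1

    def test_planted_half_nat_gap_recovered_within_015(self):
        # choose concentrations whose closed-form expected entropies differ
        # by ~0.5 nats at richness 600
        r = 600
        h_cd8 = expected_clone_entropy(r, 1.0)
        # solve for the Myeloid concentration giving h_cd8 - 0.5
        from scipy.optimize import brentq

        conc_m = brentq(lambda a: expected_clone_entropy(r, a) - (h_cd8 - 0.5),
                        1e-3, 1.0)
        planted_gap = h_cd8 - expected_clone_entropy(r, conc_m)
        assert planted_gap == pytest.approx(0.5, abs=1e-9)
        labels = pd.Series(
            {f"c{i}": "CD8" for i in range(4)} | {f"m{i}": "Myeloid" for i in range(4)}
        )
        cfg = {"CD8": (r, 1.0), "Myeloid": (r, conc_m)}
        gaps = []
        for rep in range(50):
            t = simulate_tcr(labels, cfg, umi_depth=10_000, seed=rep)
            h = shannon_entropy(t)
            h = h[h.chain == "TRB"].set_index("sample_id")["entropy"]
            gaps.append(h[labels == "CD8"].mean() - h[labels == "Myeloid"].mean())
        assert np.mean(gaps) == pytest.approx(0.5, abs=0.15)


class TestClinical:
    def test_nonpositive_hazard_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            simulate_clinical(pd.Series({"s": "CD8"}), {"CD8": 0.0}, seed=0)

    def test_full_censoring_zeroes_event_column(self):
        labels = pd.Series({f"s{i}": "CD8" for i in range(30)})
        clin = simulate_clinical(labels, censor_config={"prob": 1.0}, seed=0)
        assert clin["event"].sum() == 0
        assert (clin["efs_months"] > 0).all()

    def test_equal_hazards_give_uniform_logrank_p(self):
        from lifelines.statistics import logrank_test

        ps = []
        for rep in range(40):
            labels = pd.Series(
                {f"a{i}": "CD8" for i in range(30)}
                | {f"b{i}": "Myeloid" for i in range(30)}
            )
            clin = simulate_clinical(
                labels, {"CD8": 1.0, "Myeloid": 1.0}, seed=rep,
                factor_hazards=False,
            )
            a = clin[clin.subtype == "CD8"]
            b = clin[clin.subtype == "Myeloid"]
            ps.append(logrank_test(a.efs_months, b.efs_months,
                                   a.event, b.event).p_value)
        ps = np.asarray(ps)
        assert np.mean(ps < 0.05) < 0.2
        assert 0.2 < np.mean(ps < 0.5) < 0.8

    def test_triple_hazard_detected_in_most_replicates(self):
        from lifelines.statistics import logrank_test

        hits = 0
        reps = 60
        for rep in range(reps):
            labels = pd.Series(
                {f"a{i}": "CD8" for i in range(50)}
                | {f"b{i}": "Myeloid" for i in range(50)}
            )
            clin = simulate_clinical(labels, seed=rep)
            a = clin[clin.subtype == "CD8"]
            b = clin[clin.subtype == "Myeloid"]
            hits += logrank_test(a.efs_months, b.efs_months,
                                 a.event, b.event).p_value < 0.05
        assert hits / reps >= 0.8
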