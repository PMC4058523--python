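import numpy as np
import pandas as pd
import pytest
from scipy import stats

from helpers import make_net
from pomanet import (
    GroundTruth,
    RegulatorPlan,
    default_truth,
    generate_cohort,
    generate_reference_network,
    score_mirnas,
)
from pomanet.simulate import truth_table, write_truth


class TestGroundTruth:
    def test_default_plan_structure(self):
        t = default_truth()
        assert len(t.regulators) == 10
        assert len(t.planted_genes()) == 4 * 6 + 3 * 10
        assert len(t.planted_edges()) == 4 * 6 + 6 * 10
        assert t.biomarker_mirnas() == ["miR-001", "miR-002", "miR-003", "miR-004"]

    def test_expected_scores_match_plan(self):
        # regulator with 3 exclusive of 4 targets scores alpha 3, beta 4
        truth = GroundTruth(
            regulators=[
                RegulatorPlan("M1", exclusive_targets=("g1", "g2", "g3"),
                              shared_targets=("g4",)),
                RegulatorPlan("M2", shared_targets=("g4",)),
            ],
            shared_owners={"g4": ("M1", "M2")},
            n_mirna=5, n_gene=10,
        )
        exp = truth.expected_scores().set_index("mirna_id")
        assert exp.loc["M1", "alpha"] == 3
        assert exp.loc["M1", "beta"] == 4
        assert exp.loc["M1", "z"] == pytest.approx(0.75)
        # the same numbers must come out of the scorer on the planted network
        net = make_net(sorted(truth.planted_edges()))
        obs = score_mirnas(net).set_index("mirna_id")
        assert (obs.loc["M1", "alpha"], obs.loc["M1", "beta"]) == (3, 4)
        assert obs.loc["M1", "z"] == pytest.approx(0.75)

    @pytest.mark.parametrize(
        "regulators,shared_owners,msg",
        [
            (  # exclusive gene claimed by two regulators
                [RegulatorPlan("M1", exclusive_targets=("g1",)),
                 RegulatorPlan("M2", exclusive_targets=("g1",))],
                {}, "exclusive to multiple",
            ),
            (  # shared gene with a single owner
                [RegulatorPlan("M1", shared_targets=("g1",))],
                {"g1": ("M1", "M1")}, "exactly 2 distinct owners",
            ),
            (  # shared_owners inconsistent with plans
                [RegulatorPlan("M1", shared_targets=("g1",)),
                 RegulatorPlan("M2", shared_targets=("g1",))],
                {"g1": ("M1", "M3")}, "do not match",
            ),
            (  # gene both exclusive and shared
                [RegulatorPlan("M1", exclusive_targets=("g1",)),
                 RegulatorPlan("M2", shared_targets=("g1",))],
                {"g1": ("M1", "M2")}, "mixes exclusive and shared",
            ),
        ],
    )
    def test_infeasible_plans_rejected(self, regulators, shared_owners, msg):
        with pytest.raises(ValueError, match=msg):
            GroundTruth(regulators=regulators, shared_owners=shared_owners,
                        n_mirna=5, n_gene=10)


class TestCohort:
    def test_seed_reproducibility(self, small_truth):
        a = generate_cohort(small_truth, seed=3)
        b = generate_cohort(small_truth, seed=3)
        pd.testing.assert_frame_equal(a.mirna.data, b.mirna.data)
        pd.testing.assert_frame_equal(a.genes.data, b.genes.data)
        assert a.outlier_samples == b.outlier_samples
        c = generate_cohort(small_truth, seed=4)
        assert not np.allclose(a.mirna.values, c.mirna.values)

    def test_annotation_design(self, small_cohort):
        t = small_cohort.annotation.table
        assert (t["class_label"] == "control").sum() == 6
        assert (t["class_label"] == "case").sum() == 19

    def test_outlier_subsets_have_planned_size(self, small_truth, small_cohort):
        k = int(round(small_truth.outlier_fraction * 19))
        for reg, samples in small_cohort.outlier_samples.items():
            assert len(samples) == k
            classes = small_cohort.annotation.labels_for(samples)
            assert all(classes == "case")

    def test_co_owners_share_outlier_subset_and_direction(self, small_truth,
                                                          small_cohort):
        for a, b in small_truth.correlated_pairs():
            assert small_cohort.outlier_samples[a] == \
                small_cohort.outlier_samples[b]
            assert small_cohort.directions[a] == small_cohort.directions[b]
        # unpaired regulators draw their own subsets
        rich = small_truth.biomarker_mirnas()
        assert small_cohort.outlier_samples[rich[0]] != \
            small_cohort.outlier_samples[rich[1]]

    def test_too_small_outlier_subset_rejected(self):
        t = default_truth(n_rich=1, n_heavy_pairs=0, outlier_fraction=0.05)
        with pytest.raises(ValueError, match="< 2"):
            generate_cohort(t, n_case=19)

    def test_zero_effect_makes_planted_exchangeable_with_decoys(self):
        t = default_truth(n_mirna=40, n_gene=60, planted_effect=0.0)
        co = generate_cohort(t, seed=5)
        planted = co.mirna.data.loc[t.planted_mirnas()].to_numpy().ravel()
        decoys = co.mirna.data.drop(index=t.planted_mirnas()).to_numpy().ravel()
        # remove per-feature baselines before comparing distributions
        pl = planted - planted.mean()
        de = decoys - decoys.mean()
        assert stats.ks_2samp(pl, de).pvalue > 1e-3

    def test_generative_anticorrelation_calibration(self):
        # large balanced cohort, no shift: empirical inverse correlations
        # must match the analytic generative values
        t = default_truth(planted_effect=0.0)
        co = generate_cohort(t, n_control=400, n_case=400, seed=6)
        rho = t.generative_rho()
        m = co.mirna.data
        g = co.genes.data
        reg = t.regulators[0]  # exclusivity-rich
        for gene in reg.exclusive_targets[:2]:
            r = np.corrcoef(m.loc[reg.mirna_id], g.loc[gene])[0, 1]
            assert -r == pytest.approx(rho[(reg.mirna_id, gene)], abs=0.05)
        heavy = next(r for r in t.regulators if r.shared_targets)
        for gene in heavy.shared_targets[:2]:
            r = np.corrcoef(m.loc[heavy.mirna_id], g.loc[gene])[0, 1]
            assert -r == pytest.approx(rho[(heavy.mirna_id, gene)], abs=0.05)

    def test_partner_correlation_realized(self):
        t = default_truth(planted_effect=0.0)
        co = generate_cohort(t, n_control=400, n_case=400, seed=7)
        a, b = t.correlated_pairs()[0]
        r = np.corrcoef(co.mirna.data.loc[a], co.mirna.data.loc[b])[0, 1]
        assert r == pytest.approx(t.partner_correlation, abs=0.06)


class TestReferenceNetwork:
    def test_contains_all_planted_edges(self, small_truth, small_reference):
        assert small_truth.planted_edges() <= small_reference.edges

    def test_zero_extra_edges(self, small_truth):
        ref = generate_reference_network(small_truth, n_extra_edges=0, seed=0)
        assert ref.edges == small_truth.planted_edges()

    def test_exclusivity_plan_realized_in_reference(self, small_truth,
                                                    small_reference):
        indeg = {}
        for m, g in small_reference.edges:
            indeg[g] = indeg.get(g, 0) + 1
        for r in small_truth.regulators:
            for g in r.exclusive_targets:
                assert indeg[g] == 1
            for g in r.shared_targets:
                assert indeg[g] == 2

    def test_random_plans_realized_exactly(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            t = default_truth(
                n_mirna=int(rng.integers(10, 40)),
                n_gene=int(rng.integers(40, 120)),
                n_rich=int(rng.integers(1, 4)),
                exclusive_per_rich=int(rng.integers(2, 6)),
                n_heavy_pairs=int(rng.integers(0, 3)),
                shared_per_pair=int(rng.integers(2, 8)),
            )
            ref = generate_reference_network(
                t, n_extra_edges=int(rng.integers(0, 30)), seed=int(rng.integers(1e6))
            )
            indeg = {}
            for m, g in ref.edges:
                indeg[g] = indeg.get(g, 0) + 1
            for r in t.regulators:
                for g in r.exclusive_targets:
                    assert indeg[g] == 1
                for g in r.shared_targets:
                    assert indeg[g] == 2

    def test_decoy_budget_validated(self, small_truth):
        with pytest.raises(ValueError, match="decoy"):
            generate_reference_network(small_truth, n_extra_edges=10 ** 9, seed=0)


def test_truth_table_schema_and_write(tmp_path, small_truth):
    df = truth_table(small_truth)
    assert set(df["role"]) == {"exclusive", "shared"}
    assert set(df["regulator_class"]) == {"exclusivity_rich", "share_heavy"}
    assert len(df) == len(small_truth.planted_edges())
    write_truth(small_truth, tmp_path / "truth.tsv")
    back = pd.read_csv(tmp_path / "truth.tsv", sep="\t")
    assert len(back) == len(df)
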