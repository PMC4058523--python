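import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from helpers import exact_spearman_p
from pomanet import SampleAnnotation, screen_pairs, spearman, spearman_exact_p
from pomanet.correlation import _rank_zscores, passes_cutoffs
from pomanet.data_io import ExpressionMatrix
from pomanet.lsoss import OutlierResult


def fake_outlier(fid):
    return OutlierResult(
        feature_id=fid, statistic=5.0, split_index=1, outlier_subset=(),
        direction="up", p_value=0.01, q_value=0.01,
    )


def em(values, prefix, kind, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=[f"{prefix}{i}" for i in range(values.shape[0])],
                     columns=samples),
        feature_kind=kind, log_scale=True,
    )


def ann_for(samples, n_control=3):
    return SampleAnnotation(
        pd.DataFrame({
            "sample_id": samples,
            "class_label": ["control"] * n_control
            + ["case"] * (len(samples) - n_control),
            "pair_key": samples,
        })
    )


class TestSpearman:
    def test_perfect_antimonotone(self):
        rho, p = spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0, abs=1e-12)

    def test_perfect_comonotone(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_exact_p_matches_independent_enumeration(self):
        rng = np.random.default_rng(0)
        for n in (5, 6):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert spearman_exact_p(x, y) == pytest.approx(
                exact_spearman_p(x, y), abs=1e-12
            )

    def test_approx_p_close_to_exact_at_n7(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.normal(size=7)
            y = rng.normal(size=7)
            _, p_approx = spearman(x, y, method="approx")
            p_exact = spearman_exact_p(x, y)
            assert abs(p_approx - p_exact) <= 0.05

    @pytest.mark.parametrize(
        "transform", [np.exp, lambda v: v ** 3 + v, lambda v: 2 * v + 1]
    )
    def test_invariant_under_strictly_monotone_transforms(self, transform):
        rng = np.random.default_rng(2)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        rho0, _ = spearman(x, y)
        rho1, _ = spearman(transform(x), y)
        assert rho1 == pytest.approx(rho0, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])

    def test_short_vector_rejected(self):
        with pytest.raises(ValueError, match="n >= 4"):
            spearman([1, 2, 3], [3, 2, 1])

    def test_ties_match_scipy(self):
        rng = np.random.default_rng(3)
        x = np.round(rng.normal(size=20), 0)  # heavy ties
        y = np.round(rng.normal(size=20), 0)
        rho, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(float(ref.statistic), abs=1e-12)
        assert p == pytest.approx(float(ref.pvalue), abs=1e-12)


class TestCutoffs:
    @pytest.mark.parametrize(
        "rho,p,expected",
        [
            (-0.59, 0.001, False),  # strict boundary: -0.59 excluded
            (-0.6, 0.001, True),  # cutoff itself included
            (-0.61, 0.001, True),
            (-0.9, 0.05, False),  # p not strictly below cutoff
            (-0.9, 0.049, True),
        ],
    )
    def test_boundary_conventions(self, rho, p, expected):
        assert passes_cutoffs(rho, p, rho_cutoff=-0.6, p_cutoff=0.05) is expected


class TestScreen:
    def test_exact_negative_linear_pair_retained(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=12)
        m = em(np.vstack([base, rng.normal(size=12)]), "M", "miRNA")
        g = em(np.vstack([-2 * base + 3, rng.normal(size=12)]), "G", "mRNA")
        ann = ann_for(m.sample_ids)
        pairs = screen_pairs(
            [fake_outlier("M0"), fake_outlier("M1")],
            [fake_outlier("G0"), fake_outlier("G1")],
            m, g, ann,
        )
        top = pairs.iloc[0]
        assert (top.mirna_id, top.gene_id) == ("M0", "G0")
        assert top.rho == pytest.approx(-1.0, abs=1e-12)

    def test_screen_rho_and_p_match_scipy_per_pair(self):
        rng = np.random.default_rng(5)
        m = em(rng.normal(size=(3, 10)), "M", "miRNA")
        g = em(rng.normal(size=(4, 10)), "G", "mRNA")
        ann = ann_for(m.sample_ids)
        pairs = screen_pairs(
            [fake_outlier(f"M{i}") for i in range(3)],
            [fake_outlier(f"G{j}") for j in range(4)],
            m, g, ann, rho_cutoff=0.0, p_cutoff=1.0,  # keep all negatives
        )
        for row in pairs.itertuples():
            ref = stats.spearmanr(
                m.data.loc[row.mirna_id], g.data.loc[row.gene_id]
            )
            assert row.rho == pytest.approx(float(ref.statistic), abs=1e-12)
            assert row.p_value == pytest.approx(float(ref.pvalue), abs=1e-10)

    def test_accounting_identity_with_constant_feature(self):
        rng = np.random.default_rng(6)
        mvals = rng.normal(size=(3, 10))
        mvals[1] = 7.0  # constant miRNA: its pairs are skipped
        m = em(mvals, "M", "miRNA")
        g = em(rng.normal(size=(5, 10)), "G", "mRNA")
        pairs = screen_pairs(
            [fake_outlier(f"M{i}") for i in range(3)],
            [fake_outlier(f"G{j}") for j in range(5)],
            m, g, ann_for(m.sample_ids), rho_cutoff=0.0, p_cutoff=1.0,
        )
        assert pairs.attrs["n_tested"] == 2 * 5
        assert pairs.attrs["n_skipped"] == 1 * 5
        assert not (pairs["mirna_id"] == "M1").any()

    def test_retained_set_monotone_in_cutoffs(self):
        rng = np.random.default_rng(7)
        m = em(rng.normal(size=(6, 14)), "M", "miRNA")
        g = em(rng.normal(size=(8, 14)), "G", "mRNA")
        ann = ann_for(m.sample_ids)
        mo = [fake_outlier(f"M{i}") for i in range(6)]
        go = [fake_outlier(f"G{j}") for j in range(8)]

        def retained(rc, pc):
            df = screen_pairs(mo, go, m, g, ann, rho_cutoff=rc, p_cutoff=pc)
            return set(zip(df["mirna_id"], df["gene_id"]))

        loose = retained(-0.1, 1.0)
        assert retained(-0.4, 1.0) <= loose
        assert retained(-0.1, 0.5) <= loose
        assert retained(-0.4, 0.5) <= retained(-0.4, 1.0)

    def test_no_shared_paired_samples_is_hard_error(self):
        rng = np.random.default_rng(8)
        m = em(rng.normal(size=(2, 4)), "M", "miRNA", samples=list("abcd"))
        g = em(rng.normal(size=(2, 4)), "G", "mRNA", samples=list("wxyz"))
        ann = SampleAnnotation(pd.DataFrame({
            "sample_id": list("abcdwxyz"),
            "class_label": ["case", "case", "control", "control"] * 2,
            "pair_key": ["k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8"],
        }))
        with pytest.raises(ValueError, match="no shared paired samples"):
            screen_pairs([fake_outlier("M0")], [fake_outlier("G0")], m, g, ann)

    def test_case_only_mode_uses_case_samples(self):
        rng = np.random.default_rng(9)
        n = 16
        base = rng.normal(size=n)
        g_row = -base + 0.1 * rng.normal(size=n)
        g_row[:4] = rng.normal(size=4) * 3  # controls break the correlation
        m = em(base[None, :], "M", "miRNA")
        g = em(g_row[None, :], "G", "mRNA")
        ann = ann_for(m.sample_ids, n_control=4)
        all_mode = screen_pairs([fake_outlier("M0")], [fake_outlier("G0")],
                                m, g, ann, rho_cutoff=0.0, p_cutoff=1.0)
        case_mode = screen_pairs([fake_outlier("M0")], [fake_outlier("G0")],
                                 m, g, ann, rho_cutoff=0.0, p_cutoff=1.0,
                                 sample_mode="case-only")
        assert case_mode.attrs["n_samples"] == n - 4
        assert case_mode.iloc[0].rho < all_mode.iloc[0].rho  # cleaner in cases

    def test_planted_pairs_recovered_and_decoys_rare(self, small_truth,
                                                     small_cohort):
        # pairs with generative anticorrelation >= 0.8 must all be retained;
        # decoy x decoy pairs pass at well below the nominal 5% level
        co = small_cohort
        gen_rho = small_truth.generative_rho()
        strong = {e for e, r in gen_rho.items() if r >= 0.8}
        planted_m = small_truth.planted_mirnas()
        planted_g = small_truth.planted_genes()
        pairs = screen_pairs(
            [fake_outlier(x) for x in planted_m],
            [fake_outlier(x) for x in planted_g],
            co.mirna, co.genes, co.annotation,
        )
        retained = set(zip(pairs["mirna_id"], pairs["gene_id"]))
        assert strong <= retained

        decoy_m = [m for m in co.mirna.feature_ids if m not in planted_m][:15]
        decoy_g = [g for g in co.genes.feature_ids if g not in planted_g][:40]
        decoys = screen_pairs(
            [fake_outlier(x) for x in decoy_m],
            [fake_outlier(x) for x in decoy_g],
            co.mirna, co.genes, co.annotation,
        )
        frac = len(decoys) / decoys.attrs["n_tested"]
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / decoys.attrs["n_tested"])


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=15, deadline=None, derandomize=True)
def test_rank_zscores_flag_constant_rows(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(4, 8))
    X[2] = 1.5
    Z, keep = _rank_zscores(X)
    assert list(keep) == [True, True, False, True]
    assert np.allclose(Z[keep].mean(axis=1), 0, atol=1e-12)
    assert np.allclose((Z[keep] ** 2).mean(axis=1), 1, atol=1e-12)
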