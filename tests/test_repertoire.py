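"""Clonality, downsampling, V-J usage, and the usage signature."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igsurv import repertoire as rep


def make_table(rows, sample_id="S0"):
    """rows: list of (count, cdr3nt, v, j, isotype)."""
    df = pd.DataFrame(
        [
            {"count": c, "freq": 0.0, "cdr3nt": nt, "cdr3aa": "CAR" + nt[:4],
             "v": v, "d": ".", "j": j, "isotype": iso}
            for c, nt, v, j, iso in rows
        ]
    )
    return rep.ClonotypeTable(sample_id=sample_id, clonotypes=df)


class TestCoverageFilter:
    @pytest.mark.parametrize("total,passed", [(501, True), (500, False), (0, False)])
    def test_strictly_greater_than_threshold(self, total, passed):
        rows = [(total, "ATG", "IGHV1-2", "IGHJ4", "IgG1")] if total else []
        if not rows:
            rows = [(1, "ATG", "IGHV1-2", "IGHJ4", "IgA")]  # no IgG1 reads at all
        table = make_table(rows)
        assert rep.coverage_filter(table, "IgG1", 500) is passed


class TestDownsample:
    def test_single_clonotype_keeps_all_mass(self):
        table = make_table([(1000, "ATG", "IGHV1-2", "IGHJ4", "IgG1")])
        out = rep.downsample_reads(table, "IgG1", n=500, seed=7)
        assert out.clonotypes["count"].tolist() == [500]

    def test_total_equals_n_is_identity(self):
        table = make_table([(300, "ATG", "IGHV1-2", "IGHJ4", "IgG1"),
                            (200, "CCC", "IGHV3-11", "IGHJ6", "IgG1")])
        out = rep.downsample_reads(table, "IgG1", n=500, seed=7)
        assert sorted(out.clonotypes["count"]) == [200, 300]

    def test_sum_exact_and_deterministic(self):
        table = make_table([(900, "ATG", "IGHV1-2", "IGHJ4", "IgG1"),
                            (100, "CCC", "IGHV3-11", "IGHJ6", "IgG1")])
        a = rep.downsample_reads(table, "IgG1", n=500, seed=11)
        b = rep.downsample_reads(table, "IgG1", n=500, seed=11)
        assert a.clonotypes["count"].sum() == 500
        pd.testing.assert_frame_equal(a.clonotypes, b.clonotypes)

    def test_hypergeometric_expectation(self):
        """Mean downsampled count of a 10% clone matches n*p within MC error."""
        table = make_table([(900, "ATG", "IGHV1-2", "IGHJ4", "IgG1"),
                            (100, "CCC", "IGHV3-11", "IGHJ6", "IgG1")])
        counts = []
        for seed in range(500):
            out = rep.downsample_reads(table, "IgG1", n=500, seed=seed)
            sub = out.clonotypes.set_index("cdr3nt")["count"]
            counts.append(sub.get("CCC", 0))
        # Var of one draw: n p q (N-n)/(N-1) = 500*0.1*0.9*500/999 ~ 22.5
        se_mean = math.sqrt(500 * 0.1 * 0.9 * 500 / 999 / 500)
        assert abs(np.mean(counts) - 50.0) < 4 * se_mean

    def test_insufficient_reads_error(self):
        table = make_table([(400, "ATG", "IGHV1-2", "IGHJ4", "IgG1")])
        with pytest.raises(ValueError, match="coverage_filter"):
            rep.downsample_reads(table, "IgG1", n=500, seed=0)


class TestClonality:
    def test_uniform_repertoire_is_zero(self):
        assert rep.clonality([5] * 100) == pytest.approx(0.0, abs=1e-12)

    def test_single_clone_is_one(self):
        assert rep.clonality([17]) == 1.0

    def test_two_clone_arithmetic(self):
        # H = -(0.8 ln 0.8 + 0.2 ln 0.2); clonality = 1 - H/ln 2
        assert rep.clonality([400, 100]) == pytest.approx(0.27807, abs=1e-4)

    def test_errors(self):
        with pytest.raises(ValueError):
            rep.clonality([])
        with pytest.raises(ValueError):
            rep.clonality([3, 0])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.integers(1, 1000), min_size=2, max_size=30))
    def test_scale_invariance_and_range(self, counts):
        c = rep.clonality(counts)
        assert 0.0 <= c <= 1.0
        assert rep.clonality([7 * x for x in counts]) == pytest.approx(c, abs=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.integers(2, 500), min_size=3, max_size=10))
    def test_read_transfer_to_largest_clone_increases_clonality(self, counts):
        counts = sorted(counts)
        if counts[0] == counts[-1]:
            counts[-1] += 1
        before = rep.clonality(counts)
        moved = list(counts)
        moved[0] -= 1
        moved[-1] += 1
        assert rep.clonality(moved) > before


class TestVJUsage:
    @pytest.mark.parametrize("name,family", [
        ("IGHV3-11", "IGHV3"), ("IGHV3-13", "IGHV3"), ("IGHV6-1", "IGHV6"),
        ("IGHV1-69*02", "IGHV1"),
    ])
    def test_collapse_v_family(self, name, family):
        assert rep.collapse_v_family(name) == family

    def test_collapse_rejects_non_ighv(self):
        with pytest.raises(ValueError, match="TRBV9"):
            rep.collapse_v_family("TRBV9")

    def test_j_gene_strips_allele(self):
        assert rep.j_gene("IGHJ4*02") == "IGHJ4"
        with pytest.raises(ValueError):
            rep.j_gene("TRBJ1-1")

    def test_single_feature_row(self):
        table = make_table([(600, "ATG", "IGHV3-11", "IGHJ4", "IgG1")])
        usage = rep.vj_usage_matrix([table], "IgG1")
        assert usage.loc["S0", "IGHV3|IGHJ4"] == 1.0

    def test_weighted_frequencies(self):
        table = make_table([(300, "ATG", "IGHV1-2", "IGHJ4", "IgG1"),
                            (200, "CCC", "IGHV4-34", "IGHJ6", "IgG1")])
        usage = rep.vj_usage_matrix([table], "IgG1")
        assert usage.loc["S0", "IGHV1|IGHJ4"] == pytest.approx(0.6)
        assert usage.loc["S0", "IGHV4|IGHJ6"] == pytest.approx(0.4)

    def test_rows_sum_to_one_and_family_collapse_merges(self, rng):
        tables = []
        for s in range(5):
            rows = [(int(rng.integers(1, 50)), f"NT{s}{k}",
                     f"IGHV{rng.integers(1, 8)}-{rng.integers(1, 40)}",
                     f"IGHJ{rng.integers(1, 7)}", "IgG1") for k in range(30)]
            tables.append(make_table(rows, sample_id=f"S{s}"))
        usage = rep.vj_usage_matrix(tables, "IgG1")
        np.testing.assert_allclose(usage.sum(axis=1), 1.0, atol=1e-9)
        assert usage.shape[1] <= 7 * 6


class TestSignaturePCA:
    def _usage(self, rng, n=10):
        raw = rng.dirichlet(np.ones(8), size=n)
        return pd.DataFrame(raw, index=[f"S{i}" for i in range(n)],
                            columns=[f"IGHV{i+1}|IGHJ4" for i in range(8)])

    def test_duplicated_samples_get_identical_scores(self, rng):
        usage = self._usage(rng)
        usage.iloc[1] = usage.iloc[0]
        labels = pd.Series("excluded", index=usage.index)
        res = rep.signature_pca(usage, labels)
        np.testing.assert_allclose(res.scores.iloc[0], res.scores.iloc[1],
                                   atol=1e-10)

    def test_loadings_unit_norm_and_sign_convention(self, rng):
        usage = self._usage(rng)
        labels = pd.Series("excluded", index=usage.index)
        res = rep.signature_pca(usage, labels)
        norms = np.linalg.norm(res.loadings.to_numpy(), axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)
        for col in res.loadings:
            top = res.loadings[col].abs().idxmax()
            assert res.loadings.loc[top, col] > 0

    def test_zero_variance_errors(self):
        usage = pd.DataFrame(np.full((4, 3), 1 / 3),
                             index=list("abcd"), columns=["f1", "f2", "f3"])
        labels = pd.Series("excluded", index=usage.index)
        with pytest.raises(ValueError, match="variance"):
            rep.signature_pca(usage, labels)

    def test_group_difference_of_planted_shift(self, rng):
        base = rng.dirichlet(np.ones(6) * 8, size=40)
        usage = pd.DataFrame(base, index=[f"S{i}" for i in range(40)],
                             columns=[f"IGHV{i+1}|IGHJ4" for i in range(6)])
        labels = pd.Series(["high"] * 20 + ["low"] * 20, index=usage.index)
        shifted = 0.8 * usage.iloc[:20] + 0.2 * pd.get_dummies(
            pd.Series(["IGHV6|IGHJ4"] * 20)).reindex(
                columns=usage.columns, fill_value=0).set_index(usage.index[:20])
        usage.iloc[:20] = shifted
        res = rep.signature_pca(usage, labels)
        assert res.group_difference.idxmax() == "IGHV6|IGHJ4"
        assert res.group_difference["IGHV6|IGHJ4"] > 0


class TestSurvivalGroupLabels:
    def test_label_assignment(self, clinical_frame):
        # median os_days of the 8 patients = 750
        labels = rep.survival_group_labels(clinical_frame)
        assert labels["P1"] == "low"         # dead at 400 <= 750
        assert labels["P4"] == "high"        # censored at 1200 > 750
        assert labels["P2"] == "excluded"    # censored at 700 <= 750
        assert labels["P3"] == "high"        # dead at 900 > 750

    def test_cohort_restriction(self, clinical_frame):
        labels = rep.survival_group_labels(clinical_frame,
                                           cohort=["P0", "P1", "P5", "P7"])
        assert set(labels.index) == {"P0", "P1", "P5", "P7"}
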