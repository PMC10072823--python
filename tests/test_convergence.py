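import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from mitoevo.convergence import (
    SPECTRUM_CLASSES,
    bray_curtis_matrix,
    build_profiles,
    count_distribution_test,
    locus_specificity,
    mutation_spectrum_test,
    mutual_information_dits,
    nmds_embed,
    partition_dissimilarity,
    phenotype_association,
    substitution_class,
)
from mitoevo.errors import ConfigurationError
from mitoevo.model import DEFAULT_GENOTYPES, DEFAULT_MEDIA


def bray_curtis_direct(u, v):
    """Independent oracle: the textbook formula."""
    u, v = np.asarray(u, float), np.asarray(v, float)
    return 1.0 - 2.0 * np.minimum(u, v).sum() / (u.sum() + v.sum())


def _meta(clones):
    rows = []
    for clone_id, genotype, medium in clones:
        rows.append(
            {
                "clone_id": clone_id,
                "nuclear": genotype[0],
                "mito": genotype[1],
                "genotype": genotype,
                "medium": medium,
                "circumstance": f"{genotype}:{medium}",
            }
        )
    return pd.DataFrame(rows)


def _calls(entries):
    return pd.DataFrame(
        [
            {"clone_id": c, "type": "SNV", "chromosome": "chrI", "start": 1, "end": 1,
             "ref_allele": "A", "alt_allele": "T", "copy_ratio": np.nan,
             "annotation": a, "artifact_flag": flag}
            for c, a, flag in entries
        ]
    )


class TestBuildProfiles:
    META = _meta([("c1", "NN", "FF"), ("c2", "NN", "NF")])

    def test_counts_per_annotation(self):
        calls = _calls([("c1", "g1", False), ("c1", "g1", False), ("c1", "g2", False)])
        prof = build_profiles(calls, self.META)
        assert prof.loc["NN:FF", "g1"] == 2
        assert prof.loc["NN:FF", "g2"] == 1
        assert prof.loc["NN:NF"].sum() == 0

    def test_total_conservation(self):
        calls = _calls([("c1", "g1", False), ("c2", "g2", False), ("c2", "g1", False)])
        prof = build_profiles(calls, self.META)
        assert prof.to_numpy().sum() == len(calls)

    def test_equal_weights_all_types(self):
        # a 1,091-bp CNV and a 1-bp SNV each contribute exactly one count
        calls = pd.DataFrame(
            [
                {"clone_id": "c1", "type": "CNV", "chromosome": "chrI", "start": 1,
                 "end": 1091, "ref_allele": "", "alt_allele": "", "copy_ratio": 2.0,
                 "annotation": "g1", "artifact_flag": False},
                {"clone_id": "c1", "type": "SNV", "chromosome": "chrI", "start": 5,
                 "end": 5, "ref_allele": "A", "alt_allele": "T", "copy_ratio": np.nan,
                 "annotation": "g1", "artifact_flag": False},
            ]
        )
        prof = build_profiles(calls, self.META)
        assert prof.loc["NN:FF", "g1"] == 2

    def test_artifacts_excluded(self):
        calls = _calls([("c1", "g1", False), ("c1", "g1", True)])
        prof = build_profiles(calls, self.META)
        assert prof.loc["NN:FF", "g1"] == 1

    def test_unknown_clone_rejected(self):
        calls = _calls([("nobody", "g1", False)])
        with pytest.raises(ConfigurationError):
            build_profiles(calls, self.META)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        prof = pd.DataFrame([[3, 1, 2], [3, 1, 2]], index=["a", "b"])
        D = bray_curtis_matrix(prof)
        assert D.loc["a", "b"] == 0.0

    def test_disjoint_support_one(self):
        prof = pd.DataFrame([[3, 0, 0], [0, 2, 5]], index=["a", "b"])
        assert bray_curtis_matrix(prof).loc["a", "b"] == 1.0

    def test_formula_oracle_example(self):
        prof = pd.DataFrame([[3, 1, 0], [1, 1, 2]], index=["a", "b"])
        assert bray_curtis_matrix(prof).loc["a", "b"] == pytest.approx(0.5, abs=1e-12)
        assert bray_curtis_direct([3, 1, 0], [1, 1, 2]) == pytest.approx(0.5)

    def test_random_matrices_match_oracle(self, rng):
        for _ in range(25):
            X = rng.integers(0, 20, size=(4, 6))
            if (X.sum(axis=1) == 0).any():
                continue
            prof = pd.DataFrame(X)
            D = bray_curtis_matrix(prof)
            for i in range(4):
                for j in range(4):
                    assert D.iloc[i, j] == pytest.approx(
                        bray_curtis_direct(X[i], X[j]), abs=1e-12
                    )

    def test_matrix_properties(self, rng):
        X = rng.integers(1, 30, size=(6, 8))
        D = bray_curtis_matrix(pd.DataFrame(X)).to_numpy()
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert (D >= 0).all() and (D <= 1).all()

    def test_zero_row_pair_nan(self):
        prof = pd.DataFrame([[0, 0], [0, 0], [1, 2]], index=list("abc"))
        with pytest.warns(UserWarning):
            D = bray_curtis_matrix(prof)
        assert np.isnan(D.loc["a", "b"])


class TestNmds:
    def test_two_points_stress_zero(self):
        D = pd.DataFrame([[0, 1.0], [1.0, 0]], index=["a", "b"], columns=["a", "b"])
        res = nmds_embed(D, dims=1, n_init=5, seed=0)
        assert res.stress == pytest.approx(0.0, abs=1e-9)

    def test_perfect_2d_recovery(self, rng):
        X = rng.normal(size=(5, 2))
        D = pd.DataFrame(squareform(pdist(X)))
        res = nmds_embed(D, dims=2, n_init=50, seed=1)
        assert res.stress < 1e-6

    def test_determinism(self, rng):
        X = rng.normal(size=(6, 2))
        D = pd.DataFrame(squareform(pdist(X)))
        r1 = nmds_embed(D, dims=2, n_init=10, seed=7)
        r2 = nmds_embed(D, dims=2, n_init=10, seed=7)
        pd.testing.assert_frame_equal(r1.coordinates, r2.coordinates)
        assert r1.stress == r2.stress

    def test_best_of_inits_retained(self, rng):
        X = rng.normal(size=(7, 3))
        D = pd.DataFrame(squareform(pdist(X)))
        res = nmds_embed(D, dims=2, n_init=20, seed=3)
        assert res.stress == res.all_stresses.min()
        assert (res.all_stresses >= res.stress).all()

    def test_dims_bound(self):
        D = pd.DataFrame(np.zeros((3, 3)))
        with pytest.raises(ConfigurationError):
            nmds_embed(D, dims=3, n_init=1)


class TestPartitionDissimilarity:
    @staticmethod
    def _full_design_D(values=None):
        labels = [f"{g}:{m}" for g in DEFAULT_GENOTYPES for m in DEFAULT_MEDIA]
        n = len(labels)
        rng = np.random.default_rng(0)
        M = rng.uniform(0.5, 1.0, size=(n, n)) if values is None else values
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0.0)
        return pd.DataFrame(M, index=labels, columns=labels)

    def test_91_pairs(self):
        pairs, _ = partition_dissimilarity(self._full_design_D())
        assert len(pairs) == 91

    def test_same_genotype_diff_medium_count(self):
        pairs, _ = partition_dissimilarity(self._full_design_D())
        sub = pairs[pairs["nuclear_match"] & pairs["mito_match"] & ~pairs["env_match"]]
        assert len(sub) == 7

    def test_each_pair_in_one_class(self):
        pairs, _ = partition_dissimilarity(self._full_design_D())
        counts = pairs.groupby(["env_match", "nuclear_match", "mito_match"]).size()
        assert counts.sum() == 91

    def test_planted_nuclear_effect_detected(self):
        """Dissimilarity lower for nuclear-matched pairs -> nuclear term significant."""
        labels = [f"{g}:{m}" for g in DEFAULT_GENOTYPES for m in DEFAULT_MEDIA]
        n = len(labels)
        rng = np.random.default_rng(5)
        M = np.full((n, n), 0.9)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if a[0] == b[0]:  # same nuclear background
                    M[i, j] -= 0.3
        M += rng.normal(0, 0.01, size=(n, n))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        D = pd.DataFrame(M, index=labels, columns=labels)
        _, anova = partition_dissimilarity(D)
        tab = anova.set_index("term")
        assert tab.loc["nuclear_match", "p"] < 1e-6
        assert tab.loc["mito_match", "p"] > 0.01


class TestMutualInformation:
    def test_diagonal_2x2(self):
        assert mutual_information_dits([[10, 0], [0, 10]]) == pytest.approx(
            np.log10(2.0), abs=1e-12
        )

    def test_product_table_zero(self):
        p = np.outer([0.3, 0.7], [0.2, 0.5, 0.3]) * 1000
        assert mutual_information_dits(p) == pytest.approx(0.0, abs=1e-12)

    def test_permutation_invariance(self, rng):
        T = rng.integers(1, 50, size=(2, 5)).astype(float)
        base = mutual_information_dits(T)
        perm = rng.permutation(5)
        assert mutual_information_dits(T[:, perm]) == pytest.approx(base, abs=1e-12)
        assert mutual_information_dits(T[::-1]) == pytest.approx(base, abs=1e-12)

    @given(
        st.lists(
            st.lists(st.integers(0, 40), min_size=3, max_size=3),
            min_size=2, max_size=2,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_nonnegative(self, table):
        T = np.asarray(table, float)
        if T.sum() == 0:
            return
        assert mutual_information_dits(T) >= -1e-12


class TestLocusSpecificity:
    @staticmethod
    def _cohort(n_per=30, hot_rate=2.0, seed=0):
        """Two genotypes x two media; 'hot' locus elevated in NN:FF only."""
        rng = np.random.default_rng(seed)
        meta_rows, call_rows = [], []
        for g in ("NN", "DD"):
            for m in ("FF", "NF"):
                for r in range(n_per):
                    cid = f"{g}-{m}-{r}"
                    meta_rows.append(
                        {"clone_id": cid, "nuclear": g[0], "mito": g[1],
                         "genotype": g, "medium": m, "circumstance": f"{g}:{m}"}
                    )
                    for locus, rate in (
                        ("hot", hot_rate if (g, m) == ("NN", "FF") else 0.05),
                        ("cold1", 0.3), ("cold2", 0.3), ("cold3", 0.3),
                        ("cold4", 0.3), ("cold5", 0.3),
                    ):
                        for _ in range(rng.poisson(rate)):
                            call_rows.append(
                                {"clone_id": cid, "annotation": locus,
                                 "artifact_flag": False}
                            )
        return pd.DataFrame(meta_rows), pd.DataFrame(call_rows)

    def test_planted_locus_flagged(self):
        meta, calls = self._cohort()
        out = locus_specificity(calls, meta, factor="medium_x_background")
        out = out.set_index("annotation")
        assert bool(out.loc["hot", "specific"])
        assert not out.drop("hot")["specific"].any()

    def test_proportional_locus_mi_zero(self):
        # in-locus counts exactly proportional to category totals
        meta = _meta([("c1", "NN", "FF"), ("c2", "NN", "NF")])
        calls = pd.DataFrame(
            [{"clone_id": c, "annotation": a, "artifact_flag": False}
             for c, a in [("c1", "g1")] * 2 + [("c1", "g2")] * 2
             + [("c2", "g1")] * 2 + [("c2", "g2")] * 2]
        )
        out = locus_specificity(calls, meta, factor="medium").set_index("annotation")
        assert out.loc["g1", "mi_dits"] == pytest.approx(0.0, abs=1e-12)
        assert not out["specific"].any()

    def test_invalid_factor(self):
        meta, calls = self._cohort(n_per=5)
        with pytest.raises(ConfigurationError):
            locus_specificity(calls, meta, factor="flavor")

    def test_permutation_calibration_small(self):
        """Label permutations should flag ~nothing (quick 100-perm check)."""
        meta, calls = self._cohort(n_per=30, hot_rate=2.0, seed=2)
        rng = np.random.default_rng(3)
        flagged, total = 0, 0
        circ = meta["circumstance"].to_numpy().copy()
        for _ in range(100):
            perm_meta = meta.copy()
            perm_meta["circumstance"] = rng.permutation(circ)
            out = locus_specificity(calls, perm_meta, factor="medium_x_background")
            flagged += int(out["specific"].sum())
            total += len(out)
        rate = flagged / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert rate <= 0.05 + 2 * se


class TestCountDistributionTest:
    def test_equal_counts_chi2_zero(self):
        chi2, p = count_distribution_test([10, 10, 10, 10])
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_extreme_skew_significant(self):
        # CNV-count style skew across 14 circumstances
        counts = [92, 86, 9, 5, 3, 2, 1, 1, 0.5, 0.5, 1, 1, 1, 1]
        chi2, p = count_distribution_test(counts)
        assert p < 0.05

    def test_single_category_rejected(self):
        with pytest.raises(ConfigurationError):
            count_distribution_test([5])

    def test_supplied_proportions(self):
        chi2, p = count_distribution_test([30, 70], expected_proportions=[0.3, 0.7])
        assert chi2 == pytest.approx(0.0)


class TestMutationSpectrum:
    def test_substitution_class_collapse(self):
        assert substitution_class("G", "T") == "C>A"
        assert substitution_class("A", "G") == "T>C"
        assert substitution_class("C", "T") == "C>T"
        with pytest.raises(ConfigurationError):
            substitution_class("A", "A")

    @staticmethod
    def _snvs(clone_classes):
        pairs = {"C>A": ("C", "A"), "C>G": ("C", "G"), "C>T": ("C", "T"),
                 "T>A": ("T", "A"), "T>C": ("T", "C"), "T>G": ("T", "G")}
        rows = []
        for clone, cls in clone_classes:
            ref, alt = pairs[cls]
            rows.append({"clone_id": clone, "type": "SNV",
                         "ref_allele": ref, "alt_allele": alt})
        return pd.DataFrame(rows)

    def test_identical_spectra_chi2_zero(self):
        entries = [("a", c) for c in SPECTRUM_CLASSES] + [
            ("b", c) for c in SPECTRUM_CLASSES
        ]
        snvs = self._snvs(entries)
        groups = pd.Series({"a": "g1", "b": "g2"})
        table, chi2, p = mutation_spectrum_test(snvs, groups)
        assert chi2 == pytest.approx(0.0)

    def test_planted_ct_excess_detected(self, rng):
        entries = []
        for i in range(300):
            entries.append((f"a{i}", "C>T"))  # group 1 heavily C>T
        for i in range(300):
            entries.append((f"b{i}", SPECTRUM_CLASSES[i % 6]))
        snvs = self._snvs(entries)
        groups = pd.Series(
            {f"a{i}": "g1" for i in range(300)} | {f"b{i}": "g2" for i in range(300)}
        )
        _, chi2, p = mutation_spectrum_test(snvs, groups)
        assert p < 1e-6

    def test_empty_group_excluded(self):
        snvs = self._snvs([("a", "C>T"), ("b", "T>A")])
        groups = pd.Series({"a": "g1", "b": "g2", "c": "g3"})
        table, _, _ = mutation_spectrum_test(snvs, groups)
        assert "g3" not in table.index


class TestPhenotypeAssociation:
    @staticmethod
    def _data(shift=0.0, n=20, seed=0):
        rng = np.random.default_rng(seed)
        mutants = [f"m{i}" for i in range(n)]
        others = [f"o{i}" for i in range(n)]
        calls = pd.DataFrame(
            [{"clone_id": c, "annotation": "geneX", "artifact_flag": False}
             for c in mutants]
        )
        pheno = pd.DataFrame(
            {"clone_id": mutants + others,
             "value": np.concatenate(
                 [rng.standard_normal(n) + shift, rng.standard_normal(n)]
             )}
        )
        return calls, pheno

    def test_planted_shift_detected(self):
        calls, pheno = self._data(shift=2.0)
        out = phenotype_association(calls, pheno)
        assert len(out) == 1
        assert out.iloc[0]["q_value"] <= 0.05
        assert out.iloc[0]["effect_size"] == pytest.approx(2.0, abs=0.8)

    def test_null_not_flagged(self):
        calls, pheno = self._data(shift=0.0, seed=5)
        out = phenotype_association(calls, pheno)
        assert out.iloc[0]["q_value"] > 0.05

    def test_min_mutant_clones_skip(self):
        calls, pheno = self._data(n=3)
        out = phenotype_association(calls, pheno, min_mutant_clones=5)
        assert out.empty
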