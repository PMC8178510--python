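"""Variant QC: HWE, filtering semantics, LD, tag expansion, ancestry."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirqtl import (
    GenotypeMatrix,
    assign_ancestry,
    expand_tag_snps,
    filter_variants,
    hwe_test,
    ld_r2,
)
from mirqtl.genotype import UndefinedLdError


def make_matrix(dosage_rows, info=None, max_posterior=None, pos=None, chrom=None):
    dosage_rows = np.asarray(dosage_rows, dtype=float)
    m = len(dosage_rows)
    variants = pd.DataFrame(
        {
            "id": [f"v{i}" for i in range(m)],
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else 1 + np.arange(m) * 1000,
            "ref": "A",
            "alt": "G",
            "info_score": info if info is not None else [0.99] * m,
        }
    )
    samples = [f"S{j}" for j in range(dosage_rows.shape[1])]
    return GenotypeMatrix(variants, dosage_rows, samples, max_posterior)


def hwe_genotypes(p, n, rng):
    """Dosages drawn under exact Hardy-Weinberg proportions."""
    return rng.binomial(1, p, (n, 2)).sum(axis=1).astype(float)


class TestHwe:
    def test_exact_proportions_give_p_one(self):
        assert hwe_test((25, 50, 25)) == pytest.approx(1.0)

    def test_monomorphic_gives_p_one(self):
        assert hwe_test((100, 0, 0)) == 1.0
        assert hwe_test((0, 0, 57)) == 1.0

    def test_matches_brute_force_chi_square(self):
        counts = (50, 20, 30)
        n = sum(counts)
        p_hat = (2 * counts[2] + counts[1]) / (2 * n)  # alt-allele frequency 0.4
        exp = [n * (1 - p_hat) ** 2, 2 * n * p_hat * (1 - p_hat), n * p_hat**2]
        chi2 = sum((o - e) ** 2 / e for o, e in zip(counts, exp))
        assert hwe_test(counts) == pytest.approx(stats.chi2.sf(chi2, 1), abs=1e-10)

    def test_rejects_empty_and_negative(self):
        with pytest.raises(ValueError):
            hwe_test((0, 0, 0))
        with pytest.raises(ValueError):
            hwe_test((-1, 2, 3))

    def test_pvalues_uniform_under_hwe(self):
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(1000):
            calls = hwe_genotypes(0.3, 500, rng)
            counts = tuple(int((calls == k).sum()) for k in (0, 1, 2))
            pvals.append(hwe_test(counts))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestFilterVariants:
    def test_info_failure_attributed(self):
        rng = np.random.default_rng(0)
        rows = [hwe_genotypes(0.3, 200, rng) for _ in range(2)]
        g = make_matrix(rows, info=[0.6, 0.9])
        out, report = filter_variants(g)
        assert list(out.variants["id"]) == ["v1"]
        assert report.attrs["removal_counts"]["info"] == 1

    def test_low_maf_removed(self):
        rng = np.random.default_rng(1)
        g = make_matrix(
            [hwe_genotypes(0.02, 500, rng), hwe_genotypes(0.3, 500, rng)]
        )
        out, report = filter_variants(g)
        assert list(out.variants["id"]) == ["v1"]
        assert report.attrs["removal_counts"]["maf"] == 1

    def test_hwe_departure_removed(self):
        # all hets: maximal HWE departure at MAF 0.5
        g = make_matrix([np.ones(500), hwe_genotypes(0.3, 500, np.random.default_rng(2))])
        out, report = filter_variants(g)
        assert "v0" not in list(out.variants["id"])
        assert report.attrs["removal_counts"]["hwe"] == 1

    def test_all_passing_preserves_input_order(self):
        rng = np.random.default_rng(3)
        g = make_matrix([hwe_genotypes(0.2 + 0.05 * i, 300, rng) for i in range(5)])
        out, _ = filter_variants(g)
        assert list(out.variants["id"]) == [f"v{i}" for i in range(5)]
        np.testing.assert_array_equal(out.dosages, g.dosages)

    def test_low_posterior_calls_become_missing(self):
        rng = np.random.default_rng(4)
        d = hwe_genotypes(0.3, 300, rng)
        post = np.full((1, 300), 0.95)
        post[0, :10] = 0.5
        g = make_matrix([d], max_posterior=post)
        out, report = filter_variants(g)
        assert np.isnan(out.dosages[0, :10]).all()
        assert report.attrs["masked_calls"] == 10

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        rows = [hwe_genotypes(0.02, 300, rng)] + [
            hwe_genotypes(0.3, 300, rng) for _ in range(4)
        ]
        post = np.random.default_rng(6).uniform(0.5, 1.0, size=(5, 300))
        g = make_matrix(rows, info=[0.99, 0.6, 0.9, 0.9, 0.9], max_posterior=post)
        once, _ = filter_variants(g)
        twice, _ = filter_variants(once)
        assert list(once.variants["id"]) == list(twice.variants["id"])
        np.testing.assert_array_equal(once.dosages, twice.dosages)

    def test_output_is_subset(self):
        rng = np.random.default_rng(7)
        g = make_matrix([hwe_genotypes(0.04 * (i + 1), 200, rng) for i in range(8)])
        out, _ = filter_variants(g)
        assert set(out.variants["id"]) <= set(g.variants["id"])


class TestLdR2:
    def test_identical_vectors(self):
        a = np.array([0, 1, 2, 1, 0, 2, 1, 1, 0, 2], dtype=float)
        assert ld_r2(a, a) == pytest.approx(1.0)

    def test_allele_flip_invariant(self):
        rng = np.random.default_rng(8)
        a = rng.binomial(2, 0.4, 50).astype(float)
        assert ld_r2(a, 2 - a) == pytest.approx(1.0)
        b = rng.binomial(2, 0.4, 50).astype(float)
        assert ld_r2(a, b) == pytest.approx(ld_r2(a, 2 - b), abs=1e-12)

    def test_symmetric(self):
        rng = np.random.default_rng(9)
        a = rng.binomial(2, 0.3, 40).astype(float)
        b = rng.binomial(2, 0.5, 40).astype(float)
        assert ld_r2(a, b) == pytest.approx(ld_r2(b, a), abs=1e-15)

    def test_matches_pearson_formula(self):
        rng = np.random.default_rng(10)
        a = rng.binomial(2, 0.3, 20).astype(float)
        b = np.clip(a + rng.binomial(1, 0.3, 20) - rng.binomial(1, 0.3, 20), 0, 2)
        num = np.sum((a - a.mean()) * (b - b.mean()))
        den = np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        assert ld_r2(a, b) == pytest.approx((num / den) ** 2, abs=1e-12)

    def test_constant_vector_raises(self):
        with pytest.raises(UndefinedLdError):
            ld_r2(np.ones(10), np.arange(10, dtype=float) % 3)

    def test_pairwise_complete_missing_handling(self):
        a = np.array([0, 1, 2, np.nan, 1, 0, 2, 1])
        b = np.array([0, 1, 2, 1, np.nan, 0, 2, 1])
        ok = ~(np.isnan(a) | np.isnan(b))
        assert ld_r2(a, b) == pytest.approx(np.corrcoef(a[ok], b[ok])[0, 1] ** 2)


def _correlated_pair(base, rng, n_resample):
    out = base.copy()
    idx = rng.choice(len(base), n_resample, replace=False)
    out[idx] = rng.binomial(2, 0.4, n_resample)
    return out


class TestExpandTagSnps:
    def _panel(self):
        rng = np.random.default_rng(12)
        tag = rng.binomial(2, 0.4, 400).astype(float)
        # search deterministically for partners straddling the threshold
        low = high = None
        for k in range(1, 400):
            cand = _correlated_pair(tag, np.random.default_rng(100 + k), k)
            r2 = ld_r2(tag, cand)
            if 0.40 < r2 < 0.50 and low is None:
                low = cand
            if 0.50 < r2 < 0.60 and high is None:
                high = cand
            if low is not None and high is not None:
                break
        assert low is not None and high is not None
        far = rng.binomial(2, 0.4, 400).astype(float)
        return make_matrix(
            [tag, low, high, far],
            pos=[1_000_000, 1_000_500, 1_001_000, 5_000_000],
        )

    def test_threshold_is_strict_greater(self):
        panel = self._panel()
        out, _ = expand_tag_snps(["v0"], panel)
        assert set(out.variants["id"]) == {"v0", "v2"}  # r2>0.5 partner only

    def test_isolated_tag_returns_itself(self):
        rng = np.random.default_rng(13)
        panel = make_matrix(
            [rng.binomial(2, 0.3, 100).astype(float) for _ in range(2)],
            pos=[1, 5_000_000],
        )
        out, _ = expand_tag_snps(["v0"], panel)
        assert list(out.variants["id"]) == ["v0"]

    def test_overlapping_windows_no_duplicates(self):
        rng = np.random.default_rng(14)
        tag = rng.binomial(2, 0.4, 300).astype(float)
        shared = _correlated_pair(tag, np.random.default_rng(15), 20)
        panel = make_matrix([tag, shared, tag.copy()], pos=[1000, 2000, 3000])
        out, _ = expand_tag_snps(["v0", "v2"], panel)
        assert out.variants["id"].is_unique
        assert set(out.variants["id"]) == {"v0", "v1", "v2"}

    def test_invariant_to_tag_order(self):
        panel = self._panel()
        a, _ = expand_tag_snps(["v0", "v3"], panel)
        b, _ = expand_tag_snps(["v3", "v0"], panel)
        pd.testing.assert_frame_equal(a.variants, b.variants)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_absent_tag_skipped_with_warning(self):
        panel = self._panel()
        with pytest.warns(UserWarning, match="absent"):
            out, skipped = expand_tag_snps(["nope", "v0"], panel)
        assert list(skipped["tag"]) == ["nope"]
        assert "v0" in set(out.variants["id"])


class TestOxfordGen:
    def test_gen_sample_round_trip_preserves_hard_calls(self, tmp_path):
        from mirqtl.io import read_gen, write_gen

        rng = np.random.default_rng(30)
        rows = rng.binomial(2, 0.4, (5, 40)).astype(float)
        g = make_matrix(rows, max_posterior=np.ones((5, 40)))
        write_gen(g, tmp_path / "x.gen", tmp_path / "x.sample")
        back = read_gen(tmp_path / "x.gen", tmp_path / "x.sample")
        assert back.sample_ids == g.sample_ids
        assert list(back.variants["id"]) == list(g.variants["id"])
        np.testing.assert_allclose(back.dosages, rows, atol=1e-6)

    def test_missing_calls_survive_round_trip(self, tmp_path):
        from mirqtl.io import read_gen, write_gen

        rows = np.array([[0.0, 1.0, np.nan, 2.0, 1.0] * 4])
        g = make_matrix(rows, max_posterior=np.ones_like(rows))
        write_gen(g, tmp_path / "x.gen", tmp_path / "x.sample")
        back = read_gen(tmp_path / "x.gen", tmp_path / "x.sample")
        np.testing.assert_array_equal(np.isnan(back.dosages), np.isnan(rows))


def balding_nichols(fst, n_variants, n_per_pop, rng):
    """Two-population genotypes with divergence Fst (Balding-Nichols model)."""
    p_anc = rng.uniform(0.1, 0.9, n_variants)
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    dosages, labels = [], []
    pop_freqs = [rng.beta(a, b), rng.beta(a, b)]
    cols = []
    for pop, freqs in enumerate(pop_freqs):
        cols.append(rng.binomial(2, freqs[:, None], (n_variants, n_per_pop)))
        labels += [f"POP{pop}"] * n_per_pop
    return np.concatenate(cols, axis=1).astype(float), labels


class TestAncestry:
    def _data(self):
        rng = np.random.default_rng(21)
        dos, labels = balding_nichols(0.1, 500, 100, rng)
        # reference: first 75 of each pop; cohort: the rest
        ref_cols = list(range(75)) + list(range(100, 175))
        coh_cols = [i for i in range(200) if i not in ref_cols]
        def subset(cols, prefix):
            g = make_matrix(dos[:, cols], pos=1 + np.arange(500))
            g.sample_ids = [f"{prefix}{i}" for i in range(len(cols))]
            return g
        ref_g = subset(ref_cols, "R")
        coh_g = subset(coh_cols, "C")
        ref_labels = pd.Series(
            [labels[c] for c in ref_cols], index=ref_g.sample_ids
        )
        truth = [labels[c] for c in coh_cols]
        return coh_g, ref_g, ref_labels, truth

    def test_two_population_assignment_accuracy(self):
        coh, ref, ref_labels, truth = self._data()
        out = assign_ancestry(coh, ref, ref_labels)
        acc = np.mean(out["population"].to_numpy() == np.array(truth))
        assert acc >= 0.95

    def test_reference_sample_keeps_own_label(self):
        _, ref, ref_labels, _ = self._data()
        out = assign_ancestry(ref, ref, ref_labels)
        acc = np.mean(out["population"].to_numpy() == ref_labels.to_numpy())
        assert acc >= 0.95

    def test_duplicated_sample_identical_output(self):
        coh, ref, ref_labels, _ = self._data()
        dup = GenotypeMatrix(
            coh.variants.copy(),
            np.column_stack([coh.dosages, coh.dosages[:, :1]]),
            coh.sample_ids + ["C_dup"],
        )
        out = assign_ancestry(dup, ref, ref_labels)
        first = out.iloc[0]
        dup_row = out.loc["C_dup"]
        assert dup_row["population"] == first["population"]
        assert dup_row["PC1"] == pytest.approx(first["PC1"])
        assert dup_row["PC2"] == pytest.approx(first["PC2"])

    def test_insufficient_overlap_raises(self):
        coh, ref, ref_labels, _ = self._data()
        small = coh.take(range(10))
        with pytest.raises(ValueError, match="shared variants"):
            assign_ancestry(small, ref, ref_labels)
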