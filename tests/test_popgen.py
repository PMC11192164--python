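"""Diversity (He) and load (Pn*fn/Ps*fs) metrics, with brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seedsource.io import MISSING, FunctionalClass
from seedsource.popgen import (
    FrequencyVector,
    UndefinedLoadError,
    allele_frequencies,
    expected_heterozygosity,
    gd_gl_ratio,
    genetic_load,
    score_pool,
)

from conftest import make_ann, make_gm


def fv(p, n_called=None):
    p = np.asarray(p, dtype=float)
    if n_called is None:
        n_called = np.full(p.size, 10)
    return FrequencyVector(
        snp_ids=[f"1:{j + 1}:A:G" for j in range(p.size)],
        p=p,
        n_called_alleles=np.asarray(n_called),
    )


class TestAlleleFrequencies:
    def test_simple_trio(self):
        gm = make_gm([[0], [1], [2]], ["A", "A", "A"])
        f = allele_frequencies(gm)
        assert f.p[0] == pytest.approx(0.5)
        assert f.n_called_alleles[0] == 6

    def test_missing_excluded_from_denominator(self):
        gm = make_gm([[MISSING], [2]], ["A", "A"])
        f = allele_frequencies(gm)
        assert f.p[0] == pytest.approx(1.0)
        assert f.n_called_alleles[0] == 2

    def test_hand_computed_fixture(self):
        # 6 individuals x 5 SNPs; last SNP entirely missing
        d = [
            [0, 2, 1, 0, MISSING],
            [1, 2, 1, 0, MISSING],
            [0, 1, MISSING, 0, MISSING],
            [0, 2, 0, 0, MISSING],
            [2, 2, 2, 0, MISSING],
            [1, 1, 0, 0, MISSING],
        ]
        f = allele_frequencies(make_gm(d, ["A"] * 6))
        np.testing.assert_allclose(
            f.p[:4], [4 / 12, 10 / 12, 4 / 10, 0.0]
        )
        assert np.isnan(f.p[4]) and f.n_called_alleles[4] == 0
        assert f.usable.tolist() == [True] * 4 + [False]

    def test_empty_subset_errors(self):
        gm = make_gm([[0], [1]], ["A", "A"])
        with pytest.raises(ValueError, match="empty"):
            allele_frequencies(gm, [])


class TestExpectedHeterozygosity:
    def test_half_frequency_is_maximal(self):
        assert expected_heterozygosity(fv([0.5])) == pytest.approx(0.5)

    def test_all_monomorphic_is_zero(self):
        assert expected_heterozygosity(fv([0.0, 1.0, 0.0])) == 0.0

    def test_hand_arithmetic(self):
        # (2*.1*.9 + 2*.2*.8 + 2*.5*.5)/3 = (0.18+0.32+0.5)/3 = 1/3
        assert expected_heterozygosity(fv([0.1, 0.2, 0.5])) == pytest.approx(1 / 3)

    def test_uncalled_snps_excluded(self):
        f = fv([0.5, np.nan], n_called=[10, 0])
        assert expected_heterozygosity(f) == pytest.approx(0.5)

    def test_no_usable_snp_errors(self):
        with pytest.raises(ValueError, match="no SNP"):
            expected_heterozygosity(fv([np.nan], n_called=[0]))


class TestGeneticLoad:
    def _ann(self, classes):
        labels = {
            "n": "missense_variant",
            "s": "synonymous_variant",
            "o": "intergenic_region",
        }
        snp_ids = [f"1:{j + 1}:A:G" for j in range(len(classes))]
        return snp_ids, make_ann(snp_ids, [labels[c] for c in classes])

    def _freqs(self, p, snp_ids):
        return FrequencyVector(
            snp_ids=snp_ids, p=np.asarray(p, float),
            n_called_alleles=np.full(len(p), 10),
        )

    def test_symmetry_gives_unity(self):
        snp_ids, ann = self._ann("nnss")
        load = genetic_load(self._freqs([0.2, 0.2, 0.2, 0.2], snp_ids), ann)
        assert load.gl == pytest.approx(1.0)
        assert (load.pn, load.ps) == (2, 2)

    def test_hand_arithmetic_two_to_one(self):
        snp_ids, ann = self._ann("nnss")
        load = genetic_load(self._freqs([0.5, 0.5, 0.25, 0.25], snp_ids), ann)
        assert load.gl == pytest.approx((2 * 0.5) / (2 * 0.25))

    def test_hand_arithmetic_unbalanced_counts(self):
        snp_ids, ann = self._ann("nns")
        load = genetic_load(self._freqs([0.1, 0.3, 0.4], snp_ids), ann)
        assert load.gl == pytest.approx((2 * 0.2) / (1 * 0.4))

    def test_other_class_ignored(self):
        snp_ids, ann = self._ann("nso")
        load = genetic_load(self._freqs([0.2, 0.2, 0.9], snp_ids), ann)
        assert load.gl == pytest.approx(1.0)

    def test_fixed_sites_not_segregating(self):
        snp_ids, ann = self._ann("nnss")
        load = genetic_load(self._freqs([0.2, 1.0, 0.2, 0.0], snp_ids), ann)
        assert (load.pn, load.ps) == (1, 1)
        assert load.gl == pytest.approx(1.0)

    def test_no_segregating_synonymous_errors(self):
        snp_ids, ann = self._ann("ns")
        with pytest.raises(UndefinedLoadError):
            genetic_load(self._freqs([0.2, 0.0], snp_ids), ann)


class TestRatio:
    def test_ratio_is_plain_division(self):
        assert gd_gl_ratio(0.5, 2.0) == pytest.approx(0.25)

    @pytest.mark.parametrize("gl", [0.0, -1.0])
    def test_nonpositive_load_errors(self, gl):
        with pytest.raises(ValueError):
            gd_gl_ratio(0.1, gl)


def brute_force_gd_gl(dosages, classes):
    """Independent recomputation of GD and GL from raw dosages.

    Pure-Python loops; per-SNP frequency over called individuals, He
    averaged over SNPs with any call, class-wise segregating counts and
    frequency sums for GL.
    """
    n_ind = len(dosages)
    n_snp = len(dosages[0])
    hes, freqs = [], {}
    for j in range(n_snp):
        called = [dosages[i][j] for i in range(n_ind) if dosages[i][j] != MISSING]
        if not called:
            continue
        p = sum(called) / (2 * len(called))
        hes.append(2 * p * (1 - p))
        freqs[j] = p
    gd = sum(hes) / len(hes)
    sums = {"n": [0, 0.0], "s": [0, 0.0]}
    for j, p in freqs.items():
        if 0.0 < p < 1.0 and classes[j] in sums:
            sums[classes[j]][0] += 1
            sums[classes[j]][1] += p
    pn, sum_fn = sums["n"]
    ps, sum_fs = sums["s"]
    gl = sum_fn / sum_fs  # Pn*fn = sum of fn over the class
    return gd, gl, pn, ps


@pytest.mark.parametrize("trial", range(8))
def test_score_pool_matches_brute_force_oracle(trial):
    """GD/GL on <=10-SNP instances equals an independent recomputation."""
    rng = np.random.default_rng(100 + trial)
    n_ind, n_snp = rng.integers(3, 8), rng.integers(4, 11)
    d = rng.integers(0, 3, size=(n_ind, n_snp)).astype(np.int8)
    d[rng.random(d.shape) < 0.15] = MISSING
    classes = rng.choice(list("nso"), size=n_snp)
    # guarantee one segregating SNP of each load class
    classes[0], classes[1] = "s", "n"
    d[:, 0] = [1] + [0] * (n_ind - 1)
    d[:, 1] = [1] + [0] * (n_ind - 1)
    labels = {"n": "missense_variant", "s": "synonymous_variant",
              "o": "intergenic_region"}
    gm = make_gm(d, ["A"] * n_ind)
    ann = make_ann(gm.snp_ids, [labels[c] for c in classes])

    score = score_pool(gm, ann)
    gd, gl, pn, ps = brute_force_gd_gl(d.tolist(), list(classes))
    assert score.gd == pytest.approx(gd)
    assert score.gl == pytest.approx(gl)
    assert (score.pn, score.ps) == (pn, ps)
    assert score.ratio == pytest.approx(gd / gl)


@given(
    p=st.lists(st.floats(0.01, 0.99), min_size=1, max_size=20),
)
@settings(max_examples=50, deadline=None)
def test_gl_is_unity_for_matching_class_frequencies(p):
    """GL = 1 whenever nonsyn and syn frequency multisets coincide."""
    n = len(p)
    snp_ids = [f"1:{j + 1}:A:G" for j in range(2 * n)]
    ann = make_ann(
        snp_ids, ["missense_variant"] * n + ["synonymous_variant"] * n
    )
    freqs = FrequencyVector(
        snp_ids=snp_ids,
        p=np.array(p + p),
        n_called_alleles=np.full(2 * n, 10),
    )
    assert genetic_load(freqs, ann).gl == pytest.approx(1.0)


@given(data=st.data())
@settings(max_examples=40, deadline=None)
def test_pooled_gd_at_least_mean_of_population_gds(data):
    """Wahlund/Jensen: pooling equal-sized populations cannot lower mean He."""
    n_snp = data.draw(st.integers(1, 10))
    half = data.draw(st.integers(2, 6))
    cells = st.integers(0, 2)
    d = data.draw(
        st.lists(
            st.lists(cells, min_size=n_snp, max_size=n_snp),
            min_size=2 * half, max_size=2 * half,
        )
    )
    gm = make_gm(np.array(d, dtype=np.int8), ["A"] * half + ["B"] * half)
    f_all = allele_frequencies(gm)
    f_a = allele_frequencies(gm, gm.individuals_of(["A"]))
    f_b = allele_frequencies(gm, gm.individuals_of(["B"]))
    pooled = expected_heterozygosity(f_all)
    mean_within = 0.5 * (
        expected_heterozygosity(f_a) + expected_heterozygosity(f_b)
    )
    assert pooled >= mean_within - 1e-12


def test_duplicating_every_individual_changes_nothing():
    """GD and GL depend on frequencies, not on pool size."""
    rng = np.random.default_rng(3)
    d = rng.integers(0, 3, size=(5, 12)).astype(np.int8)
    labels = ["missense_variant"] * 6 + ["synonymous_variant"] * 6
    gm = make_gm(d, ["A"] * 5)
    gm2 = make_gm(np.vstack([d, d]), ["A"] * 10)
    ann = make_ann(gm.snp_ids, labels)
    s1, s2 = score_pool(gm, ann), score_pool(gm2, ann)
    assert s2.gd == pytest.approx(s1.gd)
    assert s2.gl == pytest.approx(s1.gl)


def test_gd_respects_biallelic_bound():
    rng = np.random.default_rng(4)
    for _ in range(10):
        d = rng.integers(0, 3, size=(6, 15)).astype(np.int8)
        gd = expected_heterozygosity(allele_frequencies(make_gm(d, ["A"] * 6)))
        assert 0.0 <= gd <= 0.5
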