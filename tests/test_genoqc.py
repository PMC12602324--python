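"""Genotype QC: HWE exact test vs enumeration, filter order, relatedness,
VIF pruning vs brute force, dominant coding and allele harmonization."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from gxewas import genoqc
from gxewas.datatypes import GenotypeMatrix
from gxewas.genoqc import QCThresholds


def hwe_enumeration_oracle(n_hom1, n_het, n_hom2):
    """Brute-force exact HWE p: enumerate every heterozygote count compatible
    with the allele counts and sum probabilities <= the observed one."""
    n = n_hom1 + n_het + n_hom2
    n_minor = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    probs = {}
    for het in range(n_minor % 2, n_minor + 1, 2):
        hom_min = (n_minor - het) // 2
        hom_maj = n - het - hom_min
        if hom_maj < 0:
            continue
        probs[het] = (comb(n, hom_maj, exact=True) * comb(n - hom_maj, het, exact=True)
                      * 2 ** het) / comb(2 * n, n_minor, exact=True)
    p_obs = probs[n_het]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


def _geno(calls, **meta_kw):
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    meta = pd.DataFrame({
        "snp": [f"s{j}" for j in range(m)],
        "chrom": meta_kw.get("chrom", [1] * m),
        "pos": meta_kw.get("pos", np.arange(1, m + 1) * 100),
        "allele1": ["A"] * m, "allele2": ["G"] * m,
    })
    if "info" in meta_kw:
        meta["info"] = meta_kw["info"]
    return GenotypeMatrix(pd.Index([f"i{i}" for i in range(n)]), meta, calls)


class TestHWEExact:
    def test_monomorphic_p_is_one(self):
        assert genoqc.hwe_exact_test(100, 0, 0) == 1.0

    def test_all_homozygote_split_fires_filter(self):
        assert genoqc.hwe_exact_test(50, 0, 50) < 1e-7

    def test_small_table_matches_enumeration(self):
        assert genoqc.hwe_exact_test(1, 2, 1) == pytest.approx(
            hwe_enumeration_oracle(1, 2, 1), abs=1e-12)

    def test_matches_enumeration_for_all_small_tables(self):
        for n in range(1, 21):
            for n_hom1 in range(n + 1):
                for n_het in range(n - n_hom1 + 1):
                    n_hom2 = n - n_hom1 - n_het
                    assert genoqc.hwe_exact_test(n_hom1, n_het, n_hom2) == pytest.approx(
                        hwe_enumeration_oracle(n_hom1, n_het, n_hom2), abs=1e-12), \
                        (n_hom1, n_het, n_hom2)

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            genoqc.hwe_exact_test(-1, 2, 3)


class TestSnpFilter:
    def test_low_call_rate_dropped(self, rng):
        calls = rng.integers(0, 3, (100, 2)).astype(float)
        calls[:6, 0] = np.nan  # 94% call rate
        geno, log = genoqc.snp_filter(_geno(calls))
        assert log.set_index("snp").loc["s0", "reason"] == "call_rate"
        assert geno.n_snps == 1

    def test_low_maf_dropped(self, rng):
        calls = np.zeros((100, 2))
        calls[:8, 0] = 1.0   # MAF 0.04
        calls[:50, 1] = 1.0  # MAF 0.25
        geno, log = genoqc.snp_filter(_geno(calls))
        assert log.set_index("snp").loc["s0", "reason"] == "maf"
        assert geno.snps["snp"].tolist() == ["s1"]

    def test_clean_common_snps_all_pass(self, rng):
        maf = rng.uniform(0.2, 0.5, 10)
        calls = rng.binomial(1, maf, (500, 10)) + rng.binomial(1, maf, (500, 10))
        geno, log = genoqc.snp_filter(_geno(calls.astype(float)))
        assert len(log) == 0 and geno.n_snps == 10

    def test_info_filter_and_indels(self, rng):
        calls = rng.integers(0, 2, (200, 3)).astype(float)
        g = _geno(calls, info=[1.0, 0.2, 1.0])
        g.snps.loc[2, "allele2"] = "AT"  # indel-style record
        geno, log = genoqc.snp_filter(g, QCThresholds(info_min=0.3, hwe_p_min=0.0))
        reasons = log.set_index("snp")["reason"]
        assert reasons.loc["s1"] == "info"
        assert reasons.loc["s2"] == "indel_multiallelic"

    def test_idempotent_for_marginal_filters(self, rng):
        maf = rng.uniform(0.2, 0.5, 8)
        calls = (rng.binomial(1, maf, (300, 8)) + rng.binomial(1, maf, (300, 8))).astype(float)
        calls[rng.random(calls.shape) < 0.02] = np.nan
        geno, _ = genoqc.snp_filter(_geno(calls))
        geno2, log2 = genoqc.snp_filter(geno)
        assert not log2["reason"].isin(["call_rate", "maf", "info"]).any()
        assert geno2.n_snps == geno.n_snps or log2["reason"].eq("hwe").all()


class TestRelatednessExclude:
    def test_no_flagged_pairs_all_retained(self):
        subs = pd.Index(list("abc"))
        pairs = pd.DataFrame({"id1": ["a"], "id2": ["b"], "ibd": [0.1]})
        out = genoqc.relatedness_exclude(subs, pairs, pd.Series(1.0, index=subs))
        assert out.tolist() == list("abc")

    def test_more_complete_member_kept(self):
        subs = pd.Index(["a", "b"])
        pairs = pd.DataFrame({"id1": ["a"], "id2": ["b"], "ibd": [0.5]})
        comp = pd.Series({"a": 0.99, "b": 0.80})
        out = genoqc.relatedness_exclude(subs, pairs, comp)
        assert out.tolist() == ["a"]

    def test_chain_resolution_leaves_no_flagged_pair(self):
        subs = pd.Index(list("abc"))
        pairs = pd.DataFrame({"id1": ["a", "b"], "id2": ["b", "c"], "ibd": [0.5, 0.4]})
        for comp_vals in itertools.product([0.7, 0.9], repeat=3):
            comp = pd.Series(dict(zip("abc", comp_vals)))
            kept = set(genoqc.relatedness_exclude(subs, pairs, comp, seed=3))
            for _, row in pairs.iterrows():
                assert not ({row["id1"], row["id2"]} <= kept)

    def test_unknown_subject_raises(self):
        pairs = pd.DataFrame({"id1": ["a"], "id2": ["z"], "ibd": [0.5]})
        with pytest.raises(ValueError, match="unknown"):
            genoqc.relatedness_exclude(pd.Index(["a", "b"]), pairs, pd.Series({"a": 1}))


def brute_force_max_retained(calls, vif_max=2.0):
    """Largest subset (ties: earliest lexicographically) with all VIFs <= cap."""
    m = calls.shape[1]
    best = ()
    for r in range(m, 0, -1):
        for combo in itertools.combinations(range(m), r):
            sub = calls[:, combo]
            if genoqc._vif(sub).max() <= vif_max:
                return set(combo)
    return set(best)


class TestVifPrune:
    def test_duplicate_column_one_removed(self, rng):
        col = rng.integers(0, 3, 100).astype(float)
        other = rng.integers(0, 3, 100).astype(float)
        geno = _geno(np.column_stack([col, col, other]))
        kept = genoqc.vif_prune(geno)
        assert len(kept) == 2 and "s2" in set(kept)

    def test_independent_snps_all_kept(self, rng):
        calls = rng.binomial(2, 0.4, (300, 8)).astype(float)
        geno = _geno(calls)
        assert len(genoqc.vif_prune(geno)) == 8

    def test_matches_brute_force_on_toy_window(self, rng):
        # 6 SNPs, some built as combinations of others
        base = rng.binomial(1, 0.4, (80, 3)).astype(float)
        noisy = base[:, 1].copy()
        flips = rng.random(80) < 0.1
        noisy[flips] = 1.0 - noisy[flips]
        calls = np.column_stack([
            base[:, 0], base[:, 1], base[:, 2],
            base[:, 0] + base[:, 1],  # exact linear combination
            noisy,                    # highly but not perfectly correlated
            rng.binomial(2, 0.3, 80),
        ])
        geno = _geno(calls)
        kept_ids = set(genoqc.vif_prune(geno, window=6, step=6))
        kept_idx = {int(s[1:]) for s in kept_ids}
        assert genoqc._vif(calls[:, sorted(kept_idx)]).max() <= 2.0
        assert len(kept_idx) == len(brute_force_max_retained(calls))

    def test_unsorted_positions_raise(self, rng):
        calls = rng.binomial(2, 0.4, (50, 3)).astype(float)
        geno = _geno(calls, pos=[300, 100, 200])
        with pytest.raises(ValueError, match="position-sorted"):
            genoqc.vif_prune(geno)


class TestDominantCode:
    def test_contrast_when_allele1_minor(self):
        coded, mono = genoqc.dominant_code(np.array([[0.0], [1.0], [2.0]]), [True])
        assert coded[:, 0].tolist() == [0.0, 1.0, 1.0]
        assert not mono[0]

    def test_monomorphic_flagged(self):
        coded, mono = genoqc.dominant_code(np.zeros((5, 1)), [True])
        assert mono[0] and set(coded[:, 0]) == {0.0}

    def test_missing_propagates(self):
        coded, _ = genoqc.dominant_code(np.array([[np.nan], [2.0]]), [True])
        assert np.isnan(coded[0, 0]) and coded[1, 0] == 1.0

    def test_label_swap_harmonizes_to_same_coding(self, rng):
        calls = rng.integers(0, 3, (50, 1)).astype(float)
        ref = pd.DataFrame({"snp": ["s0"], "allele1": ["A"], "allele2": ["G"]})
        snps_swapped = pd.DataFrame({"snp": ["s0"], "allele1": ["G"], "allele2": ["A"]})
        flip, drop = genoqc.harmonize_alleles(snps_swapped, ref)
        assert flip[0] and not drop[0]
        flipped_calls = 2.0 - calls
        a, _ = genoqc.dominant_code(calls, [True])
        b, _ = genoqc.dominant_code(flipped_calls, [False])
        assert np.array_equal(a, b, equal_nan=True)

    def test_ambiguous_strand_snp_dropped(self):
        ref = pd.DataFrame({"snp": ["s0"], "allele1": ["A"], "allele2": ["T"]})
        snps = pd.DataFrame({"snp": ["s0"], "allele1": ["A"], "allele2": ["T"]})
        flip, drop = genoqc.harmonize_alleles(snps, ref)
        assert drop[0]

    def test_true_mismatch_raises(self):
        ref = pd.DataFrame({"snp": ["s0"], "allele1": ["A"], "allele2": ["G"]})
        snps = pd.DataFrame({"snp": ["s0"], "allele1": ["A"], "allele2": ["C"]})
        with pytest.raises(ValueError, match="s0"):
            genoqc.harmonize_alleles(snps, ref)
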