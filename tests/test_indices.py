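"""CAI, RSCU (both conventions), RCBS, MRCBS and the expression threshold."""

import math

import mpmath
import pytest

from codonuse import (
    CodingSequence,
    classify_expression,
    count_codons,
    mrcbs,
    pool_counts,
    rcbs,
    reference_weights,
    rscu_classical,
    rscu_fraction,
)
from codonuse.codon_core import ALL_CODONS, STANDARD_CODE, CodonCountTable
from codonuse.indices import cai
from codonuse.synthetic import SyntheticSpec, generate_cds


def table(**counts):
    return CodonCountTable(source_id="t", counts=counts)


def geometric_mean_oracle(weighted):
    """Extended-precision product-then-Nth-root, independent of log-space code."""
    with mpmath.workdps(60):
        prod = mpmath.mpf(1)
        n = 0
        for value, count in weighted:
            prod *= mpmath.mpf(value) ** count
            n += count
        return float(prod ** (mpmath.mpf(1) / n))


class TestReferenceWeights:
    def test_phe_family(self):
        w = reference_weights(table(TTT=3, TTC=1))
        assert w["TTT"] == 1.0
        assert w["TTC"] == pytest.approx(1 / 3)

    def test_single_codon_family(self):
        w = reference_weights(table(ATG=5))
        assert w["ATG"] == 1.0

    def test_tied_family_both_one(self):
        w = reference_weights(table(GAT=4, GAC=4))
        assert w["GAT"] == w["GAC"] == 1.0

    def test_unused_family_undefined(self):
        w = reference_weights(table(TTT=3))
        assert "GGG" not in w

    def test_zero_count_in_used_family_gets_pseudo_weight(self):
        w = reference_weights(table(TTT=4))
        assert w["TTC"] == pytest.approx(0.5 / 4)
        assert "TTC" in w.pseudo_codons

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            reference_weights(table())

    def test_family_max_is_one(self, small_corpus):
        seqs, _ = small_corpus
        w = reference_weights(pool_counts([count_codons(s) for s in seqs]))
        for aa, family in STANDARD_CODE.families.items():
            defined = [w[c] for c in family if c in w]
            if defined:
                assert max(defined) == pytest.approx(1.0)


class TestCai:
    def test_all_maximal_codons_give_one(self):
        ref = table(TTT=3, TTC=1, GAT=5, GAC=2)
        gene = table(TTT=7, GAT=2)
        assert cai(gene, reference_weights(ref)).value == pytest.approx(1.0)

    def test_constant_weight_geometric_mean(self):
        ref = table(TTT=4, TTC=1)  # w(TTC) = 0.25
        gene = table(TTC=10)
        assert cai(gene, reference_weights(ref)).value == pytest.approx(0.25)

    def test_excluded_only_gene_rejected(self):
        ref = table(ATG=1, TGG=1, TTT=1)
        gene = table(ATG=3, TGG=2)  # Met/Trp excluded by default
        with pytest.raises(ValueError):
            cai(gene, reference_weights(ref))

    def test_met_trp_stop_do_not_move_cai(self):
        ref = table(TTT=4, TTC=1, ATG=2, TGG=2, TAA=1)
        w = reference_weights(ref)
        lean = table(TTC=5)
        padded = table(TTC=5, ATG=9, TGG=9, TAA=3)
        assert cai(lean, w).value == pytest.approx(cai(padded, w).value)

    def test_matches_brute_force_product(self, small_corpus):
        """Log-space CAI vs extended-precision product-then-root oracle."""
        seqs, _ = small_corpus
        tables = [count_codons(s) for s in seqs]
        w = reference_weights(pool_counts(tables))
        for t in tables[:10]:
            weighted = [
                (w[c], n)
                for c, n in t.counts.items()
                if n and c in w
                and STANDARD_CODE.codon_to_aa[c] not in {"M", "W", "*"}
            ]
            assert cai(t, w).value == pytest.approx(
                geometric_mean_oracle(weighted), abs=1e-10
            )

    def test_bounds(self, small_corpus):
        seqs, _ = small_corpus
        tables = [count_codons(s) for s in seqs]
        w = reference_weights(pool_counts(tables))
        for t in tables:
            assert 0.0 < cai(t, w).value <= 1.0


class TestRscu:
    def test_fraction_phe(self):
        v = rscu_fraction(table(TTT=3, TTC=1))
        assert v["TTT"] == 0.75 and v["TTC"] == 0.25

    def test_fraction_equal_usage_at_threshold(self):
        v = rscu_fraction(table(GAT=5, GAC=5))
        assert v["GAT"] == v["GAC"] == 0.5

    def test_fraction_fourfold_equal(self):
        v = rscu_fraction(table(GGT=2, GGC=2, GGA=2, GGG=2))
        assert all(v[c] == 0.25 for c in ("GGT", "GGC", "GGA", "GGG"))

    def test_classical_equal_usage_is_one(self):
        v = rscu_classical(table(GGT=2, GGC=2, GGA=2, GGG=2))
        assert all(v[c] == pytest.approx(1.0) for c in ("GGT", "GGC", "GGA", "GGG"))

    def test_classical_phe(self):
        v = rscu_classical(table(TTT=3, TTC=1))
        assert v["TTT"] == pytest.approx(1.5) and v["TTC"] == pytest.approx(0.5)

    def test_classical_is_degeneracy_times_fraction(self, small_corpus):
        seqs, _ = small_corpus
        t = count_codons(seqs[0])
        frac, classical = rscu_fraction(t), rscu_classical(t)
        for c in ALL_CODONS:
            ni = STANDARD_CODE.degeneracy(c)
            assert classical[c] == pytest.approx(ni * frac[c], abs=1e-12)

    def test_family_sums(self, small_corpus):
        seqs, _ = small_corpus
        t = count_codons(seqs[0])
        frac, classical = rscu_fraction(t), rscu_classical(t)
        for aa, family in STANDARD_CODE.families.items():
            if sum(t.counts[c] for c in family) == 0:
                continue
            assert sum(frac[c] for c in family) == pytest.approx(1.0, abs=1e-12)
            assert sum(classical[c] for c in family) == pytest.approx(
                len(family), abs=1e-12
            )


class TestRcbs:
    def test_two_codon_hand_arithmetic(self):
        # f(AAA)=0.5 and every positional product is 0.5^3 = 0.125
        vec, score = rcbs(table(AAA=1, TTT=1))
        assert vec["AAA"] == pytest.approx(4.0)
        assert vec["TTT"] == pytest.approx(4.0)
        assert score.value == pytest.approx(4.0)

    def test_single_codon_type_is_one(self):
        vec, score = rcbs(table(ATG=17))
        assert vec["ATG"] == pytest.approx(1.0)
        assert score.value == pytest.approx(1.0)

    def test_uncounted_codons_zero(self):
        vec, _ = rcbs(table(AAA=1, TTT=1))
        assert vec["ACG"] == 0.0


class TestMrcbs:
    def test_family_max_is_one(self, small_corpus):
        seqs, _ = small_corpus
        t = count_codons(seqs[0])
        vec, _ = mrcbs(t)
        for aa, family in STANDARD_CODE.families.items():
            used = [vec[c] for c in family if t.counts[c] > 0]
            if used:
                assert max(used) == pytest.approx(1.0)
                assert all(v <= 1.0 for v in used)

    def test_single_codon_family_is_one(self):
        vec, _ = mrcbs(table(ATG=3, TTT=2, TTC=5))
        assert vec["ATG"] == pytest.approx(1.0)

    def test_gene_score_matches_brute_force(self, small_corpus):
        seqs, _ = small_corpus
        for s in seqs[:10]:
            t = count_codons(s)
            vec, score = mrcbs(t)
            weighted = [(vec[c], n) for c, n in t.counts.items() if n]
            assert score.value == pytest.approx(
                geometric_mean_oracle(weighted), abs=1e-10
            )
            assert 0.0 < score.value <= 1.0


class TestScaleInvariance:
    def test_indices_unchanged_by_count_multiplication(self, small_corpus):
        seqs, _ = small_corpus
        t = count_codons(seqs[0])
        scaled = t.scaled(7)
        assert rscu_fraction(t).values == pytest.approx(
            rscu_fraction(scaled).values
        )
        assert rscu_classical(t).values == pytest.approx(
            rscu_classical(scaled).values
        )
        vec, score = rcbs(t)
        vec_s, score_s = rcbs(scaled)
        assert vec.values == pytest.approx(vec_s.values)
        assert score.value == pytest.approx(score_s.value)
        mvec, mscore = mrcbs(t)
        mvec_s, mscore_s = mrcbs(scaled)
        assert mvec.values == pytest.approx(mvec_s.values)
        assert mscore.value == pytest.approx(mscore_s.value)
        # observed weights are scale-free; pseudo-weights deliberately are
        # not (they stand for "fewer than one observation" in the reference)
        w = reference_weights(t)
        w_s = reference_weights(scaled)
        observed = {c for c in w.w if c not in w.pseudo_codons}
        assert {c: w[c] for c in observed} == pytest.approx(
            {c: w_s[c] for c in observed}
        )


class TestClassifyExpression:
    def test_boundary_is_low(self):
        assert classify_expression({"N": 0.62})["N"] == "low"

    def test_all_one_all_high(self):
        out = classify_expression({aa: 1.0 for aa in "NDKF"})
        assert set(out.values()) == {"high"}

    def test_engineered_asn_bias_is_high(self):
        """A corpus built to use only the preferred Asn codon scores Asn high."""
        spec = SyntheticSpec(
            n_sequences=1,
            length_range=(300, 300),
            aa_composition={"N": 0.5, "L": 0.5},
            codon_preferences={
                "N": {"AAT": 1.0},
                "L": {c: 1 / 6 for c in STANDARD_CODE.families["L"]},
            },
            target_gc_band=None,
            seed=3,
        )
        seq, _ = generate_cds(spec, 0)
        vec, _ = mrcbs(count_codons(seq))
        aa_mean = {}
        for aa in ("N", "L"):
            used = [
                vec[c]
                for c in STANDARD_CODE.families[aa]
                if count_codons(seq).counts[c] > 0
            ]
            aa_mean[aa] = sum(used) / len(used)
        out = classify_expression(aa_mean)
        assert out["N"] == "high"

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify_expression({"N": 0.5}, threshold=1.5)
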