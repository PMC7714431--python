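import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import jensenshannon

from rapscan import (
    AAFreqDist,
    BackgroundModel,
    NucSeq,
    STANDARD_CODE,
    aa_frequencies,
    bias_test,
    codon_normalize,
    codon_usage,
    ctd_reference,
    gaussian_lower_tail_p,
    jsd,
    make_rap_set,
    sample_null,
)
from rapscan.ctd_bias import _aa_counts_from_bases
from rapscan.seqcore import AA_INDEX, AA_ORDER, ProteinSeq, translate

HEPTAD_DNA = "TATTCTCCTACTTCTCCTTCT"  # frame-0 translation YSPTSPS


def dist(**freqs):
    v = np.zeros(20)
    for aa, f in freqs.items():
        v[AA_INDEX[aa]] = f
    return AAFreqDist(freqs=v)


random_dist = st.lists(
    st.floats(min_value=0.01, max_value=10.0), min_size=20, max_size=20
).map(lambda xs: AAFreqDist(freqs=np.array(xs) / np.sum(xs)))


class TestAAFrequencies:
    def test_heptad_frame0_composition(self):
        d = aa_frequencies([NucSeq(id="h", seq=HEPTAD_DNA)], frames=(0,))
        expected = dist(Y=1 / 7, S=3 / 7, P=2 / 7, T=1 / 7)
        assert np.allclose(d.freqs, expected.freqs)

    def test_all_61_sense_codons_give_multiplicity_over_61(self):
        seq = "".join(STANDARD_CODE.sense_codons)
        d = aa_frequencies([NucSeq(id="all", seq=seq)], frames=(0,))
        expected = np.array(
            [STANDARD_CODE.codon_multiplicity[aa] / 61 for aa in AA_ORDER]
        )
        assert np.allclose(d.freqs, expected)

    def test_pooling_duplicates_is_scale_invariant(self):
        s = NucSeq(id="a", seq="ATGGCTTACTAC")
        one = aa_frequencies([s])
        two = aa_frequencies([s, NucSeq(id="b", seq=s.seq)])
        assert np.allclose(one.freqs, two.freqs)

    def test_read_count_weighting_equals_duplication(self):
        a = NucSeq(id="a", seq="ATGGCTTACTACGGG")
        b = NucSeq(id="b", seq="CCTCCTTCTTCTTAT")
        weighted = aa_frequencies([a, b], weights=[3, 1])
        duplicated = aa_frequencies([a, NucSeq(id="a2", seq=a.seq), NucSeq(id="a3", seq=a.seq), b])
        assert np.allclose(weighted.freqs, duplicated.freqs)

    def test_stops_and_unknowns_excluded(self):
        # TAA stop and NNN codon contribute nothing
        d = aa_frequencies([NucSeq(id="s", seq="ATGTAANNN")], frames=(0,))
        assert d.freqs[AA_INDEX["M"]] > 0
        with pytest.raises(ValueError, match="empty composition"):
            aa_frequencies([NucSeq(id="x", seq="TAATAA")], frames=(0,))


class TestCodonNormalize:
    def test_multiplicity_distribution_becomes_uniform(self):
        raw = AAFreqDist(
            freqs=np.array([STANDARD_CODE.codon_multiplicity[aa] / 61 for aa in AA_ORDER])
        )
        normed = codon_normalize(raw)
        assert np.allclose(normed.freqs, np.full(20, 1 / 20), atol=1e-12)

    def test_heptad_distribution(self):
        normed = codon_normalize(dist(Y=1 / 7, S=3 / 7, P=2 / 7, T=1 / 7))
        expected = dist(Y=2 / 7, S=2 / 7, P=2 / 7, T=1 / 7)
        assert np.allclose(normed.freqs, expected.freqs)

    def test_point_mass_unchanged(self):
        normed = codon_normalize(dist(W=1.0))
        assert np.allclose(normed.freqs, dist(W=1.0).freqs)


class TestCtdReference:
    def test_default_heptad_reference(self):
        ref = ctd_reference()
        expected = dist(Y=2 / 7, S=2 / 7, P=2 / 7, T=1 / 7)
        assert np.allclose(ref.freqs, expected.freqs)

    def test_repetition_invariance(self):
        two = ctd_reference(ProteinSeq(id="c", seq="YSPTSPSYSPTSPS"))
        assert np.allclose(two.freqs, ctd_reference().freqs)

    def test_single_residue_point_mass(self):
        ref = ctd_reference(ProteinSeq(id="w", seq="W"))
        assert np.allclose(ref.freqs, dist(W=1.0).freqs)


class TestJSD:
    def test_identical_distributions_give_zero(self):
        p = dist(Y=0.5, S=0.5)
        assert jsd(p, p) == 0.0

    def test_disjoint_point_masses_give_one(self):
        assert jsd(dist(Y=1.0), dist(W=1.0)) == pytest.approx(1.0, abs=1e-12)

    def test_half_versus_point_mass(self):
        p = np.array([0.5, 0.5] + [0.0] * 18)
        q = np.array([1.0] + [0.0] * 19)
        assert jsd(p, q) == pytest.approx(0.31128, abs=1e-5)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            jsd(np.full(20, 0.1), np.full(20, 0.05))

    @given(p=random_dist, q=random_dist)
    @settings(max_examples=100)
    def test_axioms_and_scipy_cross_check(self, p, q):
        v = jsd(p, q)
        assert 0.0 <= v <= 1.0
        assert jsd(q, p) == pytest.approx(v, abs=1e-12)
        # scipy returns the square root of the divergence
        assert v == pytest.approx(jensenshannon(p.freqs, q.freqs, base=2) ** 2, abs=1e-9)


class TestNullSampling:
    def test_vectorised_counts_equal_string_translation(self, rng):
        """The fast numpy counting path must agree exactly with
        translating each frame as a string and tallying."""
        lengths = [23, 37, 50, 7]
        bases, bounds, seqs, pos = [], [], [], 0
        for i, L in enumerate(lengths):
            b = rng.integers(0, 4, size=L)
            bases.append(b)
            bounds.append((pos, pos + L))
            pos += L
            seqs.append(NucSeq(id=f"s{i}", seq="".join("ACGT"[x] for x in b)))
        fast = _aa_counts_from_bases(np.concatenate(bases), bounds)
        slow = np.zeros(20, dtype=int)
        for s in seqs:
            for f in (0, 1, 2):
                if len(s) - f < 3:
                    continue
                for aa in translate(s, f).seq:
                    if aa not in "*X":
                        slow[AA_INDEX[aa]] += 1
        assert np.array_equal(fast, slow)

    def test_same_seed_reproduces_samples(self):
        ref = ctd_reference()
        bg = BackgroundModel.human_genome()
        a = sample_null([60] * 5, bg, ref, n_sets=100, seed=5)
        b = sample_null([60] * 5, bg, ref, n_sets=100, seed=5)
        assert np.array_equal(a.samples, b.samples)

    def test_samples_bounded(self):
        null = sample_null([45] * 10, BackgroundModel.uniform(), ctd_reference(), 200, seed=1)
        assert np.all((null.samples >= 0) & (null.samples <= 1))

    def test_small_n_sets_rejected(self):
        with pytest.raises(ValueError, match="n_sets"):
            sample_null([60], BackgroundModel.uniform(), ctd_reference(), 50, seed=0)

    def test_null_mean_decreases_with_length_against_own_composition(self):
        # against the null's own expected composition, divergence is
        # pure sampling noise and must shrink as sequences grow
        bg = BackgroundModel.uniform()
        own = codon_normalize(
            aa_frequencies([NucSeq(id="all", seq="".join(STANDARD_CODE.sense_codons))],
                           frames=(0,))
        )
        short = sample_null([30] * 3, bg, own, 300, seed=9)
        long = sample_null([3000] * 3, bg, own, 300, seed=9)
        assert long.mean < short.mean


class TestBiasTest:
    def test_gaussian_tail_at_ten_sigma(self):
        p = gaussian_lower_tail_p(-10.0)
        assert p == pytest.approx(7.62e-24, rel=1e-2)

    def test_exact_ctd_mosaic_has_zero_frame0_divergence(self):
        seqs = make_rap_set(n=5, length=147, ctd_fraction=1.0, seed=3)
        obs = codon_normalize(aa_frequencies(seqs, frames=(0,)))
        assert jsd(obs, ctd_reference()) == pytest.approx(0.0, abs=1e-12)

    def test_background_sequences_are_not_significant(self):
        seqs = make_rap_set(n=50, length=120, ctd_fraction=0.0, seed=17)
        res = bias_test(seqs, n_sets=300, seed=18)
        assert -4 < res.z < 4
        assert res.p_empirical > 1 / 301

    def test_planted_signal_detected(self):
        seqs = make_rap_set(n=40, length=150, ctd_fraction=0.7, seed=23)
        res = bias_test(seqs, n_sets=300, seed=24)
        assert res.z < -5
        assert res.p_empirical == 1 / 301
        assert res.p_gaussian < 1e-6


class TestCodonUsage:
    def test_three_frame_enumeration(self):
        profile = codon_usage([NucSeq(id="t", seq="TCTTCT")])
        assert profile.counts == {"TCT": 2, "CTT": 1, "TTC": 1}

    def test_total_codon_count_identity(self, rng):
        seqs = [
            NucSeq(id=f"s{i}", seq="".join(rng.choice(list("ACGT"), L)))
            for i, L in enumerate([17, 30, 8])
        ]
        profile = codon_usage(seqs)
        expected = sum((len(s) - f) // 3 for s in seqs for f in (0, 1, 2))
        assert profile.total == expected

    def test_stop_codons_counted_and_flagged(self):
        profile = codon_usage([NucSeq(id="s", seq="TAATAA")])
        assert profile.counts["TAA"] == 2
        assert profile.stop_codon_total >= 2
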