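import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mlocpred import encoders as enc
from mlocpred.encoders import (
    DINUCLEOTIDES,
    GROUP_DIMS,
    TRINUCLEOTIDES,
    PropertyTable,
    encode_dataset,
    encode_dpcp,
    encode_kmer,
    encode_pseeiip,
    encode_pseknc,
    encode_tpcp,
    encode_zcurve_phase_independent,
    encode_zcurve_phase_specific,
    kmer_counts,
    load_eiip,
    oligos,
)
from mlocpred.seqio import NucleotideSequence
from tests.conftest import random_dna

dna = st.text(alphabet="ACGT", min_size=12, max_size=120)


class TestKmerCounts:
    @pytest.mark.parametrize(
        "seq,k,expected",
        [
            ("ACGT", 2, {"AC": 1, "CG": 1, "GT": 1}),
            ("AAAA", 2, {"AA": 3}),
            ("ACGT", 1, {"A": 1, "C": 1, "G": 1, "T": 1}),
        ],
    )
    def test_hand_counts(self, seq, k, expected):
        assert kmer_counts(seq, k) == expected

    def test_too_short_and_bad_k(self):
        with pytest.raises(ValueError):
            kmer_counts("ACGT", 5)
        with pytest.raises(ValueError):
            kmer_counts("ACGTACGT", 6)

    @settings(derandomize=True, max_examples=50)
    @given(dna, st.integers(1, 5))
    def test_counts_sum_to_window_count(self, seq, k):
        assert sum(kmer_counts(seq, k).values()) == len(seq) - k + 1


class TestEncodeKmer:
    def test_small_sequence_hand_arithmetic(self):
        v = encode_kmer("ACGTA")
        lookup = dict(zip(v.names, v.values))
        # dinucleotide counts AC=1, CG=1, GT=1, TA=1, each over L=5
        for d in ("AC", "CG", "GT", "TA"):
            assert lookup[f"KMER:{d}"] == pytest.approx(1 / 5)
        k2 = [val for name, val in lookup.items() if len(name) == 7]
        assert sum(k2) == pytest.approx(4 / 5)  # (L - k + 1) / L

    def test_homopolymer_ladder(self):
        v = encode_kmer("AAAAAA")
        lookup = dict(zip(v.names, v.values))
        assert lookup["KMER:AA"] == pytest.approx(5 / 6)
        assert lookup["KMER:AAA"] == pytest.approx(4 / 6)
        assert lookup["KMER:AAAA"] == pytest.approx(3 / 6)
        assert lookup["KMER:AAAAA"] == pytest.approx(2 / 6)
        assert sum(x for x in v.values) == pytest.approx((5 + 4 + 3 + 2) / 6)

    def test_dimension(self):
        assert len(encode_kmer("ACGTACGTAC").values) == 1360

    def test_too_short(self):
        with pytest.raises(ValueError):
            encode_kmer("ACGT")

    @settings(derandomize=True, max_examples=40)
    @given(dna)
    def test_block_sums_match_window_fraction(self, seq):
        """Each k block sums to (L - k + 1) / L under the length denominator."""
        v = encode_kmer(seq)
        L = len(seq)
        offset = 0
        for k in range(2, 6):
            block = v.values[offset : offset + 4**k]
            assert block.sum() == pytest.approx((L - k + 1) / L, abs=1e-12)
            offset += 4**k

    def test_per_window_normalization_sums_to_one(self):
        v = encode_kmer("ACGTACGTACGT", normalization="per_window")
        offset = 0
        for k in range(2, 6):
            assert v.values[offset : offset + 4**k].sum() == pytest.approx(1.0)
            offset += 4**k

    def test_reverse_complement_is_permutation(self, rng):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(50):
            seq = random_dna(rng, 30)
            rc = "".join(comp[b] for b in reversed(seq))
            a = np.sort(encode_kmer(seq).values)
            b = np.sort(encode_kmer(rc).values)
            np.testing.assert_allclose(a, b, atol=1e-15)

    def test_purity(self, rng):
        seq = random_dna(rng, 80)
        assert np.array_equal(encode_kmer(seq).values, encode_kmer(seq).values)


class TestPseKNC:
    def test_dimension(self):
        assert len(encode_pseknc("ACGTACGTACGTACGT").values) == 1370

    def test_lambda_zero_is_pure_composition(self):
        seq = "ACGTACGTACGTACGT"
        v = encode_pseknc(seq, lambda_=0)
        assert len(v.values) == 1360
        # each tier is the per-window k-mer composition scaled by 1/4
        offset = 0
        for k in range(2, 6):
            counts = kmer_counts(seq, k)
            expected = np.array(
                [counts.get(o, 0) / (len(seq) - k + 1) for o in oligos(k)]
            )
            np.testing.assert_allclose(
                v.values[offset : offset + 4**k], expected / 4.0, atol=1e-12
            )
            offset += 4**k

    def test_homopolymer_correlations_constant(self):
        """A homopolymer has zero property variance along the sequence, so
        every lag correlation collapses to the same value (0 for the
        squared-difference correlation function)."""
        v = encode_pseknc("A" * 50)
        lam = v.values[-10:]
        assert np.all(lam == lam[0])
        assert lam[0] == pytest.approx(0.0, abs=1e-15)

    def test_too_short_for_lambda(self):
        with pytest.raises(ValueError, match="at least"):
            encode_pseknc("ACGTACGT", lambda_=10)

    @settings(derandomize=True, max_examples=25)
    @given(dna.filter(lambda s: len(s) >= 12))
    def test_vector_sums_to_one(self, seq):
        assert encode_pseknc(seq).values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_weight_moves_mass_to_correlation_tier(self, rng):
        seq = random_dna(rng, 100)
        low = encode_pseknc(seq, w=0.01).values[-10:].sum()
        high = encode_pseknc(seq, w=1.0).values[-10:].sum()
        assert high > low


def reconstruct_prefix_freqs(components, prefix_totals):
    """Invert the Z-curve projection: recover p(LM*) from (x, y, z) plus
    the prefix marginal s = sum over the four extensions."""
    out = {}
    for i, d in enumerate(DINUCLEOTIDES):
        x, y, z = components[3 * i : 3 * i + 3]
        s = prefix_totals[d]
        out[d + "A"] = (s + x + y + z) / 4
        out[d + "C"] = (s - x + y - z) / 4
        out[d + "G"] = (s + x - y - z) / 4
        out[d + "T"] = (s - x - y + z) / 4
    return out


class TestZCurve:
    def test_homopolymer_48(self):
        v = encode_zcurve_phase_independent("A" * 30)
        lookup = dict(zip(v.names, v.values))
        assert lookup["ZC48:x_AA"] == 1.0
        assert lookup["ZC48:y_AA"] == 1.0
        assert lookup["ZC48:z_AA"] == 1.0
        others = [val for name, val in lookup.items() if "_AA" not in name]
        assert all(val == 0.0 for val in others)

    def test_homopolymer_144_all_phases(self):
        v = encode_zcurve_phase_specific("A" * 30)
        lookup = dict(zip(v.names, v.values))
        for phase in (1, 2, 3):
            for c in "xyz":
                assert lookup[f"ZC144:p{phase}_{c}_AA"] == 1.0

    def test_dimensions(self):
        seq = "ACGTACGTAC"
        assert len(encode_zcurve_phase_independent(seq).values) == 48
        assert len(encode_zcurve_phase_specific(seq).values) == 144

    def test_components_bounded(self, rng):
        for _ in range(20):
            seq = random_dna(rng, int(rng.integers(5, 200)))
            for v in (
                encode_zcurve_phase_independent(seq),
                encode_zcurve_phase_specific(seq),
            ):
                assert np.all(v.values >= -1.0) and np.all(v.values <= 1.0)

    def test_inversion_recovers_trinucleotide_frequencies(self, rng):
        """Oracle: direct trinucleotide counting."""
        for _ in range(25):
            seq = random_dna(rng, 200)
            counts = kmer_counts(seq, 3)
            total = len(seq) - 2
            truth = {t: counts.get(t, 0) / total for t in TRINUCLEOTIDES}
            prefix_totals = {
                d: sum(truth[d + b] for b in "ACGT") for d in DINUCLEOTIDES
            }
            v = encode_zcurve_phase_independent(seq)
            recon = reconstruct_prefix_freqs(v.values, prefix_totals)
            for t in TRINUCLEOTIDES:
                assert recon[t] == pytest.approx(truth[t], abs=1e-12)

    def test_phase_window_counts_partition(self, rng):
        """Per-phase window counts differ by at most 1 and sum to L - 2."""
        for L in (5, 6, 7, 8, 30, 31, 32):
            counts = [len(range(p, L - 2, 3)) for p in range(3)]
            assert sum(counts) == L - 2
            assert max(counts) - min(counts) <= 1


class TestPhysicochemical:
    def test_pseeiip_homopolymer(self):
        eiip = load_eiip()
        v = encode_pseeiip("A" * 30)
        lookup = dict(zip(v.names, v.values))
        assert lookup["PSEEIIP:AAA"] == pytest.approx(3 * eiip["A"])
        assert sum(val != 0 for val in v.values) == 1

    def test_pseeiip_dimension(self):
        assert len(encode_pseeiip("ACGTACGT").values) == 64

    def test_dpcp_homopolymer_matches_table(self):
        table = enc.default_dinucleotide_table()
        v = encode_dpcp("A" * 30)
        lookup = dict(zip(v.names, v.values))
        for scale in table.scale_names:
            assert lookup[f"DPCP:AA|{scale}"] == pytest.approx(
                table.scales[scale]["AA"]
            )
        non_aa = [
            val
            for name, val in lookup.items()
            if not name.startswith("DPCP:AA|")
        ]
        assert all(val == 0.0 for val in non_aa)

    def test_dpcp_identity_table_gives_frequencies(self, rng):
        ones = PropertyTable(
            oligo_length=2, scales={"one": {d: 1.0 for d in DINUCLEOTIDES}}
        )
        seq = random_dna(rng, 60)
        v = encode_dpcp(seq, table=ones)
        counts = kmer_counts(seq, 2)
        expected = np.array(
            [counts.get(d, 0) / (len(seq) - 1) for d in DINUCLEOTIDES]
        )
        np.testing.assert_allclose(v.values, expected, atol=1e-12)

    def test_tpcp_identity_table_gives_frequencies(self, rng):
        ones = PropertyTable(
            oligo_length=3, scales={"one": {t: 1.0 for t in TRINUCLEOTIDES}}
        )
        seq = random_dna(rng, 60)
        v = encode_tpcp(seq, table=ones)
        counts = kmer_counts(seq, 3)
        expected = np.array(
            [counts.get(t, 0) / (len(seq) - 2) for t in TRINUCLEOTIDES]
        )
        np.testing.assert_allclose(v.values, expected, atol=1e-12)

    def test_dimensions(self):
        seq = "ACGTACGTACGT"
        assert len(encode_dpcp(seq).values) == 2368
        assert len(encode_tpcp(seq).values) == 768

    def test_malformed_table_rejected(self):
        incomplete = {d: 1.0 for d in DINUCLEOTIDES if d != "GT"}
        with pytest.raises(ValueError, match="missing"):
            PropertyTable(oligo_length=2, scales={"bad": incomplete})


class TestEncodeDataset:
    def _records(self, rng, n=10, length=40):
        return [
            NucleotideSequence(id=f"s{i}", bases=random_dna(rng, length))
            for i in range(n)
        ]

    def test_full_matrix_is_6122_columns(self, rng):
        m = encode_dataset(self._records(rng))
        assert m.values.shape == (10, 6122)
        assert len(set(m.feature_names)) == 6122

    @pytest.mark.parametrize(
        "groups,expected",
        [({"KMER"}, 1360), ({"ZC48", "ZC144"}, 192), ({"PSEKNC"}, 1370)],
    )
    def test_group_subsets(self, rng, groups, expected):
        m = encode_dataset(self._records(rng, n=4), groups=groups)
        assert m.n_features == expected

    def test_group_dims_sum(self):
        assert sum(GROUP_DIMS.values()) == 6122
        assert (
            GROUP_DIMS["PSEEIIP"] + GROUP_DIMS["DPCP"] + GROUP_DIMS["TPCP"]
            == 3200
        )

    def test_block_order_is_canonical(self, rng):
        m = encode_dataset(self._records(rng, n=2))
        order = list(dict.fromkeys(m.feature_groups))
        assert order == list(enc.GROUP_ORDER)

    def test_failing_record_is_named(self, rng):
        records = self._records(rng, n=2) + [
            NucleotideSequence(id="runt", bases="ACGTA")
        ]
        with pytest.raises(ValueError, match="runt"):
            encode_dataset(records)  # PSEKNC needs >= 12 nt

    def test_unknown_group_rejected(self, rng):
        with pytest.raises(ValueError, match="valid groups"):
            encode_dataset(self._records(rng, n=2), groups={"SPECTRAL"})

    def test_row_order_matches_input(self, rng):
        records = self._records(rng, n=5)
        m = encode_dataset(records, groups={"ZC48"})
        assert m.sample_ids == [r.id for r in records]

    def test_tsv_round_trip(self, rng, tmp_path):
        m = encode_dataset(self._records(rng, n=3), groups={"ZC48", "KMER"})
        m.write_tsv(tmp_path / "m.tsv", sidecar=tmp_path / "m.meta.tsv")
        back = enc.FeatureMatrix.read_tsv(
            tmp_path / "m.tsv", tmp_path / "m.meta.tsv"
        )
        assert back.feature_names == m.feature_names
        assert back.feature_groups == m.feature_groups
        np.testing.assert_allclose(back.values, m.values, atol=1e-9)
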