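import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protfeat.alphabet import AA20, CODONS64, SA2, SS3
from protfeat.features import (
    MissingDataError,
    aa_composition,
    autocorrelation,
    codon_composition,
    codon_usage,
    ctd,
    dipeptide_composition,
    extract,
    per_state_aa_composition,
    property_profile,
    protein_length,
    pseaac,
    qso,
    signal_average,
    signal_peaks_area,
    state_composition,
    terminal_end_count,
    triangular_smooth,
    triangular_weights,
)
from protfeat.scales import (
    AminoAcidScale,
    builtin_ctd_clustering,
    builtin_distance_matrix,
    builtin_uncorrelated,
    normalize_scale,
)

aa_sequences = st.text(alphabet=AA20, min_size=1, max_size=60)


def _const_scale(value: float) -> AminoAcidScale:
    return AminoAcidScale("const", {a: value for a in AA20})


# ---------------------------------------------------------------------------
# composition


class TestAAComposition:
    def test_homopolymer(self):
        out = aa_composition("AAAA")
        assert out["aac_seg1of1_A"] == 1.0
        assert sum(out.values()) == pytest.approx(1.0)

    def test_two_segments_hand_count(self):
        out = aa_composition("ACDG", num_segments=2)
        assert out["aac_seg1of2_A"] == 0.5
        assert out["aac_seg1of2_C"] == 0.5
        assert out["aac_seg2of2_D"] == 0.5
        assert out["aac_seg2of2_G"] == 0.5

    def test_dimensionality(self):
        assert len(aa_composition("ACDEFGHIK", num_segments=3)) == 60

    def test_too_short(self):
        with pytest.raises(ValueError, match="segments"):
            aa_composition("AC", num_segments=3)

    @given(seq=st.text(alphabet=AA20, min_size=3, max_size=60),
           k=st.integers(1, 3))
    @settings(max_examples=50, deadline=None)
    def test_each_segment_sums_to_one(self, seq, k):
        out = aa_composition(seq, k)
        assert sum(out.values()) == pytest.approx(k, abs=1e-9)

    @given(seq=st.text(alphabet=AA20, min_size=2, max_size=60),
           k=st.integers(1, 4))
    @settings(max_examples=50, deadline=None)
    def test_segments_cover_sequence(self, seq, k):
        if len(seq) < k:
            return
        n = len(seq)
        bounds = [( (i - 1) * n // k, i * n // k) for i in range(1, k + 1)]
        assert bounds[0][0] == 0 and bounds[-1][1] == n
        for (a, b), (c, d) in zip(bounds, bounds[1:]):
            assert b == c


class TestDipeptideComposition:
    def test_aaa(self):
        out = dipeptide_composition("AAA")
        assert out["dpc_seg1of1_AA"] == 1.0
        assert sum(out.values()) == pytest.approx(1.0)

    def test_ac(self):
        assert dipeptide_composition("AC")["dpc_seg1of1_AC"] == 1.0

    def test_dimensionality(self):
        assert len(dipeptide_composition("ACDEF")) == 400

    def test_denominator_is_length_minus_one(self):
        out = dipeptide_composition("ACAC")
        assert out["dpc_seg1of1_AC"] == pytest.approx(2 / 3)
        assert out["dpc_seg1of1_CA"] == pytest.approx(1 / 3)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="length 1 < 2"):
            dipeptide_composition("ACD", num_segments=2)


class TestTerminalEndCount:
    def test_n_terminal(self):
        out = terminal_end_count("MKKKKLLL", end="N", length=5)
        assert out["tec_N5_M"] == 1
        assert out["tec_N5_K"] == 4
        assert sum(out.values()) == 5

    def test_c_terminal(self):
        out = terminal_end_count("MKKKKLLL", end="C", length=3)
        assert out["tec_C3_L"] == 3

    def test_dimensionality(self):
        assert len(terminal_end_count("MKKKKLLL", "N", 5)) == 20

    def test_window_too_long(self):
        with pytest.raises(ValueError, match="exceeds sequence length"):
            terminal_end_count("MK", "N", 3)


class TestStateComposition:
    def test_ss_homopolymer(self):
        out = state_composition("HHHH", SS3, prefix="ssc")
        assert out["ssc_seg1of1_H"] == 1.0

    def test_ss_uniform(self):
        out = state_composition("HEC", SS3, prefix="ssc")
        assert all(v == pytest.approx(1 / 3) for v in out.values())

    def test_sa_two_segments_dimensionality(self):
        assert len(state_composition("BEBE", SA2, 2, prefix="sac")) == 4


class TestPerStateAAComposition:
    def test_absent_states_zero(self):
        out = per_state_aa_composition("AC", "HH", SS3)
        assert out["staac_H_A"] == 0.5
        assert out["staac_H_C"] == 0.5
        for st_ in "EC":
            assert all(out[f"staac_{st_}_{aa}"] == 0.0 for aa in AA20)

    def test_dimensionality(self):
        assert len(per_state_aa_composition("AC", "HH", SS3)) == 60
        assert len(per_state_aa_composition("AC", "BE", SA2)) == 40

    def test_sa_blocks(self):
        out = per_state_aa_composition("AAAA", "BBEE", SA2)
        assert out["staac_B_A"] == 1.0
        assert out["staac_E_A"] == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            per_state_aa_composition("AC", "HHH", SS3)


class TestCodonFeatures:
    def test_composition_single_codon(self):
        assert codon_composition("ATGATG")["codon_comp_ATG"] == 1.0

    def test_composition_even_split(self):
        out = codon_composition("ATGGTT")
        assert out["codon_comp_ATG"] == 0.5
        assert out["codon_comp_GTT"] == 0.5

    def test_dimensionality(self):
        assert len(codon_composition("ATG")) == 64
        assert len(codon_usage("ATG")) == 64

    def test_usage_within_family(self):
        out = codon_usage("GCTGCC")  # two alanine codons
        assert out["codon_usage_GCT"] == 0.5
        assert out["codon_usage_GCC"] == 0.5
        assert out["codon_usage_GCA"] == 0.0
        assert out["codon_usage_GCG"] == 0.0

    def test_usage_singleton_family(self):
        assert codon_usage("ATG")["codon_usage_ATG"] == 1.0

    def test_usage_bounded(self):
        rng = np.random.default_rng(0)
        orf = "".join(rng.choice(CODONS64, size=30))
        assert all(0.0 <= v <= 1.0 for v in codon_usage(orf).values())

    def test_stop_codons_form_a_family(self):
        out = codon_usage("TAATAG")
        assert out["codon_usage_TAA"] == 0.5
        assert out["codon_usage_TAG"] == 0.5
        assert out["codon_usage_TGA"] == 0.0

    def test_bad_orf(self):
        with pytest.raises(ValueError):
            codon_composition("ATGA")


def test_protein_length():
    assert protein_length("ACDEF") == {"len": 5.0}
    assert protein_length("MK") == {"len": 2.0}


# ---------------------------------------------------------------------------
# profiles and smoothing


class TestProfile:
    def test_homopolymer_constant(self, kd_scale):
        p = property_profile("AAAA", kd_scale)
        assert np.allclose(p, kd_scale["A"])

    def test_length(self, kd_scale):
        assert len(property_profile("ACDEFG", kd_scale)) == 6

    def test_single_residue_difference(self, kd_scale):
        p1 = property_profile("ACD", kd_scale)
        p2 = property_profile("AVD", kd_scale)
        assert p1[0] == p2[0] and p1[2] == p2[2] and p1[1] != p2[1]


class TestTriangularSmooth:
    def test_window_one_identity(self):
        p = np.array([1.0, -2.0, 3.0])
        assert np.array_equal(triangular_smooth(p, 1, 0.5), p)

    def test_constant_unchanged(self):
        p = np.full(10, 2.5)
        assert np.allclose(triangular_smooth(p, 5, 0.3), p)

    def test_impulse_weights(self):
        p = np.zeros(7)
        p[3] = 1.0
        sm = triangular_smooth(p, 3, 0.5)
        assert sm[2] == pytest.approx(0.25)
        assert sm[3] == pytest.approx(0.5)
        assert sm[4] == pytest.approx(0.25)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            triangular_smooth(np.zeros(5), 4, 0.5)

    def test_weights_formula(self):
        w = triangular_weights(5, 0.0)
        assert np.allclose(w, [0.0, 0.5, 1.0, 0.5, 0.0])


class TestSignalFeatures:
    def test_average_constant(self):
        out = signal_average("AAAA", _const_scale(2.0), 1, 1.0)
        assert list(out.values()) == [2.0]

    def test_average_invariant_under_smoothing_constant(self):
        v1 = list(signal_average("AAAA", _const_scale(3.0), 1, 1.0).values())[0]
        v2 = list(signal_average("AAAA", _const_scale(3.0), 5, 0.2).values())[0]
        assert v1 == pytest.approx(v2)

    def test_peaks_zero_profile(self):
        out = signal_peaks_area("AAAA", _const_scale(0.0), 1, 1.0, 1.0)
        assert list(out.values()) == [0.0, 0.0]

    def test_peaks_hand_computed(self):
        # profile (2, 2), threshold 1, window 1: top = (1+1)/2, bottom = 0
        out = signal_peaks_area("AA", _const_scale(2.0), 1, 1.0, 1.0)
        top, bot = out.values()
        assert top == pytest.approx(1.0)
        assert bot == pytest.approx(0.0)

    def test_peaks_two_features_per_scale(self):
        assert len(signal_peaks_area("ACD", _const_scale(1.0), 1, 1.0, 1.0)) == 2

    def test_threshold_positive(self):
        with pytest.raises(ValueError, match="threshold"):
            signal_peaks_area("AA", _const_scale(1.0), 1, 1.0, 0.0)


# ---------------------------------------------------------------------------
# autocorrelation, with explicit-loop oracles


def _oracle_autocorr(p: np.ndarray, kind: str, d: int) -> float:
    n = len(p)
    if kind == "moreau_broto":
        return sum(p[i] * p[i + d] for i in range(n - d)) / (n - d)
    pbar = sum(p) / n
    if kind == "moran":
        num = sum((p[i] - pbar) * (p[i + d] - pbar) for i in range(n - d)) / (n - d)
        den = sum((x - pbar) ** 2 for x in p) / n
        return num / den
    num = sum((p[i] - p[i + d]) ** 2 for i in range(n - d)) / (2 * (n - d))
    den = sum((x - pbar) ** 2 for x in p) / (n - 1)
    return num / den


class TestAutocorrelation:
    def test_constant_profile_moreau_broto_closed_form(self):
        c = 1.7
        out = autocorrelation("AAAAA", _const_scale(c), "moreau_broto", 2)
        assert list(out.values())[0] == pytest.approx(c * c)

    def test_constant_profile_moran_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            autocorrelation("AAAAA", _const_scale(1.0), "moran", 1)

    def test_lag_too_large(self, kd_scale):
        with pytest.raises(ValueError, match="exceed lag"):
            autocorrelation("ACD", kd_scale, "geary", 3)

    @pytest.mark.parametrize("kind", ["moreau_broto", "moran", "geary"])
    def test_oracle_equivalence(self, kind, kd_scale):
        rng = np.random.default_rng(42)
        aas = list(AA20)
        for _ in range(40):
            n = int(rng.integers(5, 30))
            seq = "".join(rng.choice(aas, size=n))
            d = int(rng.integers(1, n))
            p = property_profile(seq, kd_scale)
            got = list(autocorrelation(seq, kd_scale, kind, d).values())[0]
            assert got == pytest.approx(_oracle_autocorr(p, kind, d), abs=1e-12)


# ---------------------------------------------------------------------------
# pseudo composition, CTD, QSO


@pytest.fixture()
def scales2():
    sset = builtin_uncorrelated()
    return [normalize_scale(sset.get(i)) for i in ("KYTJ820101", "HOPT810101")]


class TestPseAAC:

    def test_lambda_zero_is_composition(self, scales2):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        out = pseaac(seq, scales2, lam=0)
        comp = aa_composition(seq)
        for aa in AA20:
            assert out[f"paac1_l0_{aa}"] == comp[f"aac_seg1of1_{aa}"]

    def test_type1_dimensionality(self, scales2):
        assert len(pseaac("ACDEFGHIKL", scales2, lam=4, kind=1)) == 24

    def test_type2_dimensionality(self, scales2):
        assert len(pseaac("ACDEFGHIKL", scales2, lam=4, kind=2)) == 28

    def test_homopolymer_zero_correlations(self, scales2):
        out = pseaac("AAAAAAAA", scales2, lam=3)
        assert out["paac1_l3_A"] == pytest.approx(1.0)
        for j in range(1, 4):
            assert out[f"paac1_l3_cf{j}"] == 0.0

    def test_vector_sums_to_one(self, scales2):
        out = pseaac("MKVLAACDEFGHIKL", scales2, lam=5, kind=2)
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(0.0 <= v <= 1.0 for v in out.values())

    def test_lambda_too_large(self, scales2):
        with pytest.raises(ValueError, match="lambda"):
            pseaac("ACD", scales2, lam=3)

    def test_oracle_type1(self, scales2):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list(AA20), size=18))
        lam, w = 3, 0.05
        profiles = [property_profile(seq, s) for s in scales2]
        thetas = []
        for j in range(1, lam + 1):
            tot = 0.0
            for i in range(len(seq) - j):
                tot += sum((p[i] - p[i + j]) ** 2 for p in profiles) / len(profiles)
            thetas.append(tot / (len(seq) - j))
        denom = 1 + w * sum(thetas)
        out = pseaac(seq, scales2, lam, w, kind=1)
        for aa in AA20:
            assert out[f"paac1_l{lam}_{aa}"] == pytest.approx(
                (seq.count(aa) / len(seq)) / denom, abs=1e-12)
        for j, th in enumerate(thetas, 1):
            assert out[f"paac1_l{lam}_cf{j}"] == pytest.approx(
                w * th / denom, abs=1e-12)


class TestCTD:
    def test_dimensionality(self):
        c = builtin_ctd_clustering("hydrophobicity")
        assert len(ctd("ACDEFGHIKLMNPQRSTVWY", c)) == 21

    def test_homopolymer_distribution(self):
        # K is in group A of the charge clustering
        c = builtin_ctd_clustering("charge")
        out = ctd("K" * 10, c)
        assert out["ctd_charge_cA"] == 1.0
        assert out["ctd_charge_cB"] == 0.0
        assert out["ctd_charge_tAB"] == 0.0
        assert [out[f"ctd_charge_dA{i}"] for i in range(1, 6)] == \
            pytest.approx([0.1, 0.3, 0.5, 0.8, 1.0])
        assert all(out[f"ctd_charge_dB{i}"] == 0.0 for i in range(1, 6))

    def test_alternating_transitions(self):
        # K -> group A, A -> group B under the charge clustering
        c = builtin_ctd_clustering("charge")
        out = ctd("KAKAKAKAK", c)  # reduced ABABABABA, length 9
        assert out["ctd_charge_tAB"] == pytest.approx(1.0)
        assert out["ctd_charge_tAC"] == 0.0

    def test_composition_sums_to_one(self):
        c = builtin_ctd_clustering("polarity")
        out = ctd("MKVLAACDEFGH", c)
        total = sum(out[f"ctd_polarity_c{g}"] for g in "ABC")
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_quantile_rule_hand_case(self):
        # "KKAAK": K (group A) occurs at positions 1, 2, 5; n=3, N=5
        # marks: first=1, ceil(.75)=1st, ceil(1.5)=2nd, ceil(2.25)=3rd, last=5
        c = builtin_ctd_clustering("charge")
        out = ctd("KKAAK", c)
        assert [out[f"ctd_charge_dA{i}"] for i in range(1, 6)] == \
            pytest.approx([0.2, 0.2, 0.4, 1.0, 1.0])


class TestQSO:
    def test_homopolymer(self):
        dm = builtin_distance_matrix()
        out = qso("AAAAAA", dm, lam=3)
        assert out["qso_l3_A"] == pytest.approx(1.0)
        for j in range(1, 4):
            assert out[f"qso_l3_so{j}"] == 0.0

    def test_dimensionality(self):
        dm = builtin_distance_matrix()
        assert len(qso("ACDEFGHIKL", dm, lam=5)) == 25

    def test_vector_sums_to_one(self):
        dm = builtin_distance_matrix()
        out = qso("MKVLAACDEFGHIKL", dm, lam=4)
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-9)

    def test_brute_force_oracle(self):
        dm = builtin_distance_matrix()
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(6, 25))
            seq = "".join(rng.choice(list(AA20), size=n))
            lam = int(rng.integers(1, min(n, 6)))
            w = 0.1
            taus = []
            for j in range(1, lam + 1):
                taus.append(sum(dm(seq[i], seq[i + j]) ** 2
                                for i in range(n - j)))
            denom = 1 + w * sum(taus)
            out = qso(seq, dm, lam, w)
            for aa in AA20:
                assert out[f"qso_l{lam}_{aa}"] == pytest.approx(
                    (seq.count(aa) / n) / denom, abs=1e-12)
            for j, t in enumerate(taus, 1):
                assert out[f"qso_l{lam}_so{j}"] == pytest.approx(
                    w * t / denom, abs=1e-12)

    def test_lambda_too_large(self):
        with pytest.raises(ValueError, match="lambda"):
            qso("ACD", builtin_distance_matrix(), lam=3)


# ---------------------------------------------------------------------------
# whole-set extraction


class TestExtract:
    def test_aac_block_shape(self, small_pset):
        block = extract(small_pset, "aac")
        assert block.shape == (6, 20)
        assert list(block.index) == small_pset.ids

    def test_missing_ss_errors(self, small_pset):
        for rec in small_pset:
            rec.ss_seq = None
        with pytest.raises(MissingDataError, match="ssc.*p1"):
            extract(small_pset, "ssc")

    def test_missing_orf_errors(self, small_pset):
        small_pset.records[2].orf_seq = None
        with pytest.raises(MissingDataError, match="p3"):
            extract(small_pset, "codon_comp")

    def test_deterministic(self, small_pset):
        b1 = extract(small_pset, "ctd")
        b2 = extract(small_pset, "ctd")
        assert b1.equals(b2)

    def test_unknown_category(self, small_pset):
        with pytest.raises(ValueError, match="unknown feature category"):
            extract(small_pset, "nope")

    @pytest.mark.parametrize("category,params,ncols", [
        ("aac", {"num_segments": 2}, 40),
        ("dpc", {"num_segments": 1}, 400),
        ("tec", {"end": "N", "length": 5}, 20),
        ("ssc", {"num_segments": 2}, 6),
        ("ssaac", {}, 60),
        ("sac", {"num_segments": 2}, 4),
        ("saaac", {}, 40),
        ("codon_comp", {}, 64),
        ("codon_usage", {}, 64),
        ("length", {}, 1),
        ("sigavg", {"scales": ["KYTJ820101"], "window": 3, "edge": 0.5}, 1),
        ("sigpeak", {"scales": ["KYTJ820101"], "window": 3, "edge": 0.5,
                     "threshold": 1.0}, 2),
        ("autocorr", {"scales": ["KYTJ820101"], "lags": [1, 2]}, 2),
        ("paac1", {"scales": ["KYTJ820101", "HOPT810101"], "lam": 3}, 23),
        ("paac2", {"scales": ["KYTJ820101", "HOPT810101"], "lam": 3}, 26),
        ("ctd", {"properties": ["hydrophobicity"]}, 21),
        ("qso", {"lam": 4}, 24),
    ])
    def test_category_dimensionalities(self, small_pset, category, params, ncols):
        assert extract(small_pset, category, **params).shape[1] == ncols
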