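import numpy as np
import pandas as pd
import pytest

from microswitch.connectivity import (
    MORPHOLOGICAL_TYPES,
    ConnectivityError,
    ConnectivityMatrix,
    LesionSpec,
    RawConnectivityData,
    apply_lesion,
    build_corrected_matrix,
    jitter_matrix,
    scale_by_G,
)
from microswitch.populations import POPULATIONS, index_of

from conftest import toy_raw_tables


def full_tables(prob_value, amp_magnitude, prevalence_value=1.0, scale=0.2):
    morphs = list(MORPHOLOGICAL_TYPES)
    prob = pd.DataFrame(prob_value, index=morphs, columns=morphs, dtype=float)
    amp = pd.DataFrame(amp_magnitude, index=morphs, columns=morphs, dtype=float)
    for m in morphs:  # sign IPSP columns
        if not m.startswith("pyramidal"):
            amp[m] = -amp[m].abs()
    prevalence = pd.Series(prevalence_value, index=[
        "PV_sup", "SST_sup", "VIP_sup", "PV_deep", "SST_deep", "VIP_deep"],
        dtype=float)
    return RawConnectivityData(probability=prob, amplitude=amp,
                               prevalence=prevalence, inhibitory_scale=scale)


class TestBuildCorrectedMatrix:
    def test_zero_probability_annihilates(self):
        C = build_corrected_matrix(full_tables(0.0, 1.0))
        assert np.array_equal(C.W, np.zeros((8, 8)))

    def test_unit_tables_give_scaled_columns(self):
        """Probability 1, unit amplitudes, prevalence 1, inhibitory scale 0.2.

        Each raw product entry is +1 (excitatory) or -0.2 (inhibitory) before
        subtype merging; merged columns sum the subtype outputs.
        """
        C = build_corrected_matrix(full_tables(1.0, 1.0))
        # single-subtype inhibitory source: exactly -0.2 on every target
        assert np.allclose(C.W[:, index_of("SST_sup")], -0.2)
        # PYR source: +1 per subtype; PYR_sup column is a single subtype
        assert np.allclose(C.W[:, index_of("PYR_sup")], 1.0)
        # deep PV merges three subtypes: column sums to 3 x (-0.2)
        assert np.allclose(C.W[:, index_of("PV_deep")], -0.6)
        # superficial PV merges two subtypes
        assert np.allclose(C.W[:, index_of("PV_sup")], -0.4)

    def test_toy_pv_merge_matches_hand_computation(self):
        prob, amp, prevalence = toy_raw_tables()
        raw = RawConnectivityData(probability=prob, amplitude=amp,
                                  prevalence=prevalence, inhibitory_scale=0.2)
        C = build_corrected_matrix(raw)
        # merged PV_sup -> PYR_sup: sum of subtype products, then x0.2 x0.5
        expected_pv_to_pyr = ((-0.8 * 0.5) + (-0.5 * 0.4)) * 0.2 * 0.5
        assert C.entry("PYR_sup", "PV_sup") == pytest.approx(expected_pv_to_pyr)
        # PYR -> merged PV target: averaged over subtype rows
        expected_pyr_to_pv = (1.2 * 0.5 + 0.8 * 0.25) / 2.0
        assert C.entry("PV_sup", "PYR_sup") == pytest.approx(expected_pyr_to_pv)

    def test_homogeneous_in_amplitude(self):
        prob, amp, prevalence = toy_raw_tables()
        raw1 = RawConnectivityData(prob, amp, prevalence)
        raw3 = RawConnectivityData(prob, amp * 3.0, prevalence)
        assert np.allclose(build_corrected_matrix(raw3).W,
                           3.0 * build_corrected_matrix(raw1).W)

    def test_missing_morphological_type_is_reported(self):
        raw = full_tables(1.0, 1.0)
        raw.probability = raw.probability.drop(index="chandelier_sup")
        with pytest.raises(ConnectivityError, match="chandelier_sup"):
            build_corrected_matrix(raw)

    def test_missing_prevalence_is_reported(self):
        raw = full_tables(1.0, 1.0)
        raw.prevalence = raw.prevalence.drop("VIP_deep")
        with pytest.raises(ConnectivityError, match="VIP_deep"):
            build_corrected_matrix(raw)

    def test_probability_out_of_range_rejected(self):
        raw = full_tables(1.5, 1.0)
        with pytest.raises(ConnectivityError, match="probabilities"):
            build_corrected_matrix(raw)

    def test_positive_ipsp_amplitude_rejected(self):
        raw = full_tables(1.0, 1.0)
        raw.amplitude.loc["pyramidal_sup", "basket_sup"] = 0.4
        with pytest.raises(ConnectivityError, match="basket_sup"):
            build_corrected_matrix(raw)


class TestScaleByG:
    def test_identity_zero_and_multiplicativity(self, fixture_C):
        assert np.array_equal(scale_by_G(fixture_C, 1.0).W, fixture_C.W)
        assert np.array_equal(scale_by_G(fixture_C, 0.0).W, np.zeros((8, 8)))
        twice = scale_by_G(scale_by_G(fixture_C, 250.0), 250.0)
        once = scale_by_G(fixture_C, 62500.0)
        assert np.allclose(twice.W, once.W)
        assert twice.G == pytest.approx(once.G)

    def test_negative_G_rejected(self, fixture_C):
        with pytest.raises(ConnectivityError):
            scale_by_G(fixture_C, -1.0)

    def test_sign_pattern_preserved(self, fixture_C):
        assert scale_by_G(fixture_C, 300.0).check_sign_pattern()


class TestLesions:
    def test_silence_cell_zeroes_only_that_column(self, fixture_C):
        out = apply_lesion(fixture_C, LesionSpec("silence_cell", source="PV_sup"))
        j = index_of("PV_sup")
        assert np.array_equal(out.W[:, j], np.zeros(8))
        mask = np.ones(8, dtype=bool)
        mask[j] = False
        assert np.array_equal(out.W[:, mask], fixture_C.W[:, mask])
        assert "silence_cell(PV_sup)" in out.manipulations

    def test_remove_and_set_connection(self, fixture_C):
        out = apply_lesion(fixture_C, LesionSpec(
            "remove_connection", source="PYR_sup", target="PYR_deep"))
        assert out.entry("PYR_deep", "PYR_sup") == 0.0
        out = apply_lesion(out, LesionSpec(
            "set_connection", source="PYR_sup", target="PYR_deep", value=0.7))
        assert out.entry("PYR_deep", "PYR_sup") == 0.7

    def test_equalize_pv_self(self):
        W = np.zeros((8, 8))
        W[index_of("PV_sup"), index_of("PV_sup")] = -0.5
        W[index_of("PV_deep"), index_of("PV_deep")] = -0.9
        out = apply_lesion(ConnectivityMatrix(W), LesionSpec("equalize_pv_self"))
        assert out.entry("PV_sup", "PV_sup") == -0.9
        assert out.entry("PV_deep", "PV_deep") == -0.9

    def test_swap_self_connections_is_involution(self, fixture_C):
        once = apply_lesion(fixture_C, LesionSpec("swap_self_connections"))
        assert once.entry("SST_sup", "SST_sup") == fixture_C.entry("PV_sup", "PV_sup")
        assert once.entry("PV_sup", "PV_sup") == 0.0
        twice = apply_lesion(once, LesionSpec("swap_self_connections"))
        assert np.array_equal(twice.W, fixture_C.W)

    def test_invalid_population_rejected(self):
        with pytest.raises(KeyError):
            LesionSpec("silence_cell", source="PV_mid")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConnectivityError):
            LesionSpec("ablate_everything")


class TestJitter:
    def test_zero_scale_is_identity(self, fixture_C):
        assert np.array_equal(jitter_matrix(fixture_C, 0.0, 1).W, fixture_C.W)

    def test_seed_determinism(self, fixture_C):
        a = jitter_matrix(fixture_C, 0.2, 42)
        b = jitter_matrix(fixture_C, 0.2, 42)
        c = jitter_matrix(fixture_C, 0.2, 43)
        assert np.array_equal(a.W, b.W)
        assert not np.array_equal(a.W, c.W)

    def test_absent_connections_stay_absent(self, fixture_C):
        out = jitter_matrix(fixture_C, 0.2, 7)
        assert np.array_equal(out.W == 0.0, fixture_C.W == 0.0)

    def test_perturbations_have_zero_mean(self, fixture_C):
        """Sample mean over many jitter trials stays within the CLT bound."""
        n = 10_000
        scale = 0.2
        acc = np.zeros((8, 8))
        for seed in range(n):
            acc += jitter_matrix(fixture_C, scale, seed).W
        mean = acc / n
        bound = 3.0 * scale / np.sqrt(n)
        nz = fixture_C.W != 0
        assert np.all(np.abs(mean[nz] - fixture_C.W[nz]) < bound)


class TestMatrixIO:
    def test_csv_round_trip_is_bit_stable(self, fixture_C, tmp_path):
        path = tmp_path / "m.csv"
        scale_by_G(fixture_C, 137.0).to_csv(path)
        back = ConnectivityMatrix.from_csv(path)
        assert np.array_equal(back.W, scale_by_G(fixture_C, 137.0).W)

    def test_missing_population_in_csv_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        df = pd.DataFrame(np.zeros((7, 7)), index=list(POPULATIONS[:7]),
                          columns=list(POPULATIONS[:7]))
        df.to_csv(path)
        with pytest.raises(ConnectivityError, match="VIP_deep"):
            ConnectivityMatrix.from_csv(path)


class TestStructuralInvariants:
    def test_fixture_motifs(self, fixture_C):
        fixture_C.check_motifs()  # raises on violation
        for lbl in ("SST_sup", "SST_deep"):
            assert fixture_C.entry(lbl, lbl) == 0.0
        assert abs(fixture_C.entry("PV_deep", "PV_deep")) > abs(
            fixture_C.entry("PV_sup", "PV_sup"))

    def test_manipulated_matrices_keep_sign_pattern(self, fixture_C):
        for spec in (LesionSpec("silence_cell", source="SST_deep"),
                     LesionSpec("equalize_pv_self"),
                     LesionSpec("swap_self_connections")):
            assert apply_lesion(fixture_C, spec).check_sign_pattern()
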