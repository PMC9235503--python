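import gzip
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fpkit.spectra_data import (
    FingerprintMatrix,
    NoiseParams,
    Spectrum,
    SpectrumParseError,
    bin_spectrum_features,
    compute_sample_weights,
    fit_formula_normalization,
    formula_feature_vector,
    merge_peaks,
    merge_spectra,
    parse_formula,
    read_fingerprints,
    read_spectra,
    remove_noise_peaks,
    select_labels,
    simulate_noise,
    structure_key_from_inchikey,
    write_fingerprints,
    write_mgf,
)

MGF_ONE_BLOCK = """BEGIN IONS
TITLE=spec1
PEPMASS=301.1400
CHARGE=1+
ADDUCT=[M+H]+
STRUCTUREKEY=ABCDEF
100.05 12.0
150.10 55.5
200.00 3.2
END IONS
"""

MSP_RECORD = """Name: spec2
PrecursorMZ: 285.05
Precursor_type: [M+H]+
InChIKey: QWERTYUIOPASDFGH-UHFFFAOYSA-N
Num Peaks: 2
85.0 10
120.5 99
"""


class TestReadSpectra:
    def test_mgf_single_block(self, tmp_path):
        path = tmp_path / "one.mgf"
        path.write_text(MGF_ONE_BLOCK)
        spectra = read_spectra(path)
        assert len(spectra) == 1
        s = spectra[0]
        assert len(s.peaks) == 3
        assert s.precursor_mz == pytest.approx(301.14)
        assert s.compound_id == "spec1"
        assert s.structure_key == "ABCDEF"

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.mgf"
        path.write_text("")
        assert read_spectra(path) == []

    def test_out_of_order_peaks_sorted(self, tmp_path):
        text = "BEGIN IONS\nPEPMASS=500\n300.0 1\n100.0 2\n200.0 3\nEND IONS\n"
        path = tmp_path / "unsorted.mgf"
        path.write_text(text)
        (s,) = read_spectra(path)
        assert list(s.mz) == [100.0, 200.0, 300.0]

    def test_missing_precursor_skipped(self, tmp_path, caplog):
        text = "BEGIN IONS\nTITLE=x\n100.0 1\nEND IONS\n" + MGF_ONE_BLOCK
        path = tmp_path / "mixed.mgf"
        path.write_text(text)
        with caplog.at_level("WARNING"):
            spectra = read_spectra(path)
        assert len(spectra) == 1
        assert "skipped" in caplog.text

    def test_malformed_names_line_number(self, tmp_path):
        path = tmp_path / "bad.mgf"
        path.write_text("BEGIN IONS\nPEPMASS=500\nnot a peak line !\nEND IONS\n")
        with pytest.raises(SpectrumParseError, match="line 3"):
            read_spectra(path)

    def test_msp_record(self, tmp_path):
        path = tmp_path / "lib.msp"
        path.write_text(MSP_RECORD)
        (s,) = read_spectra(path)
        assert s.compound_id == "spec2"
        assert s.structure_key == "QWERTYUIOPASDFGH"
        assert len(s.peaks) == 2

    def test_msp_peak_count_mismatch(self, tmp_path):
        path = tmp_path / "bad.msp"
        path.write_text("Name: x\nPrecursorMZ: 100\nNum Peaks: 3\n50 1\n")
        with pytest.raises(SpectrumParseError):
            read_spectra(path)

    def test_mgf_roundtrip(self, tmp_path, make_spectrum):
        spectra = [make_spectrum(compound_id=f"c{i}") for i in range(3)]
        path = tmp_path / "round.mgf"
        write_mgf(spectra, path)
        back = read_spectra(path)
        assert len(back) == 3
        for a, b in zip(spectra, back):
            assert a.compound_id == b.compound_id
            np.testing.assert_allclose(a.mz, b.mz, atol=1e-5)


class TestSpectrumInvariants:
    def test_negative_mz_rejected(self):
        with pytest.raises(ValueError):
            Spectrum(peaks=((-1.0, 1.0),))

    def test_peak_above_precursor_rejected(self):
        with pytest.raises(ValueError, match="exceeds precursor"):
            Spectrum(peaks=((400.0, 1.0),), precursor_mz=300.0)

    def test_structure_key_helper(self):
        assert structure_key_from_inchikey("ABC-DEF-N") == "ABC"


class TestMergeSpectra:
    def _spec(self, skey, instrument="i1", adduct="[M+H]+", cid="c", peaks=None):
        return Spectrum(
            peaks=peaks or ((100.0, 1.0),),
            precursor_mz=300.0,
            instrument=instrument,
            adduct=adduct,
            structure_key=skey,
            compound_id=cid,
        )

    def test_same_group_merges_to_one(self):
        spectra = [self._spec("s1", cid=f"c{i}") for i in range(3)]
        records = merge_spectra(spectra)
        assert len(records) == 1

    def test_different_instruments_stay_separate(self):
        spectra = [self._spec("s1", instrument="i1"), self._spec("s1", instrument="i2")]
        assert len(merge_spectra(spectra)) == 2

    def test_peaks_within_10ppm_merge(self):
        # 100.0000 vs 100.0010 Da is exactly 10 ppm: one merged peak.
        merged = merge_peaks([(100.0000, 1.0), (100.0010, 1.0)], ppm=10.0)
        assert len(merged) == 1
        # intensity-weighted mean m/z, maximum intensity
        assert merged[0][0] == pytest.approx(100.0005)
        assert merged[0][1] == 1.0

    def test_peaks_beyond_tolerance_stay(self):
        merged = merge_peaks([(100.0, 1.0), (100.01, 1.0)], ppm=10.0)
        assert len(merged) == 2

    def test_single_member_group_identity(self):
        s = self._spec("s1", peaks=((100.0, 0.5), (200.0, 1.0)))
        (record,) = merge_spectra([s])
        assert record.spectrum == s

    def test_conflicting_precursors_error(self):
        a = self._spec("s1")
        b = Spectrum(
            peaks=((100.0, 1.0),),
            precursor_mz=305.0,
            instrument="i1",
            structure_key="s1",
            compound_id="c2",
        )
        with pytest.raises(ValueError, match="conflicting precursor"):
            merge_spectra([a, b])


class TestSampleWeights:
    def test_count_one(self):
        assert compute_sample_weights({"s": 1})["s"] == 1.0

    def test_count_four(self):
        assert compute_sample_weights({"s": 4})["s"] == 0.5

    def test_count_85(self):
        # 1/sqrt(85), computed independently
        expected = 1.0 / math.sqrt(85.0)
        assert compute_sample_weights({"s": 85})["s"] == pytest.approx(
            expected, abs=1e-9
        )
        assert expected == pytest.approx(0.108465, abs=1e-6)

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            compute_sample_weights({"s": 0})

    @given(st.integers(min_value=1, max_value=10_000))
    def test_weight_in_unit_interval(self, count):
        w = compute_sample_weights({"s": count})["s"]
        assert 0.0 < w <= 1.0

    def test_strictly_decreasing(self):
        weights = [compute_sample_weights({"s": c})["s"] for c in range(1, 50)]
        assert all(a > b for a, b in zip(weights, weights[1:]))


class TestSelectLabels:
    def _fp(self, counts, n=30):
        values = np.zeros((n, len(counts)), dtype=np.uint8)
        for j, c in enumerate(counts):
            values[:c, j] = 1
        return FingerprintMatrix(
            [f"s{i}" for i in range(n)], [f"l{j}" for j in range(len(counts))], values
        )

    def test_threshold_retains(self):
        fp = select_labels(self._fp([25, 19]), min_structures=20)
        assert fp.labels == ["l0"]

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            select_labels(self._fp([0, 0]), min_structures=20)

    def test_order_preserved(self):
        fp = select_labels(self._fp([25, 5, 30, 22]), min_structures=20)
        assert fp.labels == ["l0", "l2", "l3"]

    def test_tsv_roundtrip(self, tmp_path):
        fp = self._fp([3, 7], n=5)
        path = tmp_path / "fp.tsv"
        write_fingerprints(fp, path)
        assert read_fingerprints(path) == fp

    def test_gzipped_tsv_roundtrip(self, tmp_path):
        fp = self._fp([2, 4], n=6)
        path = tmp_path / "fp.tsv.gz"
        write_fingerprints(fp, path)
        with gzip.open(path, "rt") as fh:
            assert fh.readline().startswith("structure_key")
        assert read_fingerprints(path) == fp


class TestBinning:
    def test_colliding_peaks_share_bin(self):
        s = Spectrum(peaks=((100.0001, 1.0), (100.0049, 0.25)), precursor_mz=None)
        vec = bin_spectrum_features(s, bin_width=0.005, max_mass=200.0)
        # both fall in floor(100.x/0.005) = 20000; combined by max of sqrt
        assert vec[0, 20000] == 1.0
        assert vec.nnz == 1

    def test_precursor_difference_bin(self):
        s = Spectrum(peaks=((100.05, 1.0),), precursor_mz=300.10)
        vec = bin_spectrum_features(s, bin_width=0.005, max_mass=250.0)
        nb = 50000
        assert vec[0, int(100.05 / 0.005)] == 1.0
        assert vec[0, nb + int(200.05 / 0.005)] == 1.0

    def test_sqrt_intensity(self):
        s = Spectrum(peaks=((50.0, 0.25), (60.0, 1.0)), precursor_mz=None)
        vec = bin_spectrum_features(s, bin_width=0.005, max_mass=100.0)
        assert vec[0, int(50.0 / 0.005)] == pytest.approx(0.5)

    def test_single_peak_two_features(self, make_spectrum):
        s = Spectrum(peaks=((123.4, 1.0),), precursor_mz=400.0)
        vec = bin_spectrum_features(s)
        assert vec.nnz == 2

    def test_peak_above_max_mass_dropped(self):
        s = Spectrum(peaks=((150.0, 1.0), (90.0, 1.0)), precursor_mz=None)
        vec = bin_spectrum_features(s, bin_width=0.005, max_mass=100.0)
        assert vec.nnz == 1


class TestFormulaFeatures:
    def test_identity_normalization(self):
        counts = parse_formula("C6H12O6")
        vec = formula_feature_vector(
            counts, ["C", "H", "O"], {"C": 1.0, "H": 1.0, "O": 1.0}
        )
        np.testing.assert_array_equal(vec, [6, 12, 6])

    def test_std_division(self):
        vec = formula_feature_vector({"C": 6}, ["C"], {"C": 3.0})
        assert vec[0] == pytest.approx(2.0)

    def test_unknown_element_errors(self):
        with pytest.raises(ValueError, match="Se"):
            formula_feature_vector({"Se": 1}, ["C", "H"], {"C": 1.0, "H": 1.0})

    def test_zero_std_elements_dropped(self):
        formulas = [{"C": 5, "H": 8}, {"C": 5, "H": 10}]
        order, stds = fit_formula_normalization(formulas)
        assert order == ["H"]  # C is constant across training

    def test_parse_formula(self):
        assert parse_formula("C10H14N5O7P") == {
            "C": 10, "H": 14, "N": 5, "O": 7, "P": 1,
        }
        with pytest.raises(ValueError):
            parse_formula("C6h12")


class TestNoiseSimulation:
    def _spectrum(self):
        return Spectrum(
            peaks=tuple((50.0 + 10 * i, 0.1 + 0.09 * i) for i in range(10)),
            precursor_mz=300.0,
            compound_id="c",
            structure_key="s",
        )

    def test_zero_params_identity(self):
        s = self._spectrum()
        out = simulate_noise(
            s, [], NoiseParams(0.0, 0.0, 0, 0.25), seed=1
        )
        assert out.peaks == s.peaks

    def test_noise_peak_count(self):
        s = self._spectrum()
        pool = [55.0, 66.0, 77.0]
        out = simulate_noise(
            s, pool, NoiseParams(0.0, 0.0, 5, 0.25), seed=2
        )
        assert len(out.peaks) == len(s.peaks) + 5

    def test_noise_mz_from_pool(self):
        s = self._spectrum()
        pool = [55.5, 66.6, 77.7]
        out = simulate_noise(s, pool, NoiseParams(0.0, 0.0, 8, 0.25), seed=3)
        original = set(p.mz for p in s.peaks)
        added = [p.mz for p in out.peaks if p.mz not in original]
        assert len(added) == 8
        assert set(added) <= set(pool)

    def test_base_peak_never_dropped(self):
        s = self._spectrum()
        base_mz = s.peaks[s.base_peak_index].mz
        for seed in range(10):
            out = simulate_noise(
                s, [], NoiseParams(0.8, 0.0, 0, 0.25), seed=seed
            )
            assert base_mz in set(p.mz for p in out.peaks)

    def test_seed_reproducibility(self):
        s = self._spectrum()
        params = NoiseParams(0.3, 0.4, 4, 0.25)
        a = simulate_noise(s, [60.0, 70.0], params, seed=9)
        b = simulate_noise(s, [60.0, 70.0], params, seed=9)
        assert a.peaks == b.peaks

    def test_invalid_drop_fraction(self):
        with pytest.raises(ValueError):
            NoiseParams(drop_fraction=1.0)

    def test_empty_pool_with_noise_peaks_errors(self):
        with pytest.raises(ValueError, match="peak_pool"):
            simulate_noise(
                self._spectrum(), [], NoiseParams(0.0, 0.0, 3, 0.25), seed=1
            )


class TestRemoveNoisePeaks:
    def test_relative_floor_and_cap(self):
        peaks = [(float(50 + i), 1.0 if i == 0 else 0.5) for i in range(10)]
        peaks.append((200.0, 1e-5))
        s = Spectrum(peaks=tuple(peaks), precursor_mz=None)
        out = remove_noise_peaks(s, min_relative_intensity=1e-3, max_peaks=5)
        assert len(out.peaks) == 5
        assert all(p.intensity >= 1e-3 for p in out.peaks)
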