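"""The 137-feature encoding, amino-acid tables and min-max scaling."""

import numpy as np
import pandas as pd
import pytest

from sumosite import feature_encoding as fe
from sumosite import seq_windows as sw

# Independent transcription of the Hopp-Woods scale used to cross-check the
# bundled data file (hydrophilicity, PNAS 1981).
HOPP_WOODS_CHECK = {
    "R": 3.0, "D": 3.0, "E": 3.0, "K": 3.0, "S": 0.3, "N": 0.2, "Q": 0.2,
    "G": 0.0, "P": 0.0, "T": -0.4, "A": -0.5, "H": -0.5, "C": -1.0,
    "M": -1.3, "V": -1.5, "I": -1.8, "L": -1.8, "Y": -2.3, "F": -2.5, "W": -3.4,
}


@pytest.fixture
def protein():
    return sw.ProteinRecord("p", "AAIKSEAAAA")


@pytest.fixture
def window(protein):
    return sw.window_at(protein, 4)  # flanks A,A,I | K | S,E,A


@pytest.fixture
def annotation(protein):
    dis = [0.2] * protein.length
    dis[3] = 0.7  # central lysine disordered
    flex = [0] * protein.length
    flex[3] = 1
    return fe.FlexDisorderAnnotation(protein.id, tuple(flex), tuple(dis))


class TestFeatureInventory:
    def test_audit(self):
        assert len(fe.FEATURE_NAMES) == 137
        assert len(fe.BINARY_FEATURES) == 126
        assert len(fe.REAL_FEATURES) == 11
        assert len(set(fe.FEATURE_NAMES)) == 137

    def test_codebook_covers_every_feature(self):
        book = fe.feature_codebook()
        assert list(book["feature"]) == list(fe.FEATURE_NAMES)
        assert (book["kind"] == "binary").sum() == 126
        assert (book["kind"] == "real").sum() == 11


class TestEncodeSite:
    def test_binary_features_are_binary(self, window, protein, annotation):
        v = fe.encode_site(window, protein, annotation)
        assert len(v) == 137
        for name in fe.BINARY_FEATURES:
            assert v[name] in (0.0, 1.0)

    def test_example_window_flags(self, window, protein, annotation):
        v = fe.encode_site(window, protein, annotation)
        assert v["w-I_3"] == 1 and v["w+E_2"] == 1
        assert v["Consensus"] == 1 and v["wDE"] == 1 and v["wK"] == 0
        assert v["DisorderReal"] == 0.7
        assert v["DisorderBinary"] == 1 and v["Flexible"] == 1

    def test_one_hot_exactly_one_per_standard_slot(self, window, protein, annotation):
        v = fe.encode_site(window, protein, annotation)
        for slot_index in range(6):
            block = [v[f] for f in fe.ONE_HOT_FEATURES[20 * slot_index : 20 * (slot_index + 1)]]
            assert sum(block) == 1

    def test_padded_slots_all_zero(self):
        protein = sw.ProteinRecord("p", "KSEAAAA")
        w = sw.window_at(protein, 1)
        v = fe.encode_site(w, protein, fe.null_annotation(protein))
        for slot_index in range(3):  # upstream slots are padded
            block = [v[f] for f in fe.ONE_HOT_FEATURES[20 * slot_index : 20 * (slot_index + 1)]]
            assert sum(block) == 0
        assert v["BeforeVol"] == 0.0
        assert v["w-3_Hydro"] == 0.0

    def test_symmetric_window_zero_volume_difference(self):
        protein = sw.ProteinRecord("p", "IVAKIVA")
        w = sw.window_at(protein, 4)
        v = fe.encode_site(w, protein, fe.null_annotation(protein))
        assert v["BeforeVol"] == v["AfterVol"]
        assert v["Difference"] == 0.0

    def test_missing_annotation_errors(self, window, protein):
        short = fe.FlexDisorderAnnotation("p", (0,), (0.0,))
        with pytest.raises(KeyError, match="position 4"):
            fe.encode_site(window, protein, short)


class TestHydrophobicity:
    def test_bundled_table_matches_independent_transcription(self):
        assert fe.hopp_woods_scale() == HOPP_WOODS_CHECK

    def test_slot_lookup(self, window):
        values = fe.hydrophobicity_features(window)
        assert values["w-3_Hydro"] == HOPP_WOODS_CHECK["I"]
        assert values["w+2_Hydro"] == HOPP_WOODS_CHECK["E"]

    def test_locality(self):
        p1 = sw.ProteinRecord("a", "AAIKSEA")
        p2 = sw.ProteinRecord("b", "WAIKSEW")
        w1, w2 = sw.window_at(p1, 4), sw.window_at(p2, 4)
        h1, h2 = fe.hydrophobicity_features(w1), fe.hydrophobicity_features(w2)
        for name in ("w-2_Hydro", "w-3_Hydro", "w+1_Hydro", "w+2_Hydro"):
            assert h1[name] == h2[name]
        assert h1["w-1_Hydro"] != h2["w-1_Hydro"]


@pytest.mark.parametrize(
    "upstream,downstream,expected",
    [
        (("A", "A", "A"), ("A", "A", "A"), (0, 0)),
        (("A", "D", "A"), ("A", "A", "A"), (1, 0)),
        (("K", "A", "A"), ("A", "A", "E"), (1, 1)),
    ],
)
def test_composition_flags(upstream, downstream, expected):
    w = sw.SiteWindow("p", 10, upstream, downstream)
    assert fe.composition_flags(w) == expected


@pytest.mark.parametrize(
    "position,length,expected",
    [
        (5, 100, (1, -100)),
        (50, 100, (0, 100)),
        (95, 100, (1, -100)),
        (10, 100, (1, -100)),  # boundary: position <= 0.1 * length
        (90, 100, (0, 100)),  # boundary: not > 0.9 * length
        (11, 100, (0, 100)),
    ],
)
def test_terminal_and_length(position, length, expected):
    assert fe.terminal_and_length(position, length) == expected


def test_subwindow_volumes_match_accumulation_oracle():
    rng = np.random.default_rng(3)
    volumes = fe.kharakoz_volumes()
    for _ in range(25):
        flanks = rng.choice(list(fe.AMINO_ACIDS), size=6)
        w = sw.SiteWindow("p", 10, tuple(flanks[:3]), tuple(flanks[3:]))
        before, after, diff = fe.subwindow_volumes(w)
        exp_before = 0.0
        for r in flanks[:3]:
            exp_before += volumes[r]
        exp_after = 0.0
        for r in flanks[3:]:
            exp_after += volumes[r]
        assert before == pytest.approx(exp_before)
        assert after == pytest.approx(exp_after)
        assert diff == pytest.approx(exp_after - exp_before)


@pytest.mark.parametrize(
    "tendency,expected_binary", [(0.7, 1), (0.3, 0), (0.5, 1)]  # cutoff inclusive
)
def test_disorder_binary_cutoff(tendency, expected_binary):
    ann = fe.FlexDisorderAnnotation("p", (0,), (tendency,))
    real, binary, flexible = fe.disorder_features(ann, 1)
    assert real == tendency
    assert binary == expected_binary
    assert flexible == 0


class TestScaler:
    @pytest.fixture
    def matrix(self):
        rng = np.random.default_rng(11)
        return pd.DataFrame(
            {
                "a": rng.normal(5, 2, 50),
                "b": rng.integers(0, 2, 50).astype(float),
                "const": np.full(50, 3.0),
            }
        )

    def test_min_maps_to_zero_max_to_one(self, matrix):
        scaled = fe.apply_scaler(fe.fit_scaler(matrix), matrix)
        assert scaled["a"].min() == pytest.approx(0.0)
        assert scaled["a"].max() == pytest.approx(1.0)

    def test_constant_column_maps_to_zero(self, matrix):
        scaled = fe.apply_scaler(fe.fit_scaler(matrix), matrix)
        assert (scaled["const"] == 0.0).all()

    def test_binary_columns_survive(self, matrix):
        scaled = fe.apply_scaler(fe.fit_scaler(matrix), matrix)
        assert set(np.unique(scaled["b"])) == {0.0, 1.0}
        assert (scaled["b"] == matrix["b"]).all()

    def test_test_values_not_clamped(self, matrix):
        params = fe.fit_scaler(matrix)
        test = matrix.copy()
        test.loc[0, "a"] = matrix["a"].max() + 10
        scaled = fe.apply_scaler(params, test)
        assert scaled.loc[0, "a"] > 1.0

    def test_idempotent_on_scaled_training_data(self, matrix):
        params = fe.fit_scaler(matrix)
        once = fe.apply_scaler(params, matrix)
        twice = fe.apply_scaler(fe.fit_scaler(once), once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_feature_set_mismatch_rejected(self, matrix):
        params = fe.fit_scaler(matrix)
        with pytest.raises(ValueError, match="feature set mismatch"):
            fe.apply_scaler(params, matrix.rename(columns={"a": "z"}))

    def test_roundtrip_serialization(self, matrix):
        params = fe.fit_scaler(matrix)
        assert fe.ScalingParams.from_dict(params.to_dict()) == params


def test_encoding_is_deterministic(protein, window, annotation):
    v1 = fe.encode_site(window, protein, annotation)
    v2 = fe.encode_site(window, protein, annotation)
    assert v1 == v2


def test_ablation_drops_named_columns(protein, annotation):
    windows = sw.extract_lysine_windows(protein)
    df = fe.encode_dataset(
        windows, [protein], {"p": annotation},
        drop_features=("Flexible", "DisorderReal", "DisorderBinary"),
    )
    feature_cols = [c for c in df.columns if c not in fe.META_COLUMNS]
    assert len(feature_cols) == 134
    assert "Flexible" not in df.columns


def test_annotation_tsv_roundtrip(tmp_path, annotation):
    path = tmp_path / "ann.tsv"
    fe.write_annotations({"p": annotation}, path)
    loaded = fe.read_annotations(path)["p"]
    assert loaded.flexible == annotation.flexible
    assert np.allclose(loaded.disorder, annotation.disorder, atol=1e-6)


def test_sparse_svm_format(tmp_path, protein, annotation):
    windows = [sw.window_at(protein, 4, label="positive")]
    df = fe.encode_dataset(windows, [protein], {"p": annotation})
    path = tmp_path / "m.svm"
    fe.write_sparse_svm(df, path)
    line = path.read_text().strip()
    assert line.startswith("+1 ") or line.startswith("1 ")
    # indices 1-based in canonical order: w-A_1 is feature 1 (value 1 here)
    assert " 1:1" in f" {line.split(' ', 1)[1]}"
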