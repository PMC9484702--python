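"""ACC featurization: brute-force oracle agreement and analytic properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alleracc.acc import (ShortSequenceError, acc_transform, feature_names,
                          featurize_dataset)
from alleracc.descriptors import EDescriptorTable, EncodedSequence, encode_sequence
from alleracc.io import CANONICAL_ALPHABET, ProteinRecord
from conftest import ALPHABET, make_dataset, random_sequence


def brute_force_acc(E: np.ndarray, max_lag: int, dialect: str = "uncentered"):
    """Independent oracle: explicit loops over (j, k, l, i), no vectorization."""
    n = E.shape[0]
    if dialect == "centered":
        E = E - E.mean(axis=0, keepdims=True)
    out = {}
    for j in range(1, 6):
        for k in range(1, 6):
            for lag in range(1, max_lag + 1):
                total = 0.0
                for i in range(n - lag):
                    total += E[i, j - 1] * E[i + lag, k - 1]
                norm = n if dialect == "uncentered_n" else n - lag
                out[f"AC{j}{k}{lag}"] = total / norm
    return out


class TestFeatureNames:
    def test_lag5_contains_canonical_names_in_order(self):
        names = feature_names(5)
        assert len(names) == 125
        assert names[0] == "AC111" and names[-1] == "AC555"
        for expected in ("AC111", "AC121", "AC131", "AC145", "AC431", "AC555"):
            assert expected in names
        assert len(set(names)) == 125

    @pytest.mark.parametrize("max_lag, count", [(1, 25), (2, 50), (5, 125)])
    def test_counting(self, max_lag, count):
        names = feature_names(max_lag)
        assert len(names) == count
        if max_lag == 1:
            assert all(name.endswith("1") for name in names)

    def test_nonpositive_lag_rejected(self):
        with pytest.raises(ValueError):
            feature_names(0)


class TestACCTransform:
    def test_matches_brute_force_oracle_on_fixed_sequence(self, shipped_table):
        enc = encode_sequence(ProteinRecord("r", "ACDEFGHIK"), shipped_table)
        vec = acc_transform(enc, max_lag=5)
        oracle = brute_force_acc(enc.matrix, 5)
        for name, value in zip(vec.names, vec.values):
            assert value == pytest.approx(oracle[name], abs=1e-10)

    def test_matches_oracle_on_random_sequences_and_tables(self):
        """>= 200 random (sequence, table) pairs across lengths 6..400."""
        rng = np.random.default_rng(2024)
        for trial in range(200):
            length = int(rng.integers(6, 401))
            table = EDescriptorTable(
                entries={c: rng.normal(size=5) for c in ALPHABET},
                source="trial", checksum="")
            enc = encode_sequence(
                ProteinRecord(f"t{trial}", random_sequence(rng, length)), table)
            vec = acc_transform(enc, max_lag=5)
            oracle = brute_force_acc(enc.matrix, 5)
            err = max(abs(v - oracle[nm]) for nm, v in zip(vec.names, vec.values))
            assert err < 1e-10

    @pytest.mark.parametrize("dialect", ["uncentered_n", "centered"])
    def test_alternative_dialects_match_oracle(self, dialect, shipped_table):
        rng = np.random.default_rng(5)
        enc = encode_sequence(
            ProteinRecord("r", random_sequence(rng, 60)), shipped_table)
        vec = acc_transform(enc, max_lag=5, dialect=dialect)
        oracle = brute_force_acc(enc.matrix, 5, dialect=dialect)
        for name, value in zip(vec.names, vec.values):
            assert value == pytest.approx(oracle[name], abs=1e-10)

    @pytest.mark.parametrize("residue", sorted(CANONICAL_ALPHABET))
    def test_homopolymer_closed_form(self, residue, shipped_table):
        # every summand is the same product, so AC{j}{k}{l} = E_j * E_k
        e = shipped_table.entries[residue]
        enc = encode_sequence(ProteinRecord("r", residue * 10), shipped_table)
        vec = acc_transform(enc, max_lag=5)
        for name, value in zip(vec.names, vec.values):
            j, k = int(name[2]) - 1, int(name[3]) - 1
            assert value == pytest.approx(e[j] * e[k], rel=1e-12)

    def test_all_zero_table_gives_all_zero_features(self):
        table = EDescriptorTable(
            entries={c: np.zeros(5) for c in ALPHABET}, source="zeros", checksum="")
        enc = encode_sequence(ProteinRecord("r", "ACDEFGHIKLMNP"), table)
        assert np.all(acc_transform(enc).values == 0)

    def test_reversal_swaps_descriptor_indices(self, shipped_table):
        rng = np.random.default_rng(9)
        seq = random_sequence(rng, 80)
        fwd = acc_transform(encode_sequence(ProteinRecord("f", seq), shipped_table))
        rev = acc_transform(
            encode_sequence(ProteinRecord("r", seq[::-1]), shipped_table))
        fwd_map = dict(zip(fwd.names, fwd.values))
        for name, value in zip(rev.names, rev.values):
            j, k, lag = name[2], name[3], name[4]
            assert value == pytest.approx(fwd_map[f"AC{k}{j}{lag}"], rel=1e-12,
                                          abs=1e-15)

    def test_table_scaling_scales_features_quadratically(self, shipped_table):
        rng = np.random.default_rng(13)
        seq = random_sequence(rng, 40)
        base = acc_transform(encode_sequence(ProteinRecord("r", seq), shipped_table))
        scaled = acc_transform(
            encode_sequence(ProteinRecord("r", seq), shipped_table.scaled(3.0)))
        assert np.allclose(scaled.values, 9.0 * base.values, rtol=1e-12)

    @given(length=st.integers(min_value=6, max_value=120),
           max_lag=st.integers(min_value=1, max_value=5))
    @settings(max_examples=40, derandomize=True)
    def test_output_dimension_is_25L_regardless_of_length(self, length, max_lag,
                                                          shipped_table):
        rng = np.random.default_rng(length * 7 + max_lag)
        enc = encode_sequence(
            ProteinRecord("r", random_sequence(rng, length)), shipped_table)
        assert acc_transform(enc, max_lag=max_lag).values.shape == (25 * max_lag,)

    def test_too_short_sequence_error_names_record_and_minimum(self, shipped_table):
        enc = encode_sequence(ProteinRecord("tiny", "MKVLW"), shipped_table)
        with pytest.raises(ShortSequenceError, match="'tiny'.*length 5.*at least 6"):
            acc_transform(enc, max_lag=5)


class TestFeaturizeDataset:
    def test_dimension_contract(self, shipped_table):
        rng = np.random.default_rng(1)
        ds = make_dataset([random_sequence(rng, n) for n in (100, 200, 6)])
        fm = featurize_dataset(ds, shipped_table, max_lag=5)
        assert fm.values.shape == (3, 125)
        assert fm.feature_names == feature_names(5)

    def test_drop_policy_realigns_labels(self, shipped_table):
        rng = np.random.default_rng(2)
        ds = make_dataset(
            [random_sequence(rng, 50), "MKVLW", random_sequence(rng, 60)],
            labels=["allergen", "allergen", "non_allergen"])
        fm = featurize_dataset(ds, shipped_table, short_policy="drop")
        assert fm.ids == ["rec0", "rec2"]
        assert fm.labels == ["allergen", "non_allergen"]

    def test_all_too_short_raises_even_under_drop(self, shipped_table):
        ds = make_dataset(["MKV", "ACDE"])
        with pytest.raises(ShortSequenceError):
            featurize_dataset(ds, shipped_table, short_policy="drop")

    def test_batch_rows_equal_single_record_transform(self, shipped_table):
        rng = np.random.default_rng(4)
        seqs = [random_sequence(rng, int(rng.integers(6, 150))) for _ in range(10)]
        ds = make_dataset(seqs)
        fm = featurize_dataset(ds, shipped_table)
        for row, record in zip(fm.values, ds.records):
            single = acc_transform(encode_sequence(record, shipped_table))
            assert np.array_equal(row, single.values)

    def test_tsv_round_trip_bit_exact(self, shipped_table, tmp_path):
        rng = np.random.default_rng(6)
        ds = make_dataset([random_sequence(rng, 30) for _ in range(4)],
                          labels=["allergen", "allergen", "non_allergen",
                                  "non_allergen"])
        fm = featurize_dataset(ds, shipped_table)
        path = tmp_path / "features.tsv"
        fm.to_tsv(path)
        back = fm.from_tsv(path)
        assert np.array_equal(back.values, fm.values)
        assert back.ids == fm.ids and back.labels == fm.labels
        assert back.feature_names == fm.feature_names
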