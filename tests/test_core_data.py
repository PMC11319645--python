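"""Dataset ingestion, normalization, and the two model encodings."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crisprtl.core_data import (DataError, Dataset, GuideRecord, decode_rnn,
                                encode_cnn, encode_rnn, minmax_normalize,
                                normalize_dataset, read_dataset, write_dataset)
from crisprtl.biofeatures import attach_biofeatures

from conftest import make_dataset, random_guide21, random_context30


# ---------------------------------------------------------------------------
# ingestion


def _write_csv(path, rows, header="id,sequence,eff"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


def test_reads_23nt_rows_and_strips_the_fixed_gg(tmp_path):
    f = tmp_path / "t.csv"
    _write_csv(f, ["a,ACGTACGTACGTACGTACGTAGG,0.1",
                   "b,TTTTACGTACGTACGTACGTGGG,0.5",
                   "c,ACGTACGTACGTACGTACGTTGG,0.9"])
    ds = read_dataset(f, schema={"sequence": "sequence", "id": "id",
                                 "efficiency": {"eff": "eff"}})
    assert len(ds) == 3
    assert ds.records[0].guide21 == "ACGTACGTACGTACGTACGTA"
    assert ds.records[0].efficiencies == {"eff": 0.1}


def test_rejects_rows_with_bad_pam_or_alphabet_with_line_numbers(tmp_path):
    f = tmp_path / "t.csv"
    _write_csv(f, ["a,ACGTACGTACGTACGTACGTAGG,0.1",
                   "b,ACGTACGTACGTACGTACGTAAG,0.5",   # ends AG
                   "c,ACGTACGTACGTACGTACGTXGG,0.9"])  # bad letter
    ds = read_dataset(f, schema={"sequence": "sequence", "id": "id",
                                 "efficiency": {"eff": "eff"}})
    assert len(ds) == 1
    assert [line for line, _ in ds.rejected_rows] == [3, 4]


def test_zero_valid_rows_is_a_hard_error(tmp_path):
    f = tmp_path / "t.csv"
    _write_csv(f, ["a,ACGTACGTACGTACGTACGTAAG,0.1"])
    with pytest.raises(DataError, match="zero valid rows"):
        read_dataset(f, schema={"sequence": "sequence", "id": "id",
                                "efficiency": {"eff": "eff"}})


def test_30nt_context_is_stored_and_guide_derived(tmp_path):
    rng = np.random.default_rng(4)
    ctx = random_context30(rng)
    f = tmp_path / "t.csv"
    _write_csv(f, [f"a,{ctx},0.25"])
    ds = read_dataset(f, schema={"sequence": "sequence", "id": "id",
                                 "efficiency": {"eff": "eff"}})
    rec = ds.records[0]
    assert rec.context30 == ctx and rec.guide21 == ctx[4:25]


def test_roundtrip_write_then_read_is_lossless(tmp_path):
    ds = make_dataset(12, seed=3, conditions=("WT", "Esp"), with_features=False)
    out = tmp_path / "round.csv"
    write_dataset(ds, out)
    back = read_dataset(out, schema={"sequence": "sequence", "id": "id",
                                     "efficiency": {"WT": "WT", "Esp": "Esp"}})
    for a, b in zip(ds, back):
        assert a.guide21 == b.guide21 and a.context30 == b.context30
        assert a.efficiencies == b.efficiencies


def test_guide_record_invariants_enforced():
    with pytest.raises(DataError):
        GuideRecord(id="x", guide21="A" * 20)  # wrong length
    with pytest.raises(DataError):
        GuideRecord(id="x", guide21="A" * 21, efficiencies={"WT": 1.5})
    with pytest.raises(DataError):  # context must embed guide with GG PAM
        GuideRecord(id="x", guide21="A" * 21, context30="A" * 30)


# ---------------------------------------------------------------------------
# normalization


def test_minmax_examples():
    assert np.allclose(minmax_normalize([0, 5, 10]), [0, 0.5, 1])
    v = np.array([0.0, 0.3, 0.7, 1.0])
    assert np.allclose(minmax_normalize(v), v)  # fixed point


def _well_separated(v):
    # distinct values must stay distinct at the output's float precision
    s = sorted(set(v))
    return len(s) >= 3 and min(b - a for a, b in zip(s, s[1:])) > 1e-6 * (s[-1] - s[0])


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=50, unique=True)
       .filter(_well_separated))
def test_minmax_is_rank_preserving_unit_range_and_idempotent(values):
    from scipy.stats import spearmanr
    out = minmax_normalize(values)
    assert out.min() == 0.0 and out.max() == 1.0
    assert spearmanr(values, out).statistic == pytest.approx(1.0)
    assert np.allclose(minmax_normalize(out), out)


def test_minmax_rejects_constant_column():
    with pytest.raises(DataError, match="constant"):
        minmax_normalize([2.0, 2.0, 2.0])
    ds = make_dataset(5, seed=1, with_features=False)
    for rec in ds:
        rec._raw_efficiencies = {"WT": 3.3}
    with pytest.raises(DataError, match="WT"):
        normalize_dataset(ds)


# ---------------------------------------------------------------------------
# encodings


def test_rnn_encoding_layout_and_enzyme_indicator():
    rec = GuideRecord(id="a", guide21="A" * 21, efficiencies={"WT": 0.5},
                      biofeatures=np.zeros(11))
    batch = encode_rnn([rec], condition="WT")
    assert batch.seq.shape == (1, 22, 5)
    assert batch.seq[0, 0, 0] == 1.0              # start token
    assert (batch.seq[0, 1:, 1] == 1.0).all()     # A column
    assert batch.extra[0, 11:].tolist() == [1.0, 0.0, 0.0]
    assert (batch.seq.sum(axis=2) == 1.0).all()


def test_rnn_encoding_roundtrips_100_random_guides():
    rng = np.random.default_rng(7)
    guides = [random_guide21(rng) for _ in range(100)]
    recs = [GuideRecord(id=str(i), guide21=g, efficiencies={"c": 0.5},
                        biofeatures=np.zeros(11)) for i, g in enumerate(guides)]
    batch = encode_rnn(recs)
    assert decode_rnn(batch.seq) == guides


def test_rnn_encoding_requires_biofeatures():
    rec = GuideRecord(id="a", guide21="A" * 21, efficiencies={"WT": 0.5})
    with pytest.raises(DataError, match="biofeatures"):
        encode_rnn([rec])


def test_cnn_encoding_onehot_and_injectivity():
    ctx = "A" * 25 + "GG" + "AAA"
    rec = GuideRecord(id="a", guide21=ctx[4:25], context30=ctx,
                      efficiencies={"c": 0.5}, energy_score=-1.0)
    batch = encode_cnn([rec])
    assert batch.seq.shape == (1, 30, 4)
    a_col = batch.seq[0, :, 0]
    assert a_col.sum() == 28 and batch.seq[0].sum() == 30
    assert batch.extra[0, 0] == -1.0

    rng = np.random.default_rng(9)
    contexts = {random_context30(rng) for _ in range(1000)}
    recs = [GuideRecord(id=str(i), guide21=c[4:25], context30=c,
                        efficiencies={"c": 0.5}, energy_score=0.0)
            for i, c in enumerate(contexts)]
    enc = encode_cnn(recs)
    hashes = {arr.tobytes() for arr in enc.seq}
    assert len(hashes) == len(contexts)
    assert (enc.seq.sum(axis=2) == 1.0).all()


def test_cnn_encoding_errors_name_the_record():
    rec = GuideRecord(id="needle", guide21="A" * 21, efficiencies={"c": 0.5})
    with pytest.raises(DataError, match="needle"):
        encode_cnn([rec])


def test_encoders_are_deterministic():
    ds = make_dataset(6, seed=2)
    a, b = encode_rnn(ds.records), encode_rnn(ds.records)
    assert (a.seq == b.seq).all() and (a.extra == b.extra).all()
    c, d = encode_cnn(ds.records), encode_cnn(ds.records)
    assert (c.seq == d.seq).all() and (c.extra == d.extra).all()
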