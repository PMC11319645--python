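"""Training loop, fine-tuning schemes, freeze contracts, baselines."""

import numpy as np
import pytest

from crisprtl.core_data import DataError
from crisprtl.leakage import SplitPlan
from crisprtl.models import ModelSpec, build_ensemble, build_model, predict
from crisprtl.training import (HyperSearchSpace, TrainConfig, _round_half_away,
                               baseline, determine_epochs_cv, encode_for_spec,
                               fine_tune, hyper_search, pretrain, train_member)

from conftest import make_dataset


SPEC = ModelSpec(kind="rnn", embedding_dim=4, recurrent_units=6, dense_layers=(8, 4))
CFG = TrainConfig(learning_rate=3e-3, batch_size=32, max_epochs=6, patience=2,
                  ensemble_size=2, seed=0)


@pytest.fixture(scope="module")
def target_ds():
    return make_dataset(60, seed=30)


@pytest.fixture(scope="module")
def pretrained(target_ds):
    source = make_dataset(120, seed=31)
    plan = SplitPlan([r.id for r in source], [], 1.0, 5, 0)
    return pretrain(SPEC, source, plan, CFG), source


def _snapshot(ens):
    return [{k: v.data.copy() for k, v in m.params.items()} for m in ens.members]


def test_patience_zero_trains_exactly_one_epoch(target_ds):
    m = build_model(SPEC, 0)
    batch = encode_for_spec(SPEC, target_ds.records)
    cfg = TrainConfig(learning_rate=1e-3, batch_size=32, max_epochs=10,
                      patience=0, ensemble_size=1)
    log = train_member(m, batch.take(np.arange(40)), batch.take(np.arange(40, 60)), cfg)
    assert sum(e["epoch"] >= 1 for e in log) == 1


def test_training_reduces_validation_loss(pretrained):
    ens, _ = pretrained
    for log in ens.logs:
        epoch0 = next(e["val_loss"] for e in log if e["epoch"] == 0)
        trained = min(e["val_loss"] for e in log if e["epoch"] >= 1)
        assert trained < epoch0


def test_zero_epoch_fine_tune_equals_no_tl_baseline(pretrained, target_ds):
    ens, _ = pretrained
    tuned = fine_tune(ens, target_ds, "full", CFG, epochs=0)
    batch = encode_for_spec(SPEC, target_ds.records)
    assert (predict(tuned, batch) == predict(ens, batch)).all()
    assert baseline("no_tl", pretrained=ens) is ens


@pytest.mark.parametrize("scheme,frozen_prefixes", [
    ("last_layer", ("embed.", "gru.", "dense.0.")),
    ("no_input_layer", ("embed.",)),
])
def test_freeze_contract_parameters_outside_mask_are_bit_identical(
        pretrained, target_ds, scheme, frozen_prefixes):
    ens, _ = pretrained
    before = _snapshot(ens)
    tuned = fine_tune(ens, target_ds, scheme, CFG, epochs=2)
    for b, m in zip(before, tuned.members):
        changed = {k for k in m.params if not (m.params[k].data == b[k]).all()}
        for k in m.params:
            if k.startswith(frozen_prefixes):
                assert k not in changed, f"{scheme} must not touch {k}"
        assert changed  # something did train
    # the original ensemble itself is untouched by fine-tuning a copy
    for b, m in zip(before, ens.members):
        for k in m.params:
            assert (m.params[k].data == b[k]).all()


def test_gradual_phase1_matches_last_layer_end_state(pretrained, target_ds):
    ens, _ = pretrained
    ll = fine_tune(ens, target_ds, "last_layer", CFG, epochs=3)
    grad = fine_tune(ens, target_ds, "gradual", CFG, epochs=(3, 0))
    for a, b in zip(ll.members, grad.members):
        for k in a.params:
            assert (a.params[k].data == b.params[k].data).all()


def test_rounding_rule_is_half_away_from_zero():
    assert _round_half_away(3.5) == 4
    assert _round_half_away(2.5) == 3
    assert _round_half_away(2.4) == 2


def test_epoch_determination_within_fold_optima(pretrained, target_ds):
    ens, _ = pretrained
    cfg = TrainConfig(learning_rate=3e-3, batch_size=32, max_epochs=4,
                      patience=2, ensemble_size=1, seed=1)
    ep = determine_epochs_cv(ens, target_ds, cfg, k=3)
    assert 1 <= ep <= cfg.max_epochs
    with pytest.raises(DataError):
        determine_epochs_cv(ens, target_ds, cfg, k=1)


def test_full_run_is_reproducible(target_ds):
    source = make_dataset(100, seed=32)
    plan = SplitPlan([r.id for r in source], [], 1.0, 5, 0)
    batch = encode_for_spec(SPEC, target_ds.records)
    runs = []
    for _ in range(2):
        ens = pretrain(SPEC, source, plan, CFG)
        tuned = fine_tune(ens, target_ds, "full", CFG, epochs=2)
        runs.append(predict(tuned, batch))
    assert (runs[0] == runs[1]).all()


def test_no_pretrain_baseline_smoke(target_ds):
    cfg = TrainConfig(learning_rate=3e-3, batch_size=16, max_epochs=3,
                      patience=2, ensemble_size=1, seed=2)
    ens = baseline("no_pretrain", spec=SPEC, train_set=target_ds, config=cfg)
    preds = predict(ens, encode_for_spec(SPEC, target_ds.records))
    assert np.isfinite(preds).all() and len(preds) == len(target_ds)


def test_multi_task_flattening_counts_only_observed_conditions():
    ds = make_dataset(10, seed=33, conditions=("WT", "Esp", "HF"))
    del ds.records[0].efficiencies["HF"]
    del ds.records[1].efficiencies["WT"]
    spec = ModelSpec(kind="rnn", embedding_dim=4, recurrent_units=6,
                     dense_layers=(8, 4), multi_task=True)
    batch = encode_for_spec(spec, ds.records)
    assert batch.n == 30 - 2
    assert batch.extra.shape[1] == 11 + 3
    assert (batch.extra[:, 11:].sum(axis=1) == 1.0).all()


def test_hyper_search_prefers_stable_over_divergent(target_ds):
    space = HyperSearchSpace(
        train_choices={"learning_rate": [3e-3, 1e3]},
        n_trials=4, seed=0)
    spec, cfg, table = hyper_search(space, target_ds, base_spec=SPEC,
                                    base_config=TrainConfig(
                                        batch_size=32, max_epochs=3, patience=2,
                                        ensemble_size=1))
    assert cfg.learning_rate == 3e-3
    assert len(table) == 4
    # reproducible under the same seed
    _, _, table2 = hyper_search(space, target_ds, base_spec=SPEC,
                                base_config=TrainConfig(
                                    batch_size=32, max_epochs=3, patience=2,
                                    ensemble_size=1))
    assert table == table2

    single = HyperSearchSpace(train_choices={"batch_size": [16]}, n_trials=1, seed=1)
    _, cfg1, t1 = hyper_search(single, target_ds, base_spec=SPEC,
                               base_config=TrainConfig(max_epochs=2, patience=1,
                                                       ensemble_size=1))
    assert cfg1.batch_size == 16 and len(t1) == 1
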