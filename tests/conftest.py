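import numpy as np
import pytest

from subloc.encoding import load_physchem
from subloc.hierarchy import load_hierarchy


@pytest.fixture(scope="session")
def physchem():
    return load_physchem()


@pytest.fixture(scope="session")
def default_hierarchy():
    return load_hierarchy()


@pytest.fixture(scope="session")
def toy_hierarchy_file(tmp_path_factory):
    """A 2-organelle, 3-suborganelle layout written as a spec file."""
    path = tmp_path_factory.mktemp("hier") / "toy.tsv"
    path.write_text(
        "orgA\ts1\t0\n"
        "orgA\ts2\t1\n"
        "orgB\ts3\t0\n"
    )
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


RECOVERY_SEED = 1

#: reduced-scale study configuration for the planted-motif recovery runs
RECOVERY_MODEL = dict(
    encode_length=200, hidden_total=32, heads=4, attn_inner=64,
    lr=3e-3, batch_size=4, dropout_lstm=0.0, dropout_dense=0.0,
    seed=RECOVERY_SEED,
)
RECOVERY_CYCLES = 30


@pytest.fixture(scope="session")
def recovery():
    """Train the reduced-scale model once on the planted-motif study.

    Three planted-signal classes plus background, 150 proteins per class,
    a 16-unit-per-direction bidirectional LSTM with 4 attention heads at
    encoding length 200, 30 alternation cycles, pinned seed. Shared by the
    recovery-scoring tests (a few CPU-minutes, run once per session).
    """
    from subloc.evaluation import decide
    from subloc.network import ModelConfig
    from subloc.synthetic_data import (
        default_sim_config,
        simulate_proteome,
        toy_hierarchy,
    )
    from subloc.training import (
        EnsembleModel,
        ensemble_predict,
        prepare_samples,
        train_submodel,
        tune_thresholds,
    )

    sim = default_sim_config(seed=RECOVERY_SEED, n_per_class=150)
    records, truths = simulate_proteome(sim)
    h = toy_hierarchy(sim)
    cfg = ModelConfig(n_organelles=h.n_organelles, **RECOVERY_MODEL)
    samples = prepare_samples(records, h, encode_length=cfg.encode_length)
    test_idx = set(range(0, len(samples), 4))
    train_s = [s for i, s in enumerate(samples) if i not in test_idx]
    test_s = [s for i, s in enumerate(samples) if i in test_idx]
    test_recs = [r for i, r in enumerate(records) if i in test_idx]
    model = train_submodel(train_s, cfg, cycles=RECOVERY_CYCLES)
    ens = EnsembleModel(models=[model], hierarchy=h)
    tr_scores = np.array([
        model.predict(s.x.features[None], s.x.mask[None])[0][0].sub_scores
        for s in train_s
    ])
    tr_targets = np.array([s.target for s in train_s])
    ens.thresholds = tune_thresholds(tr_scores, tr_targets, h)
    results, org_truth = [], []
    for s in test_s:
        sm = ensemble_predict(ens, s.x)
        results.append(decide(sm, ens.thresholds, h, fallback="top1"))
    for r in test_recs:
        org_truth.append(set(r.organelle_labels))
    return {
        "sim": sim, "records": records, "truths": truths, "h": h,
        "ens": ens, "samples": samples, "test_s": test_s,
        "test_recs": test_recs, "results": results, "org_truth": org_truth,
    }
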