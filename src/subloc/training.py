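"""Training: folds, alternating two-level epochs, ensembling, thresholds,
and a Gaussian-process hyperparameter search harness.

Sub-models are trained by alternating one epoch on organelle-only samples
(lv1, max-pooled loss only) with one epoch on suborganelle-annotated
samples (lv2, full matrix loss), for a configurable number of alternation
cycles (80 at production scale). The ensemble prediction is the arithmetic
mean of the sub-models' score matrices, with organelle scores recomputed as
column maxima of the averaged matrix. Per-cell decision thresholds are tuned
on cross-validated scores over a grid restricted to (0, 0.5], choosing the
candidate with the highest MCC and breaking ties toward the smaller
threshold (favoring recall).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from ._nn import Tensor
from .encoding import EncodedProtein, blosum_fallback, encode, load_physchem
from .hierarchy import LabelHierarchy, labels_to_matrix
from .network import ARCHIVE_VERSION, Model, ModelConfig, ScoreMatrix

__all__ = [
    "FoldPlan",
    "make_folds",
    "TrainingSample",
    "prepare_samples",
    "train_submodel",
    "EnsembleModel",
    "ensemble_predict",
    "ThresholdSet",
    "tune_thresholds",
    "bayes_search",
    "save_ensemble",
    "load_ensemble",
]


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    k: int
    assignment: np.ndarray  # fold index per record
    mode: str
    cluster_ids: list | None = None


def make_folds(records, k: int, mode: str = "random", seed: int = 0) -> FoldPlan:
    """Partition records into k folds.

    Random mode gives fold sizes differing by at most one. Cluster mode
    consumes precomputed cluster ids (e.g. from an external 40%-identity
    clustering) and never splits a cluster across folds; clusters are
    dealt largest-first onto the currently smallest fold.
    """
    n = len(records)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds record count {n}")
    rng = np.random.default_rng(seed)
    assignment = np.zeros(n, dtype=int)
    if mode == "random":
        order = rng.permutation(n)
        for pos, idx in enumerate(order):
            assignment[idx] = pos % k
    elif mode == "cluster":
        ids = []
        for rec in records:
            cid = getattr(rec, "cluster_id", None)
            if cid is None:
                raise ValueError("cluster mode requires cluster_id on every record")
            ids.append(cid)
        members: dict = {}
        for i, cid in enumerate(ids):
            members.setdefault(cid, []).append(i)
        clusters = sorted(members.values(), key=lambda m: (-len(m), m[0]))
        sizes = [0] * k
        for m in clusters:
            f = int(np.argmin(sizes))
            for i in m:
                assignment[i] = f
            sizes[f] += len(m)
    else:
        raise ValueError(f"unknown fold mode {mode!r}")
    return FoldPlan(k=k, assignment=assignment, mode=mode,
                    cluster_ids=ids if mode == "cluster" else None)


# ---------------------------------------------------------------------------
# sample preparation and the training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainingSample:
    x: EncodedProtein
    target: np.ndarray  # (n_slots, n_org)
    org_target: np.ndarray  # (n_org,)
    lv2: bool
    accession: str = ""


def prepare_samples(records, h: LabelHierarchy, physchem=None,
                    encode_length: int = 1000) -> list:
    """Encode records with the BLOSUM62 fallback profile and attach targets."""
    if physchem is None:
        physchem = load_physchem()
    samples = []
    for rec in records:
        prof = blosum_fallback(rec.sequence)
        x = encode(rec, prof, physchem, encode_length=encode_length)
        target, org_target, lv2 = labels_to_matrix(rec, h)
        samples.append(TrainingSample(x, target, org_target, lv2, rec.accession))
    return samples


def _batch_loss_graph(model: Model, batch, lv2: bool, rng, cell_mask=None):
    """Build the graph loss for a batch of TrainingSamples.

    `cell_mask` (n_slots x n_org binary), when given, restricts the lv2
    cell loss to occupied hierarchy cells; by default EMPTY slots train
    toward zero like any other cell.
    """
    cfg = model.cfg
    x = np.stack([s.x.features for s in batch])
    mask = np.stack([s.x.mask for s in batch])
    out = model.forward_graph(x, mask, train=True, rng=rng)
    A = out["A"]
    eye = np.eye(cfg.heads)
    G = A.bmm(A.swap()) - Tensor(eye)
    penalty = (G * G).sum(axis=-1).sum(axis=-1).mean()

    org_t = np.stack([s.org_target for s in batch])
    lost2 = -(
        Tensor(org_t) * out["org"].log()
        + Tensor(1.0 - org_t) * (1.0 - out["org"]).log()
    ).mean()
    loss = lost2 + penalty * cfg.attention_reg_weight
    if lv2:
        sub_t = np.stack([s.target for s in batch])
        bce = -(
            Tensor(sub_t) * out["sub"].log()
            + Tensor(1.0 - sub_t) * (1.0 - out["sub"]).log()
        )
        if cell_mask is None:
            lost1 = bce.mean()
        else:
            m = np.asarray(cell_mask, dtype=float)
            lost1 = (bce * Tensor(m[None])).sum() * (
                1.0 / (m.sum() * len(batch))
            )
        loss = loss + lost1
    return loss


def _run_epoch(model, opt, samples, lv2, batch_size, rng, cell_mask=None):
    order = rng.permutation(len(samples))
    total, nb = 0.0, 0
    for start in range(0, len(samples), batch_size):
        batch = [samples[i] for i in order[start : start + batch_size]]
        loss = _batch_loss_graph(model, batch, lv2, rng, cell_mask=cell_mask)
        opt.zero_grad()
        loss.backward()
        opt.step()
        total += float(loss.value)
        nb += 1
    return total / max(nb, 1)


def train_submodel(samples, cfg: ModelConfig, cycles: int = 80,
                   log=None, cell_mask=None) -> Model:
    """Train one sub-model with the alternating two-level scheme.

    Each cycle runs one epoch on the lv1-only samples (skipped with a log
    note when none exist) followed by one epoch on the lv2 samples. With
    cycles=0 the initialized, untrained model is returned. `cell_mask`
    (optional) excludes EMPTY hierarchy slots from the lv2 cell loss.
    """
    lv1_set = [s for s in samples if not s.lv2]
    lv2_set = [s for s in samples if s.lv2]
    if not lv2_set:
        raise ValueError("training requires at least one lv2-annotated sample")
    model = Model(cfg)
    opt = model.make_optimizer()
    rng = np.random.default_rng(cfg.seed + 1)
    for cycle in range(cycles):
        if lv1_set:
            m1 = _run_epoch(model, opt, lv1_set, False, cfg.batch_size, rng)
            model.history.append(("lv1", cycle, m1))
        m2 = _run_epoch(model, opt, lv2_set, True, cfg.batch_size, rng,
                        cell_mask=cell_mask)
        model.history.append(("lv2", cycle, m2))
        if log is not None:
            log(cycle, model.history[-1])
    return model


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------

@dataclass
class ThresholdSet:
    """Decision threshold per occupied hierarchy cell, all <= 0.5."""

    thresholds: dict  # (row, col) -> float
    default: float = 0.5

    def get(self, cell) -> float:
        return self.thresholds.get(tuple(cell), self.default)


@dataclass
class EnsembleModel:
    models: list
    hierarchy: LabelHierarchy
    thresholds: ThresholdSet = field(
        default_factory=lambda: ThresholdSet(thresholds={})
    )

    @property
    def cfg(self) -> ModelConfig:
        return self.models[0].cfg


def ensemble_predict(ens: EnsembleModel, x) -> ScoreMatrix:
    """Cell-wise mean of sub-model score matrices; organelle scores are the
    column maxima of the averaged matrix."""
    if not ens.models:
        raise ValueError("ensemble has no sub-models")
    cfgs = {
        (m.cfg.n_organelles, m.cfg.n_slots, m.cfg.encode_length) for m in ens.models
    }
    if len(cfgs) > 1:
        raise ValueError("sub-models disagree on output configuration")
    feats, mask = (x.features, x.mask) if hasattr(x, "features") else x
    subs = []
    for m in ens.models:
        scores, _ = m.predict(feats[None], np.asarray(mask)[None])
        subs.append(scores[0].sub_scores)
    return ScoreMatrix.from_sub(np.mean(subs, axis=0))


# ---------------------------------------------------------------------------
# threshold tuning
# ---------------------------------------------------------------------------

def _mcc(tp, fp, tn, fn):
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return None
    return (tp * tn - fp * fn) / denom


def tune_thresholds(scores: np.ndarray, targets: np.ndarray,
                    h: LabelHierarchy, grid=None) -> ThresholdSet:
    """Pick, per occupied cell, the grid threshold maximizing MCC.

    `scores`/`targets` are (n, n_slots, n_org) cross-validation predictions
    and binary targets. The grid must lie in (0, 0.5]; a sample is called
    positive when its score >= threshold. Ties go to the smaller threshold
    (more positives, higher recall). Cells without both classes keep 0.5.
    """
    if grid is None:
        grid = [round(0.05 * i, 2) for i in range(1, 11)]  # 0.05 .. 0.50
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ValueError("empty threshold grid")
    if grid[0] <= 0 or grid[-1] > 0.5:
        raise ValueError("thresholds must lie in (0, 0.5]")
    out = {}
    for (r, c) in h.occupied:
        y = targets[:, r, c]
        s = scores[:, r, c]
        if y.sum() == 0 or y.sum() == len(y):
            continue  # keep default 0.5
        best_t, best_m = None, -np.inf
        for t in grid:
            pred = s >= t
            tp = int(np.sum(pred & (y == 1)))
            fp = int(np.sum(pred & (y == 0)))
            fn = int(np.sum(~pred & (y == 1)))
            tn = int(np.sum(~pred & (y == 0)))
            m = _mcc(tp, fp, tn, fn)
            m = -np.inf if m is None else m
            if m > best_m:  # strict: first (smallest) threshold wins ties
                best_m, best_t = m, t
        if best_t is not None:
            out[(r, c)] = best_t
    return ThresholdSet(thresholds=out)


# ---------------------------------------------------------------------------
# Bayesian optimization harness (reduced scale)
# ---------------------------------------------------------------------------

def bayes_search(objective, space: dict, n_trials: int, jitter: float = 0.05,
                 seed: int = 0, n_initial: int = 5):
    """Maximize `objective(config)` with a GP surrogate + expected improvement.

    `space` maps each hyperparameter name to a (low, high) range (floats) or
    a list of discrete choices. The acquisition jitter trades exploitation
    against exploration. Failed objective calls are logged and skipped.
    Returns (best configuration, trial log).
    """
    from scipy.stats import norm
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern

    if not space:
        raise ValueError("empty search space")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    names = sorted(space)

    def sample_unit(n):
        return rng.random((n, len(names)))

    def to_config(u):
        cfg = {}
        for j, name in enumerate(names):
            spec = space[name]
            if isinstance(spec, (list, tuple)) and not (
                len(spec) == 2 and all(isinstance(v, (int, float)) for v in spec)
            ):
                cfg[name] = spec[min(int(u[j] * len(spec)), len(spec) - 1)]
            else:
                lo, hi = spec
                cfg[name] = lo + u[j] * (hi - lo)
        return cfg

    trials = []  # dicts: config, unit point, value or None (failed)
    X, Y = [], []

    def run(u):
        cfg = to_config(u)
        try:
            val = float(objective(cfg))
        except Exception as exc:  # objective failure: mark, continue
            trials.append({"config": cfg, "value": None, "error": str(exc)})
            return
        trials.append({"config": cfg, "value": val, "error": None})
        X.append(u)
        Y.append(val)

    for u in sample_unit(min(n_initial, n_trials)):
        run(u)
    while len(trials) < n_trials:
        if len(X) < 2:
            run(sample_unit(1)[0])
            continue
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5), normalize_y=True, alpha=1e-6,
            random_state=int(rng.integers(2**31)),
        )
        gp.fit(np.array(X), np.array(Y))
        cand = sample_unit(256)
        mu, sd = gp.predict(cand, return_std=True)
        best = max(Y)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (mu - best - jitter) / sd
            ei = (mu - best - jitter) * norm.cdf(z) + sd * norm.pdf(z)
        ei[sd < 1e-12] = 0.0
        run(cand[int(np.argmax(ei))])

    ok = [t for t in trials if t["value"] is not None]
    if not ok:
        raise RuntimeError("every trial failed")
    best_trial = max(ok, key=lambda t: t["value"])
    return best_trial["config"], trials


# ---------------------------------------------------------------------------
# ensemble serialization (single versioned archive)
# ---------------------------------------------------------------------------

def save_ensemble(ens: EnsembleModel, path) -> None:
    from dataclasses import asdict

    arrays = {}
    for i, m in enumerate(ens.models):
        for name, t in m.params.items():
            arrays[f"m{i}/{name}"] = t.value
    meta = {
        "version": ARCHIVE_VERSION,
        "n_models": len(ens.models),
        "config": asdict(ens.cfg),
        "organelles": ens.hierarchy.organelles,
        "grid": ens.hierarchy.grid,
        "thresholds": [[r, c, t] for (r, c), t in ens.thresholds.thresholds.items()],
        "threshold_default": ens.thresholds.default,
    }
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_ensemble(path) -> EnsembleModel:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"].tobytes()).decode())
        if meta["version"] != ARCHIVE_VERSION:
            raise ValueError(f"unsupported archive version {meta['version']}")
        cfg = ModelConfig(**meta["config"])
        models = []
        for i in range(meta["n_models"]):
            m = Model(cfg)
            for name, t in m.params.items():
                t.value = npz[f"m{i}/{name}"].astype(np.float64)
            models.append(m)
    grid = [[cell if cell is not None else None for cell in row] for row in meta["grid"]]
    name_to_cell = {
        cell: (r, c)
        for r, row in enumerate(grid)
        for c, cell in enumerate(row)
        if cell is not None
    }
    h = LabelHierarchy(
        organelles=meta["organelles"], grid=grid, name_to_cell=name_to_cell
    )
    thr = ThresholdSet(
        thresholds={(int(r), int(c)): float(t) for r, c, t in meta["thresholds"]},
        default=meta["threshold_default"],
    )
    return EnsembleModel(models=models, hierarchy=h, thresholds=thr)
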