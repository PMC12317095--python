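"""Cross-validated training of the dual-branch aggregator.

Five-fold cross-validation with a 6:2:2 train/validation/test split per
fold: the five outer test sets partition the cohort, and the remaining 80%
of each fold splits 3:1 into training and validation. Training iterates
cases singly (batch size one) with AdamW, samples at most ``max_tiles``
tiles per slide per epoch during training and validation, applies branch
dropout in duet mode, and selects the checkpoint with the best validation
AUROC (evaluated every ``eval_every`` iterations and at the end of
training, earliest best on ties). Test-time inference always uses all
tiles of a slide.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .duonet import DuetTransformer, DuoNetConfig
from .evalmetrics import auroc
from .seeds import derive_seed
from .slideprep import sample_tiles
from .synthcohort import PairedCase

log = logging.getLogger("duetmil.trainer")


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    train_ids: tuple
    val_ids: tuple
    test_ids: tuple

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("train/val/test id sets must be disjoint")


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults are the published operating point)."""

    learning_rate: float = 1e-5
    weight_decay: float = 5e-4
    epochs: int = 10
    batch_size: int = 1
    eval_every: int = 500
    max_tiles: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.weight_decay) < 0 or self.learning_rate == 0:
            raise ValueError("learning_rate must be positive, weight_decay non-negative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1; refusing to return an untrained model")
        if self.batch_size != 1:
            raise ValueError("only batch size one is supported")
        if self.eval_every < 1 or self.max_tiles < 1:
            raise ValueError("eval_every and max_tiles must be >= 1")


class AdamW:
    """AdamW with decoupled weight decay over a named-parameter dict."""

    def __init__(self, params: dict, lr: float, weight_decay: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[k] / c1 / (np.sqrt(self.v[k] / c2) + self.eps)
                            + self.wd * p)


def make_folds(case_ids, k: int = 5, seed: int = 0, labels=None) -> list[FoldSplit]:
    """Deterministic k-fold 6:2:2 splits whose test sets partition the cohort.

    With ``labels`` given, test chunks and the 3:1 train/validation split are
    stratified by class so small-prevalence cohorts keep positives in every
    subset.
    """
    ids = list(case_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(ids) < k:
        raise ValueError("need at least k cases")
    rng = np.random.default_rng(derive_seed(seed, "folds"))
    if labels is None:
        strata = [np.array(ids, dtype=object)]
    else:
        lab = {i: l for i, l in zip(ids, labels)}
        strata = [np.array([i for i in ids if lab[i] == v], dtype=object)
                  for v in sorted({*labels})]
    chunks: list[list] = [[] for _ in range(k)]
    for arr in strata:
        perm = rng.permutation(arr)
        for j, part in enumerate(np.array_split(perm, k)):
            chunks[j].extend(part.tolist())
    folds = []
    for f in range(k):
        test = sorted(chunks[f])
        rest = sorted(i for j, ch in enumerate(chunks) if j != f for i in ch)
        rrng = np.random.default_rng(derive_seed(seed, "trainval", f))
        if labels is None:
            rest_strata = [np.array(rest, dtype=object)]
        else:
            lab = {i: l for i, l in zip(ids, labels)}
            rest_strata = [np.array([i for i in rest if lab[i] == v], dtype=object)
                           for v in sorted({*labels})]
        val: list = []
        train: list = []
        for arr in rest_strata:
            perm = rrng.permutation(arr)
            n_val = int(round(len(perm) / 4.0))
            val.extend(perm[:n_val].tolist())
            train.extend(perm[n_val:].tolist())
        folds.append(FoldSplit(f, tuple(sorted(train)), tuple(sorted(val)), tuple(test)))
    return folds


@dataclass
class TrainResult:
    fold_id: int
    mode: str
    best_state: dict
    best_val_auroc: float
    best_iteration: int
    history: pd.DataFrame
    config: DuoNetConfig


def _mode_bags(case: PairedCase, mode: str, idx: np.ndarray | None):
    """Pick (and optionally subsample) the bags a mode needs."""
    he = ihc = None
    if mode in ("HE_ONLY", "DUET"):
        he = case.he_bag if idx is None else case.he_bag.subset(idx)
    if mode in ("IHC_ONLY", "DUET"):
        ihc = case.ihc_bag if idx is None else case.ihc_bag.subset(idx)
    return he, ihc


def _n_tiles(case: PairedCase, mode: str) -> int:
    bag = case.he_bag if mode != "IHC_ONLY" else case.ihc_bag
    return bag.n_tiles


def _check_two_classes(ids, data, what: str) -> None:
    labs = {data[i].label for i in ids}
    if labs != {0, 1}:
        raise ValueError(f"{what} set must contain both classes (saw labels {sorted(labs)})")


def evaluate_auroc(model: DuetTransformer, data: dict, ids, mode: str,
                   max_tiles: int | None = None, seed: int = 0, tag: str = "val") -> float:
    """AUROC of the model over ``ids``; tiles capped when ``max_tiles`` is set."""
    probs, labels = [], []
    for cid in ids:
        case = data[cid]
        idx = None
        if max_tiles is not None and _n_tiles(case, mode) > max_tiles:
            idx = sample_tiles(_n_tiles(case, mode), max_tiles,
                               seed=derive_seed(seed, tag, cid))
        he, ihc = _mode_bags(case, mode, idx)
        probs.append(model.forward(he, ihc, mode=mode, training=False).probability)
        labels.append(case.label)
    return auroc(np.array(probs), np.array(labels))


def train_fold(data: dict, split: FoldSplit, model_cfg: DuoNetConfig,
               train_cfg: TrainConfig, mode: str = "DUET") -> TrainResult:
    """Train one fold and return the best-validation checkpoint plus history."""
    tc = train_cfg
    _check_two_classes(split.train_ids, data, "training")
    _check_two_classes(split.val_ids, data, "validation")
    model = DuetTransformer(model_cfg, seed=derive_seed(tc.seed, "init", split.fold_id))
    opt = AdamW(model.params, tc.learning_rate, tc.weight_decay)
    drop_rng = np.random.default_rng(derive_seed(tc.seed, "dropout", split.fold_id))

    best_auroc, best_it, best_state = -np.inf, -1, None
    hist_rows = []
    it = 0
    total_iters = tc.epochs * len(split.train_ids)

    def maybe_eval(loss: float) -> None:
        nonlocal best_auroc, best_it, best_state
        val = evaluate_auroc(model, data, split.val_ids, mode,
                             max_tiles=tc.max_tiles,
                             seed=derive_seed(tc.seed, "valtiles", split.fold_id, it))
        hist_rows.append({"iteration": it, "loss": loss, "val_auroc": val})
        if val > best_auroc:  # strict: earliest best wins ties
            best_auroc, best_it, best_state = val, it, model.state_dict()
        log.info("fold %d mode %s iter %d/%d loss %.4f val_auroc %.4f",
                 split.fold_id, mode, it, total_iters, loss, val)

    for epoch in range(tc.epochs):
        order = np.random.default_rng(
            derive_seed(tc.seed, "order", split.fold_id, epoch)).permutation(
            np.array(split.train_ids, dtype=object))
        for cid in order:
            case = data[cid]
            n = _n_tiles(case, mode)
            idx = None
            if n > tc.max_tiles:
                idx = sample_tiles(n, tc.max_tiles,
                                   seed=derive_seed(tc.seed, "tiles", epoch, cid))
            he, ihc = _mode_bags(case, mode, idx)
            trace = model.forward(he, ihc, mode=mode, training=True, rng=drop_rng)
            loss = model.bce_loss(trace.logit, case.label)
            grads = model.backward(trace, case.label)
            opt.step(grads)
            it += 1
            if it % tc.eval_every == 0:
                maybe_eval(loss)
    if it % tc.eval_every != 0:
        maybe_eval(loss)

    return TrainResult(split.fold_id, mode, best_state, float(best_auroc), best_it,
                       pd.DataFrame(hist_rows), model_cfg)


def predict_cases(model: DuetTransformer, data: dict, ids, mode: str = "DUET",
                  fold: int | None = None) -> pd.DataFrame:
    """Deterministic full-tile inference; one probability per case."""
    rows = []
    for cid in ids:
        case = data[cid]
        he, ihc = _mode_bags(case, mode, None)
        trace = model.forward(he, ihc, mode=mode, training=False)
        rows.append({
            "case_id": cid, "probability": trace.probability, "label": case.label,
            "fold": fold, "mode": mode, "scanner": case.scanner, "site": case.site,
        })
    return pd.DataFrame(rows)


@dataclass
class CVResult:
    mode: str
    predictions: pd.DataFrame  # pooled outer-test predictions
    fold_aurocs: list
    models: dict = field(default_factory=dict)  # fold_id -> DuetTransformer
    splits: list = field(default_factory=list)


def cross_validate(cases: list[PairedCase], model_cfg: DuoNetConfig,
                   train_cfg: TrainConfig, mode: str = "DUET", k: int = 5,
                   stratify: bool = True) -> CVResult:
    """Full k-fold CV: train each fold, predict its held-out test set.

    Guards against leakage by construction and by assertion: the model
    evaluated on a fold's test ids was trained and selected on ids disjoint
    from them.
    """
    data = {c.case_id: c for c in cases}
    labels = [c.label for c in cases] if stratify else None
    splits = make_folds([c.case_id for c in cases], k=k, seed=train_cfg.seed,
                        labels=labels)
    preds, fold_aurocs, models = [], [], {}
    for sp in splits:
        assert not (set(sp.test_ids) & (set(sp.train_ids) | set(sp.val_ids))), \
            "leakage: test ids overlap train/val ids"
        res = train_fold(data, sp, model_cfg, train_cfg, mode=mode)
        model = DuetTransformer(model_cfg, seed=0)
        model.load_state_dict(res.best_state)
        df = predict_cases(model, data, sp.test_ids, mode=mode, fold=sp.fold_id)
        preds.append(df)
        fold_aurocs.append(auroc(df["probability"].to_numpy(), df["label"].to_numpy()))
        models[sp.fold_id] = model
    return CVResult(mode, pd.concat(preds, ignore_index=True), fold_aurocs, models, splits)
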