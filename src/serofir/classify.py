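"""Supervised multiclass classification of preprocessed spectra.

A 1-D convolutional network (implemented in :mod:`serofir.nn`) classifies
second-derivative serum spectra into the three groups.  The surrounding
machinery mirrors standard chemometric practice:

* stratified 65/20/15 train/validation/test splits, repeated ``n_repeats``
  times ("repeated hold-out"; a strict k-fold mode is available), with
  grouping by subject (all replicates of one subject share a subset) or by
  spectrum;
* training by SGD with momentum and L2 weight decay, early stopping on the
  validation error with best-weight restoration;
* Bayesian optimization (Gaussian-process surrogate, expected-improvement
  acquisition) of section depth, learning rate, momentum, L2 strength,
  filter size and filter count;
* per-split preprocessing (MSC reference and scaler statistics fitted on
  the training rows only — no leakage) and pooling of all repeats' test
  predictions into one confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern
from sklearn.utils.validation import check_is_fitted
from scipy import stats

from . import evaluate
from .dataset import SpectralDataset
from .nn import (
    Conv1D, Dense, Dropout, Flatten, MaxPool1D, Network, ReLU, SGDMomentum,
    cross_entropy_grad, softmax,
)
from .preprocess import PreprocessModel, PreprocessParams

__all__ = [
    "SplitSpec", "make_splits",
    "CNNArchitecture", "TrainingParams", "build_cnn",
    "CNNSpectralClassifier", "train_cnn", "predict",
    "HyperparamSpace", "bayes_optimize",
    "ClassifierRun", "run_classification",
]

SUBSETS = ("train", "validation", "test")


class ClassificationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """One train/validation/test assignment of all dataset rows."""

    repeat: int
    assignment: np.ndarray          # per-row subset name
    grouping: str                   # 'subject' or 'spectrum'
    ratios: tuple
    seed: int

    def rows(self, subset: str) -> np.ndarray:
        return np.flatnonzero(self.assignment == subset)


def _largest_remainder(n: int, ratios: tuple) -> list[int]:
    """Integer subset sizes for one stratum, largest-remainder rounding."""
    quotas = [n * r for r in ratios]
    base = [int(np.floor(q)) for q in quotas]
    short = n - sum(base)
    order = np.argsort([-(q - b) for q, b in zip(quotas, base)], kind="stable")
    for i in order[:short]:
        base[i] += 1
    return base


def make_splits(dataset: SpectralDataset, ratios: tuple = (0.65, 0.20, 0.15),
                grouping: str = "subject", n_repeats: int = 10, seed: int = 0,
                mode: str = "holdout") -> list[SplitSpec]:
    """Stratified random splits at the stated ratios.

    ``mode='holdout'`` draws ``n_repeats`` independent stratified splits;
    ``mode='kfold'`` makes ``n_repeats`` folds where the test set is the
    fold and the remainder is split train/validation proportionally.
    Deterministic under ``(seed, repeat)``.
    """
    if grouping not in ("subject", "spectrum"):
        raise ClassificationError(f"unknown grouping {grouping!r}")
    if mode not in ("holdout", "kfold"):
        raise ClassificationError(f"unknown split mode {mode!r}")
    if abs(sum(ratios) - 1.0) > 1e-9 or len(ratios) != 3:
        raise ClassificationError("ratios must be three numbers summing to 1")
    meta = dataset.metadata
    unit_col = "subject_id" if grouping == "subject" else "spectrum_id"
    units = meta[[unit_col, "group"]].drop_duplicates(unit_col)
    for cls, grp in units.groupby("group"):
        if len(grp) < 3:
            raise ClassificationError(
                f"class {cls!r} has only {len(grp)} {grouping} units; "
                "cannot cover train/validation/test"
            )
    splits = []
    for rep in range(n_repeats):
        unit_subset: dict[str, str] = {}
        for cls, grp in units.groupby("group", sort=True):
            ids = grp[unit_col].to_numpy()
            if mode == "holdout":
                rng = np.random.default_rng(np.random.SeedSequence([seed, 7, rep]))
                ids = ids[rng.permutation(len(ids))]
                sizes = _largest_remainder(len(ids), tuple(ratios))
                ordered = ids
            else:
                # one fixed permutation for all repeats; fold `rep` is the test set
                rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
                ids = ids[rng.permutation(len(ids))]
                folds = np.array_split(ids, n_repeats)
                test_ids = folds[rep]
                rest = np.concatenate([f for r, f in enumerate(folds) if r != rep])
                rrng = np.random.default_rng(np.random.SeedSequence([seed, 7, rep, 1]))
                rest = rest[rrng.permutation(len(rest))]
                tv = _largest_remainder(
                    len(rest),
                    (ratios[0] / (ratios[0] + ratios[1]),
                     ratios[1] / (ratios[0] + ratios[1])),
                )
                sizes = [tv[0], tv[1], len(test_ids)]
                ordered = np.concatenate([rest, test_ids])
            cursor = 0
            for subset, size in zip(SUBSETS, sizes):
                for uid in ordered[cursor:cursor + size]:
                    unit_subset[uid] = subset
                cursor += size
        assignment = meta[unit_col].map(unit_subset).to_numpy()
        splits.append(SplitSpec(repeat=rep, assignment=assignment,
                                grouping=grouping, ratios=tuple(ratios), seed=seed))
    return splits


# ---------------------------------------------------------------------------
# architecture / training parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CNNArchitecture:
    """1-D CNN topology.

    ``section_depth`` conv+ReLU+max-pool blocks form the main section, two
    further conv+max-pool blocks are always appended; the flattened feature
    map feeds a dense layer with dropout and a softmax output of size
    ``n_classes``.  Filter counts double per block, capped at 32.
    """

    section_depth: int = 2
    filter_size: int = 5
    n_filters: int = 8
    pool_size: int = 2
    extra_conv_blocks: int = 2
    dense_units: int = 64
    dropout_rate: float = 0.3
    n_classes: int = 3

    def __post_init__(self) -> None:
        if self.section_depth < 1:
            raise ClassificationError("section_depth must be >= 1")
        if self.filter_size < 3 or self.filter_size % 2 == 0:
            raise ClassificationError("filter_size must be odd and >= 3")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ClassificationError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class TrainingParams:
    """SGD training schedule."""

    learning_rate: float = 0.02
    momentum: float = 0.9
    l2: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ClassificationError("learning rate must be >= 0")
        if not 0.0 <= self.momentum < 1.0:
            raise ClassificationError("momentum must be in [0, 1)")
        if self.l2 < 0:
            raise ClassificationError("l2 must be >= 0")


def build_cnn(arch: CNNArchitecture, input_length: int,
              rng: np.random.Generator | None = None):
    """Instantiate the network; returns (network, layer-by-layer description).

    Raises a labelled error if max pooling exhausts the spectral axis.
    """
    rng = rng or np.random.default_rng(0)
    layers: list = []
    description: list[dict] = []
    length, channels = input_length, 1
    n_blocks = arch.section_depth + arch.extra_conv_blocks
    for b in range(n_blocks):
        filters = min(arch.n_filters * 2 ** b, 32)
        conv = Conv1D(channels, filters, arch.filter_size, rng)
        layers += [conv, ReLU(), MaxPool1D(arch.pool_size)]
        pooled = length // arch.pool_size
        if pooled == 0:
            raise ClassificationError(
                f"pooled length reached 0 at conv block {b + 1} "
                f"(input length {input_length}, pool {arch.pool_size})"
            )
        description.append(
            {"layer": f"conv_block_{b + 1}",
             "kernel": arch.filter_size, "filters": filters,
             "out_length": pooled,
             "n_params": conv.W.size + conv.b.size}
        )
        length, channels = pooled, filters
    flat = length * channels
    dense1 = Dense(flat, arch.dense_units, rng)
    out = Dense(arch.dense_units, arch.n_classes, rng)
    layers += [Flatten(), dense1, ReLU(), Dropout(arch.dropout_rate, rng), out]
    description += [
        {"layer": "dense", "units": arch.dense_units,
         "n_params": dense1.W.size + dense1.b.size},
        {"layer": "dropout", "rate": arch.dropout_rate, "n_params": 0},
        {"layer": "softmax_output", "units": arch.n_classes,
         "n_params": out.W.size + out.b.size},
    ]
    return Network(layers), description


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _as_tensor(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return X[:, :, None] if X.ndim == 2 else X


def _evaluate(network: Network, X: np.ndarray, y: np.ndarray,
              batch: int = 256) -> tuple[float, float]:
    losses, hits, n = 0.0, 0, X.shape[0]
    for s in range(0, n, batch):
        logits = network.forward(X[s:s + batch], train=False)
        loss, _ = cross_entropy_grad(logits, y[s:s + batch])
        losses += loss * logits.shape[0]
        hits += int((logits.argmax(axis=1) == y[s:s + batch]).sum())
    return losses / n, hits / n


def train_cnn(network: Network, X_train, y_train, X_val, y_val,
              params: TrainingParams) -> pd.DataFrame:
    """Train with SGD+momentum+L2 and early stopping on validation error.

    Stops at ``max_epochs`` or when the validation classification error has
    not improved for ``patience`` consecutive epochs (validation loss breaks
    ties at equal error); the best-validation weights are restored.  Returns
    the per-epoch history (train/validation loss and accuracy).  Non-finite
    loss raises a labelled divergence error.
    """
    X_train, X_val = _as_tensor(X_train), _as_tensor(X_val)
    y_train = np.asarray(y_train, dtype=int)
    y_val = np.asarray(y_val, dtype=int)
    opt = SGDMomentum(network, params.learning_rate, params.momentum, params.l2)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 11]))
    history = []
    best_key, best_epoch, best_weights = (np.inf, np.inf), 0, network.get_weights()
    n = X_train.shape[0]
    for epoch in range(1, params.max_epochs + 1):
        order = rng.permutation(n)
        for s in range(0, n, params.batch_size):
            idx = order[s:s + params.batch_size]
            # overflow in a diverging run is detected via the loss check
            with np.errstate(over="ignore", invalid="ignore"):
                logits = network.forward(X_train[idx], train=True)
                loss, grad = cross_entropy_grad(logits, y_train[idx])
                if not np.isfinite(loss):
                    raise ClassificationError(
                        f"training diverged (non-finite loss) at epoch {epoch}, "
                        f"learning rate {params.learning_rate}"
                    )
                network.backward(grad)
                opt.step()
        tr_loss, tr_acc = _evaluate(network, X_train, y_train)
        va_loss, va_acc = _evaluate(network, X_val, y_val)
        history.append({"epoch": epoch, "train_loss": tr_loss,
                        "train_accuracy": tr_acc, "val_loss": va_loss,
                        "val_accuracy": va_acc})
        key = (round(1.0 - va_acc, 12), va_loss)
        if key < best_key:
            if key[0] < best_key[0]:
                best_epoch = epoch  # patience counts epochs without *error* improvement
            best_key = key
            best_weights = network.get_weights()
        if epoch - best_epoch > params.patience:
            break
    network.set_weights(best_weights)
    hist = pd.DataFrame(history)
    hist.attrs["best_epoch"] = best_epoch
    return hist


# ---------------------------------------------------------------------------
# sklearn-style classifier
# ---------------------------------------------------------------------------

class CNNSpectralClassifier(ClassifierMixin, BaseEstimator):
    """1-D CNN classifier over preprocessed spectra (rows = spectra).

    ``fit(X, y)`` holds out an internal stratified validation fraction for
    early stopping unless ``validation=(X_val, y_val)`` is passed.  Dropout
    is disabled at inference, so ``predict`` is deterministic; argmax ties
    break toward the lowest class index.
    """

    def __init__(self, arch: CNNArchitecture | None = None,
                 training: TrainingParams | None = None,
                 validation_fraction: float = 0.2, seed: int = 0):
        self.arch = arch
        self.training = training
        self.validation_fraction = validation_fraction
        self.seed = seed

    def fit(self, X, y, validation=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        arch = self.arch or CNNArchitecture(n_classes=len(self.classes_))
        if arch.n_classes != len(self.classes_):
            arch = replace(arch, n_classes=len(self.classes_))
        training = self.training or TrainingParams(seed=self.seed)
        if validation is not None:
            X_tr, y_tr = X, y_idx
            X_va = np.asarray(validation[0], dtype=float)
            y_va = np.searchsorted(self.classes_, np.asarray(validation[1]))
        else:
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, 13]))
            order = rng.permutation(X.shape[0])
            n_val = max(1, int(round(self.validation_fraction * X.shape[0])))
            val_rows, tr_rows = order[:n_val], order[n_val:]
            X_tr, y_tr = X[tr_rows], y_idx[tr_rows]
            X_va, y_va = X[val_rows], y_idx[val_rows]
        rng_net = np.random.default_rng(np.random.SeedSequence([self.seed, 17]))
        self.network_, self.description_ = build_cnn(arch, X.shape[1], rng_net)
        self.history_ = train_cnn(self.network_, X_tr, y_tr, X_va, y_va, training)
        self.input_length_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.input_length_:
            raise ClassificationError(
                f"input length {X.shape[1]} != training length {self.input_length_}"
            )
        out = []
        for s in range(0, X.shape[0], 256):
            out.append(softmax(self.network_.forward(_as_tensor(X[s:s + 256]),
                                                     train=False)))
        return np.vstack(out)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]  # argmax: lowest index wins ties


def predict(model: CNNSpectralClassifier, X) -> np.ndarray:
    """Class-probability rows for preprocessed, scaled spectra."""
    return model.predict_proba(X)


# ---------------------------------------------------------------------------
# Bayesian hyperparameter optimization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HyperparamSpace:
    """Mixed search space over architecture and SGD variables."""

    section_depth: tuple = (1, 3)
    learning_rate: tuple = (1e-3, 1e-1)      # log-uniform
    momentum: tuple = (0.5, 0.95)
    l2: tuple = (1e-6, 1e-2)                 # log-uniform
    filter_sizes: tuple = (3, 5, 7, 9)
    n_filters: tuple = (4, 16)
    budget: int = 15

    def __post_init__(self) -> None:
        if self.budget < 1:
            raise ClassificationError("budget must be >= 1")
        if not self.filter_sizes:
            raise ClassificationError("filter_sizes must be nonempty")

    # -- encoding to/from the unit hypercube --------------------------------
    @property
    def n_dims(self) -> int:
        return 6

    def decode(self, u: np.ndarray) -> dict:
        u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
        lo_d, hi_d = self.section_depth
        depth = int(np.clip(np.floor(lo_d + u[0] * (hi_d - lo_d + 1)), lo_d, hi_d))
        lr = float(np.clip(
            np.exp(np.log(self.learning_rate[0])
                   + u[1] * np.log(self.learning_rate[1] / self.learning_rate[0])),
            *self.learning_rate))
        mom = float(self.momentum[0] + u[2] * (self.momentum[1] - self.momentum[0]))
        l2 = float(np.clip(
            np.exp(np.log(self.l2[0]) + u[3] * np.log(self.l2[1] / self.l2[0])),
            *self.l2))
        fs = self.filter_sizes[
            int(np.clip(np.floor(u[4] * len(self.filter_sizes)), 0,
                        len(self.filter_sizes) - 1))
        ]
        lo_f, hi_f = self.n_filters
        nf = int(np.clip(np.floor(lo_f + u[5] * (hi_f - lo_f + 1)), lo_f, hi_f))
        return {"section_depth": depth, "learning_rate": lr, "momentum": mom,
                "l2": l2, "filter_size": int(fs), "n_filters": nf}


def _expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float) -> np.ndarray:
    sigma = np.maximum(sigma, 1e-12)
    z = (best - mu) / sigma
    return (best - mu) * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)


def bayes_optimize(space: HyperparamSpace, objective, seed: int = 0,
                   n_initial: int = 5, random_search: bool = False):
    """Sequential model-based minimisation over the mixed space.

    ``objective`` maps a decoded hyperparameter dict to a validation
    classification error.  A Gaussian-process surrogate (Matern 5/2) with
    expected-improvement acquisition proposes points after ``n_initial``
    random ones; ``random_search=True`` falls back to pure random search.
    Non-finite objective values are recorded as failures and skipped by the
    surrogate; if every point fails a labelled error is raised.  Returns
    ``(best hyperparameter dict, trace DataFrame)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    U: list[np.ndarray] = []
    records: list[dict] = []
    for it in range(space.budget):
        if random_search or it < min(n_initial, space.budget) or \
                sum(np.isfinite(r["objective"]) for r in records) < 2:
            u = rng.random(space.n_dims)
        else:
            ok = [i for i, r in enumerate(records) if np.isfinite(r["objective"])]
            X_obs = np.vstack([U[i] for i in ok])
            y_obs = np.array([records[i]["objective"] for i in ok])
            gp = GaussianProcessRegressor(
                kernel=ConstantKernel(1.0) * Matern(length_scale=0.3, nu=2.5),
                alpha=1e-4, normalize_y=True, random_state=seed,
            ).fit(X_obs, y_obs)
            cand = rng.random((512, space.n_dims))
            mu, sd = gp.predict(cand, return_std=True)
            u = cand[int(np.argmax(_expected_improvement(mu, sd, y_obs.min())))]
        params = space.decode(u)
        try:
            value = float(objective(params))
        except FloatingPointError:
            value = np.nan
        if not np.isfinite(value):
            value = np.nan
        U.append(u)
        records.append({"iteration": it, **params, "objective": value})
    trace = pd.DataFrame(records)
    finite = trace["objective"].to_numpy()
    if not np.isfinite(finite).any():
        raise ClassificationError("every hyperparameter evaluation failed")
    best_row = trace.loc[trace["objective"].idxmin()]
    best = {k: best_row[k] for k in
            ("section_depth", "learning_rate", "momentum", "l2",
             "filter_size", "n_filters")}
    best["section_depth"] = int(best["section_depth"])
    best["filter_size"] = int(best["filter_size"])
    best["n_filters"] = int(best["n_filters"])
    return best, trace


# ---------------------------------------------------------------------------
# end-to-end repeated-split evaluation
# ---------------------------------------------------------------------------

@dataclass
class ClassifierRun:
    """Everything a classification campaign produced."""

    splits: list
    best_hyperparams: dict
    trace: pd.DataFrame | None
    predictions: list            # per repeat: DataFrame(spectrum_id, true, predicted)
    histories: list
    confusion: evaluate.ConfusionMatrix
    metrics: pd.DataFrame
    class_order: tuple
    preprocess_stats: list = field(default_factory=list)


def _arch_training_from(point: dict, base_arch: CNNArchitecture,
                        base_training: TrainingParams, seed: int):
    arch = replace(base_arch, section_depth=point["section_depth"],
                   filter_size=point["filter_size"], n_filters=point["n_filters"])
    training = replace(base_training, learning_rate=point["learning_rate"],
                       momentum=point["momentum"], l2=point["l2"], seed=seed)
    return arch, training


def run_classification(
    dataset: SpectralDataset,
    preprocess_params: PreprocessParams | None = None,
    ratios: tuple = (0.65, 0.20, 0.15),
    grouping: str = "spectrum",
    n_repeats: int = 10,
    split_mode: str = "holdout",
    arch: CNNArchitecture | None = None,
    training: TrainingParams | None = None,
    space: HyperparamSpace | None = None,
    bayes_budget: int = 0,
    class_order: tuple | None = None,
    seed: int = 0,
) -> ClassifierRun:
    """Full supervised campaign on a raw (QC-filtered) dataset.

    For every repeat, the preprocessing chain — truncation, SG second
    derivative, MSC, vector normalization, per-wavenumber standardization —
    is fitted on the training rows only and applied to validation and test
    rows with the train statistics.  When ``bayes_budget > 0``,
    hyperparameters are first optimized on the repeat-0 split by minimising
    validation error, then the chosen point trains all repeats.  Test
    predictions are pooled over repeats into one confusion matrix.
    """
    labels = dataset.metadata["group"].to_numpy()
    classes = tuple(class_order or pd.unique(labels))
    if preprocess_params is None:
        preprocess_params = PreprocessParams(scale_mode="standardize")
    base_arch = arch or CNNArchitecture(n_classes=len(classes))
    base_training = training or TrainingParams()

    splits = make_splits(dataset, ratios=ratios, grouping=grouping,
                         n_repeats=n_repeats, seed=seed, mode=split_mode)

    class_index = {c: i for i, c in enumerate(classes)}

    def encode(lab: np.ndarray) -> np.ndarray:
        try:
            return np.array([class_index[v] for v in lab], dtype=int)
        except KeyError as exc:
            raise ClassificationError(
                f"label {exc.args[0]!r} outside the class order {classes}"
            ) from None

    def prepared(split: SplitSpec):
        tr, va, te = (split.rows(s) for s in SUBSETS)
        pre = PreprocessModel(preprocess_params).fit(dataset.select_rows(tr))
        out = {}
        for name, rows in zip(SUBSETS, (tr, va, te)):
            sub = pre.transform(dataset.select_rows(rows))
            out[name] = (sub.intensities,
                         encode(dataset.metadata["group"].to_numpy()[rows]),
                         dataset.metadata["spectrum_id"].to_numpy()[rows])
        return pre, out

    # -- hyperparameter search on the first split ---------------------------
    trace = None
    if bayes_budget > 0:
        space = space or HyperparamSpace(budget=bayes_budget)
        if space.budget != bayes_budget:
            space = replace(space, budget=bayes_budget)
        _, parts0 = prepared(splits[0])

        # hyperparameter evaluations run a shortened schedule; the chosen
        # point then trains every repeat with the full one
        search_training = replace(base_training,
                                  max_epochs=min(base_training.max_epochs, 30),
                                  patience=min(base_training.patience, 6))

        def objective(point: dict) -> float:
            a, t = _arch_training_from(point, base_arch, search_training, seed)
            rng_net = np.random.default_rng(np.random.SeedSequence([seed, 29]))
            net, _ = build_cnn(a, parts0["train"][0].shape[1], rng_net)
            try:
                hist = train_cnn(net, parts0["train"][0], parts0["train"][1],
                                 parts0["validation"][0], parts0["validation"][1], t)
            except ClassificationError:
                return float("nan")  # divergence: recorded as a failed point
            return 1.0 - hist["val_accuracy"].iloc[hist.attrs["best_epoch"] - 1]

        best, trace = bayes_optimize(space, objective, seed=seed)
    else:
        best = {"section_depth": base_arch.section_depth,
                "learning_rate": base_training.learning_rate,
                "momentum": base_training.momentum, "l2": base_training.l2,
                "filter_size": base_arch.filter_size,
                "n_filters": base_arch.n_filters}

    arch_best, training_best = _arch_training_from(best, base_arch,
                                                   base_training, seed)

    predictions, histories, pre_stats = [], [], []
    for split in splits:
        pre, parts = prepared(split)
        training_rep = training_best
        for attempt in range(4):
            clf = CNNSpectralClassifier(arch=arch_best, training=training_rep,
                                        seed=seed + split.repeat)
            try:
                clf.fit(parts["train"][0], np.array(classes)[parts["train"][1]],
                        validation=(parts["validation"][0],
                                    np.array(classes)[parts["validation"][1]]))
                break
            except ClassificationError:
                if attempt == 3:
                    raise
                # divergence at this init: retry with a halved learning rate
                training_rep = replace(training_rep,
                                       learning_rate=training_rep.learning_rate / 2)
        pred = clf.predict(parts["test"][0])
        predictions.append(pd.DataFrame({
            "repeat": split.repeat,
            "spectrum_id": parts["test"][2],
            "true": np.array(classes)[parts["test"][1]],
            "predicted": pred,
        }))
        histories.append(clf.history_)
        pre_stats.append({"msc_reference": pre.msc_.reference_.copy(),
                          "scaler_means": pre.scaler_.means_.copy(),
                          "train_rows": split.rows("train").copy()})

    confusion = evaluate.pool_predictions(
        [(p["true"].to_numpy(), p["predicted"].to_numpy()) for p in predictions],
        classes,
    )
    metrics = evaluate.class_metrics(confusion)
    return ClassifierRun(splits=splits, best_hyperparams=best, trace=trace,
                         predictions=predictions, histories=histories,
                         confusion=confusion, metrics=metrics,
                         class_order=classes, preprocess_stats=pre_stats)
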