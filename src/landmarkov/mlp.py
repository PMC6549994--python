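"""Per-origin-class MLP transition sub-models and transition potentials.

One multiclass sub-model is trained per origin class; its outputs are the
observed destination classes plus persistence.  Samples are drawn stratified
by label, split half/half into train and validation, features min-max scaled
with training-half statistics, and the network is a single hidden logistic
layer trained by SGD with momentum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .grid import CategoricalRaster, ContinuousRaster, assert_coregistered

__all__ = [
    "SampleSet",
    "TrainingSettings",
    "TransitionSubModel",
    "PotentialStack",
    "draw_samples",
    "train_submodel",
    "backwards_stepwise",
    "predict_potentials",
    "submodel_to_json",
    "submodel_from_json",
    "GOOD_ACCURACY_PCT",
]

#: validation accuracy at or above this is flagged "good"
GOOD_ACCURACY_PCT = 75.0


@dataclass
class SampleSet:
    """Sampled pixels for one origin class.

    ``labels`` holds the destination class code per row (the origin code
    itself marks persistence); ``split`` is "train"/"validate" per row.
    """

    features: np.ndarray          # (n, n_vars)
    labels: np.ndarray            # (n,)
    split: np.ndarray             # (n,) of {"train", "validate"}
    variable_names: list[str]
    origin: int
    seed: int
    pixel_index: np.ndarray | None = None  # flat grid indices of sampled pixels

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.features.shape[0] != n or self.split.shape[0] != n:
            raise ValueError("features, labels and split must have equal length")
        for label in np.unique(self.labels):
            lab_split = self.split[self.labels == label]
            n_train = int((lab_split == "train").sum())
            n_val = int((lab_split == "validate").sum())
            if n_train == 0:
                raise ValueError(f"label {label} has no training rows")
            if abs(n_train - n_val) > 1:
                raise ValueError(f"label {label}: train/validate counts differ by > 1")

    @property
    def train_mask(self) -> np.ndarray:
        return self.split == "train"

    @property
    def validate_mask(self) -> np.ndarray:
        return self.split == "validate"

    def subset_variables(self, names: Sequence[str]) -> "SampleSet":
        idx = [self.variable_names.index(n) for n in names]
        return SampleSet(self.features[:, idx], self.labels, self.split,
                         list(names), self.origin, self.seed, self.pixel_index)


@dataclass(frozen=True)
class TrainingSettings:
    """Hyper-parameters of a transition sub-model.

    Defaults: one hidden layer of max(4, ceil((inputs+outputs)/2)) logistic
    nodes, SGD with learning rate 0.01 and momentum 0.5, early stop after
    ``patience`` epochs without improvement.
    """

    hidden_nodes: int | None = None   # None -> max(4, ceil((in+out)/2))
    learning_rate: float = 0.01
    momentum: float = 0.5
    max_epochs: int = 1000
    patience: int = 100
    tol: float = 1e-5

    def resolve_hidden(self, n_inputs: int, n_outputs: int) -> int:
        if self.hidden_nodes is not None:
            return self.hidden_nodes
        return max(4, math.ceil((n_inputs + n_outputs) / 2))


@dataclass
class TransitionSubModel:
    """A trained per-origin-class MLP with its scaling and validation score."""

    origin: int
    destinations: list[int]        # label order of the network outputs
    variable_names: list[str]
    classifier: MLPClassifier
    scale_min: np.ndarray
    scale_range: np.ndarray
    accuracy: float                # percent correct on the validation half
    train_accuracy: float
    seed: int
    settings: TrainingSettings

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 100.0):
            raise ValueError(f"accuracy must be a percentage, got {self.accuracy}")

    @property
    def good(self) -> bool:
        return self.accuracy >= GOOD_ACCURACY_PCT

    def scale(self, features: np.ndarray) -> np.ndarray:
        return (features - self.scale_min) / self.scale_range

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """Class-membership outputs in [0, 1], columns in ``destinations`` order."""
        proba = self.classifier.predict_proba(self.scale(features))
        order = [list(self.classifier.classes_).index(d) for d in self.destinations]
        return proba[:, order]


@dataclass
class PotentialStack:
    """One transition-potential raster per (origin, destination) pair."""

    potentials: dict[tuple[int, int], ContinuousRaster]
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, key: tuple[int, int]) -> ContinuousRaster:
        return self.potentials[key]

    def __contains__(self, key: tuple[int, int]) -> bool:
        return key in self.potentials

    def items(self):
        return self.potentials.items()

    def merge(self, other: "PotentialStack") -> "PotentialStack":
        merged = dict(self.potentials)
        merged.update(other.potentials)
        return PotentialStack(merged, {**self.provenance, **other.provenance})


def submodel_to_json(model: TransitionSubModel) -> dict:
    """JSON-serializable dict with weights, scaling, variables and accuracy."""
    clf = model.classifier
    return {
        "origin": model.origin,
        "destinations": model.destinations,
        "variables": model.variable_names,
        "scale_min": model.scale_min.tolist(),
        "scale_range": model.scale_range.tolist(),
        "accuracy": model.accuracy,
        "train_accuracy": model.train_accuracy,
        "seed": model.seed,
        "settings": {
            "hidden_nodes": model.settings.hidden_nodes,
            "learning_rate": model.settings.learning_rate,
            "momentum": model.settings.momentum,
            "max_epochs": model.settings.max_epochs,
            "patience": model.settings.patience,
            "tol": model.settings.tol,
        },
        "network": {
            "coefs": [w.tolist() for w in clf.coefs_],
            "intercepts": [b.tolist() for b in clf.intercepts_],
            "classes": [int(c) for c in clf.classes_],
            "n_layers": clf.n_layers_,
            "n_outputs": clf.n_outputs_,
            "out_activation": clf.out_activation_,
        },
    }


def submodel_from_json(payload: Mapping) -> TransitionSubModel:
    """Rebuild a trained sub-model from :func:`submodel_to_json` output."""
    settings = TrainingSettings(**payload["settings"])
    net = payload["network"]
    coefs = [np.asarray(w) for w in net["coefs"]]
    clf = MLPClassifier(
        hidden_layer_sizes=(coefs[0].shape[1],),
        activation="logistic",
        solver="sgd",
        learning_rate_init=settings.learning_rate,
        momentum=settings.momentum,
        random_state=payload["seed"],
    )
    clf.coefs_ = coefs
    clf.intercepts_ = [np.asarray(b) for b in net["intercepts"]]
    clf.classes_ = np.asarray(net["classes"])
    clf.n_layers_ = net["n_layers"]
    clf.n_outputs_ = net["n_outputs"]
    clf.out_activation_ = net["out_activation"]
    clf._label_binarizer = _fitted_binarizer(clf.classes_)
    return TransitionSubModel(
        origin=int(payload["origin"]),
        destinations=[int(d) for d in payload["destinations"]],
        variable_names=list(payload["variables"]),
        classifier=clf,
        scale_min=np.asarray(payload["scale_min"]),
        scale_range=np.asarray(payload["scale_range"]),
        accuracy=float(payload["accuracy"]),
        train_accuracy=float(payload["train_accuracy"]),
        seed=int(payload["seed"]),
        settings=settings,
    )


def _fitted_binarizer(classes: np.ndarray):
    from sklearn.preprocessing import LabelBinarizer

    lb = LabelBinarizer()
    lb.fit(classes)
    return lb


def _variable_grid(variables, names: Sequence[str], reference) -> tuple[np.ndarray, np.ndarray]:
    """Stack driver rasters into an (rows*cols, n_vars) array + joint valid mask."""
    if isinstance(variables, Mapping):
        rasters = []
        for n in names:
            if n not in variables:
                raise ValueError(f"driver variable {n!r} missing")
            rasters.append(variables[n])
    else:
        rasters = list(variables)
    cols = []
    valid = np.ones(reference.shape, dtype=bool)
    for r in rasters:
        raster = getattr(r, "raster", r)
        assert_coregistered(reference, raster)
        if isinstance(raster, CategoricalRaster):
            cols.append(raster.values.astype(float).ravel())
        else:
            cols.append(raster.values.ravel())
        valid &= raster.valid
    return np.column_stack(cols), valid


def draw_samples(t1: CategoricalRaster, t2: CategoricalRaster, origin: int,
                 variables: Mapping[str, ContinuousRaster], n: int = 10_000,
                 seed: int = 0, include_persistence: bool = True) -> SampleSet:
    """Stratified random sample of origin-class pixels with their transitions.

    Labels are the destination classes observed at t2 (including persistence
    by default).  Each label gets an equal target count ``n // n_labels``,
    truncated to availability; each label's rows are split half/half into
    train and validation.  Deterministic under ``seed``.
    """
    assert_coregistered(t1, t2)
    origin = int(origin)
    names = list(variables.keys())
    if not names:
        raise ValueError("no driver variables supplied")
    feats, var_valid = _variable_grid(variables, names, t1)
    eligible = (t1.values == origin) & t1.valid & t2.valid & var_valid
    if not eligible.any():
        raise ValueError(f"origin class {origin} absent (or fully masked) at t1")
    flat_idx = np.flatnonzero(eligible.ravel())
    dest = t2.values.ravel()[flat_idx]
    labels_present = np.unique(dest)
    if not include_persistence:
        labels_present = labels_present[labels_present != origin]
        keep = dest != origin
        flat_idx, dest = flat_idx[keep], dest[keep]
    if labels_present.size < 2:
        raise ValueError(
            f"origin class {origin} needs >= 2 labels (transitions + persistence), "
            f"found {labels_present.tolist()}"
        )
    rng = np.random.default_rng(seed)
    per_label = n // labels_present.size
    rows, labs, split = [], [], []
    for label in labels_present:
        pool = flat_idx[dest == label]
        take = min(per_label, pool.size)
        chosen = rng.choice(pool, size=take, replace=False)
        n_train = (take + 1) // 2
        order = rng.permutation(take)
        rows.append(chosen[order])
        labs.append(np.full(take, label))
        s = np.full(take, "validate", dtype=object)
        s[:n_train] = "train"
        split.append(s)
    all_rows = np.concatenate(rows)
    return SampleSet(
        features=feats[all_rows],
        labels=np.concatenate(labs).astype(np.int64),
        split=np.concatenate(split).astype(object),
        variable_names=names,
        origin=origin,
        seed=seed,
        pixel_index=all_rows,
    )


def train_submodel(samples: SampleSet,
                   settings: TrainingSettings = TrainingSettings()) -> TransitionSubModel:
    """Fit the single-hidden-layer MLP on the training half.

    Validation accuracy is the percentage of validation rows whose argmax
    output equals their label.  Deterministic under the sample's seed.
    """
    labels = np.unique(samples.labels)
    if labels.size < 2:
        raise ValueError("degenerate sample: a single label cannot be modelled")
    train, val = samples.train_mask, samples.validate_mask
    x_train = samples.features[train]
    scale_min = x_train.min(axis=0)
    scale_range = x_train.max(axis=0) - scale_min
    scale_range[scale_range == 0] = 1.0
    hidden = settings.resolve_hidden(samples.features.shape[1], labels.size)
    clf = MLPClassifier(
        hidden_layer_sizes=(hidden,),
        activation="logistic",
        solver="sgd",
        learning_rate_init=settings.learning_rate,
        momentum=settings.momentum,
        nesterovs_momentum=False,
        max_iter=settings.max_epochs,
        n_iter_no_change=settings.patience,
        tol=settings.tol,
        random_state=samples.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit((x_train - scale_min) / scale_range, samples.labels[train])

    def _acc(mask: np.ndarray) -> float:
        x = (samples.features[mask] - scale_min) / scale_range
        pred = clf.predict(x)
        return 100.0 * float(np.mean(pred == samples.labels[mask]))

    return TransitionSubModel(
        origin=samples.origin,
        destinations=[int(c) for c in labels],
        variable_names=list(samples.variable_names),
        classifier=clf,
        scale_min=scale_min,
        scale_range=scale_range,
        accuracy=_acc(val),
        train_accuracy=_acc(train),
        seed=samples.seed,
        settings=settings,
    )


def backwards_stepwise(samples: SampleSet, variables: Sequence[str] | None = None,
                       tolerance: float = 1.0,
                       settings: TrainingSettings = TrainingSettings(),
                       pair_pass: bool = False) -> tuple[list[str], list[dict]]:
    """Backwards stepwise variable selection on validation accuracy.

    Repeatedly retrains with each remaining variable held out and drops the
    one whose removal degrades validation accuracy least, as long as the
    degradation does not exceed ``tolerance`` (accuracy percentage points).
    Returns the surviving variable names and an accuracy trace.  The optional
    ``pair_pass`` repeats the procedure with pairwise hold-outs once single
    hold-outs converge.
    """
    current = list(variables) if variables is not None else list(samples.variable_names)
    if len(current) < 2:
        model = train_submodel(samples.subset_variables(current), settings)
        return current, [{"variables": list(current), "accuracy": model.accuracy,
                          "dropped": None}]
    baseline = train_submodel(samples.subset_variables(current), settings).accuracy
    trace = [{"variables": list(current), "accuracy": baseline, "dropped": None}]

    def _try_drop(groups: list[list[str]]) -> bool:
        nonlocal baseline
        best_group, best_acc = None, -np.inf
        for group in groups:
            remaining = [v for v in current if v not in group]
            acc = train_submodel(samples.subset_variables(remaining), settings).accuracy
            if acc > best_acc:
                best_group, best_acc = group, acc
        if best_group is not None and baseline - best_acc <= tolerance:
            for v in best_group:
                current.remove(v)
            baseline = best_acc
            trace.append({"variables": list(current), "accuracy": best_acc,
                          "dropped": list(best_group)})
            return True
        return False

    while len(current) > 1:
        if not _try_drop([[v] for v in current]):
            break
    if pair_pass:
        while len(current) > 2:
            pairs = [[a, b] for k, a in enumerate(current) for b in current[k + 1:]]
            if not _try_drop(pairs):
                break
    return current, trace


def predict_potentials(model: TransitionSubModel,
                       variables: Mapping[str, ContinuousRaster],
                       current: CategoricalRaster,
                       include_persistence: bool = True) -> PotentialStack:
    """Per-pixel transition potentials in [0, 1] for one sub-model.

    Pixels that are not of the sub-model's origin class at the current date
    carry potential 0 for all of its transitions; nodata propagates.
    """
    feats, var_valid = _variable_grid(variables, model.variable_names, current)
    valid = current.valid & var_valid
    origin_cells = (current.values == model.origin) & valid
    flat = np.flatnonzero(origin_cells.ravel())
    proba = model.predict_proba(feats[flat]) if flat.size else np.zeros((0, len(model.destinations)))
    stack: dict[tuple[int, int], ContinuousRaster] = {}
    for col, dest in enumerate(model.destinations):
        if dest == model.origin and not include_persistence:
            continue
        grid = np.zeros(current.shape, dtype=float)
        grid.ravel()[flat] = np.clip(proba[:, col], 0.0, 1.0)
        stack[(model.origin, dest)] = ContinuousRaster(
            grid, ~valid, current.transform, current.crs_tag, units="potential")
    return PotentialStack(stack, provenance={
        "origin": model.origin, "seed": model.seed, "accuracy": model.accuracy})
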