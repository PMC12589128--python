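"""Enhancer sequence classifier: training-set construction and training.

The classifier maps 401-bp one-hot sequences to coarse lineage classes
(superclusters).  The printed architecture: four convolutional layers of
256, 60, 60 and 120 filters with kernel sizes 7, 3, 5 and 3, each followed
by batch normalization, ReLU and max pooling; two dense layers of 256
units with batch normalization, ReLU and dropout 0.4; a softmax head
trained with label-smoothed (0.1) cross-entropy under Adam at learning
rate 0.01 for 26 epochs.  Pooling size/stride 2 and 'same' padding keep
the layer stack shape-consistent for length-401 input.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .._types import ConsensusPeakSet, ResidualMatrix
from ..io import fetch_sequence
from ._nn import (
    Adam,
    BatchNorm,
    Conv1d,
    Dense,
    Dropout,
    Flatten,
    MaxPool1d,
    ReLU,
    Sequential,
    cross_entropy_grad,
    softmax,
)

SEQ_LEN = 401
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class CnnModelSpec:
    """Hyperparameters of the enhancer classifier (printed defaults)."""

    conv_filters: tuple = (256, 60, 60, 120)
    conv_kernels: tuple = (7, 3, 5, 3)
    pool_sizes: tuple = (2, 2, 2, 2)
    dense_units: tuple = (256, 256)
    dropout: float = 0.4
    label_smoothing: float = 0.1
    learning_rate: float = 0.01
    epochs: int = 26
    batch_size: int = 256
    seq_len: int = SEQ_LEN
    n_classes: int = 5


def desk_spec(epochs: int = 16, n_classes: int = 5) -> CnnModelSpec:
    """A reduced configuration for desk-scale (single CPU) experiments.

    Fewer filters and one dense layer keep a training run in the minutes
    range; the larger terminal poolings make the flattened representation
    nearly translation invariant, which matters far more than capacity
    when the training set is small.
    """
    return CnnModelSpec(
        conv_filters=(64, 32, 32, 64),
        conv_kernels=(7, 3, 5, 3),
        pool_sizes=(2, 2, 5, 10),
        dense_units=(64,),
        learning_rate=0.005,
        batch_size=64,
        epochs=epochs,
        n_classes=n_classes,
    )


@dataclass
class EnhancerExample:
    sequence: np.ndarray  # 4 x seq_len one-hot
    label: int
    region: tuple = ("", 0, 0)  # chrom, start, end
    logfc: float = 0.0

    def __post_init__(self):
        if self.sequence.shape != (4, SEQ_LEN) and self.sequence.shape[0] != 4:
            raise ValueError("sequence must be one-hot with 4 channels")
        colsum = self.sequence.sum(axis=0)
        if (colsum > 1).any():
            raise ValueError("one-hot columns must sum to at most 1")


def one_hot(seq: str) -> np.ndarray:
    """One-hot encode; ambiguous bases become all-zero columns."""
    out = np.zeros((4, len(seq)))
    for i, b in enumerate(seq.upper()):
        j = _BASE_INDEX.get(b)
        if j is not None:
            out[j, i] = 1.0
    return out


def decode_one_hot(x: np.ndarray) -> str:
    bases = np.array(list("ACGT"))
    idx = x.argmax(axis=0)
    out = bases[idx]
    out[x.sum(axis=0) == 0] = "N"
    return "".join(out)


def build_training_set(
    consensus: ConsensusPeakSet,
    residuals: ResidualMatrix,
    genome: dict[str, str],
    class_of_cluster: dict[int, int] | None = None,
    logfc_min: float = 1.0,
) -> list[EnhancerExample]:
    """Class-enriched peak sequences as one-hot training examples.

    Per peak, the class is the argmax of supercluster-level CPM (rows of
    ``residuals`` aggregated by ``class_of_cluster`` when given); the peak
    is included only when log2(top / second-highest) exceeds
    ``logfc_min``.  The window is centre-200 .. centre+200 inclusive (401
    bases); peaks whose window leaves the chromosome are skipped and
    counted.
    """
    cpm = residuals.X / residuals.X.sum(axis=1, keepdims=True) * 1e6
    if class_of_cluster is not None:
        classes = sorted(set(class_of_cluster.values()))
        agg = np.zeros((len(classes), cpm.shape[1]))
        for ci, c in enumerate(classes):
            rows = [i for i, cl in enumerate(residuals.clusters) if class_of_cluster[cl] == c]
            agg[ci] = cpm[rows].mean(axis=0)
        cpm = agg
    peaks = consensus.peaks
    fmap = {f: j for j, f in enumerate(residuals.features)}
    examples = []
    n_skipped = 0
    for i, (chrom, start, end) in enumerate(
        zip(peaks["chrom"], peaks["start"], peaks["end"])
    ):
        fid = f"{chrom}:{start}-{end}"
        j = fmap.get(fid)
        if j is None:
            continue
        col = cpm[:, j] + 1e-9
        order = np.argsort(-col)
        top, second = col[order[0]], col[order[1]]
        logfc = float(np.log2(top / second))
        if logfc <= logfc_min:
            continue
        centre = (start + end) // 2
        w_start, w_end = centre - 200, centre + 201
        if w_start < 0 or w_end > len(genome[chrom]):
            n_skipped += 1
            continue
        seq = fetch_sequence(genome, chrom, w_start, w_end)
        examples.append(
            EnhancerExample(one_hot(seq), int(order[0]), (chrom, w_start, w_end), logfc)
        )
    if n_skipped:
        import warnings

        warnings.warn(f"{n_skipped} peaks skipped at chromosome edges")
    return examples


def build_model(spec: CnnModelSpec, seed: int = 0) -> Sequential:
    rng = np.random.default_rng(seed)
    layers = []
    c_in, L = 4, spec.seq_len
    for f, k, p in zip(spec.conv_filters, spec.conv_kernels, spec.pool_sizes):
        layers += [Conv1d(c_in, f, k, rng), BatchNorm(f), ReLU(), MaxPool1d(p)]
        c_in, L = f, L // p
    if L <= 0:
        raise ValueError("pooling collapsed the sequence; reduce pool layers")
    layers.append(Flatten())
    n_in = c_in * L
    for u in spec.dense_units:
        layers += [Dense(n_in, u, rng), BatchNorm(u), ReLU(), Dropout(spec.dropout, rng)]
        n_in = u
    layers.append(Dense(n_in, spec.n_classes, rng))
    return Sequential(layers)


def predict_proba(model: Sequential, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
    out = []
    for i in range(0, len(X), batch_size):
        out.append(softmax(model.forward(X[i : i + batch_size], train=False)))
    return np.concatenate(out)


def evaluate_auc(model: Sequential, X: np.ndarray, y: np.ndarray) -> dict:
    """One-vs-rest ROC AUC per class and the mean across classes."""
    p = predict_proba(model, X)
    aucs = {}
    for c in np.unique(y):
        aucs[int(c)] = float(roc_auc_score(y == c, p[:, int(c)]))
    return {"per_class": aucs, "mean": float(np.mean(list(aucs.values())))}


def train_cnn(
    examples: list[EnhancerExample],
    spec: CnnModelSpec | None = None,
    val_fraction: float = 0.1,
    seed: int = 0,
    verbose: bool = False,
) -> tuple[Sequential, dict]:
    """Train the classifier and report validation one-vs-rest ROC AUC.

    A stratified ``val_fraction`` split is held out; training follows the
    spec's hyperparameters.  Returns the model (inference-ready: dropout
    off, batch-norm running statistics frozen) and the AUC report.
    """
    y = np.array([e.label for e in examples])
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 examples")
    X = np.stack([e.sequence for e in examples]).astype(np.float32)
    if spec is None:
        spec = CnnModelSpec(seq_len=X.shape[2], n_classes=len(classes))
    spec.n_classes = len(classes)
    spec.seq_len = X.shape[2]
    Xtr, Xva, ytr, yva = train_test_split(
        X, y, test_size=val_fraction, stratify=y, random_state=seed
    )
    model = build_model(spec, seed=seed)
    opt = Adam(model.layers, lr=spec.learning_rate)
    rng = np.random.default_rng(seed + 1)
    for epoch in range(spec.epochs):
        order = rng.permutation(len(Xtr))
        total = 0.0
        for i in range(0, len(order), spec.batch_size):
            idx = order[i : i + spec.batch_size]
            if len(idx) < 2:
                continue  # batch norm needs at least 2 samples
            logits = model.forward(Xtr[idx], train=True)
            loss, dlogits = cross_entropy_grad(
                logits, ytr[idx], spec.n_classes, spec.label_smoothing
            )
            model.backward(dlogits)
            opt.step()
            total += loss * len(idx)
        if verbose:
            print(f"epoch {epoch + 1}/{spec.epochs} loss {total / len(Xtr):.4f}")
    report = evaluate_auc(model, Xva, yva)
    return model, report
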