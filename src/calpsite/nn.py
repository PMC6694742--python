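"""Four-branch feed-forward classifier for cleavage-site scoring.

The network mirrors the feature design: one input branch per encoder
(AAC 21, BE 630, PSFM 60, CKSAAP 1764 at the defaults), each with its own
fully connected hidden stack, the branch outputs concatenated ("merged and
flattened") into shared dense layers, and a 2-unit softmax output.  The
positive-class probability is the cleavage score; the two class
probabilities sum to one by construction.

Implementation notes: rectified-linear hidden units with He initialization,
inverted dropout after every hidden layer during training, 2-class
cross-entropy loss minimized with Adam.  All randomness (initialization,
mini-batch order, dropout masks, class rebalancing) flows from a single
integer seed, so a full train/predict run is bit-reproducible on one
machine.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .encoders import FrequencyProfile, encode_windows, fit_frequency_profile
from .sequence_io import LabeledDataset, Protein, extract_window


@dataclass
class Hyperparameters:
    """Architecture and optimization settings for the four-branch classifier.

    ``branch_layers`` holds one tuple of hidden widths per branch, in encoder
    order (AAC, BE, PSFM, CKSAAP).  ``epochs`` may be 0, meaning the model is
    returned with its initial (or pretrained) weights untouched — used by the
    fine-tuning identity contract.
    """

    branch_layers: tuple = ((8,), (128, 64), (128, 64), (4,))
    merged_layers: tuple = (32,)
    dropout_rate: float = 0.2
    learning_rate: float = 1e-3
    weight_decay: float = 3e-2
    batch_size: int = 64
    epochs: int = 80

    def __post_init__(self) -> None:
        self.branch_layers = tuple(tuple(int(w) for w in b) for b in self.branch_layers)
        self.merged_layers = tuple(int(w) for w in self.merged_layers)
        if len(self.branch_layers) != 4:
            raise ValueError("branch_layers must give hidden widths for all 4 branches")
        for b in self.branch_layers:
            if len(b) < 1 or any(w < 1 for w in b):
                raise ValueError("every branch needs >= 1 hidden layer of positive width")
        if any(w < 1 for w in self.merged_layers) or len(self.merged_layers) < 1:
            raise ValueError("merged_layers must be >= 1 positive widths")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be a positive integer")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["branch_layers"] = [list(b) for b in self.branch_layers]
        d["merged_layers"] = list(self.merged_layers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Hyperparameters":
        return cls(
            branch_layers=tuple(tuple(b) for b in d["branch_layers"]),
            merged_layers=tuple(d["merged_layers"]),
            dropout_rate=float(d["dropout_rate"]),
            learning_rate=float(d["learning_rate"]),
            weight_decay=float(d.get("weight_decay", 0.0)),
            batch_size=int(d["batch_size"]),
            epochs=int(d["epochs"]),
        )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MultiBranchNet:
    """The four-branch network: weights, forward pass, and backpropagation."""

    def __init__(self, input_dims: Sequence[int], hyper: Hyperparameters, seed: int = 0):
        if len(input_dims) != 4:
            raise ValueError("expected 4 input dimensions (AAC, BE, PSFM, CKSAAP)")
        self.input_dims = tuple(int(d) for d in input_dims)
        self.hyper = hyper
        rng = np.random.default_rng(seed)
        # layers: list of dicts {W, b, group}; groups "branch0..3", "merged", "output"
        self.layers: list[dict] = []
        self._branch_slices: list[slice] = []
        for i, (din, widths) in enumerate(zip(self.input_dims, hyper.branch_layers)):
            start = len(self.layers)
            prev = din
            for w in widths:
                self.layers.append(self._make_layer(prev, w, f"branch{i}", rng))
                prev = w
            self._branch_slices.append(slice(start, len(self.layers)))
        merged_in = sum(b[-1] for b in hyper.branch_layers)
        self._merged_slice_start = len(self.layers)
        prev = merged_in
        for w in hyper.merged_layers:
            self.layers.append(self._make_layer(prev, w, "merged", rng))
            prev = w
        self.layers.append(self._make_layer(prev, 2, "output", rng))
        self._adam_state: list[dict] | None = None
        self._adam_t = 0

    @staticmethod
    def _make_layer(din: int, dout: int, group: str, rng: np.random.Generator) -> dict:
        if dout < 1:
            raise ValueError("zero-width layer")
        return {
            "W": rng.normal(0.0, np.sqrt(2.0 / din), size=(din, dout)),
            "b": np.zeros(dout),
            "group": group,
            "trainable": True,
        }

    @property
    def n_parameters(self) -> int:
        return sum(layer["W"].size + layer["b"].size for layer in self.layers)

    def copy(self) -> "MultiBranchNet":
        clone = copy.deepcopy(self)
        clone._adam_state = None
        clone._adam_t = 0
        return clone

    def set_trainable(self, groups_frozen: Sequence[str]) -> None:
        frozen = set(groups_frozen)
        for layer in self.layers:
            layer["trainable"] = layer["group"] not in frozen

    # ------------------------------------------------------------------ forward

    def forward(
        self,
        xs: Sequence[np.ndarray],
        training: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Return class probabilities (n, 2); with ``training`` also a backprop cache."""
        p_drop = self.hyper.dropout_rate if training else 0.0
        if training and p_drop > 0 and rng is None:
            raise ValueError("training forward with dropout requires an rng")
        cache: list[dict] = []
        branch_out = []
        for i, sl in enumerate(self._branch_slices):
            h = np.asarray(xs[i], dtype=float)
            for li in range(sl.start, sl.stop):
                h = self._hidden(h, li, p_drop, rng, cache, training)
            branch_out.append(h)
        h = np.concatenate(branch_out, axis=1)
        merge_cache = {"widths": [b.shape[1] for b in branch_out]}
        cache.append(merge_cache)
        for li in range(self._merged_slice_start, len(self.layers) - 1):
            h = self._hidden(h, li, p_drop, rng, cache, training)
        out = self.layers[-1]
        logits = h @ out["W"] + out["b"]
        probs = _softmax(logits)
        if training:
            cache.append({"layer": len(self.layers) - 1, "input": h})
            return probs, cache
        return probs

    def _hidden(self, h, li, p_drop, rng, cache, training):
        layer = self.layers[li]
        z = h @ layer["W"] + layer["b"]
        a = np.maximum(z, 0.0)
        mask = None
        if training and p_drop > 0:
            mask = (rng.random(a.shape) >= p_drop) / (1.0 - p_drop)
            a = a * mask
        if training:
            cache.append({"layer": li, "input": h, "z": z, "mask": mask})
        return a

    # ----------------------------------------------------------------- backward

    def backward(self, cache: list[dict], probs: np.ndarray, y_onehot: np.ndarray):
        """Cross-entropy gradients for every layer, in ``self.layers`` order."""
        n = probs.shape[0]
        grads: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        out_entry = cache[-1]
        dlogits = (probs - y_onehot) / n
        li = out_entry["layer"]
        grads[li] = (out_entry["input"].T @ dlogits, dlogits.sum(axis=0))
        dh = dlogits @ self.layers[li]["W"].T
        # merged hidden layers, reversed
        merge_pos = next(
            i for i, e in enumerate(cache) if "widths" in e
        )
        for entry in reversed(cache[merge_pos + 1 : -1]):
            dh = self._hidden_grad(entry, dh, grads)
        # split at the merge into per-branch gradients
        widths = cache[merge_pos]["widths"]
        splits = np.cumsum(widths)[:-1]
        branch_dh = np.split(dh, splits, axis=1)
        branch_entries: dict[int, list[dict]] = {i: [] for i in range(4)}
        for entry in cache[:merge_pos]:
            group = self.layers[entry["layer"]]["group"]
            branch_entries[int(group.removeprefix("branch"))].append(entry)
        for i in range(4):
            d = branch_dh[i]
            for entry in reversed(branch_entries[i]):
                d = self._hidden_grad(entry, d, grads)
        return [grads[i] for i in range(len(self.layers))]

    def _hidden_grad(self, entry, dh, grads):
        layer = self.layers[entry["layer"]]
        if entry["mask"] is not None:
            dh = dh * entry["mask"]
        dz = dh * (entry["z"] > 0)
        grads[entry["layer"]] = (entry["input"].T @ dz, dz.sum(axis=0))
        return dz @ layer["W"].T

    # --------------------------------------------------------------------- adam

    def adam_step(self, grads, lr, weight_decay=0.0, beta1=0.9, beta2=0.999, eps=1e-8):
        if self._adam_state is None:
            self._adam_state = [
                {
                    "mW": np.zeros_like(l["W"]),
                    "vW": np.zeros_like(l["W"]),
                    "mb": np.zeros_like(l["b"]),
                    "vb": np.zeros_like(l["b"]),
                }
                for l in self.layers
            ]
        self._adam_t += 1
        t = self._adam_t
        for layer, st, (dW, db) in zip(self.layers, self._adam_state, grads):
            if not layer["trainable"]:
                continue
            for key, g in (("W", dW), ("b", db)):
                m, v = st["m" + key], st["v" + key]
                m *= beta1
                m += (1 - beta1) * g
                v *= beta2
                v += (1 - beta2) * g * g
                mhat = m / (1 - beta1**t)
                vhat = v / (1 - beta2**t)
                layer[key] -= lr * mhat / (np.sqrt(vhat) + eps)
                if key == "W" and weight_decay > 0:
                    layer[key] -= lr * weight_decay * layer[key]


def build_model(
    hyper: Hyperparameters, flank: int = 15, kmax: int = 3, seed: int = 0
) -> MultiBranchNet:
    """Instantiate an untrained network with input widths set by flank and kmax."""
    from .encoders import feature_dims

    return MultiBranchNet(feature_dims(flank, kmax), hyper, seed=seed)


@dataclass
class TrainedModel:
    """A trained network bundled with everything needed to score new sequences.

    The bundled :class:`FrequencyProfile` was fit on this model's own training
    windows and is the only profile ever used at prediction time, so scores
    never depend on data the model did not train on.
    """

    net: MultiBranchNet
    hyper: Hyperparameters
    profile: FrequencyProfile
    kmax: int
    flank: int
    seed: int
    loss_trace: list = field(default_factory=list)

    def predict_windows(self, windows: list[str]) -> np.ndarray:
        """Cleavage scores (positive-class softmax probability) for peptide windows."""
        xs = encode_windows(windows, self.profile, self.kmax)
        return self.net.forward(xs)[:, 1]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, layer in enumerate(self.net.layers):
            arrays[f"W{i}"] = layer["W"]
            arrays[f"b{i}"] = layer["b"]
        np.savez(directory / "weights.npz", **arrays)
        self.profile.to_tsv(directory / "profile.tsv")
        config = {
            "hyperparameters": self.hyper.to_dict(),
            "input_dims": list(self.net.input_dims),
            "kmax": self.kmax,
            "flank": self.flank,
            "seed": self.seed,
            "loss_trace": [float(x) for x in self.loss_trace],
        }
        (directory / "config.yaml").write_text(yaml.safe_dump(config))

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        config = yaml.safe_load((directory / "config.yaml").read_text())
        hyper = Hyperparameters.from_dict(config["hyperparameters"])
        net = MultiBranchNet(config["input_dims"], hyper, seed=config["seed"])
        with np.load(directory / "weights.npz") as arrays:
            for i, layer in enumerate(net.layers):
                layer["W"] = arrays[f"W{i}"]
                layer["b"] = arrays[f"b{i}"]
        profile = FrequencyProfile.from_tsv(directory / "profile.tsv")
        return cls(
            net=net,
            hyper=hyper,
            profile=profile,
            kmax=config["kmax"],
            flank=config["flank"],
            seed=config["seed"],
            loss_trace=list(config.get("loss_trace", [])),
        )


def train(
    dataset: LabeledDataset,
    hyper: Hyperparameters | None = None,
    profile: FrequencyProfile | None = None,
    seed: int = 0,
    class_balance_mode: str = "balanced",
    kmax: int = 3,
    model: MultiBranchNet | None = None,
) -> TrainedModel:
    """Train the four-branch classifier on a labeled window dataset.

    The frequency profile is fit on ``dataset`` itself unless one is passed in
    (callers doing cross-validation fit it on the training fold only and pass
    it here).  ``class_balance_mode`` is ``"balanced"`` (each epoch draws a
    seeded subsample of the majority class so mini-batches see both classes
    in equal proportion) or ``"none"`` (the raw class ratio).  Dropout is
    applied as regularization independently of balancing.
    """
    if class_balance_mode not in ("balanced", "none"):
        raise ValueError(f"unknown class_balance_mode {class_balance_mode!r}")
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if dataset.n_positive == 0 or dataset.n_negative == 0:
        raise ValueError("training requires windows of both classes")
    if hyper is None:
        hyper = Hyperparameters()
    if profile is None:
        profile = fit_frequency_profile(dataset)
    flank = len(dataset.windows[0]) // 2

    xs = encode_windows(dataset.windows, profile, kmax)
    labels = dataset.labels
    y_onehot = np.zeros((len(labels), 2))
    y_onehot[np.arange(len(labels)), labels] = 1.0

    rng = np.random.default_rng(seed)
    if model is None:
        model = MultiBranchNet(
            [x.shape[1] for x in xs], hyper, seed=int(rng.integers(2**31))
        )
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)

    loss_trace: list[float] = []
    for epoch in range(hyper.epochs):
        if class_balance_mode == "balanced" and len(pos_idx) != len(neg_idx):
            minority, majority = sorted((pos_idx, neg_idx), key=len)
            sampled = rng.choice(majority, size=len(minority), replace=False)
            epoch_idx = np.concatenate([minority, sampled])
        else:
            epoch_idx = np.arange(len(labels))
        order = rng.permutation(epoch_idx)
        batch_losses = []
        for start in range(0, len(order), hyper.batch_size):
            batch = order[start : start + hyper.batch_size]
            bx = [x[batch] for x in xs]
            by = y_onehot[batch]
            probs, cache = model.forward(bx, training=True, rng=rng)
            loss = float(-np.mean(np.log(np.sum(probs * by, axis=1) + 1e-12)))
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch + 1}")
            grads = model.backward(cache, probs, by)
            model.adam_step(grads, hyper.learning_rate, hyper.weight_decay)
            batch_losses.append(loss)
        loss_trace.append(float(np.mean(batch_losses)))

    return TrainedModel(
        net=model,
        hyper=hyper,
        profile=profile,
        kmax=kmax,
        flank=flank,
        seed=seed,
        loss_trace=loss_trace,
    )


@dataclass(frozen=True)
class PredictionRecord:
    """Cleavage score for one bond of one protein."""

    protein_id: str
    bond: int
    score: float


def predict_scores(
    trained: TrainedModel,
    proteins: Sequence[Protein],
    positions: dict[str, Sequence[int]] | None = None,
) -> list[PredictionRecord]:
    """Score bonds of proteins with a trained model.

    ``positions`` maps protein id to the bonds to score; by default every
    bond (1..L-1) of every protein is scored.  Windows are extracted at the
    model's flank and encoded with its bundled profile.
    """
    by_id = {p.id: p for p in proteins}
    if positions is not None:
        unknown = sorted(set(positions) - set(by_id))
        if unknown:
            raise ValueError(f"unknown protein ids: {', '.join(unknown)}")
    requests: list[tuple[str, int]] = []
    for prot in proteins:
        bonds = (
            positions.get(prot.id, [])
            if positions is not None
            else range(1, len(prot))
        )
        for bond in bonds:
            requests.append((prot.id, bond))
    if not requests:
        return []
    windows = [extract_window(by_id[pid], bond, trained.flank) for pid, bond in requests]
    scores = trained.predict_windows(windows)
    return [
        PredictionRecord(pid, bond, float(s))
        for (pid, bond), s in zip(requests, scores)
    ]


def fine_tune(
    pretrained: TrainedModel,
    subtype_dataset: LabeledDataset,
    seed: int = 0,
    freeze_policy: str = "branches",
    epochs: int | None = None,
    learning_rate: float | None = None,
) -> TrainedModel:
    """Adapt a pretrained model to a protease subtype (transfer learning).

    Branch layers start from the pretrained weights; with
    ``freeze_policy="branches"`` (default) they stay fixed and only the
    merged head and output retrain on the subtype data.  ``"none"`` retrains
    everything.  The pretrained frequency profile is reused so the encoded
    features stay consistent with the pretrained branch weights.  Returns a
    distinct model; the pretrained one is untouched.
    """
    if freeze_policy not in ("branches", "none"):
        raise ValueError(f"unknown freeze_policy {freeze_policy!r}")
    W = len(subtype_dataset.windows[0]) if len(subtype_dataset) else 2 * pretrained.flank
    if W != 2 * pretrained.flank:
        raise ValueError(
            f"subtype windows of length {W} do not match pretrained flank "
            f"{pretrained.flank}"
        )
    net = pretrained.net.copy()
    if freeze_policy == "branches":
        net.set_trainable([f"branch{i}" for i in range(4)])
    hyper = Hyperparameters(
        branch_layers=pretrained.hyper.branch_layers,
        merged_layers=pretrained.hyper.merged_layers,
        dropout_rate=pretrained.hyper.dropout_rate,
        learning_rate=(
            learning_rate if learning_rate is not None else pretrained.hyper.learning_rate
        ),
        weight_decay=pretrained.hyper.weight_decay,
        batch_size=pretrained.hyper.batch_size,
        epochs=epochs if epochs is not None else pretrained.hyper.epochs,
    )
    if hyper.epochs == 0:
        return TrainedModel(
            net=net,
            hyper=hyper,
            profile=pretrained.profile,
            kmax=pretrained.kmax,
            flank=pretrained.flank,
            seed=seed,
            loss_trace=[],
        )
    return train(
        subtype_dataset,
        hyper=hyper,
        profile=pretrained.profile,
        seed=seed,
        kmax=pretrained.kmax,
        model=net,
    )
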