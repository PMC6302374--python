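"""The gene-superset autoencoder and its classifier variant.

The network reads a logTPM expression profile and passes it through a
*gene-set layer* — one node per gene set, connected only to that set's
member genes via a binary mask — followed by a dense *superset layer*
(the latent layer, default 200 nodes). Each latent node is a "superset":
a learned weighted combination of gene sets. An autoencoder head mirrors
the encoder and reconstructs the input under mean-squared error; the
classifier variant replaces the decoder with a softmax layer trained under
categorical cross-entropy.

Every layer computes ``g(b + W^T x)`` with ReLU activations in hidden
layers and a linear (autoencoder) or softmax (classifier) output. Training
is plain mini-batch SGD with Nesterov momentum and learning-rate decay;
sparsity of the gene-set layer is preserved by elementwise re-masking of
the first-layer weights (and their momentum buffer) after every update, so
masked-out weights are exactly zero at all times. Weights start from
He-uniform draws, a 5% validation split drives early stopping (stop after
``patience`` epochs without improvement).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .data import ExpressionMatrix, MembershipMask

__all__ = [
    "NetworkConfig",
    "GsaeModel",
    "ScoreMatrices",
    "relu",
    "layer_forward",
    "initialize",
    "train",
    "encode",
    "predict",
    "cross_validate",
    "fit_autoencoder",
    "fit_classifier",
    "save_model",
    "load_model",
]


def relu(x):
    """Rectified linear unit, max(x, 0)."""
    return np.maximum(x, 0.0)


def _softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


_ACTIVATIONS = {"relu": relu, "linear": lambda z: z, "softmax": _softmax}


def layer_forward(x_prev: np.ndarray, W: np.ndarray, b: np.ndarray, activation: str) -> np.ndarray:
    """One layer: g(b + W^T x_prev) for a batch of row vectors."""
    x_prev = np.atleast_2d(np.asarray(x_prev, dtype=float))
    if x_prev.shape[1] != W.shape[0]:
        raise ValueError(f"input width {x_prev.shape[1]} does not match weight rows {W.shape[0]}")
    if W.shape[1] != b.shape[0]:
        raise ValueError("bias length does not match weight columns")
    try:
        g = _ACTIVATIONS[activation]
    except KeyError:
        raise ValueError(f"unknown activation {activation!r}") from None
    return g(x_prev @ W + b)


@dataclass
class NetworkConfig:
    """Architecture and optimiser settings.

    Defaults follow the published training recipe: 200 supersets, SGD with
    learning rate 0.05, decay 1e-6, momentum 0.9, Nesterov on, a 5%
    validation split, and early stopping after 3 non-improving epochs.
    ``encoder_variant`` is ``"geneset"`` (masked gene-set layer then the
    superset layer) or a list of fully connected hidden-layer sizes whose
    last entry is the latent width (the unmasked baselines).
    """

    superset_size: int = 200
    learning_rate: float = 0.05
    decay: float = 1e-6
    momentum: float = 0.9
    nesterov: bool = True
    patience: int = 3
    validation_fraction: float = 0.05
    batch_size: int = 64
    max_epochs: int = 200
    seed: int = 0
    mode: str = "autoencoder"  # autoencoder | classifier
    encoder_variant: str | list[int] = "geneset"

    def __post_init__(self):
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.superset_size < 1:
            raise ValueError("superset_size must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.mode not in ("autoencoder", "classifier"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def small_cohort(cls, seed: int = 0, superset_size: int = 20, **overrides) -> "NetworkConfig":
        """Recipe for desk-scale cohorts (hundreds of samples and genes).

        The stock defaults were tuned for cohorts of ~10^4 samples x ~10^4
        genes, where per-weight mean-squared-error gradients are tiny and a
        3-epoch patience sees plenty of updates. On a few-hundred-gene
        matrix the same learning rate is effectively ~40x hotter (gradients
        scale as 1/n_genes) and drives hidden ReLUs into permanent
        inactivity, while a small validation split makes early stopping
        fire during the initial plateau. This recipe compensates: learning
        rate 0.01, patience 50, a 10% validation split, and a 20-node
        superset layer.
        """
        params = dict(
            superset_size=superset_size,
            learning_rate=0.01,
            patience=50,
            validation_fraction=0.1,
            max_epochs=2000,
            seed=seed,
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class Layer:
    W: np.ndarray
    b: np.ndarray
    activation: str


@dataclass
class ScoreMatrices:
    """Encoder activations: samples x gene-sets and samples x supersets."""

    gene_set_scores: np.ndarray
    superset_scores: np.ndarray
    set_names: list[str]
    samples: list[str]


@dataclass
class GsaeModel:
    """Layer stack plus the gene-set mask and training bookkeeping.

    The first ``n_encoder_layers`` layers form the encoder; with the
    ``geneset`` variant, layer 0 is the masked gene-set layer and the last
    encoder layer is the superset layer. ``history`` holds per-epoch train
    and validation losses after :func:`train`.
    """

    layers: list[Layer]
    config: NetworkConfig
    mask: MembershipMask | None
    n_encoder_layers: int
    genes: list[str]
    set_names: list[str]
    classes: list | None = None
    history: dict = field(default_factory=dict)

    @property
    def is_classifier(self) -> bool:
        return self.config.mode == "classifier"

    @property
    def superset_weights(self) -> np.ndarray:
        """Gene-set -> superset weight matrix (n_sets x superset_size)."""
        return self.layers[self.n_encoder_layers - 1].W

    def forward(self, x: np.ndarray, upto: int | None = None) -> np.ndarray:
        for layer in self.layers[:upto]:
            x = layer_forward(x, layer.W, layer.b, layer.activation)
        return x

    def check_mask(self) -> float:
        """Max |weight| over masked-out first-layer connections (0 when intact)."""
        if self.mask is None:
            return 0.0
        return float(np.abs(self.layers[0].W * (1.0 - self.mask.mask)).max())


def _layer_sizes(config: NetworkConfig, n_genes: int, n_sets: int, n_classes: int | None):
    if config.encoder_variant == "geneset":
        encoder = [n_sets, config.superset_size]
    else:
        encoder = list(config.encoder_variant)
    if config.mode == "classifier":
        if n_classes is None:
            raise ValueError("classifier mode needs n_classes")
        return encoder, [n_classes]
    decoder = list(reversed(encoder[:-1])) + [n_genes]
    return encoder, decoder


def initialize(
    config: NetworkConfig,
    mask: MembershipMask | None = None,
    n_genes: int | None = None,
    n_classes: int | None = None,
    genes: list[str] | None = None,
) -> GsaeModel:
    """He-uniform initialization; layer-1 weights zeroed outside the mask.

    Deterministic given ``config.seed``: the same seed yields bit-identical
    models. Biases start at zero.
    """
    masked = config.encoder_variant == "geneset"
    if masked:
        if mask is None:
            raise ValueError("geneset variant requires a MembershipMask")
        n_genes = mask.n_genes
        genes = list(mask.genes)
        set_names = list(mask.set_names)
        n_sets = mask.n_sets
    else:
        if n_genes is None:
            raise ValueError("fully connected variant requires n_genes")
        genes = genes if genes is not None else [f"G{j}" for j in range(n_genes)]
        set_names = []
        n_sets = 0
        mask = None

    encoder, head = _layer_sizes(config, n_genes, n_sets, n_classes)
    sizes = [n_genes] + encoder + head
    rng = np.random.default_rng(config.seed)
    layers = []
    for i, (d_in, d_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        limit = np.sqrt(6.0 / d_in)  # He uniform bound for fan_in
        W = rng.uniform(-limit, limit, size=(d_in, d_out))
        if i == 0 and masked:
            W *= mask.mask
        is_last = i == len(sizes) - 2
        activation = ("softmax" if config.mode == "classifier" else "linear") if is_last else "relu"
        layers.append(Layer(W, np.zeros(d_out), activation))
    if not masked:
        set_names = [f"H{j}" for j in range(encoder[0])]
    return GsaeModel(
        layers=layers,
        config=config,
        mask=mask,
        n_encoder_layers=len(encoder),
        genes=genes,
        set_names=set_names,
        classes=None,
    )


def _forward_cache(model: GsaeModel, x: np.ndarray):
    acts = [x]
    for layer in model.layers:
        acts.append(layer_forward(acts[-1], layer.W, layer.b, layer.activation))
    return acts


def _loss(model: GsaeModel, x: np.ndarray, target: np.ndarray) -> float:
    out = model.forward(x)
    if model.is_classifier:
        eps = 1e-12
        return float(-(target * np.log(out + eps)).sum(axis=1).mean())
    return float(((out - target) ** 2).mean())


def train(
    model: GsaeModel,
    expr: ExpressionMatrix,
    labels=None,
    config: NetworkConfig | None = None,
) -> GsaeModel:
    """Train in place with SGD (Nesterov momentum, decay, gradient masking).

    A ``validation_fraction`` split (stratified in classifier mode) is held
    out; training stops when its loss has not improved for ``patience``
    consecutive epochs, or at ``max_epochs``. After every parameter update
    the first-layer weights and momentum buffer are re-multiplied by the
    membership mask, so masked-out connections stay exactly zero.
    """
    config = config or model.config
    if list(expr.genes) != list(model.genes):
        raise ValueError("expression gene order does not match the model")
    x = expr.values
    if model.is_classifier:
        if labels is None:
            raise ValueError("classifier mode requires labels")
        labels = np.asarray(labels)
        model.classes = sorted(np.unique(labels).tolist())
        class_index = {c: i for i, c in enumerate(model.classes)}
        target = np.zeros((len(labels), len(model.classes)))
        target[np.arange(len(labels)), [class_index[l] for l in labels]] = 1.0
    else:
        target = x

    rng = np.random.default_rng(config.seed + 1)
    n = x.shape[0]
    n_val = int(round(n * config.validation_fraction))
    if n_val < 2:
        raise ValueError(
            f"validation split of {n_val} sample(s) is too small; "
            "increase the data size or validation_fraction"
        )
    strat = labels if model.is_classifier else None
    try:
        idx_train, idx_val = train_test_split(
            np.arange(n), test_size=n_val, random_state=int(rng.integers(2**31)),
            stratify=strat,
        )
    except ValueError:  # a class too small to stratify the split
        idx_train, idx_val = train_test_split(
            np.arange(n), test_size=n_val, random_state=int(rng.integers(2**31)),
        )
    x_tr, t_tr = x[idx_train], target[idx_train]
    x_val, t_val = x[idx_val], target[idx_val]

    velocity = [np.zeros_like(layer.W) for layer in model.layers]
    velocity_b = [np.zeros_like(layer.b) for layer in model.layers]
    mask = model.mask.mask if model.mask is not None else None

    history = {"train_loss": [], "val_loss": []}
    best_val, best_epoch, wait = np.inf, 0, 0
    iterations = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(x_tr))
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            xb, tb = x_tr[batch], t_tr[batch]
            acts = _forward_cache(model, xb)
            out = acts[-1]
            B = xb.shape[0]
            if model.is_classifier:
                delta = (out - tb) / B  # softmax + cross-entropy
            else:
                delta = 2.0 * (out - tb) / (B * out.shape[1])  # linear + MSE
            lr = config.learning_rate / (1.0 + config.decay * iterations)
            iterations += 1
            # backprop from the top layer down, updating as we go
            for li in range(len(model.layers) - 1, -1, -1):
                layer = model.layers[li]
                gW = acts[li].T @ delta
                gb = delta.sum(axis=0)
                if li > 0:
                    delta = (delta @ layer.W.T) * (acts[li] > 0)
                v = velocity[li]
                v *= config.momentum
                v -= lr * gW
                if config.nesterov:
                    layer.W += config.momentum * v - lr * gW
                else:
                    layer.W += v
                vb = velocity_b[li]
                vb *= config.momentum
                vb -= lr * gb
                if config.nesterov:
                    layer.b += config.momentum * vb - lr * gb
                else:
                    layer.b += vb
                if li == 0 and mask is not None:
                    layer.W *= mask
                    v *= mask
        tr_loss = _loss(model, x_tr, t_tr)
        val_loss = _loss(model, x_val, t_val)
        if not (np.isfinite(tr_loss) and np.isfinite(val_loss)):
            raise FloatingPointError(f"training diverged (NaN/inf loss) at epoch {epoch}")
        history["train_loss"].append(tr_loss)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val, best_epoch, wait = val_loss, epoch, 0
        else:
            wait += 1
            if wait >= config.patience:
                break
    history["best_epoch"] = best_epoch
    model.history = history
    return model


def encode(model: GsaeModel, expr: ExpressionMatrix) -> ScoreMatrices:
    """Gene-set and superset scores (encoder layer activations) per sample.

    The expression gene order must match the model's exactly; no silent
    reordering is performed.
    """
    if list(expr.genes) != list(model.genes):
        raise ValueError("expression gene order does not match the model; reorder explicitly")
    gene_set_scores = model.forward(expr.values, upto=1)
    superset_scores = model.forward(expr.values, upto=model.n_encoder_layers)
    return ScoreMatrices(gene_set_scores, superset_scores, list(model.set_names), list(expr.samples))


def predict(model: GsaeModel, expr: ExpressionMatrix):
    """Class probabilities and argmax labels (lowest index wins ties)."""
    if not model.is_classifier:
        raise ValueError("predict requires a classifier-mode model")
    probs = model.forward(expr.values)
    idx = probs.argmax(axis=1)
    labels = np.asarray(model.classes, dtype=object)[idx]
    return probs, labels


def fit_autoencoder(
    expr: ExpressionMatrix, mask: MembershipMask, config: NetworkConfig | None = None
) -> GsaeModel:
    """Initialize and train a gene-superset autoencoder on one matrix."""
    config = config or NetworkConfig()
    if config.mode != "autoencoder":
        raise ValueError("fit_autoencoder needs autoencoder mode")
    model = initialize(config, mask)
    return train(model, expr)


def fit_classifier(
    expr: ExpressionMatrix,
    labels,
    mask: MembershipMask | None,
    config: NetworkConfig,
) -> GsaeModel:
    model = initialize(
        config, mask, n_genes=expr.n_genes, n_classes=len(np.unique(np.asarray(labels))),
        genes=list(expr.genes),
    )
    return train(model, expr, labels=labels)


def cross_validate(
    expr: ExpressionMatrix,
    labels,
    config: NetworkConfig,
    mask: MembershipMask | None = None,
    k: int = 10,
    repeats: int = 1,
    predictor=None,
):
    """Stratified k-fold cross-validation of the classifier.

    Returns overall accuracy plus per-class sensitivity (recall) and
    specificity (one-vs-rest true-negative rate), averaged over folds and
    repeats. ``predictor(expr_train, labels_train, expr_test) -> labels``
    may replace the network (used for testing the metric plumbing).
    """
    labels = np.asarray(labels)
    classes = sorted(np.unique(labels).tolist())
    counts = {c: int((labels == c).sum()) for c in classes}
    if min(counts.values()) < k:
        raise ValueError(f"every class needs >= {k} members for {k}-fold CV; got {counts}")

    accs, sens, spec = [], {c: [] for c in classes}, {c: [] for c in classes}
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed + rep)
        for fold, (tr, te) in enumerate(skf.split(expr.values, labels)):
            e_tr, e_te = expr.subset_samples(tr), expr.subset_samples(te)
            y_tr, y_te = labels[tr], labels[te]
            if predictor is not None:
                y_hat = np.asarray(predictor(e_tr, y_tr, e_te))
            else:
                cfg = NetworkConfig(**{**asdict(config), "seed": config.seed + 1000 * rep + fold})
                fold_model = fit_classifier(e_tr, y_tr, mask, cfg)
                _, y_hat = predict(fold_model, e_te)
            accs.append(float((y_hat == y_te).mean()))
            for c in classes:
                pos = y_te == c
                neg = ~pos
                sens[c].append(float((y_hat[pos] == c).mean()) if pos.any() else np.nan)
                spec[c].append(float((y_hat[neg] != c).mean()) if neg.any() else np.nan)
    return {
        "accuracy": float(np.mean(accs)),
        "sensitivity": {c: float(np.nanmean(v)) for c, v in sens.items()},
        "specificity": {c: float(np.nanmean(v)) for c, v in spec.items()},
    }


# ---------------------------------------------------------------------------
# persistence


def save_model(model: GsaeModel, path) -> None:
    """Save weights, mask, orders, and config; reload is bit-identical."""
    arrays = {}
    for i, layer in enumerate(model.layers):
        arrays[f"W{i}"] = layer.W
        arrays[f"b{i}"] = layer.b
    if model.mask is not None:
        arrays["mask"] = model.mask.mask
    meta = {
        "config": asdict(model.config),
        "activations": [l.activation for l in model.layers],
        "n_encoder_layers": model.n_encoder_layers,
        "genes": model.genes,
        "set_names": model.set_names,
        "classes": model.classes,
        "history": model.history,
        "n_layers": len(model.layers),
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> GsaeModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        layers = [
            Layer(data[f"W{i}"], data[f"b{i}"], act)
            for i, act in enumerate(meta["activations"])
        ]
        mask = None
        if "mask" in data:
            mask = MembershipMask(data["mask"], meta["genes"], meta["set_names"])
    config = NetworkConfig(**meta["config"])
    return GsaeModel(
        layers=layers,
        config=config,
        mask=mask,
        n_encoder_layers=meta["n_encoder_layers"],
        genes=meta["genes"],
        set_names=meta["set_names"],
        classes=meta["classes"],
        history=meta["history"],
    )
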