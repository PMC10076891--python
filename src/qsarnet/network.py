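"""Feed-forward tanh network trained against a q²-based cost.

The model is a fully connected multilayer perceptron: tanh on every hidden
node, a single linear output node (activities such as pIC50 are unbounded,
so the output is not squashed). Training minimizes

    J(W, lambda) = -q2(train) + (lambda/2) * sum of squared connection weights

where q2 = 1 - SSE / SST with SST = sum of (y_i - mean(y))^2 over the
training set. Because SST is a constant for a fixed training set, J differs
from the plain mean-squared-error cost only by an affine transformation, so
minimizing J is exactly equivalent to maximizing q2 — but the reported cost
is directly interpretable as a (negated) correlation coefficient.

Optimization is plain stochastic gradient descent over seeded mini-batch
shuffles, with inverted dropout on the hidden activations and early stopping
on the cost evaluated on a held-out set. During mini-batch training the q2
denominator stays fixed at the full-training-set SST, so the stochastic
gradient is a constant rescaling of the MSE gradient and the J/q2
equivalence holds across batches; a per-batch denominator is available
behind a flag.

Weight decay applies to connection weights only, never to biases. Dropout
applies to hidden layers only, never to input or output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import NetworkConfig, logger
from .errors import TrainingError, ValidationError
from .table import DescriptorTable
from .wash import NormalizationParams


# ---------------------------------------------------------------- containers
@dataclass
class NetworkParameters:
    """Layer sizes S_1..S_L (S_1 = inputs, S_L = 1) and connection weights.

    ``weights[l]`` has shape (S_l, S_{l+1}): entry (i, j) connects node i on
    layer l to node j on layer l+1. Biases are optional per-layer vectors.
    """

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray] | None = None
    activation: str = "tanh"

    def __post_init__(self) -> None:
        sizes = self.layer_sizes
        if len(self.weights) != len(sizes) - 1:
            raise ValidationError("one weight matrix per layer pair required")
        for l, W in enumerate(self.weights):
            if W.shape != (sizes[l], sizes[l + 1]):
                raise ValidationError(
                    f"weight matrix {l} has shape {W.shape}, "
                    f"expected {(sizes[l], sizes[l + 1])}"
                )
            if not np.isfinite(W).all():
                raise ValidationError(f"non-finite entries in weight matrix {l}")
        if self.biases is not None:
            for l, b in enumerate(self.biases):
                if b.shape != (sizes[l + 1],):
                    raise ValidationError(f"bias vector {l} has wrong shape")

    def clone(self) -> "NetworkParameters":
        return NetworkParameters(
            self.layer_sizes,
            [W.copy() for W in self.weights],
            None if self.biases is None else [b.copy() for b in self.biases],
            self.activation,
        )


@dataclass
class CostBreakdown:
    """J split into its -q2 term and the L2 weight-decay term."""

    q2_term: float          # -q2 on the evaluated set
    decay_term: float       # (lambda/2) * sum of squared weights, >= 0
    total: float            # J = q2_term + decay_term

    @property
    def q2(self) -> float:
        return -self.q2_term


@dataclass
class TrainState:
    """Trajectory and early-stopping bookkeeping of one training run."""

    epochs_run: int = 0
    cost_train: list[float] = field(default_factory=list)
    cost_eval: list[tuple[int, float]] = field(default_factory=list)
    best_eval_cost: float = np.inf
    best_epoch: int = 0
    rng_seed: int = 0


@dataclass
class TrainedModel:
    """A trained network bundled with its preprocessing state.

    The network is fitted on the standardized activity scale (training-set
    mean/sd); ``activity_location``/``activity_scale`` undo that at
    prediction time. q² and r² are invariant under this joint affine
    transformation, so reported statistics are unaffected.
    """

    params: NetworkParameters
    normalization: NormalizationParams | None
    descriptor_names: list[str]
    activity_name: str
    config: dict
    activity_location: float = 0.0
    activity_scale: float = 1.0


# ------------------------------------------------------------------- helpers
def derive_seeds(master: int, n: int = 3) -> list[int]:
    """Fixed derivation of child seeds (init, shuffle, dropout) from a master
    seed. Documented contract: ``SeedSequence(master).generate_state(n)``."""
    return [int(s) for s in np.random.SeedSequence(master).generate_state(n)]


def init_network(
    layer_sizes: tuple[int, ...] | list[int],
    use_bias: bool = True,
    seed: int = 0,
) -> NetworkParameters:
    """Seeded weight initialization, zero-mean normal with sd 1/sqrt(fan-in).

    The 1/sqrt(fan-in) scale keeps pre-activations in the near-linear region
    of tanh at the start of training. Biases start at zero.
    """
    sizes = tuple(int(s) for s in layer_sizes)
    if len(sizes) < 2:
        raise ValidationError("need at least an input and an output layer")
    if any(s <= 0 for s in sizes):
        raise ValidationError(f"layer sizes must be positive, got {sizes}")
    if sizes[-1] != 1:
        raise ValidationError("output layer must have exactly one node")
    rng = np.random.default_rng(seed)
    weights = [
        rng.normal(0.0, 1.0 / np.sqrt(sizes[l]), size=(sizes[l], sizes[l + 1]))
        for l in range(len(sizes) - 1)
    ]
    biases = (
        [np.zeros(sizes[l + 1]) for l in range(len(sizes) - 1)]
        if use_bias else None
    )
    return NetworkParameters(sizes, weights, biases)


def count_parameters(params: NetworkParameters, include_bias: bool = False) -> int:
    """Number of trainable variables: sum over l of S_l * S_{l+1}, plus the
    bias counts when requested."""
    total = sum(W.size for W in params.weights)
    if include_bias and params.biases is not None:
        total += sum(b.size for b in params.biases)
    return int(total)


# ------------------------------------------------------------------- forward
def _forward_cached(
    params: NetworkParameters,
    X: np.ndarray,
    dropout_rate: float,
    rng: np.random.Generator | None,
):
    """Forward pass keeping per-layer caches for backpropagation.

    Returns (predictions, layer_inputs A, tanh outputs T, dropout masks M).
    When ``dropout_rate`` is 0 no mask is drawn and no random numbers are
    consumed, so a rate of 0 is bit-identical to inference.
    """
    L = len(params.weights)
    A: list[np.ndarray] = [np.asarray(X, dtype=float)]
    T: list[np.ndarray | None] = []
    M: list[np.ndarray | None] = []
    for l in range(L - 1):                      # hidden layers
        Z = A[l] @ params.weights[l]
        if params.biases is not None:
            Z = Z + params.biases[l]
        t = np.tanh(Z)
        if dropout_rate > 0:
            if rng is None:
                raise ValidationError("dropout requires a random generator")
            mask = (rng.random(t.shape) >= dropout_rate) / (1.0 - dropout_rate)
        else:
            mask = None
        T.append(t)
        M.append(mask)
        A.append(t if mask is None else t * mask)
    out = A[L - 1] @ params.weights[L - 1]
    if params.biases is not None:
        out = out + params.biases[L - 1]
    return out.ravel(), A, T, M


def forward(
    params: NetworkParameters,
    X: np.ndarray,
    dropout_rate: float = 0.0,
    mode: str = "infer",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Predictions h_W(x) for each row of X.

    ``mode="train"`` applies inverted dropout to hidden activations
    (surviving nodes scaled by 1/(1-rate)); ``mode="infer"`` applies no mask
    and no scaling.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != params.layer_sizes[0]:
        raise ValidationError(
            f"input has {X.shape[-1] if X.ndim == 2 else X.ndim} columns, "
            f"network expects {params.layer_sizes[0]}"
        )
    if mode not in ("train", "infer"):
        raise ValidationError(f"unknown mode {mode!r}")
    rate = dropout_rate if mode == "train" else 0.0
    preds, *_ = _forward_cached(params, X, rate, rng)
    return preds


# ---------------------------------------------------------------------- cost
def sum_squared_weights(params: NetworkParameters) -> float:
    return float(sum(np.sum(W * W) for W in params.weights))


def cost(
    params: NetworkParameters,
    X: np.ndarray,
    y: np.ndarray,
    lam: float = 0.0,
    denominator: float | None = None,
) -> CostBreakdown:
    """J = -q2 + (lambda/2) * sum of squared weights, evaluated in infer mode.

    ``denominator`` overrides the q2 denominator (used during training to
    keep it fixed at the full-training-set SST); by default it is
    sum((y - mean(y))^2) of the set being evaluated. Biases never enter the
    decay term.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise ValidationError("need at least 2 observations")
    D = float(np.sum((y - y.mean()) ** 2)) if denominator is None else denominator
    if D <= 0:
        raise ValidationError("constant activities: q2 undefined")
    h = forward(params, X)
    sse = float(np.sum((h - y) ** 2))
    q2_term = -(1.0 - sse / D)
    decay = 0.5 * lam * sum_squared_weights(params)
    return CostBreakdown(q2_term=q2_term, decay_term=decay, total=q2_term + decay)


# ------------------------------------------------------------------ gradient
def gradient(
    params: NetworkParameters,
    X: np.ndarray,
    y: np.ndarray,
    lam: float = 0.0,
    denominator: float | None = None,
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[list[np.ndarray], list[np.ndarray] | None]:
    """Backpropagated gradient of J with respect to weights (and biases).

    The -q2 term contributes grad(SSE)/D where D is the (epoch-fixed) q2
    denominator; weight decay contributes lambda * W. Bias gradients carry
    no decay term.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    D = float(np.sum((y - y.mean()) ** 2)) if denominator is None else denominator
    if D <= 0:
        raise ValidationError("constant activities: q2 undefined")
    h, A, T, M = _forward_cached(params, X, dropout_rate, rng)
    L = len(params.weights)
    grads_W: list[np.ndarray] = [np.empty(0)] * L
    grads_b: list[np.ndarray] | None = (
        [np.empty(0)] * L if params.biases is not None else None
    )
    delta = (2.0 / D) * (h - y)[:, None]        # linear output node
    for l in range(L - 1, -1, -1):
        grads_W[l] = A[l].T @ delta + lam * params.weights[l]
        if grads_b is not None:
            grads_b[l] = delta.sum(axis=0)
        if l > 0:
            dA = delta @ params.weights[l].T
            if M[l - 1] is not None:
                dA = dA * M[l - 1]
            delta = dA * (1.0 - T[l - 1] ** 2)
    for g in grads_W:
        if not np.isfinite(g).all():
            raise TrainingError(
                "NaN/Inf gradient encountered; the learning rate is likely "
                "too large for this data scale"
            )
    return grads_W, grads_b


# ------------------------------------------------------------------ training
def train(
    params: NetworkParameters,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_eval: np.ndarray,
    y_eval: np.ndarray,
    cfg: NetworkConfig,
    seed: int = 0,
    per_batch_denominator: bool = False,
) -> tuple[NetworkParameters, TrainState]:
    """Mini-batch SGD with early stopping on held-out cost.

    Each epoch runs a seeded shuffle of mini-batches of ``cfg.batch_size``
    rows; every ``cfg.eval_interval`` epochs the full cost J is computed on
    the held-out set. Training stops when the held-out cost has not improved
    for ``cfg.patience`` consecutive evaluations (``patience=0`` disables
    early stopping) or at ``cfg.max_epochs``. The returned network is the
    snapshot from the best-scoring evaluation.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    m = len(y_train)
    if cfg.batch_size > m:
        raise ValidationError(
            f"batch_size {cfg.batch_size} exceeds training-set size {m}"
        )
    D_full = float(np.sum((y_train - y_train.mean()) ** 2))
    if D_full <= 0:
        raise ValidationError("constant training activities: q2 undefined")
    _, shuffle_seed, dropout_seed = derive_seeds(seed)
    shuffle_rng = np.random.default_rng(shuffle_seed)
    dropout_rng = np.random.default_rng(dropout_seed)
    logger.info(
        "train: m=%d, net %s, seed %d (shuffle %d, dropout %d)",
        m, params.layer_sizes, seed, shuffle_seed, dropout_seed,
    )

    state = TrainState(rng_seed=seed)
    work = params.clone()
    best = work.clone()
    bad_evals = 0
    eta = cfg.learning_rate

    def evaluate(epoch: int) -> bool:
        nonlocal best, bad_evals
        j_eval = cost(work, X_eval, y_eval, cfg.lam).total
        state.cost_eval.append((epoch, j_eval))
        if j_eval < state.best_eval_cost:
            state.best_eval_cost = j_eval
            state.best_epoch = epoch
            best = work.clone()
            bad_evals = 0
        else:
            bad_evals += 1
        return cfg.patience > 0 and bad_evals >= cfg.patience

    for epoch in range(1, cfg.max_epochs + 1):
        perm = shuffle_rng.permutation(m)
        for start in range(0, m, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            yb = y_train[idx]
            if per_batch_denominator:
                D = float(np.sum((yb - yb.mean()) ** 2))
                if D <= 0:
                    continue    # degenerate batch: constant activities
            else:
                D = D_full
            gW, gb = gradient(
                work, X_train[idx], yb, cfg.lam, denominator=D,
                dropout_rate=cfg.dropout, rng=dropout_rng,
            )
            for l in range(len(work.weights)):
                work.weights[l] -= eta * gW[l]
                if work.biases is not None:
                    work.biases[l] -= eta * gb[l]
        j_train = cost(work, X_train, y_train, cfg.lam, denominator=D_full).total
        if not np.isfinite(j_train):
            raise TrainingError(
                f"training diverged at epoch {epoch} (cost {j_train}); "
                f"state: best eval {state.best_eval_cost} at epoch "
                f"{state.best_epoch}"
            )
        state.cost_train.append(j_train)
        state.epochs_run = epoch
        if epoch % cfg.eval_interval == 0 and evaluate(epoch):
            logger.info("train: early stop at epoch %d", epoch)
            break
    if not state.cost_eval:
        evaluate(state.epochs_run)
    logger.info(
        "train: stopped after %d epochs; best eval cost %.6f at epoch %d",
        state.epochs_run, state.best_eval_cost, state.best_epoch,
    )
    return best, state


# ---------------------------------------------------------------- prediction
def predict(model: TrainedModel, table: DescriptorTable) -> pd.Series:
    """Predicted activities for every compound of ``table``.

    Applies the model's stored normalization and runs the network in infer
    mode. Every descriptor the model was trained on must be present.
    """
    missing = [c for c in model.descriptor_names if c not in table.descriptors.columns]
    if missing:
        raise ValidationError(f"input is missing descriptor columns: {missing}")
    if model.normalization is not None:
        work = model.normalization.transform(table)
        work = work.select_descriptors(model.descriptor_names)
    else:
        work = table.select_descriptors(model.descriptor_names)
    preds = forward(model.params, work.X)
    preds = preds * model.activity_scale + model.activity_location
    return pd.Series(preds, index=table.descriptors.index,
                     name=f"predicted_{model.activity_name}")


def predict_with_applicability(
    model: TrainedModel,
    table: DescriptorTable,
    training_table: DescriptorTable,
) -> pd.DataFrame:
    """Predictions plus the Euclidean distance to the nearest training
    compound — the larger the distance, the less trustworthy the prediction.
    """
    preds = predict(model, table)
    if model.normalization is not None:
        q = model.normalization.transform(table).select_descriptors(
            model.descriptor_names)
        ref = model.normalization.transform(training_table).select_descriptors(
            model.descriptor_names)
    else:
        q = table.select_descriptors(model.descriptor_names)
        ref = training_table.select_descriptors(model.descriptor_names)
    rows = []
    ref_ids = ref.compound_ids
    for i, cid in enumerate(q.compound_ids):
        d = np.linalg.norm(ref.X - q.X[i], axis=1)
        if cid in ref.descriptors.index:
            d[ref_ids.index(cid)] = np.inf
        j = int(np.argmin(d))
        rows.append((ref_ids[j], float(d[j])))
    out = preds.to_frame()
    out["nearest_training_compound"] = [r[0] for r in rows]
    out["nearest_training_distance"] = [r[1] for r in rows]
    return out
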