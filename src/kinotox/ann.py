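"""Multilayer perceptron with Levenberg-Marquardt training.

The network maps (inhibitor concentration, kinase-target code, normalized
beat frequency, normalized viability, normalized live-cell count) to the
normalized Ca2+ peak magnitude; control networks map (normalized live
cells, kinase target) to normalized viability, one per concentration.

Training minimizes the sum of squared residuals with a damped
Gauss-Newton step: each accepted step solves (J'J + lambda*I) d = J'r and
strictly reduces the training RMSE; the damping factor is multiplied up on
rejection and down on acceptance.  Inputs and output are affinely scaled
to [-1, 1] before training (the scaling is stored on the network, so
``forward`` works in original units).  Model selection is an exhaustive
search over candidate architectures ranked by held-out R^2, then RMSE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from kinotox.errors import DivergedError, InvalidArgumentError

# ---------------------------------------------------------------------------
# transfer functions
# ---------------------------------------------------------------------------

def _tansig(z: np.ndarray) -> np.ndarray:
    return np.tanh(z)


def _dtansig(z: np.ndarray, a: np.ndarray) -> np.ndarray:
    return 1.0 - a * a


def _logsig(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _dlogsig(z: np.ndarray, a: np.ndarray) -> np.ndarray:
    return a * (1.0 - a)


def _purelin(z: np.ndarray) -> np.ndarray:
    return z


def _dpurelin(z: np.ndarray, a: np.ndarray) -> np.ndarray:
    return np.ones_like(z)


TRANSFERS: dict[str, tuple[Callable, Callable]] = {
    "tansig": (_tansig, _dtansig),
    "logsig": (_logsig, _dlogsig),
    "purelin": (_purelin, _dpurelin),
}


# ---------------------------------------------------------------------------
# record layouts
# ---------------------------------------------------------------------------

#: column order of the prediction-network input layer
MODEL_INPUTS = (
    "concentration_uM",
    "kinase_target",
    "norm_frequency",
    "norm_viability",
    "norm_live_cells",
)
MODEL_OUTPUT = "norm_peak_magnitude"

#: column order of the per-concentration control networks
CONTROL_INPUTS = ("norm_live_cells", "kinase_target")
CONTROL_OUTPUT = "norm_viability"


# ---------------------------------------------------------------------------
# network container
# ---------------------------------------------------------------------------

@dataclass
class MLPNetwork:
    """Feedforward network with per-layer transfer functions and scaling."""

    weights: list[np.ndarray]  # layer l: (units_l, units_{l-1})
    biases: list[np.ndarray]  # layer l: (units_l,)
    transfers: list[str]
    x_offset: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    y_offset: float = 0.0
    y_scale: float = 1.0

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.biases) or len(self.weights) != len(self.transfers):
            raise InvalidArgumentError("weights, biases and transfers must align per layer")
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            if W.shape[0] != b.shape[0]:
                raise InvalidArgumentError(f"layer {l}: bias length mismatch")
            if l > 0 and W.shape[1] != self.weights[l - 1].shape[0]:
                raise InvalidArgumentError(f"layer {l}: input dimension mismatch")
            if self.transfers[l] not in TRANSFERS:
                raise InvalidArgumentError(f"unknown transfer {self.transfers[l]!r}")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.weights[0].shape[1],) + tuple(W.shape[0] for W in self.weights)

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[1]

    @property
    def n_params(self) -> int:
        return sum(W.size + b.size for W, b in zip(self.weights, self.biases))

    @property
    def architecture(self) -> str:
        hidden = "x".join(
            f"{W.shape[0]}{t[0]}" for W, t in zip(self.weights[:-1], self.transfers[:-1])
        )
        return hidden + "-lin" if hidden else "lin"

    def copy(self) -> "MLPNetwork":
        return MLPNetwork(
            [W.copy() for W in self.weights],
            [b.copy() for b in self.biases],
            list(self.transfers),
            None if self.x_offset is None else self.x_offset.copy(),
            None if self.x_scale is None else self.x_scale.copy(),
            self.y_offset,
            self.y_scale,
        )


def init_network(
    layer_sizes: Sequence[int],
    transfers: Sequence[str] | None = None,
    seed: int = 0,
    init_range: float = 0.5,
) -> MLPNetwork:
    """Seeded uniform [-init_range, init_range] initialization.

    ``layer_sizes`` includes the input dimension; hidden transfers default
    to tansig with a linear output layer.
    """
    if len(layer_sizes) < 2:
        raise InvalidArgumentError("need at least input and output layer sizes")
    if transfers is None:
        transfers = ["tansig"] * (len(layer_sizes) - 2) + ["purelin"]
    if len(transfers) != len(layer_sizes) - 1:
        raise InvalidArgumentError("one transfer per non-input layer required")
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        weights.append(rng.uniform(-init_range, init_range, size=(n_out, n_in)))
        biases.append(rng.uniform(-init_range, init_range, size=n_out))
    return MLPNetwork(weights, biases, list(transfers))


# ---------------------------------------------------------------------------
# scaling and forward pass
# ---------------------------------------------------------------------------

def _fit_scaling(net: MLPNetwork, X: np.ndarray, y: np.ndarray) -> None:
    """Affine map of each input column and the output to [-1, 1]."""
    xmin, xmax = X.min(axis=0), X.max(axis=0)
    net.x_offset = (xmax + xmin) / 2.0
    scale = (xmax - xmin) / 2.0
    scale[scale == 0] = 1.0
    net.x_scale = scale
    ymin, ymax = float(y.min()), float(y.max())
    net.y_offset = (ymax + ymin) / 2.0
    net.y_scale = (ymax - ymin) / 2.0 or 1.0


def _scale_x(net: MLPNetwork, X: np.ndarray) -> np.ndarray:
    if net.x_offset is None:
        return X
    return (X - net.x_offset) / net.x_scale


def _forward_scaled(net: MLPNetwork, Xs: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Activations and pre-activations per layer for a scaled batch."""
    a = Xs
    zs, acts = [], [a]
    for W, b, tname in zip(net.weights, net.biases, net.transfers):
        z = a @ W.T + b
        a = TRANSFERS[tname][0](z)
        zs.append(z)
        acts.append(a)
    return zs, acts


def forward(net: MLPNetwork, X: np.ndarray) -> np.ndarray:
    """Network output in original units for inputs in original units."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != net.n_inputs:
        raise InvalidArgumentError(
            f"input dimension {X.shape[1]} != network input {net.n_inputs}"
        )
    _, acts = _forward_scaled(net, _scale_x(net, X))
    out = acts[-1][:, 0] if acts[-1].shape[1] == 1 else acts[-1]
    return out * net.y_scale + net.y_offset


# ---------------------------------------------------------------------------
# parameters and Jacobian
# ---------------------------------------------------------------------------

def _pack(net: MLPNetwork) -> np.ndarray:
    return np.concatenate([np.concatenate([W.ravel(), b]) for W, b in zip(net.weights, net.biases)])


def _unpack(net: MLPNetwork, theta: np.ndarray) -> None:
    pos = 0
    for l, (W, b) in enumerate(zip(net.weights, net.biases)):
        net.weights[l] = theta[pos : pos + W.size].reshape(W.shape)
        pos += W.size
        net.biases[l] = theta[pos : pos + b.size]
        pos += b.size


def jacobian(net: MLPNetwork, Xs: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Residuals and their parameter Jacobian (scaled space, scalar output).

    Residual r_i = yhat_i - y_i; J[i, k] = d r_i / d theta_k computed by
    per-layer backpropagation, vectorized over the batch.
    """
    if Xs.shape[0] == 0:
        raise InvalidArgumentError("batch must be nonempty")
    zs, acts = _forward_scaled(net, Xs)
    n = Xs.shape[0]
    r = acts[-1][:, 0] - ys

    # delta_l = d yhat / d z_l, shape (n, units_l)
    L = len(net.weights)
    deltas: list[np.ndarray] = [None] * L
    dlast = TRANSFERS[net.transfers[-1]][1](zs[-1], acts[-1])
    deltas[L - 1] = dlast  # output layer has 1 unit
    for l in range(L - 2, -1, -1):
        dtrans = TRANSFERS[net.transfers[l]][1](zs[l], acts[l + 1])
        deltas[l] = (deltas[l + 1] @ net.weights[l + 1]) * dtrans

    cols = []
    for l in range(L):
        a_prev = acts[l]  # (n, units_{l-1})
        d = deltas[l]  # (n, units_l)
        cols.append((d[:, :, None] * a_prev[:, None, :]).reshape(n, -1))
        cols.append(d)
    return r, np.concatenate(cols, axis=1)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LMConfig:
    max_epochs: int = 1000
    lambda_init: float = 1e-3
    lambda_up: float = 10.0
    lambda_down: float = 0.1
    min_gradient: float = 1e-7
    lambda_max: float = 1e10
    max_inner: int = 30


@dataclass
class FitResult:
    network: MLPNetwork
    rmse_curve: np.ndarray  # training RMSE (original units) at accepted steps
    train_rmse: float
    test_rmse: float = math.nan
    test_r2: float = math.nan
    epochs: int = 0
    seed: int = 0
    status: str = "ok"

    @property
    def architecture(self) -> str:
        return self.network.architecture


def train_lm(
    net: MLPNetwork,
    X: np.ndarray,
    y: np.ndarray,
    config: LMConfig = LMConfig(),
    refit_scaling: bool = True,
) -> FitResult:
    """Levenberg-Marquardt fit of the squared-error objective.

    Stops at ``max_epochs`` accepted steps, when the gradient infinity
    norm falls below ``min_gradient``, or when no damping factor up to
    ``lambda_max`` yields an improvement.  The accepted-step RMSE sequence
    is strictly decreasing by construction.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] == 0 or X.shape[0] != len(y):
        raise InvalidArgumentError("data must be nonempty with matching X/y lengths")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise InvalidArgumentError("training data must be finite")
    if refit_scaling or net.x_offset is None:
        _fit_scaling(net, X, y)
    Xs = _scale_x(net, X)
    ys = (y - net.y_offset) / net.y_scale

    theta = _pack(net)
    lam = config.lambda_init
    n = len(ys)
    eye = np.eye(len(theta))

    r, J = jacobian(net, Xs, ys)
    sse = float(r @ r)
    if not math.isfinite(sse):
        raise DivergedError("non-finite initial loss")
    curve = []
    status = "max_epochs"
    epochs = 0
    for _ in range(config.max_epochs):
        g = J.T @ r
        if np.max(np.abs(g)) < config.min_gradient:
            status = "gradient"
            break
        JTJ = J.T @ J
        accepted = False
        for _ in range(config.max_inner):
            try:
                delta = np.linalg.solve(JTJ + lam * eye, g)
            except np.linalg.LinAlgError:
                lam *= config.lambda_up
                continue
            theta_try = theta - delta
            _unpack(net, theta_try)
            r_try, J_try = jacobian(net, Xs, ys)
            sse_try = float(r_try @ r_try)
            if not math.isfinite(sse_try):
                raise DivergedError("non-finite loss during training")
            if sse_try < sse:
                theta, r, J, sse = theta_try, r_try, J_try, sse_try
                lam = max(lam * config.lambda_down, 1e-20)
                accepted = True
                break
            lam *= config.lambda_up
            if lam > config.lambda_max:
                break
        if not accepted:
            _unpack(net, theta)  # restore last accepted parameters
            status = "stalled"
            break
        epochs += 1
        curve.append(math.sqrt(sse / n) * abs(net.y_scale))

    _unpack(net, theta)
    train_rmse = math.sqrt(sse / n) * abs(net.y_scale)
    return FitResult(
        network=net,
        rmse_curve=np.asarray(curve),
        train_rmse=train_rmse,
        epochs=epochs,
        status=status,
    )


# ---------------------------------------------------------------------------
# split / evaluation
# ---------------------------------------------------------------------------

def split_indices(n: int, train_fraction: float = 0.9, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint seeded train/test index partition with |train| = round(f*n)."""
    if not 0.0 < train_fraction < 1.0:
        raise InvalidArgumentError("train_fraction must be in (0, 1)")
    if n < 2:
        raise InvalidArgumentError("need >= 2 records to split")
    n_train = min(max(int(round(train_fraction * n)), 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def split(
    X: np.ndarray, y: np.ndarray, train_fraction: float = 0.9, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    tr, te = split_indices(len(y), train_fraction, seed)
    return X[tr], y[tr], X[te], y[te]


def evaluate(net: MLPNetwork, X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(RMSE, R^2) on a held-out set.

    R^2 is the squared Pearson correlation between predicted and actual;
    it is NaN when either side has zero variance.
    """
    y = np.asarray(y, dtype=float).ravel()
    if len(y) == 0:
        raise InvalidArgumentError("test set must be nonempty")
    pred = forward(net, X)
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    if np.std(y) == 0 or np.std(pred) == 0:
        return rmse, float("nan")
    r = float(np.corrcoef(pred, y)[0, 1])
    return rmse, r * r


def r_squared_determination(pred: np.ndarray, y: np.ndarray) -> float:
    """Coefficient-of-determination variant (1 - SSE/SST)."""
    y = np.asarray(y, dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return float("nan")
    return 1.0 - float(np.sum((pred - y) ** 2)) / sst


# ---------------------------------------------------------------------------
# fitting with restarts and architecture search
# ---------------------------------------------------------------------------

def fit(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    hidden: Sequence[int] = (8,),
    transfers: Sequence[str] | None = None,
    config: LMConfig = LMConfig(),
    seed: int = 0,
    n_restarts: int = 3,
) -> FitResult:
    """Train one architecture with seeded multi-restart; keep the best
    restart by test R^2 (ties by lower test RMSE)."""
    n_in = np.atleast_2d(X_train).shape[1]
    sizes = [n_in, *hidden, 1]
    if transfers is not None:
        transfers = list(transfers) + ["purelin"]
    best: FitResult | None = None
    for k in range(n_restarts):
        net = init_network(sizes, transfers, seed=seed + 1000 * k)
        try:
            res = train_lm(net, X_train, y_train, config)
        except DivergedError:
            res = FitResult(net, np.array([]), math.nan, status="diverged", seed=seed + 1000 * k)
        else:
            res.seed = seed + 1000 * k
            res.test_rmse, res.test_r2 = evaluate(net, X_test, y_test)
        if best is None or _rank_key(res) > _rank_key(best):
            best = res
    return best


def _rank_key(res: FitResult) -> tuple[float, float]:
    r2 = res.test_r2 if math.isfinite(res.test_r2) else -math.inf
    rmse = res.test_rmse if math.isfinite(res.test_rmse) else math.inf
    if res.status == "diverged":
        return (-math.inf, -math.inf)
    return (r2, -rmse)


def default_candidate_grid(
    max_hidden_layers: int = 2,
    sizes: Sequence[int] = (3, 5, 8, 12),
    transfers: Sequence[str] = ("tansig", "logsig"),
) -> list[tuple[tuple[int, ...], tuple[str, ...]]]:
    """Exhaustive (hidden sizes, hidden transfers) grid, linear output."""
    grid: list[tuple[tuple[int, ...], tuple[str, ...]]] = []
    if max_hidden_layers >= 1:
        grid += [((s,), (t,)) for s in sizes for t in transfers]
    if max_hidden_layers >= 2:
        grid += [
            ((s1, s2), (t1, t2))
            for s1 in sizes
            for s2 in sizes
            for t1 in transfers
            for t2 in transfers
        ]
    return grid


def architecture_search(
    X: np.ndarray,
    y: np.ndarray,
    candidates: Sequence[tuple[Sequence[int], Sequence[str]]] | None = None,
    config: LMConfig = LMConfig(),
    train_fraction: float = 0.9,
    seed: int = 0,
    n_restarts: int = 3,
) -> list[FitResult]:
    """Train every candidate on the same split; rank by test R^2 then RMSE.

    Diverged fits are kept in the returned list (ranked last) so the
    search report is complete.
    """
    if candidates is None:
        candidates = default_candidate_grid()
    if len(candidates) == 0:
        raise InvalidArgumentError("candidate grid must be nonempty")
    Xtr, ytr, Xte, yte = split(np.atleast_2d(np.asarray(X, float)), y, train_fraction, seed)
    results = [
        fit(Xtr, ytr, Xte, yte, hidden, transfers, config, seed=seed + 37 * i, n_restarts=n_restarts)
        for i, (hidden, transfers) in enumerate(candidates)
    ]
    # stable sort: equal metrics keep candidate order
    order = sorted(range(len(results)), key=lambda i: tuple(-v for v in _rank_key(results[i])))
    return [results[i] for i in order]
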