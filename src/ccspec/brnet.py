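"""Feed-forward regression network trained by Levenberg-Marquardt under
Bayesian regularization (MacKay's evidence framework).

The network minimizes F = beta*E_D + alpha*E_W with E_D = 1/2 * sum of
squared residuals and E_W = 1/2 * sum of squared weights.  Each outer
iteration takes a damped Gauss-Newton (LM) step using the JtJ Hessian
approximation, then re-estimates the hyperparameters from the evidence:

    H     = beta*JtJ + alpha*I
    gamma = Nw - alpha*tr(H^-1)            (effective number of parameters)
    alpha <- gamma / (2*E_W)
    beta  <- (N - gamma) / (2*E_D)

(with half-sum energies, gamma = sum_i lambda_i/(lambda_i + alpha) over the
eigenvalues of beta*JtJ, so 0 <= gamma <= Nw by construction).

Training is deterministic given the seed: same seed, same data -> bitwise
identical weight trajectory and objective trace.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = ["NetConfig", "BayesNetState", "init_net", "train", "predict",
           "save_net", "load_net"]


@dataclass(frozen=True)
class NetConfig:
    """Architecture and training-control settings.

    layer_sizes is (n_in, hidden..., n_out); hidden units use tanh, the
    output is linear.  tolerance stops training when the accepted objective
    improves by less than this amount.
    """

    layer_sizes: tuple[int, ...]
    max_epochs: int = 100
    tolerance: float = 1e-7
    seed: int = 0
    init_scale: float = 0.5
    mu0: float = 1e-3
    mu_max: float = 1e10
    #: False freezes alpha at 0 and beta at 1 (plain Levenberg-Marquardt),
    #: used as the unregularized baseline in overfit-control comparisons.
    bayes: bool = True

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 3:
            raise ValueError("need at least one hidden layer")
        if any(s <= 0 for s in self.layer_sizes):
            raise ValueError(f"layer sizes must be positive: {self.layer_sizes}")


@dataclass
class BayesNetState:
    """Weights plus regularization hyperparameters and training trace."""

    config: NetConfig
    weights: np.ndarray
    alpha: float
    beta: float
    gamma: float
    trace: list[float] = field(default_factory=list)
    #: per accepted step, (objective before, objective after) under the
    #: hyperparameters used for that step's acceptance test
    trace_pairs: list[tuple[float, float]] = field(default_factory=list)
    x_mean: np.ndarray | None = None
    x_std: np.ndarray | None = None
    y_mean: np.ndarray | None = None
    y_std: np.ndarray | None = None
    trained: bool = False
    stop_reason: str | None = None

    @property
    def n_weights(self) -> int:
        return int(self.weights.size)


# ---------------------------------------------------------------------------
# weight packing


def _shapes(layer_sizes: tuple[int, ...]) -> list[tuple[tuple[int, int], tuple[int]]]:
    return [
        ((layer_sizes[i], layer_sizes[i + 1]), (layer_sizes[i + 1],))
        for i in range(len(layer_sizes) - 1)
    ]


def _unpack(w: np.ndarray, layer_sizes: tuple[int, ...]):
    mats, pos = [], 0
    for (wi_shape, bi_shape) in _shapes(layer_sizes):
        n = wi_shape[0] * wi_shape[1]
        W = w[pos : pos + n].reshape(wi_shape)
        pos += n
        b = w[pos : pos + bi_shape[0]]
        pos += bi_shape[0]
        mats.append((W, b))
    return mats


def n_weights(layer_sizes: tuple[int, ...]) -> int:
    return sum(i * o + o for i, o in zip(layer_sizes[:-1], layer_sizes[1:]))


def init_net(cfg: NetConfig) -> BayesNetState:
    """Initialize weights from a small symmetric uniform distribution.

    alpha starts at 0 (no weight penalty until the evidence is estimated)
    and beta at 1.
    """
    rng = np.random.default_rng(cfg.seed)
    nw = n_weights(cfg.layer_sizes)
    scale = cfg.init_scale / np.sqrt(max(cfg.layer_sizes[0], 1))
    w = rng.uniform(-scale, scale, size=nw)
    return BayesNetState(config=cfg, weights=w, alpha=0.0, beta=1.0, gamma=0.0)


# ---------------------------------------------------------------------------
# forward pass and Jacobian


def _forward(w: np.ndarray, layer_sizes, X: np.ndarray):
    """Forward pass returning activations of every layer."""
    acts = [X]
    layers = _unpack(w, layer_sizes)
    h = X
    for k, (W, b) in enumerate(layers):
        z = h @ W + b
        h = z if k == len(layers) - 1 else np.tanh(z)
        acts.append(h)
    return acts


def _jacobian(w: np.ndarray, layer_sizes, X: np.ndarray) -> np.ndarray:
    """Jacobian of the flattened outputs w.r.t. the flat weight vector.

    Returns J with shape (n_samples * n_out, n_weights); row ordering is
    sample-major.  Backpropagates one output unit at a time.
    """
    n = X.shape[0]
    n_out = layer_sizes[-1]
    layers = _unpack(w, layer_sizes)
    acts = _forward(w, layer_sizes, X)
    nw = w.size
    J = np.empty((n, n_out, nw), dtype=float)

    # d tanh = 1 - h^2 for hidden activations
    dacts = [1.0 - a * a for a in acts[1:-1]]

    for o in range(n_out):
        # delta at output layer: one-hot on unit o (linear output)
        delta = np.zeros((n, n_out))
        delta[:, o] = 1.0
        pos = nw
        grads: list[np.ndarray] = []
        for k in range(len(layers) - 1, -1, -1):
            W, b = layers[k]
            a_prev = acts[k]
            # gradient blocks for W (outer product) and b
            gW = a_prev[:, :, None] * delta[:, None, :]
            gb = delta
            grads.append(np.concatenate([gW.reshape(n, -1), gb], axis=1))
            if k > 0:
                delta = (delta @ W.T) * dacts[k - 1]
        # grads collected from last layer to first; reassemble in order
        flat = np.concatenate(list(reversed(grads)), axis=1)
        J[:, o, :] = flat
    return J.reshape(n * n_out, nw)


# ---------------------------------------------------------------------------
# training


def _standardize_fit(A: np.ndarray):
    mean = A.mean(axis=0)
    std = A.std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    return mean, std


def train(net: BayesNetState, X: np.ndarray, Y: np.ndarray) -> BayesNetState:
    """Train with LM steps and evidence re-estimation of alpha, beta, gamma.

    Inputs and targets are standardized with training-set statistics stored
    in the returned state; the accepted-objective trace is non-increasing.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        raise ValueError(f"row mismatch: X has {X.shape[0]}, Y has {Y.shape[0]}")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("non-finite entries in training data")
    cfg = net.config
    if X.shape[1] != cfg.layer_sizes[0] or Y.shape[1] != cfg.layer_sizes[-1]:
        raise ValueError(
            f"data dims {X.shape[1]}->{Y.shape[1]} do not match "
            f"config {cfg.layer_sizes[0]}->{cfg.layer_sizes[-1]}"
        )

    x_mean, x_std = _standardize_fit(X)
    y_mean, y_std = _standardize_fit(Y)
    Xs = (X - x_mean) / x_std
    Ys = (Y - y_mean) / y_std

    w = net.weights.copy()
    alpha, beta = float(net.alpha), float(net.beta)
    gamma = float(net.gamma)
    nw = w.size
    N = Ys.size
    mu = cfg.mu0
    eye = np.eye(nw)

    def objective(wv: np.ndarray):
        pred = _forward(wv, cfg.layer_sizes, Xs)[-1]
        r = (pred - Ys).ravel()
        ed = 0.5 * float(r @ r)
        ew = 0.5 * float(wv @ wv)
        return beta * ed + alpha * ew, ed, ew, r

    trace: list[float] = []
    trace_pairs: list[tuple[float, float]] = []
    stop = "max_epochs"
    for _ in range(cfg.max_epochs):
        # baseline objective under the current hyperparameters
        F0, ed, ew, r = objective(w)
        J = _jacobian(w, cfg.layer_sizes, Xs)
        jtj = J.T @ J
        g = beta * (J.T @ r) + alpha * w
        accepted = False
        while mu <= cfg.mu_max:
            H_damped = beta * jtj + (alpha + mu) * eye
            try:
                c = cho_factor(H_damped, lower=True)
                step = cho_solve(c, -g)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            w_new = w + step
            F_new, ed_new, ew_new, r_new = objective(w_new)
            if not np.isfinite(F_new):
                raise FloatingPointError("non-finite training objective")
            if F_new < F0:
                accepted = True
                w, ed, ew, r = w_new, ed_new, ew_new, r_new
                mu = max(mu * 0.1, 1e-12)
                break
            mu *= 10.0
        if not accepted:
            stop = "damping_ceiling"
            break
        trace.append(F_new)
        trace_pairs.append((F0, F_new))

        # evidence re-estimation at the accepted point
        if not cfg.bayes:
            if F0 - F_new < cfg.tolerance * max(1.0, abs(F0)):
                stop = "tolerance"
                break
            continue
        H = beta * jtj + alpha * eye
        try:
            cH = cho_factor(H, lower=True)
            tr_hinv = float(np.trace(cho_solve(cH, eye)))
        except np.linalg.LinAlgError:
            tr_hinv = float(np.trace(np.linalg.pinv(H)))
        gamma = float(np.clip(nw - alpha * tr_hinv, 0.0, nw))
        alpha = gamma / (2.0 * ew) if ew > 1e-12 else alpha
        alpha = float(np.clip(alpha, 0.0, 1e8))
        if ed > 1e-12:
            beta = float(np.clip((N - gamma) / (2.0 * ed), 1e-8, 1e12))

        if F0 - F_new < cfg.tolerance * max(1.0, abs(F0)):
            stop = "tolerance"
            break

    state = BayesNetState(
        config=cfg,
        weights=w,
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        trace=trace,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        y_std=y_std,
        trained=True,
        stop_reason=stop,
    )
    state.trace_pairs = trace_pairs
    return state


def predict(net: BayesNetState, X: np.ndarray) -> np.ndarray:
    """Deterministic forward pass on raw-scale inputs, returning raw-scale outputs."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    cfg = net.config
    if X.shape[1] != cfg.layer_sizes[0]:
        raise ValueError(
            f"input dim {X.shape[1]} does not match network input {cfg.layer_sizes[0]}"
        )
    if X.shape[0] == 0:
        return np.empty((0, cfg.layer_sizes[-1]))
    if net.x_mean is not None:
        Xs = (X - net.x_mean) / net.x_std
    else:
        Xs = X
    out = _forward(net.weights, cfg.layer_sizes, Xs)[-1]
    if net.y_mean is not None:
        out = out * net.y_std + net.y_mean
    return out


# ---------------------------------------------------------------------------
# serialization (JSON header + array payload)


def save_net(net: BayesNetState, path: str | Path) -> None:
    """Serialize to a portable .npz-free JSON container (schema v1)."""
    payload = {
        "schema": 1,
        "config": {
            "layer_sizes": list(net.config.layer_sizes),
            "max_epochs": net.config.max_epochs,
            "tolerance": net.config.tolerance,
            "seed": net.config.seed,
            "init_scale": net.config.init_scale,
            "mu0": net.config.mu0,
            "mu_max": net.config.mu_max,
            "bayes": net.config.bayes,
        },
        "alpha": net.alpha,
        "beta": net.beta,
        "gamma": net.gamma,
        "trained": net.trained,
        "stop_reason": net.stop_reason,
        "trace": list(map(float, net.trace)),
        "weights": net.weights.tolist(),
        "x_mean": None if net.x_mean is None else net.x_mean.tolist(),
        "x_std": None if net.x_std is None else net.x_std.tolist(),
        "y_mean": None if net.y_mean is None else net.y_mean.tolist(),
        "y_std": None if net.y_std is None else net.y_std.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_net(path: str | Path) -> BayesNetState:
    d = json.loads(Path(path).read_text())
    if d.get("schema") != 1:
        raise ValueError(f"unsupported model schema: {d.get('schema')}")
    cfg = NetConfig(
        layer_sizes=tuple(d["config"]["layer_sizes"]),
        max_epochs=d["config"]["max_epochs"],
        tolerance=d["config"]["tolerance"],
        seed=d["config"]["seed"],
        init_scale=d["config"]["init_scale"],
        mu0=d["config"]["mu0"],
        mu_max=d["config"]["mu_max"],
        bayes=d["config"].get("bayes", True),
    )
    opt = lambda v: None if v is None else np.asarray(v, dtype=float)
    return BayesNetState(
        config=cfg,
        weights=np.asarray(d["weights"], dtype=float),
        alpha=d["alpha"],
        beta=d["beta"],
        gamma=d["gamma"],
        trace=list(d["trace"]),
        x_mean=opt(d["x_mean"]),
        x_std=opt(d["x_std"]),
        y_mean=opt(d["y_mean"]),
        y_std=opt(d["y_std"]),
        trained=d["trained"],
        stop_reason=d.get("stop_reason"),
    )
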