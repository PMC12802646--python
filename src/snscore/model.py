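"""Zero-inflated negative-binomial autoencoder with a decorrelated bottleneck.

The network maps the standardized panel expression X' (cells x G) through a
32-unit ReLU encoder into a 2-unit tanh bottleneck, decodes through a 32-unit
ReLU layer, and emits three G-wide output heads parameterizing a ZINB
distribution per matrix entry: dropout probability pi (sigmoid), normalized
mean mu' (exp) and dispersion theta (exp).  The count-scale mean is
mu = size_factor * mu', so the latent representation is depth-independent.

The training objective is the mean ZINB negative log-likelihood over all
matrix entries plus ``lambda_penalty`` times the squared Pearson correlation
of the two bottleneck pre-activation vectors (h1, h2).  The penalty pushes
the two latent units to carry uncorrelated information, so that one can
specialize in the senescence signal.

Everything is implemented in numpy (float64) with analytic gradients and a
full-batch Adam optimizer; gradients are validated against finite
differences in the test suite.  All layers carry biases, giving
131*G + 194 trainable parameters for a G-gene panel (5,303 at G=39).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import gammaln, digamma, expit

__all__ = [
    "ModelConfig",
    "ZINBOutput",
    "FittedModel",
    "build_model",
    "count_parameters",
    "forward",
    "zinb_nll",
    "loss",
    "pearson",
    "train",
    "denoise_counts",
    "save_checkpoint",
    "load_checkpoint",
]

# numerical guards
_EPS = 1e-8
_EXP_CAP = 1e8
_LOG_LO = float(np.log(_EPS))
_LOG_HI = float(np.log(_EXP_CAP))

_WEIGHT_NAMES = (
    "W_E", "b_E", "W_B", "b_B", "W_D", "b_D",
    "W_pi", "b_pi", "W_m", "b_m", "W_t", "b_t",
)


@dataclass
class ModelConfig:
    """Architecture and optimization settings.

    ``bottleneck`` is 2 for the published scoring method (one senescence
    unit, one nuisance unit); the denoiser reuses the machinery with a wider
    bottleneck and no penalty.  ``lambda_penalty`` weighs the squared
    bottleneck correlation against the mean ZINB negative log-likelihood.
    """

    encoder_width: int = 32
    bottleneck: int = 2
    decoder_width: int = 32
    lambda_penalty: float = 1.0
    epochs: int = 300
    learning_rate: float = 0.005
    val_fraction: float = 0.10
    lr_patience: int = 10
    stop_patience: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.encoder_width, self.bottleneck, self.decoder_width) < 1:
            raise ValueError("layer widths must be >= 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")


@dataclass
class ZINBOutput:
    """Per-entry ZINB parameters: dropout pi, normalized mean mu', dispersion
    theta, and the count-scale mean mu = size_factor * mu'."""

    pi: np.ndarray
    mu_prime: np.ndarray
    theta: np.ndarray
    mu: np.ndarray


@dataclass
class FittedModel:
    """Weights, training history and bottleneck pre-activations.

    ``h_pre`` holds the bottleneck values before tanh for every cell the
    model was fitted on; column k is latent unit k.
    """

    weights: dict[str, np.ndarray]
    config: ModelConfig
    history: dict[str, list] = field(default_factory=dict)
    h_pre: np.ndarray | None = None
    panel_genes: np.ndarray | None = None

    @property
    def n_genes(self) -> int:
        return self.weights["W_E"].shape[0]

    @property
    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.weights.values()))

    def encode(self, x_prime: np.ndarray) -> np.ndarray:
        """Bottleneck pre-activations for new standardized input."""
        w = self.weights
        e = np.maximum(x_prime @ w["W_E"] + w["b_E"], 0.0)
        return e @ w["W_B"] + w["b_B"]


def count_parameters(n_genes: int, config: ModelConfig | None = None) -> int:
    """Trainable-parameter count from the layer shapes (weights + biases)."""
    c = config or ModelConfig()
    g, e, b, d = n_genes, c.encoder_width, c.bottleneck, c.decoder_width
    total = (g * e + e) + (e * b + b) + (b * d + d)
    total += 3 * (d * g + g)
    return total


def build_model(n_genes: int, config: ModelConfig | None = None) -> FittedModel:
    """Glorot-uniform initialized network for ``n_genes`` input genes."""
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    c = config or ModelConfig()
    rng = np.random.default_rng(c.seed)

    def glorot(fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    g, e, b, d = n_genes, c.encoder_width, c.bottleneck, c.decoder_width
    weights = {
        "W_E": glorot(g, e), "b_E": np.zeros(e),
        "W_B": glorot(e, b), "b_B": np.zeros(b),
        "W_D": glorot(b, d), "b_D": np.zeros(d),
        "W_pi": glorot(d, g), "b_pi": np.zeros(g),
        "W_m": glorot(d, g), "b_m": np.zeros(g),
        "W_t": glorot(d, g), "b_t": np.zeros(g),
    }
    return FittedModel(weights=weights, config=c)


def _forward_cache(weights: dict, x_prime: np.ndarray,
                   size_f: np.ndarray) -> dict:
    w = weights
    z1 = x_prime @ w["W_E"] + w["b_E"]
    e = np.maximum(z1, 0.0)
    h_pre = e @ w["W_B"] + w["b_B"]
    b = np.tanh(h_pre)
    z2 = b @ w["W_D"] + w["b_D"]
    d = np.maximum(z2, 0.0)
    a_pi = d @ w["W_pi"] + w["b_pi"]
    a_m = d @ w["W_m"] + w["b_m"]
    a_t = d @ w["W_t"] + w["b_t"]
    m_in = (a_m > _LOG_LO) & (a_m < _LOG_HI)
    t_in = (a_t > _LOG_LO) & (a_t < _LOG_HI)
    pi = np.clip(expit(a_pi), _EPS, 1.0 - _EPS)
    mu_prime = np.exp(np.clip(a_m, _LOG_LO, _LOG_HI))
    theta = np.exp(np.clip(a_t, _LOG_LO, _LOG_HI))
    mu = mu_prime * size_f[:, None]
    return dict(z1=z1, e=e, h_pre=h_pre, b=b, z2=z2, d=d,
                pi=pi, mu_prime=mu_prime, theta=theta, mu=mu,
                m_in=m_in, t_in=t_in)


def forward(model: FittedModel, x_prime: np.ndarray,
            size_factors: np.ndarray | None = None
            ) -> tuple[np.ndarray, ZINBOutput]:
    """Full forward pass; returns bottleneck pre-activations and ZINB params."""
    x_prime = np.asarray(x_prime, dtype=float)
    if x_prime.shape[1] != model.n_genes:
        raise ValueError(
            f"input has {x_prime.shape[1]} genes, model expects {model.n_genes}"
        )
    if size_factors is None:
        size_factors = np.ones(x_prime.shape[0])
    cache = _forward_cache(model.weights, x_prime, np.asarray(size_factors))
    out = ZINBOutput(pi=cache["pi"], mu_prime=cache["mu_prime"],
                     theta=cache["theta"], mu=cache["mu"])
    return cache["h_pre"], out


def zinb_nll(x: np.ndarray, pi: np.ndarray, mu: np.ndarray,
             theta: np.ndarray) -> np.ndarray:
    """Elementwise ZINB negative log-likelihood, computed in log space.

    The density is ``pi * 1{x=0} + (1-pi) * NB(x; mu, theta)`` with the
    negative binomial parameterized by mean ``mu`` and dispersion ``theta``:
    NB(x) = Gamma(x+theta) / (Gamma(theta) x!) * (theta/(theta+mu))^theta
            * (mu/(theta+mu))^x.
    """
    x = np.asarray(x, dtype=float)
    pi = np.asarray(pi, dtype=float)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if (pi < 0).any() or (pi > 1).any():
        raise ValueError("pi must lie in [0, 1]")
    if (mu <= 0).any() or (theta <= 0).any():
        raise ValueError("mu and theta must be positive")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    log_nb = (
        gammaln(x + theta) - gammaln(theta) - gammaln(x + 1.0)
        + theta * (np.log(theta) - np.log(theta + mu))
        + x * (np.log(mu) - np.log(theta + mu))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pi = np.log(pi)              # -inf at pi=0
        log_1mpi = np.log1p(-pi)         # -inf at pi=1
        zero_case = np.logaddexp(log_pi, log_1mpi + log_nb)
        # logaddexp(-inf, -inf) is -inf, as wanted; nan only from inf-inf
        zero_case = np.where(np.isnan(zero_case), log_nb, zero_case)
        nonzero_case = log_1mpi + log_nb
    ll = np.where(x == 0, zero_case, nonzero_case)
    return -ll


def pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation; 0.0 when either vector is constant."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    uc = u - u.mean()
    vc = v - v.mean()
    su = np.sqrt((uc ** 2).sum())
    sv = np.sqrt((vc ** 2).sum())
    if su < 1e-12 or sv < 1e-12:
        return 0.0
    return float((uc * vc).sum() / (su * sv))


def loss(
    x: np.ndarray,
    out: ZINBOutput,
    h_pre: np.ndarray,
    lambda_penalty: float = 1.0,
) -> tuple[float, float, float]:
    """Objective: mean entrywise ZINB NLL + lambda * rho(h1, h2)^2.

    Returns ``(total, nll_term, penalty_term)``.  The penalty uses the two
    bottleneck pre-activation columns; if either is constant the correlation
    is undefined and the penalty is 0 with a warning.
    """
    nll = float(np.mean(zinb_nll(x, out.pi, out.mu, out.theta)))
    h1, h2 = h_pre[:, 0], h_pre[:, 1]
    if np.std(h1) < 1e-12 or np.std(h2) < 1e-12:
        warnings.warn("constant bottleneck unit; penalty set to 0",
                      stacklevel=2)
        rho = 0.0
    else:
        rho = pearson(h1, h2)
    penalty = lambda_penalty * rho ** 2
    return nll + penalty, nll, penalty


def _nll_grads(x, cache):
    """d(mean NLL)/d(pre-activation) for the three output heads, un-normalized
    (caller divides by I*J)."""
    pi, mu, theta = cache["pi"], cache["mu"], cache["theta"]
    denom = theta + mu
    is_zero = x == 0
    log_nb0 = theta * (np.log(theta) - np.log(denom))
    p0 = np.exp(log_nb0)
    a = pi + (1.0 - pi) * p0
    w0 = (1.0 - pi) * p0 / a  # posterior weight of the NB branch at x=0

    # dropout head (pre-sigmoid)
    g_pi = np.where(is_zero, -pi * (1.0 - pi) * (1.0 - p0) / a, pi)
    # mean head (pre-exp); dmu/da_m = mu
    g_m = np.where(
        is_zero,
        w0 * mu * theta / denom,
        -(x - mu * (x + theta) / denom),
    )
    # dispersion head (pre-exp); dtheta/da_t = theta
    dnb_dtheta_common = np.log(theta / denom) + 1.0 - theta / denom
    dnb_dtheta = (
        digamma(x + theta) - digamma(theta)
        + dnb_dtheta_common - x / denom
    )
    g_t = np.where(
        is_zero,
        -w0 * theta * dnb_dtheta_common,
        -theta * dnb_dtheta,
    )
    g_m = np.where(cache["m_in"], g_m, 0.0)
    g_t = np.where(cache["t_in"], g_t, 0.0)
    return g_pi, g_m, g_t


def _penalty_grad_h(h_pre: np.ndarray, lam: float) -> np.ndarray:
    """Gradient of lambda*rho(h1,h2)^2 w.r.t. h_pre (zero if rho undefined)."""
    grad = np.zeros_like(h_pre)
    if h_pre.shape[1] != 2 or lam == 0.0:
        return grad
    u = h_pre[:, 0] - h_pre[:, 0].mean()
    v = h_pre[:, 1] - h_pre[:, 1].mean()
    su2, sv2 = (u ** 2).sum(), (v ** 2).sum()
    if su2 < 1e-24 or sv2 < 1e-24:
        return grad
    norm = np.sqrt(su2 * sv2)
    rho = (u * v).sum() / norm
    # centered inputs make these gradients mean-zero already
    grad[:, 0] = 2.0 * lam * rho * (v / norm - rho * u / su2)
    grad[:, 1] = 2.0 * lam * rho * (u / norm - rho * v / sv2)
    return grad


def _backward(weights, x, x_prime, cache, lam):
    """Analytic gradients of the full objective for one batch."""
    n, g = x.shape
    scale = 1.0 / (n * g)
    g_pi, g_m, g_t = _nll_grads(x, cache)
    g_pi = g_pi * scale
    g_m = g_m * scale
    g_t = g_t * scale

    d, b, e = cache["d"], cache["b"], cache["e"]
    grads = {
        "W_pi": d.T @ g_pi, "b_pi": g_pi.sum(axis=0),
        "W_m": d.T @ g_m, "b_m": g_m.sum(axis=0),
        "W_t": d.T @ g_t, "b_t": g_t.sum(axis=0),
    }
    grad_d = g_pi @ weights["W_pi"].T + g_m @ weights["W_m"].T \
        + g_t @ weights["W_t"].T
    grad_z2 = grad_d * (cache["z2"] > 0)
    grads["W_D"] = b.T @ grad_z2
    grads["b_D"] = grad_z2.sum(axis=0)
    grad_b = grad_z2 @ weights["W_D"].T
    grad_h = grad_b * (1.0 - b ** 2)
    grad_h = grad_h + _penalty_grad_h(cache["h_pre"], lam)
    grads["W_B"] = e.T @ grad_h
    grads["b_B"] = grad_h.sum(axis=0)
    grad_e = grad_h @ weights["W_B"].T
    grad_z1 = grad_e * (cache["z1"] > 0)
    grads["W_E"] = x_prime.T @ grad_z1
    grads["b_E"] = grad_z1.sum(axis=0)
    return grads


def objective_and_grads(model, x, x_prime, size_f, lam):
    """Total objective and its analytic gradient dict (for gradient checks)."""
    cache = _forward_cache(model.weights, x_prime, size_f)
    out = ZINBOutput(cache["pi"], cache["mu_prime"], cache["theta"],
                     cache["mu"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        total, nll, pen = loss(x, out, cache["h_pre"], lam)
    grads = _backward(model.weights, x, x_prime, cache, lam)
    return total, nll, pen, grads


def train(
    x: np.ndarray,
    x_prime: np.ndarray,
    size_factors: np.ndarray | None = None,
    config: ModelConfig | None = None,
    panel_genes: np.ndarray | None = None,
) -> FittedModel:
    """Fit the autoencoder with full-batch Adam, early stopping, LR halving.

    A seeded random 10% of cells is held out once before training; the
    validation metric is the mean ZINB NLL on those cells (the decorrelation
    penalty is excluded from it).  If the best validation loss fails to
    improve for ``lr_patience`` epochs the learning rate is halved; after
    ``stop_patience`` stagnant epochs training stops.  The weights from the
    best validation epoch are retained, and ``h_pre`` is recomputed on all
    cells with those weights.
    """
    c = config or ModelConfig()
    x = np.asarray(x, dtype=float)
    x_prime = np.asarray(x_prime, dtype=float)
    n_cells, n_genes = x.shape
    if x_prime.shape != x.shape:
        raise ValueError("x and x_prime must have identical shapes")
    if n_cells < 20:
        raise ValueError("at least 20 cells are required to train")
    if size_factors is None:
        size_factors = np.ones(n_cells)
    size_factors = np.asarray(size_factors, dtype=float)

    # salt the split stream so an equal seed elsewhere (e.g. in a data
    # generator) cannot yield a correlated permutation
    rng = np.random.default_rng([c.seed, 0x5EED])
    n_val = max(1, int(round(c.val_fraction * n_cells)))
    perm = rng.permutation(n_cells)
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    model = build_model(n_genes, c)
    w = model.weights
    adam_m = {k: np.zeros_like(v) for k, v in w.items()}
    adam_v = {k: np.zeros_like(v) for k, v in w.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = c.learning_rate

    xt, xpt, sft = x[train_idx], x_prime[train_idx], size_factors[train_idx]
    xv, xpv, sfv = x[val_idx], x_prime[val_idx], size_factors[val_idx]

    best_val = np.inf
    best_weights = {k: v.copy() for k, v in w.items()}
    since_best = 0
    history: dict[str, list] = {"train_loss": [], "val_loss": [], "lr": []}

    for epoch in range(1, c.epochs + 1):
        cache = _forward_cache(w, xpt, sft)
        nll = float(np.mean(zinb_nll(
            xt, cache["pi"], cache["mu"], cache["theta"])))
        if c.bottleneck == 2:
            rho = pearson(cache["h_pre"][:, 0], cache["h_pre"][:, 1])
        else:
            rho = 0.0
        train_loss = nll + c.lambda_penalty * rho ** 2
        grads = _backward(w, xt, xpt, cache,
                          c.lambda_penalty if c.bottleneck == 2 else 0.0)
        for k in w:
            adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * grads[k]
            adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * grads[k] ** 2
            mhat = adam_m[k] / (1 - beta1 ** epoch)
            vhat = adam_v[k] / (1 - beta2 ** epoch)
            w[k] -= lr * mhat / (np.sqrt(vhat) + eps)

        vc = _forward_cache(w, xpv, sfv)
        val_loss = float(np.mean(zinb_nll(
            xv, vc["pi"], vc["mu"], vc["theta"])))
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        history["lr"].append(lr)

        if val_loss < best_val:
            best_val = val_loss
            best_weights = {k: v.copy() for k, v in w.items()}
            since_best = 0
        else:
            since_best += 1
            if since_best >= c.stop_patience:
                break
            if since_best % c.lr_patience == 0:
                lr *= 0.5

    model.weights = best_weights
    model.history = history
    model.panel_genes = panel_genes
    model.h_pre = model.encode(x_prime)
    return model


def denoise_counts(
    counts: np.ndarray,
    seed: int = 0,
    bottleneck: int = 32,
    epochs: int = 150,
    learning_rate: float = 0.005,
) -> np.ndarray:
    """All-gene ZINB autoencoder denoiser: returns estimated count-scale
    means rounded to integers (no decorrelation penalty, wider bottleneck)."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=1)
    if (lib <= 0).any():
        raise ValueError("cells with zero library size cannot be denoised")
    sf = lib / np.median(lib)
    ln = np.log1p(counts / lib[:, None] * np.median(lib))
    means = ln.mean(axis=0)
    sds = ln.std(axis=0)
    safe = np.where(sds < 1e-12, 1.0, sds)
    xp = (ln - means) / safe
    xp[:, sds < 1e-12] = 0.0
    cfg = ModelConfig(bottleneck=bottleneck, lambda_penalty=0.0,
                      epochs=epochs, learning_rate=learning_rate, seed=seed)
    fitted = train(counts, xp, sf, cfg)
    _, out = forward(fitted, xp, sf)
    return np.rint(out.mu)


def save_checkpoint(model: FittedModel, path) -> None:
    """Single-archive checkpoint: weight arrays + JSON config + panel genes."""
    payload = {k: model.weights[k] for k in _WEIGHT_NAMES}
    payload["config_json"] = np.array(json.dumps(asdict(model.config)))
    if model.panel_genes is not None:
        payload["panel_genes"] = np.asarray(model.panel_genes, dtype=str)
    if model.h_pre is not None:
        payload["h_pre"] = model.h_pre
    np.savez(path, **payload)


def load_checkpoint(path) -> FittedModel:
    with np.load(path, allow_pickle=False) as z:
        weights = {k: z[k] for k in _WEIGHT_NAMES}
        config = ModelConfig(**json.loads(str(z["config_json"])))
        panel = z["panel_genes"] if "panel_genes" in z else None
        h_pre = z["h_pre"] if "h_pre" in z else None
    return FittedModel(weights=weights, config=config,
                       h_pre=h_pre, panel_genes=panel)
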