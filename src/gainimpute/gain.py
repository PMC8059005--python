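"""Generative adversarial imputation for mixed-type tables.

The generator maps ``[mean-filled encoded data , encoded mask]`` to an
imputation proposal in ``[0,1]^D`` (sigmoid on continuous columns, softmax
within each one-hot block); the discriminator maps ``[imputed data , hint]``
to per-entry observedness probabilities.  Compared with the original GAIN
construction this variant (a) feeds the column mean instead of random noise
at missing entries, (b) batch-normalizes the generator hidden layers, and
(c) splits the reconstruction loss into continuous and categorical terms
with separate weights alpha and beta, so mixed-type tables train in one
model.

Training alternates ``k`` discriminator steps with one generator step per
iteration on uniform random minibatches, and is bit-deterministic given the
config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._nn import MLP, Optimizer
from .encoding import MixedEncoder, mean_fill
from .schema import IncompleteTable, TableSchema

_EPS = 1e-8

logger = logging.getLogger("gainimpute.gain")

ACTIVATIONS = ("relu", "tanh")
OPTIMIZERS = ("sgd", "momentum", "adam")


@dataclass(frozen=True)
class GainConfig:
    """Hyperparameters of the adversarial imputer.

    ``k`` is the number of discriminator updates per generator update;
    ``p_hint`` the probability each variable's mask value is revealed to the
    discriminator; ``alpha`` and ``beta`` weight the continuous (squared
    error) and categorical (cross-entropy) reconstruction terms.
    ``neurons_per_layer=None`` means "encoded width D", resolved at fit time.
    """

    k: int = 1
    p_hint: float = 0.9
    alpha: float = 10.0
    beta: float = 10.0
    n_iterations: int = 5000
    hidden_layers: int = 2
    neurons_per_layer: int | None = None
    activation: str = "relu"
    learning_rate: float = 0.001
    optimizer: str = "adam"
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if not 0.0 <= self.p_hint <= 1.0:
            raise ValueError("p_hint must lie in [0,1]")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if self.hidden_layers < 1 or self.batch_size < 1:
            raise ValueError("hidden_layers and batch_size must be positive")
        if self.neurons_per_layer is not None and self.neurons_per_layer < 1:
            raise ValueError("neurons_per_layer must be positive")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {OPTIMIZERS}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainingTrace:
    d_loss: np.ndarray
    g_loss: np.ndarray

    def __len__(self) -> int:
        return len(self.d_loss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(len(self.d_loss)),
                "d_loss": self.d_loss,
                "g_loss": self.g_loss,
            }
        )


@dataclass
class GainModel:
    """Trained generator/discriminator plus the encoding they live in."""

    encoder: MixedEncoder
    generator: MLP = field(repr=False)
    discriminator: MLP = field(repr=False)
    fill_means: np.ndarray = field(repr=False)
    config: GainConfig
    cont_cols: np.ndarray = field(repr=False)
    cat_blocks: list[tuple[int, int]] = field(repr=False)


# ---------------------------------------------------------------------------
# layout helpers


def _layout(encoder: MixedEncoder) -> tuple[np.ndarray, list[tuple[int, int]]]:
    cont_cols, cat_blocks = [], []
    for (name, start, stop), v in zip(encoder.blocks_, encoder.schema):
        if v.is_continuous:
            cont_cols.append(start)
        else:
            cat_blocks.append((start, stop))
    return np.asarray(cont_cols, dtype=int), cat_blocks


def _head_forward(
    logits: np.ndarray, cont_cols: np.ndarray, cat_blocks: list[tuple[int, int]]
) -> np.ndarray:
    """Sigmoid on continuous columns, softmax within each one-hot block."""
    y = np.empty_like(logits)
    if len(cont_cols):
        y[:, cont_cols] = _sigmoid(logits[:, cont_cols])
    for start, stop in cat_blocks:
        z = logits[:, start:stop]
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        y[:, start:stop] = e / e.sum(axis=1, keepdims=True)
    return y


def _head_backward(
    dy: np.ndarray,
    y: np.ndarray,
    cont_cols: np.ndarray,
    cat_blocks: list[tuple[int, int]],
) -> np.ndarray:
    dlogits = np.zeros_like(dy)
    if len(cont_cols):
        yc = y[:, cont_cols]
        dlogits[:, cont_cols] = dy[:, cont_cols] * yc * (1.0 - yc)
    for start, stop in cat_blocks:
        s = y[:, start:stop]
        g = dy[:, start:stop]
        dlogits[:, start:stop] = s * (g - (g * s).sum(axis=1, keepdims=True))
    return dlogits


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# hint and losses


def sample_hint(
    mask: np.ndarray,
    p_hint: float,
    rng: np.random.Generator,
    blocks: list[tuple[str, int, int]],
) -> np.ndarray:
    """Draw a hint matrix H = B*M + 0.5*(1-B).

    B is Bernoulli(p_hint) per (row, variable) and replicated across each
    variable's encoded block, so the discriminator learns which *variables*
    were observed, not which one-hot columns.
    """
    if not 0.0 <= p_hint <= 1.0:
        raise ValueError("p_hint must lie in [0,1]")
    n = mask.shape[0]
    H = np.empty_like(mask, dtype=float)
    reveal = rng.random((n, len(blocks))) < p_hint
    for j, (_, start, stop) in enumerate(blocks):
        b = reveal[:, j : j + 1]
        H[:, start:stop] = np.where(b, mask[:, start:stop], 0.5)
    return H


def discriminator_loss(d_prob: np.ndarray, mask: np.ndarray) -> float:
    """Mean binary cross-entropy of observedness probabilities vs the mask."""
    p = np.clip(d_prob, _EPS, 1.0 - _EPS)
    m = np.asarray(mask, dtype=float)
    return float(-(m * np.log(p) + (1.0 - m) * np.log(1.0 - p)).mean())


def generator_loss(
    d_prob: np.ndarray,
    mask: np.ndarray,
    generated: np.ndarray,
    target: np.ndarray,
    cont_cols: np.ndarray,
    cat_blocks: list[tuple[int, int]],
    alpha: float,
    beta: float,
) -> float:
    """Adversarial term on missing entries plus weighted reconstruction.

    L = -mean_{missing entries} log p
        + alpha * (sum squared error over observed continuous entries)/count
        + beta  * (sum cross-entropy over observed categorical blocks)/count
    """
    m = np.asarray(mask, dtype=float)
    p = np.clip(d_prob, _EPS, 1.0 - _EPS)
    n_miss = (1.0 - m).sum()
    adv = float(-((1.0 - m) * np.log(p)).sum() / n_miss) if n_miss > 0 else 0.0
    mse = 0.0
    if len(cont_cols):
        mc = m[:, cont_cols]
        n_obs = mc.sum()
        if n_obs > 0:
            diff = (target[:, cont_cols] - generated[:, cont_cols]) ** 2
            mse = float((mc * diff).sum() / n_obs)
    ce = 0.0
    n_blocks = 0.0
    ce_sum = 0.0
    for start, stop in cat_blocks:
        mb = m[:, start]  # block observed as a whole
        g = np.clip(generated[:, start:stop], _EPS, None)
        x = target[:, start:stop]
        ce_sum += float((mb * -(x * np.log(g)).sum(axis=1)).sum())
        n_blocks += float(mb.sum())
    if n_blocks > 0:
        ce = ce_sum / n_blocks
    return adv + alpha * mse + beta * ce


# ---------------------------------------------------------------------------
# training


def train(data: IncompleteTable, config: GainConfig) -> tuple[GainModel, TrainingTrace]:
    """Train the adversarial imputer; bit-deterministic given config.seed."""
    encoder = MixedEncoder(data.schema).fit(data)
    X, M = encoder.encode(data)
    n, D = X.shape
    cont_cols, cat_blocks = _layout(encoder)

    counts = M.sum(axis=0)
    if (counts == 0).any():
        j = int(np.flatnonzero(counts == 0)[0])
        raise ValueError(f"encoded column {j} fully missing; cannot train")
    fill_means = (X * M).sum(axis=0) / counts
    X_fill = X * M + (1.0 - M) * fill_means

    neurons = config.neurons_per_layer if config.neurons_per_layer else D
    ss = np.random.SeedSequence(config.seed).generate_state(3)
    rng_g = np.random.default_rng(int(ss[0] % (2**31)))
    rng_d = np.random.default_rng(int(ss[1] % (2**31)))
    rng = np.random.default_rng(int(ss[2] % (2**31)))  # batching + hints

    G = MLP(2 * D, D, config.hidden_layers, neurons, config.activation, rng_g,
            batch_norm=True)
    Dnet = MLP(2 * D, D, config.hidden_layers, neurons, config.activation, rng_d,
               batch_norm=False)
    opt_g = Optimizer(G.params, config.optimizer, config.learning_rate)
    opt_d = Optimizer(Dnet.params, config.optimizer, config.learning_rate)

    batch = min(config.batch_size, n)
    d_trace = np.zeros(config.n_iterations)
    g_trace = np.zeros(config.n_iterations)

    for it in range(config.n_iterations):
        # --- k discriminator steps
        d_loss = np.nan
        for _ in range(config.k):
            idx = rng.integers(0, n, size=batch)
            Xb, Mb, Fb = X[idx], M[idx], X_fill[idx]
            y = _head_forward(G.forward(np.hstack([Fb, Mb]), train=True),
                              cont_cols, cat_blocks)
            x_hat = Mb * Xb + (1.0 - Mb) * y
            H = sample_hint(Mb, config.p_hint, rng, encoder.blocks_)
            d_logits = Dnet.forward(np.hstack([x_hat, H]), train=True)
            p = _sigmoid(d_logits)
            d_loss = discriminator_loss(p, Mb)
            Dnet.backward((p - Mb) / p.size)
            opt_d.step()

        # --- one generator step
        idx = rng.integers(0, n, size=batch)
        Xb, Mb, Fb = X[idx], M[idx], X_fill[idx]
        y = _head_forward(G.forward(np.hstack([Fb, Mb]), train=True),
                          cont_cols, cat_blocks)
        x_hat = Mb * Xb + (1.0 - Mb) * y
        H = sample_hint(Mb, config.p_hint, rng, encoder.blocks_)
        d_logits = Dnet.forward(np.hstack([x_hat, H]), train=True)
        p = _sigmoid(d_logits)
        g_loss = generator_loss(p, Mb, y, Xb, cont_cols, cat_blocks,
                                config.alpha, config.beta)

        dy = np.zeros_like(y)
        n_miss = (1.0 - Mb).sum()
        if n_miss > 0:
            # adversarial gradient flows through the discriminator input
            dp_logit = -(1.0 - Mb) * (1.0 - p) / n_miss
            d_in_grad = Dnet.backward(dp_logit)
            Dnet.zero_grad()  # discriminator is frozen in this step
            dy += d_in_grad[:, :D] * (1.0 - Mb)
        if len(cont_cols):
            mc = Mb[:, cont_cols]
            n_obs = mc.sum()
            if n_obs > 0:
                dy[:, cont_cols] += (
                    config.alpha * 2.0 * mc
                    * (y[:, cont_cols] - Xb[:, cont_cols]) / n_obs
                )
        n_blocks = sum(float(Mb[:, s].sum()) for s, _ in cat_blocks)
        if n_blocks > 0:
            for start, stop in cat_blocks:
                mb = Mb[:, start : start + 1]
                g_clip = np.clip(y[:, start:stop], _EPS, None)
                dy[:, start:stop] += (
                    config.beta * mb * (-Xb[:, start:stop] / g_clip) / n_blocks
                )
        G.backward(_head_backward(dy, y, cont_cols, cat_blocks))
        opt_g.step()

        if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
            raise FloatingPointError(
                f"non-finite loss at iteration {it}: d={d_loss}, g={g_loss}"
            )
        d_trace[it] = d_loss
        g_trace[it] = g_loss
        if (it + 1) % 1000 == 0:
            logger.info(
                "iteration %d: d_loss=%.4f g_loss=%.4f", it + 1, d_loss, g_loss
            )

    model = GainModel(
        encoder=encoder,
        generator=G,
        discriminator=Dnet,
        fill_means=fill_means,
        config=config,
        cont_cols=cont_cols,
        cat_blocks=cat_blocks,
    )
    return model, TrainingTrace(d_loss=d_trace, g_loss=g_trace)


def impute(model: GainModel, data: IncompleteTable) -> pd.DataFrame:
    """Impute missing cells; observed cells are copied through exactly."""
    if data.schema != model.encoder.schema:
        raise ValueError("data schema does not match the trained model")
    X, M = model.encoder.encode(data)
    X_fill = X * M + (1.0 - M) * model.fill_means
    logits = model.generator.forward(np.hstack([X_fill, M]), train=False)
    y = _head_forward(logits, model.cont_cols, model.cat_blocks)
    x_hat = M * X + (1.0 - M) * y
    out = model.encoder.decode(x_hat)
    for j, v in enumerate(data.schema):
        obs = data.mask[:, j]
        col = out[v.name].to_numpy(object if v.is_categorical else float)
        col[obs] = data.values[v.name].to_numpy()[obs]
        out[v.name] = col
    return out


def multiple_impute(
    data: IncompleteTable,
    config: GainConfig,
    m: int = 100,
    return_traces: bool = False,
) -> list[pd.DataFrame] | tuple[list[pd.DataFrame], list[TrainingTrace]]:
    """Repeat train+impute with independently derived seeds (default m=100)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    seeds = np.random.SeedSequence(config.seed).generate_state(m)
    out, traces = [], []
    for s in seeds:
        model, trace = train(data, replace(config, seed=int(s % (2**31))))
        out.append(impute(model, data))
        traces.append(trace)
    if return_traces:
        return out, traces
    return out


# ---------------------------------------------------------------------------
# estimator


class GAINImputer(BaseEstimator, TransformerMixin):
    """Adversarial imputer with a scikit-learn fit/transform surface.

    Operates on pandas DataFrames using NaN as the missing sentinel; the
    mixed-type schema is supplied at construction.

    Examples
    --------
    >>> imp = GAINImputer(schema, n_iterations=2000, seed=0)
    >>> completed = imp.fit_transform(df_with_nans)
    """

    def __init__(
        self,
        schema: TableSchema | None = None,
        k: int = 1,
        p_hint: float = 0.9,
        alpha: float = 10.0,
        beta: float = 10.0,
        n_iterations: int = 5000,
        hidden_layers: int = 2,
        neurons_per_layer: int | None = None,
        activation: str = "relu",
        learning_rate: float = 0.001,
        optimizer: str = "adam",
        batch_size: int = 128,
        seed: int = 0,
    ):
        self.schema = schema
        self.k = k
        self.p_hint = p_hint
        self.alpha = alpha
        self.beta = beta
        self.n_iterations = n_iterations
        self.hidden_layers = hidden_layers
        self.neurons_per_layer = neurons_per_layer
        self.activation = activation
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.batch_size = batch_size
        self.seed = seed

    def _config(self) -> GainConfig:
        kwargs = {
            f.name: getattr(self, f.name) for f in fields(GainConfig)
        }
        return GainConfig(**kwargs)

    def fit(self, X: pd.DataFrame, y=None) -> "GAINImputer":
        if self.schema is None:
            raise ValueError("GAINImputer requires a schema")
        data = IncompleteTable.from_dataframe(X, self.schema)
        self.model_, self.trace_ = train(data, self._config())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "model_"):
            raise RuntimeError("GAINImputer is not fitted")
        data = IncompleteTable.from_dataframe(X, self.schema)
        return impute(self.model_, data)
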