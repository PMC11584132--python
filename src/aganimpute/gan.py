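"""Attribute-aware generative-adversarial imputation (AGAN).

The imputer plays the usual two-network game on the min-max-normalized
table.  The generator receives the noise-filled matrix

    Z = M * X + (1 - M) * N,      N ~ U[noise_low, noise_high],

concatenated with the mask ``M`` (input width ``2d``), and emits a complete
candidate matrix ``X_bar`` through a sigmoid output.  The discriminator
sees the composite ``X_hat = M * X + (1 - M) * X_bar`` and scores every
cell with the probability that it is observed rather than generated — no
hint/prompt matrix is used.  Losses:

* discriminator: masked binary cross-entropy against ``M`` plus
  ``lambda_gp`` times a gradient penalty keeping the critic's input
  gradient norm near 1,
* generator: ``-log D`` on the missing cells plus ``alpha`` times the mean
  squared reconstruction error on the observed cells.

Training alternates Adam steps — one discriminator update every
``d_update_period`` generator updates — after a generator-only
reconstruction pretraining phase.  The finished generator fills the whole
table once; observed cells are kept verbatim and every filled cell in a
binary or nominal column is projected to the nearest member of that
column's category set, so the completed table is type-valid by
construction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .networks import MLP, Adam, swish
from .table import (
    AttributeVector,
    MaskMatrix,
    MixedTypeTable,
    NormalizationParams,
    REAL,
    ShapeMismatchError,
    build_mask,
    denormalize,
    infer_attributes,
    normalize,
)

__all__ = [
    "TrainingConfig",
    "ImputationResult",
    "TrainingDivergedError",
    "swish",
    "assemble_input",
    "attribute_projection",
    "compose_imputed",
    "d_loss",
    "g_loss",
    "gradient_penalty",
    "train",
    "impute",
    "AGANImputer",
]

_EPS = 1e-7  # clamp for discriminator probabilities before logs


class TrainingDivergedError(RuntimeError):
    """A loss became non-finite; carries the iteration index."""

    def __init__(self, iteration: int, what: str):
        self.iteration = iteration
        super().__init__(f"non-finite {what} at iteration {iteration}")


@dataclass
class TrainingConfig:
    """All AGAN hyperparameters.

    ``epochs`` counts passes over the data; the adversarial loop runs
    ``epochs * ceil(n / batch_size)`` generator updates (``n_iter``
    overrides that count directly when set).  ``noise_dim`` sizes an
    optional extra uniform-noise input channel appended to the generator
    input; it is unused (0-weight) by default.
    """

    alpha: float = 10.0
    lambda_gp: float = 10.0
    batch_size: int = 128
    epochs: int = 200
    pretrain_epochs: int = 30
    d_update_period: int = 8
    learning_rate: float = 1e-6
    hidden_units: int = 64
    n_hidden_layers: int = 2
    noise_dim: int = 64
    noise_low: float = -0.01
    noise_high: float = 0.01
    swish_beta: float | str = 1.0
    seed: int = 0
    n_iter: int | None = None

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.lambda_gp < 0:
            raise ValueError("alpha and lambda_gp must be nonnegative")
        if self.batch_size < 1 or self.d_update_period < 1:
            raise ValueError("batch_size and d_update_period must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.noise_low > self.noise_high:
            raise ValueError("noise_low must not exceed noise_high")
        if isinstance(self.swish_beta, str) and self.swish_beta != "learned":
            raise ValueError("swish_beta must be a number or 'learned'")

    def iterations_for(self, n: int) -> int:
        if self.n_iter is not None:
            return int(self.n_iter)
        return int(self.epochs * int(np.ceil(n / self.batch_size)))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "TrainingConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:10]


@dataclass
class ImputationResult:
    """A completed table plus training provenance."""

    x_hat: MixedTypeTable
    x_bar: np.ndarray
    x_composite_norm: np.ndarray
    mask: MaskMatrix
    attributes: AttributeVector
    norm_params: NormalizationParams
    g_loss_trace: list[float] = field(default_factory=list)
    d_loss_trace: list[float] = field(default_factory=list)
    pretrain_loss_trace: list[float] = field(default_factory=list)
    config: TrainingConfig = field(default_factory=TrainingConfig)


# ---------------------------------------------------------------------------
# elementwise building blocks
# ---------------------------------------------------------------------------

def assemble_input(x_norm: np.ndarray, m: np.ndarray, noise: np.ndarray) -> np.ndarray:
    """Noise-filled generator input ``Z``: observed cells keep their value,
    missing cells carry fresh uniform noise."""
    x_norm, m, noise = (np.asarray(a, dtype=float) for a in (x_norm, m, noise))
    if not (x_norm.shape == m.shape == noise.shape):
        raise ShapeMismatchError(
            f"shapes disagree: {x_norm.shape}, {m.shape}, {noise.shape}"
        )
    x_filled = np.where(np.isnan(x_norm), 0.0, x_norm)
    return m * x_filled + (1.0 - m) * noise


def attribute_projection(x: np.ndarray, a: AttributeVector) -> np.ndarray:
    """Snap every value in a binary/nominal column to the nearest category.

    Real columns pass through unchanged; the mapping is idempotent.
    """
    x = np.array(x, dtype=float)
    for j in a.categorical_columns():
        cats = a.category_sets[j]
        idx = np.abs(x[:, [j]] - cats[None, :]).argmin(axis=1)
        x[:, j] = cats[idx]
    return x


def compose_imputed(
    x_norm: MixedTypeTable,
    x_bar: np.ndarray,
    m: MaskMatrix,
    a: AttributeVector,
    p: NormalizationParams,
    x_original: MixedTypeTable | None = None,
) -> ImputationResult:
    """Combine observed data with generated fills and return the completed
    table on the original scale.

    The normalized composite is ``M*X + (1-M)*X_bar``; it is denormalized,
    attribute-projected, and — when the raw input is supplied — its observed
    cells are overwritten with the original values so they are preserved
    bit for bit.
    """
    x_bar = np.asarray(x_bar, dtype=float)
    if x_bar.shape != x_norm.values.shape or m.m.shape != x_bar.shape:
        raise ShapeMismatchError("x_bar / mask shape does not match table")
    mm = m.m.astype(float)
    x_obs = np.where(np.isnan(x_norm.values), 0.0, x_norm.values)
    composite = mm * x_obs + (1.0 - mm) * x_bar
    full = denormalize(MixedTypeTable(composite, list(x_norm.column_names)), p)
    projected = attribute_projection(full.values, a)
    if x_original is not None:
        obs = m.m == 1
        projected[obs] = x_original.values[obs]
    return ImputationResult(
        x_hat=MixedTypeTable(projected, list(x_norm.column_names)),
        x_bar=x_bar,
        x_composite_norm=composite,
        mask=m,
        attributes=a,
        norm_params=p,
    )


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def d_loss(d_out: np.ndarray, m: np.ndarray) -> float:
    """Masked binary cross-entropy of per-cell discriminator probabilities
    against the observedness labels ``M``."""
    d_out = np.clip(np.asarray(d_out, dtype=float), _EPS, 1.0 - _EPS)
    m = np.asarray(m, dtype=float)
    if d_out.shape != m.shape:
        raise ShapeMismatchError("d_out / mask shapes disagree")
    return float(-np.mean(m * np.log(d_out) + (1.0 - m) * np.log(1.0 - d_out)))


def g_loss(
    d_out: np.ndarray,
    m: np.ndarray,
    x_norm: np.ndarray,
    x_bar: np.ndarray,
    alpha: float,
) -> float:
    """Generator objective: fool the critic on missing cells and
    reconstruct the observed cells.

    ``-mean_{m=0} log D`` (0 when the batch has no missing cell) plus
    ``alpha * mean_{m=1} (x - x_bar)^2``.
    """
    d_out = np.clip(np.asarray(d_out, dtype=float), _EPS, 1.0 - _EPS)
    m = np.asarray(m, dtype=float)
    x_norm = np.where(np.isnan(x_norm), 0.0, np.asarray(x_norm, dtype=float))
    x_bar = np.asarray(x_bar, dtype=float)
    miss = 1.0 - m
    n_miss = miss.sum()
    adv = float(-(miss * np.log(d_out)).sum() / n_miss) if n_miss else 0.0
    n_obs = m.sum()
    rec = float((m * (x_norm - x_bar) ** 2).sum() / n_obs) if n_obs else 0.0
    return adv + alpha * rec


def gradient_penalty(dnet: MLP, x_hat_norm: np.ndarray) -> float:
    """Mean over rows of ``(||grad_x critic_score|| - 1)^2`` where the
    critic score of a row is its summed pre-sigmoid discriminator logit."""
    penalty, _ = dnet.gradient_penalty(np.asarray(x_hat_norm, dtype=float))
    return penalty


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _beta_mode(cfg: TrainingConfig) -> tuple[float, bool]:
    if cfg.swish_beta == "learned":
        return 1.0, True
    return float(cfg.swish_beta), False


def _build_networks(d: int, cfg: TrainingConfig, rng: np.random.Generator):
    beta0, learn = _beta_mode(cfg)
    hidden = [cfg.hidden_units] * cfg.n_hidden_layers
    gen = MLP([2 * d, *hidden, d], rng, "sigmoid", beta0, learn)
    disc = MLP([d, *hidden, d], rng, "sigmoid", beta0, learn)
    return gen, disc


def _check_finite(value: float, iteration: int, what: str) -> float:
    if not np.isfinite(value):
        raise TrainingDivergedError(iteration, what)
    return value


def train(
    x: MixedTypeTable,
    m: MaskMatrix,
    a: AttributeVector,
    cfg: TrainingConfig,
):
    """Run the adversarial training loop on a (normalized) table.

    Returns ``(generator, discriminator, traces)`` where ``traces`` is a
    dict with ``pretrain``, ``g`` and ``d`` loss sequences.  Fully
    deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n, d = x.n, x.d
    x_vals = np.where(np.isnan(x.values), 0.0, x.values)
    mm = m.m.astype(float)
    if (mm.sum(axis=0) < 1).any():
        raise ValueError("every column needs >= 1 observed cell")
    gen, disc = _build_networks(d, cfg, rng)
    opt_g = Adam(gen.parameters(), cfg.learning_rate)
    opt_d = Adam(disc.parameters(), cfg.learning_rate)
    mb = min(cfg.batch_size, n)

    def sample_batch():
        idx = rng.choice(n, size=mb, replace=False)
        xb, mb_ = x_vals[idx], mm[idx]
        noise = rng.uniform(cfg.noise_low, cfg.noise_high, size=xb.shape)
        z = mb_ * xb + (1.0 - mb_) * noise
        return xb, mb_, np.concatenate([z, mb_], axis=1)

    traces = {"pretrain": [], "g": [], "d": []}

    # generator-only pretraining on the observed-cell reconstruction loss
    n_batches = int(np.ceil(n / mb))
    for epoch in range(cfg.pretrain_epochs):
        for _ in range(n_batches):
            xb, mb_, g_in = sample_batch()
            x_bar, cache = gen.forward(g_in, cache=True)
            n_obs = mb_.sum()
            loss = float((mb_ * (xb - x_bar) ** 2).sum() / n_obs) if n_obs else 0.0
            traces["pretrain"].append(_check_finite(loss, epoch, "pretrain loss"))
            grad_out = 2.0 * mb_ * (x_bar - xb) / max(n_obs, 1.0)
            grads, _ = gen.backward(cache, grad_out=grad_out)
            gen.set_parameters(opt_g.step(gen.parameters(), grads))

    n_iter = cfg.iterations_for(n)
    for it in range(n_iter):
        xb, mb_, g_in = sample_batch()

        if it % cfg.d_update_period == 0:
            x_bar = gen.forward(g_in)
            x_hat = mb_ * xb + (1.0 - mb_) * x_bar
            d_out, cache_d = disc.forward(x_hat, cache=True)
            bce = d_loss(d_out, mb_)
            # BCE-with-logits gradient (clamp-free and numerically stable)
            grad_logits = (d_out - mb_) / d_out.size
            grads_bce, _ = disc.backward(cache_d, grad_logits=grad_logits)
            gp, grads_gp = disc.gradient_penalty(x_hat)
            grads = [gb + cfg.lambda_gp * gg for gb, gg in zip(grads_bce, grads_gp)]
            traces["d"].append(
                _check_finite(bce + cfg.lambda_gp * gp, it, "discriminator loss")
            )
            disc.set_parameters(opt_d.step(disc.parameters(), grads))

        x_bar, cache_g = gen.forward(g_in, cache=True)
        x_hat = mb_ * xb + (1.0 - mb_) * x_bar
        d_out, cache_d = disc.forward(x_hat, cache=True)
        loss_g = g_loss(d_out, mb_, xb, x_bar, cfg.alpha)
        traces["g"].append(_check_finite(loss_g, it, "generator loss"))

        miss = 1.0 - mb_
        n_miss = miss.sum()
        if n_miss:
            # d(-log D)/d logit = D - 1 on missing cells
            grad_logits_d = miss * (np.clip(d_out, _EPS, 1 - _EPS) - 1.0) / n_miss
            _, grad_xhat = disc.backward(cache_d, grad_logits=grad_logits_d)
            grad_xbar = grad_xhat * miss
        else:
            grad_xbar = np.zeros_like(x_bar)
        n_obs = mb_.sum()
        if n_obs:
            grad_xbar = grad_xbar + cfg.alpha * 2.0 * mb_ * (x_bar - xb) / n_obs
        grads_g, _ = gen.backward(cache_g, grad_out=grad_xbar)
        gen.set_parameters(opt_g.step(gen.parameters(), grads_g))

    return gen, disc, traces


def impute(x: MixedTypeTable, cfg: TrainingConfig | None = None) -> ImputationResult:
    """End-to-end imputation of a table with missing cells.

    Orchestrates mask construction, attribute inference, normalization,
    adversarial training, a final full-table generator pass, composition,
    denormalization and attribute projection.  A complete input is returned
    unchanged with empty loss traces.
    """
    cfg = cfg or TrainingConfig()
    mask = build_mask(x)
    attrs = infer_attributes(x)
    if x.n_missing == 0:
        x_norm, params = normalize(x, mask)
        res = ImputationResult(
            x_hat=x.copy(),
            x_bar=x_norm.values.copy(),
            x_composite_norm=x_norm.values.copy(),
            mask=mask,
            attributes=attrs,
            norm_params=params,
            config=cfg,
        )
        return res
    x_norm, params = normalize(x, mask)
    gen, disc, traces = train(x_norm, mask, attrs, cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    noise = rng.uniform(cfg.noise_low, cfg.noise_high, size=x_norm.values.shape)
    z = assemble_input(x_norm.values, mask.m, noise)
    x_bar = gen.forward(np.concatenate([z, mask.m.astype(float)], axis=1))
    res = compose_imputed(x_norm, x_bar, mask, attrs, params, x_original=x)
    res.g_loss_trace = traces["g"]
    res.d_loss_trace = traces["d"]
    res.pretrain_loss_trace = traces["pretrain"]
    res.config = cfg
    return res


# ---------------------------------------------------------------------------
# estimator front end
# ---------------------------------------------------------------------------

class AGANImputer(BaseEstimator, TransformerMixin):
    """Scikit-learn style front end for AGAN imputation.

    ``fit`` trains the adversarial pair on a matrix with ``NaN`` missing
    markers; ``transform`` fills a matrix of the same width using the
    trained generator.  ``fit_transform`` on one matrix is the canonical
    single-table usage.

    Parameters mirror :class:`TrainingConfig`.

    Attributes
    ----------
    generator_, discriminator_ : MLP
        Trained networks (absent when ``fit`` saw a complete matrix).
    attributes_ : AttributeVector
        Inferred per-column type codes and category sets.
    norm_params_ : NormalizationParams
        Min-max statistics of the training data's observed cells.
    g_loss_trace_, d_loss_trace_, pretrain_loss_trace_ : list of float
    """

    def __init__(
        self,
        alpha: float = 10.0,
        lambda_gp: float = 10.0,
        batch_size: int = 128,
        epochs: int = 200,
        pretrain_epochs: int = 30,
        d_update_period: int = 8,
        learning_rate: float = 1e-6,
        hidden_units: int = 64,
        n_hidden_layers: int = 2,
        noise_dim: int = 64,
        noise_low: float = -0.01,
        noise_high: float = 0.01,
        swish_beta: float | str = 1.0,
        seed: int = 0,
        n_iter: int | None = None,
    ):
        self.alpha = alpha
        self.lambda_gp = lambda_gp
        self.batch_size = batch_size
        self.epochs = epochs
        self.pretrain_epochs = pretrain_epochs
        self.d_update_period = d_update_period
        self.learning_rate = learning_rate
        self.hidden_units = hidden_units
        self.n_hidden_layers = n_hidden_layers
        self.noise_dim = noise_dim
        self.noise_low = noise_low
        self.noise_high = noise_high
        self.swish_beta = swish_beta
        self.seed = seed
        self.n_iter = n_iter

    def _config(self) -> TrainingConfig:
        return TrainingConfig(**{
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(TrainingConfig)
        })

    @staticmethod
    def _as_table(X) -> MixedTypeTable:
        if isinstance(X, MixedTypeTable):
            return X
        if hasattr(X, "columns"):  # DataFrame
            return MixedTypeTable(np.asarray(X, dtype=float), list(X.columns))
        X = np.asarray(X, dtype=float)
        return MixedTypeTable(X, [f"x{j}" for j in range(X.shape[1])])

    def fit(self, X, y=None):
        table = self._as_table(X)
        cfg = self._config()
        self.n_features_in_ = table.d
        self.config_ = cfg
        mask = build_mask(table)
        self.attributes_ = infer_attributes(table)
        x_norm, self.norm_params_ = normalize(table, mask)
        if table.n_missing == 0:
            self.generator_ = None
            self.discriminator_ = None
            self.g_loss_trace_ = []
            self.d_loss_trace_ = []
            self.pretrain_loss_trace_ = []
            return self
        gen, disc, traces = train(x_norm, mask, self.attributes_, cfg)
        self.generator_, self.discriminator_ = gen, disc
        self.g_loss_trace_ = traces["g"]
        self.d_loss_trace_ = traces["d"]
        self.pretrain_loss_trace_ = traces["pretrain"]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "n_features_in_"):
            raise RuntimeError("AGANImputer is not fitted")
        table = self._as_table(X)
        if table.d != self.n_features_in_:
            raise ShapeMismatchError(
                f"fitted on {self.n_features_in_} columns, got {table.d}"
            )
        return self.imputation_result(table).x_hat.values

    def imputation_result(self, X) -> ImputationResult:
        """Full provenance of a transform: completed table, raw generator
        output, mask, traces."""
        table = self._as_table(X)
        mask = build_mask(table)
        p = self.norm_params_
        span = np.where(p.span == 0, 1.0, p.span)
        x_norm = MixedTypeTable(
            (table.values - p.col_min) / span, list(table.column_names)
        )
        if table.n_missing == 0 or self.generator_ is None:
            res = ImputationResult(
                x_hat=table.copy(),
                x_bar=x_norm.values.copy(),
                x_composite_norm=np.where(np.isnan(x_norm.values), 0.0, x_norm.values),
                mask=mask,
                attributes=self.attributes_,
                norm_params=p,
                config=self.config_,
            )
            return res
        rng = np.random.default_rng(self.config_.seed + 1)
        noise = rng.uniform(
            self.config_.noise_low, self.config_.noise_high, size=table.values.shape
        )
        z = assemble_input(x_norm.values, mask.m, noise)
        x_bar = self.generator_.forward(
            np.concatenate([z, mask.m.astype(float)], axis=1)
        )
        res = compose_imputed(
            x_norm, x_bar, mask, self.attributes_, p, x_original=table
        )
        res.g_loss_trace = self.g_loss_trace_
        res.d_loss_trace = self.d_loss_trace_
        res.pretrain_loss_trace = self.pretrain_loss_trace_
        res.config = self.config_
        return res

    def save(self, path) -> None:
        """Persist the trained networks and scaling state to an ``.npz``
        archive (keys ``gen/W0`` ... ``disc/b2``, ``col_min`` ...)."""
        if getattr(self, "generator_", None) is None:
            raise RuntimeError("nothing to save: fit on incomplete data first")
        arrays = {f"gen/{k}": v for k, v in self.generator_.state_dict().items()}
        arrays |= {f"disc/{k}": v for k, v in self.discriminator_.state_dict().items()}
        arrays["col_min"] = self.norm_params_.col_min
        arrays["col_max"] = self.norm_params_.col_max
        arrays["attr_codes"] = self.attributes_.codes
        arrays["config_json"] = np.frombuffer(
            json.dumps(self.config_.to_dict()).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)
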