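"""The two-stage relational reasoning network (RRN).

For n input landmarks the network holds n(n-1) *pairwise* relational units
g_theta — one independent parameter block per ordered pair (i, j) — and n
*global* relational units f_phi_i, one per input landmark.  The forward pass
is

    G_i   = mean_{j != i} g_theta_ij( features(o_i, o_j) )
    pred  = (1/n) sum_i f_phi_i(G_i)

so there are n^2 relational units in total.  Each f_phi_i emits the stacked
3D coordinates of all m target landmarks (as offsets from the menton
reference, an internal parametrization; predictions are absolute pixel
coordinates).  Training minimizes the mean squared distance between every
per-input prediction and the ground truth (averaged over the n inputs and m
targets), optionally plus a KL penalty from variational dropout.

Two relational-unit architectures are provided: a three-layer MLP with two
batch normalizations and two ReLUs, and a dense-block unit (one block of
`db_layers` 1-D convolutions with growth rate `db_growth` over the projected
feature sequence, with concatenation), selected via `RUSpec.ru_type`.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .autodiff import Tensor, concat
from .features import FEATURE_DIM, feature_batch, feature_tensor, ordered_pairs
from .landmarks import (ConfigurationSpec, ConfigurationError, DataError,
                        Landmark, LandmarkCase, ValidationError, VOCABULARY)

__all__ = [
    "DropoutSpec",
    "RUSpec",
    "RRNModel",
    "PredictionSet",
    "build_rrn",
    "predict",
    "rrn_loss",
    "targeted_dropout_mask",
    "variational_dropout_layer",
    "VariationalDropout",
    "count_relational_units",
    "save_checkpoint",
    "load_checkpoint",
    "substream",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible child stream of the master seed."""
    tag = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DropoutSpec:
    """Dropout variant applied inside every relational unit.

    variant 'regular' masks hidden activations at `rate`; 'variational'
    multiplies hidden activations by learnable-variance Gaussian noise with a
    KL penalty; 'targeted' stochastically zeroes, at rate `alpha`, weights
    from the gamma-fraction of smallest magnitude in each weight matrix.
    """

    variant: str = "none"
    rate: float = 0.5
    gamma: float = 0.5
    alpha: float = 0.5
    kl_weight: float = 1e-4

    def __post_init__(self):
        if self.variant not in ("none", "regular", "variational", "targeted"):
            raise ValidationError(f"unknown dropout variant {self.variant!r}")
        for name in ("rate", "gamma", "alpha"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"dropout {name} must be in [0,1], got {v}")


@dataclass(frozen=True)
class RUSpec:
    """Architecture of one relational unit (shared shape, unshared weights)."""

    ru_type: str = "mlp"
    relation_dim: int = 256
    mlp_hidden: Tuple[int, int] = (256, 256)
    db_layers: int = 4
    db_growth: int = 4
    dropout: DropoutSpec = field(default_factory=DropoutSpec)
    dtype: str = "float32"

    def __post_init__(self):
        if self.ru_type not in ("mlp", "dense_block"):
            raise ValidationError(f"unknown ru_type {self.ru_type!r}")
        if self.relation_dim < 1:
            raise ValidationError("relation_dim must be >= 1")
        if self.dtype not in ("float32", "float64"):
            raise ValidationError("dtype must be float32 or float64")


# ---------------------------------------------------------------------------
# targeted dropout
# ---------------------------------------------------------------------------

def targeted_dropout_mask(weights: Sequence[float], gamma: float, alpha: float,
                          seed: Optional[int] = None,
                          rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Keep/drop mask (1 = keep, 0 = drop) for magnitude-targeted dropout.

    The target set is the floor(gamma * |W|) weights of smallest absolute
    magnitude (ties broken by index); each is dropped independently with
    probability alpha.  Weights outside the target set are never dropped.
    """
    w = np.asarray(weights, dtype=float).reshape(-1)
    if not (0.0 <= gamma <= 1.0 and 0.0 <= alpha <= 1.0):
        raise ValidationError("gamma and alpha must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    mask = np.ones(w.size)
    k = int(np.floor(gamma * w.size))
    if k == 0:
        return mask
    target = np.argsort(np.abs(w), kind="stable")[:k]
    dropped = rng.random(k) < alpha
    mask[target[dropped]] = 0.0
    return mask


# ---------------------------------------------------------------------------
# stacked layers (leading axis = unit index; parameter blocks are unshared)
# ---------------------------------------------------------------------------

class _Context:
    """Per-forward state: train/eval mode, noise stream, KL accumulator."""

    def __init__(self, train: bool, rng: Optional[np.random.Generator] = None,
                 weight_masks: Optional[Mapping[int, np.ndarray]] = None,
                 collect_stats: bool = False):
        self.train = train
        self.rng = rng
        self.weight_masks = weight_masks or {}
        self.kl_terms: List[Tensor] = []
        self.collect_stats = collect_stats


class _Linear:
    def __init__(self, units: int, d_in: int, d_out: int, rng: np.random.Generator,
                 name: str, dtype=np.float64):
        scale = np.sqrt(2.0 / d_in)
        self.W = Tensor(rng.normal(0.0, scale, size=(units, d_in, d_out)).astype(dtype),
                        requires_grad=True)
        self.b = Tensor(np.zeros((units, 1, d_out), dtype=dtype), requires_grad=True)
        self.name = name

    def params(self):
        return [(f"{self.name}.W", self.W), (f"{self.name}.b", self.b)]

    def weight_tensors(self):
        return [self.W]

    def __call__(self, x: Tensor, ctx: _Context) -> Tensor:
        W = self.W
        mask = ctx.weight_masks.get(id(self.W))
        if mask is not None:
            W = W * Tensor(mask)
        return x @ W + self.b


class _BatchNorm:
    """Per-unit, per-feature batch normalization over the batch axis."""

    # eps is large enough that float32 rounding on raw pixel-scale inputs
    # (values ~1e2) cannot dominate a degenerate zero-variance feature
    def __init__(self, units: int, dim: int, name: str, eps: float = 1e-3,
                 momentum: float = 0.02, dtype=np.float64):
        self.gamma = Tensor(np.ones((units, 1, dim), dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros((units, 1, dim), dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros((units, 1, dim), dtype=dtype)
        self.running_var = np.ones((units, 1, dim), dtype=dtype)
        self.eps = eps
        self.momentum = momentum
        self.name = name
        self._stats_seen = False  # first batch seeds the running statistics

    def params(self):
        return [(f"{self.name}.gamma", self.gamma), (f"{self.name}.beta", self.beta)]

    def weight_tensors(self):
        return []

    def begin_stats(self):
        self._acc_n = 0
        self._acc_sum = None
        self._acc_sumsq = None

    def finalize_stats(self):
        if self._acc_n:
            dt = self.running_mean.dtype
            mean = self._acc_sum / self._acc_n
            var = np.maximum(self._acc_sumsq / self._acc_n - mean ** 2, 0.0)
            self.running_mean = mean.astype(dt)
            self.running_var = var.astype(dt)
            self._stats_seen = True
        self._acc_n = 0
        self._acc_sum = None
        self._acc_sumsq = None

    def __call__(self, x: Tensor, ctx: _Context) -> Tensor:
        if ctx.train:
            mu = x.mean(axis=1, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=1, keepdims=True)
            if ctx.collect_stats:
                b = x.shape[1]
                self._acc_n += b
                x64 = x.data.astype(np.float64)  # f32 E[x^2]-m^2 cancels badly
                xsum = x64.sum(axis=1, keepdims=True)
                xsq = (x64 ** 2).sum(axis=1, keepdims=True)
                if self._acc_sum is None:
                    self._acc_sum, self._acc_sumsq = xsum, xsq
                else:
                    self._acc_sum += xsum
                    self._acc_sumsq += xsq
            elif not self._stats_seen:
                # seed from the first batch: an EMA from the arbitrary (0, 1)
                # init would leave eval mode miscalibrated on short runs
                self.running_mean = mu.data.copy()
                self.running_var = var.data.copy()
                self._stats_seen = True
            else:
                self.running_mean = ((1 - self.momentum) * self.running_mean
                                     + self.momentum * mu.data)
                self.running_var = ((1 - self.momentum) * self.running_var
                                    + self.momentum * var.data)
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            xhat = ((x - Tensor(self.running_mean))
                    * Tensor((self.running_var + self.eps) ** -0.5))
        return xhat * self.gamma + self.beta


class VariationalDropout:
    """Multiplicative Gaussian noise with learnable per-unit log-variance.

    Training mode returns x * (1 + sqrt(alpha) * eps), eps ~ N(0, 1), with
    alpha = exp(log_alpha) learned per feature, and records an approximate KL
    penalty 0.5 * sum(log(1 + 1/alpha)) pulling the noisy weights toward the
    N(0, I) prior.  Inference mode returns the noise mean, i.e. x itself.
    """

    def __init__(self, units: int, dim: int, name: str, init_log_alpha: float = -3.0,
                 dtype=np.float64):
        self.log_alpha = Tensor(np.full((units, 1, dim), init_log_alpha, dtype=dtype),
                                requires_grad=True)
        self.name = name

    def params(self):
        return [(f"{self.name}.log_alpha", self.log_alpha)]

    def weight_tensors(self):
        return []

    def __call__(self, x: Tensor, ctx: _Context) -> Tensor:
        if not ctx.train or ctx.collect_stats:
            return x
        alpha = self.log_alpha.exp()
        eps = ctx.rng.standard_normal(x.shape) if ctx.rng is not None \
            else np.random.standard_normal(x.shape)
        noise = 1.0 + alpha.sqrt() * Tensor(eps.astype(x.data.dtype, copy=False))
        ctx.kl_terms.append((0.5 * ((1.0 + alpha ** -1.0).log())).sum())
        return x * noise


def variational_dropout_layer(input: np.ndarray, parameters: VariationalDropout,
                              mode: str = "infer",
                              rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Functional wrapper around :class:`VariationalDropout` (NumPy in/out)."""
    if mode not in ("train", "infer"):
        raise ValidationError(f"mode must be 'train' or 'infer', got {mode!r}")
    ctx = _Context(train=(mode == "train"), rng=rng)
    return parameters(Tensor(np.asarray(input, dtype=float)), ctx).data


class _RegularDropout:
    def __init__(self, rate: float):
        self.rate = rate

    def params(self):
        return []

    def weight_tensors(self):
        return []

    def __call__(self, x: Tensor, ctx: _Context) -> Tensor:
        if not ctx.train or ctx.collect_stats or self.rate == 0.0:
            return x
        rng = ctx.rng if ctx.rng is not None else np.random.default_rng()
        keep = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(keep.astype(x.data.dtype, copy=False))


def _make_noise_layer(spec: DropoutSpec, units: int, dim: int, name: str,
                      dtype=np.float64):
    if spec.variant == "regular":
        return _RegularDropout(spec.rate)
    if spec.variant == "variational":
        return VariationalDropout(units, dim, name, dtype=dtype)
    return None


# ---------------------------------------------------------------------------
# relational units (stacked over the unit axis; parameters are NOT shared)
# ---------------------------------------------------------------------------

class _StackedMLPRU:
    """`units` independent MLP relational units: 3 FC layers, 2 BN, 2 ReLU."""

    def __init__(self, units: int, d_in: int, d_out: int, spec: RUSpec,
                 rng: np.random.Generator, name: str):
        dt = np.dtype(spec.dtype)
        h1, h2 = spec.mlp_hidden
        self.fc1 = _Linear(units, d_in, h1, rng, f"{name}.fc1", dtype=dt)
        self.bn1 = _BatchNorm(units, h1, f"{name}.bn1", dtype=dt)
        self.fc2 = _Linear(units, h1, h2, rng, f"{name}.fc2", dtype=dt)
        self.bn2 = _BatchNorm(units, h2, f"{name}.bn2", dtype=dt)
        self.fc3 = _Linear(units, h2, d_out, rng, f"{name}.fc3", dtype=dt)
        self.drop1 = _make_noise_layer(spec.dropout, units, h1, f"{name}.vd1", dtype=dt)
        self.drop2 = _make_noise_layer(spec.dropout, units, h2, f"{name}.vd2", dtype=dt)
        self.layers = [self.fc1, self.bn1, self.fc2, self.bn2, self.fc3]
        self.noise = [l for l in (self.drop1, self.drop2) if l is not None]

    def forward(self, x: Tensor, ctx: _Context) -> Tensor:
        h = self.bn1(self.fc1(x, ctx), ctx).relu()
        if self.drop1 is not None:
            h = self.drop1(h, ctx)
        h = self.bn2(self.fc2(h, ctx), ctx).relu()
        if self.drop2 is not None:
            h = self.drop2(h, ctx)
        return self.fc3(h, ctx)

    def params(self):
        out = []
        for l in self.layers + self.noise:
            out.extend(l.params())
        return out

    def weight_tensors(self):
        out = []
        for l in self.layers:
            out.extend(l.weight_tensors())
        return out


class _Conv1d:
    """Kernel-3, stride-1, zero-padded 1-D convolution, stacked over units.

    Implemented channels-last.  Because channel mixing and spatial shifting
    commute, each tap is one flat per-unit GEMM over all batch-and-position
    rows, and the +/-1 taps are then shifted by slicing the (small) tap
    outputs — the whole layer stays inside dense batched GEMMs.
    """

    def __init__(self, units: int, c_in: int, c_out: int, seq_len: int,
                 rng: np.random.Generator, name: str, dtype=np.float64):
        scale = np.sqrt(2.0 / (3 * c_in))
        self.W = Tensor(rng.normal(0.0, scale, size=(units, 3, c_in, c_out)).astype(dtype),
                        requires_grad=True)
        self.b = Tensor(np.zeros((units, 1, 1, c_out), dtype=dtype), requires_grad=True)
        self.c_in = c_in
        self.c_out = c_out
        self.name = name

    def params(self):
        return [(f"{self.name}.W", self.W), (f"{self.name}.b", self.b)]

    def weight_tensors(self):
        return [self.W]

    def __call__(self, x: Tensor, ctx: _Context) -> Tensor:
        # x (U, B, S, C) -> (U, B, S, G); output position l reads inputs
        # l-1, l, l+1 (zero-padded) through taps W[:, 0..2]
        U, B, S, C = x.shape
        G = self.c_out
        W = self.W
        mask = ctx.weight_masks.get(id(self.W))
        if mask is not None:
            W = W * Tensor(mask)
        xf = x.reshape(U, B * S, C)
        taps = [(xf @ W[:, t]).reshape(U, B, S, G) for t in range(3)]
        zrow = Tensor(np.zeros((U, B, 1, G), dtype=x.data.dtype))
        prev = concat([zrow, taps[0][:, :, :S - 1, :]], axis=2)
        nxt = concat([taps[2][:, :, 1:, :], zrow], axis=2)
        return prev + taps[1] + nxt + self.b


class _StackedDenseRU:
    """`units` independent dense-block relational units.

    The input is linearly projected to a length-`relation_dim` sequence
    (1 channel), passed through one dense block of `db_layers` kernel-3
    convolutions with growth rate `db_growth` (channel concatenation after
    each layer), then flattened and projected to the output width.
    """

    def __init__(self, units: int, d_in: int, d_out: int, spec: RUSpec,
                 rng: np.random.Generator, name: str):
        dt = np.dtype(spec.dtype)
        self.seq_len = spec.relation_dim
        self.proj_in = _Linear(units, d_in, self.seq_len, rng, f"{name}.proj_in", dtype=dt)
        self.bn_in = _BatchNorm(units, self.seq_len, f"{name}.bn_in", dtype=dt)
        self.convs = []
        c = 1
        for l in range(spec.db_layers):
            self.convs.append(
                _Conv1d(units, c, spec.db_growth, self.seq_len, rng,
                        f"{name}.conv{l}", dtype=dt))
            c += spec.db_growth
        flat = c * self.seq_len
        self.drop = _make_noise_layer(spec.dropout, units, flat, f"{name}.vd", dtype=dt)
        self.proj_out = _Linear(units, flat, d_out, rng, f"{name}.proj_out", dtype=dt)
        self.layers = [self.proj_in, self.bn_in] + self.convs + [self.proj_out]
        self.noise = [self.drop] if self.drop is not None else []

    def forward(self, x: Tensor, ctx: _Context) -> Tensor:
        U, B, _ = x.shape
        h = self.bn_in(self.proj_in(x, ctx), ctx).relu()
        h = h.reshape(U, B, self.seq_len, 1)
        for conv in self.convs:
            h = concat([h, conv(h, ctx).relu()], axis=3)
        h = h.reshape(U, B, self.seq_len * h.shape[3])
        if self.drop is not None:
            h = self.drop(h, ctx)
        return self.proj_out(h, ctx)

    def params(self):
        out = []
        for l in self.layers + self.noise:
            out.extend(l.params())
        return out

    def weight_tensors(self):
        out = []
        for l in self.layers:
            out.extend(l.weight_tensors())
        return out


def _make_ru_stack(units: int, d_in: int, d_out: int, spec: RUSpec,
                   rng: np.random.Generator, name: str):
    cls = _StackedMLPRU if spec.ru_type == "mlp" else _StackedDenseRU
    return cls(units, d_in, d_out, spec, rng, name)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

@dataclass
class PredictionSet:
    """Per-input-landmark predictions plus their consensus average."""

    target_set: Tuple[Landmark, ...]
    per_input_predictions: Dict[Landmark, np.ndarray]  # each (m, 3) pixel space
    consensus: np.ndarray                              # (m, 3) pixel space


class RRNModel:
    """Parameter container and forward pass for one configuration."""

    def __init__(self, config: ConfigurationSpec, ru_spec: RUSpec, seed: int):
        if config.n < 2:
            raise ConfigurationError("RRN needs at least two input landmarks")
        self.config = config
        self.ru_spec = ru_spec
        self.seed = int(seed)
        self.pairs = ordered_pairs(config)
        n, m = config.n, config.m
        self.output_dim = 3 * m
        rng = substream(seed, "init")
        self._pairwise = _make_ru_stack(len(self.pairs), FEATURE_DIM,
                                        ru_spec.relation_dim, ru_spec, rng, "g")
        self._global = _make_ru_stack(n, ru_spec.relation_dim, self.output_dim,
                                      ru_spec, rng, "f")
        # mean-aggregation matrix: G_i = (1/(n-1)) sum_{j != i} g(o_i, o_j)
        agg = np.zeros((n, len(self.pairs)))
        for p, (a, _) in enumerate(self.pairs):
            agg[config.input_set.index(a), p] = 1.0 / (n - 1)
        self._agg = agg.astype(np.dtype(ru_spec.dtype))
        self._vocab_index = {lm: k for k, lm in enumerate(VOCABULARY)}
        # affine output parametrization: offset = mu + sigma * raw.  train()
        # sets mu/sigma to the training-set offset statistics so the head
        # starts near the mean shape and learns residuals (identity before).
        self.offset_mean = np.zeros((config.m, 3))
        self.offset_scale = 1.0

    # -- bookkeeping ---------------------------------------------------------
    @property
    def pairwise_units(self) -> Dict[Tuple[Landmark, Landmark], Dict[str, np.ndarray]]:
        """Per-pair view of the (unshared) pairwise parameter blocks."""
        return {pair: {name: t.data[p] for name, t in self._pairwise.params()}
                for p, pair in enumerate(self.pairs)}

    @property
    def global_units(self) -> Dict[Landmark, Dict[str, np.ndarray]]:
        return {lm: {name: t.data[i] for name, t in self._global.params()}
                for i, lm in enumerate(self.config.input_set)}

    def parameters(self) -> List[Tuple[str, Tensor]]:
        return self._pairwise.params() + self._global.params()

    def weight_tensors(self) -> List[Tensor]:
        return self._pairwise.weight_tensors() + self._global.weight_tensors()

    def n_parameters(self) -> int:
        return int(sum(t.data.size for _, t in self.parameters()))

    # -- forward pieces (public per-pair / per-input API) --------------------
    def pairwise_relation(self, i: Landmark, j: Landmark,
                          features: np.ndarray) -> np.ndarray:
        """Inference-mode relation vector g_theta(o_i, o_j) for one pair."""
        if i == j:
            raise ValidationError("pairwise relation requires distinct landmarks")
        if (i, j) not in self.pairs:
            raise ValidationError(f"({i.symbol},{j.symbol}) is not an input pair")
        feats = np.asarray(features, dtype=float).reshape(-1)
        if feats.size != FEATURE_DIM:
            raise ValidationError(f"expected {FEATURE_DIM} features, got {feats.size}")
        P = len(self.pairs)
        X = np.zeros((P, 1, FEATURE_DIM), dtype=np.dtype(self.ru_spec.dtype))
        X[self.pairs.index((i, j)), 0] = feats
        ctx = _Context(train=False)
        out = self._pairwise.forward(Tensor(X), ctx).data
        return out[self.pairs.index((i, j)), 0]

    def aggregate_mean(self, i: Landmark,
                       relations: Mapping[Tuple[Landmark, Landmark], np.ndarray]
                       ) -> np.ndarray:
        """G_i: componentwise mean of g(o_i, o_j) over all j != i."""
        if i not in self.config.input_set:
            raise ValidationError(f"{i.symbol} is not an input landmark")
        vecs = []
        for j in self.config.input_set:
            if j == i:
                continue
            if (i, j) not in relations:
                raise ValidationError(f"missing relation for pair ({i.symbol},{j.symbol})")
            vecs.append(np.asarray(relations[(i, j)], dtype=float))
        return np.mean(vecs, axis=0)

    # -- batched forward -----------------------------------------------------
    def _forward_core(self, X: Tensor, ctx: _Context) -> Tensor:
        """(P, B, 19) features -> (n, B, m, 3) per-input coordinate offsets."""
        R = self._pairwise.forward(X, ctx)                       # (P, B, rd)
        P, B, rd = R.shape
        G = (Tensor(self._agg) @ R.reshape(P, B * rd)).reshape(
            self.config.n, B, rd)
        out = self._global.forward(G, ctx)                       # (n, B, 3m)
        raw = out.reshape(self.config.n, B, self.config.m, 3)
        dt = raw.data.dtype
        return raw * np.asarray(self.offset_scale, dtype=dt) + Tensor(
            self.offset_mean[None, None].astype(dt))

    def set_offset_normalization(self, offsets: np.ndarray) -> None:
        """Fix the output affine from observed (C, m, 3) Me-relative offsets."""
        offsets = np.asarray(offsets, dtype=float)
        self.offset_mean = offsets.mean(axis=0)
        self.offset_scale = float((offsets - self.offset_mean).std()) or 1.0

    def predict_positions(self, positions: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Batched inference.

        positions: (C, 14, 3) in vocabulary order (target rows may be NaN;
        they are not read).  Returns (per_input (n, C, m, 3), consensus
        (C, m, 3)) in pixel space.
        """
        feats = feature_tensor(positions, self.config, self._vocab_index)
        X = np.ascontiguousarray(
            np.swapaxes(feats, 0, 1), dtype=np.dtype(self.ru_spec.dtype))  # (P, C, 19)
        ctx = _Context(train=False)
        offsets = self._forward_core(Tensor(X), ctx).data          # (n, C, m, 3)
        me = positions[:, self._vocab_index[Landmark.Me], :]       # (C, 3)
        per_input = offsets + me[None, :, None, :]
        return per_input, per_input.mean(axis=0)

    def _bn_layers(self):
        from itertools import chain
        return [l for l in chain(self._pairwise.layers, self._global.layers)
                if isinstance(l, _BatchNorm)]

    def recalibrate_bn(self, feats: np.ndarray, batch_size: int = 64) -> None:
        """Precise batch-norm re-estimation under the final weights.

        `feats` is the (C, P, 19) training feature tensor.  Runs train-mode
        forward passes (noise disabled) accumulating exact population
        statistics per layer, then installs them as the inference statistics.
        The EMA collected during optimization lags the moving weights; exact
        re-estimation removes that train/eval mismatch.
        """
        layers = self._bn_layers()
        for l in layers:
            l.begin_stats()
        ctx = _Context(train=True, collect_stats=True)
        C = feats.shape[0]
        dt = np.dtype(self.ru_spec.dtype)
        for start in range(0, C, batch_size):
            X = np.ascontiguousarray(
                np.swapaxes(feats[start:start + batch_size], 0, 1), dtype=dt)
            self._forward_core(Tensor(X), ctx)
        for l in layers:
            l.finalize_stats()

    def training_loss(self, X: np.ndarray, me: np.ndarray, targets: np.ndarray,
                      rng: Optional[np.random.Generator] = None,
                      weight_masks: Optional[Mapping[int, np.ndarray]] = None
                      ) -> Tensor:
        """Differentiable batch loss: Eq-style per-input MSE plus KL terms.

        X (P, B, 19), me (B, 3), targets (B, m, 3) pixel space.
        """
        dt = np.dtype(self.ru_spec.dtype)
        ctx = _Context(train=True, rng=rng, weight_masks=weight_masks)
        offsets = self._forward_core(Tensor(X.astype(dt, copy=False)), ctx)  # (n,B,m,3)
        pred = offsets + Tensor(me[None, :, None, :].astype(dt))
        sq = ((pred - Tensor(targets[None].astype(dt))) ** 2.0).sum(axis=-1)  # (n,B,m)
        loss = sq.mean()
        if ctx.kl_terms:
            kl = ctx.kl_terms[0]
            for t in ctx.kl_terms[1:]:
                kl = kl + t
            loss = loss + self.ru_spec.dropout.kl_weight * kl
        return loss


def build_rrn(config: ConfigurationSpec, ru_spec: RUSpec, seed: int) -> RRNModel:
    """Instantiate the n^2 relational units with seeded initialization."""
    return RRNModel(config, ru_spec, seed)


def count_relational_units(model: RRNModel) -> int:
    """|pairwise units| + |global units| = n(n-1) + n = n^2."""
    return len(model.pairs) + model.config.n


def predict(model: RRNModel, case: LandmarkCase) -> PredictionSet:
    """Predict the m target landmark positions for one case (pixel space)."""
    n = model.config.n
    positions = np.full((1, len(VOCABULARY), 3), np.nan)
    for lm in model.config.input_set:
        if lm not in case.positions:
            raise DataError(f"case {case.case_id} is missing input landmark {lm.symbol}")
        positions[0, model._vocab_index[lm]] = case.positions[lm]
    per_input, consensus = model.predict_positions(positions)
    return PredictionSet(
        target_set=model.config.target_set,
        per_input_predictions={lm: per_input[i, 0]
                               for i, lm in enumerate(model.config.input_set)},
        consensus=consensus[0],
    )


def rrn_loss(predictions: PredictionSet, case: LandmarkCase,
             config: ConfigurationSpec) -> float:
    """Per-input mean squared error: (1/(n m)) sum_i sum_k ||pred_ik - o_k||^2."""
    for lm in config.target_set:
        if lm not in case.positions:
            raise DataError(f"case {case.case_id} is missing target truth {lm.symbol}")
    truth = np.stack([case.positions[lm] for lm in config.target_set])  # (m, 3)
    preds = np.stack([predictions.per_input_predictions[lm]
                      for lm in predictions.per_input_predictions])     # (n, m, 3)
    return float(((preds - truth[None]) ** 2).sum(axis=-1).mean())


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: RRNModel, path, extra: Optional[dict] = None) -> None:
    """Serialize parameters, BN statistics, config, RUSpec and seed to .npz."""
    meta = {
        "config": {
            "name": model.config.name,
            "input_set": [lm.symbol for lm in model.config.input_set],
            "target_set": [lm.symbol for lm in model.config.target_set],
        },
        "ru_spec": asdict(model.ru_spec),
        "seed": model.seed,
        "ru_census": count_relational_units(model),
        "n_parameters": model.n_parameters(),
        "extra": extra or {},
    }
    arrays = {f"param::{name}": t.data for name, t in model.parameters()}
    arrays["offset_mean"] = model.offset_mean
    arrays["offset_scale"] = np.asarray(model.offset_scale)
    for stack, tag in ((model._pairwise, "g"), (model._global, "f")):
        for layer in stack.layers:
            if isinstance(layer, _BatchNorm):
                arrays[f"bnstat::{layer.name}.mean"] = layer.running_mean
                arrays[f"bnstat::{layer.name}.var"] = layer.running_var
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(Path(path), **arrays)


def load_checkpoint(path) -> RRNModel:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        cfg = ConfigurationSpec(
            name=meta["config"]["name"],
            input_set=tuple(Landmark(s) for s in meta["config"]["input_set"]),
            target_set=tuple(Landmark(s) for s in meta["config"]["target_set"]))
        spec_d = dict(meta["ru_spec"])
        spec_d["dropout"] = DropoutSpec(**spec_d["dropout"])
        spec_d["mlp_hidden"] = tuple(spec_d["mlp_hidden"])
        ru_spec = RUSpec(**spec_d)
        model = RRNModel(cfg, ru_spec, meta["seed"])
        for name, t in model.parameters():
            t.data[...] = data[f"param::{name}"]
        model.offset_mean = np.asarray(data["offset_mean"], dtype=float)
        model.offset_scale = float(data["offset_scale"])
        for stack in (model._pairwise, model._global):
            for layer in stack.layers:
                if isinstance(layer, _BatchNorm):
                    layer.running_mean[...] = data[f"bnstat::{layer.name}.mean"]
                    layer.running_var[...] = data[f"bnstat::{layer.name}.var"]
    return model
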