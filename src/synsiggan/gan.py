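"""The adversarial model: BiGridLSTM generator vs. 1-D CNN discriminator.

The generator is a bidirectional grid LSTM.  A grid LSTM places a full LSTM
cell — gates, cell state, projection — along *each* dimension of a 2-D grid
spanned by time ``t`` and depth ``l``.  At grid point ``(t, l)`` both the
time block and the depth block read the depth-hidden state from the layer
below, ``H^dep_{t,l-1}``, and the time-hidden state from the previous step,
``H^Tm_{t-1,l}``; the time block carries its cell state ``C^Tm`` along
``t`` and the depth block carries ``C^dep`` along ``l`` (with
``C^dep_{t,0} = 0`` and the noise vector ``z_t`` entering as
``H^dep_{t,0}``).  Each gate has cell-state (peephole) weights ``D`` and the
cell output passes through a projection matrix.  Two such grids run in
opposite temporal directions (the reverse grid's recursion reads the
``t+1`` states, with zero states beyond the ends) and the top-layer depth
outputs of both are combined per time step — concatenation followed by a
learned linear map by default — into one synthetic sample per step.

The discriminator is a small 1-D CNN: conv(kernel H=5, stride P=3) -> ReLU
-> max-pool -> conv(kernel 3) -> ReLU -> max-pool -> fully connected ->
softmax over {real, fake}; the first conv layer has output length
``floor((T - H)/P) + 1``.

Training alternates one discriminator ascent step on
``E[log D(x)] + E[log(1 - D(G(z)))]`` with one generator step; the
generator descends the non-saturating ``-log D(G(z))`` by default (the
literal ``log(1 - D(G(z)))`` objective is selectable).  Everything runs on
the in-package autodiff tape with Adam, single-threaded and bit-reproducible
given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace

import numpy as np

from . import _autodiff as ad
from ._autodiff import (Adam, Tensor, concat, conv1d, data_of, log_softmax,
                        matmul, maxpool1d, mean_of_col, mul, neg, relu,
                        reshape, sigmoid, slice_cols, tanh)

__all__ = [
    "GanConfig", "LstmGates", "LstmParams", "lstm_step",
    "GridDimParams", "GridBlockParams", "BiGridLstmParams", "grid_step",
    "bigridlstm_generate", "DiscriminatorParams", "discriminator_forward",
    "GanModel", "TrainTrace", "gan_train", "train_per_class",
    "generate_synthetic", "save_model", "load_model",
]


@dataclass(frozen=True)
class GanConfig:
    """Hyperparameters of the generator, discriminator and training loop.

    ``segment_length`` is T, the number of samples per segment; the CNN's
    first kernel/stride pair (H, P) defaults to (5, 3).
    """

    segment_length: int = 64
    noise_dim: int = 8
    hidden_size: int = 50
    n_layers: int = 2
    conv_filters: tuple[int, int] = (8, 16)
    kernel_sizes: tuple[int, int] = (5, 3)
    stride: int = 3
    pool_sizes: tuple[int, int] = (2, 2)
    batch_size: int = 32
    learning_rate: float = 1e-3
    epochs: int = 200
    seed: int = 0
    loss: str = "non_saturating"          # or "literal"
    combine: str = "concat"               # or "sum"
    grad_clip: float = 5.0
    track_template_pcc: bool = False

    def __post_init__(self):
        T, (H, _K2), P = self.segment_length, self.kernel_sizes, self.stride
        if not (T >= H >= 1):
            raise ValueError(f"need segment_length >= kernel >= 1, got T={T}, H={H}")
        if P < 1:
            raise ValueError("stride must be >= 1")
        for name in ("noise_dim", "hidden_size", "n_layers", "batch_size", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.loss not in ("non_saturating", "literal"):
            raise ValueError(f"unknown loss variant {self.loss!r}")
        if self.combine not in ("concat", "sum"):
            raise ValueError(f"unknown combine variant {self.combine!r}")


# --- plain LSTM cell (the building block the grid generalises) ---------------

@dataclass
class LstmGates:
    """Gate activations and states after one step: I, F, O in (0,1)."""

    I: np.ndarray
    F: np.ndarray
    O: np.ndarray
    C: np.ndarray
    C_hat: np.ndarray
    H: np.ndarray

    @classmethod
    def initial(cls, hidden: int, proj_dim: int | None = None) -> "LstmGates":
        z = np.zeros(hidden)
        return cls(z, z.copy(), z.copy(), z.copy(), z.copy(),
                   np.zeros(proj_dim if proj_dim is not None else hidden))


@dataclass
class LstmParams:
    """Per-gate weights of one LSTM cell with peepholes and projection.

    ``A_*`` act on the input, ``B_*`` on the previous hidden state, ``D_*``
    on the cell state (peepholes; the candidate has none), ``g_*`` are
    biases and ``A_proj`` maps the gated cell output to the hidden output.
    """

    A_I: np.ndarray; B_I: np.ndarray; D_I: np.ndarray; g_I: np.ndarray
    A_F: np.ndarray; B_F: np.ndarray; D_F: np.ndarray; g_F: np.ndarray
    A_C: np.ndarray; B_C: np.ndarray; g_C: np.ndarray
    A_O: np.ndarray; B_O: np.ndarray; D_O: np.ndarray; g_O: np.ndarray
    A_proj: np.ndarray

    @classmethod
    def zeros(cls, in_dim: int, hidden: int,
              proj_dim: int | None = None) -> "LstmParams":
        proj_dim = hidden if proj_dim is None else proj_dim
        A = lambda: np.zeros((in_dim, hidden))
        B = lambda: np.zeros((hidden, hidden))
        g = lambda: np.zeros(hidden)
        return cls(A(), B(), B(), g(), A(), B(), B(), g(), A(), B(), g(),
                   A(), B(), B(), g(), np.zeros((hidden, proj_dim)))

    @classmethod
    def random(cls, rng, in_dim: int, hidden: int,
               proj_dim: int | None = None, scale: float = 0.3) -> "LstmParams":
        p = cls.zeros(in_dim, hidden, proj_dim)
        for f in fields(cls):
            arr = getattr(p, f.name)
            arr[...] = scale * rng.standard_normal(arr.shape)
        return p


def lstm_step(x, prev: LstmGates, params: LstmParams) -> LstmGates:
    """One LSTM update.

    Gate order: input gate I, forget gate F, candidate cell, new cell
    ``C = F*C_prev + I*C_hat``, output gate O (peeping at the *new* cell),
    and projected hidden output ``H = (O * tanh(C)) @ A_proj``.
    """
    x = np.asarray(x, dtype=np.float64)
    p, h_prev, c_prev = params, prev.H, prev.C
    try:
        i = _np_sigmoid(x @ p.A_I + h_prev @ p.B_I + c_prev @ p.D_I + p.g_I)
        f = _np_sigmoid(x @ p.A_F + h_prev @ p.B_F + c_prev @ p.D_F + p.g_F)
        c_hat = np.tanh(x @ p.A_C + h_prev @ p.B_C + p.g_C)
        c = f * c_prev + i * c_hat
        o = _np_sigmoid(x @ p.A_O + h_prev @ p.B_O + c @ p.D_O + p.g_O)
        h = (o * np.tanh(c)) @ p.A_proj
    except ValueError as exc:
        raise ValueError(f"LSTM shape mismatch: {exc}") from exc
    return LstmGates(i, f, o, c, c_hat, h)


def _np_sigmoid(x):
    return ad.data_of(ad.sigmoid(np.asarray(x, dtype=np.float64)))


# --- grid LSTM parameters ----------------------------------------------------

@dataclass
class GridDimParams:
    """One dimension's block at one layer: stacked gate weights.

    ``W_x``/``W_h``/``g`` stack the four gates' input, recurrent and bias
    parameters in the order (I, F, candidate, O); ``D_*`` are the per-gate
    peephole matrices and ``proj`` the output projection.  Per-gate views
    (``A_I``, ``B_F``, ...) expose the unstacked matrices.
    """

    W_x: np.ndarray
    W_h: np.ndarray
    D_I: np.ndarray
    D_F: np.ndarray
    D_O: np.ndarray
    g: np.ndarray
    proj: np.ndarray

    @property
    def hidden(self) -> int:
        return data_of(self.g).size // 4

    def _col(self, which, k):
        h = self.hidden
        return data_of(which)[..., k * h:(k + 1) * h]

    @property
    def A_I(self): return self._col(self.W_x, 0)
    @property
    def A_F(self): return self._col(self.W_x, 1)
    @property
    def A_C(self): return self._col(self.W_x, 2)
    @property
    def A_O(self): return self._col(self.W_x, 3)
    @property
    def B_I(self): return self._col(self.W_h, 0)
    @property
    def B_F(self): return self._col(self.W_h, 1)
    @property
    def B_C(self): return self._col(self.W_h, 2)
    @property
    def B_O(self): return self._col(self.W_h, 3)

    @classmethod
    def zeros(cls, in_dim: int, hidden: int) -> "GridDimParams":
        return cls(np.zeros((in_dim, 4 * hidden)), np.zeros((hidden, 4 * hidden)),
                   np.zeros((hidden, hidden)), np.zeros((hidden, hidden)),
                   np.zeros((hidden, hidden)), np.zeros(4 * hidden),
                   np.zeros((hidden, hidden)))

    @classmethod
    def glorot(cls, rng, in_dim: int, hidden: int) -> "GridDimParams":
        p = cls.zeros(in_dim, hidden)
        for name in ("W_x", "W_h", "proj"):
            arr = getattr(p, name)
            fan_in, fan_out = arr.shape
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            arr[...] = rng.uniform(-bound, bound, arr.shape)
        p.g[hidden:2 * hidden] = 1.0  # forget-gate bias: remember by default
        return p

    def as_tensors(self) -> "GridDimParams":
        """Wrap every array as a gradient leaf sharing the same memory."""
        return GridDimParams(*(Tensor(getattr(self, f.name), requires_grad=True)
                               for f in fields(self)))

    def leaves(self):
        return [getattr(self, f.name) for f in fields(self)]


@dataclass
class GridBlockParams:
    """Time- and depth-dimension blocks of one grid layer (one direction)."""

    time: GridDimParams
    depth: GridDimParams

    @classmethod
    def zeros(cls, in_dim, hidden):
        return cls(GridDimParams.zeros(in_dim, hidden),
                   GridDimParams.zeros(in_dim, hidden))

    @classmethod
    def glorot(cls, rng, in_dim, hidden):
        return cls(GridDimParams.glorot(rng, in_dim, hidden),
                   GridDimParams.glorot(rng, in_dim, hidden))

    def as_tensors(self):
        return GridBlockParams(self.time.as_tensors(), self.depth.as_tensors())

    def leaves(self):
        return self.time.leaves() + self.depth.leaves()


@dataclass
class BiGridLstmParams:
    """Forward and reverse grid stacks plus the per-step output combiner."""

    forward: list[GridBlockParams]
    reverse: list[GridBlockParams]
    W_out: np.ndarray
    b_out: np.ndarray

    @classmethod
    def init(cls, config: GanConfig, rng=None) -> "BiGridLstmParams":
        h, nd, L = config.hidden_size, config.noise_dim, config.n_layers
        make = (GridBlockParams.zeros if rng is None
                else lambda i, o: GridBlockParams.glorot(rng, i, o))
        fwd = [make(nd if l == 0 else h, h) for l in range(L)]
        rev = [make(nd if l == 0 else h, h) for l in range(L)]
        out_in = 2 * h if config.combine == "concat" else h
        if rng is None:
            w_out = np.zeros((out_in, 1))
        else:
            bound = np.sqrt(6.0 / (out_in + 1))
            w_out = rng.uniform(-bound, bound, (out_in, 1))
        return cls(fwd, rev, w_out, np.zeros(1))

    def as_tensors(self):
        return BiGridLstmParams(
            [b.as_tensors() for b in self.forward],
            [b.as_tensors() for b in self.reverse],
            Tensor(self.W_out, requires_grad=True),
            Tensor(self.b_out, requires_grad=True))

    def leaves(self):
        out = []
        for blk in self.forward + self.reverse:
            out.extend(blk.leaves())
        out.extend([self.W_out, self.b_out])
        return out

    def named_leaves(self):
        names = []
        for d, blocks in (("fwd", self.forward), ("rev", self.reverse)):
            for l, blk in enumerate(blocks):
                for dim in ("time", "depth"):
                    for f in fields(GridDimParams):
                        names.append((f"gen.{d}.{l}.{dim}.{f.name}",
                                      getattr(getattr(blk, dim), f.name)))
        names += [("gen.W_out", self.W_out), ("gen.b_out", self.b_out)]
        return names

    def direction_swapped(self) -> "BiGridLstmParams":
        """Exchange the forward/reverse stacks (and the combiner's halves)."""
        w = data_of(self.W_out)
        if w.shape[0] % 2 == 0:
            half = w.shape[0] // 2
            w = np.concatenate([w[half:], w[:half]], axis=0)
        return BiGridLstmParams(list(self.reverse), list(self.forward),
                                w, data_of(self.b_out))


# --- grid forward ------------------------------------------------------------

def _dim_block(x, h_rec, c_prev, p: GridDimParams):
    """One LSTM block along one grid dimension (works on arrays or Tensors)."""
    h = p.hidden
    pre = matmul(x, p.W_x) + matmul(h_rec, p.W_h) + p.g
    i = sigmoid(slice_cols(pre, 0, h) + matmul(c_prev, p.D_I))
    f = sigmoid(slice_cols(pre, h, 2 * h) + matmul(c_prev, p.D_F))
    c_hat = tanh(slice_cols(pre, 2 * h, 3 * h))
    c = mul(f, c_prev) + mul(i, c_hat)
    o = sigmoid(slice_cols(pre, 3 * h, 4 * h) + matmul(c, p.D_O))
    h_out = matmul(mul(o, tanh(c)), p.proj)
    return h_out, c


def grid_step(x_dep, h_time_prev, c_time_prev, c_dep_prev,
              params: GridBlockParams):
    """One grid point: the time block and the depth block.

    Both blocks read the layer-below depth hidden state ``x_dep``
    (= H^dep_{t,l-1}; the noise input at layer 1) and the previous-step
    time hidden state ``h_time_prev``.  The time block updates
    ``(H^Tm, C^Tm)`` from ``c_time_prev``; the depth block updates
    ``(H^dep, C^dep)`` from ``c_dep_prev``.

    Returns ``((h_time, c_time), (h_dep, c_dep))``.
    """
    time_states = _dim_block(x_dep, h_time_prev, c_time_prev, params.time)
    dep_states = _dim_block(x_dep, h_time_prev, c_dep_prev, params.depth)
    return time_states, dep_states


def _run_grid_direction(z, blocks, hidden, reverse: bool):
    """Run one grid stack over all time steps; return top-layer depth outputs.

    ``z``: (B, T, noise_dim) ndarray.  The forward stack reads the t-1 time
    states, the reverse stack (``reverse=True``) iterates t = T..1 and so
    reads the t+1 states; states beyond either end are zero.
    """
    B, T, _ = z.shape
    L = len(blocks)
    zeros = np.zeros((B, hidden))
    h_tm = [zeros] * L
    c_tm = [zeros] * L
    tops = [None] * T
    order = range(T - 1, -1, -1) if reverse else range(T)
    for t in order:
        x = z[:, t, :]
        c_dep = zeros
        for l, blk in enumerate(blocks):
            (h_t, c_t), (x, c_dep) = grid_step(x, h_tm[l], c_tm[l], c_dep, blk)
            h_tm[l], c_tm[l] = h_t, c_t
        tops[t] = x
    return tops


def _generator_forward(z, params: BiGridLstmParams, config: GanConfig):
    """(B, T, noise_dim) noise -> (B, T) synthetic batch (array or Tensor)."""
    hidden = config.hidden_size
    fwd = _run_grid_direction(z, params.forward, hidden, reverse=False)
    rev = _run_grid_direction(z, params.reverse, hidden, reverse=True)
    cols = []
    for f_t, r_t in zip(fwd, rev):
        combined = (concat([f_t, r_t], axis=1) if config.combine == "concat"
                    else f_t + r_t)
        cols.append(matmul(combined, params.W_out) + params.b_out)
    return concat(cols, axis=1)


def bigridlstm_generate(z, params: BiGridLstmParams,
                        config: GanConfig) -> np.ndarray:
    """Generate one length-T sequence from a (T, noise_dim) noise matrix."""
    z = np.asarray(z, dtype=np.float64)
    if z.ndim != 2 or z.shape[0] != config.segment_length:
        raise ValueError(f"noise must be (T={config.segment_length}, "
                         f"noise_dim), got {z.shape}")
    if not np.all(np.isfinite(z)):
        raise ValueError("noise must be finite")
    out = _generator_forward(z[None], params, config)
    return data_of(out)[0]


# --- discriminator -----------------------------------------------------------

@dataclass
class DiscriminatorParams:
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    w_fc: np.ndarray
    b_fc: np.ndarray

    @classmethod
    def init(cls, config: GanConfig, rng=None) -> "DiscriminatorParams":
        f1, f2 = config.conv_filters
        k1, k2 = config.kernel_sizes
        flat = _disc_flat_dim(config)

        def w(shape):
            if rng is None:
                return np.zeros(shape)
            fan_in = int(np.prod(shape[:-1]))
            bound = np.sqrt(6.0 / (fan_in + shape[-1]))
            return rng.uniform(-bound, bound, shape)

        return cls(w((k1, 1, f1)), np.zeros(f1), w((k2, f1, f2)), np.zeros(f2),
                   w((flat, 2)), np.zeros(2))

    def as_tensors(self):
        return DiscriminatorParams(*(Tensor(getattr(self, f.name),
                                            requires_grad=True)
                                     for f in fields(self)))

    def leaves(self):
        return [getattr(self, f.name) for f in fields(self)]

    def named_leaves(self):
        return [(f"disc.{f.name}", getattr(self, f.name))
                for f in fields(self)]


def _disc_layer_dims(config: GanConfig):
    T, (k1, k2), P = config.segment_length, config.kernel_sizes, config.stride
    p1, p2 = config.pool_sizes
    l1 = (T - k1) // P + 1
    l1p = l1 // p1
    l2 = l1p - k2 + 1
    l2p = l2 // p2
    if l2p < 1:
        raise ValueError(f"segment_length {T} too short for the CNN stack")
    return l1, l1p, l2, l2p


def _disc_flat_dim(config: GanConfig) -> int:
    return _disc_layer_dims(config)[3] * config.conv_filters[1]


def _disc_logits(x, params: DiscriminatorParams, config: GanConfig):
    """(B, T) batch -> (B, 2) logits (array or Tensor)."""
    p1, p2 = config.pool_sizes
    xd = x if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)
    B = data_of(xd).shape[0]
    h = reshape(xd, (B, config.segment_length, 1))
    h = maxpool1d(relu(conv1d(h, params.w1, params.b1, stride=config.stride)), p1)
    h = maxpool1d(relu(conv1d(h, params.w2, params.b2, stride=1)), p2)
    h = reshape(h, (B, _disc_flat_dim(config)))
    return matmul(h, params.w_fc) + params.b_fc


def discriminator_forward(x, params: DiscriminatorParams,
                          config: GanConfig):
    """Probabilities (p_real, p_fake), softmax-normalised.

    Accepts one length-T sequence (returns a 2-tuple) or a (B, T) batch
    (returns a (B, 2) array).
    """
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    if single:
        x = x[None]
    if x.shape[1] != config.segment_length:
        raise ValueError(f"input length {x.shape[1]} != segment_length "
                         f"{config.segment_length}")
    logits = data_of(_disc_logits(x, params, config))
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    return (float(probs[0, 0]), float(probs[0, 1])) if single else probs


# --- training ----------------------------------------------------------------

@dataclass
class TrainTrace:
    """Per-epoch generator/discriminator losses (and optional template PCC)."""

    g_loss: list[float] = field(default_factory=list)
    d_loss: list[float] = field(default_factory=list)
    template_pcc: list[float] = field(default_factory=list)


@dataclass
class GanModel:
    generator: BiGridLstmParams
    discriminator: DiscriminatorParams
    config: GanConfig


def _clip_gradients(leaves, max_norm):
    if max_norm is None or max_norm <= 0:
        return
    total = np.sqrt(sum(float((p.grad ** 2).sum())
                        for p in leaves if p.grad is not None))
    if total > max_norm:
        scale = max_norm / total
        for p in leaves:
            if p.grad is not None:
                p.grad = p.grad * scale


def gan_train(real_segments, config: GanConfig) -> tuple[GanModel, TrainTrace]:
    """Adversarially train one generator/discriminator pair on one class.

    ``real_segments``: (n, T) array of equal-length segments.  Each batch
    takes one discriminator step (ascend ``log D(x) + log(1 - D(G(z)))``)
    and one generator step (descend the configured objective).  Reproducible
    given ``config.seed``.
    """
    X = np.asarray(real_segments, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("real_segments must be a non-empty (n, T) array")
    if X.shape[1] != config.segment_length:
        config = replace(config, segment_length=X.shape[1])
    n, T = X.shape

    rng = np.random.default_rng(config.seed)
    gen = BiGridLstmParams.init(config, rng).as_tensors()
    disc = DiscriminatorParams.init(config, rng).as_tensors()
    opt_g = Adam(gen.leaves(), lr=config.learning_rate)
    opt_d = Adam(disc.leaves(), lr=config.learning_rate)
    gen_np = _detached(gen)
    all_leaves = gen.leaves() + disc.leaves()

    trace = TrainTrace()
    template = X.mean(axis=0)
    for _epoch in range(config.epochs):
        perm = rng.permutation(n)
        g_losses, d_losses = [], []
        for start in range(0, n, config.batch_size):
            batch = X[perm[start:start + config.batch_size]]
            b = batch.shape[0]

            # discriminator step (generator detached)
            z = rng.standard_normal((b, T, config.noise_dim))
            fake = data_of(_generator_forward(z, gen_np, config))
            lsm_real = log_softmax(_disc_logits(batch, disc, config))
            lsm_fake = log_softmax(_disc_logits(fake, disc, config))
            d_loss = neg(mean_of_col(lsm_real, 0)) + neg(mean_of_col(lsm_fake, 1))
            if not np.isfinite(data_of(d_loss)):
                raise FloatingPointError("non-finite discriminator loss; aborting")
            for p in all_leaves:
                p.zero_grad()
            d_loss.backward()
            _clip_gradients(disc.leaves(), config.grad_clip)
            opt_d.step()

            # generator step
            z = rng.standard_normal((b, T, config.noise_dim))
            fake_t = _generator_forward(z, gen, config)
            lsm = log_softmax(_disc_logits(fake_t, disc, config))
            g_loss = (neg(mean_of_col(lsm, 0)) if config.loss == "non_saturating"
                      else mean_of_col(lsm, 1))
            if not np.isfinite(data_of(g_loss)):
                raise FloatingPointError("non-finite generator loss; aborting")
            for p in all_leaves:
                p.zero_grad()
            g_loss.backward()
            _clip_gradients(gen.leaves(), config.grad_clip)
            opt_g.step()

            d_losses.append(float(data_of(d_loss)))
            g_losses.append(float(data_of(g_loss)))
        trace.d_loss.append(float(np.mean(d_losses)))
        trace.g_loss.append(float(np.mean(g_losses)))
        if config.track_template_pcc:
            from .metrics import pcc
            z = rng.standard_normal((8, T, config.noise_dim))
            samples = data_of(_generator_forward(z, gen_np, config))
            trace.template_pcc.append(float(np.median(
                [pcc(template, row) for row in samples])))

    model = GanModel(_materialise(gen), _materialise_disc(disc), config)
    return model, trace


def _detached(gen: BiGridLstmParams) -> BiGridLstmParams:
    """A view of the generator with raw arrays (shared memory, no tape)."""
    blocks = lambda bs: [GridBlockParams(
        GridDimParams(*(data_of(x) for x in b.time.leaves())),
        GridDimParams(*(data_of(x) for x in b.depth.leaves())))
        for b in bs]
    return BiGridLstmParams(blocks(gen.forward), blocks(gen.reverse),
                            data_of(gen.W_out), data_of(gen.b_out))


def _materialise(gen: BiGridLstmParams) -> BiGridLstmParams:
    return _detached(gen)


def _materialise_disc(disc: DiscriminatorParams) -> DiscriminatorParams:
    return DiscriminatorParams(*(data_of(x) for x in disc.leaves()))


def train_per_class(matrix, config: GanConfig) -> dict:
    """Train one GAN per annotation class of a SegmentMatrix.

    Returns ``{label: (GanModel, TrainTrace)}``; each class gets its own
    seed offset so the runs are independent but reproducible.
    """
    out = {}
    for k, (label, rows) in enumerate(sorted(matrix.matrices.items())):
        cfg = replace(config, segment_length=rows.shape[1],
                      seed=(config.seed + k) % (2 ** 31))
        out[label] = gan_train(rows, cfg)
    return out


def generate_synthetic(model: GanModel | BiGridLstmParams, n: int,
                       config: GanConfig | None = None,
                       seed: int = 0) -> list[np.ndarray]:
    """Draw exactly ``n`` synthetic length-T sequences from a trained model."""
    if isinstance(model, GanModel):
        params, config = model.generator, model.config
    else:
        params = model
        if config is None:
            raise ValueError("config required when passing raw parameters")
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, config.segment_length, config.noise_dim))
    out = data_of(_generator_forward(z, params, config))
    return [out[i].copy() for i in range(n)]


# --- checkpointing -----------------------------------------------------------

def save_model(model: GanModel, path) -> None:
    """Flat container of named weight arrays plus a config echo."""
    arrays = dict(model.generator.named_leaves())
    arrays.update(model.discriminator.named_leaves())
    arrays = {k: data_of(v) for k, v in arrays.items()}
    cfg = {f.name: getattr(model.config, f.name) for f in fields(GanConfig)}
    np.savez(path, __config__=np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> GanModel:
    with np.load(path) as npz:
        cfg_raw = json.loads(bytes(npz["__config__"]).decode())
        for key in ("conv_filters", "kernel_sizes", "pool_sizes"):
            cfg_raw[key] = tuple(cfg_raw[key])
        config = GanConfig(**cfg_raw)
        gen = BiGridLstmParams.init(config)
        disc = DiscriminatorParams.init(config)
        for name, arr in gen.named_leaves() + disc.named_leaves():
            arr[...] = npz[name]
    return GanModel(gen, disc, config)
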