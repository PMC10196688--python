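"""Generator and discriminator networks for adversarial imputation.

The generator runs a per-phylum-cluster 1-D CNN feature extractor over the
ordered taxon axis, feeds the concatenated features to a one-layer tanh
RNN in each direction, maps the hidden states to taxon space with a linear
layer, and blends the two directions with temporal-decay combination
factors lambda = exp(-ReLU(W * delta + b)).  Observed samples always pass
through unchanged: x_bar = x * e + x_tilde * (1 - e).

The discriminator is a 10-unit LSTM with two heads: a sigmoid real/fake
probability from the final hidden state, and a per-timestep softmax over
the k timepoint classes.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .datasets import MicrogenError
from .phylo import PhylumClusterMap

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "GeneratorOutput",
    "Generator",
    "Discriminator",
    "decay_factor",
    "feature_length",
]


@dataclasses.dataclass
class GeneratorConfig:
    kernel_size: int = 3
    conv_filters: tuple = (16, 8)
    dropout_rate: float = 0.7
    rnn_hidden: int = 32
    leaky_relu_slope: float = 0.2
    pool_size: int = 2
    use_cnn: bool = True

    def __post_init__(self):
        if self.kernel_size < 1:
            raise MicrogenError("kernel_size must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise MicrogenError("dropout_rate must be in [0, 1)")


@dataclasses.dataclass
class DiscriminatorConfig:
    lstm_units: int = 10

    def __post_init__(self):
        if self.lstm_units < 1:
            raise MicrogenError("lstm_units must be >= 1")


@dataclasses.dataclass
class GeneratorOutput:
    """Forward/backward generated tensors and their decay-weighted blend."""

    x_tilde_f: Tensor
    x_tilde_b: Tensor
    x_tilde: Tensor
    x_bar: Tensor
    lambda_f: Tensor
    lambda_b: Tensor


def feature_length(p: int, cfg: GeneratorConfig) -> int:
    """Per-cluster feature length after two conv/pool stages (same padding).

    Clusters smaller than the kernel bypass convolution and contribute
    their raw clr values, so their feature length is p itself.
    """
    if not cfg.use_cnn or p < cfg.kernel_size:
        return p
    after1 = math.ceil(p / cfg.pool_size)
    after2 = math.ceil(after1 / cfg.pool_size)
    return cfg.conv_filters[1] * after2


def decay_factor(delta: np.ndarray, w: Tensor | float, b: Tensor | float) -> Tensor:
    """Temporal decay lambda = exp(-ReLU(w * delta + b)), elementwise in (0, 1].

    A 1e-30 floor keeps lambda strictly positive where the exponential
    would underflow in single precision (the gradient there is zero anyway).
    """
    w = ad.astensor(w)
    b = ad.astensor(b)
    lam = ad.exp(-ad.relu(w * Tensor(np.asarray(delta, dtype=float)) + b))
    return ad.clamp(lam, 1e-30, 2.0)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    """Orthogonal recurrent init: preserves hidden-state memory over long gaps."""
    a = rng.normal(size=(n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


class Generator:
    """CNN feature extractor + bidirectional tanh RNN + decay combination."""

    def __init__(self, n_taxa: int, n_timepoints: int, cluster_map: PhylumClusterMap,
                 cfg: GeneratorConfig, rng: np.random.Generator,
                 input_stats: tuple | None = None):
        if int(cluster_map.permutation.size) != n_taxa:
            raise MicrogenError("cluster map inconsistent with the number of taxa")
        self.n_taxa = n_taxa
        self.k = n_timepoints
        self.cfg = cfg
        self.cluster_map = cluster_map
        # per-taxon affine map between clr space and the network's unit scale
        if input_stats is None:
            self.mu = np.zeros(n_taxa)
            self.sd = np.ones(n_taxa)
        else:
            self.mu = np.asarray(input_stats[0], dtype=float)
            self.sd = np.asarray(input_stats[1], dtype=float)
        self.params: list[Tensor] = []
        ks = cfg.kernel_size
        f1, f2 = cfg.conv_filters
        self._cluster_idx = dict(cluster_map.clusters)
        # clusters of equal width share one grouped-conv call (independent weights)
        self.size_groups: dict[int, list] = {}
        self.conv_params = {}
        if cfg.use_cnn:
            for name, idx in cluster_map.clusters:
                p = len(idx)
                if p >= ks:
                    self.size_groups.setdefault(p, []).append(name)
            for p, names in sorted(self.size_groups.items()):
                gn = len(names)
                w1 = Tensor(_glorot(rng, ks, ks * f1, (gn, ks, 1, f1)), requires_grad=True)
                b1 = Tensor(np.zeros((gn, 1, 1, f1)), requires_grad=True)
                w2 = Tensor(_glorot(rng, ks * f1, ks * f2, (gn, ks, f1, f2)),
                            requires_grad=True)
                b2 = Tensor(np.zeros((gn, 1, 1, f2)), requires_grad=True)
                self.conv_params[p] = (w1, b1, w2, b2)
                self.params += [w1, b1, w2, b2]
        self.d = sum(feature_length(len(idx), cfg) for _, idx in cluster_map.clusters)
        h = cfg.rnn_hidden
        # RNN input = CNN features + the mask bit and time gap for the direction
        d_in = self.d + 2
        self.rnn = {}
        for direction in ("f", "b"):
            wx = Tensor(_glorot(rng, d_in, h, (d_in, h)), requires_grad=True)
            wh = Tensor(_orthogonal(rng, h), requires_grad=True)
            bh = Tensor(np.zeros(h), requires_grad=True)
            wo = Tensor(_glorot(rng, h, n_taxa, (h, n_taxa)), requires_grad=True)
            bo = Tensor(np.zeros(n_taxa), requires_grad=True)
            self.rnn[direction] = (wx, wh, bh, wo, bo)
            self.params += [wx, wh, bh, wo, bo]
        # scalar decay weights per direction; bias ln2 starts both lambdas at
        # 0.5 so the initial blend of the two directions is not doubled
        ln2 = float(np.log(2.0))
        self.w_lambda_f = Tensor(np.array(0.1), requires_grad=True)
        self.b_lambda_f = Tensor(np.array(ln2), requires_grad=True)
        self.w_lambda_b = Tensor(np.array(0.1), requires_grad=True)
        self.b_lambda_b = Tensor(np.array(ln2), requires_grad=True)
        self.params += [self.w_lambda_f, self.b_lambda_f,
                        self.w_lambda_b, self.b_lambda_b]

    def extract_features(self, x: np.ndarray, training: bool = False,
                         rng: np.random.Generator | None = None) -> Tensor:
        """Per-cluster CNN features per timepoint: (S, k, n) -> (S, k, d)."""
        s, k, n = x.shape
        if n != self.n_taxa:
            raise MicrogenError("input taxa do not match the cluster map")
        flat = x.reshape(s * k, n)
        feat_of = {}
        for p, names in sorted(self.size_groups.items()):
            stacked = np.stack([flat[:, self._cluster_idx[name]] for name in names])
            t = Tensor(stacked[..., None])  # (G, B, p, 1)
            w1, b1, w2, b2 = self.conv_params[p]
            t = ad.conv1d_grouped(t, w1, b1)
            t = ad.leaky_relu(t, self.cfg.leaky_relu_slope)
            t = ad.maxpool1d(t, self.cfg.pool_size)
            t = ad.conv1d_grouped(t, w2, b2)
            t = ad.leaky_relu(t, self.cfg.leaky_relu_slope)
            t = ad.maxpool1d(t, self.cfg.pool_size)
            if training and rng is not None:
                # one dropout per cluster module, on its output features
                t = ad.dropout(t, self.cfg.dropout_rate, rng, training)
            t = ad.reshape(t, (len(names), s * k, -1))
            for gi, name in enumerate(names):
                feat_of[name] = t[gi]
        pieces = []
        for name, idx in self.cluster_map.clusters:
            if name in feat_of:
                pieces.append(feat_of[name])
            else:
                pieces.append(Tensor(flat[:, idx]))
        feats = ad.concat(pieces, axis=1)
        return ad.reshape(feats, (s, k, self.d))

    def forward(self, x: np.ndarray, e: np.ndarray, delta_f: np.ndarray,
                delta_b: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> GeneratorOutput:
        """Generate x_tilde and the passthrough blend x_bar for a batch.

        Each direction's output at timestep i comes from the hidden state
        of the PREVIOUS step in that direction (one-step-ahead alignment,
        as in recurrent imputation models): the network predicts a sample
        from its history/future rather than reading it from its own input.
        """
        s, k, _ = x.shape
        # standardized inputs; missing samples remain exact zero vectors
        x_std = ((x - self.mu) / self.sd) * e[:, :, None]
        feats = self.extract_features(x_std, training=training, rng=rng)
        zero_h = Tensor(np.zeros((s, 1, self.cfg.rnn_hidden)))
        mu_t = Tensor(self.mu)
        sd_t = Tensor(self.sd)

        def run_direction(direction, feats_dir, e_dir, delta_dir):
            wx, wh, bh, wo, bo = self.rnn[direction]
            extra = np.concatenate([e_dir[:, :, None], delta_dir[:, :, None]], axis=2)
            inputs = ad.concat([feats_dir, Tensor(extra)], axis=2)
            h = ad.rnn_tanh(inputs, wx, wh, bh)
            h_prev = ad.concat([zero_h, h[:, :-1, :]], axis=1)
            # de-standardize: a zero network output predicts the cohort mean
            return (ad.matmul(h_prev, wo) + bo) * sd_t + mu_t

        e_f = e.astype(float)
        x_tilde_f = run_direction("f", feats, e_f, delta_f)
        x_tilde_b = ad.flip(
            run_direction("b", ad.flip(feats, axis=1), e_f[:, ::-1],
                          delta_b[:, ::-1]),
            axis=1,
        )

        lam_f = decay_factor(delta_f, self.w_lambda_f, self.b_lambda_f)
        lam_b = decay_factor(delta_b, self.w_lambda_b, self.b_lambda_b)
        lam_f3 = ad.reshape(lam_f, (*delta_f.shape, 1))
        lam_b3 = ad.reshape(lam_b, (*delta_b.shape, 1))
        x_tilde = lam_f3 * x_tilde_f + lam_b3 * x_tilde_b
        e3 = Tensor(e[:, :, None].astype(float))
        one_minus_e3 = Tensor(1.0 - e[:, :, None].astype(float))
        x_bar = Tensor(x) * e3 + x_tilde * one_minus_e3
        for t in (x_tilde, x_bar):
            if not np.all(np.isfinite(t.data)):
                raise MicrogenError("non-finite value in generator output (divergence)")
        return GeneratorOutput(
            x_tilde_f=x_tilde_f, x_tilde_b=x_tilde_b, x_tilde=x_tilde,
            x_bar=x_bar, lambda_f=lam_f, lambda_b=lam_b,
        )

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p.data[...] = s


class Discriminator:
    """LSTM over timesteps with real/fake and timepoint-prediction heads."""

    def __init__(self, n_taxa: int, n_timepoints: int, cfg: DiscriminatorConfig,
                 rng: np.random.Generator):
        u = cfg.lstm_units
        self.k = n_timepoints
        self.cfg = cfg
        self.wx = Tensor(_glorot(rng, n_taxa, 4 * u, (n_taxa, 4 * u)), requires_grad=True)
        self.wh = Tensor(_glorot(rng, u, 4 * u, (u, 4 * u)), requires_grad=True)
        self.b = Tensor(np.zeros(4 * u), requires_grad=True)
        self.w_real = Tensor(_glorot(rng, u, 1, (u, 1)), requires_grad=True)
        self.b_real = Tensor(np.zeros(1), requires_grad=True)
        self.w_time = Tensor(_glorot(rng, u, n_timepoints, (u, n_timepoints)),
                             requires_grad=True)
        self.b_time = Tensor(np.zeros(n_timepoints), requires_grad=True)
        self.params = [self.wx, self.wh, self.b, self.w_real, self.b_real,
                       self.w_time, self.b_time]

    def forward(self, x_masked) -> tuple[Tensor, Tensor, Tensor]:
        """Score a batch of (possibly masked) sample sequences.

        Returns (p_real (S,), timepoint_probs (S, k, k) with rows summing
        to 1, logit (S,)).  The logit is exposed so training can use the
        saturation-free log-sigmoid form of the binary cross-entropy.
        """
        x_masked = ad.astensor(x_masked)
        h = ad.lstm(x_masked, self.wx, self.wh, self.b)
        h_last = h[:, -1, :]
        logit = ad.reshape(ad.matmul(h_last, self.w_real) + self.b_real, (-1,))
        p_real = ad.sigmoid(logit)
        timepoint_probs = ad.softmax(ad.matmul(h, self.w_time) + self.b_time, axis=-1)
        return p_real, timepoint_probs, logit

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p.data[...] = s
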