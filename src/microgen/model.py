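"""Adversarial imputation model: losses, training loop, Model/Results API.

`MicrobiomeGANImputer` follows the statsmodels convention: the model
object is built from data (a clr-transformed cohort plus its time gaps
and phylum cluster map), `fit()` runs the adversarial training loop and
returns an `ImputerResults` carrying the best weights, the full loss
trace and an `impute()` method.

Training schedule: per epoch the discriminator takes five Adam steps on
the current generator output, then the generator takes one step on
loss = lossG + lossR + lossC.  Training stops when the total generator
loss has not reached a new minimum for `patience_epochs` consecutive
epochs; the best weights are restored.
"""

from __future__ import annotations

import dataclasses
import json
import logging

import numpy as np
import pandas as pd

from . import _autodiff as ad
from ._autodiff import Adam, Tensor
from .datasets import (ClrDataset, ImputationResult, LongitudinalDataset,
                       MicrogenError, TimeGapPair, add_pseudocount,
                       clr_transform, time_gaps)
from .networks import (Discriminator, DiscriminatorConfig, Generator,
                       GeneratorConfig, GeneratorOutput)
from .phylo import PhylumClusterMap, build_cluster_map

logger = logging.getLogger(__name__)

LOG_CLAMP = 1e-7

__all__ = [
    "TrainingConfig",
    "TrainingDivergedError",
    "generator_loss",
    "discriminator_loss",
    "MicrobiomeGANImputer",
    "ImputerResults",
]


class TrainingDivergedError(MicrogenError):
    """Raised when a NaN loss appears; carries the epoch index."""

    def __init__(self, epoch: int):
        super().__init__(f"training diverged (NaN loss) at epoch {epoch}")
        self.epoch = epoch


@dataclasses.dataclass
class TrainingConfig:
    learning_rate: float = 1e-3
    d_steps_per_g_step: int = 5
    patience_epochs: int = 1000
    max_epochs: int = 20000
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.d_steps_per_g_step <= 0:
            raise MicrogenError("learning_rate and d_steps_per_g_step must be positive")
        if self.patience_epochs < 0 or self.max_epochs <= 0:
            raise MicrogenError("patience_epochs must be >= 0 and max_epochs > 0")


def _clog(p: Tensor) -> Tensor:
    """log with the argument clamped away from 0/1 for numerical stability."""
    return ad.log(ad.clamp(p, LOG_CLAMP, 1.0 - LOG_CLAMP))


def _recon_losses(x: np.ndarray, e: np.ndarray, outputs: GeneratorOutput):
    """lossR and lossC shared by the public loss function and the trainer."""
    n_obs = e.sum()
    if n_obs == 0:
        raise MicrogenError("no observed samples: lossR undefined")
    k = x.shape[1]
    e3 = Tensor(e[:, :, None])
    diff = ad.absolute(Tensor(x) - outputs.x_tilde) * e3
    loss_r = ad.tsum(diff) * Tensor(1.0 / n_obs)
    cons = ad.absolute(outputs.x_tilde_f - outputs.x_tilde_b)
    loss_c = ad.tsum(cons) * Tensor(1.0 / (k * x.shape[0]))
    return loss_r, loss_c


def _timepoint_ce(timepoint_probs, true_timepoints=None):
    """Cross-entropy of per-timestep timepoint predictions, mean over subjects."""
    probs = ad.astensor(timepoint_probs)
    s, k, _ = probs.shape
    if true_timepoints is None:
        true_timepoints = np.arange(k)
    onehot = np.zeros((s, k, k))
    onehot[:, np.arange(k), np.asarray(true_timepoints, dtype=int)] = 1.0
    return ad.tsum(Tensor(onehot) * (-_clog(probs))) * Tensor(1.0 / s)


def generator_loss(x, e, outputs: GeneratorOutput, d_fake_prob):
    """Total generator loss and its three components.

    lossG = -log D(x_bar * (1-e)) (mean over subjects);
    lossR = sum_i ||(x_i - x_tilde_i) e_i||_1 / ||e||_1 pooled over the batch;
    lossC = (1/k) sum_i ||x_tilde_f_i - x_tilde_b_i||_1 (mean over subjects).
    """
    x = np.asarray(x, dtype=float)
    e = np.asarray(e, dtype=float)
    loss_g = ad.tmean(-_clog(ad.astensor(d_fake_prob)))
    loss_r, loss_c = _recon_losses(x, e, outputs)
    total = loss_g + loss_r + loss_c
    return total, loss_g, loss_r, loss_c


def discriminator_loss(d_real_prob, d_fake_prob, timepoint_probs,
                       true_timepoints=None):
    """Discriminator loss: binary cross-entropy plus timepoint cross-entropy.

    lossD = -log D(real) - log(1 - D(fake)) (mean over subjects);
    lossT = -sum_i y(i) log(y_hat(i)) summed over the k timesteps with
    one-hot targets equal to each timestep's own index (mean over subjects).
    """
    p_real = ad.astensor(d_real_prob)
    p_fake = ad.astensor(d_fake_prob)
    loss_d = ad.tmean(-_clog(p_real)) + ad.tmean(-_clog(ad.astensor(1.0) - p_fake))
    loss_t = _timepoint_ce(timepoint_probs, true_timepoints)
    total = loss_d + loss_t
    return total, loss_d, loss_t


@dataclasses.dataclass
class _FitState:
    generator: Generator
    discriminator: Discriminator | None
    history: pd.DataFrame
    best_epoch: int
    stopped_epoch: int
    hit_cap: bool


class MicrobiomeGANImputer:
    """Adversarial imputer for a masked longitudinal microbiome cohort.

    Parameters
    ----------
    clr_data : ClrDataset
        Pseudo-counted, clr-transformed cohort (missing samples zero rows).
    gaps : TimeGapPair, optional
        Forward/backward time gaps; computed from the data when omitted.
    cluster_map : PhylumClusterMap, optional
        Phylum clusters with correlation ordering; built when omitted.
    variant : {"full", "bigan", "rnn"}
        "full" is the CNN + biRNN GAN; "bigan" drops the CNN feature
        extractor; "rnn" additionally drops the discriminator and trains
        on reconstruction + consistency only.
    """

    def __init__(self, clr_data: ClrDataset, gaps: TimeGapPair | None = None,
                 cluster_map: PhylumClusterMap | None = None,
                 variant: str = "full",
                 generator_config: GeneratorConfig | None = None,
                 discriminator_config: DiscriminatorConfig | None = None):
        if variant not in ("full", "bigan", "rnn"):
            raise MicrogenError(f"unknown variant {variant!r}")
        self.clr_data = clr_data
        self.gaps = gaps if gaps is not None else time_gaps(clr_data.source)
        self.cluster_map = cluster_map if cluster_map is not None else build_cluster_map(clr_data)
        self.variant = variant
        gcfg = generator_config if generator_config is not None else GeneratorConfig()
        if variant in ("bigan", "rnn"):
            gcfg = dataclasses.replace(gcfg, use_cnn=False)
        self.generator_config = gcfg
        self.discriminator_config = (discriminator_config
                                     if discriminator_config is not None
                                     else DiscriminatorConfig())

    @classmethod
    def from_dataset(cls, ds: LongitudinalDataset, **kwargs) -> "MicrobiomeGANImputer":
        """Build the model from a raw relative-abundance cohort.

        Applies the pseudo-count and clr transform; the recorded
        pseudo-count travels with the results for RA post-processing.
        """
        clr = clr_transform(add_pseudocount(ds))
        return cls(clr, **kwargs)

    def fit(self, training_config: TrainingConfig | None = None,
            **kwargs) -> "ImputerResults":
        """Run adversarial training and return the fitted results object."""
        tcfg = training_config if training_config is not None else TrainingConfig(**kwargs)
        ds = self.clr_data.source
        if ds.n_subjects < 2 or np.any(ds.mask.sum(axis=1) < 1):
            raise MicrogenError("need >=2 subjects each with >=1 observed sample")
        state = self._train(tcfg)
        return ImputerResults(self, state, tcfg)

    # ------------------------------------------------------------------
    def _train(self, tcfg: TrainingConfig) -> _FitState:
        rng = np.random.default_rng(tcfg.seed)
        x = self.clr_data.clr_values
        e = ds_mask = self.clr_data.mask.astype(float)
        s, k, n = x.shape
        use_d = self.variant != "rnn"
        obs_vals = x[self.clr_data.mask == 1]
        mu = obs_vals.mean(axis=0)
        sd = obs_vals.std(axis=0)
        sd[sd < 1e-6] = 1.0
        gen = Generator(n, k, self.cluster_map, self.generator_config, rng,
                        input_stats=(mu, sd))
        disc = Discriminator(n, k, self.discriminator_config, rng) if use_d else None
        opt_g = Adam(gen.params, lr=tcfg.learning_rate)
        opt_d = Adam(disc.params, lr=tcfg.learning_rate) if use_d else None
        df, db = self.gaps.delta_f, self.gaps.delta_b
        e3 = e[:, :, None]

        records = []
        best = np.inf
        best_epoch = -1
        best_state = None
        hit_cap = False
        epoch = 0
        while True:
            out = gen.forward(x, ds_mask, df, db, training=True, rng=rng)
            x_bar = out.x_bar.data
            loss_d_val = loss_t_val = np.nan
            if use_d:
                # discriminator sees standardized values (unit scale)
                x_bar_std = (x_bar - mu) / sd
                real_in = x_bar_std * e3
                fake_in = x_bar_std * (1.0 - e3)
                both = Tensor(np.concatenate([real_in, fake_in], axis=0))
                for _ in range(tcfg.d_steps_per_g_step):
                    p_all, tp_all, _ = disc.forward(both)
                    d_total, loss_d, loss_t = discriminator_loss(
                        p_all[:s], p_all[s:], tp_all[:s])
                    if not np.isfinite(d_total.item()):
                        raise TrainingDivergedError(epoch)
                    opt_d.zero_grad()
                    d_total.backward()
                    opt_d.step()
                loss_d_val, loss_t_val = loss_d.item(), loss_t.item()
                p_fake_g, _, _ = disc.forward(
                    (out.x_bar + Tensor(-mu)) * Tensor((1.0 - e3) / sd))
                loss_g = ad.tmean(-_clog(p_fake_g))
            else:
                # no discriminator: lossG is pinned at -log(1/2)
                loss_g = Tensor(np.log(2.0))
            loss_r, loss_c = _recon_losses(x, e, out)
            g_total = loss_g + loss_r + loss_c
            if self.variant == "rnn":
                g_obj = loss_r + loss_c
            else:
                g_obj = g_total
            val = g_total.item()
            if not np.isfinite(val):
                raise TrainingDivergedError(epoch)
            opt_g.zero_grad()
            if use_d:
                opt_d.zero_grad()
            g_obj.backward()
            opt_g.step()
            records.append((epoch, val, loss_g.item(), loss_r.item(),
                            loss_c.item(), loss_d_val, loss_t_val))
            if val < best:
                best = val
                best_epoch = epoch
                best_state = (gen.state(), disc.state() if use_d else None)
            epoch += 1
            if epoch - 1 - best_epoch >= tcfg.patience_epochs:
                break
            if epoch >= tcfg.max_epochs:
                hit_cap = True
                logger.warning("max_epochs cap (%d) reached", tcfg.max_epochs)
                break
        gen.load_state(best_state[0])
        if use_d and best_state[1] is not None:
            disc.load_state(best_state[1])
        history = pd.DataFrame(
            records,
            columns=["epoch", "loss_total", "loss_g", "loss_r", "loss_c",
                     "loss_d", "loss_t"],
        )
        return _FitState(gen, disc, history, best_epoch, epoch - 1, hit_cap)


class ImputerResults:
    """Fitted adversarial imputer: weights, loss trace, imputation, summary."""

    def __init__(self, model: MicrobiomeGANImputer, state: _FitState,
                 training_config: TrainingConfig):
        self.model = model
        self._state = state
        self.training_config = training_config
        self.loss_history = state.history
        self.best_epoch = state.best_epoch
        self.stopped_epoch = state.stopped_epoch
        self.pseudo_count = model.clr_data.pseudo_count
        self.taxon_ids = list(model.clr_data.source.taxon_ids)

    def impute(self, clr: ClrDataset | None = None,
               gaps: TimeGapPair | None = None) -> ImputationResult:
        """Impute missing samples on the clr scale; observed entries pass through."""
        if clr is None:
            clr = self.model.clr_data
        if list(clr.source.taxon_ids) != self.taxon_ids:
            raise MicrogenError("taxon set does not match the fitted model")
        if gaps is None:
            gaps = time_gaps(clr.source) if clr is not self.model.clr_data else self.model.gaps
        out = self._state.generator.forward(
            clr.clr_values, clr.mask.astype(float), gaps.delta_f, gaps.delta_b,
            training=False,
        )
        # final passthrough in float64: observed entries equal the input exactly
        e3 = clr.mask[:, :, None].astype(np.float64)
        x_bar = clr.clr_values * e3 + out.x_tilde.data.astype(np.float64) * (1.0 - e3)
        return ImputationResult(
            clr_values=x_bar, mask=clr.mask.copy(),
            method=f"gan_{self.model.variant}",
        )

    def summary(self) -> str:
        h = self.loss_history
        cmap = self.model.cluster_map
        lines = [
            "Adversarial longitudinal microbiome imputer",
            "=" * 45,
            f"variant:            {self.model.variant}",
            f"subjects x timepoints x taxa: "
            f"{self.model.clr_data.clr_values.shape}",
            f"phylum clusters:    {len(cmap.clusters)}",
            f"feature dimension:  {self._state.generator.d}",
            f"epochs run:         {len(h)} (stopped at {self.stopped_epoch})",
            f"best epoch:         {self.best_epoch}",
            f"best total G loss:  {h.loss_total.min():.4f}",
            f"final lossR:        {h.loss_r.iloc[-1]:.4f}",
            f"pseudo-count:       {self.pseudo_count:.3e}",
            f"seed:               {self.training_config.seed}",
        ]
        if self._state.hit_cap:
            lines.append("warning: max_epochs cap reached before the loss plateaued")
        return "\n".join(lines)

    # Checkpointing ----------------------------------------------------
    def save(self, path) -> None:
        """Write a JSON checkpoint: weights, configs, cluster map, pseudo-count."""
        gen = self._state.generator
        disc = self._state.discriminator
        payload = {
            "variant": self.model.variant,
            "generator_config": dataclasses.asdict(self.model.generator_config),
            "discriminator_config": dataclasses.asdict(self.model.discriminator_config),
            "training_config": dataclasses.asdict(self.training_config),
            "pseudo_count": self.pseudo_count,
            "taxon_ids": self.taxon_ids,
            "cluster_map": json.loads(self.model.cluster_map.to_json()),
            "n_timepoints": int(self.model.clr_data.clr_values.shape[1]),
            "input_stats": [gen.mu.tolist(), gen.sd.tolist()],
            "generator_state": [w.tolist() for w in gen.state()],
            "discriminator_state": ([w.tolist() for w in disc.state()]
                                    if disc is not None else None),
            "best_epoch": self.best_epoch,
            "stopped_epoch": self.stopped_epoch,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path, clr: ClrDataset,
             gaps: TimeGapPair | None = None) -> "ImputerResults":
        """Rebuild a fitted imputer from a checkpoint for a compatible dataset."""
        with open(path) as fh:
            payload = json.load(fh)
        if list(clr.source.taxon_ids) != payload["taxon_ids"]:
            raise MicrogenError("taxon set does not match the checkpoint")
        gcfg_d = payload["generator_config"]
        gcfg_d["conv_filters"] = tuple(gcfg_d["conv_filters"])
        gcfg = GeneratorConfig(**gcfg_d)
        dcfg = DiscriminatorConfig(**payload["discriminator_config"])
        cmap = PhylumClusterMap.from_json(json.dumps(payload["cluster_map"]),
                                          payload["taxon_ids"])
        model = MicrobiomeGANImputer(clr, gaps=gaps, cluster_map=cmap,
                                     variant=payload["variant"],
                                     generator_config=gcfg,
                                     discriminator_config=dcfg)
        rng = np.random.default_rng(0)
        n = len(payload["taxon_ids"])
        k = payload["n_timepoints"]
        stats = payload.get("input_stats")
        gen = Generator(n, k, cmap, gcfg, rng,
                        input_stats=None if stats is None else
                        (np.asarray(stats[0]), np.asarray(stats[1])))
        gen.load_state([np.asarray(w) for w in payload["generator_state"]])
        disc = None
        if payload["discriminator_state"] is not None:
            disc = Discriminator(n, k, dcfg, rng)
            disc.load_state([np.asarray(w) for w in payload["discriminator_state"]])
        state = _FitState(gen, disc, pd.DataFrame(
            columns=["epoch", "loss_total", "loss_g", "loss_r", "loss_c",
                     "loss_d", "loss_t"]),
            payload["best_epoch"], payload["stopped_epoch"], False)
        tcfg = TrainingConfig(**payload["training_config"])
        return cls(model, state, tcfg)
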