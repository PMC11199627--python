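"""Variational autoencoder with a recurrent meal-slot decoder.

The encoder maps the length-10 user-profile vector through one fully
connected ReLU layer to hidden size 256, then two linear maps produce the
mean and log-variance of a diagonal Gaussian over a 256-dimensional latent
space; a latent sample z = mu + sigma * eps (reparameterization trick) seeds
the decoder. The decoder is a stacked GRU (2 layers x 512 units by default)
unrolled for the six daily meal slots: at t=1 it consumes a linear projection
of z, and at t>1 it consumes its own previous top-layer hidden state. Each
step feeds three heads sharing the hidden state: a meal classifier over the
full vocabulary (logits masked to the slot's admissible meal type before the
softmax, so wrong-type meals get probability exactly zero), a slot-energy
head, and a slot-nutrient head; energy/nutrient head outputs are summed over
the six steps to predict the plan totals used by the training losses. At
inference, plan energy and nutrients are instead computed from the selected
meals' database values, which the portion optimizer requires.

Parameters live in a flat dict of autodiff Tensors; initialization is
uniform fan-in, fully determined by the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from .autodiff import Tensor, log_softmax_masked

N_SLOTS = 6
N_NUTRIENTS = 4


@dataclass(frozen=True)
class ModelConfig:
    vocab_size: int
    input_dim: int = 10
    encoder_hidden: int = 256
    latent_dim: int = 256
    decoder_layers: int = 2
    decoder_hidden: int = 512
    n_slots: int = N_SLOTS
    seed: int = 0

    def __post_init__(self):
        for name in ("vocab_size", "input_dim", "encoder_hidden",
                     "latent_dim", "decoder_layers", "decoder_hidden"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_slots != N_SLOTS:
            raise ValueError("the decoder is defined over exactly 6 slots")


@dataclass
class LatentState:
    """Encoder output: mu, log sigma^2, the noise draw and z = mu + sigma*eps."""
    mu: Tensor
    log_var: Tensor
    eps: np.ndarray
    z: Tensor


@dataclass
class DecoderTrace:
    """Per-slot decoder outputs needed by the losses and the planner."""
    hidden: list            # T top-layer hidden-state Tensors, each (B, H)
    log_probs: list         # T Tensors (B, M), slot-masked log-softmax
    y_hat: np.ndarray       # (B, T) argmax meal indices over admissible classes
    ei_hat: Tensor          # (B,) predicted plan energy (normalized units)
    nutr_hat: Tensor        # (B, 4) predicted plan macronutrients

    @property
    def probs(self) -> np.ndarray:
        """(B, T, M) class probabilities; masked classes are exactly 0."""
        return np.stack([np.exp(lp.data) * (lp.data > -1e29)
                         for lp in self.log_probs], axis=1)


def _init_params(config: ModelConfig) -> dict[str, Tensor]:
    rng = np.random.default_rng(config.seed)
    params: dict[str, Tensor] = {}

    def linear(name: str, fan_in: int, fan_out: int) -> None:
        bound = 1.0 / np.sqrt(fan_in)
        params[f"{name}_W"] = Tensor(
            rng.uniform(-bound, bound, size=(fan_in, fan_out)),
            requires_grad=True)
        params[f"{name}_b"] = Tensor(
            rng.uniform(-bound, bound, size=(fan_out,)), requires_grad=True)

    u, H, d = config.input_dim, config.encoder_hidden, config.latent_dim
    D, M = config.decoder_hidden, config.vocab_size
    linear("enc", u, H)
    linear("mu", H, d)
    linear("lv", H, d)
    linear("proj", d, D)        # latent -> first GRU input
    for layer in range(config.decoder_layers):
        in_dim = D              # t=1 input and h(t-1) feedback are both dim D
        linear(f"gru{layer}_i", in_dim, 3 * D)
        linear(f"gru{layer}_h", D, 3 * D)
    linear("cls", D, M)
    linear("ei", D, 1)
    linear("nutr", D, N_NUTRIENTS)
    return params


def _gru_cell(x: Tensor, h: Tensor, wi: Tensor, bi: Tensor,
              wh: Tensor, bh: Tensor, hidden: int) -> Tensor:
    """Standard GRU cell; gate order (reset, update, new)."""
    gi = x @ wi + bi
    gh = h @ wh + bh

    def chunk(t: Tensor, k: int) -> Tensor:
        return t.slice_cols(k * hidden, (k + 1) * hidden)

    r = (chunk(gi, 0) + chunk(gh, 0)).sigmoid()
    z = (chunk(gi, 1) + chunk(gh, 1)).sigmoid()
    n = (chunk(gi, 2) + r * chunk(gh, 2)).tanh()
    return (1.0 - z) * n + z * h


class DietVAE:
    """The full generative model plus everything needed to run it."""

    def __init__(self, config: ModelConfig,
                 params: dict[str, Tensor] | None = None,
                 bounds: dict | None = None, vocab_hash: str | None = None):
        self.config = config
        self.params = params if params is not None else _init_params(config)
        self.bounds = bounds          # normalization bounds used at training
        self.vocab_hash = vocab_hash  # hash of the training meal vocabulary

    # -- forward passes -------------------------------------------------------

    def encode(self, x: np.ndarray, eps: np.ndarray | None = None,
               rng: np.random.Generator | None = None) -> LatentState:
        """Profile batch (B, u) -> latent state; eps may be supplied for
        deterministic replay, otherwise drawn from ``rng``."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.config.input_dim:
            raise ValueError(
                f"expected input dim {self.config.input_dim}, got {x.shape[1]}")
        p = self.params
        xt = Tensor(x)
        hidden = (xt @ p["enc_W"] + p["enc_b"]).relu()
        mu = hidden @ p["mu_W"] + p["mu_b"]
        log_var = hidden @ p["lv_W"] + p["lv_b"]
        if eps is None:
            rng = rng if rng is not None else np.random.default_rng(
                self.config.seed)
            eps = rng.standard_normal(mu.shape)
        eps = np.asarray(eps, dtype=np.float64)
        if eps.shape != mu.shape:
            raise ValueError(f"eps shape {eps.shape} != latent {mu.shape}")
        z = mu + (log_var * 0.5).exp() * Tensor(eps)
        return LatentState(mu=mu, log_var=log_var, eps=eps, z=z)

    def decode(self, z: Tensor | np.ndarray,
               slot_masks: np.ndarray) -> DecoderTrace:
        """Unroll the GRU for the six slots under per-slot class masks.

        ``slot_masks`` is (6, M) or (B, 6, M) boolean; an all-false slot row
        is a generation error.
        """
        cfg, p = self.config, self.params
        z = z if isinstance(z, Tensor) else Tensor(np.atleast_2d(z))
        batch = z.shape[0]
        slot_masks = np.asarray(slot_masks, dtype=bool)
        if slot_masks.ndim == 2:
            slot_masks = np.broadcast_to(slot_masks,
                                         (batch,) + slot_masks.shape)
        if slot_masks.shape != (batch, cfg.n_slots, cfg.vocab_size):
            raise ValueError("slot_masks shape mismatch")
        if not slot_masks.any(axis=2).all():
            raise ValueError("a slot mask admits no meals")

        h_layers = [Tensor(np.zeros((batch, cfg.decoder_hidden)))
                    for _ in range(cfg.decoder_layers)]
        x_in = z @ p["proj_W"] + p["proj_b"]
        hidden, log_probs, y_hat = [], [], []
        ei_hat: Tensor | None = None
        nutr_hat: Tensor | None = None
        for t in range(cfg.n_slots):
            inp = x_in
            for layer in range(cfg.decoder_layers):
                h_layers[layer] = _gru_cell(
                    inp, h_layers[layer],
                    p[f"gru{layer}_i_W"], p[f"gru{layer}_i_b"],
                    p[f"gru{layer}_h_W"], p[f"gru{layer}_h_b"],
                    cfg.decoder_hidden)
                inp = h_layers[layer]
            h_top = h_layers[-1]
            hidden.append(h_top)
            logits = h_top @ p["cls_W"] + p["cls_b"]
            logp = log_softmax_masked(logits, slot_masks[:, t, :])
            log_probs.append(logp)
            masked = np.where(slot_masks[:, t, :], logp.data, -np.inf)
            y_hat.append(masked.argmax(axis=1))
            ei_t = (h_top @ p["ei_W"] + p["ei_b"]).sum(axis=1)
            nutr_t = h_top @ p["nutr_W"] + p["nutr_b"]
            ei_hat = ei_t if ei_hat is None else ei_hat + ei_t
            nutr_hat = nutr_t if nutr_hat is None else nutr_hat + nutr_t
            x_in = h_top  # Eq-style feedback: previous hidden is next input
        return DecoderTrace(hidden=hidden, log_probs=log_probs,
                            y_hat=np.stack(y_hat, axis=1),
                            ei_hat=ei_hat, nutr_hat=nutr_hat)

    def forward(self, x: np.ndarray, slot_masks: np.ndarray,
                eps: np.ndarray | None = None,
                rng: np.random.Generator | None = None
                ) -> tuple[LatentState, DecoderTrace]:
        latent = self.encode(x, eps=eps, rng=rng)
        return latent, self.decode(latent.z, slot_masks)

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        meta = {"config": asdict(self.config), "bounds": self.bounds,
                "vocab_hash": self.vocab_hash}
        arrays = {name: t.data for name, t in self.params.items()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path, expected_vocab_hash: str | None = None) -> "DietVAE":
        with np.load(path) as archive:
            meta = json.loads(archive["__meta__"].tobytes().decode())
            config = ModelConfig(**meta["config"])
            params = {name: Tensor(archive[name], requires_grad=True)
                      for name in archive.files if name != "__meta__"}
        model = cls(config, params=params, bounds=meta.get("bounds"),
                    vocab_hash=meta.get("vocab_hash"))
        reference = _init_params(config)
        if set(params) != set(reference):
            raise ValueError("checkpoint incompatible with model config")
        for name, tensor in params.items():
            if tensor.shape != reference[name].shape:
                raise ValueError(f"checkpoint shape mismatch for {name}")
        if (expected_vocab_hash is not None and model.vocab_hash is not None
                and expected_vocab_hash != model.vocab_hash):
            raise ValueError("checkpoint was trained on a different meal "
                             "vocabulary")
        return model
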