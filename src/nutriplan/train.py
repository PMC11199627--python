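"""Reproducible minibatch training of the generative model.

Wires profiles, ground-truth plans and the meal database into the four-term
loss: meal cross-entropy against the label plans, KL divergence of the
latent posterior, MSE on the plan energy (normalized units) and the
macronutrient range penalty applied to the nutrient head (targets normalized
with the same constant so the unweighted sum stays balanced). Optimization
is Adam, and every source of randomness — parameter init, the train/test
split, batch order and the reparameterization noise — derives from explicit
seeds, so a fixed seed reproduces the run exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import losses as L
from .autodiff import Tensor
from .meals import MealDatabase
from .model import DietVAE, ModelConfig
from .profiles import (UserProfile, derive_macro_targets, encode_profile,
                       ensure_target_ei, load_guidelines)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 64
    epochs: int = 500
    train_fraction: float = 0.8
    seed: int = 0
    loss_weights: tuple = (1.0, 1.0, 1.0, 1.0)  # (macro, ei, kld, mc)
    energy_scale: float = L.ENERGY_SCALE        # kcal per normalized unit

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        for name in ("learning_rate", "batch_size", "epochs", "energy_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PlanDataset:
    """Flat training arrays derived from profiles + truth plans + meal db."""
    x: np.ndarray            # (N, u) encoded profiles
    y: np.ndarray            # (N, 6) ground-truth meal ids
    ei: np.ndarray           # (N,) energy targets, kcal
    macro_min: np.ndarray    # (N, 4) grams
    macro_max: np.ndarray    # (N, 4) grams
    profile_ids: np.ndarray  # (N,) owning profile of each plan

    def __len__(self) -> int:
        return len(self.x)

    def subset(self, idx) -> "PlanDataset":
        return PlanDataset(self.x[idx], self.y[idx], self.ei[idx],
                           self.macro_min[idx], self.macro_max[idx],
                           self.profile_ids[idx])


def build_dataset(profiles, truth_plans, guidelines: dict | None = None
                  ) -> PlanDataset:
    guidelines = guidelines if guidelines is not None else load_guidelines()
    bounds = guidelines["normalization_bounds"]
    by_id = {p.user_id: p for p in profiles}
    enc_cache, target_cache = {}, {}
    rows_x, rows_y, rows_ei, rows_lo, rows_hi, rows_pid = [], [], [], [], [], []
    for tp in truth_plans:
        profile = by_id[tp.profile_id]
        if tp.profile_id not in enc_cache:
            enc_cache[tp.profile_id] = encode_profile(profile, bounds)
            lo, hi = derive_macro_targets(profile, guidelines).as_arrays()
            target_cache[tp.profile_id] = (ensure_target_ei(profile), lo, hi)
        ei, lo, hi = target_cache[tp.profile_id]
        rows_x.append(enc_cache[tp.profile_id])
        rows_y.append(tp.plan.meal_ids)
        rows_ei.append(ei)
        rows_lo.append(lo)
        rows_hi.append(hi)
        rows_pid.append(tp.profile_id)
    return PlanDataset(np.array(rows_x), np.array(rows_y),
                       np.array(rows_ei, dtype=float), np.array(rows_lo),
                       np.array(rows_hi), np.array(rows_pid))


def split_dataset(data: PlanDataset, train_fraction: float = 0.8,
                  seed: int = 0) -> tuple[PlanDataset, PlanDataset]:
    """Split by profile (all of a user's plans land on one side)."""
    ids = pd.unique(data.profile_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 profiles to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    train_ids = set(ids[perm[:n_train]])
    train_mask = np.array([pid in train_ids for pid in data.profile_ids])
    return data.subset(train_mask), data.subset(~train_mask)


class Adam:
    """Standard Adam on a dict of parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, tensor in self.params.items():
            if tensor.grad is None:
                continue
            g = tensor.grad
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            m_hat = self.m[key] / (1 - b1 ** self.t)
            v_hat = self.v[key] / (1 - b2 ** self.t)
            tensor.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for tensor in self.params.values():
            tensor.grad = None


def _batch_loss(model: DietVAE, db_masks: np.ndarray, batch: PlanDataset,
                config: TrainConfig, eps: np.ndarray) -> L.LossBundle:
    latent, trace = model.forward(batch.x, db_masks, eps=eps)
    scale = config.energy_scale
    l_macro = L.macro_penalty(trace.nutr_hat, batch.macro_min / scale,
                              batch.macro_max / scale)
    l_ei = L.energy_loss(trace.ei_hat, batch.ei / scale)
    l_kld = L.kld(latent.mu, latent.log_var)
    l_mc = L.meal_cross_entropy(trace.log_probs, batch.y)
    return L.total_loss(l_macro, l_ei, l_kld, l_mc,
                        weights=config.loss_weights)


def train(model: DietVAE, db: MealDatabase, data: PlanDataset,
          config: TrainConfig = TrainConfig(),
          val_data: PlanDataset | None = None
          ) -> tuple[DietVAE, pd.DataFrame]:
    """Minibatch gradient descent on the total loss.

    Returns the trained model (parameters updated in place; the best
    validation cross-entropy snapshot is restored at the end when
    ``val_data`` is given) and the per-epoch loss log with the four terms
    and their weighted sum.
    """
    if model.config.vocab_size != db.vocab_size:
        raise ValueError("model vocabulary does not match the meal database")
    if int(data.y.max()) >= db.vocab_size:
        raise ValueError("truth plans reference meals outside the vocabulary")
    masks = db.slot_masks()
    optimizer = Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = []
    best = {"val_mc": np.inf, "params": None, "epoch": -1}
    d = model.config.latent_dim
    for epoch in range(config.epochs):
        order = rng.permutation(len(data))
        sums = np.zeros(5)
        n_batches = 0
        for start in range(0, len(data), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = data.subset(idx)
            eps = rng.standard_normal((len(idx), d))
            optimizer.zero_grad()
            bundle = _batch_loss(model, masks, batch, config, eps)
            if not np.isfinite(bundle.total):
                terms = {"macro": bundle.l_macro, "ei": bundle.l_ei,
                         "kld": bundle.l_kld, "mc": bundle.l_mc}
                bad = [k for k, v in terms.items() if not np.isfinite(v)]
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: offending term(s) "
                    f"{bad or 'total'} ({terms})")
            bundle.total_tensor.backward()
            optimizer.step()
            sums += [bundle.l_macro, bundle.l_ei, bundle.l_kld, bundle.l_mc,
                     bundle.total]
            n_batches += 1
        record = dict(zip(("l_macro", "l_ei", "l_kld", "l_mc", "total"),
                          sums / n_batches))
        record["epoch"] = epoch
        if val_data is not None and len(val_data):
            val_eps = np.zeros((len(val_data), d))  # deterministic validation
            val_bundle = _batch_loss(model, masks, val_data, config, val_eps)
            record["val_l_mc"] = val_bundle.l_mc
            if val_bundle.l_mc < best["val_mc"]:
                best.update(val_mc=val_bundle.l_mc, epoch=epoch,
                            params={k: t.data.copy()
                                    for k, t in model.params.items()})
        history.append(record)
    # checkpointing is additive: the best-validation snapshot rides along,
    # the returned parameters are those after the final epoch
    model.best_checkpoint = (None if best["params"] is None else
                             {"epoch": best["epoch"],
                              "val_l_mc": best["val_mc"],
                              "params": best["params"]})
    return model, pd.DataFrame(history)
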