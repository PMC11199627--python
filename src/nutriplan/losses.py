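"""The four guideline-alignment training losses and their sum.

* ``macro_penalty`` — mean over the four macronutrients of
  |min_val(i) - n_i| + |max_val(i) - n_i|. Inside the recommended range this
  is constant (the range width); outside, it grows linearly with distance, so
  its minimum region is exactly the guideline box.
* ``energy_loss`` — mean squared error between predicted and target plan
  energy. Energies are fed in normalized units (kcal / 1000 by default) so
  the unweighted total is not dominated numerically by squared kilocalories.
* ``kld`` — closed-form KL divergence of the diagonal-Gaussian posterior
  N(mu, sigma^2) from the standard normal prior, summed over latent
  dimensions: -1/2 * sum(1 + log sigma^2 - mu^2 - sigma^2).
* ``meal_cross_entropy`` — negative log-likelihood of the ground-truth meal
  id, summed over the six slots.

Batched inputs are averaged over the batch. The total loss is the plain sum
of the four terms; per-term weights (default all 1) are exposed for
experimentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, astensor

#: energies inside the loss are expressed in units of this many kcal
ENERGY_SCALE = 1000.0

PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class LossBundle:
    """The four loss terms, their weights and the weighted total."""
    l_macro: float
    l_ei: float
    l_kld: float
    l_mc: float
    total: float
    weights: tuple = (1.0, 1.0, 1.0, 1.0)  # (macro, ei, kld, mc)
    total_tensor: Tensor | None = field(default=None, compare=False,
                                        repr=False)


def macro_penalty(n_hat, macro_min, macro_max) -> Tensor:
    """Mean over nutrients of |min - n| + |max - n|; batch-averaged.

    ``n_hat`` is (4,) or (B, 4); bounds are broadcastable to it.
    """
    n_hat = astensor(n_hat)
    lo = np.asarray(macro_min, dtype=np.float64)
    hi = np.asarray(macro_max, dtype=np.float64)
    per = (n_hat - lo).abs() + (n_hat - hi).abs()
    per_sample = per.mean(axis=-1) if n_hat.data.ndim > 1 else per.mean()
    return per_sample.mean() if per_sample.data.ndim else per_sample


def energy_loss(ei_hat, ei_target) -> Tensor:
    """MSE between predicted and target plan energies (normalized units)."""
    ei_hat = astensor(ei_hat)
    target = np.asarray(ei_target, dtype=np.float64)
    if ei_hat.data.size == 0:
        raise ValueError("empty batch")
    if ei_hat.data.shape != target.shape:
        raise ValueError("batch size mismatch between ei_hat and ei_target")
    return (ei_hat - target).square().mean()


def kld(mu, log_var) -> Tensor:
    """KL( N(mu, sigma^2) || N(0, I) ), summed over dims, batch-averaged."""
    mu = astensor(mu)
    log_var = astensor(log_var)
    if mu.shape != log_var.shape:
        raise ValueError("mu and log_var must have equal shapes")
    per = (1.0 + log_var - mu.square() - log_var.exp()) * (-0.5)
    total = per.sum(axis=-1) if mu.data.ndim > 1 else per.sum()
    return total.mean() if total.data.ndim else total


def meal_cross_entropy(log_probs, true_meals) -> Tensor:
    """-sum_t log p(true meal at slot t), batch-averaged.

    ``log_probs`` is a list of six (B, M) log-probability Tensors (or a
    single (T, M) array for an unbatched plan); ``true_meals`` is (B, T).
    A log-probability below log(1e-12) is clamped there to keep the loss
    finite when a true class was masked out.
    """
    is_tensor_list = (isinstance(log_probs, (list, tuple)) and len(log_probs)
                      and isinstance(log_probs[0], Tensor))
    if not is_tensor_list:
        arr = np.asarray(log_probs, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("expected a (T, M) probability array")
        probs = np.clip(arr, PROB_FLOOR, None)
        true = np.asarray(true_meals).reshape(-1)
        return Tensor(-np.log(probs[np.arange(len(true)), true]).sum())
    true = np.atleast_2d(np.asarray(true_meals, dtype=int))
    batch = true.shape[0]
    if len(log_probs) != true.shape[1]:
        raise ValueError("slot count mismatch")
    total: Tensor | None = None
    floor = np.log(PROB_FLOOR)
    for t, logp in enumerate(log_probs):
        if np.any(logp.data[np.arange(batch), true[:, t]] < floor):
            import logging
            logging.getLogger(__name__).warning(
                "true class has ~zero probability at slot %d; clamped", t)
        onehot = np.zeros_like(logp.data)
        onehot[np.arange(batch), true[:, t]] = 1.0
        # clamp via max(logp, floor) expressed with relu
        clamped = (logp - floor).relu() + floor
        term = -(clamped * onehot).sum() * (1.0 / batch)
        total = term if total is None else total + term
    return total


def total_loss(l_macro: Tensor, l_ei: Tensor, l_kld: Tensor, l_mc: Tensor,
               weights=(1.0, 1.0, 1.0, 1.0)) -> LossBundle:
    """Weighted sum of the four terms (default weights all 1)."""
    w = tuple(float(x) for x in weights)
    total = (l_macro * w[0] + l_ei * w[1] + l_kld * w[2] + l_mc * w[3])
    return LossBundle(l_macro=l_macro.item(), l_ei=l_ei.item(),
                      l_kld=l_kld.item(), l_mc=l_mc.item(),
                      total=total.item(), weights=w, total_tensor=total)
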