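"""Cross-entropy training of the two-pass model over shuffled windows.

The objective is the mean negative log-likelihood of the next golden
token at every window position, computed on the second pass's output
(plus, by default, an auxiliary identical term on the first pass so the
scheduled sampler draws from a trained predictor).  On long ergodic
first-order Markov data this per-token cross-entropy converges to the
path entropy rate -sum_l P_l sum_m P_ml ln Q_ml, so minimizing it drives
the learned conditionals Q toward the chain's true transition law.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .discretize import WindowDataset
from .model import GptConfig, NanoGpt

__all__ = ["TrainState", "cross_entropy_loss", "fit", "path_entropy_rate"]

_LOG_FLOOR = 1e-12


@dataclass
class TrainState:
    """Bookkeeping for one optimization run."""

    step: int = 0
    loss_history: list[float] = field(default_factory=list)
    golden_fraction_history: list[float] = field(default_factory=list)
    best_loss: float = np.inf
    seed: int = 0


def cross_entropy_loss(final_distributions: np.ndarray, targets: np.ndarray) -> float:
    """Mean negative log-probability assigned to the target tokens.

    ``final_distributions``: (B, T, K) predicted next-state distributions;
    ``targets``: (B, T) integer states.  Zero predicted probability is
    floored at 1e-12 so the loss stays finite.
    """
    probs = np.atleast_3d(final_distributions)
    targets = np.atleast_2d(np.asarray(targets, dtype=np.int64))
    picked = np.take_along_axis(probs, targets[..., None], axis=-1)[..., 0]
    return float(-np.log(np.maximum(picked, _LOG_FLOOR)).mean())


class _Adam:
    def __init__(self, params: dict, lr: float, betas=(0.9, 0.999), eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def update(self, params: dict, grads: dict) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, gr in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gr
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gr * gr
            params[k] -= self.lr * (self.m[k] / bc1) / (
                np.sqrt(self.v[k] / bc2) + self.eps
            )


def _loss_and_grads(model: NanoGpt, batch: np.ndarray, rng: np.random.Generator):
    """One two-pass forward/backward on a (B, L) batch of golden windows.

    The loss is evaluated on positions 0..L-2 predicting tokens 1..L-1.
    Sampling of the mixed window is a discrete, non-differentiable step:
    the second pass treats its mixed input as data, so gradients reach
    pass-1 parameters only through the optional auxiliary loss.
    """
    cfg = model.config
    probs1, mixed, probs2 = model.two_pass_forward(batch, model.step, rng)
    cache1, cache2, logits1, logits2 = model._last_caches
    targets = batch[:, 1:]
    B, Tm1 = targets.shape
    loss2 = cross_entropy_loss(probs2[:, :-1, :], targets)

    def dlogits_for(probs):
        d = probs.copy()
        np.put_along_axis(
            d[:, :-1, :],
            targets[..., None],
            np.take_along_axis(d[:, :-1, :], targets[..., None], -1) - 1.0,
            -1,
        )
        d[:, -1, :] = 0.0
        return d / (B * Tm1)

    grads2 = model.pass2.backward(cache2, dlogits_for(probs2))
    loss1 = cross_entropy_loss(probs1[:, :-1, :], targets)
    loss = loss2
    aux = cfg.aux_pass1_weight
    if aux > 0.0 and not cfg.share_passes:
        grads1 = model.pass1.backward(cache1, dlogits_for(probs1) * aux)
        loss = loss2 + aux * loss1
    elif cfg.share_passes:
        grads1 = None
        if aux > 0.0:
            g1 = model.pass1.backward(cache1, dlogits_for(probs1) * aux)
            for k in grads2:
                grads2[k] = grads2[k] + g1[k]
            loss = loss2 + aux * loss1
    else:
        grads1 = None
    golden_frac = float(mixed.source_mask.mean())
    return loss, loss2, grads1, grads2, golden_frac


def _cosine_lr(base: float, step: int, n_steps: int, warmup: int = 20,
               floor_frac: float = 0.1) -> float:
    """Linear warmup then cosine decay to ``floor_frac`` of the base rate."""
    if step < warmup:
        return base * (step + 1) / warmup
    frac = (step - warmup) / max(1, n_steps - warmup)
    return base * (floor_frac + (1 - floor_frac) * 0.5 * (1 + np.cos(np.pi * frac)))


def fit(
    dataset: WindowDataset,
    config: GptConfig,
    n_steps: int = 1000,
    log_every: int = 50,
    callback=None,
    lr_schedule: str = "cosine",
) -> tuple[NanoGpt, TrainState]:
    """Minibatch Adam training; fully deterministic given config.seed.

    Windows are consumed in the dataset's shuffled order, cycling as
    needed; the schedule step i advances once per optimizer step.  The
    learning rate follows warmup + cosine decay by default (constant
    Adam noise at convergence otherwise leaves the learned conditionals
    jittering around the optimum); pass ``lr_schedule="constant"`` to
    disable.
    """
    if lr_schedule not in ("cosine", "constant"):
        raise ValueError("lr_schedule must be 'cosine' or 'constant'")
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if dataset.n_states > config.vocab_size:
        raise ValueError(
            f"dataset has {dataset.n_states} states but vocab_size is "
            f"{config.vocab_size}"
        )
    model = NanoGpt(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7A6]))
    opt1 = None if config.share_passes else _Adam(
        model.pass1.params, config.learning_rate
    )
    opt2 = _Adam(model.pass2.params, config.learning_rate)
    state = TrainState(seed=config.seed)
    n_win = len(dataset)
    bs = config.batch_size
    cursor = 0
    for step in range(n_steps):
        idx = (cursor + np.arange(bs)) % n_win
        cursor = (cursor + bs) % n_win
        batch = dataset.windows[idx]
        loss, loss2, grads1, grads2, gf = _loss_and_grads(model, batch, rng)
        if not np.isfinite(loss):
            raise FloatingPointError(f"training diverged at step {model.step}")
        if lr_schedule == "cosine":
            lr = _cosine_lr(config.learning_rate, step, n_steps)
            if opt1 is not None:
                opt1.lr = lr
            opt2.lr = lr
        if grads1 is not None:
            opt1.update(model.pass1.params, grads1)
        opt2.update(model.pass2.params, grads2)
        model.step += 1
        state.step = model.step
        state.loss_history.append(loss)
        state.golden_fraction_history.append(gf)
        state.best_loss = min(state.best_loss, loss2)
        if callback is not None and (step % log_every == 0 or step == n_steps - 1):
            callback(state)
    return model, state


def path_entropy_rate(P_stationary: np.ndarray, P_trans: np.ndarray,
                      Q_trans: np.ndarray) -> float:
    """Per-token path (cross-)entropy -sum_l P_l sum_m P_ml ln Q_ml.

    With Q = P this is the chain's entropy rate; with Q = learned
    conditionals it is the value the training cross-entropy approaches on
    long ergodic first-order Markov data (ensemble average replacing the
    time average).
    """
    P_stationary = np.asarray(P_stationary, float)
    P_trans = np.asarray(P_trans, float)
    Q_trans = np.maximum(np.asarray(Q_trans, float), _LOG_FLOOR)
    terms = P_stationary[:, None] * P_trans * np.log(Q_trans)
    return float(-terms[P_trans > 0].sum())
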