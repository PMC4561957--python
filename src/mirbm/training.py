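"""Mean-field contrastive-divergence training of the conditional RBM.

Each miRNA contributes one training case: its n x t association slice v with
the covariate r derived from that slice (r_i = 1 iff the miRNA has any known
association with disease i).  Unobserved (disease, type) cells train as v = 0,
i.e. zeros are treated as the background class from which candidates are later
ranked.

Both phases of CD use expected values, never Bernoulli samples:

  data phase    h-hat = P(h | v, r) with v clamped to the data;
  model phase   T alternating mean-field sweeps started from the data
                (v' = P(v | h-hat), h' = P(h | v', r), ...), with r held
                clamped throughout.

The update for each parameter block is the learning rate times the difference
of the data-phase and model-phase expectations, averaged over the batch, e.g.
delta W[i,k,j] = eps * (<v[i,k] h_j>_data - <v'[i,k] h'_j>_T).  Because all
statistics are probabilities in [0, 1], every update is bounded by eps
elementwise.  Momentum and weight decay are available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datamodel import MultiTypeNetwork
from .rbm import (
    RBMParams,
    ShapeError,
    VisibleConfig,
    hidden_activation,
    init_params,
    visible_activation,
)


class TrainingError(ValueError):
    """Raised for invalid training inputs or configuration."""


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the CD trainer.

    Defaults follow the published protocol for this model family: m = 100
    hidden units, learning rate eps = 0.01, 100 epochs, Gaussian init with
    sd 0.1, full-batch updates (the gradient averages over all input cases),
    and T = 1 mean-field sweep in the negative phase.
    """

    learning_rate: float = 0.01
    epochs: int = 100
    mf_steps: int = 1
    hidden_units: int = 100
    init_sd: float = 0.1
    seed: int = 0
    batch: int | None = None  # None = full batch
    momentum: float = 0.0
    weight_decay: float = 0.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise TrainingError(f"learning_rate must be > 0; got {self.learning_rate}")
        if self.epochs < 1:
            raise TrainingError(f"epochs must be >= 1; got {self.epochs}")
        if self.mf_steps < 1:
            raise TrainingError(f"mf_steps must be >= 1; got {self.mf_steps}")
        if self.hidden_units < 1:
            raise TrainingError(f"hidden_units must be >= 1; got {self.hidden_units}")
        if self.batch is not None and self.batch < 1:
            raise TrainingError(f"batch must be >= 1 or None; got {self.batch}")
        if not 0.0 <= self.momentum < 1.0:
            raise TrainingError(f"momentum must be in [0, 1); got {self.momentum}")
        if self.weight_decay < 0:
            raise TrainingError(f"weight_decay must be >= 0; got {self.weight_decay}")


@dataclass
class TrainTrace:
    """Per-epoch diagnostics: mean squared reconstruction error, and the exact
    per-case log-likelihood on models small enough to enumerate."""

    recon_error: list[float] = field(default_factory=list)
    exact_ll: list[float] | None = None


def _stack_batch(batch: Sequence[VisibleConfig]) -> tuple[np.ndarray, np.ndarray]:
    if len(batch) == 0:
        raise TrainingError("empty training batch")
    V = np.stack([cfg.v for cfg in batch]).astype(float)
    R = np.stack([cfg.r for cfg in batch]).astype(float)
    return V, R


def cd_gradients(
    V: np.ndarray, R: np.ndarray, params: RBMParams, mf_steps: int = 1
) -> tuple[dict[str, np.ndarray], float]:
    """CD-T mean-field gradient estimate for a clamped batch.

    Returns (gradient blocks keyed W/a/b/D, mean squared reconstruction
    error of the first mean-field sweep).  Gradients point in the ascent
    direction of the data log-likelihood (to be added, scaled by the learning
    rate).
    """
    q = V.shape[0]
    H_data = hidden_activation(V, R, params)

    Hk = H_data
    recon = None
    for _ in range(mf_steps):
        Vk = visible_activation(Hk, params)
        if recon is None:
            recon = float(np.mean((V - Vk) ** 2))
        Hk = hidden_activation(Vk, R, params)

    grads = {
        "W": (np.einsum("qnt,qm->ntm", V, H_data) - np.einsum("qnt,qm->ntm", Vk, Hk)) / q,
        "a": (V - Vk).mean(axis=0),
        "b": (H_data - Hk).mean(axis=0),
        "D": (np.einsum("qn,qm->nm", R, H_data) - np.einsum("qn,qm->nm", R, Hk)) / q,
    }
    return grads, recon


def cd_step(
    batch: Sequence[VisibleConfig], params: RBMParams, cfg: TrainConfig
) -> RBMParams:
    """One plain CD pass over a batch: params + eps * gradient (with optional
    weight decay on W and D; momentum is handled by :func:`train`)."""
    V, R = _stack_batch(batch)
    n, t, m = params.shape
    if V.shape[1:] != (n, t):
        raise ShapeError(
            f"batch visible shape {V.shape[1:]} does not match params {(n, t)}"
        )
    grads, _ = cd_gradients(V, R, params, cfg.mf_steps)
    eps = cfg.learning_rate
    return RBMParams(
        W=params.W + eps * (grads["W"] - cfg.weight_decay * params.W),
        a=params.a + eps * grads["a"],
        b=params.b + eps * grads["b"],
        D=params.D + eps * (grads["D"] - cfg.weight_decay * params.D),
    )


def network_training_cases(net: MultiTypeNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Per-miRNA training arrays: V (q, n, t) and R (q, n) with r derived
    from each miRNA's own slice."""
    V = net.tensor.transpose(1, 0, 2).astype(float)
    R = (V.sum(axis=2) > 0).astype(float)
    return V, R


def train(
    net: MultiTypeNetwork,
    cfg: TrainConfig | None = None,
    track_exact_ll: bool = False,
) -> tuple[RBMParams, TrainTrace]:
    """Fit shared RBM parameters to a network by mean-field CD.

    Runs ``cfg.epochs`` passes over the q per-miRNA cases; full-batch by
    default, mini-batches (in a seed-shuffled order) when ``cfg.batch`` is
    set.  Deterministic given (network, config): the same seed yields
    bit-identical parameters.
    """
    cfg = cfg or TrainConfig()
    if net.n_associations == 0:
        raise TrainingError("network has no associations: nothing to train on")

    V, R = network_training_cases(net)
    q = V.shape[0]
    n, t = net.n_diseases, net.n_types

    root = np.random.SeedSequence(cfg.seed)
    init_seq, shuffle_seq = root.spawn(2)
    params = init_params(n, t, cfg.hidden_units, sd=cfg.init_sd, seed=np.random.default_rng(init_seq))
    shuffle_rng = np.random.default_rng(shuffle_seq)

    trace = TrainTrace(exact_ll=[] if track_exact_ll else None)
    if track_exact_ll:
        trace.exact_ll.append(exact_log_likelihood(net, params))

    velocity = {
        "W": np.zeros_like(params.W),
        "a": np.zeros_like(params.a),
        "b": np.zeros_like(params.b),
        "D": np.zeros_like(params.D),
    }
    eps = cfg.learning_rate

    for _ in range(cfg.epochs):
        if cfg.batch is None or cfg.batch >= q:
            slices = [np.arange(q)]
        else:
            order = shuffle_rng.permutation(q)
            slices = [order[s : s + cfg.batch] for s in range(0, q, cfg.batch)]
        epoch_err = 0.0
        for idx in slices:
            grads, recon = cd_gradients(V[idx], R[idx], params, cfg.mf_steps)
            epoch_err += recon * len(idx)
            new_blocks = {}
            for key, cur in (("W", params.W), ("a", params.a), ("b", params.b), ("D", params.D)):
                g = grads[key]
                if cfg.weight_decay and key in ("W", "D"):
                    g = g - cfg.weight_decay * cur
                velocity[key] = cfg.momentum * velocity[key] + eps * g
                new_blocks[key] = cur + velocity[key]
            params = RBMParams(**new_blocks)
        trace.recon_error.append(epoch_err / q)
        if track_exact_ll:
            trace.exact_ll.append(exact_log_likelihood(net, params))

    return params, trace


def exact_log_likelihood(net: MultiTypeNetwork, params: RBMParams) -> float:
    """Exact training log-likelihood sum_u log P(v_u | r_u) on an enumerable
    model (n*t + m <= 20); always <= 0.

    Each miRNA's marginal is computed by summing the hidden layer analytically
    and enumerating visible states for the normaliser, conditioned on that
    miRNA's covariate r.  The partition function is cached per distinct r
    pattern.
    """
    from .rbm import _log_sum_over_hidden, _require_enumerable, log_partition_exact

    _require_enumerable(params)
    V, R = network_training_cases(net)
    total = 0.0
    log_z_cache: dict[bytes, float] = {}
    for v, r in zip(V, R):
        key = r.astype(np.int8).tobytes()
        if key not in log_z_cache:
            log_z_cache[key] = log_partition_exact(params, r)
        log_num = _log_sum_over_hidden(v[None], r, params)[0]
        total += log_num - log_z_cache[key]
    return float(total)
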