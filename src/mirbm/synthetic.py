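"""Synthetic multi-type bipartite networks with planted low-rank structure.

The generator emulates the shape of the HMDD v2.0 training data — by default
174 diseases x 322 miRNAs x 4 association types with per-type totals
(682, 443, 199, 356) — while planting a recoverable low-dimensional signal:
disease and miRNA latent factors drawn from a standard Gaussian interact
through a per-type affinity transform, the resulting logits are standardised
and scaled, and a per-type intercept is calibrated by bisection so the
expected number of 1s matches the target count.  The binary tensor is
Bernoulli-sampled from the resulting probabilities and then corrupted by
density-preserving noise: each 1-cell flips to 0 with probability
``noise_flip_rate`` while 0-cells flip to 1 at the rate that keeps the
expected per-type count unchanged.

Because the RBM's hidden units are themselves a learned low-dimensional
representation, this latent-factor mechanism gives the model something it can
in principle recover, making downstream AUC > 0.5 a meaningful check rather
than a vacuous one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .datamodel import AssociationRecord, MultiTypeNetwork

#: HMDD-style defaults: network shape and per-type association totals.
DEFAULT_N_DISEASES = 174
DEFAULT_N_MIRNAS = 322
DEFAULT_TYPE_COUNTS = (682, 443, 199, 356)


class GeneratorError(ValueError):
    """Raised for unsatisfiable or invalid generator configurations."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the planted-structure network generator.

    ``signal_sd`` sets the standard deviation of the standardised per-type
    logits; 2.0 concentrates the sampled 1s in the upper tail of the planted
    affinity, a strong but noisy signal comparable to a curated database in
    which most catalogued associations are real.
    """

    n_diseases: int = DEFAULT_N_DISEASES
    n_mirnas: int = DEFAULT_N_MIRNAS
    n_types: int = 4
    latent_dim: int = 8
    per_type_target_counts: tuple[int, ...] = DEFAULT_TYPE_COUNTS
    noise_flip_rate: float = 0.01
    signal_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diseases < 1 or self.n_mirnas < 1 or self.n_types < 1:
            raise GeneratorError("network dimensions must be positive")
        if self.latent_dim < 1:
            raise GeneratorError("latent_dim must be >= 1")
        if len(self.per_type_target_counts) != self.n_types:
            raise GeneratorError(
                f"{len(self.per_type_target_counts)} per-type targets for "
                f"{self.n_types} types"
            )
        cells = self.n_diseases * self.n_mirnas
        for k, target in enumerate(self.per_type_target_counts):
            if not 0 <= target <= cells:
                raise GeneratorError(
                    f"type {k}: target count {target} outside [0, {cells}]"
                )
        if not 0.0 <= self.noise_flip_rate < 0.5:
            raise GeneratorError(
                f"noise_flip_rate must be in [0, 0.5); got {self.noise_flip_rate}"
            )


@dataclass
class PlantedTruth:
    """Ground-truth latent structure behind a generated network."""

    disease_factors: np.ndarray  # (n, d)
    mirna_factors: np.ndarray  # (q, d)
    type_transforms: np.ndarray  # (t, d, d)
    prob_tensor: np.ndarray = field(repr=False)  # (n, q, t), pre-noise

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "wb") as fh:
            np.savez(
                fh,
                disease_factors=self.disease_factors,
                mirna_factors=self.mirna_factors,
                type_transforms=self.type_transforms,
                prob_tensor=self.prob_tensor,
            )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PlantedTruth":
        with np.load(Path(path), allow_pickle=False) as npz:
            return cls(
                disease_factors=npz["disease_factors"],
                mirna_factors=npz["mirna_factors"],
                type_transforms=npz["type_transforms"],
                prob_tensor=npz["prob_tensor"],
            )


def _calibrated_probs(logits: np.ndarray, target: int) -> np.ndarray:
    """Shift logits by an intercept (found by bisection) so the expected
    count of 1s equals ``target``."""
    cells = logits.size
    if target == 0:
        return np.zeros_like(logits)
    if target == cells:
        return np.ones_like(logits)

    rate = target / cells

    def excess(c: float) -> float:
        return float(expit(logits + c).mean() - rate)

    lo, hi = -60.0, 60.0
    intercept = brentq(excess, lo, hi, xtol=1e-10)
    return expit(logits + intercept)


def default_labels(n_diseases: int, n_mirnas: int, n_types: int) -> tuple[list, list, list]:
    from .datamodel import CANONICAL_TYPES

    diseases = [f"disease_{i + 1:03d}" for i in range(n_diseases)]
    mirnas = [f"hsa-mir-{u + 1:04d}" for u in range(n_mirnas)]
    if n_types <= len(CANONICAL_TYPES):
        types = list(CANONICAL_TYPES[:n_types])
    else:
        types = list(CANONICAL_TYPES) + [
            f"type_{k + 1}" for k in range(len(CANONICAL_TYPES), n_types)
        ]
    return diseases, mirnas, types


def generate(cfg: GeneratorConfig | None = None) -> tuple[MultiTypeNetwork, PlantedTruth]:
    """Draw a planted-structure network; the same seed gives identical output."""
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    n, q, t, d = cfg.n_diseases, cfg.n_mirnas, cfg.n_types, cfg.latent_dim

    U = rng.standard_normal((n, d))
    M = rng.standard_normal((q, d))
    A = rng.standard_normal((t, d, d))

    prob = np.empty((n, q, t))
    for k in range(t):
        raw = U @ A[k] @ M.T
        sd = raw.std()
        z = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
        prob[:, :, k] = _calibrated_probs(z * cfg.signal_sd, cfg.per_type_target_counts[k])

    tensor = (rng.random((n, q, t)) < prob).astype(np.int8)

    if cfg.noise_flip_rate > 0:
        rho = cfg.noise_flip_rate
        cells = n * q
        noise = rng.random((n, q, t))
        for k in range(t):
            target = cfg.per_type_target_counts[k]
            zeros = cells - target
            up_rate = rho * target / zeros if zeros > 0 else 0.0
            sl = tensor[:, :, k]
            flip_down = (sl == 1) & (noise[:, :, k] < rho)
            flip_up = (sl == 0) & (noise[:, :, k] < up_rate)
            sl[flip_down] = 0
            sl[flip_up] = 1

    diseases, mirnas, types = default_labels(n, q, t)
    net = MultiTypeNetwork(diseases, mirnas, types, tensor)
    truth = PlantedTruth(
        disease_factors=U, mirna_factors=M, type_transforms=A, prob_tensor=prob
    )
    return net, truth


def holdout_split(
    net: MultiTypeNetwork, fraction: float, seed: int
) -> tuple[MultiTypeNetwork, list[AssociationRecord]]:
    """Uniformly remove a fraction of the 1-cells for hold-out evaluation.

    Returns the training network (held-out entries zeroed) and the removed
    triples; together they partition the original 1-cells.  At least one
    triple is always held out; removing every association is rejected.
    """
    if not 0.0 < fraction < 1.0:
        raise GeneratorError(f"fraction must be in (0, 1); got {fraction}")
    ones = np.argwhere(net.tensor == 1)
    total = len(ones)
    n_hold = max(1, round(fraction * total))
    if n_hold >= total:
        raise GeneratorError(
            f"holding out {n_hold} of {total} associations would leave no "
            "training signal"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(total, size=n_hold, replace=False)
    pick.sort()
    train_net = net.copy()
    held: list[AssociationRecord] = []
    for i, u, k in ones[pick]:
        train_net.tensor[i, u, k] = 0
        held.append(
            AssociationRecord(
                mirna=net.mirna_ids[u],
                disease=net.disease_ids[i],
                assoc_type=net.type_ids[k],
            )
        )
    return train_net, held


def planted_truth_auc(
    truth: PlantedTruth, net: MultiTypeNetwork, max_negatives: int | None = None,
    seed: int = 0,
) -> float:
    """AUC of the pre-noise probability tensor for separating the network's
    1-cells from its 0-cells — an upper reference for what any model could
    recover from this draw."""
    scores = truth.prob_tensor
    pos = scores[net.tensor == 1]
    neg = scores[net.tensor == 0]
    if max_negatives is not None and neg.size > max_negatives:
        rng = np.random.default_rng(seed)
        neg = rng.choice(neg, size=max_negatives, replace=False)
    neg_sorted = np.sort(neg)
    lo = np.searchsorted(neg_sorted, pos, side="left")
    hi = np.searchsorted(neg_sorted, pos, side="right")
    # Mann-Whitney with tie correction
    wins = lo + 0.5 * (hi - lo)
    return float(wins.mean() / neg.size)
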