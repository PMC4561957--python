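"""Conditional restricted Boltzmann machine: energy, conditionals, exact oracles.

The model is a two-layer undirected graphical model over binary visible units
``v`` (one per (disease, type) cell of a single miRNA's association slice) and
binary hidden units ``h``, conditioned on an observed binary covariate vector
``r`` of length n (``r_i = 1`` iff the miRNA has any known association with
disease i).  With weights ``W`` (n x t x m), visible biases ``a`` (n x t),
hidden biases ``b`` (m) and conditional couplings ``D`` (n x m), the energy of
a joint configuration is

    E(v, h | r) = - sum_{ikj} W[i,k,j] v[i,k] h[j]
                  - sum_{ik}  a[i,k]  v[i,k]
                  - sum_{j}   b[j]    h[j]
                  - sum_{ij}  D[i,j]  r[i] h[j]

which yields the factorised conditionals

    P(h_j = 1 | v, r) = sigma(b_j + sum_{ik} v[i,k] W[i,k,j] + sum_i D[i,j] r_i)
    P(v_ik = 1 | h)   = sigma(a[i,k] + sum_j h_j W[i,k,j])

because neither layer has intra-layer connections.  The covariate term shifts
the hidden biases only, so P(v | h) does not depend on r.

The exact partition function, joint probability and (in :mod:`mirbm.training`)
log-likelihood are enumeration oracles restricted to tiny models
(``n*t + m <= ENUMERATION_BOUND``); they exist to validate the closed-form
conditionals and the contrastive-divergence trainer, not to score real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit, logsumexp

#: Largest total number of binary units (n*t + m) for which exhaustive
#: enumeration of joint states is permitted (2^20 ~ 1e6 states).
ENUMERATION_BOUND = 20


class ShapeError(ValueError):
    """Raised when parameter or configuration shapes are inconsistent."""


class EnumerationBoundError(ValueError):
    """Raised when an exact-enumeration oracle is asked for a model too large
    to enumerate; use the closed-form conditionals instead."""


def logistic(x):
    """Logistic sigmoid sigma(x) = 1 / (1 + exp(-x)), saturation-safe."""
    return expit(x)


@dataclass(frozen=True)
class RBMParams:
    """Shared parameters of the conditional RBM (one set for all miRNAs).

    Attributes
    ----------
    W : ndarray, shape (n, t, m)
        Weight between visible variable v[i,k] and hidden unit h[j].
    a : ndarray, shape (n, t)
        Visible biases.
    b : ndarray, shape (m,)
        Hidden biases.
    D : ndarray, shape (n, m)
        Coupling of the conditional indicator r_i to hidden unit h_j.
    """

    W: np.ndarray
    a: np.ndarray
    b: np.ndarray
    D: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        D = np.asarray(self.D, dtype=float)
        if W.ndim != 3:
            raise ShapeError(f"W must be 3-d (n, t, m); got shape {W.shape}")
        n, t, m = W.shape
        if a.shape != (n, t):
            raise ShapeError(f"a has shape {a.shape}, expected {(n, t)}")
        if b.shape != (m,):
            raise ShapeError(f"b has shape {b.shape}, expected {(m,)}")
        if D.shape != (n, m):
            raise ShapeError(f"D has shape {D.shape}, expected {(n, m)}")
        for name, arr in (("W", W), ("a", a), ("b", b), ("D", D)):
            if not np.isfinite(arr).all():
                raise ShapeError(f"parameter block {name} contains non-finite values")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "D", D)

    @property
    def shape(self) -> tuple[int, int, int]:
        """(n_diseases, n_types, n_hidden)."""
        return self.W.shape

    def scaled(self, c: float) -> "RBMParams":
        return RBMParams(self.W * c, self.a * c, self.b * c, self.D * c)


@dataclass(frozen=True)
class VisibleConfig:
    """One miRNA's visible state: n x t binary matrix v and length-n
    indicator r (r_i = 1 iff the miRNA has any known association with disease
    i).  Under that definition r is implied by v; ``strict=False`` relaxes the
    implication check so r can act as a clamped covariate during enumeration.
    """

    v: np.ndarray
    r: np.ndarray
    strict: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.v)
        r = np.asarray(self.r)
        if v.ndim != 2:
            raise ShapeError(f"v must be 2-d (n, t); got shape {v.shape}")
        if r.shape != (v.shape[0],):
            raise ShapeError(f"r has shape {r.shape}, expected {(v.shape[0],)}")
        if not np.isin(v, (0, 1)).all() or not np.isin(r, (0, 1)).all():
            raise ShapeError("v and r entries must be exactly 0 or 1")
        if self.strict and np.any((v.sum(axis=1) > 0) & (r == 0)):
            raise ShapeError(
                "r_i must be 1 for every disease i with some v[i,k] = 1"
            )
        object.__setattr__(self, "v", v.astype(np.int8, copy=False))
        object.__setattr__(self, "r", r.astype(np.int8, copy=False))

    @classmethod
    def from_slice(cls, v: np.ndarray) -> "VisibleConfig":
        """Derive r from the slice itself: r_i = 1 iff any v[i,k] = 1."""
        v = np.asarray(v)
        return cls(v=v, r=(v.sum(axis=1) > 0).astype(np.int8))


@dataclass(frozen=True)
class HiddenConfig:
    """Binary hidden-layer state h of length m."""

    h: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.h)
        if h.ndim != 1:
            raise ShapeError(f"h must be 1-d; got shape {h.shape}")
        if not np.isin(h, (0, 1)).all():
            raise ShapeError("h entries must be exactly 0 or 1")
        object.__setattr__(self, "h", h.astype(np.int8, copy=False))


def _check_visible(cfg_v: VisibleConfig, params: RBMParams) -> None:
    n, t, _ = params.shape
    if cfg_v.v.shape != (n, t):
        raise ShapeError(
            f"visible config shape {cfg_v.v.shape} does not match params {(n, t)}"
        )


def _check_hidden(cfg_h: HiddenConfig, params: RBMParams) -> None:
    m = params.shape[2]
    if cfg_h.h.shape != (m,):
        raise ShapeError(
            f"hidden config shape {cfg_h.h.shape} does not match params {(m,)}"
        )


def energy(cfg_v: VisibleConfig, cfg_h: HiddenConfig, params: RBMParams) -> float:
    """Energy E(v, h | r) of a joint configuration (lower = more probable)."""
    _check_visible(cfg_v, params)
    _check_hidden(cfg_h, params)
    v = cfg_v.v.astype(float)
    r = cfg_v.r.astype(float)
    h = cfg_h.h.astype(float)
    interaction = np.einsum("nt,ntm,m->", v, params.W, h)
    return float(
        -interaction
        - np.sum(params.a * v)
        - np.dot(params.b, h)
        - np.einsum("n,nm,m->", r, params.D, h)
    )


def hidden_conditional(cfg_v: VisibleConfig, params: RBMParams) -> np.ndarray:
    """P(h_j = 1 | v, r) for every hidden unit; shape (m,)."""
    _check_visible(cfg_v, params)
    return hidden_activation(
        cfg_v.v.astype(float)[None], cfg_v.r.astype(float)[None], params
    )[0]


def visible_conditional(cfg_h: HiddenConfig, params: RBMParams) -> np.ndarray:
    """P(v[i,k] = 1 | h) for every visible variable; shape (n, t)."""
    _check_hidden(cfg_h, params)
    return visible_activation(cfg_h.h.astype(float)[None], params)[0]


def hidden_activation(V: np.ndarray, R: np.ndarray, params: RBMParams) -> np.ndarray:
    """Vectorised hidden probabilities for a batch: V (q, n, t), R (q, n) ->
    (q, m).  Accepts real-valued (mean-field) inputs."""
    pre = (
        params.b[None, :]
        + np.einsum("qnt,ntm->qm", V, params.W)
        + R @ params.D
    )
    return expit(pre)


def visible_activation(H: np.ndarray, params: RBMParams) -> np.ndarray:
    """Vectorised visible probabilities for a batch: H (q, m) -> (q, n, t).
    Accepts real-valued (mean-field) hidden inputs."""
    pre = params.a[None, :, :] + np.einsum("qm,ntm->qnt", H, params.W)
    return expit(pre)


# ---------------------------------------------------------------------------
# Exact enumeration oracles (tiny models only)
# ---------------------------------------------------------------------------

def _require_enumerable(params: RBMParams) -> None:
    n, t, m = params.shape
    if n * t + m > ENUMERATION_BOUND:
        raise EnumerationBoundError(
            f"model has n*t + m = {n * t + m} binary units, above the "
            f"enumeration bound {ENUMERATION_BOUND}; use hidden_conditional / "
            "visible_conditional, which need no enumeration"
        )


def _visible_states(n: int, t: int) -> np.ndarray:
    """All 2^(n*t) visible states, shape (2^(n*t), n, t)."""
    c = n * t
    bits = (np.arange(2**c)[:, None] >> np.arange(c)) & 1
    return bits.reshape(-1, n, t).astype(float)


def _log_sum_over_hidden(V: np.ndarray, r: np.ndarray, params: RBMParams) -> np.ndarray:
    """log sum_h exp(-E(v, h | r)) for each visible state in V (batch, n, t).

    Hidden units factorise, so the sum over h is a product of (1 + e^pre_j)
    terms; computed in log space via softplus.
    """
    pre = (
        params.b[None, :]
        + np.einsum("qnt,ntm->qm", V, params.W)
        + (r.astype(float) @ params.D)[None, :]
    )
    softplus = np.logaddexp(0.0, pre).sum(axis=1)
    visible_term = np.einsum("qnt,nt->q", V, params.a)
    return visible_term + softplus


def log_partition_exact(params: RBMParams, r: np.ndarray | None = None) -> float:
    """log Z(r) = log sum_{v,h} exp(-E(v, h | r)) by enumerating visible
    states (hidden units summed analytically).  r defaults to all zeros."""
    _require_enumerable(params)
    n, t, _ = params.shape
    if r is None:
        r = np.zeros(n, dtype=np.int8)
    V = _visible_states(n, t)
    return float(logsumexp(_log_sum_over_hidden(V, np.asarray(r), params)))


def partition_function_exact(params: RBMParams, r: np.ndarray | None = None) -> float:
    """Partition function Z(r); with all parameters zero, Z = 2^(n*t + m)."""
    return float(np.exp(log_partition_exact(params, r)))


def joint_probability_exact(
    cfg_v: VisibleConfig, cfg_h: HiddenConfig, params: RBMParams
) -> float:
    """P(v, h | r) = exp(-E(v, h | r)) / Z(r) on an enumerable model."""
    _require_enumerable(params)
    _check_visible(cfg_v, params)
    _check_hidden(cfg_h, params)
    log_z = log_partition_exact(params, cfg_v.r)
    return float(np.exp(-energy(cfg_v, cfg_h, params) - log_z))


def log_marginal_visible_exact(cfg_v: VisibleConfig, params: RBMParams) -> float:
    """log P(v | r) = log sum_h exp(-E) - log Z(r) on an enumerable model."""
    _require_enumerable(params)
    _check_visible(cfg_v, params)
    num = _log_sum_over_hidden(cfg_v.v.astype(float)[None], cfg_v.r, params)[0]
    return float(num - log_partition_exact(params, cfg_v.r))


# ---------------------------------------------------------------------------
# Initialisation and serialisation
# ---------------------------------------------------------------------------

def init_params(
    n: int,
    t: int,
    m: int,
    sd: float = 0.1,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> RBMParams:
    """Draw all parameter blocks i.i.d. from N(0, sd^2).

    The default sd of 0.1 is the customary small-Gaussian initialisation for
    RBM weights; sd = 0 yields exact zeros.  The same seed gives bit-identical
    parameters.
    """
    if n < 1 or t < 1 or m < 1:
        raise ShapeError(f"dimensions must be positive; got n={n}, t={t}, m={m}")
    if sd < 0:
        raise ShapeError(f"initialisation sd must be non-negative; got {sd}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return RBMParams(
        W=rng.normal(0.0, sd, size=(n, t, m)),
        a=rng.normal(0.0, sd, size=(n, t)),
        b=rng.normal(0.0, sd, size=m),
        D=rng.normal(0.0, sd, size=(n, m)),
    )


def save_params(
    params: RBMParams,
    path: str | Path,
    disease_ids: list[str] | None = None,
    mirna_ids: list[str] | None = None,
    type_ids: list[str] | None = None,
) -> Path:
    """Serialise a parameter set (and optional vocabularies) to one ``.npz``
    archive; :func:`load_params` restores it bit-exactly."""
    path = Path(path)
    n, t, m = params.shape
    payload: dict[str, np.ndarray] = {
        "W": params.W,
        "a": params.a,
        "b": params.b,
        "D": params.D,
        "shape": np.array([n, t, m], dtype=np.int64),
    }
    if disease_ids is not None:
        payload["disease_ids"] = np.asarray(disease_ids, dtype=np.str_)
    if mirna_ids is not None:
        payload["mirna_ids"] = np.asarray(mirna_ids, dtype=np.str_)
    if type_ids is not None:
        payload["type_ids"] = np.asarray(type_ids, dtype=np.str_)
    with open(path, "wb") as fh:
        np.savez(fh, **payload)
    return path


def load_params(path: str | Path) -> tuple[RBMParams, dict[str, list[str]]]:
    """Load a parameter archive; returns (params, vocabularies)."""
    with np.load(Path(path), allow_pickle=False) as npz:
        params = RBMParams(W=npz["W"], a=npz["a"], b=npz["b"], D=npz["D"])
        vocab = {
            key: [str(x) for x in npz[key]]
            for key in ("disease_ids", "mirna_ids", "type_ids")
            if key in npz
        }
    return params, vocab
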