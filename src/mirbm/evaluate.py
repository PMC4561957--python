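"""Scoring, candidate ranking, LOOCV and ROC/AUC for typed association prediction.

Prediction is one mean-field iteration: with a miRNA's observed slice clamped,
the hidden-unit probabilities h-hat = P(h | v, r) are computed, then the
visible distribution P(v | h-hat) — evaluated with the real-valued h-hat — is
the n x t matrix of predicted association probabilities.

Evaluation follows a global ranking protocol.  A held-out (miRNA, disease,
type) triple is scored by a model trained without it and ranked against every
candidate triple — all cells without known experimental evidence.  Sweeping a
rank threshold yields an ROC curve (TPR = fraction of held-out triples ranked
strictly above the threshold; FPR = the threshold's position among the
candidates); its trapezoidal area is the AUC, identical to the rank-sum
(Mann-Whitney) statistic 1 - mean((rank - 1) / candidates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .datamodel import AssociationRecord, MultiTypeNetwork
from .rbm import (
    RBMParams,
    ShapeError,
    VisibleConfig,
    hidden_activation,
    visible_activation,
)
from .training import TrainConfig, train

logger = logging.getLogger(__name__)

TieRule = Literal["average", "min"]


class EvaluationError(ValueError):
    """Raised for invalid evaluation inputs."""


class LeakageError(EvaluationError):
    """Raised when a test triple is still present in the seed network."""


@dataclass(frozen=True)
class ScoreMatrix:
    """Predicted association probabilities for one miRNA: n x t, in (0, 1)."""

    mirna: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2:
            raise ShapeError(f"probs must be 2-d (n, t); got {probs.shape}")
        if not ((probs > 0) & (probs < 1)).all():
            raise EvaluationError("scores must lie strictly inside (0, 1)")
        object.__setattr__(self, "probs", probs)


@dataclass
class LoocvResult:
    """Per-fold ranks plus the derived ROC curve and AUC."""

    records: pd.DataFrame  # columns: mirna, disease, type, score, rank, candidates
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    mode: str = "full"


def score_mirna(
    params: RBMParams, observed: VisibleConfig, mirna: str = ""
) -> ScoreMatrix:
    """One-mean-field-iteration prediction for a single miRNA."""
    h_prob = hidden_activation(
        observed.v.astype(float)[None], observed.r.astype(float)[None], params
    )
    probs = visible_activation(h_prob, params)[0]
    return ScoreMatrix(mirna=mirna, probs=probs)


def score_tensor(params: RBMParams, net: MultiTypeNetwork) -> np.ndarray:
    """Predicted probabilities for every cell, shape (n, q, t).

    Each miRNA is scored from its own observed slice (r derived from the
    slice); the result stacks the per-miRNA score matrices along axis 1.
    """
    V = net.tensor.transpose(1, 0, 2).astype(float)
    R = (V.sum(axis=2) > 0).astype(float)
    H = hidden_activation(V, R, params)
    probs = visible_activation(H, params)  # (q, n, t)
    return probs.transpose(1, 0, 2)


def _rank_within(
    cand_scores: np.ndarray, test_score: float, ties: TieRule
) -> float:
    greater = int(np.sum(cand_scores > test_score))
    equal = int(np.sum(cand_scores == test_score))
    if ties == "average":
        return greater + 1 + equal / 2.0
    return float(greater + 1)


def rank_candidates(
    all_scores: Sequence[ScoreMatrix] | np.ndarray,
    known: MultiTypeNetwork,
    test_triple: AssociationRecord,
    ties: TieRule = "average",
) -> tuple[float, int]:
    """Rank a test triple against every candidate (unknown) triple.

    Candidates are all cells with tensor entry 0 in ``known``, excluding the
    test cell itself; rank 1 is the highest score and score ties receive the
    average of the tied positions (``ties='min'`` for the optimistic rule).
    The test triple must be absent from ``known`` — it would otherwise leak
    into both the seed set and the test set.
    """
    if isinstance(all_scores, np.ndarray):
        scores = all_scores
    else:
        by_mirna = {sm.mirna: sm.probs for sm in all_scores}
        missing = [m for m in known.mirna_ids if m not in by_mirna]
        if missing:
            raise EvaluationError(f"missing score matrices for miRNA(s): {missing}")
        scores = np.stack([by_mirna[m] for m in known.mirna_ids]).transpose(1, 0, 2)
    if scores.shape != known.tensor.shape:
        raise ShapeError(
            f"score tensor shape {scores.shape} does not match network "
            f"{known.tensor.shape}"
        )
    i, u, k = known.triple_index(test_triple)
    if known.tensor[i, u, k] == 1:
        raise LeakageError(
            f"test triple {test_triple} is still marked known in the seed "
            "network; remove it before ranking"
        )
    mask = known.tensor == 0
    mask[i, u, k] = False
    cand = scores[mask]
    rank = _rank_within(cand, float(scores[i, u, k]), ties)
    return rank, int(cand.size)


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(ranks: Sequence[tuple[float, int]]) -> RocCurve:
    """ROC curve and AUC from per-fold (rank, candidate count) pairs.

    Each fold's normalised rank p = (rank - 1) / candidates is the fraction
    of candidates scoring above the test triple.  Sweeping the threshold over
    candidate positions, TPR at threshold theta is the fraction of folds with
    p strictly below theta; the resulting step curve runs from (0, 0) to
    (1, 1) and its trapezoidal area equals 1 - mean(p) exactly (the rank-sum
    identity, tie-corrected through average ranks).
    """
    if len(ranks) == 0:
        raise EvaluationError("empty rank list")
    p = np.array([(rank - 1.0) / nc for rank, nc in ranks], dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise EvaluationError("ranks must lie in [1, candidates + 1]")
    n = p.size
    uniq, counts = np.unique(p, return_counts=True)
    fpr = [0.0]
    tpr = [0.0]
    covered = 0
    for value, count in zip(uniq, counts):
        if value > fpr[-1]:
            fpr.append(float(value))
            tpr.append(covered / n)
        covered += count
        fpr.append(float(value))
        tpr.append(covered / n)
    if fpr[-1] < 1.0:
        fpr.append(1.0)
        tpr.append(1.0)
    fpr_arr = np.array(fpr)
    tpr_arr = np.array(tpr)
    auc = float(np.trapezoid(tpr_arr, fpr_arr))
    return RocCurve(fpr=fpr_arr, tpr=tpr_arr, auc=auc)


ScoreFn = Callable[[MultiTypeNetwork, int], np.ndarray]
"""Alternative scorer for LOOCV: (seed network, fold index) -> (n, q, t)."""


def loocv(
    net: MultiTypeNetwork,
    cfg: TrainConfig | None = None,
    mode: Literal["full", "fast"] = "full",
    ties: TieRule = "average",
    score_fn: ScoreFn | None = None,
) -> LoocvResult:
    """Leave-one-out cross-validation over every known (pair, type) triple.

    For each fold the triple's tensor entry is zeroed and the affected
    miRNA's covariate r recomputed from the remaining slice.  In ``full``
    mode the model is retrained from scratch per fold with a fresh seed
    stream derived from ``cfg.seed`` and the fold index; ``fast`` trains
    once on the complete network and only zeroes the fold in the clamped
    input at scoring time (an approximation — the held-out triple still
    influenced the shared weights).  ``score_fn`` replaces model scoring
    entirely (e.g. a random scorer for calibration checks).
    """
    cfg = cfg or TrainConfig()
    if net.n_associations < 2:
        raise EvaluationError("LOOCV needs a network with at least 2 associations")

    folds = np.argwhere(net.tensor == 1)
    shared_params: RBMParams | None = None
    shared_scores: np.ndarray | None = None
    if score_fn is None and mode == "fast":
        shared_params, _ = train(net, cfg)
        shared_scores = score_tensor(shared_params, net)

    rows = []
    rank_list: list[tuple[float, int]] = []
    for fold, (i, u, k) in enumerate(folds):
        fold_net = net.copy()
        fold_net.tensor[i, u, k] = 0
        test = AssociationRecord(
            mirna=net.mirna_ids[u],
            disease=net.disease_ids[i],
            assoc_type=net.type_ids[k],
        )
        if score_fn is not None:
            scores = score_fn(fold_net, fold)
        elif mode == "full":
            fold_seed = int(
                np.random.SeedSequence(cfg.seed, spawn_key=(fold,)).generate_state(1)[0]
                % (2**31)
            )
            fold_params, _ = train(fold_net, replace_seed(cfg, fold_seed))
            scores = score_tensor(fold_params, fold_net)
        else:
            scores = shared_scores.copy()
            slice_u = fold_net.tensor[:, u, :].astype(float)
            observed = VisibleConfig.from_slice(slice_u.astype(np.int8))
            scores[:, u, :] = score_mirna(
                shared_params, observed, mirna=test.mirna
            ).probs
        assert fold_net.tensor[i, u, k] == 0  # leakage guard
        rank, n_cand = rank_candidates(scores, fold_net, test, ties=ties)
        rank_list.append((rank, n_cand))
        rows.append(
            {
                "mirna": test.mirna,
                "disease": test.disease,
                "type": test.assoc_type,
                "score": float(scores[i, u, k]),
                "rank": rank,
                "candidates": n_cand,
            }
        )
    curve = roc_auc(rank_list)
    return LoocvResult(
        records=pd.DataFrame(rows),
        fpr=curve.fpr,
        tpr=curve.tpr,
        auc=curve.auc,
        mode=mode if score_fn is None else "custom",
    )


def replace_seed(cfg: TrainConfig, seed: int) -> TrainConfig:
    from dataclasses import replace

    return replace(cfg, seed=seed)


def evaluate_holdout(
    train_net: MultiTypeNetwork,
    held_out: Sequence[AssociationRecord],
    cfg: TrainConfig | None = None,
    ties: TieRule = "average",
    score_fn: ScoreFn | None = None,
) -> LoocvResult:
    """Rank a batch of held-out triples against the shared candidate set.

    Trains once on ``train_net`` (the network with the held-out triples
    already removed), scores every cell, and ranks each held-out triple
    against the candidates — cells unknown in both the training network and
    the held-out list.  This is the fast counterpart of full LOOCV for large
    networks.
    """
    cfg = cfg or TrainConfig()
    if len(held_out) == 0:
        raise EvaluationError("empty held-out list")
    if score_fn is not None:
        scores = score_fn(train_net, 0)
    else:
        params, _ = train(train_net, cfg)
        scores = score_tensor(params, train_net)

    held_idx = []
    for rec in held_out:
        i, u, k = train_net.triple_index(rec)
        if train_net.tensor[i, u, k] == 1:
            raise LeakageError(f"held-out triple {rec} still present in training network")
        held_idx.append((i, u, k))

    cand_mask = train_net.tensor == 0
    for i, u, k in held_idx:
        cand_mask[i, u, k] = False
    cand_sorted = np.sort(scores[cand_mask])
    n_cand = int(cand_sorted.size)

    rows = []
    rank_list: list[tuple[float, int]] = []
    for rec, (i, u, k) in zip(held_out, held_idx):
        s = float(scores[i, u, k])
        lo = int(np.searchsorted(cand_sorted, s, side="left"))
        hi = int(np.searchsorted(cand_sorted, s, side="right"))
        greater = n_cand - hi
        equal = hi - lo
        rank = greater + 1 + (equal / 2.0 if ties == "average" else 0.0)
        rank_list.append((rank, n_cand))
        rows.append(
            {
                "mirna": rec.mirna,
                "disease": rec.disease,
                "type": rec.assoc_type,
                "score": s,
                "rank": rank,
                "candidates": n_cand,
            }
        )
    curve = roc_auc(rank_list)
    return LoocvResult(
        records=pd.DataFrame(rows),
        fpr=curve.fpr,
        tpr=curve.tpr,
        auc=curve.auc,
        mode="holdout" if score_fn is None else "custom",
    )


def top_k_predictions(
    net: MultiTypeNetwork,
    params: RBMParams,
    k: int,
    disease: str | None = None,
    scores: np.ndarray | None = None,
) -> pd.DataFrame:
    """The k highest-scoring candidate triples as a prediction table.

    Known triples are always excluded.  Columns: mirna, disease, type,
    probability; sorted by descending probability with (mirna, disease, type)
    lexical tie-breaks for determinism.  ``disease`` restricts candidates to
    one disease; if k exceeds the candidate count all candidates are
    returned with a logged note.
    """
    if k < 1:
        raise EvaluationError(f"k must be >= 1; got {k}")
    if scores is None:
        scores = score_tensor(params, net)
    mask = net.tensor == 0
    if disease is not None:
        keep = np.zeros_like(mask)
        keep[net.disease_index(disease)] = True
        mask &= keep
    idx = np.argwhere(mask)
    df = pd.DataFrame(
        {
            "mirna": [net.mirna_ids[u] for _, u, _ in idx],
            "disease": [net.disease_ids[i] for i, _, _ in idx],
            "type": [net.type_ids[kk] for _, _, kk in idx],
            "probability": scores[mask],
        }
    )
    if k > len(df):
        logger.info(
            "requested top %d but only %d candidate triples exist; returning all",
            k,
            len(df),
        )
        k = len(df)
    df = df.sort_values(
        ["probability", "mirna", "disease", "type"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).head(k)
    return df.reset_index(drop=True)


def write_prediction_table(df: pd.DataFrame, path) -> None:
    """Tab-separated prediction table with probabilities to 6 decimals."""
    out = df.copy()
    out["probability"] = out["probability"].map(lambda x: f"{x:.6f}")
    out.to_csv(path, sep="\t", index=False)


def write_roc(result: LoocvResult, path) -> None:
    """Tab-separated (fpr, tpr) pairs preceded by a one-line AUC summary."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# AUC\t{result.auc:.6f}\n")
        fh.write("fpr\ttpr\n")
        for x, y in zip(result.fpr, result.tpr):
            fh.write(f"{x:.6f}\t{y:.6f}\n")
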