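"""Evaluation protocols: LOOCV, recursive leaf masking, novel-disease top-k.

All protocols share one discipline: the walk's input is rebuilt from the
*direct* (unexpanded) associations after hiding whatever the protocol
hides, and the ancestor expansion is re-derived from what remains.  Hidden
associations — and every expansion entry they alone supported — are
therefore provably absent from the walk input, which is what makes the
ranking evaluation leak-free.

* :func:`loocv` hides one direct association per fold and ranks it against
  the candidates of its row (lncRNA orientation) or column (disease
  orientation); all folds pool into a single ROC curve.
* :func:`masked_experiment` repeatedly masks, per lncRNA, a random current
  leaf of the DAG induced by that lncRNA's own diseases — mimicking how
  newly discovered associations tend to be the most specific descendants —
  and measures recovery of the masked pairs.
* :func:`novel_disease_topk` removes every lncRNA linked to one disease and
  counts how many come back in the top ranks.

AUC uses the trapezoidal/midrank convention and equals the Mann-Whitney
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .network import BiRelationalNetwork, expand_to_ancestors
from .ontology import ancestor_matrix
from .walk import WalkParameters, _predict_arrays

__all__ = [
    "RocResult",
    "LoocvResult",
    "MaskSpec",
    "MaskedResult",
    "NovelDiseaseResult",
    "LeakError",
    "roc_auc",
    "loocv",
    "masked_experiment",
    "novel_disease_topk",
    "rank_candidates",
]


class LeakError(AssertionError):
    """A hidden association (or an expansion entry only it supported)
    survived into the walk input of a cross-validation fold."""


@dataclass(frozen=True)
class RocResult:
    """ROC sweep (FPR/TPR per threshold) plus the trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass(frozen=True)
class LoocvResult:
    """Pooled ROC over all folds and the per-fold ranking table.

    ``n_skipped`` counts direct associations that could not serve as test
    samples because the remaining associations still implied them.
    """

    roc: RocResult
    ranks: pd.DataFrame  # lncrna, disease, score, rank, n_candidates
    n_skipped: int = 0


@dataclass(frozen=True)
class MaskSpec:
    """Leaf-masking protocol: ``k`` masks per lncRNA, repeated ``rounds``
    times with independent randomness derived from ``seed``."""

    k: int
    rounds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or self.rounds < 1:
            raise ValueError("k and rounds must be positive")


@dataclass(frozen=True)
class MaskedResult:
    aucs: np.ndarray  # one AUC per round

    @property
    def mean(self) -> float:
        return float(self.aucs.mean())

    @property
    def sd(self) -> float:
        return float(self.aucs.std(ddof=1)) if len(self.aucs) > 1 else 0.0


@dataclass(frozen=True)
class NovelDiseaseResult:
    disease: str
    removed: tuple[str, ...]
    recovered: int
    ranking: pd.DataFrame  # lncrna, score, rank


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC for pooled scores against binary labels.

    Trapezoidal rule with midrank tie handling, i.e. the Mann-Whitney
    U statistic.  Requires at least one positive and one negative label.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = int((labels == 1).sum())
    if pos == 0 or pos == len(labels):
        raise ValueError("roc_auc needs both a positive and a negative label")
    fpr, tpr, thr = _roc_curve(labels, scores, drop_intermediate=False)
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr,
                     auc=float(_trapezoid_auc(fpr, tpr)))


def _require_direct(net: BiRelationalNetwork) -> None:
    if net.direct is None or net.ontology is None:
        raise ValueError(
            "this protocol needs a network assembled with direct associations "
            "and an ontology (assemble_network(..., direct=..., ontology=...))"
        )


def _direct_pairs(direct: np.ndarray) -> list[tuple[int, int]]:
    rows, cols = np.nonzero(direct)
    return list(zip(rows.tolist(), cols.tolist()))


def loocv(net: BiRelationalNetwork, params: WalkParameters | None = None,
          orientation: str = "lncrna", include_known: bool = False,
          audit: bool = False) -> LoocvResult:
    """Leave-one-out cross-validation over the direct associations.

    Each direct association ``(l, d)`` is zeroed in turn, the ancestor
    expansion re-derived from the remaining direct associations, and the
    walk re-run.  A fold whose held-out pair is *re-implied* by the
    expansion of the remaining direct associations (``d`` is an ancestor of
    another disease directly associated with ``l``) is skipped: the pair is
    then still associated in the reduced matrix, so it is not a candidate —
    it was never genuinely hidden and would be rewarded for the identity
    expansion rather than for the method.  Skipped folds are counted in
    ``LoocvResult.n_skipped``.  In the ``lncrna`` orientation the held-out pair competes
    against every disease not associated with ``l`` in the reduced expanded
    matrix; in the ``disease`` orientation against every lncRNA not
    associated with ``d``.  Other known positives are excluded from the
    candidate set unless ``include_known=True``.  Scores and labels pool
    across folds into a single ROC.

    With ``audit=True`` every fold's walk input is checked against a
    brute-force recomputation of which entries the remaining direct
    associations support; any leak raises :class:`LeakError`.
    """
    if orientation not in ("lncrna", "disease"):
        raise ValueError("orientation must be 'lncrna' or 'disease'")
    _require_direct(net)
    params = params or WalkParameters()

    lnc_ids, dis_ids = net.lnc_ids, net.dis_ids
    direct = net.direct.to_numpy(dtype=float)
    if int(direct.sum()) < 2:
        raise ValueError("LOOCV needs at least two direct associations")
    anc = ancestor_matrix(net.ontology, dis_ids).to_numpy()
    w_dd = net.transition.to_numpy()
    ls_hat = net.similarity.to_numpy()

    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    rank_rows = []
    n_skipped = 0

    for li, di in _direct_pairs(direct):
        reduced = direct.copy()
        reduced[li, di] = 0.0
        a_exp = ((reduced @ anc) > 0).astype(float)
        if a_exp[li, di] != 0:
            n_skipped += 1  # still implied by remaining associations
            continue
        if audit:
            _audit_fold(reduced, a_exp, anc, li, di)
        f = _predict_arrays(w_dd, ls_hat, a_exp, params)

        if orientation == "lncrna":
            mask = a_exp[li] == 0 if not include_known else np.ones(len(dis_ids), bool)
            mask = mask.copy()
            mask[di] = True  # the held-out pair is always a candidate
            cand_scores = f[li, mask]
            labels = np.zeros(mask.sum(), dtype=int)
            labels[np.flatnonzero(np.flatnonzero(mask) == di)] = 1
            cand_ids = [dis_ids[j] for j in np.flatnonzero(mask)]
            held_id = dis_ids[di]
        else:
            mask = a_exp[:, di] == 0 if not include_known else np.ones(len(lnc_ids), bool)
            mask = mask.copy()
            mask[li] = True
            cand_scores = f[mask, di]
            labels = np.zeros(mask.sum(), dtype=int)
            labels[np.flatnonzero(np.flatnonzero(mask) == li)] = 1
            cand_ids = [lnc_ids[j] for j in np.flatnonzero(mask)]
            held_id = lnc_ids[li]

        pooled_scores.append(cand_scores)
        pooled_labels.append(labels)
        order = sorted(range(len(cand_ids)),
                       key=lambda j: (-cand_scores[j], cand_ids[j]))
        rank = order.index(cand_ids.index(held_id)) + 1
        rank_rows.append({
            "lncrna": lnc_ids[li], "disease": dis_ids[di],
            "score": float(f[li, di]), "rank": rank,
            "n_candidates": len(cand_ids),
        })

    if not pooled_scores:
        raise ValueError("every fold was re-implied by the expansion; "
                         "no testable association")
    roc = roc_auc(np.concatenate(pooled_scores), np.concatenate(pooled_labels))
    return LoocvResult(roc=roc, ranks=pd.DataFrame(rank_rows),
                       n_skipped=n_skipped)


def _audit_fold(reduced: np.ndarray, a_exp: np.ndarray, anc: np.ndarray,
                li: int, di: int) -> None:
    """Brute-force no-leak check of one fold's walk input (row ``li``)."""
    if a_exp[li, di] != 0:
        raise LeakError(f"held-out pair ({li}, {di}) present in walk input")
    kept = np.flatnonzero(reduced[li])
    supported = np.zeros(a_exp.shape[1], dtype=bool)
    for dj in kept:
        supported |= anc[dj]
    if not np.array_equal(a_exp[li] > 0, supported):
        raise LeakError(
            f"fold ({li}, {di}): expansion of row {li} does not match the "
            "entries supported by the remaining direct associations"
        )


# -- recursive leaf masking -------------------------------------------------


def _induced_leaves(current: set[int], strict_desc: dict[int, frozenset[int]]) -> list[int]:
    """Leaves of the DAG induced by ``current``: members with no strict
    descendant also in ``current``."""
    return sorted(d for d in current
                  if not (strict_desc[d] & current))


def masked_experiment(net: BiRelationalNetwork, params: WalkParameters | None,
                      spec: MaskSpec) -> MaskedResult:
    """Recursively mask leaf diseases of each lncRNA and measure recovery.

    Per round and per lncRNA: build the DAG induced by the lncRNA's direct
    diseases, repeatedly pick a uniform-random current leaf and mask it
    (masking can expose a new leaf), stopping after ``spec.k`` masks or when
    only one disease would remain.  All masked entries — and expansion
    entries they alone supported — are removed, the walk runs once, and one
    AUC is computed over masked pairs versus never-associated pairs.
    Bit-reproducible under a fixed seed.
    """
    _require_direct(net)
    params = params or WalkParameters()
    dis_ids = net.dis_ids
    direct = net.direct.to_numpy(dtype=float)
    anc = ancestor_matrix(net.ontology, dis_ids).to_numpy()
    expanded_full = (direct @ anc) > 0
    w_dd = net.transition.to_numpy()
    ls_hat = net.similarity.to_numpy()

    # strict-descendant sets over column indices, for induced-DAG leaves
    strict_desc = {
        j: frozenset(np.flatnonzero(anc[:, j]).tolist()) - {j}
        for j in range(len(dis_ids))
    }

    seeds = np.random.SeedSequence(spec.seed).spawn(spec.rounds)
    aucs = []
    for round_seq in seeds:
        rng = np.random.default_rng(round_seq)
        masked_direct = direct.copy()
        masked_pairs: list[tuple[int, int]] = []
        for li in range(direct.shape[0]):
            current = set(np.flatnonzero(direct[li]).tolist())
            for _ in range(spec.k):
                if len(current) <= 1:
                    break  # keep at least one disease unmasked
                leaves = _induced_leaves(current, strict_desc)
                pick = int(rng.choice(leaves))
                current.remove(pick)
                masked_direct[li, pick] = 0.0
                masked_pairs.append((li, pick))
        if not masked_pairs:
            raise ValueError("nothing could be masked (every lncRNA has <=1 disease)")
        a_exp = ((masked_direct @ anc) > 0).astype(float)
        f = _predict_arrays(w_dd, ls_hat, a_exp, params)
        neg_mask = ~expanded_full
        pos_scores = np.array([f[li, di] for li, di in masked_pairs])
        scores = np.concatenate([pos_scores, f[neg_mask]])
        labels = np.concatenate([np.ones(len(pos_scores), dtype=int),
                                 np.zeros(int(neg_mask.sum()), dtype=int)])
        aucs.append(roc_auc(scores, labels).auc)
    return MaskedResult(aucs=np.array(aucs))


def novel_disease_topk(net: BiRelationalNetwork,
                       params: WalkParameters | None,
                       disease: str) -> NovelDiseaseResult:
    """Hide one disease's lncRNAs entirely and count top-k recovery.

    Every lncRNA carrying a 1 in the disease's expanded column is the
    removed set; the disease's direct associations are dropped, the
    expansion re-derived, and the column forced to zero so no support path
    through this disease survives.  After one walk, all lncRNAs are ranked
    for the disease and the recovered count is the overlap between the
    removed set and the top ``k = |removed|`` ranks.
    """
    _require_direct(net)
    params = params or WalkParameters()
    dis_ids = net.dis_ids
    if disease not in dis_ids:
        raise KeyError(f"unknown disease {disease!r}")
    di = dis_ids.index(disease)
    direct = net.direct.to_numpy(dtype=float)
    anc = ancestor_matrix(net.ontology, dis_ids).to_numpy()
    expanded_full = (direct @ anc) > 0
    removed_idx = np.flatnonzero(expanded_full[:, di])
    if removed_idx.size == 0:
        raise ValueError(f"disease {disease!r} has no associated lncRNAs")
    removed = tuple(net.lnc_ids[i] for i in removed_idx)

    reduced = direct.copy()
    reduced[:, di] = 0.0
    a_exp = ((reduced @ anc) > 0).astype(float)
    a_exp[:, di] = 0.0  # entries inherited from descendants go too
    f = _predict_arrays(net.transition.to_numpy(), net.similarity.to_numpy(),
                        a_exp, params)
    scores = pd.Series(f[:, di], index=net.lnc_ids)
    ranking = rank_candidates(
        pd.DataFrame(f, index=net.lnc_ids, columns=dis_ids), disease,
        axis="lncrna")
    k = len(removed)
    top = set(ranking["identifier"].head(k))
    return NovelDiseaseResult(disease=disease, removed=removed,
                              recovered=len(top & set(removed)),
                              ranking=ranking)


def rank_candidates(f: pd.DataFrame, target: str,
                    axis: str = "disease") -> pd.DataFrame:
    """Deterministic ranked list for one row or column of a score matrix.

    ``axis='disease'`` ranks the diseases of lncRNA ``target`` (a row);
    ``axis='lncrna'`` ranks the lncRNAs of disease ``target`` (a column).
    Descending by score, ties broken by identifier lexicographic order.
    """
    if axis == "disease":
        if target not in f.index:
            raise KeyError(f"unknown lncRNA {target!r}")
        series = f.loc[target]
    elif axis == "lncrna":
        if target not in f.columns:
            raise KeyError(f"unknown disease {target!r}")
        series = f[target]
    else:
        raise ValueError("axis must be 'disease' or 'lncrna'")
    rows = sorted(series.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame({
        "identifier": [k for k, _ in rows],
        "score": [float(v) for _, v in rows],
        "rank": np.arange(1, len(rows) + 1),
    })
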