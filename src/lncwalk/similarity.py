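"""lncRNA-lncRNA similarity from GO annotations and miRNA/disease links.

Two independent sources are fused additively into one similarity network:

* **FS** — functional similarity from shared GO annotations.  The printed
  form is the conditional overlap ``|T(l1) ∩ T(l2)| / |T(l1)|``, which is
  asymmetric; the stored network symmetrises the two directions by their
  arithmetic mean because the lncRNA subnetwork is undirected.
* **MDS** — a best-match average over the miRNA partners of the two
  lncRNAs, where the similarity between two miRNAs is the raw count of
  diseases they share.  MS counts are left unscaled; the symmetric degree
  normalisation below absorbs the scale.

The combined matrix ``LS = FS + MDS`` is normalised symmetrically,
``LS(l1,l2) / sqrt(deg(l1) * deg(l2))`` with ``deg(l) = sum_j LS(l, j)``,
before it feeds the lncRNA-side walk.  Every division-by-zero case (no
annotations, no miRNA partners, zero degree) yields similarity 0 rather
than an error: real annotation data are sparse and unannotated lncRNAs are
first-class citizens of the network.

None of these operations looks at lncRNA-disease associations, so the
similarity network is, by construction, independent of the labels the walk
is later evaluated on.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "load_pair_map",
    "functional_similarity",
    "functional_similarity_matrix",
    "mirna_similarity",
    "mds_similarity",
    "mds_similarity_matrix",
    "combined_similarity_matrix",
    "normalize_similarity",
]

PairMap = Mapping[str, frozenset[str]]


def load_pair_map(path: str | Path,
                  keys: Iterable[str] | None = None) -> dict[str, frozenset[str]]:
    """Read a two-column TSV edge list into ``{left: {right, ...}}``.

    Blank lines and ``#`` comments are skipped.  ``keys``, when given,
    guarantees every listed identifier is present (possibly with an empty
    set), so downstream lookups never miss sparsely annotated entities.
    """
    path = Path(path)
    out: dict[str, set[str]] = {k: set() for k in (keys or [])}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ValueError(
                    f"{path}:{lineno}: expected two tab-separated fields, got {line!r}"
                )
            out.setdefault(fields[0], set()).add(fields[1])
    return {k: frozenset(v) for k, v in out.items()}


def functional_similarity(ann: PairMap, l1: str, l2: str) -> float:
    """Directed GO-overlap similarity ``|T(l1) ∩ T(l2)| / |T(l1)|``.

    Returns 0 when ``l1`` has no annotations.  Note the direction matters:
    ``functional_similarity(ann, l1, l2) != functional_similarity(ann, l2, l1)``
    in general; the matrix builder averages the two.
    """
    t1 = ann.get(l1, frozenset())
    t2 = ann.get(l2, frozenset())
    if not t1:
        return 0.0
    return len(t1 & t2) / len(t1)


def functional_similarity_matrix(ann: PairMap, ids: Iterable[str],
                                 symmetrize: bool = True) -> pd.DataFrame:
    """FS over ``ids``; symmetrised by arithmetic mean unless disabled."""
    ids = list(ids)
    terms = sorted(set().union(*(ann.get(l, frozenset()) for l in ids)) or set())
    col = {t: j for j, t in enumerate(terms)}
    x = np.zeros((len(ids), max(len(terms), 1)))
    for i, l in enumerate(ids):
        for t in ann.get(l, frozenset()):
            x[i, col[t]] = 1.0
    inter = x @ x.T
    sizes = x.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fs = np.where(sizes[:, None] > 0, inter / np.maximum(sizes[:, None], 1e-300), 0.0)
    if symmetrize:
        fs = (fs + fs.T) / 2.0
    return pd.DataFrame(fs, index=ids, columns=ids)


def mirna_similarity(md: PairMap, m1: str, m2: str) -> int:
    """Count of diseases shared by two miRNAs (raw intersection size)."""
    return len(md.get(m1, frozenset()) & md.get(m2, frozenset()))


def mds_similarity(lm: PairMap, md: PairMap, l1: str, l2: str) -> float:
    """Best-match-average miRNA/disease similarity between two lncRNAs.

    Each miRNA of one lncRNA is matched to its best counterpart on the
    other side; the matched counts are summed over both directions and
    divided by the total number of miRNA partners.  0 when both partner
    sets are empty; a best match against an empty set counts 0.
    """
    m1 = sorted(lm.get(l1, frozenset()))
    m2 = sorted(lm.get(l2, frozenset()))
    if not m1 and not m2:
        return 0.0

    def best(m: str, pool: list[str]) -> int:
        return max((mirna_similarity(md, m, mi) for mi in pool), default=0)

    total = sum(best(m, m2) for m in m1) + sum(best(m, m1) for m in m2)
    return total / (len(m1) + len(m2))


def mds_similarity_matrix(lm: PairMap, md: PairMap,
                          ids: Iterable[str]) -> pd.DataFrame:
    """MDS over ``ids``, vectorised.

    ``B[l, m]`` holds the best MS score of miRNA ``m`` against the partner
    set of lncRNA ``l``; the pairwise numerator is then ``Z @ B.T`` plus its
    transpose, with ``Z`` the lncRNA-miRNA incidence matrix.
    """
    ids = list(ids)
    mirnas = sorted(set().union(*(lm.get(l, frozenset()) for l in ids)) or set())
    if not mirnas:
        return pd.DataFrame(np.zeros((len(ids), len(ids))), index=ids, columns=ids)
    mcol = {m: j for j, m in enumerate(mirnas)}
    diseases = sorted(set().union(*(md.get(m, frozenset()) for m in mirnas)) or set())
    dcol = {d: j for j, d in enumerate(diseases)}
    y = np.zeros((len(mirnas), max(len(diseases), 1)))
    for m in mirnas:
        for d in md.get(m, frozenset()):
            y[mcol[m], dcol[d]] = 1.0
    ms = y @ y.T  # integer-valued shared-disease counts

    z = np.zeros((len(ids), len(mirnas)))
    for i, l in enumerate(ids):
        for m in lm.get(l, frozenset()):
            z[i, mcol[m]] = 1.0
    sizes = z.sum(axis=1)

    # B[i, m] = max_{mi in M(ids[i])} MS(m, mi); 0 when M(ids[i]) is empty
    b = np.zeros((len(ids), len(mirnas)))
    for i in range(len(ids)):
        members = np.flatnonzero(z[i])
        if members.size:
            b[i] = ms[:, members].max(axis=1)
    num = z @ b.T
    num = num + num.T
    denom = sizes[:, None] + sizes[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        mds = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
    return pd.DataFrame(mds, index=ids, columns=ids)


def combined_similarity_matrix(ann: PairMap, lm: PairMap, md: PairMap,
                               ids: Iterable[str]) -> pd.DataFrame:
    """``LS = FS + MDS`` over ``ids`` (symmetric, non-negative).

    Supplying an empty annotation map or empty interaction maps disables
    the corresponding component, giving the single-source variants of the
    similarity network for free.
    """
    ids = list(ids)
    fs = functional_similarity_matrix(ann, ids)
    mds = mds_similarity_matrix(lm, md, ids)
    return fs + mds


def normalize_similarity(ls: pd.DataFrame) -> pd.DataFrame:
    """Symmetric degree normalisation of ``LS``.

    ``LS(l1, l2) / sqrt(deg(l1) * deg(l2))`` with degrees the row sums
    (diagonal included).  Rows of degree zero map to all-zero rows; the
    result is always finite.
    """
    v = ls.to_numpy(dtype=float)
    deg = v.sum(axis=1)
    scale = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    out = v * scale[:, None] * scale[None, :]
    return pd.DataFrame(out, index=ls.index, columns=ls.columns)
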