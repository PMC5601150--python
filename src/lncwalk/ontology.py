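"""Disease ontology handling and semantic similarity.

The disease side of the bi-relational network is a rooted, possibly
multi-rooted, directed acyclic graph (DAG) of disease terms in which parent
terms describe more general conditions than their children (e.g. *thoracic
cancer* is a parent of *breast cancer*).  Two quantities are derived from it:

* a pairwise semantic similarity ``DS`` between disease terms, computed with
  the Wang contribution scheme: each ancestor ``d'`` of a term ``d``
  contributes a weight that decays by a factor ``w_e`` per hierarchy edge,
  and two terms are similar in proportion to the mass of their shared
  ancestors relative to their total semantic values;
* a directed transition matrix ``W_DD`` whose entry ``(d', d)`` equals
  ``DS(d', d)`` when ``d'`` is a direct parent of ``d`` and zero otherwise.
  A random walker on the disease subnetwork therefore only ever steps from a
  parent down to one of its children, which is how the walk favours the more
  specific descendants of diseases already associated with an lncRNA.

``W_DD`` is intentionally *not* renormalised to a stochastic matrix: the walk
keeps scores bounded through its restart weight and finite step caps, and the
raw parent-child similarities are used as transition strengths as-is.  A
column normalisation is available for experimentation via
:func:`transition_matrix`'s ``column_normalize`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_EDGE_WEIGHT",
    "OntologyError",
    "CycleError",
    "DiseaseOntology",
    "SemanticContribution",
    "load_ontology",
    "semantic_contribution",
    "semantic_value",
    "disease_similarity",
    "disease_similarity_matrix",
    "transition_matrix",
    "ancestor_matrix",
]

#: Default per-edge semantic decay for the contribution recursion.
DEFAULT_EDGE_WEIGHT = 0.9


class OntologyError(ValueError):
    """Structural problem in an ontology source (dangling ids, bad lines)."""


class CycleError(OntologyError):
    """The parent->child edge relation is not acyclic."""


class DiseaseOntology:
    """A DAG of disease terms with parent->child edges.

    Parameters
    ----------
    parent_edges:
        Iterable of ``(parent, child)`` identifier pairs.
    terms:
        Optional extra identifiers (isolated terms carry no edges).

    Raises
    ------
    CycleError
        If the edge relation contains a directed cycle; the message names
        one edge on the cycle.
    """

    def __init__(self, parent_edges: Iterable[tuple[str, str]],
                 terms: Iterable[str] = ()) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        g.add_edges_from(parent_edges)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            parent, child = cyc[0][0], cyc[0][1]
            raise CycleError(
                f"ontology contains a cycle; offending edge {parent!r} -> {child!r}"
            )
        self._graph = g
        self._terms = tuple(sorted(g.nodes))
        self._anc_cache: dict[str, frozenset[str]] = {}
        self._desc_cache: dict[str, frozenset[str]] = {}

    # -- basic accessors ---------------------------------------------------

    @property
    def graph(self) -> nx.DiGraph:
        """The underlying parent->child directed graph (do not mutate)."""
        return self._graph

    @property
    def terms(self) -> tuple[str, ...]:
        return self._terms

    @property
    def parent_edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted(self._graph.edges))

    @property
    def roots(self) -> tuple[str, ...]:
        return tuple(t for t in self._terms if self._graph.in_degree(t) == 0)

    def __contains__(self, term: str) -> bool:
        return term in self._graph

    def __len__(self) -> int:
        return len(self._terms)

    def _require(self, term: str) -> None:
        if term not in self._graph:
            raise KeyError(f"unknown disease term {term!r}")

    def parents(self, term: str) -> tuple[str, ...]:
        """Direct parents of ``term`` (``par(d)``)."""
        self._require(term)
        return tuple(sorted(self._graph.predecessors(term)))

    def children(self, term: str) -> tuple[str, ...]:
        """Direct children of ``term``."""
        self._require(term)
        return tuple(sorted(self._graph.successors(term)))

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term``, *including the term itself*."""
        self._require(term)
        if term not in self._anc_cache:
            self._anc_cache[term] = frozenset(nx.ancestors(self._graph, term)) | {term}
        return self._anc_cache[term]

    def descendants(self, term: str) -> frozenset[str]:
        """All descendants of ``term``, including the term itself."""
        self._require(term)
        if term not in self._desc_cache:
            self._desc_cache[term] = frozenset(nx.descendants(self._graph, term)) | {term}
        return self._desc_cache[term]

    def depth(self) -> int:
        """Length (in edges) of the longest root-to-leaf path."""
        if not self._graph.edges:
            return 0
        return nx.dag_longest_path_length(self._graph)


# -- parsing ---------------------------------------------------------------


def _load_tsv(path: Path) -> DiseaseOntology:
    edges: list[tuple[str, str]] = []
    lone: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if lineno == 1 and [f.lower() for f in fields[:2]] == ["child", "parent"]:
                continue  # optional header
            if len(fields) == 1 or (len(fields) == 2 and fields[1] == ""):
                lone.append(fields[0])
                continue
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise OntologyError(
                    f"{path}:{lineno}: expected 'child<TAB>parent', got {line!r}"
                )
            child, parent = fields
            edges.append((parent, child))
    return DiseaseOntology(edges, terms=lone)


def _load_obo(path: Path) -> DiseaseOntology:
    import obonet

    graph = obonet.read_obo(path)  # drops obsolete stanzas
    edges = []
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":  # part_of and friends are ignored
            edges.append((parent, child))
    return DiseaseOntology(edges, terms=graph.nodes)


def load_ontology(path: str | Path) -> DiseaseOntology:
    """Read a disease DAG from an OBO file or a child/parent TSV edge list.

    The dialect is chosen by suffix: ``.obo`` uses the OBO 1.2/1.4 reader
    (``is_a`` relations only, obsolete terms dropped); anything else is
    parsed as a two-column TSV ``child<TAB>parent`` with an optional
    ``child\\tparent`` header line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ontology file not found: {path}")
    if path.suffix.lower() == ".obo":
        return _load_obo(path)
    return _load_tsv(path)


# -- semantic similarity ---------------------------------------------------


@dataclass(frozen=True)
class SemanticContribution:
    """Contribution weights of every ancestor of a focus term.

    ``weights[d']`` is the semantic contribution ``S_d(d')`` of ancestor
    ``d'`` to the focus term ``d``; the focus itself always contributes 1,
    and each step up the hierarchy multiplies by ``edge_weight``, taking the
    maximum over the (within-ancestor-set) children of ``d'``.
    """

    focus: str
    weights: Mapping[str, float]
    edge_weight: float = DEFAULT_EDGE_WEIGHT


def semantic_contribution(ont: DiseaseOntology, term: str,
                          w_e: float = DEFAULT_EDGE_WEIGHT) -> SemanticContribution:
    """Compute ``S_d(d')`` for every ancestor ``d'`` of ``term``.

    The recursion ``S_d(d) = 1``; ``S_d(d') = max_{d''} w_e * S_d(d'')`` runs
    over the children ``d''`` of ``d'`` that are themselves ancestors of
    ``d`` (or ``d`` itself) — children outside the ancestor set carry no
    defined contribution.  Terms are processed children-first (reverse
    topological order of the ancestor-induced subgraph), so each weight is
    computed exactly once.
    """
    if not 0.0 <= w_e <= 1.0:
        raise ValueError(f"w_e must be in [0, 1], got {w_e}")
    anc = ont.ancestors(term)
    sub = ont.graph.subgraph(anc)
    weights: dict[str, float] = {}
    # the focus is the unique sink of the induced subgraph, hence first here
    for node in reversed(list(nx.topological_sort(sub))):
        if node == term:
            weights[node] = 1.0
        else:
            weights[node] = max(w_e * weights[c] for c in sub.successors(node))
    return SemanticContribution(focus=term, weights=weights, edge_weight=w_e)


def semantic_value(contrib: SemanticContribution) -> float:
    """Total semantic value ``SV(d)``: sum of all ancestor contributions."""
    return float(sum(contrib.weights.values()))


def disease_similarity(ont: DiseaseOntology, d1: str, d2: str,
                       w_e: float = DEFAULT_EDGE_WEIGHT) -> float:
    """Wang semantic similarity ``DS(d1, d2)`` in ``[0, 1]``.

    Sums the contributions both terms receive from their shared ancestors
    and scales by the sum of the two semantic values.  Terms with no common
    ancestor (a multi-rooted forest) get similarity 0.
    """
    c1 = semantic_contribution(ont, d1, w_e)
    c2 = semantic_contribution(ont, d2, w_e)
    shared = set(c1.weights) & set(c2.weights)
    if not shared:
        return 0.0
    num = sum(c1.weights[d] + c2.weights[d] for d in shared)
    return float(num / (semantic_value(c1) + semantic_value(c2)))


def disease_similarity_matrix(ont: DiseaseOntology,
                              ids: Iterable[str] | None = None,
                              w_e: float = DEFAULT_EDGE_WEIGHT) -> pd.DataFrame:
    """Pairwise ``DS`` over ``ids`` (default: every ontology term).

    Vectorised: with ``S[i, t] = S_{ids[i]}(t)`` over the full term space and
    ``B`` its ancestor-indicator, the numerator of every pair is
    ``S @ B.T + B @ S.T`` and the denominator the outer sum of semantic
    values.  Equals the elementwise application of
    :func:`disease_similarity`.
    """
    ids = list(ids) if ids is not None else list(ont.terms)
    for d in ids:
        if d not in ont:
            raise KeyError(f"unknown disease term {d!r}")
    all_terms = list(ont.terms)
    col = {t: j for j, t in enumerate(all_terms)}
    n, m = len(ids), len(all_terms)
    S = np.zeros((n, m))
    B = np.zeros((n, m))
    for i, d in enumerate(ids):
        contrib = semantic_contribution(ont, d, w_e)
        for a, v in contrib.weights.items():
            S[i, col[a]] = v
            B[i, col[a]] = 1.0
    sv = S.sum(axis=1)
    num = S @ B.T + B @ S.T
    ds = num / (sv[:, None] + sv[None, :])
    ds = np.clip((ds + ds.T) / 2.0, 0.0, 1.0)  # exact symmetry, kill fp dust
    return pd.DataFrame(ds, index=ids, columns=ids)


def transition_matrix(ont: DiseaseOntology, ds: pd.DataFrame,
                      column_normalize: bool = False) -> pd.DataFrame:
    """Directed disease-side transition matrix ``W_DD``.

    ``W_DD(d', d) = DS(d', d)`` exactly when ``(d', d)`` is a parent->child
    edge, zero elsewhere.  With ``column_normalize=True`` each nonzero
    column is scaled to sum to one (off by default; the walk uses the raw
    matrix).
    """
    ids = list(ds.index)
    idx = {t: i for i, t in enumerate(ids)}
    w = np.zeros((len(ids), len(ids)))
    dsv = ds.to_numpy()
    for parent, child in ont.parent_edges:
        if parent in idx and child in idx:
            w[idx[parent], idx[child]] = dsv[idx[parent], idx[child]]
    if column_normalize:
        sums = w.sum(axis=0)
        nz = sums > 0
        w[:, nz] = w[:, nz] / sums[nz]
    return pd.DataFrame(w, index=ids, columns=ids)


def ancestor_matrix(ont: DiseaseOntology,
                    ids: Iterable[str] | None = None) -> pd.DataFrame:
    """Boolean matrix ``M[d, a] = 1`` iff ``a`` is an ancestor of ``d``.

    Includes the reflexive pair ``(d, d)``; used by the association module's
    ancestor-expansion closure.
    """
    ids = list(ids) if ids is not None else list(ont.terms)
    idx = {t: i for i, t in enumerate(ids)}
    m = np.zeros((len(ids), len(ids)), dtype=bool)
    for d in ids:
        for a in ont.ancestors(d):
            if a in idx:
                m[idx[d], idx[a]] = True
    return pd.DataFrame(m, index=ids, columns=ids)
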