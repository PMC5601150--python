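"""Association loading, ancestor expansion, and bi-relational assembly.

Associations come in as a two-column lncRNA/disease edge list and are
expanded under the hierarchy rule: an lncRNA associated with a disease is
also associated with every ancestor of that disease.  The expanded binary
matrix, the normalised lncRNA similarity matrix, and the directed
disease-side transition matrix together form the directed bi-relational
network the walk runs on.

The disease universe of a network is the full ontology term set, not just
the diseases that currently carry associations — the walk must be able to
score diseases nobody has linked yet.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .ontology import DiseaseOntology, ancestor_matrix

__all__ = [
    "load_associations",
    "expand_to_ancestors",
    "BiRelationalNetwork",
    "assemble_network",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

logger = logging.getLogger(__name__)


def load_associations(path: str | Path, lnc_ids: Iterable[str],
                      dis_ids: Iterable[str],
                      lenient: bool = False) -> pd.DataFrame:
    """Read a lncRNA/disease TSV edge list into a binary matrix.

    Duplicate lines collapse to a single 1.  Identifiers not present in the
    supplied universes raise a :class:`ValueError` listing every offender;
    with ``lenient=True`` they are skipped with a logged warning instead
    (silent loss would corrupt evaluation denominators, so the default is
    strict).
    """
    lnc_ids, dis_ids = list(lnc_ids), list(dis_ids)
    lset, dset = set(lnc_ids), set(dis_ids)
    mat = pd.DataFrame(0.0, index=lnc_ids, columns=dis_ids)
    offenders: list[str] = []
    with open(Path(path)) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ValueError(
                    f"{path}:{lineno}: expected 'lncRNA<TAB>disease', got {line!r}"
                )
            l, d = fields
            if l not in lset or d not in dset:
                offenders.append(f"line {lineno}: ({l!r}, {d!r})")
                continue
            mat.loc[l, d] = 1.0
    if offenders and not lenient:
        raise ValueError(
            f"{path}: {len(offenders)} association(s) reference unknown "
            "identifiers: " + "; ".join(offenders)
        )
    if offenders:
        logger.warning("%s: skipped %d association(s) with unknown identifiers",
                       path, len(offenders))
    return mat


def expand_to_ancestors(associations: pd.DataFrame,
                        ont: DiseaseOntology) -> pd.DataFrame:
    """Close a binary association matrix under the ancestor relation.

    ``A(l, d) = 1`` implies ``A(l, a) = 1`` for every ancestor ``a`` of
    ``d`` present in the matrix's disease columns.  Idempotent; never
    removes a 1.
    """
    dis_ids = list(associations.columns)
    for d in dis_ids:
        if d not in ont:
            raise KeyError(f"disease {d!r} not in ontology")
    anc = ancestor_matrix(ont, dis_ids).to_numpy()
    expanded = (associations.to_numpy() @ anc) > 0
    return pd.DataFrame(expanded.astype(float), index=associations.index,
                        columns=dis_ids)


@dataclass(frozen=True)
class BiRelationalNetwork:
    """Aligned bundle of the three matrices the walk consumes.

    ``transition`` is the directed disease-side matrix (D x D),
    ``similarity`` the normalised lncRNA matrix (N x N), and
    ``associations`` the *expanded* binary matrix (N x D).  ``direct`` and
    ``ontology`` are optional but required by the evaluation protocols,
    which re-derive the expansion per fold.
    """

    transition: pd.DataFrame
    similarity: pd.DataFrame
    associations: pd.DataFrame
    direct: pd.DataFrame | None = None
    ontology: DiseaseOntology | None = None

    @property
    def lnc_ids(self) -> list[str]:
        return list(self.similarity.index)

    @property
    def dis_ids(self) -> list[str]:
        return list(self.transition.index)

    def with_associations(self, associations: pd.DataFrame,
                          direct: pd.DataFrame | None = None) -> "BiRelationalNetwork":
        """Same network with a different (already aligned) association matrix."""
        return BiRelationalNetwork(self.transition, self.similarity,
                                   associations, direct, self.ontology)


def assemble_network(transition: pd.DataFrame, similarity: pd.DataFrame,
                     associations: pd.DataFrame,
                     direct: pd.DataFrame | None = None,
                     ontology: DiseaseOntology | None = None) -> BiRelationalNetwork:
    """Validate and align the three matrices into a bi-relational network.

    Identifier order is taken from ``similarity`` (lncRNAs) and
    ``transition`` (diseases); the association matrix is realigned by label.
    Missing identifiers are an error — only reordering is repaired.
    """
    lnc_ids = list(similarity.index)
    dis_ids = list(transition.index)
    if list(transition.columns) != dis_ids:
        raise ValueError("transition matrix must be square with matching labels")
    if list(similarity.columns) != lnc_ids:
        raise ValueError("similarity matrix must be square with matching labels")
    missing_l = sorted(set(associations.index) - set(lnc_ids))
    missing_d = sorted(set(associations.columns) - set(dis_ids))
    if missing_l or missing_d:
        raise ValueError(
            "association identifiers missing from the network: "
            f"lncRNAs {missing_l}, diseases {missing_d}"
        )
    aligned = associations.reindex(index=lnc_ids, columns=dis_ids, fill_value=0.0)
    aligned_direct = None
    if direct is not None:
        aligned_direct = direct.reindex(index=lnc_ids, columns=dis_ids,
                                        fill_value=0.0)
    return BiRelationalNetwork(transition, similarity, aligned,
                               aligned_direct, ontology)


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a labelled matrix as TSV with row/column identifier headers."""
    matrix.to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a labelled matrix written by :func:`write_matrix_tsv`."""
    return pd.read_csv(path, sep="\t", index_col=0)
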