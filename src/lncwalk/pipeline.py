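"""Glue: build a ready-to-walk network from edge lists or a dataset dir."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .network import (BiRelationalNetwork, assemble_network,
                      expand_to_ancestors, load_associations)
from .ontology import (DEFAULT_EDGE_WEIGHT, DiseaseOntology,
                       disease_similarity_matrix, transition_matrix)
from .similarity import combined_similarity_matrix, normalize_similarity
from .synthetic import SyntheticDataset, load_dataset

__all__ = ["build_network", "network_from_dataset", "network_from_dir"]


def _pairs_to_map(pairs: Iterable[tuple[str, str]],
                  keys: Iterable[str]) -> dict[str, frozenset[str]]:
    out: dict[str, set[str]] = {k: set() for k in keys}
    for a, b in pairs:
        out.setdefault(a, set()).add(b)
    return {k: frozenset(v) for k, v in out.items()}


def build_network(ont: DiseaseOntology,
                  lnc_ids: Iterable[str],
                  go_annotations: Iterable[tuple[str, str]],
                  lnc_mirna: Iterable[tuple[str, str]],
                  mirna_disease: Iterable[tuple[str, str]],
                  direct_pairs: Iterable[tuple[str, str]],
                  w_e: float = DEFAULT_EDGE_WEIGHT,
                  normalize_dd: bool = False) -> BiRelationalNetwork:
    """Assemble the full bi-relational network from raw edge lists.

    The disease universe is the full ontology term set.  The direct
    association pairs are expanded to ancestors before assembly; both the
    direct and expanded matrices travel with the network so the evaluation
    protocols can re-derive expansions per fold.
    """
    lnc_ids = sorted(lnc_ids)
    dis_ids = list(ont.terms)
    ds = disease_similarity_matrix(ont, w_e=w_e)
    w_dd = transition_matrix(ont, ds, column_normalize=normalize_dd)
    ann = _pairs_to_map(go_annotations, lnc_ids)
    lm = _pairs_to_map(lnc_mirna, lnc_ids)
    md = _pairs_to_map(mirna_disease, [])
    ls = combined_similarity_matrix(ann, lm, md, lnc_ids)
    ls_hat = normalize_similarity(ls)
    direct = pd.DataFrame(0.0, index=lnc_ids, columns=dis_ids)
    for l, d in direct_pairs:
        if l not in direct.index:
            raise KeyError(f"association references unknown lncRNA {l!r}")
        if d not in direct.columns:
            raise KeyError(f"association references unknown disease {d!r}")
        direct.loc[l, d] = 1.0
    expanded = expand_to_ancestors(direct, ont)
    return assemble_network(w_dd, ls_hat, expanded, direct=direct, ontology=ont)


def network_from_dataset(ds: SyntheticDataset,
                         w_e: float = DEFAULT_EDGE_WEIGHT,
                         normalize_dd: bool = False) -> BiRelationalNetwork:
    """Network for a generated dataset (all lncRNAs, full ontology)."""
    return build_network(ds.ontology, ds.lnc_ids, ds.go_annotations,
                         ds.lnc_mirna, ds.mirna_disease, ds.associations,
                         w_e=w_e, normalize_dd=normalize_dd)


def network_from_dir(data_dir: str | Path,
                     w_e: float = DEFAULT_EDGE_WEIGHT,
                     normalize_dd: bool = False) -> BiRelationalNetwork:
    """Network from a dataset directory written by ``write_dataset``."""
    return network_from_dataset(load_dataset(data_dir), w_e=w_e,
                                normalize_dd=normalize_dd)
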