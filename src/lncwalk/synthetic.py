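"""Synthetic benchmark generator with planted module structure.

Real inputs to this method are curated edge lists (disease ontology,
lncRNA-disease associations, lncRNA GO annotations, lncRNA-miRNA
interactions, miRNA-disease associations).  The generator emulates their
joint statistical structure so the full pipeline is testable end to end:

* a layered multi-parent DAG of disease terms under a single root;
* *functional modules*: disjoint groups of lncRNAs and miRNAs, each
  anchored to one ontology subtree, whose members share a GO-term pool;
* miRNA-disease links drawn from the module's subtree and lncRNA-miRNA
  links drawn preferentially within the module, so both similarity sources
  correlate with the planted associations;
* planted lncRNA-disease associations drawn from the module subtree with a
  *descendant bias*: each additional disease of an lncRNA is, with some
  probability, a strict descendant of one already chosen — mirroring how
  newly curated associations tend to refine existing ones toward more
  specific disease terms.

``noise_rate`` interpolates toward a structureless null: each GO
annotation, interaction, and association draw is replaced by a uniform
draw from the global pool with that probability.  At ``noise_rate = 1``
the module structure (including the association placement) is gone and
ranking performance collapses to chance.

Everything is bit-reproducible under a fixed seed.  The truth/exposed
split is resolved at evaluation time (the protocols hide what they need),
so one generated dataset serves every protocol.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ontology import DiseaseOntology

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "PRESETS",
    "generate_ontology",
    "generate_entities_and_links",
    "generate",
    "write_dataset",
    "load_dataset",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults define the standard benchmark.

    ``descendant_bias`` is the probability that an additional association
    of an lncRNA is drawn from the strict descendants of one it already
    has; ``noise_rate`` is the per-draw probability of falling back to the
    global pool.
    """

    seed: int = 7
    n_disease_layers: int = 4
    diseases_per_layer: int = 10
    max_parents: int = 2
    n_lncrnas: int = 60
    n_mirnas: int = 40
    n_go_terms: int = 60
    n_modules: int = 6
    assoc_per_lncrna: int = 4
    noise_rate: float = 0.1
    descendant_bias: float = 0.7
    go_terms_per_lncrna: int = 5
    mirnas_per_lncrna: int = 3
    diseases_per_mirna: int = 3

    def __post_init__(self) -> None:
        counts = (self.n_disease_layers, self.diseases_per_layer,
                  self.max_parents, self.n_lncrnas, self.n_mirnas,
                  self.n_go_terms, self.n_modules, self.assoc_per_lncrna,
                  self.go_terms_per_lncrna, self.mirnas_per_lncrna,
                  self.diseases_per_mirna)
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be positive")
        for rate in (self.noise_rate, self.descendant_bias):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


PRESETS: dict[str, SyntheticConfig] = {
    "small": SyntheticConfig(seed=1, n_disease_layers=2, diseases_per_layer=4,
                             n_lncrnas=12, n_mirnas=8, n_go_terms=18,
                             n_modules=3, assoc_per_lncrna=2,
                             go_terms_per_lncrna=3, mirnas_per_lncrna=2,
                             diseases_per_mirna=2),
    "default": SyntheticConfig(),
    "null": SyntheticConfig(noise_rate=1.0),
}


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated ontology, edge lists, and the planted truth associations."""

    ontology: DiseaseOntology
    go_annotations: tuple[tuple[str, str], ...]
    lnc_mirna: tuple[tuple[str, str], ...]
    mirna_disease: tuple[tuple[str, str], ...]
    associations: tuple[tuple[str, str], ...]  # exposed direct pairs
    truth: frozenset[tuple[str, str]]
    lnc_ids: tuple[str, ...]
    mirna_ids: tuple[str, ...]
    config: SyntheticConfig


def generate_ontology(cfg: SyntheticConfig,
                      rng: np.random.Generator | None = None) -> DiseaseOntology:
    """Layered DAG: one root; each node draws 1..max_parents parents
    uniformly (without replacement) from the previous layer."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    root = "d0_00"
    prev = [root]
    edges: list[tuple[str, str]] = []
    for layer in range(1, cfg.n_disease_layers + 1):
        nodes = [f"d{layer}_{j:02d}" for j in range(cfg.diseases_per_layer)]
        for node in nodes:
            n_par = int(rng.integers(1, min(cfg.max_parents, len(prev)) + 1))
            parents = rng.choice(prev, size=n_par, replace=False)
            edges.extend((str(p), node) for p in sorted(parents))
        prev = nodes
    return DiseaseOntology(edges, terms=[root])


def _draw(rng: np.random.Generator, pool: list[str]) -> str:
    return str(pool[int(rng.integers(len(pool)))])


def generate_entities_and_links(cfg: SyntheticConfig, ont: DiseaseOntology,
                                rng: np.random.Generator | None = None
                                ) -> SyntheticDataset:
    """Plant modules and draw all edge lists (see module docstring)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    all_diseases = sorted(ont.terms)
    all_go = [f"g{j:03d}" for j in range(cfg.n_go_terms)]
    lnc_ids = tuple(f"l{j:03d}" for j in range(cfg.n_lncrnas))
    mirna_ids = tuple(f"m{j:03d}" for j in range(cfg.n_mirnas))

    # module anchors: distinct first-layer terms where possible, so each
    # module's subtree is deep enough to support descendant-biased draws
    root = [t for t in ont.terms if not ont.parents(t)][0]
    layer1 = sorted(ont.children(root)) or [root]
    anchors = [str(a) for a in rng.choice(
        layer1, size=cfg.n_modules, replace=cfg.n_modules > len(layer1))]
    subtrees = [sorted(ont.descendants(a)) for a in anchors]

    # contiguous GO pools per module
    pool_size = max(1, cfg.n_go_terms // cfg.n_modules)
    go_pools = [all_go[m * pool_size:(m + 1) * pool_size] or all_go
                for m in range(cfg.n_modules)]

    lnc_module = {l: i % cfg.n_modules for i, l in enumerate(lnc_ids)}
    mir_module = {m: i % cfg.n_modules for i, m in enumerate(mirna_ids)}
    module_mirnas = [[m for m in mirna_ids if mir_module[m] == k]
                     for k in range(cfg.n_modules)]

    go_ann: set[tuple[str, str]] = set()
    for l in lnc_ids:
        pool = go_pools[lnc_module[l]]
        for _ in range(cfg.go_terms_per_lncrna):
            src = all_go if rng.random() < cfg.noise_rate else pool
            go_ann.add((l, _draw(rng, src)))

    mirna_dis: set[tuple[str, str]] = set()
    for m in mirna_ids:
        subtree = subtrees[mir_module[m]]
        for _ in range(cfg.diseases_per_mirna):
            src = all_diseases if rng.random() < cfg.noise_rate else subtree
            mirna_dis.add((m, _draw(rng, src)))

    lnc_mir: set[tuple[str, str]] = set()
    for l in lnc_ids:
        own = module_mirnas[lnc_module[l]] or list(mirna_ids)
        for _ in range(cfg.mirnas_per_lncrna):
            src = list(mirna_ids) if rng.random() < cfg.noise_rate else own
            lnc_mir.add((l, _draw(rng, src)))

    truth: set[tuple[str, str]] = set()
    for l in lnc_ids:
        subtree = subtrees[lnc_module[l]]
        if len(subtree) < cfg.assoc_per_lncrna:
            logger.info("module subtree of %s smaller than assoc_per_lncrna; "
                        "drawing with replacement and deduplicating", l)
        chosen: list[str] = []
        for j in range(cfg.assoc_per_lncrna):
            if rng.random() < cfg.noise_rate:
                d = _draw(rng, all_diseases)
            elif j > 0 and rng.random() < cfg.descendant_bias:
                desc = sorted(set().union(
                    *(ont.descendants(c) for c in chosen)) - set(chosen))
                d = _draw(rng, desc) if desc else _draw(rng, subtree)
            else:
                d = _draw(rng, subtree)
            chosen.append(d)
        truth.update((l, d) for d in set(chosen))

    return SyntheticDataset(
        ontology=ont,
        go_annotations=tuple(sorted(go_ann)),
        lnc_mirna=tuple(sorted(lnc_mir)),
        mirna_disease=tuple(sorted(mirna_dis)),
        associations=tuple(sorted(truth)),
        truth=frozenset(truth),
        lnc_ids=lnc_ids,
        mirna_ids=mirna_ids,
        config=cfg,
    )


def generate(cfg: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate a full dataset from one config (single source of seeding)."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    ont = generate_ontology(cfg, rng)
    return generate_entities_and_links(cfg, ont, rng)


# -- on-disk form -----------------------------------------------------------


def _write_pairs(pairs, path: Path) -> None:
    with open(path, "w") as fh:
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def _write_obo(ont: DiseaseOntology, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in ont.terms:
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            for parent in ont.parents(term):
                fh.write(f"is_a: {parent}\n")


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset as plain TSV edge lists + OBO + a JSON manifest.

    The emitted files are directly consumable by the command-line
    interface; the manifest records the full config (including the seed)
    so a run is reproducible from the directory alone.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ontology_tsv": out / "ontology.tsv",
        "ontology_obo": out / "ontology.obo",
        "go_annotations": out / "go_annotations.tsv",
        "lnc_mirna": out / "lnc_mirna.tsv",
        "mirna_disease": out / "mirna_disease.tsv",
        "associations": out / "associations.tsv",
        "truth": out / "truth.tsv",
        "manifest": out / "manifest.json",
    }
    _write_pairs(((c, p) for p, c in ds.ontology.parent_edges),
                 paths["ontology_tsv"])
    _write_obo(ds.ontology, paths["ontology_obo"])
    _write_pairs(ds.go_annotations, paths["go_annotations"])
    _write_pairs(ds.lnc_mirna, paths["lnc_mirna"])
    _write_pairs(ds.mirna_disease, paths["mirna_disease"])
    _write_pairs(ds.associations, paths["associations"])
    _write_pairs(sorted(ds.truth), paths["truth"])
    manifest = {
        "config": dataclasses.asdict(ds.config),
        "lnc_ids": list(ds.lnc_ids),
        "mirna_ids": list(ds.mirna_ids),
        "n_diseases": len(ds.ontology),
        "n_associations": len(ds.associations),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths


def load_dataset(data_dir: str | Path) -> SyntheticDataset:
    """Load a dataset previously written by :func:`write_dataset`."""
    from .ontology import load_ontology

    data = Path(data_dir)
    manifest = json.loads((data / "manifest.json").read_text())
    cfg = SyntheticConfig(**manifest["config"])

    def pairs(name: str) -> tuple[tuple[str, str], ...]:
        rows = []
        for line in (data / name).read_text().splitlines():
            if line.strip():
                a, b = line.split("\t")
                rows.append((a, b))
        return tuple(rows)

    ont = load_ontology(data / "ontology.tsv")
    return SyntheticDataset(
        ontology=ont,
        go_annotations=pairs("go_annotations.tsv"),
        lnc_mirna=pairs("lnc_mirna.tsv"),
        mirna_disease=pairs("mirna_disease.tsv"),
        associations=pairs("associations.tsv"),
        truth=frozenset(pairs("truth.tsv")),
        lnc_ids=tuple(manifest["lnc_ids"]),
        mirna_ids=tuple(manifest["mirna_ids"]),
        config=cfg,
    )
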