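"""Synthetic superalignments with controlled phylogenetic heterogeneity.

The generator produces concatenated gene alignments with the statistical
structure that the NBS method targets:

* homogeneous control — every gene evolves on the species topology;
* ILS-like heterogeneity — gene topologies drawn from a finite mixture of
  conflicting topologies (discordance frequency set by the mixture weights,
  realized exactly by largest-remainder allocation so a nominal 50/50
  mixture is not blurred by allocation noise);
* gene-tree estimation error (GTEE) — all genes share the species topology
  but branch lengths are scaled down uniformly (0.1 / 0.07 / 0.05 for low /
  medium / high error regimes), starving per-gene trees of substitutions
  while the concatenated signal stays consistent;
* skewed gene lengths (lognormal with a target sample skewness) and
  per-taxon missing data.

Sequence evolution is plain Jukes-Cantor: sites are independent, the root
state is uniform, and along a branch of length ``t`` (expected
substitutions/site) a site changes with probability ``(3/4)(1 - e^(-4t/3))``
to a uniformly chosen different base.  Richer substitution models belong to
external simulators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import dendropy
import numpy as np
from scipy import optimize, stats as sps

from .msa_io import Superalignment
from .tree_engine import parse_newick

__all__ = [
    "SimulationSpec",
    "evolve_gene",
    "ils_like_dataset",
    "gtee_dataset",
    "inject_missing",
    "skewed_gene_lengths",
    "caterpillar_newick",
    "nni_pair",
    "random_tree",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationSpec:
    """Recipe for one concatenated dataset.

    ``mixture`` is a list of ``(topology, weight)`` gene-tree classes where
    each topology is a Newick string or dendropy tree with branch lengths in
    expected substitutions/site; weights must sum to 1.  ``gene_length`` may
    be an integer or a callable ``rng -> int``.  ``scale`` multiplies every
    branch length (the GTEE dial).  ``missing`` maps taxon name to the
    fraction of its residues replaced by '?'.
    """

    mixture: list
    n_genes: int = 100
    gene_length: Union[int, Callable] = 1600
    scale: float = 1.0
    model: str = "jc"
    missing: Optional[dict] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.model != "jc":
            raise ValueError("only the jc model is built in")
        w = sum(w for _, w in self.mixture)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"mixture weights sum to {w}, not 1")


def _as_tree(topology) -> dendropy.Tree:
    if isinstance(topology, dendropy.Tree):
        return topology
    return parse_newick(topology)


def evolve_gene(
    tree: dendropy.Tree,
    length: int,
    rng: np.random.Generator,
    scale: float = 1.0,
) -> tuple:
    """Simulate one gene under Jukes-Cantor along a tree.

    Returns ``(labels, matrix)`` with taxa in leaf-iteration order.  Every
    edge needs a branch length; lengths are multiplied by ``scale``.
    """
    if length < 1:
        raise ValueError("gene length must be >= 1")
    tree = _as_tree(tree)
    seqs = {}
    root = tree.seed_node
    seqs[root] = rng.integers(0, 4, size=length, dtype=np.int8)
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        if node is root:
            continue
        if edge.length is None:
            raise ValueError("tree has edges without branch lengths")
        t = float(edge.length) * scale
        p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
        parent_seq = seqs[edge.tail_node]
        child = parent_seq.copy()
        hit = rng.random(length) < p_change
        k = int(hit.sum())
        if k:
            # uniform over the three other bases
            child[hit] = (child[hit] + rng.integers(1, 4, size=k, dtype=np.int8)) % 4
        seqs[node] = child
    labels, rows = [], []
    for leaf in tree.leaf_node_iter():
        labels.append(leaf.taxon.label)
        rows.append(_BASES[seqs[leaf]])
    return labels, np.vstack(rows)


def _allocate_classes(weights: Sequence[float], n_genes: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder allocation of genes to mixture classes, shuffled."""
    quotas = np.array(weights) * n_genes
    counts = np.floor(quotas).astype(int)
    rem = n_genes - counts.sum()
    order = np.argsort(-(quotas - counts))
    counts[order[:rem]] += 1
    assignment = np.repeat(np.arange(len(weights)), counts)
    return rng.permutation(assignment)


def ils_like_dataset(spec: SimulationSpec) -> tuple:
    """Concatenated mixture dataset: ``(Superalignment, truth dict)``.

    Gene boundaries are recorded in the partition map (the NBS pipeline
    deliberately ignores them; they serve diagnostics and evaluation).
    The truth dict records the per-gene class and the class topologies.
    """
    rng = np.random.default_rng(spec.seed)
    trees = [_as_tree(t) for t, _ in spec.mixture]
    weights = [w for _, w in spec.mixture]
    ref_labels = sorted(lf.taxon.label for lf in trees[0].leaf_node_iter())
    for t in trees[1:]:
        if sorted(lf.taxon.label for lf in t.leaf_node_iter()) != ref_labels:
            raise ValueError("mixture topologies have mismatched taxon sets")
    classes = _allocate_classes(weights, spec.n_genes, rng)
    blocks, pmap, gene_classes = [], [], []
    offset = 0
    for gi, cls in enumerate(classes):
        length = (
            spec.gene_length
            if isinstance(spec.gene_length, int)
            else int(spec.gene_length(rng))
        )
        labels, mat = evolve_gene(trees[cls], length, rng, spec.scale)
        order = [labels.index(lab) for lab in ref_labels]
        blocks.append(mat[order])
        pmap.append((f"gene{gi + 1}", offset, offset + length))
        gene_classes.append(int(cls))
        offset += length
    aln = Superalignment(
        ref_labels, np.hstack(blocks), "dna", partition_map=pmap
    )
    if spec.missing:
        aln = inject_missing(aln, spec.missing, rng)
    truth = {
        "topologies": [t.as_string(schema="newick").strip() for t in trees],
        "weights": list(weights),
        "gene_classes": gene_classes,
        "scale": spec.scale,
        "seed": spec.seed,
    }
    return aln, truth


def gtee_dataset(
    species_tree,
    scale: float,
    n_genes: int = 1000,
    gene_length: int = 1600,
    rng: Optional[np.random.Generator] = None,
) -> list:
    """Per-gene alignments on one topology with uniformly scaled branches.

    Small ``scale`` (0.1 / 0.07 / 0.05) leaves each gene with only a few
    substitutions, producing heavy gene-tree estimation error while the
    concatenated signal remains consistent with the species topology.
    Returns a list of single-gene Superalignments.
    """
    rng = rng if rng is not None else np.random.default_rng()
    tree = _as_tree(species_tree)
    out = []
    for _ in range(n_genes):
        labels, mat = evolve_gene(tree, gene_length, rng, scale)
        out.append(Superalignment(labels, mat, "dna"))
    return out


def inject_missing(
    aln: Superalignment, per_taxon_fraction: dict, rng: np.random.Generator
) -> Superalignment:
    """Replace a fraction of each listed taxon's residues with '?' uniformly."""
    matrix = aln.matrix.copy()
    for taxon, frac in per_taxon_fraction.items():
        if not (0 <= frac < 1):
            raise ValueError(
                f"missing fraction for {taxon!r} must lie in [0, 1)"
            )
        i = aln.labels.index(taxon)
        k = int(round(frac * aln.L))
        sites = rng.choice(aln.L, size=k, replace=False)
        matrix[i, sites] = ord("?")
    return Superalignment(list(aln.labels), matrix, aln.alphabet, aln.partition_map)


def skewed_gene_lengths(
    n_genes: int,
    mean_length: float,
    target_skewness: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Lognormal gene lengths whose population skewness hits a target.

    The lognormal shape ``sigma`` solves
    ``(e^(s^2) + 2) sqrt(e^(s^2) - 1) = skew``; the log-mean is then set so
    the arithmetic mean equals ``mean_length``.  Emulates the long right
    tail of empirical phylogenomic gene-length distributions.
    """
    if mean_length < 50:
        raise ValueError("mean_length must be >= 50")
    if target_skewness <= 0:
        raise ValueError(
            "lognormal lengths cannot hit skewness <= 0; use a symmetric sampler"
        )

    def skew_of(s2):
        return (np.exp(s2) + 2.0) * np.sqrt(np.exp(s2) - 1.0) - target_skewness

    s2 = optimize.brentq(skew_of, 1e-30, 20.0)
    sigma = np.sqrt(s2)
    mu = np.log(mean_length) - s2 / 2.0
    lengths = np.exp(rng.normal(mu, sigma, size=n_genes))
    return np.maximum(np.rint(lengths).astype(int), 1)


# -- convenience topologies -------------------------------------------------

def caterpillar_newick(
    labels: Sequence[str], terminal: float = 0.06, internal: float = 0.04
) -> str:
    """Pectinate (ladder) topology over `labels` with fixed branch lengths."""
    if len(labels) < 4:
        raise ValueError("need at least 4 taxa")
    s = f"({labels[0]}:{terminal},{labels[1]}:{terminal})"
    for lab in labels[2:-1]:
        s = f"({s}:{internal},{lab}:{terminal})"
    return f"({s}:{internal},{labels[-1]}:{terminal});"


def nni_pair(
    n_taxa: int = 16, terminal: float = 0.06, internal: float = 0.04
) -> tuple:
    """Two caterpillar topologies differing by one NNI, plus the contested
    clades.

    Swapping the two taxa flanking the central internal edge changes exactly
    one bipartition.  Returns ``(newick1, newick2, clade1, clade2)`` where
    ``clade1``/``clade2`` are the taxon tuples of the conflicting split in
    each topology (every other split is shared).
    """
    if n_taxa < 6:
        raise ValueError("need at least 6 taxa for an interior NNI")
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    mid = n_taxa // 2
    swapped = labels.copy()
    swapped[mid - 1], swapped[mid] = swapped[mid], swapped[mid - 1]
    t1 = caterpillar_newick(labels, terminal, internal)
    t2 = caterpillar_newick(swapped, terminal, internal)
    return t1, t2, tuple(labels[:mid]), tuple(swapped[:mid])


def random_tree(
    labels: Sequence[str],
    rng: np.random.Generator,
    edge_min: float = 0.03,
    edge_max: float = 0.15,
) -> dendropy.Tree:
    """Random bifurcating topology by sequential random attachment, with
    uniform branch lengths in [edge_min, edge_max]."""
    if len(labels) < 4:
        raise ValueError("need at least 4 taxa")

    def elen():
        return float(rng.uniform(edge_min, edge_max))

    clusters = [f"{lab}:{elen():.6f}" for lab in labels]
    while len(clusters) > 2:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        merged = f"({clusters[i]},{clusters[j]}):{elen():.6f}"
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return parse_newick(f"({clusters[0]},{clusters[1]});")
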