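"""Replicate-tree inference.

Two routes produce a phylogeny from a (weighted) replicate alignment:

* ``builtin_nj`` — a weighted p-distance / Jukes-Cantor distance matrix fed
  to neighbor-joining.  Distances consume the sparse replicate weight vector
  directly, so a full-length upsampled replicate costs no more than its
  subsample.  This is the desk-scale engine used throughout the tests; the
  clade-support statistics downstream are agnostic to how replicate trees
  are obtained.
* ``external`` — an adapter that materializes the replicate to FASTA, runs a
  user-supplied command template (e.g. an ML program), and parses the
  resulting Newick tree.

Trees are ``dendropy.Tree`` objects throughout; a shared
``dendropy.TaxonNamespace`` keeps leaf identity stable across the thousands
of replicate trees of a run.
"""

from __future__ import annotations

import math
import os
import subprocess
import tempfile
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np

from .msa_io import Superalignment
from .resampling import ReplicateWeights, materialize

__all__ = [
    "EngineConfig",
    "EngineError",
    "weighted_distance_matrix",
    "neighbor_joining",
    "infer_tree",
    "parse_newick",
    "write_newick",
    "taxon_namespace_for",
]

PhyloTree = dendropy.Tree


class EngineError(RuntimeError):
    """A replicate tree could not be inferred."""


@dataclass
class EngineConfig:
    """How replicate trees are inferred.

    ``distance`` selects the built-in metric: ``"p"`` (proportion of
    mismatched sites) or ``"jc"`` (Jukes-Cantor corrected).  External
    engines are configured by a shell template with ``{aln}``, ``{out}`` and
    ``{seed}`` placeholders that must write exactly one Newick tree.
    ``model_hint`` is free text recorded in run manifests (e.g. "GTR+G4").
    """

    engine: str = "builtin_nj"
    distance: str = "jc"
    saturation_cap: float = 5.0
    external_cmd_template: Optional[str] = None
    model_hint: Optional[str] = None

    def __post_init__(self):
        if self.engine not in ("builtin_nj", "external"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.distance not in ("p", "jc"):
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.engine == "external" and not self.external_cmd_template:
            raise ValueError("external engine requires a command template")


def taxon_namespace_for(labels: Sequence[str]) -> dendropy.TaxonNamespace:
    return dendropy.TaxonNamespace(list(labels))


# -- distances -------------------------------------------------------------

def weighted_distance_matrix(
    aln: Superalignment,
    weights: Optional[ReplicateWeights] = None,
    distance: str = "p",
    cap: float = 5.0,
) -> np.ndarray:
    """Pairwise weighted distances under pairwise deletion of missing data.

    For each taxon pair, ``p`` is the weighted fraction of mismatches over
    sites where both taxa carry unambiguous residues.  ``jc`` applies the
    Jukes-Cantor correction ``-(3/4) ln(1 - 4p/3)`` (DNA) or the 20-state
    analogue ``-(19/20) ln(1 - 20p/19)`` (protein).  Saturated pairs are set
    to ``cap`` rather than erroring, because upsampled replicates of tiny
    subsamples can saturate by chance.
    """
    if aln.n_taxa < 4:
        raise ValueError("need at least 4 taxa for tree inference")
    valid = aln.informative_mask()
    if weights is None:
        sub = aln.matrix
        vmask = valid
        w = np.ones(aln.L)
    else:
        sub = aln.matrix[:, weights.indices]
        vmask = valid[:, weights.indices]
        w = weights.multiplicities.astype(np.float64)
    n = aln.n_taxa
    D = np.zeros((n, n))
    saturated = []
    for i in range(n):
        vi, si = vmask[i], sub[i]
        for j in range(i + 1, n):
            both = vi & vmask[j]
            denom = w @ both
            if denom == 0:
                raise ValueError(
                    f"taxa {aln.labels[i]!r} and {aln.labels[j]!r} share no "
                    "weighted comparable sites"
                )
            mism = both & (si != sub[j])
            p = (w @ mism) / denom
            if distance == "p":
                d = p
            else:
                if aln.alphabet == "dna":
                    a = 3.0 / 4.0
                else:
                    a = 19.0 / 20.0
                if p >= a:
                    saturated.append((aln.labels[i], aln.labels[j]))
                    d = cap
                else:
                    d = -a * math.log1p(-p / a)
            D[i, j] = D[j, i] = d
    if saturated:
        import warnings

        warnings.warn(
            f"{len(saturated)} saturated pair(s) capped at {cap}: "
            f"{saturated[:3]}...",
            stacklevel=2,
        )
    return D


# -- neighbor joining ------------------------------------------------------

def neighbor_joining(
    D: np.ndarray,
    labels: Sequence[str],
    taxon_namespace: Optional[dendropy.TaxonNamespace] = None,
) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The Q-criterion minimum is resolved to the lexicographically smallest
    active pair, making the output a pure function of the input matrix.
    Negative branch lengths produced by the agglomeration are clamped to 0.
    """
    D = np.array(D, dtype=np.float64)
    n = D.shape[0]
    if D.shape != (n, n) or n != len(labels):
        raise ValueError("matrix/labels size mismatch")
    if n < 4:
        raise ValueError("need at least 4 taxa")
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distances")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")
    ns = taxon_namespace or taxon_namespace_for(labels)
    taxa = {lab: ns.get_taxon(lab) for lab in labels}
    if None in taxa.values():
        missing = [lab for lab, t in taxa.items() if t is None]
        raise ValueError(f"labels absent from taxon namespace: {missing}")

    nodes = []
    for lab in labels:
        nd = dendropy.Node(taxon=taxa[lab])
        nodes.append(nd)
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # argmin scans row-major: first hit is the lexicographically
        # smallest (i, j) among ties
        flat = int(np.argmin(Q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        # reuse slot i for the new cluster
        newd = 0.5 * (D[i, active] + D[j, active] - dij)
        D[i, active] = newd
        D[active, i] = newd
        D[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    center = dendropy.Node()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[k])
        nodes[k].edge.length = max(lk, 0.0)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=center)
    tree.is_rooted = False
    return tree


# -- newick ----------------------------------------------------------------

def parse_newick(
    text: str,
    taxon_namespace: Optional[dendropy.TaxonNamespace] = None,
) -> PhyloTree:
    """Parse one Newick tree with early structural validation.

    Unbalanced parentheses are reported with a character offset; duplicate
    leaf labels are a hard error.
    """
    depth = 0
    for off, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced ')' at offset {off}")
    if depth != 0:
        raise ValueError(
            f"unbalanced parentheses: {depth} unclosed '(' at offset {len(text)}"
        )
    kwargs = dict(
        data=text,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    if taxon_namespace is not None:
        kwargs["taxon_namespace"] = taxon_namespace
    from dendropy.dataio.newickreader import NewickReader

    try:
        tree = dendropy.Tree.get(**kwargs)
    except NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate leaf labels: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dupes = {lab for lab in labels if labels.count(lab) > 1}
    if dupes:
        raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
    return tree


def write_newick(tree: PhyloTree, support_labels: Optional[dict] = None) -> str:
    """Serialize to Newick; internal node labels carry supports if present."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


# -- unified inference entry point -----------------------------------------

def infer_tree(
    aln: Superalignment,
    weights: Optional[ReplicateWeights],
    cfg: EngineConfig,
    rng: Optional[np.random.Generator] = None,
    taxon_namespace: Optional[dendropy.TaxonNamespace] = None,
) -> PhyloTree:
    """Infer one replicate tree according to the engine configuration."""
    if cfg.engine == "builtin_nj":
        D = weighted_distance_matrix(
            aln, weights, distance=cfg.distance, cap=cfg.saturation_cap
        )
        return neighbor_joining(D, aln.labels, taxon_namespace)
    return _run_external(aln, weights, cfg, rng, taxon_namespace)


def _run_external(aln, weights, cfg, rng, taxon_namespace):
    from .msa_io import write_alignment

    rep = materialize(aln, weights) if weights is not None else aln
    seed = int(rng.integers(0, 2**31 - 1)) if rng is not None else 0
    with tempfile.TemporaryDirectory(prefix="nbsupport_ext_") as tmp:
        aln_path = os.path.join(tmp, "replicate.fasta")
        out_path = os.path.join(tmp, "replicate.nwk")
        write_alignment(rep, aln_path, "fasta")
        cmd = cfg.external_cmd_template.format(
            aln=aln_path, out=out_path, seed=seed
        )
        proc = subprocess.run(
            cmd, shell=True, capture_output=True, text=True
        )
        if proc.returncode != 0:
            raise EngineError(
                f"external engine exited {proc.returncode}: {proc.stderr[-500:]}"
            )
        if not os.path.exists(out_path):
            raise EngineError("external engine produced no output tree")
        with open(out_path) as fh:
            text = fh.read().strip()
    try:
        tree = parse_newick(text, taxon_namespace)
    except Exception as exc:  # noqa: BLE001 - adapter boundary
        raise EngineError(f"unparseable external tree: {exc}") from exc
    got = {lf.taxon.label for lf in tree.leaf_node_iter()}
    want = set(aln.labels)
    if got != want:
        raise EngineError(
            f"external tree leaf set mismatch: missing {sorted(want - got)}, "
            f"extra {sorted(got - want)}"
        )
    return tree
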