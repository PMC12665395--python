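"""Net Bootstrap Support: bcl distributions, NBS/FBS/OC, adaptive stopping.

Within one subsample, the bootstrap confidence limit (*bcl*) of a clade is
the percentage of that subsample's upsampled replicate trees containing the
clade.  Across ``S`` subsamples each clade accumulates a *bcl* distribution,
from which three quantities follow:

* ``NBS  = mean(bcl)``   — net bootstrap support, the heterogeneity-
  corrected confidence in the clade;
* ``FBS ~= median(bcl)`` — an estimate of the classic full-superalignment
  Felsenstein bootstrap support;
* ``OC   = FBS - NBS``   — overconfidence, the signed excess of the
  superalignment bootstrap over subsample-level support.  ``OC = 0`` when
  the bcl distribution is symmetric around FBS; a clade torn between
  conflicting phylogenetic signals has bcl mass at both extremes, a median
  at one extreme, and hence a large OC.

The number of subsamples is increased adaptively until the root mean squared
deviation (RMSD) of per-clade NBS between successive iterations falls below
a tolerance (0.05 on the [0, 1] proportion scale, i.e. 5 support points)
on two consecutive iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from .msa_io import Superalignment
from .resampling import (
    default_subsample_size,
    draw_subsample,
    spawn_rng,
    upsample_replicate,
)
from .tree_engine import EngineConfig, EngineError, infer_tree, taxon_namespace_for

__all__ = [
    "Bipartition",
    "BclDistribution",
    "SubsampleBcl",
    "SupportRecord",
    "StoppingState",
    "NbsResult",
    "bipartitions",
    "bcl_for_subsample",
    "aggregate_bcl",
    "nbs",
    "fbs_estimate",
    "overconfidence",
    "rmsd_step",
    "adaptive_nbs_run",
    "validation_rerun",
    "consensus_with_nbs",
    "map_supports",
]


@dataclass(frozen=True, order=True)
class Bipartition:
    """Canonical split identity: bitmask of the side *not* containing the
    reference taxon (index 0 of the fixed global taxon ordering)."""

    mask: int

    def taxa(self, taxon_order: Sequence[str]) -> tuple:
        return tuple(
            lab for i, lab in enumerate(taxon_order) if self.mask >> i & 1
        )

    def size(self) -> int:
        return int(self.mask).bit_count()


def _leaf_masks(tree: dendropy.Tree, index: dict) -> dict:
    masks = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            if node.taxon is None or node.taxon.label not in index:
                lab = None if node.taxon is None else node.taxon.label
                raise ValueError(f"leaf {lab!r} not in the global taxon order")
            masks[node] = 1 << index[node.taxon.label]
        else:
            m = 0
            for ch in node.child_nodes():
                m |= masks[ch]
            masks[node] = m
    return masks


def bipartitions(tree: dendropy.Tree, taxon_order: Sequence[str]) -> set:
    """All non-trivial splits of an (un)rooted tree, in canonical form.

    At most ``n - 3`` splits for a binary unrooted tree on ``n`` taxa.
    """
    n = len(taxon_order)
    index = {lab: i for i, lab in enumerate(taxon_order)}
    masks = _leaf_masks(tree, index)
    full = (1 << n) - 1
    if masks[tree.seed_node] != full:
        got = [lf.taxon.label for lf in tree.leaf_node_iter()]
        missing = sorted(set(taxon_order) - set(got))
        raise ValueError(f"tree leaf set mismatch; missing {missing}")
    splits = set()
    for node, m in masks.items():
        if node is tree.seed_node:
            continue
        if m & 1:
            m ^= full
        k = m.bit_count()
        if 2 <= k <= n - 2:
            splits.add(Bipartition(m))
    return splits


@dataclass(frozen=True)
class SubsampleBcl:
    """Per-subsample clade support map: {Bipartition -> bcl percent}."""

    bcl: dict
    R: int


def bcl_for_subsample(
    replicate_trees: Sequence[dendropy.Tree], taxon_order: Sequence[str],
    R: Optional[int] = None,
) -> SubsampleBcl:
    """Clade frequencies among one subsample's replicate trees, in percent.

    ``R`` defaults to the number of trees; passing it explicitly keeps the
    5-point support grid intact when individual replicates failed (a failed
    replicate supports no clade).
    """
    if len(replicate_trees) < 1:
        raise ValueError("need at least one replicate tree")
    R = len(replicate_trees) if R is None else R
    counts: dict = {}
    for tree in replicate_trees:
        for split in bipartitions(tree, taxon_order):
            counts[split] = counts.get(split, 0) + 1
    return SubsampleBcl({c: 100.0 * k / R for c, k in counts.items()}, R)


@dataclass(frozen=True)
class BclDistribution:
    """Vector of S per-subsample bcl values for one clade (100/R grid)."""

    clade: Bipartition
    values: np.ndarray
    R: int

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.size < 1:
            raise ValueError("empty bcl distribution")
        if np.any((v < 0) | (v > 100)):
            raise ValueError("bcl values must lie in [0, 100]")

    @property
    def S(self) -> int:
        return int(self.values.size)


def aggregate_bcl(per_subsample: Sequence[SubsampleBcl]) -> list:
    """Union clades over subsamples into per-clade bcl distributions.

    A clade absent from a subsample's replicate trees contributes bcl = 0
    there: under resampling, absence is evidence of absence.
    """
    if len(per_subsample) < 1:
        raise ValueError("need at least one subsample")
    Rs = {sb.R for sb in per_subsample}
    if len(Rs) != 1:
        raise ValueError(f"differing replicate counts across subsamples: {Rs}")
    R = Rs.pop()
    clades = sorted({c for sb in per_subsample for c in sb.bcl})
    out = []
    for clade in clades:
        vals = np.array([sb.bcl.get(clade, 0.0) for sb in per_subsample])
        out.append(BclDistribution(clade, vals, R))
    return out


def nbs(d: BclDistribution) -> float:
    """Net bootstrap support: the mean of the bcl distribution."""
    return float(np.mean(d.values))


def fbs_estimate(d: BclDistribution) -> float:
    """Estimate of the superalignment bootstrap support: the bcl median."""
    return float(np.median(d.values))


def overconfidence(d: BclDistribution, FBS_ref: Optional[float] = None) -> float:
    """OC = FBS_ref - mean(bcl); positive when the full-data bootstrap is
    more confident than the subsample consensus.  ``FBS_ref`` defaults to
    the bcl median so both estimates come from the same distribution."""
    ref = fbs_estimate(d) if FBS_ref is None else float(FBS_ref)
    if not (0.0 <= ref <= 100.0):
        raise ValueError("FBS_ref must lie in [0, 100]")
    return ref - nbs(d)


def rmsd_step(nbs_prev: np.ndarray, nbs_curr: np.ndarray) -> float:
    """Root mean squared deviation between successive NBS vectors.

    Inputs are per-clade NBS on the [0, 1] proportion scale over the same
    (union) clade set, absentees filled with 0.
    """
    a = np.asarray(nbs_prev, dtype=np.float64)
    b = np.asarray(nbs_curr, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("NBS vectors differ in length")
    if a.size == 0:
        raise ValueError("no clades to compare")
    return float(np.sqrt(np.mean((b - a) ** 2)))


@dataclass(frozen=True)
class SupportRecord:
    """Per-clade summary: NBS, FBS estimate, OC and modality verdict."""

    clade: Bipartition
    NBS: float
    FBS_est: float
    OC: float
    S: int
    R: int
    modality: str = "untested"
    dip_p: Optional[float] = None
    n_modes: Optional[int] = None


@dataclass(frozen=True)
class StoppingState:
    """One adaptive iteration: subsample count, RMSD, convergence flag."""

    iteration: int
    S: int
    rmsd: Optional[float]
    converged: bool


@dataclass
class NbsResult:
    """Everything the adaptive run produced."""

    records: list
    history: list
    consensus: dendropy.Tree
    converged: bool
    taxon_order: list
    distributions: list
    l: int
    R: int
    seed: int
    skipped: list = field(default_factory=list)

    def record_for(self, clade: Bipartition) -> Optional[SupportRecord]:
        for rec in self.records:
            if rec.clade == clade:
                return rec
        return None


def _records_from_distributions(dists, S, R):
    recs = []
    for d in dists:
        m = nbs(d)
        med = fbs_estimate(d)
        oc = overconfidence(d)
        # the three estimators are tied by algebra; assert the identities
        assert abs(oc - (med - m)) < 1e-9
        recs.append(SupportRecord(d.clade, m, med, oc, S, R))
    return recs


def adaptive_nbs_run(
    aln: Superalignment,
    cfg: Optional[EngineConfig] = None,
    s0: int = 5,
    R: int = 20,
    rmsd_tol: float = 0.05,
    s_max: int = 100,
    g: float = 0.7,
    l: Optional[int] = None,
    seed: int = 0,
) -> NbsResult:
    """Little-bootstrap NBS analysis with adaptive subsample count.

    Starts from ``s0`` subsamples of ``l`` sites (default ``floor(L**g)``)
    with ``R`` upsampled replicates each; adds one subsample per iteration
    and stops once the NBS RMSD between successive iterations is below
    ``rmsd_tol`` on two consecutive iterations, or ``s_max`` is reached
    (flagged non-converged).  Subsamples in which some taxon has no
    unambiguous residue are skipped with a warning and redrawn.

    Every random draw descends from ``seed`` through a hierarchical stream,
    so results are bit-identical across repeats and parallel schedules.
    """
    cfg = cfg or EngineConfig()
    if l is None:
        l = default_subsample_size(aln.L, g)
    if not (0 < l < aln.L):
        raise ValueError(f"subsample size {l} not in (0, {aln.L})")
    if s0 < 2:
        raise ValueError("need at least 2 initial subsamples")
    ns = taxon_namespace_for(aln.labels)
    taxon_order = list(aln.labels)
    valid = aln.informative_mask()

    per_subsample: list = []
    skipped: list = []
    draw_counter = 0

    def next_subsample():
        nonlocal draw_counter
        while True:
            if draw_counter > 10 * s_max + 100:
                raise RuntimeError("too many skipped subsamples")
            rng = spawn_rng(seed, 0, draw_counter)
            sub = draw_subsample(aln, l, rng, seed_path=(0, draw_counter))
            draw_counter += 1
            cover = valid[:, sub.indices].any(axis=1)
            if cover.all():
                return sub
            bad = [taxon_order[i] for i in np.flatnonzero(~cover)]
            msg = (
                f"subsample {draw_counter - 1} skipped: no unambiguous sites "
                f"for taxa {bad}"
            )
            skipped.append(msg)
            warnings.warn(msg, stacklevel=2)

    def run_subsample(sub, s_index):
        trees = []
        failures = 0
        for rep in range(R):
            rng = spawn_rng(seed, 1, s_index, rep)
            rw = upsample_replicate(sub, rng)
            try:
                trees.append(infer_tree(aln, rw, cfg, rng, ns))
            except EngineError as exc:
                failures += 1
                warnings.warn(
                    f"replicate {rep} of subsample {s_index} failed: {exc}",
                    stacklevel=2,
                )
                if failures > R / 2:
                    raise RuntimeError(
                        f"more than half of the replicates of subsample "
                        f"{s_index} failed"
                    ) from exc
        return bcl_for_subsample(trees, taxon_order, R=R)

    def nbs_vector(dists, clades):
        by_clade = {d.clade: d for d in dists}
        return np.array(
            [nbs(by_clade[c]) / 100.0 if c in by_clade else 0.0 for c in clades]
        )

    history: list = []
    for s_index in range(s0):
        per_subsample.append(run_subsample(next_subsample(), s_index))
    dists = aggregate_bcl(per_subsample)
    history.append(StoppingState(0, len(per_subsample), None, False))

    converged = False
    hits = 0
    iteration = 0
    while len(per_subsample) < s_max:
        iteration += 1
        prev_dists = dists
        s_index = len(per_subsample)
        per_subsample.append(run_subsample(next_subsample(), s_index))
        dists = aggregate_bcl(per_subsample)
        clades = sorted({d.clade for d in dists} | {d.clade for d in prev_dists})
        r = rmsd_step(nbs_vector(prev_dists, clades), nbs_vector(dists, clades))
        hits = hits + 1 if r < rmsd_tol else 0
        done = hits >= 2
        history.append(StoppingState(iteration, len(per_subsample), r, done))
        if done:
            converged = True
            break

    S = len(per_subsample)
    records = _records_from_distributions(dists, S, R)
    consensus = consensus_with_nbs(records, taxon_order)
    return NbsResult(
        records=records,
        history=history,
        consensus=consensus,
        converged=converged,
        taxon_order=taxon_order,
        distributions=dists,
        l=l,
        R=R,
        seed=seed,
        skipped=skipped,
    )


def validation_rerun(
    aln: Superalignment,
    base: NbsResult,
    cfg: Optional[EngineConfig] = None,
    s0: int = 5,
    rmsd_tol: float = 0.05,
    s_max: int = 100,
) -> dict:
    """Stability check: repeat the analysis with a doubled subsample size.

    Returns ``{clade: (NBS_base, NBS_doubled, delta)}`` over the union of
    clades.  Large deltas mean the subsample size was too small to capture
    the dataset's heterogeneity structure.
    """
    l2 = min(2 * base.l, aln.L - 1)
    rerun = adaptive_nbs_run(
        aln, cfg, s0=s0, R=base.R, rmsd_tol=rmsd_tol, s_max=s_max,
        l=l2, seed=base.seed,
    )
    a = {r.clade: r.NBS for r in base.records}
    b = {r.clade: r.NBS for r in rerun.records}
    out = {}
    for clade in sorted(set(a) | set(b)):
        na, nb = a.get(clade, 0.0), b.get(clade, 0.0)
        out[clade] = (na, nb, nb - na)
    return out


# -- consensus and support mapping -----------------------------------------

def _compatible(a: int, b: int) -> bool:
    # both masks exclude the reference taxon, so split compatibility
    # reduces to nested-or-disjoint
    ab = a & b
    return ab == 0 or ab == a or ab == b


def consensus_with_nbs(
    records: Sequence[SupportRecord], taxon_order: Sequence[str]
) -> dendropy.Tree:
    """Greedy majority-rule consensus annotated with NBS.

    Clades with NBS > 50 are mutually compatible whenever R is constant
    (NBS then equals the clade's frequency among the pooled S*R replicate
    trees), and are always included; the remaining clades are added in
    descending NBS order when compatible with everything already accepted.
    NBS values are written as internal node labels.
    """
    n = len(taxon_order)
    selected: list = []
    for rec in sorted(records, key=lambda r: (-r.NBS, r.clade.mask)):
        if rec.NBS <= 0:
            continue
        if rec.NBS > 50:
            if any(not _compatible(rec.clade.mask, s.clade.mask) for s in selected):
                raise AssertionError(
                    "majority clades incompatible; replicate counts must differ"
                )
            selected.append(rec)
        elif all(_compatible(rec.clade.mask, s.clade.mask) for s in selected):
            selected.append(rec)

    ns = taxon_namespace_for(taxon_order)
    # laminar family -> rooted-at-reference cluster tree
    clusters = sorted(selected, key=lambda r: -r.clade.size())
    root = dendropy.Node()
    node_of = {}
    for rec in clusters:
        containers = [
            o
            for o in clusters
            if o is not rec
            and o.clade.mask & rec.clade.mask == rec.clade.mask
            and o.clade.mask != rec.clade.mask
        ]
        if containers:
            tightest = min(containers, key=lambda r: r.clade.size())
            parent = node_of[tightest.clade]
        else:
            parent = root
        nd = dendropy.Node()
        nd.label = f"{rec.NBS:.10g}"
        parent.add_child(nd)
        node_of[rec.clade] = nd
    # attach leaves to the smallest containing cluster
    for i, lab in enumerate(taxon_order):
        bit = 1 << i
        best = None
        for rec in clusters:
            if rec.clade.mask & bit:
                if best is None or rec.clade.size() < best.clade.size():
                    best = rec
        parent = node_of[best.clade] if best is not None else root
        leaf = dendropy.Node(taxon=ns.get_taxon(lab))
        parent.add_child(leaf)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = False
    return tree


def map_supports(
    reference: dendropy.Tree,
    records: Sequence[SupportRecord],
    taxon_order: Sequence[str],
) -> dendropy.Tree:
    """Annotate each internal edge of a reference tree with its clade's NBS
    (0 for clades never observed in any replicate tree)."""
    ref_taxa = {lf.taxon.label for lf in reference.leaf_node_iter()}
    want = set(taxon_order)
    if ref_taxa != want:
        raise ValueError(
            f"taxon set mismatch: reference-only {sorted(ref_taxa - want)}, "
            f"alignment-only {sorted(want - ref_taxa)}"
        )
    by_clade = {rec.clade: rec for rec in records}
    tree = reference.clone(depth=1)
    n = len(taxon_order)
    index = {lab: i for i, lab in enumerate(taxon_order)}
    masks = _leaf_masks(tree, index)
    full = (1 << n) - 1
    for node, m in masks.items():
        if node is tree.seed_node or node.is_leaf():
            continue
        if m & 1:
            m ^= full
        if not (2 <= m.bit_count() <= n - 2):
            continue
        rec = by_clade.get(Bipartition(m))
        node.label = f"{rec.NBS:.10g}" if rec is not None else "0"
    return tree
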