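"""Little-bootstrap resampling of superalignment sites.

The little-bootstrap scheme draws a subsample of ``l << L`` distinct sites
without replacement and then builds full-length replicates by drawing ``L``
sites with replacement *from the subsample* ("upsampling").  Each replicate
therefore contains many copies of every subsample site but only a tiny
fraction (at most ``l/L``) of the superalignment's distinct site
configurations, which is where the memory and time savings come from.
Standard and double bootstrap are provided as baselines, along with the
distinct-site diagnostics used to compare the three schemes.

Replicates are represented as sparse weight vectors and only materialized
into explicit alignments when an external tree program needs a FASTA file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, getcontext
from typing import Optional

import numpy as np

__all__ = [
    "SiteSubsample",
    "ReplicateWeights",
    "default_subsample_size",
    "draw_subsample",
    "upsample_replicate",
    "standard_bootstrap",
    "double_bootstrap",
    "distinct_fraction",
    "materialize",
    "dump_weights_tsv",
    "spawn_rng",
]


@dataclass(frozen=True)
class SiteSubsample:
    """A without-replacement draw of ``l`` distinct site indices from [0, L)."""

    indices: np.ndarray
    parent_L: int
    seed_path: Optional[tuple] = None

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.int64)
        idx = np.sort(idx)
        object.__setattr__(self, "indices", idx)
        if idx.size == 0:
            raise ValueError("empty subsample")
        if np.unique(idx).size != idx.size:
            raise ValueError("subsample indices must be unique")
        if idx[0] < 0 or idx[-1] >= self.parent_L:
            raise ValueError("subsample indices outside [0, L)")
        if idx.size >= self.parent_L:
            raise ValueError("subsample size must be smaller than L")

    @property
    def l(self) -> int:  # noqa: E743 - field name from the sampling scheme
        return int(self.indices.size)


@dataclass(frozen=True)
class ReplicateWeights:
    """Sparse site-multiplicity vector of one bootstrap replicate.

    ``indices`` are original site coordinates; ``multiplicities`` are the
    positive draw counts; their sum equals the target replicate length.
    """

    indices: np.ndarray
    multiplicities: np.ndarray
    total: int
    parent_L: int

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.int64)
        mult = np.asarray(self.multiplicities, dtype=np.int64)
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "multiplicities", mult)
        if idx.shape != mult.shape:
            raise ValueError("indices and multiplicities differ in shape")
        if np.any(mult <= 0):
            raise ValueError("multiplicities must be positive")
        if int(mult.sum()) != self.total:
            raise ValueError("multiplicities do not sum to the stated total")

    @property
    def counts(self) -> dict:
        """Mapping {site index -> multiplicity} (small replicates only)."""
        return dict(zip(self.indices.tolist(), self.multiplicities.tolist()))


def default_subsample_size(L: int, g: float = 0.7) -> int:
    """Subsample size rule ``l = floor(L**g)`` clamped to [4, L-1].

    The default exponent ``g = 0.7`` reproduces the published subsample size
    of 18,086 sites for a rodent superalignment of L = 1,207,638 sites.  The
    floor is evaluated in high-precision decimal arithmetic so that values
    sitting exactly on an integer power (e.g. 1024**0.7 = 128) are not lost
    to binary floating-point rounding.
    """
    if L < 16:
        raise ValueError("L < 16: subsampling is meaningless")
    if not (0 < g < 1):
        raise ValueError("exponent g must lie in (0, 1)")
    getcontext().prec = 50
    target = Decimal(L).ln() * Decimal(repr(g))  # = ln(L**g)
    l = int(target.exp())
    # settle the floor exactly via ln comparisons (l <= L**g iff ln l <= g ln L)
    while Decimal(l + 1).ln() <= target:
        l += 1
    while l > 1 and Decimal(l).ln() > target:
        l -= 1
    return max(4, min(l, L - 1))


def draw_subsample(aln, l: int, rng: np.random.Generator,
                   seed_path: Optional[tuple] = None) -> SiteSubsample:
    """Draw ``l`` uniformly chosen distinct sites from the alignment."""
    L = aln if isinstance(aln, (int, np.integer)) else aln.L
    if not (0 < l < L):
        raise ValueError(f"need 0 < l < L, got l={l}, L={L}")
    idx = rng.choice(L, size=l, replace=False)
    return SiteSubsample(np.sort(idx), int(L), seed_path)


def upsample_replicate(sub: SiteSubsample,
                       rng: np.random.Generator) -> ReplicateWeights:
    """Draw ``parent_L`` sites with replacement from the subsample.

    Every subsample site is expected to appear ``L/l`` times; the replicate
    is full length but supported on at most ``l`` distinct sites.
    """
    l, L = sub.l, sub.parent_L
    counts = rng.multinomial(L, np.full(l, 1.0 / l))
    nz = counts > 0
    return ReplicateWeights(sub.indices[nz], counts[nz], L, L)


def standard_bootstrap(L: int, rng: np.random.Generator) -> ReplicateWeights:
    """Classic bootstrap replicate: ``L`` draws with replacement from [0, L)."""
    if L < 1:
        raise ValueError("L must be >= 1")
    draws = rng.integers(0, L, size=L)
    idx, counts = np.unique(draws, return_counts=True)
    return ReplicateWeights(idx, counts, int(L), int(L))


def double_bootstrap(L: int, rng: np.random.Generator) -> ReplicateWeights:
    """Two nested rounds of with-replacement resampling.

    The outer round draws ``L`` sites from the alignment; the inner round
    draws ``L`` items from the outer multiset.  The support of the result is
    contained in the outer round's support.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    outer = rng.integers(0, L, size=L)
    inner = outer[rng.integers(0, L, size=L)]
    idx, counts = np.unique(inner, return_counts=True)
    return ReplicateWeights(idx, counts, int(L), int(L))


def distinct_fraction(rw: ReplicateWeights, L: Optional[int] = None) -> float:
    """Fraction of the L original site configurations present in a replicate."""
    L = rw.parent_L if L is None else L
    return rw.indices.size / L


def materialize(aln, rw: ReplicateWeights, max_cells: int = 200_000_000):
    """Expand a weight vector into an explicit replicate alignment.

    Columns appear in ascending original-site order with repeats adjacent.
    Only needed for external engines; the built-in engine consumes weights
    directly.  Refuses to allocate more than ``max_cells`` residues.
    """
    from .msa_io import Superalignment

    if rw.indices.size and (rw.indices[0] < 0 or rw.indices[-1] >= aln.L):
        raise ValueError("replicate indices outside the alignment")
    if rw.total * aln.n_taxa > max_cells:
        raise MemoryError(
            f"materializing {rw.total} x {aln.n_taxa} residues exceeds the "
            f"{max_cells}-cell cap; use a weight-aware engine instead"
        )
    cols = np.repeat(rw.indices, rw.multiplicities)
    return Superalignment(
        list(aln.labels), aln.matrix[:, cols], aln.alphabet, None
    )


def dump_weights_tsv(rw: ReplicateWeights, path) -> None:
    """Write a replicate's (site_index, count) pairs as TSV."""
    with open(path, "w") as fh:
        fh.write("site_index\tcount\n")
        for s, m in zip(rw.indices, rw.multiplicities):
            fh.write(f"{s}\t{m}\n")


def spawn_rng(master_seed: int, *path: int) -> np.random.Generator:
    """Independent, reproducible stream for (subsample, replicate, ...) paths."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(path))
    )
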