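"""Superalignment input/output, validation and missing-data profiling.

A *superalignment* is the concatenation of many gene or genomic-segment
alignments analyzed as a single taxa-by-sites character matrix.  This module
reads and writes the two plain-text formats common for such matrices
(multi-FASTA and relaxed sequential PHYLIP), profiles per-taxon data
sparsity, and enforces the warn/drop policies for data-poor taxa that
protect downstream subsampling from taxa with almost no observed residues.

Coordinates are 0-based and half-open everywhere internally; partition maps
on disk use the conventional 1-based inclusive coordinates and are converted
on read.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "AlignmentError",
    "Superalignment",
    "TaxonCoverage",
    "read_alignment",
    "write_alignment",
    "read_partition_map",
    "coverage_profile",
    "enforce_sparsity_policy",
    "detect_alphabet",
]

# Residues treated as carrying unambiguous phylogenetic information.
# Everything else (gaps, '?', 'N'/'X', IUPAC partial ambiguities, ...) counts
# toward the missing fraction *mf* but is passed through to engines untouched.
DNA_UNAMBIGUOUS = frozenset(b"ACGTU")
PROTEIN_UNAMBIGUOUS = frozenset(b"ACDEFGHIKLMNPQRSTVWY")
_DNA_DETECT = frozenset(b"ACGTUN")
_GAP_LIKE = frozenset(b"-?.")


class AlignmentError(ValueError):
    """Invalid alignment content (ragged rows, duplicate labels, ...)."""


@dataclass(frozen=True)
class TaxonCoverage:
    """Fraction of sites of one taxon that are missing/ambiguous/gap."""

    taxon: str
    mf: float


class Superalignment:
    """Taxa-by-sites character matrix with alphabet and missing-data semantics.

    Parameters
    ----------
    labels : ordered unique taxon names.
    matrix : ``(n_taxa, L)`` uint8 array of uppercase ASCII residue codes.
    alphabet : ``"dna"`` or ``"protein"``; auto-detected when ``None``.
    partition_map : optional list of ``(name, start, end)`` half-open 0-based
        site ranges; must be non-overlapping and lie within ``[0, L)``.
    """

    def __init__(self, labels, matrix, alphabet=None, partition_map=None):
        labels = list(labels)
        matrix = np.ascontiguousarray(matrix, dtype=np.uint8)
        if matrix.ndim != 2:
            raise AlignmentError("matrix must be 2-dimensional (taxa x sites)")
        if len(labels) != matrix.shape[0]:
            raise AlignmentError(
                f"{len(labels)} labels for {matrix.shape[0]} matrix rows"
            )
        if matrix.shape[1] < 1:
            raise AlignmentError("alignment has zero sites")
        seen = set()
        for lab in labels:
            if not lab:
                raise AlignmentError("empty taxon label")
            if lab in seen:
                raise AlignmentError(f"duplicate taxon label: {lab!r}")
            seen.add(lab)
        self.labels = labels
        self.matrix = matrix
        self.alphabet = alphabet or detect_alphabet(matrix)
        if self.alphabet not in ("dna", "protein"):
            raise AlignmentError(f"unknown alphabet {self.alphabet!r}")
        self.partition_map = self._check_partitions(partition_map)
        self._valid_cache = None

    def _check_partitions(self, pmap):
        if pmap is None:
            return None
        pmap = [(str(n), int(a), int(b)) for n, a, b in pmap]
        occupied = []
        for name, a, b in pmap:
            if not (0 <= a < b <= self.L):
                raise AlignmentError(
                    f"partition {name!r} range [{a},{b}) outside [0,{self.L})"
                )
            occupied.append((a, b, name))
        occupied.sort()
        for (a1, b1, n1), (a2, b2, n2) in zip(occupied, occupied[1:]):
            if a2 < b1:
                raise AlignmentError(f"partitions {n1!r} and {n2!r} overlap")
        return pmap

    # -- basic accessors ---------------------------------------------------
    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    def sequence(self, taxon) -> str:
        """Row of `taxon` (name or index) as a string."""
        i = taxon if isinstance(taxon, int) else self.labels.index(taxon)
        return self.matrix[i].tobytes().decode("ascii")

    def informative_mask(self) -> np.ndarray:
        """Boolean ``(n_taxa, L)`` mask of unambiguous residues (cached)."""
        if self._valid_cache is None:
            good = DNA_UNAMBIGUOUS if self.alphabet == "dna" else PROTEIN_UNAMBIGUOUS
            lut = np.zeros(256, dtype=bool)
            lut[list(good)] = True
            self._valid_cache = lut[self.matrix]
        return self._valid_cache

    @classmethod
    def from_sequences(cls, labels, sequences, alphabet=None, partition_map=None):
        seqs = [s.upper() for s in sequences]
        lens = {len(s) for s in seqs}
        if len(lens) > 1:
            ref = max(lens)
            for lab, s in zip(labels, seqs):
                if len(s) != ref:
                    raise AlignmentError(
                        f"taxon {lab!r} has {len(s)} sites where others have {ref}"
                    )
        matrix = np.frombuffer(
            "".join(seqs).encode("ascii"), dtype=np.uint8
        ).reshape(len(seqs), -1)
        return cls(labels, matrix.copy(), alphabet, partition_map)

    def drop_taxa(self, names: Iterable[str]) -> "Superalignment":
        names = set(names)
        keep = [i for i, lab in enumerate(self.labels) if lab not in names]
        return Superalignment(
            [self.labels[i] for i in keep],
            self.matrix[keep],
            self.alphabet,
            self.partition_map,
        )

    def __eq__(self, other):
        return (
            isinstance(other, Superalignment)
            and self.labels == other.labels
            and np.array_equal(self.matrix, other.matrix)
        )

    def __repr__(self):
        return (
            f"<Superalignment {self.n_taxa} taxa x {self.L} sites"
            f" ({self.alphabet})>"
        )


def detect_alphabet(matrix: np.ndarray) -> str:
    """DNA if >=90% of non-gap residues fall in {A,C,G,T,U,N}."""
    flat = np.asarray(matrix, dtype=np.uint8).ravel()
    gap_lut = np.zeros(256, dtype=bool)
    gap_lut[list(_GAP_LIKE)] = True
    residues = flat[~gap_lut[flat]]
    if residues.size == 0:
        return "dna"
    dna_lut = np.zeros(256, dtype=bool)
    dna_lut[list(_DNA_DETECT)] = True
    frac = dna_lut[residues].mean()
    return "dna" if frac >= 0.9 else "protein"


# -- readers / writers -----------------------------------------------------

def read_alignment(path, format: str = "auto") -> "Superalignment":
    """Read a FASTA or relaxed sequential PHYLIP superalignment.

    ``format="auto"`` sniffs the first non-blank character: ``>`` means
    FASTA, a digit means PHYLIP.
    """
    path = os.fspath(path)
    if format == "auto":
        with open(path) as fh:
            head = fh.read(4096).lstrip()
        if head.startswith(">"):
            format = "fasta"
        elif head[:1].isdigit():
            format = "phylip"
        else:
            raise AlignmentError(f"cannot sniff alignment format of {path}")
    if format == "fasta":
        labels, seqs = [], []
        for rec in SeqIO.parse(path, "fasta"):
            labels.append(rec.id)
            seqs.append(str(rec.seq))
        if not labels:
            raise AlignmentError(f"no sequences found in {path}")
        return Superalignment.from_sequences(labels, seqs)
    if format == "phylip":
        return _read_relaxed_phylip(path)
    raise ValueError(f"unknown format {format!r}")


def _read_relaxed_phylip(path) -> "Superalignment":
    """Relaxed sequential PHYLIP: whitespace-delimited labels, wrapped rows ok."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 2:
            raise AlignmentError(f"{path}: malformed PHYLIP header")
        n, L = int(header[0]), int(header[1])
        tokens = fh.read().split()
    labels, seqs = [], []
    i = 0
    for _ in range(n):
        if i >= len(tokens):
            raise AlignmentError(f"{path}: truncated PHYLIP file")
        label = tokens[i]
        i += 1
        chunks, have = [], 0
        while have < L:
            if i >= len(tokens):
                raise AlignmentError(
                    f"taxon {label!r} has {have} sites where others have {L}"
                )
            chunks.append(tokens[i])
            have += len(tokens[i])
            i += 1
        seq = "".join(chunks)
        if len(seq) != L:
            raise AlignmentError(
                f"taxon {label!r} has {len(seq)} sites where others have {L}"
            )
        labels.append(label)
        seqs.append(seq)
    if i != len(tokens):
        raise AlignmentError(f"{path}: trailing data after {n} sequences")
    return Superalignment.from_sequences(labels, seqs)


def write_alignment(aln: Superalignment, path, format: str = "fasta") -> None:
    """Write FASTA (70-column wrap) or relaxed one-line-per-taxon PHYLIP."""
    path = os.fspath(path)
    if format == "fasta":
        with open(path, "w") as fh:
            for i, lab in enumerate(aln.labels):
                fh.write(f">{lab}\n")
                seq = aln.sequence(i)
                for j in range(0, len(seq), 70):
                    fh.write(seq[j : j + 70] + "\n")
    elif format == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{aln.n_taxa} {aln.L}\n")
            for i, lab in enumerate(aln.labels):
                fh.write(f"{lab}  {aln.sequence(i)}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


_CHARSET_RE = re.compile(
    r"charset\s+(\S+)\s*=\s*(\d+)\s*-\s*(\d+)\s*;", re.IGNORECASE
)


def read_partition_map(path) -> list[tuple[str, int, int]]:
    """Gene-boundary map: NEXUS-style ``charset name = start-end;`` lines or a
    3-column TSV (name, start, end). On disk 1-based inclusive; returned
    0-based half-open."""
    with open(path) as fh:
        text = fh.read()
    out = []
    if "charset" in text.lower():
        for m in _CHARSET_RE.finditer(text):
            name, a, b = m.group(1), int(m.group(2)), int(m.group(3))
            out.append((name, a - 1, b))
    else:
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise AlignmentError(f"malformed partition line: {line!r}")
            out.append((parts[0], int(parts[1]) - 1, int(parts[2])))
    if not out:
        raise AlignmentError(f"no partitions found in {path}")
    return out


# -- sparsity profiling and policy -----------------------------------------

def coverage_profile(aln: Superalignment) -> list[TaxonCoverage]:
    """Per-taxon missing fraction *mf* = (missing+ambiguous+gap residues)/L."""
    valid = aln.informative_mask()
    mfs = 1.0 - valid.mean(axis=1)
    return [TaxonCoverage(lab, float(mf)) for lab, mf in zip(aln.labels, mfs)]


def enforce_sparsity_policy(
    aln: Superalignment,
    warn_threshold: float = 0.5,
    remove_threshold: float = 0.95,
    mode: str = "warn",
) -> tuple[Superalignment, list[str]]:
    """Warn about taxa with mf > `warn_threshold`; in ``drop`` mode remove
    taxa with mf >= `remove_threshold`.

    Returns the (possibly reduced) alignment and the list of messages.
    Dropping below 4 taxa is a hard error: no unrooted topology remains.
    """
    if not (0 < warn_threshold <= 1 and 0 < remove_threshold <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    if mode not in ("warn", "drop"):
        raise ValueError(f"unknown mode {mode!r}")
    messages = []
    to_drop = []
    for cov in coverage_profile(aln):
        if mode == "drop" and cov.mf >= remove_threshold:
            to_drop.append(cov.taxon)
            messages.append(
                f"removed taxon {cov.taxon!r}: mf={cov.mf:.4f} >= "
                f"{remove_threshold:.2f}"
            )
        elif cov.mf > warn_threshold:
            messages.append(
                f"taxon {cov.taxon!r} has mf={cov.mf:.4f} > "
                f"{warn_threshold:.2f} missing/ambiguous sites"
            )
    if to_drop:
        if aln.n_taxa - len(to_drop) < 4:
            raise AlignmentError(
                "dropping sparse taxa would leave fewer than 4 taxa"
            )
        aln = aln.drop_taxa(to_drop)
    return aln, messages
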