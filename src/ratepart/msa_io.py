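"""Alignment and tree input/output.

Reads nucleotide multiple sequence alignments from FASTA and relaxed
PHYLIP, compresses them into weighted site patterns, round-trips Newick
trees through dendropy, and exports partitioning schemes as RAxML-style
partition files or Nexus ``sets`` blocks.

Site indices are 0-based everywhere inside the package; every user-facing
subset definition is written 1-based, following the RAxML/Nexus charset
convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "SitePattern",
    "AlignmentError",
    "read_alignment",
    "write_alignment",
    "compress_patterns",
    "read_tree",
    "write_tree",
    "check_tree_taxa",
    "format_site_ranges",
    "write_raxml_partitions",
    "write_nexus_sets",
]

# IUPAC nucleotide codes -> set of compatible bases (A,C,G,T indices 0..3).
IUPAC_CODES: dict[str, tuple[int, ...]] = {
    "A": (0,), "C": (1,), "G": (2,), "T": (3,),
    "R": (0, 2), "Y": (1, 3), "S": (1, 2), "W": (0, 3),
    "K": (2, 3), "M": (0, 1),
    "B": (1, 2, 3), "D": (0, 2, 3), "H": (0, 1, 3), "V": (0, 1, 2),
    "N": (0, 1, 2, 3), "-": (0, 1, 2, 3), "?": (0, 1, 2, 3),
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent alignment input."""


@dataclass
class Alignment:
    """A nucleotide multiple sequence alignment.

    Attributes
    ----------
    taxa:
        Ordered, unique, non-empty taxon labels.
    matrix:
        ``(n_taxa, n_sites)`` array of single uppercase characters drawn
        from the IUPAC nucleotide alphabet plus ``-``/``?``.
    """

    taxa: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.taxa = tuple(self.taxa)
        self.matrix = np.asarray(self.matrix, dtype="U1")
        if self.matrix.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-D")
        if len(self.taxa) != self.matrix.shape[0]:
            raise AlignmentError("taxon count does not match matrix rows")
        if len(self.taxa) < 2:
            raise AlignmentError("an alignment needs at least two taxa")
        if any(not t for t in self.taxa):
            raise AlignmentError("taxon labels must be non-empty")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon labels")
        bad = set(np.unique(self.matrix)) - set(IUPAC_CODES) - {"U"}
        if bad:
            raise AlignmentError(f"unknown characters in alignment: {sorted(bad)}")
        # normalise: RNA U -> T
        self.matrix[self.matrix == "U"] = "T"

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def codes(self) -> np.ndarray:
        """Integer codes: A=0 C=1 G=2 T=3, anything ambiguous = -1."""
        out = np.full(self.matrix.shape, -1, dtype=np.int8)
        for base, idx in _BASE_INDEX.items():
            out[self.matrix == base] = idx
        return out

    def take_sites(self, sites: Sequence[int]) -> "Alignment":
        """Column-sliced copy restricted to ``sites`` (0-based)."""
        sites = np.asarray(sites, dtype=int)
        return Alignment(self.taxa, self.matrix[:, sites].copy())

    @classmethod
    def from_sequences(cls, taxa: Sequence[str], seqs: Sequence[str]) -> "Alignment":
        seqs = [s.upper() for s in seqs]
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise AlignmentError(f"sequences have unequal lengths: {sorted(lengths)}")
        mat = np.array([list(s) for s in seqs], dtype="U1")
        return cls(tuple(taxa), mat)


@dataclass(frozen=True)
class SitePattern:
    """A distinct alignment column with its multiplicity."""

    column: tuple[str, ...]
    weight: int
    site_indices: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise AlignmentError("pattern weight must be positive")


def read_alignment(path: str | Path, fmt: str | None = None) -> Alignment:
    """Read a FASTA or relaxed-PHYLIP alignment.

    ``fmt`` is ``"fasta"`` or ``"phylip"``; when omitted it is sniffed from
    the first non-blank character (``>`` means FASTA).
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise AlignmentError(f"empty alignment file: {path}")
    if fmt is None:
        fmt = "fasta" if text.lstrip().startswith(">") else "phylip"
    if fmt == "fasta":
        return _parse_fasta(text)
    if fmt == "phylip":
        return _parse_phylip(text)
    raise AlignmentError(f"unsupported alignment format: {fmt!r}")


def _parse_fasta(text: str) -> Alignment:
    taxa: list[str] = []
    seqs: list[str] = []
    cur: list[str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            taxa.append(line[1:].split()[0] if line[1:].strip() else "")
            cur = []
            seqs.append("")
        elif cur is None:
            raise AlignmentError("FASTA data before first header")
        else:
            seqs[-1] += line
    if not taxa:
        raise AlignmentError("no FASTA records found")
    return Alignment.from_sequences(taxa, seqs)


def _parse_phylip(text: str) -> Alignment:
    # Relaxed sequential PHYLIP: whitespace-delimited names of any length;
    # strict 10-character names also parse because split() ignores padding
    # only when a space separates name and sequence, which relaxed writers
    # and PHYLIP itself both produce.
    try:
        aln = AlignIO.read(io.StringIO(text), "phylip-relaxed")
    except ValueError as exc:
        raise AlignmentError(f"PHYLIP parse error: {exc}") from exc
    return Alignment.from_sequences(
        [rec.id for rec in aln], [str(rec.seq) for rec in aln]
    )


def write_alignment(aln: Alignment, path: str | Path, fmt: str = "fasta") -> None:
    records = [
        SeqRecord(Seq("".join(row)), id=name, description="")
        for name, row in zip(aln.taxa, aln.matrix)
    ]
    msa = MultipleSeqAlignment(records)
    biofmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}.get(fmt)
    if biofmt is None:
        raise AlignmentError(f"unsupported alignment format: {fmt!r}")
    with open(path, "w") as fh:
        AlignIO.write(msa, fh, biofmt)


def compress_patterns(
    aln: Alignment, sites: Sequence[int] | None = None
) -> list[SitePattern]:
    """Collapse the selected columns into unique weighted site patterns."""
    if sites is None:
        sites = np.arange(aln.n_sites)
    else:
        sites = np.asarray(sites, dtype=int)
        if sites.size == 0:
            raise AlignmentError("empty site selection")
        if sites.min() < 0 or sites.max() >= aln.n_sites:
            raise AlignmentError("site index out of range")
    cols = aln.matrix[:, sites]
    uniq, inverse = np.unique(cols.T, axis=0, return_inverse=True)
    inverse = inverse.ravel()
    patterns = []
    for k in range(uniq.shape[0]):
        members = np.asarray(sites)[inverse == k]
        patterns.append(
            SitePattern(
                column=tuple(uniq[k]), weight=members.size,
                site_indices=tuple(int(m) for m in members),
            )
        )
    return patterns


# ---------------------------------------------------------------------------
# Trees


def read_tree(
    path: str | Path, taxon_namespace: dendropy.TaxonNamespace | None = None
) -> dendropy.Tree:
    """Read a Newick tree (branch lengths preserved)."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            taxon_namespace=taxon_namespace,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise AlignmentError(f"Newick parse error in {path}: {exc}") from exc
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def check_tree_taxa(tree: dendropy.Tree, aln: Alignment) -> None:
    """Validate that the tree's leaf labels exactly cover the alignment taxa."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    taxa = set(aln.taxa)
    missing = taxa - leaves
    extra = leaves - taxa
    if missing or extra:
        raise AlignmentError(
            f"tree/alignment taxon mismatch (missing={sorted(missing)}, "
            f"extra={sorted(extra)})"
        )


# ---------------------------------------------------------------------------
# Partitioning-scheme export


def format_site_ranges(sites: Iterable[int]) -> str:
    """Render 0-based site indices as a 1-based RAxML range list, e.g. ``1,5,9-12``."""
    sites = sorted(int(s) + 1 for s in sites)
    if not sites:
        raise AlignmentError("cannot format an empty subset")
    chunks: list[str] = []
    start = prev = sites[0]
    for s in sites[1:]:
        if s == prev + 1:
            prev = s
            continue
        chunks.append(f"{start}-{prev}" if prev > start else f"{start}")
        start = prev = s
    chunks.append(f"{start}-{prev}" if prev > start else f"{start}")
    return ", ".join(chunks)


def write_raxml_partitions(
    subsets: Sequence[Sequence[int]], path: str | Path, names: Sequence[str] | None = None
) -> None:
    """Write ``DNA, subset1 = 1, 5, 9-12`` style partition definitions."""
    names = names or [f"subset{i + 1}" for i in range(len(subsets))]
    with open(path, "w") as fh:
        for name, sites in zip(names, subsets):
            fh.write(f"DNA, {name} = {format_site_ranges(sites)}\n")


def write_nexus_sets(
    subsets: Sequence[Sequence[int]], path: str | Path, names: Sequence[str] | None = None
) -> None:
    """Write a Nexus ``sets`` block with one charset per subset."""
    names = names or [f"subset{i + 1}" for i in range(len(subsets))]
    with open(path, "w") as fh:
        fh.write("#nexus\nbegin sets;\n")
        for name, sites in zip(names, subsets):
            ranges = format_site_ranges(sites).replace(",", "")
            fh.write(f"    charset {name} = {ranges};\n")
        fh.write("end;\n")
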