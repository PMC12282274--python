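"""Protein sequences, head-domain extraction and pairwise global alignment.

*Skunavirus* receptor-binding proteins (RBPs) carry a conserved N-terminal
shoulder/neck region (~135 aa) and a variable C-terminal *head* domain of
roughly 110 residues that contacts the host's cell-wall polysaccharide
receptor.  All classification in this package operates on that head window:
sequences are trimmed to their C-terminal ``head_length`` residues, compared
all-against-all by affine-gap global alignment, and summarised as percent
identity and pairwise coverage.

Identity is counted over columns where both sequences carry a residue
(gap columns excluded); coverage of each sequence is the fraction of its
residues that sit in such columns, and the pair-level coverage is the
minimum of the two — a conservative, symmetric reading of "across 90% of
the head domain".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

#: The 20 standard amino acids plus 'X' for an unknown residue.
AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"

DEFAULT_HEAD_LENGTH = 110


class InvalidSequenceError(ValueError):
    """Raised for empty sequences or residues outside the 21-letter alphabet."""


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence with a unique id and free-text description."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise InvalidSequenceError("sequence id must be non-empty")
        if not self.residues:
            raise InvalidSequenceError(f"sequence {self.id!r} is empty")
        if self.residues != self.residues.upper():
            raise InvalidSequenceError(f"sequence {self.id!r} must be uppercase")
        bad = set(self.residues) - set(AMINO_ALPHABET)
        if bad:
            raise InvalidSequenceError(
                f"sequence {self.id!r} contains non-amino-acid letters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class HeadDomain:
    """The C-terminal head window of an RBP.

    ``residues`` is always a suffix of the parent sequence; ``offset`` is the
    0-based index of the window start within the parent.
    """

    parent_id: str
    residues: str
    offset: int

    def __len__(self) -> int:
        return len(self.residues)


class ShortSequenceWarning(UserWarning):
    """Emitted when a sequence is shorter than the requested head window."""


def extract_head_domain(
    seq: ProteinSequence, head_length: int = DEFAULT_HEAD_LENGTH
) -> HeadDomain:
    """Return the C-terminal ``head_length`` residues of ``seq``.

    Sequences shorter than the window are returned whole, with a
    :class:`ShortSequenceWarning` recorded: a truncated RBP still carries
    whatever head region it has.
    """
    if head_length <= 0:
        raise ValueError("head_length must be positive")
    if len(seq) < head_length:
        warnings.warn(
            f"sequence {seq.id!r} has {len(seq)} residues, shorter than the "
            f"{head_length}-residue head window; using the whole sequence",
            ShortSequenceWarning,
            stacklevel=2,
        )
        return HeadDomain(parent_id=seq.id, residues=seq.residues, offset=0)
    offset = len(seq) - head_length
    return HeadDomain(parent_id=seq.id, residues=seq.residues[offset:], offset=offset)


def _blosum62_with_neutral_x() -> tuple[str, np.ndarray]:
    """BLOSUM62 restricted to the 21-letter alphabet, with X scoring 0."""
    m = substitution_matrices.load("BLOSUM62")
    n = len(AMINO_ALPHABET)
    out = np.zeros((n, n), dtype=int)
    for i, a in enumerate(AMINO_ALPHABET):
        for j, b in enumerate(AMINO_ALPHABET):
            if a == "X" or b == "X":
                out[i, j] = 0
            else:
                out[i, j] = int(m[a, b])
    return AMINO_ALPHABET, out


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap costs.

    A gap run of length L costs ``gap_open + (L - 1) * gap_extend``.
    """

    alphabet: str
    substitution: np.ndarray  # square, symmetric, indexed by alphabet position
    gap_open: int = -11
    gap_extend: int = -1

    def __post_init__(self) -> None:
        sub = np.asarray(self.substitution)
        if sub.shape != (len(self.alphabet), len(self.alphabet)):
            raise ValueError("substitution matrix shape must match alphabet")
        if not np.array_equal(sub, sub.T):
            raise ValueError("substitution matrix must be symmetric")
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("require gap_open <= gap_extend < 0")

    @classmethod
    def blosum62(cls, gap_open: int = -11, gap_extend: int = -1) -> "ScoringScheme":
        """Default scheme: BLOSUM62 with neutral X, affine gaps −11/−1."""
        alphabet, sub = _blosum62_with_neutral_x()
        return cls(alphabet=alphabet, substitution=sub, gap_open=gap_open, gap_extend=gap_extend)

    @classmethod
    def simple(
        cls,
        alphabet: str,
        match: int = 1,
        mismatch: int = -1,
        gap_open: int = -5,
        gap_extend: int = -2,
    ) -> "ScoringScheme":
        n = len(alphabet)
        sub = np.full((n, n), mismatch, dtype=int)
        np.fill_diagonal(sub, match)
        return cls(alphabet=alphabet, substitution=sub, gap_open=gap_open, gap_extend=gap_extend)

    def score(self, a: str, b: str) -> int:
        return int(self.substitution[self.alphabet.index(a), self.alphabet.index(b)])

    def _aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.Array(
            alphabet=self.alphabet, dims=2, data=self.substitution.astype(float)
        )
        aligner.open_gap_score = float(self.gap_open)
        aligner.extend_gap_score = float(self.gap_extend)
        return aligner


@dataclass(frozen=True)
class PairwiseAlignment:
    """One optimal global alignment plus its identity/coverage summary."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    matches: int = field(default=0)
    aligned_columns: int = field(default=0)
    identity_pct: float = field(default=0.0)
    coverage_pct_a: float = field(default=0.0)
    coverage_pct_b: float = field(default=0.0)


def _summarize_alignment(
    id_a: str, id_b: str, aligned_a: str, aligned_b: str, score: float
) -> PairwiseAlignment:
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings must have equal length")
    matches = 0
    aligned_columns = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" and y == "-":
            raise ValueError("alignment contains an all-gap column")
        if x != "-" and y != "-":
            aligned_columns += 1
            # X is a wildcard, never a confirmed match
            if x == y and x != "X":
                matches += 1
    len_a = len(aligned_a.replace("-", ""))
    len_b = len(aligned_b.replace("-", ""))
    identity = 100.0 * matches / aligned_columns if aligned_columns else 0.0
    return PairwiseAlignment(
        id_a=id_a,
        id_b=id_b,
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=score,
        matches=matches,
        aligned_columns=aligned_columns,
        identity_pct=identity,
        coverage_pct_a=100.0 * aligned_columns / len_a,
        coverage_pct_b=100.0 * aligned_columns / len_b,
    )


def align_global(a: HeadDomain, b: HeadDomain, scheme: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal affine-gap global (Needleman–Wunsch) alignment of two head domains.

    The input pair is canonicalised by (id, residues) before aligning, so the
    result is symmetric under swapping ``a`` and ``b`` (fields are reported in
    the caller's order).  Traceback is deterministic.
    """
    if scheme is None:
        scheme = ScoringScheme.blosum62()
    for dom in (a, b):
        if not dom.residues:
            raise InvalidSequenceError(f"head domain {dom.parent_id!r} is empty")
        bad = set(dom.residues) - set(scheme.alphabet)
        if bad:
            raise InvalidSequenceError(
                f"head domain {dom.parent_id!r} contains letters outside the "
                f"scoring alphabet: {sorted(bad)}"
            )
    swapped = (b.parent_id, b.residues) < (a.parent_id, a.residues)
    first, second = (b, a) if swapped else (a, b)
    aligner = scheme._aligner()
    alignment = aligner.align(first.residues, second.residues)[0]
    g_first, g_second = str(alignment[0]), str(alignment[1])
    if swapped:
        g_first, g_second = g_second, g_first
    return _summarize_alignment(a.parent_id, b.parent_id, g_first, g_second, float(alignment.score))


def identity_and_coverage(aln: PairwiseAlignment) -> tuple[float, float]:
    """Percent identity and pair-level coverage (min over the two sequences)."""
    return aln.identity_pct, min(aln.coverage_pct_a, aln.coverage_pct_b)


# ---------------------------------------------------------------------------
# FASTA I/O

def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read protein sequences from FASTA; id = first whitespace token."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InvalidSequenceError(f"no sequences found in {path}")
    seqs = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise InvalidSequenceError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seqs.append(
            ProteinSequence(id=rec.id, residues=str(rec.seq).upper(), description=rec.description)
        )
    return seqs


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    """Write sequences as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as handle:
        for s in seqs:
            header = s.description if s.description.startswith(s.id) else s.id
            handle.write(f">{header}\n")
            for i in range(0, len(s.residues), width):
                handle.write(s.residues[i : i + width] + "\n")


def heads_from_sequences(
    seqs: Iterable[ProteinSequence], head_length: int = DEFAULT_HEAD_LENGTH
) -> list[HeadDomain]:
    """Extract the head window from every sequence, in input order."""
    return [extract_head_domain(s, head_length) for s in seqs]
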