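"""Sequence handling: validation, mutation codes, FASTA input, test fixtures.

RNA sequences are stored over the alphabet {A, C, G, U}; DNA input is
accepted and transcribed on the fly (T -> U, case-folded to upper).  All
user-facing coordinates -- mutation codes, reports, plots -- are 1-based
and inclusive; 0-based indexing is an internal detail that never leaks.

Mutation codes follow the common ``<wt><pos><mut>`` grammar: ``G10A`` is a
single substitution (G at position 10 becomes A), and multiple edits are
joined with ``-`` as in ``G10A-C12G``.  Only substitutions are supported;
indels are out of scope.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "RnaSequence",
    "PointEdit",
    "MutationSpec",
    "MutationError",
    "SequenceError",
    "validate_sequence",
    "parse_mutation_code",
    "apply_mutations",
    "read_fasta",
    "make_fixture_sequences",
]

_NUCLEOTIDES = frozenset("ACGU")

#: Default cap on sequence length; cubic-time folding keeps this at desk scale.
MAX_SEQUENCE_LENGTH = 2000


class SequenceError(ValueError):
    """Raised for empty, non-nucleotide or over-long sequence input."""


class MutationError(ValueError):
    """Raised for malformed mutation codes or edits inconsistent with the WT."""


@dataclass(frozen=True)
class RnaSequence:
    """An identified RNA sequence over {A, C, G, U}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError("sequence is empty")
        bad = [(k + 1, c) for k, c in enumerate(self.residues) if c not in _NUCLEOTIDES]
        if bad:
            pos, char = bad[0]
            raise SequenceError(
                f"invalid character {char!r} at position {pos} (expected A/C/G/U)"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n(self) -> int:
        return len(self.residues)

    def base(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= self.n:
            raise IndexError(f"position {position} out of range 1..{self.n}")
        return self.residues[position - 1]


@dataclass(frozen=True)
class PointEdit:
    """One substitution: WT base at a 1-based position replaced by another."""

    position: int
    wt_base: str
    mut_base: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise MutationError(f"position must be >= 1, got {self.position}")
        for b in (self.wt_base, self.mut_base):
            if b not in _NUCLEOTIDES:
                raise MutationError(f"{b!r} is not a nucleotide (A/C/G/U)")

    @property
    def is_identity(self) -> bool:
        return self.wt_base == self.mut_base

    def code(self) -> str:
        return f"{self.wt_base}{self.position}{self.mut_base}"


@dataclass(frozen=True)
class MutationSpec:
    """An ordered list of point substitutions at strictly increasing positions."""

    edits: tuple[PointEdit, ...]

    def __post_init__(self) -> None:
        positions = [e.position for e in self.edits]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise MutationError(
                f"edit positions must be strictly increasing, got {positions}"
            )

    @property
    def is_identity(self) -> bool:
        return all(e.is_identity for e in self.edits)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(e.position for e in self.edits)

    def code(self) -> str:
        return "-".join(e.code() for e in self.edits)


def validate_sequence(raw: str, id: str = "seq") -> RnaSequence:
    """Normalize raw sequence text into an :class:`RnaSequence`.

    Whitespace is stripped, lowercase is folded and T is transcribed to U.
    Any other character raises :class:`SequenceError` naming the offending
    character and its 1-based position (in the whitespace-stripped text).
    """
    compact = "".join(raw.split())
    if not compact:
        raise SequenceError("sequence is empty")
    normalized = compact.upper().replace("T", "U")
    if len(normalized) > MAX_SEQUENCE_LENGTH:
        raise SequenceError(
            f"sequence length {len(normalized)} exceeds the configured maximum "
            f"of {MAX_SEQUENCE_LENGTH} nt"
        )
    return RnaSequence(id=id, residues=normalized)


_TOKEN_RE = re.compile(r"^([ACGTUacgtu])(\d+)([ACGTUacgtu])$")


def parse_mutation_code(code: str) -> MutationSpec:
    """Parse a mutation code like ``G10A`` or ``G10A-C12G``.

    Case-insensitive; T is normalized to U.  Duplicate positions are
    rejected; tokens are reordered by position so the code grammar is
    order-free while the parsed MutationSpec stays canonical.
    """
    if not code or not code.strip():
        raise MutationError("mutation code is empty")
    edits = []
    for token in code.strip().split("-"):
        m = _TOKEN_RE.match(token)
        if m is None:
            raise MutationError(
                f"malformed mutation token {token!r} "
                "(expected <base><position><base>, e.g. G10A)"
            )
        wt, pos, mut = m.groups()
        norm = lambda b: b.upper().replace("T", "U")
        edits.append(PointEdit(int(pos), norm(wt), norm(mut)))
    positions = [e.position for e in edits]
    if len(set(positions)) != len(positions):
        dup = sorted({p for p in positions if positions.count(p) > 1})
        raise MutationError(f"duplicate mutation position(s): {dup}")
    edits.sort(key=lambda e: e.position)
    return MutationSpec(edits=tuple(edits))


def apply_mutations(wt: RnaSequence, spec: MutationSpec) -> RnaSequence:
    """Apply a :class:`MutationSpec` to the WT, checking each stated WT base."""
    residues = list(wt.residues)
    for edit in spec.edits:
        if edit.position > wt.n:
            raise MutationError(
                f"mutation position {edit.position} out of range (sequence "
                f"length {wt.n})"
            )
        found = residues[edit.position - 1]
        if found != edit.wt_base:
            raise MutationError(
                f"expected {edit.wt_base} at position {edit.position}, found {found}"
            )
        residues[edit.position - 1] = edit.mut_base
    return RnaSequence(id=f"{wt.id}|{spec.code()}", residues="".join(residues))


def read_fasta(path) -> RnaSequence:
    """Read a single-record FASTA file (bare sequence without header accepted).

    If the file holds several records only the first is used, with a warning.
    """
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise SequenceError(f"{path}: file is empty")
    if text.lstrip().startswith(">"):
        records = list(SeqIO.parse(io.StringIO(text), "fasta"))
        if not records:
            raise SequenceError(f"{path}: no FASTA records found")
        if len(records) > 1:
            warnings.warn(
                f"{path}: {len(records)} FASTA records found; using only the "
                f"first ({records[0].id})",
                stacklevel=2,
            )
        return validate_sequence(str(records[0].seq), id=records[0].id)
    return validate_sequence(text, id="seq")


_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def make_fixture_sequences(
    seed: int, count: int, length: int
) -> list[RnaSequence]:
    """Deterministic random sequences, each with a planted stem of >= 4 bp.

    The stem guarantees every fixture has non-trivial ensemble structure
    (an all-random short sequence can easily fold into nothing).  Layout:
    random background, then a complementary arm pair (Watson-Crick
    reverse complement) separated by a loop of >= 3 nt is written over it.
    A 4 bp stem plus the minimal loop needs 11 nt; for lengths 8-10 the
    longest stem that fits, (length - 3) // 2 bp, is planted instead.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if length < 8:
        raise ValueError("length must be >= 8 (shortest 4 bp stem + minimal features)")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGU"))
    out = []
    for k in range(count):
        residues = list(alphabet[rng.integers(0, 4, size=length)])
        # stem geometry: arm + loop(>=3) + arm must fit
        max_arm = (length - 3) // 2
        arm = int(rng.integers(4, max_arm + 1)) if max_arm > 4 else min(4, max_arm)
        loop = 3 + int(rng.integers(0, max(1, length - 2 * arm - 3 + 1)))
        start = int(rng.integers(0, length - (2 * arm + loop) + 1))
        left = alphabet[rng.integers(0, 4, size=arm)]
        right = [_COMPLEMENT[b] for b in reversed(left)]
        residues[start : start + arm] = list(left)
        rstart = start + arm + loop
        residues[rstart : rstart + arm] = right
        out.append(
            validate_sequence("".join(residues), id=f"fixture-{seed}-{k}")
        )
    return out
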