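"""Bridge to an installed RNAstructure for data-driven secondary structure.

The folding algorithm itself is not reimplemented here: this adapter writes
the sequence (single-record FASTA) and the normalized reactivities as a
.shape restraint file (missing positions as -999, so no restraint is applied
there), invokes the external ``Fold`` executable, and parses its
connectivity-table (CT) output into dot-bracket notation.  Crossing pairs
(pseudoknots) cannot be encoded in plain dot-bracket and are rejected.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import FrozenSet, Optional, Sequence, Tuple, Union

from .core import NormalizedProfile, RnaSequence
from .errors import (
    DependencyError,
    ExternalToolError,
    FormatError,
    PseudoknotError,
    ValidationError,
)
from .probing_io import write_shape

MIN_PAIR_SPAN = 3  # paired positions must be at least this far apart

DEFAULT_EXECUTABLE = "Fold"


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free secondary structure with its dot-bracket encoding."""

    sequence: RnaSequence
    pairs: FrozenSet[Tuple[int, int]]
    dot_bracket: str

    def __post_init__(self) -> None:
        if len(self.dot_bracket) != self.sequence.length:
            raise ValidationError("dot-bracket length must equal sequence length")


def _check_pairs(pairs: Sequence[Tuple[int, int]], length: int) -> Tuple[Tuple[int, int], ...]:
    seen = {}
    norm = []
    for i, j in pairs:
        if i > j:
            i, j = j, i
        if i < 1 or j > length:
            raise FormatError(f"pair ({i},{j}) outside 1..{length}")
        if i == j:
            raise FormatError(f"position {i} paired with itself")
        if j - i < MIN_PAIR_SPAN:
            raise FormatError(f"pair ({i},{j}) closer than {MIN_PAIR_SPAN} nt")
        for p in (i, j):
            if p in seen:
                raise FormatError(f"position {p} appears in more than one pair")
            seen[p] = True
        norm.append((i, j))
    return tuple(sorted(norm))


def pairs_to_dotbracket(pairs: Sequence[Tuple[int, int]], length: int) -> str:
    """Render nested pairs as (); crossing pairs raise PseudoknotError."""
    norm = _check_pairs(pairs, length)
    for a in norm:
        for b in norm:
            if a[0] < b[0] < a[1] < b[1]:
                raise PseudoknotError(
                    f"pseudoknot not representable: pairs {a} and {b} cross"
                )
    chars = ["."] * length
    for i, j in norm:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


def dotbracket_to_pairs(db: str) -> FrozenSet[Tuple[int, int]]:
    """Recover the pair set from a plain dot-bracket string."""
    stack = []
    pairs = set()
    for idx, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise FormatError(f"unbalanced ')' at position {idx}")
            pairs.add((stack.pop(), idx))
        elif ch != ".":
            raise FormatError(f"invalid dot-bracket character {ch!r}")
    if stack:
        raise FormatError(f"unbalanced '(' at position {stack[-1]}")
    return frozenset(pairs)


def parse_ct(text: str) -> Tuple[str, Tuple[Tuple[int, int], ...]]:
    """Parse a connectivity table into (sequence, pairs).

    Expects the standard layout: a header line starting with the length,
    then one line per nucleotide ``i base i-1 i+1 pair index``.  Pairing must
    be symmetric (i -> j implies j -> i).
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty connectivity table")
    try:
        length = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise FormatError(f"bad CT header: {lines[0]!r}")
    if len(lines) - 1 < length:
        raise FormatError(f"CT declares {length} nucleotides but has {len(lines)-1} rows")

    bases = []
    partner = {}
    for ln in lines[1 : 1 + length]:
        fields = ln.split()
        if len(fields) < 5:
            raise FormatError(f"bad CT row: {ln!r}")
        i = int(fields[0])
        bases.append(fields[1].upper().replace("T", "U"))
        partner[i] = int(fields[4])

    pairs = []
    for i, j in partner.items():
        if j == 0:
            continue
        if partner.get(j) != i:
            raise FormatError(
                f"inconsistent pairing: {i} -> {j} but {j} -> {partner.get(j)}"
            )
        if i < j:
            pairs.append((i, j))
    return "".join(bases), tuple(sorted(pairs))


def ct_to_dotbracket(ct_text: str) -> SecondaryStructure:
    """Convert connectivity-table text to a SecondaryStructure."""
    seq, pairs = parse_ct(ct_text)
    db = pairs_to_dotbracket(pairs, len(seq))
    return SecondaryStructure(RnaSequence(seq), frozenset(pairs), db)


def predict_structure(
    seq: RnaSequence,
    profile: NormalizedProfile,
    tool_path: Optional[Union[str, Path]] = None,
    slope: Optional[float] = None,
    intercept: Optional[float] = None,
    is_dms: bool = False,
    workdir: Optional[Union[str, Path]] = None,
) -> SecondaryStructure:
    """Run reactivity-driven folding through an external RNAstructure Fold.

    Writes the FASTA and .shape restraint inputs, invokes the executable
    (``tool_path`` or ``Fold`` on PATH), and parses the resulting CT file.
    ``slope``/``intercept`` are passed through to the tool's pseudo-energy
    parameters; ``is_dms`` selects its DMS restraint mode.  A missing tool
    raises DependencyError — never a silent skip.
    """
    tool = str(tool_path) if tool_path else shutil.which(DEFAULT_EXECUTABLE)
    if tool is None or not Path(tool).exists():
        raise DependencyError(
            "external dependency missing: RNAstructure executable "
            f"{tool_path or DEFAULT_EXECUTABLE!r} not found"
        )
    if profile.positions[-1] > seq.length or not profile.is_contiguous_from_one:
        raise ValidationError("profile must cover contiguous positions 1..L of the sequence")

    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        tmp = Path(tmp)
        fasta = tmp / "input.fasta"
        fasta.write_text(f">{profile.label or 'rna'}\n{seq.residues}\n")
        shape_file = write_shape(profile, tmp / "restraints.shape")
        ct_file = tmp / "output.ct"

        cmd = [tool, str(fasta), str(ct_file)]
        cmd += ["--DMS" if is_dms else "--SHAPE", str(shape_file)]
        if slope is not None:
            cmd += ["--SHAPEslope", str(slope)]
        if intercept is not None:
            cmd += ["--SHAPEintercept", str(intercept)]
        result = subprocess.run(cmd, capture_output=True, text=True)
        if result.returncode != 0:
            raise ExternalToolError(
                f"{tool} exited with {result.returncode}:\n"
                f"stdout: {result.stdout}\nstderr: {result.stderr}"
            )
        if not ct_file.exists():
            raise ExternalToolError(f"{tool} produced no CT output")
        return ct_to_dotbracket(ct_file.read_text())
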