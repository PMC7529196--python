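"""Reading and writing of probing-data file formats.

Two tab-delimited peak-table dialects are supported:

* ``QUSHAPE`` — a header-bearing table whose columns are matched
  case-insensitively against ``seqNum``/``posSeq``, ``seqRNA``, ``areaRX``,
  ``areaBG`` and (optionally) ``areaDiff``.
* ``SHAPEFINDER`` — a headerless (or label-row) table read positionally as
  ``(position, base, rx_area, bg_area, reactivity)``.

Output formats: the two-column ``.shape`` restraint file consumed by
data-driven RNA folding software (missing positions written as ``-999``),
and an XLSX workbook with raw, normalized and averaged sheets.
"""

from __future__ import annotations

import io
import warnings
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

from .core import (
    MISSING_CODE,
    AveragedProfile,
    ColorBin,
    Dialect,
    Experiment,
    NormalizedProfile,
    ProbingRecord,
    Reagent,
    RnaSequence,
)
from .errors import DialectError, FormatError, ValidationError

_QUSHAPE_POSITION_HEADERS = ("seqnum", "posseq")

_SHAPE_PRECISION = 3  # decimals written to .shape files


def _parse_float(token: str) -> Optional[float]:
    token = token.strip()
    if not token or token.upper() in {"NA", "NAN", "-"}:
        return None
    try:
        return float(token)
    except ValueError:
        return None


def _clean_base(token: str) -> str:
    b = token.strip().upper().replace("T", "U")
    return b if b in set("ACGUN") else "N"


def _read_rows(path: Union[str, Path]) -> List[List[str]]:
    text = Path(path).read_text()
    rows = [line.rstrip("\n").rstrip("\r").split("\t") for line in text.splitlines()]
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    if not rows:
        raise FormatError(f"{path}: empty file")
    return rows


def sniff_dialect(path: Union[str, Path]) -> Dialect:
    """Pick the dialect from the first non-blank row: an ``areaRX`` header
    selects QUSHAPE, anything else is read positionally as SHAPEFINDER."""
    rows = _read_rows(path)
    header = [c.strip().lower() for c in rows[0]]
    return Dialect.QUSHAPE if "arearx" in header else Dialect.SHAPEFINDER


def parse_probing_file(
    path: Union[str, Path],
    dialect: Optional[Dialect] = None,
    reagent: Reagent = Reagent.SHAPE,
    label: Optional[str] = None,
) -> Experiment:
    """Parse one ShapeFinder/QuShape-style peak table into an Experiment.

    Rows whose numeric fields cannot be parsed become missing-flagged
    records; no row of the table is ever dropped.  The absolute reactivity
    is taken from the file's reactivity column when present, otherwise
    computed as ``rx_area - bg_area``.
    """
    path = Path(path)
    rows = _read_rows(path)
    if dialect is None:
        dialect = sniff_dialect(path)

    if dialect is Dialect.QUSHAPE:
        records = _parse_qushape(rows, path)
    else:
        records = _parse_shapefinder(rows, path)

    if not records:
        raise FormatError(f"{path}: no data rows")

    seen = {}
    for r in records:
        if r.position in seen:
            raise ValidationError(f"{path}: duplicate position {r.position}")
        seen[r.position] = r
    records.sort(key=lambda r: r.position)

    return Experiment(
        records=tuple(records),
        reagent=reagent,
        dialect=dialect,
        label=label if label is not None else path.stem,
    )


def _make_record(pos_tok: str, base_tok: str, rx_tok: str, bg_tok: str,
                 diff_tok: Optional[str], source: str, line_no: int) -> ProbingRecord:
    pos_f = _parse_float(pos_tok)
    if pos_f is None or int(pos_f) != pos_f:
        raise ValidationError(f"{source}: line {line_no}: bad position {pos_tok!r}")
    rx = _parse_float(rx_tok)
    bg = _parse_float(bg_tok)
    reactivity = _parse_float(diff_tok) if diff_tok is not None else None
    if reactivity is None and rx is not None and bg is not None:
        reactivity = rx - bg
    return ProbingRecord(int(pos_f), _clean_base(base_tok), rx, bg, reactivity)


def _parse_qushape(rows: List[List[str]], source: Path) -> List[ProbingRecord]:
    header = [c.strip().lower() for c in rows[0]]

    def col(*names: str) -> Optional[int]:
        for n in names:
            if n in header:
                return header.index(n)
        return None

    i_pos = col(*_QUSHAPE_POSITION_HEADERS)
    i_base = col("seqrna")
    i_rx = col("arearx")
    i_bg = col("areabg")
    i_diff = col("areadiff")
    if i_pos is None or i_base is None or i_rx is None or i_bg is None:
        raise DialectError(
            f"{source}: QuShape dialect needs headers seqNum|posSeq, seqRNA, "
            f"areaRX, areaBG (optionally areaDiff); got {rows[0]}"
        )

    def cell(row: List[str], i: Optional[int]) -> str:
        return row[i] if i is not None and i < len(row) else ""

    out = []
    for ln, row in enumerate(rows[1:], start=2):
        out.append(
            _make_record(
                cell(row, i_pos), cell(row, i_base), cell(row, i_rx),
                cell(row, i_bg), cell(row, i_diff) if i_diff is not None else None,
                str(source), ln,
            )
        )
    return out


def _parse_shapefinder(rows: List[List[str]], source: Path) -> List[ProbingRecord]:
    start = 0
    # skip a label row (non-numeric first cell) if present
    if rows and _parse_float(rows[0][0]) is None:
        start = 1
    out = []
    for ln, row in enumerate(rows[start:], start=start + 1):
        if len(row) < 4:
            raise DialectError(
                f"{source}: ShapeFinder dialect needs >= 4 tab-separated columns "
                f"(position, base, rx_area, bg_area[, reactivity]); line {ln} has {len(row)}"
            )
        diff_tok = row[4] if len(row) >= 5 else None
        out.append(_make_record(row[0], row[1], row[2], row[3], diff_tok, str(source), ln))
    return out


def validate_sequence(
    raw: str, experiments: Sequence[Experiment] = ()
) -> RnaSequence:
    """Validate a user-provided RNA sequence against the probing data.

    Accepts a raw string or single-record FASTA text.  The sequence must be
    RNA (DNA ``T`` is accepted and converted to ``U``) and at least as long
    as the highest nucleotide position in every experiment.  Base identity
    against the peak tables' base column is deliberately *not* enforced
    (only a warning is emitted on mismatch): the validation contract is a
    length check.
    """
    raw = raw.strip()
    if raw.startswith(">"):
        from Bio import SeqIO

        seq_records = list(SeqIO.parse(io.StringIO(raw), "fasta"))
        if len(seq_records) != 1:
            raise FormatError(f"expected a single FASTA record, got {len(seq_records)}")
        raw = str(seq_records[0].seq)
    raw = "".join(raw.split())
    if not raw:
        raise FormatError("empty sequence")

    bad = sorted(set(raw) - set("ACGUTacgut"))
    if bad:
        raise _not_rna_error(bad)
    residues = raw.upper().replace("T", "U")

    for exp in experiments:
        if len(residues) < exp.max_position:
            raise ValidationError(
                f"sequence length {len(residues)} is shorter than the probing data "
                f"(max position {exp.max_position} in {exp.label or 'experiment'})"
            )
        mismatches = [
            r.position
            for r in exp.records
            if r.base != "N" and r.base != residues[r.position - 1]
        ]
        if mismatches:
            warnings.warn(
                f"{exp.label or 'experiment'}: base column disagrees with the sequence "
                f"at {len(mismatches)} positions (first: {mismatches[0]})",
                stacklevel=2,
            )
    return RnaSequence(residues)


def _not_rna_error(bad: List[str]):
    from .errors import SequenceError

    return SequenceError(f"not RNA: invalid characters {bad}")


def format_shape_value(value: Optional[float]) -> str:
    """Render one .shape value: fixed 3-decimal reals, literal -999 for missing."""
    if value is None:
        return str(MISSING_CODE)
    return f"{value:.{_SHAPE_PRECISION}f}"


def write_shape(
    profile: Union[NormalizedProfile, AveragedProfile], path: Union[str, Path]
) -> Path:
    """Write a profile as a two-column .shape restraint file.

    One ``position<TAB>value`` line per nucleotide 1..L; missing/excluded
    positions carry the no-data code ``-999``.  The profile must cover
    contiguous positions starting at 1 (pad with :func:`pad_profile` first).
    """
    if isinstance(profile, AveragedProfile):
        profile = profile.as_profile()
    if len(profile) == 0:
        raise ValidationError("cannot write an empty profile")
    if not profile.is_contiguous_from_one:
        raise ValidationError(
            "profile must cover contiguous positions 1..L; pad missing positions first"
        )
    path = Path(path)
    lines = [
        f"{pos}\t{format_shape_value(val)}"
        for pos, val in zip(profile.positions, profile.values)
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def parse_shape(path: Union[str, Path], label: str = "") -> NormalizedProfile:
    """Read a two-column .shape file back into a NormalizedProfile."""
    rows = _read_rows(path)
    positions: List[int] = []
    values: List[Optional[float]] = []
    for ln, row in enumerate(rows, start=1):
        if len(row) < 2:
            raise FormatError(f"{path}: line {ln}: expected 'position<TAB>value'")
        pos = _parse_float(row[0])
        if pos is None or int(pos) != pos:
            raise FormatError(f"{path}: line {ln}: bad position {row[0]!r}")
        val = _parse_float(row[1])
        if val is None:
            raise FormatError(f"{path}: line {ln}: bad value {row[1]!r}")
        positions.append(int(pos))
        values.append(None if val == MISSING_CODE else val)
    return NormalizedProfile(tuple(positions), tuple(values), label=label or Path(path).stem)


def pad_profile(profile: NormalizedProfile, length: Optional[int] = None) -> NormalizedProfile:
    """Pad a profile to contiguous positions 1..L, filling gaps with missing."""
    length = length if length is not None else profile.positions[-1]
    by_pos = dict(zip(profile.positions, profile.values))
    positions = tuple(range(1, length + 1))
    values = tuple(by_pos.get(p) for p in positions)
    return NormalizedProfile(positions, values, label=profile.label,
                             diagnostics=profile.diagnostics)


def export_workbook(
    experiments: Sequence[Experiment],
    profiles: Sequence[NormalizedProfile],
    averaged: AveragedProfile,
    path: Union[str, Path],
    thresholds: Tuple[float, float] = (0.4, 0.85),
) -> Path:
    """Write the spreadsheet report: one raw sheet per input experiment, one
    normalized sheet per replicate (rows tagged and filled with their color
    bin), and a per-position mean +/- SD sheet for the averaged profile."""
    from openpyxl import Workbook
    from openpyxl.styles import Font, PatternFill

    from .normalize import assign_color_bins

    if len(experiments) != len(profiles):
        raise ValidationError(
            f"{len(experiments)} experiments but {len(profiles)} normalized profiles"
        )

    fills = {
        ColorBin.LOW: PatternFill("solid", fgColor="FF000000"),
        ColorBin.MID: PatternFill("solid", fgColor="FFFFA500"),
        ColorBin.HIGH: PatternFill("solid", fgColor="FFFF0000"),
    }
    fonts = {
        ColorBin.LOW: Font(color="FFFFFFFF"),
        ColorBin.MID: Font(color="FF000000"),
        ColorBin.HIGH: Font(color="FFFFFFFF"),
    }

    wb = Workbook()
    wb.remove(wb.active)

    for i, exp in enumerate(experiments, start=1):
        ws = wb.create_sheet(f"input_{i}_{_sheet_safe(exp.label)}"[:31])
        ws.append(["position", "base", "rx_area", "bg_area", "reactivity"])
        for r in exp.records:
            ws.append([r.position, r.base, r.rx_area, r.bg_area, r.reactivity])

    for i, prof in enumerate(profiles, start=1):
        binned = prof if prof.bins is not None else assign_color_bins(prof, thresholds)
        ws = wb.create_sheet(f"normalized_{i}_{_sheet_safe(prof.label)}"[:31])
        ws.append(["position", "normalized_reactivity", "color_bin"])
        for pos, val, colbin in zip(binned.positions, binned.values, binned.bins):
            if val is None:
                ws.append([pos, MISSING_CODE, ""])
            else:
                ws.append([pos, val, colbin.name])
                cell = ws.cell(row=ws.max_row, column=2)
                cell.fill = fills[colbin]
                cell.font = fonts[colbin]

    ws = wb.create_sheet("averaged")
    ws.append(["position", "mean", "sd", "n_obs"])
    for pos, mean, sd, n in zip(averaged.positions, averaged.means, averaged.sds, averaged.n_obs):
        ws.append([pos, MISSING_CODE if mean is None else mean,
                   "" if sd is None else sd, n])

    path = Path(path)
    wb.save(path)
    return path


def _sheet_safe(label: str, maxlen: int = 20) -> str:
    safe = "".join(c if c.isalnum() or c in "-_" else "_" for c in label)
    return safe[:maxlen] or "exp"
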