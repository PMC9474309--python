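"""FASTA input and tab-delimited result writers.

Reading goes through Biopython's FASTA parser with two stricter checks layered
on top: text before the first ``>`` header is an error rather than silently
skipped, and a header with no residues is an error naming the record.
Residues are normalised to uppercase ``{A, C, G, T, N}`` (``U`` -> ``T``);
soft-masked lowercase is folded to uppercase, so masked regions are searched.
Any other character is rejected — assemblies legitimately contain ``N`` gaps,
but rarer IUPAC ambiguity codes signal input this scanner is not meant for.

Coordinates are 0-based half-open in BED output; the human-readable
occurrence report additionally prints 1-based starts.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import FastaFormatError, SequenceAlphabetError
from .search import CountMatrix, OccurrenceSet, tandem_runs

__all__ = [
    "GenomeSequence",
    "normalize_sequence",
    "read_fasta",
    "write_fasta",
    "write_occurrences_bed",
    "read_occurrences_bed",
    "write_count_table",
    "read_count_table",
    "write_anova_report",
    "write_tukey_report",
    "reverse_complement",
]

_VALID = frozenset("ACGTN")
# fold case, map U/u->T, drop ASCII whitespace
_TRANS = str.maketrans(
    {"a": "A", "c": "C", "g": "G", "t": "T", "n": "N", "u": "T", "U": "T",
     " ": None, "\t": None, "\r": None, "\n": None, "\v": None, "\f": None}
)

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(motif: str) -> str:
    return motif.translate(_RC)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome or contig: identifier plus validated residue text.

    ``id`` is the first whitespace-delimited token of the FASTA header;
    ``description`` is the remainder (possibly empty).  ``residues`` holds
    only ``{A, C, G, T, N}`` with no whitespace.
    """

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        bad = set(self.residues) - _VALID
        if bad:
            raise SequenceAlphabetError(sorted(bad)[0], self.residues.index(sorted(bad)[0]), self.id)

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


def normalize_sequence(raw: str, *, context: str = "") -> str:
    """Normalise raw sequence text to validated uppercase residues.

    Case is folded, ``U`` becomes ``T``, whitespace is removed.  Any other
    character raises :class:`SequenceAlphabetError` carrying the 0-based
    position of the first offender in ``raw``.
    """
    cleaned = raw.translate(_TRANS)
    if set(cleaned) <= _VALID:
        return cleaned
    # error path: locate the first offending character in the raw text
    for pos, ch in enumerate(raw):
        if ch.isspace():
            continue
        if ch.translate(_TRANS) not in _VALID:
            raise SequenceAlphabetError(ch, pos, context)
    raise AssertionError("unreachable")  # pragma: no cover


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def read_fasta(path) -> list[GenomeSequence]:
    """Read a (possibly gzipped) multi-record FASTA file.

    Record order is preserved.  Errors: missing file, sequence text before the
    first header, a record with no residues, or a residue outside the allowed
    alphabet.
    """
    path = Path(path)
    with _open_text(path) as handle:
        for line in handle:
            if line.strip():
                if not line.lstrip().startswith(">"):
                    raise FastaFormatError(
                        f"{path}: sequence data before any '>' header"
                    )
                break
        else:
            raise FastaFormatError(f"{path}: no FASTA records found")

    records: list[GenomeSequence] = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            residues = normalize_sequence(str(rec.seq), context=rec.id)
            if not residues:
                raise FastaFormatError(
                    f"{path}: record {rec.id!r} has a header but no residues"
                )
            desc = rec.description
            rest = desc.split(None, 1)[1] if len(desc.split(None, 1)) > 1 else ""
            records.append(GenomeSequence(rec.id, rest, residues))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeSequence], path, *, width: int = 70) -> None:
    """Write records as line-wrapped FASTA."""
    with open(path, "w", encoding="utf-8") as out:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            out.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                out.write(rec.residues[i : i + width] + "\n")


def write_occurrences_bed(occurrence_sets: Iterable[OccurrenceSet], path) -> None:
    """Write occurrences as BED6, sorted by (sequence id, start).

    Columns: chrom, 0-based start, half-open end (``start + m``), motif as
    name, score, strand ``+``.  The score column holds the number of tandem
    copies in the maximal run the occurrence belongs to (1 for an isolated
    occurrence); this reuse of the score slot is this tool's convention.
    """
    rows = []
    for occ in occurrence_sets:
        m = len(occ.motif)
        runs, _ = tandem_runs(occ)
        copies_at = {}
        for run in runs:
            for k in range(run.copies):
                copies_at[run.start + k * m] = run.copies
        for s in occ.starts:
            rows.append((occ.sequence_id, s, s + m, occ.motif, copies_at[s], "+"))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w", encoding="utf-8") as out:
        for r in rows:
            out.write("\t".join(str(x) for x in r) + "\n")


def read_occurrences_bed(path) -> pd.DataFrame:
    """Parse a BED6 occurrence file back into a DataFrame."""
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        return pd.read_csv(path, sep="\t", header=None, names=cols)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=cols)


def write_count_table(matrix: CountMatrix, path) -> None:
    """Write a genome x motif count TSV with row, column and grand totals.

    The last column (``total``) holds per-genome totals, the last row
    (``total``) per-motif totals, and the bottom-right cell the grand total.
    """
    df = matrix.counts.copy()
    if df.empty:
        raise ValueError("count matrix must be non-empty")
    df["total"] = matrix.row_totals
    totals = df.sum(axis=0)
    totals.name = "total"
    df = pd.concat([df, totals.to_frame().T])
    df.index.name = "genome"
    df.astype(int).to_csv(path, sep="\t")


def read_count_table(path) -> pd.DataFrame:
    """Read back a count table written by :func:`write_count_table`."""
    return pd.read_csv(path, sep="\t", index_col="genome")


def write_anova_report(rows: Sequence[dict], path) -> None:
    """Write one-row-per-test ANOVA report TSV.

    Expected keys per row: ``test_id``, ``factor``, ``ss_between``,
    ``df_between``, ``ms_between``, ``ss_within``, ``df_within``,
    ``ms_within``, ``f_statistic``, ``p_value``, ``reject``, ``error``.
    Missing keys are written as empty fields.
    """
    cols = [
        "test_id", "factor", "ss_between", "df_between", "ms_between",
        "ss_within", "df_within", "ms_within", "f_statistic", "p_value",
        "reject", "error",
    ]
    df = pd.DataFrame(list(rows))
    for c in cols:
        if c not in df.columns:
            df[c] = ""
    df[cols].to_csv(path, sep="\t", index=False)


def write_tukey_report(rows: Sequence[dict], path) -> None:
    """Write an all-pairs Tukey report TSV.

    Expected keys: ``family``, ``group1``, ``group2``, ``meandiff``,
    ``lower``, ``upper``, ``reject``.
    """
    cols = ["family", "group1", "group2", "meandiff", "lower", "upper", "reject"]
    df = pd.DataFrame(list(rows))
    for c in cols:
        if c not in df.columns:
            df[c] = ""
    df[cols].to_csv(path, sep="\t", index=False)
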