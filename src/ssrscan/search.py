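"""Exact-match SSR scanning with Boyer-Moore heuristics.

A simple sequence repeat (SSR, microsatellite) locus is a tandem tract of a
short motif such as ``TAGA``.  This module locates every exact occurrence of a
motif on the forward strand of a nucleotide sequence using the classic
Boyer-Moore machinery: a *first-occurrence* pre-scan that jumps the search to
the first alignment whose final character can match, the *bad-character* table
that skips past mismatching residues, and the *strong good-suffix* table built
from border (prefix-function) arrays of the motif and its reversal.

Conventions
-----------
* All coordinates are 0-based; occurrence intervals are half-open
  ``[start, start + m)``.
* All occurrences are reported, including overlapping ones: the shift applied
  after a full match is the motif's period, so a motif like ``ATAT`` planted
  as ``ATATATAT`` yields starts ``0, 2, 4``.
* ``N`` may appear in the text (assembly gaps) but never in a motif, and never
  matches any motif character.
* Matching is forward-strand only; callers wanting both strands add the
  reverse-complement motifs explicitly.

``naive_find_occurrences`` is a brute-force scanner over every alignment kept
deliberately independent of the heuristic engine; it is the reference
semantics the engine is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_MOTIFS",
    "MOTIF_ALPHABET",
    "TEXT_ALPHABET",
    "MotifPattern",
    "OccurrenceSet",
    "TandemRun",
    "CountMatrix",
    "prefix_function",
    "bad_character_table",
    "good_suffix_table",
    "first_occurrence_position",
    "find_occurrences",
    "naive_find_occurrences",
    "count_occurrences",
    "tandem_runs",
]

#: The ten tetranucleotide SSR motifs scanned by default.
DEFAULT_MOTIFS: tuple[str, ...] = (
    "TAGA", "AGAA", "GATA", "TCTA", "TCAT",
    "GAAT", "AGAT", "CTTT", "TATC", "TCTG",
)

MOTIF_ALPHABET = "ACGT"
TEXT_ALPHABET = "ACGTN"


def prefix_function(motif: str) -> list[int]:
    """Border array of ``motif``.

    ``tau[i]`` is the length of the longest proper prefix of ``motif[:i+1]``
    that is also a suffix of it (the Knuth-Morris-Pratt failure function).
    ``tau[0] == 0`` and ``tau[i] <= i`` always hold.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    tau = [0] * len(motif)
    k = 0
    for i in range(1, len(motif)):
        while k > 0 and motif[i] != motif[k]:
            k = tau[k - 1]
        if motif[i] == motif[k]:
            k += 1
        tau[i] = k
    return tau


def bad_character_table(motif: str, alphabet: str = TEXT_ALPHABET) -> dict[str, int]:
    """Last-occurrence (bad-character) table ``beta``.

    Maps each alphabet character to the largest 0-based index at which it
    occurs in ``motif``, or ``-1`` when it does not occur.  On a mismatch at
    motif index ``j`` against text character ``c`` the pattern may shift by
    ``j - beta[c]`` (clamped to at least 1 by taking the max with the
    good-suffix shift).  ``N`` is in the default alphabet so that gap
    characters in the text resolve to the sentinel ``-1``.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    beta = {a: -1 for a in alphabet}
    for i, c in enumerate(motif):
        beta[c] = i
    return beta


def good_suffix_table(motif: str) -> list[int]:
    """Strong good-suffix shift table ``gamma`` of length ``m + 1``.

    ``gamma[0]`` is the shift applied after a full match and equals the
    motif's period ``m - tau[m-1]``, which guarantees overlapping occurrences
    are not skipped.  ``gamma[j]`` for ``j`` in ``1..m`` is the safe shift
    after a mismatch at 1-based motif position ``j`` (i.e. after the suffix
    ``motif[j:]`` matched).  Built from the border arrays of the motif
    (``tau``) and of its reversal (``tau'``): the default shift is the period,
    improved for each suffix length ``k`` by the case-2 shift ``k - tau'[k]``
    at slot ``m - tau'[k]``.  Every entry lies in ``[1, m]``.
    """
    m = len(motif)
    tau = prefix_function(motif)
    tau_rev = prefix_function(motif[::-1])
    gamma = [m - tau[m - 1]] * (m + 1)
    for k in range(1, m + 1):
        j = m - tau_rev[k - 1]
        shift = k - tau_rev[k - 1]
        if shift < gamma[j]:
            gamma[j] = shift
    return gamma


@dataclass(frozen=True)
class MotifPattern:
    """An SSR motif together with its precomputed shift tables.

    Parameters
    ----------
    motif:
        Uppercase repeat unit over ``{A, C, G, T}`` (no ``N``), length >= 1.

    Attributes
    ----------
    bad_char:
        Last-occurrence table over ``{A, C, G, T, N}`` (``N`` -> ``-1``).
    good_suffix:
        Strong good-suffix shifts, length ``m + 1``.
    prefix_fn, prefix_fn_reversed:
        Border arrays of the motif and of its reversal.
    """

    motif: str
    bad_char: Mapping[str, int] = field(init=False, repr=False, compare=False)
    good_suffix: tuple[int, ...] = field(init=False, repr=False, compare=False)
    prefix_fn: tuple[int, ...] = field(init=False, repr=False, compare=False)
    prefix_fn_reversed: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.motif:
            raise ValueError("motif must be non-empty")
        bad = set(self.motif) - set(MOTIF_ALPHABET)
        if bad:
            raise ValueError(
                f"motif {self.motif!r} contains characters outside "
                f"{{A,C,G,T}}: {sorted(bad)}"
            )
        object.__setattr__(self, "bad_char", bad_character_table(self.motif))
        object.__setattr__(
            self, "good_suffix", tuple(good_suffix_table(self.motif))
        )
        object.__setattr__(self, "prefix_fn", tuple(prefix_function(self.motif)))
        object.__setattr__(
            self, "prefix_fn_reversed", tuple(prefix_function(self.motif[::-1]))
        )

    @property
    def length(self) -> int:
        return len(self.motif)

    @property
    def period(self) -> int:
        """Smallest shift mapping the motif onto itself (``m - tau[m-1]``)."""
        return len(self.motif) - self.prefix_fn[-1]


@dataclass(frozen=True)
class OccurrenceSet:
    """All start positions of one motif in one sequence.

    ``starts`` is a strictly increasing tuple of 0-based offsets; each
    occurrence occupies ``[start, start + len(motif))``.
    """

    sequence_id: str
    motif: str
    starts: tuple[int, ...]

    def __post_init__(self) -> None:
        starts = tuple(self.starts)
        object.__setattr__(self, "starts", starts)
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("starts must be strictly increasing")
        if starts and starts[0] < 0:
            raise ValueError("starts must be non-negative")

    def __len__(self) -> int:
        return len(self.starts)


@dataclass(frozen=True)
class TandemRun:
    """A maximal chain of occurrences spaced exactly one motif length apart.

    ``span = copies * m`` is the tract length in bases.
    """

    start: int
    copies: int
    span: int

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if self.span % self.copies != 0:
            raise ValueError("span must equal copies * motif length")


def _as_text(sequence) -> tuple[str, str]:
    """Accept a plain string or an object with ``.residues``/``.id``."""
    if isinstance(sequence, str):
        return sequence, ""
    return sequence.residues, sequence.id


def _as_pattern(motif) -> MotifPattern:
    return motif if isinstance(motif, MotifPattern) else MotifPattern(motif)


def first_occurrence_position(sequence, motif) -> int | None:
    """First alignment offset at which the motif's final character can match.

    Returns the smallest offset ``i`` such that
    ``text[i + m - 1] == motif[m - 1]``, i.e. the first alignment that is not
    immediately ruled out by its rightmost comparison.  Returns ``None``
    ("absent") when the final character never appears at a valid alignment or
    when the motif is longer than the text; in either case the motif cannot
    occur anywhere and the search can stop before scanning.
    """
    text, _ = _as_text(sequence)
    pat = _as_pattern(motif)
    m = pat.length
    if m > len(text):
        return None
    hit = text.find(pat.motif[-1], m - 1)
    if hit == -1:
        return None
    return hit - (m - 1)


def find_occurrences(sequence, motif, *, sequence_id: str | None = None) -> OccurrenceSet:
    """Locate every occurrence of ``motif`` with the heuristic engine.

    The scan starts at :func:`first_occurrence_position` (an absent final
    character short-circuits to an empty result).  At each alignment the motif
    is compared right-to-left; after a full match the window advances by the
    good-suffix full-match shift (the motif's period), after a mismatch at
    motif index ``j`` by ``max(gamma[j + 1], j - beta[text char])``.  Both
    components are bounded below so every advance is >= 1.

    Overlapping occurrences are reported.  ``N`` in the text never matches.
    """
    text, auto_id = _as_text(sequence)
    pat = _as_pattern(motif)
    if sequence_id is None:
        sequence_id = auto_id
    motif_str = pat.motif
    m = pat.length
    n = len(text)

    start = first_occurrence_position(text, pat)
    if start is None:
        return OccurrenceSet(sequence_id, motif_str, ())

    beta = dict(pat.bad_char)
    gamma = pat.good_suffix
    limit = n - m
    out: list[int] = []
    s = start
    while s <= limit:
        j = m - 1
        while j >= 0 and motif_str[j] == text[s + j]:
            j -= 1
        if j < 0:
            out.append(s)
            s += gamma[0]
        else:
            bad = beta.get(text[s + j], -1)
            s += max(gamma[j + 1], j - bad)
    return OccurrenceSet(sequence_id, motif_str, tuple(out))


def naive_find_occurrences(sequence, motif, *, sequence_id: str | None = None) -> OccurrenceSet:
    """Brute-force reference scanner: test every alignment.

    Checks all ``n - m + 1`` alignments character-for-character (vectorised
    over alignments with numpy) with no shift heuristics; this is the
    independent oracle for :func:`find_occurrences`.
    """
    text, auto_id = _as_text(sequence)
    pat = _as_pattern(motif)
    if sequence_id is None:
        sequence_id = auto_id
    m = pat.length
    n = len(text)
    if m > n:
        return OccurrenceSet(sequence_id, pat.motif, ())
    arr = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    mot = np.frombuffer(pat.motif.encode("ascii"), dtype=np.uint8)
    mask = arr[: n - m + 1] == mot[0]
    for k in range(1, m):
        mask &= arr[k : n - m + 1 + k] == mot[k]
    starts = tuple(int(i) for i in np.nonzero(mask)[0])
    return OccurrenceSet(sequence_id, pat.motif, starts)


@dataclass(frozen=True)
class CountMatrix:
    """Genome x motif occurrence counts with marginal totals.

    ``counts`` is an integer DataFrame indexed by genome identifier with one
    column per motif.  Totals are derived, never stored, so they cannot drift
    out of sync with the cells.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())


def count_occurrences(
    genomes: Iterable, motifs: Sequence, *, engine=find_occurrences
) -> CountMatrix:
    """Occurrence count of each motif in each genome.

    ``engine`` defaults to the heuristic scanner; the naive scanner can be
    substituted to build truth tables.  Counting includes overlapping
    occurrences (see module notes).
    """
    patterns = [_as_pattern(p) for p in motifs]
    if not patterns:
        raise ValueError("at least one motif is required")
    genomes = list(genomes)
    if not genomes:
        raise ValueError("at least one genome is required")
    data = {}
    for g in genomes:
        data[g.id] = [len(engine(g, p)) for p in patterns]
    df = pd.DataFrame.from_dict(
        data, orient="index", columns=[p.motif for p in patterns]
    ).astype(int)
    return CountMatrix(df)


def tandem_runs(occ: OccurrenceSet) -> tuple[list[TandemRun], int]:
    """Merge occurrences into maximal tandem runs.

    Consecutive starts exactly ``m`` apart belong to the same run; ``copies``
    is the chain length and ``span = copies * m`` the tract length in bases.
    Returns ``(runs, max_run_span)`` with ``max_run_span == 0`` for an empty
    occurrence set.
    """
    m = len(occ.motif)
    runs: list[TandemRun] = []
    starts = occ.starts
    i = 0
    while i < len(starts):
        j = i
        while j + 1 < len(starts) and starts[j + 1] - starts[j] == m:
            j += 1
        copies = j - i + 1
        runs.append(TandemRun(start=starts[i], copies=copies, span=copies * m))
        i = j + 1
    max_span = max((r.span for r in runs), default=0)
    return runs, max_span
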