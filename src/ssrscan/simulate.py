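"""Synthetic genome panels with planted SSR tracts and exact truth tables.

The generator emulates the input a chromosome-scale SSR scan sees: long
stretches of background nucleotide sequence punctuated by sparse tandem
tracts of the target motifs, with per-genome abundance multipliers so the
ANOVA layer has real between-genome signal (or a true null) to work with.

Two properties make the truth tables *exact* rather than probabilistic:

* the background is generated i.i.d. at a target GC fraction and then locally
  re-rolled until it contains zero occurrences of every forbidden motif, so
  background never contributes counts;
* panel truth is the exhaustive brute-force scan of the final sequence, which
  by construction captures every occurrence the planting implies — including
  the overlapping occurrences of periodic motifs and the occurrences of one
  motif inside another's tract when the two are cyclic rotations (planting
  ``TAGATAGA...`` necessarily plants ``AGAT`` and ``GATA`` occurrences too).

Defaults model the tetranucleotide SSR density of a primate unplaced
chromosome: GC fraction 0.41, about 8 tandem tracts per motif per 100 kb
window, and geometrically distributed copy numbers (mean 2) so long tracts
occur but are rare.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import RetryLimitError
from .search import (
    DEFAULT_MOTIFS,
    CountMatrix,
    MotifPattern,
    naive_find_occurrences,
)
from .sequence_io import GenomeSequence, write_fasta

__all__ = [
    "PlantSpec",
    "Panel",
    "generate_background",
    "plant_runs",
    "generate_panel",
    "write_panel",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _base_probs(gc_fraction: float) -> np.ndarray:
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    return np.array([at, gc, gc, at])  # order A, C, G, T


def _draw_bases(rng: np.random.Generator, n: int, gc_fraction: float) -> np.ndarray:
    idx = rng.choice(4, size=n, p=_base_probs(gc_fraction))
    return _BASES[idx]


def _scan_bytes(arr: np.ndarray, motif: str) -> np.ndarray:
    """All 0-based occurrence starts of ``motif`` in a uint8 residue array."""
    m = len(motif)
    n = arr.size
    if m > n:
        return np.empty(0, dtype=np.int64)
    mot = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
    mask = arr[: n - m + 1] == mot[0]
    for k in range(1, m):
        mask &= arr[k : n - m + 1 + k] == mot[k]
    return np.nonzero(mask)[0]


def generate_background(
    length: int,
    gc_fraction: float = 0.41,
    seed: int | np.random.Generator = 0,
    forbid: Sequence[str] = (),
    *,
    max_sweeps: int = 100,
) -> str:
    """I.i.d. background sequence guaranteed free of the forbidden motifs.

    Residues are drawn independently with ``P(G) + P(C) = gc_fraction``.
    After the initial draw, each occurrence of a forbidden motif has one of
    its bases re-rolled; the sweep repeats until no forbidden occurrence
    remains (a :class:`RetryLimitError` after ``max_sweeps`` sweeps guards
    against infeasible forbid sets).  Fully deterministic per seed.
    """
    if length < 0:
        raise ValueError("length must be >= 0")
    rng = np.random.default_rng(seed)
    arr = _draw_bases(rng, length, gc_fraction)
    forbid = [str(m).upper() for m in forbid]
    if length == 0 or not forbid:
        return arr.tobytes().decode("ascii")
    for _ in range(max_sweeps):
        reroll: list[int] = []
        for motif in forbid:
            starts = _scan_bytes(arr, motif)
            if starts.size:
                offs = rng.integers(0, len(motif), size=starts.size)
                reroll.extend((starts + offs).tolist())
        if not reroll:
            return arr.tobytes().decode("ascii")
        pos = np.unique(np.asarray(reroll, dtype=np.int64))
        arr[pos] = _draw_bases(rng, pos.size, gc_fraction)
    raise RetryLimitError(
        f"could not purge forbidden motifs {forbid} within {max_sweeps} sweeps"
    )


@dataclass(frozen=True)
class PlantSpec:
    """Plan for planting tandem runs of one motif into a background.

    ``runs`` is a sequence of ``(start, copies)`` pairs; run intervals
    ``[start, start + copies*m)`` must not overlap and must fit inside
    ``background_length``.  ``seed`` drives the junction repair re-rolls.
    """

    motif: str
    runs: tuple[tuple[int, int], ...]
    background_length: int
    seed: int = 0
    gc_fraction: float = 0.41

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "runs", tuple((int(s), int(c)) for s, c in self.runs)
        )
        m = len(self.motif)
        if m == 0:
            raise ValueError("motif must be non-empty")
        intervals = sorted(
            (s, s + c * m) for s, c in self.runs
        )
        for (s, e), (s2, e2) in zip(intervals, intervals[1:]):
            if s2 < e:
                raise ValueError(f"planted runs overlap: [{s},{e}) and [{s2},{e2})")
        for s, c in self.runs:
            if c < 1:
                raise ValueError("copies must be >= 1")
            if s < 0 or s + c * m > self.background_length:
                raise ValueError(
                    f"run at {s} (copies {c}) exceeds background length "
                    f"{self.background_length}"
                )

    @property
    def intervals(self) -> list[tuple[int, int]]:
        m = len(self.motif)
        return sorted((s, s + c * m) for s, c in self.runs)


def plant_runs(
    background: str, spec: PlantSpec, *, max_repairs: int = 100
) -> tuple[str, tuple[int, ...]]:
    """Write the planted tandem runs into ``background``.

    Returns ``(sequence, truth_starts)`` where ``truth_starts`` are all
    occurrence starts whose window lies fully inside a planted interval —
    including the overlapping occurrences a periodic motif implies.  The
    background is expected to be free of the motif; any *junction* occurrence
    straddling a planted-interval boundary is removed by re-rolling one
    adjacent background base (bounded by ``max_repairs``), so after return
    the full-sequence occurrence set equals the truth exactly.
    """
    if len(background) != spec.background_length:
        raise ValueError("background length does not match the spec")
    m = len(spec.motif)
    arr = np.frombuffer(background.encode("ascii"), dtype=np.uint8).copy()
    unit = np.frombuffer(spec.motif.encode("ascii"), dtype=np.uint8)
    for s, c in spec.runs:
        arr[s : s + c * m] = np.tile(unit, c)

    intervals = spec.intervals
    starts_cover = np.zeros(arr.size + 1, dtype=bool)
    for s, e in intervals:
        starts_cover[s:e] = True

    def inside(p: int) -> bool:
        return bool(starts_cover[p])

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x9E37]))
    for _ in range(max_repairs):
        found = _scan_bytes(arr, spec.motif)
        truth = [int(p) for p in found if starts_cover[p : p + m].all()]
        spurious = [int(p) for p in found if not starts_cover[p : p + m].all()]
        if not spurious:
            return arr.tobytes().decode("ascii"), tuple(truth)
        for p in spurious:
            free = [q for q in range(p, p + m) if not inside(q)]
            if not free:
                raise RetryLimitError(
                    f"junction occurrence at {p} has no background base to re-roll"
                )
            q = int(rng.choice(free))
            arr[q] = _draw_bases(rng, 1, spec.gc_fraction)[0]
    raise RetryLimitError(
        f"could not repair junction occurrences within {max_repairs} passes"
    )


@dataclass(frozen=True)
class Panel:
    """A simulated multi-genome panel with its exact truth tables."""

    genomes: tuple[GenomeSequence, ...]
    truth_starts: Mapping[tuple[str, str], tuple[int, ...]]
    truth_counts: CountMatrix
    planted: pd.DataFrame  # genome, motif, start, copies
    params: dict = field(repr=False)


def _place_runs(
    rng: np.random.Generator,
    length: int,
    spans: list[int],
    *,
    max_attempts_factor: int = 200,
) -> list[int]:
    """Uniform non-overlapping starts for intervals of the given spans."""
    occupied: list[tuple[int, int]] = []
    starts: list[int] = []
    budget = max_attempts_factor * max(1, len(spans))
    import bisect

    for span in spans:
        if span > length:
            raise RetryLimitError("planted run longer than the genome")
        placed = False
        while budget > 0:
            budget -= 1
            s = int(rng.integers(0, length - span + 1))
            e = s + span
            i = bisect.bisect_left(occupied, (s, e))
            ok = True
            if i > 0 and occupied[i - 1][1] > s:
                ok = False
            if ok and i < len(occupied) and occupied[i][0] < e:
                ok = False
            if ok:
                occupied.insert(i, (s, e))
                starts.append(s)
                placed = True
                break
        if not placed:
            raise RetryLimitError(
                "could not place planted runs without overlap; "
                "requested density is infeasible"
            )
    return starts


def generate_panel(
    n_genomes: int = 5,
    motifs: Sequence[str] = DEFAULT_MOTIFS,
    density_multipliers: Sequence[float] | None = None,
    genome_length: int = 1_000_000,
    window_size: int = 100_000,
    seed: int = 0,
    *,
    runs_per_window: float = 8.0,
    copies_geometric_p: float = 0.5,
    max_copies: int = 25,
    gc_fraction: float = 0.41,
) -> Panel:
    """Simulate a genome panel with controllable per-genome SSR density.

    Genome ``g`` receives, for each motif, ``Poisson(multiplier_g *
    runs_per_window * n_windows)`` tandem runs at uniform non-overlapping
    positions.  Each entry of ``density_multipliers`` is either a scalar
    applied to all motifs of that genome or a ``{motif: multiplier}`` mapping
    (missing motifs default to 1).  Copy numbers are geometric (success probability
    ``copies_geometric_p``, mean ``1/p``) truncated at ``max_copies``.  The
    background forbids every panel motif, so all occurrences stem from
    planting.  Truth tables are the exhaustive brute-force scan of each final
    sequence — exact, and inclusive of rotation-overlap occurrences between
    motifs.  Fully deterministic per ``seed``.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    motifs = [str(m).upper() for m in motifs]
    if len(set(motifs)) != len(motifs):
        raise ValueError("motifs must be unique")
    patterns = [MotifPattern(m) for m in motifs]
    if density_multipliers is None:
        density_multipliers = [1.0] * n_genomes
    density_multipliers = [
        dict(d) if isinstance(d, Mapping) else float(d) for d in density_multipliers
    ]
    if len(density_multipliers) != n_genomes:
        raise ValueError("need one density multiplier per genome")

    def _multiplier(g: int, motif: str) -> float:
        d = density_multipliers[g]
        mult = float(d.get(motif, 1.0)) if isinstance(d, dict) else d
        if mult < 0:
            raise ValueError("density multipliers must be >= 0")
        return mult
    n_windows = genome_length // window_size
    if n_windows < 1:
        raise ValueError("genome_length must cover at least one window")

    root = np.random.SeedSequence(seed)
    genome_seeds = root.spawn(n_genomes)

    genomes: list[GenomeSequence] = []
    truth_starts: dict[tuple[str, str], tuple[int, ...]] = {}
    planted_rows: list[dict] = []
    counts: dict[str, list[int]] = {}

    for g in range(n_genomes):
        rng = np.random.default_rng(genome_seeds[g])
        gid = f"genome{g:02d}"
        background = generate_background(
            genome_length, gc_fraction, rng, forbid=motifs
        )
        arr = np.frombuffer(background.encode("ascii"), dtype=np.uint8).copy()

        # sample all runs for this genome, then place them jointly so that
        # tracts of different motifs never overlap
        run_motifs: list[str] = []
        run_copies: list[int] = []
        for pat in patterns:
            mean_runs = _multiplier(g, pat.motif) * runs_per_window * n_windows
            k = int(rng.poisson(mean_runs)) if mean_runs > 0 else 0
            for _ in range(k):
                c = min(int(rng.geometric(copies_geometric_p)), max_copies)
                run_motifs.append(pat.motif)
                run_copies.append(c)
        spans = [len(mo) * c for mo, c in zip(run_motifs, run_copies)]
        starts = _place_runs(rng, genome_length, spans)
        for mo, c, s in zip(run_motifs, run_copies, starts):
            unit = np.frombuffer(mo.encode("ascii"), dtype=np.uint8)
            arr[s : s + len(mo) * c] = np.tile(unit, c)
            planted_rows.append(
                {"genome": gid, "motif": mo, "start": s, "copies": c}
            )

        sequence = arr.tobytes().decode("ascii")
        genome = GenomeSequence(gid, f"simulated length={genome_length}", sequence)
        genomes.append(genome)
        row = []
        for pat in patterns:
            occ = naive_find_occurrences(genome, pat)
            truth_starts[(gid, pat.motif)] = occ.starts
            row.append(len(occ))
        counts[gid] = row

    truth_counts = CountMatrix(
        pd.DataFrame.from_dict(counts, orient="index", columns=list(motifs)).astype(int)
    )
    planted = pd.DataFrame(
        planted_rows, columns=["genome", "motif", "start", "copies"]
    )
    params = {
        "n_genomes": n_genomes, "motifs": list(motifs),
        "density_multipliers": density_multipliers,
        "genome_length": genome_length, "window_size": window_size,
        "seed": seed, "runs_per_window": runs_per_window,
        "copies_geometric_p": copies_geometric_p, "max_copies": max_copies,
        "gc_fraction": gc_fraction,
    }
    return Panel(
        genomes=tuple(genomes), truth_starts=truth_starts,
        truth_counts=truth_counts, planted=planted, params=params,
    )


def write_panel(panel: Panel, out_dir) -> dict:
    """Write a panel to disk: one FASTA per genome, truth TSV, manifest JSON.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta_paths = {}
    for g in panel.genomes:
        p = out / f"{g.id}.fasta"
        write_fasta([g], p)
        fasta_paths[g.id] = p.name
    rows = []
    for (gid, motif), starts in sorted(panel.truth_starts.items()):
        for s in starts:
            rows.append({"genome_id": gid, "motif": motif, "start": s})
    pd.DataFrame(rows, columns=["genome_id", "motif", "start"]).to_csv(
        out / "truth.tsv", sep="\t", index=False
    )
    manifest = {"params": panel.params, "fasta": fasta_paths, "truth": "truth.tsv"}
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
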