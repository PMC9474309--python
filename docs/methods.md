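# Methods

## Search engine

The scanner performs exact, forward-strand matching of short repeat units
(motifs) against nucleotide text over `{A,C,G,T,N}` using the Boyer–Moore
machinery, with all coordinates 0-based and occurrence intervals half-open.

Three precomputed structures drive the search:

* **First-occurrence pre-scan.** The smallest alignment offset `i` with
  `text[i+m−1] == motif[m−1]` starts the search; if the motif's final
  character never appears at a valid alignment (or `m > n`), the motif
  cannot occur and the scan returns empty without examining the text
  further. Starting at any later offset could skip a genuine occurrence, so
  the smallest such offset is the only sound choice.
* **Bad-character table** `β(a)`: last 0-based index of `a` in the motif,
  `−1` if absent. After a mismatch at motif index `j` against text character
  `c`, the candidate shift is `j − β(c)`. `N` maps to the sentinel, so gap
  characters produce the maximal bad-character shift and can never match.
* **Strong good-suffix table** `γ[0..m]`, built from the border (prefix
  function) arrays of the motif (`τ`) and of its reversal (`τ′`): every slot
  is initialised to the motif's period `m − τ[m−1]` and improved, for each
  suffix length `k`, by the case-2 shift `k − τ′[k]` at slot `m − τ′[k]`.
  `γ[0]`, the shift after a full match, equals the period; this is what
  guarantees that overlapping occurrences of periodic motifs are all found.
  Every entry lies in `[1, m]`, so the search always advances (termination)
  and never jumps farther than one pattern length past the examined
  alignment.

The applied shift after a mismatch is `max(γ[j+1], j − β(c))`. Correctness
is not argued from the table construction alone: a brute-force
all-alignments scanner (vectorised over alignments) defines the reference
semantics, and the engine is required to agree with it exactly on randomized
texts, adversarial periodic motifs, and every simulated panel.

**Overlap policy.** All occurrences are reported and counted, including
overlapping ones. Counting tandem *runs* once is exposed separately
(`run_count`, and the BED score column carries each occurrence's run copy
number), so either convention can be read from the output. A tandem run is
a maximal chain of occurrences whose consecutive starts differ by exactly
`m`; its span in bases (`copies × m`) summarises tract length, and both the
per-run copy number and the per-genome maximum span are reported, since
"longest repeat tract" can reasonably mean either.

**Strand policy.** Motifs are matched exactly as given, forward strand
only; the default ten-motif panel already contains reverse-complement pairs
(e.g. `TAGA`/`TCTA`). `ssrscan scan --reverse-complement` adds the missing
reverse complements explicitly; it is off by default.

**Input normalisation.** FASTA residues are uppercased (soft-masked
lowercase is searched — masking conventions vary between assemblies and
silently skipping masked repeats would bias counts), `U` maps to `T`, and
any character outside `{A,C,G,T,N}` is rejected with its position. `N` is
retained and never matches. Reading is strict: text before the first `>`
header and records without residues are errors rather than silently
skipped.

## Observation units and the inference layer

Genome-scale SSR counts come as one number per (genome, motif); an ANOVA
needs replicates. The package defines the replicate as the per-motif
occurrence count in non-overlapping genomic windows (default 100 kb,
configurable; windows must be at least 10× the motif length, the trailing
partial window is dropped, and an occurrence belongs to the window
containing its start). This is an explicit modelling choice — windows are
treated as exchangeable sampling units of a genome's SSR density.

* **One-way, per genome:** counts grouped by motif (k = number of motifs),
  testing whether motifs differ in abundance within one genome.
* **One-way, per motif:** counts grouped by genome, testing whether genomes
  differ for one motif.
* **Two-way:** genome × motif with windows as replicates, balanced by
  truncating every genome to the minimum common window count (the balanced
  factorial decomposition is exact; unbalanced layouts are rejected rather
  than approximated). With one window per cell the additive model is
  fitted and the interaction is not estimable.
* **Tukey HSD** within each one-way family: interval half-width
  `q(1−α; k, df_w)/√2 · √(MS_w(1/nₐ+1/n_b))` (Tukey–Kramer for unequal
  sizes), rejection iff the interval excludes zero. The studentized-range
  quantile is memoised because scipy's `ppf` is expensive and the same
  (α, k, df) recurs across families.

F tail probabilities come from `scipy.stats.f`. Counts can optionally be
`log1p`-transformed before testing (`--transform`); the default is the
identity.

**Degenerate inputs.** Zero within-group (or residual) variance makes the
F denominator undefined; the package raises a degenerate-data error naming
the constant groups instead of returning an infinite statistic. The CLI
converts these into per-test error rows and continues with the remaining
tests.

**Decision rules.** The default rule rejects when `p < α`. A `paper`
compatibility rule implements the inverted inequality
(reject when `F < F_critical`) found in some published software output;
it exists purely so results produced under that convention can be
reproduced and compared, and the report records which rule was used.

## Synthetic panels

The generator produces the study conditions every integration test runs
under: multi-genome panels with planted SSR tracts and exact truth tables.

* **Background**: i.i.d. residues at GC fraction 0.41 (typical of primate
  genomic sequence). Occurrences of every panel motif arising by chance are
  removed by locally re-rolling one base per occurrence and re-scanning
  (bounded sweeps), so the background contributes exactly zero counts and
  truth tables are equalities, not probabilistic statements.
* **Planting**: per genome and motif, a Poisson number of tandem runs with
  mean `multiplier × runs_per_window × n_windows` (default 8 runs per
  100 kb window per motif — with geometric copy numbers this yields SSR
  densities of the order observed on primate unplaced chromosomes, roughly
  10⁵ occurrences of a ten-motif panel per 10⁸ bases); copy numbers are
  geometric with mean 2 (long tracts occur but are rare), truncated at 25;
  placements are uniform and non-overlapping across all motifs of the
  genome. Per-genome multipliers may be scalars or per-motif maps, so both
  global and motif-specific density contrasts can be planted.
* **Truth**: the exhaustive brute-force scan of the final sequence, per
  motif. This is exact by construction and deliberately includes two
  classes of "extra" occurrences the planting implies: overlapping
  occurrences of periodic motifs, and occurrences of one motif inside
  another's tract when the two are cyclic rotations (a `TAGA` tract
  contains `GATA` and `AGAT`). For the single-motif `plant_runs` primitive
  the stricter semantics holds: junction matches straddling a planted
  boundary are repaired by re-rolling an adjacent background base, so truth
  equals exactly the planted starts.
* **Determinism**: one seed sequence drives background, run sampling,
  placement and repair; identical seeds give byte-identical FASTA.

What passing tests on these panels shows: the engine finds exactly the
planted occurrences in realistic-density, realistic-length sequence, and
the inference layer detects planted density contrasts while staying
calibrated on null panels. What they do not show: behaviour under repeat
clustering, indel/substitution mutation within tracts, heterozygosity, or
soft-masked input — real assemblies differ in all four respects, and the
generator makes no attempt to model them.

## Numerical and design choices

* Internal coordinates and BED output are 0-based half-open; the
  human-readable report adds 1-based starts.
* The one-way decomposition is computed directly from the defining sums of
  squares (not via a regression fit); agreement with independent references
  (`scipy.stats.f_oneway`, `scipy.stats.tukey_hsd`, statsmodels `anova_lm`)
  is enforced in tests at 1e−8, but those libraries are cross-checks, never
  the implementation.
* Problem sizes in the self-contained verification script (1,000 × 10 kb
  texts for oracle equivalence; a 5 × 400 kb panel for planted recovery;
  10,000 replicates for type-I calibration) were chosen to give tight
  statistical resolution (±0.004 on a 0.05 rejection rate) while remaining
  desk-scale.
* Type-I calibration uses k = 11 groups of 10 windows, mirroring an
  eleven-genome comparison.
* Tie-breaking and edge cases: motif longer than text → empty result;
  empty occurrence set → zero runs and max span 0; window boundaries are
  half-open so a start at `i·w` belongs to window `i`.

## Known limitations

* Exact matching only: a single substitution inside a tract splits it into
  two runs; mismatch-tolerant SSR discovery (MISA-style) is out of scope.
* The windowed-replicate ANOVA treats windows as independent; genomic
  autocorrelation of repeat density will make p-values anti-conservative on
  real data. The calibration guarantees hold under the generator's
  Poisson-uniform placement, not under clustering.
* Variance-heterogeneity corrections (Welch), nonparametric alternatives
  and mixed models are intentionally not provided.
* Two-way analysis requires balance; genomes with very different lengths
  lose windows to truncation.
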