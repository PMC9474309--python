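# ssrscan

Exact scanning of genome sequences for simple sequence repeat (SSR /
microsatellite) motifs, and statistical comparison of SSR abundance across
genomes and motifs.

SSRs are tandem tracts of a short motif (here, 4 bp units such as `TAGA`)
whose copy number mutates rapidly; their density and tract lengths vary
between genomes and are widely used markers of genetic variation. `ssrscan`
is for researchers who want to (1) locate every exact occurrence of a motif
panel in chromosome-scale FASTA, (2) summarise occurrences into tandem runs
and genome × motif count tables, and (3) test whether SSR abundance differs
between genomes or motifs.

## What it computes

**Search engine.** Exact forward-strand matching with the Boyer–Moore
heuristics: a first-occurrence pre-scan (jump to the first alignment whose
rightmost character can match), the bad-character table
β(a) = last index of a in the pattern, and the strong good-suffix table γ
built from the border arrays τ (pattern) and τ′ (reversed pattern). After a
full match the window advances by the pattern's period m − τ[m−1], so
overlapping occurrences (e.g. `ATAT` in `ATATATAT`) are all reported. `N`
(assembly gap) never matches. A brute-force all-alignments scanner provides
independent reference semantics, and every simulated panel carries an exact
truth table the engine is checked against.

**Inference layer.** Occurrence counts in non-overlapping genomic windows
(default 100 kb) are the replicate observations. One-way ANOVA uses the
textbook decomposition

    SS_between = Σᵢ nᵢ (x̄ᵢ − x̄_G)²,  df = k − 1
    SS_within  = Σᵢⱼ (x_ij − x̄ᵢ)²,   df = N − k
    F = MS_between / MS_within,  p = P(F_{k−1,N−k} ≥ F)

Two-way ANOVA (genome × motif, balanced, windows as replicates) uses the
exact factorial decomposition with an interaction term when replicated.
Tukey HSD compares all group pairs with studentized-range intervals
q/√2 · √(MS_w(1/nₐ + 1/n_b)); a pair is rejected exactly when its interval
excludes zero. The default decision rule is the standard one (reject when
p < α); a `paper` compatibility rule with the inverted inequality is
available for traceability against prior published output.

## Worked example

Simulate a 3-genome panel in which the third genome has 4× SSR density,
scan it, and run the ANOVA layer:

```sh
ssrscan simulate --n-genomes 3 --genome-length 200000 --window-size 20000 \
        --multipliers 1,1,4 --seed 7 --out panel
ssrscan scan --fasta panel/genome00.fasta --fasta panel/genome01.fasta \
        --fasta panel/genome02.fasta --window-size 20000 --out scan
ssrscan anova --windows scan/window_counts.tsv --out anova
```

`scan/counts.tsv` (occurrence counts per genome and motif, with totals):

```
genome	TAGA	AGAA	GATA	TCTA	TCAT	GAAT	AGAT	CTTT	TATC	TCTG	total
genome00	414	203	382	245	180	221	396	143	246	171	2601
genome01	391	209	366	279	158	197	387	168	297	132	2584
genome02	1527	902	1389	995	677	825	1418	610	1052	599	9994
total	2332	1314	2137	1519	1015	1243	2201	921	1595	902	15179
```

genome02's ~4× counts reflect the planted density multiplier. Note that
rotation-related motifs (`TAGA`, `GATA`, `AGAT`) show correlated counts: a
`TAGA` tandem tract necessarily contains `GATA` and `AGAT` occurrences.

`anova/anova_report.tsv` (excerpt):

```
test_id	factor	f_statistic	p_value	reject
oneway_motif:TAGA	genome	214.25	2.71e-17	True
twoway:genome_x_motif	genome	1261.97	9.88e-138	True
twoway:genome_x_motif	motif	67.17	8.99e-64	True
twoway:genome_x_motif	interaction	14.11	1.54e-29	True
```

The across-genome test for `TAGA` rejects equality of means (F = 214.25 on
10 windows per genome), and the two-way decomposition attributes variance to
genome, motif, and their interaction. The Tukey family for that test flags
exactly the pairs involving the dense genome:

```
family	group1	group2	meandiff	lower	upper	reject
oneway_motif:TAGA	genome00	genome01	-2.3	-17.85	13.25	False
oneway_motif:TAGA	genome00	genome02	111.3	95.75	126.85	True
oneway_motif:TAGA	genome01	genome02	113.6	98.05	129.15	True
```

Per-occurrence output is BED6 (`scan/genome00.bed`): 0-based half-open
coordinates, motif as name, tandem-run copy number in the score column.
`ssrscan report` converts scan output into a human-readable table with
1-based starts added.

The default motif panel is the ten tetranucleotide SSRs `TAGA AGAA GATA
TCTA TCAT GAAT AGAT CTTT TATC TCTG`; any motif list over `{A,C,G,T}` can be
supplied with `--motifs`.

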