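# Methods

This note records the scientific model behind each stage of the package, the
parameters that matter, the numerical choices, what the synthetic-data
generators do and do not emulate, and the known limitations.

## IMGT position model and numbering

V-domain positions live on the IMGT unique numbering 1–128 with the
standard delimitations FR1 1–26, CDR1 27–38, FR2 39–55, CDR2 56–65,
FR3 66–104, CDR3 105–117, FR4 118–128. The nine β-strands carry fixed
position sets (module `imgt`); positions 10 and 73 are universal gaps of
the scheme and belong to no strand. The sheet partition {A, B, D, E} vs
{C, C′, C″, F, G} is what makes the canonical Cys23–Cys104 linkage (B–F)
*inter*-sheet and drives the intra/inter classification of every candidate
pair; it reproduces the intra/inter labelling of all 17 study libraries,
which is how it was fixed.

Numbering is template-based: a global alignment (BLOSUM62, gap open −11 /
extend −1, cheap end gaps) to a numbered template transfers framework
positions, after which each CDR is renumbered wholesale from its observed
length by the IMGT loop rule — a loop of length L in a slot of capacity N
occupies the first ⌈L/2⌉ and last ⌊L/2⌋ slots, leaving the gaps at the
apex. Tying CDR occupancy to loop length alone (rather than to alignment
detail inside the loop) makes the gapping deterministic. Sequences that
cannot anchor positions 23 and 104, fall outside 90–140 residues, or carry
framework insertions raise a `NumberingError` with an explicit record;
there are no silent partial mappings. This is a desk-scale stand-in for a
full germline-database annotator: it performs no V/D/J gene calling, no
junction analysis and no species-specific exceptions, and its built-in
template is a synthetic IMGT-complete VH-like sequence (gaps only at 10 and
73, CDRs at full capacity), not any individual germline. Templates with
other gap patterns can be supplied; the occupancy of 10/73 is a template
property, not a scheme constant.

## Library design

Theoretical diversity of a strand-pair library is the product of the two
strand sizes; enumeration is the Cartesian product in lexicographic order.
The built-in study slate is the 17-library configuration (7 intra-sheet,
10 inter-sheet) with the published functional library sizes attached;
expected per-pair copy number is functional size / diversity (minimum
≈ 29 over the slate). The three libraries containing previously known
linkages (B–F with 23–104, C–C′ with 40–55, C′–D with 54–78) are flaggable
but their pairs stay in enumeration, mirroring the study's exclusion of
whole test libraries rather than of individual pairs.

Mutagenic oligos follow Kunkel-style chemistry: each oligo is the reverse
complement of the mutated coding-strand window (it anneals to the
phage-strand dU-ssDNA), with parent-matching flanks. Defaults — Cys codon
TGC, 15 nt flanks, one oligo when the target codons start within 60 nt,
else two — are conventional choices for annealing-based mutagenesis, not
published values, and are configurable. Designs are validated in silico:
applying the oligo(s) and translating must change exactly the targeted
residues, both to Cys. No melting-temperature or secondary-structure
optimisation is attempted.

## Clone QC

Clones are compared to the parent position-by-position on the IMGT
alignment. Exactly the two designed Cys substitutions → `correct_pair`;
exactly one Cys at a library position → `single_cys`; no differences →
`unmodified`; everything else — extra mutations, non-Cys changes, Cys
outside the library grid — is `off_target`, a conservative choice since
the source percentages do not define that subclass. DNA-level silent
differences are invisible because classification is at the protein level
(DNA inputs are translated first). Unnumberable clones are counted and
reported, never dropped. The per-pair count matrix's marginals equal the
per-position substitution counts by construction.

## Panning

Titer: virions/ml = (A₂₆₉ − A₃₂₀) × 10¹⁶ / genome bases. Enrichment is
summarised per pair as round frequencies, fold change versus round 1
(flagged undefined when the initial frequency is zero — no pseudocounts)
and final-round rank with stable position-order tie-breaking. Because no
numeric enrichment criterion is published, candidate calling defaults to
final-round frequency ≥ 0.05 with a nondecreasing last-to-final round, and
the rule applied is echoed in the output; the rule is monotone in the
frequency threshold. The heat-treatment condition (30 min at 50 °C before
each round) is carried as metadata only — no temperature effect is
modelled.

## Geometry screen

A pair is plausible when its Cα–Cα distance lies in the closed window
[4.0, 7.0] Å; the interval endpoints are included because the source
range "4–7 Å" states no endpoint semantics. The ~90° dihedral criterion
has no usable tolerance and real χ-ss dihedrals need sulfur atoms that
pre-mutagenesis structures lack, so the default screen is distance-only;
an optional Cβ-based proxy dihedral (|Cβ–Cα–Cα–Cβ|, tolerance ±30°) is
available and labelled heuristic. PDB chains are renumbered through the
same IMGT numbering path (author numbering is never trusted); altlocs
resolve by highest occupancy; pairs with missing coordinates are listed
separately, not scored. Ranking orders pairs by distance from the window
midpoint (5.5 Å).

## Repertoire census

Positions 23/104 are disregarded in every noncanonical statistic. Region
frequencies are the fraction of units with ≥ 1 noncanonical Cys in that
region; both whole-domain and FR-only per-unit Cys-count histograms are
reported because the published per-read histogram does not state which it
counts. The "≥ 4 FR Cys" subset counts all framework Cys *including* the
canonical pair (four Cys total = canonical two plus one noncanonical FR
pair). Co-occurrence sums weight 1 for every unordered noncanonical FR
Cys pair in each subset unit, keyed by strand (non-strand FR positions bin
as "FR-other"), emitted as a Circos-compatible three-column table.
Statistics default to per unique amino-acid sequence (configurable to per
read). Because repertoire amplification primers force the strand-A
N-terminus and strand-G C-terminus, a default mask suppresses positions
{1, 2, 3} and {126, 127, 128} — the exact primer-forced extent is not
published, so the mask is configurable. Reads failing numbering are
counted and excluded.

## Melt curves and statistics

The CD melt model is the four-parameter Boltzmann sigmoid. The fit is a
bounded least squares (`scipy.optimize.curve_fit`) initialised with Tm at
the half-range crossing and slope from the 25–75% span (≈ 2.2 slope units);
Tm is constrained to the observed temperature range. Percent-scale
normalisation is taken over the fitted plateaus rather than the raw
extremes, which makes it robust to endpoint noise; since whether the
original analysis pinned plateaus to 0/100 after normalisation is unstated,
both modes exist and the default leaves plateaus free. A fit must beat a
flat line on AIC or it is refused (`FitError`) — no Tm is reported for
non-sigmoidal data. The fit assumes the analysed signal increases with
unfolding (the generator's convention); descending raw ellipticity traces
should be negated by the caller.

The α-value is the second melt's upper plateau over the first's after
normalising both on the first melt's fitted scale, so identical curves give
exactly 1 and a second melt reaching 80% of the first's plateau gives 0.8.

DSF Tm is the grid temperature of the maximum first derivative (central
differences; optional odd moving-average smoothing), resolved to one grid
step (0.5 °C on the default grid); flat or linear traces are refused.

The exact signed-rank test drops zero deltas (with the count reported),
assigns midranks to tied magnitudes, and computes the null distribution of
W⁺ over all 2ⁿ sign assignments exactly by dynamic programming on the
doubled (integer) ranks — algebraically identical to literal enumeration
but feasible at the n ≤ 25 sizes the pipeline meets. The two-sided p is
the null probability of a deviation from the mean at least as large as
observed (equal to twice the smaller tail by symmetry, capped at 1).
Fisher's exact test sums hypergeometric point probabilities ≤ the observed
table's; degenerate margins return p = 1 flagged as no association. K_D
deltas are reported as engineered/wild-type ratios (> 1 = weaker binding)
and tested on log-ratios; Tm, α and monomer deltas are plain differences.

## Synthetic data

The generators exist so the full pipeline runs and is testable with no
external data, under the study's stated conditions: clone pools default to
the 70/14/16% composition; pannings run four rounds; melt grids span
25–106 °C at 0.5 °C as in the CD protocol. All randomness flows from a
single seed and identical configuration + seed gives identical output.

What they emulate — and what they do not:

- **Clone pools** draw classes i.i.d. and pairs uniformly; no mutagenesis
  position bias (the study saw one library with end-biased incorporation),
  no sequencing error, no chimeras.
- **Panning** is multinomial resampling with probabilities ∝ frequency ×
  fitness: a one-parameter-per-pair caricature with no phage biology
  (display level, elution, infectivity, inter-round amplification bias).
- **Repertoires** are template-derived with independent per-position Cys
  substitutions and doped pairs; there is no germline diversity, somatic
  hypermutation structure, or CDR length variation, so census recovery
  results demonstrate the counting machinery, not performance on real
  repertoire complexity.
- **Melt curves** are exactly Boltzmann plus Gaussian noise — fitting them
  shows estimator calibration under the model, not robustness to real CD
  baseline drift or aggregation artefacts.
- **Coordinates** come either from explicit placements or an idealised
  two-sheet lattice (strands as straight rows, configurable spacings); the
  lattice ignores the β-sandwich twist and is only a closed-loop harness
  for the screen.

Passing recovery tests on these inputs therefore validates the analysis
code paths and their statistical calibration under the stated models; it
does not certify performance on experimental data.

## Problem sizes and tolerances

The recovery analyses run at sizes chosen to make their statistical bounds
meaningful while keeping the whole suite quick: 100 melt replicates at
noise sd 2% of range (tolerance |ΔTm| ≤ 0.5 °C), clone QC at n = 500
against exact binomial 95% intervals, panning at depth 10⁴ × 100 seeded
runs, census at 10⁴ reads with a 1% doped pair against exact binomial
bounds, and exact-test validation over all signed-rank inputs to n = 10 and
all 2×2 tables with margins ≤ 12.

## Known limitations

- The numbering module is alignment-based and template-relative; heavily
  divergent or insertion-bearing frameworks are rejected rather than
  numbered approximately.
- The geometry screen evaluates backbone feasibility only; it cannot
  distinguish pairs that fail for rotameric or chemical (pKa/redox)
  reasons, and no ΔΔG or rotamer modelling is attempted.
- The candidate-calling rule and the clone-QC off-target convention are
  package choices where the source is silent; both are configurable and
  reported in outputs.
- SPR kinetic fitting, SEC-MALS mass computation, LC-MS label counting and
  densitometry are out of scope: their outputs enter only as numbers to be
  summarised by the Δ statistics.
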