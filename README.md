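# cysscan

Computational design and analysis for exhaustive **cysteine-pair scanning of
immunoglobulin variable-domain frameworks** — the strategy of engineering
noncanonical intradomain disulfide linkages into the β-sandwich scaffold of
V_H/V_L/V_HH domains and reading the results out by phage-display selection,
structural screening, repertoire sequencing and biophysical characterisation.

It is written for antibody engineers and computational immunologists who
need the desk-side half of such a campaign: enumerate the libraries, design
the mutagenic oligos, QC the sequenced clones, quantify the pannings, screen
candidate pairs on structures, census a natural repertoire for the same
pairs, and fit/summarise the stability measurements.

## The model

Positions follow the IMGT unique numbering (1–128). The nine framework
β-strands occupy fixed position sets (A: 1–9, 11–15; B: 16–26; C: 39–46;
C′: 47–55; C″: 66–72, 74; D: 75–84; E: 85–96; F: 97–104; G: 118–128) and
partition into the two sheets of the Ig fold, {A, B, D, E} and
{C, C′, C″, F, G}. The canonical intradomain disulfide joins Cys23
(strand B) to Cys104 (strand F); any other framework Cys pair is a
*noncanonical* candidate, *intra-* or *inter-β-sheet* according to the
sheet partition.

A scan library over strands *X*, *Y* holds every mutant with one Cys in
each strand, so its theoretical diversity is |X|·|Y| and the functional
library size is cfu × (fraction of clones correctly mutagenized). Phage
titers follow (A₂₆₉ − A₃₂₀) × 10¹⁶ / (bases in genome). Disulfide
plausibility on a structure requires a Cα–Cα distance in the closed window
[4, 7] Å (optionally a ~90° dihedral proxy). CD melts are fitted to the
Boltzmann sigmoid

    y(T) = lower + (upper − lower) / (1 + exp((Tm − T)/slope))

DSF takes Tm at the maximum d(signal)/dT; refolding efficiency α is the
ratio of second-melt to first-melt upper plateau on a shared scale. Paired
wild-type/engineered comparisons use the exact two-sided Wilcoxon
signed-rank test and expression proportions use Fisher's exact test, both
by full enumeration of the null.

## Worked example

```python
from cysscan import build_manifest, classify_pair, fit_boltzmann
from cysscan.synthetic import gen_melt

manifest = build_manifest()          # the 17-library study slate
print(len(manifest), manifest.count_by_category())
lib = manifest.by_name("C'-D")
print(lib.theoretical_diversity, round(lib.expected_copies(), 1))

print(classify_pair(6, 119).category, classify_pair(4, 25).category)

res = fit_boltzmann(gen_melt(tm=65.0, slope=2.5, noise_sd=2.0, seed=5))
print(round(res.tm, 2))
```

prints

```
17 {'intra': 7, 'inter': 10}
90 35.6
inter_sheet intra_sheet
65.1
```

— the full slate of 7 intra-sheet plus 10 inter-sheet libraries; the C′–D
library's 90 Cys pair combinations, each expected ≈ 35.6 times given its
functional size of 3.2 × 10³; the sheet topology of two of the enriched
pairs (Cys6–Cys119 bridges the sheets, Cys4–Cys25 stays within one); and a
Tm of 65.1 °C recovered from a noisy synthetic melt generated at 65.0 °C.

The same functionality is exposed on the command line:

```bash
cysscan design --out design/                 # manifest (+ oligos with --parent)
cysscan simulate clones --library "C'-D" --n 500 --seed 1 --out clones.fasta
cysscan qc --parent parent.fasta --library "C'-D" clones.fasta
cysscan simulate repertoire --n 10000 --dope 40,55:0.01 --seed 1 --out reads.fasta
cysscan census --in reads.fasta
cysscan melt fit melt.csv
```

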