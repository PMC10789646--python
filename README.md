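# xlquant

Quantitative post-processing for photo-cross-linking interactome studies.

In a photo-cross-linking experiment, a bait protein (here the motivating
case is a bromodomain carrying a photo-reactive unnatural amino acid)
covalently traps its binding partners under UV irradiation; label-free
LC-MS/MS of paired +UV and −UV samples then reveals the partners as
proteins enriched — or detected exclusively — under UV.  `xlquant`
implements the analysis chain downstream of the search engine, plus the two
companion analyses such a study leans on:

1. **Proteomics enrichment** — read MaxQuant-style `proteinGroups` tables,
   remove contaminant/decoy entries (retaining only-identified-by-site
   rows), merge proteins sharing >30% of their peptides, normalize iBAQ to
   compositional riBAQ under a present-in-both-replicates rule, and
   classify every group as exclusive to one condition or common, with fold
   enrichment FC = mean riBAQ₊/mean riBAQ₋ and a two-sided t-test on
   log₂ riBAQ (high-confidence call: p ≤ 0.05 and FC ≥ 2).
2. **One-site ITC** — forward-simulate and fit the one-set-of-sites
   (Wiseman) isotherm with perfusion-cell dilution corrections, recovering
   N, K_D, ΔH and the derived ΔG = RT·ln K_D and −TΔS = ΔG − ΔH.
3. **Peak colocalization** — asymmetric peak-overlap fractions,
   three-perspective Venn classification, ±5 kb TSS-anchored signal
   matrices (tornado-plot input) and genome-wide binned-signal correlation.

Every stage has a synthetic-data generator with ground-truth labels
(`xlquant.simulate`), so the full pipeline is testable and benchmarkable
with no external downloads.  See `docs/methods.md` for the models,
assumptions and numerical choices.

## Worked example

`examples/` holds one narrative script per capability.
`python examples/itc_binding.py` simulates a noisy titration of an
acetylated peptide into a 90 μM bromodomain solution (one 0.4 μl priming
injection, then 18 × 2 μl, 15 °C) with a true K_D of 24.6 μM, and fits it:

```
fitted one-site parameters (truth in parentheses):
  N      =  0.998  +/- 0.023   (1.0)
  Kd     =  20.26 +/- 2.81 uM (24.6)
  dH     =  -7.88 +/- 0.38 kcal/mol (-8.5)
  dG     =  -6.19 kcal/mol
  -T.dS  =   1.69 kcal/mol
```

The fitted K_D lands within ~2 standard errors of the truth at 0.5 μcal
heat noise; the negative ΔG with ΔH < 0 is the signature of enthalpy-driven
acetyllysine recognition.  `python examples/interactome_enrichment.py`
runs the proteomics chain on a simulated ±UV cohort (400 background
proteins, 25 spiked 8× interactors, 20 UV-exclusive partners) and prints

```
Venn partition (groups present in +UV only / -UV only / both):
  n_exclusive_plus: 21
  n_exclusive_minus: 2
  n_common: 396
  n_common_enriched: 20
...
spiked-truth recovery: 40/45 true partners called, 1 false calls
```

i.e. the exclusive-plus-enriched call set recovers 89% of the spiked truth
with one false call.  `python examples/peak_colocalization.py` does the
same for the genomics summaries.

A thin CLI wraps the same functions for shell use:

```sh
xlquant simulate proteomics --seed 1 --out-dir sim
xlquant enrich --protein-groups sim/proteinGroups.tsv --design sim/design.tsv \
        --p 0.05 --fc 2.0 --share 0.30 --out-dir results
xlquant itc simulate --kd 25 --out iso.csv   &&   xlquant itc fit iso.csv
xlquant coloc overlap a.bed b.bed
```

Identical invocations are byte-identical: outputs carry a config hash but
no timestamps, and all randomness flows from `--seed`.

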