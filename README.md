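# qtap — differential AP-MS interactomics with a degrading bait

`qtap` post-processes label-free quantitative affinity-purification
mass-spectrometry (AP-MS / TAP-MS) experiments that compare a bait protein's
interactome between two conditions — typically a *mock* versus *treatment*
pulldown with four replicates each. Its target use case is the hard one: a
bait that is itself **degraded** by the treatment (e.g., a hormone-induced
proteasome target such as the strigolactone-signaling repressor SMXL7), so
that every co-purifying prey drops with the bait and naive abundance testing
mostly reports the bait's loss rather than genuine interaction dynamics.

## What it computes

Starting from a MaxQuant-style `proteinGroups.txt` (protein groups × samples,
"LFQ intensity"/"Intensity" columns, decoy/contaminant flags) and a sample
design, the pipeline runs, in order:

1. removal of reverse-database hits, contaminants and site-only IDs;
2. log2 transform of the intensities (raw 0 ⇒ missing);
3. **bait normalization** (intensity arm only): per sample, the bait's log2
   intensity is subtracted from every protein, re-expressing preys relative
   to the bait — a prey bound at constant stoichiometry becomes flat, a prey
   whose absolute level is constant appears treatment-enriched by exactly
   the bait's drop;
4. valid-value filter: keep proteins with ≥ `min_valid` (default 4)
   quantifications in at least one group;
5. replicate QC: pairwise Pearson correlations on observed values;
6. left-censored imputation: missing cells drawn from
   N(μ − d·σ, (w·σ)²) per sample (d = 1.8, w = 0.3), or from a normal
   centered on the observed minimum (`min_centered`);
7. moderated two-group testing: per protein,
   `D = mean(mock) − mean(treatment)`, `d* = D / (s + S0)` with the pooled
   two-sample standard error `s` and `S0 = 0.1` (SAM-style moderation), plus
   the unmoderated Student *t* and *p*;
8. **permutation-based FDR**: the null of `d*` over all distinct group-label
   reassignments (exhaustive for 4v4: C(8,4) − 1 = 69), with
   `FDR(c) = mean permuted exceedances / observed exceedances` made monotone
   by a running minimum; the smallest `c` with `FDR(c) ≤ 0.05` is the
   significance threshold;
9. a volcano table/plot of `log2(mock/treatment)` against `−log10 p`.

A first-class synthetic-data module generates ground-truthed pulldowns —
a degrading bait, constitutive (constant-stoichiometry) preys,
treatment-recruited preys (receptor-like, below the detection limit under
mock), mock-enriched released preys (corepressor-like), degradation-machinery
preys, stable background binders, log-normal abundances, Gaussian replicate
noise, and logistic left-censored missingness — so every stage and every
statistical guarantee is testable without raw MS data.

## Worked example

Simulate an experiment and analyze it with both arms:

```bash
qtap simulate --seed 4 --out example/
qtap -v run --protein-groups example/proteinGroups.txt \
            --design example/design.tsv --mode both --seed 4 --out run/
```

which logs

```
INFO qtap: lfq arm: flagged-row filter 291 -> 281 rows
INFO qtap: lfq arm: valid-value filter 281 -> 268 rows
INFO qtap: lfq arm: 11/268 rows significant (|d*| >= 3.417)
INFO qtap: intensity arm: flagged-row filter 291 -> 281 rows
INFO qtap: intensity arm: valid-value filter 281 -> 268 rows
INFO qtap: intensity arm: 260/268 rows significant (|d*| >= 2.165)
run complete: run
```

The LFQ arm calls 11 proteins — the strong absolute changes (recruited and
released preys). After bait normalization the intensity arm calls 260: every
prey that did **not** drop with the degrading bait now shows a
treatment-side shift of ≥ 1.5 log2 relative to the bait, which is precisely
how bait normalization surfaces candidate interactors of a degrading bait
(at the cost of false positives among stable background binders — the
candidate list is a screening set, not a validated interactome). The top of
`run/intensity/results.tsv`:

```
group_id   mean_mock  mean_treatment  difference  t_statistic  p_value   significant
RECR0005   -6.81      3.40            -10.21      -21.92       5.9e-07   True
RECR0001   -6.92      1.82            -8.74       -16.56       3.1e-06   True
```

(recruited preys sit far on the treatment-enriched side, like a receptor
recruited to the complex only under hormone treatment), and the replicate QC
(`run/lfq/qc_summary.txt`) reports

```
within-group Pearson r: min=0.867 max=0.917 (12 pairs)
```

Each run directory also contains the imputation audit trail
(`imputed_values.tsv`), the volcano image, the bait-normalization state and
the fully resolved `config.yaml`, from which the run re-executes
byte-identically.

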