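# nirscausal

Directed ("effective") connectivity analysis for developmental fNIRS
studies, built around the question of how children's cortical networks for
own- versus other-race face recognition change with age.

## The problem and the method

A cohort of children (ages ~3–13) each performs two face-recognition tasks
(own-race and other-race faces) while a 46-channel fNIRS montage — 24
channels over the frontal cortex, 22 over the occipital cortex — records
oxygenated-hemoglobin concentration changes at 10 Hz. The analysis asks
three questions per directed channel pair: does coupling change with age,
does it differ between face-race conditions, and does the race difference
itself develop with age (the *neural other-race effect*, NORE)?

The chain implemented here:

1. **Preprocessing** (`nirscausal.preprocess`) — each channel is low-pass
   filtered with the canonical double-gamma hemodynamic response function,
   detrended (DCT high-pass, 128 s cutoff, or a wavelet/MDL variant), and
   baseline-corrected by the line through the 2 s pre-/post-task window
   means.
2. **Pairwise Granger causality** (`nirscausal.gca`) — for channels A, B
   and a BIC-selected common order *p*, nested least-squares AR models give

   `G(B→A) = ln( σ²[A | past of A] / σ²[A | past of A, past of B] ) ≥ 0`

   producing one 46×46 causal map per participant per condition.
3. **Edge-level group inference** (`nirscausal.groupstats`) — per directed
   edge, a repeated-measures ANOVA (race within-subject × continuous age)
   via the exact difference/mean-score reduction, df (1, N−2), with
   partial η² = F/(F + N − 2). The observed statistic is the mean η² over
   B random 50% participant subsamples; significance uses a permutation
   null (fair-coin scrambling of each participant's two condition labels)
   with the top-5% rule. `RaceAgeAnova` / `ConnectivityStudy` are the
   model objects; their `fit()` returns results objects with `summary()`.
4. **Network reporting** (`nirscausal.netreport`) — significant edges are
   assembled into directed networks, classified by area pair
   (intra-frontal / intra-occipital / frontal→occipital /
   occipital→frontal) and developmental trend subtype, and exported as
   GraphML + TSV (+ optional diagrams).

No recordings from the original study are publicly available, so the
package ships a first-class synthetic cohort generator
(`nirscausal.synthcohort`): VAR signals with *planted* directed couplings
whose strength depends on age, condition, and their interaction, plus
cardiac/respiratory/Mayer-wave/slow-drift nuisance components. The
generator emits a ground-truth ledger so recovery can be scored.

## Worked example

Generate a small cohort with one planted interaction edge (channel 1 → 4,
coupling `0.08 + 0.02·age` under the own-race condition only), run the full
chain, and inspect the planted edge:

```python
from nirscausal import (SynthConfig, PlantedEdge, generate_cohort,
                        preprocess, causal_map, ConnectivityStudy, RaceAgeAnova)

cfg = SynthConfig(n_participants=24, n_channels=6,
                  planted=(PlantedEdge(1, 4, base=0.08, inter_slope=0.02),),
                  seed=7)
cohort = generate_cohort(cfg)
maps = [causal_map(preprocess(rec), p_max=10) for rec in cohort.recordings]
study = ConnectivityStudy.from_causal_maps(maps)
results = study.fit(b_boot=500, b_perm=500, seed=0)
print(results.summary())

k = study.edges.index((1, 4))
edge = RaceAgeAnova(study.weights_own[:, k], study.weights_other[:, k], study.ages)
print(edge.fit(b_boot=500, b_perm=500, seed=0).summary())
```

prints

```
Connectivity study: race x continuous-age edge inference
N participants: 24   directed edges: 30
resampling: {'b_boot': 500, 'b_perm': 500, 'frac': 0.5, 'seed': 0, 'null_stat': 'averaged', 'b_inner': 100}
significant age          edges: 3
significant race         edges: 2
significant interaction  edges: 2

Repeated-measures race x continuous-age ANOVA
N participants: 24   df per effect: (1, 22)
effect               F         p   eta_p^2  boot eta2   perm p  sig
age              7.935    0.0100    0.2651     0.3013   0.0060 True
race           149.685    0.0000    0.8719     0.8800   0.0020 True
interaction     16.880    0.0005    0.4342     0.4497   0.0020 True
NORE-age Pearson r = 0.6589 (p = 0.0004629)
```

The planted edge is flagged for all three effects — its coupling grows with
age, is stronger under the own-race condition at every age, and the race
difference widens with age — and its per-participant NORE (own − other
weight) correlates positively with age, which is exactly the planted
`inter_slope > 0` structure.

A YAML-driven CLI wires the same stages end to end
(`nirscausal run-all -c config.yaml`; stages: simulate, preprocess, gca,
stats, report), dumping every stage's effective configuration and hash next
to its outputs.

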