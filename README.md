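# txnkinetics

Stochastic simulation and FRAP analysis of mRNA retention kinetics at
MS2-tagged transcription sites.

## The problem

A reporter gene array carrying MS2 stem-loops in its 3'UTR makes a single
transcription site visible in a living nucleus, and photobleaching that spot
(FRAP) reads out how fast nascent mRNA is made and released. On such
reporters, a spliced transcript does not leave the gene the moment
transcription ends: it is *retained* at the site until splicing is
completed. The intron-rich E6 reporter (6 exons / 5 introns) releases its
mRNA slowly (retention ≈ 11 min), while the shorter E3 (3 exons / 2 introns)
— or E6 when the kinase Clk1 floods the nucleoplasm with hyper-phosphorylated
splicing factors — releases quickly (≈ 50 s). This package implements the
kinetic machinery needed to reason about those observations end-to-end on
synthetic data:

* a Monte-Carlo simulator of the gene array — initiation, elongation with
  stochastic pausing, stochastic termination, post-termination retention,
  MS2 fluorescence accumulation, and co-transcriptional splicing modeled as
  positional intron depletion (an intron's signal disappears once the
  polymerase is 750 bp past its 3' end; 500 bp under Clk1);
* in-silico FRAP (bleach at steady state, sample on the experimental
  acquisition schedule) and steady-state intron/exon FISH snapshots, with
  closed-form stationary oracles for both;
* the FRAP analysis pipeline: double normalization of raw traces,
  mono/bi-exponential fitting with model selection
  `f(t) = y0 + Σ A_j (1 − e^(−k_j t))`, permutation comparison of
  conditions with Benjamini–Hochberg FDR, and retrieval of the retention
  time by fitting the simulator to an observed curve;
* synthetic-data generators (replicate FRAP traces with acquisition
  bleaching and day effects; noisy FISH tables) that return their ground
  truth, so every estimator has a recovery target.

The model and its parameters are documented in `docs/methods.md`.

## Worked example

Which retention time explains an observed recovery curve? Simulate an
"observed" E6 experiment at the slow retention and ask the simulator which
grid value reproduces it:

```python
from txnkinetics import (AcquisitionSchedule, KineticParams, build_gene,
                         fit_retention_time, simulate_frap)

gene = build_gene("E6")                      # 6 exons, 5 introns, 18 MS2 loops
base = KineticParams(dt=0.5)                 # defaults: 55 bp/s, pausing on
sched = AcquisitionSchedule(n_prebleach=5, segments=((180.0, 4.0),))

observed = simulate_frap(gene, base.with_(retention_mean=660.0), sched,
                         n_sites=200, seed=14)
best, table = fit_retention_time(observed, gene, base, [50.0, 660.0],
                                 n_sites=200, seed=24)
print(table.to_string(index=False), f"\nbest retention: {best:.0f} s")
```

```
 retention_s       sse
        50.0 23.116835
       660.0  0.000057
best retention: 660 s
```

The 50 s candidate misses by three orders of magnitude in SSE: by 180 s
post-bleach a fast-releasing site has fully exchanged its mRNA while the
slow-releasing one is still dark. The same machinery drives the analysis
scripts:

```sh
python analysis/01_simulate_frap.py        # E3 / E6 / E6+Clk1 recovery curves
python analysis/02_fit_recovery_models.py  # bi-exponential fits + fractions
python analysis/03_fish_ratios.py          # intron/exon ratios, all regimes
python analysis/04_retention_retrieval.py  # retention retrieval, both regimes
```

each of which prints a short summary and writes its table under `results/`.
For instance `03_fish_ratios.py` shows the two diagnostic behaviours of the
steady-state intron/exon ratio: shortening the depletion distance
750 → 500 bp (Clk1) lowers the E6 ratio only modestly (≈ 0.60 → 0.44, fast
retention), while slowing the release 50 s → 660 s collapses it
(≈ 0.60 → 0.12), because retained, fully spliced transcripts pile up exon
signal after their introns are gone.

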