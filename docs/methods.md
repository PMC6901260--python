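# Methods

## The model

`txnkinetics` simulates transcription at a stably integrated, multi-copy
reporter gene array whose nascent transcripts are visualized through MS2
stem-loops in the 3'UTR. Two reporter geometries are packaged: **E3**
(3 exons, 2 introns) and **E6** (6 exons, 5 introns), both carrying 18 MS2
repeats downstream of the last intron. On every gene copy:

1. **Initiation.** A polymerase loads at the promoter at rate
   `init_rate` (s⁻¹ per copy), provided the promoter-proximal footprint
   (35 bp) is clear. Blocked attempts are lost, as in a Bernoulli arrival
   process with exclusion.
2. **Elongation and pausing.** Non-paused polymerases advance at
   `elong_rate` bp/s, clamped so that they never come within one footprint
   of the polymerase ahead. While elongating, a polymerase enters a paused
   state at rate `pause_on_rate` and exits at `pause_off_rate`; the expected
   transit time is therefore `(L/v)·(1 + k_on/k_off)`.
3. **Termination and retention.** A polymerase that reaches the gene end is
   released at rate `termination_rate`. The completed transcript then stays
   at the site for a *retention time* before leaving — a fixed delay
   `retention_mean` by default, or an exponential draw with that mean
   (`retention_model="exponential"`); the true dispersion is unknown, and
   the fast/slow regimes of interest (50 s vs 660 s) are quoted as single
   times, hence the fixed default.
4. **Channels.** The MS2 signal of a transcript is the fraction of the MS2
   cassette synthesized; it is kept until the transcript leaves the site.
   Probe signals for the FISH read-out accrue the same way: an intron's
   signal grows proportionally with its synthesis and is removed once the
   polymerase has moved `splice_depletion_bp` past the intron's 3' end —
   splicing enters the model purely as positional depletion, with 750 bp in
   the control regime and 500 bp under Clk1 overexpression. The first-exon
   probe accrues proportionally and persists until release.

Time is discretized in fixed steps of `dt` seconds. Every stochastic event
is a per-step Bernoulli trial with probability `rate·dt`; a validation guard
enforces `dt ≤ 0.1/rate` for every active rate so that no per-step
probability exceeds 0.1. Internally the Bernoulli sequences are realized by
geometric skip counters (inverse-CDF draw of the number of trials to the
next success), which is sample-path equivalent and costs one random draw per
event rather than per step. All operations are bit-reproducible given their
seed.

### Parameter defaults and units

| parameter | default | unit | rationale |
|---|---|---|---|
| `init_rate` | 0.05 | s⁻¹ per copy | a few initiations per minute per copy, typical of an induced strong promoter |
| `elong_rate` | 55 | bp/s | ≈3.3 kb/min elongation |
| `pause_on_rate` | 0.01 | s⁻¹ | occasional pausing, ~1 pause per 100 s of elongation |
| `pause_off_rate` | 0.1 | s⁻¹ | ~10 s mean pause duration |
| `termination_rate` | 0.2 | s⁻¹ | ~5 s mean release wait at the gene end |
| `retention_mean` | 50 | s | the fast regime (E3, E6+Clk1); the slow regime uses 660 s |
| `splice_depletion_bp` | 750 | bp | control splicing efficiency; 500 bp under Clk1 |
| `dt` | 0.1 | s | satisfies the stability guard for all default rates |
| `n_copies` | 20 | — | plausible tandem-array copy number; not published |

None of the rate values are published for these constructs; results shipped
with the package are stated relative to the parameters actually used, and
every acceptance-level property (Little's law, recovery timing, ratio
ordering, retrieval) is parameter-relative rather than tied to the
defaults. The exact exon/intron lengths are likewise not published;
defaults use 300 bp exons, 400 bp introns and a 1200 bp MS2 cassette, fully
overridable per model.

## FRAP simulation

`simulate_frap` runs `n_sites` independent sites to steady state, bleaches
every transcript at t = 0 (the already-synthesized MS2 fraction of each
nascent and retained transcript is marked dark; the free coat-protein pool
is assumed unbleached and in excess, so loops synthesized after the bleach
are fluorescent), then samples the site at the frame times of an
`AcquisitionSchedule`. Per-site intensities are divided by that site's
pre-bleach mean; the curve reports the across-site mean and standard error.

Steady state is declared when the mean total MS2 signal over two
consecutive windows, each 5 mean dwell times long (dwell = transit +
termination wait + retention), differs by less than 5% (relative). The
state is initialized by sampling the stationary occupancy implied by the
parameters (Poisson polymerase counts at uniform positions with footprint
enforcement, Poisson retained transcripts with residual delays), which
shortens the burn-in; the window test is still what certifies convergence,
and an empty start is available (`start="empty"`).

Schedule presets: `sf-frap` (5 pre-bleach frames, 0.5 s post-bleach
interval — four images per 2 s — for 60 s) and `mrna-frap` (6 pre-bleach
frames; 45 s at 0.3 s, 90 s at 6 s, 480 s at 30 s). The second and fourth
intervals of the published mRNA protocol are printed as milliseconds, which
is inconsistent with the stated segment durations and with EM-CCD frame
rates; the preset uses the second/thirty-second readings and the literal
printed values are preserved as `mrna-frap-printed`. Nothing downstream
depends on the choice — schedules are plain data.

## FISH snapshots and the stationary oracle

`simulate_fish_snapshot` takes one steady-state snapshot per site and sums,
over all transcripts at the site, the intron-probe and exon-probe signals;
the per-site ratio intron/exon is the simulated quantitative-FISH read-out.
Sites with zero exon signal are dropped and counted. Ratios can be divided
by a control condition's mean (the E3-control normalization convention).

In the no-pause, deterministic-elongation, fixed-retention regime the
stationary ratio has a closed form (`expected_fish_ratio`): by stationarity
each probe's expected signal equals arrival rate × signal-weighted lifetime,
and the arrival rate cancels in the ratio. A target of length `l`
contributes `l/(2v)` while being synthesized; an intron then holds full
signal for `splice_depletion_bp/v` (or, if never depleted on the gene, until
release); the exon probe holds until release: transit to the gene end +
mean termination wait `1/k_term` + retention. The same reasoning gives the
stationary occupancy `n_copies·init_rate·(transit + 1/k_term + retention)`
(`expected_transcript_count`, Little's law). These oracles are exact for
the simulator up to discretization O(dt) and promoter-footprint blocking
O(init·footprint/v), both at the sub-percent level for the regimes tested.

Probe accrual is deliberately length-proportional rather than binary
(present/absent on crossing the 3' end): proportional accrual is what makes
the half-length synthesis term of the stationary oracle exact, so simulator
and closed form can be held to tight agreement in tests; with binary accrual
the two would differ by `(l/2)/depletion` per intron (~27% at the default
geometry), which is a model-vs-oracle discrepancy with no physical content.

## FRAP analysis

* **Normalization** (`normalize_frap`): double normalization
  `(roi − background)/(whole − background)`, then division by the pre-bleach
  mean of the quotient (window = all pre-bleach frames, configurable by
  construction of the trace). This makes the pre-bleach level exactly 1 and
  cancels acquisition photobleaching identically.
* **Fitting** (`fit_recovery`): least squares of
  `y0 + Σ A_j (1 − exp(−k_j t))` on the post-bleach frames. Bi-exponential
  objectives are multimodal, so fitting is multi-start: rates on a log grid
  in [10⁻³, 1] s⁻¹ (5 per component), intercept/amplitudes solved linearly
  at fixed rates, the three best starts refined with bounded trust-region
  least squares (rates > 0, amplitudes ≥ 0). The bleach depth `y0` is
  fitted rather than pinned to the (noisy) first post-bleach frame. The
  plateau is not constrained to ≤ 1; a value above 1.05 raises a warning.
* **Model selection** (`select_model`): the 2-exponent model is preferred
  only when its AIC is lower by ≥ 2 *and* the rates are separated by ≥ 3×.
  The AIC margin and separation factor are package choices — the biology
  fixes only the conclusion (two sub-populations: an unbound rapidly
  diffusing pool and a bound fraction).
* **Comparison** (`compare_curves`): the study compared conditions with
  polynomial mixed-model regression over experiments; that requires the raw
  per-cell data and is off-the-shelf statistics, so the package substitutes
  a replicate-label permutation test on the mean absolute difference between
  condition mean curves, p = (1 + #{permuted ≥ observed})/(1 + B). With
  B = 199 the test attains the 5% level exactly under exchangeability.
  Benjamini–Hochberg adjustment (`fdr_adjust`, via statsmodels) covers
  families of comparisons.
* **Retention retrieval** (`fit_retention_time`): for each candidate
  retention, the FRAP experiment is simulated with a matched seed and
  schedule and the SSE against the observed mean curve tabulated; the
  argmin wins, ties broken toward the smaller retention (the more
  conservative kinetic claim).

## Synthetic data

`gen_frap_dataset` emulates the structure of the real measurements: ≥ 10
cells per condition measured on 3 independent days (day effect = Gaussian
multiplier on the recovery amplitudes, sd 5% by default — the replicate
structure is published, its variance is not), Gaussian noise on the
normalized intensity (sd 0.02 default), and per-frame multiplicative
acquisition bleaching applied to the ROI and whole-cell series so that the
normalization has real work to do. The true curve comes either from the
closed-form bi-exponential or from the simulator with per-cell sub-seeds,
and the generator returns its ground truth, so every downstream estimate
has a recovery target. `gen_fish_table` dresses simulator snapshots with
independent lognormal channel noise (sd 0.2 default) — strictly positive
intensities, median-preserving ratios.

What the generators do *not* emulate: spatial imaging (no PSF, no ROI
segmentation, no z-stacks), correlated noise across frames, cell-to-cell
kinetic heterogeneity beyond the day effect, and partial/heterogeneous
bleaching. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated noise model, not robustness to every
artifact of real microscopy.

## Numerical choices and problem sizes

* Discretization bias is O(dt) on crossing/waiting times; with the default
  `dt = 0.1 s` this is ≤ 0.5% of any time scale in play. The
  retention-retrieval study (analysis script 04, the 40-repetition test,
  and the acceptance script) runs at `dt = 0.5 s` — still within the
  stability guard for the default rates — because the 50 s vs 660 s
  contrast it probes is enormous compared with discretization effects.
* Steady-state checks use 100–300 sites; FRAP orderings 200 sites;
  FISH ratios 300 sites; the permutation calibration 200 datasets of
  10 + 10 replicate curves with B = 199 permutations. These sizes put
  Monte-Carlo standard errors well inside every asserted tolerance.
* Retained-transcript buffers are ring buffers sized at 4× the stationary
  mean plus a 20-σ Poisson margin; overflow is detected and raised, never
  silently dropped.
* Degenerate inputs: `init_rate = 0` yields an empty steady state and an
  identically-zero recovery curve; intron-free genes yield ratio 0; sites
  with zero exon signal are dropped and reported; constant recovery curves
  fit as 1-exponent with zero amplitude.

## Known limitations

* The analytic oracles require the no-pause regime; with pausing enabled
  they raise `UnsupportedRegimeError` rather than return an approximation.
* Little's law and the FISH oracle neglect promoter-footprint blocking
  (≈ `init·footprint/v`, ~1–3% at the defaults); tests choose regimes where
  this is inside the Monte-Carlo tolerance.
* The bleach is instantaneous and total at the site; partial bleaching and
  diffusion-limited exchange of the coat protein are not modeled (the
  protein-FRAP side of the study is handled empirically, via the
  exponential fits, not mechanistically).
* Segment lengths, array copy number and the absolute kinetic rates are
  unpublished for these constructs; all are configurable, and no packaged
  result depends on their specific default values.
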