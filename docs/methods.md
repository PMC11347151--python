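# Methods

## Kinetic scheme and what the generator emulates

The simulator reproduces the observable structure of a two-color
single-molecule termination assay. One immobilized elongation complex is
one trace: a donor channel (Cy3 on the nascent RNA, donor excitation) and
an acceptor channel (Cy5 at the downstream DNA end, acceptor excitation)
sampled on a common 0.4-s frame clock. Alternating excitation is modeled
as two already-demultiplexed channels; the 0.2-s sub-exposures within each
frame are not modeled separately because classification only consumes the
demultiplexed channels.

The latent schedule of a trace is drawn as follows:

| parameter | default | meaning |
| --- | --- | --- |
| `p_active` | 0.7 | fraction of complexes that resume elongation after NTP injection; not a published number, chosen once as a typical active fraction of surface-immobilized complexes |
| `p_termination` | 0.54 | probability an active complex terminates rather than reads through (reference terminator condition) |
| `p_recycling_given_termination` | 0 | recycling share within termination; the reference preset has none |
| `t_resume` | Γ(mean 2 s, sd 1 s) | resumption of elongation (donor PIFE drop); only constrained to precede the first downstream event, so it is resampled until it does |
| τ_e | Γ(7.5 s, 2.2 s) | arrival at the acceptor-labeled DNA end (acceptor PIFE onset), measured from injection |
| τ_t | Γ(52 s, 13 s) | terminational RNA release (donor loss), measured from injection |
| recycling arrival lag | Exp(10 s) | time from RNA release to end arrival of the DNA-bound polymerase; stands in for unquantified 1-D diffusion |
| `runoff_dwell_s` | 2 s | duration of the acceptor PIFE pulse before runoff; a finite pulse is visible in such assays but no number is published |
| bleach means | 1380 s / 2340 s | exponential donor / acceptor photobleaching (23 and 39 min) |
| levels | dark 0, base 1, PIFE 2 | per channel; PIFE = 2 × base because the enhancement factor is not quantified — it is configurable |
| `noise_sd` | 0.1 | additive Gaussian per-frame noise, in units of the base level |
| `window_s` | 300 s | event window anchored at each trace's resumption |

Dwell times use the gamma family moment-matched to (mean, sd): only means
and SDs of the experimental dwell times are available, and gamma keeps
positivity while nesting the exponential. Whether the real dwell
distributions are exponential or peaked is unknown; conclusions that
depend on distribution shape (not just moments) are therefore outside what
these simulations can support. Dye blinking is not modeled (experiments
of this kind suppress it chemically with triplet quenchers); neither are
photon-count (Poisson) statistics, FRET between the dyes, baseline drift,
nor multiple transcription rounds on one template. Passing tests
demonstrate correctness of the analysis chain under this generative model,
not robustness to those unmodeled features of real movies.

Rendering is pointwise: frame i shows the ideal level holding at time
`(i − t0_index)·Δt`, so a transition at time τ first appears on the first
frame at or after τ. Noise is added to every frame. Ensembles are
deterministic given the seed (one spawned RNG stream per trace, so a
trace's content does not depend on ensemble size) and are split
round-robin into three equal replicate groups standing in for independent
experiments; the traces are exchangeable, so a round-robin split is
equivalent in distribution to a random equal partition.

## Step detection

Channels are idealized by exact minimization of

    Σ_k SSE(segment_k) + β · (#change points)

over all segmentations with segments of at least 2 frames, solved by
optimal-partitioning dynamic programming with PELT-style pruning. An
exact solver is used rather than greedy binary segmentation so the result
provably equals exhaustive partition search, which the test suite checks
directly on small signals. The default penalty is the BIC-style
`β = 2·σ̂²·log n` per change point with σ̂ estimated from the median
absolute deviation of first differences (differences within a segment are
N(0, 2σ²); the few differences straddling steps are outliers the MAD
ignores). Numerical choices: a tiny penalty floor (`1e-9·n·max(x)²`)
prevents floating-point phantom gains from paying for change points on
noiseless input; cost ties are broken toward fewer segments, then the
earlier split. Segment means are exact arithmetic means; segments are
labeled dark/base/PIFE by nearest level with ties toward the lower level,
and adjacent equal labels are merged, which silently absorbs any spurious
split inside a constant stretch.

The 2-frame (0.8 s) minimum segment length equals the classifier's
coincidence tolerance: one frame of timing jitter per channel under
alternating excitation.

## Classification

A trace is **active** iff its donor shows a PIFE→base transition after the
injection frame and before the window end; inactive traces are excluded
from all statistics. Events are then read inside
`[t_resume, t_resume + 300 s]`:

1. acceptor dark transition before any terminal evidence → **censored**
   (the absence of acceptor PIFE can no longer be asserted — conservative;
   an alternative would be to call decomposing);
2. no donor loss inside the window → **censored**;
3. acceptor pulse starting before the donor loss, ending within 2 frames
   of it → **readthrough**, τ̂_e = pulse onset;
4. acceptor pulse starting more than 2 frames after the donor loss →
   **recycling**, τ̂_t = donor loss;
5. donor loss with no acceptor pulse in the window → **decomposing**,
   τ̂_t = donor loss;
6. anything else (ambiguous coincidence) → unclassified.

Estimated event times carry a mid-frame correction: a transition first
visible on frame f occurred somewhere in the preceding inter-frame
interval, so its conditional mean is `(f − 0.5)·Δt`; reporting the raw
frame time would bias all dwell means late by 0.2 s, which is comparable
to the standard error of the arrival-time mean at realistic ensemble
sizes.

Donor bleaching and RNA release are indistinguishable within a trace —
both are a step to dark. Because bleaching (23 / 39 min means) is slow
relative to the 5-min window, dark transitions inside the window are
treated as events and no statistical bleaching correction is applied.

### Observable ground truth and the recycling mimicry floor

The generator derives, alongside the latent outcome, the *observable*
classification: the label an ideal observer would assign at frame
resolution given bleaching, the finite window, and the 2-frame resolution
limit (`synthetic_data.observable_classification`). The classifier is
benchmarked against this observable truth — on noiseless ensembles the
agreement is exactly 100%, and it remains ≈100% at the default noise.

The observable and latent truths differ in a small, quantifiable set of
traces, most importantly: a readthrough whose donor bleaches between
resumption and τ_e shows donor loss first and an acceptor pulse later —
exactly the recycling pattern. With exponential bleaching at a 23-min
mean, the probability is roughly `(E[τ_e] − E[t_resume]) / 1380 s ≈ 0.4%`
per readthrough trace, i.e. an expected ~2–3 spurious recycling calls per
1400 active complexes even when the generator's recycling channel is off.
No per-trace information can remove this floor, and it is notable that it
sits at the same order of magnitude (~0.1–0.2% of complexes) as the small
recycling fractions such experiments report for phage polymerases, so
measured recycling fractions at or below this level should be interpreted
as upper bounds. Decomposing calls have the analogous confound
(bleach-induced donor loss before the true τ_t shifts the estimated
release time earlier) at a similarly negligible rate.

## Ensemble statistics

* **Termination efficiency** = (decomposing + recycling) / classified per
  replicate, censored traces excluded from the denominator; reported as
  mean ± sample SD over the replicate groups (matching how such
  experiments report "mean ± SD of independent datasets"), not a binomial
  SE. A single replicate reports SD 0 by convention. Decomposing and
  recycling efficiencies decompose the total exactly.
* **Recycling fraction** pools recycling events over classified active
  complexes, per pair and overall.
* **Timing**: mean, SD and median of τ̂_e (readthrough) and τ̂_t
  (termination); the fold delay is the ratio of means (a median-based
  ratio is also emitted).
* **Rank-sum test**: Wilcoxon two-sided with mid-ranks; exact enumeration
  of all C(n1+n2, n1) rank assignments for combined samples ≤ 12,
  otherwise a normal approximation with tie-corrected variance and a 0.5
  continuity correction. Degenerate all-tied input returns p = 1.
* **Mismatch scan**: per-position efficiencies (from per-position
  ensembles or a TSV) are scanned for the minimum; ties resolve toward
  the termination site, then upstream. The offset is reported as
  termination site − peak, positive meaning upstream.

## Genomic distances

Nearest-start distances are linear |t − s| minima (sorted starts + binary
search, verified against a brute-force double loop), strand-blind by
definition of the question. A circular-genome option takes the
wrap-around minimum, since bacterial chromosomes are circular and a linear
convention is an approximation; circular ≤ linear always. Histograms use
half-open 100-bp bins; "within L" is a closed bound (d ≤ L). The
synthetic annotation generator plants an exact `⌈fraction·n⌉` of
termination sites within the limit of some start site and the rest
strictly farther (rejection-sampled), so the planted fraction is recovered
exactly — a degenerate packing (genome too crowded to place far sites)
raises an error rather than degrading silently.

## Problem sizes and determinism

The reference analyses use 1400 active traces (≈750 frames × 2 channels
each), 2000 traces for the noiseless classifier benchmark, 120 traces per
mismatch position, and 371/888-site annotations — sizes at which the
binomial/Monte-Carlo standard errors quoted in the tests are meaningful
while a full run stays in the minutes range on one core. Every stochastic
step flows from a single integer seed; reruns are bit-identical.

## Known limitations

* The recycling-pattern floor from donor bleaching (above) bounds how
  small a recycling fraction the pipeline can attribute to kinetics.
* Acceptor-bleach censoring is differential: termination events (τ_t ≈
  52 s) sit in the window ~6-fold longer than readthrough arrivals, so they
  are censored slightly more often, biasing the measured efficiency down by
  roughly half a percentage point at the default bleach times — well inside
  the replicate SD, and no correction is applied.
* Dwell distributions beyond their first two moments are a modeling
  choice, not data.
* The optional dark-state flicker (blinking) switch is not implemented;
  the generator assumes blinking-suppressed imaging throughout.
* No FRET channel is modeled; classification uses only the two
  directly-excited channels.
* Premature (pre-terminator) release and multi-round transcription on one
  template are out of scope; such traces would surface as unclassified.
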