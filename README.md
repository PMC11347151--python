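# smterm — single-molecule transcription-termination trace analysis

`smterm` is a simulation and analysis toolkit for two-color single-molecule
fluorescence assays of intrinsic transcription termination. In these
assays an immobilized transcription elongation complex carries a donor dye
(Cy3) on its nascent RNA and an acceptor dye (Cy5) at the downstream DNA
end; protein-induced fluorescence enhancement (PIFE) reports when the
polymerase sits next to either dye. After NTP injection at time zero each
complex produces one of a small set of trace patterns:

* **readthrough** — the polymerase ignores the terminator, reaches the
  Cy5-labeled DNA end at time τ_e (acceptor PIFE pulse), and runs off,
  taking the labeled RNA with it (donor loss coincides with the end of the
  pulse);
* **decomposing termination** — RNA and DNA are released together at time
  τ_t: the donor signal is lost with no acceptor PIFE at all;
* **recycling termination** — only the RNA is released at τ_t; the
  polymerase stays on the DNA and diffuses to the labeled end, so the
  acceptor PIFE appears *after* the donor loss.

The package is aimed at single-molecule biophysicists who need a tested,
fully synthetic counterpart of such an experiment: a generator with exact
ground truth, a change-point detector, a rule-based outcome classifier,
and the ensemble statistics that summarize an experiment — termination
efficiency (mean ± SD over replicate groups), dwell-time moments and the
fold delay of termination versus readthrough, recycling fractions,
Wilcoxon rank-sum comparisons, a terminator mismatch-scan peak analysis,
and terminator-to-nearest-promoter genomic distance distributions.

## The model in brief

Each trace is a latent event schedule plus a piecewise-constant two-channel
rendering with additive Gaussian camera noise. A complex is active with
probability `p_active`; an active complex terminates with probability
`p_termination` (recycling with conditional probability
`p_recycling_given_termination`), otherwise reads through. Dwell times are
gamma distributed, moment-matched to (mean, sd): arrival
τ_e ~ Γ(7.5 s, 2.2 s), release τ_t ~ Γ(52 s, 13 s) by default. Dyes
photobleach exponentially (donor mean 23 min, acceptor 39 min). Frames are
0.4 s; events are counted in a 5-minute window anchored at each trace's
elongation resumption.

Channel idealization is exact penalized least-squares segmentation
(optimal-partitioning dynamic programming) with a BIC-style penalty
`2·σ̂²·log n` per change point, σ̂ estimated from the median absolute
deviation of first differences. Segments are labeled dark/base/PIFE by
nearest level and the classifier applies the pattern rules above, with a
2-frame coincidence tolerance and conservative censoring when the acceptor
dye bleaches before any terminal evidence.

## Worked example

```sh
python analysis/01_simulate_and_classify.py
python analysis/02_termination_kinetics.py
```

prints (seed 1):

```
simulated + classified 1400 traces (seed 1)
termination efficiency: 53.3% +/- 3.5 (SD over 3 replicates)
counts: {'inactive': 1, 'readthrough': 642, 'decomposing': 729, 'recycling': 3, 'unclassified': 25}
tau_e: 7.6 +/- 2.2 s (n=642, median 7.4)
tau_t: 51.1 +/- 13.3 s (n=732, median 51.4)
fold delay (means): 6.8
rank-sum tau_t replicate 0 vs 1: W=66080, z=0.81, p=0.42
```

Reading: of 1400 simulated active complexes, 53.3% terminated (the
generator's truth is 54%), the end-arrival time recovered 7.6 s against a
true mean of 7.5 s, the release time 51.1 s against 52 s, and termination
is ~7-fold slower than readthrough. The three recycling calls are
readthrough traces whose donor bleached before the polymerase reached the
end — an irreducible mimic of the recycling pattern discussed in
`docs/methods.md`. The rank-sum p of 0.42 between two replicate groups of
the same condition is the expected null behavior.

The remaining drivers survey the named presets for recycling occurrence
(`03`), push a 12-position terminator mismatch scan through the full
pipeline and locate the efficiency minimum 10 bp upstream of the +130
termination site (`04`), and analyze terminator–promoter distances on
synthetic genome annotations with 100-bp-bin histograms and within-limit
fractions (`05`). All outputs land under `results/`.

The same steps are scriptable from the shell:

```sh
smterm pipeline --preset T7_Tphi --n 1400 --seed 1 --out results/run1
smterm distances --sites sites.bed --genome-length 4600000 --out results/dist.json
```

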