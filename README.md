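# attentrack

Monte-Carlo evaluation of adaptive psychoacoustic threshold procedures
under listener inattention.

Adaptive staircases and Bayesian placement rules are the workhorses of
hearing-threshold measurement, but they were designed for attentive,
supervised listeners. Self-administered testing (e.g. on a smartphone)
breaks that assumption: listeners lapse, guess, and false-alarm.
`attentrack` simulates such listeners and quantifies how robust and
efficient seven adaptive procedures remain — including the
graded-response bracketing procedure (GRaBr), a two-tone counting
staircase designed to stay accurate under inattention. It is intended
for psychoacousticians and methodologists choosing or designing tracking
procedures for unsupervised testing.

## Models

**Observer.** A virtual listener answers according to a four-parameter
logistic psychometric function

```
p(L) = p_min + (p_max − p_min) / (1 + e^{−4 s (L − L50)})
```

with false-alarm floor `p_min`, lapse rate `1 − p_max`, midpoint slope
`s` (per dB) and threshold `L50` (defaults 0, 1, 0.125/dB, 15 dB).
Inattention enters in two ways:

* **long-term** (sustained): `p_max` is reduced to 1 / 0.95 / 0.9 for
  fully (FC), moderately (MC) and non-concentrated (NC) listeners — a
  stationary deformation applied on every trial;
* **short-term** (sporadic): a nested two-state process; with
  probability `p_inatt` ∈ {0, 0.1, 0.2} the trial is answered at random
  (p("yes") = 0.5) regardless of level. Averaged over a track this
  behaves like a stationary PF with asymptotes `1 − p_inatt/2` and
  `(1 − p_inatt)·p_min + p_inatt/2`, but the trial-by-trial dynamics
  differ — and that difference is what model-based procedures feel.

Crossing both modes with three false-alarm floors (0, 0.05, 0.1) yields
the standard 18-listener grid.

**Procedures.** SIUD and GRaBr (two-tone 0/1/2 counting staircases with
20% catch trials and abort-on-false-alarm), APTA (modified
Hughson–Westlake ascending audiometry), QUEST+ (posterior-entropy
minimisation), MLP (maximum-likelihood placement at p-target 0.6310),
UML (Bayesian posterior with a 2-down/1-up sweet-point overlay) and SIAM
(single-interval adjustment matrix, t = 0.75). Each runs 50 main trials
per track; 1000 Monte-Carlo tracks per condition.

**Measures.** Bias `L̂50 − L50`; RMSE with a bootstrap mean ± SD (1000
replicates × 10,000 resamples); the sweat factor `SF = N σ²_{L50}`; the
normalized efficiency `NE = (1 − p_aborted) / (τ N σ²_{L50})` with
τ = 1.5 s per one-interval trial and 2.5 s per two-tone trial; and
convergence curves `σ_{L50}(i)`, the across-track SD of the interim
estimate after trial i.

## Worked example

```python
from attentrack import SimConfig, run_grid, summarize

cfg = SimConfig(procedures=("grabr", "quest_plus", "siam"),
                observer_types=("long_term",),
                concentrations=("FC", "NC"),
                p_mins=(0.0,),
                n_runs=200, master_seed=7)
metrics = summarize(run_grid(cfg))
print(metrics[["procedure", "concentration", "rmse_boot_mean", "rmse_boot_sd",
               "bias_median", "normalized_efficiency"]].round(4).to_string(index=False))
```

prints

```
 procedure concentration  rmse_boot_mean  rmse_boot_sd  bias_median  normalized_efficiency
     grabr            FC          0.5968        0.0039          0.0                 0.0224
     grabr            NC          1.2973        0.0544          0.5                 0.0059
quest_plus            FC          0.6708        0.0050          0.0                 0.0295
      siam            FC          3.8709        0.0177          3.0                 0.0045
      siam            NC         13.6758        0.1103          7.0                 0.0002
```

(one row elided): for the attentive listener GRaBr and QUEST+ recover
the 15 dB threshold with sub-dB error and no median bias, while SIAM —
whose adjustment matrix assumes perfect hit/false-alarm ceilings and
whose estimator targets its 75%-correct point — is already biased ~3 dB
high. A 10% lapse rate (NC) barely degrades GRaBr but sends SIAM's error
above 13 dB with a collapse in normalized efficiency.

## Command line

```sh
attentrack simulate --config config.yaml --out results/   # tracks.csv, interim.csv, metrics.csv, table2.csv, sigma.csv, manifest.json
attentrack metrics  --tracks ... --interim ... --manifest ... --out m/
attentrack report   --metrics m/metrics.csv --out report/ [--plots]
```

Every key in the YAML config is optional; defaults are the full study
conditions (see `attentrack.cli_io`). The manifest written next to each
run suffices to reproduce it bit-identically.

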