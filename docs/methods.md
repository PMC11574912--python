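# Methods

This note documents the models, the procedure implementations, the
numerical choices, and where the design was genuinely open, what was
chosen and why.

## Observer models

The listener is a four-parameter logistic psychometric function (PF)
`p(L) = p_min + (p_max − p_min)/(1 + e^{−4s(L−L50)})`; `s` is the slope
at the midpoint (the factor 4 makes `s` the derivative of the
normalized PF at `L50`). Defaults: `p_min = 0`, `p_max = 1`,
`s = 0.125`/dB, `L50 = 15` dB. `pf_eval` uses `scipy.special.expit`, so
±∞ map exactly to the asymptotes — a signal-absent presentation is
evaluated at −∞ and yields the false-alarm floor.

**Long-term inattention** is a stationary reduction of `p_max`
(1 / 0.95 / 0.9 for FC / MC / NC listeners): every trial uses the same
deformed PF.

**Short-term inattention** is a nested two-state process: per trial, an
independent Bernoulli(`p_inatt`) draw selects the inattentive state, in
which the response is a coin flip (p("yes") = 0.5) regardless of level;
otherwise the regular PF (with `p_max = 1`) applies. States are i.i.d.
across trials; temporally correlated "bursts" of inattention are not
modelled.

**Equivalent expected PF.** Marginalising the two-state process gives
again a logistic PF with the same `s` and `L50` and asymptotes
`p_max,short = 1 − p_inatt/2` and
`p_min,short = (1 − p_inatt)·p_min + p_inatt/2`. The lower asymptote is
the exact expectation of the nested process; the commonly quoted
shortcut `p_min + p_inatt/2` coincides with it only when `p_min = 0`.
The package returns the exact expectation, because it is the quantity
the marginal yes-rate of the simulated listener actually converges to
(the test suite verifies this to four binomial standard errors at
10⁵ draws).

**Counting task.** The two-tone procedures ask how many tones were
heard (0/1/2). One attention-state draw governs the whole trial (the
state is indexed by trial, not by tone). While attentive, each presented
tone is heard independently with its PF probability and a muted slot is
"heard" with probability `p_min` (the false-alarm floor applies per
slot); while inattentive, each slot is heard independently with
probability 0.5, so counts 0/1/2 occur with probability
0.25/0.5/0.25. A uniform draw over {0,1,2} is a defensible alternative;
both were measured during development and change condition-level RMSEs
by less than 0.1 dB, so the per-slot extension of the p("yes") = 0.5
rule was kept.

`StepObserver` is a deterministic diagnostic listener (yes iff
`L ≥ threshold`, never false-alarms) used to check that each procedure
recovers a known threshold to its own final resolution.

## Procedures

All procedures run until the 50th *main* trial; catch trials are extra
presentations and do not consume the budget. Starting levels: discrete
uniform on {35, …, 45} dB, except APTA (−10 dB) and QUEST+ (stimulus
range midpoint, 20 dB). Threshold estimators: staircases take the
median of main-track levels from the first reversal onward (falling
back, flagged, to all levels if the track never reversed); MLP the
median of all 50 presented levels; QUEST+ the posterior mode; UML the
posterior mean; APTA the level of the last "yes".

A *reversal* is a trial whose level change has the opposite sign of the
previous non-zero change; zero changes inherit the prior direction
(`detect_reversals`). When a response determines the move direction
directly (GRaBr, SIAM), the reversal counter is updated before the move,
so the reduced step applies from the reversal move itself.

**SIUD.** Cue tone fixed 10 dB above the probe; 10 dB steps; the first
"one tone" response sets the probe to the midpoint of the previous two
probe levels and switches to 2 dB steps. After that switch, "two"
lowers and "zero"/"one" raise the probe (a "one" means only the cue was
heard, i.e. the probe was inaudible). Each trial is independently a
catch trial (muted cue) with probability 0.2; a reported count of 2 on
a catch trial is a false alarm on the muted cue and aborts the track
(a count of 1 is ambiguous — it may be the probe — and does not).
Aborted tracks restart from a fresh starting level; attempts are capped
at 20 per run (a guard for high-false-alarm listeners), after which
aborts are still counted but no longer restart. The abort counter feeds
`p_aborted`.

**GRaBr.** As SIUD, but the probe–cue gap Δ adapts: 10 → 5 dB at the
first "one tone" response, 5 → 2 dB at the second, then fixed. On a
"one", the new, smaller bracket is re-centred on the midpoint of the
previous pair — a "one" localises the threshold between the tones, and
the midpoint is the minimax placement (shifting only one tone is the
alternative). On "two"/"zero" the pair shifts down/up with the cue-step
schedule 8/6/3/1 dB keyed to reversals of the shift direction;
"one"-responses are not themselves reversals. Two deliberate choices:

* *Reversal counting starts at bracketing.* The 8/6/3/1 refinement
  engages only after the first "one tone" response, exactly as SIUD
  keys its step change to the first "1". Counting direction flips from
  trial one lets a single lapse 25 dB above threshold collapse the step
  to 1 dB and strand the track high — a failure mode that contradicts
  the procedure's defining robustness (it raised the short-term NC RMSE
  from ≈1 dB to ≈2 dB by stranding ~2% of tracks 15+ dB high).
* *The estimator pools both tones.* The threshold is the median of all
  main-track tone levels (probe and cue) from the first reversal of the
  pair midpoint. The probe alone sits Δ/2 below the bracketed
  threshold, which would build in a −1 dB bias; in GRaBr both tones are
  informative stimuli and both belong to the estimation track.

**APTA.** Modified Hughson–Westlake: ascend in 5 dB steps from −10 dB
until the first "yes"; reset and ascend to a second "yes"; then enter
the bracketing phase 5 dB below the second "yes", dropping 10 dB after
every "yes" and ascending in 5 dB steps. Terminate once ≥7 "yes"
responses were given and the last two "yes" levels differ by <3 dB (or
at trial 50). The 5 dB ascent is the clinical convention; the source
method does not state it. All "yes" responses count toward the 7.

**QUEST+.** Posterior over `L50` on a 1 dB grid spanning the stimulus
space [−10, 50] dB, uniform prior, likelihood from the logistic PF with
`p_min = 0`, `p_max = 1`, `s = 0.125` fixed. The next level minimises
the expected posterior Shannon entropy over the two response outcomes
(ties → lowest level); the first trial uses the procedure's own
starting rule, the stimulus-range midpoint. With a uniform prior the
posterior mode equals the ML estimate, which is what the final
threshold reports.

**MLP.** Hypotheses: `L50` on a 0.1 dB grid × false-alarm floors
{0, 0.05, 0.1}, slope and `p_max` fixed. After each trial the
whole-history likelihood is maximised (ties → lowest `L50`) and the
next level is the selected PF's inverse at the p-target 0.6310, clamped
to [−10, 50]. The likelihood is accumulated in log space. The final
threshold is the median of all presented levels; the conventional
ML-inverse-at-p-target readout is a one-line change but is not the
default.

**UML.** Posterior over `L50` (1 dB grid) as in QUEST+. Placement is a
two-down one-up sweet-point overlay on the posterior-mean PF: after two
consecutive "yes" responses the lower target (the 50% point — the
posterior mean itself) is used and the counter resets; after any "no"
the upper target (75% point, mean + ln 3/(4s) ≈ mean + 2.20 dB);
otherwise the current target is kept (initially the upper target).
The reference multi-parameter sweet-point logic collapses to this
two-target rule when `L50` is the only free parameter. Threshold:
posterior mean.

**SIAM.** Signal present with probability 0.5. Level change = step ×
adjustment-matrix entry for target proportion `t`: hit −1, miss
`+t/(1−t)`, false alarm `+1/(1−t)`, correct rejection 0 — the classic
matrix whose expected signal-trial drift vanishes exactly at
p(yes|signal) = t (= 0.75 → −1/+3/+4/0). Step schedule: 4 dB, halved
after the second reversal, 1 dB from the third. Overriding `t` in the
configuration rebuilds the matrix (t = 0.5 → −1/+1/+2/0).

## Engine and reproducibility

Each track draws from its own `numpy` PCG64 substream seeded by
`SeedSequence([master_seed, crc32(procedure), crc32(observer), run])`,
so results are bit-identical for a configuration and any subset of the
grid reproduces the corresponding tracks of the full grid. Interim
estimates are recorded after every main trial by applying the
procedure's estimator to the prefix (Bayesian procedures: the current
posterior); APTA tracks that terminate early carry their final estimate
forward to trial 50 for the convergence curves.

## Metrics

* Bias: `L̂50 − L50`, positive = overestimation; summarised by median
  and quartiles per condition.
* RMSE: `sqrt(mean((L̂50 − L50)²))` over the 1000 runs; the bootstrap
  draws 1000 replicates of 10,000 estimates resampled with replacement
  from the condition's pool and reports the replicate mean ± SD. The
  10× oversampling is reproduced deliberately for comparability (it
  shrinks the bootstrap SD relative to a same-size resample).
  Resampling is implemented via multinomial counts, which is
  distributionally identical to drawing indices and much faster.
* Sweat factor `N σ²` and normalized efficiency
  `(1 − p_aborted)/(τ N σ²)` use N = 50 (catch trials excluded), σ =
  the SD of the final estimates (= σ(50) of the convergence curve), τ =
  1.5 s (one-interval) or 2.5 s (two-tone, from 2×0.5 s tones + 0.5 s
  pause + 1 s response), and `p_aborted` = aborted attempts / total
  attempts per condition (procedures without catch trials have
  `p_aborted = 0` by construction).
* Convergence: `σ(i)` is the across-run sample SD (N−1) of the interim
  estimate at trial i.
* The bootstrap per condition is seeded from the master seed, so
  metrics tables are reproducible.

## What the simulations do and do not show

The generator emulates stationary lapse rates and i.i.d. per-trial
inattention with a known, fixed true threshold (15 dB), fixed slope,
and a 10 dB-wide band of starting levels. Real listeners drift in
criterion, lapse in correlated bursts, fatigue over a session, and have
thresholds that vary between tracks; none of that is modelled. Within
the model, results are shift-invariant in the true threshold and
scale-invariant in (step size × slope), so the absolute threshold value
is immaterial; conclusions about initial-phase behaviour do depend on
the chosen starting-level band.

Problem sizes: the shipped evaluation uses the full study conditions —
1000 runs × 50 trials for all 7 × 18 conditions (the complete grid
simulates in ≈5 minutes on one CPU; the acceptance script, which runs
only the reported conditions, in ≈1 minute).

## Known limitations

* APTA's last-"yes" estimator with 5 dB ascents overestimates the
  threshold by ≈ +2 dB for an attentive listener (an ascending pass
  tends to first succeed above the 50% point). The clinical reference
  implementation is proprietary; its internal corrections, if any, are
  not modelled.
* SIAM's median-from-first-reversal estimator retains the initial
  4 dB-step transient: even a noise-free listener starting 25 dB above
  threshold can land the estimate several dB high. This is consistent
  with SIAM being the most biased and least robust procedure in the
  evaluation, but it means SIAM does not satisfy the
  "noise-free recovery to final resolution" property the other six
  procedures do (the corresponding test documents this failure).
* Bayesian procedures quantize estimates to their grids (1 dB for
  QUEST+/UML modes/means in practice, 0.1 dB hypothesis spacing for
  MLP); grid resolution was chosen so quantization is well below the
  reported RMSEs.
* The hybrid case of simultaneous long- and short-term inattention is
  out of scope, as are multi-parameter UML posteriors, forced-choice
  variants, and inferential statistics (ANOVA/post-hoc tests) on the
  exported tables — the tidy CSVs are the interface to external stats
  tools.
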