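# Methods

## Overview

`claw-cbgt` analyzes how activity flows through the cortico-basal
ganglia-thalamic (CBGT) circuit while a two-choice decision is being made.
The pipeline has five stages:

1. **Simulation** — a stochastic population-rate model of the CBGT circuit
   generates binned firing rates and behavior (choice, decision time) for
   many network configurations.
2. **Binarization** — per-population thresholds derived from pooled
   firing-rate histograms convert the rates to Boolean activity.
3. **CLAW** — the Boolean patterns over 10 encoded populations are read as
   integer state labels; pooled per-trial state sequences yield a pruned
   transition graph of the decision process, per-state statistics, and a
   partition of states into six functional zones.
4. **DDM fitting** — each network's choices and decision times are fitted
   with a four-parameter drift-diffusion model.
5. **Control ensembles** — canonical correlation analysis between
   per-network activity features and DDM parameters yields three component
   pairs (choice, responsiveness, pliancy); bin-to-bin and zone-to-zone
   activity changes are projected through them to time-resolved "drives"
   and predicted decision-policy changes.

## The rate network

The circuit comprises 10 cell types — cortex (Cx), cortical interneurons
(CxI), striatal direct and indirect spiny projection neurons (dSPN, iSPN),
striatal fast-spiking interneurons (FSI), prototypic and arkypallidal
external pallidum (GPeP, GPeA), subthalamic nucleus (STN), internal
pallidum (GPi), and thalamus (Th). All but CxI and FSI are duplicated into
left and right action channels (18 population instances). Connectivity
follows the three classical sub-circuits: the direct pathway
(Cx→dSPN⊣GPi⊣Th, with Th→Cx closing the loop), the indirect pathway
(Cx→iSPN⊣GPeP⊣{STN, GPi}, STN→{GPeP, GPi}), and the pallidostriatal
pathway (STN→GPeA⊣{dSPN, iSPN, FSI}), plus the hyperdirect Cx→STN edge,
shared feedback inhibition (CxI⊣Cx, FSI⊣SPNs) and thalamostriatal support
(Th→SPNs). Lateralized populations connect within their channel; shared
populations couple the channels and mediate the between-channel
competition.

Each population's rate follows a noisy leaky update

    r_i(t+dt) = r_i + dt/τ_i · (−r_i + φ(Σ_j W_ij r_j + I_i + s_i(t)))
                + σ_i √dt · ξ_i,

with `φ(x) = r_max tanh(x₊/r_max)` a non-negative saturating transfer
(`r_max` = 150 Hz), rates clipped at zero, τ between 10 and 20 ms, and dt
= 1 ms. A trial runs 200 ms without stimulus, then a step input of 20 Hz
is applied to Cx in both channels. A decision occurs when either thalamic
population's 10 ms-binned rate first reaches 30 Hz; trials with no
decision within 1000 ms time out and are excluded downstream. After the
decision, half of the cortical input to the selected channel is sustained
for a 200 ms consolidation phase, followed by a 150 ms inter-trial
interval; these phases are simulated for realism but excluded from every
analysis, which uses bins up to the decision only.

**Calibration.** The shipped default weights and tonic drives were chosen
once so the model occupies the qualitative operating regimes of the real
circuit: GPeP (~64 Hz) and GPi (~40 Hz) sit high at rest and dip under
drive; dSPN, iSPN and GPeA sit low (0–10 Hz) and surge after stimulus
onset; thalamus ramps from ~12 Hz through the 30 Hz decision threshold as
GPi output collapses; fewer than 1% of trials time out; and trial-mean
cortical and striatal activity correlate positively across trials. With
symmetric input, channel competition is resolved by noise amplified
through the direct-pathway loop (Cx→dSPN⊣GPi⊣Th→Cx) against the shared
CxI normalization, giving a balanced choice distribution and decision
times of roughly 50–700 ms.

**What the surrogate does not capture.** Rates are population means: no
spike synchrony, bursting, conductance dynamics, or within-population
heterogeneity; no dopaminergic plasticity or reward feedback. Passing
tests therefore demonstrate the correctness of the analysis machinery and
the qualitative circuit logic, not quantitative fidelity to any spiking
model or biological recording.

## Network surveys

The survey-scale analysis averages over many network configurations. The
`genetic_search` operation explores the 13 searchable connection weights
(spanning all three pathways) with tournament selection, uniform
crossover, and bound-clipped Gaussian mutation; fitness is feasibility
first (rates inside per-population target ranges, <1% timeouts, positive
cortex–striatum correlation), then distance to the range midpoints. The
end-to-end pipeline samples its networks more cheaply: the 13 weights are
jittered uniformly within ±15% of the defaults and candidates that time
out in a 16-trial screen are rejected — the same feasibility-filter role
at a fraction of the cost. The default desk scale is 30 networks × 50
trials (a scaled-down version of the survey scale of 300 × 50); reports
are labelled with their scale, and 30 is the minimum that keeps the
18+4-variable CCA overdetermined.

## Binarization

Per population, rates from all non-timeout trials are pooled up to each
trial's decision time into a histogram (Freedman–Diaconis bins, 1 Hz
minimum width). Modality is decided on counts smoothed with a 5-bin moving
average: exactly two local maxima with prominence ≥10% of the global
maximum means bimodal, in which case the threshold is the midpoint of the
two peak locations. Otherwise the threshold sits at the rate where the
cumulative counts reach 10% of the total when the pre-stimulus baseline
exceeds the near-decision rate (the dip populations, GPeP and GPi), and at
90% otherwise (the surge populations). The baseline window is the
pre-stimulus bins; the near-decision window is the last 3 bins before the
decision (configurable). A bin's bit is 1 iff its rate is strictly above
the threshold; a rate exactly at threshold maps to 0. Thresholds are
estimated per network, matching the per-network analyses downstream.
Degenerate single-valued histograms threshold at that value with a
warning.

## CLAW

States are the Boolean patterns of 10 encoded populations — dSPN, iSPN,
GPi, GPeP, Th in both channels — read as integers under the fixed bit
order (MSB→LSB) dSPN-L, dSPN-R, iSPN-L, iSPN-R, GPi-L, GPi-R, GPeP-L,
GPeP-R, Th-L, Th-R. This order reproduces the landmark labels of the
decision process: the pre-stimulus state 60 (both GPi and GPeP active),
the launch states 61–63 (thalamic bits joining), the left-commitment
sequence 575→543→535/663, the deliberation loops 63→55→183→191→63 and
247↔243↔251, and the neutral competition state 783. STN and GPeA bits are
tracked separately for per-state activation statistics but do not enter
the label.

Transitions are counted over the pooled per-trial state sequences either
at label-change events (`per_change`, the default — dwell repetitions
collapse, so edges connect distinct states) or over every consecutive bin
pair (`per_bin`, including self-transitions). Each trial's final label
adds one *end* count; probabilities normalize each source state's outgoing
plus end mass to one. Pruning keeps each state's outgoing edges in
descending probability order up to the first relative gap of at least 25%:
retain edges 1..p for the smallest p with (prob_p − prob_{p+1})/prob_p ≥
0.25, all edges if no gap qualifies. End probabilities are always
retained.

Per-state statistics are computed over the trials that visit the state:
mean decision time, left/right choice counts, the Kullback–Leibler
divergence KL(left‖right) between the choice-conditioned decision-time
histograms (10 shared bins, additive smoothing ε = 1/total count, natural
log; flagged undefined rather than infinite when only one choice class
visits), and the STN/GPeA activation probabilities over occupied bins.
Decision-time tertiles use the empirical 1/3 and 2/3 quantiles
(inverted-CDF convention, so nine distinct values split exactly 3/3/3).

**Zones.** The canonical partition assigns: zone I = {60, 61, 62, 63}
(launch), zone II = {55, 59, 183, 191, 123, 127} (initial deliberation),
zone V = {247, 243, 251} (second deliberation), zone VI = {783} (neutral
competition), and zones III/IV (left/right commitment arms) seeded with
{575, 543, 535, 663} and its channel mirror. The arms are closed to a
fixpoint under two rules: (a) a retained successor of an arm state joins
that arm if it carries end mass (or leads to the arms) *and* its visiting
trials lean toward that arm's choice; (b) the L/R bit-swap mirror of any
arm state joins the opposite arm. The lean requirement keeps the closure
faithful to the arms' meaning as committed trajectories; without it, on
some samples the first-closed arm absorbs ambiguous states. Everything
else is `unassigned`. Zone-level edges aggregate occupancy-weighted state
transition probabilities; a zone's stay probability is its within-zone
plus end mass.

## Drift-diffusion model

Evidence x(t) starts at z·a between absorbing boundaries 0 and a, drifts
at rate v (positive toward the left/upper boundary) with unit diffusion
(the standard identifiability convention), and the response time adds the
onset time t. The simulator is Euler–Maruyama at dt ≤ 1 ms. The fitter
maximizes the exact first-passage likelihood with the truncated-series
density — small-time and large-time expansions selected per evaluation by
the standard accuracy criterion at 10⁻⁷ — starting from closed-form
moment-based estimates and refined by Nelder–Mead under transforms that
enforce a > 0, 0 < z < 1 and 0 < t < min RT. The right-choice density uses
the reflection v → −v, z → 1 − z. Fitting is per network by maximum
likelihood (each network is an independent ~50-trial sample and the
downstream CCA needs only point estimates); z is fitted freely by default
(`fit_z=False` pins it near 0.5). One-sided samples and non-convergence
are flagged, never silent.

## Control ensembles

Per network, activity is summarized by 18 features: sum and difference
(left − right) of the trial-averaged rates of the 8 lateralized cell types,
plus CxI and FSI. CCA between the feature matrix and the per-network DDM
parameters standardizes both sides, whitens with a 10⁻⁸ ridge, and takes
the SVD of the whitened cross-covariance; loadings are reported in
standardized units with each activity-side component's largest-magnitude
loading made positive (CCA signs are arbitrary). Components are labelled
by pattern: *choice* has the largest combined mass on difference features
and on v; of the remaining two, *responsiveness* is the one whose a and t
loadings share a sign, and *pliancy* the one where they differ; ambiguous
patterns are labelled with a low-confidence flag.

Within trials, the drive of each ensemble at bin k is the projection of
the standardized feature increment between bins k−1 and k onto the
activity loadings (the onset bin's increment is zero by the baseline
convention). Trials are grouped fast/slow (first/third decision-time
tertile) × left/right, aligned backward from the decision time, and the
cumulative group-mean drives are reported as a percentage of the group's
pre-stimulus standardized feature magnitude. Onset timing of a drive is
the earliest aligned bin from which the curve stays on the sign of its
final value at ≥20% of its magnitude. For zone transitions, per-network
zone-mean features are differenced for each directly-observed ordered zone
pair, projected to drives (×U) and then to standardized DDM-parameter
changes (×Vᵀ), rescaled to raw parameter units, and summarized by medians
and by percentage change relative to each network's fitted static
parameters; pairs observed in no network are omitted.

## Numerical and design notes

- All randomness derives from one global seed through named substreams
  (network sampling, trials, screening, DDM); identical configuration and
  seed give byte-identical outputs.
- Ties: a rate equal to a binarization threshold is inactive; if both
  thalamic populations cross 30 Hz in the same bin the higher rate wins.
- The transition graph normalizes per source state, so retained + pruned +
  end mass is exactly 1 before pruning; after pruning, retained + end ≤ 1.
- Equal-mass tertiles warn and collapse to a single class when all
  decision times coincide.
- Output directories are stamped with the pipeline-config hash and refuse
  to overwrite results produced under a different hash.

## Known limitations

- Desk-scale CCA (30 networks, 22 variables) is close to saturation; the
  leading canonical correlation is optimistic and component loadings are
  noisier than at survey scale. The component *ordering* by correlation
  may differ from larger studies.
- The zone-arm closure depends on the pruned graph and choice-lean
  statistics; very small samples can leave arm states unassigned.
- The DDM has fixed boundaries; time-varying policies are represented only
  through the ensemble projections, not by a time-varying likelihood.
- Scripted traces and the rate surrogate share the package's binarization
  conventions; external data with different dynamic ranges should be
  checked against the histogram modality heuristics before trusting
  thresholds.
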