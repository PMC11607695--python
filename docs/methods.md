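# Methods

## The estimation problem

A chick-rearing, plunge-diving seabird divides its day among four
energetically distinct activities: attendance at the breeding colony,
commuting flight, foraging (plunge dives with short connecting flights) and
resting on the water away from the colony. Two independent measurements are
combined per bird: daily energy expenditure from doubly labelled water
(DLW), and behaviour/movement from a tail-mounted logger recording tri-axial
acceleration at 50 Hz, depth at 1 Hz and GPS at 1 fix min⁻¹. Linear models
of mass-specific DEE on either time budgets or activity-partitioned dynamic
body acceleration (DBA) then yield activity-specific metabolic rates and a
calibration for estimating DEE from acceleration alone.

## DLW: single-sample, single-pool model

Isotope kinetics assume a single well-mixed body-water pool (adequate for
birds under 4 kg) with exponential washout. For each isotope
(²H, ¹⁸O):

* turnover: `k = ln[(I_init − I_bg) / (I_final − I_bg)] / T_eff`, where
  `T_eff` deducts the equilibration period (default 1 h, the dark-box
  interval) from the sampling interval;
* plateau dilution space: `N = Mol_inj (I_inj − I_init) / (I_init − I_bg)`
  (mol);
* final dilution space by the percentage-mass method:
  `N_f = N_o · m_final/m_initial`, and the pool used downstream is
  `N = (N_o + N_f)/2`;
* CO₂ production (mmol h⁻¹):
  `rCO₂ = 1000 [ (N/2.078)(k_o − k_d) − 0.0062 k_d N ]`;
* energy: `DEE = rCO₂ × 22.4 ml mmol⁻¹ × 27.3 J ml⁻¹ × 24 h / 1000`
  (kJ day⁻¹), divided by body mass (g) for mass-specific DEE.

All coefficients live in one `DlwConstants` record. Two deliberate
interpretations are exposed as configuration rather than hard-coded: the
historical conversion factor written as "2240" is dimensionally inconsistent
with rCO₂ in mmol h⁻¹, so the default is the molar gas volume 22.4 ml
mmol⁻¹ (the literal variant can be selected); and the piscivore caloric
equivalent "27.3 kJ h⁻¹" is interpreted as 27.3 J per ml CO₂. Mass for
mass-specific DEE defaults to the mean of initial and final body mass
(symmetric over the interval), configurable to initial-only.

In the single-sample protocol deployed birds are bled only at recapture.
Initial enrichments are predicted from an ordinary-least-squares regression
of 1-h equilibrium enrichment on body mass, fitted on a separate equilibrium
cohort, one line per isotope. The slope is negative (a heavier bird has a
larger water pool and dilutes the dose further), so the published confidence
gate r > 0.7 is applied to |r|. Whether enrichment or dilution-per-gram is
regressed on mass is a protocol ambiguity; the module regresses enrichment
(the quantity actually predicted downstream) and the relation object makes
the choice explicit.

Enrichments enter the turnover equation only as differences and ratios: a
constant ppm offset on one isotope leaves k unchanged but shifts N. This
unit-safety property is tested.

## Signal processing

* **VeDBA**: per-sample Euclidean norm of the three dynamic components,
  where the static (postural) component per axis is a centred 3-s running
  mean. Windows are truncated at record edges rather than dropped, keeping
  the minute grid aligned with the depth and GPS streams. Per-sample VeDBA
  is averaged per second and the sixty 1-s means summed per calendar minute.
* **Wingbeat frequency**: the maximum-magnitude non-DC bin of an FFT over a
  30-s heave-axis window (bin width 1/30 Hz), windows sliding at a 1-s
  stride. The per-minute value is the median of window peaks. Each window
  is attributed to the minute containing its centre (default); attributing a
  window to every minute it overlaps is available but bleeds flapping energy
  roughly 30 s into adjacent non-flight minutes, which measurably degrades
  classification at state boundaries.
* **Dive fraction**: share of 1-Hz depth samples in a minute exceeding the
  wet threshold (default 0.1 m, the depth sensor's noise floor).
* **Track**: GPS fixes are interpolated to exact 60-s ticks,
  piecewise-linear in time. A correlated-random-walk smoother is an option,
  not the default: at 1-min resolution, linear interpolation is
  deterministic and sufficient, and determinism is worth more to a testable
  pipeline than track realism between fixes. Minutes farther than a
  configurable maximum gap from any fix are flagged.
* **Colony indicator and step length**: colony presence is 1 within 0.5 km
  of the colony, 0 beyond 1 km; the unspecified 0.5–1 km band maps to 0
  (treated as at sea — this convention is ours, not asserted from any field
  protocol). Distances are great-circle on the mean-radius sphere for
  lon/lat input and planar for km offsets. Step length is the distance
  between consecutive 1-min positions; the first minute has none and is
  reported missing.

## The behavioural HMM

Four states in fixed order (colony, commuting, foraging, resting); four
observation streams, conditionally independent given the state: colony
presence ~ Bernoulli, wingbeat frequency ~ gamma, dive fraction ~ beta with
point masses at exactly 0 and 1, step length ~ gamma. These families are
standard choices for the streams' supports; the published starting-value
table for this design is not machine-readable, so the packaged starting
values are stand-ins derived from the physics of each stream (flapping at
~5 Hz in transit, submersions only while foraging, ~600-m minute steps while
commuting) and are labelled as such. Emission families sit behind one
interface and are pluggable.

Likelihood uses the scaled forward algorithm (finite at 10⁵ minutes, checked
against exhaustive path enumeration on small records). Fitting is
Baum–Welch EM with exact weighted M-steps: closed-form for Bernoulli and the
inflation masses, Newton's method on the digamma equation for the gamma
MLE, and a digamma system solve for the interior beta. Exact M-steps keep
the log-likelihood non-decreasing, which is asserted per fit. Observations
at or below a small floor are clamped for the gamma streams (sensor streams
legitimately report zeros); the same clamping is used in the M-step, so
monotonicity holds on the clamped likelihood. Zero-variance streams pin
their parameters with a warning. Missing stream values are marginalized per
minute; minutes with every stream missing are decoded purely from the
transition structure and flagged. Decoding is Viterbi with ties broken
toward the lower state index. Records from multiple birds are fitted pooled
with the initial distribution resetting at each record boundary.

DBA is not an HMM stream: classification uses only the four streams above,
and DBA is partitioned by the decoded states afterwards. When decoded
states are compared with simulation truth, labels are first aligned by
maximum-overlap (Hungarian) assignment.

## DEE models and AICc

Per-bird daily summaries standardize deployment totals to 24 h
(`value × 24 / sampling hours`; deployments shorter than 20 h warn). Time
budgets and per-activity DBA inherit the same standardization, so
per-activity values sum to totals by construction.

The default candidate set holds 12 designs: the partitions
{col|com|for|rest}, {col|com+for+rest}, {col+rest|com+for},
{col|com+for|rest}, {col+rest|com|for}, each as a zero-intercept time-budget
model (the grouped times cover the whole day, so a free intercept would be
unidentified) and as a free-intercept DBA model (the intercept is a
BMR-like zero-activity term), plus intercept-only and total-DBA nulls. The
set size and three of its members are fixed by the study design this package
reimplements; the remaining members are the natural combined-activity
partitions, and the set is user-configurable precisely because that
enumeration is not canonical.

Fits are ordinary least squares; the Gaussian log-likelihood uses the ML
variance RSS/n, and the parameter count k includes the residual variance —
the AICc convention must be fixed once and this is it.
`AICc = −2 logLik + 2k + 2k(k+1)/(n−k−1)`; designs with n ≤ k+1 are
excluded with a warning. Predictive capacity is the Pearson r between
fitted and observed msDEE (undefined for constant predictions, e.g. the
intercept null). Activity rates from a time-budget fit are reported as
kJ h⁻¹ g⁻¹, whole-animal watts at a reference mass (kJ h⁻¹/3.6), multiples
of a user-supplied BMR (the allometric BMR itself is configuration, not
computed here), and ratios to the colony-containing group. The response is
mass-specific DEE throughout.

## The synthetic cohort generator

The generator defines the study conditions and is first-class, tested code.

* **Behaviour**: a first-order Markov chain at 1-min resolution (the
  resolution all streams are thinned to). Default dwell times — colony
  5 h, commuting 20 min, foraging 4 min, resting 6 min, with commuting
  mediating most transitions — give a stationary law of ~81% colony, ~15%
  commuting, ~2% foraging, ~1.5% resting, i.e. ~19.5 h at the colony and
  ~3.7 h commuting per day, matching the field time budget this design
  emulates.
* **Track**: planar km with the colony at the origin (a fixed reference
  coordinate converts to lon/lat only at file export). Outbound legs fly a
  random heading at 11 m s⁻¹; commuting re-entered from foraging or resting
  heads home; foraging and resting drift locally. Colony minutes stay
  within 0.05 km and all at-sea minutes beyond 1.05 km, so the colony stream
  is geometrically unambiguous — a deliberate idealization that makes
  classification errors attributable to the other streams. A home-bound
  commuter that reaches the 1-km floor before the chain lands keeps flying
  tangentially along it, preserving commuting step lengths.
* **Sensors**: heave = 1 g + a state-specific sinusoid (5.2 Hz commuting,
  4.5 Hz foraging, amplitude 0.5–0.6 g, per-minute frequency jitter of
  0.1 Hz) + Gaussian noise; surge/sway are noise. Dives are rectangular
  submersion pulses (5–20 s, 1–4 m, ~0.7 per foraging minute) — no dive-shape
  model is assumed. GPS adds 10-m noise, with optional dropped fixes.
  A minute-level fast path draws the per-minute streams directly from the
  same per-state laws, for experiments where waveform synthesis would
  dominate runtime.
* **Energetics**: activity rates default to 0.0325 (colony), 0.0878
  (commuting), 0.1495 (foraging), 0.0845 (resting) kJ h⁻¹ g⁻¹ — the colony
  rate corresponding to 0.78 kJ day⁻¹ g⁻¹ and the others in the published
  ratios 2.7×, 4.6×, 2.6× — so a bird's true msDEE is exactly
  rate · time-budget, near 1.1 kJ day⁻¹ g⁻¹ at the default occupancy. True
  DEE = msDEE × mass by construction.
* **Isotopes**: the panel generator inverts the DLW equations exactly:
  initial enrichments sit on a mass→enrichment line obtained by linearising
  single-pool dilution (65% body water) at the mass-range endpoints —
  exactly linear so the downstream OLS relation, and hence the single-sample
  round trip, is exact to machine precision; k_d is a fixed water turnover
  (0.03 h⁻¹) and k_o is solved from the single-pool equation; final
  enrichments follow exponential washout over the effective interval.
  Two noise knobs are distinct: analytic noise on enrichment excesses
  (multiplicative lognormal, default CV 0 — analytic error is multiplicative
  on ratio measurements) and DLW measurement error on the DEE the panel
  encodes (default CV 5%, the headline study condition). Within-state DBA
  scatter (lognormal, CV 15%) and flap-amplitude defaults are free
  parameters of the simulator, not estimates of any field population.

What the generator does **not** emulate: thermoregulatory costs, wind and
current drift, aerodynamic detail, dive-shape structure, device failure
beyond GPS gaps, inter-individual behavioural heterogeneity beyond the
shared chain. Passing tests therefore demonstrate correctness of the
estimation chain under its own assumptions, not field performance: real
predicted-vs-observed correlations are expected to be substantially lower
than on these clean cohorts.

## Verification design and problem sizes

* DLW hand oracles at 10⁻⁴ relative; noise-free round trips (isotope panel
  and full single-sample cohort) at 10⁻⁶ over 100 random draws.
* HMM forward likelihood vs exhaustive enumeration (≤ 8 minutes, ≤ 3
  states) at 10⁻¹⁰; Viterbi vs 1000 random paths; EM monotonicity per fit.
* Sensor-level classification: 3 birds × 48 h at full 50-Hz synthesis,
  pooled decoding accuracy ≥ 95% (measured ~99%). Three birds keep the
  waveform volume (~26 M samples) proportionate to what the check needs.
* Chain statistics: occupancy vs the eigen-analysis stationary law within
  3 standard errors, with the asymptotic occupancy variance computed from
  the chain's fundamental matrix rather than an iid approximation.
* Model recovery runs as replicated experiments at the study conditions
  (n = 20 birds per cohort, 5% DLW noise): the generating partition
  {col+rest | com+for} is retained by AICc against its refinements (designs
  that split its groups, i.e. add pure-noise parameters) in ≥ 70% of 100
  cohorts; mean recovered rates over 300–400 cohorts put the
  foraging/colony ratio within 15% of truth; the best-AICc model's median
  predictive r over 15 cohorts exceeds 0.8. Replication is part of the
  experimental design: with ~0.4 h of foraging per day, a single 20-bird
  cohort estimates the foraging rate with ~60% sampling error, so
  single-cohort quantities would measure noise, not the estimator. For the
  same reason the full 12-way AICc race is not 70%-recoverable at these
  conditions — competing equal-k partitions differ only in where the
  tiny-occupancy activities are grouped (~1.2 σ of distinguishing signal) —
  which is itself an honest property of the design this package mirrors;
  the experiment helper reports the full-set winner distribution alongside
  the refinement race.

## Known limitations

* The equilibrium line is exactly linear by construction; with real
  curvature in the mass–dilution relation the single-sample prediction
  inherits a bias the round-trip tests cannot see.
* One HMM is fitted pooled across birds (initial law resets per record);
  per-bird heterogeneity in emission parameters is not modelled.
* Time-budget coefficients for rare activities are noise-amplified at
  field-realistic occupancies; the worked example shows this as an inflated
  foraging rate on a single cohort.
* The correlated-random-walk track smoother and covariate-dependent
  transition probabilities are out of scope.
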