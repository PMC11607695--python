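# plungedee

Energetics of plunge-diving seabirds from biologging data: doubly-labelled-water
(DLW) field metabolism, dynamic body acceleration (DBA), hidden-Markov
behavioural classification and time–energy budget modelling, exercised end to
end on synthetic cohorts with known ground truth.

The package is aimed at movement ecologists and ecophysiologists who combine
tri-axial accelerometry (50 Hz), depth (1 Hz) and GPS (1 min) with the
single-sample DLW protocol in colonial seabirds, and want every step of that
chain — from raw waveforms to activity-specific metabolic rates — as tested,
reusable code.

## What it computes

**Single-sample DLW energetics.** Turnover rates per isotope
k = ln[(I_init − I_bg)/(I_final − I_bg)]/T_eff, plateau dilution spaces
N = Mol_inj (I_inj − I_init)/(I_init − I_bg), the percentage-mass final
dilution space, and single-pool CO₂ production
rCO₂ = 1000[(N/2.078)(k_o − k_d) − 0.0062 k_d N] (mmol h⁻¹), converted to
daily energy expenditure with a molar gas volume of 22.4 ml mmol⁻¹ and a
piscivore caloric equivalent of 27.3 J ml⁻¹ CO₂. Deployed birds give only a
final blood sample; their initial enrichment is predicted from an
equilibrium cohort's mass–enrichment regression (gated at Pearson |r| > 0.7).

**VeDBA.** Per sample, the Euclidean norm of the dynamic acceleration
components (each axis minus its centred 3-s running mean), smoothed to 1-s
means and summed per minute.

**Behavioural states.** A four-state HMM (colony, commuting, foraging,
resting) over four per-minute streams — colony presence (Bernoulli), FFT
wingbeat frequency (gamma), dive fraction (zero/one-inflated beta), step
length (gamma) — with scaled forward likelihood, Baum–Welch EM and Viterbi
decoding. DBA is deliberately not a classification stream; it is joined to
decoded states afterwards.

**DEE models.** Twelve candidate linear models of mass-specific DEE: five
activity partitions under zero-intercept time-budget and free-intercept DBA
parametrizations, plus intercept-only and total-DBA nulls, ranked by AICc,
with predicted-vs-observed Pearson r, activity-specific metabolic rates and
×BMR multiples.

**Synthetic cohorts.** A Markov-chain behaviour simulator with consistent
tracks, 50-Hz/1-Hz waveform synthesis and an isotope generator that is the
exact inverse of the DLW equations, so noise-free cohorts round-trip to
machine precision and every estimator can be checked against truth.

## Worked example

```sh
plungedee run-all --out demo_run --seed 1
```

runs the full chain on the default synthetic cohort (10 equilibrium birds,
20 deployed birds, 46–61 h deployments, 5% DLW measurement noise) and prints,
among other things:

```
msDEE: 1.109 +/- 0.121 kJ day^-1 g^-1
Mean time budget (h per 24 h): col=19.12, com=3.95, for=0.50, rest=0.43

                     design      kind  k    logLik       AICc     dAICc        r
  DBA: col | com+for | rest       dba  5 48.769406 -83.253098  0.000000 0.983884
DBA: col | com | for | rest       dba  6 48.870948 -79.280358  3.972740 0.984048
    T: col+rest | com | for      time  4 42.302295 -73.937923  9.315176 0.968998
  ...

activity  MR_kJ_h_g     watts     x_bmr  ratio_vs_colony
col+rest   0.034704 14.460104  3.293873         1.000000
     com   0.078955 32.898085  7.493869         2.275093
     for   0.236614 98.589339 22.457708         6.818024
```

The cohort mean mass-specific DEE (~1.1 kJ day⁻¹ g⁻¹), the time budget
(~19 h at the colony, ~4 h commuting) and the commuting cost (~7.5 × a
4.39 W BMR) follow from the default scenario's activity rates and occupancy;
the AICc table shows DBA-partitioned models leading the time-budget forms,
with the nulls last. Foraging occupies so little of the day that its rate
carries the widest uncertainty — visible here as an inflated foraging
coefficient.

The run directory contains `config.yaml`, the simulated cohort, `states.csv`
(decoded behaviour), `dlw_results.csv`, `summaries.csv`, `model_ranking.csv`,
`activity_rates.csv` and `report.md`; every reported number is recomputable
from those tables. Individual stages are available as `plungedee simulate`,
`features`, `classify`, `dlw`, `models` and `validate`.

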