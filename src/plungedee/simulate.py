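"""Synthetic biologging cohorts with known ground truth.

Emulates the full data footprint of a plunge-diving seabird study: a colony
of birds carrying 50-Hz tri-axial accelerometers, 1-Hz depth sensors and
1-min GPS, plus a doubly-labelled-water (DLW) protocol with an equilibrium
set (measured at isotopic equilibrium) and a deployed set (single-sample).
Behaviour is a first-order Markov chain at 1-min resolution over four states
(colony, commuting, foraging, resting); the assigned true daily energy
expenditure of each bird is the sum over states of activity-specific
metabolic rate x time x mass, and the generated isotope panel is the exact
inverse of the energetics pipeline, so noise-free cohorts round-trip to
machine precision.

Geometry is planar, in km, with the colony at the origin; a fixed reference
coordinate converts to lon/lat only when files are written.  Colony minutes
stay within 0.5 km of the colony and all at-sea minutes beyond 1 km so the
colony-presence stream is geometrically unambiguous.

Two fidelity levels are offered: full sensor synthesis
(:func:`simulate_sensors`; waveform-level, expensive) and a minute-level
fast path (:func:`simulate_minute_features`) that draws the per-minute
observation streams directly from the same per-state emission model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import dlw as dlw_mod
from .dlw import DlwConstants

STATES = ("colony", "commuting", "foraging", "resting")
COLONY_LONLAT = (-78.9636, -8.5447)  # reference coordinate for file export
_DEG_PER_KM_LAT = 1.0 / 111.19493  # mean-radius sphere, consistent with haversine

__all__ = [
    "SimScenario", "GroundTruth", "CohortData",
    "simulate_states", "simulate_sensors", "simulate_minute_features",
    "simulate_isotopes", "simulate_cohort", "write_cohort", "stationary_distribution",
    "km_to_lonlat", "default_transition_matrix",
]


def default_transition_matrix() -> np.ndarray:
    """Dwell times ~5 h at the colony, ~20 min commuting, short foraging and
    resting bouts; stationary occupancy ~80% colony / ~15% commuting."""
    tmat = np.zeros((4, 4))
    # colony
    tmat[0] = np.array([0, 1.0, 0, 0]) * (1 / 300.0)
    tmat[0, 0] = 1 - 1 / 300.0
    # commuting
    tmat[1] = np.array([0.35, 0, 0.5, 0.15]) * (1 / 20.0)
    tmat[1, 1] = 1 - 1 / 20.0
    # foraging
    tmat[2] = np.array([0, 0.7, 0, 0.3]) * (1 / 4.0)
    tmat[2, 2] = 1 - 1 / 4.0
    # resting
    tmat[3] = np.array([0, 0.8, 0.2, 0]) * (1 / 6.0)
    tmat[3, 3] = 1 - 1 / 6.0
    return tmat


def stationary_distribution(tmat: np.ndarray) -> np.ndarray:
    """Stationary law of an ergodic chain via eigen-analysis."""
    vals, vecs = np.linalg.eig(np.asarray(tmat, dtype=float).T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


@dataclass
class SimScenario:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the study design: 10 equilibrium + 20 deployed birds,
    deployments drawn from 46-61 h, ~80% of the day at the colony, activity
    rates in the ratios colony : commuting : foraging : resting of
    1 : 2.7 : 4.6 : 2.6 anchored at a colony rate of 0.0325 kJ h^-1 g^-1
    (0.78 kJ day^-1 g^-1), giving a cohort-mean mass-specific DEE near
    1.1 kJ day^-1 g^-1.
    """

    seed: int = 0
    n_equilibrium_birds: int = 10
    n_deployed_birds: int = 20
    deployment_hours: tuple = (46.0, 61.0)
    mass_range_g: tuple = (1200.0, 1800.0)
    transition_matrix: np.ndarray = field(default_factory=default_transition_matrix)
    initial_state: int = 0

    # per-state emission parameters, ordered (colony, commuting, foraging, resting)
    wingbeat_hz: tuple = (0.0, 5.2, 4.5, 0.0)
    flap_amp_g: tuple = (0.0, 0.6, 0.5, 0.0)
    accel_noise_sd_g: tuple = (0.05, 0.05, 0.08, 0.03)
    speed_m_s: tuple = (0.0, 11.0, 2.0, 0.8)
    dba_per_min: tuple = (2.0, 23.0, 28.0, 1.2)
    dba_cv: float = 0.15
    dive_prob_per_min: float = 0.7
    dive_duration_s: tuple = (5.0, 20.0)
    dive_depth_m: tuple = (1.0, 4.0)
    gps_noise_km: float = 0.01
    gps_gap_prob: float = 0.0

    # true activity-specific metabolic rates, kJ h^-1 g^-1
    activity_rates: tuple = (0.0325, 0.0878, 0.1495, 0.0845)

    # isotope / DLW parameters
    I_inj_d: float = 150000.0
    I_inj_o: float = 90000.0
    I_bg_d: float = 150.0
    I_bg_o: float = 2005.0
    mol_inj: float = 0.053
    body_water_fraction: float = 0.65
    k_d: float = 0.03                   # deuterium (water) turnover, h^-1
    mass_loss_frac: tuple = (0.0, 0.03)
    equilibrium_scatter_cv: float = 0.0  # scatter on the equilibrium line
    enrichment_noise_cv: float = 0.0     # analytic noise on enrichments
    dee_noise_cv: float = 0.05           # DLW measurement error on encoded DEE
    dlw_constants: DlwConstants = field(default_factory=DlwConstants)

    def __post_init__(self):
        tmat = np.asarray(self.transition_matrix, dtype=float)
        if tmat.shape != (4, 4) or (tmat < 0).any() \
                or not np.allclose(tmat.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix must be 4x4 row-stochastic")
        self.transition_matrix = tmat
        if not (0 < self.deployment_hours[0] <= self.deployment_hours[1] <= 24 * 14):
            raise ValueError("deployment_hours must be a positive range")
        for name in ("wingbeat_hz", "flap_amp_g", "accel_noise_sd_g",
                     "speed_m_s", "dba_per_min", "activity_rates"):
            if min(getattr(self, name)) < 0:
                raise ValueError(f"{name} must be non-negative")

    # -- equilibrium enrichment line ------------------------------------
    # Linearised single-pool dilution at the mass-range endpoints: heavier
    # bird -> bigger water pool -> more dilution -> lower equilibrium
    # enrichment.  The line is exactly linear in mass so the downstream OLS
    # relation recovers it exactly (single-sample round trip).
    def _pool_at(self, mass_g: float) -> float:
        return self.body_water_fraction * mass_g / 18.0153

    def equilibrium_enrichment(self, mass_g, iso: str):
        lo, hi = self.mass_range_g
        out = {}
        inj = getattr(self, f"I_inj_{iso}")
        bg = getattr(self, f"I_bg_{iso}")

        def exact(m):
            N = self._pool_at(m)
            return (self.mol_inj * inj + N * bg) / (N + self.mol_inj)
        y0, y1 = exact(lo), exact(hi)
        slope = (y1 - y0) / (hi - lo)
        return y0 + slope * (np.asarray(mass_g, dtype=float) - lo)


@dataclass
class GroundTruth:
    """Recovery targets for one cohort: per-bird truth the pipeline should find."""

    states: dict                  # bird -> int state sequence (1-min)
    budgets: pd.DataFrame         # bird, T_col..T_rest (h per 24 h), sampling_h
    energetics: pd.DataFrame      # bird, mass_g, DEE, msDEE, rCO2, dee_encoded


@dataclass
class CohortData:
    scenario: SimScenario
    dlw: pd.DataFrame             # dlw.csv schema, equilibrium + deployed sets
    minutes: dict                 # bird -> minute-level observation table
    tracks: dict                  # bird -> states+positions table
    truth: GroundTruth
    sensors: dict = field(default_factory=dict)  # bird -> SensorBundle (optional)


# ---------------------------------------------------------------------------
# Behaviour and track
# ---------------------------------------------------------------------------

def simulate_states(scenario: SimScenario, bird_id: str, n_minutes: int,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Minute-resolution Markov state sequence with a consistent planar track.

    Track logic: leaving the colony starts an outbound commuting leg on a
    random heading; commuting re-entered from foraging/resting heads home;
    foraging and resting are localized.  Positions in at-sea states are kept
    beyond 1 km of the colony and colony positions within 0.05 km, so the
    colony-presence stream separates geometrically.
    """
    tmat = scenario.transition_matrix
    states = np.empty(n_minutes, dtype=int)
    states[0] = scenario.initial_state
    u = rng.random(n_minutes)
    cum = tmat.cumsum(axis=1)
    for t in range(1, n_minutes):
        states[t] = int(np.searchsorted(cum[states[t - 1]], u[t]))

    xy = np.zeros((n_minutes, 2))
    heading = np.array([1.0, 0.0])
    outbound = True
    r_min = 1.05  # km; at-sea floor radius
    pos = np.zeros(2)
    for t in range(n_minutes):
        s = states[t]
        prev = states[t - 1] if t else 0
        if s == 0:  # colony
            pos = rng.uniform(-0.035, 0.035, size=2)
        else:
            if prev == 0:  # leaving the colony: new trip
                th = rng.uniform(0, 2 * np.pi)
                heading = np.array([np.cos(th), np.sin(th)])
                outbound = True
                pos = heading * r_min  # first at-sea fix just beyond the band
            elif s == 1:  # commuting
                if prev in (2, 3):
                    outbound = False
                step = scenario.speed_m_s[1] * 60.0 / 1000.0
                direction = heading if outbound else -pos / max(np.hypot(*pos), 1e-9)
                cand = pos + step * direction + rng.normal(0, 0.02, 2)
                if np.hypot(*cand) < r_min:
                    # home-bound but the chain has not landed yet: keep flying,
                    # tangentially along the offshore floor circle
                    r = max(np.hypot(*pos), r_min)
                    dtheta = step / r
                    th0 = np.arctan2(pos[1], pos[0])
                    cand = r_min * np.array([np.cos(th0 + dtheta),
                                             np.sin(th0 + dtheta)])
                pos = cand
            else:  # foraging / resting: localized movement
                outbound = False
                step = scenario.speed_m_s[s] * 60.0 / 1000.0
                cand = pos + rng.normal(0, max(step, 0.01), 2)
                if np.hypot(*cand) < r_min:
                    cand *= r_min / max(np.hypot(*cand), 1e-9)
                pos = cand
        xy[t] = pos
    return pd.DataFrame({"bird": bird_id, "minute": np.arange(n_minutes),
                         "state": states, "x_km": xy[:, 0], "y_km": xy[:, 1]})


def simulate_state_matrix(tmat: np.ndarray, n_chains: int, n_steps: int,
                          rng: np.random.Generator, initial_state: int = 0
                          ) -> np.ndarray:
    """(n_chains, n_steps) Markov state paths, vectorized across chains."""
    tmat = np.asarray(tmat, dtype=float)
    cum = tmat.cumsum(axis=1)
    out = np.empty((n_chains, n_steps), dtype=np.int8)
    out[:, 0] = initial_state
    u = rng.random((n_chains, n_steps))
    for t in range(1, n_steps):
        out[:, t] = (u[:, t, None] > cum[out[:, t - 1]]).sum(axis=1)
    return out


def simulate_budget_summaries(scenario: SimScenario, rng: np.random.Generator,
                              n_birds: int | None = None,
                              rates_by_state: np.ndarray | None = None,
                              deployment_minutes: int = 2880) -> pd.DataFrame:
    """Per-bird DailyActivitySummary table straight from chain occupancy.

    The fast generator for replicated model-selection experiments: time
    budgets come from vectorized Markov chains, per-activity DBA from the
    per-state DBA rates (with lognormal scatter), and msDEE from the
    activity-rate model plus DLW measurement noise (``dee_noise_cv``).
    ``rates_by_state`` overrides the scenario's activity rates, e.g. to
    generate from a grouped (combined-activity) truth.
    """
    n = scenario.n_deployed_birds if n_birds is None else n_birds
    rates = (np.asarray(scenario.activity_rates) if rates_by_state is None
             else np.asarray(rates_by_state, dtype=float))
    states = simulate_state_matrix(scenario.transition_matrix, n,
                                   deployment_minutes, rng,
                                   scenario.initial_state)
    hours = deployment_minutes / 60.0
    counts = np.stack([(states == j).sum(axis=1) for j in range(4)], axis=1)
    budget24 = counts / 60.0 * 24.0 / hours
    msdee = budget24 @ rates
    cv = scenario.dee_noise_cv
    if cv > 0:
        msdee = msdee * np.exp(rng.normal(0, cv, n) - cv ** 2 / 2)
    dba_rate = np.asarray(scenario.dba_per_min)
    dcv = scenario.dba_cv
    scatter = np.exp(rng.normal(0, dcv, (n, 4)) - dcv ** 2 / 2)
    dba24 = counts * dba_rate * scatter * 24.0 / hours
    out = pd.DataFrame({
        "bird": [f"B{i:03d}" for i in range(n)],
        "T_col": budget24[:, 0], "T_com": budget24[:, 1],
        "T_for": budget24[:, 2], "T_rest": budget24[:, 3],
        "DBA_col": dba24[:, 0], "DBA_com": dba24[:, 1],
        "DBA_for": dba24[:, 2], "DBA_rest": dba24[:, 3],
        "DBA_total": dba24.sum(axis=1), "msDEE": msdee,
        "sampling_h": hours})
    return out


# ---------------------------------------------------------------------------
# Sensors
# ---------------------------------------------------------------------------

@dataclass
class SensorBundle:
    accel: pd.DataFrame   # t, ax, ay, az  (50 Hz, g)
    depth: pd.DataFrame   # t, depth       (1 Hz, m)
    gps: pd.DataFrame     # t, x_km, y_km  (1 per min)


def simulate_sensors(states_df: pd.DataFrame, scenario: SimScenario,
                     rng: np.random.Generator, fs: float = 50.0) -> SensorBundle:
    """50-Hz acceleration, 1-Hz depth and 1-min GPS for one deployment.

    Acceleration: gravity on the heave axis plus a state-specific sinusoid at
    the state's wingbeat frequency/amplitude plus Gaussian noise.  Depth:
    rectangular submersion pulses in foraging minutes only.  GPS: the track
    positions plus isotropic noise, with optional dropped fixes.
    """
    if min(scenario.accel_noise_sd_g) < 0:
        raise ValueError("noise SD must be non-negative")
    states = states_df["state"].to_numpy()
    n_min = len(states)
    spm = int(60 * fs)
    t = np.arange(n_min * spm) / fs
    st_per_sample = np.repeat(states, spm)
    amp = np.asarray(scenario.flap_amp_g)[st_per_sample]
    # per-minute physiological jitter on the wingbeat frequency (sd 0.1 Hz)
    f_min = np.asarray(scenario.wingbeat_hz)[states]
    f_min = np.where(f_min > 0, np.abs(f_min + rng.normal(0, 0.1, n_min)), 0.0)
    freq = np.repeat(f_min, spm)
    sd = np.asarray(scenario.accel_noise_sd_g)[st_per_sample]
    flap = amp * np.sin(2 * np.pi * freq * t)
    noise = rng.normal(0.0, 1.0, (3, t.size)) * sd
    accel = pd.DataFrame({"t": t, "ax": noise[0], "ay": noise[1],
                          "az": 1.0 + flap + noise[2]})

    t_depth = np.arange(n_min * 60, dtype=float)
    depth = np.zeros(t_depth.size)
    for m in np.nonzero(states == 2)[0]:
        if rng.random() < scenario.dive_prob_per_min:
            dur = int(round(rng.uniform(*scenario.dive_duration_s)))
            d = rng.uniform(*scenario.dive_depth_m)
            start = 60 * m + rng.integers(0, max(60 - dur, 1))
            depth[start:start + dur] = d
    depth_df = pd.DataFrame({"t": t_depth, "depth": depth})

    gps = states_df[["minute", "x_km", "y_km"]].copy()
    gps["t"] = gps["minute"].to_numpy(dtype=float) * 60.0
    gps["x_km"] += rng.normal(0, scenario.gps_noise_km, n_min)
    gps["y_km"] += rng.normal(0, scenario.gps_noise_km, n_min)
    if scenario.gps_gap_prob > 0:
        keep = rng.random(n_min) >= scenario.gps_gap_prob
        keep[0] = keep[-1] = True
        gps = gps[keep]
    return SensorBundle(accel=accel, depth=depth_df,
                        gps=gps[["t", "x_km", "y_km"]].reset_index(drop=True))


def simulate_minute_features(states_df: pd.DataFrame, scenario: SimScenario,
                             rng: np.random.Generator) -> pd.DataFrame:
    """Minute-level observation streams drawn directly from the emission model.

    The fast alternative to synthesizing 50-Hz waveforms: wingbeat frequency
    is the state's flapping frequency plus FFT-bin-scale jitter in flapping
    states and a broad noise-peak draw otherwise; dive fraction, step length
    and DBA follow the same per-state laws the sensor path would yield.
    """
    states = states_df["state"].to_numpy()
    n = len(states)
    wb = np.empty(n)
    flap = np.asarray(scenario.wingbeat_hz)[states]
    is_flap = flap > 0
    wb[is_flap] = flap[is_flap] + rng.normal(0, 0.05, is_flap.sum())
    wb[~is_flap] = rng.uniform(0.5, 25.0, (~is_flap).sum())  # noise-floor peak
    dive = np.zeros(n)
    forage = states == 2
    diving = forage & (rng.random(n) < scenario.dive_prob_per_min)
    dive[diving] = rng.uniform(*scenario.dive_duration_s, diving.sum()) / 60.0
    step = np.asarray(scenario.speed_m_s)[states] * 60.0
    step = np.abs(step + rng.normal(0, np.maximum(0.15 * step, 12.0), n))
    dba_mu = np.asarray(scenario.dba_per_min)[states]
    cv = scenario.dba_cv
    dba = dba_mu * np.exp(rng.normal(0, cv, n) - cv ** 2 / 2)
    colony = (states == 0).astype(float)
    return pd.DataFrame({"bird": states_df["bird"].to_numpy(),
                         "minute": states_df["minute"].to_numpy(),
                         "colony": colony, "wingbeat_hz": wb,
                         "dive_frac": dive, "step_m": step, "dba": dba})


# ---------------------------------------------------------------------------
# Isotopes
# ---------------------------------------------------------------------------

def simulate_isotopes(true_dee_kj_day: float, mass_initial_g: float,
                      mass_final_g: float, deployment_h: float,
                      scenario: SimScenario,
                      rng: np.random.Generator | None = None,
                      enrichment_noise_cv: float | None = None) -> dict:
    """Isotope panel that the energetics pipeline inverts back to ``true_dee``.

    Exact inverse of the single-sample calculation under the scenario's
    constants: initial enrichments sit on the equilibrium line at the bird's
    mass, the oxygen turnover is solved from the single-pool equation, and
    final enrichments follow exponential washout over the effective interval.
    Optional multiplicative lognormal noise applies to enrichment excesses.
    """
    if true_dee_kj_day <= 0:
        raise ValueError("true DEE must be positive")
    c = scenario.dlw_constants
    I_init = {iso: float(scenario.equilibrium_enrichment(mass_initial_g, iso))
              for iso in ("d", "o")}
    bg = {"d": scenario.I_bg_d, "o": scenario.I_bg_o}
    inj = {"d": scenario.I_inj_d, "o": scenario.I_inj_o}
    N_o = scenario.mol_inj * (inj["o"] - I_init["o"]) / (I_init["o"] - bg["o"])
    N_pool = N_o * (1.0 + mass_final_g / mass_initial_g) / 2.0
    rco2 = true_dee_kj_day * 1000.0 / (c.ml_per_mmol * c.joule_per_ml_co2 * 24.0)
    k_d = scenario.k_d
    k_o = k_d + (c.pool_divisor / N_pool) * (rco2 / 1000.0
                                             + c.fractionation_coeff * k_d * N_pool)
    t_eff = deployment_h - c.equilibration_h
    cv = scenario.enrichment_noise_cv if enrichment_noise_cv is None else enrichment_noise_cv
    if cv < 0:
        raise ValueError("enrichment noise CV must be non-negative")
    out = {"mol_inj": scenario.mol_inj, "t_deploy_h": deployment_h,
           "I_inj_d": inj["d"], "I_inj_o": inj["o"],
           "I_bg_d": bg["d"], "I_bg_o": bg["o"],
           "true_k_d": k_d, "true_k_o": k_o, "true_rco2": rco2, "true_N_o": N_o}
    for iso, k in (("d", k_d), ("o", k_o)):
        excess = (I_init[iso] - bg[iso]) * np.exp(-k * t_eff)
        if cv > 0 and rng is not None:
            excess *= np.exp(rng.normal(0, cv) - cv ** 2 / 2)
        if excess <= 0:
            raise ValueError(f"isotope {iso!r} washed out below background: "
                             "deployment too long for the dose")
        out[f"I_init_{iso}"] = I_init[iso]
        out[f"I_final_{iso}"] = bg[iso] + excess
    return out


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def simulate_cohort(scenario: SimScenario, with_sensors: bool = False,
                    sensor_birds: int | None = None) -> CohortData:
    """Full cohort: equilibrium set, deployed set, sensors/minutes, ground truth.

    ``with_sensors`` synthesizes the 50-Hz/1-Hz waveforms; by default only
    minute-level observation tables are produced (``sensor_birds`` limits the
    waveform synthesis to the first few deployed birds).
    """
    rng = np.random.default_rng(scenario.seed)
    if scenario.n_deployed_birds < 3:
        warnings.warn("fewer than 3 deployed birds: model fitting is degenerate",
                      stacklevel=2)
    rates = np.asarray(scenario.activity_rates)

    # equilibrium set
    eq_rows = []
    for i in range(scenario.n_equilibrium_birds):
        mass = rng.uniform(*scenario.mass_range_g)
        row = {"bird": f"EQ{i:02d}", "set": "equilibrium",
               "mass_initial_g": mass, "mass_final_g": mass,
               "I_bg_d": scenario.I_bg_d, "I_bg_o": scenario.I_bg_o,
               "I_inj_d": scenario.I_inj_d, "I_inj_o": scenario.I_inj_o,
               "mol_inj": scenario.mol_inj, "t_deploy_h": np.nan,
               "I_final_d": np.nan, "I_final_o": np.nan}
        for iso in ("d", "o"):
            y = float(scenario.equilibrium_enrichment(mass, iso))
            cv = scenario.equilibrium_scatter_cv
            if cv > 0:
                bg = getattr(scenario, f"I_bg_{iso}")
                y = bg + (y - bg) * np.exp(rng.normal(0, cv) - cv ** 2 / 2)
            row[f"I_init_{iso}"] = y
        eq_rows.append(row)

    # deployed set
    dep_rows, minutes, tracks, states_by_bird, sensors = [], {}, {}, {}, {}
    budget_rows, energy_rows = [], []
    n_sensor = scenario.n_deployed_birds if sensor_birds is None else sensor_birds
    for i in range(scenario.n_deployed_birds):
        bird = f"DP{i:02d}"
        hours = rng.uniform(*scenario.deployment_hours)
        n_min = int(round(hours * 60))
        hours = n_min / 60.0
        mass_i = rng.uniform(*scenario.mass_range_g)
        mass_f = mass_i * (1.0 - rng.uniform(*scenario.mass_loss_frac))
        track = simulate_states(scenario, bird, n_min, rng)
        states = track["state"].to_numpy()
        counts = np.bincount(states, minlength=4)
        hours_per_state = counts / 60.0
        budget24 = hours_per_state * 24.0 / hours
        mass_mean = 0.5 * (mass_i + mass_f)
        msdee_true = float((rates * budget24).sum())
        dee_true = msdee_true * mass_mean
        # DLW measurement error: the panel encodes a noisy version of truth
        cvd = scenario.dee_noise_cv
        dee_enc = dee_true * (np.exp(rng.normal(0, cvd) - cvd ** 2 / 2)
                              if cvd > 0 else 1.0)
        panel = simulate_isotopes(dee_enc, mass_i, mass_f, hours, scenario, rng)
        dep_rows.append({"bird": bird, "set": "deployed",
                         "mass_initial_g": mass_i, "mass_final_g": mass_f,
                         "I_bg_d": scenario.I_bg_d, "I_bg_o": scenario.I_bg_o,
                         "I_init_d": np.nan, "I_init_o": np.nan,  # single-sample
                         "I_final_d": panel["I_final_d"],
                         "I_final_o": panel["I_final_o"],
                         "I_inj_d": scenario.I_inj_d, "I_inj_o": scenario.I_inj_o,
                         "mol_inj": scenario.mol_inj, "t_deploy_h": hours})
        minutes[bird] = simulate_minute_features(track, scenario, rng)
        tracks[bird] = track
        states_by_bird[bird] = states
        if with_sensors and i < n_sensor:
            sensors[bird] = simulate_sensors(track, scenario, rng)
        budget_rows.append({"bird": bird, "sampling_h": hours,
                            "T_col": budget24[0], "T_com": budget24[1],
                            "T_for": budget24[2], "T_rest": budget24[3]})
        energy_rows.append({"bird": bird, "mass_g": mass_mean,
                            "mass_initial_g": mass_i, "mass_final_g": mass_f,
                            "DEE_kJ_day": dee_true, "msDEE": msdee_true,
                            "rCO2_mmol_h": panel["true_rco2"],
                            "dee_encoded": dee_enc,
                            "msdee_encoded": dee_enc / mass_mean,
                            "sex": "M" if mass_i < np.mean(scenario.mass_range_g)
                            else "F"})

    truth = GroundTruth(states=states_by_bird,
                        budgets=pd.DataFrame(budget_rows),
                        energetics=pd.DataFrame(energy_rows))
    return CohortData(scenario=scenario,
                      dlw=pd.DataFrame(eq_rows + dep_rows),
                      minutes=minutes, tracks=tracks, truth=truth,
                      sensors=sensors)


# ---------------------------------------------------------------------------
# File export
# ---------------------------------------------------------------------------

def km_to_lonlat(x_km, y_km, origin=COLONY_LONLAT):
    lon0, lat0 = origin
    lat = lat0 + np.asarray(y_km) * _DEG_PER_KM_LAT
    lon = lon0 + np.asarray(x_km) * _DEG_PER_KM_LAT / np.cos(np.radians(lat0))
    return lon, lat


_T0 = pd.Timestamp("2019-11-11T00:00:00Z")


def write_cohort(cohort: CohortData, outdir) -> Path:
    """Serialize a cohort to the documented plain-text layout.

    ``<outdir>/dlw.csv`` plus one directory per deployed bird containing
    ``gps.csv`` (ISO-8601 UTC, lon/lat), ``minutes.csv``, and, when sensor
    waveforms were generated, ``accel.csv`` and ``depth.csv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.dlw.to_csv(outdir / "dlw.csv", index=False, float_format="%.10g")
    for bird, track in cohort.tracks.items():
        bdir = outdir / bird
        bdir.mkdir(exist_ok=True)
        lon, lat = km_to_lonlat(track["x_km"], track["y_km"])
        gps = pd.DataFrame({
            "timestamp": (_T0 + pd.to_timedelta(track["minute"] * 60, unit="s")
                          ).dt.strftime("%Y-%m-%dT%H:%M:%SZ"),
            "lon": np.round(lon, 7), "lat": np.round(lat, 7)})
        gps.to_csv(bdir / "gps.csv", index=False)
        cohort.minutes[bird].to_csv(bdir / "minutes.csv", index=False,
                                    float_format="%.8g")
        if bird in cohort.sensors:
            sb = cohort.sensors[bird]
            sb.accel.to_csv(bdir / "accel.csv", index=False, float_format="%.6g")
            sb.depth.to_csv(bdir / "depth.csv", index=False, float_format="%.4g")
    return outdir
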