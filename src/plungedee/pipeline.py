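"""Pipeline orchestration: simulate -> features -> classify -> DLW -> models.

One run writes one immutable directory holding the config copy, every
intermediate table and a plain-text report, so each reported number can be
recomputed from the shipped artefacts.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dlw as dlw_mod
from . import hmm as hmm_mod
from . import models as models_mod
from . import signal as signal_mod
from .dlw import DlwConstants
from .simulate import SimScenario, simulate_cohort, write_cohort, COLONY_LONLAT

log = logging.getLogger("plungedee")

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Everything a run needs: scenario, signal constants, DLW constants, model set."""

    seed: int = 1
    colony_lonlat: tuple = COLONY_LONLAT
    # signal constants
    fs_hz: float = 50.0
    static_window_s: float = 3.0
    wingbeat_window_s: float = 30.0
    wet_threshold_m: float = 0.1
    r_in_km: float = 0.5
    r_out_km: float = 1.0
    # HMM
    hmm_max_iter: int = 60
    hmm_tol: float = 1e-6
    # models
    bmr_w: float = 4.39
    reference_mass_g: float = 1500.0
    # simulation
    scenario: SimScenario = field(default_factory=SimScenario)
    with_sensors: bool = False
    sensor_birds: int = 3

    def __post_init__(self):
        for name, lo, hi in (("fs_hz", 1, 1000), ("static_window_s", 0.1, 60),
                             ("wingbeat_window_s", 1, 300), ("wet_threshold_m", 0, 5),
                             ("r_in_km", 0, 10), ("r_out_km", 0, 50),
                             ("bmr_w", 0, 1000)):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside valid range [{lo}, {hi}]")
        if self.r_out_km < self.r_in_km:
            raise ValueError("r_out_km must be >= r_in_km")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    scen = d.pop("scenario", {})
    const = scen.pop("dlw_constants", {})
    scen["dlw_constants"] = DlwConstants(**const)
    for key in ("deployment_hours", "mass_range_g", "wingbeat_hz", "flap_amp_g",
                "accel_noise_sd_g", "speed_m_s", "dba_per_min", "activity_rates",
                "dive_duration_s", "dive_depth_m", "mass_loss_frac"):
        if key in scen:
            scen[key] = tuple(scen[key])
    scen["transition_matrix"] = np.asarray(scen["transition_matrix"], dtype=float)
    d["scenario"] = SimScenario(**scen)
    d["colony_lonlat"] = tuple(d.get("colony_lonlat", COLONY_LONLAT))
    return RunConfig(**d)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full chain and write the run directory.

    Stages: cohort simulation, per-minute features (from sensors when
    present, otherwise the simulator's minute tables), pooled HMM fit +
    Viterbi decoding, single-sample DLW energetics, daily summaries, the
    12-design AICc comparison, activity-specific rates, report.
    Deterministic given ``config.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(config, outdir / "config.yaml")
    scenario = dataclasses.replace(config.scenario, seed=config.seed)

    stage = "simulate"
    try:
        cohort = simulate_cohort(scenario, with_sensors=config.with_sensors,
                                 sensor_birds=config.sensor_birds)
        write_cohort(cohort, outdir / "cohort")

        stage = "features"
        minutes_by_bird = {}
        for bird in cohort.minutes:
            if bird in cohort.sensors:
                sb = cohort.sensors[bird]
                minutes_by_bird[bird] = signal_mod.build_minutes(
                    sb.accel, sb.depth, sb.gps.rename(columns={"x_km": "x_km"}),
                    colony_point=(0.0, 0.0), fs=config.fs_hz,
                    static_window_s=config.static_window_s,
                    wingbeat_window_s=config.wingbeat_window_s,
                    wet_threshold_m=config.wet_threshold_m,
                    r_in_km=config.r_in_km, r_out_km=config.r_out_km)
            else:
                minutes_by_bird[bird] = cohort.minutes[bird]

        stage = "classify"
        seqs = list(minutes_by_bird.values())
        fit = hmm_mod.hmm_fit(seqs, hmm_mod.default_spec(),
                              max_iter=config.hmm_max_iter, tol=config.hmm_tol)
        states_by_bird = {}
        state_rows = []
        for bird, mins in minutes_by_bird.items():
            dec = hmm_mod.hmm_decode(fit, mins)
            mapping = None
            states_by_bird[bird] = dec["state_idx"].to_numpy()
            dec.insert(0, "bird", bird)
            state_rows.append(dec[["bird", "minute", "state", "posterior"]])
        pd.concat(state_rows).to_csv(outdir / "states.csv", index=False)

        stage = "dlw"
        dlw_results = dlw_mod.process_cohort(cohort.dlw, config.scenario.dlw_constants)
        dlw_results.to_csv(outdir / "dlw_results.csv", index=False,
                           float_format="%.8g")

        stage = "models"
        summaries = models_mod.build_summaries(minutes_by_bird, states_by_bird,
                                               dlw_results, cohort.dlw)
        summaries.to_csv(outdir / "summaries.csv", index=False, float_format="%.8g")
        fits = []
        for design in models_mod.candidate_models():
            f = models_mod.fit_dee_model(design, summaries)
            models_mod.predictive_r(f, summaries)
            fits.append(f)
        ranking = models_mod.aicc_rank(fits)
        ranking.to_csv(outdir / "model_ranking.csv", index=False, float_format="%.8g")
        best_time = min((f for f in fits if f.design.kind == "time"),
                        key=lambda f: f.aicc)
        rates = models_mod.activity_rates(best_time, config.reference_mass_g,
                                          config.bmr_w)
        rates.to_csv(outdir / "activity_rates.csv", index=False, float_format="%.8g")
    except Exception as err:  # pragma: no cover - error path
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    report = _report(cohort, summaries, ranking, rates, fit)
    (outdir / "report.md").write_text(report)
    return {"cohort": cohort, "summaries": summaries, "ranking": ranking,
            "rates": rates, "hmm_fit": fit, "dlw_results": dlw_results,
            "states_by_bird": states_by_bird, "report": report}


def _report(cohort, summaries, ranking, rates, fit) -> str:
    ms = summaries["msDEE"]
    lines = [
        "# plungedee run report", "",
        f"Birds: {len(cohort.dlw[cohort.dlw['set'] == 'equilibrium'])} equilibrium, "
        f"{len(summaries)} deployed",
        f"msDEE: {ms.mean():.3f} +/- {ms.std():.3f} kJ day^-1 g^-1",
        "Mean time budget (h per 24 h): "
        + ", ".join(f"{a}={summaries['T_' + a].mean():.2f}"
                    for a in ("col", "com", "for", "rest")),
        f"HMM: loglik {fit.loglik:.1f}, {fit.n_iter} EM iterations, "
        f"converged={fit.converged}", "",
        f"## Model ranking ({len(ranking)} candidate designs)", "",
        ranking.to_string(index=False), "",
        "## Activity-specific rates (best time-budget design)", "",
        rates.to_string(index=False), "",
    ]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Input QC
# ---------------------------------------------------------------------------

_SCHEMAS = {
    "accel.csv": ["t", "ax", "ay", "az"],
    "depth.csv": ["t", "depth"],
    "gps.csv": ["timestamp", "lon", "lat"],
    "minutes.csv": ["minute"],
}
_NOMINAL_DT = {"accel.csv": 1.0 / 50.0, "depth.csv": 1.0, "gps.csv": 60.0}


def validate_inputs(paths) -> pd.DataFrame:
    """Schema, monotonicity, sampling-rate and coverage checks per input file.

    Returns a QC table with one row per check; ``ok`` False rows carry a
    human-readable detail (file, first bad row, gap duration).
    """
    rows = []

    def add(f, check, ok, detail=""):
        rows.append({"file": str(f), "check": check, "ok": bool(ok), "detail": detail})

    for path in map(Path, paths):
        name = path.name
        if not path.exists():
            add(path, "exists", False, "file not found")
            continue
        add(path, "exists", True)
        try:
            df = pd.read_csv(path)
        except Exception as err:
            add(path, "readable", False, str(err))
            continue
        expected = _SCHEMAS.get(name, [])
        missing = [c for c in expected if c not in df.columns]
        add(path, "schema", not missing,
            f"missing columns {missing}" if missing else "")
        if missing:
            continue
        if name == "gps.csv":
            t = pd.to_datetime(df["timestamp"]).astype("int64").to_numpy() / 1e9
        elif "t" in df.columns:
            t = df["t"].to_numpy(float)
        else:
            continue
        dt = np.diff(t)
        bad = np.nonzero(dt <= 0)[0]
        add(path, "monotone", bad.size == 0,
            f"first non-increasing timestamp at row {bad[0] + 1}" if bad.size else "")
        nominal = _NOMINAL_DT.get(name)
        if nominal and dt.size:
            med = float(np.median(dt))
            add(path, "sampling_rate", abs(med - nominal) <= 0.1 * nominal,
                f"median dt {med:.4g} s vs nominal {nominal:.4g} s")
            gaps = np.nonzero(dt > 5 * nominal)[0]
            if gaps.size:
                worst = float(dt[gaps].max())
                add(path, "coverage", False,
                    f"{gaps.size} gap(s), longest {worst:.1f} s")
            else:
                add(path, "coverage", True)
    return pd.DataFrame(rows)
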