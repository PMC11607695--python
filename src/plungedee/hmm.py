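"""Four-state hidden Markov model over the per-minute data streams.

States (in fixed order): ``colony``, ``commuting``, ``foraging``, ``resting``.
Observed streams, conditionally independent given the state:

* ``colony``      - Bernoulli colony-presence indicator
* ``wingbeat_hz`` - gamma
* ``dive_frac``   - beta with point masses at 0 and 1 (zero/one inflation)
* ``step_m``      - gamma

DBA is intentionally *not* an observation stream: the classifier uses only
the four streams above, and DBA is joined onto the decoded states afterwards
for the energetics models.

Likelihood uses the scaled forward algorithm; fitting is Baum-Welch EM with
exact weighted M-steps (so the log-likelihood is non-decreasing); decoding is
Viterbi with ties broken toward the lower state index.  Missing stream
values (NaN) are marginalized per minute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

STATES = ("colony", "commuting", "foraging", "resting")
STREAMS = ("colony", "wingbeat_hz", "dive_frac", "step_m")

__all__ = [
    "STATES", "STREAMS",
    "BernoulliEmission", "GammaEmission", "ZeroOneInflatedBeta",
    "HmmSpec", "HmmFit", "default_spec",
    "hmm_loglik", "hmm_fit", "hmm_decode", "hmm_simulate",
    "align_labels", "decoding_accuracy",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Emission families
# ---------------------------------------------------------------------------

class BernoulliEmission:
    """Bernoulli emission for a 0/1 indicator stream."""

    def __init__(self, p: float):
        if not 0.0 <= p <= 1.0:
            raise ValueError("Bernoulli p must lie in [0, 1]")
        self.p = float(p)

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        p = np.clip(self.p, _EPS, 1.0 - _EPS)
        out = np.where(x > 0.5, np.log(p), np.log1p(-p))
        return np.where(np.isnan(x), 0.0, out)

    def mstep(self, x: np.ndarray, w: np.ndarray) -> None:
        ok = ~np.isnan(x)
        tot = w[ok].sum()
        if tot > 0:
            self.p = float(np.clip((w[ok] * x[ok]).sum() / tot, 0.0, 1.0))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return (rng.random(n) < self.p).astype(float)

    def params(self) -> dict:
        return {"p": self.p}


class GammaEmission:
    """Gamma emission for a positive stream (wingbeat frequency, step length).

    Observations at or below ``floor`` are clamped to ``floor`` before
    evaluation (sensor streams can legitimately report zeros); the M-step
    uses the same clamping, which keeps EM monotone on the clamped
    likelihood.
    """

    def __init__(self, shape: float, scale: float, floor: float = 1e-3):
        if shape <= 0 or scale <= 0:
            raise ValueError("gamma shape and scale must be positive")
        self.shape, self.scale, self.floor = float(shape), float(scale), float(floor)

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        xc = np.clip(x, self.floor, None)
        out = stats.gamma.logpdf(xc, self.shape, scale=self.scale)
        return np.where(np.isnan(x), 0.0, out)

    def mstep(self, x: np.ndarray, w: np.ndarray) -> None:
        ok = ~np.isnan(x)
        xc = np.clip(x[ok], self.floor, None)
        ww = w[ok]
        tot = ww.sum()
        if tot <= 0:
            return
        m = float((ww * xc).sum() / tot)
        lbar = float((ww * np.log(xc)).sum() / tot)
        s = np.log(m) - lbar
        if s <= 1e-12:  # zero weighted variance: pin parameters
            warnings.warn("degenerate gamma stream; parameters pinned", stacklevel=2)
            return
        # Newton on  log(k) - digamma(k) = s  (strictly decreasing in k)
        k = (3 - s + np.sqrt((s - 3) ** 2 + 24 * s)) / (12 * s)  # Minka init
        for _ in range(50):
            f = np.log(k) - special.digamma(k) - s
            fp = 1.0 / k - special.polygamma(1, k)
            step = f / fp
            k_new = k - step
            if k_new <= 0:
                k_new = k / 2
            if abs(k_new - k) < 1e-12 * k:
                k = k_new
                break
            k = k_new
        self.shape = float(np.clip(k, 1e-3, 1e4))
        self.scale = m / self.shape

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.gamma(self.shape, self.scale, size=n)

    def params(self) -> dict:
        return {"shape": self.shape, "scale": self.scale}


class ZeroOneInflatedBeta:
    """Beta emission with point masses at exactly 0 and exactly 1.

    Suits the dive-fraction stream, which is 0 in any minute without a
    submersion and could be 1 in a fully submerged minute.
    """

    def __init__(self, p0: float, p1: float, a: float, b: float):
        if min(p0, p1) < 0 or p0 + p1 > 1:
            raise ValueError("point masses must satisfy p0, p1 >= 0, p0 + p1 <= 1")
        if a <= 0 or b <= 0:
            raise ValueError("beta parameters must be positive")
        self.p0, self.p1, self.a, self.b = float(p0), float(p1), float(a), float(b)

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        p0 = np.clip(self.p0, _EPS, 1.0)
        p1 = np.clip(self.p1, _EPS, 1.0)
        pc = np.clip(1.0 - self.p0 - self.p1, _EPS, 1.0)
        xi = np.clip(x, 1e-9, 1 - 1e-9)
        interior = np.log(pc) + stats.beta.logpdf(xi, self.a, self.b)
        out = np.where(x <= 0.0, np.log(p0), np.where(x >= 1.0, np.log(p1), interior))
        return np.where(np.isnan(x), 0.0, out)

    def mstep(self, x: np.ndarray, w: np.ndarray) -> None:
        ok = ~np.isnan(x)
        xx, ww = x[ok], w[ok]
        tot = ww.sum()
        if tot <= 0:
            return
        at0, at1 = xx <= 0.0, xx >= 1.0
        inter = ~(at0 | at1)
        self.p0 = float(ww[at0].sum() / tot)
        self.p1 = float(ww[at1].sum() / tot)
        wi = ww[inter]
        if wi.sum() <= 0:
            return  # no interior mass: beta parameters pinned
        xi = np.clip(xx[inter], 1e-9, 1 - 1e-9)
        mlog = float((wi * np.log(xi)).sum() / wi.sum())
        mlog1 = float((wi * np.log1p(-xi)).sum() / wi.sum())

        def eqs(theta):
            a, b = np.exp(theta)
            d = special.digamma(a + b)
            return [special.digamma(a) - d - mlog, special.digamma(b) - d - mlog1]

        m = float((wi * xi).sum() / wi.sum())
        v = float((wi * (xi - m) ** 2).sum() / wi.sum())
        if v < 1e-12:
            return
        common = max(m * (1 - m) / v - 1, 1e-3)  # moments initialisation
        sol, info, ok_flag, _ = optimize.fsolve(
            eqs, np.log([max(m * common, 1e-3), max((1 - m) * common, 1e-3)]),
            full_output=True)
        if ok_flag == 1:
            self.a, self.b = (float(np.clip(np.exp(s), 1e-3, 1e6)) for s in sol)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        u = rng.random(n)
        out = rng.beta(self.a, self.b, size=n)
        out[u < self.p0] = 0.0
        out[u > 1.0 - self.p1] = 1.0
        return out

    def params(self) -> dict:
        return {"p0": self.p0, "p1": self.p1, "a": self.a, "b": self.b}


# ---------------------------------------------------------------------------
# Model spec
# ---------------------------------------------------------------------------

@dataclass
class HmmSpec:
    """State set, per-stream emissions, transition matrix and initial law."""

    emissions: dict                      # stream name -> list of emissions per state
    tmat: np.ndarray                     # (n, n) row-stochastic
    delta: np.ndarray                    # (n,) initial distribution
    states: tuple = STATES

    @property
    def n_states(self) -> int:
        return len(self.states)

    def validate(self) -> None:
        problems = []
        tmat = np.asarray(self.tmat, dtype=float)
        if tmat.shape != (self.n_states, self.n_states):
            problems.append(f"transition matrix shape {tmat.shape}")
        else:
            if (tmat < 0).any():
                problems.append("negative transition probabilities")
            if not np.allclose(tmat.sum(axis=1), 1.0, atol=1e-10):
                problems.append("transition rows do not sum to 1")
        delta = np.asarray(self.delta, dtype=float)
        if delta.shape != (self.n_states,) or not np.isclose(delta.sum(), 1.0, atol=1e-10) \
                or (delta < 0).any():
            problems.append("initial distribution invalid")
        for stream, ems in self.emissions.items():
            if len(ems) != self.n_states:
                problems.append(f"stream {stream!r}: {len(ems)} emissions for "
                                f"{self.n_states} states")
        if problems:
            raise ValueError("invalid HMM spec: " + "; ".join(problems))

    def log_obs(self, minutes: pd.DataFrame) -> np.ndarray:
        """(T, n_states) log emission densities; missing streams contribute 0."""
        T = len(minutes)
        logb = np.zeros((T, self.n_states))
        for stream, ems in self.emissions.items():
            if stream not in minutes.columns:
                continue
            x = minutes[stream].to_numpy(dtype=float)
            for j, em in enumerate(ems):
                logb[:, j] += em.logpdf(x)
        return logb

    def copy(self) -> "HmmSpec":
        import copy
        return copy.deepcopy(self)

    def to_dict(self) -> dict:
        return {
            "states": list(self.states),
            "tmat": np.asarray(self.tmat).tolist(),
            "delta": np.asarray(self.delta).tolist(),
            "emissions": {s: [{"family": type(e).__name__, **e.params()} for e in ems]
                          for s, ems in self.emissions.items()},
        }


_FAMILIES = {"BernoulliEmission": BernoulliEmission, "GammaEmission": GammaEmission,
             "ZeroOneInflatedBeta": ZeroOneInflatedBeta}


def spec_from_dict(d: dict) -> HmmSpec:
    ems = {}
    for stream, lst in d["emissions"].items():
        built = []
        for e in lst:
            e = dict(e)
            fam = _FAMILIES[e.pop("family")]
            built.append(fam(**e))
        ems[stream] = built
    return HmmSpec(emissions=ems, tmat=np.asarray(d["tmat"], dtype=float),
                   delta=np.asarray(d["delta"], dtype=float),
                   states=tuple(d["states"]))


def default_spec() -> HmmSpec:
    """Stand-in starting values for the four-state booby model.

    Chosen from the physics of each stream (perfect colony indicator at the
    colony; flapping at ~5 Hz while commuting; submersions only while
    foraging; ~600 m minute steps in transit), not from any field fit.
    """
    tmat = np.full((4, 4), 0.02)
    np.fill_diagonal(tmat, 0.94)
    tmat /= tmat.sum(axis=1, keepdims=True)
    delta = np.array([0.7, 0.1, 0.1, 0.1])
    g = GammaEmission
    emissions = {
        # colony, commuting, foraging, resting
        "colony": [BernoulliEmission(0.95), BernoulliEmission(0.02),
                   BernoulliEmission(0.02), BernoulliEmission(0.02)],
        "wingbeat_hz": [g(2.0, 6.0), g(25.0, 0.2), g(20.0, 0.25), g(2.0, 6.0)],
        "dive_frac": [ZeroOneInflatedBeta(0.98, 0.001, 2.0, 8.0),
                      ZeroOneInflatedBeta(0.98, 0.001, 2.0, 8.0),
                      ZeroOneInflatedBeta(0.30, 0.001, 2.0, 8.0),
                      ZeroOneInflatedBeta(0.98, 0.001, 2.0, 8.0)],
        "step_m": [g(1.5, 15.0), g(10.0, 60.0), g(2.0, 75.0), g(2.0, 30.0)],
    }
    return HmmSpec(emissions=emissions, tmat=tmat, delta=delta)


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def _as_sequences(minutes) -> list:
    if isinstance(minutes, pd.DataFrame):
        return [minutes]
    return list(minutes)


def _forward(logb: np.ndarray, tmat: np.ndarray, delta: np.ndarray):
    """Scaled forward pass; returns (loglik, scaled alphas, per-step log scale)."""
    T, n = logb.shape
    alpha = np.empty((T, n))
    logc = np.empty(T)
    m = logb[0].max()
    a = delta * np.exp(logb[0] - m)
    c = a.sum()
    alpha[0] = a / c
    logc[0] = np.log(c) + m
    for t in range(1, T):
        m = logb[t].max()
        a = (alpha[t - 1] @ tmat) * np.exp(logb[t] - m)
        c = a.sum()
        alpha[t] = a / c
        logc[t] = np.log(c) + m
    return float(logc.sum()), alpha, logc


def _backward(logb: np.ndarray, tmat: np.ndarray, logc: np.ndarray) -> np.ndarray:
    T, n = logb.shape
    beta = np.empty((T, n))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        m = logb[t + 1].max()
        b = tmat @ (np.exp(logb[t + 1] - m) * beta[t + 1])
        beta[t] = b / np.exp(logc[t + 1] - m)
    return beta


def hmm_loglik(spec: HmmSpec, minutes) -> float:
    """Forward-algorithm log-likelihood (scaled; safe for 1e5+ minutes).

    ``minutes`` is one observation table or a list of tables (one per bird);
    each table restarts from the initial distribution.
    """
    spec.validate()
    tmat = np.asarray(spec.tmat, dtype=float)
    delta = np.asarray(spec.delta, dtype=float)
    total = 0.0
    for seq in _as_sequences(minutes):
        logb = spec.log_obs(seq)
        ll, _, _ = _forward(logb, tmat, delta)
        total += ll
    return total


@dataclass
class HmmFit:
    spec: HmmSpec
    loglik: float
    trace: list = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0


def hmm_fit(minutes, starting_spec: HmmSpec, max_iter: int = 100,
            tol: float = 1e-6) -> HmmFit:
    """Baum-Welch EM from explicit starting values.

    Each observation table is treated as an independent record (the initial
    distribution resets per bird).  Exact weighted M-steps are used for every
    emission family, so the log-likelihood trace is non-decreasing.
    """
    spec = starting_spec.copy()
    spec.validate()
    seqs = _as_sequences(minutes)
    n = spec.n_states
    trace = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        tmat = np.asarray(spec.tmat, dtype=float)
        delta = np.asarray(spec.delta, dtype=float)
        ll_total = 0.0
        xi_sum = np.zeros((n, n))
        delta_sum = np.zeros(n)
        gammas, logbs = [], []
        for seq in seqs:
            logb = spec.log_obs(seq)
            ll, alpha, logc = _forward(logb, tmat, delta)
            beta = _backward(logb, tmat, logc)
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            ll_total += ll
            delta_sum += gamma[0]
            for t in range(len(seq) - 1):
                m = logb[t + 1].max()
                xi = (alpha[t][:, None] * tmat
                      * (np.exp(logb[t + 1] - m) * beta[t + 1])[None, :])
                xi /= np.exp(logc[t + 1] - m)
                xi_sum += xi
            gammas.append(gamma)
            logbs.append(logb)
        trace.append(ll_total)
        if prev > -np.inf and ll_total - prev < tol * abs(prev):
            converged = True
            break
        prev = ll_total
        # M-step
        spec.delta = delta_sum / delta_sum.sum()
        rows = xi_sum.sum(axis=1, keepdims=True)
        rows[rows == 0] = 1.0
        spec.tmat = xi_sum / rows
        gamma_all = np.vstack(gammas)
        obs_all = pd.concat(seqs, ignore_index=True)
        for stream, ems in spec.emissions.items():
            if stream not in obs_all.columns:
                continue
            x = obs_all[stream].to_numpy(dtype=float)
            for j, em in enumerate(ems):
                em.mstep(x, gamma_all[:, j])
    return HmmFit(spec=spec, loglik=trace[-1], trace=trace,
                  converged=converged, n_iter=it)


def hmm_decode(spec_or_fit, minutes) -> pd.DataFrame:
    """Viterbi maximum a-posteriori state path with posterior state probabilities.

    Ties in the dynamic program break toward the lower state index.  Minutes
    with every stream missing are imputed purely through the transition
    structure and flagged.
    """
    spec = spec_or_fit.spec if isinstance(spec_or_fit, HmmFit) else spec_or_fit
    spec.validate()
    tmat = np.asarray(spec.tmat, dtype=float)
    delta = np.asarray(spec.delta, dtype=float)
    out = []
    for seq in _as_sequences(minutes):
        logb = spec.log_obs(seq)
        T, n = logb.shape
        with np.errstate(divide="ignore"):
            logt = np.log(tmat)
            logd = np.log(delta)
        v = logd + logb[0]
        back = np.zeros((T, n), dtype=int)
        for t in range(1, T):
            cand = v[:, None] + logt
            back[t] = cand.argmax(axis=0)      # first max = lower index on ties
            v = cand.max(axis=0) + logb[t]
        path = np.empty(T, dtype=int)
        path[-1] = int(v.argmax())
        for t in range(T - 2, -1, -1):
            path[t] = back[t + 1][path[t + 1]]
        _, alpha, logc = _forward(logb, tmat, delta)
        beta = _backward(logb, tmat, logc)
        post = alpha * beta
        post /= post.sum(axis=1, keepdims=True)
        all_missing = np.all(logb == 0.0, axis=1)
        df = pd.DataFrame({
            "minute": seq["minute"].to_numpy() if "minute" in seq.columns
            else np.arange(T),
            "state": [spec.states[s] for s in path],
            "state_idx": path,
            "posterior": post[np.arange(T), path],
            "imputed": all_missing,
        })
        out.append(df)
    return pd.concat(out, ignore_index=True) if len(out) > 1 else out[0]


def hmm_simulate(spec: HmmSpec, n_minutes: int, seed) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw a synthetic observation table plus its true state sequence."""
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.n_states
    states = np.empty(n_minutes, dtype=int)
    states[0] = rng.choice(n, p=np.asarray(spec.delta, dtype=float))
    tmat = np.asarray(spec.tmat, dtype=float)
    for t in range(1, n_minutes):
        states[t] = rng.choice(n, p=tmat[states[t - 1]])
    data = {"minute": np.arange(n_minutes)}
    for stream, ems in spec.emissions.items():
        col = np.empty(n_minutes)
        for j, em in enumerate(ems):
            idx = np.nonzero(states == j)[0]
            if idx.size:
                col[idx] = em.sample(rng, idx.size)
        data[stream] = col
    return pd.DataFrame(data), states


# ---------------------------------------------------------------------------
# Evaluation helpers
# ---------------------------------------------------------------------------

def align_labels(truth: np.ndarray, decoded: np.ndarray, n_states: int = 4) -> np.ndarray:
    """Maximum-overlap (Hungarian) mapping decoded label -> truth label."""
    from scipy.optimize import linear_sum_assignment
    conf = np.zeros((n_states, n_states))
    for d, t in zip(decoded, truth):
        conf[d, t] += 1
    rows, cols = linear_sum_assignment(-conf)
    mapping = np.arange(n_states)
    mapping[rows] = cols
    return mapping


def decoding_accuracy(truth: np.ndarray, decoded: np.ndarray,
                      n_states: int = 4, align: bool = True) -> float:
    """Fraction of minutes decoded to the true state (after label alignment)."""
    decoded = np.asarray(decoded)
    truth = np.asarray(truth)
    if align:
        decoded = align_labels(truth, decoded, n_states)[decoded]
    return float((decoded == truth).mean())
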