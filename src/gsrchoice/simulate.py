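"""Trial-level simulation of the 2-D stochastic accumulation process.

Evidence accumulates as a 2-D Euler-Maruyama random walk whose increments
are bivariate normal with mean given by the drift vector and isotropic
variance ``sigma**2 * dt``.  After each step the state is projected onto the
two option vectors; the first projection to reach the threshold ``theta``
triggers the corresponding choice.

Because the stopping rule only consults the two projections, the process is
simulated directly in projection space: the pair ``(p_A, p_B)`` is itself a
bivariate diffusion whose noise components have correlation ``cos(gamma)``.
This is exact (no approximation beyond time discretisation) and lets one
vectorised engine cover diffusion (``gamma = pi``), accumulator
(``gamma = pi/2``) and every intermediate geometry, with arbitrary per-trial
parameters.

Across-trial drift variability ``nu`` enters in a model-class-specific way:

* diffusion: a single zero-mean Gaussian perturbation of the signed balance
  drift ``delta`` (the classic DDM convention);
* accumulator: an independent perturbation added to each accumulator's
  drift, matching how racing models specify per-accumulator variability;
* gsr: a perturbation of the drift magnitude ``|mu|``, which keeps the
  perturbed drift a genuine 2-D vector for any ``gamma``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .geometry import OptionFrame, make_option_frame
from .parameters import MODEL_CLASSES, ParameterSet

__all__ = [
    "TrialRecord",
    "DesignSpec",
    "ConditionParameterMap",
    "first_passage",
    "sample_start",
    "start_projections",
    "trial_drifts",
    "simulate_trial",
    "simulate_dataset",
    "accumulator_drifts_from_match",
    "build_condition_parameters",
    "match_favoring_probability",
]

DEFAULT_DT = 1e-3
DEFAULT_T_MAX = 10.0

#: columns of the trial-table CSV interface
TRIAL_COLUMNS = [
    "participant",
    "condition",
    "coherence",
    "match",
    "discriminability",
    "choice",
    "rt",
    "correct",
    "censored",
]


@dataclass
class TrialRecord:
    """One simulated trial.

    ``trace`` holds the per-step signed balance-of-evidence increments
    (projection onto A minus projection onto B) when trace recording was
    requested.  ``rt`` includes the non-decision time.
    """

    condition_id: Any
    choice: str | None
    rt: float
    censored: bool = False
    n_steps: int = 0
    balance_start: float = 0.0
    balance_end: float = 0.0
    trace: np.ndarray | None = None


# ---------------------------------------------------------------------------
# experimental designs


@dataclass
class DesignSpec:
    """Factorial experimental design: coherence x match x discriminability.

    ``conditions`` is a sequence of ``(coherence, match, discriminability)``
    level tuples in canonical (lexicographic) order.  The stimulus metadata
    dictionaries translate factor levels into physical stimulus quantities
    (wrapped-normal orientation SD per coherence level, fraction of the way
    from the option bisector per match level, inter-option angle per
    discriminability level); they are used by the match-proportion drift rule
    and the stimulus-trace generator.
    """

    conditions: Sequence[tuple]
    trials_per_condition: int
    coherence_sd: dict = field(default_factory=dict)
    match_frac: dict = field(default_factory=dict)
    discriminability_sep: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.conditions = [tuple(c) for c in self.conditions]
        if self.trials_per_condition < 0:
            raise ValueError("trials_per_condition must be >= 0")

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_trials(self) -> int:
        return self.n_conditions * self.trials_per_condition

    @classmethod
    def application(cls, trials_per_condition: int = 10) -> "DesignSpec":
        """The 12-condition design: 2 coherence x 3 match x 2 discriminability.

        Ten trials per condition gives 120 trials per participant.  Level 0
        of each factor is the harder one: low coherence (30 deg orientation
        SD), ambiguous match (0/3), low discriminability (30 deg between
        options).
        """
        conds = list(itertools.product((0, 1), (0, 1, 2), (0, 1)))
        return cls(
            conditions=conds,
            trials_per_condition=trials_per_condition,
            coherence_sd={0: math.radians(30.0), 1: math.radians(15.0)},
            match_frac={0: 0.0, 1: 1.0 / 3.0, 2: 2.0 / 3.0},
            discriminability_sep={0: math.radians(30.0), 1: math.radians(60.0)},
        )

    @classmethod
    def single(cls, trials: int) -> "DesignSpec":
        """A one-condition design with ``trials`` trials."""
        return cls(
            conditions=[(0, 0, 0)],
            trials_per_condition=trials,
            coherence_sd={0: math.radians(15.0)},
            match_frac={0: 1.0 / 3.0},
            discriminability_sep={0: math.radians(60.0)},
        )

    @staticmethod
    def condition_label(cond: tuple) -> str:
        c, m, d = cond
        return f"c{c}m{m}d{d}"


@dataclass
class ConditionParameterMap:
    """Resolved per-condition parameters plus bookkeeping.

    ``drift_rule`` selects how per-trial drifts are derived: ``"geometric"``
    projects the drift vector onto the option directions, while
    ``"match_proportion"`` uses the stimulus-sample favouring probabilities
    (the single-drift-parameter accumulator construction).
    """

    params: dict
    n_free_parameters: int
    model_class: str = "gsr"
    drift_rule: str = "geometric"

    def __getitem__(self, cond: tuple) -> ParameterSet:
        try:
            return self.params[tuple(cond)]
        except KeyError as exc:
            raise KeyError(f"no parameters resolved for condition {cond!r}") from exc


# ---------------------------------------------------------------------------
# start points


def start_projections(
    model_class: str, s_v: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-trial starting projections ``(p_A0, p_B0)``.

    Diffusion: the starting balance of evidence ``p_A - p_B`` is uniform on
    ``[-s_v, +s_v]`` (the region between the diagonal lines ``y = x +- s_v``
    collapsed onto the balance coordinate).  Accumulator / gsr: each
    accumulator starts at an independent uniform draw from ``[0, s_v]``, so
    the starting balance is triangular and peaked at zero.
    """
    if model_class not in MODEL_CLASSES:
        raise ValueError(f"unknown model_class {model_class!r}")
    if s_v < 0:
        raise ValueError("s_v must be non-negative")
    if s_v == 0:
        z = np.zeros(n)
        return z, z.copy()
    if model_class == "diffusion":
        b = rng.uniform(-s_v, s_v, n)
        return b / 2.0, -b / 2.0
    a = rng.uniform(0.0, s_v, n)
    b = rng.uniform(0.0, s_v, n)
    return a, b


def sample_start(
    model_class: str,
    s_v: float,
    rng: np.random.Generator,
    frame: OptionFrame | None = None,
) -> np.ndarray:
    """Draw one 2-D start state for the given model class.

    For the gsr class an :class:`OptionFrame` is needed to place the two
    independent per-accumulator draws back into the plane; at ``gamma = pi``
    the option vectors are collinear and the diffusion rule applies.
    """
    p_a, p_b = start_projections(model_class, s_v, 1, rng)
    a, b = float(p_a[0]), float(p_b[0])
    if model_class == "diffusion":
        return np.array([a, 0.0])
    if model_class == "accumulator":
        return np.array([a, b])
    if frame is None:
        raise ValueError("gsr start points require an OptionFrame")
    if abs(frame.gamma - np.pi) < 1e-9:
        return np.array([(a - b) / 2.0, 0.0])
    basis = np.stack([frame.u_A, frame.u_B])
    return np.linalg.solve(basis, np.array([a, b]))


# ---------------------------------------------------------------------------
# drifts


def trial_drifts(
    model_class: str,
    phi,
    mu_mag,
    nu,
    gamma,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial drift projections ``(drift_A, drift_B)`` with variability.

    The mean drift vector ``|mu| (cos phi, sin phi)`` projects onto the
    option directions as ``|mu| cos(phi)`` and ``|mu| cos(gamma - phi)``.
    Across-trial variability ``nu`` is resampled each trial; see the module
    docstring for where it enters per model class.
    """
    phi = np.broadcast_to(np.asarray(phi, float), (n,))
    mu_mag = np.broadcast_to(np.asarray(mu_mag, float), (n,))
    nu = np.broadcast_to(np.asarray(nu, float), (n,))
    gamma = np.broadcast_to(np.asarray(gamma, float), (n,))
    if model_class == "diffusion":
        delta = mu_mag * np.cos(phi) + nu * rng.standard_normal(n)
        return delta, -delta
    if model_class == "accumulator":
        d_a = mu_mag * np.cos(phi) + nu * rng.standard_normal(n)
        d_b = mu_mag * np.cos(gamma - phi) + nu * rng.standard_normal(n)
        return d_a, d_b
    if model_class == "gsr":
        mag = mu_mag + nu * rng.standard_normal(n)
        return mag * np.cos(phi), mag * np.cos(gamma - phi)
    raise ValueError(f"unknown model_class {model_class!r}")


def match_favoring_probability(
    match_frac: float,
    stimulus_sd: float,
    option_separation: float,
    period: float = 2.0 * math.pi,
    n_wraps: int = 5,
) -> float:
    """Probability that a stimulus sample favours the correct option.

    Stimulus orientations are drawn from a wrapped normal centred
    ``match_frac * option_separation / 2`` away from the option bisector; a
    sample favours the option on whose side of the bisector it falls.  At
    ``match_frac = 0`` the stimulus is perfectly ambiguous and the
    probability is one half.
    """
    if stimulus_sd <= 0:
        raise ValueError("stimulus_sd must be positive")
    mean = match_frac * option_separation / 2.0
    half = period / 2.0
    p = 0.0
    for k in range(-n_wraps, n_wraps + 1):
        shift = k * period
        p += norm.cdf((half + shift - mean) / stimulus_sd) - norm.cdf(
            (shift - mean) / stimulus_sd
        )
    return float(np.clip(p, 0.0, 1.0))


def accumulator_drifts_from_match(
    mu_mag: float,
    match_frac: float,
    nu: float,
    rng: np.random.Generator,
    *,
    stimulus_sd: float = math.pi / 12.0,
    option_separation: float = math.pi / 3.0,
    n: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Correct/incorrect accumulator drifts from a single drift parameter.

    The proportion of stimulus samples favouring each option is evaluated
    under the wrapped-normal stimulus model, multiplied by the drift-rate
    parameter, and per-accumulator drift variability is added — so one
    ``mu_mag`` parameter specifies both racing drifts.
    """
    if mu_mag < 0:
        raise ValueError("mu_mag must be non-negative")
    p = match_favoring_probability(match_frac, stimulus_sd, option_separation)
    d_correct = p * mu_mag + nu * rng.standard_normal(n)
    d_incorrect = (1.0 - p) * mu_mag + nu * rng.standard_normal(n)
    return d_correct, d_incorrect


# ---------------------------------------------------------------------------
# the first-passage engine


def first_passage(
    drift_A,
    drift_B,
    gamma,
    theta,
    *,
    start_A=0.0,
    start_B=0.0,
    sigma=1.0,
    dt: float = DEFAULT_DT,
    t_max: float = DEFAULT_T_MAX,
    rng: np.random.Generator,
    keep_trace: bool = False,
) -> dict:
    """Vectorised first-passage simulation in projection space.

    All parameters broadcast to a common trial count ``n``.  Returns a dict
    of arrays: ``choice`` (0 = A, 1 = B, -1 = censored), ``n_steps``,
    ``decision_time``, end projections ``p_A``/``p_B``, ``balance_net``
    (accumulated balance-of-evidence increments, excluding the start point)
    and, when ``keep_trace``, a list of per-trial increment arrays.

    If both projections cross the threshold on the same step the larger one
    wins; exact ties are broken by a fair coin from ``rng``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    arrays = np.broadcast_arrays(
        np.asarray(drift_A, float),
        np.asarray(drift_B, float),
        np.asarray(gamma, float),
        np.asarray(theta, float),
        np.asarray(start_A, float),
        np.asarray(start_B, float),
        np.asarray(sigma, float),
    )
    d_a, d_b, gam, th, s_a, s_b, sig = (np.ravel(a).astype(float) for a in arrays)
    n = d_a.size
    for name, arr in (("drift", d_a), ("drift", d_b), ("theta", th), ("sigma", sig)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite {name} parameter")
    if np.any(th <= 0):
        raise ValueError("theta must be positive")
    if np.any(sig <= 0):
        raise ValueError("sigma must be positive")

    rho = np.cos(gam)
    srho = np.sin(gam)  # gamma in (0, pi] so sin(gamma) >= 0
    sdt = math.sqrt(dt)
    max_steps = int(round(t_max / dt))

    out_choice = np.full(n, -1, dtype=np.int8)
    out_steps = np.full(n, max_steps, dtype=np.int64)
    out_pa = np.empty(n)
    out_pb = np.empty(n)

    # compacted working copies of the active trials
    idx = np.arange(n)
    p_a = s_a.copy()
    p_b = s_b.copy()
    w_da = d_a * dt
    w_db = d_b * dt
    w_rho = rho.copy()
    w_srho = srho.copy()
    w_th = th.copy()
    w_sig = sig * sdt

    traces: list[list[float]] | None = None
    if keep_trace:
        traces = [[] for _ in range(n)]

    for step in range(max_steps):
        m = idx.size
        if m == 0:
            break
        z1 = rng.standard_normal(m)
        z2 = rng.standard_normal(m)
        inc_a = w_da + w_sig * z1
        inc_b = w_db + w_sig * (w_rho * z1 + w_srho * z2)
        p_a += inc_a
        p_b += inc_b
        if keep_trace:
            bal_inc = inc_a - inc_b
            for j, i in enumerate(idx):
                traces[i].append(bal_inc[j])
        done = (p_a >= w_th) | (p_b >= w_th)
        if done.any():
            d_idx = idx[done]
            pa_d = p_a[done]
            pb_d = p_b[done]
            choice = np.where(pa_d > pb_d, 0, 1).astype(np.int8)
            tie = pa_d == pb_d
            if tie.any():
                choice[tie] = rng.integers(0, 2, int(tie.sum())).astype(np.int8)
            out_choice[d_idx] = choice
            out_steps[d_idx] = step + 1
            out_pa[d_idx] = pa_d
            out_pb[d_idx] = pb_d
            keep = ~done
            idx = idx[keep]
            p_a = p_a[keep]
            p_b = p_b[keep]
            w_da = w_da[keep]
            w_db = w_db[keep]
            w_rho = w_rho[keep]
            w_srho = w_srho[keep]
            w_th = w_th[keep]
            w_sig = w_sig[keep]

    # censored trials keep their final state
    if idx.size:
        out_pa[idx] = p_a
        out_pb[idx] = p_b

    result = {
        "choice": out_choice,
        "n_steps": out_steps,
        "decision_time": out_steps * dt,
        "p_A": out_pa,
        "p_B": out_pb,
        "balance_net": (out_pa - s_a) - (out_pb - s_b),
        "censored": out_choice < 0,
    }
    if keep_trace:
        result["traces"] = [np.asarray(t) for t in traces]
    return result


# ---------------------------------------------------------------------------
# trial- and dataset-level wrappers


def _infer_model_class(gamma: float) -> str:
    if abs(gamma - np.pi) < 1e-9:
        return "diffusion"
    if abs(gamma - np.pi / 2) < 1e-9:
        return "accumulator"
    return "gsr"


def simulate_trial(
    params: ParameterSet,
    frame: OptionFrame | None = None,
    *,
    dt: float = DEFAULT_DT,
    t_max: float = DEFAULT_T_MAX,
    rng: np.random.Generator,
    keep_trace: bool = False,
    model_class: str | None = None,
    condition_id: Any = None,
) -> TrialRecord:
    """Simulate a single trial for one parameter set.

    The model class (which controls the start-point and drift-variability
    conventions) defaults to the class implied by ``gamma``.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if frame is None:
        frame = make_option_frame(params.gamma)
    if model_class is None:
        model_class = _infer_model_class(params.gamma)
    p_a0, p_b0 = start_projections(model_class, params.s_v, 1, rng)
    if params.beta != 0.0 and model_class == "diffusion":
        p_a0 = p_a0 + params.beta / 2.0
        p_b0 = p_b0 - params.beta / 2.0
    d_a, d_b = trial_drifts(
        model_class, params.phi, params.mu_mag, params.nu, params.gamma, 1, rng
    )
    res = first_passage(
        d_a,
        d_b,
        params.gamma,
        params.theta,
        start_A=p_a0,
        start_B=p_b0,
        sigma=params.sigma,
        dt=dt,
        t_max=t_max,
        rng=rng,
        keep_trace=keep_trace,
    )
    censored = bool(res["censored"][0])
    choice = None if censored else ("A" if res["choice"][0] == 0 else "B")
    rt = float(res["decision_time"][0]) + params.tau
    return TrialRecord(
        condition_id=condition_id,
        choice=choice,
        rt=rt,
        censored=censored,
        n_steps=int(res["n_steps"][0]),
        balance_start=float(p_a0[0] - p_b0[0]),
        balance_end=float(res["p_A"][0] - res["p_B"][0]),
        trace=res["traces"][0] if keep_trace else None,
    )


def _condition_drifts(
    cond_map: ConditionParameterMap,
    design: DesignSpec,
    cond: tuple,
    ps: ParameterSet,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, str]:
    """Per-trial drifts for one condition, plus which option is correct."""
    if cond_map.drift_rule == "match_proportion":
        c, m, d = cond
        d_a, d_b = accumulator_drifts_from_match(
            ps.mu_mag,
            design.match_frac.get(m, 0.0),
            ps.nu,
            rng,
            stimulus_sd=design.coherence_sd.get(c, math.pi / 12.0),
            option_separation=design.discriminability_sep.get(d, math.pi / 3.0),
            n=n,
        )
        return d_a, d_b, "A"
    d_a, d_b = trial_drifts(
        cond_map.model_class, ps.phi, ps.mu_mag, ps.nu, ps.gamma, n, rng
    )
    mean_a = ps.mu_mag * math.cos(ps.phi)
    mean_b = ps.mu_mag * math.cos(ps.gamma - ps.phi)
    correct = "A" if mean_a >= mean_b else "B"
    return d_a, d_b, correct


def simulate_dataset(
    cond_map: ConditionParameterMap,
    design: DesignSpec,
    rng: np.random.Generator,
    *,
    dt: float = DEFAULT_DT,
    t_max: float = DEFAULT_T_MAX,
    keep_trace: bool = False,
    participant: int = 0,
) -> pd.DataFrame:
    """Simulate one participant's full design.

    Returns a trial table with ``trials_per_condition x n_conditions`` rows
    (per-trial drift variability is resampled on every trial).  Censored
    trials are flagged, not dropped.
    """
    frames = []
    all_traces = []
    for cond in design.conditions:
        ps = cond_map[cond]
        n = design.trials_per_condition
        if n == 0:
            continue
        p_a0, p_b0 = start_projections(cond_map.model_class, ps.s_v, n, rng)
        d_a, d_b, correct_opt = _condition_drifts(cond_map, design, cond, ps, n, rng)
        res = first_passage(
            d_a,
            d_b,
            ps.gamma,
            ps.theta,
            start_A=p_a0,
            start_B=p_b0,
            sigma=ps.sigma,
            dt=dt,
            t_max=t_max,
            rng=rng,
            keep_trace=keep_trace,
        )
        choice = np.where(res["choice"] == 0, "A", "B")
        choice = np.where(res["censored"], "", choice)
        c, m, d = cond
        frames.append(
            pd.DataFrame(
                {
                    "participant": participant,
                    "condition": DesignSpec.condition_label(cond),
                    "coherence": c,
                    "match": m,
                    "discriminability": d,
                    "choice": choice,
                    "rt": res["decision_time"] + ps.tau,
                    "correct": (choice == correct_opt).astype(int),
                    "censored": res["censored"],
                    "n_steps": res["n_steps"],
                    "balance_start": p_a0 - p_b0,
                    "balance_net": res["balance_net"],
                }
            )
        )
        if keep_trace:
            all_traces.extend(res["traces"])
    if not frames:
        table = pd.DataFrame(
            columns=TRIAL_COLUMNS + ["n_steps", "balance_start", "balance_net"]
        )
        table.attrs["traces"] = []
        return table
    table = pd.concat(frames, ignore_index=True)
    if keep_trace:
        table.attrs["traces"] = all_traces
    return table


# ---------------------------------------------------------------------------
# condition-parameter mapping

# which design factor indexes each per-condition field
_FIELD_AXIS = {
    "phi": "match",
    "theta": "discriminability",
    "gamma": "discriminability",
    "mu_mag": ("coherence", "match"),
}
_SHARED_FIELDS = ("tau", "nu", "s_v", "sigma")
_COUNTED_FIELDS = ("phi", "mu_mag", "theta", "tau", "nu", "gamma", "s_v")
_AXIS_INDEX = {"coherence": 0, "match": 1, "discriminability": 2}


def _resolve_field(name: str, value, cond: tuple, lowest_match) -> float:
    if np.isscalar(value):
        return float(value)
    axis = _FIELD_AXIS.get(name)
    if axis is None:
        raise ValueError(f"field {name!r} must be shared (scalar) across conditions")
    key = (
        (cond[_AXIS_INDEX[axis[0]]], cond[_AXIS_INDEX[axis[1]]])
        if isinstance(axis, tuple)
        else cond[_AXIS_INDEX[axis]]
    )
    if key in value:
        return float(value[key])
    if name == "mu_mag" and cond[1] == lowest_match:
        # perfectly ambiguous stimulus: mean drift pinned to zero
        return 0.0
    raise KeyError(f"no level {key!r} provided for field {name!r} (condition {cond})")


def _count_leaves(value) -> int:
    return 1 if np.isscalar(value) else len(value)


def build_condition_parameters(
    base: dict,
    design: DesignSpec,
    *,
    model_class: str = "gsr",
    drift_rule: str = "geometric",
) -> ConditionParameterMap:
    """Resolve per-factor parameter values into one ParameterSet per condition.

    ``base`` maps field names to either a scalar (shared across conditions)
    or a dict keyed by the relevant factor level: ``phi`` by match level,
    ``theta`` and ``gamma`` by discriminability level, and ``mu_mag`` by
    ``(coherence, match)`` pairs.  ``tau``, ``nu``, ``s_v`` and ``sigma``
    are always shared.  A missing ``mu_mag`` entry is allowed only for the
    lowest match level, where the mean drift is pinned to zero.

    The free-parameter count is the number of numeric leaves over
    ``phi, mu_mag, theta, tau, nu, gamma, s_v`` (``sigma`` is a fixed
    scaling convention): the 12-condition application mapping has
    3 + 4 + 2 + 2 + 1 + 1 + 1 = 14.
    """
    if model_class not in MODEL_CLASSES:
        raise ValueError(f"unknown model_class {model_class!r}")
    if drift_rule not in ("geometric", "match_proportion"):
        raise ValueError(f"unknown drift_rule {drift_rule!r}")
    unknown = set(base) - set(_COUNTED_FIELDS) - set(_SHARED_FIELDS)
    if unknown:
        raise ValueError(f"unknown parameter fields: {sorted(unknown)}")
    lowest_match = min(c[1] for c in design.conditions)
    params: dict[tuple, ParameterSet] = {}
    for cond in design.conditions:
        kwargs = {}
        for name in ("phi", "mu_mag", "theta", "tau", "nu", "gamma", "s_v", "sigma"):
            if name not in base:
                continue
            try:
                kwargs[name] = _resolve_field(name, base[name], cond, lowest_match)
            except KeyError as exc:
                raise KeyError(str(exc)) from None
        missing = {"phi", "mu_mag", "theta", "tau", "nu", "gamma"} - set(kwargs)
        if missing:
            raise KeyError(f"base is missing required fields: {sorted(missing)}")
        params[cond] = ParameterSet(**kwargs)
    n_free = sum(_count_leaves(base[f]) for f in _COUNTED_FIELDS if f in base)
    return ConditionParameterMap(
        params=params,
        n_free_parameters=n_free,
        model_class=model_class,
        drift_rule=drift_rule,
    )
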