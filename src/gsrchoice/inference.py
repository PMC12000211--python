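"""Amortized model identification by simulation-based training.

Two feed-forward networks are trained on simulated participants: a
*classifier* that maps a summary vector to the posterior probability that
the data came from an accumulator (vs. diffusion) model, and an *estimator*
that regresses the generative parameters (on the log scale, so that
exponentiating guarantees positive estimates) from the same summaries.
Once trained, inference on new data is a single forward pass.

Networks are fully connected (three hidden layers of 128 rectified units by
default) with standardized inputs and early stopping on a held-out split.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .parameters import SQRT2, PriorSpec, sample_parameter_arrays
from .simulate import (
    DEFAULT_DT,
    DEFAULT_T_MAX,
    DesignSpec,
    build_condition_parameters,
    first_passage,
    simulate_dataset,
    start_projections,
    trial_drifts,
)
from .summaries import QUANTILE_PROBS, summarize_design, SummaryVector

__all__ = [
    "NetSpec",
    "TrainingSet",
    "ClassifierModel",
    "EstimatorModel",
    "generate_training_set",
    "split_training_set",
    "train_classifier",
    "classify",
    "evaluate_classifier",
    "train_estimator",
    "estimate_parameters",
    "recovery_report",
    "save_model",
    "load_model",
]

_QPROBS = np.asarray(QUANTILE_PROBS)

SINGLE_LAYOUT = (
    ["accuracy", "min_rt_correct", "min_rt_error", "mean_rt_correct", "mean_rt_error"]
    + [f"q{int(p * 100)}_correct" for p in QUANTILE_PROBS]
    + [f"q{int(p * 100)}_error" for p in QUANTILE_PROBS]
)

SINGLE_TARGETS = ("phi", "mu_mag", "theta", "tau", "nu", "gamma")


@dataclass
class NetSpec:
    """Architecture and training settings for the amortized networks."""

    hidden_layers: tuple = (128, 128, 128)
    activation: str = "relu"
    max_iter: int = 200
    patience: int = 10
    validation_fraction: float = 0.1
    alpha: float = 1e-4
    learning_rate_init: float = 1e-3
    batch_size: int | str = "auto"


@dataclass
class TrainingSet:
    """Summary-vector inputs paired with labels or log-parameter targets."""

    X: np.ndarray
    y: np.ndarray
    mode: str  # "classify" | "estimate"
    layout: tuple
    target_names: tuple = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("inputs and targets must have equal row counts")
        if self.mode == "classify" and not np.all(np.isin(self.y, (0.0, 1.0))):
            raise ValueError("classification labels must be 0 (diffusion) or 1 (accumulator)")

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class ClassifierModel:
    pipeline: Pipeline
    layout: tuple
    meta: dict = field(default_factory=dict)


@dataclass
class EstimatorModel:
    pipeline: Pipeline
    layout: tuple
    target_names: tuple
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# batched single-condition simulation


def _summaries_single_from_arrays(
    rt: np.ndarray, correct: np.ndarray, ok: np.ndarray, n_participants: int, n_trials: int
) -> tuple[np.ndarray, np.ndarray]:
    """15-slot summaries per participant from flat per-trial arrays.

    Returns (X, valid) where ``valid`` marks participants with at least one
    uncensored trial.  Missing-side RT slots are imputed from the other
    response type, mirroring the summary module's rule.
    """
    X = np.empty((n_participants, 15))
    valid = np.ones(n_participants, dtype=bool)
    for p in range(n_participants):
        sl = slice(p * n_trials, (p + 1) * n_trials)
        m_ok = ok[sl]
        if not m_ok.any():
            valid[p] = False
            continue
        r = rt[sl][m_ok]
        c = correct[sl][m_ok]
        r_c = r[c]
        r_e = r[~c]
        acc = r_c.size / r.size
        base_c = r_c if r_c.size else r_e
        base_e = r_e if r_e.size else r_c
        X[p, 0] = acc
        X[p, 1] = base_c.min()
        X[p, 2] = base_e.min()
        X[p, 3] = base_c.mean()
        X[p, 4] = base_e.mean()
        X[p, 5:10] = np.quantile(base_c, _QPROBS)
        X[p, 10:15] = np.quantile(base_e, _QPROBS)
    return X, valid


def _simulate_single_condition_class(
    model_class: str,
    n_sims: int,
    n_trials: int,
    priors: PriorSpec,
    rng: np.random.Generator,
    *,
    dt: float,
    t_max: float,
    chunk_trials: int = 400_000,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Simulate ``n_sims`` single-condition participants of one model class.

    Returns their 15-slot summary matrix and the generative parameter
    arrays.  Participants whose every trial is censored are resampled; the
    resample count is recorded by the caller.
    """
    per_chunk = max(1, chunk_trials // max(n_trials, 1))
    X_parts: list[np.ndarray] = []
    par_parts: list[dict] = []
    n_resampled = 0
    remaining = n_sims
    while remaining > 0:
        p = min(per_chunk, remaining)
        pars = sample_parameter_arrays(priors, p, model_class, rng)
        phi_t = np.repeat(pars["phi"], n_trials)
        mu_t = np.repeat(pars["mu_mag"], n_trials)
        nu_t = np.repeat(pars["nu"], n_trials)
        gam_t = np.repeat(pars["gamma"], n_trials)
        th_t = np.repeat(pars["theta"], n_trials)
        d_a, d_b = trial_drifts(model_class, phi_t, mu_t, nu_t, gam_t, p * n_trials, rng)
        res = first_passage(
            d_a, d_b, gam_t, th_t, dt=dt, t_max=t_max, rng=rng
        )
        # option with the larger mean drift projection is "correct"
        correct_a = pars["mu_mag"] * np.cos(pars["phi"]) >= pars["mu_mag"] * np.cos(
            pars["gamma"] - pars["phi"]
        )
        correct = (res["choice"] == 0) == np.repeat(correct_a, n_trials)
        rt = res["decision_time"] + np.repeat(pars["tau"], n_trials)
        ok = ~res["censored"]
        X, valid = _summaries_single_from_arrays(rt, correct, ok, p, n_trials)
        X_parts.append(X[valid])
        par_parts.append({k: v[valid] for k, v in pars.items()})
        n_kept = int(valid.sum())
        n_resampled += p - n_kept
        remaining -= n_kept
    X = np.vstack(X_parts)[:n_sims]
    pars = {
        k: np.concatenate([d[k] for d in par_parts])[:n_sims] for k in par_parts[0]
    }
    pars["_n_resampled"] = np.array([n_resampled])
    return X, pars


# ---------------------------------------------------------------------------
# design-replicating simulation (multi-condition)

DESIGN_TARGETS = (
    "phi_m0", "phi_m1", "phi_m2",
    "mu_c0m1", "mu_c0m2", "mu_c1m1", "mu_c1m2",
    "theta_d0", "theta_d1",
    "gamma_d0", "gamma_d1",
    "tau", "nu", "s_v",
)


def _draw_design_base(
    priors: PriorSpec, model_class: str, rng: np.random.Generator
) -> dict:
    """Draw one participant's per-factor application-model parameters."""
    mu_scale = SQRT2 if model_class == "diffusion" else 1.0
    theta = {d: float(priors.draw("theta", 1, rng)[0]) for d in (0, 1)}
    if model_class == "diffusion":
        gamma = {0: math.pi, 1: math.pi}
    elif model_class == "accumulator":
        gamma = {0: math.pi / 2, 1: math.pi / 2}
    else:
        g = np.clip(priors.draw("gamma", 2, rng), 1e-9, math.pi)
        gamma = {0: float(g[0]), 1: float(g[1])}
    base = {
        "phi": {m: float(priors.draw("phi", 1, rng)[0]) for m in (0, 1, 2)},
        "mu_mag": {
            (c, m): float(priors.draw("mu_mag", 1, rng)[0]) * mu_scale
            for c in (0, 1)
            for m in (1, 2)
        },
        "theta": theta,
        "gamma": gamma,
        "tau": float(priors.draw("tau", 1, rng)[0]),
        "nu": float(priors.draw("nu", 1, rng)[0]),
        # start-point variability prior: uniform up to half the smaller threshold
        "s_v": float(rng.uniform(0.0, min(theta.values()) / 2.0)),
    }
    return base


def _design_targets_from_base(base: dict) -> np.ndarray:
    return np.array(
        [base["phi"][0], base["phi"][1], base["phi"][2],
         base["mu_mag"][(0, 1)], base["mu_mag"][(0, 2)],
         base["mu_mag"][(1, 1)], base["mu_mag"][(1, 2)],
         base["theta"][0], base["theta"][1],
         base["gamma"][0], base["gamma"][1],
         base["tau"], base["nu"], base["s_v"]]
    )


def _simulate_design_class(
    model_class: str,
    n_sims: int,
    design: DesignSpec,
    priors: PriorSpec,
    rng: np.random.Generator,
    *,
    dt: float,
    t_max: float,
    drift_rule: str = "geometric",
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate design-replicating participants; returns (X, target matrix)."""
    rows: list[np.ndarray] = []
    targets: list[np.ndarray] = []
    n_resampled = 0
    while len(rows) < n_sims:
        base = _draw_design_base(priors, model_class, rng)
        cond_map = build_condition_parameters(
            base, design, model_class=model_class, drift_rule=drift_rule
        )
        trials = simulate_dataset(cond_map, design, rng, dt=dt, t_max=t_max)
        try:
            sv = summarize_design(trials, design)
        except ValueError:
            n_resampled += 1
            continue
        rows.append(sv.values)
        targets.append(_design_targets_from_base(base))
    return np.vstack(rows), np.vstack(targets)


# ---------------------------------------------------------------------------
# training-set generation


def generate_training_set(
    mode: str,
    design: DesignSpec,
    n_sims: int,
    priors: PriorSpec,
    rng: np.random.Generator,
    *,
    dt: float = DEFAULT_DT,
    t_max: float = DEFAULT_T_MAX,
    seed_note: int | None = None,
) -> TrainingSet:
    """Simulate a corpus of artificial participants and summarize them.

    ``mode="classify"`` simulates ``n_sims`` participants per class —
    diffusion (``gamma = pi``, with the sqrt(2) drift scaling) labelled 0
    and accumulator (``gamma = pi/2``) labelled 1.  ``mode="estimate"``
    simulates ``n_sims`` gsr participants with ``gamma`` drawn from its
    uniform prior and log-transformed generative parameters as targets.

    A single-condition design produces 15-input rows; a multi-condition
    design produces 8-inputs-per-condition rows (96 for the 12-condition
    application design) with the per-factor application parameterization.
    """
    if mode not in ("classify", "estimate"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    single = design.n_conditions == 1
    meta = {"design_conditions": design.n_conditions, "seed": seed_note,
            "n_trials": design.n_trials, "dt": dt, "t_max": t_max}

    if mode == "classify":
        if single:
            n_trials = design.trials_per_condition
            X_d, _ = _simulate_single_condition_class(
                "diffusion", n_sims, n_trials, priors, rng, dt=dt, t_max=t_max
            )
            X_a, _ = _simulate_single_condition_class(
                "accumulator", n_sims, n_trials, priors, rng, dt=dt, t_max=t_max
            )
            layout = tuple(SINGLE_LAYOUT)
        else:
            X_d, _ = _simulate_design_class(
                "diffusion", n_sims, design, priors, rng, dt=dt, t_max=t_max
            )
            X_a, _ = _simulate_design_class(
                "accumulator", n_sims, design, priors, rng, dt=dt, t_max=t_max,
                drift_rule="match_proportion",
            )
            layout = _design_layout(design)
        X = np.vstack([X_d, X_a])
        y = np.concatenate([np.zeros(len(X_d)), np.ones(len(X_a))])
        return TrainingSet(X=X, y=y, mode="classify", layout=layout, meta=meta)

    # estimate
    if single:
        n_trials = design.trials_per_condition
        X, pars = _simulate_single_condition_class(
            "gsr", n_sims, n_trials, priors, rng, dt=dt, t_max=t_max
        )
        y = np.log(np.column_stack([pars[k] for k in SINGLE_TARGETS]))
        return TrainingSet(
            X=X, y=y, mode="estimate", layout=tuple(SINGLE_LAYOUT),
            target_names=SINGLE_TARGETS, meta=meta,
        )
    X, tgt = _simulate_design_class(
        "gsr", n_sims, design, priors, rng, dt=dt, t_max=t_max
    )
    return TrainingSet(
        X=X, y=np.log(tgt), mode="estimate", layout=_design_layout(design),
        target_names=DESIGN_TARGETS, meta=meta,
    )


def _design_layout(design: DesignSpec) -> tuple:
    layout = []
    for cond in design.conditions:
        label = DesignSpec.condition_label(cond)
        layout.extend(
            [f"{label}:accuracy", f"{label}:mean_rt_correct", f"{label}:mean_rt_error"]
            + [f"{label}:q{int(p * 100)}" for p in QUANTILE_PROBS]
        )
    return tuple(layout)


def split_training_set(
    ts: TrainingSet, test_fraction: float, rng: np.random.Generator
) -> tuple[TrainingSet, TrainingSet]:
    """Random disjoint train/test split of a training set."""
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie in (0, 1)")
    n = ts.n
    perm = rng.permutation(n)
    n_test = max(1, int(round(n * test_fraction)))
    te, tr = perm[:n_test], perm[n_test:]
    mk = lambda idx: TrainingSet(
        X=ts.X[idx], y=ts.y[idx], mode=ts.mode, layout=ts.layout,
        target_names=ts.target_names, meta=dict(ts.meta),
    )
    return mk(tr), mk(te)


# ---------------------------------------------------------------------------
# training and application


def _check_finite(X: np.ndarray) -> None:
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in network inputs")


def _mk_pipeline(net: NetSpec, estimator) -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("net", estimator)])


def train_classifier(
    train: TrainingSet, net: NetSpec | None = None, rng: np.random.Generator | None = None
) -> ClassifierModel:
    """Train the diffusion-vs-accumulator classification network."""
    if train.mode != "classify":
        raise ValueError("training set is not in classify mode")
    _check_finite(train.X)
    net = net or NetSpec()
    seed = int(rng.integers(2**31)) if rng is not None else 0
    clf = MLPClassifier(
        hidden_layer_sizes=net.hidden_layers,
        activation=net.activation,
        alpha=net.alpha,
        batch_size=net.batch_size,
        learning_rate_init=net.learning_rate_init,
        max_iter=net.max_iter,
        early_stopping=True,
        validation_fraction=net.validation_fraction,
        n_iter_no_change=net.patience,
        random_state=seed,
    )
    pipe = _mk_pipeline(net, clf)
    pipe.fit(train.X, train.y.astype(int))
    return ClassifierModel(pipeline=pipe, layout=train.layout, meta={"n_train": train.n})


def _as_matrix(summary, layout) -> np.ndarray:
    if isinstance(summary, SummaryVector):
        if tuple(summary.layout) != tuple(layout):
            raise ValueError("summary layout does not match the model's training layout")
        return summary.values[None, :]
    X = np.atleast_2d(np.asarray(summary, dtype=float))
    if X.shape[1] != len(layout):
        raise ValueError(
            f"expected {len(layout)} inputs per row, got {X.shape[1]}"
        )
    return X


def classify(model: ClassifierModel, summary):
    """Posterior probability that the data came from an accumulator model.

    Accepts a single :class:`SummaryVector` (returns a float) or a matrix of
    summary rows (returns an array).  ``P(diffusion) = 1 - value``.
    """
    X = _as_matrix(summary, model.layout)
    proba = model.pipeline.predict_proba(X)[:, list(model.pipeline.classes_).index(1)]
    if isinstance(summary, SummaryVector):
        return float(proba[0])
    return proba


def evaluate_classifier(
    model: ClassifierModel, test: TrainingSet, threshold: float = 0.5
) -> tuple[float, pd.DataFrame]:
    """Held-out accuracy and row-normalised 2x2 confusion matrix.

    Accuracy is the proportion of rows whose posterior falls on the correct
    side of ``threshold``; rows of the confusion matrix are the true model,
    columns the recovered model, and each row sums to one.
    """
    if test.n == 0:
        raise ValueError("empty test set")
    p_acc = classify(model, test.X)
    pred = (p_acc > threshold).astype(int)
    y = test.y.astype(int)
    labels = ("diffusion", "accumulator")
    mat = np.zeros((2, 2))
    for t in (0, 1):
        mask = y == t
        if mask.any():
            mat[t, 0] = np.mean(pred[mask] == 0)
            mat[t, 1] = np.mean(pred[mask] == 1)
        else:
            mat[t, t] = 1.0
    accuracy = float(np.mean(pred == y))
    cm = pd.DataFrame(mat, index=pd.Index(labels, name="true"), columns=pd.Index(labels, name="recovered"))
    return accuracy, cm


def train_estimator(
    train: TrainingSet, net: NetSpec | None = None, rng: np.random.Generator | None = None
) -> EstimatorModel:
    """Train the parameter-estimation network (multi-output, log targets)."""
    if train.mode != "estimate":
        raise ValueError("training set is not in estimate mode")
    _check_finite(train.X)
    _check_finite(train.y)
    net = net or NetSpec()
    seed = int(rng.integers(2**31)) if rng is not None else 0
    reg = MLPRegressor(
        hidden_layer_sizes=net.hidden_layers,
        activation=net.activation,
        alpha=net.alpha,
        batch_size=net.batch_size,
        learning_rate_init=net.learning_rate_init,
        max_iter=net.max_iter,
        early_stopping=True,
        validation_fraction=net.validation_fraction,
        n_iter_no_change=net.patience,
        random_state=seed,
    )
    pipe = _mk_pipeline(net, reg)
    pipe.fit(train.X, train.y)
    return EstimatorModel(
        pipeline=pipe, layout=train.layout, target_names=tuple(train.target_names),
        meta={"n_train": train.n},
    )


def estimate_parameters(model: EstimatorModel, summary):
    """Parameter estimates on the natural scale (exponentiated outputs).

    All estimates are strictly positive by construction; option-angle
    parameters are clipped into ``(0, pi]``.
    """
    X = _as_matrix(summary, model.layout)
    log_est = np.atleast_2d(model.pipeline.predict(X))
    est = np.exp(log_est)
    for j, name in enumerate(model.target_names):
        if name.startswith("gamma"):
            est[:, j] = np.clip(est[:, j], 1e-9, math.pi)
    if isinstance(summary, SummaryVector):
        return pd.Series(est[0], index=list(model.target_names))
    return pd.DataFrame(est, columns=list(model.target_names))


def recovery_report(
    true: np.ndarray,
    estimated: np.ndarray,
    target_names=None,
    split=None,
) -> pd.DataFrame:
    """Per-parameter recovery: linear correlation r and log-scale RMSE.

    ``true`` and ``estimated`` are natural-scale matrices of matching shape;
    ``split`` optionally labels each row (e.g. training vs validation) and
    the report is then stratified by label.
    """
    true = np.asarray(true, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if true.shape != estimated.shape:
        raise ValueError("true and estimated matrices must have the same shape")
    if true.ndim != 2:
        raise ValueError("expected 2-D parameter matrices")
    k = true.shape[1]
    names = list(target_names) if target_names is not None else [f"param_{j}" for j in range(k)]
    split = np.asarray(split) if split is not None else np.full(true.shape[0], "all")
    rows = []
    for lab in pd.unique(split):
        mask = split == lab
        t, e = true[mask], estimated[mask]
        for j in range(k):
            tj, ej = t[:, j], e[:, j]
            sd_t, sd_e = tj.std(), ej.std()
            r = float(np.corrcoef(tj, ej)[0, 1]) if sd_t > 0 and sd_e > 0 else np.nan
            rmse = float(np.sqrt(np.mean((np.log(tj) - np.log(ej)) ** 2)))
            rows.append({"split": lab, "parameter": names[j], "r": r, "rmse_log": rmse})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence


def save_model(model, path) -> None:
    """Persist a trained model with a JSON sidecar recording its layout."""
    path = Path(path)
    joblib.dump(model.pipeline, path)
    sidecar = {
        "kind": type(model).__name__,
        "layout": list(model.layout),
        "target_names": list(getattr(model, "target_names", ())),
        "meta": {k: v for k, v in model.meta.items() if isinstance(v, (int, float, str))},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path):
    path = Path(path)
    pipeline = joblib.load(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if sidecar["kind"] == "ClassifierModel":
        return ClassifierModel(pipeline=pipeline, layout=tuple(sidecar["layout"]), meta=sidecar["meta"])
    return EstimatorModel(
        pipeline=pipeline,
        layout=tuple(sidecar["layout"]),
        target_names=tuple(sidecar["target_names"]),
        meta=sidecar["meta"],
    )
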