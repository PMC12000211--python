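"""Seeded fixture generation: simulated participants with known ground truth.

The fixture set mirrors the shape of the study the package targets: by
default 34 participants, each completing the 12-condition application design
at 10 trials per condition (120 trials each, 4080 in total).  Ground-truth
model classes and parameters are stored in a manifest next to the trial
table, and regeneration from the same seed is byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .inference import _draw_design_base, _design_targets_from_base, DESIGN_TARGETS
from .parameters import PriorSpec, sample_parameter_arrays
from .simulate import (
    DesignSpec,
    TRIAL_COLUMNS,
    build_condition_parameters,
    simulate_dataset,
)

__all__ = ["FixtureSet", "generate_fixtures"]

_EXTRA_COLUMNS = ["n_steps", "balance_start", "balance_net"]


@dataclass
class FixtureSet:
    trials: pd.DataFrame
    manifest: pd.DataFrame
    design: DesignSpec


def _participant_class(i: int, model: str) -> str:
    if model == "mixed":
        return "diffusion" if i % 2 == 0 else "accumulator"
    return model


def generate_fixtures(
    config: RunConfig,
    rng: np.random.Generator | None = None,
    *,
    gamma_range: tuple[float, float] = (math.pi / 2, math.pi),
    out_dir: str | Path | None = None,
) -> FixtureSet:
    """Generate the fixture participants and optionally write them as CSV.

    ``config.model`` selects the generative class per participant:
    ``"mixed"`` alternates diffusion and accumulator, ``"gsr"`` draws the
    option angle uniformly from ``gamma_range``.  When ``out_dir`` is given,
    ``trials.csv`` and ``manifest.csv`` are written there.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    design = config.design_spec()
    priors = config.priors
    trials_frames = []
    manifest_rows = []
    for i in range(config.n_participants):
        model_class = _participant_class(i, config.model)
        if design.n_conditions == 1:
            pars = sample_parameter_arrays(priors, 1, model_class, rng)
            if model_class == "gsr":
                pars["gamma"] = np.array([rng.uniform(*gamma_range)])
            base = {k: float(v[0]) for k, v in pars.items()}
            cond_map = build_condition_parameters(base, design, model_class=model_class)
            truth = dict(base)
        else:
            base = _draw_design_base(priors, model_class, rng)
            if model_class == "gsr":
                base["gamma"] = {d: float(rng.uniform(*gamma_range)) for d in (0, 1)}
            cond_map = build_condition_parameters(base, design, model_class=model_class)
            truth = dict(zip(DESIGN_TARGETS, _design_targets_from_base(base)))
        table = simulate_dataset(
            cond_map, design, rng, dt=config.sim.dt, t_max=config.sim.t_max,
            participant=i,
        )
        trials_frames.append(table)
        gammas = [ps.gamma for ps in cond_map.params.values()]
        manifest_rows.append(
            {
                "participant": i,
                "model_class": model_class,
                "gamma": float(np.mean(gammas)),
                "n_free_parameters": cond_map.n_free_parameters,
                "parameters": json.dumps(truth, sort_keys=True),
            }
        )
    columns = TRIAL_COLUMNS + _EXTRA_COLUMNS
    if trials_frames:
        trials = pd.concat(trials_frames, ignore_index=True)[columns]
    else:
        trials = pd.DataFrame(columns=columns)
    manifest = pd.DataFrame(
        manifest_rows,
        columns=["participant", "model_class", "gamma", "n_free_parameters", "parameters"],
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        trials.to_csv(out / "trials.csv", index=False)
        manifest.to_csv(out / "manifest.csv", index=False)
    return FixtureSet(trials=trials, manifest=manifest, design=design)
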