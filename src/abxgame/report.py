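"""Tables, aggregated reports, and run manifests.

Everything here is plumbing over the model, equilibrium and dynamics
modules: an evenly spaced payoff table (the data behind the two-curve
payoff figure), a single JSON-serializable report combining the dilemma
classification, ESS evidence, rest points and peak velocity, and a
manifest that records enough to reproduce any output byte-for-byte.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import find_rest_points, peak_velocity
from .equilibrium import check_ess, classify_dilemma, find_symmetric_nash
from .game_model import ModelParams, Variant

__all__ = ["RunManifest", "payoff_table", "full_report", "write_csv", "write_json"]

REPORT_SCHEMA_VERSION = 1

#: CSV float formatting: 12 significant digits, '.' decimal separator
CSV_FLOAT_FORMAT = "%.12g"


@dataclass
class RunManifest:
    """Everything needed to reproduce an output deterministically."""

    command: str
    parameters: dict
    seed: int | None = None
    version: str = __version__
    created_unix: float = field(default_factory=time.time)

    def to_dict(self) -> dict:
        return asdict(self)


def params_dict(params: ModelParams) -> dict:
    d = asdict(params)
    d["variant"] = params.variant.value
    return d


def payoff_table(phi: float, q_steps: int = 101, params: ModelParams | None = None) -> pd.DataFrame:
    """Pure-strategy payoffs on an even q grid: columns (q, payoff_T, payoff_U).

    For the baseline model at phi = 0.5 this reproduces the two payoff
    lines -phi*q (treat) and -phi (don't treat) of the payoff figure.
    """
    if q_steps < 2:
        raise ValueError(f"q_steps must be >= 2, got {q_steps}")
    if params is None:
        params = ModelParams(phi=phi)
    elif params.phi != phi:
        params = params.with_(phi=phi)
    from .game_model import pure_payoffs

    rows = []
    for q in np.linspace(0.0, 1.0, q_steps):
        pp = pure_payoffs(float(q), params)
        rows.append((float(q), pp.payoff_T, pp.payoff_U))
    return pd.DataFrame(rows, columns=["q", "payoff_T", "payoff_U"])


def full_report(params: ModelParams, seed: int | None = None) -> dict:
    """One structured document tying the whole analysis together.

    Contains the dilemma classification, the symmetric Nash set, ESS
    evidence for the all-treat strategy, classified rest points, the
    cooperative optimum and the peak prescribing velocity.
    """
    dilemma = classify_dilemma(params)
    nash = find_symmetric_nash(params)
    ess = check_ess(1.0, params)
    rest = find_rest_points(params.phi, params)
    q_peak, qdot_peak = peak_velocity(params.phi)
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "parameters": params_dict(params),
        "dilemma": dilemma.to_dict(),
        "symmetric_nash": [
            {"p_star": p, "strict": strict} for p, strict in nash
        ],
        "ess_all_treat": ess.to_dict(),
        "rest_points": {
            "entire_interval": rest.entire_interval,
            "points": [
                {
                    "q": rp.q_star,
                    "derivative": rp.derivative,
                    "classification": rp.classification.value,
                }
                for rp in rest.points
            ],
        },
        "peak_velocity": {"q_at_max": q_peak, "qdot_max": qdot_peak},
        "seed": seed,
    }


def write_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
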