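"""Delimited-text response files and YAML run configuration.

Response files are CSV with header columns ``subject_id``,
``presentation_index``, ``dilution_step``, optional ``target_position``
(1-3) and ``response``, where response is one of the tokens ``1``
(correct), ``0`` (incorrect), ``DK`` (don't know) or ``REF`` (refused).
DK and REF are kept distinct on disk (survey provenance) even though
the imputer treats them identically.  Dilution steps are on the
Sniffin'-Sticks scale (1 = 4% v/v), with steps <= 0 permitted for
stronger pens.

A run configuration is a YAML mapping with a ``population`` block
(``preset: <name>`` or explicit ``family``/parameters/``beta``), one or
more protocol blocks, and the run sizes/seed.  The resolved
configuration is serialized next to every output so a run can be
reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from .impute import CORRECT, INCORRECT, DONT_KNOW, REFUSED
from .populations import PopulationModel, preset
from .protocols import ConstantStimuliProtocol, StaircaseProtocol

__all__ = [
    "read_responses", "write_responses", "RunConfig",
    "load_config", "population_from_config", "protocol_from_config",
]

_TOKEN_TO_CODE = {"1": CORRECT, "0": INCORRECT, "DK": DONT_KNOW, "REF": REFUSED}
_CODE_TO_TOKEN = {v: k for k, v in _TOKEN_TO_CODE.items()}
_COLUMNS = ["subject_id", "presentation_index", "dilution_step", "response"]


class ResponseFileError(ValueError):
    """Malformed response file (message names the offending line)."""


def read_responses(path) -> pd.DataFrame:
    """Read a response CSV; returns a validated DataFrame.

    Responses are returned as int8 codes (1, 0, DK=2, REF=3).  Raises
    :class:`ResponseFileError` naming the first offending line for
    unknown response tokens or duplicate (subject, presentation_index)
    pairs.
    """
    df = pd.read_csv(path, dtype={"response": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ResponseFileError(f"{path}: missing columns {missing}")
    tokens = df["response"].str.strip()
    bad = ~tokens.isin(_TOKEN_TO_CODE)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
        raise ResponseFileError(
            f"{path}: line {line}: unknown response token "
            f"{df['response'].iloc[int(np.flatnonzero(bad)[0])]!r} "
            f"(expected one of {sorted(_TOKEN_TO_CODE)})")
    dup = df.duplicated(subset=["subject_id", "presentation_index"])
    if dup.any():
        line = int(np.flatnonzero(dup)[0]) + 2
        raise ResponseFileError(
            f"{path}: line {line}: duplicate (subject_id, presentation_index)")
    out = df.copy()
    out["response"] = tokens.map(_TOKEN_TO_CODE).astype(np.int8)
    out["dilution_step"] = out["dilution_step"].astype(float)
    if not np.isfinite(out["dilution_step"]).all():
        raise ResponseFileError(f"{path}: non-finite dilution_step present")
    return out


def write_responses(table: pd.DataFrame, path) -> None:
    """Write a response DataFrame as CSV (codes mapped back to tokens)."""
    out = table.copy()
    out["response"] = out["response"].map(_CODE_TO_TOKEN)
    if out["response"].isna().any():
        raise ValueError("response column contains codes outside {1,0,DK,REF}")
    out.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulation run."""

    population: dict
    protocol: dict
    n_subjects: int = 100
    n_reps: int = 500
    seed: int = 0
    estimator: str = "irt_eb"
    imputations: int = 10
    quadrature: int = 21

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known - {"designs"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: v for k, v in mapping.items() if k in known})

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def population_from_config(block) -> PopulationModel:
    """Build a PopulationModel from a config block (preset or explicit)."""
    if isinstance(block, str):
        return preset(block)
    if "preset" in block:
        return preset(block["preset"])
    family = block.get("family")
    beta = block.get("beta")
    if family == "normal":
        return PopulationModel.normal(block["mean"], block["sd"], beta)
    if family == "shifted_gamma":
        return PopulationModel.shifted_gamma(block["shape"], block["scale"],
                                             block["location"], beta)
    raise ValueError(f"population block needs a preset or a known family, got {block!r}")


def protocol_from_config(block):
    """Build a protocol from a config block (``type: constant | staircase``)."""
    kind = block.get("type", "constant")
    if kind == "constant":
        return ConstantStimuliProtocol(
            tuple(block["steps"]),
            order_policy=block.get("order_policy", "as_given"),
            target_positions=(tuple(block["target_positions"])
                              if block.get("target_positions") else None))
    if kind == "staircase":
        return StaircaseProtocol(
            step_min=block.get("step_min", 1),
            step_max=block.get("step_max", 16),
            start_steps=tuple(block.get("start_steps", (15, 16))),
            reversals_to_stop=block.get("reversals_to_stop", 7),
            reversals_to_score=block.get("reversals_to_score", 4),
            max_presentations=block.get("max_presentations", 60))
    raise ValueError(f"unknown protocol type {kind!r}")
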