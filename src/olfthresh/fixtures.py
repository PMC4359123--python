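"""Deterministic small datasets for tests, demos and format checks.

All fixtures are generated programmatically (nothing is shipped as
data); given the same seed the output is bit-identical.  The staircase
fixture replays a fixed, hand-traced response script whose reversal
sequence is [9, 11, 9, 11, 9, 11, 9], scoring 10.0.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .impute import DONT_KNOW, REFUSED
from .populations import preset
from .protocols import (ConstantStimuliProtocol, StaircaseProtocol, NSHAP_STEPS,
                        replay_staircase, simulate_constant_stimuli)

__all__ = ["make_fixtures", "HAND_TRACE_RESPONSES", "HAND_TRACE_START"]

#: Scripted responses driving the staircase from pen 15 down to the 9/11
#: band and oscillating there: descent by six incorrects, then repeated
#: correct-pairs and incorrects producing reversals [9,11,9,11,9,11,9].
HAND_TRACE_RESPONSES = (
    0, 0, 0, 0, 0, 0,      # 15..10 incorrect, arrive at 9
    1, 1,                  # pair at 9  -> reversal 1 at 9, move to 10
    1, 1,                  # pair at 10 -> to 11
    0,                     # incorrect at 11 -> reversal 2, to 10
    0,                     # incorrect at 10 -> to 9
    1, 1,                  # pair at 9  -> reversal 3, to 10
    1, 1,                  # pair at 10 -> to 11
    0,                     # reversal 4 at 11, to 10
    0,                     # to 9
    1, 1,                  # reversal 5 at 9, to 10
    1, 1,                  # to 11
    0,                     # reversal 6 at 11, to 10
    0,                     # to 9
    1, 1,                  # reversal 7 at 9 -> stop; score mean(11,9,11,9)=10.0
)
HAND_TRACE_START = 15

# NSHAP-style target-position schedule (fixed for all respondents; the
# published schedule is not enumerated, so this synthetic one stands in).
_NSHAP_POSITIONS = (2, 1, 3, 1, 2, 3)


def make_fixtures(seed: int = 0, out_dir=None) -> dict:
    """Build the bundled fixtures; optionally write them under ``out_dir``.

    Returns a dict with keys ``survey`` (5-subject, 6-item NSHAP-style
    table containing DK and REF codes), ``normosmic`` (20-subject,
    16-item table) and ``staircase`` (the hand-traced StaircaseRun).
    """
    ss = np.random.SeedSequence(seed).spawn(2)

    nshap = preset("nshap_gamma")
    proto6 = ConstantStimuliProtocol(NSHAP_STEPS, target_positions=_NSHAP_POSITIONS)
    rng = np.random.default_rng(ss[0])
    thresholds = nshap.sample_thresholds(5, rng)
    survey = simulate_constant_stimuli(thresholds, nshap.beta, proto6, rng)
    # plant one DK and one REF at the weakest dilution, where survey
    # non-response concentrates
    survey.loc[survey.index[0], "response"] = DONT_KNOW
    survey.loc[survey.index[6], "response"] = REFUSED
    survey["response"] = survey["response"].astype(np.int8)

    normo = preset("normosmic")
    proto16 = ConstantStimuliProtocol(tuple(range(1, 17)))
    rng2 = np.random.default_rng(ss[1])
    normosmic = simulate_constant_stimuli(
        normo.sample_thresholds(20, rng2), normo.beta, proto16, rng2)

    run = replay_staircase(HAND_TRACE_RESPONSES, HAND_TRACE_START,
                           StaircaseProtocol())

    fixtures = {"survey": survey, "normosmic": normosmic, "staircase": run}
    if out_dir is not None:
        from .io import write_responses

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_responses(survey, out / "survey_responses.csv")
        write_responses(normosmic, out / "normosmic_responses.csv")
        pd.DataFrame(run.presentations,
                     columns=["dilution_step", "response"]).to_csv(
            out / "staircase_trace.csv", index=False)
    return fixtures
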