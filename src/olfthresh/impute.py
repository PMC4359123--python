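"""Non-response handling: chance-level imputation, pooling, sum scores.

Survey administrations allow "don't know" (DK) and "refused" (REF)
responses.  Treating these as incorrect would bias thresholds downward,
because a forced guess would have been correct 1/3 of the time.  The
imputation model therefore replaces each DK/REF record with an
independent Bernoulli(1/3) correct/incorrect draw, repeated across
``m`` imputations; fits on the completed tables are combined by Rubin's
rules and per-subject thresholds by their mean across imputations.
DK and REF are distinct codes in files but identical to the imputer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scale import GUESS_FLOOR

__all__ = [
    "CORRECT", "INCORRECT", "DONT_KNOW", "REFUSED",
    "impute_responses", "pool_parameters", "pool_subject_estimates",
    "sum_score", "fit_with_imputation", "PooledIRTFit",
]

# integer response codes used in-memory (files use tokens 1/0/DK/REF)
CORRECT, INCORRECT, DONT_KNOW, REFUSED = 1, 0, 2, 3
MISSING_CODES = (DONT_KNOW, REFUSED)


def impute_responses(data: pd.DataFrame, m: int = 10, seed=None,
                     response_col: str = "response") -> list[pd.DataFrame]:
    """Return ``m`` completed copies of ``data``.

    Each DK/REF record is independently replaced by a Bernoulli(1/3)
    correct response; observed records are untouched.  Given the same
    seed the full list of imputations is reproducible; each imputation
    uses its own substream.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    missing = data[response_col].isin(MISSING_CODES).to_numpy()
    streams = np.random.SeedSequence(seed).spawn(m)
    out = []
    for ss in streams:
        completed = data.copy()
        if missing.any():
            rng = np.random.default_rng(ss)
            draws = (rng.random(int(missing.sum())) < GUESS_FLOOR).astype(
                data[response_col].dtype)
            col = completed[response_col].to_numpy().copy()
            col[missing] = draws
            completed[response_col] = col
        out.append(completed)
    return out


def pool_parameters(estimates, within_variances) -> tuple[np.ndarray, np.ndarray]:
    """Rubin's rules for ``m`` point estimates and within-imputation variances.

    Returns (pooled estimate, total variance) where total variance is
    ``mean(within) + (1 + 1/m) * between`` with ``between`` the ddof=1
    variance of the estimates.  Inputs may be scalars-per-imputation or
    (m, p) arrays.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(within_variances, dtype=float)
    if q.ndim == 1:
        q = q[:, None]
    if u.ndim == 1:
        u = u[:, None]
    m = q.shape[0]
    qbar = q.mean(axis=0)
    ubar = u.mean(axis=0)
    between = q.var(axis=0, ddof=1) if m > 1 else np.zeros_like(qbar)
    total = ubar + (1.0 + 1.0 / m) * between
    return np.squeeze(qbar), np.squeeze(total)


def pool_subject_estimates(estimate_frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean across imputations of per-subject EB estimates.

    Frames must share the ``subject_id`` column; numeric columns are
    averaged element-wise.
    """
    stacked = pd.concat(estimate_frames)
    return stacked.groupby("subject_id", sort=True).mean().reset_index()


def sum_score(data: pd.DataFrame, response_col: str = "response",
              subject_col: str = "subject_id") -> pd.Series:
    """Number of correct responses per subject; DK/REF count as incorrect."""
    correct = (data[response_col] == CORRECT).astype(int)
    return correct.groupby(data[subject_col]).sum()


@dataclass
class PooledIRTFit:
    """IRT fit pooled over multiple imputations (Rubin's rules)."""

    params: pd.Series            # pooled (beta, mu_alpha, var_alpha)
    bse: pd.Series               # sqrt of Rubin total variance
    subject_estimates: pd.DataFrame
    m: int
    n_converged: int
    fits: list                   # per-imputation ThresholdIRTResults


def fit_with_imputation(data: pd.DataFrame, m: int = 10, seed=None,
                        **model_kwargs) -> PooledIRTFit:
    """Impute DK/REF, fit the IRT per imputation, pool by Rubin's rules.

    Per-subject thresholds are pooled by their mean across converged
    imputations.  Raises if no imputation converges.
    """
    from .irt import ThresholdIRT

    completed = impute_responses(data, m=m, seed=seed)
    fits, ebs = [], []
    for table in completed:
        res = ThresholdIRT.from_dataframe(table, **model_kwargs).fit()
        fits.append(res)
        if res.converged:
            ebs.append(res.empirical_bayes())
    if not ebs:
        raise RuntimeError("no imputation produced a converged fit")
    used = [f for f in fits if f.converged]
    q = np.vstack([f.params.to_numpy() for f in used])
    u = np.vstack([f.bse.to_numpy() ** 2 for f in used])
    pooled, total = pool_parameters(q, u)
    names = used[0].params.index
    return PooledIRTFit(
        params=pd.Series(np.atleast_1d(pooled), index=names),
        bse=pd.Series(np.sqrt(np.atleast_1d(total)), index=names),
        subject_estimates=pool_subject_estimates(ebs),
        m=m,
        n_converged=len(used),
        fits=fits,
    )
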