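"""Monte-Carlo evaluation of protocol accuracy and reliability.

The replication engine answers the design question "how well would this
protocol measure thresholds in this population?" without human
subjects: per replication it draws true thresholds from a population
model, simulates an administration, estimates each subject's threshold
(empirical-Bayes IRT for constant stimuli, last-reversal scoring or IRT
for the staircase), and records the Pearson correlation ``r`` between
estimates and truths.  Reliability is ``r**2``; summaries average the
per-replication reliabilities over converged replications (the mean of
squares, not the square of the mean) and report the 5/50/95 percentiles
and the fraction of convergence failures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .irt import ThresholdIRT
from .populations import PopulationModel
from .protocols import (ConstantStimuliProtocol, StaircaseProtocol,
                        simulate_constant_stimuli, simulate_staircase,
                        staircase_scores, runs_to_table)

__all__ = [
    "reliability", "ReplicationSummary", "AgreementSummary",
    "run_replications", "method_correlation", "agreement_summary",
    "protocol_table",
]


def reliability(estimates, truths) -> tuple[float, float]:
    """Pearson correlation and its square for paired estimate/truth vectors.

    Raises ``ValueError`` on constant input (correlation undefined).
    """
    a = np.asarray(estimates, dtype=float)
    b = np.asarray(truths, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need paired vectors of equal length >= 3")
    for v in (a, b):
        if np.std(v) <= 1e-10 * max(1.0, float(np.abs(v).max())):
            raise ValueError("correlation undefined for a (near-)constant vector")
    r = float(stats.pearsonr(a, b).statistic)
    return r, r * r


@dataclass
class ReplicationSummary:
    """Per-replication reliabilities plus their aggregates.

    Aggregates are computed over converged replications only; the
    failure rate is reported separately, never silently dropped.
    """

    per_rep: pd.DataFrame  # columns: rep, correlation, reliability, converged
    n_subjects: int = 0
    label: str = ""

    @property
    def n_reps(self) -> int:
        return len(self.per_rep)

    @property
    def _ok(self) -> pd.DataFrame:
        return self.per_rep[self.per_rep["converged"]]

    @property
    def usable(self) -> bool:
        return len(self._ok) > 0

    @property
    def mean_reliability(self) -> float:
        return float(self._ok["reliability"].mean()) if self.usable else float("nan")

    @property
    def mean_correlation(self) -> float:
        return float(self._ok["correlation"].mean()) if self.usable else float("nan")

    @property
    def se_of_mean(self) -> float:
        ok = self._ok["reliability"]
        if len(ok) < 2:
            return float("nan")
        return float(ok.std(ddof=1) / np.sqrt(len(ok)))

    def percentiles(self, q=(5, 50, 95)) -> np.ndarray:
        if not self.usable:
            return np.full(len(q), np.nan)
        return np.percentile(self._ok["reliability"], q)

    @property
    def pct_convergence_failures(self) -> float:
        return 100.0 * (1.0 - self.per_rep["converged"].mean())

    def to_row(self) -> dict:
        p5, p50, p95 = self.percentiles()
        return {
            "design": self.label,
            "n_subjects": self.n_subjects,
            "n_reps": self.n_reps,
            "mean_reliability": self.mean_reliability,
            "se": self.se_of_mean,
            "mean_correlation": self.mean_correlation,
            "p5": p5, "p50": p50, "p95": p95,
            "pct_convergence_failures": self.pct_convergence_failures,
        }


@dataclass
class AgreementSummary:
    """Bland-Altman style agreement between two paired estimate vectors."""

    mean_difference: float
    sd_difference: float
    band: tuple
    band_mean_difference: float
    band_sd_difference: float
    n: int
    n_in_band: int


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _estimate_constant_stimuli(table, n_quadrature):
    model = ThresholdIRT.from_dataframe(table, n_quadrature=n_quadrature)
    res = model.fit()
    est = res.empirical_bayes()["threshold_eb"].to_numpy()
    return est, res.converged


def _one_replication(pop: PopulationModel, protocol, n_subjects, estimator,
                     n_quadrature, rng):
    truths = pop.sample_thresholds(n_subjects, rng)
    if isinstance(protocol, StaircaseProtocol):
        runs = simulate_staircase(truths, pop.beta, protocol, rng)
        if estimator == "staircase_score":
            return staircase_scores(runs), truths, True
        if estimator == "irt_eb":
            est, ok = _estimate_constant_stimuli(runs_to_table(runs), n_quadrature)
            return est, truths, ok
        raise ValueError(f"unknown estimator {estimator!r} for a staircase protocol")
    if estimator != "irt_eb":
        raise ValueError("constant-stimuli data require the irt_eb estimator")
    table = simulate_constant_stimuli(truths, pop.beta, protocol, rng)
    est, ok = _estimate_constant_stimuli(table, n_quadrature)
    return est, truths, ok


def run_replications(pop: PopulationModel, protocol, n_subjects: int,
                     n_reps: int, seed, estimator: str = "irt_eb",
                     n_quadrature: int = 21, label: str = "") -> ReplicationSummary:
    """Estimate protocol reliability for a population by simulation.

    Per replication: draw ``n_subjects`` thresholds, simulate the
    protocol, estimate individual thresholds, and record the Pearson
    correlation with truth.  Each replication consumes an independent
    substream spawned from ``seed``, so results are reproducible and
    independent of execution order.
    """
    if n_subjects < 10:
        raise ValueError("n_subjects must be >= 10")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    for rep, ss in enumerate(_as_seedseq(seed).spawn(n_reps)):
        rng = np.random.default_rng(ss)
        try:
            est, truths, ok = _one_replication(pop, protocol, n_subjects,
                                               estimator, n_quadrature, rng)
            r, r2 = reliability(est, truths) if ok else (np.nan, np.nan)
        except ValueError:
            ok, r, r2 = False, np.nan, np.nan
        rows.append({"rep": rep, "correlation": r, "reliability": r2,
                     "converged": bool(ok)})
    return ReplicationSummary(pd.DataFrame(rows), n_subjects=n_subjects, label=label)


def method_correlation(pop: PopulationModel, n_subjects: int, n_reps: int, seed,
                       cs_protocol: ConstantStimuliProtocol | None = None,
                       sc_protocol: StaircaseProtocol | None = None,
                       n_quadrature: int = 21) -> ReplicationSummary:
    """Correlation between staircase and constant-stimuli estimates.

    Per replication the two protocols are administered to the *same*
    ability draws with independent response noise; the recorded
    correlation is between the staircase scores (last-4-reversal mean)
    and the constant-stimuli empirical-Bayes thresholds.
    """
    if cs_protocol is None:
        cs_protocol = ConstantStimuliProtocol(tuple(range(1, 17)))
    if sc_protocol is None:
        sc_protocol = StaircaseProtocol()
    rows = []
    for rep, ss in enumerate(_as_seedseq(seed).spawn(n_reps)):
        rng = np.random.default_rng(ss)
        truths = pop.sample_thresholds(n_subjects, rng)
        runs = simulate_staircase(truths, pop.beta, sc_protocol, rng)
        sc_est = staircase_scores(runs)
        table = simulate_constant_stimuli(truths, pop.beta, cs_protocol, rng)
        try:
            cs_est, ok = _estimate_constant_stimuli(table, n_quadrature)
            r, r2 = reliability(sc_est, cs_est) if ok else (np.nan, np.nan)
        except ValueError:
            ok, r, r2 = False, np.nan, np.nan
        rows.append({"rep": rep, "correlation": r, "reliability": r2,
                     "converged": bool(ok)})
    return ReplicationSummary(pd.DataFrame(rows), n_subjects=n_subjects,
                              label="staircase vs constant stimuli")


def agreement_summary(estimates_a, estimates_b,
                      band: tuple = (0.25, 0.75)) -> AgreementSummary:
    """Mean and SD of (a - b), overall and within a quantile band of b."""
    a = np.asarray(estimates_a, dtype=float)
    b = np.asarray(estimates_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    lo, hi = np.quantile(b, band)
    mask = (b >= lo) & (b <= hi)
    return AgreementSummary(
        mean_difference=float(d.mean()),
        sd_difference=float(d.std(ddof=1)) if d.size > 1 else 0.0,
        band=tuple(band),
        band_mean_difference=float(d[mask].mean()) if mask.any() else float("nan"),
        band_sd_difference=(float(d[mask].std(ddof=1))
                            if mask.sum() > 1 else 0.0),
        n=int(d.size),
        n_in_band=int(mask.sum()),
    )


def protocol_table(pop: PopulationModel, designs, n_subjects: int, n_reps: int,
                   seed, n_quadrature: int = 21) -> pd.DataFrame:
    """Reliability comparison table over candidate designs.

    ``designs`` maps a label to a protocol object (constant-stimuli or
    staircase); staircase rows use the last-4-reversal score.  One
    summary row per design, with independent seed substreams per design.
    """
    if not designs:
        raise ValueError("need at least one design")
    items = list(designs.items()) if isinstance(designs, dict) else list(designs)
    rows = []
    for ss, (label, protocol) in zip(
            _as_seedseq(seed).spawn(len(items)), items):
        estimator = ("staircase_score" if isinstance(protocol, StaircaseProtocol)
                     else "irt_eb")
        summ = run_replications(pop, protocol, n_subjects, n_reps,
                                ss, estimator=estimator,
                                n_quadrature=n_quadrature, label=label)
        rows.append(summ.to_row())
    return pd.DataFrame(rows)
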