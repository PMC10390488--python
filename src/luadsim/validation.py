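"""Trial-level validation statistics.

The validation protocol compares simulated time-to-progression (TTP)
against an observed arm in five steps: (1) generate a virtual population
ten times the real arm's event count, (2) check baseline agreement,
(3) estimate Kaplan-Meier curves, (4) build a bootstrapped 95% pointwise
prediction interval from 1000 subsamples of real-arm size, and (5) score
two metrics -- raw coverage (percentage of the observed curve's step
points inside the interval, pass at >= 80%) and the bootstrapped log-rank
test (7000 tests of real vs virtual subsample, pass when >= 80% are
non-significant at alpha = 0.05).

Observed TTP is recovered from published PFS and OS event lists by
removing, for each death, at most one coincident PFS event (patients who
died before progression contribute the same time to both lists).

The Kaplan-Meier and log-rank routines are lightweight numpy
implementations (the bootstrap loops run them tens of thousands of times);
they are cross-checked against an established survival-analysis library in
the test-suite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class EventTable:
    """Right-censored time-to-event records (times in months)."""

    times: np.ndarray
    events: np.ndarray
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=int)
        if t.size != e.size:
            raise ValueError("times and events must have equal length")
        if t.size == 0:
            raise ValueError("empty event table")
        if np.any(t <= 0):
            raise ValueError("event times must be > 0")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("event flags must be 0 or 1")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)

    def __len__(self) -> int:
        return self.times.size

    @classmethod
    def from_frame(cls, df: pd.DataFrame, time_col: str = "time_months",
                   event_col: str = "event", id_col: str | None = "id") -> "EventTable":
        ids = df[id_col].to_numpy() if id_col and id_col in df.columns else None
        return cls(df[time_col].to_numpy(float), df[event_col].to_numpy(int), ids)

    @classmethod
    def from_csv(cls, path, **kw) -> "EventTable":
        return cls.from_frame(pd.read_csv(path), **kw)

    def to_frame(self) -> pd.DataFrame:
        data = {"time_months": self.times, "event": self.events}
        if self.ids is not None:
            data = {"id": self.ids, **data}
        return pd.DataFrame(data)

    def subsample(self, n: int, rng: np.random.Generator,
                  replace: bool = False) -> "EventTable":
        if n > len(self) and not replace:
            raise ValueError("subsample larger than table without replacement")
        idx = rng.choice(len(self), size=n, replace=replace)
        return EventTable(self.times[idx], self.events[idx])


@dataclass(frozen=True)
class SurvivalCurve:
    """Right-continuous step-function survival estimate.

    ``times`` are the step (event) times, ``surv`` the survival probability
    just after each step, ``n_risk`` the number at risk just before it.
    S(0) = 1 by construction.
    """

    times: np.ndarray
    surv: np.ndarray
    n_risk: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        s = np.asarray(self.surv, float)
        if np.any(np.diff(t) < 0):
            raise ValueError("step times must be non-decreasing")
        if np.any((s < -1e-12) | (s > 1.0 + 1e-12)) or np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be non-increasing within [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "surv", s)

    def evaluate(self, t) -> np.ndarray:
        """S(t) for arbitrary times (right-continuous; 1 before first step)."""
        idx = np.searchsorted(self.times, np.asarray(t, float), side="right")
        padded = np.concatenate([[1.0], self.surv])
        return padded[idx]

    def to_frame(self) -> pd.DataFrame:
        data = {"time_months": self.times, "survival": self.surv}
        if self.n_risk is not None:
            data["n_risk"] = self.n_risk
        return pd.DataFrame(data)


def _km_arrays(times: np.ndarray, events: np.ndarray):
    """Distinct event times with deaths, at-risk counts and survival values."""
    order = np.argsort(times, kind="mergesort")
    t = times[order]
    e = events[order]
    uniq, start = np.unique(t, return_index=True)
    deaths = np.add.reduceat(e.astype(float), start) if uniq.size else np.array([])
    n_at_risk = t.size - start
    mask = deaths > 0
    event_times = uniq[mask]
    deaths = deaths[mask]
    n_risk = n_at_risk[mask].astype(float)
    surv = np.cumprod(1.0 - deaths / n_risk) if event_times.size else np.array([])
    return event_times, deaths, n_risk, surv


def km_estimate(events: EventTable) -> SurvivalCurve:
    """Product-limit (Kaplan-Meier) survival estimate.

    Censored times reduce the risk set without producing steps.
    """
    et, _, n_risk, surv = _km_arrays(events.times, events.events)
    return SurvivalCurve(times=et, surv=surv,
                         n_risk=n_risk if et.size else None)


def infer_ttp(pfs_event_times: Sequence[float], os_event_times: Sequence[float],
              tol: float = 0.0) -> np.ndarray:
    """Progression times recovered from PFS and OS event lists.

    Patients who died before progressing contribute the same time to both
    lists; each OS (death) event therefore removes at most one PFS event
    lying within ``tol`` months of it. The remaining PFS events are the
    progression events.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    pfs = sorted(float(x) for x in pfs_event_times)
    removed = np.zeros(len(pfs), dtype=bool)
    n_matched = 0
    for death in sorted(float(x) for x in os_event_times):
        best, best_gap = None, tol
        for i, t in enumerate(pfs):
            if removed[i]:
                continue
            gap = abs(t - death)
            if gap <= best_gap + 1e-12 and (best is None or gap < best_gap):
                best, best_gap = i, gap
        if best is not None:
            removed[best] = True
            n_matched += 1
    if n_matched > len(pfs):  # unreachable by construction; defensive
        raise ValueError("matched more deaths than PFS events")
    return np.array([t for i, t in enumerate(pfs) if not removed[i]])


@dataclass(frozen=True)
class PredictionBand:
    """Pointwise survival band on a common grid (step interpolation)."""

    grid: np.ndarray
    lo: np.ndarray
    hi: np.ndarray

    def evaluate(self, t):
        """Band limits at arbitrary times (previous-point interpolation)."""
        idx = np.searchsorted(self.grid, np.asarray(t, float), side="right") - 1
        idx = np.clip(idx, 0, self.grid.size - 1)
        return self.lo[idx], self.hi[idx]


def _km_eval_on_grid(times: np.ndarray, events: np.ndarray,
                     grid: np.ndarray) -> np.ndarray:
    et, _, _, surv = _km_arrays(times, events)
    idx = np.searchsorted(et, grid, side="right")
    padded = np.concatenate([[1.0], surv])
    return padded[idx]


def bootstrap_pi(vpop_outcomes: EventTable, n_real: int, B: int = 1000,
                 level: float = 0.95, seed=None, grid: np.ndarray | None = None,
                 replace: bool = False) -> PredictionBand:
    """Bootstrapped pointwise prediction interval of the simulated KM curve.

    Draws ``B`` subsamples of size ``n_real`` from the virtual outcomes
    (without replacement by default), estimates each subsample's KM curve
    on a common grid, and takes pointwise ``(1-level)/2`` and
    ``1-(1-level)/2`` percentiles.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if n_real > len(vpop_outcomes) and not replace:
        raise ValueError("n_real exceeds virtual population size")
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = np.unique(np.concatenate([[0.0], vpop_outcomes.times]))
    curves = np.empty((B, grid.size))
    for b in range(B):
        idx = rng.choice(len(vpop_outcomes), size=n_real, replace=replace)
        curves[b] = _km_eval_on_grid(vpop_outcomes.times[idx],
                                     vpop_outcomes.events[idx], grid)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(curves, [alpha, 1.0 - alpha], axis=0)
    return PredictionBand(grid=grid, lo=lo, hi=hi)


def raw_coverage(observed: SurvivalCurve, band: PredictionBand,
                 tol: float = 1e-9) -> float:
    """Percentage of the observed curve's step points inside the band.

    The observed step function is evaluated at each of its own step times;
    a point counts as covered when it lies within ``[lo, hi]`` there.
    """
    t = observed.times
    if t.size == 0:
        raise ValueError("observed curve has no step points")
    # the band extends rightward by step interpolation; only a curve that
    # ends before the band starts has no overlap at all
    if t.max() < band.grid.min():
        raise ValueError("observed curve and band have disjoint time ranges")
    s = observed.surv
    lo, hi = band.evaluate(t)
    inside = (s >= lo - tol) & (s <= hi + tol)
    return float(100.0 * inside.mean())


def time_weighted_coverage(observed: SurvivalCurve, band: PredictionBand) -> float:
    """Coverage weighted by the time each observed step value persists."""
    t = observed.times
    if t.size == 0:
        raise ValueError("observed curve has no step points")
    widths = np.diff(np.concatenate([t, [max(t[-1], band.grid.max())]]))
    if widths.sum() <= 0:
        return raw_coverage(observed, band)
    lo, hi = band.evaluate(t)
    inside = ((observed.surv >= lo - 1e-9) & (observed.surv <= hi + 1e-9))
    return float(100.0 * np.average(inside, weights=np.maximum(widths, 0.0)))


def logrank(group_a: EventTable, group_b: EventTable) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic with 1 df, p-value)."""
    ta, ea = group_a.times, group_a.events
    tb, eb = group_b.times, group_b.events
    if ea.sum() + eb.sum() == 0:
        warnings.warn("no events in either group; p = 1")
        return 0.0, 1.0
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    ta_s = np.sort(ta)
    tb_s = np.sort(tb)
    ta_ev = np.sort(ta[ea == 1])
    tb_ev = np.sort(tb[eb == 1])
    n1 = (ta.size - np.searchsorted(ta_s, event_times, side="left")).astype(float)
    n2 = (tb.size - np.searchsorted(tb_s, event_times, side="left")).astype(float)
    nj = n1 + n2
    d1 = (np.searchsorted(ta_ev, event_times, side="right")
          - np.searchsorted(ta_ev, event_times, side="left")).astype(float)
    d2 = (np.searchsorted(tb_ev, event_times, side="right")
          - np.searchsorted(tb_ev, event_times, side="left")).astype(float)
    dj = d1 + d2
    keep = nj > 0
    n1, n2, nj, d1, dj = n1[keep], n2[keep], nj[keep], d1[keep], dj[keep]
    expected = dj * n1 / nj
    with np.errstate(divide="ignore", invalid="ignore"):
        var = dj * (n1 / nj) * (n2 / nj) * (nj - dj) / np.maximum(nj - 1, 1)
    var[nj <= 1] = 0.0
    o_minus_e = float(np.sum(d1 - expected))
    v = float(np.sum(var))
    if v <= 0:
        warnings.warn("log-rank variance is zero; p = 1")
        return 0.0, 1.0
    chi2 = o_minus_e**2 / v
    return chi2, float(stats.chi2.sf(chi2, df=1))


def bootstrapped_logrank(vpop_outcomes: EventTable, real: EventTable,
                         n_tests: int = 7000, seed=None, alpha: float = 0.05,
                         replace: bool = False) -> float:
    """Percentage of log-rank tests (real vs virtual subsample) with p > alpha.

    Each of the ``n_tests`` tests draws a subsample of the real arm's size
    from the virtual outcomes and compares it to the real arm.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if len(real) > len(vpop_outcomes) and not replace:
        raise ValueError("real arm larger than virtual population")
    rng = np.random.default_rng(seed)
    negative = 0
    for _ in range(n_tests):
        sub = vpop_outcomes.subsample(len(real), rng, replace=replace)
        _, p = logrank(sub, real)
        if p > alpha:
            negative += 1
    return 100.0 * negative / n_tests


@dataclass(frozen=True)
class ValidationConfig:
    n_bootstrap_pi: int = 1000
    n_lr_tests: int = 7000
    pi_level: float = 0.95
    coverage_threshold_pct: float = 80.0
    lr_threshold_pct: float = 80.0
    alpha: float = 0.05
    replace: bool = False


@dataclass(frozen=True)
class ValidationReport:
    raw_coverage_pct: float
    lr_negative_pct: float
    coverage_threshold_pct: float
    lr_threshold_pct: float
    n_bootstrap_pi: int
    n_lr_tests: int
    seed: int | None
    passed_coverage: bool = field(init=False)
    passed_lr: bool = field(init=False)
    passed: bool = field(init=False)

    def __post_init__(self) -> None:
        for v in (self.raw_coverage_pct, self.lr_negative_pct):
            if not 0.0 <= v <= 100.0:
                raise ValueError("percentages must lie in [0, 100]")
        object.__setattr__(self, "passed_coverage",
                           self.raw_coverage_pct >= self.coverage_threshold_pct)
        object.__setattr__(self, "passed_lr",
                           self.lr_negative_pct >= self.lr_threshold_pct)
        object.__setattr__(self, "passed", self.passed_coverage and self.passed_lr)

    def to_json(self, indent: int = 2) -> str:
        d = {k: getattr(self, k) for k in (
            "raw_coverage_pct", "lr_negative_pct", "coverage_threshold_pct",
            "lr_threshold_pct", "n_bootstrap_pi", "n_lr_tests", "seed",
            "passed_coverage", "passed_lr", "passed")}
        return json.dumps(d, indent=indent)


def validate(vpop_outcomes: EventTable,
             observed: EventTable | SurvivalCurve,
             config: ValidationConfig | None = None,
             seed: int | None = None) -> ValidationReport:
    """Run the full validation protocol and apply the pass thresholds.

    ``observed`` may be an event table (its KM curve is estimated here) or
    an already-digitized survival curve.
    """
    config = config or ValidationConfig()
    if isinstance(observed, EventTable):
        observed_curve = km_estimate(observed)
        n_real = len(observed)
        real_events = observed
    else:
        observed_curve = observed
        # reconstruct an approximate event table from the digitized curve
        real_events = events_from_curve(observed)
        n_real = len(real_events)
    band = bootstrap_pi(vpop_outcomes, n_real, B=config.n_bootstrap_pi,
                        level=config.pi_level, seed=seed, replace=config.replace)
    cov = raw_coverage(observed_curve, band)
    lr_neg = bootstrapped_logrank(vpop_outcomes, real_events,
                                  n_tests=config.n_lr_tests,
                                  seed=None if seed is None else seed + 1,
                                  alpha=config.alpha, replace=config.replace)
    return ValidationReport(
        raw_coverage_pct=cov, lr_negative_pct=lr_neg,
        coverage_threshold_pct=config.coverage_threshold_pct,
        lr_threshold_pct=config.lr_threshold_pct,
        n_bootstrap_pi=config.n_bootstrap_pi, n_lr_tests=config.n_lr_tests,
        seed=seed)


def events_from_curve(curve: SurvivalCurve) -> EventTable:
    """Approximate individual event records from a digitized KM curve.

    Uses the at-risk counts (required) to recover the number of deaths and
    censorings in each step interval, inverting the product-limit formula.
    """
    if curve.n_risk is None:
        raise ValueError("digitized curve needs at-risk counts to recover events")
    times = []
    events = []
    prev_s = 1.0
    n_risk = np.asarray(curve.n_risk, float)
    for j, (t, s) in enumerate(zip(curve.times, curve.surv)):
        nj = n_risk[j]
        dj = int(round(nj * (1.0 - s / prev_s))) if prev_s > 0 else 0
        times.extend([t] * dj)
        events.extend([1] * dj)
        next_n = n_risk[j + 1] if j + 1 < n_risk.size else 0
        censored = int(round(nj - dj - next_n))
        if censored > 0:
            times.extend([t] * censored)
            events.extend([0] * censored)
        prev_s = s
    return EventTable(np.array(times), np.array(events))
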