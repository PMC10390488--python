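"""Virtual-population generation and baseline comparison statistics.

A virtual population is a cohort of parameter vectors ("descriptors")
sampled from marginal distributions with an optional Gaussian-copula rank
correlation structure. Categorical descriptors (sex, EGFR variant, smoking
status, ...) use the frequencies of the target trial arm; continuous
descriptors use parametric families whose spread, when only a median and a
range are published, is recovered by treating the range as a central
quantile interval.

Baseline agreement between a virtual and a real population is assessed
characteristic by characteristic with Fisher's exact test (2x2 directly,
r x c by exact enumeration with a chi-square fallback above a size limit)
and, for continuous descriptors, a two-sided two-sample t-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, ndtr

from .core import VirtualPatient


def estimate_sd_from_quantiles(q_lo: float, q_hi: float, coverage: float) -> float:
    """Standard deviation implied by a central quantile interval of a normal.

    ``sd = (q_hi - q_lo) / (2 * z)`` with ``z`` the standard-normal quantile
    at ``(1 + coverage)/2``; e.g. a printed range treated as a central 99%
    interval.
    """
    if q_hi <= q_lo:
        raise ValueError("q_hi must exceed q_lo")
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must lie in (0, 1)")
    z = stats.norm.ppf(0.5 * (1.0 + coverage))
    return (q_hi - q_lo) / (2.0 * z)


@dataclass(frozen=True)
class ContinuousSpec:
    """One continuous marginal: family, parameters and truncation bounds.

    Families: ``truncnorm`` (params: center, sd), ``lognormal`` (params:
    median, sigma of log), ``uniform`` (params: lo, hi). ``bounds`` clips
    the support (applied through the CDF, so sampling stays exact).
    """

    dist: str
    params: Mapping[str, float]
    bounds: tuple[float, float] | None = None

    def _frozen(self):
        p = self.params
        if self.dist == "truncnorm":
            return stats.norm(loc=p["center"], scale=p["sd"])
        if self.dist == "lognormal":
            return stats.lognorm(s=p["sigma"], scale=p["median"])
        if self.dist == "uniform":
            return stats.uniform(loc=p["lo"], scale=p["hi"] - p["lo"])
        raise ValueError(f"unknown distribution family {self.dist!r}")

    def ppf(self, u):
        """Quantile function with truncation folded in."""
        d = self._frozen()
        if self.bounds is None:
            return d.ppf(u)
        lo, hi = d.cdf(self.bounds[0]), d.cdf(self.bounds[1])
        return d.ppf(lo + np.asarray(u) * (hi - lo))


@dataclass(frozen=True)
class VPopSpec:
    """Descriptor distributions defining a virtual population.

    ``categoricals`` maps descriptor name to ``{category: probability}``
    (probabilities sum to 1); ``continuous`` maps name to
    :class:`ContinuousSpec`. ``rank_corr`` is an optional positive
    semi-definite rank-correlation matrix over ``corr_order`` (Gaussian
    copula); identity (independence) by default. ``size_multiplier`` is the
    virtual-to-real population size ratio used when sizing from an event
    count (default 10).
    """

    categoricals: Mapping[str, Mapping[str, float]]
    continuous: Mapping[str, ContinuousSpec]
    rank_corr: np.ndarray | None = None
    corr_order: tuple[str, ...] | None = None
    size_multiplier: float = 10.0

    def __post_init__(self) -> None:
        for name, probs in self.categoricals.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"probabilities for {name!r} sum to {total}, expected 1")
        if self.rank_corr is not None:
            r = np.asarray(self.rank_corr, float)
            if self.corr_order is None or r.shape != (len(self.corr_order),) * 2:
                raise ValueError("rank_corr requires a matching corr_order")
            if not np.allclose(r, r.T):
                raise ValueError("rank_corr must be symmetric")
            w = np.linalg.eigvalsh(r)
            if w.min() < -1e-10:
                raise ValueError("rank_corr must be positive semi-definite")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.categoricals) + tuple(self.continuous)

    def population_size(self, n_real_events: int) -> int:
        """Virtual population size: ``size_multiplier`` x real event count."""
        return int(round(self.size_multiplier * n_real_events))


def _uniforms(spec: VPopSpec, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """One U(0,1) column per descriptor, correlated through the copula."""
    names = list(spec.names)
    if spec.rank_corr is None:
        return {name: rng.random(n) for name in names}
    order = list(spec.corr_order)
    extra = [name for name in names if name not in order]
    r = np.asarray(spec.rank_corr, float)
    # Pearson correlation of the latent normals that induces the requested
    # Spearman correlation (Gaussian copula identity).
    rho = 2.0 * np.sin(np.pi * r / 6.0)
    w, v = np.linalg.eigh(rho)
    chol = v @ np.diag(np.sqrt(np.maximum(w, 0.0)))
    z = rng.standard_normal((n, len(order))) @ chol.T
    u = {name: ndtr(z[:, j]) for j, name in enumerate(order)}
    for name in extra:
        u[name] = rng.random(n)
    return u


def _categorical_from_u(u: np.ndarray, probs: Mapping[str, float]) -> np.ndarray:
    cats = list(probs)
    edges = np.cumsum([probs[c] for c in cats])
    idx = np.searchsorted(edges, u, side="right").clip(max=len(cats) - 1)
    return np.array(cats, dtype=object)[idx]


def sample_descriptors(spec: VPopSpec, n: int, seed=None) -> pd.DataFrame:
    """Sample a descriptor table (one row per virtual patient)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    u = _uniforms(spec, n, rng)
    data: dict[str, np.ndarray] = {}
    for name, probs in spec.categoricals.items():
        data[name] = _categorical_from_u(u[name], probs)
    for name, cspec in spec.continuous.items():
        data[name] = np.asarray(cspec.ppf(u[name]), float)
    return pd.DataFrame(data, index=pd.RangeIndex(n))


def patients_from_frame(df: pd.DataFrame, id_prefix: str = "vp") -> list[VirtualPatient]:
    """Turn a descriptor table into :class:`VirtualPatient` objects.

    Mechanistic columns (``r0_cm``, ``prolif_frac``, ``f_res``,
    ``m_prolif``, ``rho_imm``, ``kappa_imm``, ``alpha_ang``) become patient
    fields or growth-parameter overrides; missing columns fall back to the
    patient defaults.
    """
    override_fields = ("rho_imm", "kappa_imm", "alpha_ang")
    patients = []
    for i, row in enumerate(df.itertuples(index=False)):
        d = row._asdict()
        kw = dict(id=f"{id_prefix}-{i}")
        for name in ("sex", "age", "smoking", "ethnicity", "stage",
                     "egfr_variant", "r0_cm", "prolif_frac", "f_res", "m_prolif",
                     "pace"):
            if name in d:
                kw[name] = d[name]
        for name in ("kras", "pik3ca"):
            if name in d:
                kw[name] = d[name] in (True, "True", "carrier", 1)
        overrides = {f: float(d[f]) for f in override_fields if f in d}
        if overrides:
            kw["growth_overrides"] = overrides
        patients.append(VirtualPatient(**kw))
    return patients


def sample_population(spec: VPopSpec, n: int, seed=None) -> list[VirtualPatient]:
    """Sample ``n`` virtual patients (reproducible under a fixed seed)."""
    return patients_from_frame(sample_descriptors(spec, n, seed))


# ---------------------------------------------------------------------------
# baseline comparison statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaselineTable:
    """Observed baseline of a real trial arm.

    ``categorical`` maps characteristic -> {category: count};
    ``continuous`` maps characteristic -> summary dict with keys ``n``,
    ``median``, ``range`` (lo, hi) and ``coverage`` (the central-quantile
    coverage the range is taken to represent).
    """

    categorical: Mapping[str, Mapping[str, int]] = field(default_factory=dict)
    continuous: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, counts in self.categorical.items():
            if any(v < 0 for v in counts.values()):
                raise ValueError(f"negative count in {name!r}")


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value of the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities over all tables with the observed
    margins whose probability does not exceed the observed one (to a 1e-7
    relative tolerance). Degenerate margins give p = 1 with a notice.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be non-negative integers")
    if (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0):
        warnings.warn("degenerate margin in 2x2 table; p = 1")
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def _log_table_prob(table: np.ndarray, row_margins, col_margins, n: int) -> float:
    return (sum(gammaln(r + 1) for r in row_margins)
            + sum(gammaln(c + 1) for c in col_margins)
            - gammaln(n + 1) - gammaln(table + 1.0).sum())


def fisher_exact_rxc(table, max_tables: int = 2_000_000) -> float:
    """Two-sided Fisher exact p for an r x c table by full enumeration.

    Enumerates every table with the observed margins, summing the
    probabilities of those no more probable than the observed table
    (1e-7 relative tolerance). Above ``max_tables`` candidate tables, falls
    back to the large-sample chi-square test with a logged notice.
    """
    t = np.asarray(table, dtype=int)
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    rows, cols = t.shape
    if rows == 2 and cols == 2:
        return fisher_exact_2x2(*t.ravel())
    row_m = t.sum(axis=1)
    col_m = t.sum(axis=0)
    n = int(t.sum())
    if n == 0:
        warnings.warn("all-zero table; p = 1")
        return 1.0
    bound = float(np.prod([min(r, c) + 1 for r in row_m[:-1] for c in col_m[:-1]]))
    if bound > max_tables:
        warnings.warn("table too large for exact enumeration; using chi-square")
        return float(stats.chi2_contingency(t)[1])

    log_p_obs = _log_table_prob(t, row_m, col_m, n)
    total = 0.0

    cells = np.zeros((rows, cols), dtype=int)

    def recurse(i: int, j: int, row_left, col_left) -> None:
        nonlocal total
        if i == rows - 1:
            # last row fully determined by column margins
            last = np.asarray(col_left)
            if np.any(last < 0):
                return
            cells[rows - 1, :] = last
            lp = _log_table_prob(cells, row_m, col_m, n)
            if lp <= log_p_obs + math.log1p(1e-7):
                total += math.exp(lp)
            return
        if j == cols - 1:
            v = row_left
            if v < 0 or v > col_left[j]:
                return
            cells[i, j] = v
            new_col = list(col_left)
            new_col[j] -= v
            recurse(i + 1, 0, row_m[i + 1], new_col)
            return
        for v in range(min(row_left, col_left[j]) + 1):
            cells[i, j] = v
            new_col = list(col_left)
            new_col[j] -= v
            recurse(i, j + 1, row_left - v, new_col)

    recurse(0, 0, int(row_m[0]), list(col_m))
    return float(min(total, 1.0))


def compare_baselines(vpop: pd.DataFrame, real: BaselineTable) -> pd.DataFrame:
    """Per-characteristic comparison of a virtual population to a real arm.

    Categorical characteristics are tested with Fisher's exact test on the
    (real counts) x (virtual counts) contingency table; continuous ones
    with a two-sided two-sample t-test, reconstructing the real arm's mean
    and SD from its published median and range. Returns a frame with
    columns (characteristic, test, p_value).
    """
    rows = []
    for name, counts in real.categorical.items():
        if name not in vpop.columns:
            raise ValueError(f"characteristic {name!r} missing from virtual population")
        cats = [c for c in counts if counts[c] > 0 or (vpop[name] == c).any()]
        dropped = set(counts) - set(cats)
        if dropped:
            warnings.warn(f"empty categories {sorted(dropped)} collapsed for {name!r}")
        if len(cats) < 2:
            rows.append((name, "fisher", 1.0))
            continue
        real_counts = [int(counts[c]) for c in cats]
        v_counts = [int((vpop[name] == c).sum()) for c in cats]
        table = np.array([real_counts, v_counts]).T  # categories x (real, virtual)
        p = fisher_exact_rxc(table)
        rows.append((name, "fisher", p))
    for name, summ in real.continuous.items():
        if name not in vpop.columns:
            raise ValueError(f"characteristic {name!r} missing from virtual population")
        lo, hi = summ["range"]
        sd = estimate_sd_from_quantiles(lo, hi, summ.get("coverage", 0.99))
        res = stats.ttest_ind_from_stats(
            mean1=summ["median"], std1=sd, nobs1=summ["n"],
            mean2=float(vpop[name].mean()), std2=float(vpop[name].std(ddof=1)),
            nobs2=len(vpop), equal_var=False)
        rows.append((name, "t-test", float(res.pvalue)))
    return pd.DataFrame(rows, columns=["characteristic", "test", "p_value"])
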