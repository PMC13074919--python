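"""Abundance-based rarefaction/extrapolation and bootstrap pairwise richness tests.

Species richness (the Hill number of order q = 0) is standardized across fossil
assemblages by rarefying every assemblage to a common number of individuals
``m0`` before comparison.  Rarefied richness is the hypergeometric expectation

    S(m) = S_obs - sum_i C(N - N_i, m) / C(N, m)

where ``N_i`` are the taxon counts, ``N`` their total, and ``C`` the binomial
coefficient (evaluated in log space so tables with N ~ 1e4 do not overflow).
Extrapolation beyond N uses the Chao-type unseen-species estimate.  Pairwise
inference resamples each assemblage multinomially (total N fixed), recomputes
S*(m0) per replicate, and reports the bootstrap percentile interval and a
two-sided bootstrap p-value for the difference Delta = S_A(m0) - S_B(m0),
with a Bonferroni adjustment over the family of pairwise tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "AbundanceTable",
    "PairwiseComparison",
    "rarefy",
    "unseen_species",
    "extrapolate",
    "rarefaction_curve",
    "exclusion_rule",
    "bootstrap_richness",
    "pairwise_test",
    "bonferroni",
    "compare_all",
    "read_abundance_csv",
    "comparisons_to_frame",
]


@dataclass(frozen=True)
class AbundanceTable:
    """Taxon abundance counts for one assemblage.

    Zero-count taxa are dropped at construction; ``S_obs``, ``f1`` and ``f2``
    therefore refer to taxa actually observed in this assemblage.
    """

    name: str
    counts: np.ndarray
    taxa: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be non-negative integers")
        counts = counts.astype(np.int64)
        taxa = self.taxa if self.taxa else tuple(f"taxon{i + 1}" for i in range(counts.size))
        if len(taxa) != counts.size:
            raise ValueError("taxa and counts length mismatch")
        keep = counts > 0
        object.__setattr__(self, "counts", counts[keep])
        object.__setattr__(self, "taxa", tuple(t for t, k in zip(taxa, keep) if k))
        if self.counts.size == 0:
            raise ValueError(f"assemblage {self.name!r} has no individuals")

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def S_obs(self) -> int:
        return int(self.counts.size)

    @property
    def f1(self) -> int:
        return int(np.sum(self.counts == 1))

    @property
    def f2(self) -> int:
        return int(np.sum(self.counts == 2))


def _ln_choose(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def _rarefy_counts(counts: np.ndarray, m: int) -> float:
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    n = counts.sum()
    s_obs = counts.size
    if m == n:
        return float(s_obs)
    # P(taxon i absent from subsample of m) = C(N - N_i, m) / C(N, m)
    rest = n - counts
    ok = rest >= m
    if not np.any(ok):
        return float(s_obs)
    log_p_absent = _ln_choose(rest[ok].astype(float), float(m)) - _ln_choose(
        float(n), float(m)
    )
    return float(s_obs - np.exp(log_p_absent).sum())


def rarefy(table: AbundanceTable, m: int) -> float:
    """Expected richness in a random subsample of ``m`` individuals (1 <= m <= N)."""
    m = int(m)
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > table.N:
        raise ValueError(
            f"m = {m} exceeds N = {table.N}; use extrapolate() beyond the sample"
        )
    return _rarefy_counts(table.counts, m)


def unseen_species(table: AbundanceTable) -> float:
    """Chao-type estimate of the number of unseen taxa, f0_hat.

    f0_hat = ((N-1)/N) * f1^2 / (2 f2) when doubletons exist, otherwise the
    bias-corrected form ((N-1)/N) * f1 (f1 - 1) / 2.
    """
    n, f1, f2 = table.N, table.f1, table.f2
    if n < 2:
        raise ValueError("need at least 2 individuals")
    if f1 == 0:
        return 0.0
    if f2 > 0:
        return (n - 1) / n * f1 * f1 / (2.0 * f2)
    return (n - 1) / n * f1 * (f1 - 1) / 2.0


def extrapolate(table: AbundanceTable, m_star: int) -> float:
    """Expected richness at N + m_star individuals (m_star >= 0).

    Flat at S_obs when there are no singletons; approaches S_obs + f0_hat as
    m_star grows.
    """
    m_star = int(m_star)
    if m_star < 0:
        raise ValueError("m_star must be >= 0")
    if m_star == 0:
        return float(table.S_obs)
    f1 = table.f1
    if f1 == 0:
        return float(table.S_obs)
    f0 = unseen_species(table)
    n = table.N
    ratio = f1 / (n * f0 + f1)
    return float(table.S_obs + f0 * (1.0 - (1.0 - ratio) ** m_star))


def richness_at(table: AbundanceTable, m: int) -> float:
    """S(m) by interpolation for m <= N and extrapolation beyond."""
    if m <= table.N:
        return rarefy(table, m)
    return extrapolate(table, m - table.N)


def rarefaction_curve(
    table: AbundanceTable,
    m_values: np.ndarray | None = None,
    B: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Rarefaction/extrapolation curve with 95% bootstrap bands.

    Returns a frame with columns m, S, lower, upper, extrapolated.  The bands
    come from ``B`` multinomial resamples of the assemblage (total N fixed).
    """
    n = table.N
    if m_values is None:
        m_values = np.unique(
            np.clip(np.round(np.linspace(1, 2 * n, 41)), 1, None).astype(int)
        )
    m_values = np.asarray(m_values, dtype=int)
    point = np.array([richness_at(table, m) for m in m_values])
    rng = np.random.default_rng(seed)
    p = table.counts / n
    boot = np.empty((B, m_values.size))
    for b in range(B):
        resampled = rng.multinomial(n, p)
        t = AbundanceTable(table.name, resampled[resampled > 0])
        boot[b] = [richness_at(t, m) for m in m_values]
    lower, upper = np.percentile(boot, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "m": m_values,
            "S": point,
            "lower": np.minimum(lower, point),
            "upper": np.maximum(upper, point),
            "extrapolated": m_values > n,
        }
    )


def exclusion_rule(totals: dict[str, int]) -> tuple[list[str], int]:
    """Drop under-sampled assemblages and fix the common sample size m0.

    An assemblage is excluded when N < max(1000, 0.5 * N_2nd_smallest), where
    the second-smallest N is taken over *all* input assemblages.  m0 is the
    minimum N among those retained, so no comparison requires extrapolation.
    """
    if len(totals) < 2:
        raise ValueError("need at least 2 assemblages")
    ns = sorted(totals.values())
    threshold = max(1000.0, 0.5 * ns[1])
    retained = [name for name, n in totals.items() if n >= threshold]
    if len(retained) < 2:
        raise ValueError(
            f"fewer than 2 assemblages at or above threshold {threshold:g}"
        )
    m0 = min(totals[name] for name in retained)
    return retained, int(m0)


def bootstrap_richness(
    table: AbundanceTable,
    m0: int,
    B: int = 200,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """B bootstrap values of S*(m0) via multinomial resampling with N fixed."""
    if m0 > table.N:
        raise ValueError(f"m0 = {m0} exceeds N = {table.N}")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = table.counts / table.N
    draws = rng.multinomial(table.N, p, size=B)
    return np.array([_rarefy_counts(row, m0) for row in draws])


def bonferroni(p: float, K: int) -> float:
    """Bonferroni-adjusted p-value, min(1, K * p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if K < 1:
        raise ValueError("K must be >= 1")
    return min(1.0, K * p)


@dataclass(frozen=True)
class PairwiseComparison:
    """Bootstrap comparison of rarefied richness for one assemblage pair."""

    pair: tuple[str, str]
    m0: int
    delta: float
    ci95: tuple[float, float]
    p: float
    p_bonf: float
    K: int
    B: int
    censored: bool  # True when no bootstrap Delta* crossed zero

    @property
    def p_label(self) -> str:
        return f"<{1.0 / self.B:g}" if self.censored else f"{self.p:g}"

    @property
    def p_bonf_label(self) -> str:
        if self.censored:
            return f"<{min(1.0, self.K / self.B):g}"
        return f"{self.p_bonf:g}"


def pairwise_test(
    a: AbundanceTable,
    b: AbundanceTable,
    m0: int,
    B_reps: int = 200,
    seed: int | None = None,
    K: int = 1,
) -> PairwiseComparison:
    """Two-sided bootstrap test of Delta = S_A(m0) - S_B(m0).

    p = 2 * min(#{Delta* <= 0}, #{Delta* >= 0}) / B, clipped to [0, 1]; when
    no replicate crosses zero the p-value is censored below 1/B (reported via
    ``p_label``).  The CI is the simple percentile interval of Delta*.
    """
    if m0 > min(a.N, b.N):
        raise ValueError("m0 exceeds the total abundance of one assemblage")
    delta = rarefy(a, m0) - rarefy(b, m0)
    rng = np.random.default_rng(seed)
    sa = bootstrap_richness(a, m0, B_reps, rng)
    sb = bootstrap_richness(b, m0, B_reps, rng)
    dstar = sa - sb
    lo, hi = np.percentile(dstar, [2.5, 97.5])
    n_le = int(np.sum(dstar <= 0))
    n_ge = int(np.sum(dstar >= 0))
    m = min(n_le, n_ge)
    censored = m == 0
    p = min(1.0, 2.0 * m / B_reps) if not censored else 1.0 / B_reps
    return PairwiseComparison(
        pair=(a.name, b.name),
        m0=int(m0),
        delta=float(delta),
        ci95=(float(lo), float(hi)),
        p=float(p),
        p_bonf=bonferroni(p, K),
        K=K,
        B=B_reps,
        censored=censored,
    )


def compare_all(
    tables: list[AbundanceTable],
    B_reps: int = 200,
    seed: int | None = None,
) -> list[PairwiseComparison]:
    """All pairwise bootstrap tests among assemblages retained by the exclusion rule.

    K for the Bonferroni adjustment equals the number of tests actually run,
    C(k, 2) for k retained assemblages.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 assemblages")
    totals = {t.name: t.N for t in tables}
    retained, m0 = exclusion_rule(totals)
    kept = [t for t in tables if t.name in retained]
    pairs = list(itertools.combinations(kept, 2))
    K = len(pairs)
    seeds = np.random.SeedSequence(seed).spawn(K)
    out = []
    for (ta, tb), ss in zip(pairs, seeds):
        child = int(ss.generate_state(1)[0] % (2**31))
        out.append(pairwise_test(ta, tb, m0, B_reps=B_reps, seed=child, K=K))
    return out


def read_abundance_csv(path) -> list[AbundanceTable]:
    """Read a taxa x assemblages CSV count matrix (first column = taxon names)."""
    df = pd.read_csv(path, index_col=0)
    tables = []
    for col in df.columns:
        counts = df[col].to_numpy()
        if np.any(pd.isna(counts)):
            raise ValueError(f"missing counts in column {col!r}")
        tables.append(AbundanceTable(str(col), counts, tuple(map(str, df.index))))
    return tables


def comparisons_to_frame(comps: list[PairwiseComparison]) -> pd.DataFrame:
    """Tabulate pairwise comparisons (pair, m0, Delta, CI bounds, p, p_Bonf)."""
    return pd.DataFrame(
        {
            "pair": [f"{c.pair[0]} vs. {c.pair[1]}" for c in comps],
            "m0": [c.m0 for c in comps],
            "delta": [round(c.delta, 1) for c in comps],
            "ci_low": [round(c.ci95[0], 1) for c in comps],
            "ci_high": [round(c.ci95[1], 1) for c in comps],
            "p": [c.p_label for c in comps],
            "p_bonf": [c.p_bonf_label for c in comps],
        }
    )
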