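"""The four statistical test families for somatic-insertion analyses.

* exact two-sample Poisson rate comparison (conditional binomial),
  used pairwise between libraries and for one library against the
  pooled rest;
* Monte-Carlo genomic-distribution test: draw coordinate sets of the
  observed size uniformly over the genome and compare genic/promoter
  hit counts with the observation;
* an overdispersion (heterogeneity) test for grouped proportions;
* the exact binomial orientation test against a null of no strand
  preference.

Two-sided exact p-values use the minimum-likelihood convention: the
p-value sums the probabilities of all outcomes no more likely than the
observed one (with the customary 1 + 1e-7 relative tolerance on the
comparison).  Empirical Monte-Carlo p-values use the (1 + hits)/(R + 1)
estimator, which can never return zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

_REL_TOL = 1.0 + 1e-7


def binom_minlike_pvalue(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p-value, minimum-likelihood convention."""
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    if n == 0:
        return 1.0
    support = np.arange(n + 1)
    pmf = sps.binom.pmf(support, n, p0)
    mask = pmf <= pmf[k] * _REL_TOL
    if mask.all():
        return 1.0
    p = float(pmf[mask].sum())
    return min(max(p, np.nextafter(0, 1)), 1.0)


@dataclass
class RateTestResult:
    """Exact conditional Poisson comparison of two read rates.

    Conditional on the total T = x1 + x2 of somatic-representing reads,
    x1 ~ Binomial(T, n1/(n1+n2)) under equal underlying rates.
    """

    x1: int
    n1: int
    x2: int
    n2: int
    p_value: float
    label: str = ""

    def to_dict(self) -> dict:
        return {"test": "poisson_rate", **asdict(self)}


def poisson_rate_test(
    x1: int, n1: int, x2: int, n2: int, label: str = ""
) -> RateTestResult:
    """Exact two-sample Poisson rate test via the conditional binomial."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("totals n1 and n2 must be positive")
    if x1 < 0 or x2 < 0:
        raise ValueError("counts must be non-negative")
    total = x1 + x2
    if total == 0:
        return RateTestResult(x1, n1, x2, n2, 1.0, label)
    p0 = n1 / (n1 + n2)
    p = binom_minlike_pvalue(x1, total, p0)
    return RateTestResult(x1, n1, x2, n2, p, label)


def one_vs_pooled_test(
    counts: dict[str, tuple[int, int]], target: str
) -> RateTestResult:
    """One library's (x, n) against the element-wise sum of all others."""
    if target not in counts:
        raise KeyError(f"{target!r} not among libraries {sorted(counts)}")
    if len(counts) < 2:
        raise ValueError("need at least two libraries")
    x1, n1 = counts[target]
    x2 = sum(x for lib, (x, _n) in counts.items() if lib != target)
    n2 = sum(n for lib, (_x, n) in counts.items() if lib != target)
    return poisson_rate_test(x1, n1, x2, n2, label=f"{target}_vs_pooled")


@dataclass
class OrientationTestResult:
    co: int
    total: int
    null_proportion: float
    p_value: float
    label: str = ""

    def to_dict(self) -> dict:
        return {"test": "orientation_binomial", **asdict(self)}


def orientation_test(co: int, total: int, label: str = "") -> OrientationTestResult:
    """Exact binomial test of co-orientation against no preference (0.5)."""
    if total < 1:
        raise ValueError("total must be >= 1")
    if co > total:
        raise ValueError("co count cannot exceed total")
    p = binom_minlike_pvalue(co, total, 0.5)
    return OrientationTestResult(co, total, 0.5, p, label)


@dataclass
class OverdispersionResult:
    """Chi-square heterogeneity test for k grouped proportions.

    D = sum (x_i - n_i p̄)^2 / (n_i p̄ (1 - p̄)) with p̄ the pooled
    proportion, referred to chi-square with k - 1 degrees of freedom;
    the upper tail measures excess variability between groups.
    """

    x: tuple[int, ...]
    n: tuple[int, ...]
    pooled: float
    statistic: float
    df: int
    p_value: float
    label: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        d["x"] = list(self.x)
        d["n"] = list(self.n)
        return {"test": "overdispersion", **d}


def overdispersion_test(
    x: "list[int]", n: "list[int]", label: str = ""
) -> OverdispersionResult:
    x_arr = np.asarray(x, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if len(x_arr) != len(n_arr) or len(x_arr) < 2:
        raise ValueError("need k >= 2 groups with matching x and n")
    if (n_arr <= 0).any():
        raise ValueError("all group totals must be positive")
    if ((x_arr < 0) | (x_arr > n_arr)).any():
        raise ValueError("successes must satisfy 0 <= x_i <= n_i")
    k = len(x_arr)
    pooled = float(x_arr.sum() / n_arr.sum())
    if pooled in (0.0, 1.0):
        d_stat = 0.0
    else:
        d_stat = float(
            (((x_arr - n_arr * pooled) ** 2) / (n_arr * pooled * (1 - pooled))).sum()
        )
    p = float(sps.chi2.sf(d_stat, k - 1))
    return OverdispersionResult(
        tuple(int(v) for v in x_arr),
        tuple(int(v) for v in n_arr),
        pooled,
        d_stat,
        k - 1,
        min(max(p, np.nextafter(0, 1)), 1.0),
        label,
    )


@dataclass
class PermutationResult:
    """Monte-Carlo null distribution of compartment hit counts."""

    compartment: str
    observed: int
    n_insertions: int
    replicates: int
    sim_mean: float
    sim_sd: float
    p_enrichment: float
    p_depletion: float
    seed: int

    def to_dict(self) -> dict:
        return {"test": "monte_carlo_distribution", **asdict(self)}


def _membership(boundaries: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Point-in-union test against flattened merged-interval boundaries."""
    if boundaries.size == 0:
        return np.zeros(len(positions), dtype=bool)
    idx = np.searchsorted(boundaries, positions, side="right")
    return (idx % 2) == 1


def monte_carlo_distribution_test(
    n_insertions: int,
    genic_boundaries: dict[str, np.ndarray],
    promoter_boundaries: dict[str, np.ndarray],
    chrom_lengths: dict[str, int],
    observed_genic: int,
    observed_promoter: int,
    replicates: int = 1000,
    seed: int = 0,
) -> tuple[PermutationResult, PermutationResult]:
    """Compare observed genic/promoter hit counts against a uniform null.

    Each replicate draws ``n_insertions`` coordinates uniformly over the
    genome (chromosome proportional to length, offset uniform) and
    counts hits in the merged gene intervals and in the promoter-only
    space (promoter windows minus gene bodies, matching the genic-over-
    promoter precedence of the annotation).
    """
    if n_insertions < 1:
        raise ValueError("n_insertions must be >= 1")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if replicates < 100:
        warnings.warn(
            f"R={replicates} Monte-Carlo replicates give unstable p-values",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(offsets[-1])
    genic_global = _globalize(genic_boundaries, chroms, offsets)
    promoter_global = _globalize(promoter_boundaries, chroms, offsets)

    genic_counts = np.empty(replicates, dtype=np.int64)
    promoter_counts = np.empty(replicates, dtype=np.int64)
    for r in range(replicates):
        pos = rng.integers(0, total, size=n_insertions)
        in_gene = _membership(genic_global, pos)
        in_prom = _membership(promoter_global, pos) & ~in_gene
        genic_counts[r] = int(in_gene.sum())
        promoter_counts[r] = int(in_prom.sum())

    def summarize(counts: np.ndarray, observed: int, name: str) -> PermutationResult:
        enrich = (1 + int((counts >= observed).sum())) / (replicates + 1)
        deplete = (1 + int((counts <= observed).sum())) / (replicates + 1)
        return PermutationResult(
            name,
            observed,
            n_insertions,
            replicates,
            float(counts.mean()),
            float(counts.std(ddof=1)) if replicates > 1 else 0.0,
            enrich,
            deplete,
            seed,
        )

    return (
        summarize(genic_counts, observed_genic, "genic"),
        summarize(promoter_counts, observed_promoter, "promoter"),
    )


def _globalize(
    boundaries: dict[str, np.ndarray], chroms: list[str], offsets: np.ndarray
) -> np.ndarray:
    parts = []
    for i, c in enumerate(chroms):
        b = boundaries.get(c)
        if b is not None and b.size:
            parts.append(np.asarray(b, dtype=np.int64) + offsets[i])
    if not parts:
        return np.array([], dtype=np.int64)
    return np.concatenate(parts)
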