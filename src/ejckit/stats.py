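"""Statistics used across the analysis.

Exact one-sided hypergeometric enrichment (log-space, safe far below
double underflow of the naive sum), Welch's two-sample t test,
Benjamini-Hochberg step-up adjustment, and a self-contained stand-in for
gene-level differential binding. The stand-in is deliberately NOT a
negative-binomial GLM: it normalizes to counts-per-million, tests each
gene's pooled group-A count against the library-size-implied proportion
with an exact binomial test and BH-adjusts; raw count matrices remain
exportable for external NB-based tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln, logsumexp


@dataclass
class EnrichmentInput:
    k: int  # successes in sample
    n: int  # sample size
    K: int  # successes in population
    N: int  # population size

    def __post_init__(self):
        if not (0 <= self.k <= min(self.n, self.K) and self.n <= self.N and self.K <= self.N):
            raise ValueError(f"invalid hypergeometric input {self}")


def hypergeom_enrichment(inp: EnrichmentInput, log10: bool = False) -> float:
    """One-sided upper-tail P[X >= k], X ~ Hypergeom(N, K, n).

    The tail is summed in log space (gammaln + logsumexp), so p-values far
    below 1e-300 are returned accurately; set ``log10=True`` to get
    log10(p) directly when p itself would underflow.
    """
    k, n, K, N = inp.k, inp.n, inp.K, inp.N
    ks = np.arange(k, min(n, K) + 1)
    if len(ks) == 0:
        return 0.0 if not log10 else -np.inf
    log_pmf = (
        gammaln(K + 1) - gammaln(ks + 1) - gammaln(K - ks + 1)
        + gammaln(N - K + 1) - gammaln(n - ks + 1) - gammaln(N - K - (n - ks) + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    lp = min(0.0, float(logsumexp(log_pmf)))
    return lp / np.log(10) if log10 else float(np.exp(lp))


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t test -> (t, df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("Welch t test needs >= 2 observations per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        return 0.0, float(nx + ny - 2), 1.0
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(min(1.0, p))


def benjamini_hochberg(pvals) -> np.ndarray:
    """Step-up FDR adjustment; order-preserving, monotone, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def differential_binding_standin(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    adj_p_threshold: float = 0.05,
    strong_log2fc: float = 3.0,
) -> pd.DataFrame:
    """Per-gene log2FC (CPM means, pseudo-count 0.5), exact binomial p,
    BH-adjusted significance, and strong-binding flags.

    ``counts`` is genes x libraries; the binomial tests each gene's pooled
    group-A count against n = pooled A+B at the library-size-implied
    success proportion.
    """
    if not group_a or not group_b:
        raise ValueError("both groups need >= 1 library")
    A = counts[group_a]
    B = counts[group_b]
    lib_a = A.sum(axis=0)
    lib_b = B.sum(axis=0)
    cpm_a = (A * 1e6 / lib_a).mean(axis=1)
    cpm_b = (B * 1e6 / lib_b).mean(axis=1)
    log2fc = np.log2((cpm_a + 0.5) / (cpm_b + 0.5))

    tot_a = float(lib_a.sum())
    tot_b = float(lib_b.sum())
    p0 = tot_a / (tot_a + tot_b)
    xa = A.sum(axis=1).to_numpy()
    nt = xa + B.sum(axis=1).to_numpy()
    pvals = np.ones(len(counts))
    for i, (x, n) in enumerate(zip(xa, nt)):
        if n > 0:
            pvals[i] = sps.binomtest(int(x), int(n), p0).pvalue
    adj = benjamini_hochberg(pvals)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvals,
            "adj_pvalue": adj,
            "enriched": (adj < adj_p_threshold) & (log2fc > 0),
            "strongly_bound": log2fc > strong_log2fc,
        },
        index=counts.index,
    )
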