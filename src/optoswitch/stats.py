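"""Nonparametric statistics battery and cohort summaries.

Rank tests used throughout the pipeline (Mann-Whitney U, Wilcoxon signed
rank in paired and one-sample form, Kruskal-Wallis, Friedman, Dunn's post
hoc on mean ranks), per-cell activation factors, and the kinetics-vs-
amplitude correlation check.  Mid-ranks with variance tie correction are
used everywhere; the Mann-Whitney test switches to full enumeration of the
group assignments when the smaller group has at most ``EXACT_N`` members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

EXACT_N = 8  # per-group threshold for exact enumeration


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: tuple
    test: str
    exact: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0 + 1e-12:
            raise ValueError("p value outside (0, 1]")
        self.p_value = min(self.p_value, 1.0)


@dataclass
class CohortSummary:
    median: float
    q1: float
    q3: float
    sd: float
    n: int


def summarize(values: Sequence[float]) -> CohortSummary:
    """Boxplot-style summary: median, quartiles, SD (nan for n = 1), n."""
    x = np.asarray(values, float)
    if x.size == 0:
        raise ValueError("empty sample")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else float("nan")
    return CohortSummary(
        median=float(np.median(x)),
        q1=float(np.percentile(x, 25)),
        q3=float(np.percentile(x, 75)),
        sd=sd,
        n=int(x.size),
    )


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x (mid-rank convention for ties)."""
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r_x = ranks[: x.size].sum()
    return float(r_x - x.size * (x.size + 1) / 2.0)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], sided: str = "two-sided"
) -> TestResult:
    """Unpaired rank-sum test.

    Exact null distribution by enumeration of all C(n+m, n) group
    assignments (tie-safe) when min(n, m) <= 8; otherwise the normal
    approximation with tie correction.  Two-sided exact p is
    ``min(1, 2 * min(P(U <= u), P(U >= u)))``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    if min(x.size, y.size) <= EXACT_N:
        u_obs = _u_statistic(x, y)
        combined = np.concatenate([x, y])
        n = x.size
        # ranks are fixed by the pooled sample; each assignment's U is a
        # subset rank sum, so one ranking serves the whole enumeration
        ranks = sps.rankdata(combined)
        idx = np.fromiter(
            (i for ix in combinations(range(combined.size), n) for i in ix),
            dtype=np.intp,
        ).reshape(-1, n)
        us = ranks[idx].sum(axis=1) - n * (n + 1) / 2.0
        tol = 1e-9
        p_le = np.mean(us <= u_obs + tol)
        p_ge = np.mean(us >= u_obs - tol)
        if sided == "two-sided":
            p = min(1.0, 2.0 * min(p_le, p_ge))
        elif sided == "greater":
            p = p_ge
        elif sided == "less":
            p = p_le
        else:
            raise ValueError("sided must be two-sided/greater/less")
        return TestResult(u_obs, float(p), (x.size, y.size), "mann-whitney-u", exact=True)
    res = sps.mannwhitneyu(x, y, alternative=sided, method="asymptotic")
    return TestResult(
        float(res.statistic), float(res.pvalue), (x.size, y.size), "mann-whitney-u"
    )


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float] | None = None, mu0: float = 0.0
) -> TestResult:
    """Paired (x vs y) or one-sample (x vs mu0) signed-rank test."""
    x = np.asarray(x, float)
    d = x - (np.asarray(y, float) if y is not None else mu0)
    d = d[d != 0.0]
    if d.size == 0:
        # identical pairs carry no evidence against the null
        return TestResult(0.0, 1.0, (x.size,), "wilcoxon-signed-rank", exact=True)
    res = sps.wilcoxon(d)
    name = "wilcoxon-signed-rank" if y is not None else "one-sample-wilcoxon"
    return TestResult(float(res.statistic), float(res.pvalue), (x.size,), name)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Rank one-way ANOVA over >= 2 independent groups."""
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if np.ptp(np.concatenate(arrays)) == 0.0:
        # scipy rejects all-identical data; a constant sample carries no
        # evidence against the null
        return TestResult(0.0, 1.0, tuple(a.size for a in arrays), "kruskal-wallis")
    stat, p = sps.kruskal(*arrays)
    return TestResult(float(stat), float(p), tuple(a.size for a in arrays), "kruskal-wallis")


def friedman(blocks: np.ndarray) -> TestResult:
    """Friedman test on an (n_blocks, n_treatments) matrix."""
    blocks = np.asarray(blocks, float)
    if blocks.ndim != 2 or blocks.shape[1] < 3:
        raise ValueError("need a 2-D blocks matrix with >= 3 treatments")
    if np.all(blocks == blocks[:, [0]]):
        return TestResult(0.0, 1.0, blocks.shape, "friedman")
    stat, p = sps.friedmanchisquare(*[blocks[:, j] for j in range(blocks.shape[1])])
    return TestResult(float(stat), float(p), blocks.shape, "friedman")


def dunns_posthoc(
    groups: dict[str, Sequence[float]], adjust: str = "bonferroni"
) -> dict[tuple[str, str], TestResult]:
    """Dunn's multiple-comparison post hoc after Kruskal-Wallis.

    z statistics on mean ranks of the pooled sample with tie-corrected
    variance; p values adjusted across the k(k-1)/2 pairs by Bonferroni
    (default), Holm, or left raw.
    """
    if adjust not in ("none", "bonferroni", "holm"):
        raise ValueError("adjust must be none/bonferroni/holm")
    names = list(groups)
    arrays = [np.asarray(groups[n], float) for n in names]
    if len(names) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    pos = 0
    for a in arrays:
        mean_ranks.append(ranks[pos : pos + a.size].mean())
        sizes.append(a.size)
        pos += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    base_var = N * (N + 1) / 12.0 - tie_term

    pairs = list(combinations(range(len(names)), 2))
    raw = []
    for i, j in pairs:
        se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0.0 else (mean_ranks[i] - mean_ranks[j]) / se
        raw.append((z, 2.0 * sps.norm.sf(abs(z))))
    k = len(pairs)
    if adjust == "bonferroni":
        adj = [min(1.0, k * p) for _, p in raw]
    elif adjust == "holm":
        order = sorted(range(k), key=lambda i: raw[i][1])
        adj = [0.0] * k
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (k - rank) * raw[idx][1])
            adj[idx] = min(running, 1.0)
    else:
        adj = [p for _, p in raw]
    out = {}
    for (i, j), (z, _), p in zip(pairs, raw, adj):
        out[(names[i], names[j])] = TestResult(
            z, max(p, np.nextafter(0, 1)), (sizes[i], sizes[j]), f"dunn-{adjust}"
        )
    return out


def activation_factor(
    trans_cds: Sequence[float],
    cis_cds: Sequence[float],
    min_trans_pApF: float = 1e-3,
) -> tuple[np.ndarray, CohortSummary]:
    """Per-cell current-density increase factors |cis| / |trans|.

    Cells whose trans-state density is below ``min_trans_pApF`` in magnitude
    are excluded (near-zero denominator).  Returns the per-cell factors and
    their median +/- SD summary.
    """
    trans = np.asarray(trans_cds, float)
    cis = np.asarray(cis_cds, float)
    if trans.size != cis.size:
        raise ValueError("trans and cis arrays must be paired")
    keep = np.abs(trans) >= min_trans_pApF
    if not np.any(keep):
        raise ValueError("all trans densities below the denominator threshold")
    factors = np.abs(cis[keep]) / np.abs(trans[keep])
    return factors, summarize(factors)


def correlate_kinetics_amplitude(
    taus: Sequence[float], current_densities: Sequence[float]
) -> float:
    """R^2 of the ordinary least-squares fit of tau on current density."""
    taus = np.asarray(taus, float)
    cds = np.asarray(current_densities, float)
    if taus.size != cds.size or taus.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(taus) == 0.0 or np.ptp(cds) == 0.0:
        raise ValueError("R^2 undefined for a constant sample")
    res = sps.linregress(cds, taus)
    return float(res.rvalue**2)
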