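"""Enrichment statistics for clustered fibers across genomic domains.

Covers: Fisher's exact cluster-by-domain enrichment with Storey
q-value correction (q < 0.05 significance), differential odds-ratio
matrices between conditions, PCA of a differential matrix with
correlation of PC1 against per-domain mean nucleosome density,
log-odds nucleosome-density enrichment of a cluster against the
background, and exact weighted interval scheduling to resolve
overlapping scored repeat matches (e.g. BLAST tabular hits to
satellite/telomere consensus sequences).
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate as spi
from scipy import stats as sps
from sklearn.decomposition import PCA

Q_CUTOFF = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    """Cluster x domain Fisher enrichment with FDR control."""

    clusters: tuple
    domains: tuple
    odds_ratio: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    undefined: np.ndarray  # True where the 2x2 table had an empty margin

    @property
    def significant(self) -> np.ndarray:
        return (self.q_value < Q_CUTOFF) & ~self.undefined


@dataclass(frozen=True)
class ScoredInterval:
    """A half-open scored interval (e.g. one BLAST hit)."""

    start: int
    end: int
    score: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if self.score < 0:
            raise ValueError("scores must be non-negative")

    def overlaps(self, other: "ScoredInterval") -> bool:
        return self.start < other.end and other.start < self.end


def fisher_enrichment(cluster_labels, domain_labels) -> EnrichmentResult:
    """Two-sided Fisher exact tests for every (cluster, domain) pair.

    For each pair the 2x2 table counts molecules in/out of the cluster
    crossed with in/out of the domain.  The odds ratio is the sample
    ratio ad/bc with infinities preserved; tables with an empty margin
    are flagged undefined rather than dropped.  q-values cover the
    whole cluster x domain family in one run.
    """
    cl = np.asarray(cluster_labels)
    dm = np.asarray(domain_labels)
    if len(cl) != len(dm):
        raise ValueError("label vectors must have equal length")
    clusters = tuple(pd.unique(pd.Series(cl).sort_values()))
    domains = tuple(pd.unique(pd.Series(dm).sort_values()))
    nc, nd = len(clusters), len(domains)
    odds = np.zeros((nc, nd))
    pvals = np.ones((nc, nd))
    undef = np.zeros((nc, nd), dtype=bool)
    for i, c in enumerate(clusters):
        in_c = cl == c
        for j, d in enumerate(domains):
            in_d = dm == d
            a = int(np.sum(in_c & in_d))
            b = int(np.sum(in_c & ~in_d))
            cc = int(np.sum(~in_c & in_d))
            dd = int(np.sum(~in_c & ~in_d))
            if min(a + b, cc + dd, a + cc, b + dd) == 0:
                undef[i, j] = True
                odds[i, j] = np.nan
                pvals[i, j] = 1.0
                continue
            _, p = sps.fisher_exact([[a, b], [cc, dd]], alternative="two-sided")
            pvals[i, j] = p
            if b * cc == 0:
                odds[i, j] = np.inf if a * dd > 0 else np.nan
            else:
                odds[i, j] = (a * dd) / (b * cc)
    qvals = storey_qvalues(pvals.ravel()).reshape(pvals.shape)
    return EnrichmentResult(clusters, domains, odds, pvals, qvals, undef)


def storey_qvalues(p_values, lambdas=None, pi0: float | None = None) -> np.ndarray:
    """Storey q-values with smoother-based pi0 estimation.

    pi0 (the null proportion) is estimated on the lambda grid
    0.05..0.95 (step 0.05) with a cubic smoothing spline evaluated at
    the largest lambda, as in the published q-value procedure; for
    small families (< 100 tests) or a degenerate estimate, pi0 falls
    back to 1, which makes the q-values identical to
    Benjamini-Hochberg adjusted p-values.  ``pi0`` may be forced.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    if pi0 is None:
        if lambdas is None:
            lambdas = np.arange(0.05, 0.96, 0.05)
        lambdas = np.asarray(lambdas, dtype=float)
        if m < 100 or p.max() < lambdas.max():
            pi0 = 1.0
        else:
            pi0_lambda = np.array(
                [np.mean(p > lam) / (1.0 - lam) for lam in lambdas]
            )
            spline = spi.UnivariateSpline(lambdas, pi0_lambda, k=3)
            pi0 = float(spline(lambdas.max()))
            if not np.isfinite(pi0) or pi0 <= 0 or pi0 > 1:
                pi0 = 1.0
    pi0 = min(max(float(pi0), 0.0), 1.0)
    if pi0 == 0.0:
        pi0 = 1.0

    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def differential_matrix(or_a: np.ndarray, or_b: np.ndarray, log: bool = False) -> np.ndarray:
    """Elementwise odds-ratio difference between two conditions.

    ``log=True`` differences log-odds instead; infinite or undefined
    cells propagate as NaN so they are reported, not imputed.
    """
    a = np.asarray(or_a, dtype=float)
    b = np.asarray(or_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matrices must have matching shapes")
    if log:
        with np.errstate(divide="ignore"):
            a, b = np.log(a), np.log(b)
    diff = a - b
    diff[~np.isfinite(a) | ~np.isfinite(b)] = np.nan
    return diff


def pca_density_correlation(
    diff: np.ndarray, mean_density_per_domain, n_components: int = 4
) -> dict:
    """PCA of a cluster x domain differential matrix; PC1 vs density.

    Domains are the PCA samples (the matrix is transposed), centered
    per feature.  Returns the per-domain PC scores, explained-variance
    ratios, and the Pearson/Spearman correlation of PC1 scores with the
    per-domain mean nucleosome densities (two-sided p-values).
    """
    X = np.asarray(diff, dtype=float).T  # domains x clusters
    dens = np.asarray(mean_density_per_domain, dtype=float)
    if X.shape[0] != len(dens):
        raise ValueError("one mean density per domain required")
    if X.shape[0] < 3:
        raise ValueError("need at least three domains")
    if np.any(~np.isfinite(X)):
        raise ValueError("differential matrix contains non-finite cells; mask them first")
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    pc1 = scores[:, 0]
    if np.ptp(pc1) == 0 or np.ptp(dens) == 0:
        pr = (0.0, 1.0)
        sr = (0.0, 1.0)
    else:
        r = sps.pearsonr(pc1, dens)
        s = sps.spearmanr(pc1, dens)
        pr = (float(r.statistic), float(r.pvalue))
        sr = (float(s.statistic), float(s.pvalue))
    return {
        "scores": scores,
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "pearson_r": pr[0],
        "pearson_p": pr[1],
        "spearman_rho": sr[0],
        "spearman_p": sr[1],
    }


def log_odds_density_enrichment(
    cluster_densities, background_densities, bins, pseudocount: float = 0.5
) -> np.ndarray:
    """Per-bin log-odds of cluster vs background density distributions.

    Both samples are histogrammed on the shared ``bins``; additive
    smoothing (``pseudocount`` per bin) keeps empty bins finite.
    Identical distributions give all-zero log-odds.
    """
    c = np.asarray(cluster_densities, dtype=float)
    b = np.asarray(background_densities, dtype=float)
    if len(c) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    hc, _ = np.histogram(c, bins=bins)
    hb, _ = np.histogram(b, bins=bins)
    pc = (hc + pseudocount) / (hc + pseudocount).sum()
    pb = (hb + pseudocount) / (hb + pseudocount).sum()
    return np.log(pc / pb)


def weighted_interval_schedule(
    intervals,
) -> tuple[list[ScoredInterval], float]:
    """Maximum-total-score subset of pairwise non-overlapping intervals.

    Classic dynamic program: sort by end (ties by start), binary-search
    the latest compatible predecessor, and take the better of including
    or skipping each interval.  On equal scores the skip branch wins,
    which together with the sort yields a deterministic selection
    preferring earlier-ending intervals.  Exact for the given scores.
    """
    items = [
        iv if isinstance(iv, ScoredInterval) else ScoredInterval(*iv) for iv in intervals
    ]
    if not items:
        return [], 0.0
    items.sort(key=lambda iv: (iv.end, iv.start))
    ends = [iv.end for iv in items]
    n = len(items)
    # p[i]: number of intervals ending at or before items[i].start
    p = [bisect_right(ends, items[i].start) for i in range(n)]
    best = [0.0] * (n + 1)
    take = [False] * n
    for i in range(1, n + 1):
        include = items[i - 1].score + best[p[i - 1]]
        if include > best[i - 1]:
            best[i] = include
            take[i - 1] = True
        else:
            best[i] = best[i - 1]
    chosen: list[ScoredInterval] = []
    i = n
    while i > 0:
        if take[i - 1]:
            chosen.append(items[i - 1])
            i = p[i - 1]
        else:
            i -= 1
    chosen.reverse()
    return chosen, float(best[n])


def read_blast_tabular(path) -> list[ScoredInterval]:
    """Read BLAST outfmt-6-style hits as scored query intervals.

    Uses query start/end (1-based inclusive, converted to 0-based
    half-open), the bitscore as the score and the subject id as the
    label.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            qstart, qend = int(f[6]), int(f[7])
            if qstart > qend:
                qstart, qend = qend, qstart
            out.append(
                ScoredInterval(start=qstart - 1, end=qend, score=float(f[11]), label=f[1])
            )
    return out


def write_enrichment_tsv(result: EnrichmentResult, path) -> None:
    """Long-format enrichment table: cluster, domain, OR, p, q, significant."""
    with open(path, "w") as fh:
        fh.write("cluster\tdomain\todds_ratio\tp_value\tq_value\tsignificant\n")
        for i, c in enumerate(result.clusters):
            for j, d in enumerate(result.domains):
                fh.write(
                    f"{c}\t{d}\t{result.odds_ratio[i, j]:.6g}\t"
                    f"{result.p_value[i, j]:.6g}\t{result.q_value[i, j]:.6g}\t"
                    f"{int(result.significant[i, j])}\n"
                )
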