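"""Admixture and differentiation estimation.

Implements the mixture model behind model-based clustering of unlinked
multiallelic genotypes: each gene copy of individual ``i`` at locus ``l``
comes from cluster ``k`` with probability ``Q_ik`` and is then allele ``a``
with probability ``F_kla``.  Point estimation is by maximum likelihood EM
(deterministic given a seed) with random restarts, rather than MCMC.

Also provides the supervised maximum-likelihood hybrid index (ancestry
proportion given two known parental allele-frequency profiles), label
alignment of clustering replicates, the Evanno second-difference statistic
for choosing the number of clusters, the multiallelic Weir-Cockerham (1984)
theta estimator of F_ST, and a pure/mixed population classification rule.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, minimize_scalar

from .geno_io import MISSING, GenotypeMatrix

_FREQ_EPS = 1e-6  # frequency floor before likelihood evaluation
_CI_DELTA = 1.92


@dataclass
class AncestryResult:
    """Output of one EM admixture run (the best of its restarts).

    ``Q`` is individuals x K ancestry proportions (rows sum to 1); ``F`` is
    K x loci x max-alleles cluster allele frequencies, zero-padded beyond
    each locus's observed allele count.
    """

    Q: np.ndarray
    F: np.ndarray
    loglik_trace: np.ndarray
    K: int
    converged: bool
    seed: int | None
    ids: list[str] = field(default_factory=list)
    pops: list[str] = field(default_factory=list)
    allele_counts: list[int] = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def mean_q_by_population(self) -> pd.DataFrame:
        df = pd.DataFrame(self.Q, columns=[f"Q{k+1}" for k in range(self.K)])
        df.insert(0, "population", self.pops)
        return df.groupby("population", sort=False).mean()


def _observed_copies(gm: GenotypeMatrix):
    """Flatten non-missing gene copies to parallel (individual, locus, allele) arrays."""
    calls = gm.calls
    mask = calls != MISSING
    ii, ll, _ = np.nonzero(mask)
    aa = calls[mask]
    return ii, ll, aa


def em_admixture(
    genotypes: GenotypeMatrix,
    K: int,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
) -> AncestryResult:
    """Maximum-likelihood admixture estimation by EM.

    The model is ``P(gene copy = a | i, l) = sum_k Q_ik F_kla``.  EM
    alternates responsibilities over gene copies with closed-form updates of
    Q and F; the log-likelihood is non-decreasing within each run.  The best
    of ``n_restarts`` random initializations (by final log-likelihood) is
    returned.  Missing gene copies are simply dropped from the likelihood.

    Convergence is declared when the relative log-likelihood change drops
    below ``tol``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    n, L = genotypes.n_individuals, genotypes.n_loci
    if n == 0 or L == 0:
        raise ValueError("empty genotype matrix")
    allele_counts = [genotypes.allele_count(l) for l in range(L)]
    if any(a < 1 for a in allele_counts):
        raise ValueError("every locus needs at least one observed allele")
    a_max = max(allele_counts)
    ii, ll, aa = _observed_copies(genotypes)
    if ii.size == 0:
        raise ValueError("no observed gene copies")
    n_distinct = len({tuple(row.ravel()) for row in genotypes.calls})
    if K > n_distinct:
        warnings.warn(
            f"K={K} exceeds the {n_distinct} distinct multilocus genotypes; "
            "clusters will be redundant",
            stacklevel=2,
        )
    copies_per_ind = np.bincount(ii, minlength=n).astype(float)
    if (copies_per_ind == 0).any():
        raise ValueError("individual with no observed gene copies")

    valid = np.zeros((L, a_max), dtype=bool)
    for l, na in enumerate(allele_counts):
        valid[l, :na] = True

    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, list[float], bool] | None = None
    for _ in range(n_restarts):
        Q = rng.dirichlet(np.ones(K), size=n)
        F = np.zeros((K, L, a_max))
        for k in range(K):
            for l, na in enumerate(allele_counts):
                F[k, l, :na] = np.maximum(rng.dirichlet(np.ones(na)), _FREQ_EPS)
                F[k, l, :na] /= F[k, l, :na].sum()
        trace: list[float] = []
        converged = False
        for _ in range(max_iter):
            # E-step: responsibilities per observed gene copy
            W = Q[ii, :] * F[:, ll, aa].T  # (n_obs, K)
            denom = W.sum(axis=1)
            ll_val = float(np.log(denom).sum())
            trace.append(ll_val)
            R = W / denom[:, None]
            # M-step
            Q_num = np.zeros((n, K))
            np.add.at(Q_num, ii, R)
            Q = Q_num / copies_per_ind[:, None]
            F_num = np.zeros((L, a_max, K))
            np.add.at(F_num, (ll, aa), R)
            F_den = F_num.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                F = np.where(F_den > 0, F_num / F_den, 0.0).transpose(2, 0, 1)
            F[:, ~valid] = 0.0
            if len(trace) > 1:
                prev = trace[-2]
                if abs(trace[-1] - prev) <= tol * max(1.0, abs(prev)):
                    converged = True
                    break
        # final loglik at the converged parameters
        W = Q[ii, :] * F[:, ll, aa].T
        trace.append(float(np.log(W.sum(axis=1)).sum()))
        if best is None or trace[-1] > best[2][-1]:
            best = (Q, F, trace, converged)

    Q, F, trace, converged = best
    return AncestryResult(
        Q=Q,
        F=F,
        loglik_trace=np.asarray(trace),
        K=K,
        converged=converged,
        seed=seed,
        ids=list(genotypes.ids),
        pops=list(genotypes.pops),
        allele_counts=allele_counts,
    )


def pooled_frequencies(gm: GenotypeMatrix, mask: np.ndarray | None = None) -> np.ndarray:
    """Observed allele frequencies pooled over (a subset of) individuals;
    returns loci x max-alleles, zero-padded."""
    sub = gm if mask is None else gm.subset(mask)
    L = sub.n_loci
    a_max = max(gm.allele_count(l) for l in range(L))
    out = np.zeros((L, a_max))
    for l in range(L):
        obs = sub.calls[:, l, :]
        obs = obs[obs != MISSING]
        if obs.size:
            counts = np.bincount(obs, minlength=a_max)
            out[l] = counts / counts.sum()
    return out


# ---------------------------------------------------------------------------
# supervised hybrid index


@dataclass
class HybridIndexResult:
    """Per-individual maximum-likelihood hybrid index with profile-likelihood CI."""

    h: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_copies: np.ndarray
    ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual": self.ids,
                "h": self.h,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n_copies": self.n_copies,
            }
        )


def _hybrid_loglik(h: float, fa: np.ndarray, fb: np.ndarray) -> float:
    return float(np.log(h * fb + (1.0 - h) * fa).sum())


def hybrid_index_ml(
    genotypes: GenotypeMatrix,
    freq_a: np.ndarray,
    freq_b: np.ndarray,
    eps: float = _FREQ_EPS,
) -> HybridIndexResult:
    """Maximum-likelihood hybrid index h per individual.

    Maximizes ``prod over observed gene copies [h f_B + (1 - h) f_A]`` over
    h in [0, 1]; the log-likelihood is concave in h, so bounded scalar
    optimization (checked against the interval endpoints) finds the global
    optimum.  Reference frequencies are floored at ``eps`` so private
    alleles do not zero the likelihood.  Individuals with no observed gene
    copies get ``h = nan``.
    """
    freq_a = np.maximum(np.asarray(freq_a, dtype=float), 0.0)
    freq_b = np.maximum(np.asarray(freq_b, dtype=float), 0.0)
    n = genotypes.n_individuals
    h_hat = np.full(n, np.nan)
    lo = np.full(n, np.nan)
    hi = np.full(n, np.nan)
    n_copies = np.zeros(n, dtype=int)
    for i in range(n):
        calls = genotypes.calls[i]
        mask = calls != MISSING
        if not mask.any():
            warnings.warn(
                f"individual {genotypes.ids[i]!r} has no observed gene copies; "
                "hybrid index undefined",
                stacklevel=2,
            )
            continue
        locus_idx, _ = np.nonzero(mask)
        alleles = calls[mask]
        fa = np.maximum(freq_a[locus_idx, alleles], eps)
        fb = np.maximum(freq_b[locus_idx, alleles], eps)
        n_copies[i] = alleles.size

        res = minimize_scalar(
            lambda h: -_hybrid_loglik(h, fa, fb),
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": 1e-8},
        )
        candidates = [(0.0, _hybrid_loglik(0.0, fa, fb)),
                      (1.0, _hybrid_loglik(1.0, fa, fb)),
                      (float(res.x), -float(res.fun))]
        h_best, ll_best = max(candidates, key=lambda t: t[1])
        h_hat[i] = h_best
        lo[i], hi[i] = _hybrid_ci(h_best, ll_best, fa, fb)
    return HybridIndexResult(h=h_hat, ci_low=lo, ci_high=hi,
                             n_copies=n_copies, ids=list(genotypes.ids))


def _hybrid_ci(h_hat, ll_hat, fa, fb, delta: float = _CI_DELTA):
    target = ll_hat - delta

    def edge(bound):
        if _hybrid_loglik(bound, fa, fb) >= target:
            return bound
        a, b = sorted((h_hat, bound))
        for _ in range(60):
            mid = 0.5 * (a + b)
            inside = _hybrid_loglik(mid, fa, fb) >= target
            if bound < h_hat:
                a, b = (a, mid) if inside else (mid, b)
            else:
                a, b = (mid, b) if inside else (a, mid)
        return 0.5 * (a + b)

    return edge(0.0), edge(1.0)


# ---------------------------------------------------------------------------
# replicate alignment (label switching)


def align_replicates(results: list[AncestryResult]) -> tuple[list[AncestryResult], np.ndarray]:
    """Align cluster labels across clustering replicates.

    Solves the assignment problem maximizing the summed Pearson correlation
    between each replicate's Q columns and the first replicate's (globally
    optimal over permutations, equivalent to exhaustive search).  Returns the
    relabelled replicates and the mean Q matrix (rows still sum to 1).
    """
    if not results:
        raise ValueError("no replicates to align")
    K = results[0].K
    n = results[0].Q.shape[0]
    for r in results:
        if r.K != K or r.Q.shape[0] != n:
            raise ValueError("replicates must share K and individuals")
    ref = results[0].Q
    aligned = [results[0]]
    for r in results[1:]:
        cost = np.zeros((K, K))
        for a in range(K):
            for b in range(K):
                va, vb = ref[:, a], r.Q[:, b]
                if va.std() == 0 or vb.std() == 0:
                    cost[a, b] = 0.0
                else:
                    cost[a, b] = -np.corrcoef(va, vb)[0, 1]
        _, perm = linear_sum_assignment(cost)
        aligned.append(
            AncestryResult(
                Q=r.Q[:, perm],
                F=r.F[perm],
                loglik_trace=r.loglik_trace,
                K=r.K,
                converged=r.converged,
                seed=r.seed,
                ids=r.ids,
                pops=r.pops,
                allele_counts=r.allele_counts,
            )
        )
    mean_q = np.mean([r.Q for r in aligned], axis=0)
    mean_q /= mean_q.sum(axis=1, keepdims=True)
    return aligned, mean_q


def brute_force_alignment(ref: np.ndarray, other: np.ndarray) -> tuple[int, ...]:
    """Exhaustive best permutation of ``other``'s columns against ``ref``
    (for small K; cross-check of :func:`align_replicates`)."""
    K = ref.shape[1]
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(K)):
        score = 0.0
        for a in range(K):
            va, vb = ref[:, a], other[:, perm[a]]
            if va.std() > 0 and vb.std() > 0:
                score += np.corrcoef(va, vb)[0, 1]
        if score > best_score:
            best_perm, best_score = perm, score
    return best_perm


# ---------------------------------------------------------------------------
# Evanno delta-K


def evanno_delta_k(loglik_by_k: dict[int, list[float]]) -> dict[int, float]:
    """Second-difference statistic over clustering log-likelihoods.

    ``delta_K = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K))`` with
    the sample (n-1) standard deviation, for each K whose neighbours are
    present.  Requires >= 3 consecutive K values with >= 2 replicates each;
    a zero standard deviation yields ``inf`` with a warning.
    """
    ks = sorted(loglik_by_k)
    if len(ks) < 3:
        raise ValueError("need at least three consecutive K values")
    for k in ks:
        if len(loglik_by_k[k]) < 2:
            raise ValueError(f"K={k} has fewer than two replicates")
    means = {k: float(np.mean(loglik_by_k[k])) for k in ks}
    out: dict[int, float] = {}
    for k in ks:
        if k - 1 not in means or k + 1 not in means:
            continue
        sd = float(np.std(loglik_by_k[k], ddof=1))
        num = abs(means[k + 1] - 2.0 * means[k] + means[k - 1])
        if sd == 0.0:
            warnings.warn(f"sd of L(K={k}) is zero; delta-K infinite", stacklevel=2)
            out[k] = np.inf
        else:
            out[k] = num / sd
    return out


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST


@dataclass
class FstMatrix:
    """Pairwise multilocus Weir-Cockerham theta with per-locus components.

    ``theta`` is a symmetric DataFrame (diagonal 0); slightly negative
    estimates are a known property of the estimator and are reported as-is.
    Undefined pairs (no variance anywhere) are NaN.
    """

    theta: pd.DataFrame
    components: dict[tuple[str, str], pd.DataFrame]

    def pair(self, p1: str, p2: str) -> float:
        return float(self.theta.loc[p1, p2])


def _wc_components_locus(calls_by_pop: list[np.ndarray]) -> tuple[float, float, float] | None:
    """Weir & Cockerham (1984) variance components (a, b, c) for one locus,
    summed over alleles.  ``calls_by_pop``: per population, (n_i, 2) arrays
    of non-missing allele codes.  Returns None when undefined (some
    population unobserved, or mean sample size <= 1)."""
    counts = [c.shape[0] for c in calls_by_pop]
    if any(n == 0 for n in counts):
        return None
    r = len(calls_by_pop)
    n_i = np.asarray(counts, dtype=float)
    nbar = n_i.mean()
    if nbar <= 1:
        return None
    n_c = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    if n_c <= 0:
        return None
    alleles = np.unique(np.concatenate([c.ravel() for c in calls_by_pop]))
    A = B = C = 0.0
    for a in alleles:
        p_i = np.array([(c == a).mean() for c in calls_by_pop])
        h_i = np.array([((c == a).sum(axis=1) == 1).mean() for c in calls_by_pop])
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a_comp = (nbar / n_c) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b_comp = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c_comp = hbar / 2.0
        A += a_comp
        B += b_comp
        C += c_comp
    return A, B, C


def weir_cockerham_fst(
    genotypes: GenotypeMatrix,
    pairs: list[tuple[str, str]] | None = None,
    min_n: int = 5,
) -> FstMatrix:
    """Pairwise multilocus Weir-Cockerham theta.

    ``theta = sum_l a_l / sum_l (a_l + b_l + c_l)`` with variance components
    ``a`` (among populations), ``b`` (among individuals within populations)
    and ``c`` (within individuals), summed over loci and alleles.  Missing
    genotypes are dropped per locus.  Populations with fewer than ``min_n``
    individuals are excluded.  A pair monomorphic at every usable locus has
    an undefined theta, reported as NaN.
    """
    sizes = genotypes.population_sizes()
    pops = [p for p in dict.fromkeys(genotypes.pops) if sizes[p] >= min_n]
    dropped = [p for p in dict.fromkeys(genotypes.pops) if sizes[p] < min_n]
    if dropped:
        warnings.warn(
            f"populations below min_n={min_n} excluded: {dropped}", stacklevel=2
        )
    if pairs is None:
        pairs = list(itertools.combinations(pops, 2))
    theta = pd.DataFrame(0.0, index=pops, columns=pops)
    components: dict[tuple[str, str], pd.DataFrame] = {}
    calls_by_pop = {
        p: genotypes.by_population(p).calls for p in pops
    }
    for p1, p2 in pairs:
        if p1 not in pops or p2 not in pops:
            raise ValueError(f"population pair ({p1}, {p2}) not available at min_n={min_n}")
        rows = []
        for l, locus in enumerate(genotypes.loci):
            per_pop = []
            for p in (p1, p2):
                cl = calls_by_pop[p][:, l, :]
                keep = (cl != MISSING).all(axis=1)
                per_pop.append(cl[keep])
            comps = _wc_components_locus(per_pop)
            if comps is not None:
                rows.append((locus, *comps))
        comp_df = pd.DataFrame(rows, columns=["locus", "a", "b", "c"]).set_index("locus")
        components[(p1, p2)] = comp_df
        denom = float((comp_df["a"] + comp_df["b"] + comp_df["c"]).sum())
        value = float(comp_df["a"].sum()) / denom if denom != 0.0 else np.nan
        if np.isnan(value):
            warnings.warn(
                f"theta undefined for ({p1}, {p2}): no allele-frequency variance",
                stacklevel=2,
            )
        theta.loc[p1, p2] = theta.loc[p2, p1] = value
    return FstMatrix(theta=theta, components=components)


# ---------------------------------------------------------------------------
# pure/mixed classification


def classify_population(
    mean_q_max: float | None,
    haplotype_counts: tuple[int, int] | None,
    q_threshold: float = 0.9,
) -> str:
    """Classify a population as "pure" or "mixed" for mapping purposes.

    A population is mixed iff both mtDNA haplotypes are present and/or its
    nuclear genotypes are consistent with admixture, i.e. the mean ancestry
    proportion of its majority cluster falls strictly below ``q_threshold``
    (default 0.9).  With no data at all the verdict is "unclassified".
    """
    if not 0.5 < q_threshold <= 1.0:
        raise ValueError("q_threshold must lie in (0.5, 1]")
    if mean_q_max is None and haplotype_counts is None:
        return "unclassified"
    if haplotype_counts is not None:
        if min(haplotype_counts) > 0:
            return "mixed"
    if mean_q_max is not None:
        if not 0.0 <= mean_q_max <= 1.0:
            raise ValueError("mean Q must lie in [0, 1]")
        if mean_q_max < q_threshold:
            return "mixed"
    return "pure"
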