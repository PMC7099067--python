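"""Comparative contact-zone statistics.

Given a table of secondary contact zones — each with a divergence time, a
contact epoch, and an ordered transition category reflecting the amount of
admixture (``no_gene_flow < steep < wide``) — this module runs the
meta-analysis linking contact history to admixture:

* a proportional-odds ordinal regression of transition category on a numeric
  or binary predictor, with a likelihood-ratio test against the
  intercepts-only model;
* a Yates-corrected chi-square test of independence on a 2x2 table
  (wide/steep transitions by Holocene-Anthropocene/Pleistocene contact);
* a tie-aware Mann-Whitney comparison of divergence times between steep and
  wide transitions, exact by enumeration when tie-free and small.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm, rankdata

from .geno_io import ContactZoneRecord

_BETA_CLIP = 50.0


@dataclass
class OrdinalModelFit:
    """Proportional-odds model fit: P(Y <= j | x) = logistic(alpha_j - beta x)."""

    cutpoints: np.ndarray
    beta: float
    loglik: float
    null_loglik: float
    lr_statistic: float
    df: int
    p_value: float
    converged: bool
    n_iter: int

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.cutpoints) > 0):
            raise ValueError("cutpoints must be strictly increasing")


@dataclass
class TestResult:
    """A named test statistic with its p-value and method notes."""

    name: str
    statistic: float
    p_value: float
    df: int | None = None
    notes: dict = field(default_factory=dict)


def _expand_logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))


def _ordinal_loglik_grad(theta: np.ndarray, y: np.ndarray, x: np.ndarray, J: int):
    """Log-likelihood and analytic gradient of the proportional-odds model.

    theta = (alpha_1 .. alpha_{J-1}, beta); y in {0..J-1}."""
    alpha = theta[:-1]
    beta = theta[-1]
    # eta_j = alpha_j - beta x, with virtual -inf / +inf flanks
    eta = alpha[None, :] - beta * x[:, None]  # (n, J-1)
    F = _expand_logistic(eta)
    F_hi = np.concatenate([F, np.ones((len(x), 1))], axis=1)  # F(eta_{j+1}), j=y
    F_lo = np.concatenate([np.zeros((len(x), 1)), F], axis=1)  # F(eta_y)
    idx = np.arange(len(x))
    P = F_hi[idx, y] - F_lo[idx, y]
    P = np.maximum(P, 1e-300)
    ll = float(np.log(P).sum())

    f = F * (1.0 - F)  # logistic density at each cutpoint
    f_hi = np.concatenate([f, np.zeros((len(x), 1))], axis=1)
    f_lo = np.concatenate([np.zeros((len(x), 1)), f], axis=1)
    grad = np.zeros(J)  # J-1 alphas + 1 beta
    d_hi = f_hi[idx, y] / P  # derivative wrt eta at the upper cutpoint
    d_lo = f_lo[idx, y] / P
    # wrt alpha_m: +d_hi where m == y+1, -d_lo where m == y
    for m in range(J - 1):
        grad[m] = d_hi[y == m].sum() - d_lo[y == m + 1].sum()
    grad[-1] = float((-x * d_hi + x * d_lo).sum())
    return ll, grad


def _null_loglik(y: np.ndarray, J: int) -> float:
    counts = np.bincount(y, minlength=J).astype(float)
    n = counts.sum()
    nz = counts[counts > 0]
    return float((nz * np.log(nz / n)).sum())


def fit_ordinal_logistic(
    y,
    x,
    categories: list | None = None,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> OrdinalModelFit:
    """Fit a proportional-odds ordinal regression by Newton iterations.

    ``y`` holds ordered categories (integer ranks 0..J-1, or labels resolved
    against ``categories`` in increasing order); ``x`` is a single numeric or
    binary predictor.  The likelihood-ratio statistic is
    ``2 (lnL_full - lnL_null)`` against the intercepts-only model, with the
    p-value from a chi-square with df = 1 (one slope parameter).

    Newton steps use the analytic gradient with a finite-difference Hessian
    and step-halving; the slope is clipped at |beta| <= 50 with a separation
    warning.
    """
    if categories is not None:
        lookup = {c: i for i, c in enumerate(categories)}
        y = np.array([lookup[v] for v in y], dtype=int)
    else:
        y = np.asarray(y, dtype=int)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("y and x must have the same length")
    J = int(y.max()) + 1
    observed = np.unique(y)
    if len(observed) < 2:
        raise ValueError("no ordinal variation: all outcomes in one category")
    if J < 2:
        raise ValueError("need at least two categories")

    # start at the null MLE: empirical cumulative logits, beta = 0
    counts = np.bincount(y, minlength=J).astype(float)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    cum = np.clip(cum, 1e-6, 1 - 1e-6)
    theta = np.concatenate([np.log(cum / (1 - cum)), [0.0]])

    ll, grad = _ordinal_loglik_grad(theta, y, x, J)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        # finite-difference Hessian of the gradient
        H = np.zeros((J, J))
        h = 1e-6
        for m in range(J):
            step = np.zeros(J)
            step[m] = h
            _, gp = _ordinal_loglik_grad(theta + step, y, x, J)
            _, gm = _ordinal_loglik_grad(theta - step, y, x, J)
            H[:, m] = (gp - gm) / (2 * h)
        H = 0.5 * (H + H.T)
        try:
            delta = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            delta = grad / max(1.0, np.abs(grad).max())
        step_scale = 1.0
        improved = False
        for _ in range(40):  # step-halving
            cand = theta - step_scale * delta
            cand[-1] = np.clip(cand[-1], -_BETA_CLIP, _BETA_CLIP)
            if np.all(np.diff(cand[:-1]) > 0):
                ll_new, grad_new = _ordinal_loglik_grad(cand, y, x, J)
                if ll_new >= ll - 1e-12:
                    theta, ll, grad = cand, ll_new, grad_new
                    improved = True
                    break
            step_scale *= 0.5
        if not improved:
            break
        if np.abs(grad).max() < 1e-8 or step_scale * np.abs(delta).max() < tol:
            converged = True
            break
    if abs(theta[-1]) >= _BETA_CLIP - 1e-9:
        warnings.warn(
            "slope at clip boundary: outcome may be separated by the predictor",
            stacklevel=2,
        )
    ll0 = _null_loglik(y, J)
    lr = max(0.0, 2.0 * (ll - ll0))
    return OrdinalModelFit(
        cutpoints=theta[:-1],
        beta=float(theta[-1]),
        loglik=ll,
        null_loglik=ll0,
        lr_statistic=lr,
        df=1,
        p_value=float(chi2_dist.sf(lr, 1)),
        converged=converged,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# 2x2 chi-square of independence


def chi2_independence_2x2(table, continuity_correction: bool = True) -> TestResult:
    """Chi-square test of independence on a 2x2 table.

    With the Yates continuity correction (default):
    ``chi2 = N (max(0, |ad - bc| - N/2))^2 / (r1 r2 c1 c2)``.
    A zero marginal makes the statistic undefined (NaN reported).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2x2 with non-negative integer counts")
    n = t.sum()
    if n < 1:
        raise ValueError("empty table")
    a, b, c, d = t.ravel()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    notes = {"continuity_correction": continuity_correction}
    if min(r1, r2, c1, c2) == 0:
        warnings.warn("zero marginal: chi-square undefined", stacklevel=2)
        return TestResult("chi2_independence", np.nan, np.nan, df=1,
                          notes={**notes, "undefined": "zero marginal"})
    diff = abs(a * d - b * c)
    if continuity_correction:
        diff = max(0.0, diff - n / 2.0)
    stat = n * diff**2 / (r1 * r2 * c1 * c2)
    return TestResult(
        "chi2_independence", float(stat), float(chi2_dist.sf(stat, 1)), df=1, notes=notes
    )


# ---------------------------------------------------------------------------
# Mann-Whitney


def mann_whitney(group_a, group_b, method: str = "auto") -> TestResult:
    """Mann-Whitney-Wilcoxon rank test with midranks for ties.

    The reported statistic is ``W = (rank sum of group_a) - n_a (n_a + 1)/2``
    (the U statistic of the first group; the opposite orientation
    ``n_a n_b - W`` is included in the notes).  The p-value is exact by
    enumeration of all C(n, n_a) assignments when the pooled sample is
    tie-free and n <= 12, otherwise a normal approximation with
    tie-corrected variance and a 0.5 continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = a.size, b.size
    n = na + nb
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks
    w = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    has_ties = len(np.unique(pooled)) < n

    if method == "auto":
        method = "exact" if (not has_ties and n <= 12) else "normal"
    notes = {"method": method, "ties": has_ties, "W_other_orientation": na * nb - w}

    if method == "exact":
        if has_ties:
            raise ValueError("exact enumeration requires tie-free data")
        us = []
        all_ranks = np.arange(1, n + 1)
        for comb in itertools.combinations(range(n), na):
            us.append(all_ranks[list(comb)].sum() - na * (na + 1) / 2.0)
        us = np.asarray(us)
        p = 2.0 * min((us <= w).mean(), (us >= w).mean())
        p = min(1.0, p)
    elif method == "normal":
        mu = na * nb / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum())
        var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
            notes["degenerate"] = "zero variance (all values tied)"
        else:
            cc = 0.5 if w != mu else 0.0
            z = (w - mu - np.sign(w - mu) * cc) / np.sqrt(var)
            p = float(2.0 * norm.sf(abs(z)))
            notes["z"] = float(z)
        p = min(1.0, p)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult("mann_whitney", w, float(p), df=None, notes=notes)


# ---------------------------------------------------------------------------
# the composed suite


@dataclass
class ComparativeReport:
    """Machine-readable report of the four contact-zone statistics."""

    ordinal_divergence: OrdinalModelFit
    ordinal_contact_age: OrdinalModelFit
    chi2_wide_steep: TestResult
    mann_whitney_divergence: TestResult
    coding: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "ordinal_divergence": {
                "lr_statistic": self.ordinal_divergence.lr_statistic,
                "df": self.ordinal_divergence.df,
                "p_value": self.ordinal_divergence.p_value,
                "beta": self.ordinal_divergence.beta,
                "n": len(self.coding),
            },
            "ordinal_contact_age": {
                "lr_statistic": self.ordinal_contact_age.lr_statistic,
                "df": self.ordinal_contact_age.df,
                "p_value": self.ordinal_contact_age.p_value,
                "beta": self.ordinal_contact_age.beta,
                "n": len(self.coding),
            },
            "chi2_wide_steep": {
                "statistic": self.chi2_wide_steep.statistic,
                "df": self.chi2_wide_steep.df,
                "p_value": self.chi2_wide_steep.p_value,
                "n": int(self.coding["category"].isin(["steep", "wide"]).sum()),
            },
            "mann_whitney_divergence": {
                "W": self.mann_whitney_divergence.statistic,
                "p_value": self.mann_whitney_divergence.p_value,
                "method": self.mann_whitney_divergence.notes["method"],
                "n": int(self.coding["category"].isin(["steep", "wide"]).sum()),
            },
        }


def run_comparative_suite(records: list[ContactZoneRecord]) -> ComparativeReport:
    """Run the four-statistic meta-analysis over a contact-zone table.

    1. Ordinal regression of transition category on divergence time (all
       contacts).
    2. Ordinal regression of transition category on binary relative contact
       age: Holocene/Anthropocene (Antiquity, 1950s, post-glacial) coded 1
       versus Pleistocene (>= LGM) coded 0.
    3. Yates chi-square of independence on wide/steep x post-LGM/pre-LGM,
       excluding the sympatry-without-gene-flow contact.
    4. Mann-Whitney comparison of divergence times, steep group first, over
       the same steep + wide contacts.
    """
    if not records:
        raise ValueError("no contact-zone records")
    coding = pd.DataFrame(
        {
            "node": [r.node for r in records],
            "region": [r.region for r in records],
            "category": [r.transition_category for r in records],
            "category_rank": [r.category_rank for r in records],
            "divergence_ma": [r.divergence_ma for r in records],
            "post_lgm": [int(r.post_lgm_contact) for r in records],
        }
    )
    fit_div = fit_ordinal_logistic(
        coding["category_rank"].to_numpy(), coding["divergence_ma"].to_numpy()
    )
    fit_age = fit_ordinal_logistic(
        coding["category_rank"].to_numpy(), coding["post_lgm"].to_numpy()
    )
    sub = coding[coding["category"].isin(["steep", "wide"])]
    table = [
        [int(((sub["category"] == "wide") & (sub["post_lgm"] == 1)).sum()),
         int(((sub["category"] == "wide") & (sub["post_lgm"] == 0)).sum())],
        [int(((sub["category"] == "steep") & (sub["post_lgm"] == 1)).sum()),
         int(((sub["category"] == "steep") & (sub["post_lgm"] == 0)).sum())],
    ]
    chi2_res = chi2_independence_2x2(table, continuity_correction=True)
    chi2_res.notes["table"] = table
    chi2_res.notes["rows"] = ["wide", "steep"]
    chi2_res.notes["cols"] = ["post_lgm", "pre_lgm"]
    mw = mann_whitney(
        sub.loc[sub["category"] == "steep", "divergence_ma"].to_numpy(),
        sub.loc[sub["category"] == "wide", "divergence_ma"].to_numpy(),
    )
    return ComparativeReport(
        ordinal_divergence=fit_div,
        ordinal_contact_age=fit_age,
        chi2_wide_steep=chi2_res,
        mann_whitney_divergence=mw,
        coding=coding,
    )
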