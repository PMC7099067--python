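"""Geographic cline model, likelihood fitting, AIC model selection, and the
cline-width to selection-coefficient conversion.

The cline describes how a trait frequency (mtDNA haplotype frequency, or a
nuclear admixture coefficient treated as an allele frequency) changes along a
one-dimensional transect through a hybrid zone.  The central segment is a
sigmoid

    f(x) = 1 / (1 + exp(-4 (x - c) / w))

whose width ``w`` is the inverse of the maximum slope and whose center ``c``
is the position of the 0.5 crossing.  Beyond optional attachment points at
``c - delta_L`` and ``c + delta_R`` the curve switches to exponential
introgression tails whose steepness is a fraction ``tau`` of the sigmoid
slope at the attachment point (the Szymura-Barton parameterization used by
hybrid-zone cline software).  With free scaling the observed frequency is
``p(x) = p_min + (p_max - p_min) f(x)``.

Model selection runs a ladder of 10 candidate models — {fixed, free} scaling
crossed with {none, left, right, mirror, both} tails, 2 to 8 parameters —
and ranks them by AIC.

Under a tension-zone model with heterozygote disadvantage, cline width
relates to per-generation dispersal sigma and the selection coefficient s*
against hybrids via ``w ~ 2 sigma / sqrt(s*)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .geno_io import LocalityTable, transect_distances

TAIL_MODES = ("none", "left", "right", "mirror", "both")
SCALING_MODES = ("fixed", "free")

_P_EPS = 1e-9  # frequency clamp inside the binomial likelihood
_CI_DELTA = 1.92  # loglik drop for a ~95% profile-likelihood interval


@dataclass
class ClineModel:
    """A 2-8 parameter geographic cline.

    Parameters
    ----------
    center : float
        Position of the frequency midpoint (km along the transect).
    width : float
        Cline width, 1 / (maximum frequency slope); km.
    p_min, p_max : float
        Parental trait frequencies at the two ends of the transect.  With
        ``scaling_mode="fixed"`` they are pinned at 0 and 1.
    delta_l, tau_l : float
        Left introgression tail: attachment distance from the center (km,
        >= 0) and slope ratio in (0, 1].  ``tau = 1`` collapses the tail
        onto the sigmoid.
    delta_r, tau_r : float
        Right tail, mirrored.
    tail_mode : {"none", "left", "right", "mirror", "both"}
        Which tails are active; "mirror" shares delta/tau across sides.
    scaling_mode : {"fixed", "free"}
    """

    center: float
    width: float
    p_min: float = 0.0
    p_max: float = 1.0
    delta_l: float = 0.0
    tau_l: float = 1.0
    delta_r: float = 0.0
    tau_r: float = 1.0
    tail_mode: str = "none"
    scaling_mode: str = "fixed"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("cline width must be positive")
        if self.tail_mode not in TAIL_MODES:
            raise ValueError(f"unknown tail_mode {self.tail_mode!r}")
        if self.scaling_mode not in SCALING_MODES:
            raise ValueError(f"unknown scaling_mode {self.scaling_mode!r}")
        if self.scaling_mode == "fixed":
            self.p_min, self.p_max = 0.0, 1.0
        elif not (0.0 <= self.p_min < self.p_max <= 1.0):
            raise ValueError("free scaling requires 0 <= p_min < p_max <= 1")
        for d, t, side in ((self.delta_l, self.tau_l, "left"), (self.delta_r, self.tau_r, "right")):
            if d < 0:
                raise ValueError(f"{side} tail attachment distance must be >= 0")
            if not 0.0 < t <= 1.0:
                raise ValueError(f"{side} tail slope ratio must be in (0, 1]")

    @property
    def n_parameters(self) -> int:
        """2 (fixed, none) up to 8 (free, both); mirror shares delta/tau."""
        k = 2
        if self.scaling_mode == "free":
            k += 2
        k += {"none": 0, "left": 2, "right": 2, "mirror": 2, "both": 4}[self.tail_mode]
        return k

    def value(self, x) -> np.ndarray | float:
        return cline_value(self, x)


def cline_value(model: ClineModel, x) -> np.ndarray | float:
    """Trait frequency predicted by ``model`` at transect position(s) ``x``.

    Total, continuous and non-decreasing in ``x``; tails attach to the
    central sigmoid continuously (to machine precision).
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    c, w = model.center, model.width
    f = 1.0 / (1.0 + np.exp(np.clip(-4.0 * (x - c) / w, -700, 700)))

    left = model.tail_mode in ("left", "mirror", "both")
    right = model.tail_mode in ("right", "mirror", "both")
    if left:
        dl, tl = model.delta_l, model.tau_l
        mask = x < c - dl
        if mask.any():
            g = 1.0 / (1.0 + np.exp(min(4.0 * dl / w, 700.0)))
            rate = 4.0 * tl / (w * (1.0 + np.exp(min(-4.0 * dl / w, 700.0))))
            f[mask] = g * np.exp(np.clip(rate * (x[mask] - c + dl), -700, 0))
    if right:
        dr, tr = model.delta_r, model.tau_r
        mask = x > c + dr
        if mask.any():
            g = 1.0 / (1.0 + np.exp(min(4.0 * dr / w, 700.0)))
            rate = 4.0 * tr / (w * (1.0 + np.exp(min(-4.0 * dr / w, 700.0))))
            f[mask] = 1.0 - g * np.exp(np.clip(-rate * (x[mask] - c - dr), -700, 0))

    p = model.p_min + (model.p_max - model.p_min) * f
    return float(p[0]) if scalar else p


@dataclass
class TransectSeries:
    """Per-deme binomial counts along a transect.

    ``x`` is the distance along the transect (km), ``k`` the focal trait
    count and ``n`` the total: haplotype counts for mtDNA, or effective
    allele counts (2 x individuals, k = round(mean Q x 2n)) for nuclear
    admixture.
    """

    x: np.ndarray
    k: np.ndarray
    n: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if not (self.x.shape == self.k.shape == self.n.shape):
            raise ValueError("x, k, n must have the same length")
        if not np.isfinite(self.x).all():
            raise ValueError("transect distances must be finite")
        if (self.n < 1).any():
            raise ValueError("totals must be >= 1")
        if ((self.k < 0) | (self.k > self.n)).any():
            raise ValueError("counts must satisfy 0 <= k <= n")
        if not self.labels:
            self.labels = [f"deme_{i}" for i in range(len(self.x))]

    def __len__(self) -> int:
        return len(self.x)

    @property
    def frequencies(self) -> np.ndarray:
        return self.k / self.n


def cline_loglik(model: ClineModel, series: TransectSeries) -> float:
    """Binomial log-likelihood of ``series`` under ``model`` (p clamped to
    [1e-9, 1 - 1e-9]); combinatorial constant omitted."""
    p = np.clip(cline_value(model, series.x), _P_EPS, 1.0 - _P_EPS)
    return float(np.sum(series.k * np.log(p) + (series.n - series.k) * np.log1p(-p)))


# ---------------------------------------------------------------------------
# fitting


@dataclass(frozen=True)
class ClineModelSpec:
    """One rung of the model ladder: a tail mode and a scaling mode."""

    tail_mode: str = "none"
    scaling_mode: str = "fixed"

    def __post_init__(self) -> None:
        if self.tail_mode not in TAIL_MODES:
            raise ValueError(f"unknown tail_mode {self.tail_mode!r}")
        if self.scaling_mode not in SCALING_MODES:
            raise ValueError(f"unknown scaling_mode {self.scaling_mode!r}")

    @property
    def name(self) -> str:
        return f"{self.scaling_mode}/{self.tail_mode}"

    @property
    def parameter_names(self) -> tuple[str, ...]:
        names = ["center", "width"]
        if self.scaling_mode == "free":
            names += ["p_min", "p_max"]
        if self.tail_mode in ("left", "both"):
            names += ["delta_l", "tau_l"]
        if self.tail_mode == "mirror":
            names += ["delta", "tau"]
        if self.tail_mode in ("right", "both"):
            names += ["delta_r", "tau_r"]
        return tuple(names)

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    def build(self, theta: np.ndarray) -> ClineModel:
        """Build a ClineModel from a packed parameter vector."""
        params = dict(zip(self.parameter_names, theta))
        kw = dict(
            center=params["center"],
            width=params["width"],
            tail_mode=self.tail_mode,
            scaling_mode=self.scaling_mode,
        )
        if self.scaling_mode == "free":
            lo, hi = sorted((params["p_min"], params["p_max"]))
            if hi - lo < 1e-9:
                hi = min(lo + 1e-9, 1.0)
                lo = hi - 1e-9
            kw["p_min"], kw["p_max"] = lo, hi
        if self.tail_mode == "mirror":
            kw["delta_l"] = kw["delta_r"] = params["delta"]
            kw["tau_l"] = kw["tau_r"] = params["tau"]
        else:
            if "delta_l" in params:
                kw["delta_l"], kw["tau_l"] = params["delta_l"], params["tau_l"]
            if "delta_r" in params:
                kw["delta_r"], kw["tau_r"] = params["delta_r"], params["tau_r"]
        return ClineModel(**kw)

    def pack(self, model: ClineModel) -> np.ndarray:
        vals = {"center": model.center, "width": model.width,
                "p_min": model.p_min, "p_max": model.p_max,
                "delta_l": model.delta_l, "tau_l": model.tau_l,
                "delta_r": model.delta_r, "tau_r": model.tau_r,
                "delta": model.delta_l, "tau": model.tau_l}
        return np.array([vals[name] for name in self.parameter_names])


MODEL_LADDER: tuple[ClineModelSpec, ...] = tuple(
    ClineModelSpec(tail_mode=t, scaling_mode=s)
    for s in SCALING_MODES
    for t in TAIL_MODES
)


@dataclass
class ClineFit:
    """Result of fitting one cline model to one transect series."""

    model: ClineModel
    spec: ClineModelSpec
    loglik: float
    aic: float
    intervals: dict[str, tuple[float, float]]
    converged: bool
    n_starts: int
    seed: int | None
    diagnostics: dict = field(default_factory=dict)


class ClineFitError(RuntimeError):
    """All optimization starts failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


def _default_bounds(spec: ClineModelSpec, series: TransectSeries) -> list[tuple[float, float]]:
    xmin, xmax = float(series.x.min()), float(series.x.max())
    span = max(xmax - xmin, 1e-6)
    table = {
        "center": (xmin - span, xmax + span),
        "width": (1e-3 * span, 4.0 * span),
        "p_min": (0.0, 1.0),
        "p_max": (0.0, 1.0),
        "delta_l": (0.0, span),
        "delta_r": (0.0, span),
        "delta": (0.0, span),
        "tau_l": (1e-3, 1.0),
        "tau_r": (1e-3, 1.0),
        "tau": (1e-3, 1.0),
    }
    return [table[name] for name in spec.parameter_names]


def _random_start(spec, bounds, series, rng) -> np.ndarray:
    xmin, xmax = float(series.x.min()), float(series.x.max())
    span = max(xmax - xmin, 1e-6)
    draws = {
        "center": rng.uniform(xmin, xmax),
        "width": np.exp(rng.uniform(np.log(span / 50.0), np.log(2.0 * span))),
        "p_min": rng.uniform(0.0, 0.2),
        "p_max": rng.uniform(0.8, 1.0),
        "delta_l": rng.uniform(0.0, span / 2.0),
        "delta_r": rng.uniform(0.0, span / 2.0),
        "delta": rng.uniform(0.0, span / 2.0),
        "tau_l": rng.uniform(0.1, 1.0),
        "tau_r": rng.uniform(0.1, 1.0),
        "tau": rng.uniform(0.1, 1.0),
    }
    theta = np.array([draws[name] for name in spec.parameter_names])
    return np.clip(theta, [b[0] for b in bounds], [b[1] for b in bounds])


def fit_cline(
    series: TransectSeries,
    model_spec: ClineModelSpec | str = "fixed/none",
    n_starts: int = 50,
    seed: int | None = None,
    bounds: list[tuple[float, float]] | None = None,
    compute_ci: bool = True,
) -> ClineFit:
    """Maximum-likelihood cline fit by bounded multi-start optimization.

    Starts are drawn from stratified random initializations inside the
    parameter bounds (center within the sampled range, width log-uniform,
    tails anywhere up to half the span); each start runs bounded L-BFGS-B
    with a Nelder-Mead polish.  The best final log-likelihood wins.
    Per-parameter ~95% intervals are obtained by profile likelihood
    (loglik drop of 1.92).
    """
    if isinstance(model_spec, str):
        scaling, tail = model_spec.split("/")
        model_spec = ClineModelSpec(tail_mode=tail, scaling_mode=scaling)
    if len(series) < model_spec.n_parameters + 1:
        warnings.warn(
            f"only {len(series)} demes for a {model_spec.n_parameters}-parameter "
            "cline model; estimates may be unstable",
            stacklevel=2,
        )
    if bounds is None:
        bounds = _default_bounds(model_spec, series)
    rng = np.random.default_rng(seed)

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def negll(theta: np.ndarray) -> float:
        # project into the box so derivative-free polish steps stay valid
        return -cline_loglik(model_spec.build(np.clip(theta, lo, hi)), series)

    best = None
    diags = []
    for start_idx in range(n_starts):
        theta0 = _random_start(model_spec, bounds, series, rng)
        try:
            res = minimize(negll, theta0, method="L-BFGS-B", bounds=bounds)
            res2 = minimize(
                negll, res.x, method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
            )
            theta, fval = (res2.x, res2.fun) if res2.fun < res.fun else (res.x, res.fun)
            theta = np.clip(theta, [b[0] for b in bounds], [b[1] for b in bounds])
            fval = negll(theta)
            ok = np.isfinite(fval)
        except (ValueError, FloatingPointError) as exc:  # pragma: no cover
            diags.append({"start": start_idx, "error": str(exc)})
            continue
        diags.append({"start": start_idx, "negll": float(fval), "converged": bool(ok)})
        if ok and (best is None or fval < best[1]):
            best = (theta, fval)
    if best is None:
        raise ClineFitError("no optimization start converged", diags)

    theta_hat, negll_hat = best
    model = model_spec.build(theta_hat)
    loglik = -negll_hat
    aic = 2.0 * model_spec.n_parameters - 2.0 * loglik
    intervals = (
        _profile_intervals(model_spec, theta_hat, loglik, bounds, series)
        if compute_ci
        else {}
    )
    return ClineFit(
        model=model,
        spec=model_spec,
        loglik=loglik,
        aic=aic,
        intervals=intervals,
        converged=True,
        n_starts=n_starts,
        seed=seed,
        diagnostics={"starts": diags},
    )


def _profile_loglik(spec, theta_hat, j, value, bounds, series) -> float:
    """Maximize loglik with parameter j pinned, warm-started at the MLE."""
    free = [i for i in range(len(theta_hat)) if i != j]
    if not free:
        theta = theta_hat.copy()
        theta[j] = value
        return cline_loglik(spec.build(theta), series)

    def negll(sub: np.ndarray) -> float:
        theta = theta_hat.copy()
        theta[free] = sub
        theta[j] = value
        return -cline_loglik(spec.build(theta), series)

    res = minimize(
        negll, theta_hat[free], method="L-BFGS-B",
        bounds=[bounds[i] for i in free],
    )
    return -float(res.fun)


def _profile_intervals(spec, theta_hat, loglik_hat, bounds, series,
                       delta: float = _CI_DELTA) -> dict[str, tuple[float, float]]:
    target = loglik_hat - delta
    intervals: dict[str, tuple[float, float]] = {}
    for j, name in enumerate(spec.parameter_names):
        lo_b, hi_b = bounds[j]
        limits = []
        for bound in (lo_b, hi_b):
            if _profile_loglik(spec, theta_hat, j, bound, bounds, series) >= target:
                limits.append(bound)  # interval truncated at the box bound
                continue
            a, b = sorted((theta_hat[j], bound))
            # bisection: profile loglik is >= target at the MLE side
            for _ in range(40):
                mid = 0.5 * (a + b)
                if _profile_loglik(spec, theta_hat, j, mid, bounds, series) >= target:
                    if bound < theta_hat[j]:
                        b = mid
                    else:
                        a = mid
                else:
                    if bound < theta_hat[j]:
                        a = mid
                    else:
                        b = mid
                if b - a < 1e-6 * max(1.0, abs(theta_hat[j])):
                    break
            limits.append(0.5 * (a + b))
        intervals[name] = (min(limits), max(limits))
    return intervals


def select_cline_model(
    series: TransectSeries,
    n_starts: int = 50,
    seed: int | None = None,
    compute_ci: bool = False,
    ladder: tuple[ClineModelSpec, ...] = MODEL_LADDER,
) -> list[ClineFit]:
    """Fit the full 10-model ladder and rank by AIC.

    Ties are broken by fewer parameters, then lexical model name.  A model
    whose fit fails entirely is excluded with a warning.
    """
    rng = np.random.default_rng(seed)
    fits: list[ClineFit] = []
    for spec in ladder:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            fits.append(
                fit_cline(series, spec, n_starts=n_starts, seed=sub_seed,
                          compute_ci=compute_ci)
            )
        except ClineFitError as exc:
            warnings.warn(f"model {spec.name} excluded: {exc}", stacklevel=2)
    fits.sort(key=lambda f: (f.aic, f.spec.n_parameters, f.spec.name))
    return fits


# ---------------------------------------------------------------------------
# selection against hybrids


def selection_coefficient(width_km: float, sigma_km: float) -> float:
    """Selection coefficient s* against hybrids implied by a cline width.

    Under a tension-zone model with heterozygote disadvantage,
    ``w ~ 2 sigma / sqrt(s*)``, so ``s* = (2 sigma / w)**2``.  ``sigma`` is
    the per-generation parent-offspring dispersal (km / generation^0.5 on
    the diffusion scale).
    """
    if width_km <= 0:
        raise ValueError("cline width must be positive")
    if sigma_km <= 0:
        raise ValueError("dispersal sigma must be positive")
    return (2.0 * sigma_km / width_km) ** 2


def width_for_selection(s_star: float, sigma_km: float) -> float:
    """Inverse of :func:`selection_coefficient`: w = 2 sigma / sqrt(s*)."""
    if s_star <= 0 or sigma_km <= 0:
        raise ValueError("s* and sigma must be positive")
    return 2.0 * sigma_km / np.sqrt(s_star)


def calibrate_sigma(width_km: float, s_star: float) -> float:
    """Dispersal sigma consistent with a (width, s*) pair: sigma = w sqrt(s*) / 2."""
    if width_km <= 0 or s_star <= 0:
        raise ValueError("width and s* must be positive")
    return width_km * np.sqrt(s_star) / 2.0


# ---------------------------------------------------------------------------
# building transect series


def build_transect_series(
    table,
    localities: LocalityTable | dict[str, float],
    origin_rule: str = "northernmost",
    kind: str = "nuclear",
) -> TransectSeries:
    """Assemble a binomial transect series from per-deme summaries.

    ``table`` is a DataFrame with a ``locality`` column plus, for
    ``kind="nuclear"``, ``mean_q`` (mean admixture proportion) and ``n``
    (diploid individuals): the effective allele counts are
    ``k = round(mean_q * 2n)`` (round-half-even) out of ``N = 2n``.  For
    ``kind="mtdna"`` the columns are ``focal_count`` and ``total``.
    ``localities`` may be a LocalityTable (distances computed from the
    origin rule) or a precomputed {locality: km} map.
    """
    if isinstance(localities, LocalityTable):
        dist = transect_distances(localities, origin_rule)
    else:
        dist = dict(localities)
    xs, ks, ns, labels = [], [], [], []
    for row in table.itertuples(index=False):
        loc = str(row.locality)
        if loc not in dist:
            warnings.warn(f"locality {loc!r} not on transect; dropped", stacklevel=2)
            continue
        if kind == "nuclear":
            n_ind = int(row.n)
            if n_ind == 0:
                warnings.warn(f"locality {loc!r} has n=0; dropped", stacklevel=2)
                continue
            total = 2 * n_ind
            # round-half-even, matching numpy's convention
            k = float(np.round(float(row.mean_q) * total))
        elif kind == "mtdna":
            total = int(row.total)
            if total == 0:
                warnings.warn(f"locality {loc!r} has no typed individuals; dropped", stacklevel=2)
                continue
            k = float(row.focal_count)
        else:
            raise ValueError(f"unknown series kind {kind!r}")
        xs.append(dist[loc])
        ks.append(k)
        ns.append(float(total))
        labels.append(loc)
    if not xs:
        raise ValueError("no usable demes for transect series")
    order = np.argsort(xs)
    return TransectSeries(
        x=np.asarray(xs)[order],
        k=np.asarray(ks)[order],
        n=np.asarray(ns)[order],
        labels=[labels[i] for i in order],
    )
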