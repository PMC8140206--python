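"""Maximum-likelihood inference of the distribution of fitness effects (DFE).

The model is a Poisson Random Field over two unfolded site frequency spectra:
a putatively neutral reference (e.g. 4-fold degenerate sites) and a focal,
potentially selected class.  Selected mutations carry a population-scaled
selection coefficient gamma = 4*Ne*s whose magnitude is gamma-distributed
(all selected mutations deleterious; "reflected" gamma).  Both spectra share
a vector r of per-frequency-class distortion multipliers that absorbs
demography and other shared nuisances (Eyre-Walker, Woolfit & Phelps 2006
style correction), and each spectrum has its own mutation-rate scale theta
and ancestral-state misidentification (polarization error) rate epsilon.

Expected counts at derived-allele frequency i of n sampled chromosomes:

    neutral:   e_i = theta_n * r_i / i
    selected:  e_i = theta_s * r_i * Integral f_Gamma(g; a, b) H(i; n, -g) dg

followed in both cases by polarization mixing
e_i' = (1 - eps) e_i + eps e_{n-i}.  H is the standard PRF sampling
integral (Wright's stationary density of a selected allele, binomially
sampled); see :func:`sojourn_kernel`.  The observed counts x_i are modelled
as independent Poisson with these means, and the log-likelihood
sum(x_i log e_i - e_i) (constants dropped) is maximized by bounded
quasi-Newton over log/logit-transformed parameters from multiple seeded
starting points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import integrate, optimize, special, stats
from scipy.interpolate import CubicSpline

__all__ = [
    "DFEModel",
    "DFEFit",
    "DFEFitError",
    "sojourn_kernel",
    "expected_sfs_neutral",
    "expected_sfs_selected",
    "fit_dfe",
    "bin_dfe",
    "BIN_EDGES",
]

# gamma = 4*Ne*s magnitude boundaries of the conventional selective bins:
# effectively neutral / weakly deleterious / deleterious / strongly deleterious
BIN_EDGES = (1.0, 10.0, 100.0)

_S_EPS = 1e-8  # |S| below this uses the analytic neutral limit

# gamma-magnitude grid on which the sojourn kernel is tabulated per n
_GRID_LO = 1e-6
_GRID_HI = 1e6
_GRID_PER_DECADE = 16

_NODES_PER_DECADE = 10  # composite Gauss-Legendre nodes per gamma decade


class DFEFitError(RuntimeError):
    """Raised when no optimization start converges to a finite optimum."""


@dataclass
class DFEModel:
    """Parameters of the paired neutral/selected PRF model.

    theta_n, theta_s : per-class scaled mutation rates (4*Ne*mu summed over
        sites of the class), >= 0.
    shape, scale : gamma parameters (a, b) of the deleterious-effect
        magnitude gamma = -4*Ne*s, both > 0.
    eps_n, eps_s : polarization error rates in [0, 0.5].
    r : frequency-class distortion multipliers, length n-1, r[0] == 1
        (identifiability anchor).  ``None`` means no distortion.
    """

    theta_n: float
    theta_s: float
    shape: float
    scale: float
    eps_n: float = 0.0
    eps_s: float = 0.0
    r: np.ndarray | None = None

    def validate(self, n: int | None = None) -> None:
        if not (self.theta_n >= 0 and self.theta_s >= 0):
            raise ValueError("theta must be >= 0")
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError("gamma shape and scale must be > 0")
        for e in (self.eps_n, self.eps_s):
            if not (0.0 <= e <= 0.5):
                raise ValueError("epsilon must lie in [0, 0.5]")
        if self.r is not None:
            r = np.asarray(self.r, dtype=float)
            if np.any(~np.isfinite(r)) or np.any(r <= 0):
                raise ValueError("r must be finite and > 0")
            if abs(r[0] - 1.0) > 1e-12:
                raise ValueError("r[0] must equal 1 (anchor)")
            if n is not None and len(r) != n - 1:
                raise ValueError("r must have length n - 1")

    def distortion(self, n: int) -> np.ndarray:
        if self.r is None:
            return np.ones(n - 1)
        return np.asarray(self.r, dtype=float)


@dataclass
class DFEFit:
    """Result of :func:`fit_dfe`."""

    model: DFEModel
    loglik: float
    bins: np.ndarray  # P(neutral), P(weak), P(del), P(strong)
    converged: bool
    n_starts: int
    start_logliks: np.ndarray = field(default_factory=lambda: np.array([]))
    grad_norm: float = np.nan

    def as_dict(self) -> dict:
        m = self.model
        return {
            "theta_n": m.theta_n,
            "theta_s": m.theta_s,
            "shape": m.shape,
            "scale": m.scale,
            "eps_n": m.eps_n,
            "eps_s": m.eps_s,
            "loglik": self.loglik,
            "p_neutral": self.bins[0],
            "p_weak": self.bins[1],
            "p_del": self.bins[2],
            "p_strong": self.bins[3],
            "converged": self.converged,
            "n_starts": self.n_starts,
        }


def _log_expm1(y: np.ndarray) -> np.ndarray:
    """log(exp(y) - 1) for y > 0, stable for large y."""
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    small = y < 30.0
    out[small] = np.log(np.expm1(y[small]))
    out[~small] = y[~small]  # log(e^y - 1) ~ y
    return out


def _selection_ratio(x: np.ndarray, S: float) -> np.ndarray:
    """(1 - exp(-S (1 - x))) / (1 - exp(-S)), stable over the full S range."""
    x = np.asarray(x, dtype=float)
    if abs(S) < _S_EPS:
        return 1.0 - x
    if S < 0:
        # both numerator and denominator are expm1 of positive arguments
        return np.exp(_log_expm1(-S * (1.0 - x)) - _log_expm1(-S))
    # S > 0: exponents are negative, no overflow
    return np.expm1(-S * (1.0 - x)) / np.expm1(-S)


def sojourn_kernel(i: int, n: int, S: float) -> float:
    """Expected relative PRF density H(i; n, S) at derived count i.

    H = Integral_0^1 C(n,i) x^i (1-x)^{n-i}
        (1 - e^{-S(1-x)}) / ((1 - e^{-S}) x (1-x)) dx

    with signed scaled coefficient S = 4*Ne*s.  At S -> 0 this reduces to
    the Watterson expectation 1/i (returned analytically for |S| < 1e-8).
    Evaluated by adaptive quadrature; stable for |S| up to ~1e8 via a
    log-space form of the selection ratio.
    """
    if not (1 <= i <= n - 1):
        raise ValueError("frequency class i must satisfy 1 <= i <= n-1")
    if abs(S) < _S_EPS:
        return 1.0 / i
    log_c = special.gammaln(n + 1) - special.gammaln(i + 1) - special.gammaln(n - i + 1)

    def f(x: float) -> float:
        if x <= 0.0 or x >= 1.0:
            return 0.0
        lw = log_c + (i - 1) * np.log(x) + (n - i - 1) * np.log1p(-x)
        return float(np.exp(lw) * _selection_ratio(np.array(x), S))

    pts = None
    if S < -50.0:
        # integrand concentrates near x ~ 1/|S|
        pts = sorted({min(1.0 - 1e-12, k / abs(S)) for k in (1.0, 5.0, 20.0)})
    val, _ = integrate.quad(f, 0.0, 1.0, epsabs=1e-12, epsrel=1e-10, limit=400, points=pts)
    return val


@lru_cache(maxsize=8)
def _kernel_table(n: int):
    """Tabulate H(i; n, -gamma) on a log-spaced gamma grid, spline in log(gamma).

    Below the grid H == 1/i to within the grid tolerance; above it the
    strong-selection asymptote H ~ C(n,i) (i-1)! / gamma^i applies.
    """
    decades = int(np.log10(_GRID_HI / _GRID_LO))
    gam = np.logspace(np.log10(_GRID_LO), np.log10(_GRID_HI), decades * _GRID_PER_DECADE + 1)
    H = np.empty((n - 1, gam.size))
    for i in range(1, n):
        for k, g in enumerate(gam):
            H[i - 1, k] = sojourn_kernel(i, n, -g)
    spline = CubicSpline(np.log(gam), H, axis=1)
    iarr = np.arange(1, n)
    log_tail_coef = (
        special.gammaln(n + 1)
        - special.gammaln(iarr + 1)
        - special.gammaln(n - iarr + 1)
        + special.gammaln(iarr)
    )
    return spline, log_tail_coef


@lru_cache(maxsize=8)
def _quadrature_nodes(n: int):
    """Fixed composite Gauss-Legendre nodes in log(gamma) over the kernel grid.

    The kernel values at the nodes are precomputed once per n, so each
    likelihood evaluation only needs the gamma density at fixed nodes and
    one matrix-vector product.
    """
    spline, log_tail = _kernel_table(n)
    x, w = np.polynomial.legendre.leggauss(_NODES_PER_DECADE)
    decades = int(np.log10(_GRID_HI / _GRID_LO))
    log10_edges = np.arange(decades + 1) + np.log10(_GRID_LO)
    log_g, weights = [], []
    ln10 = np.log(10.0)
    for lo, hi in zip(log10_edges[:-1], log10_edges[1:]):
        mid, half = 0.5 * (lo + hi) * ln10, 0.5 * (hi - lo) * ln10
        log_g.append(mid + half * x)
        weights.append(half * w)
    log_g = np.concatenate(log_g)
    weights = np.concatenate(weights)
    H = spline(log_g)  # (n-1, J)
    iarr = np.arange(1, n)
    tail_at_max = np.exp(log_tail - iarr * np.log(_GRID_HI))
    return log_g, weights, H, 1.0 / iarr, tail_at_max


def _dfe_integrals(shape: float, scale: float, n: int) -> np.ndarray:
    """I_i = E_gamma[ H(i; n, -gamma) ] for i = 1..n-1 (fast cached path).

    Composite Gauss-Legendre in log(gamma) over [1e-6, 1e6] with analytic
    corrections beyond the grid: H == 1/i below (neutral limit) and the
    strong-selection asymptote above.
    """
    log_g, weights, H, h0, tail = _quadrature_nodes(n)
    # gamma density times gamma (the log-space Jacobian), in logs
    lf = (
        shape * log_g
        - np.exp(log_g) / scale
        - shape * np.log(scale)
        - special.gammaln(shape)
    )
    with np.errstate(under="ignore"):
        dens = np.exp(lf)
    out = H @ (weights * dens)
    mass_below = special.gammainc(shape, _GRID_LO / scale)
    mass_above = special.gammaincc(shape, _GRID_HI / scale)
    return out + mass_below * h0 + mass_above * tail


def _mix_polarization(e: np.ndarray, eps: float) -> np.ndarray:
    """Misidentification mixing: e_i' = (1 - eps) e_i + eps e_{n-i}."""
    return (1.0 - eps) * e + eps * e[::-1]


def expected_sfs_neutral(model: DFEModel, n: int) -> np.ndarray:
    """Expected neutral SFS counts e_1..e_{n-1} including distortion and mixing."""
    model.validate(n)
    iarr = np.arange(1, n)
    e = model.theta_n * model.distortion(n) / iarr
    return _mix_polarization(e, model.eps_n)


def expected_sfs_selected(model: DFEModel, n: int, method: str = "grid") -> np.ndarray:
    """Expected selected SFS counts under the reflected-gamma DFE.

    method="grid" (default) uses the cached sojourn-kernel table with
    probability-space Gauss-Legendre quadrature over the gamma distribution
    (validated against the direct path to <1e-6 relative).  method="quad"
    evaluates the nested adaptive quadrature directly; slow but reference.
    """
    model.validate(n)
    a, b = model.shape, model.scale
    if method == "grid":
        integrals = _dfe_integrals(a, b, n)
    elif method == "quad":
        integrals = np.array(
            [
                _dfe_integral_quad(i, n, a, b)
                for i in range(1, n)
            ]
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    e = model.theta_s * model.distortion(n) * integrals
    return _mix_polarization(e, model.eps_s)


def _dfe_integral_quad(i: int, n: int, shape: float, scale: float) -> float:
    """Reference adaptive quadrature of E_gamma[H(i; n, -gamma)]."""

    def f(g: float) -> float:
        return stats.gamma.pdf(g, shape, scale=scale) * sojourn_kernel(i, n, -g)

    mid = shape * scale
    parts = [(0.0, mid), (mid, np.inf)]
    total = 0.0
    for lo, hi in parts:
        v, _ = integrate.quad(f, lo, hi, epsabs=1e-12, epsrel=1e-7, limit=400)
        total += v
    return total


def bin_dfe(shape: float, scale: float, edges: tuple = BIN_EDGES) -> np.ndarray:
    """Proportions of mutations in the conventional gamma-magnitude bins.

    Returns (F(1), F(10)-F(1), F(100)-F(10), 1-F(100)) for the
    Gamma(shape, scale) distribution of gamma = 4*Ne*s magnitudes.
    """
    if not (shape > 0 and scale > 0):
        raise ValueError("shape and scale must be > 0")
    cdf = stats.gamma.cdf(np.asarray(edges, dtype=float), shape, scale=scale)
    return np.diff(np.concatenate([[0.0], cdf, [1.0]]))


# ---------------------------------------------------------------------------
# fitting

_LOG_THETA_BOUNDS = (np.log(1e-8), np.log(1e12))
_LOG_SHAPE_BOUNDS = (np.log(1e-3), np.log(1e3))
_LOG_SCALE_BOUNDS = (np.log(1e-6), np.log(1e8))
_EPS_RAW_BOUNDS = (-20.0, 20.0)
_LOG_R_BOUNDS = (-8.0, 8.0)


def _unpack(params: np.ndarray, n: int):
    theta_n, theta_s, shape, scale = np.exp(params[:4])
    eps_n = 0.5 * special.expit(params[4])
    eps_s = 0.5 * special.expit(params[5])
    r = np.concatenate([[1.0], np.exp(params[6:])])
    assert r.size == n - 1
    return theta_n, theta_s, shape, scale, eps_n, eps_s, r


def _neg_loglik(params: np.ndarray, xn: np.ndarray, xs: np.ndarray, n: int) -> float:
    theta_n, theta_s, shape, scale, eps_n, eps_s, r = _unpack(params, n)
    iarr = np.arange(1, n)
    en = _mix_polarization(theta_n * r / iarr, eps_n)
    es = _mix_polarization(theta_s * r * _dfe_integrals(shape, scale, n), eps_s)
    en = np.maximum(en, 1e-300)
    es = np.maximum(es, 1e-300)
    ll = np.sum(xn * np.log(en) - en) + np.sum(xs * np.log(es) - es)
    if not np.isfinite(ll):
        return 1e300
    return -ll


def poisson_loglik(model: DFEModel, neutral_sfs, selected_sfs) -> float:
    """Joint Poisson log-likelihood (constants dropped) of the two spectra."""
    n = neutral_sfs.n
    en = np.maximum(expected_sfs_neutral(model, n), 1e-300)
    es = np.maximum(expected_sfs_selected(model, n), 1e-300)
    return float(
        np.sum(neutral_sfs.x * np.log(en) - en)
        + np.sum(selected_sfs.x * np.log(es) - es)
    )


def _initial_points(xn: np.ndarray, xs: np.ndarray, n: int, n_starts: int, rng) -> list:
    """A moment-based start plus seeded dispersed perturbations."""
    iarr = np.arange(1, n)
    harmonic = np.sum(1.0 / iarr)
    theta_n0 = max(xn.sum() / harmonic, 1e-6)
    theta_s0 = max(xs.sum() / harmonic, 1e-6)
    # distortion guess from the neutral spectrum shape
    r0 = np.clip((xn + 0.5) * iarr / theta_n0, 1e-3, 1e3)
    r0 = r0 / r0[0]
    base = np.concatenate(
        [
            [np.log(theta_n0), np.log(theta_s0), np.log(0.5), np.log(100.0)],
            [special.logit(2 * 0.02), special.logit(2 * 0.02)],
            np.log(r0[1:]),
        ]
    )
    points = [base]
    for _ in range(n_starts - 1):
        p = base.copy()
        p[:2] += rng.normal(0.0, 0.3, size=2)
        p[2] = np.log(np.exp(rng.uniform(np.log(0.05), np.log(5.0))))
        p[3] = rng.uniform(np.log(0.5), np.log(5e3))
        p[4:6] = rng.normal(-4.0, 1.5, size=2)
        p[6:] += rng.normal(0.0, 0.2, size=p.size - 6)
        points.append(p)
    return points


def fit_dfe(neutral_sfs, selected_sfs, n_starts: int = 10, seed: int | None = None) -> DFEFit:
    """Jointly fit the paired neutral/selected PRF model by maximum likelihood.

    Parameters
    ----------
    neutral_sfs, selected_sfs : SFS
        Unfolded spectra sharing the same sample size n.
    n_starts : int
        Number of seeded optimization starts; the best optimum is returned.
    seed : int
        Seeds the dispersion of starting points.

    Raises
    ------
    DFEFitError
        If no start reaches a finite optimum.
    """
    if neutral_sfs.n != selected_sfs.n:
        raise ValueError("neutral and selected SFS must share the sample size n")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    n = neutral_sfs.n
    xn = np.asarray(neutral_sfs.x, dtype=float)
    xs = np.asarray(selected_sfs.x, dtype=float)
    rng = np.random.default_rng(seed)

    bounds = (
        [_LOG_THETA_BOUNDS] * 2
        + [_LOG_SHAPE_BOUNDS, _LOG_SCALE_BOUNDS]
        + [_EPS_RAW_BOUNDS] * 2
        + [_LOG_R_BOUNDS] * (n - 2)
    )
    best = None
    logliks = []
    for x0 in _initial_points(xn, xs, n, n_starts, rng):
        res = optimize.minimize(
            _neg_loglik,
            x0,
            args=(xn, xs, n),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        ll = -res.fun
        logliks.append(ll)
        if np.isfinite(ll) and (best is None or ll > -best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise DFEFitError("no optimization start converged to a finite optimum")

    theta_n, theta_s, shape, scale, eps_n, eps_s, r = _unpack(best.x, n)
    model = DFEModel(theta_n, theta_s, shape, scale, eps_n, eps_s, r)
    return DFEFit(
        model=model,
        loglik=-best.fun,
        bins=bin_dfe(shape, scale),
        converged=bool(best.success),
        n_starts=n_starts,
        start_logliks=np.array(logliks),
        grad_norm=float(np.max(np.abs(best.jac))) if best.jac is not None else np.nan,
    )
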