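"""K80 divergence, the salmon-branch extraction, and the alpha estimator.

alpha — the proportion of substitutions on the focal branch fixed by
positive selection — is estimated from the focal-category divergence d_N,
the neutral (4-fold) divergence d_S, and the DFE-averaged relative fixation
probability of deleterious mutations mu_minus:

    alpha = (d_N - d_S * mu_minus) / d_N

mu_minus integrates Kimura's relative fixation probability of a deleterious
mutation, gamma / (e^gamma - 1), over the fitted Gamma(a, b) distribution
of gamma = 4*Ne*s magnitudes; it tends to 1 in the neutral limit and 0
under strong selection, so alpha reduces to the classic (d_N - d_S)/d_N
when all segregating deleterious mutations are effectively neutral.
Slightly negative alpha indicates no evidence of positive selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

__all__ = [
    "DivergenceSet",
    "AlphaEstimate",
    "K80SaturationError",
    "k80_distance",
    "salmon_branch_divergence",
    "mu_minus",
    "alpha",
]

logger = logging.getLogger(__name__)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = {"A", "C", "G", "T"}


class K80SaturationError(ValueError):
    """Raised when observed divergence exceeds the K80 correctable range."""


@dataclass
class DivergenceSet:
    """Pairwise K80 distances among salmon/trout/charr plus branch estimates."""

    d_salmon_trout: float
    d_salmon_charr: float
    d_trout_charr: float
    category: str = ""

    @property
    def salmon_branch(self) -> float:
        return salmon_branch_divergence(
            self.d_salmon_trout, self.d_salmon_charr, self.d_trout_charr
        )


@dataclass
class AlphaEstimate:
    alpha: float
    mu_minus: float
    d_n: float
    d_s: float
    category: str = ""


def k80_distance(seq_a: str, seq_b: str) -> float:
    """Kimura (1980) two-parameter distance between aligned sequences.

    Sites where either sequence carries a gap or ambiguity are excluded
    pairwise.  With P the transition and Q the transversion proportion:

        d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    valid_bases = np.frombuffer(b"ACGT", dtype="S1")
    ok = np.isin(a, valid_bases) & np.isin(b, valid_bases)
    if not ok.any():
        raise ValueError("no comparable sites after excluding gaps/ambiguity")
    a, b = a[ok], b[ok]
    diff = a != b
    n = a.size
    if not diff.any():
        return 0.0
    ts = sum(
        1
        for x, y in zip(a[diff].astype("U1"), b[diff].astype("U1"))
        if (x, y) in _TRANSITIONS
    )
    tv = int(diff.sum()) - ts
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise K80SaturationError(f"saturated divergence (P={P:.4f}, Q={Q:.4f})")
    return float(-0.5 * np.log(w1) - 0.25 * np.log(w2))


def salmon_branch_divergence(
    d_salmon_trout: float,
    d_salmon_charr: float,
    d_trout_charr: float,
    tol: float = 1e-6,
) -> float:
    """Focal-branch length by the three-point formula, floored at 0.

    branch = (d(salmon,trout) + d(salmon,charr) - d(trout,charr)) / 2.
    Strong non-additivity (a negative value beyond ``tol``) is logged.
    """
    for d in (d_salmon_trout, d_salmon_charr, d_trout_charr):
        if d < 0:
            raise ValueError("distances must be non-negative")
    branch = 0.5 * (d_salmon_trout + d_salmon_charr - d_trout_charr)
    if branch < -tol:
        logger.warning("non-additive distances: three-point branch %.3g < 0", branch)
    return max(branch, 0.0)


def _kimura_relative_fixation(g: np.ndarray) -> np.ndarray:
    """gamma / (e^gamma - 1): fixation probability relative to neutral."""
    g = np.asarray(g, dtype=float)
    out = np.empty_like(g)
    small = g < 1e-8
    out[small] = 1.0
    big = g > 700.0
    mid = ~small & ~big
    out[mid] = g[mid] / np.expm1(g[mid])
    # large gamma: g e^-g / (1 - e^-g) ~ g e^-g, underflows harmlessly to 0
    with np.errstate(under="ignore"):
        out[big] = g[big] * np.exp(-g[big])
    return out


def mu_minus(shape: float, scale: float) -> float:
    """DFE-averaged fixation probability of deleterious mutations.

    mu_minus = Integral_0^inf f_Gamma(g; shape, scale) g / (e^g - 1) dg,
    in (0, 1]; the integrand is taken as 1 at g -> 0.  Adaptive quadrature
    split at the distribution mean for robustness at small shapes.
    """
    if not (shape > 0 and scale > 0):
        raise ValueError("shape and scale must be > 0")

    # substitute t = gamma / scale so the density peak is always at O(1)
    def f(t: float) -> float:
        return stats.gamma.pdf(t, shape) * float(
            _kimura_relative_fixation(np.array([t * scale]))[0]
        )

    mid = max(shape, 1.0)
    total = 0.0
    for lo, hi in ((0.0, mid), (mid, np.inf)):
        v, _ = integrate.quad(f, lo, hi, epsabs=1e-12, epsrel=1e-9, limit=500)
        total += v
    return float(min(total, 1.0))


def alpha(d_n: float, d_s: float, mu: float) -> float:
    """Proportion of focal-branch substitutions fixed by positive selection.

    May be negative; d_N = 0 is undefined and raises.
    """
    if d_n <= 0:
        raise ValueError("alpha undefined for d_N <= 0")
    if d_s < 0:
        raise ValueError("d_S must be >= 0")
    if not (0 < mu <= 1):
        raise ValueError("mu_minus must lie in (0, 1]")
    return (d_n - d_s * mu) / d_n
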