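"""Euler decomposition of polygenic overlap and the maximum-entropy baseline.

The stepwise fit yields univariate polygenicities (pi_i^u), bivariate shared
polygenicities (pi_ij^b) and the triple overlap (pi_123).  These reconstruct
the seven disjoint Euler components

    pi_ij  = pi_ij^b - pi_123
    pi_i   = pi_i^u - pi_ij - pi_ik - pi_123

The triple overlap is constrained to an interval by the lower-order
quantities; with no further information, the "naive" expectation picks the
value in that interval that maximizes the entropy of the seven-component
pattern — the reference against which the fitted pattern is judged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import pearsonr

from .params import COMPONENT_NAMES

_CLIP = 1e-10  # negative components within numerical noise are clipped to 0


class InfeasibleOverlapError(ValueError):
    """Raised when pi_u / pi_b / pi_123 cannot form a valid pattern."""


@dataclass(frozen=True)
class Pi123Bounds:
    """Feasible interval for the triple overlap."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= self.hi):
            raise InfeasibleOverlapError(
                f"invalid bounds [{self.lo:.6g}, {self.hi:.6g}]")

    def clip(self, x: float) -> float:
        return float(min(max(x, self.lo), self.hi))


@dataclass(frozen=True)
class OverlapPattern:
    """Seven disjoint Euler components, as proportions of panel variants."""

    pi7: np.ndarray
    source: str = "fitted"  # fitted | naive | truth

    def __post_init__(self) -> None:
        arr = np.asarray(self.pi7, dtype=float)
        if arr.shape != (7,):
            raise InfeasibleOverlapError("pi7 must have 7 components")
        neg = arr < 0
        if np.any(arr < -_CLIP):
            raise InfeasibleOverlapError(
                f"negative component(s): {dict(zip(COMPONENT_NAMES, arr))}")
        arr = np.where(neg, 0.0, arr)
        object.__setattr__(self, "pi7", arr)

    @property
    def union(self) -> float:
        return float(self.pi7.sum())

    @property
    def pi123(self) -> float:
        return float(self.pi7[6])

    def pi_univariate(self) -> np.ndarray:
        p = self.pi7
        return np.array([p[0] + p[3] + p[4] + p[6],
                         p[1] + p[3] + p[5] + p[6],
                         p[2] + p[4] + p[5] + p[6]])

    def pi_bivariate(self) -> np.ndarray:
        p = self.pi7
        return np.array([p[3] + p[6], p[4] + p[6], p[5] + p[6]])

    def as_dict(self) -> dict:
        return {
            "pi7": dict(zip(COMPONENT_NAMES, self.pi7.tolist())),
            "union": self.union,
            "percentages": dict(zip(COMPONENT_NAMES,
                                    euler_percentages(self)[0].tolist())),
            "source": self.source,
        }


def pi123_bounds(pi_u, pi_b) -> Pi123Bounds:
    """Feasible interval for pi_123 given univariate and bivariate totals.

    lo = max(0, pi_12^b + pi_13^b - pi_1^u, ...), hi = min(pi_ij^b).
    """
    pi_u = np.asarray(pi_u, dtype=float)
    pi_b = np.asarray(pi_b, dtype=float)
    lo = max(0.0,
             pi_b[0] + pi_b[1] - pi_u[0],
             pi_b[0] + pi_b[2] - pi_u[1],
             pi_b[1] + pi_b[2] - pi_u[2])
    hi = float(pi_b.min())
    if lo > hi + _CLIP:
        raise InfeasibleOverlapError(
            f"pi123 bounds empty: lo={lo:.6g} > hi={hi:.6g} "
            f"(pi_u={pi_u.tolist()}, pi_b={pi_b.tolist()})")
    return Pi123Bounds(lo=lo, hi=max(lo, hi))


def decompose(pi_u, pi_b, pi123: float, source: str = "fitted") -> OverlapPattern:
    """Build the seven disjoint components from (pi_u, pi_b, pi_123)."""
    pi_u = np.asarray(pi_u, dtype=float)
    pi_b = np.asarray(pi_b, dtype=float)
    pair = pi_b - pi123
    spec = np.array([
        pi_u[0] - pair[0] - pair[1] - pi123,
        pi_u[1] - pair[0] - pair[2] - pi123,
        pi_u[2] - pair[1] - pair[2] - pi123,
    ])
    return OverlapPattern(pi7=np.concatenate([spec, pair, [pi123]]),
                          source=source)


def entropy(pattern: OverlapPattern) -> float:
    """Shannon entropy -sum p*ln(p) of the raw seven components (0 ln 0 = 0)."""
    p = pattern.pi7
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def normalized_entropy(pattern: OverlapPattern) -> float:
    """Entropy of the union-normalized seven-component distribution.

    Equals entropy(pattern)/U + ln U for union U.  This is the objective the
    naive baseline maximizes: the raw-proportion entropy is maximized at a
    *larger* triple overlap than the balanced pattern, because increasing
    pi_123 raises the union itself, whereas the balanced (all-components-
    equal) pattern — the configuration the maximum-entropy argument is meant
    to single out — is the argmax only after normalization.
    """
    u = pattern.union
    if u <= 0:
        return 0.0
    return entropy(pattern) / u + np.log(u)


def _entropy_at(pi_u: np.ndarray, pi_b: np.ndarray, x: float) -> float:
    return normalized_entropy(decompose(pi_u, pi_b, x, source="naive"))


def naive_max_entropy(pi_u, pi_b) -> OverlapPattern:
    """Maximum-entropy pattern over the feasible pi_123 interval.

    Maximizes the entropy of the union-normalized seven-component
    distribution (see ``normalized_entropy``); a coarse grid pre-scan
    brackets the maximum and bounded refinement locates it.
    """
    pi_u = np.asarray(pi_u, dtype=float)
    pi_b = np.asarray(pi_b, dtype=float)
    b = pi123_bounds(pi_u, pi_b)
    if b.hi - b.lo < 1e-14:
        return decompose(pi_u, pi_b, b.lo, source="naive")
    xs = np.linspace(b.lo, b.hi, 33)
    hs = np.array([_entropy_at(pi_u, pi_b, x) for x in xs])
    k = int(np.argmax(hs))
    lo = xs[max(k - 1, 0)]
    hi = xs[min(k + 1, xs.size - 1)]
    res = minimize_scalar(lambda x: -_entropy_at(pi_u, pi_b, x),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": max((b.hi - b.lo) * 1e-9, 1e-15)})
    best = b.clip(float(res.x))
    if _entropy_at(pi_u, pi_b, best) < hs[k]:
        best = float(xs[k])
    return decompose(pi_u, pi_b, best, source="naive")


def euler_percentages(pattern: OverlapPattern) -> tuple[np.ndarray, np.ndarray]:
    """Components as percentages of the union (full precision, and rounded).

    This is the convention of area-proportional Euler diagrams: each of the
    seven regions as a share of the combined total area.
    """
    if pattern.union <= 0:
        raise InfeasibleOverlapError("union must be positive")
    pct = 100.0 * pattern.pi7 / pattern.union
    return pct, np.rint(pct).astype(int)


def param_vector_correlation(a, b) -> float:
    """Pearson correlation between two polygenicity-parameter vectors.

    Used to compare runs across LD reference panels: the vector is
    (pi_1^u, pi_2^u, pi_3^u, pi_12^b, pi_13^b, pi_23^b, pi_123).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined: zero variance input")
    return float(pearsonr(a, b).statistic)
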