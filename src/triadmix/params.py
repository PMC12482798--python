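"""Parameters of the trivariate causal mixture model.

The joint distribution of direct (per-allele, standardized-genotype) effects of
one variant on three phenotypes is a zero-mean mixture of eight multivariate
normal components: a null component and one component for every non-empty
subset ``S`` of the three traits.  A variant in component ``S`` affects exactly
the traits in ``S``; its effects on those traits have per-trait variances
``sigma_i**2`` (the same for every component the trait belongs to) and
pairwise correlations ``rho_ij`` inside shared components.  Nineteen scalars
describe the model: seven mixture proportions, three effect-size SDs, three
residual SDs and three-plus-three correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# Canonical order of the seven causal components, and of the full 8-component
# mixture (null first).  Tuples list the traits (0-based) each component hits.
COMPONENTS: tuple[tuple[int, ...], ...] = (
    (0,), (1,), (2,), (0, 1), (0, 2), (1, 2), (0, 1, 2),
)
COMPONENT_NAMES: tuple[str, ...] = ("1", "2", "3", "12", "13", "23", "123")
PAIRS: tuple[tuple[int, int], ...] = ((0, 1), (0, 2), (1, 2))


class ParameterError(ValueError):
    """Raised for parameter vectors outside the model's domain."""


@dataclass(frozen=True)
class MixtureParams:
    """The 19 parameters of the eight-component trivariate mixture.

    Parameters
    ----------
    pi : array-like, shape (7,)
        Mixture proportions (pi_1, pi_2, pi_3, pi_12, pi_13, pi_23, pi_123)
        of the seven causal components; pi_0 = 1 - sum(pi).
    sigma : array-like, shape (3,)
        Per-trait effect-size SDs among causal variants (discoverability is
        sigma**2).
    sigma0 : array-like, shape (3,)
        Residual z-score SDs (1 under the pure null).
    rho : array-like, shape (3,)
        Effect-size correlations (rho_12, rho_13, rho_23) within shared
        components.
    rho0 : array-like, shape (3,)
        Residual correlations (e.g. from sample overlap), same pair order.
    """

    pi: np.ndarray
    sigma: np.ndarray
    sigma0: np.ndarray
    rho: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rho0: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        for name, n in (("pi", 7), ("sigma", 3), ("sigma0", 3),
                        ("rho", 3), ("rho0", 3)):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ParameterError(f"{name} must have shape ({n},)")
            object.__setattr__(self, name, arr)
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if np.any(self.pi < 0):
            raise ParameterError("mixture proportions must be non-negative")
        if self.pi.sum() > 1 + 1e-12:
            raise ParameterError("sum of mixture proportions exceeds 1")
        if np.any(self.sigma <= 0) or np.any(self.sigma0 <= 0):
            raise ParameterError("sigma and sigma0 must be positive")
        if np.any(np.abs(self.rho) >= 1) or np.any(np.abs(self.rho0) >= 1):
            raise ParameterError("correlations must lie in (-1, 1)")
        for mat, label in ((self.sigma_full(), "effect"),
                           (self.sigma0_matrix(), "residual")):
            if np.linalg.eigvalsh(mat).min() < -1e-10:
                raise ParameterError(
                    f"{label} covariance matrix is not positive semi-definite")

    # -- covariance builders ---------------------------------------------

    @property
    def pi0(self) -> float:
        return float(max(0.0, 1.0 - self.pi.sum()))

    def _rho_lookup(self, i: int, j: int) -> float:
        a, b = min(i, j), max(i, j)
        return float(self.rho[PAIRS.index((a, b))])

    def sigma_full(self) -> np.ndarray:
        """Covariance of the all-traits component (Sigma_123)."""
        s = self.sigma
        m = np.diag(s ** 2).astype(float)
        for k, (i, j) in enumerate(PAIRS):
            m[i, j] = m[j, i] = self.rho[k] * s[i] * s[j]
        return m

    def component_cov(self, comp: tuple[int, ...]) -> np.ndarray:
        """3x3 covariance of one causal component (zeros off its traits)."""
        full = self.sigma_full()
        m = np.zeros((3, 3))
        idx = np.array(comp)
        m[np.ix_(idx, idx)] = full[np.ix_(idx, idx)]
        return m

    def sigma0_matrix(self) -> np.ndarray:
        """Residual covariance Sigma_0 of the z-score noise term."""
        s = self.sigma0
        m = np.diag(s ** 2).astype(float)
        for k, (i, j) in enumerate(PAIRS):
            m[i, j] = m[j, i] = self.rho0[k] * s[i] * s[j]
        return m

    # -- marginalization over traits -------------------------------------

    def collapse(self, active: tuple[int, ...]) -> tuple[np.ndarray, list[np.ndarray]]:
        """Marginalize the 8-component mixture onto a subset of traits.

        Components whose restriction to ``active`` coincide are merged:
        e.g. for traits (0, 1) the pair component and the triple component
        share the same restricted covariance, so their proportions add.

        Returns
        -------
        weights : ndarray
            Mixture proportions of the collapsed components; the first entry
            is the effective null proportion.
        covs : list of ndarray
            Restricted covariance (len(active) x len(active)) per collapsed
            component, a zero matrix for the null entry.
        """
        active = tuple(sorted(active))
        d = len(active)
        if d == 0 or any(t not in (0, 1, 2) for t in active):
            raise ParameterError("active traits must be a subset of {0,1,2}")
        groups: dict[tuple[int, ...], float] = {}
        for comp, p in zip(COMPONENTS, self.pi):
            key = tuple(t for t in comp if t in active)
            groups[key] = groups.get(key, 0.0) + float(p)
        null_w = self.pi0 + groups.pop((), 0.0)
        weights = [null_w]
        covs = [np.zeros((d, d))]
        full = self.sigma_full()
        pos = {t: k for k, t in enumerate(active)}
        for key in sorted(groups, key=lambda k: (len(k), k)):
            weights.append(groups[key])
            m = np.zeros((d, d))
            idx_full = np.array(key, dtype=int)
            idx_loc = np.array([pos[t] for t in key], dtype=int)
            m[np.ix_(idx_loc, idx_loc)] = full[np.ix_(idx_full, idx_full)]
            covs.append(m)
        return np.array(weights), covs

    def sigma0_sub(self, active: tuple[int, ...]) -> np.ndarray:
        idx = np.array(sorted(active), dtype=int)
        return self.sigma0_matrix()[np.ix_(idx, idx)]

    # -- convenience ------------------------------------------------------

    def pi_univariate(self) -> np.ndarray:
        """Per-trait total causal proportions (pi_i^u)."""
        out = np.zeros(3)
        for comp, p in zip(COMPONENTS, self.pi):
            for t in comp:
                out[t] += p
        return out

    def pi_bivariate(self) -> np.ndarray:
        """Per-pair total shared proportions (pi_ij^b = pi_ij + pi_123)."""
        out = np.zeros(3)
        for comp, p in zip(COMPONENTS, self.pi):
            for k, (i, j) in enumerate(PAIRS):
                if i in comp and j in comp:
                    out[k] += p
        return out

    def replace(self, **kw) -> "MixtureParams":
        return replace(self, **kw)
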