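"""Mixture likelihood of GWAS z-scores: characteristic function, densities.

A tag variant's observed z-score triple is the LD-weighted sum of the direct
effects of its neighbors plus correlated residual noise.  Because every
mixture component is a zero-mean Gaussian, the characteristic function of the
z triple factorizes over neighbors, and the density follows by numerical
inversion (trapezoidal rule on a fixed grid).  ``pdf_exact`` enumerates the
finite mixture directly and serves as an independent oracle for the inversion
path on small neighborhoods.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .grid import GridSpec
from .params import MixtureParams, ParameterError

DENSITY_FLOOR = 1e-300


class FeasibilityError(ValueError):
    """Raised when exact mixture enumeration would be intractably large."""


@dataclass(frozen=True)
class TraitSubset:
    """Non-empty subset of the three traits a likelihood is computed over."""

    active: tuple[int, ...]

    def __post_init__(self) -> None:
        act = tuple(sorted(set(self.active)))
        if not act or any(t not in (0, 1, 2) for t in act):
            raise ParameterError("active traits must be a non-empty subset of {0,1,2}")
        object.__setattr__(self, "active", act)

    @property
    def d(self) -> int:
        return len(self.active)


@dataclass
class VariantContext:
    """LD neighborhood and sample sizes of one tag variant.

    nbr_weights holds w_k = h_k * r2_jk for every neighbor k (self included);
    n holds the three per-trait GWAS sample sizes of the tag variant, which
    apply to all neighbors.
    """

    nbr_weights: np.ndarray
    n: np.ndarray
    z: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nbr_weights = np.asarray(self.nbr_weights, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.nbr_weights.ndim != 1 or self.nbr_weights.size == 0:
            raise ParameterError("nbr_weights must be a non-empty 1-D array")
        if np.any(self.nbr_weights <= 0):
            raise ParameterError("neighborhood weights must be positive")
        if self.n.shape != (3,) or np.any(self.n <= 0):
            raise ParameterError("n must hold three positive sample sizes")


def _scaled_covs(params: MixtureParams, ctx: VariantContext,
                 subset: TraitSubset) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Collapsed weights, N-scaled component covariances, residual cov."""
    weights, covs = params.collapse(subset.active)
    sqrt_n = np.sqrt(ctx.n[list(subset.active)])
    dn = np.outer(sqrt_n, sqrt_n)
    scaled = [c * dn for c in covs]
    s0 = params.sigma0_sub(subset.active)
    return weights, scaled, s0


def char_fn(t: np.ndarray, params: MixtureParams, ctx: VariantContext,
            subset: TraitSubset) -> float | np.ndarray:
    """Characteristic function phi(t) of the z-scores over the active traits.

    ``t`` may be a single d-vector or an array of shape (..., d).  phi is
    real-valued because every component is zero-mean symmetric.
    """
    t = np.asarray(t, dtype=float)
    d = subset.d
    if t.ndim == 0:
        t = t.reshape(1)
    single = t.shape == (d,)
    batch_shape = () if single else t.shape[:-1]
    tb = t.reshape(-1, d)
    weights, scaled, s0 = _scaled_covs(params, ctx, subset)
    q0 = np.einsum("bi,ij,bj->b", tb, s0, tb)
    out = np.exp(-0.5 * q0)
    qs = np.stack([np.einsum("bi,ij,bj->b", tb, c, tb) for c in scaled])  # (ncomp,b)
    for w in ctx.nbr_weights:
        out *= weights @ np.exp(-0.5 * w * qs)
    return float(out[0]) if single else out.reshape(batch_shape)


def _default_grid(params: MixtureParams, subset: TraitSubset,
                  zmax: np.ndarray | float, mode: str,
                  ctx: VariantContext | None = None) -> GridSpec:
    sigma0 = params.sigma0[list(subset.active)]
    sigma_z = None
    if ctx is not None:
        # conservative per-axis z SD: residual plus full causal LD load
        act = list(subset.active)
        wsum = float(ctx.nbr_weights.sum())
        sigma_z = np.sqrt(params.sigma0[act] ** 2
                          + ctx.n[act] * params.sigma[act] ** 2 * wsum)
    return GridSpec.for_model(sigma0, zmax, mode=mode, sigma_z=sigma_z)


def _env_grid(params: MixtureParams, subset: TraitSubset,
              axes: list[np.ndarray]) -> np.ndarray:
    """Residual-covariance factor exp(-t' S0 t / 2) on the tensor grid."""
    s0 = params.sigma0_sub(subset.active)
    d = subset.d
    if d == 1:
        return np.exp(-0.5 * s0[0, 0] * axes[0] ** 2)
    mesh = np.meshgrid(*axes, indexing="ij")
    q = np.zeros_like(mesh[0])
    for i in range(d):
        for j in range(d):
            q += s0[i, j] * mesh[i] * mesh[j]
    return np.exp(-0.5 * q)


def _kernel_inputs(params: MixtureParams, subset: TraitSubset,
                   n: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapsed proportions plus per-variant alpha/gamma coefficient arrays.

    n : (nvar, 3) per-trait sample sizes.  alpha_i = sigma_i^2 * N_i,
    gamma_ij = rho_ij * sigma_i * sigma_j * sqrt(N_i * N_j) over active axes.
    """
    act = list(subset.active)
    d = subset.d
    weights, covs = params.collapse(subset.active)
    nact = n[:, act]
    sig = params.sigma[act]
    alpha = (sig ** 2)[None, :] * nact
    full = params.sigma_full()[np.ix_(act, act)]
    pair_idx = list(itertools.combinations(range(d), 2))
    gamma = np.stack(
        [full[i, j] * np.sqrt(nact[:, i] * nact[:, j]) for i, j in pair_idx],
        axis=1) if pair_idx else np.zeros((n.shape[0], 0))
    return weights, alpha, gamma


def _image_correction(z: np.ndarray, n: np.ndarray, w_data: np.ndarray,
                      w_counts: np.ndarray, indptr: np.ndarray,
                      params: MixtureParams, subset: TraitSubset,
                      grid: GridSpec) -> np.ndarray:
    """First-order aliasing images of the trapezoidal inversion.

    A fixed-step trapezoidal sum returns the L-periodized density
    (L_i = 2*pi/dt_i per axis), so images of the density leak back into the
    evaluation window.  Narrow (null-like) components decay long before the
    period, but a single causal neighbor with a large N*sigma^2 load makes a
    wide Gaussian whose image is not negligible.  Those single-causal-neighbor
    terms dominate the leakage and have closed-form Gaussian densities; this
    returns their total mass at the 2*d nearest image points so the caller
    can subtract it.  Higher-order terms (two or more causal neighbors, corner
    images) are smaller by further factors of pi and distance.
    """
    act = list(subset.active)
    d = subset.d
    nvar = z.shape[0]
    weights, covs = params.collapse(subset.active)
    s0 = params.sigma0_sub(subset.active)
    L = 2.0 * np.pi / np.asarray(grid.steps)
    j_idx = np.repeat(np.arange(nvar), np.diff(indptr))
    nj = n[:, act][j_idx]
    zj = np.asarray(z)[:, act][j_idx]
    out = np.zeros(nvar)
    two_pi_d = (2.0 * np.pi) ** d
    for cidx in range(1, len(weights)):
        if weights[cidx] <= 0:
            continue
        base = covs[cidx]
        # cov_ab = s0_ab + w * base_ab * sqrt(n_a n_b); skip narrow bins whose
        # diagonal load cannot reach the image points
        diag = np.stack([s0[a, a] + w_data * base[a, a] * nj[:, a]
                         for a in range(d)], axis=1)  # (J,d)
        wide = diag.max(axis=1) > 1.0 + 1e-9
        if not wide.any():
            continue
        wd = w_data[wide]
        njw = nj[wide]
        zw = zj[wide]
        dg = [diag[wide, a] for a in range(d)]
        if d == 1:
            det = dg[0]
            inv = [[1.0 / dg[0]]]
        elif d == 2:
            c01 = s0[0, 1] + wd * base[0, 1] * np.sqrt(njw[:, 0] * njw[:, 1])
            det = dg[0] * dg[1] - c01 ** 2
            inv = [[dg[1] / det, -c01 / det], [None, dg[0] / det]]
        else:
            c01 = s0[0, 1] + wd * base[0, 1] * np.sqrt(njw[:, 0] * njw[:, 1])
            c02 = s0[0, 2] + wd * base[0, 2] * np.sqrt(njw[:, 0] * njw[:, 2])
            c12 = s0[1, 2] + wd * base[1, 2] * np.sqrt(njw[:, 1] * njw[:, 2])
            det = (dg[0] * (dg[1] * dg[2] - c12 ** 2)
                   - c01 * (c01 * dg[2] - c12 * c02)
                   + c02 * (c01 * c12 - dg[1] * c02))
            inv = [[(dg[1] * dg[2] - c12 ** 2) / det,
                    (c02 * c12 - c01 * dg[2]) / det,
                    (c01 * c12 - c02 * dg[1]) / det],
                   [None, (dg[0] * dg[2] - c02 ** 2) / det,
                    (c02 * c01 - c12 * dg[0]) / det],
                   [None, None, (dg[0] * dg[1] - c01 ** 2) / det]]
        norm = weights[cidx] * w_counts[wide] / np.sqrt(two_pi_d * det)
        contrib = np.zeros(zw.shape[0])
        for a in range(d):
            for sgn in (1.0, -1.0):
                dv = zw.copy()
                dv[:, a] -= sgn * L[a]
                q = np.zeros(zw.shape[0])
                for i in range(d):
                    q += inv[i][i] * dv[:, i] ** 2
                    for k in range(i + 1, d):
                        q += 2.0 * inv[i][k] * dv[:, i] * dv[:, k]
                near = q < 200.0
                if near.any():
                    contrib[near] += np.exp(-0.5 * q[near])
        np.add.at(out, j_idx[wide], norm * contrib)
    return out


def dens_cf_batch(z: np.ndarray, n: np.ndarray, w_data: np.ndarray,
                  indptr: np.ndarray, params: MixtureParams,
                  subset: TraitSubset, grid: GridSpec,
                  w_counts: np.ndarray | None = None,
                  alias_correct: bool = False) -> np.ndarray:
    """Inversion densities for a batch of variants (production path)."""
    act = list(subset.active)
    d = subset.d
    z = np.ascontiguousarray(np.asarray(z, dtype=float).reshape(-1, 3)[:, act])
    n = np.asarray(n, dtype=float).reshape(-1, 3)
    grid.check_aliasing(np.abs(z).max(axis=0) if z.size else 0.0)
    axes = [np.ascontiguousarray(a) for a in grid.axes()]
    env = _env_grid(params, subset, axes)
    weights, alpha, gamma = _kernel_inputs(params, subset, n)
    w_data = np.ascontiguousarray(w_data, dtype=float)
    if w_counts is None:
        w_counts = np.ones(w_data.size, dtype=np.int64)
    w_counts = np.ascontiguousarray(w_counts, dtype=np.int64)
    indptr = np.ascontiguousarray(indptr, dtype=np.int64)
    alpha = np.ascontiguousarray(alpha)
    gamma = np.ascontiguousarray(gamma)
    if d == 1:
        dens = _kernels.dens_1d(axes[0], grid.steps[0], env,
                                np.ascontiguousarray(z[:, 0]),
                                np.ascontiguousarray(alpha[:, 0]),
                                w_data, w_counts, indptr, weights[0], weights[1])
    elif d == 2:
        dens = _kernels.dens_2d(axes[0], axes[1], grid.steps[0], grid.steps[1],
                                env, z, alpha, np.ascontiguousarray(gamma[:, 0]),
                                w_data, w_counts, indptr, weights)
    else:
        dens = _kernels.dens_3d(axes[0], axes[1], axes[2],
                                grid.steps[0], grid.steps[1], grid.steps[2],
                                env, z, alpha, gamma, w_data, w_counts, indptr,
                                weights)
    if alias_correct:
        zact = np.zeros((z.shape[0], 3))
        zact[:, act] = z
        dens = dens - _image_correction(zact, n, w_data, w_counts, indptr,
                                        params, subset, grid)
    return dens


def pdf_cf(z: np.ndarray, params: MixtureParams, ctx: VariantContext,
           subset: TraitSubset, grid: GridSpec | None = None) -> float:
    """Density of one variant's z-scores by characteristic-function inversion.

    With no explicit grid, a high-accuracy per-call grid is derived from the
    residual SDs and |z| itself.
    """
    d = subset.d
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if z.shape != (d,):
        raise ParameterError(f"z must have shape ({d},)")
    if grid is None:
        grid = _default_grid(params, subset, np.abs(z), mode="oracle", ctx=ctx)
    zfull = np.zeros(3)
    zfull[list(subset.active)] = z
    dens = dens_cf_batch(zfull[None, :], ctx.n[None, :], ctx.nbr_weights,
                         np.array([0, ctx.nbr_weights.size]), params, subset, grid)
    return max(float(dens[0]), 0.0)


def pdf_exact(z: np.ndarray, params: MixtureParams, ctx: VariantContext,
              subset: TraitSubset, max_terms: int = 400_000) -> float:
    """Exact finite-mixture density by enumerating neighbor assignments.

    Each of the M neighbors independently lands in one collapsed component;
    conditional on the assignment the z vector is Gaussian with covariance
    S0 + sum_k w_k * D Sigma_{c_k} D.  Feasible only for small M.
    """
    d = subset.d
    z = np.atleast_1d(np.asarray(z, dtype=float))
    weights, scaled, s0 = _scaled_covs(params, ctx, subset)
    ncomp = len(weights)
    M = ctx.nbr_weights.size
    if ncomp ** M > max_terms:
        raise FeasibilityError(
            f"{ncomp}^{M} assignment terms exceed the enumeration budget")
    covs = np.asarray(s0)[None, :, :]
    wts = np.array([1.0])
    for w in ctx.nbr_weights:
        covs = (covs[:, None, :, :] +
                w * np.stack(scaled)[None, :, :, :]).reshape(-1, d, d)
        wts = (wts[:, None] * weights[None, :]).reshape(-1)
    # batched multivariate normal pdf at z
    dets = np.linalg.det(covs)
    invs = np.linalg.inv(covs)
    quad = np.einsum("i,bij,j->b", z, invs, z)
    dens = np.exp(-0.5 * quad) / np.sqrt((2 * np.pi) ** d * dets)
    return float(wts @ dens)


def sample_variant_z(params: MixtureParams, ctx: VariantContext,
                     subset: TraitSubset, size: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw z vectors from one variant's exact model (Monte-Carlo oracle)."""
    d = subset.d
    weights, scaled, s0 = _scaled_covs(params, ctx, subset)
    out = rng.multivariate_normal(np.zeros(d), s0, size=size)
    for w in ctx.nbr_weights:
        comp = rng.choice(len(weights), size=size, p=weights / weights.sum())
        for c in range(1, len(weights)):
            m = comp == c
            if m.any():
                out[m] += rng.multivariate_normal(np.zeros(d), w * scaled[c],
                                                  size=int(m.sum()))
    return out


class BandedData:
    """Dataset split into |z| bands, each with its own inversion grid.

    The grid step must resolve the largest |z| in the batch; a handful of
    outlying z-scores would otherwise force a needlessly fine (and, in 3-D,
    cubically expensive) grid on every variant.  Splitting the variants at
    fixed |z| edges and giving each band its own grid keeps the bulk cheap.
    """

    def __init__(self, data, subset: TraitSubset, sigma0: np.ndarray,
                 mode: str = "fit", edges: tuple = (6.0, 12.0)):
        act = list(subset.active)
        zmax_var = np.abs(np.asarray(data.z)[:, act]).max(axis=1)
        bounds = (0.0, *edges, np.inf)
        self.parts: list[tuple[object, GridSpec]] = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            rows = np.flatnonzero((zmax_var > lo) & (zmax_var <= hi))
            if rows.size == 0:
                continue
            sub = data.subset(rows)
            zm = np.abs(np.asarray(sub.z)[:, act]).max(axis=0) + 1e-9
            self.parts.append(
                (sub, GridSpec.for_model(np.asarray(sigma0, float), zm, mode=mode)))


def loglik(data, params: MixtureParams, subset: TraitSubset,
           grid: GridSpec | None = None, floor: float = DENSITY_FLOOR) -> float:
    """Total log-likelihood of a dataset view over the active traits.

    ``data`` is any object exposing ``z`` (nvar,3), ``n_eff`` (nvar,3) and the
    CSR neighborhood arrays ``w_indptr``/``w_data``, or a ``BandedData``
    (in which case ``grid`` is ignored).  Uniform per-variant weights;
    densities are floored before the log.
    """
    if isinstance(data, BandedData):
        return sum(loglik(sub, params, subset, grid=g, floor=floor)
                   for sub, g in data.parts)
    if grid is None:
        act = list(subset.active)
        zmax = np.abs(np.asarray(data.z)[:, act]).max(axis=0)
        grid = _default_grid(params, subset, zmax + 1e-9, mode="fit")
    dens = dens_cf_batch(data.z, data.n_eff, data.w_data, data.w_indptr,
                         params, subset, grid,
                         w_counts=getattr(data, "w_counts", None),
                         alias_correct=True)
    return float(np.sum(np.log(np.maximum(dens, floor))))
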