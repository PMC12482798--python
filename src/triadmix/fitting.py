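"""Stepwise maximum-likelihood estimation and multi-run orchestration.

The nineteen model parameters are estimated in three stages, each maximizing
the characteristic-function likelihood with earlier stages held fixed:

1. univariate  — (pi_i^u, sigma_i, sigma0_i) per trait;
2. bivariate   — (pi_ij^b, rho_ij, rho0_ij) per pair, univariate fixed;
3. trivariate  — the single triple-overlap proportion pi_123 inside its
   feasibility interval, everything else fixed.

Each run draws its own random pruning and tag-variant subset from one seed;
an ensemble of runs is summarized by per-component medians, and the run
closest to the median pattern is selected as representative.

``TriadMixtureModel`` / ``TriadMixtureResults`` present the procedure in the
model-object idiom: build the model from data, call ``fit``, inspect the
results object.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .data import JointDataset
from .grid import GridSpec
from .ld import LDPanel, random_prune, select_subset
from .model import BandedData, TraitSubset, loglik
from .overlap import (OverlapPattern, decompose, naive_max_entropy,
                      pi123_bounds)
from .params import COMPONENT_NAMES, MixtureParams, PAIRS

logger = logging.getLogger(__name__)


@dataclass
class OptimizerConfig:
    """Knobs of the derivative-free stage optimizers."""

    pi_starts: tuple = (3e-4, 5e-3)         # log-spaced univariate multi-starts
    pi_bounds: tuple = (1e-6, 0.5)
    sigma2_bounds: tuple = (1e-12, 10.0)
    sigma0_bounds: tuple = (0.7, 1.6)       # z residual SD stays near 1
    maxfev_uni: int = 130
    bi_frac_starts: tuple = (0.5,)          # pi^b starts as fractions of the bound
    maxfev_bi: int = 140
    tri_scan_points: int = 5
    tri_refine_iters: int = 6
    rho_max: float = 0.95
    w_bin_tol: float | None = 0.25          # neighborhood-weight binning
    # scalar re-refinement after the cheaper search stages: pi^b on a seeded
    # subsample capped at polish_max, pi_123 on the full selection (a single
    # scalar, worth the most data)
    polish_bi: bool = True
    polish_tri: bool = True
    polish_max: int = 12_000


# ---------------------------------------------------------------------------
# stage results


@dataclass
class UnivariateFit:
    trait: int
    pi_u: float
    sigma: float
    sigma0: float
    loglik: float
    converged: bool = True
    n_evals: int = 0


@dataclass
class BivariateFit:
    pair: tuple[int, int]
    pi_b: float
    rho: float
    rho0: float
    loglik: float
    converged: bool = True
    n_evals: int = 0


@dataclass
class TrivariateFit:
    pi123: float
    loglik: float
    lo: float
    hi: float
    converged: bool = True
    n_evals: int = 0


def _psd_shrink(rho: np.ndarray) -> np.ndarray:
    """Largest multiple of a pairwise-correlation triple that is jointly PSD.

    The three correlations are estimated pair by pair, so nothing guarantees
    the assembled 3x3 matrix is a valid correlation matrix; when it is not,
    the triple is scaled toward zero to the feasibility boundary.
    """
    def ok(t: float) -> bool:
        m = np.eye(3)
        m[0, 1] = m[1, 0] = t * rho[0]
        m[0, 2] = m[2, 0] = t * rho[1]
        m[1, 2] = m[2, 1] = t * rho[2]
        return np.linalg.eigvalsh(m).min() >= 1e-9
    if ok(1.0):
        return rho
    lo_t, hi_t = 0.0, 1.0
    for _ in range(40):
        mid = 0.5 * (lo_t + hi_t)
        if ok(mid):
            lo_t = mid
        else:
            hi_t = mid
    logger.warning("pairwise correlations jointly infeasible; shrunk by %.3f",
                   lo_t)
    return rho * lo_t


def _assemble_params(uni: list[UnivariateFit], bi: list[BivariateFit],
                     pi123: float) -> MixtureParams:
    """Full 19-parameter vector from the three stage fits."""
    pi_u = np.array([u.pi_u for u in uni])
    pi_b = np.array([b.pi_b for b in bi])
    pattern = decompose(pi_u, pi_b, pi123)
    return MixtureParams(
        pi=pattern.pi7,
        sigma=np.array([u.sigma for u in uni]),
        sigma0=np.array([u.sigma0 for u in uni]),
        rho=_psd_shrink(np.array([b.rho for b in bi])),
        rho0=_psd_shrink(np.array([b.rho0 for b in bi])),
    )




def _simplex(x0: np.ndarray, steps, lb, ub) -> np.ndarray:
    """Initial Nelder-Mead simplex with per-coordinate steps, kept in bounds."""
    x0 = np.asarray(x0, dtype=float)
    sim = [x0]
    for i, s in enumerate(steps):
        v = x0.copy()
        v[i] = v[i] + s if v[i] + s <= ub[i] else v[i] - s
        v[i] = min(max(v[i], lb[i] + 1e-9), ub[i] - 1e-9)
        sim.append(v)
    return np.array(sim)




# ---------------------------------------------------------------------------
# stage 1: univariate


def _uni_params(trait: int, pi_u: float, sigma: float, sigma0: float) -> MixtureParams:
    pi = np.zeros(7)
    pi[trait] = pi_u
    sig = np.full(3, 0.1)
    sig[trait] = sigma
    s0 = np.ones(3)
    s0[trait] = sigma0
    return MixtureParams(pi=pi, sigma=sig, sigma0=s0)


def fit_univariate(data: JointDataset, trait: int,
                   grid: GridSpec | None = None,
                   opt_cfg: OptimizerConfig | None = None,
                   total_het: float | None = None) -> UnivariateFit:
    """Maximize the univariate likelihood over (pi^u, sigma, sigma0).

    Nelder-Mead on log-transformed coordinates with multiple log-spaced
    polygenicity starts; discoverability starts are matched to each start by
    a method-of-moments inversion of the mean z-score inflation.

    ``total_het`` (the panel's summed heterozygosity) activates a physical
    constraint: the implied SNP-heritability pi * sigma^2 * sum_k h_k cannot
    exceed 1.  Without it the flat pi/sigma^2 ridge can wander into regimes
    whose characteristic function the inversion grid cannot resolve.
    """
    cfg = opt_cfg or OptimizerConfig()
    subset = TraitSubset((trait,))
    z = data.z[:, trait]
    if grid is None:
        eval_data = BandedData(data, subset,
                               np.array([cfg.sigma0_bounds[0]]), mode="fit")
    else:
        eval_data = data
    # mean per-variant LD-weighted N, for moment-matching sigma^2 starts
    wsum = np.add.reduceat(
        data.w_data * data.w_counts, data.w_indptr[:-1]) if data.nvar \
        else np.array([1.0])
    mean_nw = float(np.mean(wsum * data.n_eff[:, trait]))
    excess = max(float(np.mean(z ** 2)) - 1.0, 1e-3)
    nfev = 0

    def objective(x):
        nonlocal nfev
        nfev += 1
        pi_u, s2, s02 = np.exp(x)
        if total_het is not None:
            h2_implied = pi_u * s2 * total_het
            if h2_implied > 1.0:
                return 1e8 * (1.0 + h2_implied)
        p = _uni_params(trait, pi_u, np.sqrt(s2), np.sqrt(s02))
        return -loglik(eval_data, p, subset, grid)

    lb = np.log([cfg.pi_bounds[0], cfg.sigma2_bounds[0], cfg.sigma0_bounds[0] ** 2])
    ub = np.log([cfg.pi_bounds[1], cfg.sigma2_bounds[1], cfg.sigma0_bounds[1] ** 2])
    best = None
    for pi0 in cfg.pi_starts:
        s2_0 = np.clip(excess / (pi0 * mean_nw), *cfg.sigma2_bounds)
        x0 = np.log([pi0, s2_0, 1.0])
        x0 = np.clip(x0, lb + 1e-9, ub - 1e-9)
        # explicit simplex: scipy's default perturbs zero coordinates by
        # 2.5e-4, which stalls immediately at these convergence tolerances
        res = minimize(objective, x0, method="Nelder-Mead",
                       bounds=list(zip(lb, ub)),
                       options={"maxfev": cfg.maxfev_uni, "xatol": 0.02,
                                "fatol": 0.05, "adaptive": True,
                                "initial_simplex": _simplex(x0, (0.7, 0.7, 0.1),
                                                            lb, ub)})
        if best is None or res.fun < best.fun:
            best = res
    pi_u, s2, s02 = np.exp(best.x)
    return UnivariateFit(trait=trait, pi_u=float(pi_u), sigma=float(np.sqrt(s2)),
                         sigma0=float(np.sqrt(s02)), loglik=float(-best.fun),
                         converged=bool(best.success), n_evals=nfev)


# ---------------------------------------------------------------------------
# stage 2: bivariate


def _bi_params(pair: tuple[int, int], uni: dict[int, UnivariateFit],
               pi_b: float, rho: float, rho0: float) -> MixtureParams:
    i, j = pair
    pi = np.zeros(7)
    pi[i] = uni[i].pi_u - pi_b
    pi[j] = uni[j].pi_u - pi_b
    pi[3 + PAIRS.index(pair)] = pi_b
    sig = np.full(3, 0.1)
    s0 = np.ones(3)
    for t in pair:
        sig[t] = uni[t].sigma
        s0[t] = uni[t].sigma0
    rho3 = np.zeros(3)
    rho3[PAIRS.index(pair)] = rho
    rho03 = np.zeros(3)
    rho03[PAIRS.index(pair)] = rho0
    return MixtureParams(pi=pi, sigma=sig, sigma0=s0, rho=rho3, rho0=rho03)


def fit_bivariate(data: JointDataset, pair: tuple[int, int],
                  fixed_uni: list[UnivariateFit],
                  grid: GridSpec | None = None,
                  opt_cfg: OptimizerConfig | None = None,
                  polish_data: JointDataset | None = None) -> BivariateFit:
    """Maximize the bivariate likelihood over (pi^b, rho, rho0).

    Univariate parameters stay fixed; pi^b is box-constrained to
    [0, min(pi_i^u, pi_j^u)] through a scaled logistic transform and the
    correlations through atanh.  The residual-correlation start is the
    empirical correlation of near-null z-scores.

    When ``polish_data`` is given (a larger tag selection than ``data``),
    the shared proportion — the parameter whose sampling noise dominates the
    overlap pattern — gets a final bounded scalar refinement on it with the
    correlations held at their fitted values.
    """
    cfg = opt_cfg or OptimizerConfig()
    pair = tuple(sorted(pair))
    uni = {u.trait: u for u in fixed_uni}
    if pair[0] not in uni or pair[1] not in uni:
        raise ValueError("fixed_uni must contain both traits of the pair")
    subset = TraitSubset(pair)
    bound = min(uni[pair[0]].pi_u, uni[pair[1]].pi_u)
    zi, zj = data.z[:, pair[0]], data.z[:, pair[1]]
    if grid is None:
        s0 = np.array([uni[pair[0]].sigma0, uni[pair[1]].sigma0])
        eval_data = BandedData(data, subset, s0, mode="fit")
    else:
        eval_data = data
    nullish = (np.abs(zi) < 1.5) & (np.abs(zj) < 1.5)
    if nullish.sum() > 30:
        rho0_start = float(np.clip(np.corrcoef(zi[nullish], zj[nullish])[0, 1],
                                   -0.8, 0.8))
    else:
        rho0_start = 0.0
    nfev = 0
    rmax = cfg.rho_max

    def objective(x):
        nonlocal nfev
        nfev += 1
        pi_b = bound * expit(x[0])
        rho = rmax * np.tanh(x[1])
        rho0 = rmax * np.tanh(x[2])
        p = _bi_params(pair, uni, pi_b, rho, rho0)
        return -loglik(eval_data, p, subset, grid)

    best = None
    blb = np.array([-12.0, -3.0, -3.0])
    bub = np.array([12.0, 3.0, 3.0])
    for frac in cfg.bi_frac_starts:
        x0 = np.array([logit(frac), 0.0, np.arctanh(rho0_start / rmax)])
        res = minimize(objective, x0, method="Nelder-Mead",
                       bounds=list(zip(blb, bub)),
                       options={"maxfev": cfg.maxfev_bi, "xatol": 0.02,
                                "fatol": 0.05, "adaptive": True,
                                "initial_simplex": _simplex(x0, (0.8, 0.5, 0.3),
                                                            blb, bub)})
        if best is None or res.fun < best.fun:
            best = res
    pi_b = float(bound * expit(best.x[0]))
    rho = float(rmax * np.tanh(best.x[1]))
    rho0 = float(rmax * np.tanh(best.x[2]))
    ll = float(-best.fun)
    if polish_data is not None and polish_data.nvar > data.nvar:
        pol = BandedData(polish_data, subset,
                         np.array([uni[pair[0]].sigma0, uni[pair[1]].sigma0]))
        cache: dict[float, float] = {}

        def profile(x: float) -> float:
            nonlocal nfev
            x = min(max(x, 0.0), bound)
            if x not in cache:
                nfev += 1
                cache[x] = loglik(pol, _bi_params(pair, uni, x, rho, rho0),
                                  subset, None)
            return cache[x]

        xs = np.linspace(max(0.0, pi_b - 0.35 * bound),
                         min(bound, pi_b + 0.35 * bound), 5)
        vals = [profile(x) for x in xs]
        k = int(np.argmax(vals))
        a, b = xs[max(k - 1, 0)], xs[min(k + 1, len(xs) - 1)]
        invphi = (np.sqrt(5.0) - 1.0) / 2.0
        c, dgs = b - invphi * (b - a), a + invphi * (b - a)
        for _ in range(4):
            if profile(c) >= profile(dgs):
                b, dgs = dgs, c
                c = b - invphi * (b - a)
            else:
                a, c = c, dgs
                dgs = a + invphi * (b - a)
        pi_b = max(cache, key=cache.get)
        ll = cache[pi_b]
    return BivariateFit(pair=pair, pi_b=float(pi_b), rho=rho, rho0=rho0,
                        loglik=ll, converged=bool(best.success),
                        n_evals=nfev)


# ---------------------------------------------------------------------------
# stage 3: trivariate


def fit_trivariate(data: JointDataset, fixed_uni: list[UnivariateFit],
                   fixed_bi: list[BivariateFit],
                   grid: GridSpec | None = None,
                   opt_cfg: OptimizerConfig | None = None,
                   polish_data: JointDataset | None = None) -> TrivariateFit:
    """Bounded scalar search for pi_123 with all other parameters fixed.

    A coarse grid pre-scan over the feasibility interval brackets the
    maximum; golden-section refinement narrows it.  Degenerate intervals
    return the clipped point with a warning.  With ``polish_data`` (a larger
    selection), the estimate is refined by a three-point parabolic step on
    the larger likelihood.
    """
    cfg = opt_cfg or OptimizerConfig()
    uni = sorted(fixed_uni, key=lambda u: u.trait)
    bi = sorted(fixed_bi, key=lambda b: b.pair)
    pi_u = np.array([u.pi_u for u in uni])
    pi_b = np.array([b.pi_b for b in bi])
    bounds = pi123_bounds(pi_u, pi_b)
    lo, hi = bounds.lo, bounds.hi
    subset = TraitSubset((0, 1, 2))
    if grid is None:
        s0 = np.array([u.sigma0 for u in uni])
        eval_data = BandedData(data, subset, s0, mode="fit")
    else:
        eval_data = data
    nfev = 0
    cache: dict[float, float] = {}

    def objective(x: float) -> float:
        nonlocal nfev
        x = bounds.clip(x)
        if x not in cache:
            nfev += 1
            cache[x] = loglik(eval_data, _assemble_params(uni, bi, x),
                              subset, grid)
        return cache[x]

    if hi - lo < 1e-12:
        point = bounds.clip(lo)
        if hi < lo:
            logger.warning("degenerate pi123 bounds; returning clipped point")
        return TrivariateFit(pi123=point, loglik=objective(point),
                             lo=lo, hi=hi, n_evals=nfev)
    xs = np.linspace(lo, hi, cfg.tri_scan_points)
    vals = [objective(x) for x in xs]
    k = int(np.argmax(vals))
    a = xs[max(k - 1, 0)]
    b = xs[min(k + 1, len(xs) - 1)]
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    for _ in range(cfg.tri_refine_iters):
        if b - a < 0.02 * (hi - lo) + 1e-15:
            break
        if objective(c) >= objective(d):
            b, d = d, c
            c = b - invphi * (b - a)
        else:
            a, c = c, d
            d = a + invphi * (b - a)
    best = max(cache, key=cache.get)
    best_ll = cache[best]
    if polish_data is not None and polish_data.nvar > data.nvar \
            and hi - lo > 1e-8:
        pol = BandedData(polish_data, subset,
                         np.array([u.sigma0 for u in uni]))
        delta = min(0.12 * (hi - lo), (hi - lo) / 2.0)
        # three distinct support points even when the estimate sits on a
        # boundary of the feasibility interval
        if best - lo < delta:
            xs = [lo, lo + delta, lo + 2 * delta]
        elif hi - best < delta:
            xs = [hi - 2 * delta, hi - delta, hi]
        else:
            xs = [best - delta, best, best + delta]
        ys = []
        for x in xs:
            nfev += 1
            ys.append(loglik(pol, _assemble_params(uni, bi, x), subset, None))
        # parabolic vertex through the three points, clipped to the interval
        x0, x1, x2 = xs
        y0, y1, y2 = ys
        denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
        cand = dict(zip(xs, ys))
        if abs(denom) > 0:
            a_c = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
            b_c = (x2 ** 2 * (y0 - y1) + x1 ** 2 * (y2 - y0)
                   + x0 ** 2 * (y1 - y2)) / denom
            if a_c < 0:
                vx = bounds.clip(-b_c / (2 * a_c))
                if min(abs(vx - x) for x in xs) > 1e-15:
                    nfev += 1
                    cand[vx] = loglik(pol, _assemble_params(uni, bi, vx),
                                      subset, None)
        best = max(cand, key=cand.get)
        best_ll = cand[best]
    return TrivariateFit(pi123=float(best), loglik=float(best_ll),
                         lo=lo, hi=hi, n_evals=nfev)


# ---------------------------------------------------------------------------
# one full run


@dataclass
class RunResult:
    """All stage outputs of one seeded optimization run."""

    seed: int
    uni: list[UnivariateFit]
    bi: list[BivariateFit]
    tri: TrivariateFit
    selected_variants: int
    wall_time: float = 0.0

    @property
    def pi123(self) -> float:
        return self.tri.pi123

    @property
    def params(self) -> MixtureParams:
        return _assemble_params(self.uni, self.bi, self.tri.pi123)

    @property
    def pattern(self) -> OverlapPattern:
        return decompose(np.array([u.pi_u for u in self.uni]),
                         np.array([b.pi_b for b in self.bi]), self.tri.pi123)

    @property
    def converged(self) -> bool:
        return (all(u.converged for u in self.uni)
                and all(b.converged for b in self.bi) and self.tri.converged)

    def polygenicity_vector(self) -> np.ndarray:
        """(pi_1^u, pi_2^u, pi_3^u, pi_12^b, pi_13^b, pi_23^b, pi_123)."""
        return np.array([u.pi_u for u in self.uni]
                        + [b.pi_b for b in self.bi] + [self.tri.pi123])

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "selected_variants": self.selected_variants,
            "converged": self.converged,
            "uni": [asdict(u) for u in self.uni],
            "bi": [{**asdict(b), "pair": list(b.pair)} for b in self.bi],
            "tri": asdict(self.tri),
            "pi7": dict(zip(COMPONENT_NAMES, self.pattern.pi7.tolist())),
            "wall_time": self.wall_time,
        }


def _fit_one_run(data: JointDataset, seed: int,
                 opt_cfg: OptimizerConfig | None = None) -> RunResult:
    """Stepwise fit on an already-selected tag-variant dataset."""
    t0 = time.time()
    uni = [fit_univariate(data, t, opt_cfg=opt_cfg) for t in range(3)]
    logger.info("seed %d univariate: %s", seed,
                [(round(u.pi_u, 6), round(u.sigma0, 3)) for u in uni])
    bi = [fit_bivariate(data, p, uni, opt_cfg=opt_cfg) for p in PAIRS]
    logger.info("seed %d bivariate: %s", seed,
                [(b.pair, round(b.pi_b, 6)) for b in bi])
    tri = fit_trivariate(data, uni, bi, opt_cfg=opt_cfg)
    logger.info("seed %d pi123=%.6g in [%.3g, %.3g]", seed, tri.pi123,
                tri.lo, tri.hi)
    return RunResult(seed=seed, uni=uni, bi=bi, tri=tri,
                     selected_variants=data.nvar, wall_time=time.time() - t0)


# ---------------------------------------------------------------------------
# multi-run aggregation


@dataclass
class AggregateResult:
    runs: list[RunResult]
    median_pi7: np.ndarray
    representative: int  # index into runs

    @property
    def representative_run(self) -> RunResult:
        return self.runs[self.representative]


def aggregate_runs(results: list[RunResult]) -> AggregateResult:
    """Per-component medians and the run closest to the median pattern.

    The representative run minimizes the union-normalized Euclidean distance
    of its seven-component pattern from the component-wise median pattern.
    The median pattern itself is reported but is not guaranteed to be a
    feasible pattern.
    """
    if len(results) < 2:
        raise ValueError("aggregation needs at least two runs")
    mat = np.stack([r.pattern.pi7 for r in results])
    med = np.median(mat, axis=0)
    union_med = med.sum()
    dev = (((mat - med) / max(union_med, 1e-300)) ** 2).sum(axis=1)
    return AggregateResult(runs=list(results), median_pi7=med,
                           representative=int(np.argmin(dev)))


# ---------------------------------------------------------------------------
# model-object interface


class TriadMixtureModel:
    """Trivariate causal mixture model bound to a harmonized dataset.

    Parameters
    ----------
    dataset : JointDataset
        Harmonized, filtered per-variant data (z, N, LD neighborhoods) for
        the candidate tag variants.
    panel : LDPanel, optional
        Needed for per-seed random pruning; without it, runs use a plain
        random subset of the dataset rows.
    config : Config, optional
        Selection settings (do_pruning, r2_prune_thresh, n_random, optional
        trivariate-stage subsample); defaults mirror ``Config``.
    """

    def __init__(self, dataset: JointDataset, panel: LDPanel | None = None,
                 config=None, opt_cfg: OptimizerConfig | None = None):
        self.dataset = dataset
        self.panel = panel
        self.config = config
        self.opt_cfg = opt_cfg

    # -- construction helpers -------------------------------------------

    @classmethod
    def from_files(cls, config) -> "TriadMixtureModel":
        """Read sumstats + LD panel files, harmonize and filter per config."""
        from .pipeline import build_model_from_config
        return build_model_from_config(config, cls)

    @classmethod
    def from_simulation(cls, sim, config=None,
                        opt_cfg: OptimizerConfig | None = None) -> "TriadMixtureModel":
        """Bind the model to a synthetic scenario draw (no file round trip)."""
        from .config import Config
        cfg = config or Config()
        n = np.broadcast_to(np.asarray(sim.spec.n_traits_N, float),
                            (sim.panel.nvar, 3))
        mask = np.abs(sim.z).max(axis=1) <= cfg.z_thresh
        idx = np.flatnonzero(mask)
        data = JointDataset.from_panel(sim.panel, sim.z[idx], n[idx], idx)
        return cls(data, panel=sim.panel, config=cfg, opt_cfg=opt_cfg)

    # -- per-seed selection ----------------------------------------------

    def _select(self, seed: int) -> tuple[JointDataset, JointDataset]:
        from .config import Config
        cfg = self.config or Config()
        panel_idx = self.dataset.panel_idx
        if self.panel is not None and cfg.do_pruning and panel_idx is not None:
            pruned = random_prune(self.panel, cfg.r2_prune_thresh, seed,
                                  within=panel_idx).kept
        else:
            if cfg.do_pruning and self.panel is None:
                logger.warning("no panel attached; pruning stage skipped")
            pruned = panel_idx if panel_idx is not None \
                else np.arange(self.dataset.nvar)
        tags = select_subset(pruned, cfg.n_random, seed)
        if panel_idx is not None:
            rowmap = {int(p): r for r, p in enumerate(panel_idx)}
            rows = np.array([rowmap[int(t)] for t in tags], dtype=np.int64)
        else:
            rows = tags
        data = self.dataset.subset(rows)
        tol = self.opt_cfg.w_bin_tol if self.opt_cfg is not None \
            else OptimizerConfig.w_bin_tol
        if tol:
            data = data.binned(tol)
        # nested stage subsets: the costlier 2-D/3-D inversions may run on a
        # seeded subsample of the same selection
        def _stage(n, offset):
            if n and n < data.nvar:
                return data.subset(select_subset(np.arange(data.nvar), n,
                                                 seed + offset))
            return data
        bi_data = _stage(getattr(cfg, "n_random_bivariate", None), 5_000)
        tri_data = _stage(getattr(cfg, "n_random_trivariate", None), 10_000)
        return data, bi_data, tri_data

    # -- fitting ----------------------------------------------------------

    def fit(self, seed: int = 1) -> "TriadMixtureResults":
        """One stepwise optimization run with this seed's variant subset."""
        data, bi_data, tri_data = self._select(seed)
        total_het = float(self.panel.het.sum()) if self.panel is not None else None
        t0 = time.time()
        uni = [fit_univariate(data, t, opt_cfg=self.opt_cfg,
                              total_het=total_het) for t in range(3)]
        ocfg = self.opt_cfg or OptimizerConfig()
        if data.nvar > ocfg.polish_max:
            pol_rows = select_subset(np.arange(data.nvar), ocfg.polish_max,
                                     seed + 20_000)
            pol_data = data.subset(pol_rows)
        else:
            pol_data = data
        bi = [fit_bivariate(bi_data, p, uni, opt_cfg=self.opt_cfg,
                            polish_data=pol_data if ocfg.polish_bi
                            and bi_data.nvar < pol_data.nvar else None)
              for p in PAIRS]
        tri = fit_trivariate(tri_data, uni, bi, opt_cfg=self.opt_cfg,
                             polish_data=data if ocfg.polish_tri
                             and tri_data.nvar < data.nvar else None)
        run = RunResult(seed=seed, uni=uni, bi=bi, tri=tri,
                        selected_variants=data.nvar, wall_time=time.time() - t0)
        return TriadMixtureResults(self, run)

    def fit_ensemble(self, seeds) -> "TriadEnsembleResults":
        """Independent runs over seeds, aggregated by pattern medians."""
        runs = [self.fit(seed).run for seed in seeds]
        agg = aggregate_runs(runs) if len(runs) > 1 else None
        return TriadEnsembleResults(self, runs, agg)


def run_pipeline(config, dataset: JointDataset | None = None,
                 panel: LDPanel | None = None,
                 opt_cfg: OptimizerConfig | None = None) -> RunResult:
    """Filters -> prune(seed) -> subset(seed) -> stepwise fit, from config.

    When ``dataset``/``panel`` are not supplied they are built from the file
    paths in the config.
    """
    if dataset is None:
        model = TriadMixtureModel.from_files(config)
        model.opt_cfg = opt_cfg
    else:
        model = TriadMixtureModel(dataset, panel=panel, config=config,
                                  opt_cfg=opt_cfg)
    seed = config.rand_prune_seed if np.isscalar(config.rand_prune_seed) \
        else config.rand_prune_seed[0]
    return model.fit(seed=int(seed)).run


# ---------------------------------------------------------------------------
# results objects


class TriadMixtureResults:
    """Estimates, overlap pattern and diagnostics of one fitted run."""

    def __init__(self, model: TriadMixtureModel, run: RunResult):
        self.model = model
        self.run = run

    @property
    def params(self) -> MixtureParams:
        return self.run.params

    @property
    def pattern(self) -> OverlapPattern:
        return self.run.pattern

    @property
    def naive_pattern(self) -> OverlapPattern:
        """Maximum-entropy baseline from this run's uni/bi estimates."""
        return naive_max_entropy(np.array([u.pi_u for u in self.run.uni]),
                                 np.array([b.pi_b for b in self.run.bi]))

    @property
    def logliks(self) -> dict:
        return {"univariate": [u.loglik for u in self.run.uni],
                "bivariate": [b.loglik for b in self.run.bi],
                "trivariate": self.run.tri.loglik}

    def summary(self) -> str:
        r = self.run
        lines = [
            "Trivariate causal mixture model — stepwise ML fit",
            "=" * 58,
            f"seed: {r.seed}    tag variants: {r.selected_variants}"
            f"    converged: {r.converged}",
            "",
            "Univariate stage (per trait)",
            f"{'trait':>6} {'pi^u':>12} {'sigma':>10} {'sigma0':>8} {'loglik':>14}",
        ]
        for u in r.uni:
            lines.append(f"{u.trait + 1:>6} {u.pi_u:>12.4e} {u.sigma:>10.4e} "
                         f"{u.sigma0:>8.3f} {u.loglik:>14.2f}")
        lines += ["", "Bivariate stage (per pair)",
                  f"{'pair':>6} {'pi^b':>12} {'rho':>8} {'rho0':>8} {'loglik':>14}"]
        for b in r.bi:
            lines.append(f"{b.pair[0] + 1}-{b.pair[1] + 1:>4} {b.pi_b:>12.4e} "
                         f"{b.rho:>8.3f} {b.rho0:>8.3f} {b.loglik:>14.2f}")
        lines += ["", f"Trivariate stage: pi_123 = {r.tri.pi123:.4e} "
                      f"in [{r.tri.lo:.3e}, {r.tri.hi:.3e}]",
                  "", "Euler components (% of union):"]
        from .overlap import euler_percentages
        pct, rounded = euler_percentages(self.pattern)
        lines.append("  " + "  ".join(f"{n}:{p}%" for n, p
                                      in zip(COMPONENT_NAMES, rounded)))
        return "\n".join(lines)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.run.to_dict(), fh, indent=2)


class TriadEnsembleResults:
    """Ensemble of independent runs plus the median-based aggregate."""

    def __init__(self, model: TriadMixtureModel, runs: list[RunResult],
                 aggregate: AggregateResult | None):
        self.model = model
        self.runs = runs
        self.aggregate = aggregate

    @property
    def representative(self) -> TriadMixtureResults:
        run = self.runs[0] if self.aggregate is None \
            else self.aggregate.representative_run
        return TriadMixtureResults(self.model, run)

    @property
    def median_pi7(self) -> np.ndarray:
        if self.aggregate is None:
            return self.runs[0].pattern.pi7
        return self.aggregate.median_pi7

    def to_frame(self):
        """One row per run, columns per parameter (ensemble table layout)."""
        import pandas as pd
        rows = []
        for r in self.runs:
            row = {"seed": r.seed, "selected_variants": r.selected_variants}
            for u in r.uni:
                row[f"pi{u.trait + 1}_u"] = u.pi_u
                row[f"sigma{u.trait + 1}"] = u.sigma
                row[f"sigma0{u.trait + 1}"] = u.sigma0
            for b in r.bi:
                tag = f"{b.pair[0] + 1}{b.pair[1] + 1}"
                row[f"pi{tag}_b"] = b.pi_b
                row[f"rho{tag}"] = b.rho
                row[f"rho0{tag}"] = b.rho0
            row["pi123"] = r.tri.pi123
            for name, val in zip(COMPONENT_NAMES, r.pattern.pi7):
                row[f"pi{name}"] = val
            rows.append(row)
        return pd.DataFrame(rows)
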