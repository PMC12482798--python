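"""Inversion grids for the characteristic-function likelihood.

Densities are recovered from the model's characteristic function phi(t) by a
trapezoidal sum on a fixed uniform grid over ``[-T_i, T_i]`` per axis.  Two
numerical knobs matter:

* the half-width ``T_i`` — chosen so the Gaussian residual envelope
  ``exp(-sigma0_i**2 t**2 / 2)`` has decayed below ``tail_tol`` at ``|t|=T_i``
  (the mixture factors only shrink phi further, so this bounds the truncated
  tail);
* the step ``dt_i`` — a trapezoidal sum makes the recovered density periodic
  with period ``2*pi/dt_i``, so ``dt_i <= pi/(z_max + margin)`` is required to
  keep the aliased images away from the evaluation points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class GridError(ValueError):
    """Raised when an inversion grid cannot resolve the requested z-scores."""


# Tail tolerance of the residual envelope at the grid edge, per accuracy mode.
_TAIL_TOL = {"oracle": 1e-13, "fit": 1e-9, "fit2d": 1e-7, "fit3d": 1e-5}
_MARGIN = {"oracle": 2.0, "fit": 4.0, "fit3d": 4.0}


@dataclass(frozen=True)
class GridSpec:
    """Uniform symmetric inversion grid, one step/half-width pair per axis."""

    steps: tuple[float, ...]
    half_widths: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.steps) != len(self.half_widths):
            raise GridError("steps and half_widths must have equal length")
        if any(s <= 0 for s in self.steps) or any(h <= 0 for h in self.half_widths):
            raise GridError("grid steps and half-widths must be positive")

    @property
    def ndim(self) -> int:
        return len(self.steps)

    def axes(self) -> list[np.ndarray]:
        """Symmetric per-axis grids including t=0."""
        out = []
        for dt, hw in zip(self.steps, self.half_widths):
            n = int(np.ceil(hw / dt))
            out.append(np.arange(-n, n + 1, dtype=float) * dt)
        return out

    def check_aliasing(self, zmax: np.ndarray | float) -> None:
        """Fail if the step is too coarse for the largest |z| evaluated."""
        zmax = np.broadcast_to(np.asarray(zmax, dtype=float), (self.ndim,))
        for dt, zm in zip(self.steps, zmax):
            if dt > np.pi / (zm + 2.0):
                raise GridError(
                    f"grid step {dt:.4f} aliases at |z|={zm:.2f}: "
                    f"need dt <= pi/(z_max+2) = {np.pi / (zm + 2.0):.4f}")

    @classmethod
    def for_model(cls, sigma0: np.ndarray, zmax: np.ndarray | float,
                  mode: str = "fit",
                  sigma_z: np.ndarray | float | None = None) -> "GridSpec":
        """Choose per-axis steps and half-widths for given residual SDs.

        Parameters
        ----------
        sigma0 : array of residual SDs over the active traits.
        zmax : largest |z| at which densities will be evaluated (scalar or
            per-axis).
        mode : "oracle" for high-accuracy single-variant evaluation,
            "fit" for 1-D/2-D likelihoods, "fit3d" for the coarser default
            used by the 3-D inversion (its cost is cubic in grid size).
        sigma_z : optional per-axis SD of the model's z marginal; the step
            margin grows with it so the periodic density images stay several
            SDs beyond the evaluation points.
        """
        sigma0 = np.atleast_1d(np.asarray(sigma0, dtype=float))
        d = sigma0.size
        zmax = np.broadcast_to(np.asarray(zmax, dtype=float), (d,))
        if mode == "fit" and d > 1:
            tail = _TAIL_TOL["fit3d" if d == 3 else "fit2d"]
        else:
            tail = _TAIL_TOL.get(mode)
        if tail is None:
            raise GridError(f"unknown grid mode {mode!r}")
        margin = np.full(d, _MARGIN[mode if mode in _MARGIN else "fit"])
        if sigma_z is not None:
            sz = np.broadcast_to(np.asarray(sigma_z, dtype=float), (d,))
            margin = margin + 3.0 * sz
        t_edge = np.sqrt(2.0 * np.log(1.0 / tail))
        steps = tuple(float(np.pi / (zm + m)) for zm, m in zip(zmax, margin))
        hws = tuple(float(t_edge / s0) for s0 in sigma0)
        return cls(steps=steps, half_widths=hws)
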