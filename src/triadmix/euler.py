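"""Approximate area-proportional three-set Euler diagrams.

Each phenotype is drawn as a circle with area proportional to its univariate
polygenicity; pairwise centre distances are solved so the two-circle lens
area matches the bivariate overlap.  Exact three-set area-proportional
diagrams are not always realizable, so the rendering is best-effort and the
numerical pattern is the source of truth; region labels show integer
percentages of the union.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .overlap import OverlapPattern, euler_percentages
from .params import COMPONENT_NAMES


def _lens_area(d: float, r1: float, r2: float) -> float:
    """Intersection area of two circles with radii r1, r2 at distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return np.pi * min(r1, r2) ** 2
    a1 = r1 ** 2 * np.arccos((d ** 2 + r1 ** 2 - r2 ** 2) / (2 * d * r1))
    a2 = r2 ** 2 * np.arccos((d ** 2 + r2 ** 2 - r1 ** 2) / (2 * d * r2))
    tri = 0.5 * np.sqrt(max((-d + r1 + r2) * (d + r1 - r2)
                            * (d - r1 + r2) * (d + r1 + r2), 0.0))
    return a1 + a2 - tri


def _pair_distance(target: float, r1: float, r2: float) -> float:
    full = np.pi * min(r1, r2) ** 2
    if target <= 0:
        return r1 + r2 + 0.1 * min(r1, r2)
    if target >= full:
        return abs(r1 - r2) * 0.999
    return brentq(lambda d: _lens_area(d, r1, r2) - target,
                  abs(r1 - r2) + 1e-12, r1 + r2 - 1e-12)


def circle_layout(pattern: OverlapPattern) -> tuple[np.ndarray, np.ndarray]:
    """Radii and centres of the three circles (areas ~ pi_i^u)."""
    pi_u = pattern.pi_univariate()
    pi_b = pattern.pi_bivariate()
    radii = np.sqrt(np.maximum(pi_u, 1e-12) / np.pi)
    d12 = _pair_distance(pi_b[0], radii[0], radii[1])
    d13 = _pair_distance(pi_b[1], radii[0], radii[2])
    d23 = _pair_distance(pi_b[2], radii[1], radii[2])
    # triangle from the three distances, clamped when not realizable
    d23 = min(max(d23, abs(d12 - d13) * 1.001), (d12 + d13) * 0.999)
    c1 = np.array([0.0, 0.0])
    c2 = np.array([d12, 0.0])
    x3 = (d12 ** 2 + d13 ** 2 - d23 ** 2) / (2 * d12) if d12 > 0 else 0.0
    y3 = np.sqrt(max(d13 ** 2 - x3 ** 2, 0.0))
    centres = np.stack([c1, c2, np.array([x3, y3])])
    return radii, centres


def plot_euler(pattern: OverlapPattern, labels=("Trait 1", "Trait 2", "Trait 3"),
               ax=None, title: str | None = None):
    """Render the three-ellipse (circle) Euler diagram with % labels."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    radii, centres = circle_layout(pattern)
    colors = ["#1f77b4", "#d62728", "#2ca02c"]
    for r, c, col, lab in zip(radii, centres, colors, labels):
        ax.add_patch(Circle(c, r, alpha=0.35, facecolor=col,
                            edgecolor="black", label=lab))
        ax.annotate(lab, c + np.array([0, r * 1.05]), ha="center", fontsize=9)
    _, pct = euler_percentages(pattern)
    # heuristic label anchors: circle centres pushed away from the others
    centroid = centres.mean(axis=0)
    anchors = {
        "1": centres[0] + 0.55 * (centres[0] - centroid),
        "2": centres[1] + 0.55 * (centres[1] - centroid),
        "3": centres[2] + 0.55 * (centres[2] - centroid),
        "12": 0.5 * (centres[0] + centres[1]) + 0.25 * (0.5 * (centres[0] + centres[1]) - centroid),
        "13": 0.5 * (centres[0] + centres[2]) + 0.25 * (0.5 * (centres[0] + centres[2]) - centroid),
        "23": 0.5 * (centres[1] + centres[2]) + 0.25 * (0.5 * (centres[1] + centres[2]) - centroid),
        "123": centroid,
    }
    for name, p in zip(COMPONENT_NAMES, pct):
        ax.annotate(f"{p}%", anchors[name], ha="center", va="center", fontsize=8)
    ax.set_aspect("equal")
    ax.set_axis_off()
    lim = float(np.max(np.abs(centres).max(axis=0) + radii.max())) * 1.25
    ax.set_xlim(-lim, lim + centres[:, 0].max())
    ax.set_ylim(-lim, lim + centres[:, 1].max())
    if title:
        ax.set_title(title)
    return ax
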