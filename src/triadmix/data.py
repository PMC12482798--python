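"""In-memory container joining z-scores, sample sizes and LD neighborhoods."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class JointDataset:
    """Harmonized per-variant data for the likelihood.

    z, n_eff : (nvar, 3) aligned z-scores and per-trait sample sizes.
    w_indptr, w_data : CSR rows of neighborhood weights w_k = h_k * r2_jk
        (self term included); neighbors cover the full reference panel, not
        just the variants whose z-scores enter the likelihood.
    panel_idx : indices of these variants in the source panel (provenance).
    """

    z: np.ndarray
    n_eff: np.ndarray
    w_indptr: np.ndarray
    w_data: np.ndarray
    w_counts: np.ndarray | None = None
    panel_idx: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z = np.ascontiguousarray(self.z, dtype=float)
        self.n_eff = np.ascontiguousarray(self.n_eff, dtype=float)
        self.w_indptr = np.ascontiguousarray(self.w_indptr, dtype=np.int64)
        self.w_data = np.ascontiguousarray(self.w_data, dtype=float)
        if self.w_counts is None:
            self.w_counts = np.ones(self.w_data.size, dtype=np.int64)
        self.w_counts = np.ascontiguousarray(self.w_counts, dtype=np.int64)
        if self.z.shape != self.n_eff.shape or self.z.shape[1] != 3:
            raise ValueError("z and n_eff must both have shape (nvar, 3)")
        if self.w_indptr.shape != (self.z.shape[0] + 1,):
            raise ValueError("w_indptr must have nvar+1 entries")

    @property
    def nvar(self) -> int:
        return self.z.shape[0]

    def subset(self, idx) -> "JointDataset":
        """Row-subset view (copies the CSR rows)."""
        idx = np.asarray(idx, dtype=np.int64)
        counts = self.w_indptr[idx + 1] - self.w_indptr[idx]
        indptr = np.zeros(idx.size + 1, dtype=np.int64)
        np.cumsum(counts, out=indptr[1:])
        total = int(indptr[-1])
        # vectorized CSR row gather: flat source positions for every entry
        pos = np.repeat(self.w_indptr[idx] - indptr[:-1], counts) \
            + np.arange(total, dtype=np.int64)
        return JointDataset(
            z=self.z[idx], n_eff=self.n_eff[idx],
            w_indptr=indptr, w_data=self.w_data[pos],
            w_counts=self.w_counts[pos],
            panel_idx=None if self.panel_idx is None else self.panel_idx[idx])

    def binned(self, rel_tol: float = 0.25) -> "JointDataset":
        """Merge near-equal neighborhood weights into multiplicity bins.

        Within each variant, weights sorted descending are greedily merged
        while the ratio between a bin's largest and smallest member stays
        below 1 + rel_tol; the bin weight is the arithmetic mean (preserving
        the variant's total LD-weighted load exactly).  This trades a small,
        smooth perturbation of the characteristic function for a roughly
        proportional reduction in kernel cost.
        """
        new_data, new_counts, indptr = [], [], [0]
        for j in range(self.nvar):
            lo, hi = self.w_indptr[j], self.w_indptr[j + 1]
            w = np.sort(self.w_data[lo:hi] .repeat(self.w_counts[lo:hi]))[::-1]
            start = 0
            for k in range(1, w.size + 1):
                if k == w.size or w[start] > w[k] * (1.0 + rel_tol):
                    new_data.append(float(w[start:k].mean()))
                    new_counts.append(k - start)
                    start = k
            indptr.append(len(new_data))
        return JointDataset(
            z=self.z, n_eff=self.n_eff,
            w_indptr=np.array(indptr, dtype=np.int64),
            w_data=np.array(new_data), w_counts=np.array(new_counts, dtype=np.int64),
            panel_idx=self.panel_idx)

    @classmethod
    def from_panel(cls, panel, z: np.ndarray, n_eff: np.ndarray,
                   panel_idx: np.ndarray) -> "JointDataset":
        """Attach LD-panel neighborhoods to aligned z/N rows.

        panel : an LDPanel; panel_idx maps each z row to its panel variant.
        """
        panel_idx = np.asarray(panel_idx, dtype=np.int64)
        counts = panel.nbr_indptr[panel_idx + 1] - panel.nbr_indptr[panel_idx]
        indptr = np.zeros(panel_idx.size + 1, dtype=np.int64)
        np.cumsum(counts, out=indptr[1:])
        total = int(indptr[-1])
        pos = np.repeat(panel.nbr_indptr[panel_idx] - indptr[:-1], counts) \
            + np.arange(total, dtype=np.int64)
        data = panel.het[panel.nbr_idx[pos]] * panel.nbr_r2[pos]
        return cls(z=np.asarray(z, dtype=float),
                   n_eff=np.asarray(n_eff, dtype=float),
                   w_indptr=indptr, w_data=data, panel_idx=panel_idx)
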