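"""LD reference panel: pairwise r2 neighborhoods, heterozygosity, pruning.

The reference panel supplies, for every variant, the list of variants in
appreciable LD with it (with squared allelic correlations r2) plus its allele
frequency.  The model consumes LD only through r2 and the heterozygosity
h = 2f(1-f): every mixture component is zero-mean, so the characteristic
function depends on the signed correlation r_jk only through its square.
Signed correlations are optionally carried for the synthetic generator, which
needs them to build z-scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order of the PLINK 1.9 ``--r2`` text table
PLINK_R2_COLUMNS = ["CHR_A", "BP_A", "SNP_A", "CHR_B", "BP_B", "SNP_B", "R2"]


class PanelError(ValueError):
    pass


def heterozygosity(freq) -> np.ndarray | float:
    """h = 2 f (1 - f) for allele frequency f in [0, 1]."""
    arr = np.asarray(freq, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("allele frequency must lie in [0, 1]")
    h = 2.0 * arr * (1.0 - arr)
    return float(h) if np.isscalar(freq) or arr.ndim == 0 else h


@dataclass
class LDPanel:
    """Reference variants with symmetric CSR r2 neighbor lists.

    variants : DataFrame with columns id, chrom, pos, a1, a2, freq (panel
        order defines the index space used everywhere downstream).
    nbr_indptr, nbr_idx, nbr_r2 : CSR neighbor lists; every variant is its
        own neighbor with r2 = 1, and pairs appear in both directions.
    nbr_r : optional signed correlations aligned with nbr_r2 (synthetic
        panels only).
    """

    variants: pd.DataFrame
    nbr_indptr: np.ndarray
    nbr_idx: np.ndarray
    nbr_r2: np.ndarray
    nbr_r: np.ndarray | None = None
    het: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.nbr_indptr = np.ascontiguousarray(self.nbr_indptr, dtype=np.int64)
        self.nbr_idx = np.ascontiguousarray(self.nbr_idx, dtype=np.int64)
        self.nbr_r2 = np.ascontiguousarray(self.nbr_r2, dtype=float)
        if self.nbr_indptr.shape != (len(self.variants) + 1,):
            raise PanelError("nbr_indptr length must be nvariants + 1")
        self.het = heterozygosity(self.variants["freq"].to_numpy())

    @property
    def nvar(self) -> int:
        return len(self.variants)

    def neighbors(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.nbr_indptr[j], self.nbr_indptr[j + 1]
        return self.nbr_idx[lo:hi], self.nbr_r2[lo:hi]


def _build_csr(nvar: int, ia: np.ndarray, ib: np.ndarray, r2: np.ndarray,
               r_signed: np.ndarray | None = None) -> dict:
    """Symmetrize pair lists and add self-pairs; returns CSR arrays."""
    rows = np.concatenate([ia, ib, np.arange(nvar)])
    cols = np.concatenate([ib, ia, np.arange(nvar)])
    vals = np.concatenate([r2, r2, np.ones(nvar)])
    if r_signed is not None:
        svals = np.concatenate([r_signed, r_signed, np.ones(nvar)])
    order = np.lexsort((cols, rows))
    rows, cols, vals = rows[order], cols[order], vals[order]
    if r_signed is not None:
        svals = svals[order]
    # drop duplicate pairs (keep first occurrence)
    keep = np.ones(rows.size, dtype=bool)
    keep[1:] = (rows[1:] != rows[:-1]) | (cols[1:] != cols[:-1])
    ndup = int((~keep).sum())
    if ndup:
        warnings.warn(f"{ndup} duplicate LD pair(s) collapsed", stacklevel=3)
        rows, cols, vals = rows[keep], cols[keep], vals[keep]
        if r_signed is not None:
            svals = svals[keep]
    indptr = np.zeros(nvar + 1, dtype=np.int64)
    np.add.at(indptr, rows + 1, 1)
    np.cumsum(indptr, out=indptr)
    out = {"nbr_indptr": indptr, "nbr_idx": cols, "nbr_r2": vals}
    if r_signed is not None:
        out["nbr_r"] = svals
    return out


def load_ld_text(paths, panel_meta: pd.DataFrame) -> LDPanel:
    """Load per-chromosome PLINK ``--r2`` text tables into an LDPanel.

    paths : iterable of file paths (PLINK 1.9 --r2 dialect, whitespace
        delimited, header CHR_A BP_A SNP_A CHR_B BP_B SNP_B R2).
    panel_meta : variant table with columns id, chrom, pos, a1, a2, freq;
        every SNP_A/SNP_B in the pair files must appear here.
    """
    meta = panel_meta.reset_index(drop=True)
    required = {"id", "chrom", "pos", "a1", "a2", "freq"}
    if not required.issubset(meta.columns):
        raise PanelError(f"panel_meta missing columns {required - set(meta.columns)}")
    pos = pd.Series(np.arange(len(meta)), index=meta["id"].astype(str))
    if pos.index.has_duplicates:
        raise PanelError("duplicate variant IDs in panel_meta")
    ia_all, ib_all, r2_all = [], [], []
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    for path in paths:
        try:
            df = pd.read_csv(path, sep=r"\s+", dtype={"SNP_A": str, "SNP_B": str})
        except Exception as exc:  # noqa: BLE001 - surface the file name
            raise PanelError(f"cannot parse LD pair file {path}: {exc}") from exc
        missing = [c for c in PLINK_R2_COLUMNS if c not in df.columns]
        if missing:
            raise PanelError(f"{path}: missing column(s) {missing}")
        bad = df["R2"].isna() | (df["R2"] <= 0) | (df["R2"] > 1 + 1e-9)
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
            raise PanelError(f"{path}: malformed R2 value at line {line}")
        for col in ("SNP_A", "SNP_B"):
            mapped = pos.reindex(df[col])
            if mapped.isna().any():
                unknown = df[col][mapped.isna().to_numpy()].iloc[0]
                raise PanelError(f"{path}: unknown variant ID {unknown!r}")
        ia_all.append(pos.reindex(df["SNP_A"]).to_numpy(dtype=np.int64))
        ib_all.append(pos.reindex(df["SNP_B"]).to_numpy(dtype=np.int64))
        r2_all.append(np.minimum(df["R2"].to_numpy(dtype=float), 1.0))
    nvar = len(meta)
    ia = np.concatenate(ia_all) if ia_all else np.empty(0, dtype=np.int64)
    ib = np.concatenate(ib_all) if ib_all else np.empty(0, dtype=np.int64)
    r2 = np.concatenate(r2_all) if r2_all else np.empty(0)
    self_mask = ia == ib
    if self_mask.any():  # self pairs are implied; avoid duplicating them
        ia, ib, r2 = ia[~self_mask], ib[~self_mask], r2[~self_mask]
    csr = _build_csr(nvar, ia, ib, r2)
    return LDPanel(variants=meta, **csr)


@dataclass(frozen=True)
class PruneResult:
    """Outcome of seeded random LD pruning."""

    kept: np.ndarray
    seed: int


def random_prune(panel: LDPanel, r2_thresh: float, seed: int,
                 within: np.ndarray | None = None) -> PruneResult:
    """Random-order greedy pruning at an r2 threshold.

    Variants are visited in a seeded random order; a variant is kept iff no
    already-kept variant is in LD with it at r2 >= r2_thresh.  The kept set
    is maximal for the visit order and deterministic given (panel, threshold,
    seed); output follows panel order.  When ``within`` is given, only those
    panel indices participate (the candidates that survived filtering).
    """
    if not (0 < r2_thresh <= 1):
        raise ValueError("r2_thresh must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    eligible = np.ones(panel.nvar, dtype=bool)
    if within is not None:
        eligible[:] = False
        eligible[np.asarray(within, dtype=np.int64)] = True
    order = rng.permutation(panel.nvar)
    kept = np.zeros(panel.nvar, dtype=bool)
    removed = np.zeros(panel.nvar, dtype=bool)
    indptr, idx, r2 = panel.nbr_indptr, panel.nbr_idx, panel.nbr_r2
    for j in order:
        if removed[j] or not eligible[j]:
            continue
        kept[j] = True
        lo, hi = indptr[j], indptr[j + 1]
        nb = idx[lo:hi]
        strong = nb[(r2[lo:hi] >= r2_thresh) & (nb != j)]
        removed[strong] = True
    return PruneResult(kept=np.flatnonzero(kept), seed=int(seed))


def select_subset(kept: np.ndarray, n_random: int, seed: int) -> np.ndarray:
    """Seeded uniform sample (without replacement) of tag variants.

    The same seed drives pruning and subsetting; a sample of
    min(n_random, len(kept)) indices is returned in sorted order.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    kept = np.asarray(kept)
    if n_random >= kept.size:
        return np.sort(kept)
    rng = np.random.default_rng(seed)
    pick = rng.choice(kept.size, size=int(n_random), replace=False)
    return np.sort(kept[pick])
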