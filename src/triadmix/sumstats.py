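"""Reading, harmonizing and filtering GWAS summary-statistics tables.

Input tables are whitespace/tab-delimited text with a header; common column
aliases (SNP/ID, CHR, BP/POS, A1/EA, A2/OA, Z or BETA+SE, N, INFO, FRQ/EAF)
are recognised, with an explicit ``column_map`` taking precedence.  Three
tables are aligned to a shared reference-panel variant list before modelling:
alleles are matched (flipping the z sign when effect/other alleles are
swapped), strand-ambiguous variants are removed, and per-variant filters
(MAF, INFO, |z|, excluded regions) select the variants whose z-scores enter
the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SumStatsConfigError(ValueError):
    """A required column is missing or ambiguous."""


class SumStatsInputError(ValueError):
    """The file or the table intersection is unusable."""


_ALIASES = {
    "variant_id": ["SNP", "ID", "RSID", "MARKERNAME", "VARIANT_ID"],
    "chrom": ["CHR", "CHROM", "CHROMOSOME"],
    "pos": ["BP", "POS", "POSITION", "BASE_PAIR_LOCATION"],
    "a1": ["A1", "EA", "EFFECT_ALLELE", "ALT"],
    "a2": ["A2", "OA", "OTHER_ALLELE", "NEA", "REF"],
    "z": ["Z", "ZSCORE", "Z_SCORE"],
    "beta": ["BETA", "B", "EFFECT"],
    "se": ["SE", "STDERR", "STANDARD_ERROR"],
    "n": ["N", "NEFF", "N_TOTAL"],
    "info": ["INFO", "IMPINFO", "IMPUTATION_QUALITY"],
    "freq": ["FRQ", "EAF", "FREQ", "AF", "MAF_A1", "EFFECT_ALLELE_FREQUENCY"],
}
_REQUIRED = ("variant_id", "a1", "a2")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _resolve_columns(columns, column_map: dict | None) -> dict[str, str]:
    upper = {c.upper(): c for c in columns}
    resolved: dict[str, str] = {}
    column_map = column_map or {}
    for field_name, aliases in _ALIASES.items():
        if field_name in column_map:
            col = column_map[field_name]
            if col not in columns:
                raise SumStatsConfigError(
                    f"mapped column {col!r} for {field_name!r} not in file")
            resolved[field_name] = col
            continue
        for alias in aliases:
            if alias in upper:
                resolved[field_name] = upper[alias]
                break
    return resolved


def read_sumstats(path, column_map: dict | None = None,
                  n_const: float | None = None) -> tuple[pd.DataFrame, dict]:
    """Read one summary-statistics table.

    Returns a normalized table (variant_id, chrom, pos, a1, a2, z, n, info,
    freq — the last two NaN when absent) and a log dict with per-reason drop
    counts.  z is computed as beta/se when no z column exists; a constant
    sample size ``n_const`` substitutes for a missing N column.
    """
    raw = pd.read_csv(path, sep=r"\s+", dtype={0: str})
    cols = _resolve_columns(raw.columns, column_map)
    missing = [f for f in _REQUIRED if f not in cols]
    if missing:
        raise SumStatsConfigError(f"{path}: missing required column(s) {missing}")
    if "z" not in cols and not ("beta" in cols and "se" in cols):
        raise SumStatsConfigError(
            f"{path}: need a Z column or both BETA and SE columns")
    if "n" not in cols and n_const is None:
        raise SumStatsConfigError(
            f"{path}: no N column and no constant sample size supplied")
    out = pd.DataFrame({
        "variant_id": raw[cols["variant_id"]].astype(str),
        "a1": raw[cols["a1"]].astype(str).str.upper(),
        "a2": raw[cols["a2"]].astype(str).str.upper(),
    })
    for opt in ("chrom", "pos"):
        if opt in cols:
            out[opt] = pd.to_numeric(raw[cols[opt]], errors="coerce")
    if "z" in cols:
        out["z"] = pd.to_numeric(raw[cols["z"]], errors="coerce")
    else:
        beta = pd.to_numeric(raw[cols["beta"]], errors="coerce")
        se = pd.to_numeric(raw[cols["se"]], errors="coerce")
        out["z"] = beta / se.replace(0.0, np.nan)
    out["n"] = (pd.to_numeric(raw[cols["n"]], errors="coerce")
                if "n" in cols else float(n_const))
    for opt in ("info", "freq"):
        out[opt] = (pd.to_numeric(raw[cols[opt]], errors="coerce")
                    if opt in cols else np.nan)
    log = {"rows_in": len(out)}
    bad = ~np.isfinite(out["z"]) | ~(out["n"] > 0)
    log["dropped_missing"] = int(bad.sum())
    out = out[~bad]
    dup = out["variant_id"].duplicated(keep=False)
    log["dropped_duplicate_id"] = int(dup.sum())
    out = out[~dup].reset_index(drop=True)
    log["rows_out"] = len(out)
    if len(out) == 0:
        raise SumStatsInputError(f"{path}: zero parseable rows")
    return out, log


def _is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return a2 == a1.str.translate(_COMPLEMENT)


@dataclass
class HarmonizedData:
    """Z/N matrices aligned to panel indices for three traits."""

    panel_idx: np.ndarray   # (m,) indices into the panel variant table
    z: np.ndarray           # (m, 3)
    n: np.ndarray           # (m, 3)
    info: np.ndarray        # (m, 3), NaN where absent
    log: dict = field(default_factory=dict)


def harmonize(tables, panel_variants: pd.DataFrame) -> HarmonizedData:
    """Align three tables to the panel's variant list and allele orientation.

    Variants present in all three tables and the panel are retained; a table
    row whose (a1, a2) equals the panel's (a2, a1) has its z sign flipped;
    strand-ambiguous (A/T, C/G) variants and allele mismatches are dropped
    and counted per trait.
    """
    if len(tables) != 3:
        raise ValueError("harmonize expects exactly three tables")
    panel = panel_variants.reset_index(drop=True)
    pidx = pd.Series(np.arange(len(panel)), index=panel["id"].astype(str))
    pa1 = panel["a1"].astype(str).str.upper().to_numpy()
    pa2 = panel["a2"].astype(str).str.upper().to_numpy()
    log: dict = {}
    aligned = []
    for t, tab in enumerate(tables):
        loc = pidx.reindex(tab["variant_id"])
        in_panel = loc.notna().to_numpy()
        log[f"trait{t + 1}_not_in_panel"] = int((~in_panel).sum())
        sub = tab[in_panel].copy()
        rows = loc[in_panel].to_numpy(dtype=np.int64)
        palin = _is_palindromic(sub["a1"], sub["a2"]).to_numpy()
        same = (sub["a1"].to_numpy() == pa1[rows]) & (sub["a2"].to_numpy() == pa2[rows])
        swap = (sub["a1"].to_numpy() == pa2[rows]) & (sub["a2"].to_numpy() == pa1[rows])
        log[f"trait{t + 1}_palindromic"] = int((palin & (same | swap)).sum())
        log[f"trait{t + 1}_allele_mismatch"] = int((~same & ~swap).sum())
        ok = (same | swap) & ~palin
        sub = sub[ok]
        rows = rows[ok]
        z = sub["z"].to_numpy(dtype=float)
        z[swap[ok]] *= -1.0
        aligned.append(pd.DataFrame({
            "row": rows, "z": z,
            "n": sub["n"].to_numpy(dtype=float),
            "info": sub["info"].to_numpy(dtype=float),
        }).set_index("row"))
    common = aligned[0].index
    for a in aligned[1:]:
        common = common.intersection(a.index)
    common = np.sort(common.to_numpy())
    if common.size == 0:
        raise SumStatsInputError("no variants shared by all three tables and the panel")
    log["retained"] = int(common.size)
    z = np.column_stack([a.loc[common, "z"].to_numpy() for a in aligned])
    n = np.column_stack([a.loc[common, "n"].to_numpy() for a in aligned])
    info = np.column_stack([a.loc[common, "info"].to_numpy() for a in aligned])
    return HarmonizedData(panel_idx=common, z=z, n=n, info=info, log=log)


@dataclass(frozen=True)
class FilterConfig:
    """Variant-selection thresholds (inclusive boundaries retain)."""

    maf_thresh: float = 0.05
    info_thresh: float = 0.8
    z_thresh: float = 32.0
    exclude_regions: tuple = (("6", 25_000_000, 34_000_000),)

    def __post_init__(self) -> None:
        if not (0 <= self.maf_thresh <= 0.5):
            raise ValueError("maf_thresh must lie in [0, 0.5]")
        if not (0 <= self.info_thresh <= 1):
            raise ValueError("info_thresh must lie in [0, 1]")
        if self.z_thresh <= 0:
            raise ValueError("z_thresh must be positive")
        regions = []
        for chrom, start, end in self.exclude_regions:
            if start > end:
                raise ValueError(f"region {chrom}:{start}-{end} has start > end")
            regions.append((str(chrom), int(start), int(end)))
        object.__setattr__(self, "exclude_regions", tuple(regions))


def apply_filters(harm: HarmonizedData, cfg: FilterConfig,
                  panel_variants: pd.DataFrame) -> tuple[np.ndarray, dict]:
    """Boolean retention mask over harmonized rows, plus drop counts.

    A variant is retained iff the panel MAF is >= maf_thresh, every trait's
    INFO is missing or >= info_thresh, every trait's |z| is <= z_thresh, and
    its position lies outside all excluded regions (1-based inclusive).
    Frequencies come from the LD panel, matching how a reference panel's
    genotypes define MAF.
    """
    panel = panel_variants.reset_index(drop=True)
    idx = harm.panel_idx
    freq = panel["freq"].to_numpy()[idx]
    maf = np.minimum(freq, 1.0 - freq)
    ok_maf = maf >= cfg.maf_thresh
    info = harm.info
    ok_info = np.all(np.isnan(info) | (info >= cfg.info_thresh), axis=1)
    ok_z = np.all(np.abs(harm.z) <= cfg.z_thresh, axis=1)
    chrom = panel["chrom"].astype(str).to_numpy()[idx]
    pos = panel["pos"].to_numpy()[idx]
    in_region = np.zeros(idx.size, dtype=bool)
    for rchrom, start, end in cfg.exclude_regions:
        in_region |= (chrom == rchrom) & (pos >= start) & (pos <= end)
    mask = ok_maf & ok_info & ok_z & ~in_region
    log = {
        "variants_in": int(idx.size),
        "dropped_maf": int((~ok_maf).sum()),
        "dropped_info": int((ok_maf & ~ok_info).sum()),
        "dropped_z": int((ok_maf & ok_info & ~ok_z).sum()),
        "dropped_region": int((ok_maf & ok_info & ok_z & in_region).sum()),
        "retained": int(mask.sum()),
    }
    return mask, log
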