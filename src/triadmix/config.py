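"""JSON configuration with the analysis defaults used throughout.

Defaults follow the standard settings for summary-statistics causal mixture
fits: MAF >= 5%, INFO >= 0.8, |z| <= 32, the MHC (chr6:25,000,000-34,000,000,
hg19) excluded, random pruning at r2 < 0.8, 300,000 tag variants per run,
seed 1.  Region strings are written CHR:START-END (comma separators and an
en dash are accepted).
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, asdict, fields as dc_fields


class ConfigError(ValueError):
    pass


_REGION_RE = re.compile(r"^\s*(\w+)\s*:\s*([\d,]+)\s*[-–—]\s*([\d,]+)\s*$")


def parse_region(text: str) -> tuple[str, int, int]:
    """Parse 'CHR:START-END' (1-based inclusive; commas and en dash ok)."""
    m = _REGION_RE.match(str(text))
    if not m:
        raise ConfigError(f"cannot parse region {text!r} (expect CHR:START-END)")
    chrom = m.group(1)
    start = int(m.group(2).replace(",", ""))
    end = int(m.group(3).replace(",", ""))
    if start > end:
        raise ConfigError(f"region {text!r} has start > end")
    return (chrom, start, end)


@dataclass
class Config:
    """Analysis configuration (JSON-serializable)."""

    sumstats: tuple = ()            # three file paths
    ld_files: tuple = ()            # per-chromosome PLINK --r2 text files
    panel_meta: str | None = None   # panel variant table (ID CHR BP A1 A2 FRQ)
    maf_thresh: float = 0.05
    info_thresh: float = 0.8
    z_thresh: float = 32.0
    exclude_regions: tuple = ("6:25,000,000-34,000,000",)
    do_pruning: bool = True
    r2_prune_thresh: float = 0.8
    n_random: int = 300_000
    rand_prune_seed: int | tuple = 1
    n_random_bivariate: int | None = None   # optional 2-D stage subsample
    n_random_trivariate: int | None = None  # optional 3-D stage subsample
    n_const: float | None = None    # constant N when sumstats lack an N column
    column_maps: tuple = (None, None, None)
    grid_overrides: dict = field(default_factory=dict)
    out_dir: str = "triadmix_out"

    def __post_init__(self) -> None:
        if not (0 <= self.maf_thresh <= 0.5):
            raise ConfigError("maf_thresh must lie in [0, 0.5]")
        if not (0 <= self.info_thresh <= 1):
            raise ConfigError("info_thresh must lie in [0, 1]")
        if self.z_thresh <= 0:
            raise ConfigError("z_thresh must be positive")
        if not (0 < self.r2_prune_thresh <= 1):
            raise ConfigError("r2_prune_thresh must lie in (0, 1]")
        if self.n_random < 1:
            raise ConfigError("n_random must be >= 1")
        parsed = []
        for reg in self.exclude_regions:
            parsed.append(reg if isinstance(reg, tuple) else parse_region(reg))
        self.exclude_regions = tuple(parsed)
        if isinstance(self.sumstats, list):
            self.sumstats = tuple(self.sumstats)
        if isinstance(self.ld_files, list):
            self.ld_files = tuple(self.ld_files)
        if isinstance(self.rand_prune_seed, list):
            self.rand_prune_seed = tuple(self.rand_prune_seed)
        if isinstance(self.column_maps, list):
            self.column_maps = tuple(self.column_maps)

    @property
    def seeds(self) -> tuple[int, ...]:
        s = self.rand_prune_seed
        return (int(s),) if isinstance(s, (int, float)) else tuple(int(x) for x in s)

    def filter_config(self):
        from .sumstats import FilterConfig
        return FilterConfig(maf_thresh=self.maf_thresh,
                            info_thresh=self.info_thresh,
                            z_thresh=self.z_thresh,
                            exclude_regions=self.exclude_regions)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["exclude_regions"] = [f"{c}:{s}-{e}" for c, s, e in self.exclude_regions]
        return d

    def digest(self) -> str:
        """Short provenance hash of the canonical JSON form."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_config(path) -> Config:
    """Load a JSON config; unknown keys are rejected, missing keys defaulted."""
    try:
        with open(path) as fh:
            raw = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: malformed JSON at line {exc.lineno}, "
                          f"column {exc.colno}: {exc.msg}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top-level JSON value must be an object")
    known = {f.name for f in dc_fields(Config)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {unknown}")
    try:
        return Config(**raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
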