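"""File-based assembly: sumstats + LD panel -> model ready to fit."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import Config, ConfigError
from .data import JointDataset
from .ld import load_ld_text
from .sumstats import apply_filters, harmonize, read_sumstats

logger = logging.getLogger(__name__)

_PANEL_COLS = {"ID": "id", "CHR": "chrom", "BP": "pos",
               "A1": "a1", "A2": "a2", "FRQ": "freq"}


def read_panel_meta(path) -> pd.DataFrame:
    """Panel variant table: delimited text with ID CHR BP A1 A2 FRQ columns."""
    df = pd.read_csv(path, sep=r"\s+", dtype={"ID": str})
    missing = [c for c in _PANEL_COLS if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: panel table missing column(s) {missing}")
    out = df.rename(columns=_PANEL_COLS)[list(_PANEL_COLS.values())]
    out["a1"] = out["a1"].str.upper()
    out["a2"] = out["a2"].str.upper()
    return out


def build_model_from_config(config: Config, model_cls=None):
    """Read, harmonize, filter; return a model over the candidate variants."""
    if model_cls is None:
        from .fitting import TriadMixtureModel as model_cls
    if len(config.sumstats) != 3:
        raise ConfigError("config must list exactly three sumstats paths")
    if config.panel_meta is None:
        raise ConfigError("config must set panel_meta")
    meta = read_panel_meta(config.panel_meta)
    panel = load_ld_text(list(config.ld_files), meta)
    tables = []
    for path, cmap in zip(config.sumstats, config.column_maps):
        tab, log = read_sumstats(path, column_map=cmap, n_const=config.n_const)
        logger.info("read %s: %s", path, log)
        tables.append(tab)
    harm = harmonize(tables, panel.variants)
    logger.info("harmonized: %s", harm.log)
    mask, flog = apply_filters(harm, config.filter_config(), panel.variants)
    logger.info("filters: %s", flog)
    idx = np.flatnonzero(mask)
    data = JointDataset.from_panel(panel, harm.z[idx], harm.n[idx],
                                   harm.panel_idx[idx])
    return model_cls(data, panel=panel, config=config)
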