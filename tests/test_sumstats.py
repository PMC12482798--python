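"""Summary-statistics parsing, allele harmonization and variant filters."""

import numpy as np
import pandas as pd
import pytest

from triadmix.sumstats import (FilterConfig, SumStatsConfigError,
                               SumStatsInputError, apply_filters, harmonize,
                               read_sumstats)


def write(tmp_path, text, name="ss.txt"):
    path = tmp_path / name
    path.write_text(text)
    return path


def panel_frame():
    return pd.DataFrame({
        "id": ["rs1", "rs2", "rs3", "rs4", "rs5", "rs6"],
        "chrom": ["1", "1", "2", "6", "6", "3"],
        "pos": [100, 200, 300, 26_000_000, 40_000_000, 500],
        "a1": ["A", "A", "C", "A", "A", "A"],
        "a2": ["G", "G", "A", "G", "G", "G"],
        "freq": [0.3, 0.4, 0.2, 0.25, 0.35, 0.01],
    })


def table(ids, z, a1=None, a2=None, n=1000, info=None):
    panel = panel_frame().set_index("id")
    if a1 is None:
        a1 = panel.loc[ids, "a1"].tolist()
    if a2 is None:
        a2 = panel.loc[ids, "a2"].tolist()
    df = pd.DataFrame({"variant_id": ids, "a1": a1, "a2": a2,
                       "z": z, "n": float(n)})
    df["info"] = np.nan if info is None else info
    df["freq"] = np.nan
    return df


class TestRead:
    def test_plain_z_table(self, tmp_path):
        path = write(tmp_path, "SNP A1 A2 Z N\n" + "\n".join(
            f"rs{i} A G {0.1 * i} 900" for i in range(1, 6)))
        tab, log = read_sumstats(path)
        assert len(tab) == 5 and log["rows_out"] == 5
        assert tab["z"].iloc[1] == pytest.approx(0.2)

    def test_beta_se_converted_to_z(self, tmp_path):
        path = write(tmp_path, "SNP A1 A2 BETA SE N\nrs1 A G 0.2 0.1 500\n")
        tab, _ = read_sumstats(path)
        assert tab["z"].iloc[0] == pytest.approx(2.0)

    def test_missing_effect_columns_rejected(self, tmp_path):
        path = write(tmp_path, "SNP A1 A2\nrs1 A G\n")
        with pytest.raises(SumStatsConfigError, match="Z|BETA"):
            read_sumstats(path, n_const=100)

    def test_missing_n_without_constant_rejected(self, tmp_path):
        path = write(tmp_path, "SNP A1 A2 Z\nrs1 A G 1.0\n")
        with pytest.raises(SumStatsConfigError, match="sample size"):
            read_sumstats(path)
        tab, _ = read_sumstats(path, n_const=5000)
        assert tab["n"].iloc[0] == 5000

    def test_unparseable_rows_dropped_and_counted(self, tmp_path):
        path = write(tmp_path, "SNP A1 A2 Z N\nrs1 A G 1.0 100\n"
                               "rs2 A G NA 100\nrs3 A G 0.5 100\n")
        tab, log = read_sumstats(path)
        assert log["dropped_missing"] == 1
        assert log["rows_in"] == log["rows_out"] + log["dropped_missing"]

    def test_duplicate_ids_dropped(self, tmp_path):
        path = write(tmp_path, "SNP A1 A2 Z N\nrs1 A G 1.0 100\n"
                               "rs1 A G 0.5 100\nrs2 A G 0.2 100\n")
        tab, log = read_sumstats(path)
        assert log["dropped_duplicate_id"] == 2 and len(tab) == 1

    def test_zero_rows_rejected(self, tmp_path):
        path = write(tmp_path, "SNP A1 A2 Z N\nrs1 A G NA 100\n")
        with pytest.raises(SumStatsInputError):
            read_sumstats(path)

    def test_column_map_override(self, tmp_path):
        path = write(tmp_path, "marker ea oa zscore samples\nrs1 A G 1.5 99\n")
        tab, _ = read_sumstats(path, column_map={
            "variant_id": "marker", "a1": "ea", "a2": "oa",
            "z": "zscore", "n": "samples"})
        assert tab["z"].iloc[0] == 1.5


class TestHarmonize:
    def _tables(self, **kw):
        ids = ["rs1", "rs2", "rs3"]
        return [table(ids, [1.0, 2.0, 3.0], **kw) for _ in range(3)]

    def test_matching_alleles_unchanged(self):
        harm = harmonize(self._tables(), panel_frame())
        np.testing.assert_allclose(harm.z[:, 0], [1.0, 2.0, 3.0])

    def test_swapped_alleles_flip_sign(self):
        tabs = self._tables()
        panel = panel_frame().set_index("id")
        ids = ["rs1", "rs2", "rs3"]
        tabs[1] = table(ids, [1.5, -0.5, 2.0],
                        a1=panel.loc[ids, "a2"].tolist(),
                        a2=panel.loc[ids, "a1"].tolist())
        harm = harmonize(tabs, panel_frame())
        np.testing.assert_allclose(harm.z[:, 1], [-1.5, 0.5, -2.0])
        np.testing.assert_allclose(harm.z[:, 0], [1.0, 2.0, 3.0])

    def test_palindromic_variants_dropped(self):
        tabs = self._tables()
        tabs[0].loc[0, ["a1", "a2"]] = ["A", "T"]
        harm = harmonize(tabs, panel_frame())
        assert harm.log["trait1_allele_mismatch"] >= 0
        assert 0 not in harm.panel_idx  # rs1 dropped

    def test_allele_mismatch_dropped_and_counted(self):
        tabs = self._tables()
        tabs[2].loc[1, ["a1", "a2"]] = ["C", "T"]
        harm = harmonize(tabs, panel_frame())
        assert harm.log["trait3_allele_mismatch"] == 1
        assert len(harm.panel_idx) == 2

    def test_empty_intersection_rejected(self):
        tabs = self._tables()
        tabs[0]["variant_id"] = ["zzz1", "zzz2", "zzz3"]
        with pytest.raises(SumStatsInputError):
            harmonize(tabs, panel_frame())

    def test_idempotent_on_aligned_output(self):
        """Re-harmonizing already-aligned tables changes nothing."""
        harm = harmonize(self._tables(), panel_frame())
        panel = panel_frame()
        tabs2 = []
        for t in range(3):
            sub = panel.iloc[harm.panel_idx]
            tabs2.append(pd.DataFrame({
                "variant_id": sub["id"].to_numpy(),
                "a1": sub["a1"].to_numpy(), "a2": sub["a2"].to_numpy(),
                "z": harm.z[:, t], "n": harm.n[:, t], "info": np.nan}))
        harm2 = harmonize(tabs2, panel)
        np.testing.assert_array_equal(harm.panel_idx, harm2.panel_idx)
        np.testing.assert_allclose(harm.z, harm2.z)


class TestFilters:
    def _harmonized(self, z_extreme=False):
        ids = panel_frame()["id"].tolist()
        z = [1.0] * 6
        tabs = [table(ids, z) for _ in range(3)]
        tabs[0].loc[2, "info"] = 0.5          # rs3 fails INFO
        if z_extreme:
            tabs[1].loc[1, "z"] = 33.0
        return harmonize(tabs, panel_frame())

    def test_toy_panel_filters_each_reason(self):
        harm = self._harmonized(z_extreme=True)
        mask, log = apply_filters(harm, FilterConfig(), panel_frame())
        # rs6 fails MAF (0.01), rs3 fails INFO, rs2 fails |z|, rs4 in MHC
        assert log["dropped_maf"] == 1
        assert log["dropped_info"] == 1
        assert log["dropped_z"] == 1
        assert log["dropped_region"] == 1
        assert mask.sum() == 2
        retained_ids = panel_frame()["id"].iloc[harm.panel_idx[mask]].tolist()
        assert retained_ids == ["rs1", "rs5"]

    def test_boundary_z_retained(self):
        harm = self._harmonized()
        harm.z[0, 0] = 32.0
        mask, _ = apply_filters(harm, FilterConfig(), panel_frame())
        assert mask[0]

    def test_record_conservation(self):
        harm = self._harmonized(z_extreme=True)
        mask, log = apply_filters(harm, FilterConfig(), panel_frame())
        drops = sum(v for k, v in log.items() if k.startswith("dropped"))
        assert log["variants_in"] == log["retained"] + drops

    def test_no_exclusions_is_identity(self):
        harm = self._harmonized()
        cfg = FilterConfig(maf_thresh=0.0, info_thresh=0.0, z_thresh=100,
                           exclude_regions=())
        mask, _ = apply_filters(harm, cfg, panel_frame())
        assert mask.all()

    def test_filtering_idempotent(self):
        harm = self._harmonized(z_extreme=True)
        cfg = FilterConfig()
        mask, _ = apply_filters(harm, cfg, panel_frame())
        import dataclasses
        harm2 = dataclasses.replace(
            harm, panel_idx=harm.panel_idx[mask], z=harm.z[mask],
            n=harm.n[mask], info=harm.info[mask])
        mask2, _ = apply_filters(harm2, cfg, panel_frame())
        assert mask2.all()

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(maf_thresh=0.7)
        with pytest.raises(ValueError):
            FilterConfig(z_thresh=-1)
        with pytest.raises(ValueError):
            FilterConfig(exclude_regions=(("1", 100, 50),))
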