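import io as stdio

import numpy as np
import pandas as pd
import pytest

from lakech4 import compilation as comp


HEADER = "site_id,lat,lon,pathway,flux,month,sampling_window,method"


def read_csv_text(text: str) -> pd.DataFrame:
    return comp.read_compilation(stdio.StringIO(text))


class TestReadCompilation:
    def test_header_only_file_gives_empty_collection(self):
        assert len(read_csv_text(HEADER + "\n")) == 0

    def test_named_month_parsing(self):
        df = read_csv_text(HEADER + "\ns1,60.0,10.0,diffusion,12.5,July,daytime,direct\n")
        assert df["month"].iloc[0] == 7

    @pytest.mark.parametrize("value, expected", [("3", 3), ("nonsense", np.nan),
                                                 ("13", np.nan), ("aug", 8)])
    def test_month_values(self, value, expected):
        df = read_csv_text(HEADER + f"\ns1,60.0,10.0,diffusion,12.5,{value},24h,direct\n")
        got = df["month"].iloc[0]
        assert got == expected or (np.isnan(got) and np.isnan(expected))

    def test_missing_required_column_names_it(self):
        with pytest.raises(comp.SchemaError, match="sampling_window"):
            read_csv_text("site_id,lat,lon,pathway,flux,month,method\n")

    def test_round_trip_preserves_count(self, small_world, tmp_path):
        path = tmp_path / "c.csv"
        comp.write_compilation(small_world.records, path)
        again = comp.read_compilation(path)
        assert len(again) == len(small_world.records)
        np.testing.assert_allclose(again["flux"].values,
                                   small_world.records["flux"].values)


class TestFilterRecords:
    def _records(self, **overrides):
        base = dict(site_id="s1", lat=60.0, lon=5.0, pathway="diffusion", flux=10.0,
                    month=6.0, sampling_window="daytime", method="direct",
                    system_class="lake", components=None, diel_corrected=False,
                    record_id=0)
        base.update(overrides)
        return pd.DataFrame([base])

    @pytest.mark.parametrize(
        "overrides, reason",
        [
            (dict(method="indirect"), comp.REASON_INDIRECT),
            (dict(system_class="beaver_pond"), comp.REASON_BEAVER_POND),
            (dict(pathway=None), comp.REASON_MISSING_PATHWAY),
            (dict(month=np.nan), comp.REASON_MISSING_MONTH),
            (dict(sampling_window=None), comp.REASON_MISSING_WINDOW),
            # precedence: indirect outranks every later reason
            (dict(method="indirect", month=np.nan), comp.REASON_INDIRECT),
            (dict(system_class="beaver_pond", pathway=None), comp.REASON_BEAVER_POND),
        ],
    )
    def test_single_primary_rejection_reason(self, overrides, reason):
        kept, rejected = comp.filter_records(self._records(**overrides))
        assert len(kept) == 0
        assert rejected["reason"].iloc[0] == reason

    def test_fully_specified_direct_lake_record_is_kept(self):
        kept, rejected = comp.filter_records(self._records())
        assert len(kept) == 1 and len(rejected) == 0

    def test_partition_is_exhaustive_and_disjoint(self, small_world):
        kept, rejected = comp.filter_records(small_world.records)
        assert len(kept) + len(rejected) == len(small_world.records)
        assert set(kept["record_id"]).isdisjoint(rejected["record_id"])

    def test_rejection_tally_matches_planted_contamination(self, small_world):
        """The generator plants known violation counts per category."""
        cfg = small_world.cfg
        n = len(small_world.records)
        _, rejected = comp.filter_records(small_world.records)
        counts = rejected["reason"].value_counts()
        n_missing = int(round(cfg.missing_metadata_fraction * n))
        expected = {
            comp.REASON_INDIRECT: int(round(cfg.indirect_fraction * n)),
            comp.REASON_BEAVER_POND: int(round(cfg.beaver_pond_fraction * n)),
            comp.REASON_MISSING_PATHWAY: n_missing // 3,
            comp.REASON_MISSING_MONTH: n_missing // 3,
            comp.REASON_MISSING_WINDOW: n_missing - 2 * (n_missing // 3),
        }
        assert counts.to_dict() == expected


class TestDisaggregate:
    def _record(self, flux, components):
        return pd.DataFrame([
            dict(record_id="r0", site_id="s1", flux=flux, components=components,
                 pathway="diffusion", month=6.0, n_underlying=len(components or [1]))
        ])

    def test_component_record_expands(self):
        out = comp.disaggregate(self._record(10.0, [5.0, 15.0]))
        assert sorted(out["flux"]) == [5.0, 15.0]
        assert (out["pathway"] == "diffusion").all()

    def test_record_without_components_unchanged(self):
        df = self._record(10.0, None)
        out = comp.disaggregate(df)
        pd.testing.assert_frame_equal(out.reset_index(drop=True), df)

    def test_count_identity(self, small_world):
        df = small_world.records
        k = df["components"].map(lambda c: len(c) if isinstance(c, list) else 1)
        out = comp.disaggregate(df)
        assert len(out) == len(df) + int((k - 1).sum())

    def test_inconsistent_mean_warns_but_uses_components(self, caplog):
        with caplog.at_level("WARNING"):
            out = comp.disaggregate(self._record(99.0, [5.0, 15.0]))
        assert "differs" in caplog.text
        assert sorted(out["flux"]) == [5.0, 15.0]


class TestDielCorrection:
    def _df(self):
        return pd.DataFrame(
            {
                "flux": [100.0, 100.0],
                "sampling_window": ["daytime", "24h"],
                "diel_corrected": [False, False],
            }
        )

    def test_daytime_scaled_24h_unchanged(self):
        out = comp.apply_diel_correction(self._df())
        assert out["flux"].tolist() == [70.0, 100.0]

    def test_correction_is_linear_over_groups(self):
        df = self._df()
        out = comp.apply_diel_correction(df)
        day = df.loc[df["sampling_window"] == "daytime", "flux"].sum()
        full = df.loc[df["sampling_window"] == "24h", "flux"].sum()
        assert out["flux"].sum() == pytest.approx(0.7 * day + full)

    def test_double_application_refused(self):
        out = comp.apply_diel_correction(self._df())
        with pytest.raises(ValueError, match="already applied"):
            comp.apply_diel_correction(out)

    def test_missing_window_is_contract_violation(self):
        df = self._df()
        df.loc[0, "sampling_window"] = None
        with pytest.raises(ValueError, match="missing sampling window"):
            comp.apply_diel_correction(df)


class TestAssignLakeType:
    def test_explicit_label_wins(self, small_result):
        df = pd.DataFrame([dict(record_id=0, lake_type="thermokarst",
                                lat=0.0, lon=0.0)])
        out, rejected = comp.assign_lake_type(df, small_result.type_map)
        assert out["lake_type"].iloc[0] == "thermokarst"

    def test_out_of_domain_rejected(self, small_result):
        df = pd.DataFrame([dict(record_id=0, lake_type=None, lat=60.0, lon=170.0)])
        out, rejected = comp.assign_lake_type(df, small_result.type_map)
        assert len(out) == 0
        assert rejected["reason"].iloc[0] == comp.REASON_OUT_OF_DOMAIN

    def test_assigned_labels_match_generator_truth(self, small_world, small_result):
        """Round trip: cell-classified labels equal the embedded true types."""
        kept, _ = comp.filter_records(small_world.records)
        labelled, rejected = comp.assign_lake_type(kept, small_result.type_map)
        assert len(rejected) == 0
        truth = kept.loc[labelled.index, "true_lake_type"]
        assert (labelled["lake_type"] == truth).all()
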