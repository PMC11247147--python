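"""Bundle validation, serialisation round-trips, proxies and table fixtures."""
import pytest

from ckdsim import input_model as im
from ckdsim import load_country_bundle, resolve_proxy, save_country_bundle
from ckdsim.synthetic_data import generate_bundle


class TestBundleValidation:
    def test_round_trip_is_identity(self, tmp_path, small_aged_bundle):
        path = tmp_path / "bundle.yaml"
        save_country_bundle(small_aged_bundle, path)
        reloaded = load_country_bundle(path)
        assert reloaded.model_dump() == small_aged_bundle.model_dump()
        assert set(reloaded.population_by_year) == set(range(2022, 2028))

    def test_stage_row_not_summing_to_one_rejected(self, small_aged_bundle):
        payload = small_aged_bundle.model_dump()
        payload["stage_distribution"]["65+"]["F"]["none"] -= 0.02
        with pytest.raises(ValueError, match="stage_distribution"):
            im.CountryInputBundle.model_validate(payload)

    def test_missing_year_rejected(self, small_aged_bundle):
        payload = small_aged_bundle.model_dump()
        del payload["population_by_year"][2027]
        with pytest.raises(ValueError, match="2027"):
            im.CountryInputBundle.model_validate(payload)

    def test_probability_out_of_range_rejected(self, small_aged_bundle):
        payload = small_aged_bundle.model_dump()
        payload["diagnosis_rate_by_stage"]["G3a"] = 1.2
        with pytest.raises(ValueError, match="G3a"):
            im.CountryInputBundle.model_validate(payload)

    def test_incomplete_grid_rejected(self):
        with pytest.raises(ValueError, match="missing cells"):
            im.KdigoRiskGrid(category={"G1/A1": "low"}, rr={})

    def test_low_category_rr_must_be_one(self, small_aged_bundle):
        grid = small_aged_bundle.kdigo_grid.model_dump()
        grid["rr"]["low"]["death"] = 1.5
        with pytest.raises(ValueError, match="low"):
            im.KdigoRiskGrid.model_validate(grid)

    def test_modality_shares_must_sum_to_one(self):
        with pytest.raises(ValueError, match="modality_shares"):
            im.KrtParameters(egfr_initiation_threshold=10,
                             access_probability=0.5,
                             modality_shares={"HD": 0.6, "PD": 0.3})


class TestResolveProxy:
    def _incomplete(self):
        b = generate_bundle("small_aged", seed=3)
        payload = b.model_dump()
        payload["diagnosis_rate_by_stage"] = None
        payload["country_code"] = "TARGET"
        return im.CountryInputBundle.model_validate(payload)

    def test_first_donor_in_priority_wins(self):
        target = self._incomplete()
        x = generate_bundle("small_aged", seed=4, country_code="X")
        y = generate_bundle("large_young", seed=5, country_code="Y")
        filled = resolve_proxy(target, "diagnosis_rate_by_stage", [x, y],
                               ["X", "Y"])
        assert filled.diagnosis_rate_by_stage == x.diagnosis_rate_by_stage
        assert filled.metadata["proxy_sources"]["diagnosis_rate_by_stage"] == "X"

    def test_falls_back_to_later_donor(self):
        target = self._incomplete()
        x_payload = generate_bundle("small_aged", seed=4).model_dump()
        x_payload.update(country_code="X", diagnosis_rate_by_stage=None)
        x = im.CountryInputBundle.model_validate(x_payload)
        y = generate_bundle("large_young", seed=5, country_code="Y")
        filled = resolve_proxy(target, "diagnosis_rate_by_stage", [x, y],
                               ["X", "Y"])
        assert filled.metadata["proxy_sources"]["diagnosis_rate_by_stage"] == "Y"

    def test_no_donor_has_field_raises_listing_donors(self):
        target = self._incomplete()
        x_payload = generate_bundle("small_aged", seed=4).model_dump()
        x_payload.update(country_code="X", diagnosis_rate_by_stage=None)
        x = im.CountryInputBundle.model_validate(x_payload)
        with pytest.raises(LookupError, match="X"):
            resolve_proxy(target, "diagnosis_rate_by_stage", [x], ["X"])

    def test_never_overwrites_present_field(self, small_aged_bundle):
        donor = generate_bundle("large_young", seed=9, country_code="D")
        with pytest.raises(ValueError, match="already present"):
            resolve_proxy(small_aged_bundle, "diagnosis_rate_by_stage",
                          [donor], ["D"])


class TestPublishedTables:
    def test_row_counts(self, tables):
        assert len(tables.demographics) == 31
        assert len(tables.cv_complications) == 31
        assert len(tables.prevalence) == 31 * 4
        assert len(tables.countries) == 31

    def test_demographics_spot_cells(self, tables):
        d = tables.demographics.set_index("country")
        assert d.loc["USA", "population_2027"] == 344_100_699
        assert d.loc["Brazil", "population_2022"] == 215_353_588
        assert d.loc["China", "population_2022"] == 1_448_471_404
        assert d.loc["Japan", "age_65_plus_pct"] == 28.9
        assert d.loc["UAE Emirati", "age_65_plus_pct"] == 3.6
        assert d.loc["Saudi Arabia", "male_pct"] == 57.8

    def test_prevalence_spot_cells(self, tables):
        p = tables.prevalence.set_index(["country", "status", "year"])
        assert p.loc[("USA", "diagnosed", 2027), "total"] == 3394
        assert p.loc[("Brazil", "diagnosed", 2022), "total"] == 2963
        assert p.loc[("Brazil", "diagnosed", 2022),
                     "pct_change_2022_2027"] == 7.8
        assert p.loc[("China", "undiagnosed", 2027), "total"] == 7516
        assert p.loc[("Japan", "undiagnosed", 2022), "total"] == 12860
        assert p.loc[("Japan", "diagnosed", 2027), "total"] == 6514

    def test_cv_spot_cells(self, tables):
        cv = tables.cv_complications.set_index("country")
        assert cv.loc["Brazil", "heart_failure"] == 7595
        assert cv.loc["USA", "stroke"] == 12876
        assert cv.loc["Germany", "total"] == 2735
        assert cv.loc["Japan", "myocardial_infarction"] == 21231
        assert cv.loc["Poland", "stroke"] == 44838

    def test_internal_row_sums_match_printed_totals(self, tables):
        # stage cells were transcribed under a sum-to-total constraint
        p = tables.prevalence
        stage_sum = p[["g1", "g2", "g3a", "g3b", "g4", "g5"]].sum(axis=1)
        assert (stage_sum - p["total"]).abs().max() <= 6
        cv = tables.cv_complications
        parts = cv[["heart_failure", "myocardial_infarction", "stroke"]].sum(axis=1)
        assert (parts - cv["total"]).abs().max() <= 3

    def test_missing_rows_raise(self, tmp_path, tables):
        d = im.fixture_dir()
        for f in d.glob("*.csv"):
            (tmp_path / f.name).write_text(f.read_text())
        trimmed = tables.demographics.iloc[:-1]
        trimmed.to_csv(tmp_path / "demographics.csv", index=False)
        with pytest.raises(ValueError, match="expected 31"):
            im.load_published_tables(tmp_path)
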