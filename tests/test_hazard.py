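import pytest

from herbtrends import hazard as hz
from herbtrends.errors import MissingDataError, ValidationError
from herbtrends.survey_io import CropAreaRecord, ToxicityProfile, UseRecord

AREAS = [CropAreaRecord("maize", 1990, 100.0)]


def profile(ai, ld50=1000.0, noel=10.0, censored=False):
    return ToxicityProfile(ai=ai, acute_ld50=ld50, acute_censored=censored, chronic_noel=noel)


class TestCensorLd50:
    def test_censored_bound(self):
        assert hz.censor_ld50(">5,000") == (5000.0, True)

    def test_plain_number(self):
        assert hz.censor_ld50("112") == (112.0, False)

    def test_numeric_input(self):
        assert hz.censor_ld50(3556) == (3556.0, False)

    @pytest.mark.parametrize("raw", [">0", "0", "-12", ">-5"])
    def test_nonpositive_rejected(self, raw):
        with pytest.raises(ValidationError):
            hz.censor_ld50(raw)

    def test_unparsable_rejected(self):
        with pytest.raises(ValidationError):
            hz.censor_ld50("about five thousand")


class TestHazardQuotient:
    def test_single_term(self):
        # 5,000 mg/ha over toxicity 50 -> hq 100
        records = [UseRecord("maize", 1990, "atrazine", 5000e-6 * 100.0, 1.0)]
        res = hz.hazard_quotient(records, AREAS, [profile("atrazine", noel=50.0)], "chronic")
        assert res.hq == pytest.approx(100.0)
        assert res.contributions[0].share_pct == pytest.approx(100.0)

    def test_empty_records(self):
        res = hz.hazard_quotient([], AREAS, [], "chronic")
        assert res.hq == 0.0
        assert res.contributions == ()

    def test_two_terms_forced_arithmetic(self):
        records = [
            UseRecord("maize", 1990, "a", 1000e-6 * 100.0, 1.0),  # 1000 mg/ha, tox 10
            UseRecord("maize", 1990, "b", 500e-6 * 100.0, 1.0),  # 500 mg/ha, tox 100
        ]
        profiles = [profile("a", noel=10.0), profile("b", noel=100.0)]
        res = hz.hazard_quotient(records, AREAS, profiles, "chronic")
        assert res.hq == pytest.approx(105.0)
        shares = {c.ai: c.share_pct for c in res.contributions}
        assert shares["a"] == pytest.approx(100 * 100 / 105)
        assert shares["b"] == pytest.approx(100 * 5 / 105)

    def test_endpoint_selection(self):
        records = [UseRecord("maize", 1990, "a", 1.0, 1.0)]
        profiles = [profile("a", ld50=100.0, noel=10.0)]
        chronic = hz.hazard_quotient(records, AREAS, profiles, "chronic")
        acute = hz.hazard_quotient(records, AREAS, profiles, "acute")
        assert chronic.hq == pytest.approx(10 * acute.hq)

    def test_missing_profile_excluded_and_logged(self, caplog):
        records = [
            UseRecord("maize", 1990, "a", 1.0, 1.0),
            UseRecord("maize", 1990, "mystery", 1.0, 1.0),
        ]
        with caplog.at_level("WARNING", logger="herbtrends"):
            res = hz.hazard_quotient(records, AREAS, [profile("a")], "acute")
        assert res.excluded == ("mystery",)
        assert "mystery" in caplog.text
        assert len(res.contributions) == 1

    def test_missing_area_rejected(self):
        records = [UseRecord("cotton", 1994, "a", 1.0, 1.0)]
        with pytest.raises(MissingDataError):
            hz.hazard_quotient(records, AREAS, [profile("a")], "acute")

    def test_mixed_crop_years_rejected(self):
        records = [
            UseRecord("maize", 1990, "a", 1.0, 1.0),
            UseRecord("maize", 1991, "a", 1.0, 1.0),
        ]
        with pytest.raises(ValidationError, match="multiple"):
            hz.hazard_quotient(records, AREAS, [profile("a")], "acute")

    def test_shares_sum_to_100(self):
        records = [UseRecord("maize", 1990, f"ai{i}", float(i + 1), 1.0) for i in range(7)]
        profiles = [profile(f"ai{i}", noel=float(2 + i)) for i in range(7)]
        res = hz.hazard_quotient(records, AREAS, profiles, "chronic")
        assert sum(c.share_pct for c in res.contributions) == pytest.approx(100.0, abs=1e-9)

    def test_linearity(self):
        records = [UseRecord("maize", 1990, f"ai{i}", float(i + 1), 1.0) for i in range(3)]
        doubled = [UseRecord(r.crop, r.year, r.ingredient_label, 2 * r.amount_applied, r.avg_rate) for r in records]
        profiles = [profile(f"ai{i}", noel=float(2 + i)) for i in range(3)]
        r1 = hz.hazard_quotient(records, AREAS, profiles, "chronic")
        r2 = hz.hazard_quotient(doubled, AREAS, profiles, "chronic")
        assert r2.hq == pytest.approx(2 * r1.hq)
        for c1, c2 in zip(r1.contributions, r2.contributions):
            assert c2.share_pct == pytest.approx(c1.share_pct)

    def test_censoring_is_conservative(self):
        records = [UseRecord("maize", 1990, "a", 1.0, 1.0)]
        censored = hz.hazard_quotient(records, AREAS, [profile("a", ld50=5000.0, censored=True)], "acute")
        for true_ld50 in (5001.0, 7500.0, 9000.0):
            uncensored = hz.hazard_quotient(records, AREAS, [profile("a", ld50=true_ld50)], "acute")
            assert censored.hq >= uncensored.hq


class TestContributionShare:
    def test_single_ai(self):
        records = [UseRecord("maize", 1990, "a", 1.0, 1.0)]
        res = hz.hazard_quotient(records, AREAS, [profile("a")], "acute")
        assert hz.contribution_share(res, "a") == pytest.approx(100.0)

    def test_absent_ai_is_zero(self):
        records = [UseRecord("maize", 1990, "a", 1.0, 1.0)]
        res = hz.hazard_quotient(records, AREAS, [profile("a")], "acute")
        assert hz.contribution_share(res, "ghost") == 0.0

    def test_equal_partials(self):
        records = [UseRecord("maize", 1990, f"ai{i}", 1.0, 1.0) for i in range(4)]
        profiles = [profile(f"ai{i}", noel=10.0) for i in range(4)]
        res = hz.hazard_quotient(records, AREAS, profiles, "chronic")
        for i in range(4):
            assert hz.contribution_share(res, f"ai{i}") == pytest.approx(25.0)

    def test_zero_hq_rejected(self):
        res = hz.hazard_quotient([], AREAS, [], "chronic")
        with pytest.raises(ValidationError):
            hz.contribution_share(res, "a")


class TestToxicityPercentile:
    def test_minimum_scores_zero(self):
        profiles = [profile(f"ai{i}", ld50=100.0 * (i + 1)) for i in range(5)]
        assert hz.toxicity_percentile(profiles, "ai0", "acute") == 0.0

    def test_ranked_fourth_lowest_of_five(self):
        # brute-force oracle over the 4 other values
        values = {"a": 100.0, "b": 250.0, "c": 700.0, "d": 2000.0, "e": 5000.0}
        profiles = [profile(ai, ld50=v) for ai, v in values.items()]
        others = [v for ai, v in values.items() if ai != "d"]
        expected = 100.0 * sum(1 for v in others if v < values["d"]) / len(others)
        assert expected == 75.0
        assert hz.toxicity_percentile(profiles, "d", "acute") == pytest.approx(expected)

    def test_all_tied_scores_zero(self):
        profiles = [profile(f"ai{i}", ld50=5000.0) for i in range(4)]
        assert hz.toxicity_percentile(profiles, "ai1", "acute") == 0.0

    def test_unknown_ai_rejected(self):
        with pytest.raises(ValidationError):
            hz.toxicity_percentile([profile("a")], "ghost", "acute")


class TestToxicitySummary:
    def test_odd_median(self):
        profiles = [profile(f"ai{i}", noel=v) for i, v in enumerate([1.0, 2.0, 3.0])]
        assert hz.toxicity_summary(profiles, "chronic").median == 2.0

    def test_even_median_midpoint(self):
        profiles = [profile(f"ai{i}", noel=v) for i, v in enumerate([1.0, 2.0, 3.0, 4.0])]
        summary = hz.toxicity_summary(profiles, "chronic")
        assert summary.median == 2.5
        assert (summary.minimum, summary.maximum) == (1.0, 4.0)

    def test_count_below_category_boundary(self):
        lds = [112.0, 300.0, 499.0, 500.0, 3556.0, 5000.0]
        profiles = [profile(f"ai{i}", ld50=v) for i, v in enumerate(lds)]
        assert hz.toxicity_summary(profiles, "acute").n_below_threshold == 3

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            hz.toxicity_summary([], "acute")
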