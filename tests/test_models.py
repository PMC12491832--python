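"""Marginal-slope models: windows, collinearity, fits and invariances."""

import datetime as dt
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from batphen import simulate as sim
from batphen.models import (
    DEFAULT_WINDOWS,
    PhenologyTrendModel,
    TemperatureResponseModel,
    median_window_temperature,
    project_total_change,
    temperature_collinearity,
)


def hourly(start, end, temps):
    ts = pd.date_range(start, end, freq="h")
    return pd.DataFrame({"timestamp": ts, "temp_c": temps(ts)})


def exact_table(**overrides):
    """Noise-free fractional-day phenology table straight from the generator."""
    base = dict(
        years=tuple(range(2013, 2020)),
        n_new_tags_per_year_per_species=10,
        individual_sd=0.0,
        residual_sd=0.0,
        annual_survival=1.0,
        swarming_visits_mean=0.0,
        winter_exit_prob=0.0,
    )
    base.update(sim.zero_temp_overrides())
    base.update(overrides)
    cfg = sim.SimConfig(**base)
    weather = sim.simulate_weather(cfg)
    truth, _ = sim.simulate_schedules(cfg, weather)
    return sim.truth_to_phenology(truth), weather, cfg


class TestMedianWindowTemperature:
    def test_constant_series(self):
        w = hourly("2015-07-01", "2016-06-30", lambda ts: np.full(len(ts), 5.0))
        assert median_window_temperature(w, (8, 9), 2015) == 5.0

    def test_alternating_hours(self):
        w = hourly("2015-07-01", "2016-06-30", lambda ts: np.where(np.arange(len(ts)) % 2, 10.0, 0.0))
        assert median_window_temperature(w, (8, 9), 2015) == 5.0

    def test_window_crossing_new_year_resolves_forward(self):
        # Feb–Mar of bat year 2015 lies in calendar 2016
        w = hourly("2015-07-01", "2016-06-30", lambda ts: np.asarray(ts.year == 2016, dtype=float))
        assert median_window_temperature(w, (2, 3), 2015) == 1.0
        assert median_window_temperature(w, (11, 12), 2015) == 0.0

    def test_sinusoid_matches_brute_force(self):
        w = hourly(
            "2015-07-01", "2016-06-30",
            lambda ts: 8 - 8 * np.cos(2 * np.pi * (ts.dayofyear - 15) / 365.25),
        )
        got = median_window_temperature(w, (11, 12), 2015)
        vals = [
            r.temp_c
            for r in w.itertuples(index=False)
            if r.timestamp.year == 2015 and r.timestamp.month in (11, 12)
        ]
        assert got == pytest.approx(float(np.median(vals)), abs=1e-12)

    def test_empty_window_errors(self):
        w = hourly("2015-07-01", "2015-10-01", lambda ts: np.zeros(len(ts)))
        with pytest.raises(ValueError, match="bat year"):
            median_window_temperature(w, (2, 3), 2015)


class TestTemperatureCollinearity:
    def test_identical_summaries_give_r_one(self):
        # constant within each bat year, varying across years:
        # median = min = max of daily means year by year
        ts = pd.date_range("2014-07-01", "2018-06-30", freq="h")
        by = np.where(ts.month >= 7, ts.year, ts.year - 1)
        w = pd.DataFrame({"timestamp": ts, "temp_c": (by - 2014) * 1.5})
        out = temperature_collinearity(w, {"start": (11, 12)})
        assert out.loc[0, "r_median_max"] == pytest.approx(1.0)
        assert out.loc[0, "r_median_min"] == pytest.approx(1.0)

    def test_realistic_weather_positively_correlated(self):
        cfg = sim.SimConfig(years=tuple(range(2010, 2023)), seed=5, annual_anomaly_sd=1.0)
        w = sim.simulate_weather(cfg)
        out = temperature_collinearity(w, dict(DEFAULT_WINDOWS))
        assert (out["r_median_max"] > 0).all()
        assert (out["r_median_min"] > 0).all()

    def test_constant_series_flagged(self):
        ts = pd.date_range("2014-07-01", "2018-06-30", freq="h")
        w = pd.DataFrame({"timestamp": ts, "temp_c": 4.0})
        out = temperature_collinearity(w, {"start": (11, 12)})
        assert out.loc[0, "flagged"]
        assert np.isnan(out.loc[0, "r_median_max"])


class TestProjection:
    @pytest.mark.parametrize(
        "slope, years, total",
        [(1.81, 13, 23.53), (-1.87, 13, -24.31), (0.0, 13, 0.0)],
    )
    def test_slope_times_span(self, slope, years, total):
        assert project_total_change(slope, years) == pytest.approx(total, abs=0.005)

    def test_invalid_span(self):
        with pytest.raises(ValueError):
            project_total_change(1.0, 0)


class TestYearTrendModel:
    def test_noise_free_fit_is_exact(self):
        table, _, cfg = exact_table()
        res = PhenologyTrendModel(table, "start", "daubentonii").fit()
        assert res.class_slope("adult M") == pytest.approx(-2.14, abs=1e-6)
        assert res.class_slope("adult F") == pytest.approx(-0.97, abs=1e-6)

    def test_overall_is_mean_of_class_slopes(self):
        table, _, _ = exact_table()
        res = PhenologyTrendModel(table, "duration", "nattereri").fit()
        four = [res.class_slope(c) for c in ("adult F", "adult M", "juvenile F", "juvenile M")]
        assert res.overall == pytest.approx(np.mean(four), abs=1e-12)

    def test_row_permutation_invariance(self):
        table, _, _ = exact_table()
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = PhenologyTrendModel(table, "start", "nattereri").fit()
        b = PhenologyTrendModel(shuffled, "start", "nattereri").fit()
        np.testing.assert_allclose(a.slopes["slope"], b.slopes["slope"], atol=1e-8)

    def test_contrast_coding_invariance(self):
        table, _, _ = exact_table()
        order = ["juvenile M", "adult F", "juvenile F", "adult M"]
        a = PhenologyTrendModel(table, "start", "daubentonii").fit()
        b = PhenologyTrendModel(table, "start", "daubentonii", class_order=order).fit()
        sa = a.slopes.set_index("cls")["slope"]
        sb = b.slopes.set_index("cls")["slope"]
        for c in sa.index:
            assert sa[c] == pytest.approx(sb[c], abs=1e-8)

    def test_mixed_fit_recovers_trend_with_noise(self):
        # moderate noise, truth-level table: REML point estimates near truth
        table, _, cfg = exact_table(
            individual_sd=6.0, residual_sd=4.0, n_new_tags_per_year_per_species=40,
            annual_survival=0.75, seed=13,
        )
        res = PhenologyTrendModel(table, "start", "daubentonii").fit()
        assert not res.used_fallback
        assert res.class_slope("adult M") == pytest.approx(-2.14, abs=0.35)

    def test_fitted_slope_magnitude_tracks_configured_trend(self):
        # steeper configured entry trend → strictly steeper fitted slope
        fitted = []
        for trend in (-0.5, -1.5, -3.0):
            trends = {k: 0.0 for k in sim.SimConfig().entry_trend}
            trends[("daubentonii", "M", "adult")] = trend
            table, _, _ = exact_table(entry_trend=trends, end_trend=dict(trends))
            res = PhenologyTrendModel(table, "start", "daubentonii").fit()
            fitted.append(abs(res.class_slope("adult M")))
        assert fitted[0] < fitted[1] < fitted[2]

    def test_requires_two_years(self):
        table, _, _ = exact_table()
        one_year = table[table["bat_year"] == 2013]
        with pytest.raises(ValueError):
            PhenologyTrendModel(one_year, "start", "daubentonii")

    def test_plot_returns_errorbar_axis(self):
        import matplotlib

        matplotlib.use("Agg")
        table, _, _ = exact_table()
        res = PhenologyTrendModel(table, "start", "daubentonii").fit()
        ax = res.plot()
        assert "days/year" in ax.get_ylabel()
        assert ax.get_title() == "daubentonii"

    def test_summary_mentions_unit_and_species(self):
        table, _, _ = exact_table()
        res = PhenologyTrendModel(table, "start", "daubentonii").fit()
        text = res.summary()
        assert "days/year" in text and "daubentonii" in text


class TestTemperatureModel:
    def test_shift_invariance(self):
        table, weather, _ = exact_table(
            **{**sim.zero_trend_overrides()},
            temp_effect_entry=sim.SimConfig().temp_effect_entry,
            warming_c_per_year=0.0,
            annual_anomaly_sd=1.0,
            weather_noise_sd=1.0,
        )
        res1 = TemperatureResponseModel(table, weather, "start", "nattereri").fit()
        shifted = weather.assign(temp_c=weather["temp_c"] + 10.0)
        res2 = TemperatureResponseModel(table, shifted, "start", "nattereri").fit()
        s1 = res1.slopes.set_index("cls")["slope"]
        s2 = res2.slopes.set_index("cls")["slope"]
        for c in s1.index:
            assert s1[c] == pytest.approx(s2[c], abs=1e-6)

    def test_refuses_constant_temperatures(self):
        table, _, _ = exact_table()
        flat = hourly("2013-07-01", "2020-06-30", lambda ts: np.full(len(ts), 7.0))
        with pytest.raises(ValueError, match="distinct"):
            TemperatureResponseModel(table, flat, "start", "daubentonii")

    def test_duration_not_a_temperature_response(self):
        table, weather, _ = exact_table()
        with pytest.raises(ValueError):
            TemperatureResponseModel(table, weather, "duration", "daubentonii")


def test_class_slopes_match_lme4():
    """Cross-check the mixed-model marginal slopes against R lme4/emmeans-style contrasts."""
    table, _, _ = exact_table(
        individual_sd=6.0, residual_sd=4.0, n_new_tags_per_year_per_species=25,
        annual_survival=0.8, seed=31,
    )
    model = PhenologyTrendModel(table, "start", "daubentonii")
    res = model.fit()
    df = model.data[["resp", "year_c", "cls", "tag_id"]].copy()
    df["cls"] = df["cls"].astype(str)

    import tempfile, os, json
    with tempfile.TemporaryDirectory() as tmp:
        csv = os.path.join(tmp, "d.csv")
        out = os.path.join(tmp, "slopes.json")
        df.to_csv(csv, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            suppressMessages(library(jsonlite))
            d <- read.csv("{csv}")
            d$cls <- factor(d$cls, levels=c("adult F","adult M","juvenile F","juvenile M"))
            m <- lmer(resp ~ year_c * cls + (1|tag_id), data=d, REML=TRUE)
            fe <- fixef(m)
            lv <- levels(droplevels(d$cls))
            slopes <- sapply(lv, function(l) {{
              s <- fe[["year_c"]]
              nm <- paste0("year_c:cls", l)
              if (nm %in% names(fe)) s <- s + fe[[nm]]
              s
            }})
            write(toJSON(as.list(slopes), auto_unbox=TRUE), "{out}")
        """)
        proc = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        with open(out) as fh:
            lme4_slopes = json.load(fh)

    for cls, want in lme4_slopes.items():
        assert res.class_slope(cls) == pytest.approx(want, abs=0.02), cls
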