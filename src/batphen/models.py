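"""Mixed-model trend estimation for hibernation phenology.

Two model families, fitted separately per species and response:

* **Year trends** — response (start/end day index or duration in days) on
  centred bat year, the four-level sex-age class, and their interaction,
  with a random intercept per individual.  The per-class *marginal slope*
  (days/year) is the year coefficient plus the class-specific interaction
  contrast; the "overall" slope is the unweighted mean of the four.

* **Temperature effects** — start or end day index on the median air
  temperature of a species-specific 2-month climate window (Aug–Sep /
  Feb–Mar for *M. daubentonii*, Nov–Dec / Jan–Feb for *M. nattereri*),
  class, and their interaction, with a random intercept per bat year.
  Marginal effects are in days/°C.

Estimation is restricted maximum likelihood via ``statsmodels`` MixedLM;
uncertainty is Wald (normal approximation).  Degenerate fits (zero variance
components, non-convergence) drop to an ordinary-least-squares fixed-effects
fit, flagged on the results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf

CLASS_LEVELS = ["adult F", "adult M", "juvenile F", "juvenile M"]

RESPONSE_COLUMNS = {
    "start": "start_day_index",
    "end": "end_day_index",
    "duration": "duration_days",
}

#: 2-month climate windows (calendar months) per (species, response)
DEFAULT_WINDOWS = {
    ("daubentonii", "start"): (8, 9),
    ("daubentonii", "end"): (2, 3),
    ("nattereri", "start"): (11, 12),
    ("nattereri", "end"): (1, 2),
}


@dataclass(frozen=True)
class ClassSlope:
    """Marginal effect of the covariate for one sex-age class (or overall)."""

    species: str
    cls: str  # "adult F", ..., or "overall"
    response: str
    slope: float  # days per year or days per °C
    se: float
    t: float
    p: float


def project_total_change(slope_days_per_year: float, n_years: int) -> float:
    """Total change over a study span: slope × number of years."""
    if n_years <= 0:
        raise ValueError("n_years must be positive")
    return slope_days_per_year * n_years


# ---------------------------------------------------------------------------
# climate windows
# ---------------------------------------------------------------------------

def _window_mask(timestamps: pd.Series, months: tuple, bat_year: int) -> np.ndarray:
    """Hours falling in the window's two calendar months of one bat year.

    Months ≥ July belong to the bat year's own calendar year, months < July
    to the following one (Aug–Sep of bat year 2015 → Aug–Sep 2015; Feb–Mar
    → Feb–Mar 2016).
    """
    month = timestamps.dt.month.to_numpy()
    year = timestamps.dt.year.to_numpy()
    mask = np.zeros(len(timestamps), dtype=bool)
    for m in months:
        cal_year = bat_year if m >= 7 else bat_year + 1
        mask |= (month == m) & (year == cal_year)
    return mask


def median_window_temperature(weather: pd.DataFrame, months: tuple, bat_year: int) -> float:
    """Median of all hourly samples inside a 2-month window of one bat year."""
    ts = pd.to_datetime(weather["timestamp"])
    mask = _window_mask(ts, months, int(bat_year))
    if not mask.any():
        raise ValueError(f"no weather samples in months {months} of bat year {bat_year}")
    return float(np.median(weather["temp_c"].to_numpy()[mask]))


def window_medians(weather: pd.DataFrame, months: tuple, years) -> dict[int, float]:
    """Per-bat-year window medians (see :func:`median_window_temperature`)."""
    return {int(y): median_window_temperature(weather, months, int(y)) for y in years}


def temperature_collinearity(weather: pd.DataFrame, windows: dict) -> pd.DataFrame:
    """Correlation of window summaries (median vs max/min of daily means).

    For each window and each bat year covered by the series, daily mean
    temperatures inside the window are summarised by their median, minimum
    and maximum; Pearson *r* between the median and the extremes is then
    computed across bat years.  Windows with a constant summary get *r* =
    NaN and ``flagged=True``.
    """
    ts = pd.to_datetime(weather["timestamp"])
    bat_years = sorted(set(np.where(ts.dt.month >= 7, ts.dt.year, ts.dt.year - 1)))
    rows = []
    for label, months in windows.items():
        med, mn, mx = [], [], []
        for by in bat_years:
            mask = _window_mask(ts, months, by)
            if not mask.any():
                continue
            sub = weather[mask]
            daily = sub.groupby(ts[mask].dt.date)["temp_c"].mean()
            med.append(float(daily.median()))
            mn.append(float(daily.min()))
            mx.append(float(daily.max()))
        if len(med) < 3:
            raise ValueError(f"window {label}: need ≥3 bat years, got {len(med)}")
        med, mn, mx = map(np.asarray, (med, mn, mx))
        flagged = med.std() == 0 or mn.std() == 0 or mx.std() == 0
        r_max = float(stats.pearsonr(med, mx)[0]) if not flagged else float("nan")
        r_min = float(stats.pearsonr(med, mn)[0]) if not flagged else float("nan")
        rows.append(
            {
                "window": label if isinstance(label, str) else str(label),
                "months": tuple(months),
                "n_years": len(med),
                "r_median_max": r_max,
                "r_median_min": r_min,
                "flagged": bool(flagged),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# shared interaction-model machinery
# ---------------------------------------------------------------------------

def _marginal_slopes(fe_params, cov_fe, xname: str, classes: list[str]):
    """Per-class marginal slopes from a covariate×class interaction fit.

    The reference class's slope is the main covariate coefficient; other
    classes add their interaction term.  The overall slope is the unweighted
    mean of the class slopes (an estimated-marginal-means-style average),
    with its standard error from the same covariance matrix — all invariant
    to the contrast coding / class ordering.
    """
    names = list(fe_params.index)
    cov = cov_fe.to_numpy()
    vecs = {}
    for c in classes:
        L = np.zeros(len(names))
        L[names.index(xname)] = 1.0
        inter = f"{xname}:cls[T.{c}]"
        if inter in names:
            L[names.index(inter)] = 1.0
        vecs[c] = L
    vecs["overall"] = np.mean([vecs[c] for c in classes], axis=0)

    rows = []
    for c, L in vecs.items():
        slope = float(L @ fe_params.to_numpy())
        var = float(L @ cov @ L)
        se = float(np.sqrt(max(var, 0.0)))
        t = slope / se if se > 0 else np.inf * np.sign(slope) if slope else 0.0
        p = float(2 * stats.norm.sf(abs(t))) if np.isfinite(t) else 0.0
        rows.append({"cls": c, "slope": slope, "se": se, "t": t, "p": p})
    return pd.DataFrame(rows)


def _fit_interaction(df: pd.DataFrame, xname: str, group_col: str, reml: bool = True):
    """Fit resp ~ x * class with a random intercept; OLS fallback if degenerate.

    Returns (fe_params, cov_fe, fallback_used, fit_result).
    """
    formula = f"resp ~ {xname} * cls"
    fallback = False
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # lbfgs occasionally reports convergence at a degenerate point
        # (non-finite REML criterion, garbage fixed effects); fall through
        # to slower but robust optimizers before giving up on the mixed fit
        for method in ("lbfgs", "powell", "nm"):
            try:
                md = smf.mixedlm(formula, data=df, groups=df[group_col])
                cand = md.fit(reml=reml, method=method)
            except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
                continue
            if (
                cand.converged
                and np.isfinite(cand.llf)
                and np.isfinite(cand.fe_params).all()
                and np.isfinite(cand.bse_fe).all()
            ):
                res = cand
                break
    if res is None:
        fallback = True
        res = smf.ols(formula, data=df).fit()
        fe = res.params
        cov = res.cov_params()
    else:
        fe = res.fe_params
        cov = res.cov_params().loc[fe.index, fe.index]
    return fe, cov, fallback, res


def _prepare(
    table: pd.DataFrame, response: str, species: str, class_order=None
) -> pd.DataFrame:
    if response not in RESPONSE_COLUMNS:
        raise ValueError(f"response must be one of {sorted(RESPONSE_COLUMNS)}")
    col = RESPONSE_COLUMNS[response]
    df = table[table["species"] == species].copy()
    df["cls"] = (df["age"].astype(str) + " " + df["sex"].astype(str))
    present = [c for c in (class_order or CLASS_LEVELS) if c in set(df["cls"])]
    df["cls"] = pd.Categorical(df["cls"], categories=present)
    df["resp"] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=["resp"]).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

class ClassSlopeResults:
    """Marginal slopes per sex-age class plus the overall average.

    Attributes
    ----------
    slopes : DataFrame with columns cls, slope, se, t, p (last row "overall")
    unit : "days/year" or "days/°C"
    used_fallback : True when the mixed fit was degenerate and an OLS
        fixed-effects fit was used instead.
    fit_result : the underlying statsmodels results object.
    """

    def __init__(self, species, response, unit, slopes, used_fallback, fit_result, n_obs):
        self.species = species
        self.response = response
        self.unit = unit
        self.slopes = slopes
        self.used_fallback = used_fallback
        self.fit_result = fit_result
        self.n_obs = n_obs

    def class_slope(self, cls: str) -> float:
        return float(self.slopes.set_index("cls").loc[cls, "slope"])

    @property
    def overall(self) -> float:
        return self.class_slope("overall")

    def to_class_slopes(self) -> list[ClassSlope]:
        return [
            ClassSlope(self.species, r.cls, self.response, r.slope, r.se, r.t, r.p)
            for r in self.slopes.itertuples(index=False)
        ]

    def project(self, n_years: int) -> pd.Series:
        """Total change per class over ``n_years`` (slope × span)."""
        return self.slopes.set_index("cls")["slope"] * n_years

    def summary(self) -> str:
        head = (
            f"Marginal {self.response} slopes [{self.unit}] — {self.species} "
            f"(n={self.n_obs}{', OLS fallback' if self.used_fallback else ', REML'})"
        )
        lines = [head, "-" * len(head)]
        for r in self.slopes.itertuples(index=False):
            lines.append(
                f"{r.cls:<12} {r.slope:+8.3f}  se={r.se:6.3f}  t={r.t:7.2f}  p={r.p:.3g}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Slope-per-class error-bar plot (95% Wald interval)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        s = self.slopes
        ax.errorbar(range(len(s)), s["slope"], yerr=1.96 * s["se"], fmt="o", capsize=3)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xticks(range(len(s)), s["cls"], rotation=30)
        ax.set_ylabel(f"{self.response} slope [{self.unit}]")
        ax.set_title(self.species)
        return ax


# ---------------------------------------------------------------------------
# model classes
# ---------------------------------------------------------------------------

class PhenologyTrendModel:
    """Year-trend mixed model for one species and response.

    ``response ~ year_c * class`` with a random intercept per individual;
    the year covariate is centred at the first bat year present (slopes are
    unaffected).  Rows with a masked response are dropped before fitting.
    """

    def __init__(self, table: pd.DataFrame, response: str, species: str, class_order=None):
        self.species = species
        self.response = response
        self.data = _prepare(table, response, species, class_order)
        if self.data.empty:
            raise ValueError(f"no usable {response} records for {species}")
        self.data["year_c"] = self.data["bat_year"] - int(self.data["bat_year"].min())
        if self.data["bat_year"].nunique() < 2:
            raise ValueError("need records from at least 2 bat years")

    @classmethod
    def from_dataframe(cls, table, response, species):
        return cls(table, response, species)

    def fit(self, reml: bool = True) -> ClassSlopeResults:
        df = self.data
        fe, cov, fallback, res = _fit_interaction(df, "year_c", "tag_id", reml=reml)
        classes = [c for c in CLASS_LEVELS if c in set(df["cls"].astype(str))]
        slopes = _marginal_slopes(fe, cov, "year_c", classes)
        return ClassSlopeResults(
            self.species, self.response, "days/year", slopes, fallback, res, len(df)
        )


class TemperatureResponseModel:
    """Temperature-effect mixed model for one species and response.

    ``response ~ window_median_°C * class`` with a random intercept per bat
    year.  The window median is the species/response-specific 2-month
    climate window; effects are marginal days/°C per class.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        weather: pd.DataFrame,
        response: str,
        species: str,
        months: tuple | None = None,
    ):
        if response not in ("start", "end"):
            raise ValueError("temperature models are defined for 'start' and 'end' only")
        self.species = species
        self.response = response
        self.months = tuple(months) if months else DEFAULT_WINDOWS[(species, response)]
        df = _prepare(table, response, species)
        if df.empty:
            raise ValueError(f"no usable {response} records for {species}")
        temps = window_medians(weather, self.months, sorted(df["bat_year"].unique()))
        df["temp"] = df["bat_year"].map(temps)
        if df["temp"].round(6).nunique() < 3:
            raise ValueError("need at least 3 distinct window temperatures to fit")
        df["bat_year_factor"] = df["bat_year"].astype(str)
        self.data = df
        self.window_temperatures = temps

    @classmethod
    def from_dataframe(cls, table, weather, response, species, months=None):
        return cls(table, weather, response, species, months)

    def fit(self, reml: bool = True) -> ClassSlopeResults:
        df = self.data
        fe, cov, fallback, res = _fit_interaction(df, "temp", "bat_year_factor", reml=reml)
        classes = [c for c in CLASS_LEVELS if c in set(df["cls"].astype(str))]
        slopes = _marginal_slopes(fe, cov, "temp", classes)
        return ClassSlopeResults(
            self.species, self.response, "days/°C", slopes, fallback, res, len(df)
        )


# ---------------------------------------------------------------------------
# tidy wrappers
# ---------------------------------------------------------------------------

def fit_year_trend(phenology_table: pd.DataFrame, response: str) -> list[ClassSlope]:
    """Year-trend marginal slopes for every species in the table."""
    out: list[ClassSlope] = []
    for sp in sorted(phenology_table["species"].unique()):
        out.extend(PhenologyTrendModel(phenology_table, response, sp).fit().to_class_slopes())
    return out


def fit_temperature_model(
    phenology_table: pd.DataFrame,
    weather: pd.DataFrame,
    response: str,
    windows: dict | None = None,
) -> list[ClassSlope]:
    """Temperature-effect marginal slopes (days/°C) for every species."""
    out: list[ClassSlope] = []
    for sp in sorted(phenology_table["species"].unique()):
        months = (windows or DEFAULT_WINDOWS)[(sp, response)]
        model = TemperatureResponseModel(phenology_table, weather, response, sp, months)
        out.extend(model.fit().to_class_slopes())
    return out


def slopes_to_frame(slopes: list[ClassSlope]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in slopes])
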