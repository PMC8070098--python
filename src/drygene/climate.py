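"""Habitat drought-stress indices from monthly climate normals.

Thornthwaite's classic potential-evapotranspiration (PET) model estimates
the climatic water demand of a site from monthly mean air temperature, an
annual heat index, and latitude-corrected day length.  Comparing monthly
PET with monthly precipitation yields a dimensionless drought index

    DI_j = 100 * (PET_j - P_j) / PET_j        (bounded above by 100)

which is positive when evaporative demand exceeds supply.  Aggregating
DI_j over accumulated windows (3, 6, 12 months) or calendar trimesters
gives per-accession habitat drought-stress indices that can be compared
among taxonomic groups and used as environmental variables in
genotype-environment association scans.

The model, in order of evaluation:

* annual heat index       I = sum_j (T_j / 5)**1.514 over months with T_j > 0
* Thornthwaite exponent   a = 6.75e-7*I^3 - 7.71e-5*I^2 + 1.792e-2*I + 0.49239
* solar declination term  A_j from the mid-month ordinal day (Forsythe model)
* day length (hours)      D_j with a 0.8333 degree sun-altitude correction
* radiation factor        L_j = D_j / 12
* monthly PET (cm)        PET_j = 1.6 * L_j * (10 T_j / I)**a  for T_j > 0, else 0

PET is converted to mm/month (x10) before the drought index so that it is
commensurate with precipitation totals in mm.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Ordinal day of the 15th of each month in a fixed non-leap calendar.
MID_MONTH_DAY = (15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349)

#: Supported aggregation timeframes: accumulated windows and calendar trimesters.
TIMEFRAMES = ("m3", "m6", "m12", "T1", "T2", "T3", "T4")

#: Sun-altitude correction (degrees) accounting for atmospheric refraction
#: and the apparent solar disc at sunrise/sunset.
SUN_ALTITUDE_DEG = 0.8333


@dataclass
class MonthlyClimate:
    """Monthly climate normals for one geo-referenced accession.

    Parameters
    ----------
    accession_id : str
        Accession identifier matching the sample sheet.
    latitude : float
        Collection-site latitude in signed sexagesimal degrees.
    temperature : array-like of 12 floats
        Monthly mean air temperatures, January..December, in deg C.
    precipitation : array-like of 12 floats
        Monthly precipitation totals, January..December, in mm.
    """

    accession_id: str
    latitude: float
    temperature: np.ndarray
    precipitation: np.ndarray

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.precipitation = np.asarray(self.precipitation, dtype=float)
        if self.temperature.shape != (12,):
            raise ValueError(
                f"{self.accession_id}: expected 12 monthly temperatures, "
                f"got shape {self.temperature.shape}"
            )
        if self.precipitation.shape != (12,):
            raise ValueError(
                f"{self.accession_id}: expected 12 monthly precipitation "
                f"totals, got shape {self.precipitation.shape}"
            )
        if np.any(self.precipitation < 0):
            raise ValueError(f"{self.accession_id}: negative precipitation")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"{self.accession_id}: latitude out of [-90, 90]")


@dataclass
class DroughtProfile:
    """Monthly PET / drought-index series plus aggregated indices."""

    accession_id: str
    heat_index: float
    exponent: float
    day_length: np.ndarray  # hours, 12 values
    radiation: np.ndarray  # dimensionless L_j = D_j / 12
    pet: np.ndarray  # mm/month
    di: np.ndarray | None = None  # dimensionless, <= 100
    aggregates: dict = field(default_factory=dict)


def heat_index(temperature) -> float:
    """Annual heat index I; months at or below 0 deg C contribute nothing."""
    t = np.asarray(temperature, dtype=float)
    if t.shape != (12,):
        raise ValueError("heat_index expects 12 monthly temperatures")
    pos = t[t > 0]
    return float(np.sum((pos / 5.0) ** 1.514))


def thornthwaite_exponent(i: float) -> float:
    """Cubic polynomial a(I) of the Thornthwaite model."""
    return 6.75e-7 * i**3 - 7.71e-5 * i**2 + 1.792e-2 * i + 0.49239


def solar_declination_term(month: int) -> float:
    """Intermediate angle A_j (radians) for the mid-month ordinal day."""
    j_i = MID_MONTH_DAY[month - 1]
    return math.asin(
        0.39795
        * math.cos(0.2163108 + 2.0 * math.atan(0.9671396 * math.tan(0.00860 * (j_i - 186))))
    )


def day_length(latitude: float, month: int) -> float:
    """Day length D_j in hours for a latitude and month (Forsythe model).

    The arccos argument is clamped to [-1, 1] so polar day / polar night
    return 24 and 0 hours instead of a domain error.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude out of [-90, 90]")
    if month not in range(1, 13):
        raise ValueError("month must be 1..12")
    a_j = solar_declination_term(month)
    lat = math.radians(latitude)
    num = math.sin(math.radians(SUN_ALTITUDE_DEG)) + math.sin(lat) * math.sin(a_j)
    den = math.cos(lat) * math.cos(a_j)
    arg = min(1.0, max(-1.0, num / den))
    return 24.0 - (24.0 / math.pi) * math.acos(arg)


def monthly_pet(climate: MonthlyClimate) -> DroughtProfile:
    """Monthly Thornthwaite PET in mm/month.

    PET_j = 1.6 * L_j * (10 T_j / I)**a  (cm/month) for months with
    T_j > 0, and exactly 0 otherwise; the cm value is converted to mm
    (x10) so that it shares units with WorldClim-style precipitation.
    """
    i = heat_index(climate.temperature)
    a = thornthwaite_exponent(i)
    d = np.array([day_length(climate.latitude, m) for m in range(1, 13)])
    radiation = d / 12.0
    pet = np.zeros(12)
    warm = climate.temperature > 0
    if np.any(warm):
        # I > 0 whenever any T_j > 0, so the division is safe.
        pet[warm] = 1.6 * radiation[warm] * (10.0 * climate.temperature[warm] / i) ** a
    pet *= 10.0  # cm -> mm
    return DroughtProfile(
        accession_id=climate.accession_id,
        heat_index=i,
        exponent=a,
        day_length=d,
        radiation=radiation,
        pet=pet,
    )


def monthly_di(profile: DroughtProfile, climate: MonthlyClimate) -> DroughtProfile:
    """Fill the monthly drought index DI_j = 100 (PET_j - P_j) / PET_j.

    Months with zero PET (no evaporative demand) are assigned DI_j = 0:
    with nothing to evaporate there is no drought stress, and the ratio
    is undefined there.  Each such month is logged.
    """
    if np.any(climate.precipitation < 0):
        raise ValueError("negative precipitation")
    di = np.zeros(12)
    demand = profile.pet > 0
    di[demand] = 100.0 * (profile.pet[demand] - climate.precipitation[demand]) / profile.pet[demand]
    for m in np.nonzero(~demand)[0]:
        logger.info(
            "%s: PET = 0 in month %d, drought index set to 0",
            profile.accession_id,
            m + 1,
        )
    profile.di = di
    return profile


def aggregate_di(profile: DroughtProfile, timeframe: str, anchor_month: int = 1) -> float:
    """Mean drought index over one timeframe.

    Accumulated windows ``m3``/``m6``/``m12`` start at ``anchor_month``
    and wrap around the calendar year; trimesters ``T1``..``T4`` are the
    fixed calendar quarters Jan-Mar, Apr-Jun, Jul-Sep, Oct-Dec.
    """
    if profile.di is None:
        raise ValueError("drought index not computed; call monthly_di first")
    if timeframe not in TIMEFRAMES:
        raise ValueError(f"unknown timeframe {timeframe!r}; expected one of {TIMEFRAMES}")
    if anchor_month not in range(1, 13):
        raise ValueError("anchor_month must be 1..12")
    if timeframe.startswith("m"):
        k = int(timeframe[1:])
        months = [(anchor_month - 1 + off) % 12 for off in range(k)]
    else:
        q = int(timeframe[1])
        months = list(range(3 * (q - 1), 3 * q))
    return float(np.mean(profile.di[months]))


def drought_profile(climate: MonthlyClimate, anchor_month: int = 1) -> DroughtProfile:
    """Full PET -> DI -> aggregation chain for one accession."""
    profile = monthly_di(monthly_pet(climate), climate)
    profile.aggregates = {tf: aggregate_di(profile, tf, anchor_month) for tf in TIMEFRAMES}
    return profile


def build_index_table(
    climates: list[MonthlyClimate],
    taxa: dict[str, str] | None = None,
    anchor_month: int = 1,
) -> pd.DataFrame:
    """Per-accession drought-index table with one column per timeframe."""
    rows = []
    for clim in climates:
        prof = drought_profile(clim, anchor_month)
        row = {"accession": clim.accession_id}
        row["taxon"] = (taxa or {}).get(clim.accession_id, "")
        row.update(prof.aggregates)
        rows.append(row)
    return pd.DataFrame(rows)


def scale_indices(table: pd.DataFrame, columns=TIMEFRAMES) -> pd.DataFrame:
    """Append z-scaled copies (``<col>_z``) of the index columns.

    Scaling uses the sample (n-1) standard deviation across accessions.
    A zero-variance column yields a scaled column of zeros and a warning.
    """
    out = table.copy()
    for col in columns:
        values = out[col].to_numpy(dtype=float)
        finite = np.isfinite(values)
        if finite.sum() < 2:
            raise ValueError(f"column {col!r}: need >= 2 finite values to scale")
        sd = np.std(values[finite], ddof=1)
        mean = np.mean(values[finite])
        if sd == 0:
            warnings.warn(f"column {col!r} has zero variance; scaled to zeros")
            out[f"{col}_z"] = 0.0
        else:
            out[f"{col}_z"] = (values - mean) / sd
    return out


@dataclass
class GroupComparison:
    """Outcome of a between-taxa comparison of one drought index."""

    index: str
    route: str  # "anova" or "kruskal"
    normality: dict[str, float]  # Shapiro-Wilk p per group (nan if untestable)
    global_stat: float
    global_p: float
    pairwise: pd.DataFrame  # columns: group1, group2, stat, p, p_adj
    excluded: list[str] = field(default_factory=list)


def _shapiro_p(values: np.ndarray) -> float:
    if len(values) < 3 or np.ptp(values) == 0:
        return float("nan")  # untestable; treated as non-normal
    return float(stats.shapiro(values).pvalue)


def compare_groups(
    table: pd.DataFrame,
    index: str,
    group: str = "taxon",
    alpha_normality: float = 0.05,
) -> GroupComparison:
    """Compare one drought index among taxonomic groups.

    Each group is screened for normality with a Shapiro-Wilk test at
    ``alpha_normality``.  If every group looks normal the comparison is a
    one-way ANOVA with Tukey HSD pairwise contrasts; otherwise it is a
    Kruskal-Wallis test with pairwise Wilcoxon rank-sum tests under a
    Bonferroni correction.  Groups with fewer than 2 members are excluded
    with a warning.
    """
    groups: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for label, sub in table.groupby(group):
        vals = sub[index].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            warnings.warn(f"group {label!r} has < 2 members; excluded from comparison")
            excluded.append(str(label))
        else:
            groups[str(label)] = vals
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")

    normality = {label: _shapiro_p(vals) for label, vals in groups.items()}
    normal = all(p >= alpha_normality for p in normality.values() if not math.isnan(p)) and not any(
        math.isnan(p) for p in normality.values()
    )

    labels = sorted(groups)
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    if normal:
        route = "anova"
        stat, p = stats.f_oneway(*(groups[k] for k in labels))
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        data = np.concatenate([groups[k] for k in labels])
        grp = np.concatenate([[k] * len(groups[k]) for k in labels])
        tukey = pairwise_tukeyhsd(data, grp)
        frame = pd.DataFrame(data=tukey.summary().data[1:], columns=tukey.summary().data[0])
        pw = pd.DataFrame(
            {
                "group1": frame["group1"].astype(str),
                "group2": frame["group2"].astype(str),
                "stat": frame["meandiff"].astype(float),
                "p": frame["p-adj"].astype(float),
                "p_adj": frame["p-adj"].astype(float),  # Tukey is already family-wise
            }
        )
    else:
        route = "kruskal"
        stat, p = stats.kruskal(*(groups[k] for k in labels))
        rows = []
        for a, b in pairs:
            res = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            rows.append({"group1": a, "group2": b, "stat": float(res.statistic), "p": float(res.pvalue)})
        pw = pd.DataFrame(rows)
        pw["p_adj"] = np.minimum(1.0, pw["p"] * len(pairs))
    return GroupComparison(
        index=index,
        route=route,
        normality=normality,
        global_stat=float(stat),
        global_p=float(p),
        pairwise=pw,
        excluded=excluded,
    )
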