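"""From raw urine-sample tables to a model-ready dataset.

The response modelled downstream is the natural log of specific-gravity
(SG) corrected urinary cortisol (ng/ml SG).  This module applies the
correction, assigns demographic and reproductive classes, enforces the
exclusion rules (pregnancy, sickness, post-maternal-loss immaturity,
unassignable reproductive state), drops individual-years whose sampling
cannot support a quadratic circadian curve, and encodes circadian,
circannual and standardized covariates.

Input schemas
-------------
samples CSV: sample_id, individual, group, project, date (ISO),
    time (HH:MM or decimal hours), cortisol_raw (ng/ml),
    specific_gravity, lcms_method ({old,new}), sex ({male,female}),
    birth_date (ISO) or age_years, group_size, sex_ratio,
    sick_flag (0/1); optional: site, dominance.
events CSV (reproductive histories): mother, offspring,
    birth_date (ISO); optional mother_death_date (ISO).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

DEMOGRAPHIC_LEVELS = [
    "adult male", "cycling female", "lactating female",
    "immature male", "immature female",
]

#: z-scored numeric covariates, in encoding order
_ZSCORE_COLS = ["t", "age_z", "groupsize_z", "sexratio_z"]


@dataclass
class FilterConfig:
    """Windows and thresholds for sample inclusion.

    Defaults follow chimpanzee life history: ~240-day gestation,
    ~3-year (1095-day) lactation until resumption of cycling, social
    maturity at 12 years.  The circadian-coverage rule requires at
    least 3 samples per individual-year spanning >= 6 h with at least
    one morning and one afternoon sample.
    """

    pregnancy_window_days: int = 240
    lactation_window_days: int = 1095
    adult_age_years: float = 12.0
    min_samples_per_year: int = 3
    min_span_hours: float = 6.0
    morning_cutoff_hour: float = 12.0

    def __post_init__(self) -> None:
        for name, val in asdict(self).items():
            if val <= 0:
                raise ValueError(f"FilterConfig.{name} must be positive")


@dataclass
class PreparedDataset:
    """Encoded, filtered sample table plus the statistics to re-encode."""

    data: pd.DataFrame
    reference_stats: dict[str, tuple[float, float]]
    exclusion_log: dict[str, int] = field(default_factory=dict)
    sg_population_mean: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)


def sg_correct(raw: float | np.ndarray, sg_sample, sg_population_mean):
    """Correct a hormone concentration for urine dilution.

    corrected = raw * (SG_pop_mean - 1) / (SG_sample - 1).  Both SG
    values must exceed 1.0 (urine denser than water); a sample at the
    population-mean SG is returned unchanged.
    """
    raw = np.asarray(raw, dtype=float)
    sg_sample = np.asarray(sg_sample, dtype=float)
    if np.any(np.asarray(sg_population_mean) <= 1.0):
        raise ValueError("SG population mean must exceed 1.0")
    if np.any(sg_sample <= 1.0):
        raise ValueError("sample specific gravity must exceed 1.0")
    out = raw * (np.asarray(sg_population_mean) - 1.0) / (sg_sample - 1.0)
    return float(out) if out.ndim == 0 else out


def parse_clock_time(value) -> float:
    """Clock time -> decimal hours since midnight ('06:45' -> 6.75)."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        hours = float(value)
    else:
        text = str(value).strip()
        if ":" in text:
            parts = text.split(":")
            hours = float(parts[0]) + float(parts[1]) / 60.0
            if len(parts) > 2:
                hours += float(parts[2]) / 3600.0
        else:
            hours = float(text)
    if not 0.0 <= hours < 24.0:
        raise ValueError(f"clock time out of range: {value!r}")
    return hours


def assign_reproductive_state(female: str, sample_date, events: pd.DataFrame,
                              cfg: FilterConfig | None = None) -> str:
    """State of an adult female at a sampling date.

    pregnant: within ``pregnancy_window_days`` before any offspring
    birth; lactating: within ``lactation_window_days`` after any birth;
    cycling otherwise.  Pregnancy wins when a new conception overlaps a
    prior lactation window (pregnant samples are excluded downstream,
    so the precedence maximizes exclusion safety).
    """
    cfg = cfg or FilterConfig()
    date = pd.Timestamp(sample_date)
    births = pd.to_datetime(
        events.loc[events["mother"].astype(str) == str(female), "birth_date"])
    for b in births:
        if b - pd.Timedelta(days=cfg.pregnancy_window_days) <= date < b:
            return "pregnant"
    for b in births:
        if b <= date <= b + pd.Timedelta(days=cfg.lactation_window_days):
            return "lactating"
    return "cycling"


def _normalize_samples(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    required = {"individual", "group", "date", "time", "cortisol_raw",
                "specific_gravity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample table missing column(s): {sorted(missing)}")
    df["individual"] = df["individual"].astype(str)
    df["group"] = df["group"].astype(str)
    if "project" not in df.columns:
        df["project"] = "default"
    df["project"] = df["project"].astype(str)
    df["date"] = pd.to_datetime(df["date"])
    df["hours"] = [parse_clock_time(v) for v in df["time"]]
    if "sick_flag" not in df.columns:
        df["sick_flag"] = False
    df["sick_flag"] = df["sick_flag"].fillna(0).astype(float).astype(bool)
    if "sex" not in df.columns:
        df["sex"] = "unknown"
    df["sex"] = df["sex"].astype(str).str.lower()
    if "lcms_method" not in df.columns:
        df["lcms_method"] = "new"
    if "birth_date" in df.columns:
        bd = pd.to_datetime(df["birth_date"])
        df["age_years"] = (df["date"] - bd).dt.days / 365.25
    elif "age_years" not in df.columns:
        raise ValueError("sample table needs either birth_date or age_years")
    df["age_years"] = df["age_years"].astype(float)
    df["year"] = df["date"].dt.year
    return df


def _demographic(row, cfg: FilterConfig) -> str:
    adult = row["age_years"] >= cfg.adult_age_years
    if row["sex"] == "male":
        return "adult male" if adult else "immature male"
    if adult:
        # reproductive_state filled beforehand for adult females
        return ("lactating female" if row.get("reproductive_state") ==
                "lactating" else "cycling female")
    return "immature female"


def apply_exclusions(samples: pd.DataFrame, events: pd.DataFrame | None,
                     cfg: FilterConfig | None = None,
                     ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the sample-level exclusion rules.

    Drops (with per-rule counts): non-positive cortisol or degenerate
    SG; sick/injured sampling days; samples from pregnant females;
    adult-female samples whose reproductive state cannot be assigned
    (no event history); samples from immatures after maternal loss.
    Rules are independent predicates, so application order is
    immaterial; a sample hit by several rules is counted under each.
    """
    cfg = cfg or FilterConfig()
    df = _normalize_samples(samples)
    events = events if events is not None else pd.DataFrame(
        columns=["mother", "offspring", "birth_date"])
    ev = events.copy()
    if len(ev):
        ev["mother"] = ev["mother"].astype(str)
        ev["offspring"] = ev["offspring"].astype(str)

    log = {"nonpositive_cortisol": 0, "degenerate_sg": 0, "sick": 0,
           "pregnant": 0, "state_unassignable": 0, "maternal_loss": 0}
    drop = pd.Series(False, index=df.index)

    bad_cort = ~(df["cortisol_raw"] > 0)
    bad_sg = ~(df["specific_gravity"] > 1.0)
    log["nonpositive_cortisol"] = int(bad_cort.sum())
    log["degenerate_sg"] = int(bad_sg.sum())
    drop |= bad_cort | bad_sg

    log["sick"] = int(df["sick_flag"].sum())
    drop |= df["sick_flag"]

    # reproductive state for adult females
    adult_female = (df["sex"] == "female") & (
        df["age_years"] >= cfg.adult_age_years)
    known_mothers = set(ev["mother"]) if len(ev) else set()
    states = pd.Series(pd.NA, index=df.index, dtype=object)
    for idx in df.index[adult_female]:
        ind = df.at[idx, "individual"]
        if ind not in known_mothers:
            log["state_unassignable"] += 1
            drop.at[idx] = True
            continue
        states.at[idx] = assign_reproductive_state(
            ind, df.at[idx, "date"], ev, cfg)
    df["reproductive_state"] = states
    pregnant = states == "pregnant"
    log["pregnant"] = int(pregnant.sum())
    drop |= pregnant.fillna(False).astype(bool)

    # maternal loss during immaturity: exclude immature samples taken
    # after the mother's death; mature samples are always retained
    if len(ev) and "mother_death_date" in ev.columns:
        deaths = (ev.dropna(subset=["mother_death_date"])
                    .set_index("offspring")["mother_death_date"])
        deaths = pd.to_datetime(deaths)
        immature = df["age_years"] < cfg.adult_age_years
        for idx in df.index[immature]:
            ind = df.at[idx, "individual"]
            if ind in deaths.index and df.at[idx, "date"] > deaths[ind]:
                log["maternal_loss"] += 1
                drop.at[idx] = True

    return df.loc[~drop].copy(), log


def sampling_span_filter(samples: pd.DataFrame,
                         cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Keep only individual-years able to anchor a circadian curve.

    An individual-year is retained when it has >= ``min_samples_per_year``
    samples, the earliest and latest clock times are >= ``min_span_hours``
    apart, and both a morning (< cutoff) and an afternoon (>= cutoff)
    sample are present.
    """
    cfg = cfg or FilterConfig()
    df = samples if "hours" in samples.columns else _normalize_samples(samples)

    def ok(g: pd.DataFrame) -> bool:
        h = g["hours"]
        return (len(g) >= cfg.min_samples_per_year
                and h.max() - h.min() >= cfg.min_span_hours
                and (h < cfg.morning_cutoff_hour).any()
                and (h >= cfg.morning_cutoff_hour).any())

    keep = df.groupby(["individual", "year"]).filter(ok)
    return keep.copy()


def _zscore(x: pd.Series, stats: dict, name: str) -> pd.Series:
    if name in stats:
        mean, sd = stats[name]
    else:
        mean, sd = float(x.mean()), float(x.std(ddof=0))
        stats[name] = (mean, sd if sd > 0 else 1.0)
        mean, sd = stats[name]
    return (x - mean) / (sd if sd > 0 else 1.0)


def encode_covariates(samples: pd.DataFrame,
                      reference_stats: dict | None = None,
                      sg_population_mean: float | dict | None = None,
                      cfg: FilterConfig | None = None) -> PreparedDataset:
    """Encode a filtered sample table into model-ready columns.

    y = ln(SG-corrected cortisol); t = z-scored hours-since-midnight
    and t2 = t**2 (quadratic of the standardized linear term, so slope
    scales are comparable across runs); season_sin/cos from the
    day-of-year angle 2*pi*doy/365.25; z-scores for age, group size and
    sex ratio; composite group_year and id_year factors.  Passing
    ``reference_stats`` from a previous encoding reproduces it exactly
    (idempotent re-encoding).
    """
    cfg = cfg or FilterConfig()
    df = samples if "hours" in samples.columns else _normalize_samples(samples)
    df = df.copy()
    stats = dict(reference_stats or {})

    # SG population mean per site over the retained samples (override
    # with a number, or a {site: mean} mapping)
    site = df["site"].astype(str) if "site" in df.columns else pd.Series(
        "all", index=df.index)
    if sg_population_mean is None:
        means = df.groupby(site)["specific_gravity"].mean().to_dict()
    elif isinstance(sg_population_mean, dict):
        means = dict(sg_population_mean)
    else:
        means = {s: float(sg_population_mean) for s in site.unique()}
    pop = site.map(means).astype(float)
    df["cortisol_sg"] = sg_correct(df["cortisol_raw"], df["specific_gravity"],
                                   pop)
    df["y"] = np.log(df["cortisol_sg"])

    df["t"] = _zscore(df["hours"], stats, "t")
    df["t2"] = df["t"] ** 2
    doy = df["date"].dt.dayofyear
    angle = 2.0 * np.pi * doy / 365.25
    df["season_sin"] = np.sin(angle)
    df["season_cos"] = np.cos(angle)
    df["age_z"] = _zscore(df["age_years"], stats, "age_z")
    for src, dst in (("group_size", "groupsize_z"), ("sex_ratio", "sexratio_z")):
        if src in df.columns:
            df[dst] = _zscore(df[src].astype(float), stats, dst)
        else:
            df[dst] = 0.0
            stats.setdefault(dst, (0.0, 1.0))
    if "reproductive_state" not in df.columns:
        df["reproductive_state"] = pd.NA
    df["demographic"] = df.apply(lambda r: _demographic(r, cfg), axis=1)
    df["group_year"] = df["group"] + "::" + df["year"].astype(str)
    df["id_year"] = df["individual"] + "::" + df["year"].astype(str)
    df["lcms_method"] = df["lcms_method"].astype(str).str.lower()

    if "mother" not in df.columns:
        df["mother"] = pd.NA
    # unknown mothers get unique singleton levels so every row has a
    # maternal factor level
    unknown = df["mother"].isna() | (df["mother"].astype(str).str.len() == 0)
    df.loc[unknown, "mother"] = "mother_of_" + df.loc[unknown, "individual"]
    df["mother"] = df["mother"].astype(str)

    keep = ["sample_id"] if "sample_id" in df.columns else []
    keep += ["individual", "group", "project", "date", "year", "hours",
             "cortisol_sg", "y", "t", "t2", "demographic", "age_z",
             "season_sin", "season_cos", "sexratio_z", "groupsize_z",
             "lcms_method", "group_year", "id_year", "mother", "sex",
             "reproductive_state"]
    if "dominance" in df.columns:
        keep.append("dominance")
    return PreparedDataset(df[keep].reset_index(drop=True), stats,
                           sg_population_mean=means)


def prepare(samples: pd.DataFrame, events: pd.DataFrame | None = None,
            cfg: FilterConfig | None = None,
            reference_stats: dict | None = None,
            sg_population_mean: float | dict | None = None,
            mother_map: dict[str, str] | None = None) -> PreparedDataset:
    """Full preprocessing pipeline: exclusions -> span filter -> encoding."""
    cfg = cfg or FilterConfig()
    retained, log = apply_exclusions(samples, events, cfg)
    n0 = len(retained)
    retained = sampling_span_filter(retained, cfg)
    log["span_rule"] = n0 - len(retained)
    if mother_map is None and events is not None and len(events):
        mother_map = (events.astype({"offspring": str, "mother": str})
                      .set_index("offspring")["mother"].to_dict())
    if mother_map:
        retained = retained.copy()
        retained["mother"] = retained["individual"].map(mother_map)
    prepared = encode_covariates(retained, reference_stats,
                                 sg_population_mean, cfg)
    prepared.exclusion_log = log
    return prepared
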