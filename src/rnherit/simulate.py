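"""Synthetic pedigrees and cortisol datasets with known variance structure.

The generator mirrors the study system: several chimpanzee-like
communities, a shallow multi-generation pedigree per community (mothers
with several offspring, maternal/paternal half-sibs, unrelated founder
"immigrants"), longitudinal urine sampling whose schedules satisfy the
circadian-coverage inclusion rules by construction, and log cortisol
generated from

    y = X beta + sum_k Z_k u_k + eps

with per-factor 3x3 reaction-norm covariance matrices (intercept,
linear, quadratic time-of-day) and a genetic term with covariance
A (x) Sigma_genetic.  Raw concentrations are back-transformed through
the inverse specific-gravity correction so the whole preprocessing
pipeline can round-trip the data.

The analytic ground-truth decomposition applies the same
repeatability/heritability formulas as the inference pipeline to the
configured variances, giving exact targets for parameter-recovery
tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess
from .model import fixed_design, _FULL_COVARIATES
from .pedigree import (Pedigree, PedigreeRecord, RelatednessMatrix,
                       additive_relationship_matrix)

#: z-scale of clock times drawn uniformly on [06:00, 18:00]
_T_SD = 12.0 / np.sqrt(12.0)


def rn_cov(v_intercept: float, v_linear: float = 0.0, v_quadratic: float = 0.0
           ) -> np.ndarray:
    """Diagonal 3x3 reaction-norm covariance (intercept, t, t2)."""
    return np.diag([v_intercept, v_linear, v_quadratic]).astype(float)


@dataclass
class SimulationConfig:
    # population structure
    n_groups: int = 5
    individuals_per_group: int = 34
    founders_fraction: float = 0.4
    p_sire_known: float = 0.6
    n_projects: int = 2
    # sampling design
    n_years: int = 2
    start_year: int = 2014
    mean_samples_per_ind_year: float = 14.0
    # fixed effects on log cortisol (keys are encoded design-column names)
    mean_log_cortisol: float = 4.0
    beta_t: float = -0.5
    beta_t2: float = 0.1
    fixed_effects: dict = field(default_factory=lambda: {
        "demographic[cycling female]": 0.10,
        "demographic[lactating female]": 0.15,
        "demographic[immature male]": -0.10,
        "demographic[immature female]": -0.10,
        "lcms_method[old]": -0.30,
        "age_z": 0.05, "season_sin": 0.05, "season_cos": -0.05,
        "groupsize_z": -0.15, "sexratio_z": 0.05,
    })
    # variance structure: loosely mirrors the study system, where
    # long-term community differences dominate average levels and the
    # maternal share of within-group variance exceeds the genetic share
    Sigma_group: np.ndarray = field(
        default_factory=lambda: rn_cov(2.0, 0.05, 0.01))
    Sigma_group_year: np.ndarray = field(
        default_factory=lambda: rn_cov(0.185, 0.02, 0.02))
    Sigma_project: np.ndarray = field(
        default_factory=lambda: rn_cov(0.01, 0.002, 0.002))
    Sigma_individual: np.ndarray = field(
        default_factory=lambda: rn_cov(0.005, 0.003, 0.002))
    Sigma_id_year: np.ndarray = field(
        default_factory=lambda: rn_cov(0.0325, 0.008, 0.02))
    Sigma_mother: np.ndarray = field(
        default_factory=lambda: rn_cov(0.02, 0.005, 0.002))
    Sigma_genetic: np.ndarray = field(
        default_factory=lambda: rn_cov(0.0025, 0.003, 0.002))
    sigma2_residual: float = 0.35
    # assay / collection nuisance structure
    sg_population_mean: float = 1.02
    sg_range: tuple[float, float] = (1.008, 1.035)
    sampling_window: tuple[float, float] = (6.0, 18.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("Sigma_group", "Sigma_group_year", "Sigma_project",
                     "Sigma_individual", "Sigma_id_year", "Sigma_mother",
                     "Sigma_genetic"):
            S = np.asarray(getattr(self, name), dtype=float)
            if S.shape != (3, 3) or not np.allclose(S, S.T):
                raise ValueError(f"{name} must be a symmetric 3x3 matrix")
            if np.min(np.linalg.eigvalsh(S)) < -1e-10:
                raise ValueError(f"{name} is not positive semi-definite")
            setattr(self, name, S)
        if self.sigma2_residual < 0:
            raise ValueError("sigma2_residual must be non-negative")

    def sigma_for(self, factor: str) -> np.ndarray:
        return getattr(self, f"Sigma_{factor}")


def preset(name: str, seed: int = 0) -> SimulationConfig:
    """Named study conditions.

    ``study``: full-scale defaults (5 groups, ~34 individuals each).
    ``recovery``: reduced parameter-recovery scale — 3 groups x 15
    individuals, 2 years, ~10 samples per individual-year, with
    within-group intercept shares genetic 0.1 / maternal 0.2 /
    group-year 0.4 / individual 0.2 / ID-year 0.1.
    ``tiny``: smoke-test scale.
    """
    if name == "study":
        return SimulationConfig(seed=seed)
    if name == "recovery":
        return SimulationConfig(
            n_groups=3, individuals_per_group=15, n_years=2,
            mean_samples_per_ind_year=10.0, seed=seed,
            Sigma_group=rn_cov(0.3, 0.03, 0.01),
            Sigma_group_year=rn_cov(0.4, 0.04, 0.04),
            Sigma_project=rn_cov(0.01, 0.002, 0.002),
            Sigma_individual=rn_cov(0.2, 0.02, 0.01),
            Sigma_id_year=rn_cov(0.1, 0.01, 0.02),
            Sigma_mother=rn_cov(0.2, 0.02, 0.01),
            Sigma_genetic=rn_cov(0.1, 0.01, 0.005),
            sigma2_residual=0.5)
    if name == "tiny":
        return SimulationConfig(
            n_groups=3, individuals_per_group=8, n_years=2,
            mean_samples_per_ind_year=5.0, seed=seed,
            Sigma_group=rn_cov(0.3, 0.02, 0.01),
            Sigma_group_year=rn_cov(0.3, 0.02, 0.02),
            Sigma_project=rn_cov(0.01, 0.002, 0.002),
            Sigma_individual=rn_cov(0.25, 0.02, 0.01),
            Sigma_id_year=rn_cov(0.1, 0.01, 0.01),
            Sigma_mother=rn_cov(0.15, 0.01, 0.01),
            Sigma_genetic=rn_cov(0.1, 0.01, 0.005),
            sigma2_residual=0.5)
    raise KeyError(f"unknown preset {name!r}")


@dataclass
class SimulatedDataset:
    samples: pd.DataFrame
    events: pd.DataFrame
    pedigree_frame: pd.DataFrame
    pedigree: Pedigree
    A: RelatednessMatrix
    mother_map: dict[str, str | None]
    truth: dict
    config: SimulationConfig

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.samples.to_csv(directory / "samples.csv", index=False)
        self.events.to_csv(directory / "events.csv", index=False)
        self.pedigree_frame.to_csv(directory / "pedigree.csv", index=False)
        (directory / "truth.json").write_text(json.dumps(self.truth, indent=2))


# ---------------------------------------------------------------------------
# pedigree generation

def simulate_pedigree(cfg: SimulationConfig,
                      rng: np.random.Generator | None = None
                      ) -> tuple[Pedigree, dict]:
    """Multi-generation pedigree per community.

    Founders are unrelated immigrants with unknown parents; two
    offspring generations draw dams and sires among within-group
    adults, so maternal sibs, paternal half-sibs and full sibs all
    arise.  Returns the pedigree and auxiliary per-individual info
    (sex, birth date, group).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    start = pd.Timestamp(cfg.start_year, 1, 1)
    records: list[PedigreeRecord] = []
    info: dict[str, dict] = {}

    def birth(years_before_low, years_before_high) -> pd.Timestamp:
        days = rng.integers(int(years_before_low * 365.25),
                            int(years_before_high * 365.25))
        return start - pd.Timedelta(days=int(days))

    for g in range(cfg.n_groups):
        group = f"g{g + 1}"
        n = cfg.individuals_per_group
        n_f = max(4, int(round(cfg.founders_fraction * n)))
        n_f = min(n_f, n)
        founders = []
        for i in range(n_f):
            ind = f"{group}_F{i + 1}"
            sex = "female" if i % 2 == 0 else "male"
            records.append(PedigreeRecord(ind, None, None, group, sex))
            info[ind] = {"sex": sex, "group": group,
                         "birth_date": birth(15, 35)}
            founders.append(ind)
        f_dams = [i for i in founders if info[i]["sex"] == "female"]
        f_sires = [i for i in founders if info[i]["sex"] == "male"]
        n_off = n - n_f
        n_g1 = (n_off + 1) // 2
        gen1 = []
        for i in range(n_off):
            ind = f"{group}_O{i + 1}"
            sex = "female" if rng.random() < 0.5 else "male"
            if i < n_g1:
                dam = str(rng.choice(f_dams))
                sire = str(rng.choice(f_sires))
                bd = birth(6, 14)
            else:
                dams = f_dams + [x for x in gen1 if info[x]["sex"] == "female"]
                sires = f_sires + [x for x in gen1 if info[x]["sex"] == "male"]
                dam = str(rng.choice(dams))
                sire = str(rng.choice(sires))
                bd = birth(1, 6)
            if rng.random() > cfg.p_sire_known:
                sire = None
            records.append(PedigreeRecord(ind, dam, sire, group, sex))
            info[ind] = {"sex": sex, "group": group, "birth_date": bd}
            if i < n_g1:
                gen1.append(ind)
    return Pedigree(records), info


def _events_frame(ped: Pedigree, info: dict, cfg: SimulationConfig,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Reproductive histories: the pedigree's own mother-offspring
    births, plus one past birth for each childless adult female so that
    every adult female has an assignable reproductive state."""
    start = pd.Timestamp(cfg.start_year, 1, 1)
    end = pd.Timestamp(cfg.start_year + cfg.n_years, 1, 1)
    rows = []
    dams = set()
    for r in ped.records:
        if r.dam is not None:
            rows.append({"mother": r.dam, "offspring": r.individual,
                         "birth_date": info[r.individual]["birth_date"]})
            dams.add(r.dam)
    for ind, meta in info.items():
        # females reaching adulthood at any point of the sampling window
        age_end = (end - meta["birth_date"]).days / 365.25
        if meta["sex"] == "female" and age_end >= 12.0 and ind not in dams:
            bd = start - pd.Timedelta(days=int(rng.integers(400, 2500)))
            rows.append({"mother": ind, "offspring": f"unsampled_{ind}",
                         "birth_date": bd})
    ev = pd.DataFrame(rows)
    ev["birth_date"] = pd.to_datetime(ev["birth_date"]).dt.date
    return ev


# ---------------------------------------------------------------------------
# cortisol generation

def _sampling_schedule(cfg: SimulationConfig, rng: np.random.Generator,
                       n: int) -> np.ndarray:
    """Clock times for one individual-year: guaranteed to satisfy the
    3-sample / 6-h span / morning+afternoon rule."""
    lo, hi = cfg.sampling_window
    times = [rng.uniform(lo, min(9.0, hi - 6.5)),
             rng.uniform(max(15.5, lo + 6.5), hi)]
    times += list(rng.uniform(lo, hi, size=max(0, n - 2)))
    return np.array(times)


def _draw_effects(levels: list[str], Sigma: np.ndarray,
                  rng: np.random.Generator,
                  L_A: np.ndarray | None = None) -> pd.DataFrame:
    """Realized (intercept, t, t2) deviates per level; rows iid
    N(0, Sigma), or A-correlated when a Cholesky factor is given."""
    m = len(levels)
    vals, vecs = np.linalg.eigh(np.asarray(Sigma, float))
    root = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))
    G = rng.standard_normal((m, 3))
    U = G @ root.T
    if L_A is not None:
        U = L_A @ U
    return pd.DataFrame(U, index=levels, columns=["intercept", "t", "t2"])


def simulate_cortisol(cfg: SimulationConfig,
                      rng: np.random.Generator | None = None
                      ) -> SimulatedDataset:
    """Generate a full synthetic dataset under ``cfg``.

    The emitted raw sample table round-trips through preprocessing: the
    generator encodes its own covariates with the same code path the
    pipeline uses, adds the simulated reaction-norm deviations and
    residual noise on the log scale, and back-transforms through the
    inverse SG correction.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    ped, info = simulate_pedigree(cfg, rng)
    events = _events_frame(ped, info, cfg, rng)
    A = additive_relationship_matrix(ped)
    mother_map = ped.mother_map()

    inds = [r.individual for r in ped.records]
    project_of = {i: f"p{1 + rng.integers(cfg.n_projects)}" for i in inds}
    start = pd.Timestamp(cfg.start_year, 1, 1)
    # adult head-counts and sex ratios per group (with yearly jitter)
    by_group: dict[str, list[str]] = {}
    for i in inds:
        by_group.setdefault(info[i]["group"], []).append(i)
    rows = []
    sid = 0
    for ind in inds:
        meta = info[ind]
        g = meta["group"]
        adults = [j for j in by_group[g]
                  if (start - info[j]["birth_date"]).days / 365.25 >= 12]
        males = sum(info[j]["sex"] == "male" for j in adults)
        females = max(1, len(adults) - males)
        for yr in range(cfg.start_year, cfg.start_year + cfg.n_years):
            n_s = max(3, int(rng.poisson(cfg.mean_samples_per_ind_year)))
            times = _sampling_schedule(cfg, rng, n_s)
            days = rng.integers(0, 365, size=n_s)
            gsize = len(adults) + int(rng.integers(-2, 3))
            sratio = round(males / females + rng.normal(0, 0.03), 3)
            for h, day in zip(times, days):
                date = pd.Timestamp(yr, 1, 1) + pd.Timedelta(days=int(day))
                sid += 1
                rows.append({
                    "sample_id": f"s{sid:06d}",
                    "individual": ind, "group": g,
                    "project": project_of[ind],
                    "date": date.date(),
                    "time": f"{int(h):02d}:{int(round((h % 1) * 60)) % 60:02d}",
                    "cortisol_raw": 1.0,
                    "specific_gravity": round(rng.uniform(*cfg.sg_range), 4),
                    "lcms_method": "old" if date < _changeover(cfg) else "new",
                    "sex": meta["sex"],
                    "birth_date": meta["birth_date"].date(),
                    "group_size": max(2, gsize),
                    "sex_ratio": max(0.05, sratio),
                    "sick_flag": 0,
                })
    samples = pd.DataFrame(rows)

    # encode covariates exactly as the pipeline will
    prep = preprocess.prepare(samples, events,
                              sg_population_mean=cfg.sg_population_mean)
    if len(prep.data) != len(samples):
        raise RuntimeError(
            "simulated schedule unexpectedly failed the inclusion rules")
    df = prep.data.set_index("sample_id")

    X, names = fixed_design(df, _FULL_COVARIATES)
    beta = np.zeros(len(names))
    coef = dict(cfg.fixed_effects)
    coef.update({"intercept": cfg.mean_log_cortisol,
                 "t": cfg.beta_t, "t2": cfg.beta_t2})
    for j, name in enumerate(names):
        beta[j] = coef.get(name, 0.0)
    y = X @ beta

    t = df["t"].to_numpy(float)
    t2 = df["t2"].to_numpy(float)
    realized = {}
    for factor in ("group", "group_year", "project", "individual",
                   "id_year", "mother"):
        levels = sorted(df[factor].unique())
        U = _draw_effects(levels, cfg.sigma_for(factor), rng)
        realized[factor] = U
        eff = U.loc[df[factor]].to_numpy()
        y = y + eff[:, 0] + eff[:, 1] * t + eff[:, 2] * t2
    # genetic term over the whole pedigree, A-correlated
    Lvals, Lvecs = np.linalg.eigh(A.A)
    L_A = Lvecs @ np.diag(np.sqrt(np.clip(Lvals, 0.0, None))) @ Lvecs.T
    U_gen = _draw_effects(list(A.ids), cfg.Sigma_genetic, rng, L_A=L_A)
    realized["genetic"] = U_gen
    eff = U_gen.loc[df["individual"]].to_numpy()
    y = y + eff[:, 0] + eff[:, 1] * t + eff[:, 2] * t2
    y = y + rng.normal(0.0, np.sqrt(cfg.sigma2_residual), size=len(y))

    sg = samples.set_index("sample_id").loc[
        df.index, "specific_gravity"].to_numpy(float)
    raw = np.exp(y) * (sg - 1.0) / (cfg.sg_population_mean - 1.0)
    samples = samples.set_index("sample_id")
    samples.loc[df.index, "cortisol_raw"] = raw
    samples = samples.reset_index()

    ped_frame = pd.DataFrame(
        [{"individual": r.individual, "dam": r.dam or "", "sire": r.sire or "",
          "group": r.group, "sex": r.sex} for r in ped.records])
    truth = {"decomposition": ground_truth_decomposition(cfg),
             "true_y_mean": float(np.mean(y))}
    return SimulatedDataset(samples=samples, events=events,
                            pedigree_frame=ped_frame, pedigree=ped, A=A,
                            mother_map=mother_map, truth=truth, config=cfg)


def _changeover(cfg: SimulationConfig) -> pd.Timestamp:
    """LCMS internal-standard changeover date: midpoint of the window."""
    return pd.Timestamp(cfg.start_year + cfg.n_years // 2, 7, 1) \
        if cfg.n_years > 1 else pd.Timestamp(cfg.start_year, 7, 1)


# ---------------------------------------------------------------------------
# analytic ground truth

def ground_truth_decomposition(cfg: SimulationConfig) -> dict[str, float]:
    """Exact decomposition implied by the configured covariances,
    using the same formulas as the inference pipeline."""
    comp_index = {"intercept": 0, "linear": 1, "quadratic": 2}
    out: dict[str, float] = {}
    v = {f: np.diag(cfg.sigma_for(f)) for f in
         ("group", "group_year", "project", "individual", "id_year",
          "mother", "genetic")}
    for comp, k in comp_index.items():
        within = (v["genetic"][k] + v["mother"][k] + v["group_year"][k]
                  + v["individual"][k] + v["id_year"][k])
        total_bw = v["group"][k] + within
        if total_bw > 0:
            out[f"between_group_{comp}"] = v["group"][k] / total_bw
            out[f"within_group_{comp}"] = within / total_bw
        if within > 0:
            out[f"h2_genetic_{comp}"] = v["genetic"][k] / within
            out[f"m2_maternal_{comp}"] = v["mother"][k] / within
            out[f"p_group_year_{comp}"] = v["group_year"][k] / within
            out[f"p_individual_{comp}"] = v["individual"][k] / within
            out[f"p_id_year_{comp}"] = v["id_year"][k] / within
        rn_den = v["individual"][k] + v["id_year"][k]
        if rn_den > 0:
            out[f"rn_repeatability_{comp}"] = v["individual"][k] / rn_den
    tot = (v["individual"][0] + v["id_year"][0] + v["group"][0]
           + v["group_year"][0])
    if tot > 0:
        out["trait_repeatability_long_term"] = v["individual"][0] / tot
        out["trait_repeatability_short_term"] = (
            v["individual"][0] + v["id_year"][0]) / tot
    within0 = (v["genetic"][0] + v["mother"][0] + v["group_year"][0]
               + v["individual"][0] + v["id_year"][0])
    den = within0 + cfg.sigma2_residual
    if den > 0:
        out["trait_heritability"] = v["genetic"][0] / den
    return out


def null_truth(cfg: SimulationConfig) -> SimulationConfig:
    """Copy of ``cfg`` with zero maternal and genetic variance."""
    return replace(cfg, Sigma_mother=np.zeros((3, 3)),
                   Sigma_genetic=np.zeros((3, 3)))
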