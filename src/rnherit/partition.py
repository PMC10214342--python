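"""Variance partitioning: repeatability and heritability with credible
intervals.

All quantities are computed per posterior draw (ratio first, summarize
second — this is what produces credible intervals on proportions) and
summarized as the median with an equal-tailed 95% interval.  Components
refer to the three reaction-norm dimensions: intercept (average cortisol
level), linear and quadratic time-of-day slopes.

By default the research-project term — a technical predictor — is
excluded from every denominator; ``include_technical=True`` adds it to
the within-group sum (which mechanically lowers the biological shares).
Draws with a zero denominator propagate as missing and are dropped from
summaries with a recorded count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import FitResult

log = logging.getLogger(__name__)

#: reaction-norm component names -> slope-dimension names used by the model
COMPONENTS = {"intercept": "intercept", "linear": "t", "quadratic": "t2"}

#: biological within-group factors of the animal model
WITHIN_FACTORS = ["genetic", "mother", "group_year", "individual", "id_year"]


class PartitionError(ValueError):
    """Requested quantity unavailable from this fit."""


@dataclass
class VarianceComponents:
    """Per-draw variances by factor and reaction-norm component."""

    variances: dict[str, dict[str, np.ndarray]]   # factor -> component -> draws
    residual: np.ndarray | None = None
    variant: str = ""

    def get(self, factor: str, component: str = "intercept") -> np.ndarray:
        try:
            return self.variances[factor][component]
        except KeyError:
            raise PartitionError(
                f"fit has no {component!r} variance for factor {factor!r} "
                f"(variant {self.variant!r})")

    def has(self, factor: str, component: str = "intercept") -> bool:
        return component in self.variances.get(factor, {})


def extract_components(fit: FitResult) -> VarianceComponents:
    """Pull the diagonal of each factor's covariance draws."""
    variances: dict[str, dict[str, np.ndarray]] = {}
    for factor, dims in fit.term_dims.items():
        variances[factor] = {}
        for comp, dim in COMPONENTS.items():
            if dim in dims:
                variances[factor][comp] = fit.component_draws(factor, dim)
    return VarianceComponents(variances, residual=fit.residual_draws(),
                              variant=fit.spec.variant)


def _ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Per-draw ratio; zero denominators propagate as NaN (undefined)."""
    out = np.full_like(den, np.nan, dtype=float)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def summarize(draws: np.ndarray) -> dict:
    """Median and equal-tailed 95% interval of a draw vector.

    NaN draws (undefined ratios) are dropped with a logged count.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("cannot summarize an empty draw vector")
    n_nan = int(np.isnan(draws).sum())
    if n_nan:
        log.warning("dropping %d undefined draw(s) from summary", n_nan)
    valid = draws[~np.isnan(draws)]
    if valid.size == 0:
        raise ValueError("all draws are undefined (zero denominators)")
    lo, med, hi = np.percentile(valid, [2.5, 50.0, 97.5])
    return {"median": float(med), "lo": float(lo), "hi": float(hi),
            "n_draws": int(valid.size)}


def trait_repeatability(vc: VarianceComponents) -> dict[str, np.ndarray]:
    """Long- and short-term trait repeatability of cortisol levels.

    The total is the intercept variance of individual + ID-year +
    group + group-year; long-term uses the individual share, short-term
    the individual + ID-year share.
    """
    v_ind = vc.get("individual")
    v_idy = vc.get("id_year")
    v_total = v_ind + v_idy + vc.get("group") + vc.get("group_year")
    return {"long_term": _ratio(v_ind, v_total),
            "short_term": _ratio(v_ind + v_idy, v_total)}


def rn_repeatability(vc: VarianceComponents, component: str = "intercept"
                     ) -> np.ndarray:
    """Reaction-norm repeatability: V_individual / (V_individual +
    V_ID-year) for the given component."""
    if not (vc.has("individual", component) and vc.has("id_year", component)):
        raise PartitionError(
            f"reaction-norm repeatability needs individual and id_year "
            f"{component!r} variances (fit random slopes for them)")
    v_ind = vc.get("individual", component)
    v_idy = vc.get("id_year", component)
    return _ratio(v_ind, v_ind + v_idy)


def _within_sum(vc: VarianceComponents, component: str,
                include_technical: bool) -> np.ndarray:
    tot = np.zeros_like(vc.get("group_year", component))
    for f in WITHIN_FACTORS:
        tot = tot + vc.get(f, component)
    if include_technical:
        tot = tot + vc.get("project", component)
    return tot


def between_within_partition(vc: VarianceComponents,
                             component: str = "intercept",
                             include_technical: bool = False
                             ) -> dict[str, np.ndarray]:
    """Share of variance between vs within communities; the two shares
    sum to one per draw."""
    v_group = vc.get("group", component)
    v_within = _within_sum(vc, component, include_technical)
    den = v_group + v_within
    return {"between_group": _ratio(v_group, den),
            "within_group": _ratio(v_within, den)}


def within_group_heritability(vc: VarianceComponents,
                              component: str = "intercept",
                              include_technical: bool = False
                              ) -> dict[str, np.ndarray]:
    """Within-group variance shares: genetic heritability (h2), maternal
    effects (m2), and the group-year / individual / ID-year shares.
    The shares sum to one per draw."""
    den = _within_sum(vc, component, include_technical)
    out = {
        "h2_genetic": _ratio(vc.get("genetic", component), den),
        "m2_maternal": _ratio(vc.get("mother", component), den),
        "p_group_year": _ratio(vc.get("group_year", component), den),
        "p_individual": _ratio(vc.get("individual", component), den),
        "p_id_year": _ratio(vc.get("id_year", component), den),
    }
    if include_technical:
        out["p_project"] = _ratio(vc.get("project", component), den)
    return out


def trait_heritability(vc: VarianceComponents) -> np.ndarray:
    """Narrow-sense trait heritability from the no-slope animal model:
    V_genetic over the biological within-group variance plus residual."""
    if vc.variant and vc.variant != "trait_heritability":
        raise PartitionError(
            "trait heritability is defined for the trait_heritability "
            f"variant (no random slopes); got {vc.variant!r}")
    if vc.residual is None:
        raise PartitionError("fit carries no residual variance draws")
    den = _within_sum(vc, "intercept", False) + vc.residual
    return _ratio(vc.get("genetic", "intercept"), den)


def decompose(fit: FitResult, include_technical: bool = False) -> dict:
    """Every quantity the fit's structure supports, summarized.

    Returns {name: {median, lo, hi, n_draws}}.
    """
    vc = extract_components(fit)
    out: dict[str, dict] = {}

    def add(name: str, draws: np.ndarray) -> None:
        out[name] = summarize(draws)

    if all(vc.has(f) for f in ("individual", "id_year", "group",
                               "group_year")):
        for k, v in trait_repeatability(vc).items():
            add(f"trait_repeatability_{k}", v)
    for comp in COMPONENTS:
        try:
            add(f"rn_repeatability_{comp}", rn_repeatability(vc, comp))
        except PartitionError:
            pass
    animal = all(vc.has(f) for f in WITHIN_FACTORS + ["group"])
    if animal:
        for comp in COMPONENTS:
            if not vc.has("genetic", comp):
                continue
            bw = between_within_partition(vc, comp, include_technical)
            add(f"between_group_{comp}", bw["between_group"])
            add(f"within_group_{comp}", bw["within_group"])
            for k, v in within_group_heritability(
                    vc, comp, include_technical).items():
                add(f"{k}_{comp}", v)
        if vc.variant == "trait_heritability":
            add("trait_heritability", trait_heritability(vc))
    return out
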