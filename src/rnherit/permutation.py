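"""Within-community permutation null for genetic vs maternal effects.

Variance components are bounded below by zero, so a credible interval
alone cannot say whether a genetic or maternal share is distinguishable
from chance.  The null implemented here reshuffles the identities of
the sampled individuals *within their communities* in the additive
genetic matrix (A_perm = P A P'), reassigning mothers through the same
permutation so that genetic and maternal relationships stay concordant
(new genetic sibs share a mother).  Group-level environmental and
social structure, the sample table, and the spectrum of A are all left
untouched; only who-is-related-to-whom is randomized.

The animal model is refit for every permuted dataset and the posterior
medians of the within-group genetic (h2) and maternal (m2) shares form
the null distribution.  Exceedance probabilities are one-sided
("permuted >= observed", ties counting toward the null); the lower
tail is also recorded so either reading convention is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (FitResult, ModelSpec, SamplerSettings, build_model,
                    fit_model, reduced_settings)
from .partition import (COMPONENTS, extract_components, summarize,
                        within_group_heritability)
from .pedigree import RelatednessMatrix
from .preprocess import PreparedDataset

log = logging.getLogger(__name__)


@dataclass
class PermutationPlan:
    n_permutations: int = 100
    seed: int = 0
    group_membership: dict[str, str] = field(default_factory=dict)

    def rng_for(self, index: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, index]))


@dataclass
class PermutationResult:
    observed: dict                       # component -> {h2, m2}
    permuted: pd.DataFrame               # permutation, component, h2, m2
    n_permutations: int
    n_failed: int = 0

    def exceedance(self, statistic: str, component: str = "intercept"
                   ) -> dict:
        """One-sided exceedance for 'h2' or 'm2': fraction of valid
        permutations with statistic >= observed (ties count), plus the
        lower-tail count."""
        obs = self.observed[component][statistic]
        vals = self.permuted.loc[self.permuted["component"] == component,
                                 statistic].to_numpy()
        if vals.size == 0:
            raise ValueError("empty permutation null")
        return {
            "observed": obs,
            "n": int(vals.size),
            "p_upper": float(np.mean(vals >= obs)),
            "n_lower": int(np.sum(vals < obs)),
        }


def draw_permutation(ids: list[str], groups: dict[str, str],
                     rng: np.random.Generator) -> dict[str, str]:
    """A bijection on ``ids`` that fixes group membership."""
    missing = [i for i in ids if i not in groups]
    if missing:
        raise ValueError(f"individual(s) lacking a group assignment: "
                         f"{missing[:5]}")
    pi: dict[str, str] = {}
    by_group: dict[str, list[str]] = {}
    for i in ids:
        by_group.setdefault(groups[i], []).append(i)
    for members in by_group.values():
        perm = rng.permutation(len(members))
        for a, b in zip(members, perm):
            pi[a] = members[b]
    return pi


def permute_identities(pi: dict[str, str], A: RelatednessMatrix,
                       mother_map: dict[str, str | None],
                       groups: dict[str, str] | None = None
                       ) -> tuple[RelatednessMatrix, dict[str, str | None]]:
    """Apply a within-group identity permutation to A and the mothers.

    A_perm[i, j] = A[pi(i), pi(j)] and mother_perm(i) = mother(pi(i)),
    so any pair newly classified as maternal sibs is also genetically
    related exactly as the source sibs were — concordance by
    construction.  Ids absent from ``pi`` (unsampled ancestors) keep
    their own identity.
    """
    if groups:
        for a, b in pi.items():
            if groups.get(a) != groups.get(b):
                raise ValueError(
                    f"permutation moves {a!r} across groups "
                    f"({groups.get(a)} -> {groups.get(b)})")
    perm_idx = np.array([A.index[pi.get(i, i)] for i in A.ids])
    A_perm = RelatednessMatrix(list(A.ids),
                               A.A[np.ix_(perm_idx, perm_idx)])
    mother_perm = {i: mother_map.get(pi.get(i, i))
                   for i in set(mother_map) | set(pi)}
    return A_perm, mother_perm


def _with_mothers(df: pd.DataFrame, pi: dict[str, str],
                  mother_map: dict[str, str | None]) -> pd.DataFrame:
    """Rewrite the mother factor column under the permutation; unknown
    mothers keep unique singleton levels named for the source id."""
    out = df.copy()

    def mother_of(ind: str) -> str:
        src = pi.get(ind, ind)
        m = mother_map.get(src)
        return m if m else f"mother_of_{src}"

    out["mother"] = [mother_of(i) for i in out["individual"]]
    return out


def _medians(fit: FitResult, include_technical: bool) -> dict:
    vc = extract_components(fit)
    out = {}
    for comp in COMPONENTS:
        if not vc.has("genetic", comp):
            continue
        shares = within_group_heritability(vc, comp, include_technical)
        out[comp] = {"h2": summarize(shares["h2_genetic"])["median"],
                     "m2": summarize(shares["m2_maternal"])["median"]}
    return out


def run_permutation_null(dataset, A: RelatednessMatrix,
                         mother_map: dict[str, str | None],
                         plan: PermutationPlan,
                         settings: SamplerSettings,
                         variant: str = "full_heritability",
                         observed_fit: FitResult | None = None,
                         perm_settings: SamplerSettings | None = None,
                         include_technical: bool = False
                         ) -> PermutationResult:
    """Fit the animal model on the observed data and on each permuted
    dataset; collect per-component h2/m2 posterior medians.

    ``perm_settings`` lets permutation refits use shorter chains than
    the observed fit (only point summaries feed the null); by default
    they are halved single-chain runs.  A permutation whose refit
    raises or produces non-finite draws is recorded as failed and
    excluded from the counts.
    """
    df = dataset.data if isinstance(dataset, PreparedDataset) else dataset
    ids = sorted(df["individual"].astype(str).unique())
    groups = plan.group_membership or (
        df.drop_duplicates("individual")
          .set_index("individual")["group"].astype(str).to_dict())
    if observed_fit is None:
        spec = build_model(df, variant, A=A)
        observed_fit = fit_model(spec, df, settings)
    observed = _medians(observed_fit, include_technical)

    perm_settings = perm_settings or reduced_settings(settings)
    records, n_failed = [], 0
    for k in range(plan.n_permutations):
        rng = plan.rng_for(k)
        pi = draw_permutation(ids, groups, rng)
        A_perm, mother_perm = permute_identities(pi, A, mother_map, groups)
        df_k = _with_mothers(df, pi, mother_perm)
        try:
            spec_k = build_model(df_k, variant, A=A_perm)
            fit_k = fit_model(spec_k, df_k, perm_settings)
            med = _medians(fit_k, include_technical)
            flat = [x for v in med.values() for x in v.values()]
            if not np.all(np.isfinite(flat)):
                raise FloatingPointError("non-finite permutation medians")
        except Exception as exc:      # noqa: BLE001 — recorded, never silent
            n_failed += 1
            log.warning("permutation %d failed and was excluded: %s", k, exc)
            continue
        for comp, v in med.items():
            records.append({"permutation": k, "component": comp,
                            "h2": v["h2"], "m2": v["m2"],
                            "diff": v["m2"] - v["h2"]})
    permuted = pd.DataFrame(records,
                            columns=["permutation", "component", "h2",
                                     "m2", "diff"])
    return PermutationResult(observed=observed, permuted=permuted,
                             n_permutations=plan.n_permutations,
                             n_failed=n_failed)


def difference_test(result: PermutationResult, component: str = "intercept"
                    ) -> dict:
    """Exceedance of the maternal-minus-genetic difference (m2 - h2):
    fraction of permutations with a difference >= the observed one
    (ties count toward the null)."""
    obs = (result.observed[component]["m2"]
           - result.observed[component]["h2"])
    vals = result.permuted.loc[result.permuted["component"] == component,
                               "diff"].to_numpy()
    if vals.size == 0:
        raise ValueError("empty permutation null")
    return {"observed_difference": obs, "n": int(vals.size),
            "p_upper": float(np.mean(vals >= obs))}
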