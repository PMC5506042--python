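"""Dual comparison of pooled and control-only eigen-decompositions.

The heart of the analysis: compute the SVD of the pooled (treatment +
control) profile and of the control-only profile, match their components
through the absolute cosine of the *gene* eigenvectors (the sample sets
differ, so sample eigenvectors are not comparable), then classify each
pooled component:

* matched with high similarity -> *endogenous* (present with or without
  the treatment, e.g. driven by age);
* unmatched in the control decomposition but associated with diet ->
  *exogenous-candidate* (the treatment-driven component that disappears
  when only controls are decomposed);
* otherwise unclassified.

Sample-loading/factor association uses a two-sided Wilcoxon rank-sum test
for binary factors (diet, subgroup; exact null when both groups are small)
and Spearman correlation for ordinal or continuous factors (week, tolerance
test AUCs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .eigen import EigenDecomposition

BINARY_FACTORS = ("diet", "subgroup")
ORDINAL_FACTORS = ("week", "gtt_auc", "itt_auc")

ENDOGENOUS = "endogenous"
EXOGENOUS = "exogenous-candidate"
UNCLASSIFIED = "unclassified"


@dataclass
class ComponentMatch:
    pooled_index: int
    control_index: int | None
    similarity: float                  # |cos| of gene eigenvectors
    classification: str = UNCLASSIFIED


@dataclass
class FactorAssociation:
    component_index: int
    factor: str
    statistic: float
    p_value: float
    direction: int                     # sign of the association
    degenerate: bool = False


def match_components(
    pooled: EigenDecomposition,
    control: EigenDecomposition,
    top_k: int = 3,
    min_similarity: float = 0.3,
) -> list[ComponentMatch]:
    """Greedy matching of the top pooled/control gene eigenvectors.

    Builds the top_k x top_k |cosine| matrix and assigns pairs largest
    similarity first; pairs below ``min_similarity`` stay unmatched.  An
    unmatched pooled component records its best (rejected) similarity for
    transparency.  Gene universes must agree exactly.
    """
    if len(pooled.genes) != len(control.genes) or not (pooled.genes == control.genes).all():
        raise ValueError("gene universes differ between the two decompositions")
    kp = min(top_k, pooled.n_components)
    kc = min(top_k, control.n_components)
    sim = np.abs(pooled.u[:, :kp].T @ control.u[:, :kc])   # columns orthonormal

    matches: dict[int, ComponentMatch] = {}
    used_p: set[int] = set()
    used_c: set[int] = set()
    # greedy: largest similarity first, ties broken by original component order
    order = sorted(
        ((i, j) for i in range(kp) for j in range(kc)),
        key=lambda ij: (-sim[ij], ij[0], ij[1]),
    )
    for i, j in order:
        if i in used_p or j in used_c:
            continue
        if sim[i, j] < min_similarity:
            break
        matches[i] = ComponentMatch(i, j, float(sim[i, j]))
        used_p.add(i)
        used_c.add(j)
    for i in range(kp):
        if i not in matches:
            best = float(sim[i].max()) if kc else 0.0
            matches[i] = ComponentMatch(i, None, best)
    return [matches[i] for i in range(kp)]


def associate_factor(
    v: np.ndarray,
    attributes: pd.DataFrame,
    factor: str,
    component_index: int = 0,
) -> FactorAssociation:
    """Association between one sample-loading vector and one design factor."""
    if factor not in attributes.columns:
        raise KeyError(f"factor {factor!r} not present in the attribute table")
    v = np.asarray(v, dtype=float)
    col = attributes[factor]
    mask = col.notna().to_numpy()
    vals = col[mask]
    load = v[mask]

    if len(np.unique(load)) < 2:
        return FactorAssociation(component_index, factor, float("nan"), 1.0, 0,
                                 degenerate=True)

    if factor in BINARY_FACTORS:
        levels = sorted(set(vals))
        if len(levels) != 2:
            raise ValueError(f"factor {factor!r} is not binary on these samples: {levels}")
        # convention: group1 = treatment-like level (HFD / Gw), group0 = the other
        lv1 = "HFD" if "HFD" in levels else levels[1]
        lv0 = [l for l in levels if l != lv1][0]
        g1 = load[(vals == lv1).to_numpy()]
        g0 = load[(vals == lv0).to_numpy()]
        if len(g0) == 0 or len(g1) == 0:
            raise ValueError(f"factor {factor!r}: one group is empty")
        ties = len(np.unique(load)) < len(load)
        method = "exact" if (len(g0) <= 12 and len(g1) <= 12 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(g1, g0, alternative="two-sided", method=method)
        direction = int(np.sign(res.statistic - len(g0) * len(g1) / 2.0))
        return FactorAssociation(component_index, factor, float(res.statistic),
                                 float(res.pvalue), direction)

    # ordinal / continuous: Spearman with t-approximation p-value
    x = vals.astype(float).to_numpy()
    if len(np.unique(x)) < 2:
        return FactorAssociation(component_index, factor, float("nan"), 1.0, 0,
                                 degenerate=True)
    res = stats.spearmanr(load, x)
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return FactorAssociation(component_index, factor, float(res.statistic),
                             p, int(np.sign(res.statistic)))


def associate_all(
    decomposition: EigenDecomposition,
    attributes: pd.DataFrame,
    top_k: int = 3,
    factors: tuple = ("diet", "week", "gtt_auc", "itt_auc", "subgroup"),
) -> list[FactorAssociation]:
    """Factor associations for each of the top components, where testable."""
    attributes = attributes.loc[decomposition.samples]
    out: list[FactorAssociation] = []
    for k in range(min(top_k, decomposition.n_components)):
        for factor in factors:
            if factor not in attributes.columns:
                continue
            col = attributes[factor].dropna()
            if factor in BINARY_FACTORS and len(set(col)) != 2:
                continue    # e.g. control-only profile has a single diet level
            if len(col) < 3:
                continue
            out.append(associate_factor(decomposition.v[:, k], attributes, factor, k))
    return out


def classify_components(
    matches: list[ComponentMatch],
    associations: list[FactorAssociation],
    sim_threshold: float = 0.6,
    alpha: float = 0.05,
    diet_factor: str = "diet",
) -> list[ComponentMatch]:
    """Endogenous / exogenous-candidate / unclassified labels.

    A pooled component matched in the control decomposition with similarity
    >= ``sim_threshold`` is endogenous.  A component with *no* control
    match whose diet association survives a Bonferroni correction over the
    factors tested for that component is an exogenous candidate.  Everything
    else (including matched-but-dissimilar components) is unclassified, so
    raising the threshold can only demote endogenous to unclassified.
    """
    by_component: dict[int, list[FactorAssociation]] = {}
    for a in associations:
        by_component.setdefault(a.component_index, []).append(a)

    out = []
    for m in matches:
        label = UNCLASSIFIED
        if m.control_index is not None and m.similarity >= sim_threshold:
            label = ENDOGENOUS
        elif m.control_index is None:
            assocs = by_component.get(m.pooled_index, [])
            n_tests = max(1, len(assocs))
            for a in assocs:
                if a.factor == diet_factor and min(1.0, a.p_value * n_tests) <= alpha:
                    label = EXOGENOUS
                    break
        out.append(replace(m, classification=label))
    return out
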