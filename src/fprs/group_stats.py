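"""Genus/family aggregation and the significance protocol for PRS indices.

Per index and climate scenario, species-level values are aggregated to
genus means and standard deviations (and to the family by pooling the
genera).  The protocol is:

1. one-sample two-sided t tests of I, Dx, Dy, Dz against zero at
   alpha = 0.05, with ** marking p < 0.01 and * marking p < 0.05 (the O
   index, being a bounded positive ratio, is excluded from this test);
2. one-way fixed-effects ANOVA across scenarios at alpha = 0.05, treating
   species as independent replicates;
3. if — and only if — the ANOVA is significant, Fisher's least
   significant difference (LSD) pairwise t tests between scenarios using
   the pooled ANOVA mean-square error, at alpha = 0.10, summarised as a
   compact letter display (scenarios sharing a letter do not differ).

Scenarios are in truth repeated measures on the same species; the plain
one-way ANOVA is kept as the faithful default, with a repeated-measures
variant available behind ``repeated_measures=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "IndexSample",
    "GroupSummary",
    "ScenarioComparison",
    "summarize",
    "t_vs_zero",
    "anova_scenarios",
    "lsd_t",
    "family_pool",
    "ZeroVarianceError",
    "GateViolationError",
]

ALPHA_T = 0.05
ALPHA_T_STRONG = 0.01
ALPHA_ANOVA = 0.05
ALPHA_LSD = 0.10


class ZeroVarianceError(ValueError):
    """A t test was requested on a sample with no variance."""


class GateViolationError(RuntimeError):
    """LSD-t requested in strict mode although the ANOVA gate failed."""


@dataclass
class IndexSample:
    """One group's species-level values of a single index in one scenario."""

    values: np.ndarray
    group_label: str = ""
    scenario_label: str = ""
    index_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValueError("empty sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sample contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class GroupSummary:
    mean: float
    std: float | None  # sample std (n-1); None when n < 2
    n: int
    sig_class: str | None = None  # "ns", "*", "**" once a t test has run


@dataclass
class ScenarioComparison:
    """ANOVA p, pairwise LSD-t p-values and the compact letter display."""

    anova_f: float
    anova_p: float
    performed: bool  # False when the ANOVA gate blocked pairwise tests
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    letters: dict[str, str] = field(default_factory=dict)


def summarize(sample: IndexSample) -> GroupSummary:
    """Mean, sample standard deviation (n-1 denominator) and n."""
    std = float(np.std(sample.values, ddof=1)) if sample.n >= 2 else None
    return GroupSummary(mean=float(np.mean(sample.values)), std=std, n=sample.n)


def _sig_class(p: float) -> str:
    if p < ALPHA_T_STRONG:
        return "**"
    if p < ALPHA_T:
        return "*"
    return "ns"


def t_vs_zero(sample: IndexSample) -> tuple[float, float, str]:
    """One-sample two-sided t test of the mean against zero (n-1 df)."""
    if sample.n < 2:
        raise ValueError("t test needs n >= 2")
    if np.std(sample.values, ddof=1) == 0:
        raise ZeroVarianceError("sample has zero variance")
    t, p = stats.ttest_1samp(sample.values, 0.0)
    return float(t), float(p), _sig_class(float(p))


def anova_scenarios(
    groups: Sequence[IndexSample], *, repeated_measures: bool = False
) -> tuple[float, float]:
    """One-way ANOVA F and p across scenario groups.

    The default treats species as independent replicates within each
    scenario.  ``repeated_measures=True`` instead removes the per-species
    block effect before testing (species must then be in identical order
    and number across groups).
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for g in groups:
        if g.n < 2:
            raise ValueError("each group needs n >= 2")
    arrays = [g.values for g in groups]
    if not repeated_measures:
        f, p = stats.f_oneway(*arrays)
        return float(f), float(p)
    mat = np.vstack(arrays)  # scenarios x species
    k, n = mat.shape
    grand = mat.mean()
    ss_scen = n * ((mat.mean(axis=1) - grand) ** 2).sum()
    ss_subj = k * ((mat.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((mat - grand) ** 2).sum()
    ss_err = ss_tot - ss_scen - ss_subj
    df_scen, df_err = k - 1, (k - 1) * (n - 1)
    f = (ss_scen / df_scen) / (ss_err / df_err)
    p = float(stats.f.sf(f, df_scen, df_err))
    return float(f), p


def _absorb(sets: list[list[str]]) -> list[list[str]]:
    """Drop letter sets that are subsets (or duplicates) of another."""
    keep: list[list[str]] = []
    for s in sets:
        ss = set(s)
        if any(ss < set(t) for t in sets):
            continue
        if ss in [set(t) for t in keep]:
            continue
        keep.append(s)
    return keep


def _letters_from_pairs(
    labels: Sequence[str],
    means: Sequence[float],
    differ: set[tuple[str, str]],
) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Groups sharing a letter are not significantly different under any of
    the pairwise decisions in ``differ`` (unordered significant pairs).
    """
    def differs(a: str, b: str) -> bool:
        return (a, b) in differ or (b, a) in differ

    order = sorted(range(len(labels)), key=lambda i: means[i])
    ordered = [labels[i] for i in order]
    # insert-and-absorb: maintain letter sets (cliques of mutually
    # non-different groups); on conflict, split off the compatible subset
    letter_sets: list[list[str]] = [[ordered[0]]] if ordered else []
    for lab in ordered[1:]:
        new_sets: list[list[str]] = []
        placed = False
        for s in letter_sets:
            if not any(differs(lab, other) for other in s):
                s.append(lab)
                placed = True
            else:
                sub = [o for o in s if not differs(lab, o)] + [lab]
                new_sets.append(sub)
        if not placed and not new_sets:
            new_sets.append([lab])
        letter_sets.extend(new_sets)
        # absorb duplicates/subsets as we go
        letter_sets = _absorb(letter_sets)
    keep = _absorb(letter_sets)
    keep.sort(key=lambda s: min(ordered.index(lab) for lab in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for letter, s in zip(alphabet, keep):
        for lab in s:
            out[lab] += letter
    return out


def lsd_t(
    groups: Sequence[IndexSample],
    *,
    strict: bool = False,
    anova_alpha: float = ALPHA_ANOVA,
    lsd_alpha: float = ALPHA_LSD,
) -> ScenarioComparison:
    """Fisher's LSD pairwise t tests, gated on a significant ANOVA.

    Pairwise t statistics use the pooled within-group mean-square error
    and its N - k degrees of freedom.  When the ANOVA is not significant
    at ``anova_alpha`` the pairwise stage is not performed: the result is
    returned with ``performed=False`` (the table convention is "/"), or a
    :class:`GateViolationError` is raised in strict mode.
    """
    f, p = anova_scenarios(groups)
    if p >= anova_alpha:
        if strict:
            raise GateViolationError(
                f"ANOVA p = {p:.4f} >= {anova_alpha}; pairwise LSD-t not allowed"
            )
        return ScenarioComparison(anova_f=f, anova_p=p, performed=False)

    labels = [g.scenario_label or f"group{i}" for i, g in enumerate(groups)]
    if len(set(labels)) != len(labels):
        raise ValueError("scenario labels must be unique")
    n_tot = sum(g.n for g in groups)
    k = len(groups)
    df_err = n_tot - k
    mse = sum((g.n - 1) * np.var(g.values, ddof=1) for g in groups) / df_err

    means = [float(np.mean(g.values)) for g in groups]
    pairwise: dict[tuple[str, str], float] = {}
    differ: set[tuple[str, str]] = set()
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse * (1 / groups[i].n + 1 / groups[j].n))
            t = (means[i] - means[j]) / se
            pij = float(2 * stats.t.sf(abs(t), df_err))
            pairwise[(labels[i], labels[j])] = pij
            if pij < lsd_alpha:
                differ.add((labels[i], labels[j]))
    letters = _letters_from_pairs(labels, means, differ)
    return ScenarioComparison(
        anova_f=f, anova_p=p, performed=True, pairwise=pairwise, letters=letters
    )


def family_pool(per_genus: Sequence[IndexSample]) -> IndexSample:
    """Pool genus samples into one family-level sample.

    All inputs must share the index name and scenario label; values are
    concatenated (so the pooled mean is the species-count-weighted mean
    of genus means).
    """
    if not per_genus:
        raise ValueError("nothing to pool")
    idx = {g.index_name for g in per_genus}
    scen = {g.scenario_label for g in per_genus}
    if len(idx) != 1 or len(scen) != 1:
        raise ValueError(
            f"cannot pool mixed samples (index names {idx}, scenarios {scen})"
        )
    values = np.concatenate([g.values for g in per_genus])
    return IndexSample(
        values=values,
        group_label="family",
        scenario_label=per_genus[0].scenario_label,
        index_name=per_genus[0].index_name,
    )
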