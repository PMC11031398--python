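"""Descriptive and inferential statistics across diagnosis groups.

The machinery behind the cross-disorder comparisons:

* dot statistics — per attribute x diagnosis group, the mean number of
  observation-years per donor (dot colour, display-capped at 5) and the
  proportion of donors with at least one observation (dot size);
* permutation enrichment — is an attribute observed more often in a
  diagnosis group than under random relabeling of donors? One-sided upper
  tail, ties counted as >=, add-one corrected
  ``p = (1 + #{perm >= obs}) / (1 + n_perm)``; an exhaustive mode
  enumerates every distinct label assignment on tiny cohorts (no add-one
  there, since the identity assignment is included). BH-FDR across the
  attribute x diagnosis panel, significance at q < 0.1;
* a two-sided Pearson chi-square test (no continuity correction) for
  whether significant enrichments coincide with a-priori
  diagnostic-importance flags;
* sex-balanced subsampling (each group downsampled to its minority sex);
* pairwise two-sided Mann-Whitney U tests with BH-FDR, used for
  observation-count profiles, temporal (age-of-observation) profiles and
  post-onset survival comparisons. Small samples get an exact permutation
  enumeration (valid under ties); larger ones the tie-corrected normal
  approximation;
* Kaplan-Meier survival after the first observation of a sign/symptom.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DOT_COLOR_CAP",
    "ENRICHMENT_Q_THRESHOLD",
    "PROFILE_P_THRESHOLD",
    "SurvivalCurve",
    "dot_statistics",
    "donor_attribute_counts",
    "permutation_enrichment",
    "enrichment_table",
    "bh_fdr",
    "chi2_2x2",
    "diagnostic_importance_chi2",
    "sex_balance_subsample",
    "mwu_test",
    "pairwise_mwu",
    "observation_count_tests",
    "temporal_distribution_tests",
    "km_survival",
    "survival_tests",
]

#: Display cap for the dot-plot colour scale (mean observations).
DOT_COLOR_CAP = 5.0
#: FDR threshold for calling an enrichment significant.
ENRICHMENT_Q_THRESHOLD = 0.1
#: Display threshold for the pairwise-profiling heatmaps.
PROFILE_P_THRESHOLD = 0.01


# ---------------------------------------------------------------------------
# dot statistics and permutation enrichment


def donor_attribute_counts(
    observations: pd.DataFrame, donors: Sequence[str] | None = None
) -> pd.DataFrame:
    """Donor x attribute matrix of observation-year counts.

    ``observations`` is a long table with ``donor_id`` and ``attribute``
    columns, one row per (donor, attribute, year) observation. Donors
    listed in ``donors`` but absent from the table get all-zero rows.
    """
    counts = (
        observations.groupby(["donor_id", "attribute"]).size().unstack(fill_value=0)
    )
    if donors is not None:
        counts = counts.reindex(list(donors), fill_value=0)
    return counts.sort_index()


def dot_statistics(
    counts: pd.DataFrame, groups: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Mean observations and donor proportion per attribute x group.

    ``counts`` is the donor x attribute count matrix; ``groups`` maps each
    donor to exactly one diagnosis group. The colour cap is recorded in
    ``result.attrs["color_cap"]``.
    """
    labels = pd.Series(groups).reindex(counts.index)
    if labels.isna().any():
        raise ValueError("every donor in the count matrix needs a group label")
    rows = []
    for group, block in counts.groupby(labels):
        if len(block) == 0:
            raise ValueError(f"group {group!r} is empty")
        means = block.mean(axis=0)
        proportions = (block > 0).mean(axis=0)
        for attribute in counts.columns:
            rows.append(
                {
                    "attribute": attribute,
                    "diagnosis": group,
                    "mean_observations": float(means[attribute]),
                    "donor_proportion": float(proportions[attribute]),
                    "n_donors": int(len(block)),
                }
            )
    result = pd.DataFrame(rows)
    result.attrs["color_cap"] = DOT_COLOR_CAP
    return result


def _group_stat(
    counts: np.ndarray, group_idx: np.ndarray, n_groups: int, statistic: str
) -> np.ndarray:
    """(n_groups x n_attributes) per-group statistic of donor counts."""
    values = counts if statistic == "mean" else (counts > 0).astype(float)
    sums = np.zeros((n_groups, counts.shape[1]))
    sizes = np.bincount(group_idx, minlength=n_groups).astype(float)
    np.add.at(sums, group_idx, values)
    return sums / sizes[:, None]


def permutation_enrichment(
    counts: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    n_perm: int = 100_000,
    seed: int = 0,
    statistic: str = "mean",
    exhaustive: bool = False,
) -> pd.DataFrame:
    """One-sided permutation p-values per attribute x diagnosis group.

    The permuted statistic is the per-group mean observation count
    (``statistic="proportion"`` switches to the donor proportion). Sampled
    mode applies the add-one correction; exhaustive mode enumerates all
    distinct assignments of the observed label multiset.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic not in {"mean", "proportion"}:
        raise ValueError(f"unknown statistic {statistic!r}")
    labels = pd.Series(groups).reindex(counts.index)
    if labels.isna().any():
        raise ValueError("every donor needs a group label")
    group_names = sorted(labels.unique())
    if len(group_names) < 2:
        raise ValueError("permutation enrichment needs >= 2 groups")
    group_idx = labels.map({g: i for i, g in enumerate(group_names)}).to_numpy()
    matrix = counts.to_numpy(dtype=float)
    n_groups = len(group_names)

    observed = _group_stat(matrix, group_idx, n_groups, statistic)
    tol = 1e-12

    if exhaustive:
        seen: set[tuple[int, ...]] = set()
        exceed = np.zeros_like(observed)
        total = 0
        for perm in itertools.permutations(group_idx):
            if perm in seen:
                continue
            seen.add(perm)
            stat = _group_stat(matrix, np.array(perm), n_groups, statistic)
            exceed += stat >= observed - tol
            total += 1
        p = exceed / total
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros_like(observed)
        for _ in range(n_perm):
            perm = rng.permutation(group_idx)
            stat = _group_stat(matrix, perm, n_groups, statistic)
            exceed += stat >= observed - tol
        p = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for gi, group in enumerate(group_names):
        for ai, attribute in enumerate(counts.columns):
            rows.append(
                {
                    "attribute": attribute,
                    "diagnosis": group,
                    "statistic": float(observed[gi, ai]),
                    "p_perm": float(p[gi, ai]),
                }
            )
    return pd.DataFrame(rows)


def enrichment_table(
    counts: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    diagnostic_importance: Mapping[str, set[str]] | None = None,
    n_perm: int = 100_000,
    seed: int = 0,
    q_threshold: float = ENRICHMENT_Q_THRESHOLD,
) -> pd.DataFrame:
    """Full enrichment panel: dot statistics + permutation p + BH-FDR q.

    ``diagnostic_importance`` maps an attribute to the set of ND codes for
    which it is a-priori diagnostic (from the ontology flags).
    """
    dots = dot_statistics(counts, groups)
    perm = permutation_enrichment(counts, groups, n_perm=n_perm, seed=seed)
    table = dots.merge(perm, on=["attribute", "diagnosis"])
    table["q"] = bh_fdr(table["p_perm"].to_numpy())
    table["significant"] = table["q"] < q_threshold
    if diagnostic_importance is not None:
        table["diagnostic_importance"] = [
            row.diagnosis in diagnostic_importance.get(row.attribute, set())
            for row in table.itertuples(index=False)
        ]
    return table


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# chi-square on significance vs diagnostic importance


def chi2_2x2(table: np.ndarray | Sequence[Sequence[float]]) -> tuple[float, float]:
    """Two-sided Pearson chi-square on a 2x2 table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    expected = stats.contingency.expected_freq(table)
    if np.any(expected == 0):
        raise ValueError(
            "a 2x2 cell has expected count 0; the test is undefined — check that "
            "both flags vary across the grid"
        )
    result = stats.chi2_contingency(table, correction=False)
    return float(result.statistic), float(result.pvalue)


def diagnostic_importance_chi2(
    significant_flags: Sequence[bool] | np.ndarray,
    apriori_flags: Sequence[bool] | np.ndarray,
) -> tuple[float, float]:
    """Chi-square of significant-enrichment vs a-priori diagnostic-importance
    flags over the same attribute x diagnosis grid."""
    sig = np.asarray(significant_flags, dtype=bool)
    apriori = np.asarray(apriori_flags, dtype=bool)
    if sig.shape != apriori.shape:
        raise ValueError("flag arrays must share shape")
    table = np.array(
        [
            [np.sum(sig & apriori), np.sum(sig & ~apriori)],
            [np.sum(~sig & apriori), np.sum(~sig & ~apriori)],
        ]
    )
    return chi2_2x2(table)


# ---------------------------------------------------------------------------
# sex balancing and pairwise Mann-Whitney panels


def sex_balance_subsample(
    metadata: pd.DataFrame, seed: int = 0
) -> list[str]:
    """Per diagnosis group, subsample to the minority-sex count.

    ``metadata`` needs ``donor_id``, ``group`` and ``sex`` columns. Groups
    missing one sex entirely are dropped with a warning.
    """
    rng = np.random.default_rng(seed)
    kept: list[str] = []
    for group, block in metadata.groupby("group", sort=True):
        sexes = block["sex"].unique()
        if len(sexes) < 2:
            warnings.warn(
                f"group {group!r} has a single sex; dropped from balanced panels",
                stacklevel=2,
            )
            continue
        minority = int(block.groupby("sex").size().min())
        for _, sex_block in block.groupby("sex", sort=True):
            ids = sex_block["donor_id"].to_numpy()
            take = rng.choice(len(ids), size=minority, replace=False)
            kept.extend(ids[np.sort(take)])
    return kept


def _u_statistic(x: np.ndarray, y: np.ndarray, axis: int = -1) -> np.ndarray:
    """Mann-Whitney U of the first sample, with 0.5 credit for ties."""
    n_x = x.shape[axis]
    ranks = stats.rankdata(np.concatenate((x, y), axis=axis), axis=axis)
    rank_sum = np.take(ranks, np.arange(n_x), axis=axis).sum(axis=axis)
    return rank_sum - n_x * (n_x + 1) / 2.0


def mwu_test(
    x: Sequence[float],
    y: Sequence[float],
    max_exact: int = 25_000,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    When the number of distinct group assignments is at most ``max_exact``
    the null distribution of U is enumerated exactly (correct under ties);
    otherwise the tie-corrected normal approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 observations")
    u_obs = float(_u_statistic(x, y))
    if comb(len(x) + len(y), len(x)) <= max_exact:
        result = stats.permutation_test(
            (x, y),
            _u_statistic,
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=max_exact + 1,
        )
        return u_obs, float(min(result.pvalue, 1.0))
    result = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(result.pvalue)


def pairwise_mwu(
    values_by_group: Mapping[str, Sequence[float]],
    q_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Two-sided pairwise Mann-Whitney U tests with BH-FDR over all pairs.

    Groups with fewer than 2 observations are skipped with a warning.
    Returns one row per unordered pair: U (first-named group), raw p, q.
    """
    usable = {}
    for group, values in values_by_group.items():
        values = np.asarray(values, dtype=float)
        if len(values) < 2:
            warnings.warn(f"group {group!r} has <2 observations; skipped", stacklevel=2)
            continue
        usable[group] = values
    rows = []
    for a, b in itertools.combinations(sorted(usable), 2):
        u, p = mwu_test(usable[a], usable[b])
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "U": u,
                "p": p,
                "n_a": len(usable[a]),
                "n_b": len(usable[b]),
            }
        )
    frame = pd.DataFrame(rows, columns=["group_a", "group_b", "U", "p", "n_a", "n_b"])
    if len(frame):
        frame["q"] = multipletests(frame["p"], method=q_method)[1]
    else:
        frame["q"] = pd.Series(dtype=float)
    return frame


def observation_count_tests(
    counts: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    attribute: str,
) -> pd.DataFrame:
    """Pairwise tests on the per-donor number of observation-years of one
    attribute across diagnosis groups."""
    labels = pd.Series(groups).reindex(counts.index)
    values_by_group = {
        str(g): counts.loc[labels == g, attribute].to_numpy()
        for g in sorted(labels.dropna().unique())
    }
    return pairwise_mwu(values_by_group)


def temporal_distribution_tests(
    observations: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    attribute: str,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Pairwise tests on the ages at which one attribute was observed.

    ``observations`` is the long (donor_id, attribute, age) table. Returns
    the test matrix plus the raw per-group age samples (for density plots).
    """
    labels = pd.Series(groups)
    block = observations[observations["attribute"] == attribute]
    ages_by_group: dict[str, np.ndarray] = {}
    for group in sorted(labels.dropna().unique()):
        donors = set(labels.index[labels == group])
        ages = block.loc[block["donor_id"].isin(donors), "age"].to_numpy(dtype=float)
        ages_by_group[str(group)] = ages
    return pairwise_mwu(ages_by_group), ages_by_group


# ---------------------------------------------------------------------------
# survival


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate of survival after first
    observation of a sign/symptom."""

    event_times: np.ndarray  # years after first observation
    survival: np.ndarray  # S(t) at each event time, non-increasing from 1
    at_risk: np.ndarray  # number at risk just before each time
    censored: np.ndarray  # per-donor censoring indicator (input order)

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_survival(
    first_observation_age: Sequence[float],
    death_age: Sequence[float],
    censored: Sequence[bool] | None = None,
) -> SurvivalCurve:
    """Kaplan-Meier curve over duration = death_age - first_observation_age.

    ``censored`` marks donors whose death is not an observed event (e.g.
    lost records); by default every duration ends in an event.
    """
    onset = np.asarray(first_observation_age, dtype=float)
    death = np.asarray(death_age, dtype=float)
    durations = death - onset
    if np.any(durations < 0):
        raise ValueError("death before first observation: negative duration")
    censored_arr = (
        np.zeros(len(durations), dtype=bool)
        if censored is None
        else np.asarray(censored, dtype=bool)
    )
    fitter = KaplanMeierFitter()
    fitter.fit(durations, event_observed=~censored_arr)
    timeline = fitter.survival_function_.index.to_numpy(dtype=float)
    survival = fitter.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = (
        fitter.event_table["at_risk"].reindex(timeline).to_numpy(dtype=float)
    )
    return SurvivalCurve(
        event_times=timeline,
        survival=survival,
        at_risk=at_risk,
        censored=censored_arr,
    )


def survival_tests(
    durations_by_group: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U tests on post-onset survival
    durations (a log-rank test is deliberately not the default here; the
    durations are fully observed in the autopsy setting)."""
    return pairwise_mwu(durations_by_group)
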