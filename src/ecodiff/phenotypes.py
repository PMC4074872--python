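"""Phenotype differentiation statistics between ecotypes and environments.

Works on a long-format phenotype table with one row per (accession,
ecotype, environment, trait) and a numeric value.  The two ecotypes are
``upland`` and ``irrigated``; the two growth environments are likewise
``irrigated`` (paddy, submerged) and ``upland`` (rain-fed dry land).

Reporting conventions follow the field's usual summary-table layout:
group cells are "mean ± sd" to one decimal, the between-ecotype column
is "absolute difference / percentage of the irrigated-ecotype mean", and
between-environment changes are signed percentages of the
irrigated-condition mean.  Rounding is half-away-from-zero at one
decimal, the convention of the printed tables this layout mirrors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ECOTYPES = ("irrigated", "upland")
ENVIRONMENTS = ("irrigated", "upland")

#: Reference group means and standard deviations, trait ->
#: {(environment, ecotype): (mean, sd)}.  These are the published group
#: summaries for a panel of 84 upland and 82 irrigated rice accessions
#: phenotyped under both conditions; the synthetic phenotype generator
#: defaults to them.  Units: cm for heights/lengths, g for weights,
#: counts otherwise.  Under the rain-fed upland condition nearly every
#: tiller bears a panicle, so tiller number and productive-panicle
#: number coincide there.
REFERENCE_TRAIT_TABLE: dict[str, dict[tuple[str, str], tuple[float, float]]] = {
    "plant_height": {
        ("irrigated", "irrigated"): (89.5, 16.0),
        ("irrigated", "upland"): (116.1, 22.1),
        ("upland", "irrigated"): (81.2, 12.6),
        ("upland", "upland"): (103.9, 15.4),
    },
    "tillering_number": {
        ("irrigated", "irrigated"): (9.8, 3.1),
        ("irrigated", "upland"): (8.7, 2.7),
        ("upland", "irrigated"): (1.5, 0.6),
        ("upland", "upland"): (1.3, 0.5),
    },
    "root_weight": {
        ("irrigated", "irrigated"): (12.8, 5.7),
        ("irrigated", "upland"): (17.2, 7.1),
        ("upland", "irrigated"): (1.8, 0.9),
        ("upland", "upland"): (2.4, 1.0),
    },
    "max_root_length": {
        ("irrigated", "irrigated"): (24.1, 2.5),
        ("irrigated", "upland"): (27.2, 4.1),
        ("upland", "irrigated"): (23.5, 4.0),
        ("upland", "upland"): (29.9, 6.1),
    },
    "thousand_grain_weight": {
        ("irrigated", "irrigated"): (23.8, 2.9),
        ("irrigated", "upland"): (25.9, 4.3),
        ("upland", "irrigated"): (23.4, 4.7),
        ("upland", "upland"): (25.6, 4.4),
    },
    "productive_panicles": {
        ("irrigated", "irrigated"): (11.0, 3.1),
        ("irrigated", "upland"): (9.6, 2.7),
        ("upland", "irrigated"): (1.5, 0.6),
        ("upland", "upland"): (1.3, 0.5),
    },
    "filled_grain_per_panicle": {
        ("irrigated", "irrigated"): (124.2, 27.6),
        ("irrigated", "upland"): (129.8, 35.3),
        ("upland", "irrigated"): (33.3, 16.6),
        ("upland", "upland"): (40.5, 16.9),
    },
    "empty_grain_per_panicle": {
        ("irrigated", "irrigated"): (31.0, 21.1),
        ("irrigated", "upland"): (31.4, 15.4),
        ("upland", "irrigated"): (26.3, 10.1),
        ("upland", "upland"): (18.9, 9.8),
    },
}


def round1(x: float) -> float:
    """Round half away from zero at one decimal."""
    return math.copysign(math.floor(abs(x) * 10 + 0.5) / 10, x)


def _values(table: pd.DataFrame, trait: str, environment: str, ecotype: str) -> np.ndarray:
    sel = (
        (table["trait"] == trait)
        & (table["environment"] == environment)
        & (table["ecotype"] == ecotype)
    )
    return table.loc[sel, "value"].to_numpy(dtype=float)


def group_summary(table: pd.DataFrame, trait: str, environment: str) -> dict[str, tuple[float, float]]:
    """Mean and sample standard deviation per ecotype for one trait/environment."""
    out = {}
    for eco in ECOTYPES:
        v = _values(table, trait, environment, eco)
        if len(v) < 2:
            raise ValueError(f"need >= 2 values for {eco}/{trait}/{environment}")
        out[eco] = (float(np.mean(v)), float(np.std(v, ddof=1)))
    return out


def ecotype_difference(mean_irrigated: float, mean_upland: float) -> tuple[float, float]:
    """Between-ecotype absolute difference and percentage of the irrigated mean.

    Both values are rounded half-away-from-zero to one decimal, matching
    the summary-table convention.  Raises for a zero irrigated mean (the
    percentage base).
    """
    if mean_irrigated == 0:
        raise ZeroDivisionError("percentage undefined: irrigated-ecotype mean is 0")
    diff = abs(mean_upland - mean_irrigated)
    return round1(diff), round1(diff / mean_irrigated * 100.0)


def environment_change(mean_env_irrigated: float, mean_env_upland: float) -> tuple[float, float]:
    """Signed change from the irrigated to the dry-land condition.

    Returns ``(signed difference, signed percent of the
    irrigated-condition mean)``, one decimal each.
    """
    if mean_env_irrigated == 0:
        raise ZeroDivisionError("percentage undefined: irrigated-condition mean is 0")
    diff = mean_env_upland - mean_env_irrigated
    return round1(diff), round1(diff / mean_env_irrigated * 100.0)


def two_sample_t(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided Student's t-test (equal-variance by default; Welch optional).

    Degenerate input with zero pooled variance and equal means returns
    ``(0.0, 1.0)`` by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per group")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def trait_correlation(
    table: pd.DataFrame, trait_a: str, trait_b: str, environment: str
) -> tuple[float, float]:
    """Pearson correlation between two traits across accessions in one environment.

    Values are paired by accession; accessions missing either trait are
    dropped.  Returns (rho, two-sided P via the t transform).
    """
    sel = table["environment"] == environment
    wide = (
        table[sel & table["trait"].isin([trait_a, trait_b])]
        .pivot_table(index="accession", columns="trait", values="value")
        .dropna()
    )
    if len(wide) < 3:
        raise ValueError("need >= 3 paired observations")
    x = wide[trait_a].to_numpy()
    y = wide[trait_b].to_numpy()
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


@dataclass
class TraitSummaryRow:
    environment: str
    trait: str
    mean_irrigated: float
    sd_irrigated: float
    mean_upland: float
    sd_upland: float
    p_value: float
    diff: float
    percent: float


def summary_table(table: pd.DataFrame) -> pd.DataFrame:
    """Full per-trait summary mirroring the standard two-ecotype layout.

    One row per (environment, trait): group means/sds, Student's t P
    value, and the between-ecotype difference/percentage cells.
    """
    rows = []
    for env in ENVIRONMENTS:
        for trait in sorted(table["trait"].unique()):
            try:
                g = group_summary(table, trait, env)
            except ValueError:
                continue
            (mi, si), (mu, su) = g["irrigated"], g["upland"]
            _, p = two_sample_t(
                _values(table, trait, env, "irrigated"),
                _values(table, trait, env, "upland"),
            )
            diff, pct = ecotype_difference(round1(mi), round1(mu))
            rows.append(
                TraitSummaryRow(env, trait, round1(mi), round1(si), round1(mu), round1(su), p, diff, pct)
            )
    return pd.DataFrame([vars(r) for r in rows])
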