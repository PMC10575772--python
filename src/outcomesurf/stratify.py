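"""Change scores, MCID outcome labels, filters, and cohort summary tables.

Autistic participants are grouped by the change in Vineland-II (VABS-II)
composite standard score between visits, ∆V = T2 − T1, against the minimal
clinically important difference (MCID) of 4 standard-score points:
Increasers (∆V ≥ 4), No-changers (−4 < ∆V < 4), Decreasers (∆V ≤ −4).
Alternative stratifications reuse the same rule on a different change score
(VABS-II domains, ADOS calibrated severity domains) with a configurable
threshold.  Summary statistics reproduce a demographics-table layout:
mean ± SD per group with one-way fixed-effects ANOVA F (from raw data or from
printed summaries) and Pearson χ² for categorical rows, uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SUBGROUPS",
    "DEFAULT_AGE_BANDS",
    "OutcomeLabel",
    "MissingDataError",
    "change_score",
    "classify_outcome",
    "add_outcome_labels",
    "anova_f_from_summary",
    "pearson_chi_square",
    "build_cohort_table",
    "apply_filters",
]

SUBGROUPS = ("Decreaser", "No-changer", "Increaser")

# children / adolescents / adults; bounds are a config default, not a claim
DEFAULT_AGE_BANDS = ((6.0, 12.0), (12.0, 18.0), (18.0, 31.0))


@dataclass(frozen=True)
class OutcomeLabel:
    """Outcome classification with its provenance (basis column, threshold)."""

    value: str
    basis: str = "vabs_standard"
    mcid: float = 4.0


class MissingDataError(ValueError):
    """A score required for classification is missing."""


def change_score(score_t1: float, score_t2: float) -> float:
    """∆ = T2 − T1.  Raises MissingDataError on missing/non-finite inputs."""
    if score_t1 is None or score_t2 is None:
        raise MissingDataError("both timepoint scores are required")
    a, b = float(score_t1), float(score_t2)
    if not (np.isfinite(a) and np.isfinite(b)):
        raise MissingDataError("both timepoint scores must be finite")
    return b - a


def classify_outcome(
    delta: float, mcid: float = 4.0, basis: str = "vabs_standard"
) -> OutcomeLabel:
    """MCID interval rule: ∆ ≥ mcid → Increaser; ∆ ≤ −mcid → Decreaser;
    −mcid < ∆ < mcid → No-changer.  Boundaries belong to the changer groups."""
    if not mcid > 0:
        raise ValueError("mcid must be positive")
    d = float(delta)
    if not np.isfinite(d):
        raise MissingDataError("change score must be finite")
    if d >= mcid:
        value = "Increaser"
    elif d <= -mcid:
        value = "Decreaser"
    else:
        value = "No-changer"
    return OutcomeLabel(value=value, basis=basis, mcid=mcid)


def add_outcome_labels(
    phenotypes: pd.DataFrame, basis: str = "vabs_standard", mcid: float = 4.0
) -> pd.DataFrame:
    """Derive ∆ and outcome-label columns for the autistic rows.

    Adds ``delta_<basis>`` for all rows and ``outcome_<basis>`` for autistic
    rows (neurotypicals get NA).  The basis names a score pair
    ``<basis>_t1`` / ``<basis>_t2``, e.g. ``vabs_standard`` or ``ados_sa_css``.
    """
    c1, c2 = f"{basis}_t1", f"{basis}_t2"
    if c1 not in phenotypes or c2 not in phenotypes:
        raise KeyError(f"phenotypes lack {c1}/{c2}")
    out = phenotypes.copy()
    out[f"delta_{basis}"] = out[c2] - out[c1]
    autistic = out["diagnosis"] == "autistic"
    if out.loc[autistic, [c1, c2]].isna().any().any():
        raise MissingDataError(
            f"autistic rows with missing {basis} scores must be excluded upstream"
        )
    labels = out.loc[autistic, f"delta_{basis}"].map(
        lambda d: classify_outcome(d, mcid=mcid, basis=basis).value
    )
    out[f"outcome_{basis}"] = pd.Series(pd.NA, index=out.index, dtype="object")
    out.loc[autistic, f"outcome_{basis}"] = labels
    return out


def anova_f_from_summary(means, sds, ns) -> tuple[float, int, int]:
    """One-way fixed-effects ANOVA F from per-group summary statistics.

    Between-group SS from group means about the weighted grand mean;
    within-group SS = Σ(nᵢ−1)·sdᵢ².  Returns (F, df1, df2).
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if not (len(means) == len(sds) == len(ns)):
        raise ValueError("means, sds, ns must have equal length")
    k = len(means)
    if k < 2:
        raise ValueError("need at least two groups")
    if np.any(ns < 2) or np.any(sds <= 0):
        raise ValueError("all group ns must be >= 2 and sds > 0")
    grand = float((ns * means).sum() / ns.sum())
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df1 = k - 1
    df2 = int(ns.sum()) - k
    f = (ss_between / df1) / (ss_within / df2)
    return f, df1, df2


def pearson_chi_square(table) -> tuple[float, int]:
    """Pearson χ² of independence on an r×c count table, no continuity
    correction.  Returns (χ², df)."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero row or column margin")
    expected = np.outer(rows, cols) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return chi2, df


_TABLE_MEASURES = [
    # (label, column, kind)
    ("Age (years)", "age_t1", "numeric"),
    ("FSIQ", "fsiq", "numeric"),
    ("Sex", "sex", "categorical"),
    ("ID", "id_flag", "categorical"),
    ("Time between visits (years)", "delta_t", "numeric"),
    ("Total SA (cm2)", "total_sa_t1", "numeric"),
    ("Mean CT (mm)", "mean_ct_t1", "numeric"),
    ("T1 VABS standard", "vabs_standard_t1", "numeric"),
    ("Delta VABS standard", "delta_vabs_standard", "numeric"),
    ("T2 VABS standard", "vabs_standard_t2", "numeric"),
]


def build_cohort_table(
    phenotypes: pd.DataFrame, grouping: str = "subgroups"
) -> pd.DataFrame:
    """Demographics-style summary: one row per measure, one column per group
    with mean ± SD (or counts), plus the between-group test statistic.

    grouping="subgroups" compares the three autistic outcome groups;
    grouping="diagnosis" compares autistic vs neurotypical participants.
    P-values are uncorrected.
    """
    ph = phenotypes
    if grouping == "subgroups":
        ph = ph[ph["diagnosis"] == "autistic"]
        groups = [(g, ph[ph["outcome_vabs_standard"] == g]) for g in SUBGROUPS]
    elif grouping == "diagnosis":
        groups = [
            ("Autistic", ph[ph["diagnosis"] == "autistic"]),
            ("Neurotypical", ph[ph["diagnosis"] == "neurotypical"]),
        ]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    if any(len(g) == 0 for _, g in groups):
        empty = [name for name, g in groups if len(g) == 0]
        raise ValueError(f"empty group(s): {empty}")

    rows = []
    for label, col, kind in _TABLE_MEASURES:
        if col not in ph.columns:
            continue
        row: dict = {"measure": label}
        if kind == "numeric":
            means, sds, ns = [], [], []
            for name, g in groups:
                v = g[col].dropna().to_numpy(dtype=float)
                if len(v) >= 2:
                    means.append(v.mean())
                    sds.append(v.std(ddof=1))
                    ns.append(len(v))
                    row[f"{name} (n={len(g)})"] = f"{v.mean():.2f} ± {v.std(ddof=1):.2f}"
                else:
                    row[f"{name} (n={len(g)})"] = "—"
            if len(means) >= 2:
                f, df1, df2 = anova_f_from_summary(means, sds, ns)
                p = float(stats.f.sf(f, df1, df2))
                row["test"] = f"F{df1},{df2} = {f:.3f}"
                row.update(p=p, statistic=f, df1=df1, df2=df2)
            else:  # measure collected in one group only (e.g. clinical scores)
                row.update(test="", p=np.nan, statistic=np.nan, df1=0, df2=0)
        else:
            levels = sorted(ph[col].dropna().unique())
            counts = np.array(
                [[int((g[col] == lev).sum()) for lev in levels] for _, g in groups]
            ).T
            for (name, g), cvec in zip(groups, counts.T):
                row[f"{name} (n={len(g)})"] = ", ".join(
                    f"{c} {lev}" for lev, c in zip(levels, cvec)
                )
            chi2, df = pearson_chi_square(counts)
            p = float(stats.chi2.sf(chi2, df))
            row["test"] = f"chi2_{df} = {chi2:.3f}"
            row.update(p=p, statistic=chi2, df1=df, df2=0)
        rows.append(row)
    return pd.DataFrame(rows)


def render_cohort_table(table: pd.DataFrame) -> str:
    """Plain-text rendering of a summary table."""
    return table.drop(columns=["statistic", "df1", "df2"]).to_string(index=False)


def apply_filters(
    phenotypes: pd.DataFrame,
    exclude_id: bool = False,
    exclude_medicated: bool = False,
    age_band: tuple[float, float] | None = None,
    outcome_column: str = "outcome_vabs_standard",
) -> pd.DataFrame:
    """Row-subset sensitivity filters.

    ``age_band`` is half-open [low, high) on age at T1.  Raises if a filter
    empties any comparison group (an outcome subgroup or the neurotypicals).
    Per-filter removal counts are recorded in ``.attrs['filter_log']``.
    """
    out = phenotypes
    log: dict[str, int] = {}
    if exclude_id:
        n0 = len(out)
        out = out[~out["id_flag"].astype(bool)]
        log["exclude_id"] = n0 - len(out)
    if exclude_medicated:
        n0 = len(out)
        out = out[~out["medication_flag"].astype(bool)]
        log["exclude_medicated"] = n0 - len(out)
    if age_band is not None:
        lo, hi = age_band
        n0 = len(out)
        out = out[(out["age_t1"] >= lo) & (out["age_t1"] < hi)]
        log["age_band"] = n0 - len(out)
    if (out["diagnosis"] == "neurotypical").sum() == 0:
        raise ValueError("filters removed the entire neurotypical group")
    if outcome_column in out.columns:
        present = set(out[outcome_column].dropna())
        before = set(phenotypes[outcome_column].dropna())
        gone = before - present
        if gone:
            raise ValueError(f"filters removed entire outcome group(s): {sorted(gone)}")
    out = out.copy()
    out.attrs["filter_log"] = log
    return out
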