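"""Group statistical comparison of the extracted parameters.

Builds a long-format table (one row per subject x stimulus x parameter with
between- and within-subject factor columns) and runs the supported test
matrix per parameter:

* ``mixed_anova``  — one between + one within factor (pingouin)
* ``rm_anova``     — up to two within factors (pingouin)
* ``nway_anova``   — any number of between factors (statsmodels OLS + anova_lm)
* ``pairwise_t``   — pairwise Student's t over factor levels (pingouin)
* ``welch_t``      — exactly one factor, unequal-variance t (scipy)

Results come back as one tidy table per parameter (effect, df, statistic,
p) and can be written to CSV. No multiple-testing correction is applied
across parameters by default; an optional Bonferroni/FDR flag is provided.
Tests needing one observation per subject x within-cell aggregate repeated
stimuli by the mean. Cells with zero variance cause that parameter's test
to be skipped with a warning, as do parameters with missing cells
(listwise deletion).
"""

from __future__ import annotations

import itertools
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .parameters import PARAMETER_NAMES, ParameterSet

__all__ = [
    "build_long_table",
    "run_statistical_test",
    "export_parameters_csv",
    "TESTS",
]

TESTS = ("mixed_anova", "rm_anova", "nway_anova", "pairwise_t", "welch_t")


def build_long_table(
    sets: list[ParameterSet],
    config,
    parameters: list[str] | str = "all",
) -> pd.DataFrame:
    """Melt parameter sets into long format with factor columns.

    ``config`` is an :class:`gazekit.experiment.ExperimentConfig` (anything
    exposing ``subject_group``, ``stimulus_group`` and
    ``subject_attributes`` works).

    Columns: subject, subject_group, stimulus, stimulus_group, one column
    per subject attribute (candidate between factors), parameter, value.
    """
    if parameters == "all":
        parameters = list(PARAMETER_NAMES)
    bad = [p for p in parameters if p not in PARAMETER_NAMES]
    if bad:
        raise ValueError(
            f"unknown parameter(s) {bad}; valid names: {PARAMETER_NAMES}"
        )
    rows = []
    for s in sets:
        sgroup = config.subject_group(s.subject)
        tgroup = config.stimulus_group(s.stimulus)
        attrs = config.subject_attributes(s.subject)
        for name in parameters:
            row = {
                "subject": s.subject,
                "subject_group": sgroup,
                "stimulus": s.stimulus,
                "stimulus_group": tgroup,
            }
            row.update(attrs)
            row["parameter"] = name
            row["value"] = getattr(s, name)
            rows.append(row)
    return pd.DataFrame(rows)


def _welch(table: pd.DataFrame, factor: str) -> pd.DataFrame:
    levels = sorted(table[factor].unique())
    out = []
    for a, b in itertools.combinations(levels, 2):
        va = table.loc[table[factor] == a, "value"].to_numpy()
        vb = table.loc[table[factor] == b, "value"].to_numpy()
        res = sps.ttest_ind(va, vb, equal_var=False)
        out.append(
            {
                "effect": f"{factor}: {a} vs {b}",
                "df": float(res.df),
                "statistic": float(res.statistic),
                "p": float(res.pvalue),
            }
        )
    return pd.DataFrame(out)


def _tidy_pingouin(df: pd.DataFrame, effect_col: str = "Source") -> pd.DataFrame:
    stat_col = "F" if "F" in df.columns else "T"
    df_col = next((c for c in ("DF", "DF1", "ddof1", "dof") if c in df.columns), None)
    p_col = next((c for c in ("p-unc", "p_unc", "p-val") if c in df.columns), None)
    out = pd.DataFrame(
        {
            "effect": df[effect_col] if effect_col in df.columns else df.index,
            "df": df[df_col] if df_col else np.nan,
            "statistic": df[stat_col],
            "p": df[p_col],
        }
    )
    return out.reset_index(drop=True)


def _aggregate_cells(sub: pd.DataFrame, factors: list[str]) -> pd.DataFrame:
    keep = ["subject"] + factors
    return sub.groupby(keep, as_index=False)["value"].mean()


def run_statistical_test(
    table: pd.DataFrame,
    test: str,
    between: list[str] | None = None,
    within: list[str] | None = None,
    out_dir: str | Path | None = None,
    correction: str | None = None,
) -> pd.DataFrame:
    """Run one test per parameter on the long table; returns a combined
    tidy results table and optionally writes one CSV per parameter.

    ``correction`` may be 'bonferroni' or 'fdr_bh' to adjust p values
    across parameters (off by default).
    """
    import pingouin as pg
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    between = list(between or [])
    within = list(within or [])
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}; expected one of {TESTS}")
    if test == "mixed_anova" and (len(between) != 1 or len(within) != 1):
        raise ValueError("mixed_anova needs exactly one between and one within factor")
    if test == "rm_anova" and not (1 <= len(within) <= 2 and not between):
        raise ValueError("rm_anova needs one or two within factors and no between")
    if test == "nway_anova" and (not between or within):
        raise ValueError("nway_anova needs >=1 between factors and no within")
    if test == "welch_t" and len(between) + len(within) != 1:
        raise ValueError("welch_t needs exactly one factor")
    if test == "pairwise_t" and len(between) + len(within) != 1:
        raise ValueError("pairwise_t needs exactly one factor")
    factors = between + within
    for f in factors:
        if f not in table.columns:
            raise ValueError(f"factor column {f!r} not in table")

    results = []
    for param, sub in table.groupby("parameter", sort=True):
        sub = sub.dropna(subset=["value"])
        if sub["value"].isna().any() or len(sub) == 0:
            warnings.warn(f"{param}: missing values dropped listwise")
        cells = sub.groupby(factors)["value"] if factors else None
        if cells is not None and any(
            v.std(ddof=1) == 0 or len(v) < 2 for _, v in cells
        ):
            warnings.warn(f"{param}: zero-variance or singleton cell; test skipped")
            continue
        try:
            if test == "welch_t":
                res = _welch(sub, factors[0])
            elif test == "pairwise_t":
                res = _tidy_pingouin(
                    pg.pairwise_tests(
                        data=_aggregate_cells(sub, factors),
                        dv="value",
                        between=between[0] if between else None,
                        within=within[0] if within else None,
                        subject="subject",
                    ).assign(
                        Source=lambda d: d["Contrast"]
                        + ": "
                        + d["A"].astype(str)
                        + " vs "
                        + d["B"].astype(str)
                    )
                )
            elif test == "mixed_anova":
                agg = _aggregate_cells(sub, factors)
                res = _tidy_pingouin(
                    pg.mixed_anova(
                        data=agg,
                        dv="value",
                        between=between[0],
                        within=within[0],
                        subject="subject",
                    )
                )
            elif test == "rm_anova":
                agg = _aggregate_cells(sub, within)
                res = _tidy_pingouin(
                    pg.rm_anova(
                        data=agg,
                        dv="value",
                        within=within if len(within) > 1 else within[0],
                        subject="subject",
                        detailed=True,
                    )
                )
            else:  # nway_anova
                agg = _aggregate_cells(sub, between)
                formula = "value ~ " + " * ".join(f"C({b})" for b in between)
                fit = smf.ols(formula, data=agg).fit()
                aov = sm.stats.anova_lm(fit, typ=2)
                aov = aov[aov.index != "Residual"]
                res = pd.DataFrame(
                    {
                        "effect": aov.index,
                        "df": aov["df"].to_numpy(),
                        "statistic": aov["F"].to_numpy(),
                        "p": aov["PR(>F)"].to_numpy(),
                    }
                )
        except Exception as exc:  # degenerate designs surface as warnings
            warnings.warn(f"{param}: {test} failed ({exc}); skipped")
            continue
        res.insert(0, "parameter", param)
        results.append(res)
    combined = (
        pd.concat(results, ignore_index=True)
        if results
        else pd.DataFrame(columns=["parameter", "effect", "df", "statistic", "p"])
    )
    combined = combined.dropna(subset=["p"]).reset_index(drop=True)
    if correction:
        from statsmodels.stats.multitest import multipletests

        combined["p_adj"] = multipletests(combined["p"], method=correction)[1]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        combined.to_csv(out_dir / f"{test}_results.csv", index=False)
    return combined


def export_parameters_csv(sets: list[ParameterSet], path: str | Path) -> Path:
    """Write one row per (subject, stimulus) with the 21 parameter columns;
    header order frozen."""
    path = Path(path)
    header = ["subject", "stimulus"] + PARAMETER_NAMES
    if not sets:
        warnings.warn("no parameter sets; writing header-only file")
        path.write_text(",".join(header) + "\n")
        return path
    rows = [
        {"subject": s.subject, "stimulus": s.stimulus, **s.values()} for s in sets
    ]
    df = pd.DataFrame(rows, columns=header)
    df = df.sort_values(["subject", "stimulus"]).reset_index(drop=True)
    df.to_csv(path, index=False)
    return path
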