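"""Statistics layer: paired/two-sample t-tests, Pearson correlations,
cohort summaries, and the reference-table regression report.

The reference study analyzed eight subjects with two-tailed paired Student
t-tests (pre vs post), a two-sample t-test between its good-response and
remaining subgroups, and Pearson correlations between symptom scores and
flow metrics, with p < 0.05 taken as significant and no multiple-testing
correction.  This module reproduces that layer exactly on the packaged
per-subject transcriptions and applies the same machinery to synthetic
cohorts.

Two standard-deviation conventions are computed throughout because the
reference tables mix them: SAMPLE (n−1 denominator, used in the per-subject
tables) and POPULATION (n, used in the running text).  Reports stamp the
convention used.

For correlations between the symptom score *level* and metric levels the
reference pooling is ambiguous (8 preoperative subjects vs 16 pooled model
states); both variants are computed and labeled.  The pooled variant
reproduces every printed value to ±0.01, so it is the one the regression
report gates on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, DomainError
from .tables import CohortTable

__all__ = [
    "StatResult",
    "paired_t_test",
    "two_sample_t_test",
    "pearson_correlation",
    "CohortSummary",
    "summarize_cohort",
    "load_reference_cohort",
    "load_reference_printed_means",
    "reproduce_reference_tables",
]


@dataclass(frozen=True)
class StatResult:
    statistic: float
    df: float
    p_value: float
    method: str
    n: int


def _as_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise DomainError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"{name} contains non-finite values")
    return arr


def paired_t_test(pre, post) -> StatResult:
    """Classical two-tailed paired Student t-test on pre − post differences."""
    pre = _as_array(pre, "pre")
    post = _as_array(post, "post")
    if pre.size != post.size:
        raise DomainError("paired samples must have equal length")
    if pre.size < 2:
        raise DomainError("paired t-test needs n ≥ 2")
    diff = pre - post
    if np.ptp(diff) == 0.0:
        raise DegenerateDataError("all paired differences identical; t undefined")
    n = diff.size
    t = diff.mean() / (diff.std(ddof=1) / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return StatResult(float(t), float(n - 1), float(p), "paired t (two-tailed)", n)


def two_sample_t_test(group_a, group_b, variant: str = "WELCH") -> StatResult:
    """Two-tailed two-sample t-test, Welch (default) or pooled variance.

    Welch is the default because it reproduces the reference study's printed
    subgroup comparison (p ≈ 0.004, vs ≈ 0.002 pooled).
    """
    a = _as_array(group_a, "group_a")
    b = _as_array(group_b, "group_b")
    if a.size < 2 or b.size < 2:
        raise DomainError("each group needs n ≥ 2")
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        raise DegenerateDataError("both groups have zero variance; t undefined")
    if variant == "WELCH":
        res = sps.ttest_ind(a, b, equal_var=False)
    elif variant == "POOLED":
        res = sps.ttest_ind(a, b, equal_var=True)
    else:
        raise DomainError(f"unknown variant {variant!r}")
    return StatResult(
        float(res.statistic),
        float(res.df),
        float(res.pvalue),
        f"two-sample t ({variant.lower()}, two-tailed)",
        a.size + b.size,
    )


def pearson_correlation(x, y) -> StatResult:
    """Sample Pearson r with the two-sided t-based p (t = r·√((n−2)/(1−r²)))."""
    x = _as_array(x, "x")
    y = _as_array(y, "y")
    if x.size != y.size:
        raise DomainError("x and y must have equal length")
    if x.size < 3:
        raise DomainError("Pearson correlation needs n ≥ 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateDataError("zero variance; correlation undefined")
    res = sps.pearsonr(x, y)
    return StatResult(
        float(res.statistic), float(x.size - 2), float(res.pvalue), "Pearson r", x.size
    )


def _sd(values: np.ndarray, convention: str) -> float:
    if convention == "SAMPLE":
        return float(np.std(values, ddof=1))
    if convention == "POPULATION":
        return float(np.std(values, ddof=0))
    raise DomainError(f"unknown SD convention {convention!r}")


# canonical paired variables, in reporting order
_PAIRED_VARIABLES = [
    "nose",
    "flow_partition_mos_pct",
    "partition_ratio_los_over_mos",
    "nr_unilateral_mos_Pa_per_mL_s",
    "nr_unilateral_los_Pa_per_mL_s",
    "nr_bilateral_Pa_per_mL_s",
    "nr_ratio_mos_over_los",
    "plane1_mos_RH_pct",
    "plane1_los_RH_pct",
    "plane2_RH_pct",
    "plane1_mos_T_C",
    "plane1_los_T_C",
    "plane2_T_C",
]

# NOSE-level correlation partners
_LEVEL_VARIABLES = [
    "flow_partition_mos_pct",
    "partition_ratio_los_over_mos",
    "nr_unilateral_mos_Pa_per_mL_s",
    "nr_unilateral_los_Pa_per_mL_s",
    "nr_bilateral_Pa_per_mL_s",
    "nr_ratio_mos_over_los",
]


@dataclass
class CohortSummary:
    variables: pd.DataFrame  # per-variable pre/post mean ± SD and paired p
    correlations: pd.DataFrame  # r blocks: NOSE levels, improvement vs changes
    metadata: dict


def _flux_columns(columns) -> list[str]:
    return sorted(c for c in columns if c.startswith("q_") and c.endswith("_W_m2"))


def summarize_cohort(table: CohortTable, sd_convention: str = "SAMPLE") -> CohortSummary:
    """Per-variable pre/post summary plus the correlation blocks.

    Mirrors the reference reporting: mean ± SD per state with the paired p,
    NOSE-level correlations in both poolings, and improvement-vs-change
    correlations (ΔNR, and % increase of regional surface heat flux when
    transport metrics are present).  No multiple-testing correction is
    applied, matching the reference convention; the metadata counts the
    tests performed.
    """
    table.check_paired()
    pre = table.state_frame("PREOP")
    post = table.state_frame("POSTOP")
    n = len(table.subjects)
    n_tests = 0

    var_rows = []
    for var in _PAIRED_VARIABLES:
        if var not in pre.columns or pre[var].isna().any():
            continue
        a, b = pre[var].to_numpy(float), post[var].to_numpy(float)
        try:
            p = paired_t_test(a, b).p_value
            n_tests += 1
        except DegenerateDataError:
            p = np.nan
        var_rows.append(
            {
                "variable": var,
                "pre_mean": a.mean(),
                "pre_sd": _sd(a, sd_convention),
                "post_mean": b.mean(),
                "post_sd": _sd(b, sd_convention),
                "p_paired": p,
                "n": n,
            }
        )
    variables = pd.DataFrame(var_rows).set_index("variable")

    corr_rows = []

    def add_corr(var1, var2, x, y, convention):
        nonlocal n_tests
        try:
            res = pearson_correlation(x, y)
        except (DegenerateDataError, DomainError):
            return
        n_tests += 1
        corr_rows.append(
            {
                "variable_1": var1,
                "variable_2": var2,
                "r": res.statistic,
                "p": res.p_value,
                "n": res.n,
                "convention": convention,
            }
        )

    has_nose = "nose" in pre.columns and not pre["nose"].isna().any()
    if has_nose:
        nose_pre = pre["nose"].to_numpy(float)
        nose_post = post["nose"].to_numpy(float)
        improvement = nose_pre - nose_post
        for var in _LEVEL_VARIABLES:
            if var not in pre.columns or pre[var].isna().any():
                continue
            add_corr("nose", var, nose_pre, pre[var].to_numpy(float), "preop (n states)")
            add_corr(
                "nose",
                var,
                np.r_[nose_pre, nose_post],
                np.r_[pre[var].to_numpy(float), post[var].to_numpy(float)],
                "pooled pre+post (2n states)",
            )
        for var, label in [
            ("nr_unilateral_mos_Pa_per_mL_s", "reduction in unilateral NR (preop MOS)"),
            ("nr_bilateral_Pa_per_mL_s", "reduction in bilateral NR"),
        ]:
            if var in pre.columns and not pre[var].isna().any():
                add_corr(
                    "nose improvement",
                    label,
                    improvement,
                    pre[var].to_numpy(float) - post[var].to_numpy(float),
                    "paired change",
                )
        for col in _flux_columns(pre.columns):
            if pre[col].isna().any():
                continue
            base = pre[col].to_numpy(float)
            if np.any(base <= 0.0):
                continue
            pct = 100.0 * (post[col].to_numpy(float) - base) / base
            add_corr(
                "nose improvement",
                f"% increase of {col[:-5]}",
                improvement,
                pct,
                "paired % change",
            )
    correlations = pd.DataFrame(corr_rows)

    return CohortSummary(
        variables=variables,
        correlations=correlations,
        metadata={
            "sd_convention": sd_convention,
            "n_subjects": n,
            "n_tests_performed": n_tests,
            "multiple_testing_correction": "none",
            "provenance": dict(table.provenance),
        },
    )


# ---------------------------------------------------------------------------
# packaged reference fixtures


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("rhinoflow").joinpath("data", name).open() as fh:
        return pd.read_csv(fh, comment="#")


def load_reference_cohort() -> CohortTable:
    """The eight-subject reference cohort as a paired CohortTable.

    Unilateral LOS resistance is derived per subject as the printed MOS
    resistance divided by the printed MOS/LOS resistance ratio.
    """
    flow = _read_packaged("reference_flow_resistance.csv")
    nose = _read_packaged("reference_nose_scores.csv")
    flow = flow.copy()
    flow["nr_unilateral_los_Pa_per_mL_s"] = (
        flow["nr_unilateral_mos_Pa_per_mL_s"] / flow["nr_ratio_mos_over_los"]
    )
    nose_long = pd.concat(
        [
            pd.DataFrame(
                {"subject": nose["subject"], "state": "PREOP", "nose": nose["nose_pre"]}
            ),
            pd.DataFrame(
                {"subject": nose["subject"], "state": "POSTOP", "nose": nose["nose_post"]}
            ),
        ]
    )
    rows = flow.merge(nose_long, on=["subject", "state"]).rename(
        columns={"subject": "subject_id"}
    )
    rows["good_response"] = rows["subject_id"].map(
        nose.set_index("subject")["good_response"]
    )
    return CohortTable(rows, {"source": "REFERENCE_FIXTURE", "n_subjects": len(nose)})


def load_reference_printed_means() -> pd.DataFrame:
    """Printed summary rows (means/SDs) of the reference tables."""
    return _read_packaged("reference_printed_means.csv")


# printed Pearson r-values; NOSE-level rows use the pooled pre+post states
_PRINTED_CORRELATIONS = [
    ("nose", "flow_partition_mos_pct", -0.67),
    ("nose", "partition_ratio_los_over_mos", 0.65),
    ("nose", "nr_unilateral_mos_Pa_per_mL_s", 0.86),
    ("nose", "nr_unilateral_los_Pa_per_mL_s", 0.66),
    ("nose", "nr_bilateral_Pa_per_mL_s", 0.84),
    ("nose", "nr_ratio_mos_over_los", 0.60),
    ("nose improvement", "reduction in unilateral NR (preop MOS)", 0.81),
    ("nose improvement", "reduction in bilateral NR", 0.31),
]

# printed paired p-values; None means printed as "< 0.001"
_PRINTED_PAIRED_P = {
    "nose": None,
    "flow_partition_mos_pct": 0.043,
    "partition_ratio_los_over_mos": 0.052,
    "nr_unilateral_mos_Pa_per_mL_s": 0.004,
    "nr_unilateral_los_Pa_per_mL_s": 0.044,
    "nr_bilateral_Pa_per_mL_s": None,
    "nr_ratio_mos_over_los": 0.129,
}

#: variables derived from printed values rounded upstream: second moments and
#: p-values cannot be reproduced to print precision, only to a rounding-
#: propagation envelope.
_DERIVED_VARIABLES = {"nr_unilateral_los_Pa_per_mL_s"}

#: printed statistics that disagree with the per-subject prints beyond one
#: unit in the last place (evidently computed from unrounded upstream
#: fields); reported but not gated on.
_PRINT_INCONSISTENT = {("flow_partition_mos_pct", "POSTOP", "sd_population")}


def _fixture_series(table: CohortTable, variable: str, state: str) -> np.ndarray:
    pre = table.state_frame("PREOP")
    post = table.state_frame("POSTOP")
    if variable == "nose_improvement":
        return (pre["nose"] - post["nose"]).to_numpy(float)
    if variable == "nose_improvement_good_response":
        mask = pre["good_response"].to_numpy(bool)
        return (pre["nose"] - post["nose"]).to_numpy(float)[mask]
    if variable == "nose_improvement_other":
        mask = ~pre["good_response"].to_numpy(bool)
        return (pre["nose"] - post["nose"]).to_numpy(float)[mask]
    if variable == "nr_bilateral_reduction_Pa_per_mL_s":
        col = "nr_bilateral_Pa_per_mL_s"
        return (pre[col] - post[col]).to_numpy(float)
    frame = pre if state == "PREOP" else post
    return frame[variable].to_numpy(float)


def reproduce_reference_tables() -> pd.DataFrame:
    """Recompute every recomputable printed statistic and compare.

    Returns a machine-readable report with one row per check: the computed
    value, the printed value, the tolerance applied, and the verdict.
    Tolerances: half a unit in the last printed decimal (with 10 % slack)
    for means and SDs, doubled for variables derived from already-rounded
    prints; ±0.01 for correlations; ±0.0015 for exact printed p-values.
    Rows flagged ``gating=False`` are informational (known print-rounding
    artifacts), and non-recomputable rows are not emitted at all.
    """
    table = load_reference_cohort()
    printed = load_reference_printed_means()
    checks: list[dict] = []

    for _, row in printed[printed["recomputable"]].iterrows():
        values = _fixture_series(table, row["variable"], row["state"])
        stat = row["statistic"]
        if stat == "mean":
            computed = float(values.mean())
        elif stat == "sd_sample":
            computed = _sd(values, "SAMPLE")
        elif stat == "sd_population":
            computed = _sd(values, "POPULATION")
        else:
            raise DomainError(f"unknown statistic {stat!r}")
        tol = 0.55 * 10.0 ** (-int(row["decimals"]))
        gating = True
        note = ""
        if row["variable"] in _DERIVED_VARIABLES and stat != "mean":
            tol *= 2.0
            note = "derived from rounded prints; widened tolerance"
        if (row["variable"], row["state"], stat) in _PRINT_INCONSISTENT:
            gating = False
            note = "informational: print inconsistent with per-subject table"
        checks.append(
            {
                "check": f"{row['variable']} [{row['state']}] {stat}",
                "computed": computed,
                "printed": float(row["value"]),
                "tolerance": tol,
                "passed": abs(computed - float(row["value"])) <= tol,
                "gating": gating,
                "note": note,
            }
        )

    pre = table.state_frame("PREOP")
    post = table.state_frame("POSTOP")
    for var, printed_p in _PRINTED_PAIRED_P.items():
        res = paired_t_test(pre[var].to_numpy(float), post[var].to_numpy(float))
        if printed_p is None:
            checks.append(
                {
                    "check": f"{var} paired p < 0.001",
                    "computed": res.p_value,
                    "printed": 0.001,
                    "tolerance": 0.0,
                    "passed": res.p_value < 0.001,
                    "gating": True,
                    "note": "printed as a bound",
                }
            )
        else:
            derived = var in _DERIVED_VARIABLES
            checks.append(
                {
                    "check": f"{var} paired p",
                    "computed": res.p_value,
                    "printed": printed_p,
                    "tolerance": np.nan if derived else 0.0015,
                    "passed": derived or abs(res.p_value - printed_p) <= 0.0015,
                    "gating": not derived,
                    "note": "informational: derived from rounded prints" if derived else "",
                }
            )

    imp = (pre["nose"] - post["nose"]).to_numpy(float)
    good = pre["good_response"].to_numpy(bool)
    welch = two_sample_t_test(imp[good], imp[~good], "WELCH")
    checks.append(
        {
            "check": "good-response vs rest improvement, Welch p",
            "computed": welch.p_value,
            "printed": 0.004,
            "tolerance": 0.001,
            "passed": abs(welch.p_value - 0.004) <= 0.001,
            "gating": True,
            "note": "Welch convention (pooled variance gives ≈ 0.002)",
        }
    )

    summary = summarize_cohort(table)
    corr = summary.correlations
    for var1, var2, printed_r in _PRINTED_CORRELATIONS:
        convention = (
            "pooled pre+post (2n states)" if var1 == "nose" else "paired change"
        )
        match = corr[
            (corr["variable_1"] == var1)
            & (corr["variable_2"] == var2)
            & (corr["convention"] == convention)
        ]
        computed = float(match["r"].iloc[0])
        checks.append(
            {
                "check": f"r({var1}, {var2})",
                "computed": computed,
                "printed": printed_r,
                "tolerance": 0.01,
                "passed": abs(computed - printed_r) <= 0.01,
                "gating": True,
                "note": convention,
            }
        )
        if var1 == "nose":
            alt = corr[
                (corr["variable_1"] == var1)
                & (corr["variable_2"] == var2)
                & (corr["convention"] == "preop (n states)")
            ]
            checks.append(
                {
                    "check": f"r({var1}, {var2}) [preop-only variant]",
                    "computed": float(alt["r"].iloc[0]),
                    "printed": printed_r,
                    "tolerance": np.nan,
                    "passed": True,
                    "gating": False,
                    "note": "informational: ambiguous pooling, preop-only variant",
                }
            )

    return pd.DataFrame(checks)
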