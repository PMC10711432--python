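"""Replicate aggregation, pooled-variance t-tests, and figure-style reports.

The study's statistics are deliberately simple: per-condition means with
standard error of the mean (SEM) over whole-experiment replicates, and
Student t-tests with pooled (homoscedastic) variance. One-tailed tests are
used when a transfected sample is compared against the untransfected
baseline (alternative: the transfected value exceeds it); two-tailed tests
when two transfected conditions are compared. No multiple-testing
correction is applied by default (a Holm adjustment is available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .assays import Scenario, generate_scenario_dataset
from .quantify import QuantifyParams, quantify_table

__all__ = [
    "GroupSummary",
    "TestResult",
    "summarize",
    "t_test",
    "holm_adjust",
    "select_sidedness",
    "build_report",
]

Sidedness = Literal["one_tailed", "two_tailed"]

#: Smallest positive float, reported when a zero-variance comparison has
#: unequal means ("p < machine minimum").
_P_FLOOR = 5e-324


@dataclass(frozen=True)
class GroupSummary:
    scenario_id: str
    measure: str
    n: int
    mean: float
    sem: float  # NaN when n == 1


@dataclass(frozen=True)
class TestResult:
    group_a: str
    group_b: str
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    sidedness: Sidedness
    zero_variance: bool = False


def summarize(
    estimates: pd.DataFrame,
    value_col: str,
    group_keys: Sequence[str] = ("scenario_id",),
) -> pd.DataFrame:
    """Mean and SEM per group; SEM is NaN for singleton groups.

    SEM is the sample standard deviation (ddof = 1) over replicates divided
    by sqrt(n) — error bars over whole-experiment repeats, matching how the
    study reports its panels.
    """
    if estimates.empty:
        return pd.DataFrame(columns=[*group_keys, "measure", "n", "mean", "sem"])
    rows = []
    for keys, grp in estimates.groupby(list(group_keys), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        vals = grp[value_col].astype(float).to_numpy()
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        n = int(vals.size)
        sem = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        rows.append(
            dict(zip(group_keys, keys))
            | {"measure": value_col, "n": n, "mean": float(vals.mean()), "sem": sem}
        )
    return pd.DataFrame(rows)


def t_test(
    a: Sequence[float],
    b: Sequence[float],
    sidedness: Sidedness = "two_tailed",
    group_a: str = "a",
    group_b: str = "b",
) -> TestResult:
    """Student t-test with pooled (homoscedastic) variance.

    One-tailed p is the upper-tail probability for the alternative
    mean(a) > mean(b); two-tailed doubles the symmetric tail. Zero pooled
    variance is handled explicitly: equal means give t = 0 (p = 0.5
    one-tailed, 1.0 two-tailed); unequal means are reported at the smallest
    positive float with ``zero_variance`` flagged.
    """
    if sidedness not in ("one_tailed", "two_tailed"):
        raise ValueError(f"unknown sidedness: {sidedness!r}")
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    na, nb = x.size, y.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 values")
    df = na + nb - 2
    pooled = ((na - 1) * np.var(x, ddof=1) + (nb - 1) * np.var(y, ddof=1)) / df
    diff = float(x.mean() - y.mean())
    if pooled == 0.0:
        if diff == 0.0:
            t_stat, p = 0.0, (0.5 if sidedness == "one_tailed" else 1.0)
            return TestResult(group_a, group_b, t_stat, df, p, sidedness, True)
        t_stat = math.copysign(math.inf, diff)
        return TestResult(group_a, group_b, t_stat, df, _P_FLOOR, sidedness, True)
    t_stat = diff / math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    if sidedness == "one_tailed":
        p = float(sps.t.sf(t_stat, df))
    else:
        p = float(2.0 * sps.t.sf(abs(t_stat), df))
    p = min(max(p, _P_FLOOR), 1.0)
    return TestResult(group_a, group_b, float(t_stat), df, p, sidedness, False)


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment (available but off by default in reports)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj.tolist()


def select_sidedness(a_is_baseline: bool, b_is_baseline: bool) -> Sidedness:
    """The study's rule: vs-untransfected comparisons are one-tailed,
    transfected-vs-transfected comparisons two-tailed."""
    return "one_tailed" if (a_is_baseline or b_is_baseline) else "two_tailed"


# --------------------------------------------------------------------------
# Figure-style panel reports

_MEASURE_BY_ASSAY = {
    "sspe": ("repair", "percent_repair"),
    "kcl_sds": ("removal", "percent_removal"),
    "ip": ("enrichment", "fold_enrichment"),
}


def build_report(
    panels: dict[str, list[Scenario]],
    seed: int,
    quantify_params: QuantifyParams = QuantifyParams(),
    holm: bool = False,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Simulate, quantify, and test every arm of the given panels.

    For each panel: every arm (scenario) is simulated with the shared master
    seed, the relevant estimator applied, per-arm mean ± SEM computed, and
    all pairwise t-tests run with sidedness auto-selected by the
    vs-untransfected rule. The untransfected t = 0 baseline of each arm is
    included as a group (suffix ``/t0``) so each arm is also tested against
    its own baseline, one-tailed. Deterministic given (panels, seed).

    Returns ``{panel_id: {"summaries": DataFrame, "tests": DataFrame,
    "estimates": DataFrame}}``.
    """
    report: dict[str, dict[str, pd.DataFrame]] = {}
    for panel_id, arms in panels.items():
        groups: dict[str, np.ndarray] = {}
        baseline_flag: dict[str, bool] = {}
        summary_rows: list[pd.DataFrame] = []
        est_frames: list[pd.DataFrame] = []

        for arm in arms:
            table = generate_scenario_dataset(arm, seed)
            est = quantify_table(table, quantify_params)
            assay = arm.assays[0]
            key, value_col = _MEASURE_BY_ASSAY[assay]
            frame = est[key]
            if assay == "ip":
                # one group per antibody
                arm_groups = {
                    f"{arm.scenario_id}/{ab}": grp
                    for ab, grp in frame[frame["timepoint"] > 0].groupby("antibody")
                }
            else:
                arm_groups = {arm.scenario_id: frame[frame["timepoint"] > 0]}
            for gname, grp in arm_groups.items():
                vals = grp[value_col].astype(float).to_numpy()
                groups[gname] = vals
                baseline_flag[gname] = arm.is_baseline_arm
                summary_rows.append(
                    summarize(grp, value_col, ["scenario_id"]).assign(group=gname)
                )
            # untransfected baseline group (repair/removal only: IP input-
            # normalizes instead of using a t0 sample)
            base = frame[frame["timepoint"] == 0.0]
            if assay != "ip" and not base.empty:
                gname = f"{arm.scenario_id}/t0"
                groups[gname] = base[value_col].astype(float).to_numpy()
                baseline_flag[gname] = True
                summary_rows.append(
                    summarize(base, value_col, ["scenario_id"]).assign(group=gname)
                )
            est_frames.append(frame.assign(panel=panel_id, group=arm.scenario_id))

        test_rows = []
        names = list(groups)
        for i, ga in enumerate(names):
            for gb in names[i + 1:]:
                if baseline_flag[ga] and baseline_flag[gb]:
                    continue  # baseline-vs-baseline is uninformative
                a, b = groups[ga], groups[gb]
                if a.size < 2 or b.size < 2:
                    continue
                side = select_sidedness(baseline_flag[ga], baseline_flag[gb])
                # orient one-tailed tests as transfected-exceeds-baseline
                na_, nb_, xa, xb = ga, gb, a, b
                if side == "one_tailed" and baseline_flag[ga]:
                    na_, nb_, xa, xb = gb, ga, b, a
                res = t_test(xa, xb, side, na_, nb_)
                test_rows.append(res.__dict__)
        tests = pd.DataFrame(
            test_rows,
            columns=["group_a", "group_b", "t_statistic", "degrees_of_freedom",
                     "p_value", "sidedness", "zero_variance"],
        )
        if holm and not tests.empty:
            tests["p_adjusted"] = holm_adjust(tests["p_value"].tolist())

        summaries = (
            pd.concat(summary_rows, ignore_index=True)
            if summary_rows
            else pd.DataFrame(columns=["scenario_id", "measure", "n", "mean",
                                       "sem", "group"])
        )
        estimates = pd.concat(est_frames, ignore_index=True) if est_frames else pd.DataFrame()
        report[panel_id] = {
            "summaries": summaries,
            "tests": tests,
            "estimates": estimates,
        }
    return report
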