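"""Estimators that turn CtRecord tables into repair/removal/enrichment values.

Implements the study's quantification arithmetic:

* SSPE-qPCR: ΔCt = Ct(reference tube) − Ct(pre-amplified tube);
  percent undamaged = 2^ΔCt / 2^3 × 100; percent repair = percent undamaged
  at t minus percent undamaged of the untransfected input substrate (t0).
* KCl-SDS-qPCR: relative abundance of the lesion fragment b over the control
  fragment c, efficiency^(Ct_c − Ct_b); percent removal is the affine
  rescaling that maps the pre-transfection (fully crosslinked) baseline
  ratio to 0% and a protein-free control ratio to 100%.
* IP-qPCR: fold enrichment = (eluate b/c ratio) / (input b/c ratio).

Estimates are never clamped to [0, 100]: noise can push them outside, and
the downstream t-tests need the unclamped values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assays import CT_COLUMNS, parse_sample_id

__all__ = [
    "QuantifyParams",
    "delta_ct",
    "percent_undamaged",
    "percent_repair",
    "relative_abundance",
    "percent_removal",
    "fold_enrichment",
    "quantify_table",
]

logger = logging.getLogger(__name__)


def delta_ct(ct_reference_tube: float, ct_pre_amplified: float) -> float:
    """ΔCt of an SSPE sample pair; positive when pre-amplification helped."""
    if not (math.isfinite(ct_reference_tube) and math.isfinite(ct_pre_amplified)):
        raise ValueError("Ct values must be finite")
    return ct_reference_tube - ct_pre_amplified


def percent_undamaged(dct: float) -> float:
    """Percent undamaged DNA: 2^ΔCt / 2^3 × 100 (not clamped to [0, 100])."""
    if not math.isfinite(dct):
        raise ValueError("delta Ct must be finite")
    return 2.0**dct / 2.0**3 * 100.0


def percent_repair(pu_at_t: float, pu_at_t0: float) -> float:
    """Percent repair: percent undamaged at t minus the t0 baseline."""
    if not (math.isfinite(pu_at_t) and math.isfinite(pu_at_t0)):
        raise ValueError("percent-undamaged values must be finite")
    return pu_at_t - pu_at_t0


def relative_abundance(ct_b: float, ct_c: float, efficiency: float = 2.0) -> float:
    """Abundance of fragment b relative to fragment c: efficiency^(Ct_c − Ct_b)."""
    if not (math.isfinite(ct_b) and math.isfinite(ct_c)):
        raise ValueError("Ct values must be finite")
    if not (1.0 < efficiency <= 2.0):
        raise ValueError(f"efficiency must be in (1, 2], got {efficiency}")
    return efficiency ** (ct_c - ct_b)


def percent_removal(a_t: float, a_t0: float, a_full: float = 1.0) -> float:
    """Percent of recovered molecules whose crosslinked protein is removed.

    Affine rescaling of the supernatant b/c ratio: the pre-transfection
    (fully crosslinked) baseline ``a_t0`` maps to 0% and the ratio of a
    fully protein-free control ``a_full`` to 100%.
    """
    if a_t0 < 0:
        raise ValueError("baseline ratio must be >= 0")
    if a_full <= a_t0:
        raise ValueError(
            f"degenerate baseline: a_full ({a_full}) must exceed a_t0 ({a_t0})"
        )
    return (a_t - a_t0) / (a_full - a_t0) * 100.0


def fold_enrichment(a_eluate: float, a_input: float) -> float:
    """Eluate b/c ratio normalized to the input-control b/c ratio."""
    if a_input <= 0:
        raise ValueError("input ratio must be > 0")
    return a_eluate / a_input


@dataclass(frozen=True)
class QuantifyParams:
    """Estimation-side parameters.

    ``efficiency`` defaults to 2.0 — the 2^ΔCt arithmetic of the estimators
    assumes perfect doubling — independently of whatever efficiency the
    simulator used, so estimator bias under imperfect efficiency can be
    studied. Baselines (``pu_t0``, ``removal_a_t0``) are taken from t = 0
    rows of the table when present; the explicit values here are fallbacks
    used when a table carries no baseline sample. ``removal_a_full`` is the
    b/c ratio of a fully protein-free control (1 under the forward model's
    symmetric-loss assumption). ``input_normalized=False`` reports the raw
    eluate ratio instead of input-normalized fold enrichment.
    """

    efficiency: float = 2.0
    pu_t0: float | None = None
    removal_a_t0: float | None = None
    removal_a_full: float = 1.0
    input_normalized: bool = True


def _validate_table(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"CtRecord table missing columns: {sorted(missing)}")
    df = records.copy()
    dup = df.duplicated(subset=["sample_id", "assay", "tube", "replicate"], keep=False)
    if dup.any():
        first = df.index[dup][0]
        raise ValueError(
            f"duplicate (sample_id, assay, tube, replicate) key at row {first}: "
            f"{df.loc[first, ['sample_id', 'assay', 'tube', 'replicate']].tolist()}"
        )
    if not np.isfinite(df["ct"]).all() or (df["ct"] <= 0).any():
        bad = df.index[~(np.isfinite(df["ct"]) & (df["ct"] > 0))][0]
        raise ValueError(f"invalid Ct at row {bad}: {df.loc[bad, 'ct']}")
    return df


def _pivot(group: pd.DataFrame, tubes: tuple[str, ...]) -> dict[str, float] | None:
    """Map tube -> ct for one (sample, replicate) group; None if incomplete."""
    have = dict(zip(group["tube"], group["ct"]))
    if any(t not in have for t in tubes):
        return None
    return have


def quantify_table(
    records: pd.DataFrame, params: QuantifyParams = QuantifyParams()
) -> dict[str, pd.DataFrame]:
    """Dispatch a CtRecord table to the three estimators.

    Returns ``{"repair": ..., "removal": ..., "enrichment": ...}`` with one
    row per (sample, replicate). Groups with a missing tube are skipped with
    a logged warning, never imputed. t = 0 samples provide the per-scenario
    baselines (averaged over replicates) for percent repair and percent
    removal; estimates at t = 0 are reported too (they straddle zero by
    construction).
    """
    empty = {
        "repair": pd.DataFrame(
            columns=["scenario_id", "timepoint", "replicate", "delta_ct",
                     "percent_undamaged", "percent_repair"]
        ),
        "removal": pd.DataFrame(
            columns=["scenario_id", "timepoint", "replicate",
                     "relative_abundance", "percent_removal"]
        ),
        "enrichment": pd.DataFrame(
            columns=["scenario_id", "timepoint", "antibody", "replicate",
                     "fold_enrichment"]
        ),
    }
    if records.empty:
        return empty
    df = _validate_table(records)

    meta = df["sample_id"].map(parse_sample_id)
    df["_scenario"] = [m[0] for m in meta]
    df["_timepoint"] = [m[1] for m in meta]
    df["_antibody"] = [m[2] for m in meta]

    repair_rows: list[dict] = []
    removal_rows: list[dict] = []
    enrich_rows: list[dict] = []

    for (sid, assay, rep), group in df.groupby(
        ["sample_id", "assay", "replicate"], sort=True
    ):
        scenario = group["_scenario"].iloc[0]
        tp = group["_timepoint"].iloc[0]
        if assay == "sspe":
            tubes = _pivot(group, ("pre_amplified", "reference"))
            if tubes is None:
                logger.warning(
                    "skipping sspe sample %r replicate %s: missing tube", sid, rep
                )
                continue
            dct = delta_ct(tubes["reference"], tubes["pre_amplified"])
            repair_rows.append(
                {
                    "scenario_id": scenario,
                    "timepoint": tp,
                    "replicate": rep,
                    "delta_ct": dct,
                    "percent_undamaged": percent_undamaged(dct),
                }
            )
        elif assay == "kcl_sds":
            tubes = _pivot(group, ("b_supernatant", "c_supernatant"))
            if tubes is None:
                logger.warning(
                    "skipping kcl_sds sample %r replicate %s: missing tube", sid, rep
                )
                continue
            removal_rows.append(
                {
                    "scenario_id": scenario,
                    "timepoint": tp,
                    "replicate": rep,
                    "relative_abundance": relative_abundance(
                        tubes["b_supernatant"], tubes["c_supernatant"],
                        params.efficiency,
                    ),
                }
            )
        elif assay == "ip":
            tubes = _pivot(group, ("b_eluate", "c_eluate", "b_input", "c_input"))
            if tubes is None:
                logger.warning(
                    "skipping ip sample %r replicate %s: missing tube", sid, rep
                )
                continue
            a_el = relative_abundance(
                tubes["b_eluate"], tubes["c_eluate"], params.efficiency
            )
            a_in = relative_abundance(
                tubes["b_input"], tubes["c_input"], params.efficiency
            )
            fe = fold_enrichment(a_el, a_in) if params.input_normalized else a_el
            enrich_rows.append(
                {
                    "scenario_id": scenario,
                    "timepoint": tp,
                    "antibody": group["_antibody"].iloc[0],
                    "replicate": rep,
                    "fold_enrichment": fe,
                }
            )
        else:
            logger.warning("skipping unknown assay %r in sample %r", assay, sid)

    repair = empty["repair"]
    if repair_rows:
        repair = pd.DataFrame(repair_rows)
        # per-scenario t0 baseline, averaged over baseline replicates
        base = (
            repair[repair["timepoint"] == 0.0]
            .groupby("scenario_id")["percent_undamaged"]
            .mean()
        )
        def pu0(row):
            if row["scenario_id"] in base.index:
                return base[row["scenario_id"]]
            return params.pu_t0
        baselines = repair.apply(pu0, axis=1)
        repair["percent_repair"] = np.where(
            baselines.notna(),
            repair["percent_undamaged"] - baselines.astype(float),
            np.nan,
        )

    removal = empty["removal"]
    if removal_rows:
        removal = pd.DataFrame(removal_rows)
        base = (
            removal[removal["timepoint"] == 0.0]
            .groupby("scenario_id")["relative_abundance"]
            .mean()
        )
        def a0(row):
            if row["scenario_id"] in base.index:
                return base[row["scenario_id"]]
            return params.removal_a_t0
        baselines = removal.apply(a0, axis=1)
        pr = []
        for a_t, a_t0 in zip(removal["relative_abundance"], baselines):
            if a_t0 is None or not math.isfinite(float(a_t0)):
                pr.append(np.nan)
            else:
                pr.append(percent_removal(a_t, float(a_t0), params.removal_a_full))
        removal["percent_removal"] = pr

    enrichment = pd.DataFrame(enrich_rows) if enrich_rows else empty["enrichment"]

    return {"repair": repair, "removal": removal, "enrichment": enrichment}
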