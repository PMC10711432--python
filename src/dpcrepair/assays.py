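"""Forward models of the three qPCR readouts, and the scenario simulator.

Converts a pathway :class:`~dpcrepair.pathway.StateDistribution` into noisy
threshold-cycle (Ct) tables for:

* **SSPE-qPCR** — strand-specific primer extension: the sample is split into
  two tubes, one receives several rounds of linear pre-amplification that
  only repaired (fully duplex) templates support, then both are quantified
  by qPCR. Repaired molecules lower the Ct of the pre-amplified tube.
* **KCl-SDS-qPCR** — after restriction digestion decouples the lesion-bearing
  fragment (b) from a control fragment (c) on the same plasmid, KCl/SDS
  selectively precipitates protein-crosslinked fragments; the supernatant is
  quantified for both fragments.
* **IP-qPCR** — an anti-ubiquitin antibody (pan, K48- or K63-linkage
  selective) enriches ubiquitin-conjugated fragments; eluate and a saved
  input aliquot are quantified for fragments b and c.

All randomness is Gaussian Ct noise plus (optionally) per-molecule pathway
sampling; tubes are independent. The output is a tidy CtRecord table — the
single interchange format consumed by the estimators.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .pathway import (
    Condition,
    PathwayState,
    RateSet,
    StateDistribution,
    build_generator,
    population_summary,
    propagate_exact,
    simulate_gillespie,
)

__all__ = [
    "QPCRParams",
    "SSPEParams",
    "PrecipParams",
    "IPParams",
    "Scenario",
    "CT_COLUMNS",
    "PSEUDO_ABUNDANCE_FLOOR",
    "ct_from_template",
    "sspe_readout",
    "kcl_sds_readout",
    "ip_readout",
    "antibody_capture_fraction",
    "generate_scenario_dataset",
    "make_sample_id",
    "parse_sample_id",
]

logger = logging.getLogger(__name__)

#: Relative template abundance substituted for an analytically empty pool,
#: mimicking late nonspecific amplification instead of a censored "no Ct".
#: Small enough (~+30 cycles at perfect efficiency) that flooring an empty
#: pool perturbs downstream percent estimates by well under 1e-6.
PSEUDO_ABUNDANCE_FLOOR = 1e-9

#: Column order of the CtRecord interchange table.
CT_COLUMNS = ("sample_id", "scenario_id", "assay", "tube", "replicate", "ct")

Antibody = Literal["pan_ub", "k48", "k63"]


@dataclass(frozen=True)
class QPCRParams:
    """Threshold-cycle generation parameters.

    ``efficiency`` is the per-cycle amplification factor (2.0 = perfect
    doubling); ``ct_reference`` the Ct produced by unit template abundance;
    ``ct_noise_sd`` the standard deviation of Gaussian Ct noise in cycles.
    """

    efficiency: float = 2.0
    ct_reference: float = 30.0
    ct_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError(f"efficiency must be in (1, 2], got {self.efficiency}")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")


@dataclass(frozen=True)
class SSPEParams:
    """Strand-specific pre-amplification parameters.

    ``gain`` is the effective amplification factor a repaired template gains
    over the pre-amplification rounds; the default of 8 (= 2**3) matches the
    2**3 normalization built into the percent-undamaged estimator.
    ``damaged_leak`` is the relative amplification of unrepaired templates
    during pre-amplification: 1 means they persist un-amplified but still
    amplify in the final two-primer qPCR; 0 removes them entirely.
    """

    cycles: int = 8
    gain: float = 8.0
    damaged_leak: float = 1.0

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.gain < 1:
            raise ValueError("gain must be >= 1")
        if not (0.0 <= self.damaged_leak <= 1.0):
            raise ValueError("damaged_leak must lie in [0, 1]")


@dataclass(frozen=True)
class PrecipParams:
    """KCl-SDS precipitation parameters.

    ``capture_prob``: probability a crosslink-bearing fragment precipitates;
    ``nonspecific_loss``: probability any fragment is lost to the pellet
    nonspecifically. ``proteolyzed_precipitates`` optionally treats the
    residual peptide adduct of PROTEOLYZED molecules as precipitable (off by
    default: the peptide is too small to co-precipitate).
    """

    capture_prob: float = 0.98
    nonspecific_loss: float = 0.02
    proteolyzed_precipitates: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.capture_prob <= 1.0):
            raise ValueError("capture_prob must lie in [0, 1]")
        if not (0.0 <= self.nonspecific_loss <= 1.0):
            raise ValueError("nonspecific_loss must lie in [0, 1]")


@dataclass(frozen=True)
class IPParams:
    """Immunoprecipitation parameters.

    ``antibody`` selects the capture predicate: ``pan_ub`` and ``k63`` match
    K63-chain-bearing states, ``k48`` matches K48-chain-bearing states (a
    subset, since K48 chains are built on K63-tagged molecules here).
    ``proteolyzed_retains_tags`` optionally lets the PROTEOLYZED peptide
    adduct keep its ubiquitin chains (off by default: tags are assumed
    degraded with the protein).
    """

    antibody: Antibody = "pan_ub"
    capture_efficiency: float = 0.5
    background_rate: float = 0.01
    proteolyzed_retains_tags: bool = False

    def __post_init__(self) -> None:
        if self.antibody not in ("pan_ub", "k48", "k63"):
            raise ValueError(f"unknown antibody: {self.antibody!r}")
        if not (0.0 < self.capture_efficiency <= 1.0):
            raise ValueError("capture_efficiency must lie in (0, 1]")
        if not (0.0 < self.background_rate < 1.0):
            raise ValueError("background_rate must lie in (0, 1)")
        if self.background_rate >= self.capture_efficiency:
            raise ValueError("background_rate must be < capture_efficiency")


def ct_from_template(
    abundance: float, qp: QPCRParams, rng: np.random.Generator
) -> float:
    """Threshold cycle for a given relative template abundance.

    ct = ct_reference − log(abundance)/log(efficiency) + N(0, ct_noise_sd),
    truncated below at 1 cycle. Empty pools must be floored by the caller
    (:data:`PSEUDO_ABUNDANCE_FLOOR`) before calling.
    """
    if not np.isfinite(abundance) or abundance <= 0:
        raise ValueError(f"abundance must be finite and > 0, got {abundance}")
    ct = qp.ct_reference - np.log(abundance) / np.log(qp.efficiency)
    ct += rng.normal(0.0, qp.ct_noise_sd)
    return float(max(ct, 1.0))


def _floored(abundance: float) -> float:
    return abundance if abundance > 0 else PSEUDO_ABUNDANCE_FLOOR


def sspe_readout(
    dist: StateDistribution,
    sp: SSPEParams,
    qp: QPCRParams,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Simulate the two SSPE tubes; returns (ct_pre_amplified, ct_reference).

    With repaired fraction ``f``, the reference tube carries unit template
    and the pre-amplified tube ``(1 − f)·damaged_leak + gain·f``.
    """
    f = population_summary(dist).repaired_fraction
    pre = _floored((1.0 - f) * sp.damaged_leak + sp.gain * f)
    ct_pre = ct_from_template(pre, qp, rng)
    ct_ref = ct_from_template(1.0, qp, rng)
    return ct_pre, ct_ref


def _removed_for_precip(dist: StateDistribution, pp: PrecipParams) -> float:
    s = population_summary(dist)
    if pp.proteolyzed_precipitates:
        return s.repaired_fraction
    return s.removed_fraction


def kcl_sds_readout(
    dist: StateDistribution,
    pp: PrecipParams,
    qp: QPCRParams,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Simulate supernatant qPCR; returns (ct_fragment_b, ct_fragment_c).

    With protein-removed fraction ``r`` (crosslink-bearing ``x = 1 − r``),
    the supernatant retains fragment b at ``(r + x·(1 − capture_prob))·
    (1 − nonspecific_loss)`` and the control fragment c at
    ``1 − nonspecific_loss``.
    """
    r = _removed_for_precip(dist, pp)
    x = 1.0 - r
    ab_b = _floored((r + x * (1.0 - pp.capture_prob)) * (1.0 - pp.nonspecific_loss))
    ab_c = _floored(1.0 - pp.nonspecific_loss)
    ct_b = ct_from_template(ab_b, qp, rng)
    ct_c = ct_from_template(ab_c, qp, rng)
    return ct_b, ct_c


def antibody_capture_fraction(dist: StateDistribution, ip: IPParams) -> float:
    """Fraction of molecules matched by the antibody's linkage predicate."""
    s = population_summary(dist)
    u = s.k48_fraction if ip.antibody == "k48" else s.k63_fraction
    if ip.proteolyzed_retains_tags:
        u += dist.fraction(PathwayState.PROTEOLYZED)
    return u


def ip_readout(
    dist: StateDistribution,
    ip: IPParams,
    qp: QPCRParams,
    rng: np.random.Generator,
) -> tuple[float, float, float, float]:
    """Simulate IP-qPCR; returns (ct_b_eluate, ct_c_eluate, ct_b_input, ct_c_input).

    With matched fraction ``u``, eluate abundances are
    ``u·capture_efficiency + background_rate`` for the lesion fragment b and
    ``background_rate`` for the control fragment c; the saved input aliquot
    carries unit abundance of both.
    """
    u = antibody_capture_fraction(dist, ip)
    ab_b_el = _floored(u * ip.capture_efficiency + ip.background_rate)
    ab_c_el = _floored(ip.background_rate)
    ct_b_el = ct_from_template(ab_b_el, qp, rng)
    ct_c_el = ct_from_template(ab_c_el, qp, rng)
    ct_b_in = ct_from_template(1.0, qp, rng)
    ct_c_in = ct_from_template(1.0, qp, rng)
    return ct_b_el, ct_c_el, ct_b_in, ct_c_in


# --------------------------------------------------------------------------
# Scenario-level simulation


@dataclass(frozen=True)
class Scenario:
    """A fully resolved experimental scenario: one arm of a figure panel.

    ``assays`` selects which readouts to simulate; ``ip_antibodies`` which
    antibodies to run when "ip" is included. ``include_baseline`` adds a
    t = 0 sample of the untransfected input substrate (all molecules
    NASCENT), which the estimators use as the t0 baseline. ``propagation``
    chooses per-molecule Gillespie sampling ("gillespie", ``n_molecules``
    independent chains per replicate) or the deterministic matrix-exponential
    solution ("exact"). ``is_baseline_arm`` marks untransfected control arms
    for the one-tailed/two-tailed test-selection rule.
    """

    scenario_id: str
    condition: Condition = field(default_factory=Condition)
    timepoints: tuple[float, ...] = (1.0,)
    replicates: int = 3
    assays: tuple[str, ...] = ("sspe", "kcl_sds", "ip")
    ip_antibodies: tuple[Antibody, ...] = ("pan_ub",)
    rates: RateSet = field(default_factory=RateSet)
    qpcr: QPCRParams = field(default_factory=QPCRParams)
    sspe: SSPEParams = field(default_factory=SSPEParams)
    precip: PrecipParams = field(default_factory=PrecipParams)
    ip: IPParams = field(default_factory=IPParams)
    n_molecules: int = 10_000
    propagation: Literal["gillespie", "exact"] = "gillespie"
    include_baseline: bool = True
    is_baseline_arm: bool = False
    #: random-stream key; arms that differ only by a structurally inert
    #: switch share a seed_group so the toggle is exactly a no-op
    #: (common random numbers). Defaults to scenario_id.
    seed_group: str | None = None

    @property
    def stream_key(self) -> str:
        return self.seed_group or self.scenario_id

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        unknown = set(self.assays) - {"sspe", "kcl_sds", "ip"}
        if unknown:
            raise ValueError(f"unknown assays: {sorted(unknown)}")
        if any(t < 0 for t in self.timepoints):
            raise ValueError("timepoints must be >= 0")


def make_sample_id(scenario_id: str, timepoint: float, antibody: str | None = None) -> str:
    """Sample identifier encoding the fields the CtRecord schema lacks.

    Format: ``<scenario_id>|t<hours>`` with an optional ``|<antibody>``
    segment for IP samples (the pipe character is reserved).
    """
    base = f"{scenario_id}|t{timepoint:g}"
    return f"{base}|{antibody}" if antibody else base


def parse_sample_id(sample_id: str) -> tuple[str, float, str | None]:
    """Inverse of :func:`make_sample_id`; returns (scenario_id, timepoint, antibody)."""
    parts = sample_id.split("|")
    if len(parts) < 2 or not parts[1].startswith("t"):
        raise ValueError(f"malformed sample_id: {sample_id!r}")
    antibody = parts[2] if len(parts) > 2 else None
    return parts[0], float(parts[1][1:]), antibody


def _child_rng(master_seed: int, scenario_id: str, timepoint: float,
               replicate: int, stream: str) -> np.random.Generator:
    """Deterministic child stream per (scenario, timepoint, replicate, stream)."""
    key = f"{scenario_id}|{timepoint:.6g}|{replicate}|{stream}".encode()
    return np.random.default_rng(
        np.random.SeedSequence([master_seed & 0x7FFFFFFF, zlib.crc32(key)])
    )


def _replicate_distribution(
    scenario: Scenario, timepoint: float, replicate: int, master_seed: int
) -> StateDistribution:
    if timepoint == 0.0:
        # untransfected input substrate: every molecule still NASCENT
        return StateDistribution.point_mass(PathwayState.NASCENT)
    gen = build_generator(scenario.rates, scenario.condition)
    if scenario.propagation == "exact":
        return propagate_exact(
            gen, timepoint, StateDistribution.point_mass(PathwayState.NASCENT)
        )
    rng = _child_rng(master_seed, scenario.stream_key, timepoint, replicate, "pathway")
    return simulate_gillespie(gen, timepoint, scenario.n_molecules, rng)


def generate_scenario_dataset(scenario: Scenario, seed: int) -> pd.DataFrame:
    """Simulate a full CtRecord table for one scenario.

    One row per (timepoint, assay, tube, replicate); each replicate is a
    fresh, independent pathway simulation followed by independent assay
    noise. Fully reproducible given ``seed``: the master seed is combined
    with (scenario id, timepoint, replicate, assay) to derive independent
    child streams, so adding assays or replicates never perturbs the draws
    of existing rows.
    """
    rows: list[dict] = []
    timepoints = tuple(scenario.timepoints)
    if scenario.include_baseline and 0.0 not in timepoints:
        timepoints = (0.0, *timepoints)

    for tp in timepoints:
        for rep in range(1, scenario.replicates + 1):
            dist = _replicate_distribution(scenario, tp, rep, seed)
            sid = make_sample_id(scenario.scenario_id, tp)

            def add(assay: str, tube: str, ct: float, sample_id: str = None) -> None:
                rows.append(
                    {
                        "sample_id": sample_id or sid,
                        "scenario_id": scenario.scenario_id,
                        "assay": assay,
                        "tube": tube,
                        "replicate": rep,
                        "ct": ct,
                    }
                )

            if "sspe" in scenario.assays:
                rng = _child_rng(seed, scenario.stream_key, tp, rep, "sspe")
                ct_pre, ct_ref = sspe_readout(dist, scenario.sspe, scenario.qpcr, rng)
                add("sspe", "pre_amplified", ct_pre)
                add("sspe", "reference", ct_ref)

            if "kcl_sds" in scenario.assays:
                rng = _child_rng(seed, scenario.stream_key, tp, rep, "kcl_sds")
                ct_b, ct_c = kcl_sds_readout(dist, scenario.precip, scenario.qpcr, rng)
                add("kcl_sds", "b_supernatant", ct_b)
                add("kcl_sds", "c_supernatant", ct_c)

            if "ip" in scenario.assays:
                for antibody in scenario.ip_antibodies:
                    rng = _child_rng(
                        seed, scenario.stream_key, tp, rep, f"ip:{antibody}"
                    )
                    ip = IPParams(
                        antibody=antibody,
                        capture_efficiency=scenario.ip.capture_efficiency,
                        background_rate=scenario.ip.background_rate,
                        proteolyzed_retains_tags=scenario.ip.proteolyzed_retains_tags,
                    )
                    quartet = ip_readout(dist, ip, scenario.qpcr, rng)
                    ip_sid = make_sample_id(scenario.scenario_id, tp, antibody)
                    for tube, ct in zip(
                        ("b_eluate", "c_eluate", "b_input", "c_input"), quartet
                    ):
                        add("ip", tube, ct, sample_id=ip_sid)

    df = pd.DataFrame(rows, columns=list(CT_COLUMNS))
    dup = df.duplicated(subset=["sample_id", "assay", "tube", "replicate"])
    if dup.any():  # pragma: no cover - guards future edits
        raise RuntimeError("duplicate CtRecord keys generated")
    return df


def write_ct_table(df: pd.DataFrame, path) -> None:
    """Write a CtRecord table as the fixed-dialect interchange CSV."""
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")


def read_ct_table(path) -> pd.DataFrame:
    """Read a CtRecord CSV, validating the schema."""
    df = pd.read_csv(path)
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"CtRecord table missing columns: {sorted(missing)}")
    if df["ct"].notna().all() and (df["ct"] <= 0).any():
        bad = df.index[df["ct"] <= 0][0]
        raise ValueError(f"non-positive Ct at row {bad}")
    return df[list(CT_COLUMNS)]
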