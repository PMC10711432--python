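"""Built-in scenario library: the experimental designs of the figure panels.

Each panel is a list of :class:`~dpcrepair.assays.Scenario` arms. Cell-line
genotypes map onto the condition switches: XPD patient fibroblasts and the
XPA-knockout line are NER-deficient; XPDC (gene-corrected), HEK293T, HT1080
wild type and the MEF lines are NER-proficient; MEF7 is SPRTN-deficient.
Repair (SSPE-qPCR) panels are read at 3 h post-transfection, removal
(KCl-SDS-qPCR) and ubiquitination (IP-qPCR) panels at 1 h, matching the
collection times of the corresponding experiments. Replicates default to 3
(5 for the B02 panel, which was repeated five times).
"""

from __future__ import annotations

from .assays import Scenario
from .pathway import Condition

__all__ = ["PANEL_IDS", "panel_scenarios", "paper_panels", "all_scenarios"]

PANEL_IDS = (
    "fig1a",
    "fig1b",
    "fig2b",
    "fig3b",
    "fig3c",
    "fig4",
    "fig5a",
    "fig5b",
    "supp_xpa",
    "supp_sprtn",
)


def _sspe(scenario_id: str, condition: Condition, replicates: int = 3,
          t: float = 3.0, **kw) -> Scenario:
    return Scenario(
        scenario_id=scenario_id, condition=condition, timepoints=(t,),
        replicates=replicates, assays=("sspe",), **kw,
    )


def _removal(scenario_id: str, condition: Condition, replicates: int = 3,
             t: float = 1.0, **kw) -> Scenario:
    return Scenario(
        scenario_id=scenario_id, condition=condition, timepoints=(t,),
        replicates=replicates, assays=("kcl_sds",), **kw,
    )


def _ip(scenario_id: str, condition: Condition, antibodies=("pan_ub",),
        replicates: int = 3, t: float = 1.0, **kw) -> Scenario:
    return Scenario(
        scenario_id=scenario_id, condition=condition, timepoints=(t,),
        replicates=replicates, assays=("ip",), ip_antibodies=tuple(antibodies),
        **kw,
    )


def panel_scenarios(panel_id: str) -> list[Scenario]:
    """Arms of one figure panel; raises on unknown ids, listing the panels."""
    builders = {
        # HR repair requires a homologous donor (XPD cells, SSPE at 3 h)
        "fig1a": lambda: [
            _sspe("fig1a_heterologous",
                  Condition(ner_functional=False, donor="heterologous")),
            _sspe("fig1a_homologous",
                  Condition(ner_functional=False, donor="homologous")),
        ],
        # Rad51 inhibition by B02 suppresses HR repair (5 repeats)
        "fig1b": lambda: [
            _sspe("fig1b_untreated",
                  Condition(ner_functional=False, donor="homologous"),
                  replicates=5),
            _sspe("fig1b_b02",
                  Condition(ner_functional=False, donor="homologous",
                            rad51_inhibited=True),
                  replicates=5),
        ],
        # protein removal, NER-proficient vs -deficient x donor type
        "fig2b": lambda: [
            _removal("fig2b_nerpos_heterologous",
                     Condition(ner_functional=True, donor="heterologous")),
            _removal("fig2b_nerpos_homologous",
                     Condition(ner_functional=True, donor="homologous")),
            _removal("fig2b_nerneg_heterologous",
                     Condition(ner_functional=False, donor="heterologous")),
            _removal("fig2b_nerneg_homologous",
                     Condition(ner_functional=False, donor="homologous")),
        ],
        # pan-ubiquitin IP across the same 2x2 design
        "fig3b": lambda: [
            _ip("fig3b_nerpos_heterologous",
                Condition(ner_functional=True, donor="heterologous")),
            _ip("fig3b_nerpos_homologous",
                Condition(ner_functional=True, donor="homologous")),
            _ip("fig3b_nerneg_heterologous",
                Condition(ner_functional=False, donor="heterologous")),
            _ip("fig3b_nerneg_homologous",
                Condition(ner_functional=False, donor="homologous")),
        ],
        # removal of wild-type vs ubiquitination-impaired (R341) protein
        "fig3c": lambda: [
            _removal("fig3c_ner_k341",
                     Condition(ner_functional=True, donor="none")),
            _removal("fig3c_ner_r341",
                     Condition(ner_functional=True, donor="none",
                               ogg1_variant="R341")),
            _removal("fig3c_hr_k341",
                     Condition(ner_functional=False, donor="homologous")),
            _removal("fig3c_hr_r341",
                     Condition(ner_functional=False, donor="homologous",
                               ogg1_variant="R341")),
        ],
        # proteasome inhibition hits NER-mediated removal, not HR-mediated;
        # each +/- MG132 pair shares its random stream (common random
        # numbers), so a structurally inert toggle is exactly a no-op
        "fig4": lambda: [
            _removal("fig4_ner_untreated",
                     Condition(ner_functional=True, donor="heterologous"),
                     seed_group="fig4_ner"),
            _removal("fig4_ner_mg132",
                     Condition(ner_functional=True, donor="heterologous",
                               proteasome_inhibited=True),
                     seed_group="fig4_ner"),
            _removal("fig4_hr_untreated",
                     Condition(ner_functional=False, donor="homologous"),
                     seed_group="fig4_hr"),
            _removal("fig4_hr_mg132",
                     Condition(ner_functional=False, donor="homologous",
                               proteasome_inhibited=True),
                     seed_group="fig4_hr"),
        ],
        # linkage-selective IPs, NER-proficient cells
        "fig5a": lambda: [
            _ip("fig5a_nerpos", Condition(ner_functional=True, donor="none"),
                antibodies=("k48", "k63")),
        ],
        # linkage-selective IPs, NER-deficient cells +/- homologous donor
        "fig5b": lambda: [
            _ip("fig5b_heterologous",
                Condition(ner_functional=False, donor="heterologous"),
                antibodies=("k48", "k63")),
            _ip("fig5b_homologous",
                Condition(ner_functional=False, donor="homologous"),
                antibodies=("k48", "k63")),
        ],
        # XPA knockout reproduces the NER-deficient removal defect
        "supp_xpa": lambda: [
            _removal("supp_xpa_wt", Condition(ner_functional=True, donor="none")),
            _removal("supp_xpa_ko", Condition(ner_functional=False, donor="none")),
        ],
        # SPRTN deficiency is a structural no-op on removal; shared stream
        # makes the two arms byte-identical apart from their labels
        "supp_sprtn": lambda: [
            _removal("supp_sprtn_mef5",
                     Condition(ner_functional=True, donor="none",
                               sprtn_deficient=False),
                     seed_group="supp_sprtn"),
            _removal("supp_sprtn_mef7",
                     Condition(ner_functional=True, donor="none",
                               sprtn_deficient=True),
                     seed_group="supp_sprtn"),
        ],
    }
    if panel_id not in builders:
        raise KeyError(
            f"unknown panel {panel_id!r}; available panels: {', '.join(PANEL_IDS)}"
        )
    return builders[panel_id]()


def paper_panels(panel_ids=PANEL_IDS) -> dict[str, list[Scenario]]:
    """The full built-in panel set (or a subset), keyed by panel id."""
    return {pid: panel_scenarios(pid) for pid in panel_ids}


def all_scenarios() -> list[Scenario]:
    """Every arm of every built-in panel, flattened."""
    return [arm for pid in PANEL_IDS for arm in panel_scenarios(pid)]
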