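# dpcrepair

Stochastic modelling of DNA–protein crosslink (DPC) repair and of the
qPCR-based assays used to measure it.

## The problem

A DPC is a protein covalently trapped on DNA — here a glycosylase
site-specifically crosslinked to a circular plasmid, transfected into human
cells and recovered hours later. Which repair pathway handles such a lesion
is controlled by ubiquitin signaling: the crosslinked protein first
receives a K63-linked polyubiquitin chain; if nucleotide excision repair
(NER) machinery is present, a K48-linked chain is added, the proteasome
degrades the protein, and NER excises the residual peptide adduct; without
NER, the lesion can only be rescued by homologous recombination (HR), which
requires a co-transfected homologous donor and active Rad51 — otherwise it
stalls, K63-tagged, indefinitely.

`dpcrepair` implements this orchestration model as a six-state
continuous-time Markov chain whose transitions are gated by the
experimental condition (NER genotype, donor type, Rad51/proteasome
inhibitors, a ubiquitination-impaired protein variant), forward-simulates
the three threshold-cycle (Ct) readouts used in such studies —

* **SSPE-qPCR**: strand-specific pre-amplification; measures the fraction
  of molecules with a fully repaired duplex,
* **KCl-SDS-qPCR**: selective precipitation of protein-crosslinked
  restriction fragments; measures protein removal,
* **IP-qPCR**: pan-, K48- or K63-selective anti-ubiquitin pulldown;
  measures fold enrichment of the lesion fragment,

— and implements the matching estimators (ΔCt → percent undamaged →
percent repair; fragment-ratio → percent removal; input-normalised fold
enrichment) plus replicate statistics (mean ± SEM, pooled-variance one- and
two-tailed t-tests). Simulator and estimators close the loop: synthetic Ct
tables can be pushed through the analysis and checked against the known
ground truth, exactly in the noise-free limit.

The core quantities, for a population with repaired fraction *f*, removed
fraction *r*, and antibody-matched fraction *u*:

```
ΔCt              = Ct(reference tube) − Ct(pre-amplified tube)
percent undamaged = 2^ΔCt / 2³ × 100
percent repair    = percent undamaged(t) − percent undamaged(t₀)     (= 87.5·f noise-free)
percent removal   = (A_t − A_t₀) / (A_full − A_t₀) × 100             (= 100·r noise-free)
fold enrichment   = (eluate b/c) / (input b/c)                        (= (u·c + b)/b noise-free)
```

It is aimed at researchers who want to reason quantitatively about
pathway-choice experiments of this design: power and bias of the
estimators, which contrasts are structural versus kinetic, and what a
proposed mechanism predicts each assay should show.

## Worked example

Propagate the model for NER-deficient cells with a homologous donor, then
simulate and re-analyse a triplicate repair experiment:

```python
from dpcrepair import *

cond = Condition(ner_functional=False, donor="homologous")
gen = build_generator(RateSet(), cond)
dist = propagate_exact(gen, 3.0, StateDistribution.point_mass(PathwayState.NASCENT))
s = population_summary(dist)
print(f"repaired fraction at 3 h: {s.repaired_fraction:.3f}")
print(f"K63-tagged fraction     : {s.k63_fraction:.3f}")

sc = panel_scenarios("fig1a")[1]          # the homologous-donor arm
table = generate_scenario_dataset(sc, seed=7)
est = quantify_table(table)["repair"]
print(est[est.timepoint > 0][["scenario_id", "replicate", "delta_ct", "percent_repair"]]
      .to_string(index=False))
```

prints

```
repaired fraction at 3 h: 0.754
K63-tagged fraction     : 0.241
     scenario_id  replicate  delta_ct  percent_repair
fig1a_homologous          1  2.443537       55.347365
fig1a_homologous          2  2.611438       63.739713
fig1a_homologous          3  2.552641       60.689086
```

Exact propagation says 75.4% of molecules are repaired at 3 h (the rest
mostly still K63-tagged); each simulated replicate converts that, through
10,000-molecule sampling and Ct noise, into a percent-repair estimate near
the noise-free value 87.5 × 0.754 ≈ 66.

The same panel from the command line, with summary and test tables:

```
$ dpcrepair report --seed 7 --panel fig1a --out report/
$ head -4 report/fig1a.summaries.csv
scenario_id,measure,n,mean,sem,group
fig1a_heterologous,percent_repair,3,0.8431192623909679,0.18437374095636566,fig1a_heterologous
fig1a_heterologous,percent_repair,3,5.921189464667501e-16,0.6840061467959195,fig1a_heterologous/t0
fig1a_homologous,percent_repair,3,59.925387804792074,2.452570256414085,fig1a_homologous
```

The heterologous-donor arm sits at ~0.8% repair (the stall), the
homologous-donor arm at ~60%; the accompanying `fig1a.tests.csv` reports
the two-tailed pooled-variance contrast between the arms at
p ≈ 1.8 × 10⁻⁵. Other subcommands: `dpcrepair simulate` (Ct tables + run
manifest, replayable byte-identically via `--from-manifest`),
`dpcrepair quantify` (estimates from any CtRecord CSV), and
`dpcrepair recover` (parameter-recovery study over a grid of true repaired
fractions).

Scenario configuration is YAML with a strict schema (unknown keys
rejected, seed mandatory); the built-in name `paper_panels` resolves to the
ten-panel scenario library covering donor rescue, Rad51 and proteasome
inhibition, the ubiquitination-impaired protein variant, linkage-selective
pulldowns, and the XPA/SPRTN controls.

The CtRecord interchange CSV has columns
`sample_id,scenario_id,assay,tube,replicate,ct`, where `sample_id` encodes
scenario, timepoint, and (for IP rows) antibody as
`<scenario>|t<hours>[|<antibody>]`.

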