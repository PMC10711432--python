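# Methods

## The model

`dpcrepair` models the fate of a single plasmid-borne DNA–protein crosslink
(DPC) — a glycosylase covalently trapped on double-stranded DNA — after
transfection into human cells, as a continuous-time Markov chain (CTMC) over
six states:

```
NASCENT → K63_TAGGED → K48_K63_TAGGED → PROTEOLYZED → NER_REPAIRED
              └──────────────→ HR_REPAIRED
```

* **NASCENT**: the unmodified crosslink, as delivered.
* **K63_TAGGED**: the crosslinked protein carries a K63-linked polyubiquitin
  chain — the initial recognition mark, required for everything downstream.
* **K48_K63_TAGGED**: a K48-linked chain has been added on top. K48 tagging
  is treated as strictly NER-machinery-dependent; it commits the lesion to
  the excision route.
* **PROTEOLYZED**: the proteasome has degraded the protein, leaving a small
  peptide adduct; the strand is not yet repaired. This state is what
  distinguishes *removal* (protein gone, measured by KCl-SDS precipitation
  at 1 h) from *repair* (duplex restored, measured by SSPE-qPCR at 3 h).
* **NER_REPAIRED / HR_REPAIRED**: absorbing, fully restored duplex.

Transitions are gated by the experimental condition:

| transition | rate | gate |
|---|---|---|
| NASCENT → K63_TAGGED | `k63_rate` × variant factor | always open |
| K63_TAGGED → K48_K63_TAGGED | `k48_rate` × variant factor | NER functional |
| K48_K63_TAGGED → PROTEOLYZED | `proteolysis_rate` × MG132 factor | NER functional |
| PROTEOLYZED → NER_REPAIRED | `ner_excision_rate` | NER functional |
| K63_TAGGED → HR_REPAIRED | `hr_rate` × B02 factor | homologous donor |

The entire K48/proteolysis/excision arm is gated on NER because K48
tagging — its only entry point — is NER-dependent; gating the downstream
steps as well gives NER-deficient conditions the pure one-step stall
topology (the only open move is the initial K63 tagging). `sprtn_deficient`
is carried on the condition for scenario fidelity but is never read when
rates are assembled: replication-independent DPC removal is structurally
SPRTN-independent in this model.

Deubiquitination is not modelled as a separate transition. Loss of the K63
chain is implicit in entry to `HR_REPAIRED`; whether the chain is removed
before or during recombination is left open deliberately. A consequence
(see Limitations) is that HR intermediates remain K63-positive.

The chain is propagated two ways: exactly, as `p(t) = p(0)·exp(Qt)` via
`scipy.linalg.expm`; and stochastically per molecule with Gillespie's direct
method (vectorised over molecules: exponential waiting times from the exit
rate, categorical jump choice from the row of the generator). The two agree
to total-variation distance < 0.02 at 10,000 molecules, which the test suite
and acceptance script verify against random rate sets.

## Rate constants

No kinetic constants for this system exist; the defaults are a calibration
of this package, not measurements. They were chosen once, before any test
was written, so that under default conditions the model sits in the regime
the assays operate in: substantial (tens of percent) protein removal at 1 h
in NER-proficient cells, and high (~three quarters) recombinational repair
at 3 h in NER-deficient cells given a homologous donor.

| parameter | default | unit | meaning |
|---|---|---|---|
| `k63_rate` | 1.8 | /h | initial K63 polyubiquitination |
| `k48_rate` | 3.0 | /h | K48 chain addition (NER-dependent) |
| `proteolysis_rate` | 3.0 | /h | proteasomal degradation of the tagged protein |
| `ner_excision_rate` | 1.0 | /h | excision + resynthesis past the peptide adduct |
| `hr_rate` | 0.6 | /h | donor search + recombinational repair |
| `b02_factor` | 0.25 | – | multiplies `hr_rate` under Rad51 inhibition |
| `mg132_factor` | 0.25 | – | multiplies `proteolysis_rate` under proteasome inhibition |
| `k341r_ub_factor` | 0.5 | – | multiplies both ubiquitination rates for the R341 variant |

Drug effects are multiplicative factors rather than hard zeros because the
observed endpoint effects are roughly two-fold reductions, not complete
blocks; with the defaults above, both B02 and MG132 produce ≈2.1–2.4-fold
endpoint reductions. The R341 factor of 0.5 encodes two-fold-lower
ubiquitination of the lysine-341-substituted protein and is applied to both
ubiquitination steps because the data do not localise the impairment to one
of them. All of these are user-settable per scenario.

A heterologous donor and no donor are behaviourally identical (both leave
the recombination branch closed); they are kept as distinct configuration
values so scenarios read like the experimental designs they mirror.

## Forward assay models (the synthetic-data generator)

Each replicate of a scenario is one fresh, independent pathway simulation
(default: Gillespie with 10,000 molecules; exact propagation available)
followed by independent measurement noise — mirroring experiments in which
each replicate is a separately transfected well carried through the whole
protocol. The only measurement noise is Gaussian Ct noise (default sd 0.15
cycles), independent across tubes; there are no replicate-level random
effects, plate effects, or per-amplicon efficiency offsets.

Threshold cycles follow the standard relation
`ct = ct_reference − log(abundance)/log(efficiency) + N(0, sd)`, truncated
below at one cycle. An analytically empty pool is represented by a
pseudo-abundance floor of 1e-9 relative units (a Ct offset of ≈ +30 cycles
at perfect efficiency — late nonspecific amplification) rather than a
censored "no Ct", keeping downstream arithmetic total; the floor is small
enough that it perturbs percent-scale estimates by well under 1e-6.

* **SSPE-qPCR** (strand repair). The sample splits into a reference tube
  (unit template) and a pre-amplified tube carrying
  `(1−f)·damaged_leak + gain·f`, where `f` is the repaired fraction. The
  default gain is 8 (= 2³), matching the 2³ normalisation inside the
  percent-undamaged estimator, even though 8 ideal linear rounds would
  yield 9 copies; the discrepancy is deliberately exposed as the `gain`
  parameter. The default `damaged_leak` of 1 means unrepaired templates
  pass through pre-amplification un-amplified but still amplify in the
  final qPCR; consequently the noise-free pipeline returns
  `percent_repair = 87.5·f` after baseline subtraction. With `leak = 0` it
  returns `100·f`. Both chemistries are supported; the nonzero-leak default
  was chosen because the estimator subtracts a t₀ baseline, which implies a
  nonzero floor to subtract.
* **KCl-SDS-qPCR** (protein removal). After restriction digestion decouples
  the lesion fragment (b) from an on-plasmid control fragment (c),
  crosslink-bearing fragments precipitate with probability `capture_prob`
  (default 0.98) and any fragment is lost nonspecifically with probability
  `nonspecific_loss` (default 0.02). PROTEOLYZED molecules do **not**
  precipitate by default (the residual peptide is treated as too small);
  this is a single switch (`proteolyzed_precipitates`).
* **IP-qPCR** (ubiquitination). The antibody predicate maps pan-ubiquitin
  and K63-selective antibodies to K63-chain-bearing states and the
  K48-selective antibody to K48-bearing states (a subset — K48 chains only
  exist on K63-tagged molecules here, so pan capture ≥ K48 capture for any
  distribution). Eluate abundances are `u·capture_efficiency +
  background_rate` (lesion fragment) and `background_rate` (control); a
  saved input aliquot carries unit abundance of both. PROTEOLYZED molecules
  are not captured by default (tags assumed degraded with the protein;
  switch `proteolyzed_retains_tags`).

Every scenario also emits a t = 0 sample of the untransfected input
substrate (all molecules NASCENT), which the estimators use as the t₀
baseline.

### Seeding

Seeds are mandatory; there is no implicit entropy. One master seed per run
is combined (via CRC-32 of a structured key) with
(scenario stream key, timepoint, replicate, assay) into independent
`numpy` child streams, so adding assays or replicates never perturbs
existing draws, and identical (scenario, seed) pairs are byte-identical.
Arms that differ only by a structurally inert switch (SPRTN genotype;
MG132 on the NER-independent arm) share a stream key (`seed_group`), i.e.
common random numbers: an inert toggle then reproduces the identical Ct
payload exactly, not merely in distribution.

## Estimators

* `ΔCt = Ct(reference) − Ct(pre-amplified)`;
  `percent_undamaged = 2^ΔCt / 2³ × 100`;
  `percent_repair = percent_undamaged(t) − percent_undamaged(t₀)`.
* `relative_abundance = efficiency^(Ct_c − Ct_b)` (lesion over control
  fragment).
* `percent_removal = (A_t − A_t₀) / (A_full − A_t₀) × 100`, the unique
  affine map sending the pre-transfection (fully crosslinked) supernatant
  ratio to 0% and a protein-free control ratio (`A_full`, default 1) to
  100%. No explicit removal formula is standard for this assay; this
  baseline-anchored rescaling is the package's definition, stated here
  prominently.
* `fold_enrichment = (eluate b/c) / (input b/c)`; input normalisation can
  be disabled to obtain the raw eluate ratio.

Estimates are never clamped to [0, 100]: noise legitimately pushes them
outside, and clamping would distort the replicate variance the t-tests use.
Estimation assumes perfect doubling (`efficiency = 2`) regardless of the
simulator's efficiency, so estimator bias under imperfect amplification can
be studied by decoupling the two. Baselines are taken from t = 0 rows when
present, with explicit parameter fallbacks; groups with a missing tube are
skipped with a logged warning, never imputed.

## Statistics

Per-condition summaries are mean ± SEM (sample sd / √n) over
whole-experiment replicates (default 3; 5 for the Rad51-inhibition panel).
Comparisons use Student's t-test with pooled (homoscedastic) variance:
one-tailed (alternative: transfected exceeds baseline) when a condition is
compared against the untransfected baseline, two-tailed when two
transfected conditions are compared; the report generator applies this rule
automatically. The one-tailed direction had to be fixed by us — "treated
exceeds baseline" matches the purpose of every such comparison in the
panel set. Zero pooled variance is handled explicitly (t = 0 → one-tailed
p = 0.5, two-tailed p = 1; unequal means → p floored at the smallest
positive float and flagged). Raw p-values are reported; a Holm adjustment
exists but is off by default. The implementation is checked against
`scipy.stats.ttest_ind` to 1e-9.

## Built-in panels

Ten panels mirror the experimental designs: HR rescue by a homologous donor
(SSPE, 3 h), its Rad51-dependence (±B02, 5 replicates), removal across
NER-proficient/deficient × donor (KCl-SDS, 1 h), pan-ubiquitin enrichment
across the same grid, K341 vs R341 removal in the NER and HR arms, ±MG132
in both arms, linkage-selective IPs in NER-proficient cells and in
NER-deficient cells ± homologous donor, an XPA-knockout removal control,
and the SPRTN no-op control.

## Problem sizes and numerics

Default problem sizes — 10,000 molecules per replicate, triplicates, the
11-point fraction grid, 20 seeds for the stochastic-recovery study, 100
datasets for the t-test cross-check — were chosen so the full suite and the
acceptance script each complete in seconds while keeping Monte-Carlo error
well inside the asserted bounds (TV < 0.02 needs ~10⁴ molecules; the ~4-point
recovery MAE is dominated by Ct noise, not molecule sampling). `expm`
round-off is clipped at zero and renormalised; generator rows must sum to
zero within 1e-12; probability vectors within 1e-9.

## What the synthetic data does and does not show

The generator emulates the statistical structure the estimators assume:
log-scale template-to-Ct mapping with Gaussian cycle noise, selective
capture with nonspecific background, and per-replicate biological
independence. It does not emulate transfection-efficiency variation,
HIRT-recovery losses, melt-curve artifacts, per-fragment amplification
differences, or partial ubiquitin occupancy during IP. Passing round-trip
tests therefore demonstrates that the estimators invert the assumed
measurement model and are robust to its noise — not that the model captures
every nuisance present in real qPCR data.

## Known limitations

* Because deubiquitination is unmodelled, HR intermediates stay
  K63-positive: at 1 h the homologous-donor arm shows K63 enrichment even
  though repair is proceeding. Real measurements found no K63 signal in
  exactly that arm, suggesting active chain removal during recombination —
  a mechanism outside this model's scope. The package's structural claims
  about K63 are therefore confined to the stall (heterologous-donor)
  condition.
* Rates are calibrated, not measured; absolute timecourses are
  illustrative. Contrasts between conditions (fold-changes, no-ops,
  orderings) are the meaningful outputs.
* Replication-coupled repair, transcription-coupled excision, and chromatin
  context are out of scope; the model speaks only to plasmid-borne lesions.
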