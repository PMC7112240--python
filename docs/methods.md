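# Methods

## Producibility inference (scope expansion)

An organism's metabolism is represented as a set of qualitative reactions
(id, EC, substrates, products, reversibility, route class). Reversible
reactions are split into two directed firings before inference. Given seed
compounds S, the *scope* is the least fixpoint of "a reaction whose
substrates are all available adds its products". The implementation scans
pending reactions until no firing adds a compound; the result is
iteration-order independent because the least fixpoint is unique, and the
test suite checks equality with a naive re-scan-until-stable brute force on
random networks.

Seeding a realistic medium alone deadlocks on currency metabolites (every
ATP-consuming reaction waits for ATP synthesis and vice versa), so a
configurable bootstrap set — water, ATP/ADP/AMP, NAD(P)(H), CoA, phosphate,
PPi, CO2, protons — is always added to the seeds. Stoichiometry is ignored:
the question is pathway completeness, not flux.

The verdict for nutrient X on medium M is computed with seeds = M \ {X}:

* `feasible` — X is reachable using primary-route reactions only (a primary
  witness always wins over a secondary one);
* `limited` — X is reachable, but every derivation includes at least one
  reaction flagged `route=secondary`. The flag is curated per reaction, not
  computed: "limited biosynthesis" encodes expert judgement about
  derivative/promiscuous catalysis, which no reachability computation can
  recover;
* `impossible` — X is unreachable; inorganic nutrients (metal ions) are
  `impossible` unconditionally.

A witness (the reaction ids of one derivation, obtained by backward-tracing
first-producer links) is attached to every positive verdict.

## Diet model

The complete FLYAA holidic diet is a component → (concentration, unit)
mapping with 39 droppable nutrients: 10 fly-essential amino acids, 10
fly-nonessential amino acids, 7 B-vitamins, 4 nucleic-acid/lipid precursors
(choline, inosine, myo-inositol, uridine), cholesterol, sucrose, and 6 metal
ions (Ca, Cu, Fe, Mg, Mn, Zn). Agar and the acetate buffer are carried but
never droppable — no Δagar/Δbuffer condition exists in the screen design,
and acetate doubles as a carbon source. The liquid variant (for plate-reader
growth) omits agar and cholesterol. Concentrations are recorded for
bookkeeping; producibility inference uses only the component set.
Concentration values in the packaged composition are representative of the
published recipe class (8 g/L total amino acids); they do not enter any
computed result.

## Growth screen summarization

OD600 series are blank-corrected by subtracting the t=0 reading when no
blank well exists (the reference protocol has none); negative corrected
readings are clipped to zero and counted. OD_Max is the series maximum;
per-condition summaries are arithmetic means over replicates. The verbal
categories of the screen are operationalized with two configurable
thresholds: a condition is `none` when mean OD_Max ≤ baseline + 0.05 OD and
`reduced` below 25% of the same organism/regime's complete-diet OD_Max;
otherwise `growth`. Agitated (96-well) and static (closed-tube) regimes are
kept separate: agitation oxygenates the medium and suppresses
*L. plantarum* growth in marginal conditions, which is exactly the
contradiction the discrepancy ledger flags as regime-dependent. CFU
endpoints are reported as log10(cfu/inoculum); zero counts are floored at
−log10(inoculum) and flagged censored.

## Developmental timing (D50)

Per replicate, the cumulative pupariation fraction — of the finally emerged
count, not of seeded eggs — is fitted with a two-parameter logistic CDF
1/(1 + exp(−(t − D50)/s)) by least squares (initialized at the linear
interpolation of the 50% crossing, D50 bounded to the observed event
window); the closed-form interpolation is the deterministic fallback when
the fit cannot converge, and a single-day cohort returns that day exactly.
Defining the denominator as emerged pupae keeps D50 defined for
delayed-but-developed conditions, which low-survival denominators would
destroy. Replicates with zero pupae are censored, never averaged.

Exclusion rules mirror the screen design: replicates with egg-to-pupa
survival < 25% (i.e. < 10 of 40 eggs) are dropped — larvae are cannibalistic
and sibling corpses become an uncontrolled nutrient source — and a condition
is "failed to develop" when the pre-exclusion mean survival of its
replicates is below 25%. The dropout classification is then: `essential`
(failed to develop), `limiting` (developed, Dunn p < 0.05 vs the complete
diet and slower), `dispensable` otherwise.

Group comparison is a Kruskal–Wallis test followed by Dunn's post hoc test
against the designated control: one joint ranking over all groups, tie
correction Σ(t³−t)/(12(N−1)), z = (R̄i − R̄j)/SE with
SE² = (N(N+1)/12 − C)(1/ni + 1/nj), two-sided normal p. The multiplicity
adjustment defaults to none (raw Dunn p-values) and accepts any
`statsmodels` method name. With 5-replicate groups the empirical type-I
error of the unadjusted comparison is within the binomial 95% CI of the
nominal 0.05 (checked by simulation in the test suite). Pearson's
product–moment correlation (with a zero-variance guard) serves the
bacterial-load vs D50 association analyses.

## Reconciliation

For every GF-essential nutrient and bacterium, the record (producibility
verdict, growth category, rescue outcome) is classified: S1 when the
bacterium can synthesize the nutrient (feasible *or* limited — a derivative
route still counts as synthesis) and rescues; EXC when it can synthesize
but does not rescue; S4 when a metal deficiency is rescued (metals are
never synthesizable, and S4 takes precedence over S3); S3 when an organic
nutrient is rescued without de novo synthesis; S2 otherwise. Rescue is read
from larval outcomes alone; the growth category never gates it, because a
bacterium may be sustained by the host (the Cys case). Headline counting is
per nutrient over the union of bacteria — a nutrient is S1 if *any rescuing*
bacterium synthesizes it — which is the convention under which the 19
compensations of 22 auxotrophies split 15/3/1. The discrepancy ledger lists
every (nutrient, organism) where prediction and observation disagree
(growth without predicted synthesis, predicted synthesis without growth,
agitated/static contradictions) with a free-text hypothesis slot.

## Packaged fixture

The categorical outcomes of the published screen (GF requirement per
nutrient, per-bacterium growth per dropout and regime, rescue per bacterium
and heat-killed control) are hand-transcribed data with a provenance string
per cell, guarded by a SHA-256 manifest — they are inputs, never computed.
Two cells (Asp, Ser requirements) are inferred rather than stated: they
appear in neither the essential nor the delayed enumerations, and the
22-auxotrophy total forces them to be dispensable; their provenance strings
say so. Heat-killed rescue cells are transcribed only where the outcome is
stated (Asn, biotin, folate develop; the rest of the essential set fails).

The per-organism reaction tables are curated *synthetic* toy networks built
for this package: compressed central metabolism (sucrose → glycolysis/PPP/
TCA handles) plus 1–3 step routes per nutrient, encoding each organism's
final verdict structurally — complete primary route, secondary-flagged
step, or a dead-ended intermediate. The Lp phenylalanine motif is encoded
for real: prephenate dehydratase (EC 4.2.1.51) absent, arogenate formed on
the tyrosine branch, and a secondary-route arogenate → Phe derivative
catalysis (EC 2.5.1.47). A test asserts that scope expansion over these
networks reproduces the transcribed verdict table cell-for-cell, but the
transcription, not the networks, feeds the headline reconciliation.

## Synthetic-data generators

* **Networks**: a random backbone over a 5-compound seed pool plus
  intermediates; each requested target is produced by exactly one
  bottleneck reaction whose substrates are drawn from the seed pool, so the
  planted verdict (bottleneck present / demoted to secondary / deleted) is
  the ground truth by construction and must be recovered in 100% of cases.
* **Growth curves**: logistic OD with configurable carrying capacity K
  (default 1.2 OD), rate 0.25 h⁻¹, lag 8 h, additive Gaussian noise
  σ = 0.01 OD, sampled every 30 min over 72 h.
* **Cohorts**: per replicate, survivors ~ Binomial(n_eggs = 40, survival);
  latent pupariation times are logistic(D50, scale) — logistic, not normal,
  so that recovery tests are self-consistent with the logistic-CDF
  estimator — and the observed day is ceil(t): a pupa scored on day k
  formed during (k−1, k], so the observed cumulative fraction at day k
  estimates the latent CDF at k and the estimator is unbiased by
  construction (rounding to the nearest day would inject a 0.5 d
  generator/estimator bias). Events past day 30 are censored, matching the
  screen's stopping rule. Defaults (40 eggs, 5 replicates, D50 8.4 d,
  scale 1 d) mirror the reference screen design.

What the generators deliberately do not emulate: plate-edge and evaporation
artifacts in OD curves, day-to-day scoring error in pupae counts,
between-replicate heterogeneity of survival, or any host–microbe feedback
(the generators are stage-local). Passing recovery tests therefore
demonstrates estimator correctness under the stated noise model, not
robustness to those real-data effects.

## Numerical and design choices

* D50 fit: `scipy.optimize.curve_fit`, p0 = (interpolated crossing, 1 d),
  bounds D50 ∈ [first, last event day], scale ∈ [1e−6, 50] d; any fit
  failure falls back to interpolation, so the estimator is total.
* Tie-break in producibility: primary witness preferred; a bootstrap-set
  nutrient would be trivially `feasible` (flagged `<bootstrap>` witness).
* Growth thresholds (0.05 OD margin, 25% of complete-diet OD_Max) and the
  survival cutoff (25%) and alpha (0.05) are configurable flags surfaced by
  the CLI; the defaults are the package's operationalization of the verbal
  screen categories.
* Test problem sizes (30 oracle networks, 50 planted-recovery networks,
  5 simulations per D50 grid cell, 1,000 simulations for the calibration
  checks) were chosen as the package's own balance between statistical
  resolution and suite runtime.

## Known limitations

* Producibility is qualitative reachability; it cannot express rate limits,
  regulation, or condition-dependent enzyme switches (e.g. aerobic/anaerobic
  succinate-dehydrogenase promiscuity) except through the curated
  `secondary` flag.
* The situation classification inherits the transcription's granularity:
  cells the published narrative does not state are marked missing rather
  than guessed, and per-replicate quantitative D50/OD source tables are not
  distributable with the package, so the quantitative complete-diet D50
  comparison runs only when a user supplies that file.
* Dunn's test uses the normal approximation; at very small group sizes an
  exact permutation procedure is preferable (the test suite enumerates
  permutations to validate the extreme case).
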