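# gnotodiet

Analysis pipeline for gnotobiotic nutritional screens of *Drosophila
melanogaster* larvae on chemically defined (holidic) diets.

Fly larvae reared germ-free (GF) on a holidic diet with one nutrient removed
(HDΔX) reveal the host's own auxotrophies: nutrients whose absence blocks
development. Mono-association with a fly-associated bacterium —
*Acetobacter pomorum* (Ap) or *Lactiplantibacillus plantarum* (Lp) — can
compensate some of those auxotrophies. `gnotodiet` links three layers of
evidence for every diet nutrient:

1. **genome-scale producibility** — can each organism synthesize the
   nutrient at all? Inferred by network *expansion* (scope) over a
   qualitative reaction network: starting from the medium components plus a
   bootstrap set of currency cofactors, a reaction fires when all of its
   substrates are available; the verdict for nutrient X is computed on the
   medium lacking X and is `feasible` (primary-metabolism route),
   `limited` (route requires a secondary/derivative catalysis), or
   `impossible`;
2. **bacterial growth** on each dropout medium — OD600 time series reduced
   to OD_Max and a categorical call (`growth` / `reduced` / `none`), plus
   CFU endpoints for static cultures;
3. **larval development** — daily pupariation counts per replicate reduced
   to D50, the day by which 50% of the finally emerged pupae have entered
   metamorphosis (cumulative-logistic fit with interpolation fallback),
   with replicate-level exclusion below 25% egg-to-pupa survival, and
   Kruskal–Wallis + Dunn post hoc comparisons against the complete diet.

The reconciliation stage joins the three layers and classifies every
compensated host auxotrophy:

| situation | meaning |
|---|---|
| S1 | the bacterium synthesizes the missing nutrient and rescues development |
| S2 | it neither synthesizes nor rescues |
| S3 | it cannot synthesize the nutrient de novo yet rescues (intermediate / derivative provision) |
| S4 | rescue of a mineral or trace-metal deficiency (concentration of contaminating traces) |
| EXC | it synthesizes the nutrient but does not rescue |

## Worked example

The package ships a hand-transcribed table of the published categorical
screen outcomes (39 dropout diets × {GF, Ap, Lp, heat-killed controls})
together with per-organism producibility verdicts. Running

```
gnotodiet reconcile
```

prints:

```
GF-essential nutrients: 22
- Ap rescues: 19
- Lp rescues: 12
- rescued by at least one bacterium: 19

| situation | nutrients (union convention) |
|---|---|
| S1 (15) | Arg, Asn, His, Ile, Leu, Lys, Met, Phe, Thr, Trp, Val, biotin, folate, riboflavin, thiamine |
| S2 (2) | Mg, cholesterol |
| S3 (3) | choline, nicotinate, pyridoxine |
| S4 (1) | Zn |
| EXC (1) | pantothenate |
```

Read: GF larvae show 22 auxotrophies on this diet; Ap fulfills 19 of them
and Lp 12; of the 19 compensations, 15 are explained by direct bacterial
synthesis (S1), 3 by provision of intermediates or functional analogues
(S3: choline, nicotinate, pyridoxine), and 1 is a trace-metal rescue (S4:
Zn). Pantothenate is the exception: Ap makes it for its own growth but the
larvae see none of it.

Other entry points: `gnotodiet expand` (producibility from the curated
networks — e.g. `--organism Lp --nutrient Phe` reports `limited`, via the
arogenate-derivative route that substitutes for the lost prephenate
dehydratase), `gnotodiet d50`, `gnotodiet screen-growth`,
`gnotodiet simulate` (synthetic cohorts/curves), and `gnotodiet run-all`,
which writes the full report bundle (summary TSVs, discrepancy ledger,
`headline.json`).

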