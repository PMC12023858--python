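# clonaltrace

**¹⁵N tracer mass balance and source partitioning in clonal plant
fragments, with a transcriptome candidate-gene screen.**

Fast-growing clonal plants such as Moso bamboo build a new offspring
ramet (the shoot) in weeks, fuelled by nitrogen it cannot yet absorb
itself. Two sources supply it: reserves translocated from the parent
ramet, and soil N taken up by the roots of the connecting rhizome.
`clonaltrace` quantifies that division of labour from dual ¹⁵N-labelling
experiments — one treatment injects tracer into the parent culm (PL),
the other labels the rhizosphere soil (RL) — and screens an organ × stage
expression panel for the transporter genes that move the N.

## What it computes

For each organ, stage and replicate, the standard isotope-dilution chain
(*b* = measured atom% ¹⁵N, *a* = control background, *c* = tracer
enrichment):

```
Ndff (%)           = 100 (b − a)/(c − a)
¹⁵N conc (mg kg⁻¹) = TN conc × Ndff × 10⁻²
¹⁵N content (g)    = ¹⁵N conc × biomass × 10⁻³
recovery (%)       = 100 Σ organs ¹⁵N content / applied ¹⁵N
```

On top of that: per-organ allocation shares of the dose (with the
unrecovered remainder as loss), the parent-vs-rhizome-root contribution
split for the offspring ramet
(`parent share = 100·PL/(PL+RL)` on dose-normalised offspring
recoveries), between-stage backflow (net withdrawal of previously
allocated label), Duncan's multiple range test with compact letter
displays, and a DEG → intersection → trait-correlation screening funnel
for candidate genes.

A compartmental label-flux simulator generates complete synthetic
experiments (3 treatments × 4 stages × 3 replicates) with exactly known
ground truth, which is how the pipeline is validated end to end.

## Worked example

Run the bundled synthetic scenario end to end:

```
clonaltrace run-all --seed 1 --out demo/
```

which finishes with

```
{
  "seed": 1,
  "config_hash": "ba0d419c587b",
  "labelled_15N_mg": 150.7,
  "outputs": [ "backflow.csv", "contribution_table.csv", "fate_panel.csv",
               "isotope_aggregated.csv", "isotope_results.csv",
               "measurements.csv", "screen_edges.csv",
               "trait_correlated_genes.csv" ]
}
```

`labelled_15N_mg` is the applied tracer mass per fragment: 10 ml of
doubly labelled ammonium nitrate solution at 50 mg N ml⁻¹ and 30.14 atom%
gives 150.7 mg of ¹⁵N. `demo/contribution_table.csv` holds the headline
result, the offspring ramet's N-supply split by growth stage:

```
stage,parent_share,rhizome_share
ES,73.61,26.39
PS,51.62,48.37
BS,50.37,49.63
LS,31.87,68.13
```

(values rounded here; the file carries full precision). Read: at the
early stage ~74% of the offspring's labelled N came via the parent ramet;
by the leafing stage the rhizome's own root uptake dominates (~68%) —
the simulator's planted truth is 70.0 / 50.2 / 49.9 / 33.6 and the noisy
3-replicate estimate recovers it to a few percentage points.
`backflow.csv` shows the late-stage reversal: under parent labelling,
part of the label previously allocated to the offspring is withdrawn
again between branching and leafing.

Each step is also available separately (`clonaltrace simulate | isotope |
partition | stats | screen | qpcr`); `clonaltrace isotope` accepts any
tidy measurement CSV with columns
`treatment,stage,organ,replicate,atom_pct_15N,tn_conc_mg_per_kg,biomass_kg`,
so real field data drop in where the simulator writes its tables.

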