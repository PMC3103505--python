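# tractnet

Structural brain-network construction, weighted graph metrics, and automated
group discrimination from diffusion-tensor tractography — built for
two-group rodent studies (e.g. healthy controls vs. dysmyelinated *shiverer*
mutants), and fully exercisable on synthetic data.

## What it does

Dysmyelinating disease degrades white-matter integrity; modeling the brain
as a weighted graph over gray-matter regions turns that degradation into
measurable topology. `tractnet` implements the whole chain:

1. **Tractography** — deterministic streamline tracking (FACT, tensorline
   TL, tensor-deflection TEND) on diffusion-tensor fields, with brute-force
   seeding at FA > 0.12, 25 µm steps, ±80° curvature and 200 mm length caps.
2. **Connectome construction** — an arc between regions *i*, *j* weighted by

       w(a_ij) = 1/(n_i+n_j) · Σ_{f ∈ F_ij} (1/N_f) Σ_steps 1/MD(step)

   the effective number of connecting fibers, each quantified by the mean
   inverse of its local mean diffusivity (an integrity index), normalized by
   the regions' surface voxel counts. `mean_fa` and pure `count` weighting
   are available as variants.
3. **Backbone extraction** — maximum spanning tree plus the strongest
   remaining edges until average node degree 4 (2n edges).
4. **Graph measures** — weighted clustering C (geometric triangle mean),
   characteristic path length L (arc length 1/w), modularity Q (Newman
   spectral optimization), global/local efficiency, and small-worldness
   σ = γ/λ against a degree-preserving, weight-shuffled null ensemble.
5. **Group statistics** — exact max-t permutation test across tracking
   variants (family-wise error controlled; all 924 relabelings enumerated
   for 6 vs 6).
6. **Classification** — each subject becomes a point in a per-measure
   "representation space" (one axis per tracking algorithm); leave-one-out
   LDA yields per-subject control posteriors, a mean boundary hyperplane,
   and a forward-selected combination of measures.

A first-class synthetic-data module generates reproducible two-group
cohorts (modular small-world base graph; the case group gets attenuated
weights and partially rewired topology) plus tensor phantoms with labeled
bundle end-caps, so every stage is testable without imaging data. See
`docs/methods.md` for models, assumptions and limitations.

## Worked example

```python
import tractnet as tn

cfg = tn.PipelineConfig(design=tn.GroupDesign(seed=42),
                        metric_seed=42, stat_seed=42)
summary = tn.run_pipeline(cfg)
print({m: round(p, 4) for m, p in summary["p_values"].items()})
print(summary["single_measure_accuracy"], summary["combined_accuracy"])
```

prints

```
{'C': 0.0022, 'L': 0.0022, 'Q': 0.0022, 'E_glob': 0.0022, 'E_loc': 0.0022, 'sigma': 0.3874}
{'C': 75.0, 'L': 100.0, 'Q': 100.0, 'E_glob': 100.0, 'E_loc': 100.0, 'sigma': 58.33} 100.0
```

Reading this: five of the six measures separate the groups at the exact
permutation floor (p = 2/924 ≈ 0.0022 — only the identity relabeling and
the full group swap reach the observed max |t|), while σ does not reach
significance in this cohort (its null-ensemble estimate is the noisiest of
the six measures; see the methods note). Leave-one-out LDA classifies all
12 subjects correctly from the best single measure (path length), so the
forward selection stops after one measure and the combined accuracy is
100%.

The same pipeline is scriptable from the shell:

```bash
tractnet simulate --seed 42 --out cohort/
tractnet metrics --input cohort/ --ensemble 20 --seed 42 --out metrics.csv
tractnet permtest --metrics metrics.csv --measure C --mode exact
tractnet classify --metrics metrics.csv --select forward
tractnet run-all --seed 42 --out results/
```

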