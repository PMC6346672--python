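# pbtgsi

Parentage-based tagging (PBT) + genetic stock identification (GSI) for
mixed-stock fishery analysis, with a synthetic-data generator providing
fully labelled test worlds.

The pipeline identifies individuals sampled from mixed-stock fisheries
in two stages: first by matching their genotypes against pooled hatchery
broodstock genotypes (pairwise-likelihood parentage assignment with a
posterior-probability acceptance rule), then — for everyone without an
accepted parent match — by a Bayesian conditional mixture model against
a multi-population allele-frequency baseline. Accepted parentage
assignments enter stock-composition estimates as probability-1
allocations; the rest contribute their Gibbs-sampled origins.
Downstream estimators cover seasonal sample weighting, hatchery-origin
catch, population-specific catch, coded-wire-tag expansion, escapement
hatchery components, exploitation rates and stray rates.

## Layout

| module | role |
| --- | --- |
| `pbtgsi.panel` | biallelic SNP panel description (analytic vs special loci) |
| `pbtgsi.genotype_io` | delimited genotype dialect, registries, QC filters |
| `pbtgsi.synthetic_data` | hierarchical F-model baselines, broodstocks, Mendelian offspring, mixtures, tagging programs |
| `pbtgsi.parentage` | pairwise-likelihood parentage engine with acceptance rules |
| `pbtgsi.gsi` | conditional mixture Gibbs sampler, roll-ups, self-assignment |
| `pbtgsi.combine` | PBT-first routing and combined composition estimates |
| `pbtgsi.fishery_estimation` | catch/escapement/exploitation/stray estimators |
| `pbtgsi.scenarios` | canned simulation studies used by the evaluation suite |
| `pbtgsi.cli` | `pbtgsi simulate / identify / estimate` subcommands |

## CLI

```bash
# generate a synthetic world (panel, registry, baseline, broodstock,
# mixture, truth labels) into simout/
pbtgsi simulate -c sim.yaml -o simout

# QC + parentage + GSI + routing; writes parentage.csv, assignments.csv
# and composition tables at population/CU/region level
pbtgsi identify -c identify.yaml -o identout

# fishery estimators from CSV metadata tables
pbtgsi estimate -c estimate.yaml -o estout
```

Minimal configs:

```yaml
# sim.yaml
sim: {n_loci: 302, n_cus: 4, pops_per_cu: 5, seed: 1}
n_mixture: 600
n_hatchery_pops: 8

# identify.yaml
inputs: simout
gsi: {burn_in: 25000, keep: 1000, seed: 1}
parentage: {error_rate: 0.01, accept_prob: 0.85}

# estimate.yaml
fishery_csv: fishery.csv        # fishery, month, catch, n_genotypes, clip_rate, sampling_rate
escapement_csv: escapement.csv  # population, escapement, clip_proportion[, catch]
cwt_csv: cwt.csv                # population, tag_code, count, loss_rate, mark_rate, sampling_rate
```

Every run writes a `manifest.json` (seed, config hash, outputs) so
seeded reruns are byte-identical. Exit codes: 0 success, 2 validation
error, 3 runtime error.

## Notes

* Genotypes are stored as dosages of each locus's second allele code;
  allele pairs are unordered. Missing is `-1` internally, empty/`0` on
  disk.
* The GSI sampler is conditional: baseline allele frequencies are fixed
  at their Dirichlet posterior means while the chain samples origins
  and mixture proportions. Default chain: 25,000 burn-in, 1,000 kept.
* Parentage treats parental genotypes as true and applies the
  genotyping-error model to the offspring observation only; candidate
  pairs are enumerated within population and brood year from a
  shortlist of the best single-parent matches.
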