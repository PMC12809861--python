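# twinace

Bivariate ACE liability-threshold modelling of twin/sibling cohorts, built for
identifying neurocognitive endophenotypes of categorical diagnoses.

A continuous cognitive measure and a binary diagnostic phenotype are analysed
jointly per pair as a 4-variate normal over (cognition₁, cognition₂,
liability₁, liability₂) by full-information maximum likelihood: each pair
contributes the density of its observed continuous values times the orthant
probability of its observed affection pattern under the conditional liability
distribution. The disease side (variance proportions h², c², e² of the
liability and the prevalence-derived threshold) is *fixed* at published
population values — the ascertainment correction for proband-selected samples —
while the cognitive ACE structure, the A/C/E cross-trait correlations
(r_g, r_c, r_e) and covariate effects (age, sex, education, centre) are free.

Main components:

| module | contents |
| --- | --- |
| `twinace.core_data` | pair-structured records, CSV I/O, IQ/age inclusion filters with exclusion log, covariate encoding |
| `twinace.bvn` | vectorised bivariate-normal rectangle probabilities (Genz/Drezner–Wesolowsky 20-point scheme) |
| `twinace.liability_model` | disease profiles, thresholds, kinship, expected pair covariance, FIML pair/dataset likelihood |
| `twinace.estimation` | multi-start ML fitting, standardized estimates, profile-likelihood CIs, likelihood-ratio tests, sub-models |
| `twinace.correlation_models` | constrained saturated correlation model with fixed liability cross-twin correlations |
| `twinace.decomposition` | r_ph = r_ph-a + r_ph-c + r_ph-e decomposition, genetic sharing (100·r_g²), the four endophenotype criteria |
| `twinace.synthetic_data` | cohort simulator with exact model structure, covariates, missingness, stratified (proband-selected) ascertainment |
| `twinace.pipeline` / `twinace.cli` | end-to-end analysis producing CSV report tables + run log |

Built-in disease profiles (`src/twinace/profiles.yaml`): `maudsley_sz`
(h²=0.84, K=0.75%), `maudsley_bd1` (h²=0.85, K=0.32%), `maudsley_broad`
(h²=0.90, K=1.7%), and the sensitivity set `polderman_sz` / `polderman_bd1`
(K=1%).

## CLI

```sh
# generate a proband-selected synthetic cohort
twinace simulate --seed 7 --out study.csv --n-mz 30000 --n-dz 30000 \
    --rg -0.4 --ascertain --n-concordant 30 --n-discordant 80 --n-control 150

# single fit / correlation model
twinace fit --input study.csv --measure iq --phenotype SZ --profile maudsley_sz
twinace correlations --input study.csv --measure iq --phenotype SZ

# full pipeline: filters -> constrained correlations -> phenotypic-correlation
# gate -> bivariate ACE fit -> decomposition -> endophenotype criteria
twinace pipeline --input study.csv --measure iq --phenotype SZ \
    --profile-set main --out reports/ --seed 7
```

The pipeline writes `correlations.csv`, `variance_components.csv`,
`decomposition.csv`, `endophenotypes.csv` and `run_log.json` (seeds, profiles,
log-likelihoods, gradient norms, per-cell errors). Reruns with the same input
and seed are byte-identical. A YAML file passed with `--config` overrides
flags.

Expected input CSV: one row per individual with columns `pair_id`,
`member_index` (1/2), `zygosity` (MZ/DZ/SIB), `affected_<phenotype>` (0/1 or
empty/NA), one column per cognitive measure, and `age`, `sex`, `education`,
`centre`. Missing cells stay missing — FIML needs no imputation.

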