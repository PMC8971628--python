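# famvar

Pedigree-based driver-variant analysis for familial disease studies.
Given a family (PED), multi-sample variants (VCF 4.2 plus an
ANNOVAR-style annotation table), CNV call sets, and per-member
brain-structure volume tables, the package provides:

- **core** — validated domain types (pedigree, annotated variant, CNV,
  volume table) and plain-text readers/writers for each format.
- **synth** — synthetic data generation with ground truth: a
  three-generation 17-member family template, Mendelian gene dropping,
  a planted heterozygous driver variant with configurable penetrance,
  background variants, null CNV call sets, and volume tables with a
  configurable group effect.
- **dmd** — differential mutation density landscapes per fixed
  chromosome window (affected minus healthy carrier fractions, summed
  per window with exact rational granularity), hotspot calling with
  merge-adjacent semantics, consensus CNV intersection (reciprocal
  overlap), and group-differential CNV screening.
- **segregation** — exact pedigree likelihoods for sporadic,
  shared-frailty, and Mendelian dominant/recessive trait models via
  batched Elston–Stewart-style factor elimination; AIC model comparison;
  per-variant Mendelian-consistency and co-segregation filters.
- **prioritize** — a four-stage rare-variant cascade (functional/
  differential extraction → co-segregation → population rarity →
  deleteriousness-prediction voting over a 13-predictor panel) with a
  ranked candidate report.
- **endophenotype** — per-structure volume comparisons: Student/Welch
  t-tests and label-randomization tests with automatic exact enumeration
  for small samples.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (worked
examples, oracle-equivalence, recovery and calibration checks). One
criterion — AD-model AIC preference in ≥95/100 simulated replicates —
is intentionally left failing: on a 17-member pedigree the dominant
model's attainable log-likelihood gain over the 1-parameter sporadic
model is smaller than the AIC parameter penalty for most replicates, so
the stated rate is not reachable (see the test docstring).

## CLI

```sh
famvar simulate --config config.json --out-dir fixtures/ --seed 1
famvar dmd --vcf fixtures/variants.vcf --anno fixtures/variants.annotation.tsv \
           --ped fixtures/family.ped --window 1000000 --threshold 20
famvar segregate --ped fixtures/family.ped --format tsv
famvar prioritize --vcf fixtures/variants.vcf \
                  --anno fixtures/variants.annotation.tsv \
                  --ped fixtures/family.ped
famvar endopheno --volumes fixtures/volumes.tsv --ped fixtures/family.ped \
                 --n-perm 10000 --seed 1
```

`simulate` accepts a JSON or YAML config mirroring
`famvar.synth.SimulationConfig` (template, background variant count,
driver allele frequency/penetrance, predictor damaging probabilities,
volume effect size, seed).

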