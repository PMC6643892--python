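# polyqtl

QTL detection in outcrossing autopolyploids (autotetraploid and
autohexaploid F1 populations), built around multipoint identity-by-descent
(IBD) probabilities estimated from SNP dosage data on a known phased
parental linkage map.

The package covers the full simulation-to-analysis loop:

* **`polyqtl.maps`** — phased parental map generation (even or clustered
  marker coverage, founder-haplotype pools) and marker segregation-type
  algebra: canonical dosage-pair conversion (e.g. 1x4 → 1x0) and
  enumeration of the 9 (tetraploid) / 19 (hexaploid) fundamental types.
* **`polyqtl.meiosis`** — polysomic meiosis simulation with random
  bivalent pairing or ring multivalents (rate `q`), Haldane crossovers, and
  double reduction whose rate is zero at the centromere and rises distally.
  Truth records (chromatid mosaics) are kept for every gamete; offspring
  are genotyped with configurable dosage error and missingness.
* **`polyqtl.ibd`** — ancestry HMM over the 36 (bivalent-only, "noDR") or
  100 (double-reduction-aware, "DR") tetraploid ancestry classes
  (400 / 3136 in hexaploids): forward-backward posteriors, haplotypic
  (per-homolog) probabilities, and smoothing-spline interpolation onto a
  1 cM grid.
* **`polyqtl.gic`** — per-homolog genotypic information coefficient
  GIC = 1 − (4/N) Σ π(1−π), with high/low classification of the homologs
  carrying QTL alleles.
* **`polyqtl.scan`** — IBD-weighted regression QTL scan (homolog main
  effects, collinear terms dropped), LOD = (N/2)·log10(RSS0/RSS1),
  permutation thresholds, LOD-1/LOD-2 support intervals, single-marker
  ANOVA baseline and per-homolog allele effects.
* **`polyqtl.models`** — BIC-based diagnosis of the QTL configuration
  (phase) and mode of action: weighted genotype-class means at a peak are
  fitted against all 224 identifiable bi-allelic additive / simplex-dominant
  tetraploid configurations.
* **`polyqtl.power`** — factorial power/precision study engine
  (multivalent rate × population size × heritability × QTL type × gene
  action × model), with pooled permutation thresholds, detection and
  precision metrics, and GIC-category power tables.

## Tests

```sh
python -m pytest -q
```

The suite (~2 min) includes unit tests per module, property-based tests
(hypothesis), and `tests/test_acceptance.py`, which re-derives the headline
combinatorial identities and re-runs scaled-down simulation studies
against independent oracles (exhaustive-path HMM marginals, expanded
weighted-least-squares fits, closed-form GIC values).

## CLI

A `polyqtl` console script chains the pipeline on TSV inputs:

```sh
polyqtl simulate-map --ploidy 4 --n-markers 100 --length-cm 100 --seed 1 --out map.tsv
polyqtl simulate-pop --map map.tsv --n 200 --q 0.2 --seed 2 --out-prefix pop
polyqtl genotype     --map map.tsv --truth pop.truth.tsv --eps 0.001 --out dosages.tsv
polyqtl ibd          --map map.tsv --dosages dosages.tsv --model DR --q 0.2 --out ibd.tsv
polyqtl gic          --map map.tsv --dosages dosages.tsv --out gic.tsv
polyqtl scan         --map map.tsv --dosages dosages.tsv --pheno pheno.tsv \
                     --permutations 1000 --alpha 0.05 --seed 3 --out-prefix scan
polyqtl select-model --map map.tsv --dosages dosages.tsv --pheno pheno.tsv \
                     --position 40.0 --out models.tsv
polyqtl power-study  --config study.yaml --out results/
```

`study.yaml` mirrors the factor-grid field names used throughout
(`q`, `Pop`, `h2`, `QTLseg`, `QTLact`, `QTLpos`, `model`, replication and
seed); see `polyqtl.power.StudyConfig`.

## File formats

All I/O is plain text: phased maps
(`marker chrom position_cM h1 … h8`), truth segments
(`individual parent chromatid start_cM end_cM homolog`), dosage matrices
(markers × individuals, `NA` missing), long-format IBD probabilities with a
state-definition table, GIC tracks, LOD profiles, and JSON scan summaries.
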