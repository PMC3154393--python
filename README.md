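# phosphosat

Saturation, richness, enrichment-bias and cross-species conservation
analysis of phosphoproteomics datasets.

High-throughput MS phosphoproteomics never sees a complete phosphoproteome:
every repeat of an experiment finds sites the previous runs missed, and the
phosphopeptide enrichment chemistry (anti-phosphotyrosine antibodies, TiO2
affinity, IMAC) selects its own slice of what is there.  Comparative
analyses — between conditions, techniques or species — therefore confound
real biological differences with missing data and technique bias.
`phosphosat` implements the bioinformatics toolkit for quantifying exactly
that, for anyone comparing phosphosite datasets:

* **Saturation / rarefaction** (`phosphosat.saturation`).  Pool one copy of a
  site per source (replicate or publication) that reports it, draw without
  replacement, and plot fraction drawn against fraction of unique sites seen.
  A curve on the diagonal means no site was seen twice; bending above it
  means approaching saturation.  Includes exact subset-union curves over
  technical replicates, tail novelty (how much the last 10 % of draws still
  adds) and a matched-draw randomization comparison between two pools.
* **Richness estimation** (`phosphosat.richness`).  Chao1,
  `S_obs + f1^2 / (2 f2)` with the bias-corrected fallback at `f2 = 0`,
  treating per-site source multiplicity as species abundance — plus the
  jackknife consistency diagnostic: if subsampling the observations
  systematically lowers the estimate, the estimator's homogeneous-detection
  assumption does not hold for the data.
* **Enrichment bias** (`phosphosat.bias`).  Flanking amino-acid composition
  (±5 residues, central residue excluded), a label-shuffling randomization
  test with Bonferroni correction for composition differences between
  enrichment strategies, the common-reference overlap correction factor
  `frac_a / frac_b`, and Fisher-exact term (e.g. GOslim) over-representation
  with Benjamini–Hochberg control.
* **Cross-species conservation** (`phosphosat.conservation`).  Map each
  query phosphosite through ortholog pairings and pairwise alignments; a
  site is conserved when its alignment column carries a phosphosite in the
  target species.  Includes Fisher enrichment of protein categories (e.g.
  kinases) in the conserved fraction, and a built-in global aligner for
  self-contained use.
* **Synthetic data with ground truth** (`phosphosat.synthetic`).  Generates
  proteomes, phosphoproteomes with controllable detection-weight
  heterogeneity, enrichment-biased experiments, and diverged ortholog pairs
  with a known site-conservation rate — so every analysis above can be
  validated against a known answer.

## A worked example

Simulate a phosphoproteome whose sites differ strongly in detectability
(log-normal detection weights, dispersion 2), measure it six times, and ask
how complete the dataset is:

```python
import numpy as np
from phosphosat import (
    EnrichmentProfile, SiteDataset, chao1, generate_phosphoproteome,
    generate_proteome, jackknife_consistency, pooled_rarefaction,
    simulate_experiment, tail_novelty,
)

rng = np.random.default_rng(0)
proteome = generate_proteome(n_proteins=60, mean_length=300, seed=rng)
truth = generate_phosphoproteome(proteome, site_fraction=0.18,
                                 weight_dispersion=2.0, seed=rng)
print(f"true phosphosites: {len(truth.true_sites)}")

obs = []
for r in range(6):
    exp = simulate_experiment(truth, EnrichmentProfile.neutral(depth=200),
                              f"rep{r}", seed=rng)
    obs.extend(exp.observations)
pooled = SiteDataset(obs)
print(f"pooled: {pooled.pool_size} observations of {pooled.n_unique} unique sites")

est = chao1(pooled)
print(f"Chao1: S_obs={est.s_obs} f1={est.f1} f2={est.f2} "
      f"estimate={est.estimate:.1f} ({est.variant})")

half_mean, half_sd, _ = jackknife_consistency(pooled, fraction=0.5,
                                              n_repeats=100, seed=rng)
print(f"half-data jackknife: {half_mean:.1f} +/- {half_sd:.1f}")

curve = pooled_rarefaction(pooled, n_repeats=100, seed=rng)
percent, new = tail_novelty(curve, tail_fraction=0.10)
print(f"final 10% of draws adds {percent:.1f}% ({new:.1f} sites)")
```

Output:

```
true phosphosites: 575
pooled: 492 observations of 229 unique sites
Chao1: S_obs=229 f1=119 f2=46 estimate=382.9 (classic)
half-data jackknife: 304.6 +/- 41.3
final 10% of draws adds 5.9% (12.8 sites)
```

Reading this: six experiments saw 229 of the 575 real sites, and the tail of
the rarefaction curve is still rising (+5.9 %), so sampling is far from
saturated.  Chao1 extrapolates to 383 sites — a substantial undercount,
because detection here is strongly heterogeneous, violating the estimator's
assumption.  The jackknife makes that violation visible without knowing the
truth: recomputing on half the observations drops the estimate from 383 to
~305, the signature of an estimator that keeps growing with sampling effort
rather than converging.

## Command line

Every analysis is also a subcommand of the `phosphosat` entry point, with
`--seed` for reproducibility; runs write TSV/JSON outputs plus a
`manifest.json` (parameters, seed, input checksums, version):

```sh
phosphosat simulate --seed 7 --out sim/
phosphosat richness chao --input sim/experiment_rep1.tsv --jackknife 0.5 --out out/
phosphosat saturate pool --input sim/experiment_rep1.tsv --seed 1 --out out/
phosphosat bias compare --a tio2.tsv --b antiyp.tsv --fasta proteome.fasta --out out/
phosphosat conserve map --query sim/truth_sites.tsv --target sim/target_truth_sites.tsv \
    --orthologs sim/orthologs.tsv --alignments sim/alignments --out out/
```

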