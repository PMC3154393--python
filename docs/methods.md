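# Methods

This note documents the statistical procedures implemented in `phosphosat`,
their assumptions, the defaults that matter, and the design choices made
where more than one reasonable convention exists.

## Data model

A *phosphosite* is identified by `(protein_id, position, residue)`, with
1-based positions on the ungapped protein sequence and residue ∈ {S, T, Y}.
An *observation* is a site reported by one *source* — a technical replicate
or a publication.  A `SiteDataset` deduplicates to at most one observation
per (site, source) pair: replicate site lists and publication site lists
record presence, not within-source recurrence.  The *multiplicity* of a site
(number of distinct sources reporting it) is the abundance used by all
saturation and richness machinery; the *pool* of a dataset contains one copy
of each site per source reporting it, so `pool_size = Σ multiplicity`.

Sites validated against a proteome must match the sequence letter at their
position.  The default on mismatch is a hard error rather than silent
dropping — mapping discrepancies change downstream counts, so they are
surfaced; an explicit lenient mode drops and logs.

## Saturation and rarefaction

`replicate_saturation` enumerates every k-subset of R replicate site sets
(R ≤ 20) and records union cardinalities exactly; with four replicates the
value counts per k are 4, 6, 4, 1.

`pooled_rarefaction` permutes the multiplicity-weighted pool uniformly at
random (drawing without replacement until exhaustion — the x-axis reaches 1)
and records unique sites discovered after each draw, averaged over
`n_repeats = 100` permutations.  Averaging is over full permutations, not
independent subsamples per grid point.  Curves are evaluated on a grid of
~100 draw counts (every draw for pools of ≤ 100 observations) to keep large
pools tractable.  The mean curve has the closed form
`E[U(k)] = U − Σ_s C(N − m_s, k) / C(N, k)`, which the tests use as an
independent oracle on small pools.  When every multiplicity is 1 the curve
is the diagonal exactly, for every repeat.

`tail_novelty` reports `100 · (U(1) − U(1 − t)) / U(1 − t)` for tail
fraction `t` (default 0.10).  Given a precomputed curve it interpolates
linearly between grid points; given a dataset it evaluates the two relevant
draw counts exactly.

`matched_unique_comparison` draws `n_draws` observations without
replacement from each of two pools, `n_trials = 1000` times, and reports
mean unique counts and an add-one one-sided p-value: the estimated
probability that the comparison pool yields as few unique sites as the
focal pool's mean.  This p-value is designed to detect a saturation
*difference*; under exact equality of pools it concentrates near 0.5 rather
than being uniform (the comparison is against a mean, not an exchangeable
statistic), so it is conservative as a null test — a property to keep in
mind when interpreting non-significant results.

## Chao1 richness and the jackknife diagnostic

With `S_obs` observed sites, `f1` singletons and `f2` doubletons:

    classic:         S = S_obs + f1² / (2 f2)        (f2 > 0)
    bias-corrected:  S = S_obs + f1 (f1 − 1) / (2 (f2 + 1))   (f2 = 0)

The variant used is recorded in the result.  Chao1 assumes homogeneous
per-site detection probability and is a lower bound on true richness.  On
synthetic data with equal detection weights and mean multiplicity ≥ 2 it
recovers the true site count within a few percent (the acceptance suite
measures ~2 % mean error over 50 seeds at ~500 true sites, six simulated
replicates of 250 draws each).

`jackknife_consistency` subsamples `⌊fraction · pool_size⌋` *observations*
(pool entries) without replacement — subsampling unique sites instead would
destroy the abundance distribution the estimator needs — and recomputes
Chao1, 100 times by default.  Under homogeneous detection, subsample means
sit close to the full-data estimate (mildly above it at small fractions,
converging from above as the fraction grows).  Under heterogeneous
detection (log-normal weights, dispersion ≥ ~1) the subsample mean climbs
monotonically with fraction and stays well below the full-data estimate,
which itself badly undercounts the truth: the estimate grows with sampling
effort instead of converging.  That pattern — half-data mean below the
full-data estimate, both far below truth — is the operational signature
that the estimator's assumptions fail for phosphoproteomics abundance data.

## Enrichment-bias quantification

**Flank composition.**  Amino acids are counted in the ±5-residue window
around each site (10 flanking residues), truncated at protein termini, with
the central phosphorylated residue always excluded.  Prevalences are
percentages of the pooled flank counts — one number per residue per site
group, not per-site means.

**Randomization test.**  The statistic per residue letter is the absolute
difference in pooled prevalence between the two groups (two-sided, since
both enrichments and depletions are of interest).  The null is built by
randomly reassigning sites to groups with group sizes fixed,
`n_permutations = 10000` by default, and the add-one estimate
`p = (1 + #{perm ≥ obs}) / (1 + n_perm)` avoids zero p-values.  Bonferroni
correction multiplies by the number of residue letters actually observed in
the pooled flanks (≤ 20).  Implementation details: the pooled site rows are
brought into a canonical order and permutations always select the smaller
group size (the statistic is complement-symmetric), which makes the
Monte-Carlo p-value at a fixed seed invariant to swapping the two groups.
Calibration caveat: when all sites carry a full 10-residue flank the
statistic lives on a lattice with spacing `100·2/(10·G)` for group size G,
and at small G (~50) the attainable p-values are so coarse that the test is
conservative in the extreme tail.  At the group sizes real enrichment
comparisons involve (hundreds of sites), the lattice is fine and the
measured type-I error is at its nominal level (0.043–0.05 at α = 0.05,
G = 300, over 1000 null runs).

**Common-reference correction.**  `frac_x` is the fraction of dataset x's
unique sites present in a shared reference dataset; the correction factor is
`frac_a / frac_b`.  Multiplying an observed cross-technique overlap by this
factor estimates the overlap had both experiments used technique a.  All
site collections must already live on one proteome identifier space;
cross-database identifier reconciliation is the caller's responsibility.

**Term enrichment.**  Per term, a one-sided Fisher exact test on the 2×2
table (phosphoprotein × term membership within the proteome); fold change
is `log2(k/n) − log2(K/N)`; Benjamini–Hochberg across terms.  Terms with no
annotated protein in the proteome are skipped with a log entry.

## Cross-species conservation

A query site is mapped through a pairwise alignment by locating the column
holding its ungapped query position; a target-row gap means no equivalent
residue exists; otherwise the target position is the count of target
non-gaps up to that column, and the site is *conserved* iff that (protein,
position) carries a phosphosite in the target dataset.  By default any
phosphosite at the aligned position counts regardless of S/T/Y identity
(a phosphorylation event, not a specific residue, is what is conserved);
`strict_residue=True` additionally requires residue identity.

Many-to-many ortholog pairings are allowed; a site is mapped through every
listed ortholog and counts as conserved if any mapping succeeds.  The
conservation fraction's denominator is *all* query sites, including those
with no ortholog or no alignment — this is what a comparative analysis of
two real datasets observes.  Category enrichment (e.g. kinases among
conserved sites) is a one-sided Fisher exact test on the site-level 2×2
table; degenerate margins return p = 1 with a warning.

The built-in `align_pair` is Biopython's global Needleman–Wunsch with
BLOSUM62 and affine gap penalties (open 10, extend 1), taking the first
optimal traceback deterministically.  It exists so conservation analyses
are self-contained on small inputs; externally produced alignments take
precedence when supplied.

## Synthetic data generator

The generator emulates the dataset-level consequences of a phosphoproteomics
workflow, with known ground truth:

* `generate_proteome`: i.i.d. sequences from vertebrate-like background
  amino-acid frequencies; lengths geometric around the mean with a floor of
  20 residues.
* `generate_phosphoproteome`: a uniform `site_fraction` of all S/T/Y
  positions becomes true sites (the limiting case 1.0 is the pervasive-
  phosphorylation scenario); detection weights are i.i.d. log-normal with
  log-sd `weight_dispersion` — 0 gives the homogeneous regime in which
  Chao1 is well-behaved, values ≥ 1 give the heterogeneous regime that
  reproduces its failure.  Log-normal weights are the minimal heterogeneity
  model with a single dispersion knob, standing in for protein abundance
  and phosphorylation stoichiometry jointly.
* `simulate_experiment`: `depth` draws with per-site probability ∝
  detection weight × residue selectivity × exp(Σ flank log-bias),
  deduplicated to one observation per site per source, so `depth` directly
  controls saturation.  Built-in profiles: `neutral`, `anti_py` (tyrosine
  only, emulating anti-phosphotyrosine immunoaffinity) and `tio2_like`
  (log-weight `acidic_bonus = 1.0` per flanking D/E).  The default bonus
  was set so sampled sites show a ~1.6–1.9× excess of acidic flank residues
  over an unbiased sample, the magnitude seen when TiO2-enriched and
  antibody-enriched phosphotyrosine data are compared.  An optional
  `false_site_rate` replaces draws with spurious non-true acceptor sites,
  for exploring how identification error inflates apparent novelty; it has
  no calibrated default.
* `generate_ortholog_pair`: copies each protein with i.i.d. point
  substitutions and short (1–3 residue) indels; each true site is conserved
  with probability `conservation_prob`, in which case its column is
  protected from substitution and deletion and the aligned target position
  becomes a target-species phosphosite.  The true alignment is emitted by
  construction, so generator→analyzer round-trips are exact and do not
  depend on aligner quality.

What the generator does **not** model: peptide-level effects (digestion,
missed cleavages, peptide detectability), spectra and identification error,
correlated detection between nearby sites, isoforms, and real phylogenetic
substitution processes.  Passing round-trip tests therefore demonstrates
the correctness of the analysis machinery under the stated sampling model,
not the behaviour of any particular instrument pipeline on real data.

## Numerical conventions

* All randomness flows through `numpy.random.Generator`; every stochastic
  function accepts a seed or generator and is bit-reproducible per seed.
* Permutation/randomization p-values use the add-one estimator; ties count
  as exceedances (`≥` with a 1e-12 tolerance).
* Rarefaction curves store fractions; interior evaluation interpolates
  linearly between grid points.
* Degenerate inputs fail loudly: empty datasets, zero-overlap correction
  denominators, unselectable enrichment profiles and out-of-range sites all
  raise, rather than returning NaN.

## Problem sizes used in validation

The test and acceptance runs use synthetic studies of ~40–150 proteins of
mean length 300–400 (≈500–2000 true sites), six replicates of 200–250
draws for richness work, group sizes of 300 sites for composition testing,
and 200 null runs of 199 permutations for calibration.  These sizes put
every check in the regime the statistics are designed for while keeping a
full validation run in well under a minute of compute.

## Known limitations

* Chao1 is the only richness estimator provided; no ACE or coverage-based
  extrapolation, and deliberately no parametric fitting or extrapolation of
  saturation curves (the choice of functional form would dominate the
  answer).
* The matched-draw comparison p-value is conservative under the null (see
  above).
* The permutation test is conservative for very small site groups on
  full-length flanks, a discreteness property of the statistic itself.
* Reference-overlap correction assumes both datasets and the reference are
  expressed on a common proteome; no isoform/position harmonisation is
  attempted.
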