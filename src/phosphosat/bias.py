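"""Quantifying phosphopeptide enrichment-strategy bias.

Different phosphopeptide purification chemistries (anti-phosphotyrosine
immunoaffinity, TiO2 affinity, IMAC) select overlapping but distinct slices
of a phosphoproteome.  Two complementary quantifications are provided:

* **Flank composition** — amino-acid prevalence in the +/-5-residue window
  around phosphosites, compared between two strategies with a label-shuffling
  randomization test (TiO2-selected peptides, for instance, are visibly
  enriched in the acidic residues D and E).
* **Common-reference correction** — the ratio of two datasets' fractional
  overlaps with a shared benchmark dataset estimates how much overlap is
  lost purely to technique, and serves as a multiplicative correction when
  comparing datasets across techniques.

Also included: Fisher-exact term (e.g. GOslim) over-representation of the
phosphoproteome relative to the proteome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .io import AMINO_ACIDS, AnnotationTable, PhosphoSite, Proteome, SiteDataset

logger = logging.getLogger(__name__)

__all__ = [
    "FlankProfile",
    "CompositionTest",
    "CorrectionResult",
    "TermEnrichment",
    "flank_composition",
    "composition_randomization_test",
    "common_reference_correction",
    "term_enrichment",
]

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class FlankProfile:
    """Amino-acid counts and prevalences in phosphosite flanking windows.

    The central phosphorylated residue is excluded from the counts.
    """

    counts: dict[str, int]
    total: int

    @property
    def prevalence(self) -> dict[str, float]:
        """Percent prevalence per residue letter (sums to 100)."""
        if self.total == 0:
            return {aa: 0.0 for aa in self.counts}
        return {aa: 100.0 * c / self.total for aa, c in self.counts.items()}


@dataclass
class CompositionTest:
    """Per-residue comparison of flank composition between two site groups."""

    residues: list[str]
    prevalence_a: dict[str, float]
    prevalence_b: dict[str, float]
    abs_difference: dict[str, float]
    p_raw: dict[str, float]
    p_adjusted: dict[str, float]  # Bonferroni over residues tested
    n_permutations: int
    alpha: float

    @property
    def significant(self) -> list[str]:
        return [r for r in self.residues if self.p_adjusted[r] < self.alpha]

    def to_rows(self) -> list[tuple[str, float, float, float, float]]:
        """(residue, prevalence_a, prevalence_b, p_raw, p_adjusted) rows."""
        return [
            (r, self.prevalence_a[r], self.prevalence_b[r], self.p_raw[r], self.p_adjusted[r])
            for r in self.residues
        ]


@dataclass
class CorrectionResult:
    """Common-reference overlap correction between two datasets.

    ``factor = frac_a / frac_b`` where ``frac_x`` is the fraction of
    dataset x's unique sites present in the reference.  Multiplying an
    observed cross-technique overlap by this factor estimates the overlap
    that would have been seen had both experiments used technique a.
    """

    n_a: int
    n_b: int
    n_reference: int
    overlap_a: int
    overlap_b: int
    frac_a: float
    frac_b: float
    factor: float


@dataclass
class TermEnrichment:
    """Per-term Fisher-exact over-representation in the phosphoproteome.

    Fold enrichment is log2(k/n) - log2(K/N): k of n phosphoproteins versus
    K of N proteome proteins annotated with the term.
    """

    terms: list[str]
    k: dict[str, int]
    n: int
    K: dict[str, int]
    N: int
    fold: dict[str, float]
    p: dict[str, float]
    p_adjusted: dict[str, float]  # Benjamini-Hochberg across terms

    def to_rows(self) -> list[tuple[str, int, int, float, float, float]]:
        return [
            (t, self.k[t], self.K[t], self.fold[t], self.p[t], self.p_adjusted[t])
            for t in self.terms
        ]


def _flank_letters(site: PhosphoSite, proteome: Proteome, window: int) -> str:
    seq = proteome[site.protein_id]
    if not 1 <= site.position <= len(seq):
        raise IndexError(
            f"site {site.protein_id}:{site.position} outside sequence of length {len(seq)}"
        )
    i = site.position - 1
    return seq[max(0, i - window) : i] + seq[i + 1 : i + 1 + window]


def _flank_count_vector(site: PhosphoSite, proteome: Proteome, window: int) -> np.ndarray:
    v = np.zeros(len(AMINO_ACIDS), dtype=float)
    for aa in _flank_letters(site, proteome, window):
        idx = _AA_INDEX.get(aa)
        if idx is not None:
            v[idx] += 1
    return v


def flank_composition(
    sites: Iterable[PhosphoSite],
    proteome: Proteome,
    window: int = 5,
    lenient: bool = False,
) -> FlankProfile:
    """Pooled amino-acid composition of the +/-``window`` residues around sites.

    The window is truncated at protein termini and the central phosphorylated
    residue is never counted.  Sites that fall outside their protein raise an
    error unless ``lenient=True`` (skip with a log message).  Non-standard
    letters in the flanks are ignored.
    """
    counts = np.zeros(len(AMINO_ACIDS), dtype=int)
    skipped = 0
    for site in sites:
        try:
            counts += _flank_count_vector(site, proteome, window).astype(int)
        except (IndexError, KeyError):
            if not lenient:
                raise
            skipped += 1
    if skipped:
        logger.warning("skipped %d sites outside their protein sequences", skipped)
    return FlankProfile(
        counts={aa: int(counts[i]) for aa, i in _AA_INDEX.items()}, total=int(counts.sum())
    )


def composition_randomization_test(
    sites_a: Iterable[PhosphoSite],
    sites_b: Iterable[PhosphoSite],
    proteome: Proteome,
    window: int = 5,
    n_permutations: int = 10000,
    alpha: float = 0.01,
    seed: int | np.random.Generator | None = None,
) -> CompositionTest:
    """Randomization test for flank-composition differences between strategies.

    The statistic per residue is the absolute difference in pooled-flank
    percent prevalence between the two groups (two-sided: both enrichment
    and depletion count).  The null distribution is built by shuffling the
    site-to-group labels with group sizes fixed; p-values use the add-one
    estimate (1 + #{perm >= obs}) / (1 + n_permutations) and are Bonferroni
    corrected over the residue letters actually observed in the pooled
    flanks.
    """
    if n_permutations < 1:
        raise ValueError(f"n_permutations must be >= 1, got {n_permutations}")
    sites_a, sites_b = list(sites_a), list(sites_b)
    if not sites_a or not sites_b:
        raise ValueError("both site groups must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # canonical pooled row order, so the permutation stream (and hence the
    # Monte-Carlo p-value at a given seed) is invariant to swapping the groups
    vecs = np.vstack(
        [
            _flank_count_vector(s, proteome, window)
            for s in sorted(sites_a) + sorted(sites_b)
        ]
    )  # (n_sites, 20)
    n_a = len(sites_a)
    n_sites = vecs.shape[0]
    vecs_canon = vecs[np.lexsort(vecs.T[::-1])]

    def prevalences(matrix: np.ndarray) -> np.ndarray:
        totals = matrix.sum(axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, 100.0 * matrix / totals, 0.0)

    sum_all = vecs.sum(axis=0)
    obs_a = vecs[:n_a].sum(axis=0)
    obs_prev_a = prevalences(obs_a)
    obs_prev_b = prevalences(sum_all - obs_a)
    obs_stat = np.abs(obs_prev_a - obs_prev_b)

    # |prev(G) - prev(complement)| is the same for a subset and its
    # complement, so permutations always select the smaller group size
    k = min(n_a, n_sites - n_a)
    exceed = np.zeros(len(AMINO_ACIDS))
    chunk = max(1, min(n_permutations, 2_000_000 // max(1, n_sites)))
    done = 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        # each row of `order` is an independent permutation of the site labels
        order = np.argsort(rng.random((b, n_sites)), axis=1)
        group = vecs_canon[order[:, :k]].sum(axis=1)  # (b, 20)
        perm_stat = np.abs(prevalences(group) - prevalences(sum_all - group))
        exceed += np.sum(perm_stat >= obs_stat - 1e-12, axis=0)
        done += b

    tested = [aa for aa in AMINO_ACIDS if sum_all[_AA_INDEX[aa]] > 0]
    m = len(tested)
    p_raw, p_adj = {}, {}
    for aa in tested:
        i = _AA_INDEX[aa]
        p = (1.0 + exceed[i]) / (1.0 + n_permutations)
        p_raw[aa] = p
        p_adj[aa] = min(1.0, p * m)
    return CompositionTest(
        residues=tested,
        prevalence_a={aa: float(obs_prev_a[_AA_INDEX[aa]]) for aa in tested},
        prevalence_b={aa: float(obs_prev_b[_AA_INDEX[aa]]) for aa in tested},
        abs_difference={aa: float(obs_stat[_AA_INDEX[aa]]) for aa in tested},
        p_raw=p_raw,
        p_adjusted=p_adj,
        n_permutations=n_permutations,
        alpha=alpha,
    )


def common_reference_correction(
    dataset_a: SiteDataset | set[PhosphoSite],
    dataset_b: SiteDataset | set[PhosphoSite],
    reference: SiteDataset | set[PhosphoSite],
) -> CorrectionResult:
    """Technique-bias correction factor from overlaps with a common reference.

    All three site collections must live on the same proteome identifier
    space; reconciling identifiers across source databases is the caller's
    responsibility.
    """

    def as_set(x) -> set[PhosphoSite]:
        return x.unique_sites if isinstance(x, SiteDataset) else set(x)

    a, b, ref = as_set(dataset_a), as_set(dataset_b), as_set(reference)
    if not a or not b:
        raise ValueError("both datasets must contain at least one site")
    overlap_a, overlap_b = len(a & ref), len(b & ref)
    frac_a, frac_b = overlap_a / len(a), overlap_b / len(b)
    if frac_b == 0:
        raise ValueError("dataset b has no overlap with the reference; factor undefined")
    return CorrectionResult(
        n_a=len(a),
        n_b=len(b),
        n_reference=len(ref),
        overlap_a=overlap_a,
        overlap_b=overlap_b,
        frac_a=frac_a,
        frac_b=frac_b,
        factor=frac_a / frac_b,
    )


def term_enrichment(
    phospho_proteins: set[str],
    proteome_proteins: set[str],
    annotations: AnnotationTable | Mapping[str, set[str]],
) -> TermEnrichment:
    """Fisher-exact over-representation of annotation terms among phosphoproteins.

    For each term a one-sided (enrichment) Fisher exact test is run on the
    2x2 table of phosphoprotein membership versus term membership within the
    proteome; p-values are Benjamini-Hochberg corrected across terms.  Terms
    with no annotated protein in the proteome are skipped with a log entry.
    """
    if not phospho_proteins <= proteome_proteins:
        raise ValueError("phospho_proteins must be a subset of proteome_proteins")
    if isinstance(annotations, AnnotationTable):
        term_map = {t: annotations.proteins_of(t) for t in annotations.terms}
    else:
        term_map = {t: set(ps) for t, ps in annotations.items()}

    n, N = len(phospho_proteins), len(proteome_proteins)
    terms, k_d, K_d, fold_d, p_d = [], {}, {}, {}, {}
    for term in sorted(term_map):
        annotated = term_map[term] & proteome_proteins
        K = len(annotated)
        if K == 0:
            logger.warning("term %r has no annotated protein in the proteome; skipped", term)
            continue
        k = len(annotated & phospho_proteins)
        table = [[k, n - k], [K - k, N - n - (K - k)]]
        _, p = stats.fisher_exact(table, alternative="greater")
        fold = (
            math.log2(k / n) - math.log2(K / N) if k > 0 else float("-inf")
        )
        terms.append(term)
        k_d[term], K_d[term], fold_d[term], p_d[term] = k, K, fold, float(p)

    if terms:
        adj = stats.false_discovery_control([p_d[t] for t in terms], method="bh")
        p_adj = {t: float(q) for t, q in zip(terms, adj)}
    else:
        p_adj = {}
    return TermEnrichment(
        terms=terms, k=k_d, n=n, K=K_d, N=N, fold=fold_d, p=p_d, p_adjusted=p_adj
    )
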