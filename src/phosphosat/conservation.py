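"""Cross-species phosphosite conservation via orthologs and alignments.

A phosphosite in a query species is *conserved* when a pairwise alignment of
its protein with an orthologous protein from the target species puts the
phosphorylated residue in the same column as a residue that is itself
phosphorylated in the target dataset.  Sites without orthologs, without
alignments, or aligned to gaps stay in the denominator: the conservation
fraction is over *all* query sites, so it directly reflects what a
comparative analysis of two real datasets would see.

By default any phosphosite at the aligned target position counts, regardless
of whether it is the same residue type (S/T/Y); ``strict_residue=True``
additionally requires residue identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

from .io import AMINO_ACIDS, GAP, AlignedPair, OrthologTable, PhosphoSite, SiteDataset

logger = logging.getLogger(__name__)

__all__ = [
    "MappingStatus",
    "SiteMapping",
    "ConservationResult",
    "CategoryEnrichment",
    "align_pair",
    "map_site",
    "cross_species_overlap",
    "category_enrichment",
    "category_enrichment_from_counts",
]


class MappingStatus(str, Enum):
    NO_ORTHOLOG = "no_ortholog"
    NO_ALIGNMENT = "no_alignment"
    GAP_IN_TARGET = "gap_in_target"
    ALIGNED_NOT_PHOSPHORYLATED = "aligned_not_phosphorylated"
    CONSERVED = "conserved"


@dataclass
class SiteMapping:
    """Outcome of mapping one query site into the target species."""

    query_site: PhosphoSite
    target_protein: str | None
    target_position: int | None
    status: MappingStatus


@dataclass
class ConservationResult:
    """Per-site mappings plus aggregate conservation counts."""

    mappings: list[SiteMapping]
    n_query_sites: int
    n_conserved: int

    @property
    def fraction_conserved(self) -> float:
        return self.n_conserved / self.n_query_sites if self.n_query_sites else 0.0

    @property
    def conserved_sites(self) -> list[PhosphoSite]:
        return [m.query_site for m in self.mappings if m.status is MappingStatus.CONSERVED]

    def status_counts(self) -> dict[str, int]:
        out: dict[str, int] = {s.value: 0 for s in MappingStatus}
        for m in self.mappings:
            out[m.status.value] += 1
        return out


@dataclass
class CategoryEnrichment:
    """2x2 Fisher test: conserved vs not x in-category vs not, at site level."""

    table: list[list[int]]  # [[conserved&cat, conserved&not], [rest&cat, rest&not]]
    odds_ratio: float
    p_value: float


def align_pair(
    query_id: str,
    query_seq: str,
    target_id: str,
    target_seq: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> AlignedPair:
    """Global pairwise protein alignment (Needleman-Wunsch, affine gaps).

    Convenience aligner for tests and small inputs; externally produced
    alignments take precedence when supplied to :func:`cross_species_overlap`.
    Ties between optimal alignments are broken deterministically by taking
    the first optimal traceback.
    """
    for name, seq in ((query_id, query_seq), (target_id, target_seq)):
        if not seq:
            raise ValueError(f"empty sequence for {name!r}")
        bad = set(seq.upper()) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-amino-acid characters in {name!r}: {''.join(sorted(bad))}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    alignment = next(iter(aligner.align(query_seq.upper(), target_seq.upper())))
    return AlignedPair(query_id, target_id, str(alignment[0]), str(alignment[1]))


def _column_of_query_position(query_row: str, position: int) -> int:
    """0-based alignment column holding the 1-based ungapped query position."""
    seen = 0
    for col, ch in enumerate(query_row):
        if ch != GAP:
            seen += 1
            if seen == position:
                return col
    raise IndexError(
        f"position {position} exceeds ungapped query row length {seen}"
    )


def map_site(
    site: PhosphoSite,
    pair: AlignedPair,
    target_sites: set[PhosphoSite],
    strict_residue: bool = False,
) -> SiteMapping:
    """Map one query phosphosite through a pairwise alignment.

    Locates the alignment column carrying the site's ungapped query
    position; a gap in the target row means the site has no equivalent
    residue (``gap_in_target``), otherwise the target's ungapped position is
    the count of target non-gaps up to that column, and the site is
    conserved iff that (protein, position) carries a phosphosite in
    ``target_sites``.
    """
    if site.protein_id != pair.query_id:
        raise ValueError(
            f"site protein {site.protein_id!r} does not match alignment query {pair.query_id!r}"
        )
    col = _column_of_query_position(pair.query_row, site.position)
    if pair.target_row[col] == GAP:
        return SiteMapping(site, pair.target_id, None, MappingStatus.GAP_IN_TARGET)
    target_pos = sum(1 for ch in pair.target_row[: col + 1] if ch != GAP)
    hit = any(
        t.protein_id == pair.target_id
        and t.position == target_pos
        and (not strict_residue or t.residue == site.residue)
        for t in target_sites
    )
    status = MappingStatus.CONSERVED if hit else MappingStatus.ALIGNED_NOT_PHOSPHORYLATED
    return SiteMapping(site, pair.target_id, target_pos, status)


_STATUS_RANK = {
    MappingStatus.NO_ORTHOLOG: 0,
    MappingStatus.NO_ALIGNMENT: 1,
    MappingStatus.GAP_IN_TARGET: 2,
    MappingStatus.ALIGNED_NOT_PHOSPHORYLATED: 3,
    MappingStatus.CONSERVED: 4,
}


def cross_species_overlap(
    query_dataset: SiteDataset | set[PhosphoSite],
    target_dataset: SiteDataset | set[PhosphoSite],
    orthologs: OrthologTable,
    alignments: list[AlignedPair],
    strict_residue: bool = False,
) -> ConservationResult:
    """Map every unique query site into the target phosphoproteome.

    Many-to-many ortholog pairings are allowed: a site is mapped through
    every listed ortholog of its protein and called conserved if any mapping
    succeeds; the reported mapping is the most advanced one reached.  Sites
    whose protein has no ortholog, or whose ortholog pair has no alignment,
    count in the denominator of the conservation fraction.
    """
    query_sites = (
        query_dataset.unique_sites if isinstance(query_dataset, SiteDataset) else set(query_dataset)
    )
    target_sites = (
        target_dataset.unique_sites
        if isinstance(target_dataset, SiteDataset)
        else set(target_dataset)
    )
    aln_index: dict[tuple[str, str], AlignedPair] = {
        (p.query_id, p.target_id): p for p in alignments
    }
    mappings = []
    for site in sorted(query_sites):
        targets = orthologs.targets_of(site.protein_id)
        if not targets:
            mappings.append(SiteMapping(site, None, None, MappingStatus.NO_ORTHOLOG))
            continue
        best: SiteMapping | None = None
        for tid in targets:
            pair = aln_index.get((site.protein_id, tid))
            if pair is None:
                cand = SiteMapping(site, tid, None, MappingStatus.NO_ALIGNMENT)
            else:
                cand = map_site(site, pair, target_sites, strict_residue=strict_residue)
            if best is None or _STATUS_RANK[cand.status] > _STATUS_RANK[best.status]:
                best = cand
            if best.status is MappingStatus.CONSERVED:
                break
        mappings.append(best)
    n_conserved = sum(1 for m in mappings if m.status is MappingStatus.CONSERVED)
    return ConservationResult(
        mappings=mappings, n_query_sites=len(mappings), n_conserved=n_conserved
    )


def category_enrichment_from_counts(
    n_sites: int, n_conserved: int, n_category: int, n_category_conserved: int
) -> CategoryEnrichment:
    """Fisher enrichment of a protein category among conserved sites.

    Counts are at site level: of ``n_sites`` total sites ``n_category`` lie
    on category (e.g. kinase) proteins; of the ``n_conserved`` conserved
    sites ``n_category_conserved`` do.  One-sided test for over-representation
    of the category in the conserved fraction.
    """
    if not (
        0 <= n_category_conserved <= min(n_conserved, n_category)
        and n_conserved <= n_sites
        and n_category <= n_sites
    ):
        raise ValueError("inconsistent contingency counts")
    a = n_category_conserved
    b = n_conserved - a
    c = n_category - a
    d = (n_sites - n_conserved) - c
    table = [[a, b], [c, d]]
    if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
        logger.warning("degenerate contingency margins; p = 1")
        return CategoryEnrichment(table=table, odds_ratio=float("nan"), p_value=1.0)
    odds, p = stats.fisher_exact(table, alternative="greater")
    return CategoryEnrichment(table=table, odds_ratio=float(odds), p_value=float(p))


def category_enrichment(
    result: ConservationResult, category_proteins: set[str]
) -> CategoryEnrichment:
    """Fisher test of category over-representation in the conserved fraction."""
    in_cat = [m.query_site.protein_id in category_proteins for m in result.mappings]
    conserved = [m.status is MappingStatus.CONSERVED for m in result.mappings]
    return category_enrichment_from_counts(
        n_sites=len(result.mappings),
        n_conserved=sum(conserved),
        n_category=sum(in_cat),
        n_category_conserved=sum(1 for c, k in zip(conserved, in_cat) if c and k),
    )
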