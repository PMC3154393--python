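"""Domain types and readers/writers for phosphoproteomics site data.

The central object is the :class:`SiteDataset`: a multiset of phosphosite
observations, where each observation records *which source* (technical
replicate or publication) reported the site.  The number of distinct sources
reporting a site is its *multiplicity* — the abundance fed to all
saturation and richness analyses.

Coordinates are 1-based and inclusive on the ungapped protein sequence,
matching the convention used when phosphosites are reported in the
literature.  All conversions to 0-based indexing are internal.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Standard 20-letter amino-acid alphabet.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residues that can carry a phosphate group in this analysis.
PHOSPHO_RESIDUES = frozenset("STY")

GAP = "-"


class ValidationError(ValueError):
    """Raised when input data violates a domain invariant."""


@dataclass(frozen=True, order=True)
class PhosphoSite:
    """One phosphorylated residue on one protein.

    Identity is the triple (protein_id, position, residue); two observations
    of the same triple are observations of the same site.
    """

    protein_id: str
    position: int  # 1-based
    residue: str  # one of S, T, Y

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"site position must be >= 1, got {self.position} on {self.protein_id}"
            )
        if self.residue not in PHOSPHO_RESIDUES:
            raise ValidationError(
                f"residue must be one of S/T/Y, got {self.residue!r} "
                f"at {self.protein_id}:{self.position}"
            )


@dataclass(frozen=True)
class Observation:
    """A phosphosite reported by one source (replicate or publication)."""

    site: PhosphoSite
    source_id: str


class SiteDataset:
    """A multiset of phosphosite observations with source provenance.

    The dataset deduplicates to at most one observation per (site, source)
    pair: neither replicate site lists nor publication site lists count
    within-source recurrence.
    """

    def __init__(self, observations: Iterable[Observation]):
        seen: set[tuple[PhosphoSite, str]] = set()
        obs: list[Observation] = []
        dropped = 0
        for o in observations:
            key = (o.site, o.source_id)
            if key in seen:
                dropped += 1
                continue
            seen.add(key)
            obs.append(o)
        if dropped:
            logger.warning("collapsed %d duplicate (site, source) observations", dropped)
        self._observations = obs
        self._multiplicity = Counter(o.site for o in obs)

    @property
    def observations(self) -> list[Observation]:
        return list(self._observations)

    @property
    def unique_sites(self) -> set[PhosphoSite]:
        return set(self._multiplicity)

    @property
    def n_unique(self) -> int:
        return len(self._multiplicity)

    @property
    def pool_size(self) -> int:
        """Total observation count = sum of multiplicities."""
        return len(self._observations)

    def multiplicity(self, site: PhosphoSite) -> int:
        """Number of distinct sources reporting ``site``."""
        return self._multiplicity[site]

    def multiplicities(self) -> dict[PhosphoSite, int]:
        return dict(self._multiplicity)

    @property
    def source_ids(self) -> list[str]:
        return sorted({o.source_id for o in self._observations})

    def site_set(self, source_id: str) -> set[PhosphoSite]:
        """Unique sites reported by one source."""
        return {o.site for o in self._observations if o.source_id == source_id}

    def __len__(self) -> int:
        return self.pool_size

    def __iter__(self) -> Iterator[Observation]:
        return iter(self._observations)

    def __repr__(self) -> str:
        return (
            f"SiteDataset(pool_size={self.pool_size}, n_unique={self.n_unique}, "
            f"n_sources={len(self.source_ids)})"
        )

    @classmethod
    def from_multiplicities(
        cls, multiplicities: Mapping[PhosphoSite, int] | Iterable[tuple[PhosphoSite, int]]
    ) -> "SiteDataset":
        """Build a dataset from site -> multiplicity, inventing source labels."""
        items = multiplicities.items() if isinstance(multiplicities, Mapping) else multiplicities
        obs = []
        for site, m in items:
            if m < 1:
                raise ValidationError(f"multiplicity must be >= 1, got {m}")
            obs.extend(Observation(site, f"src{j}") for j in range(1, m + 1))
        return cls(obs)

    def validate_against(self, proteome: "Proteome", lenient: bool = False) -> "SiteDataset":
        """Check every site's residue letter against the proteome sequence.

        Returns a dataset containing only valid observations.  With
        ``lenient=False`` (the default) any mismatch is a hard error; with
        ``lenient=True`` mismatching observations are dropped and counted in
        a log message.  Mapping discrepancies silently change downstream
        counts, so they are surfaced rather than absorbed.
        """
        good, bad = [], []
        for o in self._observations:
            try:
                ok = proteome.residue_at(o.site.protein_id, o.site.position) == o.site.residue
            except KeyError:
                ok = False
            (good if ok else bad).append(o)
        if bad:
            if not lenient:
                s = bad[0].site
                raise ValidationError(
                    f"{len(bad)} observations disagree with the proteome "
                    f"(first: {s.protein_id}:{s.position}{s.residue})"
                )
            logger.warning("dropped %d observations disagreeing with the proteome", len(bad))
        return SiteDataset(good)


class Proteome:
    """Mapping protein_id -> amino-acid sequence (uppercase)."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for pid, seq in sequences.items():
            seq = seq.upper()
            if not seq:
                raise ValidationError(f"empty sequence for protein {pid!r}")
            unknown = set(seq) - set(AMINO_ACIDS)
            if unknown:
                logger.warning(
                    "protein %s contains non-standard letters: %s", pid, "".join(sorted(unknown))
                )
            self._seqs[pid] = seq

    def __getitem__(self, protein_id: str) -> str:
        return self._seqs[protein_id]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def items(self):
        return self._seqs.items()

    @property
    def protein_ids(self) -> list[str]:
        return list(self._seqs)

    def residue_at(self, protein_id: str, position: int) -> str:
        """Residue letter at a 1-based position; KeyError/IndexError on bad input."""
        seq = self._seqs[protein_id]
        if not 1 <= position <= len(seq):
            raise IndexError(f"position {position} outside protein {protein_id} (len {len(seq)})")
        return seq[position - 1]

    def phospho_acceptor_sites(self) -> list[PhosphoSite]:
        """All S/T/Y positions in the proteome, as candidate sites."""
        out = []
        for pid, seq in self._seqs.items():
            for i, aa in enumerate(seq, start=1):
                if aa in PHOSPHO_RESIDUES:
                    out.append(PhosphoSite(pid, i, aa))
        return out


@dataclass
class AlignedPair:
    """A pairwise alignment of a query and a target protein.

    Rows are equal-length strings over the amino-acid alphabet plus ``-``;
    removing gaps from a row reproduces the corresponding protein sequence.
    """

    query_id: str
    target_id: str
    query_row: str
    target_row: str

    def __post_init__(self) -> None:
        if len(self.query_row) != len(self.target_row):
            raise ValidationError(
                f"alignment rows for {self.query_id}/{self.target_id} have unequal "
                f"lengths {len(self.query_row)} and {len(self.target_row)}"
            )

    @property
    def query_seq(self) -> str:
        return self.query_row.replace(GAP, "")

    @property
    def target_seq(self) -> str:
        return self.target_row.replace(GAP, "")

    def swapped(self) -> "AlignedPair":
        return AlignedPair(self.target_id, self.query_id, self.target_row, self.query_row)


@dataclass
class OrthologTable:
    """Pairs (query_protein_id, target_protein_id), Inparanoid-style.

    Many-to-many pairings are allowed; duplicates are collapsed.
    """

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pairs = sorted(set(self.pairs))

    def targets_of(self, query_id: str) -> list[str]:
        return [t for q, t in self.pairs if q == query_id]

    def validate_against(self, query_proteome: Proteome, target_proteome: Proteome) -> None:
        for q, t in self.pairs:
            if q not in query_proteome:
                raise ValidationError(f"ortholog table references unknown query protein {q!r}")
            if t not in target_proteome:
                raise ValidationError(f"ortholog table references unknown target protein {t!r}")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class AnnotationTable:
    """Pairs (protein_id, term), e.g. kinase flags or GOslim terms."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for pid, term in self.pairs:
            if not pid or not term:
                raise ValidationError("annotation rows must have non-empty protein id and term")
        self.pairs = sorted(set(self.pairs))

    def proteins_of(self, term: str) -> set[str]:
        return {p for p, t in self.pairs if t == term}

    @property
    def terms(self) -> list[str]:
        return sorted({t for _, t in self.pairs})

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

SITE_TABLE_COLUMNS = ["protein_id", "position", "residue", "source_id"]


def read_site_table(
    path: str | Path, proteome: Proteome | None = None, lenient: bool = False
) -> SiteDataset:
    """Read a phosphosite observation table.

    TSV with header columns ``protein_id  position  residue  source_id``.
    Duplicate (site, source) rows are collapsed with a logged count.  When a
    proteome is supplied, every site's residue letter is checked against the
    sequence (hard error by default, drop-and-log with ``lenient=True``).
    """
    path = Path(path)
    obs: list[Observation] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != SITE_TABLE_COLUMNS:
            raise ValidationError(
                f"{path}: expected header {SITE_TABLE_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValidationError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            pid, pos_s, residue, source = fields
            try:
                pos = int(pos_s)
                if pos < 1:
                    raise ValueError
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: position must be a positive integer, got {pos_s!r}"
                ) from None
            try:
                site = PhosphoSite(pid, pos, residue)
            except ValidationError as e:
                raise ValidationError(f"{path}:{lineno}: {e}") from None
            obs.append(Observation(site, source))
    dataset = SiteDataset(obs)
    if proteome is not None:
        dataset = dataset.validate_against(proteome, lenient=lenient)
    return dataset


def write_site_table(dataset: SiteDataset, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(SITE_TABLE_COLUMNS) + "\n")
        rows = sorted(
            dataset.observations, key=lambda o: (o.site.protein_id, o.site.position, o.source_id)
        )
        for o in rows:
            fh.write(f"{o.site.protein_id}\t{o.site.position}\t{o.site.residue}\t{o.source_id}\n")


def read_fasta(path: str | Path) -> Proteome:
    """Read a protein FASTA into a Proteome; id = first token of the header."""
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValidationError(f"{path}: duplicate FASTA id {record.id!r}")
        seq = str(record.seq)
        if not seq:
            raise ValidationError(f"{path}: empty sequence for {record.id!r}")
        seqs[record.id] = seq
    return Proteome(seqs)


def write_fasta(proteome: Proteome, path: str | Path, width: int = 60) -> None:
    with Path(path).open("w") as fh:
        for pid, seq in proteome.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_aligned_fasta(path: str | Path) -> AlignedPair:
    """Read a pairwise alignment: FASTA with exactly two equal-length rows."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValidationError(f"{path}: expected exactly 2 aligned records, got {len(records)}")
    q, t = records
    qrow, trow = str(q.seq).upper(), str(t.seq).upper()
    pair = AlignedPair(q.id, t.id, qrow, trow)  # raises on unequal lengths
    if any(a == GAP and b == GAP for a, b in zip(qrow, trow)):
        logger.warning("%s: alignment contains gap-only columns", path)
    return pair


def write_aligned_fasta(pair: AlignedPair, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f">{pair.query_id}\n{pair.query_row}\n>{pair.target_id}\n{pair.target_row}\n")


def _read_two_column_tsv(path: str | Path) -> list[tuple[str, str]]:
    pairs = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValidationError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            pairs.append((fields[0], fields[1]))
    return pairs


def read_ortholog_table(path: str | Path) -> OrthologTable:
    """Two-column TSV of (query_protein_id, target_protein_id) pairs."""
    return OrthologTable(_read_two_column_tsv(path))


def read_annotation_table(path: str | Path) -> AnnotationTable:
    """Two-column TSV of (protein_id, term) pairs."""
    return AnnotationTable(_read_two_column_tsv(path))


def write_two_column_tsv(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")
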