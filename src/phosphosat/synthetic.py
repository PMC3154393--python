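"""Synthetic phosphoproteomics data with known ground truth.

Real phosphoproteomics datasets are shaped by losses at every step of the
workflow: protein abundance and phosphorylation stoichiometry determine how
likely a site is to be seen at all, and the phosphopeptide enrichment
chemistry prefers certain residues and flanking compositions.  The
generators here emulate exactly those features — and nothing
peptide-level (no digestion, spectra or identification error model):

* :func:`generate_proteome` — i.i.d. random protein sequences.
* :func:`generate_phosphoproteome` — a true phosphosite set over the
  proteome's S/T/Y positions, each with a log-normal detection weight
  (``weight_dispersion = 0`` gives the homogeneous-detection regime in
  which the Chao1 estimator is well behaved).
* :func:`simulate_experiment` — one experiment (source): ``depth`` draws
  from the true sites with probability proportional to detection weight x
  residue selectivity x flank-composition bias, deduplicated to one
  observation per site.
* :func:`generate_ortholog_pair` — a diverged copy of the proteome with
  point substitutions and short indels, the *true* alignments by
  construction, and each true site conserved with a controlled probability.

Everything is deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bias import _flank_letters
from .io import (
    AMINO_ACIDS,
    GAP,
    AlignedPair,
    Observation,
    OrthologTable,
    PhosphoSite,
    Proteome,
    SiteDataset,
)

__all__ = [
    "DEFAULT_AA_FREQUENCIES",
    "SyntheticTruth",
    "EnrichmentProfile",
    "OrthologPairData",
    "generate_proteome",
    "generate_phosphoproteome",
    "simulate_experiment",
    "generate_ortholog_pair",
]

#: Approximate amino-acid background frequencies of a vertebrate proteome.
DEFAULT_AA_FREQUENCIES: dict[str, float] = {
    "A": 0.070, "C": 0.023, "D": 0.047, "E": 0.071, "F": 0.037,
    "G": 0.066, "H": 0.026, "I": 0.043, "K": 0.057, "L": 0.100,
    "M": 0.021, "N": 0.036, "P": 0.063, "Q": 0.048, "R": 0.056,
    "S": 0.083, "T": 0.053, "V": 0.060, "W": 0.012, "Y": 0.027,
}

MIN_PROTEIN_LENGTH = 20


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class SyntheticTruth:
    """A synthetic phosphoproteome with known detection weights."""

    proteome: Proteome
    true_sites: list[PhosphoSite]
    detection_weight: dict[PhosphoSite, float]
    parameters: dict
    seed: int | None

    @property
    def site_set(self) -> set[PhosphoSite]:
        return set(self.true_sites)


@dataclass
class EnrichmentProfile:
    """A phosphopeptide enrichment strategy, as selection multipliers.

    ``residue_selectivity`` multiplies a site's detection weight by residue
    type (an anti-phosphotyrosine antibody selects Y only); ``flank_bias``
    adds per-letter log-weights summed over the +/-5 flank (TiO2-like
    chemistry favours acidic D/E-rich flanks); ``depth`` is the number of
    observation draws per experiment.
    """

    residue_selectivity: dict[str, float] = field(
        default_factory=lambda: {"S": 1.0, "T": 1.0, "Y": 1.0}
    )
    flank_bias: dict[str, float] = field(default_factory=dict)
    depth: int = 1000
    name: str = "custom"

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.residue_selectivity.values()):
            raise ValueError("residue selectivity multipliers must be >= 0")
        if all(v == 0 for v in self.residue_selectivity.values()):
            raise ValueError("at least one residue must be selectable")
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")

    @classmethod
    def neutral(cls, depth: int = 1000) -> "EnrichmentProfile":
        return cls(depth=depth, name="neutral")

    @classmethod
    def anti_py(cls, depth: int = 1000) -> "EnrichmentProfile":
        """Anti-phosphotyrosine immunoaffinity: Y sites only."""
        return cls(
            residue_selectivity={"S": 0.0, "T": 0.0, "Y": 1.0}, depth=depth, name="anti_py"
        )

    @classmethod
    def tio2_like(cls, acidic_bonus: float = 1.0, depth: int = 1000) -> "EnrichmentProfile":
        """TiO2-affinity-like: favours acidic (D/E) flanking composition.

        ``acidic_bonus`` is the per-residue log-weight added for every D or E
        in the flank.  The default of 1.0 makes the D and E flank prevalence
        of sampled sites roughly 1.6-1.9x that of an unbiased sample,
        matching the acidic excess TiO2 chemistry shows against
        antibody-based enrichment in real comparisons.
        """
        return cls(flank_bias={"D": acidic_bonus, "E": acidic_bonus}, depth=depth, name="tio2_like")


def generate_proteome(
    n_proteins: int,
    mean_length: float = 300.0,
    aa_frequencies: Mapping[str, float] | None = None,
    seed: int | np.random.Generator | None = None,
) -> Proteome:
    """Random proteome: i.i.d. sequences, geometric lengths around the mean.

    Lengths are ``MIN_PROTEIN_LENGTH - 1`` plus a geometric variable with the
    matching mean (so no protein is shorter than 20 residues).
    """
    if n_proteins < 1:
        raise ValueError(f"n_proteins must be >= 1, got {n_proteins}")
    freqs = dict(aa_frequencies) if aa_frequencies is not None else dict(DEFAULT_AA_FREQUENCIES)
    letters = sorted(freqs)
    probs = np.array([freqs[a] for a in letters], dtype=float)
    if np.any(probs < 0) or not math.isclose(probs.sum(), 1.0, abs_tol=1e-2):
        raise ValueError("aa_frequencies must be non-negative and sum to 1")
    probs = probs / probs.sum()
    if mean_length < MIN_PROTEIN_LENGTH:
        raise ValueError(f"mean_length must be >= {MIN_PROTEIN_LENGTH}")
    rng = _rng(seed)

    excess_mean = mean_length - (MIN_PROTEIN_LENGTH - 1)
    lengths = (MIN_PROTEIN_LENGTH - 1) + rng.geometric(1.0 / excess_mean, size=n_proteins)
    width = len(str(n_proteins))
    seqs = {}
    for i, L in enumerate(lengths, start=1):
        letters_drawn = rng.choice(letters, size=int(L), p=probs)
        seqs[f"prot{i:0{width}d}"] = "".join(letters_drawn)
    return Proteome(seqs)


def generate_phosphoproteome(
    proteome: Proteome,
    site_fraction: float = 0.05,
    weight_dispersion: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> SyntheticTruth:
    """Select a true phosphosite set and assign detection weights.

    A ``site_fraction`` of all S/T/Y positions is chosen uniformly (the
    limiting case ``site_fraction = 1`` is the pervasive-phosphorylation
    scenario in which every acceptor residue is a site).  Detection weights
    are i.i.d. log-normal with log-scale standard deviation
    ``weight_dispersion``; 0 means every site is equally detectable.
    """
    if not 0.0 < site_fraction <= 1.0:
        raise ValueError(f"site_fraction must be in (0, 1], got {site_fraction}")
    if weight_dispersion < 0:
        raise ValueError("weight_dispersion must be >= 0")
    rng = _rng(seed)
    acceptors = proteome.phospho_acceptor_sites()
    if not acceptors:
        raise ValueError("proteome contains no S/T/Y residues")
    n_pick = int(round(site_fraction * len(acceptors))) or 1
    idx = rng.choice(len(acceptors), size=min(n_pick, len(acceptors)), replace=False)
    sites = sorted(acceptors[i] for i in idx)
    if weight_dispersion == 0:
        weights = np.ones(len(sites))
    else:
        weights = rng.lognormal(mean=0.0, sigma=weight_dispersion, size=len(sites))
    return SyntheticTruth(
        proteome=proteome,
        true_sites=sites,
        detection_weight=dict(zip(sites, weights.tolist())),
        parameters={
            "site_fraction": site_fraction,
            "weight_dispersion": weight_dispersion,
            "n_acceptors": len(acceptors),
        },
        seed=seed if isinstance(seed, int) else None,
    )


def simulate_experiment(
    truth: SyntheticTruth,
    profile: EnrichmentProfile,
    source_id: str,
    seed: int | np.random.Generator | None = None,
    window: int = 5,
    false_site_rate: float = 0.0,
) -> SiteDataset:
    """Simulate one experiment (a single source) against a synthetic truth.

    Draws ``profile.depth`` observations with per-site probability
    proportional to detection weight x residue selectivity x
    exp(sum of flank log-bias over the +/-``window`` flank), then
    deduplicates to one observation per site.  ``false_site_rate`` optionally
    replaces each draw, with that probability, by a spurious site at a
    random non-true acceptor position.
    """
    if not 0.0 <= false_site_rate < 1.0:
        raise ValueError("false_site_rate must be in [0, 1)")
    rng = _rng(seed)
    sites = truth.true_sites
    w = np.empty(len(sites))
    for i, s in enumerate(sites):
        sel = profile.residue_selectivity.get(s.residue, 0.0)
        if sel == 0.0:
            w[i] = 0.0
            continue
        log_flank = sum(
            profile.flank_bias.get(aa, 0.0)
            for aa in _flank_letters(s, truth.proteome, window)
        ) if profile.flank_bias else 0.0
        w[i] = truth.detection_weight[s] * sel * math.exp(log_flank)
    total = w.sum()
    if total == 0:
        raise ValueError("no true site is selectable under this enrichment profile")
    drawn = rng.choice(len(sites), size=profile.depth, replace=True, p=w / total)
    observed = [sites[i] for i in drawn]
    if false_site_rate > 0:
        decoys = sorted(set(truth.proteome.phospho_acceptor_sites()) - set(sites))
        if decoys:
            flip = rng.random(len(observed)) < false_site_rate
            picks = rng.choice(len(decoys), size=int(flip.sum()), replace=True)
            j = 0
            for i, f in enumerate(flip):
                if f:
                    observed[i] = decoys[picks[j]]
                    j += 1
    return SiteDataset(Observation(s, source_id) for s in observed)


@dataclass
class OrthologPairData:
    """A diverged target species with true alignments and conserved sites."""

    target_proteome: Proteome
    orthologs: OrthologTable
    alignments: list[AlignedPair]
    target_sites: set[PhosphoSite]
    conserved_query_sites: set[PhosphoSite]


def generate_ortholog_pair(
    truth: SyntheticTruth,
    substitution_rate: float = 0.2,
    indel_rate: float = 0.02,
    conservation_prob: float = 0.3,
    seed: int | np.random.Generator | None = None,
    target_suffix: str = "_t",
) -> OrthologPairData:
    """Derive a diverged ortholog proteome with known site conservation.

    Each protein is copied with i.i.d. point substitutions and short (1-3
    residue) insertions/deletions; each true phosphosite is chosen conserved
    with probability ``conservation_prob``, in which case its column is
    protected from substitution and deletion and the aligned target position
    is recorded as a target-species phosphosite.  The true alignment is
    emitted by construction, so conservation analyses on this data are exact
    (no aligner in the loop).
    """
    for name, rate in (("substitution_rate", substitution_rate), ("indel_rate", indel_rate)):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"{name} must be in [0, 1), got {rate}")
    if not 0.0 <= conservation_prob <= 1.0:
        raise ValueError(f"conservation_prob must be in [0, 1], got {conservation_prob}")
    rng = _rng(seed)
    letters = sorted(DEFAULT_AA_FREQUENCIES)
    probs = np.array([DEFAULT_AA_FREQUENCIES[a] for a in letters])
    probs = probs / probs.sum()

    sites_by_protein: dict[str, list[PhosphoSite]] = {}
    for s in truth.true_sites:
        sites_by_protein.setdefault(s.protein_id, []).append(s)

    target_seqs: dict[str, str] = {}
    pairs: list[tuple[str, str]] = []
    alignments: list[AlignedPair] = []
    target_sites: set[PhosphoSite] = set()
    conserved_query: set[PhosphoSite] = set()

    for pid, seq in truth.proteome.items():
        tid = pid + target_suffix
        prot_sites = sites_by_protein.get(pid, [])
        conserved_here = {
            s.position: s for s in prot_sites if rng.random() < conservation_prob
        }
        qrow, trow = [], []
        target_pos = 0
        target_position_of: dict[int, int] = {}
        for pos, aa in enumerate(seq, start=1):
            protected = pos in conserved_here
            if not protected and rng.random() < indel_rate / 2:  # deletion in target
                qrow.append(aa)
                trow.append(GAP)
            else:
                if protected or rng.random() >= substitution_rate:
                    taa = aa
                else:
                    taa = aa
                    while taa == aa:
                        taa = str(rng.choice(letters, p=probs))
                qrow.append(aa)
                trow.append(taa)
                target_pos += 1
                if protected:
                    target_position_of[pos] = target_pos
            if rng.random() < indel_rate / 2:  # insertion in target
                for ins in rng.choice(letters, size=int(rng.integers(1, 4)), p=probs):
                    qrow.append(GAP)
                    trow.append(str(ins))
                    target_pos += 1
        target_seqs[tid] = "".join(trow).replace(GAP, "")
        pairs.append((pid, tid))
        alignments.append(AlignedPair(pid, tid, "".join(qrow), "".join(trow)))
        for pos, s in conserved_here.items():
            conserved_query.add(s)
            target_sites.add(PhosphoSite(tid, target_position_of[pos], s.residue))

    return OrthologPairData(
        target_proteome=Proteome(target_seqs),
        orthologs=OrthologTable(pairs),
        alignments=alignments,
        target_sites=target_sites,
        conserved_query_sites=conserved_query,
    )
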