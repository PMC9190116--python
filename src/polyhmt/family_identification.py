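"""Homology-based family membership filters and nomenclature.

Family members are nominated by two independent evidence streams — a
profile-HMM domain search (e.g. the SET domain PF00856, or the PRMT5 domain
PF05185) and a BLASTP search seeded with known family proteins — then merged
and renamed in chromosome order across the A/B/D subgenomes.  All filter
thresholds use *strict* inequalities, mirroring their textbook statement
("E < 1e-10", "bit-score > 100", "identity > 50%", "matching length must
exceed 50% of the longer sequence").
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils.ProtParam import ProteinAnalysis

from polyhmt.formats_io import BlastHit, DomainHit, GeneModel, ValidationError

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: chromosome sort rank: 1A < 1B < 1D < 2A < ... < 7D < U (unplaced last)
_SUBGENOME_RANK = {"A": 0, "B": 1, "D": 2}


@dataclass(frozen=True)
class CandidateGene:
    """A nominated family member with its evidence flags."""

    gene_id: str
    evidence: frozenset[str]
    family: str

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValidationError(f"{self.gene_id}: empty evidence set")
        if not self.evidence <= {"hmm", "blast"}:
            raise ValidationError(f"{self.gene_id}: bad evidence {self.evidence}")


@dataclass(frozen=True)
class ProteinProperties:
    """ProtParam-style physicochemical summary of one protein."""

    length: int
    molecular_weight: float
    isoelectric_point: float
    instability_index: float
    is_stable: bool


def filter_hmm_candidates(
    hits: list[DomainHit],
    e_threshold: float = 1e-10,
    domain_accession: str | None = None,
) -> set[str]:
    """Gene ids whose domain hit clears the E-value cutoff (strict ``<``).

    ``domain_accession`` optionally restricts the scan to one Pfam accession,
    which also supports SET-independent searches such as DOT1L (PF08123).
    """
    if e_threshold <= 0:
        raise ValueError("e_threshold must be positive")
    return {
        h.query_id
        for h in hits
        if h.evalue < e_threshold
        and (domain_accession is None or h.domain_accession == domain_accession)
    }


def filter_blast_candidates(
    hits: list[BlastHit],
    e: float = 1e-10,
    score: float = 100.0,
    identity: float = 50.0,
    coverage: float = 0.5,
) -> set[str]:
    """Gene ids passing the three-part BLASTP criterion.

    Keep a query iff, for at least one of its hits, all of
    ``evalue < e``, ``bit_score > score``, ``percent_identity > identity`` and
    ``alignment_length > coverage * max(query_length, subject_length)`` hold.
    The coverage denominator is the *longer* of the two sequences, so a short
    local match against a long subject cannot sneak through.
    """
    kept: set[str] = set()
    for h in hits:
        if h.query_length is None or h.subject_length is None:
            raise ValidationError(f"{h.query_id}: missing qlen/slen")
        longer = max(h.query_length, h.subject_length)
        if (
            h.evalue < e
            and h.bit_score > score
            and h.percent_identity > identity
            and h.alignment_length > coverage * longer
        ):
            kept.add(h.query_id)
    return kept


def merge_candidates(
    hmm_set: set[str], blast_set: set[str], family: str
) -> list[CandidateGene]:
    """Union of both evidence streams with per-gene evidence flags.

    Output sorted by gene id for determinism.
    """
    out = []
    for gid in sorted(hmm_set | blast_set):
        ev = set()
        if gid in hmm_set:
            ev.add("hmm")
        if gid in blast_set:
            ev.add("blast")
        out.append(CandidateGene(gene_id=gid, evidence=frozenset(ev), family=family))
    return out


def chromosome_rank(chromosome: str, subgenome: str) -> tuple[int, int]:
    """Sort key giving the order 1A < 1B < 1D < 2A < ... < 7D < U."""
    if subgenome in _SUBGENOME_RANK and chromosome[:-1].isdigit():
        return (int(chromosome[:-1]), _SUBGENOME_RANK[subgenome])
    return (10**6, 3)  # anything unplaced sorts last


def assign_family_names(
    candidates: list[CandidateGene],
    gene_models: dict[str, GeneModel],
    prefix: str,
) -> dict[str, str]:
    """Gap-free names ``prefix+1..N`` in chromosome order.

    Genes sort by (chromosome rank 1A<1B<1D<...<7D<U, start ascending,
    gene_id lexicographic); numbering is a bijection onto 1..N regardless of
    candidate input order.
    """
    missing = sorted(c.gene_id for c in candidates if c.gene_id not in gene_models)
    if missing:
        raise ValidationError(f"candidates without gene models: {missing}")

    def key(c: CandidateGene):
        m = gene_models[c.gene_id]
        return (*chromosome_rank(m.chromosome, m.subgenome), m.start, m.gene_id)

    ordered = sorted(candidates, key=key)
    return {c.gene_id: f"{prefix}{i}" for i, c in enumerate(ordered, start=1)}


def compute_protein_properties(sequence: str) -> ProteinProperties:
    """Length, MW, pI and instability index of a protein sequence.

    Computed with Biopython's ProtParam implementation (average residue
    masses plus one water for MW; Henderson-Hasselbalch bisection for pI;
    the Guruprasad dipeptide-weight method for the instability index).  A
    protein is called unstable when the instability index exceeds 40.
    Non-standard residues are rejected rather than guessed at.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValidationError("empty protein sequence")
    bad = sorted(set(seq) - STANDARD_AA)
    if bad:
        raise ValidationError(f"non-standard residues: {bad}")
    analysis = ProteinAnalysis(seq)
    instability = analysis.instability_index()
    return ProteinProperties(
        length=len(seq),
        molecular_weight=analysis.molecular_weight(),
        isoelectric_point=analysis.isoelectric_point(),
        instability_index=instability,
        is_stable=instability <= 40.0,
    )
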