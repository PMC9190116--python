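"""Promoter extraction, cis-element scanning and lncRNA target assignment.

The promoter of a gene is the stretch of sequence immediately 5' of its
first CDS base (2 kb by default), read 5'->3' toward the CDS — i.e. the
reverse complement of the downstream genomic slice for minus-strand genes.
Promoters are scanned for short cis-regulatory elements (e.g. the
light-responsiveness elements SP1 ``GGGCGG`` and the GT1 motif ``GGTTAA``)
with exact IUPAC matching on both strands.

lncRNA targets are assigned by the conventional two-mode rule: *cis* targets
are protein-coding genes within a genomic window (100 kb by default, edge to
edge, inclusive) of the lncRNA locus; *trans* targets are distant genes
whose expression is strongly Pearson-correlated with the lncRNA across
samples.  A pair satisfying both rules is reported once, as cis.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
from pyfaidx import Fasta
from scipy import stats

from polyhmt.formats_io import GeneModel, ValidationError

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

DEFAULT_MOTIFS = {"SP1": "GGGCGG", "GT1": "GGTTAA"}


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PromoterSeq:
    """A strand-oriented promoter slice with its genomic span."""

    gene_id: str
    sequence: str
    chromosome: str
    start: int  # genomic span, 1-based inclusive
    end: int
    strand: str


@dataclass(frozen=True)
class MotifHit:
    """One exact cis-element occurrence inside a promoter."""

    gene_id: str
    element_name: str
    motif_string: str
    position: int  # 0-based offset of the match start within the promoter
    strand: str  # strand of the match relative to the promoter


@dataclass(frozen=True)
class LncRNALink:
    """A lncRNA -> gene regulatory link, cis (proximity) or trans (correlation)."""

    lncrna_id: str
    gene_id: str
    mode: str
    distance: int | None = None  # bp gap, cis only (0 for overlap)
    R: float | None = None  # trans only
    p: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("cis", "trans"):
            raise ValidationError(f"bad link mode {self.mode!r}")
        if self.mode == "cis" and self.distance is None:
            raise ValidationError("cis link needs a distance")
        if self.mode == "trans" and (self.R is None or self.p is None):
            raise ValidationError("trans link needs R and p")


# ---------------------------------------------------------------------------
# promoters


def extract_promoter(
    genome_fasta: str | Fasta, model: GeneModel, length: int = 2000
) -> PromoterSeq:
    """The ``length`` bases immediately 5' of the first CDS base.

    Plus strand: genomic [cds_start-length, cds_start-1]; minus strand:
    genomic [cds_start+1, cds_start+length] reverse-complemented.  The slice
    is truncated (never padded) at chromosome boundaries; a gene whose CDS
    starts at the very chromosome edge yields an empty promoter with a
    warning.
    """
    fasta = genome_fasta if isinstance(genome_fasta, Fasta) else Fasta(str(genome_fasta))
    if model.chromosome not in fasta:
        raise ValidationError(f"{model.gene_id}: chromosome {model.chromosome!r} not in FASTA")
    chrom_len = len(fasta[model.chromosome])
    if model.strand == "+":
        start = max(1, model.cds_start - length)
        end = model.cds_start - 1
    else:
        start = model.cds_start + 1
        end = min(chrom_len, model.cds_start + length)
    if end < start:
        warnings.warn(f"{model.gene_id}: empty promoter at chromosome edge")
        seq = ""
        start, end = model.cds_start, model.cds_start - 1
    else:
        seq = str(fasta[model.chromosome][start - 1 : end]).upper()
        if model.strand == "-":
            seq = reverse_complement(seq)
    return PromoterSeq(
        gene_id=model.gene_id,
        sequence=seq,
        chromosome=model.chromosome,
        start=start,
        end=end,
        strand=model.strand,
    )


def _iupac_regex(motif: str) -> re.Pattern:
    parts = []
    for ch in motif.upper():
        if ch not in IUPAC:
            raise ValidationError(f"invalid IUPAC character {ch!r} in motif {motif!r}")
        alts = IUPAC[ch]
        parts.append(alts if len(alts) == 1 else f"[{alts}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({''.join(parts)}))")


def scan_motifs(
    promoter: PromoterSeq,
    motif_table: dict[str, str] | None = None,
    both_strands: bool = True,
) -> list[MotifHit]:
    """All (possibly overlapping) exact IUPAC motif occurrences in a promoter.

    Positions are 0-based offsets within the promoter sequence regardless of
    match strand; a minus-strand hit means the reverse complement of the
    motif occurs at that offset.  Matching is case-insensitive.  Hits are
    ordered by (element name, position, strand).
    """
    motifs = DEFAULT_MOTIFS if motif_table is None else motif_table
    seq = promoter.sequence.upper()
    hits: list[MotifHit] = []
    for name in sorted(motifs):
        motif = motifs[name].upper()
        for m in _iupac_regex(motif).finditer(seq):
            hits.append(
                MotifHit(
                    gene_id=promoter.gene_id,
                    element_name=name,
                    motif_string=m.group(1),
                    position=m.start(),
                    strand="+",
                )
            )
        if both_strands:
            rc = reverse_complement(motif)
            if rc == motif:
                continue  # palindromic: the + scan already reported it
            for m in _iupac_regex(rc).finditer(seq):
                hits.append(
                    MotifHit(
                        gene_id=promoter.gene_id,
                        element_name=name,
                        motif_string=m.group(1),
                        position=m.start(),
                        strand="-",
                    )
                )
    hits.sort(key=lambda h: (h.element_name, h.position, h.strand))
    return hits


# ---------------------------------------------------------------------------
# lncRNA targets


def _interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """bp gap between two closed intervals; 0 when they touch or overlap."""
    if a_end < b_start:
        return b_start - a_end
    if b_end < a_start:
        return a_start - b_end
    return 0


def assign_cis_targets(
    lncrna_models: list[GeneModel],
    gene_models: list[GeneModel],
    window: int = 100_000,
) -> list[LncRNALink]:
    """Protein-coding genes within ``window`` bp of each lncRNA locus.

    Distance is measured edge to edge between the two gene spans on the same
    chromosome (overlap counts as 0) and the window boundary is inclusive.
    Links are ordered by (lncrna_id, gene_id).
    """
    links: list[LncRNALink] = []
    coding = [g for g in gene_models if g.biotype == "protein_coding"]
    for lnc in lncrna_models:
        for g in coding:
            if g.chromosome != lnc.chromosome or g.gene_id == lnc.gene_id:
                continue
            gap = _interval_gap(lnc.start, lnc.end, g.start, g.end)
            if gap <= window:
                links.append(
                    LncRNALink(
                        lncrna_id=lnc.gene_id, gene_id=g.gene_id, mode="cis", distance=gap
                    )
                )
    links.sort(key=lambda l: (l.lncrna_id, l.gene_id))
    return links


def assign_trans_targets(
    lncrna_expr,
    gene_expr,
    cis_links: list[LncRNALink],
    r_threshold: float = 0.90,
    alpha: float = 0.05,
) -> list[LncRNALink]:
    """Expression-correlated trans targets among non-cis (lncRNA, gene) pairs.

    ``lncrna_expr`` and ``gene_expr`` are feature-by-sample DataFrames over a
    shared sample set (n >= 3).  A pair not already linked in cis becomes a
    trans link iff |Pearson R| >= ``r_threshold`` and p < ``alpha``.
    Zero-variance vectors are skipped with a warning.
    """
    shared = [s for s in lncrna_expr.columns if s in gene_expr.columns]
    if len(shared) < 3:
        raise ValidationError("need >=3 shared samples")
    cis_pairs = {(l.lncrna_id, l.gene_id) for l in cis_links}
    links: list[LncRNALink] = []
    for lnc in lncrna_expr.index:
        x = lncrna_expr.loc[lnc, shared].to_numpy(float)
        if np.ptp(x) == 0:
            warnings.warn(f"{lnc}: zero-variance lncRNA expression, skipped")
            continue
        for gene in gene_expr.index:
            if (lnc, gene) in cis_pairs:
                continue
            y = gene_expr.loc[gene, shared].to_numpy(float)
            if np.ptp(y) == 0:
                warnings.warn(f"{gene}: zero-variance gene expression, skipped")
                continue
            r, p = stats.pearsonr(x, y)
            if abs(r) >= r_threshold and p < alpha:
                links.append(
                    LncRNALink(
                        lncrna_id=lnc, gene_id=gene, mode="trans",
                        R=float(r), p=float(p),
                    )
                )
    links.sort(key=lambda l: (l.lncrna_id, l.gene_id))
    return links
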