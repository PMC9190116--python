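"""Readers/writers for every external table the pipeline touches.

All genomic coordinates are 1-based inclusive (GFF3 convention).  Parsers are
strict: a malformed line raises :class:`ParseError` naming the line number,
and every container validates its invariants on construction.  Output order
is always a documented deterministic function of the input, never silently
shuffled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd

SUBGENOMES = ("A", "B", "D", "U")
ROLES = ("F1", "mother", "father")


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed content violates a documented invariant."""


def subgenome_from_chromosome(chromosome: str) -> str:
    """Deterministic subgenome label from a chromosome name.

    A token of the form ``<number><letter>`` (e.g. ``"3B"``) maps to its
    final letter; any other name — unplaced scaffolds, ``"Un"``, etc. — maps
    to ``"U"``, mirroring the convention of merging non-chromosome sequences
    into an unfound-chromosome bin.
    """
    token = chromosome.strip()
    if len(token) >= 2 and token[:-1].isdigit() and token[-1].upper() in "ABD":
        return token[-1].upper()
    return "U"


@dataclass(frozen=True, order=True)
class GeneModel:
    """A located, stranded gene with its subgenome label.

    ``cds_start`` is the first CDS base in genome coordinates, strand-aware:
    the minimum CDS coordinate on ``+``, the maximum on ``-``.
    """

    gene_id: str
    chromosome: str
    subgenome: str
    start: int
    end: int
    strand: str
    cds_start: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.subgenome not in SUBGENOMES:
            raise ValidationError(
                f"{self.gene_id}: subgenome {self.subgenome!r} not in {SUBGENOMES}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not (self.start <= self.cds_start <= self.end):
            raise ValidationError(
                f"{self.gene_id}: cds_start {self.cds_start} outside "
                f"[{self.start}, {self.end}]"
            )
        if self.biotype not in ("protein_coding", "lncRNA"):
            raise ValidationError(f"{self.gene_id}: bad biotype {self.biotype!r}")


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM domain match (domtblout-style row)."""

    query_id: str
    domain_accession: str
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(f"{self.query_id}: negative evalue {self.evalue}")


@dataclass(frozen=True)
class BlastHit:
    """One BLAST tabular hit (outfmt-6 plus qlen/slen)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bit_score: float
    query_length: int
    subject_length: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValidationError(
                f"{self.query_id}: identity {self.percent_identity} outside [0,100]"
            )
        if self.alignment_length > self.query_length + self.subject_length:
            raise ValidationError(
                f"{self.query_id}: alignment length {self.alignment_length} exceeds "
                f"qlen+slen ({self.query_length}+{self.subject_length})"
            )
        if self.evalue < 0:
            raise ValidationError(f"{self.query_id}: negative evalue {self.evalue}")


@dataclass(frozen=True)
class OrthologPairStat:
    """Ortholog counts for one (focal, partner) species pair.

    ``n_orthologs`` counts focal-species genes in ortholog groups with the
    partner; ``n_groups`` counts the groups themselves, so
    ``n_orthologs / n_groups`` is the mean group size on the focal side.
    """

    focal_species: str
    partner_species: str
    n_orthologs: int
    n_groups: int

    def __post_init__(self) -> None:
        if self.n_orthologs >= 1 and self.n_groups < 1:
            raise ValidationError(
                f"{self.focal_species}/{self.partner_species}: orthologs without groups"
            )
        if self.n_orthologs < self.n_groups:
            raise ValidationError(
                f"{self.focal_species}/{self.partner_species}: "
                f"n_orthologs {self.n_orthologs} < n_groups {self.n_groups}"
            )


@dataclass
class ExpressionMatrix:
    """Gene x sample expression with pedigree metadata per sample.

    ``values`` is a genes-by-samples DataFrame of non-negative reals;
    ``sample_meta`` is indexed by sample id with columns ``combination_id``,
    ``role`` (F1/mother/father), ``replicate_index`` and ``tissue``.  Every
    combination present must carry all three roles with at least two
    replicates each.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValidationError(
                f"samples missing from metadata: {sorted(missing)}"
            )
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("negative expression values")
        bad_roles = set(self.sample_meta["role"]) - set(ROLES)
        if bad_roles:
            raise ValidationError(f"unknown roles: {sorted(bad_roles)}")
        meta = self.sample_meta.loc[list(self.values.columns)]
        for combo, grp in meta.groupby("combination_id"):
            counts = grp["role"].value_counts()
            for role in ROLES:
                if counts.get(role, 0) < 2:
                    raise ValidationError(
                        f"combination {combo}: role {role} has "
                        f"{counts.get(role, 0)} replicates (<2)"
                    )

    def samples_for(self, combination_id: str, role: str) -> list[str]:
        meta = self.sample_meta
        mask = (meta["combination_id"] == combination_id) & (meta["role"] == role)
        return [s for s in self.values.columns if s in meta.index[mask]]

    @property
    def combinations(self) -> list[str]:
        return sorted(self.sample_meta["combination_id"].unique())


@dataclass
class TraitTable:
    """Replicated trait measurements per (combination, role, trait).

    ``data`` has columns combination_id, trait_name, role, replicate_index,
    value.  At least two replicates per (combination, role, trait).
    """

    data: pd.DataFrame

    REQUIRED = ("combination_id", "trait_name", "role", "replicate_index", "value")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValidationError(f"trait table missing columns: {sorted(missing)}")
        bad_roles = set(self.data["role"]) - set(ROLES)
        if bad_roles:
            raise ValidationError(f"unknown roles: {sorted(bad_roles)}")
        sizes = self.data.groupby(["combination_id", "role", "trait_name"]).size()
        if (sizes < 2).any():
            offenders = sizes[sizes < 2].index.tolist()
            raise ValidationError(f"<2 replicates for {offenders}")

    def replicates(self, combination_id: str, role: str, trait: str) -> list[float]:
        d = self.data
        mask = (
            (d["combination_id"] == combination_id)
            & (d["role"] == role)
            & (d["trait_name"] == trait)
        )
        sub = d[mask].sort_values("replicate_index")
        return sub["value"].tolist()

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait_name"].unique())

    @property
    def combinations(self) -> list[str]:
        return sorted(self.data["combination_id"].unique())


# ---------------------------------------------------------------------------
# parsers


def parse_gff3(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 into GeneModels, ordered by (chromosome, start, gene_id).

    One model per ``gene`` feature.  ``cds_start`` is taken from the
    strand-appropriate extreme CDS coordinate of the gene's CDS children;
    genes whose ``biotype`` attribute is ``lncRNA`` need no CDS and use their
    own strand-aware 5' end.  A protein-coding gene without CDS raises
    :class:`ValidationError`.
    """
    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils wraps line context in its message
        raise ParseError(f"{path}: {exc}") from exc

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        biotype = gene.attributes.get("biotype", ["protein_coding"])[0]
        cds_coords: list[tuple[int, int]] = [
            (c.start, c.end) for c in db.children(gene, featuretype="CDS")
        ]
        if biotype == "protein_coding":
            if not cds_coords:
                raise ValidationError(
                    f"{path}: gene {gene.id} is protein_coding but has no CDS"
                )
            if gene.strand == "+":
                cds_start = min(s for s, _ in cds_coords)
            else:
                cds_start = max(e for _, e in cds_coords)
        else:
            cds_start = gene.start if gene.strand == "+" else gene.end
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                subgenome=subgenome_from_chromosome(gene.seqid),
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                cds_start=cds_start,
                biotype=biotype,
            )
        )
    models.sort(key=lambda m: (m.chromosome, m.start, m.gene_id))
    return models


def parse_domain_hits(path: str | Path) -> list[DomainHit]:
    """Parse a whitespace-delimited domtblout-style table, input order kept.

    Expected columns: query_id, domain_accession, evalue, bit_score.  Lines
    starting with ``#`` are comments.
    """
    hits: list[DomainHit] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}:{lineno}: expected >=4 fields, got {len(parts)}")
        try:
            hits.append(
                DomainHit(
                    query_id=parts[0],
                    domain_accession=parts[1],
                    evalue=float(parts[2]),
                    bit_score=float(parts[3]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


#: column order of the fixed BLAST tabular dialect: the 12 standard outfmt-6
#: columns with query and subject sequence lengths appended.
BLAST_COLUMNS = (
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bit_score",
    "query_length",
    "subject_length",
)


def parse_blast_tab(path: str | Path) -> list[BlastHit]:
    """Parse tab-separated BLAST hits (outfmt 6 + qlen + slen), input order kept."""
    hits: list[BlastHit] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 14:
            raise ParseError(
                f"{path}:{lineno}: expected 14 tab-separated fields, got {len(parts)}"
            )
        try:
            hits.append(
                BlastHit(
                    query_id=parts[0],
                    subject_id=parts[1],
                    percent_identity=float(parts[2]),
                    alignment_length=int(parts[3]),
                    evalue=float(parts[10]),
                    bit_score=float(parts[11]),
                    query_length=int(parts[12]),
                    subject_length=int(parts[13]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def read_expression(path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix (genes x samples) with sidecar metadata.

    The matrix's first column holds gene ids; the metadata TSV is keyed by
    ``sample_id`` and must cover every matrix column.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    return ExpressionMatrix(values=values, sample_meta=meta)


def read_traits(path: str | Path) -> TraitTable:
    """Read a long-format trait TSV."""
    return TraitTable(data=pd.read_csv(path, sep="\t"))


def read_ortholog_stats(path: str | Path) -> list[OrthologPairStat]:
    """Read an InParanoid-style pair summary TSV.

    Columns: focal_species, partner_species, n_orthologs, n_groups.
    """
    df = pd.read_csv(path, sep="\t")
    return [
        OrthologPairStat(
            focal_species=row.focal_species,
            partner_species=row.partner_species,
            n_orthologs=int(row.n_orthologs),
            n_groups=int(row.n_groups),
        )
        for row in df.itertuples(index=False)
    ]


def write_table(records: Iterable[Mapping] | pd.DataFrame, path: str | Path) -> None:
    """Write records as TSV with deterministic column and row order.

    Column order follows the first record (or the DataFrame); rows keep the
    given order.  Floats are rendered with repr-level precision so rewriting
    identical data is byte-identical.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records))
    records.to_csv(path, sep="\t", index=False, lineterminator="\n")
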