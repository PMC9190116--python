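"""Seeded synthetic hexaploid dataset with fully known planted truth.

The generator emulates the data shape of an allohexaploid gene-family study:
21 chromosomes (1A..7D) plus an unplaced scaffold; a gene family planted
with a configurable triad/paired/orphan composition; decoy genes whose
homology hits fail exactly one filter criterion each; diploid-relative
family counts near a 1/3 ratio; F1/mother/father replicate expression with
planted dominance modes; yield traits with planted material classes and a
planted module-trait correlation; and lncRNA loci placed inside/outside the
cis window with planted trans correlations.

One integer seed drives a single ``numpy.random.default_rng`` stream in a
fixed draw order, so identical configs produce byte-identical files.  What
the generator does *not* emulate: real sequence homology (hit scores are
planted around the thresholds, not computed from sequence), codon structure,
splice variants, or read-level noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from polyhmt.formats_io import (
    ExpressionMatrix,
    GeneModel,
    TraitTable,
    ValidationError,
    subgenome_from_chromosome,
)
from polyhmt.polyploid_evolution import HomoeologGroup, make_group

DOMINANCE_CYCLE = (
    "over_dominant",
    "under_dominant",
    "high_parent_dominant",
    "low_parent_dominant",
    "additive_or_none",
)

MATERIAL_CYCLE = ("HP", "MP", "LP")


@dataclass
class SimulationConfig:
    """Every knob of the generator; defaults are the study conditions.

    The family composition defaults to the lysine-methyltransferase-like
    47 triads / 3 paired / 5 orphans (152 genes); homology-score margins
    default to 10x around every filter threshold; expression uses 6 crosses
    with 3 replicates per role, lognormal noise of CV 0.1 and a 4-fold
    dominance effect.
    """

    seed: int = 0
    # genome
    n_chromosome_pairs: int = 7
    chromosome_length: int = 300_000
    # family composition
    n_triads: int = 47
    n_paired: int = 3
    n_orphans: int = 5
    n_other: int = 0
    n_decoys: int = 50
    family: str = "HKMT"
    prefix: str = "TaHMT"
    # filter thresholds and the score margin planted around them
    e_threshold: float = 1e-10
    blast_score: float = 100.0
    blast_identity: float = 50.0
    blast_coverage: float = 0.5
    margin: float = 10.0
    domain_accession: str = "PF00856"
    # diploid relatives
    relatives: tuple[str, ...] = (
        "Arabidopsis",
        "Rice",
        "Sorghum",
        "Brachypodium",
        "Hordeum",
    )
    expected_ratio: float = 3.0
    poisson_noise: bool = True
    inflation: float = 1.0
    # expression design
    n_combinations: int = 6
    replicates: int = 3
    cv: float = 0.1
    effect: float = 4.0
    # traits
    trait_cv: float = 0.05
    module_size: int = 6
    module_trait_rho: float = -0.6
    # lncRNA design
    n_cis_lncrna: int = 4
    n_trans_lncrna: int = 4
    cis_window: int = 100_000
    trans_rho: float = 0.95
    lncrna_log_sd: float = 0.5

    @property
    def family_size(self) -> int:
        return 3 * self.n_triads + 2 * self.n_paired + self.n_orphans + 4 * self.n_other

    def validate(self) -> None:
        if min(
            self.n_triads, self.n_paired, self.n_orphans, self.n_other, self.n_decoys
        ) < 0:
            raise ValidationError("all counts must be >= 0")
        if self.family_size == 0:
            raise ValidationError("empty family")
        coding_limit = int(0.6 * self.chromosome_length)
        if self.chromosome_length - 2_500 - coding_limit <= self.cis_window:
            raise ValidationError(
                "chromosome_length too small to place lncRNAs outside the cis window"
            )


@dataclass
class SimulatedTruth:
    """Planted ground truth, consistent with every emitted file."""

    family_members: list[str] = field(default_factory=list)
    decoys: list[str] = field(default_factory=list)
    decoy_failed_criterion: dict[str, str] = field(default_factory=dict)
    gene_models: dict[str, GeneModel] = field(default_factory=dict)
    groups: list[HomoeologGroup] = field(default_factory=list)
    lncrna_models: dict[str, GeneModel] = field(default_factory=dict)
    cis_anchor_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    trans_pairs: list[tuple[str, str]] = field(default_factory=list)
    dominance_modes: dict[str, str] = field(default_factory=dict)
    material_classes: dict[tuple[str, str], str] = field(default_factory=dict)
    module_genes: list[str] = field(default_factory=list)


@dataclass
class SimulatedDataset:
    """Everything one seeded run produces, in memory."""

    config: SimulationConfig
    truth: SimulatedTruth
    genome: dict[str, str]
    domain_hits: pd.DataFrame
    blast_hits: pd.DataFrame
    relative_counts: pd.DataFrame
    expression: ExpressionMatrix
    traits: TraitTable
    lncrna_expression: pd.DataFrame


# ---------------------------------------------------------------------------
# genome and family layout


def _chromosome_names(n_pairs: int) -> list[str]:
    return [f"{i}{sg}" for i in range(1, n_pairs + 1) for sg in ("A", "B", "D")]


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, str], SimulatedTruth]:
    """Random chromosome sequences plus placed family, decoy and lncRNA loci.

    Coding genes occupy the first 60% of each chromosome (sequential
    placement with random gaps, so loci never overlap); "distant" lncRNAs
    sit near the chromosome end, guaranteed farther than the cis window from
    every coding gene.
    """
    config.validate()
    truth = SimulatedTruth()
    chroms = _chromosome_names(config.n_chromosome_pairs)
    all_seqs: dict[str, str] = {}
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for name in chroms + ["scaffoldU"]:
        length = config.chromosome_length if name != "scaffoldU" else config.chromosome_length // 3
        all_seqs[name] = bytes(rng.choice(bases, size=length)).decode("ascii")

    coding_limit = int(0.6 * config.chromosome_length)
    cursor = {name: 1000 for name in all_seqs}
    counter = 0

    def place_gene(chrom: str, biotype: str = "protein_coding") -> GeneModel:
        nonlocal counter
        counter += 1
        gid = f"SYNG{counter:04d}" if biotype == "protein_coding" else f"SYNL{counter:04d}"
        gap = int(rng.integers(1_000, 4_001))
        length = int(rng.integers(2_400, 3_601)) if biotype == "protein_coding" else 500
        start = cursor[chrom] + gap
        end = start + length - 1
        limit = coding_limit if chrom != "scaffoldU" else len(all_seqs[chrom]) - 100
        if end > limit:
            raise ValidationError(
                f"{chrom}: gene layout exceeds the coding region; "
                "reduce counts or enlarge chromosome_length"
            )
        cursor[chrom] = end
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        if biotype == "protein_coding":
            cds_start = start + 800 if strand == "+" else end - 800
        else:
            cds_start = start if strand == "+" else end
        return GeneModel(
            gene_id=gid,
            chromosome=chrom,
            subgenome=subgenome_from_chromosome(chrom),
            start=start,
            end=end,
            strand=strand,
            cds_start=cds_start,
            biotype=biotype,
        )

    pair_cycle = (("A", "B"), ("A", "D"), ("B", "D"))
    orphan_cycle = ("A", "B", "D")
    group_idx = 0

    def add_group(subgenome_members: dict[str, int]) -> None:
        nonlocal group_idx
        group_idx += 1
        chrom_num = (group_idx - 1) % config.n_chromosome_pairs + 1
        members: dict[str, list[str]] = {}
        for sg, n in subgenome_members.items():
            for _ in range(n):
                m = place_gene(f"{chrom_num}{sg}")
                truth.gene_models[m.gene_id] = m
                truth.family_members.append(m.gene_id)
                members.setdefault(sg, []).append(m.gene_id)
        truth.groups.append(make_group(f"HG{group_idx:03d}", members))

    for _ in range(config.n_triads):
        add_group({"A": 1, "B": 1, "D": 1})
    for i in range(config.n_paired):
        a, b = pair_cycle[i % 3]
        add_group({a: 1, b: 1})
    for i in range(config.n_orphans):
        add_group({orphan_cycle[i % 3]: 1})
    for _ in range(config.n_other):
        add_group({"A": 2, "B": 1, "D": 1})

    decoy_chroms = chroms + ["scaffoldU"]
    for i in range(config.n_decoys):
        m = place_gene(decoy_chroms[i % len(decoy_chroms)])
        truth.gene_models[m.gene_id] = m
        truth.decoys.append(m.gene_id)

    # cis lncRNAs: shortly downstream of the first family genes
    anchors = truth.family_members[: config.n_cis_lncrna]
    for i, anchor in enumerate(anchors):
        g = truth.gene_models[anchor]
        gap = int(rng.integers(5_000, min(50_000, config.cis_window) + 1))
        start = g.end + gap
        end = start + 499
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        lid = f"SYNLNC{i + 1:02d}"
        truth.lncrna_models[lid] = GeneModel(
            gene_id=lid,
            chromosome=g.chromosome,
            subgenome=g.subgenome,
            start=start,
            end=end,
            strand=strand,
            cds_start=start if strand == "+" else end,
            biotype="lncRNA",
        )
        truth.cis_anchor_pairs.append((lid, anchor, gap))

    # distant lncRNAs: near the chromosome end, beyond the cis window
    for i in range(config.n_trans_lncrna):
        chrom = chroms[(i * 4) % len(chroms)]
        end = config.chromosome_length - 1_000
        start = end - 499
        lid = f"SYNLNC{config.n_cis_lncrna + i + 1:02d}"
        truth.lncrna_models[lid] = GeneModel(
            gene_id=lid,
            chromosome=chrom,
            subgenome=subgenome_from_chromosome(chrom),
            start=start,
            end=end,
            strand="+",
            cds_start=start,
            biotype="lncRNA",
        )

    return all_seqs, truth


def write_genome_files(
    genome: dict[str, str],
    truth: SimulatedTruth,
    fasta_path: str | Path,
    gff_path: str | Path,
) -> None:
    """Write the FASTA and a GFF3 covering coding genes and lncRNA loci."""
    with open(fasta_path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    models = sorted(
        list(truth.gene_models.values()) + list(truth.lncrna_models.values()),
        key=lambda m: (m.chromosome, m.start, m.gene_id),
    )
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(
                f"{m.chromosome}\tpolyhmt_sim\tgene\t{m.start}\t{m.end}\t.\t"
                f"{m.strand}\t.\tID={m.gene_id};biotype={m.biotype}\n"
            )
            if m.biotype == "protein_coding":
                if m.strand == "+":
                    cs, ce = m.cds_start, m.end - 200
                else:
                    cs, ce = m.start + 200, m.cds_start
                fh.write(
                    f"{m.chromosome}\tpolyhmt_sim\tCDS\t{cs}\t{ce}\t.\t"
                    f"{m.strand}\t0\tID={m.gene_id}.cds;Parent={m.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# homology hits


_BLAST_CRITERIA = ("evalue", "bit_score", "identity", "coverage")


def simulate_family_and_hits(
    config: SimulationConfig, truth: SimulatedTruth, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Domain- and BLAST-hit tables straddling every filter threshold.

    Planted members clear each criterion by the configured multiplicative
    margin; with margin 0 their values sit exactly on each threshold, which
    the strict inequalities must then reject.  Each decoy fails exactly one
    BLAST criterion (cycled, recorded in the truth) and the HMM E-value cut.
    """
    f = config.margin if config.margin > 0 else 1.0
    qlen = slen = 500

    ev_pass = config.e_threshold / f
    bit_pass = config.blast_score * f
    id_pass = min(config.blast_identity * f, 95.0) if config.margin > 0 else config.blast_identity
    aln_pass = min(int(config.blast_coverage * qlen * f), qlen)
    if config.margin == 0:
        bit_pass = config.blast_score
        aln_pass = int(config.blast_coverage * qlen)

    ev_fail = config.e_threshold * f
    bit_fail = config.blast_score / f
    id_fail = config.blast_identity / f
    aln_fail = int(config.blast_coverage * qlen / f) if f > 1 else int(config.blast_coverage * qlen)

    domain_rows = []
    blast_rows = []
    for gid in truth.family_members:
        domain_rows.append(
            {
                "query_id": gid,
                "domain_accession": config.domain_accession,
                # extra downward jitter keeps passing E-values varied without
                # ever crossing back over the cutoff; at margin 0 the value
                # must sit exactly on the threshold, so no jitter
                "evalue": ev_pass
                * (10.0 ** -float(rng.integers(0, 3)) if config.margin > 0 else 1.0),
                "bit_score": round(float(rng.uniform(200, 500)), 1),
            }
        )
        blast_rows.append(
            {
                "query_id": gid,
                "subject_id": "SEED_PROTEIN",
                "percent_identity": id_pass,
                "alignment_length": aln_pass,
                "evalue": ev_pass,
                "bit_score": bit_pass,
                "query_length": qlen,
                "subject_length": slen,
            }
        )
    for i, gid in enumerate(truth.decoys):
        domain_rows.append(
            {
                "query_id": gid,
                "domain_accession": config.domain_accession,
                "evalue": ev_fail,
                "bit_score": round(float(rng.uniform(10, 40)), 1),
            }
        )
        crit = _BLAST_CRITERIA[i % 4]
        truth.decoy_failed_criterion[gid] = crit
        blast_rows.append(
            {
                "query_id": gid,
                "subject_id": "SEED_PROTEIN",
                "percent_identity": id_fail if crit == "identity" else id_pass,
                "alignment_length": aln_fail if crit == "coverage" else aln_pass,
                "evalue": ev_fail if crit == "evalue" else ev_pass,
                "bit_score": bit_fail if crit == "bit_score" else bit_pass,
                "query_length": qlen,
                "subject_length": slen,
            }
        )
    return pd.DataFrame(domain_rows), pd.DataFrame(blast_rows)


def write_domain_hits(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# synthetic domtblout-style table: query accession evalue score\n")
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.query_id} {row.domain_accession} {row.evalue:.3g} {row.bit_score}\n"
            )


def write_blast_hits(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fields = [
                row.query_id, row.subject_id, f"{row.percent_identity:g}",
                str(row.alignment_length), "0", "0", "1", str(row.alignment_length),
                "1", str(row.alignment_length), f"{row.evalue:.3g}",
                f"{row.bit_score:g}", str(row.query_length), str(row.subject_length),
            ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# relatives


def simulate_relative_counts(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-relative family counts around focal/(k*inflation).

    With Poisson noise off the relative count is the rounded expectation, so
    at inflation 1 the count ratio is exactly k whenever the focal count is
    divisible by k.
    """
    base = config.family_size / (config.expected_ratio * config.inflation)
    rows = []
    for sp in config.relatives:
        if config.poisson_noise:
            count = max(1, int(rng.poisson(base)))
        else:
            count = max(1, round(base))
        rows.append({"species": sp, "family": config.family, "count": count})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression, traits, lncRNA


def _lognormal_reps(
    mean: float, cv: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n positive replicates with the given mean and coefficient of variation."""
    if cv == 0:
        return np.full(n, mean)
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return mean * np.exp(rng.normal(0.0, sigma, size=n) - sigma * sigma / 2.0)


def _mode_means(
    mode: str, mu: float, effect: float, father_is_high: bool
) -> tuple[float, float, float]:
    """(f1, mother, father) means for one planted dominance mode."""
    lo, hi = mu, mu * effect
    if mode == "over_dominant":
        return mu * effect, mu, mu
    if mode == "under_dominant":
        return mu / effect, mu, mu
    mother, father = (lo, hi) if father_is_high else (hi, lo)
    if mode == "high_parent_dominant":
        return hi, mother, father
    if mode == "low_parent_dominant":
        return lo, mother, father
    return (lo + hi) / 2.0, mother, father  # additive_or_none


def simulate_expression(
    config: SimulationConfig, truth: SimulatedTruth, rng: np.random.Generator
) -> tuple[ExpressionMatrix, TraitTable]:
    """Replicate expression with planted dominance modes, plus yield traits.

    Every family gene gets one mode (cycled over the five), applied in every
    cross; which parent is the high one is drawn per gene.  Traits: a
    seed-weight-like trait carries the planted HP/MP/LP class per cross; a
    tiller-like trait is generated per sample with the planted Pearson
    correlation to the module genes' mean z-scored expression.
    """
    genes = list(truth.family_members)
    combos = [f"M{i + 1}" for i in range(config.n_combinations)]
    samples = [
        (f"{c}_{role}_{r + 1}", c, role, r + 1)
        for c in combos
        for role in ("F1", "mother", "father")
        for r in range(config.replicates)
    ]
    meta = pd.DataFrame(
        [
            {
                "sample_id": sid,
                "combination_id": c,
                "role": role,
                "replicate_index": rep,
                "tissue": "spike",
            }
            for sid, c, role, rep in samples
        ]
    ).set_index("sample_id")

    for i, g in enumerate(genes):
        truth.dominance_modes[g] = DOMINANCE_CYCLE[i % len(DOMINANCE_CYCLE)]

    values = np.zeros((len(genes), len(samples)))
    sample_cols = {sid: j for j, (sid, *_rest) in enumerate(samples)}
    for i, g in enumerate(genes):
        mode = truth.dominance_modes[g]
        mu = float(np.exp(rng.normal(4.0, 0.5)))
        father_is_high = bool(rng.integers(0, 2))
        for c in combos:
            f1_m, mo_m, fa_m = _mode_means(mode, mu, config.effect, father_is_high)
            for role, m in (("F1", f1_m), ("mother", mo_m), ("father", fa_m)):
                reps = _lognormal_reps(m, config.cv, config.replicates, rng)
                for r in range(config.replicates):
                    values[i, sample_cols[f"{c}_{role}_{r + 1}"]] = reps[r]

    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=[s[0] for s in samples]),
        sample_meta=meta,
    )

    # seed-weight-like trait with planted HP/MP/LP per cross
    trait_rows = []
    for ci, c in enumerate(combos):
        cls = MATERIAL_CYCLE[ci % 3]
        mo_m, fa_m = 30.0, 40.0
        f1_m = {"HP": fa_m * 1.4, "MP": (mo_m + fa_m) / 2.0, "LP": mo_m / 1.4}[cls]
        truth.material_classes[(c, "TSW")] = cls
        for role, m in (("F1", f1_m), ("mother", mo_m), ("father", fa_m)):
            reps = m * (1.0 + rng.normal(0.0, config.trait_cv, size=config.replicates))
            for r in range(config.replicates):
                trait_rows.append(
                    {
                        "combination_id": c,
                        "trait_name": "TSW",
                        "role": role,
                        "replicate_index": r + 1,
                        "value": float(reps[r]),
                    }
                )

    # tiller-like trait correlated with the module genes' mean z profile
    truth.module_genes = genes[: min(config.module_size, len(genes))]
    sub = expr.values.loc[truth.module_genes]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
    profile = z.mean(axis=0)
    zp = (profile - profile.mean()) / profile.std(ddof=1)
    rho = config.module_trait_rho
    noise = rng.normal(0.0, 1.0, size=len(zp))
    latent = rho * zp.to_numpy() + np.sqrt(max(0.0, 1.0 - rho * rho)) * noise
    tiller = np.maximum(0.5, 10.0 + 2.0 * latent)
    for j, (sid, c, role, rep) in enumerate(samples):
        trait_rows.append(
            {
                "combination_id": c,
                "trait_name": "tillers",
                "role": role,
                "replicate_index": rep,
                "value": float(tiller[j]),
            }
        )

    return expr, TraitTable(data=pd.DataFrame(trait_rows))


def simulate_lncrna_expression(
    config: SimulationConfig,
    truth: SimulatedTruth,
    expr: ExpressionMatrix,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """lncRNA expression rows over the same samples as the gene matrix.

    Each distant lncRNA is planted as a trans partner of one family gene via
    a shared latent factor at the configured correlation (on the log scale);
    cis-placed lncRNAs are generated independently, as the cis rule is
    positional, not correlational.
    """
    lnc_ids = sorted(truth.lncrna_models)
    distant = [l for l in lnc_ids if all(l != c for c, _, _ in truth.cis_anchor_pairs)]
    cis = [l for l, _, _ in truth.cis_anchor_pairs]
    genes = list(truth.family_members)
    n = expr.values.shape[1]
    rows = {}
    truth.trans_pairs = []
    for i, lid in enumerate(distant):
        target = genes[(7 * i) % len(genes)]
        truth.trans_pairs.append((lid, target))
        logg = np.log(expr.values.loc[target].to_numpy(float))
        zg = (logg - logg.mean()) / logg.std(ddof=1)
        eps = rng.normal(0.0, 1.0, size=n)
        rho = config.trans_rho
        latent = rho * zg + np.sqrt(max(0.0, 1.0 - rho * rho)) * eps
        rows[lid] = np.exp(2.0 + config.lncrna_log_sd * latent)
    for lid in cis:
        rows[lid] = np.exp(rng.normal(2.0, config.lncrna_log_sd, size=n))
    return pd.DataFrame.from_dict(rows, orient="index", columns=expr.values.columns).loc[
        sorted(rows)
    ]


# ---------------------------------------------------------------------------
# one-call bundle and file emission


def simulate_all(config: SimulationConfig) -> SimulatedDataset:
    """Run every generator stage off one seeded stream, in a fixed order."""
    rng = np.random.default_rng(config.seed)
    genome, truth = simulate_genome(config, rng)
    domain_hits, blast_hits = simulate_family_and_hits(config, truth, rng)
    relative_counts = simulate_relative_counts(config, rng)
    expr, traits = simulate_expression(config, truth, rng)
    lnc_expr = simulate_lncrna_expression(config, truth, expr, rng)
    return SimulatedDataset(
        config=config,
        truth=truth,
        genome=genome,
        domain_hits=domain_hits,
        blast_hits=blast_hits,
        relative_counts=relative_counts,
        expression=expr,
        traits=traits,
        lncrna_expression=lnc_expr,
    )


def truth_to_json(truth: SimulatedTruth) -> dict:
    """JSON-serialisable view of the planted truth."""
    return {
        "family_members": truth.family_members,
        "decoys": truth.decoys,
        "decoy_failed_criterion": truth.decoy_failed_criterion,
        "groups": [
            {
                "group_id": g.group_id,
                "members_by_subgenome": {k: list(v) for k, v in g.members_by_subgenome.items()},
                "group_class": g.group_class,
            }
            for g in truth.groups
        ],
        "cis_anchor_pairs": [list(p) for p in truth.cis_anchor_pairs],
        "trans_pairs": [list(p) for p in truth.trans_pairs],
        "dominance_modes": truth.dominance_modes,
        "material_classes": {f"{c}|{t}": v for (c, t), v in truth.material_classes.items()},
        "module_genes": truth.module_genes,
    }


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit every file of a simulated dataset; byte-deterministic per seed."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome_fasta": out / "genome.fa",
        "gff": out / "annotation.gff3",
        "domain_hits": out / "domain_hits.txt",
        "blast_hits": out / "blast_hits.tsv",
        "relative_counts": out / "relative_counts.tsv",
        "expression": out / "expression.tsv",
        "sample_meta": out / "sample_meta.tsv",
        "traits": out / "traits.tsv",
        "lncrna_expression": out / "lncrna_expression.tsv",
        "truth": out / "truth.json",
    }
    write_genome_files(ds.genome, ds.truth, paths["genome_fasta"], paths["gff"])
    write_domain_hits(ds.domain_hits, paths["domain_hits"])
    write_blast_hits(ds.blast_hits, paths["blast_hits"])
    ds.relative_counts.to_csv(paths["relative_counts"], sep="\t", index=False, lineterminator="\n")
    ds.expression.values.to_csv(paths["expression"], sep="\t", index_label="gene_id", lineterminator="\n")
    ds.expression.sample_meta.to_csv(paths["sample_meta"], sep="\t", index_label="sample_id", lineterminator="\n")
    ds.traits.data.to_csv(paths["traits"], sep="\t", index=False, lineterminator="\n")
    ds.lncrna_expression.to_csv(paths["lncrna_expression"], sep="\t", index_label="lncrna_id", lineterminator="\n")
    with open(paths["truth"], "w") as fh:
        json.dump(truth_to_json(ds.truth), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
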