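"""Promoter extraction, motif scanning, cis/trans lncRNA target assignment."""

import numpy as np
import pandas as pd
import pytest
from pyfaidx import Fasta

from polyhmt.formats_io import GeneModel, ValidationError
from polyhmt.regulation_links import (
    _interval_gap,
    assign_cis_targets,
    assign_trans_targets,
    extract_promoter,
    reverse_complement,
    scan_motifs,
    DEFAULT_MOTIFS,
    PromoterSeq,
)


def _write_fasta(tmp_path, seqs):
    p = tmp_path / "genome.fa"
    with open(p, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
    return p


def _gene(gid, chrom, start, end, strand, cds_start, biotype="protein_coding"):
    from polyhmt.formats_io import subgenome_from_chromosome
    return GeneModel(gid, chrom, subgenome_from_chromosome(chrom), start, end,
                     strand, cds_start, biotype)


def test_promoter_plus_strand_coordinates(tmp_path):
    rng = np.random.default_rng(41)
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    fasta = Fasta(str(_write_fasta(tmp_path, {"1A": seq})))
    model = _gene("g", "1A", 2500, 4500, "+", 3001)
    p = extract_promoter(fasta, model)
    assert p.sequence == seq[1000:3000]  # genomic [1001..3000]
    assert (p.start, p.end) == (1001, 3000)


def test_promoter_truncated_at_chromosome_edge(tmp_path):
    seq = "ACGT" * 500
    fasta = Fasta(str(_write_fasta(tmp_path, {"1A": seq})))
    model = _gene("g", "1A", 100, 1500, "+", 500)
    p = extract_promoter(fasta, model)
    assert p.sequence == seq[:499]  # only 499 bases exist upstream
    model_edge = _gene("g2", "1A", 1, 1500, "+", 1)
    with pytest.warns(UserWarning, match="empty promoter"):
        p2 = extract_promoter(fasta, model_edge)
    assert p2.sequence == ""


def test_promoter_minus_strand_is_reverse_complement(tmp_path):
    rng = np.random.default_rng(43)
    seq = "".join(rng.choice(list("ACGT"), size=6000))
    fasta = Fasta(str(_write_fasta(tmp_path, {"1A": seq})))
    model = _gene("g", "1A", 500, 2500, "-", 2000)
    p = extract_promoter(fasta, model)
    assert p.sequence == reverse_complement(seq[2000:4000])


def test_promoters_match_naive_slicing_oracle(dataset, dataset_dir):
    fasta = Fasta(str(dataset_dir["genome_fasta"]))
    for m in list(dataset.truth.gene_models.values())[:50]:
        p = extract_promoter(fasta, m)
        chrom = dataset.genome[m.chromosome]
        if m.strand == "+":
            oracle = chrom[max(0, m.cds_start - 2001): m.cds_start - 1]
        else:
            oracle = reverse_complement(chrom[m.cds_start: m.cds_start + 2000])
        assert p.sequence == oracle, m.gene_id


def _prom(seq, gid="g"):
    return PromoterSeq(gid, seq, "1A", 1, len(seq), "+")


def test_scan_motifs_forward_hit():
    hits = scan_motifs(_prom("AAGGGCGGTT"), {"SP1": "GGGCGG"})
    assert [(h.element_name, h.position, h.strand) for h in hits] == [("SP1", 2, "+")]


def test_scan_motifs_reverse_strand_hit():
    hits = scan_motifs(_prom("TTCCGCCCAA"), {"SP1": "GGGCGG"})
    assert [(h.element_name, h.position, h.strand) for h in hits] == [("SP1", 2, "-")]


def test_scan_motifs_case_insensitive_and_overlapping():
    lower = scan_motifs(_prom("aagggcggtt"), {"SP1": "GGGCGG"})
    assert len(lower) == 1 and lower[0].position == 2
    # overlapping AA run: IUPAC W = A/T
    hits = scan_motifs(_prom("AAAA"), {"polyA": "AAA"}, both_strands=False)
    assert [h.position for h in hits] == [0, 1]


def test_scan_motifs_iupac_and_invalid_character():
    hits = scan_motifs(_prom("GGTTAACA"), {"GT1": "GGTTAA"})
    assert hits[0].position == 0
    with pytest.raises(ValidationError, match="IUPAC"):
        scan_motifs(_prom("ACGT"), {"bad": "GGX"})


def test_scan_motifs_matches_brute_force(dataset, dataset_dir):
    fasta = Fasta(str(dataset_dir["genome_fasta"]))
    models = list(dataset.truth.gene_models.values())[:20]
    for m in models:
        p = extract_promoter(fasta, m)
        hits = scan_motifs(p)
        seq = p.sequence
        expected = []
        for name in sorted(DEFAULT_MOTIFS):
            motif = DEFAULT_MOTIFS[name]
            rc = reverse_complement(motif)
            for i in range(len(seq) - len(motif) + 1):
                if seq[i: i + len(motif)] == motif:
                    expected.append((name, i, "+"))
                if rc != motif and seq[i: i + len(rc)] == rc:
                    expected.append((name, i, "-"))
        expected.sort()
        assert [(h.element_name, h.position, h.strand) for h in hits] == expected


def test_strand_symmetry_promoter_plus_scan(dataset, dataset_dir, tmp_path):
    """Mirroring the genome (reverse-complement + coordinate flip) changes nothing."""
    mirror = tmp_path / "mirror.fa"
    with open(mirror, "w") as fh:
        for name in sorted(dataset.genome):
            fh.write(f">{name}\n{reverse_complement(dataset.genome[name])}\n")
    fasta = Fasta(str(dataset_dir["genome_fasta"]))
    mfasta = Fasta(str(mirror))
    for m in list(dataset.truth.gene_models.values())[:25]:
        L = len(dataset.genome[m.chromosome])
        mm = GeneModel(m.gene_id, m.chromosome, m.subgenome,
                       L - m.end + 1, L - m.start + 1,
                       "-" if m.strand == "+" else "+",
                       L - m.cds_start + 1, m.biotype)
        p, pm = extract_promoter(fasta, m), extract_promoter(mfasta, mm)
        assert p.sequence == pm.sequence
        assert [(h.element_name, h.position, h.strand) for h in scan_motifs(p)] == [
            (h.element_name, h.position, h.strand) for h in scan_motifs(pm)
        ]


def test_interval_gap_semantics():
    assert _interval_gap(100, 200, 150, 250) == 0  # overlap
    assert _interval_gap(100, 200, 250, 300) == 50
    assert _interval_gap(250, 300, 100, 200) == 50


def test_cis_window_boundary_inclusive():
    lnc = [_gene("lnc", "1A", 1000, 1499, "+", 1000, biotype="lncRNA")]
    near = _gene("near", "1A", 51_499, 53_000, "+", 51_600)
    at_edge = _gene("edge", "1A", 101_499, 103_000, "+", 101_600)
    beyond = _gene("far", "1A", 151_500, 153_000, "+", 151_600)
    links = assign_cis_targets(lnc, [near, at_edge, beyond])
    by_gene = {l.gene_id: l for l in links}
    assert by_gene["near"].distance == 50_000
    assert by_gene["edge"].distance == 100_000  # exactly at the window: linked
    assert "far" not in by_gene


def test_cis_targets_equal_brute_force(dataset):
    lnc = list(dataset.truth.lncrna_models.values())
    coding = list(dataset.truth.gene_models.values())
    links = assign_cis_targets(lnc, coding)
    expected = set()
    for l in lnc:
        for g in coding:
            if g.chromosome != l.chromosome:
                continue
            gap = max(0, max(l.start, g.start) - min(l.end, g.end))
            if gap <= 100_000:
                expected.add((l.gene_id, g.gene_id))
    assert {(x.lncrna_id, x.gene_id) for x in links} == expected
    # planted anchors present with their planted distances
    by_pair = {(x.lncrna_id, x.gene_id): x.distance for x in links}
    for lid, gid, dist in dataset.truth.cis_anchor_pairs:
        assert by_pair[(lid, gid)] == dist


def test_trans_proportional_vector_links():
    samples = [f"s{i}" for i in range(10)]
    base = np.linspace(1, 10, 10)
    lnc = pd.DataFrame([base], index=["lnc1"], columns=samples)
    genes = pd.DataFrame([2 * base], index=["g1"], columns=samples)
    (link,) = assign_trans_targets(lnc, genes, [])
    assert link.mode == "trans" and link.R == pytest.approx(1.0)


def test_trans_independent_noise_not_linked():
    rng = np.random.default_rng(47)
    samples = [f"s{i}" for i in range(12)]
    lnc = pd.DataFrame(rng.normal(10, 2, size=(3, 12)),
                       index=["l1", "l2", "l3"], columns=samples)
    genes = pd.DataFrame(rng.normal(10, 2, size=(5, 12)),
                         index=[f"g{i}" for i in range(5)], columns=samples)
    assert assign_trans_targets(lnc, genes, []) == []


def test_trans_skips_cis_pairs_and_zero_variance():
    samples = [f"s{i}" for i in range(10)]
    base = np.linspace(1, 10, 10)
    lnc = pd.DataFrame([base, np.ones(10)], index=["l1", "l2"], columns=samples)
    genes = pd.DataFrame([base], index=["g1"], columns=samples)
    from polyhmt.regulation_links import LncRNALink
    cis = [LncRNALink("l1", "g1", "cis", distance=10)]
    with pytest.warns(UserWarning, match="zero-variance"):
        assert assign_trans_targets(lnc, genes, cis) == []


def test_trans_planted_pairs_recovered(dataset):
    cis = assign_cis_targets(
        list(dataset.truth.lncrna_models.values()),
        list(dataset.truth.gene_models.values()),
    )
    links = assign_trans_targets(
        dataset.lncrna_expression, dataset.expression.values, cis
    )
    found = {(l.lncrna_id, l.gene_id) for l in links}
    for pair in dataset.truth.trans_pairs:
        assert tuple(pair) in found
    # cis and trans link sets are disjoint by construction
    assert not found & {(l.lncrna_id, l.gene_id) for l in cis}
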