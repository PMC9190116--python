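"""Homoeolog triad classification, ortholog statistics and expansion tests.

In an allohexaploid (AABBDD) genome every ancestral locus is expected in
three homoeologous copies, one per subgenome.  A homoeolog group is a
*triad* when it retains exactly one copy on each of A, B and D (1:1:1),
*paired* when one copy was lost, an *orphan/singleton* when two were lost,
and *other* for any multi-copy pattern.  Against a diploid relative the
family size is expected near 3:1; deviation is tested with a two-category
chi-square goodness-of-fit (df=1, no continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from scipy import stats

from polyhmt.formats_io import OrthologPairStat, ValidationError

GROUP_CLASSES = ("triad", "paired", "orphan", "other")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding as used for all displayed ratios/percents."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class HomoeologGroup:
    """A/B/D member sets of one homoeolog group with its retention class."""

    group_id: str
    members_by_subgenome: dict[str, tuple[str, ...]]
    group_class: str

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.members_by_subgenome.values())


@dataclass(frozen=True)
class ClassSummary:
    n_groups: int
    n_genes: int
    percent_of_family: float  # displayed 2-decimal figure
    percent_unrounded: float


@dataclass(frozen=True)
class TriadSummary:
    """Per-class retention summary for one gene family."""

    family_size: int
    per_class: dict[str, ClassSummary]

    def __post_init__(self) -> None:
        total = sum(c.n_genes for c in self.per_class.values())
        if total != self.family_size:
            raise ValidationError(
                f"class gene counts sum to {total}, family size {self.family_size}"
            )


@dataclass(frozen=True)
class ExpansionTestResult:
    """Two-category chi-square test of a family count against a k:1 ratio."""

    focal_count: int
    relative_count: int
    expected_ratio: float
    count_ratio: float  # 2-decimal display value
    chi2: float
    p: float
    significant: bool


@dataclass(frozen=True)
class OrthologStatsSummary:
    """Per-partner ortholog group sizes and their average for a focal species."""

    focal_species: str
    per_partner: dict[str, float]  # partner -> group size (n_orthologs/n_groups)
    average_group_size: float
    average_in_paralogs: float


def classify_homoeolog_group(
    members_by_subgenome: dict[str, list[str] | tuple[str, ...]],
) -> str:
    """Retention class from subgenome member counts.

    (1,1,1) over A/B/D -> triad; one member in each of exactly two
    subgenomes -> paired; a single member -> orphan; every other pattern
    (multi-copy, or any member on an unplaced U scaffold) -> other.
    """
    counts = {sg: len(v) for sg, v in members_by_subgenome.items() if len(v) > 0}
    total = sum(counts.values())
    if total == 0:
        raise ValidationError("empty homoeolog group")
    if counts.get("U", 0) > 0:
        return "other"
    abd = [counts.get(sg, 0) for sg in ("A", "B", "D")]
    if abd == [1, 1, 1]:
        return "triad"
    if total == 2 and sorted(abd) == [0, 1, 1]:
        return "paired"
    if total == 1:
        return "orphan"
    return "other"


def make_group(group_id: str, members_by_subgenome: dict[str, list[str]]) -> HomoeologGroup:
    """Build a HomoeologGroup, deriving its class from the member counts."""
    frozen = {sg: tuple(v) for sg, v in members_by_subgenome.items() if v}
    return HomoeologGroup(
        group_id=group_id,
        members_by_subgenome=frozen,
        group_class=classify_homoeolog_group(frozen),
    )


def summarize_retention(groups: list[HomoeologGroup], family_size: int) -> TriadSummary:
    """Per-class group/gene counts and percent of family (half-up, 2 dp).

    Percentages are 100 * n_genes / family_size; gene counts over the four
    classes must conserve the family size.
    """
    if family_size <= 0:
        raise ValidationError("family_size must be positive")
    per_class: dict[str, ClassSummary] = {}
    for cls in GROUP_CLASSES:
        cls_groups = [g for g in groups if g.group_class == cls]
        n_genes = sum(g.n_genes for g in cls_groups)
        pct = 100.0 * n_genes / family_size
        per_class[cls] = ClassSummary(
            n_groups=len(cls_groups),
            n_genes=n_genes,
            percent_of_family=round_half_up(pct, 2),
            percent_unrounded=pct,
        )
    return TriadSummary(family_size=family_size, per_class=per_class)


def ortholog_stats(
    pair_stats: list[OrthologPairStat], focal_species: str
) -> OrthologStatsSummary:
    """Average ortholog group size and in-paralog count for one species.

    Per partner the group size is n_orthologs / n_groups; the average is the
    arithmetic mean over partners, and the average number of in-paralogs per
    gene is that mean minus one (one member of each group is the gene
    itself).  Values are reported unrounded; display rounding is the
    caller's concern.
    """
    pairs = [p for p in pair_stats if p.focal_species == focal_species]
    if not pairs:
        raise ValidationError(f"no partners for focal species {focal_species!r}")
    per_partner: dict[str, float] = {}
    for p in pairs:
        if p.n_groups == 0:
            raise ValidationError(
                f"{p.focal_species}/{p.partner_species}: zero ortholog groups"
            )
        per_partner[p.partner_species] = p.n_orthologs / p.n_groups
    avg = sum(per_partner.values()) / len(per_partner)
    return OrthologStatsSummary(
        focal_species=focal_species,
        per_partner=per_partner,
        average_group_size=avg,
        average_in_paralogs=avg - 1.0,
    )


def family_count_ratio(focal_count: int, relative_count: int) -> float:
    """focal/relative family-size ratio, half-up to 2 decimals."""
    if relative_count <= 0:
        raise ValidationError("relative_count must be positive")
    return round_half_up(focal_count / relative_count, 2)


def expansion_chi2(
    focal_count: int,
    relative_count: int,
    k: float = 3.0,
    alpha: float = 0.05,
) -> ExpansionTestResult:
    """Chi-square goodness-of-fit of (focal, relative) counts against k:1.

    Two categories with expected proportions k/(k+1) and 1/(k+1) of the
    total, df=1, no continuity correction; ``significant`` flags p < alpha.
    chi2 is exactly 0 iff focal == k * relative.
    """
    if focal_count < 0 or relative_count < 0:
        raise ValidationError("counts must be non-negative")
    total = focal_count + relative_count
    if total == 0:
        raise ValidationError("total count is zero")
    expected = [total * k / (k + 1.0), total / (k + 1.0)]
    chi2, p = stats.chisquare([focal_count, relative_count], f_exp=expected)
    return ExpansionTestResult(
        focal_count=focal_count,
        relative_count=relative_count,
        expected_ratio=k,
        count_ratio=family_count_ratio(focal_count, relative_count)
        if relative_count > 0
        else float("inf"),
        chi2=float(chi2),
        p=float(p),
        significant=bool(p < alpha),
    )
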