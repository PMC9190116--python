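"""F1-versus-parent expression analysis for heterosis studies.

Covers relative qPCR quantification (2^-ddCt), maternal-standardised
expression, dominance-mode classification of F1 hybrids against their
parents, a t-test + fold-change differential-expression screen, HP/MP/LP
material classification from trait replicates, Pearson expression-trait
correlation, and ChIP-qPCR percent-input normalisation.

Dominance vocabulary: a gene is *over-dominant* in a cross when its F1
expression is significantly above both parents, *under-dominant* when
significantly below both; *high-/low-parent dominant* when F1 differs
significantly from exactly one parent and is statistically indistinguishable
from the higher-/lower-expressed parent; anything else (including the
significant-vs-both-but-between-parents case) is *additive_or_none*.

Welch's unequal-variance t-test is the default everywhere a two-group test
is needed: with the typical three biological replicates the equal-variance
assumption of the pooled test is fragile.  The classical pooled (Student)
test is available via ``equal_var=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from polyhmt.formats_io import ExpressionMatrix, TraitTable, ValidationError

DOMINANCE_MODES = (
    "over_dominant",
    "under_dominant",
    "high_parent_dominant",
    "low_parent_dominant",
    "additive_or_none",
)

MATERIAL_CLASSES = ("HP", "MP", "LP")


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: target and reference-gene Ct for a sample."""

    sample_id: str
    gene: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        if self.ct_target <= 0 or self.ct_reference <= 0:
            raise ValidationError(f"{self.sample_id}/{self.gene}: Ct must be > 0")


@dataclass(frozen=True)
class DominanceCall:
    """Per gene x cross dominance mode with the two parent-test p-values."""

    gene: str
    combination_id: str
    mode: str
    p_vs_mother: float
    p_vs_father: float


@dataclass(frozen=True)
class MaterialClass:
    """HP/MP/LP call for one (combination, trait)."""

    combination_id: str
    trait: str
    material_class: str


@dataclass(frozen=True)
class DEGRecord:
    """Differential-expression call of one gene in one cross."""

    gene: str
    combination_id: str
    log2_fc_vs_mother: float
    log2_fc_vs_father: float
    p_vs_mother: float
    p_vs_father: float
    is_deg: bool


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson R with its two-sided p-value and the sample count."""

    R: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValidationError(f"need n >= 3 samples, got {self.n}")
        if not -1.0 <= self.R <= 1.0 + 1e-12:
            raise ValidationError(f"R={self.R} outside [-1, 1]")


@dataclass(frozen=True)
class ChipEnrichment:
    """ChIP-qPCR enrichment of one region, as percent of input chromatin."""

    region: str
    antibody: str
    percent_input: float

    def __post_init__(self) -> None:
        if self.percent_input < 0:
            raise ValidationError("percent_input must be >= 0")


# ---------------------------------------------------------------------------
# qPCR quantification


def ddct(sample: CtRecord, calibrator: CtRecord) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = ct_target - ct_reference within each sample; the result is
    2^-(dCt_sample - dCt_calibrator).  Equal dCts give exactly 1; each cycle
    of earlier target amplification doubles the value.
    """
    d_sample = sample.ct_target - sample.ct_reference
    d_cal = calibrator.ct_target - calibrator.ct_reference
    return 2.0 ** (-(d_sample - d_cal))


def chip_percent_input(
    ct_ip: float, ct_input: float, input_fraction: float, region: str = "", antibody: str = ""
) -> ChipEnrichment:
    """ChIP-qPCR enrichment normalised to the input sample.

    The saved input is a fraction of the chromatin used for IP, so its Ct is
    first adjusted by log2(1/input_fraction) dilution cycles; enrichment is
    then 100 * 2^(adjusted_input_Ct - ct_ip) percent.
    """
    if not 0.0 < input_fraction <= 1.0:
        raise ValidationError("input_fraction must be in (0, 1]")
    adjusted_input = ct_input - math.log2(1.0 / input_fraction)
    return ChipEnrichment(
        region=region,
        antibody=antibody,
        percent_input=100.0 * 2.0 ** (adjusted_input - ct_ip),
    )


# ---------------------------------------------------------------------------
# expression rescaling and dominance classification


def normalize_to_maternal(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale every combination so the maternal replicate mean is exactly 1.

    Within each combination, each gene's values across all samples of that
    combination are divided by the mother's replicate mean for that gene.
    A zero maternal mean raises: the rescaling is undefined there.
    """
    values = expr.values.copy().astype(float)
    for combo in expr.combinations:
        mother_cols = expr.samples_for(combo, "mother")
        combo_cols = [
            s
            for s in values.columns
            if expr.sample_meta.loc[s, "combination_id"] == combo
        ]
        mother_mean = values[mother_cols].mean(axis=1)
        if (mother_mean == 0).any():
            bad = mother_mean.index[mother_mean == 0].tolist()
            raise ValidationError(
                f"combination {combo}: zero maternal mean for genes {bad[:5]}"
            )
        values[combo_cols] = values[combo_cols].div(mother_mean, axis=0)
    return ExpressionMatrix(values=values, sample_meta=expr.sample_meta.copy())


def _welch_p(a: np.ndarray, b: np.ndarray, equal_var: bool) -> float:
    """Two-sided t-test p-value; identical constant groups count as no evidence."""
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    p = stats.ttest_ind(a, b, equal_var=equal_var).pvalue
    return float(p) if np.isfinite(p) else 1.0


def classify_dominance(
    f1_reps,
    mother_reps,
    father_reps,
    alpha: float = 0.05,
    gene: str = "",
    combination_id: str = "",
    equal_var: bool = False,
) -> DominanceCall:
    """Classify the F1 expression mode of one gene in one cross.

    Two-sided Welch t-tests of F1 against each parent drive the call; see the
    module docstring for the decision table.  The classification is
    exhaustive and mutually exclusive, and depends on the parents only
    through their expression rank, never their mother/father identity.
    """
    f1 = np.asarray(f1_reps, dtype=float)
    mo = np.asarray(mother_reps, dtype=float)
    fa = np.asarray(father_reps, dtype=float)
    for name, arr in (("F1", f1), ("mother", mo), ("father", fa)):
        if arr.size < 2:
            raise ValidationError(f"{name}: need >=2 replicates, got {arr.size}")

    p_mo = _welch_p(f1, mo, equal_var)
    p_fa = _welch_p(f1, fa, equal_var)
    sig_mo = p_mo < alpha
    sig_fa = p_fa < alpha
    f1_mean, mo_mean, fa_mean = f1.mean(), mo.mean(), fa.mean()
    hi_mean, lo_mean = max(mo_mean, fa_mean), min(mo_mean, fa_mean)

    if sig_mo and sig_fa:
        if f1_mean > hi_mean:
            mode = "over_dominant"
        elif f1_mean < lo_mean:
            mode = "under_dominant"
        else:
            mode = "additive_or_none"
    elif sig_mo ^ sig_fa:
        # F1 is indistinguishable from exactly one parent; the mode names
        # whether that parent is the higher- or lower-expressed one.
        matched_mean = fa_mean if sig_mo else mo_mean
        # equal parent means leave the rank arbitrary; call high by convention
        mode = (
            "high_parent_dominant"
            if matched_mean == hi_mean
            else "low_parent_dominant"
        )
    else:
        mode = "additive_or_none"

    return DominanceCall(
        gene=gene,
        combination_id=combination_id,
        mode=mode,
        p_vs_mother=p_mo,
        p_vs_father=p_fa,
    )


def classify_dominance_matrix(
    expr: ExpressionMatrix, alpha: float = 0.05, equal_var: bool = False
) -> list[DominanceCall]:
    """classify_dominance for every gene x combination of a matrix."""
    calls: list[DominanceCall] = []
    for combo in expr.combinations:
        cols = {role: expr.samples_for(combo, role) for role in ("F1", "mother", "father")}
        for gene in expr.values.index:
            calls.append(
                classify_dominance(
                    expr.values.loc[gene, cols["F1"]],
                    expr.values.loc[gene, cols["mother"]],
                    expr.values.loc[gene, cols["father"]],
                    alpha=alpha,
                    gene=gene,
                    combination_id=combo,
                    equal_var=equal_var,
                )
            )
    return calls


# ---------------------------------------------------------------------------
# DEG screen and material classes


def screen_degs(
    expr: ExpressionMatrix,
    combination_id: str,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> list[DEGRecord]:
    """t-test + fold-change screen of F1 against each parent, on linear values.

    A gene is a DEG in the cross when, against at least one parent, the fold
    change exceeds ``fc_threshold`` in either direction (|log2 FC| >
    log2(fc_threshold)) and the two-sided p-value is below ``alpha``.
    """
    f1_cols = expr.samples_for(combination_id, "F1")
    mo_cols = expr.samples_for(combination_id, "mother")
    fa_cols = expr.samples_for(combination_id, "father")
    if not f1_cols:
        raise ValidationError(f"unknown combination {combination_id!r}")
    records: list[DEGRecord] = []
    log2_thr = math.log2(fc_threshold) if fc_threshold > 0 else -math.inf
    for gene in expr.values.index:
        f1 = expr.values.loc[gene, f1_cols].to_numpy(float)
        stats_vs = {}
        for parent, cols in (("mother", mo_cols), ("father", fa_cols)):
            pv = _welch_p(f1, expr.values.loc[gene, cols].to_numpy(float), equal_var)
            pmean = expr.values.loc[gene, cols].mean()
            with np.errstate(divide="ignore"):
                l2fc = (
                    math.log2(f1.mean() / pmean)
                    if pmean > 0 and f1.mean() > 0
                    else math.inf * np.sign(f1.mean() - pmean)
                )
            stats_vs[parent] = (l2fc, pv)
        is_deg = any(
            abs(l2fc) > log2_thr and pv < alpha for l2fc, pv in stats_vs.values()
        )
        records.append(
            DEGRecord(
                gene=gene,
                combination_id=combination_id,
                log2_fc_vs_mother=stats_vs["mother"][0],
                log2_fc_vs_father=stats_vs["father"][0],
                p_vs_mother=stats_vs["mother"][1],
                p_vs_father=stats_vs["father"][1],
                is_deg=is_deg,
            )
        )
    return records


def classify_material(
    f1_reps, mother_reps, father_reps,
    alpha: float = 0.05,
    combination_id: str = "",
    trait: str = "",
    equal_var: bool = False,
) -> MaterialClass:
    """HP/MP/LP call for one (combination, trait) from replicate values.

    HP: the F1 trait mean is above both parents with p < alpha against both;
    LP: below both with p < alpha against both; everything else is MP.
    """
    f1 = np.asarray(f1_reps, dtype=float)
    mo = np.asarray(mother_reps, dtype=float)
    fa = np.asarray(father_reps, dtype=float)
    p_mo = _welch_p(f1, mo, equal_var)
    p_fa = _welch_p(f1, fa, equal_var)
    sig_both = p_mo < alpha and p_fa < alpha
    if sig_both and f1.mean() > max(mo.mean(), fa.mean()):
        cls = "HP"
    elif sig_both and f1.mean() < min(mo.mean(), fa.mean()):
        cls = "LP"
    else:
        cls = "MP"
    return MaterialClass(combination_id=combination_id, trait=trait, material_class=cls)


def classify_materials(traits: TraitTable, alpha: float = 0.05) -> list[MaterialClass]:
    """classify_material for every (combination, trait) of a trait table."""
    out = []
    for combo in traits.combinations:
        for trait in traits.traits:
            out.append(
                classify_material(
                    traits.replicates(combo, "F1", trait),
                    traits.replicates(combo, "mother", trait),
                    traits.replicates(combo, "father", trait),
                    alpha=alpha,
                    combination_id=combo,
                    trait=trait,
                )
            )
    return out


# ---------------------------------------------------------------------------
# correlation


def correlate(x, y) -> CorrelationResult:
    """Pearson R between two vectors with its two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise ValidationError(f"need n >= 3, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero-variance vector")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(R=float(np.clip(r, -1.0, 1.0)), p=float(p), n=int(x.size))


def group_trait_correlation(
    gene_sets: dict[str, list[str]],
    expr_values: pd.DataFrame,
    trait: pd.Series,
) -> dict[str, CorrelationResult]:
    """Correlate each gene set's summary expression with a trait.

    Each member gene is z-scored across samples, the set is averaged into a
    single profile, and that profile is Pearson-correlated with the trait
    over the shared samples.  A set of one gene reduces to plain
    ``correlate`` on that gene (z-scoring does not change R).
    """
    shared = [s for s in expr_values.columns if s in trait.index]
    if len(shared) < 3:
        raise ValidationError("need >=3 shared samples between expression and trait")
    out: dict[str, CorrelationResult] = {}
    for name, genes in gene_sets.items():
        missing = [g for g in genes if g not in expr_values.index]
        if missing:
            raise ValidationError(f"set {name!r}: unknown genes {missing[:5]}")
        sub = expr_values.loc[genes, shared].astype(float)
        sd = sub.std(axis=1, ddof=1)
        if (sd == 0).any():
            raise ValidationError(f"set {name!r}: zero-variance gene expression")
        z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
        profile = z.mean(axis=0)
        out[name] = correlate(profile.to_numpy(), trait.loc[shared].to_numpy())
    return out
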