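"""qPCR math, dominance classification, DEG screen, materials, correlation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polyhmt.formats_io import ValidationError
from polyhmt.heterosis_expression import (
    DOMINANCE_MODES,
    CtRecord,
    chip_percent_input,
    classify_dominance,
    classify_dominance_matrix,
    classify_material,
    correlate,
    ddct,
    group_trait_correlation,
    normalize_to_maternal,
    screen_degs,
)


def _ct(sample, tgt, ref):
    return CtRecord(sample, "gene", tgt, ref)


def test_ddct_calibrator_identity():
    assert ddct(_ct("s", 25.0, 20.0), _ct("c", 28.0, 23.0)) == 1.0


def test_ddct_doubles_per_cycle():
    # sample dCt two cycles below the calibrator's -> 4-fold
    assert ddct(_ct("s", 23.0, 20.0), _ct("c", 28.0, 23.0)) == 4.0


def test_ddct_matches_direct_formula():
    rng = np.random.default_rng(23)
    for _ in range(50):
        t1, r1, t2, r2 = rng.uniform(10, 35, size=4)
        expected = 2.0 ** (-((t1 - r1) - (t2 - r2)))
        assert ddct(_ct("s", t1, r1), _ct("c", t2, r2)) == pytest.approx(expected)


def test_ddct_scale_free_in_common_shift():
    base = ddct(_ct("s", 24.0, 21.0), _ct("c", 26.0, 22.0))
    shifted = ddct(_ct("s", 27.5, 24.5), _ct("c", 26.0, 22.0))
    assert shifted == pytest.approx(base)


def test_chip_percent_input_anchors():
    # IP Ct equal to the dilution-adjusted input Ct -> 100 percent
    assert chip_percent_input(20.0, 20.0 + math.log2(100), 0.01).percent_input == pytest.approx(100.0)
    # one cycle later halves the recovery
    assert chip_percent_input(21.0, 20.0 + math.log2(100), 0.01).percent_input == pytest.approx(50.0)


def test_chip_percent_input_matches_formula():
    rng = np.random.default_rng(29)
    for _ in range(30):
        ct_ip, ct_in = rng.uniform(18, 32, size=2)
        frac = float(rng.choice([0.01, 0.05, 0.1]))
        oracle = 100.0 * 2.0 ** ((ct_in - math.log2(1.0 / frac)) - ct_ip)
        assert chip_percent_input(ct_ip, ct_in, frac).percent_input == pytest.approx(oracle)


def test_normalize_to_maternal_unit_mother(dataset):
    norm = normalize_to_maternal(dataset.expression)
    for combo in norm.combinations:
        cols = norm.samples_for(combo, "mother")
        means = norm.values[cols].mean(axis=1)
        assert np.allclose(means, 1.0)


def test_normalize_to_maternal_simple_and_zero_mother():
    values = pd.DataFrame(
        {"M1_F1_1": [4.0], "M1_F1_2": [4.0], "M1_mother_1": [2.0],
         "M1_mother_2": [2.0], "M1_father_1": [1.0], "M1_father_2": [1.0]},
        index=["g"],
    )
    meta = pd.DataFrame(
        [(s, "M1", s.split("_")[1], int(s.split("_")[2]), "spike")
         for s in values.columns],
        columns=["sample_id", "combination_id", "role", "replicate_index", "tissue"],
    ).set_index("sample_id")
    from polyhmt.formats_io import ExpressionMatrix
    norm = normalize_to_maternal(ExpressionMatrix(values, meta))
    assert norm.values.loc["g", ["M1_F1_1", "M1_F1_2"]].tolist() == [2.0, 2.0]

    zero = ExpressionMatrix(values.copy(), meta)
    zero.values.loc["g", ["M1_mother_1", "M1_mother_2"]] = 0.0
    with pytest.raises(ValidationError, match="zero maternal mean"):
        normalize_to_maternal(zero)


def test_dominance_large_margin_over_dominant():
    call = classify_dominance([10, 10.2, 9.8], [1, 1.1, 0.9], [2, 2.1, 1.9])
    assert call.mode == "over_dominant"


def test_dominance_tracks_high_parent():
    call = classify_dominance([2.0, 2.05, 1.95], [1.0, 1.02, 0.98], [2.0, 1.98, 2.02])
    assert call.mode == "high_parent_dominant"


def test_dominance_tracks_low_parent():
    call = classify_dominance([1.0, 1.02, 0.98], [1.0, 0.99, 1.01], [2.0, 2.05, 1.95])
    assert call.mode == "low_parent_dominant"


def test_dominance_under_and_additive():
    assert classify_dominance([0.2, 0.21, 0.19], [1, 1.1, 0.9], [2, 2.1, 1.9]).mode == "under_dominant"
    # significant vs both but between the parents -> additive_or_none
    assert classify_dominance([1.5, 1.51, 1.49], [1, 1.01, 0.99], [2, 2.01, 1.99]).mode == "additive_or_none"


def test_dominance_zero_variance_equal_means_is_additive():
    call = classify_dominance([1.0, 1.0], [1.0, 1.0], [1.0, 1.0])
    assert call.mode == "additive_or_none"


def test_dominance_requires_replicates():
    with pytest.raises(ValidationError, match="replicates"):
        classify_dominance([1.0], [1.0, 1.0], [1.0, 1.0])


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(0.01, 100), min_size=2, max_size=5),
    st.lists(st.floats(0.01, 100), min_size=2, max_size=5),
    st.lists(st.floats(0.01, 100), min_size=2, max_size=5),
)
def test_dominance_exhaustive_and_parent_swap_symmetry(f1, mo, fa):
    call = classify_dominance(f1, mo, fa)
    assert call.mode in DOMINANCE_MODES
    swapped = classify_dominance(f1, fa, mo)
    # parent identity is irrelevant; only expression rank matters
    assert swapped.mode == call.mode
    assert swapped.p_vs_mother == pytest.approx(call.p_vs_father)


def test_dominance_recovery_on_planted_modes(dataset):
    calls = classify_dominance_matrix(dataset.expression)
    correct = np.mean(
        [dataset.truth.dominance_modes[c.gene] == c.mode for c in calls]
    )
    assert correct >= 0.95


def _tiny_matrix(f1, mo, fa):
    from polyhmt.formats_io import ExpressionMatrix
    cols, vals = [], []
    for role, reps in (("F1", f1), ("mother", mo), ("father", fa)):
        for i, v in enumerate(reps, 1):
            cols.append(f"M1_{role}_{i}")
            vals.append(v)
    values = pd.DataFrame([vals], index=["g"], columns=cols)
    meta = pd.DataFrame(
        [(c, "M1", c.split("_")[1], int(c.split("_")[2]), "spike") for c in cols],
        columns=["sample_id", "combination_id", "role", "replicate_index", "tissue"],
    ).set_index("sample_id")
    return ExpressionMatrix(values, meta)


def test_screen_degs_clean_difference_and_null():
    up = _tiny_matrix([8.0, 8.1, 7.9], [1.0, 1.05, 0.95], [1.0, 0.98, 1.02])
    (rec,) = screen_degs(up, "M1")
    assert rec.is_deg and rec.log2_fc_vs_mother == pytest.approx(3.0, abs=0.1)

    flat = _tiny_matrix([1.0, 1.01, 0.99], [1.0, 1.02, 0.98], [1.0, 0.99, 1.01])
    (rec,) = screen_degs(flat, "M1")
    assert not rec.is_deg


def test_screen_degs_degenerate_thresholds_flag_unequal_means():
    m = _tiny_matrix([1.2, 1.2, 1.2], [1.0, 1.0, 1.0], [1.2, 1.2, 1.2])
    (rec,) = screen_degs(m, "M1", fc_threshold=1.0, alpha=1.0)
    assert rec.is_deg


def test_screen_degs_recovers_planted_large_effects(dataset):
    """Planted over/under-dominant genes are 4-fold off both parents -> DEGs."""
    recs = screen_degs(dataset.expression, "M1")
    by_gene = {r.gene: r for r in recs}
    for gene, mode in dataset.truth.dominance_modes.items():
        if mode in ("over_dominant", "under_dominant"):
            assert by_gene[gene].is_deg, (gene, mode)


def test_material_classes():
    hp = classify_material([60, 61, 59], [30, 30.5, 29.5], [40, 40.5, 39.5])
    assert hp.material_class == "HP"
    mp = classify_material([35, 35.2, 34.8], [30, 30.5, 29.5], [40, 40.5, 39.5])
    assert mp.material_class == "MP"
    lp = classify_material([20, 20.2, 19.8], [30, 30.5, 29.5], [40, 40.5, 39.5])
    assert lp.material_class == "LP"


def test_material_recovery_on_planted_truth(dataset):
    from polyhmt.heterosis_expression import classify_materials
    for m in classify_materials(dataset.traits):
        if m.trait == "TSW":
            assert m.material_class == dataset.truth.material_classes[(m.combination_id, "TSW")]


def test_correlate_exact_lines():
    x = np.arange(10, dtype=float)
    assert correlate(x, 2 * x + 1).R == pytest.approx(1.0)
    assert correlate(x, -x).R == pytest.approx(-1.0)


def test_correlate_matches_textbook_formula():
    rng = np.random.default_rng(31)
    x, y = rng.normal(size=30), rng.normal(size=30)
    res = correlate(x, y)
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))
    assert res.R == pytest.approx(r, abs=1e-12)
    from scipy import stats
    t = r * math.sqrt((30 - 2) / (1 - r * r))
    assert res.p == pytest.approx(2 * stats.t.sf(abs(t), df=28), rel=1e-6)


def test_correlate_rejects_degenerate_inputs():
    with pytest.raises(ValidationError):
        correlate([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValidationError, match="zero-variance"):
        correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_group_trait_correlation_reductions():
    rng = np.random.default_rng(37)
    samples = [f"s{i}" for i in range(12)]
    g1 = rng.normal(10, 2, size=12)
    expr = pd.DataFrame([g1, 3 * g1 + 1], index=["g1", "g2"], columns=samples)
    trait = pd.Series(rng.normal(size=12), index=samples)
    single = group_trait_correlation({"set": ["g1"]}, expr, trait)["set"]
    assert single.R == pytest.approx(correlate(g1, trait.values).R)
    # two perfectly correlated genes give the same R as either alone
    both = group_trait_correlation({"set": ["g1", "g2"]}, expr, trait)["set"]
    assert both.R == pytest.approx(single.R)


def test_group_trait_correlation_recovers_planted_module(dataset):
    tt = dataset.traits.data
    series = pd.Series(
        {f"{r.combination_id}_{r.role}_{r.replicate_index}": r.value
         for r in tt[tt.trait_name == "tillers"].itertuples(index=False)}
    )
    res = group_trait_correlation(
        {"module": dataset.truth.module_genes}, dataset.expression.values, series
    )["module"]
    rho = dataset.config.module_trait_rho
    # planted rho recovered within a wide CI at n=54
    assert res.R == pytest.approx(rho, abs=0.25)
    assert res.p < 0.05
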