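"""Bland-Altman, ICC (against independent oracles) and the agreement table."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from strainrepro.agreement import (
    DegenerateDataError,
    PairedSeries,
    agreement_table,
    bland_altman,
    bland_altman_points,
    classify_agreement,
    icc,
)
from strainrepro.model import aggregate_dataset
from strainrepro.simulate import GeneratorConfig, ObserverSpec, generate


def icc_oracle(matrix, variant):
    """ICC from ANOVA sums of squares assembled by explicit Python loops.

    Deliberately scalar and loop-based: an independent route to the same
    two-way single-measures estimands as the vectorised implementation.
    """
    n = len(matrix)
    k = len(matrix[0])
    grand = 0.0
    for i in range(n):
        for j in range(k):
            grand += matrix[i][j]
    grand /= n * k
    row_means = []
    for i in range(n):
        total = 0.0
        for j in range(k):
            total += matrix[i][j]
        row_means.append(total / k)
    col_means = []
    for j in range(k):
        total = 0.0
        for i in range(n):
            total += matrix[i][j]
        col_means.append(total / n)
    ss_rows = 0.0
    for i in range(n):
        ss_rows += k * (row_means[i] - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        ss_cols += n * (col_means[j] - grand) ** 2
    ss_total = 0.0
    for i in range(n):
        for j in range(k):
            ss_total += (matrix[i][j] - grand) ** 2
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    if variant == "C-1":
        return (msr - mse) / (msr + (k - 1) * mse)
    if variant == "A-1":
        return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    raise ValueError(variant)


# ---------------------------------------------------------------- Bland-Altman

def test_bland_altman_identical_raters_collapse_to_zero():
    a = np.array([-26.0, -24.0, -28.0, -22.0])
    res = bland_altman(a=a, b=a)
    assert res.mean_diff == 0.0 and res.sd_diff == 0.0
    assert res.loa_lower == res.loa_upper == 0.0


def test_bland_altman_hand_computed_differences():
    # differences {-4, -1, 2}: mean -1, sample SD 3, LoA -1 -/+ 1.96*3
    res = bland_altman(a=np.array([-4.0, -1.0, 2.0]), b=np.zeros(3))
    assert res.mean_diff == pytest.approx(-1.0)
    assert res.sd_diff == pytest.approx(3.0)
    assert res.loa_lower == pytest.approx(-6.88)
    assert res.loa_upper == pytest.approx(4.88)


@given(
    diffs=st.lists(st.floats(-100, 100), min_size=2, max_size=12),
    base=st.lists(st.floats(-100, 100), min_size=12, max_size=12),
)
def test_bland_altman_antisymmetry_and_width(diffs, base):
    a = np.asarray(base[: len(diffs)]) + np.asarray(diffs)
    b = np.asarray(base[: len(diffs)])
    fwd, rev = bland_altman(a=a, b=b), bland_altman(a=b, b=a)
    assert rev.mean_diff == pytest.approx(-fwd.mean_diff, abs=1e-9)
    assert rev.loa_lower == pytest.approx(-fwd.loa_upper, abs=1e-9)
    assert rev.loa_upper == pytest.approx(-fwd.loa_lower, abs=1e-9)
    assert fwd.loa_upper - fwd.loa_lower == pytest.approx(2 * 1.96 * fwd.sd_diff, abs=1e-9)
    assert fwd.loa_lower - 1e-9 <= fwd.mean_diff <= fwd.loa_upper + 1e-9


def test_paired_series_requires_two_animals():
    with pytest.raises(ValueError):
        PairedSeries(("A01",), np.array([1.0]), np.array([2.0]))


# ------------------------------------------------------------------------ ICC

def test_icc_perfect_agreement_is_one():
    x = np.column_stack([[1.0, 2.0, 3.0, 4.0]] * 2)
    for variant in ("A-1", "C-1"):
        res = icc(x, variant=variant)
        assert res.estimate == pytest.approx(1.0)
        assert res.category == "excellent"


@pytest.mark.parametrize("shift", [0.5, 1.0, 2.0, 4.0])
def test_icc_additive_bias_separates_variants(shift):
    a = np.array([1.0, 2.0, 3.0, 4.0])
    x = np.column_stack([a, a + shift])
    assert icc(x, variant="C-1").estimate == pytest.approx(1.0)
    absolute = icc(x, variant="A-1").estimate
    assert absolute < 1.0
    bigger = icc(np.column_stack([a, a + 2 * shift]), variant="A-1").estimate
    assert bigger < absolute  # strictly decreasing in the bias magnitude


def test_icc_consistency_invariant_under_rater_shift():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, (6, 2)) + rng.normal(0, 2, (6, 1))
    base = icc(x, variant="C-1").estimate
    shifted = x.copy()
    shifted[:, 1] += 7.3
    assert icc(shifted, variant="C-1").estimate == pytest.approx(base, abs=1e-12)


def test_icc_matches_loop_oracle_on_random_matrices():
    rng = np.random.default_rng(2024)
    for _ in range(50):
        n = int(rng.integers(4, 9))
        k = int(rng.integers(2, 4))
        x = (rng.normal(0, 1, (n, k))
             + rng.normal(0, 2, (n, 1))
             + rng.normal(0, 1, (1, k)))
        for variant in ("A-1", "C-1"):
            mine = icc(x, variant=variant).estimate
            ref = icc_oracle(x.tolist(), variant)
            assert mine == pytest.approx(ref, abs=1e-10)


def test_icc_matches_pingouin_cross_check():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(5)
    n, k = 8, 3
    x = rng.normal(0, 1, (n, k)) + rng.normal(0, 2, (n, 1)) + rng.normal(0, 1, (1, k))
    long = pd.DataFrame({
        "subj": np.repeat(np.arange(n), k),
        "rater": np.tile(np.arange(k), n),
        "y": x.ravel(),
    })
    ref = pg.intraclass_corr(long, targets="subj", raters="rater", ratings="y")
    ref = ref.set_index("Type")
    for variant, label in [("A-1", "ICC(A,1)"), ("C-1", "ICC(C,1)"),
                           ("A-k", "ICC(A,k)"), ("C-k", "ICC(C,k)")]:
        mine = icc(x, variant=variant)
        row = ref.loc[label]
        assert mine.estimate == pytest.approx(row["ICC"], abs=1e-12)
        lo, hi = row["CI95"]  # pingouin rounds its CI to 2 decimals
        assert mine.ci_lower == pytest.approx(lo, abs=5e-3)
        assert mine.ci_upper == pytest.approx(hi, abs=5e-3)


def test_icc_ci_brackets_estimate():
    rng = np.random.default_rng(11)
    for _ in range(10):
        x = rng.normal(0, 1, (7, 2)) + rng.normal(0, 1.5, (7, 1))
        for variant in ("A-1", "C-1", "A-k", "C-k"):
            res = icc(x, variant=variant)
            assert res.ci_lower <= res.estimate <= res.ci_upper
            assert res.estimate <= 1.0 + 1e-12


def test_icc_rejects_incomplete_or_degenerate_input():
    x = np.array([[1.0, 2.0], [3.0, np.nan], [4.0, 5.0]])
    with pytest.raises(ValueError):
        icc(x)
    with pytest.raises(DegenerateDataError):
        icc(np.full((4, 2), 7.0))
    with pytest.raises(ValueError):
        icc(np.array([[1.0, 2.0]]))  # single subject


# -------------------------------------------------------------- classification

@pytest.mark.parametrize(
    "estimate, category",
    [
        (0.88, "excellent"), (0.75, "excellent"),
        (0.74, "good"), (0.60, "good"),
        (0.59, "fair"), (0.51, "fair"), (0.40, "fair"),
        (0.399, "poor"), (0.24, "poor"), (0.0, "poor"), (-1.60, "poor"),
    ],
)
def test_classify_agreement_boundaries(estimate, category):
    assert classify_agreement(estimate) == category


def test_classify_agreement_rejects_non_finite():
    with pytest.raises(ValueError):
        classify_agreement(math.nan)


# ------------------------------------------------------------ agreement table

def test_agreement_table_full_design(preset_globals_rep):
    result = agreement_table(preset_globals_rep)
    assert len(result.table) == 18
    assert not result.gaps
    # internal consistency with bland_altman invariants on every row
    t = result.table
    assert np.allclose(t["loa_upper"] - t["loa_lower"], 2 * 1.96 * t["sd_diff"])
    assert (t["icc_ci_lower"] <= t["icc"] + 1e-12).all()
    assert (t["icc"] <= t["icc_ci_upper"] + 1e-12).all()
    assert (t["n"] == 10).all()


def test_agreement_table_partial_design_records_gaps(preset_globals_rep):
    without_ver = preset_globals_rep[preset_globals_rep["state"] != "Ver"]
    result = agreement_table(without_ver)
    assert len(result.table) == 12
    assert len(result.gaps) == 6
    assert {g["state"] for g in result.gaps} == {"Ver"}


def test_agreement_table_noiseless_limit():
    cfg = GeneratorConfig(
        observers=[ObserverSpec(id="obs1"), ObserverSpec(id="obs2")],
        noise_sd=0.0,
        noise_sd_by_cell={},
    )
    data = generate(cfg, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        globals_rep = aggregate_dataset(data, average_over_replicates=False)
    result = agreement_table(globals_rep)
    assert len(result.table) == 18
    assert np.allclose(result.table["mean_diff"], 0.0)
    assert np.allclose(result.table["icc"], 1.0)
    assert (result.table["category"] == "excellent").all()


def test_bland_altman_points_cover_all_panels(preset_globals_rep):
    points = bland_altman_points(preset_globals_rep)
    # 18 panels x 10 animals
    assert len(points) == 180
    gls_bl = points[
        (points["comparison"] == "inter_observer")
        & (points["component"] == "longitudinal")
        & (points["state"] == "BL")
    ]
    assert len(gls_bl) == 10
    series_mean = gls_bl["difference"].mean()
    table = agreement_table(preset_globals_rep).table
    row = table[
        (table["comparison"] == "inter_observer")
        & (table["component"] == "longitudinal")
        & (table["state"] == "BL")
    ].iloc[0]
    assert series_mean == pytest.approx(row["mean_diff"])
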