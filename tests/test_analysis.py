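"""Study statistics: summaries, ANOVA, correlations, demarcation."""

import numpy as np
import pandas as pd
import pytest

from ssoptk.analysis import (
    AnalysisError,
    cell_summaries,
    correlation_matrix,
    detect_demarcation,
    two_way_anova,
)
from ssoptk.scenes import make_ischemia_scene
from ssoptk.study import StudySpec, simulate_study

REPORTED_STO2_DROPS = {
    ("TVIO", "LL", "sto2"): 29.8,
    ("TVIO", "LM", "sto2"): 36.3,
    ("HAO", "LL", "sto2"): 13.6,
    ("HAO", "LM", "sto2"): 19.8,
    ("TVIO", "LL", "ref_sto2"): 23.0,
    ("TVIO", "LM", "ref_sto2"): 21.1,
    ("HAO", "LL", "ref_sto2"): 12.0,
    ("HAO", "LM", "ref_sto2"): 12.9,
}


@pytest.fixture(scope="module")
def exact_table():
    return simulate_study(StudySpec().with_zero_noise())


def test_saturation_drops_match_reported_values(exact_table):
    """From the exact cell means, every reported baseline-to-ischemia StO2
    drop (imaging and contact oximeter, both groups) is reproduced."""
    _, deltas = cell_summaries(exact_table)
    idx = deltas.set_index(["group", "lobe", "variable"])["delta"]
    for key, expected in REPORTED_STO2_DROPS.items():
        assert idx.loc[key] == pytest.approx(expected, abs=1e-9)


def test_lactate_delta_reported_as_rise(exact_table):
    _, deltas = cell_summaries(exact_table)
    idx = deltas.set_index(["group", "lobe", "variable"])["delta"]
    assert idx.loc[("TVIO", "LL", "lactate")] == pytest.approx(8.5 - 1.3, abs=1e-9)
    assert idx.loc[("HAO", "LM", "lactate")] == pytest.approx(0.0, abs=1e-9)


def test_no_change_gives_zero_delta(exact_table):
    frozen = exact_table.copy()
    t0 = frozen[frozen.timepoint == "T0"].copy()
    t1 = t0.copy()
    t1["timepoint"] = "T1"
    _, deltas = cell_summaries(pd.concat([t0, t1]))
    assert np.allclose(deltas["delta"], 0.0)


def test_missing_cell_reported_explicitly(exact_table):
    partial = exact_table[exact_table.timepoint != "T1"]
    _, deltas = cell_summaries(partial)
    assert deltas["missing"].all()


def _manual_two_way_anova(df, response, fa, fb):
    """Textbook balanced two-way sums-of-squares arithmetic (independent
    of the statsmodels fitting route)."""
    y = df[response].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    a_means = df.groupby(fa)[response].mean()
    b_means = df.groupby(fb)[response].mean()
    cell_means = df.groupby([fa, fb])[response].mean()
    n_a = df.groupby(fa).size()
    n_b = df.groupby(fb).size()
    n_cell = df.groupby([fa, fb]).size()
    ss_a = (n_a * (a_means - grand) ** 2).sum()
    ss_b = (n_b * (b_means - grand) ** 2).sum()
    ss_cells = (n_cell * (cell_means - grand) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    ss_e = ss_total - ss_cells
    df_a = len(a_means) - 1
    df_b = len(b_means) - 1
    df_ab = df_a * df_b
    df_e = len(y) - len(cell_means)
    ms_e = ss_e / df_e
    return {
        "A": (ss_a, ss_a / df_a / ms_e),
        "B": (ss_b, ss_b / df_b / ms_e),
        "AB": (ss_ab, ss_ab / df_ab / ms_e),
    }


def test_anova_matches_manual_sums_of_squares():
    """A small balanced 2x2x2 table checked against pencil-and-paper
    two-way ANOVA arithmetic."""
    df = pd.DataFrame(
        {
            "lobe": ["LL"] * 4 + ["RM"] * 4,
            "timepoint": (["T0", "T0", "T1", "T1"] * 2),
            "sto2": [46.0, 48.0, 16.0, 18.0, 47.0, 49.0, 44.0, 42.0],
        }
    )
    manual = _manual_two_way_anova(df, "sto2", "lobe", "timepoint")
    res = two_way_anova(df, response="sto2")
    tab = res.anova_table
    assert tab.loc["C(lobe)", "sum_sq"] == pytest.approx(manual["A"][0], rel=1e-10)
    assert tab.loc["C(timepoint)", "sum_sq"] == pytest.approx(manual["B"][0], rel=1e-10)
    assert tab.loc["C(lobe):C(timepoint)", "sum_sq"] == pytest.approx(manual["AB"][0], rel=1e-10)
    assert tab.loc["C(lobe)", "F"] == pytest.approx(manual["A"][1], rel=1e-10)
    assert tab.loc["C(timepoint)", "F"] == pytest.approx(manual["B"][1], rel=1e-10)


def test_constant_response_yields_zero_f_unit_p():
    df = pd.DataFrame(
        {
            "lobe": ["LL", "LL", "RM", "RM"] * 2,
            "timepoint": ["T0", "T1"] * 4,
            "sto2": [42.0] * 8,
        }
    )
    res = two_way_anova(df, response="sto2")
    assert (res.anova_table["F"] == 0).all()
    assert (res.anova_table["PR(>F)"] == 1).all()
    assert (res.comparisons["p_adj"] == 1).all()


def test_anova_invariant_to_row_order_and_labels():
    tab = simulate_study(StudySpec(seed=2))
    res1 = two_way_anova(tab, group="TVIO")
    shuffled = tab.sample(frac=1.0, random_state=4)
    shuffled = shuffled.assign(animal_id=shuffled["animal_id"].str.replace("TVIO", "pig"))
    res2 = two_way_anova(shuffled, group="TVIO")
    pd.testing.assert_frame_equal(
        res1.anova_table, res2.anova_table, check_exact=False, rtol=1e-10
    )
    c1 = res1.comparisons.sort_values(["lobe", "level_a", "level_b"]).reset_index(drop=True)
    c2 = res2.comparisons.sort_values(["lobe", "level_a", "level_b"]).reset_index(drop=True)
    assert np.allclose(c1["p_adj"], c2["p_adj"])


def test_adjusted_p_never_below_raw(exact_table):
    tab = simulate_study(StudySpec(seed=3))
    res = two_way_anova(tab, group="HAO")
    assert (res.comparisons["p_adj"] >= res.comparisons["p_raw"] - 1e-15).all()


def test_underpopulated_cells_named_in_error():
    tab = simulate_study(StudySpec(seed=1))
    idx = tab[(tab.group == "TVIO") & (tab.lobe == "RM") & (tab.timepoint == "T2")].index
    sub = tab.drop(idx[1:])  # leave a single replicate in one cell
    with pytest.raises(AnalysisError, match="RM"):
        two_way_anova(sub, group="TVIO")


def test_correlation_trivial_cases():
    df = pd.DataFrame({"sto2": [1.0, 2, 3, 4], "lactate": [2.0, 4, 6, 8],
                       "ref_sto2": [5.0, 5, 5, 5]})
    corr = correlation_matrix(df).set_index(["var_x", "var_y"])
    assert corr.loc[("sto2", "lactate"), "r"] == pytest.approx(1.0)
    assert corr.loc[("sto2", "lactate"), "r"] == corr.loc[("lactate", "sto2"), "r"]
    assert corr.loc[("sto2", "sto2"), "r"] == 1.0
    assert np.isnan(corr.loc[("sto2", "ref_sto2"), "r"])
    assert corr.loc[("sto2", "ref_sto2"), "note"] == "zero variance"


def test_correlation_pairwise_complete():
    df = pd.DataFrame({
        "sto2": [1.0, 2, 3, 4, np.nan],
        "lactate": [8.0, 6, 4, 2, 1],
        "ref_sto2": [1.0, 2, 3, 4, 5],
    })
    corr = correlation_matrix(df).set_index(["var_x", "var_y"])
    assert corr.loc[("sto2", "lactate"), "n"] == 4
    assert corr.loc[("sto2", "lactate"), "r"] == pytest.approx(-1.0)


def test_demarcation_covers_left_territory_only():
    """On the total-occlusion ischemic scene the detected territory covers
    nearly all of LL+LM and almost none of RM (ground-truth masks)."""
    scene = make_ischemia_scene("TVIO", "T1", shape=(128, 160))
    res = detect_demarcation(scene.sto2_map, threshold=25.0,
                             pixel_pitch=scene.pixel_pitch)
    left = scene.lobe_masks["LL"] | scene.lobe_masks["LM"]
    rm = scene.lobe_masks["RM"]
    assert res.mask[left].mean() >= 0.95
    assert res.mask[rm].mean() <= 0.05
    assert len(res.boundary) > 0
    assert np.isfinite(res.sharpness)


def test_arterial_occlusion_demarcation_less_sharp():
    """The wide transition band of arterial-only occlusion gives a lower
    boundary-gradient score than total occlusion's sharp line."""
    tvio = make_ischemia_scene("TVIO", "T1", shape=(128, 160))
    hao = make_ischemia_scene("HAO", "T1", shape=(128, 160))
    s_tvio = detect_demarcation(tvio.sto2_map, pixel_pitch=tvio.pixel_pitch).sharpness
    s_hao = detect_demarcation(hao.sto2_map, pixel_pitch=hao.pixel_pitch).sharpness
    assert s_hao < s_tvio


def test_fully_oxygenated_map_gives_empty_mask():
    res = detect_demarcation(np.full((32, 32), 100.0))
    assert not res.mask.any()
    assert len(res.boundary) == 0
    assert np.isnan(res.sharpness)
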