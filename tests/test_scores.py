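"""Statistics: exact Mann-Whitney U against brute-force enumeration,
selection rules, normalization, and composite-score properties."""

import itertools

import numpy as np
import pandas as pd
import pytest

import fibroscope as fs
from fibroscope.scores import _bh_qvalues, composite_scores, select_traits

from helpers import MPP  # noqa: F401  (keeps the import path consistent)


def brute_force_mwu(x, y):
    """Exact two-sided MWU p by enumerating all group assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum((xi > yj) for xi in x for yj in y)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        xs = pooled[list(comb)]
        ys = np.delete(pooled, list(comb))
        us.append(sum((xi > yj) for xi in xs for yj in ys))
    us = np.asarray(us)
    p_le = (us <= u_obs).mean()
    p_ge = (us >= u_obs).mean()
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def test_mwu_textbook_example():
    res = fs.mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    assert res.U == 0.0
    assert res.p == pytest.approx(0.1)
    assert res.method == "exact"


def test_mwu_six_vs_six_separation():
    res = fs.mann_whitney_u(np.arange(6.0), np.arange(10.0, 16.0))
    assert res.U == 0.0
    assert res.p == pytest.approx(2.0 / 924.0)


def test_mwu_symmetry_and_u_identity():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n1, n2 = rng.integers(1, 7, size=2)
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        a = fs.mann_whitney_u(x, y)
        b = fs.mann_whitney_u(y, x)
        assert a.U + b.U == pytest.approx(n1 * n2)  # U1 + U2 = n1*n2
        assert a.p == pytest.approx(b.p)


def test_mwu_exact_matches_brute_force():
    rng = np.random.default_rng(1)
    for _ in range(100):
        n1, n2 = rng.integers(2, 7, size=2)
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        u_bf, p_bf = brute_force_mwu(x, y)
        res = fs.mann_whitney_u(x, y)
        assert res.method == "exact"
        assert res.U == pytest.approx(u_bf)
        assert res.p == pytest.approx(p_bf, abs=1e-12)


def test_mwu_matches_scipy():
    from scipy import stats

    rng = np.random.default_rng(2)
    for _ in range(20):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        ours = fs.mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours.U == pytest.approx(ref.statistic)
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)


def test_mwu_ties_fall_back_to_asymptotic():
    res = fs.mann_whitney_u([1.0, 1.0, 2.0], [1.0, 3.0, 4.0])
    assert res.method == "asymptotic"
    with pytest.raises(ValueError):
        fs.mann_whitney_u([1.0, 1.0], [1.0, 2.0], method="exact")


def test_mwu_asymptotic_close_to_exact():
    rng = np.random.default_rng(3)
    for _ in range(20):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        pe = fs.mann_whitney_u(x, y, method="exact").p
        pa = fs.mann_whitney_u(x, y, method="asymptotic").p
        assert pa == pytest.approx(pe, abs=0.03)


def test_mwu_empty_raises():
    with pytest.raises(ValueError):
        fs.mann_whitney_u([], [1.0])


def test_group_mean_change_arithmetic():
    assert fs.group_mean_change([3.0, 5.0], [2.0, 2.0]) == pytest.approx(100.0)
    assert fs.group_mean_change([1.0], [2.0]) == pytest.approx(-50.0)
    # signed values: -2 -> -1 is a +50% change relative to |reference|
    assert fs.group_mean_change([-1.0], [-2.0]) == pytest.approx(50.0)
    assert fs.group_mean_change([0.0], [0.0]) == 0.0
    assert fs.group_mean_change([1.0], [0.0]) == np.inf
    with pytest.raises(ValueError):
        fs.group_mean_change([-1.0], [2.0], nonnegative=True)
    with pytest.raises(ValueError):
        fs.group_mean_change([], [1.0])


def _toy_study(n=6):
    ids = [f"P{i}_peri" for i in range(n)] + [f"P{i}_rem" for i in range(n)]
    return pd.DataFrame(
        {
            "sample_id": ids,
            "patient_id": [f"P{i}" for i in range(n)] * 2,
            "region": ["peri_papillary"] * n + ["remote"] * n,
        }
    )


def _toy_catalog():
    return fs.trait_catalog(("whole",))


def test_select_traits_thresholds():
    study = _toy_study()
    catalog = _toy_catalog()
    name_big = "whole.content.collagen_area_fraction.value"
    name_small = "whole.content.collagen_area.value"
    name_nsig = "whole.content.nodularity.value"
    rng = np.random.default_rng(4)
    traits = pd.DataFrame(
        {
            # +100% change, perfectly separated: selected
            name_big: np.r_[np.linspace(2.0, 2.2, 6), np.linspace(1.0, 1.1, 6)],
            # +10% change only: excluded by the change threshold
            name_small: np.r_[np.linspace(1.10, 1.15, 6), np.linspace(1.00, 1.05, 6)],
            # big change but hopeless overlap: excluded by the p threshold
            name_nsig: np.r_[rng.permutation(np.linspace(0, 3, 6)) + 0.001,
                             rng.permutation(np.linspace(0, 3, 6))],
        },
        index=_toy_study()["sample_id"],
    )
    traits.index.name = "sample_id"
    sel = select_traits(traits, study, catalog)
    assert name_big in sel.selected
    assert name_small not in sel.selected
    table = sel.table
    assert table.loc[name_big, "delta_pct"] == pytest.approx(100.0, abs=5.0)
    assert table.loc[name_big, "method"] == "exact"
    assert not table.loc[name_nsig, "selected"] or table.loc[name_nsig, "p"] < 0.05


def test_select_traits_missing_excluded():
    study = _toy_study()
    catalog = _toy_catalog()
    name = "whole.content.collagen_area_fraction.value"
    col = np.full(12, np.nan)
    col[:3] = [1.0, 2.0, 3.0]
    traits = pd.DataFrame({name: col}, index=study["sample_id"])
    sel = select_traits(traits, study, catalog)
    assert sel.table.loc[name, "excluded_reason"] == "missing_gt_50pct"
    assert not sel.table.loc[name, "selected"]


def test_select_traits_literal_greater_direction():
    """p_direction='greater' implements the literal p > alpha reading."""
    study = _toy_study()
    catalog = _toy_catalog()
    name = "whole.content.collagen_area_fraction.value"
    traits = pd.DataFrame(
        {name: np.r_[np.linspace(2.0, 2.2, 6), np.linspace(1.0, 1.1, 6)]},
        index=study["sample_id"],
    )
    assert name in select_traits(traits, study, catalog, p_direction="less").selected
    assert name not in select_traits(traits, study, catalog, p_direction="greater").selected


def test_normalize_minmax_values():
    catalog = _toy_catalog()
    traits = pd.DataFrame({"whole.content.collagen_area.value": [2.0, 4.0, 6.0]})
    out = fs.normalize_traits(traits, catalog)
    assert np.allclose(out.iloc[:, 0], [0.0, 0.5, 1.0])


def test_normalize_affine_invariance():
    catalog = _toy_catalog()
    rng = np.random.default_rng(5)
    v = rng.normal(size=8)
    a = fs.normalize_traits(
        pd.DataFrame({"whole.content.collagen_area.value": v}), catalog
    )
    b = fs.normalize_traits(
        pd.DataFrame({"whole.content.collagen_area.value": 3.0 * v + 11.0}), catalog
    )
    assert np.allclose(a.to_numpy(), b.to_numpy())


def test_normalize_orients_negative_direction():
    catalog = _toy_catalog()
    name = "whole.architecture.orientation_order.value"  # direction -1
    out = fs.normalize_traits(pd.DataFrame({name: [0.0, 1.0]}), catalog)
    assert np.allclose(out[name], [1.0, 0.0])  # flipped: low order = more fibrotic


def test_normalize_drops_constant():
    catalog = _toy_catalog()
    out = fs.normalize_traits(
        pd.DataFrame({"whole.content.collagen_area.value": [2.0, 2.0, 2.0]}), catalog
    )
    assert out.shape[1] == 0


def test_significance_stars():
    assert fs.significance_stars(0.005) == "**"
    assert fs.significance_stars(0.03) == "*"
    assert fs.significance_stars(0.2) == ""
    assert fs.significance_stars(float("nan")) == ""


def _selection_for(traits, study, catalog):
    return select_traits(traits, study, catalog)


def test_composite_families_always_reported():
    study = _toy_study()
    catalog = _toy_catalog()
    name = "whole.content.collagen_area_fraction.value"
    traits = pd.DataFrame(
        {name: np.r_[np.linspace(2.0, 2.2, 6), np.linspace(1.0, 1.1, 6)]},
        index=study["sample_id"],
    )
    sel = _selection_for(traits, study, catalog)
    normalized = fs.normalize_traits(traits[list(sel.selected)], catalog)
    res = composite_scores(normalized, study, sel, catalog)
    assert set(fs.scores.SCORE_FAMILIES) == {"Ph-FCS", "CCS", "MCS", "ACS"}
    for fam in fs.scores.SCORE_FAMILIES:
        assert fam in res.scores.columns
        assert fam in res.stats.index
    # only the content family had a selected trait; others are NaN, not 0
    assert res.scores["CCS"].notna().all()
    assert res.scores["MCS"].isna().all()
    assert res.stats.loc["Ph-FCS", "p"] < 0.05


def test_composite_scale_and_monotonicity():
    """One selected trait: the composite equals the scaled normalized trait,
    so score ordering follows the trait ordering."""
    study = _toy_study()
    catalog = _toy_catalog()
    name = "whole.content.collagen_area_fraction.value"
    vals = np.r_[np.linspace(2.0, 3.0, 6), np.linspace(1.0, 1.4, 6)]
    traits = pd.DataFrame({name: vals}, index=study["sample_id"])
    sel = _selection_for(traits, study, catalog)
    normalized = fs.normalize_traits(traits[[name]], catalog)
    res = composite_scores(normalized, study, sel, catalog, scale=10.0)
    expected = 10.0 * (vals - vals.min()) / (vals.max() - vals.min())
    assert np.allclose(res.scores["Ph-FCS"].to_numpy(), expected)
    assert res.scores["Ph-FCS"].max() <= 10.0 and res.scores["Ph-FCS"].min() >= 0.0


def test_composite_empty_selection():
    study = _toy_study()
    catalog = _toy_catalog()
    name = "whole.content.collagen_area_fraction.value"
    rng = np.random.default_rng(6)
    traits = pd.DataFrame({name: rng.normal(10.0, 0.1, size=12)}, index=study["sample_id"])
    sel = _selection_for(traits, study, catalog)
    assert len(sel.selected) == 0
    res = composite_scores(fs.normalize_traits(traits[[]], catalog), study, sel, catalog)
    assert res.empty_selection
    assert res.scores["Ph-FCS"].isna().all()
    assert np.isnan(res.stats.loc["Ph-FCS", "p"])


def test_composite_paired_test():
    study = _toy_study()
    catalog = _toy_catalog()
    name = "whole.content.collagen_area_fraction.value"
    traits = pd.DataFrame(
        {name: np.r_[np.linspace(2.0, 2.5, 6), np.linspace(1.0, 1.2, 6)]},
        index=study["sample_id"],
    )
    sel = _selection_for(traits, study, catalog)
    normalized = fs.normalize_traits(traits[list(sel.selected)], catalog)
    res = composite_scores(normalized, study, sel, catalog, test="paired")
    assert res.stats.loc["Ph-FCS", "method"] == "wilcoxon_signed_rank"
    assert res.stats.loc["Ph-FCS", "p"] < 0.05


def test_score_study_permutation_invariance(study_result, small_bundle):
    """Shuffling sample rows does not change selection or group statistics."""
    traits = study_result.traits
    rng = np.random.default_rng(7)
    perm = rng.permutation(len(traits))
    shuffled = traits.iloc[perm]
    res = fs.score_study(shuffled, small_bundle.table)
    base = study_result.results
    for comp in base:
        assert set(base[comp].selection.selected) == set(res[comp].selection.selected)
        pd.testing.assert_frame_equal(
            base[comp].stats, res[comp].stats, check_exact=False, rtol=1e-12
        )


def test_bh_qvalues():
    p = np.array([0.01, 0.02, 0.03, 0.04])
    q = _bh_qvalues(p)
    assert np.all(q >= p - 1e-15)
    assert np.all(np.diff(q[np.argsort(p)]) >= -1e-15)
    assert q[-1] == pytest.approx(0.04)
    q_nan = _bh_qvalues(np.array([0.01, np.nan]))
    assert np.isnan(q_nan[1]) and q_nan[0] == pytest.approx(0.01)


def test_report_is_json_serializable(study_result):
    import json

    text = json.dumps(study_result.report)
    assert "compartments" in json.loads(text)
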