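"""Generator correctness: determinism, ground-truth bookkeeping, and the
analytic Poisson-branching expectation."""

import numpy as np
import pytest

import fibroscope as fs
from fibroscope.synthgen import merge_fiber_sets


def test_empty_fiber_set():
    params = fs.FiberSynthesisParams(n_fibers=0, canvas=(64, 64))
    out = fs.make_fiber_set(params)
    assert out.fibers == []
    assert not out.truth_mask.any()


def test_single_unbranched_fiber():
    params = fs.FiberSynthesisParams(
        n_fibers=1, branch_rate=0.0, canvas=(512, 512), seed=3
    )
    out = fs.make_fiber_set(params)
    assert len(out.fibers) == 1
    f = out.fibers[0]
    assert f.n_branches == 0
    assert len(f.polylines) == 1
    assert f.arc_length_um > 0
    assert out.truth_mask.sum() == f.footprint_area_px


def test_determinism_bit_identical():
    params = fs.FiberSynthesisParams(n_fibers=10, canvas=(128, 128), seed=42)
    a = fs.make_fiber_set(params)
    b = fs.make_fiber_set(params)
    assert np.array_equal(a.truth_mask, b.truth_mask)
    for fa, fb in zip(a.fibers, b.fibers):
        assert fa.n_branches == fb.n_branches
        assert fa.arc_length_um == fb.arc_length_um
        assert np.array_equal(fa.pixel_indices, fb.pixel_indices)
    img_a = fs.render_trichrome(a, seed=5)
    img_b = fs.render_trichrome(b, seed=5)
    assert np.array_equal(img_a.pixels, img_b.pixels)


def test_seed_changes_output():
    p1 = fs.FiberSynthesisParams(n_fibers=10, canvas=(128, 128), seed=1)
    p2 = fs.FiberSynthesisParams(n_fibers=10, canvas=(128, 128), seed=2)
    assert not np.array_equal(
        fs.make_fiber_set(p1).truth_mask, fs.make_fiber_set(p2).truth_mask
    )


def test_poisson_branch_expectation():
    """Junction count matches the analytic Poisson-process expectation.

    Branch events are Bernoulli per step with probability rate*step_um/100,
    so conditional on the eligible arc the total count is a sum of
    independent Bernoullis with mean exactly rate * eligible_arc / 100.
    """
    rate = 2.0
    total_junc, total_eligible = 0, 0.0
    for seed in range(200):
        params = fs.FiberSynthesisParams(
            n_fibers=4,
            canvas=(600, 600),
            seed=seed,
            branch_rate=rate,
            length_um=(50.0, 5.0),
            thickness_um=(1.0, 0.0),
        )
        out = fs.make_fiber_set(params)
        total_junc += out.total_junctions
        total_eligible += out.total_eligible_arc_um
    expected = rate / 100.0 * total_eligible
    assert expected > 200  # the experiment is informative
    z = (total_junc - expected) / np.sqrt(expected)
    assert abs(z) < 4.0, f"junction count z-score {z:.2f} vs Poisson expectation"


def test_zero_branch_rate_never_branches():
    for seed in range(20):
        params = fs.FiberSynthesisParams(
            n_fibers=5, branch_rate=0.0, canvas=(256, 256), seed=seed
        )
        assert fs.make_fiber_set(params).total_junctions == 0


def test_footprint_bookkeeping():
    params = fs.FiberSynthesisParams(n_fibers=12, canvas=(256, 256), seed=9)
    out = fs.make_fiber_set(params)
    union = int(out.truth_mask.sum())
    total = sum(f.footprint_area_px for f in out.fibers)
    assert union <= total  # overlaps only ever reduce the union
    assert union > 0
    # flat indices are valid and unique per fiber
    for f in out.fibers:
        assert f.pixel_indices.size == np.unique(f.pixel_indices).size
        assert f.pixel_indices.max() < 256 * 256


def test_merge_fiber_sets_reindexes():
    pa = fs.FiberSynthesisParams(n_fibers=3, canvas=(128, 128), seed=1)
    pb = fs.FiberSynthesisParams(n_fibers=4, canvas=(128, 128), seed=2)
    merged = merge_fiber_sets(fs.make_fiber_set(pa), fs.make_fiber_set(pb))
    ids = [f.fiber_id for f in merged.fibers]
    assert len(ids) == len(set(ids))


def test_render_separates_stroke_and_background_stains():
    """Deconvolving a rendered tile recovers the collagen stain on strokes
    and only the cytoplasm stain elsewhere."""
    params = fs.FiberSynthesisParams(n_fibers=8, canvas=(128, 128), seed=4)
    out = fs.make_fiber_set(params)
    bg_model = fs.BackgroundParams()
    img = fs.render_trichrome(out, background=bg_model, seed=0)
    conc = fs.deconvolve_stains(img)
    stroke_coll = conc[..., 0][out.truth_mask].mean()
    bg_coll = conc[..., 0][~out.truth_mask].mean()
    assert stroke_coll > 5 * bg_coll
    assert stroke_coll == pytest.approx(bg_model.collagen_od, rel=0.15)
    bg_cyto = conc[..., 1][~out.truth_mask].mean()
    assert bg_cyto == pytest.approx(bg_model.cytoplasm_od, rel=0.15)


def test_invalid_params_raise():
    with pytest.raises(ValueError):
        fs.FiberSynthesisParams(n_fibers=-1)
    with pytest.raises(ValueError):
        fs.FiberSynthesisParams(mpp=0.0)
    with pytest.raises(ValueError):
        fs.FiberSynthesisParams(branch_rate=-0.1)
    with pytest.raises(ValueError):
        # canvas far too small for the default 60 um mean fiber length
        fs.make_fiber_set(fs.FiberSynthesisParams(canvas=(8, 8)))


def test_study_structure(small_bundle, small_design):
    assert len(small_bundle.samples) == small_design.n_patients * 2
    table = small_bundle.table
    assert set(table["region"]) == {"peri_papillary", "remote"}
    counts = table.groupby("patient_id")["region"].nunique()
    assert (counts == 2).all()  # paired design: both regions per patient
    for s in small_bundle.samples:
        assert s.image.pixels.shape == (256, 256, 3)
        assert s.roi["type"] == "FeatureCollection"
        labels = {f["properties"]["label"] for f in s.roi["features"]}
        assert labels == {"endocardium", "myocardium"}


def test_study_determinism(small_design, small_bundle):
    again = fs.make_study(small_design)
    for a, b in zip(small_bundle.samples, again.samples):
        assert a.sample_id == b.sample_id
        assert np.array_equal(a.image.pixels, b.image.pixels)


def test_thickness_multiplier_exact_by_construction():
    """With zero thickness sd the peri/remote true-width ratio is exactly
    the design multiplier, patient by patient."""
    base = fs.FiberSynthesisParams(
        n_fibers=6, canvas=(256, 256), length_um=(40.0, 5.0), thickness_um=(1.5, 0.0)
    )
    design = fs.StudyDesignParams(
        n_patients=3, base=base, thickness_mult=2.0, endocardial_band_um=0.0, seed=11
    )
    bundle = fs.make_study(design)
    widths = {}
    for s in bundle.samples:
        hw = {f.half_width_px for f in s.truth.fibers}
        assert len(hw) == 1  # sd=0: all fibers share the exact design width
        widths[(s.patient_id, s.region)] = hw.pop()
    for p in {k[0] for k in widths}:
        ratio = widths[(p, "peri_papillary")] / widths[(p, "remote")]
        assert ratio == pytest.approx(2.0, abs=1e-12)


def test_branch_multiplier_raises_junctions():
    base = fs.FiberSynthesisParams(
        n_fibers=15, canvas=(256, 256), length_um=(40.0, 5.0), branch_rate=0.5
    )
    design = fs.StudyDesignParams(
        n_patients=4, base=base, branch_rate_mult=6.0, endocardial_band_um=0.0, seed=5
    )
    bundle = fs.make_study(design)
    peri = sum(s.truth.total_junctions for s in bundle.samples if s.region == "peri_papillary")
    remote = sum(s.truth.total_junctions for s in bundle.samples if s.region == "remote")
    assert peri > remote


def test_write_study_round_trip(tmp_path, small_bundle):
    import pandas as pd
    from PIL import Image

    manifest = fs.write_study(small_bundle, tmp_path)
    table = pd.read_csv(manifest)
    assert len(table) == len(small_bundle.samples)
    first = table.iloc[0]
    arr = np.asarray(Image.open(tmp_path / first["image_path"]))
    assert np.array_equal(arr, small_bundle.samples[0].image.pixels)
    roiset = fs.load_rois(tmp_path / first["roi_path"])
    assert len(roiset.polygons) == 2
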