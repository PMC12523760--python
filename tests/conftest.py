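"""Shared fixtures: one small synthetic paired study, generated and analyzed
once per session, plus the trait catalog."""

from __future__ import annotations

import pytest

import fibroscope as fs


@pytest.fixture(scope="session")
def catalog():
    return fs.trait_catalog()


@pytest.fixture(scope="session")
def small_design():
    base = fs.FiberSynthesisParams(
        n_fibers=25, length_um=(40.0, 10.0), canvas=(256, 256), orientation_kappa=0.5
    )
    return fs.StudyDesignParams(n_patients=6, base=base, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_design):
    return fs.make_study(small_design)


@pytest.fixture(scope="session")
def study_result(small_bundle):
    return fs.run_study(small_bundle)


@pytest.fixture(scope="session")
def analyzed_sample(small_bundle, catalog):
    from fibroscope.pipeline import analyze_sample

    sample = small_bundle.samples[0]
    return analyze_sample(sample.image, rois=sample.roi, catalog=catalog)
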