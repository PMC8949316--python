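"""Generator correctness: the packaged composition config reproduces the
study's printed values, sections are reproducible and noise-calibrated, and
the expression study carries the planted couplings."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from glioims.ims_proc import tic_normalize
from glioims.lipid_chem import LipidClass, parse_shorthand
from glioims.synth_data import (
    NoiseModel,
    Region,
    SectionSpec,
    default_section_spec,
    default_study_spec,
    simulate_expression_study,
    simulate_section,
)


# ---------------------------------------------------------------------------
# composition profiles
# ---------------------------------------------------------------------------

def test_configured_class_fold_changes_are_exact(study_config):
    profiles, _, _ = study_config
    hv, gv, ht = (profiles[k] for k in
                  ("healthy_vehicle", "gbm_vehicle", "healthy_tmz"))
    assert gv.class_share(LipidClass.PE) / hv.class_share(LipidClass.PE) == pytest.approx(1.5)
    assert gv.class_share(LipidClass.PI) / hv.class_share(LipidClass.PI) == pytest.approx(3.6)
    assert gv.class_share(LipidClass.SM) / hv.class_share(LipidClass.SM) == pytest.approx(1.8)
    assert hv.class_share(LipidClass.SULF) / gv.class_share(LipidClass.SULF) == pytest.approx(2.9)
    assert ht.class_share(LipidClass.PI) / hv.class_share(LipidClass.PI) == pytest.approx(2.2)
    assert hv.class_share(LipidClass.SULF) / ht.class_share(LipidClass.SULF) == pytest.approx(1.6)
    assert hv.class_share(LipidClass.HEXCER) / ht.class_share(LipidClass.HEXCER) == pytest.approx(1.8)


def test_configured_species_percentages(study_config):
    profiles, _, _ = study_config
    hv, gv, ht = (profiles[k] for k in
                  ("healthy_vehicle", "gbm_vehicle", "healthy_tmz"))
    assert hv.species_molpct(parse_shorthand("PE 36:1")) == pytest.approx(35.6)
    assert hv.species_molpct(parse_shorthand("PE 40:6")) == pytest.approx(13.9)
    assert hv.species_molpct(parse_shorthand("PE P-36:2")) == pytest.approx(20.8)
    assert hv.species_molpct(parse_shorthand("PI 38:4")) == pytest.approx(54.9)
    assert gv.species_molpct(parse_shorthand("PI 38:4")) == pytest.approx(75.7)
    assert gv.species_molpct(parse_shorthand("PE 36:1")) == pytest.approx(30.0)
    assert gv.species_molpct(parse_shorthand("SM d34:1")) == pytest.approx(37.5)
    assert ht.species_molpct(parse_shorthand("PI 38:4")) == pytest.approx(80.4)
    assert ht.species_molpct(parse_shorthand("PE P-40:6")) == pytest.approx(23.5)


def test_fraction_normalisation(study_config, panel):
    profiles, _, _ = study_config
    for profile in profiles.values():
        for cls, fractions in profile.species_fractions.items():
            assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-9)
        for polarity in ("negative", "positive"):
            assert sum(profile.class_shares[polarity].values()) == pytest.approx(1.0, abs=1e-9)
            vec = profile.expected_intensity(panel, polarity)
            assert vec.sum() == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# section simulation
# ---------------------------------------------------------------------------

def test_section_reproducible_from_seed(study_config, panel):
    profiles, noise, _ = study_config
    spec = default_section_spec("gbm", "vehicle", grid=(24, 24), seed=5)
    a, roi_a = simulate_section(spec, profiles, panel, noise)
    b, roi_b = simulate_section(spec, profiles, panel, noise)
    assert np.array_equal(roi_a, roi_b)
    assert all(np.array_equal(x, y) for x, y in zip(a.mzs, b.mzs))
    assert all(np.array_equal(x, y) for x, y in zip(a.intensities, b.intensities))


def test_noise_free_pixels_equal_profile(study_config, panel):
    profiles, _, _ = study_config
    spec = default_section_spec("healthy", "vehicle", grid=(24, 24), seed=2)
    dataset, roi = simulate_section(
        spec, profiles, panel, NoiseModel(sigma=0.0, mz_jitter_ppm=0.0)
    )
    expected = profiles["healthy_vehicle"].expected_intensity(panel, "negative")
    expected = expected[expected > 0]
    in_roi = roi[dataset.coords[:, 1], dataset.coords[:, 0]]
    for i in np.flatnonzero(in_roi)[:20]:
        np.testing.assert_allclose(dataset.intensities[i], expected, rtol=1e-12)


def test_mz_jitter_bounded(study_config, panel):
    profiles, _, _ = study_config
    spec = default_section_spec("gbm", "vehicle", grid=(24, 24), seed=3)
    dataset, roi = simulate_section(
        spec, profiles, panel, NoiseModel(sigma=0.0, mz_jitter_ppm=3.0)
    )
    theoretical = panel.subset("negative").mzs
    in_roi = roi[dataset.coords[:, 1], dataset.coords[:, 0]]
    for i in np.flatnonzero(in_roi)[:50]:
        obs = np.sort(dataset.mzs[i])
        ppm = (obs - theoretical) / theoretical * 1e6
        assert np.abs(ppm).max() <= 3.0 + 1e-9


def test_class_share_estimator_montecarlo(study_config, panel):
    # 1000 proliferative pixels at sigma 0.3: the mean-vector estimator of the
    # PI 38:4 within-class fraction stays within half a point of the profile
    profiles, _, _ = study_config
    gv = profiles["gbm_vehicle"]
    rng = np.random.default_rng(42)
    base = gv.expected_intensity(panel, "negative")
    pixels = base * np.exp(0.3 * rng.standard_normal((1000, base.size)))
    mean_vec = pixels.mean(axis=0)
    sub = panel.subset("negative")
    pi_idx = [i for i, e in enumerate(sub.entries)
              if e.species.lipid_class is LipidClass.PI]
    target = [i for i in pi_idx
              if sub.entries[i].species == parse_shorthand("PI 38:4")][0]
    frac = 100.0 * mean_vec[target] / mean_vec[pi_idx].sum()
    assert frac == pytest.approx(gv.species_molpct(parse_shorthand("PI 38:4")),
                                 abs=0.5)


def test_section_spec_validation():
    grid = (24, 24)
    full = np.ones(grid, bool)
    with pytest.raises(ValueError, match="disjoint"):
        SectionSpec("healthy", "vehicle", "negative", grid,
                    [Region("a", full, "x"), Region("b", full, "y")], seed=0)
    with pytest.raises(ValueError, match="20x20"):
        default_section_spec("healthy", "vehicle", grid=(10, 10))
    spec = default_section_spec("healthy", "vehicle", grid=grid, seed=1)
    with pytest.raises(ValueError, match="unknown composition"):
        simulate_section(spec, {}, panel=None)


def test_background_fraction_and_roi_geometry():
    spec = default_section_spec("gbm", "tmz", grid=(60, 60), seed=9)
    assert 0.1 < spec.background_fraction < 0.35
    blob = spec.regions[0].mask
    tissue = ~spec.background_mask
    assert 0.1 <= blob.sum() / tissue.sum() <= 0.3


# ---------------------------------------------------------------------------
# expression / methylation / survival study
# ---------------------------------------------------------------------------

def test_study_reproducible_and_shaped():
    spec = default_study_spec(seed=4)
    a = simulate_expression_study(spec)
    b = simulate_expression_study(spec)
    pd.testing.assert_frame_equal(a.expr, b.expr)
    pd.testing.assert_frame_equal(a.methylation, b.methylation)
    assert a.expr.shape == (300, 100)
    assert a.methylation.to_numpy().min() >= 0
    assert a.methylation.to_numpy().max() <= 1
    assert (a.survival["time"] > 0).all()


def test_methylation_anticorrelated_for_coupled_genes():
    study = simulate_expression_study(default_study_spec(seed=8, n_per_subtype=40))
    for gene in ("PLA2G5", "FABP7", "ALOX5AP"):
        r = np.corrcoef(study.expr.loc[gene], study.methylation.loc[gene])[0, 1]
        assert r < -0.5
    # uncoupled gene: no systematic coupling
    r0 = np.corrcoef(study.expr.loc["G0000"], study.methylation.loc["G0000"])[0, 1]
    assert abs(r0) < 0.3


def test_survival_direction_for_positive_coefficient():
    # high expression of an adverse gene -> shorter survival (n = 200)
    study = simulate_expression_study(default_study_spec(seed=21, n_per_subtype=40))
    values = study.expr.loc["ELOVL2"]
    high = values > values.median()
    surv = study.survival
    med_high = surv.loc[high.values, "time"].median()
    med_low = surv.loc[~high.values, "time"].median()
    assert med_high < med_low


def test_planted_module_elevation():
    study = simulate_expression_study(default_study_spec(seed=13))
    classical = study.subtypes == "Classical"
    gene = study.expr.loc["PLA2G5"]
    assert gene[classical.values].mean() > gene[~classical.values].mean() + 0.5
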