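"""Statistical structure and determinism of the synthetic cohort generator."""

import numpy as np
import pytest

from readerprob.posterior import GROUP_ORDER, DiagnosisGroup, expected_posterior, sigmoid
from readerprob.synthetic import (
    DistributionSpec,
    FindingConfig,
    ImageConfig,
    SimConfig,
    SubjectTruth,
    apex_mask,
    background_mask,
    first_stage_positive_rate,
    render_images,
    sample_subjects,
    simulate_annotations,
    simulate_logits,
    uniform_latent_config,
)


def _constant_p_truths(p, n):
    return [SubjectTruth(subject_id=f"S{i:06d}", severity={"f": 0.0}, p={"f": p})
            for i in range(n)]


def test_sample_subjects_empty_and_deterministic():
    assert sample_subjects(SimConfig(n_subjects=0, seed=1)) == []
    a = sample_subjects(SimConfig(n_subjects=50, seed=9))
    b = sample_subjects(SimConfig(n_subjects=50, seed=9))
    assert a == b
    c = sample_subjects(SimConfig(n_subjects=50, seed=10))
    assert a != c


def test_default_prevalence_matches_quadrature_oracle():
    cfg = SimConfig(n_subjects=50_000, seed=3)
    truths = sample_subjects(cfg)
    ann = simulate_annotations(truths, seed=4)
    for f in cfg.findings:
        rate = first_stage_positive_rate(f)
        emp = np.mean([a.merged_first(f.name) == "P" for a in ann])
        se = np.sqrt(rate * (1 - rate) / len(ann))
        assert abs(emp - rate) < 3 * se
        # and the oracle itself sits at the configured prevalence targets
        target = {"pleural_thickening": 0.0446, "scoliosis": 0.0158}[f.name]
        assert rate == pytest.approx(target, rel=0.01)


def test_annotations_at_probability_extremes():
    ann1 = simulate_annotations(_constant_p_truths(1.0, 50), seed=0)
    assert all(a.group("f") is DiagnosisGroup.P_PP for a in ann1)
    ann0 = simulate_annotations(_constant_p_truths(0.0, 50), seed=0)
    assert all(a.group("f") is DiagnosisGroup.N_NN for a in ann0)


def test_first_stage_rate_at_half():
    ann = simulate_annotations(_constant_p_truths(0.5, 100_000), seed=5)
    emp = np.mean([a.merged_first("f") == "P" for a in ann])
    se = np.sqrt(0.75 * 0.25 / 100_000)
    assert abs(emp - 0.75) < 3 * se


def test_group_frequencies_multinomial():
    p = 0.3
    n = 100_000
    ann = simulate_annotations(_constant_p_truths(p, n), seed=6)
    first = {"P": 1 - (1 - p) ** 2, "N": (1 - p) ** 2}
    second = {"PP": p**2, "PN": 2 * p * (1 - p), "NN": (1 - p) ** 2}
    counts = {g: 0 for g in GROUP_ORDER}
    for a in ann:
        counts[a.group("f")] += 1
    for g in GROUP_ORDER:
        prob = first[g.first_stage] * second[g.second_stage]
        se = np.sqrt(prob * (1 - prob) / n)
        assert abs(counts[g] / n - prob) < 4 * se


def test_uniform_latent_group_means_converge_to_expected_posteriors():
    # with latent p ~ U(0,1) the mean true p within group D estimates E[x|D]
    cfg = uniform_latent_config(200_000, seed=12)
    truths = sample_subjects(cfg)
    ann = simulate_annotations(truths, seed=13)
    p = np.array([t.p["pleural_thickening"] for t in truths])
    groups = np.array([ann[i].group("pleural_thickening") for i in range(len(ann))])
    for g in GROUP_ORDER:
        mean_p = p[groups == g].mean()
        assert abs(mean_p - float(expected_posterior(g))) < 0.01


def test_simulate_logits_roundtrip_and_errors():
    truths = sample_subjects(uniform_latent_config(200, seed=2))
    p = np.clip([t.p["pleural_thickening"] for t in truths], 1e-6, 1 - 1e-6)
    for lam in (1.0, 0.22, 0.79):
        u = simulate_logits(truths, lam, 0.0, seed=3, finding="pleural_thickening")
        np.testing.assert_allclose(sigmoid(-lam * u), p, atol=1e-9)
    half = _constant_p_truths(0.5, 5)
    assert np.all(simulate_logits(half, 0.22, 0.0, seed=1) == 0.0)
    with pytest.raises(ValueError):
        simulate_logits(truths, -1.0, 0.1, seed=0)


def test_invalid_distribution_parameters_raise():
    with pytest.raises(ValueError):
        DistributionSpec("exponential", (-1.0,)).sample(np.random.default_rng(0), 5)
    with pytest.raises(ValueError):
        DistributionSpec("nonsense", (1.0,)).sample(np.random.default_rng(0), 5)
    with pytest.raises(ValueError):
        FindingConfig("f", 1.5, DistributionSpec("constant", (0.0,)),
                      DistributionSpec("constant", (1.0,)), 1, 0, 1.0, 0.1)


def test_images_deterministic_and_shapes():
    truths = sample_subjects(SimConfig(n_subjects=4, seed=8))
    cfg = ImageConfig()
    a = render_images(truths, cfg, seed=5)
    b = render_images(truths, cfg, seed=5)
    assert a.shape == (4, 64, 64)
    np.testing.assert_array_equal(a, b)
    with pytest.raises(ValueError):
        ImageConfig(side=16)


def test_image_contrast_tracks_severity():
    cfg = ImageConfig(noise_sd=0.0)
    zero = SubjectTruth("S0", {"a": 0.0, "b": 0.0}, {"a": 0.0, "b": 0.0})
    hot = SubjectTruth("S1", {"a": cfg.severity_max, "b": 0.0},
                       {"a": 1.0, "b": 0.0})
    imgs = render_images([zero, hot], cfg, seed=0)
    am, bm = apex_mask(cfg), background_mask(cfg)
    # no severity, no noise: apex mean equals background mean
    assert imgs[0][am].mean() == pytest.approx(imgs[0][bm].mean(), abs=1e-12)
    # max severity: apex brighter by exactly the configured contrast
    assert imgs[1][am].mean() - imgs[1][bm].mean() == pytest.approx(
        cfg.apex_contrast, abs=1e-6
    )


def test_spine_displacement_moves_ridge():
    cfg = ImageConfig(noise_sd=0.0)
    straight = SubjectTruth("S0", {"a": 0.0, "b": 0.0}, {"a": 0.0, "b": 0.0})
    curved = SubjectTruth("S1", {"a": 0.0, "b": cfg.severity_max},
                          {"a": 0.0, "b": 1.0})
    imgs = render_images([straight, curved], cfg, seed=0)
    assert not np.array_equal(imgs[0], imgs[1])
    # ridge column centroid varies across rows only in the curved image
    cols = np.arange(cfg.side)
    for img, expect_varying in ((imgs[0], False), (imgs[1], True)):
        excess = img - img.min()
        centroid = (excess * cols).sum(axis=1) / excess.sum(axis=1)
        assert (np.ptp(centroid[20:60]) > 1.0) == expect_varying
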