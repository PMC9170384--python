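"""Generator correctness: moment recovery, correlation structure,
determinism, tally inversion and label-map ground truth."""

import numpy as np
import pytest

from ihcdx.hscore import hscore_from_tally
from ihcdx.image_quant import PARENT_CODES, classify_pixels, hscore_per_region, region_area_fractions
from ihcdx.paired import tabulate_pairs
from ihcdx.synthetic import (
    CohortConfig,
    GroupParams,
    ImageSpec,
    RegionSpec,
    default_cohort_config,
    default_paired_config,
    generate_cell_tally,
    generate_cohort,
    generate_label_map,
    generate_paired_cohort,
)


def _single_group_config(params, seed=0, **kwargs):
    return CohortConfig(groups={("TGFBR1", "HCC"): params}, seed=seed, **kwargs)


def test_degenerate_sd_zero_gives_constant_scores():
    cfg = _single_group_config(GroupParams("g", 5, 200.0, 0.0))
    scores = generate_cohort(cfg)["h_score"]
    assert (scores == 200.0).all()


def test_clipping_at_lower_bound():
    cfg = _single_group_config(GroupParams("g", 50, -50.0, 1.0, clip=True))
    scores = generate_cohort(cfg)["h_score"]
    assert (scores == 0.0).all()


def test_group_sizes_exact():
    cohort = generate_cohort(default_cohort_config(seed=3))
    sizes = cohort.groupby(["marker", "region"]).size()
    assert sizes[("TGFBR1", "CIRRHOSIS")] == 28
    assert sizes[("TGFBR1", "HCC")] == 53
    assert sizes[("TGFBR2", "CIRRHOSIS")] == 28
    assert sizes[("TGFBR2", "HCC")] == 53


def test_moment_recovery_at_large_n():
    """Unclipped sample moments converge to the configured group normals;
    tolerance 3 standard errors at n = 10^4."""
    n = 10_000
    params = GroupParams("g", n, 196.1, 44.6)
    scores = generate_cohort(_single_group_config(params, seed=11))["h_score"].to_numpy()
    se_mean = params.sd / np.sqrt(n)
    se_sd = params.sd / np.sqrt(2 * n)
    assert abs(scores.mean() - params.mean) < 3 * se_mean
    assert abs(scores.std(ddof=1) - params.sd) < 3 * se_sd


def test_cross_marker_correlation():
    cfg = default_cohort_config(seed=5)
    cfg.cross_marker_rho = 0.8
    for key, g in list(cfg.groups.items()):
        cfg.groups[key] = GroupParams(g.label, 5000, g.mean, g.sd)
    wide = generate_cohort(cfg).pivot_table(
        index=["patient_id", "region"], columns="marker", values="h_score"
    )
    rho = np.corrcoef(wide["TGFBR1"], wide["TGFBR2"])[0, 1]
    assert rho == pytest.approx(0.8, abs=0.03)


def test_seed_determinism_byte_identical():
    cfg = default_cohort_config(seed=42)
    a = generate_cohort(cfg).to_csv(index=False)
    b = generate_cohort(default_cohort_config(seed=42)).to_csv(index=False)
    assert a == b
    assert a != generate_cohort(default_cohort_config(seed=43)).to_csv(index=False)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        CohortConfig(groups={}, cross_marker_rho=1.5)
    with pytest.raises(ValueError):
        GroupParams("g", 3, 100.0, -1.0)
    with pytest.raises(ValueError):
        CohortConfig(groups={}, missingness=1.2)


def test_config_json_round_trip(tmp_path):
    cfg = default_cohort_config(seed=9)
    path = tmp_path / "cfg.json"
    cfg.to_json(path)
    back = CohortConfig.from_json(path)
    assert back.groups == dict(cfg.groups)
    assert back.seed == cfg.seed


def test_paired_perfect_correlation_equal_distributions():
    groups = {
        ("TGFBR2", "HCC"): GroupParams("h", 40, 150.0, 30.0),
        ("TGFBR2", "TAT"): GroupParams("t", 40, 150.0, 30.0),
    }
    cfg = CohortConfig(groups=groups, paired_rho=1.0, seed=2)
    pairs = generate_paired_cohort(cfg)
    np.testing.assert_allclose(pairs["hcc"], pairs["tat"])


def test_paired_majority_flagged_when_tat_higher():
    """With the tumor mean a full SD below tumor-adjacent, most generated
    pairs should be flagged lower-in-HCC — checked by direct count."""
    cfg = default_paired_config("TGFBR2", seed=7)  # 105.8 +/- 56.9 vs 202.3 +/- 55.5
    pairs = generate_paired_cohort(cfg)
    comparison = tabulate_pairs(pairs)
    direct_count = int((pairs["hcc"] < pairs["tat"]).sum())
    assert comparison.n_hcc_lower == direct_count
    assert comparison.n_hcc_lower > comparison.evaluable / 2


def test_paired_missingness_rate():
    """Binomial expectation: ~20 of 100 pairs incomplete at rate 0.2
    (within 3 sigma = 12 of the expectation)."""
    groups = {
        ("TGFBR1", "HCC"): GroupParams("h", 100, 150.0, 30.0),
        ("TGFBR1", "TAT"): GroupParams("t", 100, 180.0, 30.0),
    }
    cfg = CohortConfig(groups=groups, seed=13, missingness=0.2)
    pairs = generate_paired_cohort(cfg)
    incomplete = int((pairs["hcc"].isna() | pairs["tat"].isna()).sum())
    assert abs(incomplete - 20) <= 12


@pytest.mark.parametrize("target, n_cells", [(0.0, 50), (300.0, 50), (160.0, 100)])
def test_cell_tally_exact_targets(target, n_cells):
    tally = generate_cell_tally(target, n_cells)
    assert hscore_from_tally(tally) == pytest.approx(target)


def test_cell_tally_boundaries_are_pure():
    assert generate_cell_tally(300.0, 25).counts == (0, 0, 0, 25)
    assert generate_cell_tally(0.0, 25).counts == (25, 0, 0, 0)


def test_cell_tally_quantization_bound():
    """Round trip within the stated quantization error 300 / n_cells."""
    for n_cells in (7, 33, 100):
        for target in np.linspace(0, 300, 41):
            tally = generate_cell_tally(float(target), n_cells)
            assert abs(hscore_from_tally(tally) - target) <= 300.0 / n_cells + 1e-9


def test_cell_tally_rejects_out_of_range():
    with pytest.raises(ValueError):
        generate_cell_tally(301.0, 10)
    with pytest.raises(ValueError):
        generate_cell_tally(-1.0, 10)


def _two_region_spec(seed=0, sds=(0.0, 0.0, 0.0, 0.0)):
    return ImageSpec(
        width=120,
        height=80,
        regions=[
            RegionSpec("HCC", 0.4, (0.1, 0.4, 0.3, 0.2)),
            RegionSpec("cirrhotic", 0.35, (0.0, 0.1, 0.3, 0.6)),
        ],
        stain_sds=sds,
        seed=seed,
    )


def test_label_map_area_fractions_match_spec():
    image = generate_label_map(_two_region_spec(seed=4, sds=(3.0, 5.0, 5.0, 6.0)))
    for region, mix in (("HCC", (0.1, 0.4, 0.3, 0.2)), ("cirrhotic", (0.0, 0.1, 0.3, 0.6))):
        realized = region_area_fractions(image, region).fractions
        np.testing.assert_allclose(realized, mix, atol=0.02)


def test_label_map_single_pure_region_scores_300():
    spec = ImageSpec(width=30, height=30, regions=[RegionSpec("HCC", 1.0, (0.0, 0.0, 0.0, 1.0))])
    image = generate_label_map(spec)
    assert hscore_per_region(image)["HCC"] == pytest.approx(300.0)


def test_zero_noise_classification_recovers_truth():
    """With well-separated class means and zero noise, fixed-threshold
    classification reproduces the generator's intensity layer exactly on
    tissue pixels."""
    image = generate_label_map(_two_region_spec(seed=8, sds=(0.0, 0.0, 0.0, 0.0)))
    predicted = classify_pixels(image.stain, (45.0, 120.0, 200.0))
    tissue = image.parent != PARENT_CODES["background"]
    np.testing.assert_array_equal(predicted[tissue], image.intensity[tissue])


def test_region_fractions_exceeding_one_rejected():
    with pytest.raises(ValueError):
        ImageSpec(
            width=10,
            height=10,
            regions=[
                RegionSpec("HCC", 0.7, (1.0, 0.0, 0.0, 0.0)),
                RegionSpec("cirrhotic", 0.5, (1.0, 0.0, 0.0, 0.0)),
            ],
        )
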