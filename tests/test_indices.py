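"""Six-index computation: closed forms, oracles, symmetry and invariance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import datspect as d
from datspect.indices import FDConfig, fractal_dimension, threshold_counts
from datspect.phantom import REFERENCE_STATS
from datspect.volume import Volume

from conftest import panels_by_class


# --- SBR-Q --------------------------------------------------------------------


def test_sbr_q_zero_on_uniform_volume(uniform_volume, fitted_vois):
    assert d.sbr_q(uniform_volume, fitted_vois) == (0.0, 0.0, 0.0)


def test_sbr_q_closed_form_on_unblurred_phantom(template, fitted_vois):
    """Striatal mean exactly 3x the occipital mean gives SBR 2 on both sides."""
    spec = d.PhantomSpec(
        caudate_intensity=3.0,
        anterior_putamen_intensity=3.0,
        posterior_putamen_intensity=3.0,
        background_intensity=1.0,
        psf_fwhm_mm=0.0,
        total_counts=None,
    )
    volume, _ = d.make_striatal_phantom(spec, template)
    left, right, mean = d.sbr_q(volume, fitted_vois)
    assert (left, right, mean) == pytest.approx((2.0, 2.0, 2.0))


def test_sbr_q_nps_cohort_mean_near_calibration(image_cohort_panels):
    nps = panels_by_class(image_cohort_panels, "sbr_q")["NPS"]
    assert nps.mean() == pytest.approx(REFERENCE_STATS["NPS"]["sbr_q"][0], rel=0.10)


# --- SBR-V --------------------------------------------------------------------


def test_sbr_v_zero_on_uniform_volume(uniform_volume, pentagonal_vois):
    left, right, mean = d.sbr_v(uniform_volume, pentagonal_vois)
    assert (left, right, mean) == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)


def test_sbr_v_algebraic_closed_form(sharp_phantom, pentagonal_vois):
    """Concentration k=6 over volume V_s with V_str = V_s gives SBR = k-1 = 5."""
    volume, truth = sharp_phantom
    v_s = truth.striatal_volume_ml["left"]
    left, right, mean = d.sbr_v(volume, pentagonal_vois, v_str_ml=v_s)
    assert (left, right, mean) == pytest.approx((5.0, 5.0, 5.0))


def test_sbr_v_blur_robust_while_sbr_q_drops(template, fitted_vois, pentagonal_vois):
    """Partial-volume rationale: blur barely moves SBR-V but collapses SBR-Q."""
    kwargs = dict(
        caudate_intensity=6.0,
        anterior_putamen_intensity=6.0,
        posterior_putamen_intensity=6.0,
        total_counts=None,
    )
    sharp, truth = d.make_striatal_phantom(
        d.PhantomSpec(psf_fwhm_mm=0.0, **kwargs), template
    )
    blurred, _ = d.make_striatal_phantom(
        d.PhantomSpec(psf_fwhm_mm=12.0, **kwargs), template
    )
    v_s = truth.striatal_volume_ml["left"]
    sbr_v_sharp = d.sbr_v(sharp, pentagonal_vois, v_str_ml=v_s)[2]
    sbr_v_blur = d.sbr_v(blurred, pentagonal_vois, v_str_ml=v_s)[2]
    assert sbr_v_blur == pytest.approx(sbr_v_sharp, rel=0.02)
    sbr_q_sharp = d.sbr_q(sharp, fitted_vois)[2]
    sbr_q_blur = d.sbr_q(blurred, fitted_vois)[2]
    assert sbr_q_blur < 0.75 * sbr_q_sharp


def test_sbr_v_concentration_formulation_on_unblurred_phantom(sharp_phantom, pentagonal_vois):
    """Plain concentration ratio equals specific counts diluted over the prism."""
    volume, truth = sharp_phantom
    left, _, _ = d.sbr_v(volume, pentagonal_vois, formulation="concentration")
    prism_ml = (
        pentagonal_vois.masks["striatal_prism_left"].sum() * volume.voxel_volume_ml
    )
    expected = 5.0 * truth.striatal_volume_ml["left"] / prism_ml
    assert left == pytest.approx(expected)


# --- PCR ----------------------------------------------------------------------


def test_pcr_one_on_uniform_volume(uniform_volume, fitted_vois):
    assert d.pcr(uniform_volume, fitted_vois) == pytest.approx((1.0, 1.0, 1.0))


def test_pcr_matches_voi_mean_ratio_oracle(template, fitted_vois):
    """On a blurred phantom, PCR equals the measured putamen/caudate mean ratio."""
    spec = d.PhantomSpec(
        caudate_intensity=7.0,
        anterior_putamen_intensity=5.0,
        posterior_putamen_intensity=5.0,
        psf_fwhm_mm=12.0,
        total_counts=None,
    )
    volume, _ = d.make_striatal_phantom(spec, template)
    left, _, _ = d.pcr(volume, fitted_vois)
    put = (
        fitted_vois.masks["anterior_putamen_left"] | fitted_vois.masks["posterior_putamen_left"]
    )
    expected = volume.data[put].mean() / volume.data[fitted_vois.masks["caudate_left"]].mean()
    assert left == pytest.approx(expected)


def test_pcr_exact_on_unblurred_phantom(template, fitted_vois):
    spec = d.PhantomSpec(
        caudate_intensity=5.0,
        anterior_putamen_intensity=4.0,
        posterior_putamen_intensity=4.0,
        psf_fwhm_mm=0.0,
        total_counts=None,
    )
    volume, _ = d.make_striatal_phantom(spec, template)
    assert d.pcr(volume, fitted_vois)[2] == pytest.approx(0.8)


def test_pcr_nps_cohort_mean_near_calibration(image_cohort_panels):
    nps = panels_by_class(image_cohort_panels, "pcr_q")["NPS"]
    assert nps.mean() == pytest.approx(REFERENCE_STATS["NPS"]["pcr_q"][0], rel=0.10)


# --- asymmetry index ----------------------------------------------------------


@pytest.mark.parametrize(
    "left,right,scale,expected",
    [
        (1.7, 1.7, 1.0, 0.0),
        (2.0, 1.0, 1.0, 2.0 / 3.0),
        (2.0, 1.0, 100.0, 200.0 / 3.0),
        (1.0, 2.0, 1.0, 2.0 / 3.0),  # symmetric in its arguments
    ],
)
def test_asymmetry_index_hand_arithmetic(left, right, scale, expected):
    assert d.asymmetry_index(left, right, scale) == pytest.approx(expected)


def test_asymmetry_index_rejects_nonpositive_mean():
    with pytest.raises(ValueError):
        d.asymmetry_index(0.0, 0.0)


# --- fractal dimension --------------------------------------------------------


def _profile_volume(level_counts, thresholds):
    """Build a volume whose suprathreshold counts hit `level_counts` exactly.

    level_counts[i] = number of voxels >= thresholds[i] * max; the remaining
    voxels sit below the lowest threshold.
    """
    n_total = level_counts[0] + 50
    values = np.full(n_total, thresholds[0] / 2.0)
    bounds = list(thresholds[1:]) + [1.0]
    start = 0
    # groups between consecutive thresholds, hottest group last at the max
    sizes = [a - b for a, b in zip(level_counts, level_counts[1:])] + [level_counts[-1]]
    for i, size in enumerate(sizes):
        level = thresholds[i] + 1e-6 if i < len(sizes) - 1 else 1.0
        values[start : start + size] = level
        start += size
    data = np.zeros((n_total, 1, 1))
    data[:, 0, 0] = values
    mask = np.ones_like(data, dtype=bool)
    return Volume(data, 1.0), mask


def test_fd_zero_for_binary_blob():
    """Constant N(t) across the five stages means zero slope."""
    data = np.zeros((10, 10, 1))
    data[2:6, 2:6, 0] = 1.0
    mask = np.ones_like(data, dtype=bool)
    assert fractal_dimension(Volume(data, 1.0), mask) == pytest.approx(0.0)


@pytest.mark.parametrize("exponent", [2.0, 4.0])
def test_fd_recovers_exact_power_law(exponent):
    """N(t) = c * t^(-FD) at the five stages returns FD exactly."""
    thresholds = tuple(2.0 ** (-(5 - i) / 2.0) for i in range(5))  # 0.177 .. 0.707
    counts = [int(round(th**-exponent)) for th in thresholds]
    volume, mask = _profile_volume(counts, thresholds)
    config = FDConfig(threshold_fractions=thresholds)
    assert np.array_equal(threshold_counts(volume, mask, config), counts)
    assert fractal_dimension(volume, mask, config) == pytest.approx(exponent, abs=1e-9)


def test_fd_matches_bruteforce_threshold_count_oracle(template, pentagonal_vois):
    """FD equals the two-loop count/fit oracle on an arbitrary volume."""
    rng = np.random.default_rng(8)
    volume = Volume(rng.random(template.grid_shape), template.voxel_mm)
    mask = pentagonal_vois.masks["striatal_prism_left"]
    config = FDConfig()
    vmax = volume.data[mask].max()
    counts = []
    for t in config.threshold_fractions:
        n = 0
        for v in volume.data[mask]:
            if v >= t * vmax:
                n += 1
        counts.append(n)
    slope, _ = np.polyfit(np.log(config.threshold_fractions), np.log(counts), 1)
    assert fractal_dimension(volume, mask, config) == pytest.approx(-slope)


def test_eroded_phantom_has_higher_fd_than_comma(template, pentagonal_vois):
    """Dot-like uptake shrinks faster across thresholds than the full comma.

    The fully eroded caudate dot scores a higher FD than the comma; mid-path
    values need not be monotone (losing only the posterior lobe temporarily
    makes the suprathreshold region more compact), so the endpoints carry the
    diagnostic direction.
    """
    fds = {}
    for erosion in (0.0, 1.0):
        spec = d.PhantomSpec(shape_erosion=erosion, total_counts=None)
        volume, _ = d.make_striatal_phantom(spec, template)
        fds[erosion] = fractal_dimension(
            volume, pentagonal_vois.masks["striatal_prism_left"]
        )
    assert fds[1.0] > fds[0.0]


def test_fd_separates_ps_from_nps_at_cohort_level(image_cohort_panels):
    by = panels_by_class(image_cohort_panels, "fd_v")
    assert by["PS"].mean() > by["NPS"].mean()


def test_fd_vanishing_stage_flagged_and_requires_three():
    """Zero-count stages are dropped with a warning; < 3 stages is an error."""
    from datspect.indices import fd_from_counts

    thresholds = (0.2, 0.4, 0.6, 0.8, 0.9)
    with pytest.warns(RuntimeWarning, match="vanished"):
        fd = fd_from_counts(thresholds, [100, 40, 10, 0, 0])
    slope = np.polyfit(np.log(thresholds[:3]), np.log([100, 40, 10]), 1)[0]
    assert fd == pytest.approx(-slope)
    with pytest.raises(ValueError, match="fewer than 3"):
        with pytest.warns(RuntimeWarning, match="vanished"):
            fd_from_counts(thresholds, [100, 40, 0, 0, 0])


# --- panel composition and invariances ----------------------------------------


def test_panel_matches_component_calls(template, fitted_vois, pentagonal_vois):
    volume, _ = d.make_striatal_phantom(d.PhantomSpec(seed=4), template)
    p = d.compute_panel(volume, fitted_vois, pentagonal_vois)
    assert p.sbr_q == d.sbr_q(volume, fitted_vois)[2]
    assert p.sbr_v == d.sbr_v(volume, pentagonal_vois)[2]
    assert p.pcr_q == d.pcr(volume, fitted_vois)[2]
    assert p.ai_q == d.asymmetry_index(p.sbr_q_left, p.sbr_q_right)
    assert p.ai_v == d.asymmetry_index(p.sbr_v_left, p.sbr_v_right, scale=100.0)
    fd = np.mean(
        [
            fractal_dimension(volume, pentagonal_vois.masks[f"striatal_prism_{s}"])
            for s in ("left", "right")
        ]
    )
    assert p.fd_v == pytest.approx(fd)


def test_symmetric_phantom_has_zero_asymmetry(template, fitted_vois, pentagonal_vois):
    volume, truth = d.make_striatal_phantom(
        d.PhantomSpec(asymmetry_factor=1.0, total_counts=None), template
    )
    p = d.compute_panel(volume, fitted_vois, pentagonal_vois)
    assert p.ai_q == 0.0 and p.ai_v == 0.0


def test_panel_deterministic(template, fitted_vois, pentagonal_vois):
    volume, _ = d.make_striatal_phantom(d.PhantomSpec(seed=2), template)
    p1 = d.compute_panel(volume, fitted_vois, pentagonal_vois)
    p2 = d.compute_panel(volume, fitted_vois, pentagonal_vois)
    assert p1 == p2


@settings(deadline=None, max_examples=10)
@given(factor=st.floats(0.1, 50.0, allow_nan=False))
def test_all_indices_scale_invariant(factor, template, fitted_vois, pentagonal_vois):
    """Every index is a ratio or threshold-relative count: c*V changes nothing.

    Checked on the continuous-valued (noiseless) volume; integer count data
    can tie an FD threshold exactly (e.g. 218/545 = 0.40), and such ties are
    not representable stably under arbitrary float rescaling — that case is
    covered separately with an exactly-representable factor.
    """
    volume, truth = d.make_striatal_phantom(
        d.PhantomSpec(seed=6, asymmetry_factor=1.06, total_counts=None), template
    )
    scaled = Volume(volume.data * factor, volume.voxel_mm)
    p0 = d.compute_panel(volume, fitted_vois, pentagonal_vois)
    p1 = d.compute_panel(scaled, fitted_vois, pentagonal_vois)
    for name in ("sbr_q", "pcr_q", "ai_q", "sbr_v", "fd_v", "ai_v"):
        assert getattr(p1, name) == pytest.approx(getattr(p0, name), rel=1e-9, abs=1e-12)


def test_scale_invariance_integer_counts_power_of_two(template, fitted_vois, pentagonal_vois):
    """Poisson-count volumes rescaled by 2^k keep threshold ties, hence all indices."""
    volume, _ = d.make_striatal_phantom(d.PhantomSpec(seed=6), template)
    scaled = Volume(volume.data * 8.0, volume.voxel_mm)
    p0 = d.compute_panel(volume, fitted_vois, pentagonal_vois)
    p1 = d.compute_panel(scaled, fitted_vois, pentagonal_vois)
    for name in ("sbr_q", "pcr_q", "ai_q", "sbr_v", "fd_v", "ai_v"):
        assert getattr(p1, name) == pytest.approx(getattr(p0, name), rel=1e-12)


def test_left_right_flip_swaps_sides_and_preserves_summaries(
    template, fitted_vois, pentagonal_vois
):
    volume, _ = d.make_striatal_phantom(
        d.PhantomSpec(seed=9, asymmetry_factor=1.12), template
    )
    p = d.compute_panel(volume, fitted_vois, pentagonal_vois)
    q = d.compute_panel(volume.flipped_lr(), fitted_vois, pentagonal_vois)
    assert q.sbr_q_left == pytest.approx(p.sbr_q_right)
    assert q.sbr_q_right == pytest.approx(p.sbr_q_left)
    assert q.sbr_v_left == pytest.approx(p.sbr_v_right)
    assert q.sbr_v_right == pytest.approx(p.sbr_v_left)
    for name in ("sbr_q", "pcr_q", "ai_q", "sbr_v", "fd_v", "ai_v"):
        assert getattr(q, name) == pytest.approx(getattr(p, name), rel=1e-12)


def test_scaling_striatum_down_never_raises_sbr(template, fitted_vois, pentagonal_vois):
    """Monotonicity: less striatal uptake cannot increase either SBR."""
    prev_q, prev_v = np.inf, np.inf
    for k in (6.0, 4.0, 2.5, 1.5, 1.0):
        volume, _ = d.make_striatal_phantom(
            d.PhantomSpec(
                caudate_intensity=k,
                anterior_putamen_intensity=k,
                posterior_putamen_intensity=k,
                total_counts=None,
            ),
            template,
        )
        q = d.sbr_q(volume, fitted_vois)[2]
        v = d.sbr_v(volume, pentagonal_vois)[2]
        assert q <= prev_q + 1e-12 and v <= prev_v + 1e-12
        prev_q, prev_v = q, v


def test_scheme_mismatch_rejected(uniform_volume, fitted_vois, pentagonal_vois):
    with pytest.raises(ValueError, match="fitted_q"):
        d.sbr_q(uniform_volume, pentagonal_vois)
    with pytest.raises(ValueError, match="pentagonal_v"):
        d.sbr_v(uniform_volume, fitted_vois)
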