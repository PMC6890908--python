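"""Synthetic striatal phantoms and parametric cohorts.

Two generative routes are provided:

* an image route (`make_striatal_phantom`, `sample_cohort`) that renders
  3-D SPECT-like count volumes — a uniform brain-shaped background with six
  ellipsoidal striatal compartments, Gaussian post-reconstruction blur and
  Poisson count noise.  A healthy subject shows the bilateral "comma"
  pattern (caudate plus anterior/posterior putamen); increasing
  ``shape_erosion`` attenuates the posterior then the anterior putamen
  toward background, leaving the caudate "dot" typical of parkinsonian
  syndromes, and ``asymmetry_factor`` rescales one hemisphere.

* a tabular route (`tabular_cohort`) that draws six-index panels directly
  from per-class truncated-normal marginals calibrated to published
  PS/NPS group statistics, bypassing the image stages for classifier and
  evaluation work at scale.

All randomness flows from explicit integer seeds; there is no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np
from scipy import ndimage, stats

from .geometry import (
    SIDES,
    STRIATAL_COMPARTMENTS,
    TemplateGeometry,
    cached_brain_mask,
    cached_compartment_masks,
    check_within_grid,
    load_template,
)
from .panel import INDEX_COLUMNS, IndexPanel
from .volume import Volume

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: Published PS/NPS group means and standard deviations of the six indices,
#: used as the default calibration of the tabular cohort generator.
REFERENCE_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "NPS": {
        "sbr_q": (2.32, 0.56),
        "pcr_q": (0.86, 0.04),
        "ai_q": (0.03, 0.02),
        "sbr_v": (5.61, 1.51),
        "fd_v": (2.44, 0.21),
        "ai_v": (3.94, 3.37),
    },
    "PS": {
        "sbr_q": (1.07, 0.42),
        "pcr_q": (0.75, 0.10),
        "ai_q": (0.09, 0.06),
        "sbr_v": (3.26, 1.15),
        "fd_v": (4.19, 1.06),
        "ai_v": (15.2, 13.3),
    },
}


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one synthetic subject.

    Compartment intensities are count concentrations in arbitrary units
    relative to ``background_intensity``; ``shape_erosion`` in [0, 1]
    attenuates the putamen toward background (posterior first, so 1.0 leaves
    a caudate-only dot); ``asymmetry_factor`` multiplies the intensities of
    ``asymmetric_side``.  ``total_counts`` scales the volume before Poisson
    sampling; None disables count noise.
    """

    caudate_intensity: float = 7.0
    anterior_putamen_intensity: float = 7.0
    posterior_putamen_intensity: float = 7.0
    background_intensity: float = 1.0
    shape_erosion: float = 0.0
    asymmetry_factor: float = 1.0
    asymmetric_side: str = "left"
    psf_fwhm_mm: float = 12.0
    total_counts: float | None = 2.0e6
    grid_shape: tuple[int, int, int] = (128, 128, 64)
    voxel_mm: float = 4.4
    seed: int = 0

    def __post_init__(self):
        for name in (
            "caudate_intensity",
            "anterior_putamen_intensity",
            "posterior_putamen_intensity",
            "background_intensity",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.shape_erosion <= 1.0:
            raise ValueError("shape_erosion must lie in [0, 1]")
        if self.asymmetry_factor < 0:
            raise ValueError("asymmetry_factor must be >= 0")
        if self.asymmetric_side not in SIDES:
            raise ValueError(f"asymmetric_side must be one of {SIDES}")
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be >= 0 (0 disables the PSF)")
        if self.total_counts is not None and self.total_counts <= 0:
            raise ValueError("total_counts must be positive or None")
        if len(self.grid_shape) != 3 or any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")

    def erosion_factors(self) -> dict[str, float]:
        """Contrast retention per putaminal compartment (posterior fades first)."""
        e = self.shape_erosion
        return {
            "caudate": 1.0,
            "anterior_putamen": 1.0 - max(2.0 * e - 1.0, 0.0),
            "posterior_putamen": 1.0 - min(2.0 * e, 1.0),
        }

    def effective_intensity(self, compartment: str, side: str) -> float:
        base = {
            "caudate": self.caudate_intensity,
            "anterior_putamen": self.anterior_putamen_intensity,
            "posterior_putamen": self.posterior_putamen_intensity,
        }[compartment]
        bg = self.background_intensity
        value = bg + (base - bg) * self.erosion_factors()[compartment]
        if side == self.asymmetric_side:
            value *= self.asymmetry_factor
        return value


@dataclass(frozen=True)
class GroundTruth:
    """The generating spec plus noiseless derived quantities."""

    spec: PhantomSpec
    concentration_ratios: dict[str, float]  # effective intensity / background
    striatal_volume_ml: dict[str, float]  # voxelised, per side and total
    true_asymmetry: float  # |L-R| specific uptake / mean of sides
    posterior_anterior_specific_ratio: float  # in [0, 1]; falls as erosion rises
    noiseless: Volume  # post-PSF, pre-Poisson


def _specific_uptake(spec: PhantomSpec, volumes_ml: dict[str, float], side: str) -> float:
    bg = spec.background_intensity
    return sum(
        volumes_ml[f"{c}_{side}"] * (spec.effective_intensity(c, side) - bg)
        for c in STRIATAL_COMPARTMENTS
    )


def make_striatal_phantom(
    spec: PhantomSpec, template: TemplateGeometry | None = None
) -> tuple[Volume, GroundTruth]:
    """Render one synthetic subject; returns the noisy volume and its truth."""
    if template is None:
        template = load_template()
    if template.grid_shape != tuple(spec.grid_shape) or template.voxel_mm != spec.voxel_mm:
        template = replace(
            template, grid_shape=tuple(spec.grid_shape), voxel_mm=float(spec.voxel_mm)
        )
    check_within_grid(template)

    bg = spec.background_intensity
    data = np.zeros(template.grid_shape)
    data[cached_brain_mask(template)] = bg
    masks = cached_compartment_masks(template)
    for side in SIDES:
        for comp in STRIATAL_COMPARTMENTS:
            data[masks[f"{comp}_{side}"]] = spec.effective_intensity(comp, side)

    if spec.psf_fwhm_mm > 0:
        sigma_vox = spec.psf_fwhm_mm * FWHM_TO_SIGMA / spec.voxel_mm
        data = ndimage.gaussian_filter(data, sigma_vox, mode="constant")
    noiseless = Volume(data, spec.voxel_mm)

    if spec.total_counts is not None:
        rng = np.random.default_rng(spec.seed)
        lam = data * (spec.total_counts / data.sum())
        noisy = Volume(rng.poisson(lam).astype(float), spec.voxel_mm)
    else:
        noisy = Volume(data.copy(), spec.voxel_mm)

    voxel_ml = template.voxel_volume_ml
    volumes_ml = {name: float(m.sum()) * voxel_ml for name, m in masks.items()}
    per_side = {
        side: sum(volumes_ml[f"{c}_{side}"] for c in STRIATAL_COMPARTMENTS) for side in SIDES
    }
    spec_uptake = {side: _specific_uptake(spec, volumes_ml, side) for side in SIDES}
    mean_uptake = (spec_uptake["left"] + spec_uptake["right"]) / 2.0
    true_ai = (
        abs(spec_uptake["left"] - spec_uptake["right"]) / mean_uptake if mean_uptake > 0 else 0.0
    )
    factors = spec.erosion_factors()
    ant = factors["anterior_putamen"]
    post = factors["posterior_putamen"]
    pa_ratio = post / ant if ant > 0 else 0.0

    truth = GroundTruth(
        spec=spec,
        concentration_ratios={
            f"{c}_{s}": spec.effective_intensity(c, s) / bg if bg > 0 else np.inf
            for s in SIDES
            for c in STRIATAL_COMPARTMENTS
        },
        striatal_volume_ml={**per_side, "total": per_side["left"] + per_side["right"]},
        true_asymmetry=true_ai,
        posterior_anterior_specific_ratio=pa_ratio,
        noiseless=noiseless,
    )
    return noisy, truth


@dataclass(frozen=True)
class ClassImagingParams:
    """Per-class distribution of image-route phantom parameters.

    A single subject draws a global uptake scalar (lognormal-free truncated
    normal with coefficient of variation ``uptake_cv``) multiplying the
    specific (above-background) signal of all compartments, plus erosion and
    asymmetry levels.  Defaults were calibrated so that the rendered cohort's
    index panels land on the published PS/NPS group statistics.
    """

    caudate_ratio: float
    putamen_ratio: float
    uptake_cv: float
    erosion_mean: float
    erosion_sd: float
    asymmetry_mean: float
    asymmetry_sd: float
    psf_fwhm_mm: float = 12.0
    total_counts: float = 2.0e6
    background_intensity: float = 1.0


#: Image-route class defaults, calibrated so the rendered NPS cohort's group
#: means land on the published statistics (the PS class keeps physiologic
#: caudate-dominant uptake and is checked directionally).
IMAGE_COHORT_DEFAULTS: dict[str, ClassImagingParams] = {
    "NPS": ClassImagingParams(
        caudate_ratio=7.60,
        putamen_ratio=6.45,
        uptake_cv=0.27,
        erosion_mean=0.05,
        erosion_sd=0.04,
        asymmetry_mean=0.03,
        asymmetry_sd=0.02,
        psf_fwhm_mm=14.0,
    ),
    "PS": ClassImagingParams(
        caudate_ratio=5.80,
        putamen_ratio=5.20,
        uptake_cv=0.35,
        erosion_mean=0.60,
        erosion_sd=0.15,
        asymmetry_mean=0.09,
        asymmetry_sd=0.06,
        psf_fwhm_mm=14.0,
    ),
}


@dataclass(frozen=True)
class CohortSpec:
    """PS/NPS cohort sizes plus per-class generative parameters."""

    n_ps: int
    n_nps: int
    seed: int = 0
    image_params: dict[str, ClassImagingParams] = field(
        default_factory=lambda: dict(IMAGE_COHORT_DEFAULTS)
    )
    tabular_stats: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in REFERENCE_STATS.items()}
    )
    #: optional 6x6 correlation matrix (Gaussian copula) for the tabular route
    tabular_correlation: np.ndarray | None = None

    def __post_init__(self):
        if self.n_ps <= 0 or self.n_nps <= 0:
            raise ValueError("n_ps and n_nps must be positive")
        if self.n_ps + self.n_nps < 4:
            raise ValueError("cohort must contain at least 4 subjects")


def _truncnorm(rng, mean, sd, lo=0.0, hi=np.inf, size=None):
    if sd <= 0:
        return np.full(size, mean) if size else float(mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _asymmetry_factor(target_ai: float, mean_ratio: float) -> float:
    """Hemisphere scale factor producing a given specific-uptake asymmetry.

    With mean concentration ratio k over background, scaling one hemisphere's
    intensities by a gives specific uptake proportional to (a*k - 1) against
    (k - 1); solve (a*k-1)/(k-1) = (2+AI)/(2-AI) for a.
    """
    r = (2.0 + target_ai) / (2.0 - target_ai)
    return (1.0 + r * (mean_ratio - 1.0)) / mean_ratio


def sample_cohort(cohort: CohortSpec) -> list[tuple[PhantomSpec, str]]:
    """Draw image-route phantom specs with PS/NPS labels (reproducible by seed)."""
    rng = np.random.default_rng(cohort.seed)
    out: list[tuple[PhantomSpec, str]] = []
    for label, n in (("PS", cohort.n_ps), ("NPS", cohort.n_nps)):
        p = cohort.image_params[label]
        uptake = _truncnorm(rng, 1.0, p.uptake_cv, lo=0.05, size=n)
        erosion = _truncnorm(rng, p.erosion_mean, p.erosion_sd, lo=0.0, hi=1.0, size=n)
        ai = _truncnorm(rng, p.asymmetry_mean, p.asymmetry_sd, lo=0.0, hi=1.5, size=n)
        sides = rng.choice(SIDES, size=n)
        seeds = rng.integers(0, 2**31 - 1, size=n)
        for i in range(n):
            bg = p.background_intensity
            k_c = 1.0 + (p.caudate_ratio - 1.0) * uptake[i]
            k_p = 1.0 + (p.putamen_ratio - 1.0) * uptake[i]
            k_mean = (k_c + 2.0 * k_p) / 3.0
            out.append(
                (
                    PhantomSpec(
                        caudate_intensity=k_c * bg,
                        anterior_putamen_intensity=k_p * bg,
                        posterior_putamen_intensity=k_p * bg,
                        background_intensity=bg,
                        shape_erosion=float(erosion[i]),
                        asymmetry_factor=_asymmetry_factor(float(ai[i]), k_mean),
                        asymmetric_side=str(sides[i]),
                        psf_fwhm_mm=p.psf_fwhm_mm,
                        total_counts=p.total_counts,
                        seed=int(seeds[i]),
                    ),
                    label,
                )
            )
    return out


def tabular_cohort(cohort: CohortSpec) -> list[IndexPanel]:
    """Draw six-index panels directly from the per-class calibrated marginals.

    Marginals are normals truncated at zero with the calibration means/SDs;
    an optional correlation matrix couples them through a Gaussian copula.
    """
    rng = np.random.default_rng(cohort.seed)
    panels: list[IndexPanel] = []
    for label, n in (("PS", cohort.n_ps), ("NPS", cohort.n_nps)):
        params = cohort.tabular_stats[label]
        draws = np.empty((n, len(INDEX_COLUMNS)))
        if cohort.tabular_correlation is not None:
            corr = np.asarray(cohort.tabular_correlation, dtype=float)
            if corr.shape != (6, 6):
                raise ValueError("tabular_correlation must be a 6x6 matrix")
            z = rng.multivariate_normal(np.zeros(6), corr, size=n, method="cholesky")
            u = stats.norm.cdf(z)
            for j, name in enumerate(INDEX_COLUMNS):
                mean, sd = params[name]
                a = (0.0 - mean) / sd
                draws[:, j] = stats.truncnorm.ppf(u[:, j], a, np.inf, loc=mean, scale=sd)
        else:
            for j, name in enumerate(INDEX_COLUMNS):
                mean, sd = params[name]
                draws[:, j] = _truncnorm(rng, mean, sd, lo=0.0, size=n)
        side_signs = rng.choice([-1.0, 1.0], size=n)
        for i in range(n):
            row = dict(zip(INDEX_COLUMNS, draws[i]))
            s = side_signs[i]
            panels.append(
                IndexPanel(
                    subject_id=f"{label}{i + 1:04d}",
                    label=label,
                    **row,
                    sbr_q_left=row["sbr_q"] * (1.0 + s * row["ai_q"] / 2.0),
                    sbr_q_right=row["sbr_q"] * (1.0 - s * row["ai_q"] / 2.0),
                    sbr_v_left=row["sbr_v"] * (1.0 + s * row["ai_v"] / 200.0),
                    sbr_v_right=row["sbr_v"] * (1.0 - s * row["ai_v"] / 200.0),
                )
            )
    return panels


def spec_to_dict(spec: PhantomSpec) -> dict:
    d = asdict(spec)
    d["grid_shape"] = list(spec.grid_shape)
    return d


def spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    d["grid_shape"] = tuple(d["grid_shape"])
    return PhantomSpec(**d)
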