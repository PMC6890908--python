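import numpy as np
import pytest

import datspect as d
from datspect.phantom import CohortSpec, sample_cohort


@pytest.fixture(scope="session")
def template():
    return d.load_template()


@pytest.fixture(scope="session")
def fitted_vois(template):
    return d.build_fitted_vois(template)


@pytest.fixture(scope="session")
def pentagonal_vois(template):
    return d.build_pentagonal_vois(template)


@pytest.fixture(scope="session")
def uniform_volume(template):
    """Noiseless, PSF-free volume with unit counts everywhere in the brain."""
    spec = d.PhantomSpec(
        caudate_intensity=1.0,
        anterior_putamen_intensity=1.0,
        posterior_putamen_intensity=1.0,
        background_intensity=1.0,
        psf_fwhm_mm=0.0,
        total_counts=None,
    )
    volume, _ = d.make_striatal_phantom(spec, template)
    return volume


@pytest.fixture(scope="session")
def sharp_phantom(template):
    """Noiseless, PSF-free comma-shaped phantom with 6:1 striatal contrast."""
    spec = d.PhantomSpec(
        caudate_intensity=6.0,
        anterior_putamen_intensity=6.0,
        posterior_putamen_intensity=6.0,
        psf_fwhm_mm=0.0,
        total_counts=None,
    )
    return d.make_striatal_phantom(spec, template)


@pytest.fixture(scope="session")
def image_cohort_panels(template, fitted_vois, pentagonal_vois):
    """Rendered 71 PS / 40 NPS cohort at the default calibration (one seed)."""
    cohort = CohortSpec(n_ps=71, n_nps=40, seed=0)
    panels = []
    for i, (spec, label) in enumerate(sample_cohort(cohort)):
        volume, _ = d.make_striatal_phantom(spec, template)
        panels.append(
            d.compute_panel(
                volume,
                fitted_vois,
                pentagonal_vois,
                subject_id=f"{label}{i:03d}",
                label=label,
            )
        )
    return panels


def panels_by_class(panels, index):
    out = {}
    for label in ("NPS", "PS"):
        out[label] = np.array([getattr(p, index) for p in panels if p.label == label])
    return out
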