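"""The six striatal uptake indices.

Intensity: SBR-Q (background-subtracted mean-count ratio over the occipital
reference) and SBR-V (large-VOI count-concentration formulation: total prism
counts converted to an equivalent specific volume and divided by an assumed
striatal volume).  Shape: PCR-Q (putamen/caudate mean-count ratio) and FD-V
(magnitude of the log-log slope of suprathreshold voxel count versus
threshold over five stages).  Asymmetry: AI, the absolute left-right SBR
difference over the mean of the sides, as a fraction (Q) or percent (V).

All indices are ratios or threshold-relative counts, hence invariant to a
global rescaling of the volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .panel import IndexPanel
from .voi import VOISet, voi_stats
from .volume import Volume

#: canonical striatal volume (mL, one hemisphere) of the large-VOI SBR method
DEFAULT_STRIATAL_VOLUME_ML = 11.2


@dataclass(frozen=True)
class FDConfig:
    """Five-stage threshold configuration for the fractal-dimension index."""

    threshold_fractions: tuple[float, ...] = (0.35, 0.40, 0.45, 0.50, 0.55)
    mode: str = "3d"  # "3d": count voxels in the prism; "2d": the peak axial slice

    def __post_init__(self):
        t = np.asarray(self.threshold_fractions, dtype=float)
        if len(t) != 5:
            raise ValueError("exactly 5 threshold stages are required")
        if not ((t > 0).all() and (t < 1).all() and (np.diff(t) > 0).all()):
            raise ValueError("threshold fractions must be strictly increasing within (0, 1)")
        if self.mode not in ("3d", "2d"):
            raise ValueError("mode must be '3d' or '2d'")


@dataclass(frozen=True)
class IndexConfig:
    """Everything the index panel computation depends on."""

    fd: FDConfig = field(default_factory=FDConfig)
    striatal_volume_ml: float = DEFAULT_STRIATAL_VOLUME_ML
    ai_q_scale: float = 1.0  # AI-Q reported as a fraction
    ai_v_scale: float = 100.0  # AI-V reported as a percentage
    sbr_v_formulation: str = "volume"  # "volume" (total-count) | "concentration"


def _require_scheme(vois: VOISet, scheme: str) -> None:
    if vois.scheme != scheme:
        raise ValueError(f"expected a {scheme!r} VOI set, got {vois.scheme!r}")


def sbr_q(volume: Volume, fitted_vois: VOISet) -> tuple[float, float, float]:
    """Background-subtracted striatal/occipital mean-count ratio, per side."""
    _require_scheme(fitted_vois, "fitted_q")
    occ = voi_stats(volume, fitted_vois.masks["occipital_reference"]).mean_counts
    if occ <= 0:
        raise ValueError("occipital reference mean is not positive")
    out = []
    for side in ("left", "right"):
        striatal = voi_stats(volume, fitted_vois.side_mask(side)).mean_counts
        out.append((striatal - occ) / occ)
    left, right = out
    return left, right, (left + right) / 2.0


def sbr_v(
    volume: Volume,
    pentagonal_vois: VOISet,
    v_str_ml: float = DEFAULT_STRIATAL_VOLUME_ML,
    formulation: str = "volume",
) -> tuple[float, float, float]:
    """Large-VOI specific binding ratio, per side.

    The default "volume" formulation converts total prism counts C_t and the
    reference count concentration C_r into the specific volume C_t/C_r -
    V_voi and divides by the assumed striatal volume ``v_str_ml``; because it
    uses totals over a generous prism it is nearly insensitive to resolution
    blur.  The "concentration" option returns the plain background-subtracted
    concentration ratio of the prism instead.
    """
    _require_scheme(pentagonal_vois, "pentagonal_v")
    if v_str_ml <= 0:
        raise ValueError("v_str_ml must be positive")
    ref = voi_stats(volume, pentagonal_vois.masks["whole_brain_reference"])
    c_r = ref.mean_counts / volume.voxel_volume_ml  # counts per mL
    if c_r <= 0:
        raise ValueError("reference count concentration is not positive")
    out = []
    for side in ("left", "right"):
        prism = voi_stats(volume, pentagonal_vois.masks[f"striatal_prism_{side}"])
        if formulation == "volume":
            out.append((prism.total_counts / c_r - prism.volume_ml) / v_str_ml)
        elif formulation == "concentration":
            conc = prism.mean_counts / volume.voxel_volume_ml
            out.append((conc - c_r) / c_r)
        else:
            raise ValueError(f"unknown SBR-V formulation {formulation!r}")
    left, right = out
    return left, right, (left + right) / 2.0


def pcr(volume: Volume, fitted_vois: VOISet) -> tuple[float, float, float]:
    """Putamen/caudate raw mean-count ratio, per side then averaged."""
    _require_scheme(fitted_vois, "fitted_q")
    out = []
    for side in ("left", "right"):
        caud = voi_stats(volume, fitted_vois.masks[f"caudate_{side}"]).mean_counts
        if caud <= 0:
            raise ValueError(f"caudate mean on the {side} is not positive")
        put_mask = (
            fitted_vois.masks[f"anterior_putamen_{side}"]
            | fitted_vois.masks[f"posterior_putamen_{side}"]
        )
        put = voi_stats(volume, put_mask).mean_counts
        out.append(put / caud)
    left, right = out
    return left, right, (left + right) / 2.0


def asymmetry_index(sbr_left: float, sbr_right: float, scale: float = 1.0) -> float:
    """|L - R| divided by the mean of the sides, times ``scale``."""
    mean = (sbr_left + sbr_right) / 2.0
    if mean <= 0:
        raise ValueError("mean SBR of the two sides must be positive")
    return abs(sbr_left - sbr_right) / mean * scale


def threshold_counts(volume: Volume, mask: np.ndarray, config: FDConfig) -> np.ndarray:
    """Suprathreshold voxel counts at each stage (thresholds relative to in-VOI max)."""
    if mask.shape != volume.data.shape:
        raise ValueError("mask shape does not match volume")
    values = volume.data[mask]
    if values.size == 0:
        raise ValueError("mask is empty")
    vmax = values.max()
    if vmax <= 0:
        raise ValueError("in-VOI maximum must be positive")
    if config.mode == "2d":
        flat = np.argmax(volume.data * mask)
        z_peak = np.unravel_index(flat, volume.data.shape)[2]
        values = volume.data[:, :, z_peak][mask[:, :, z_peak]]
    # comparing max-normalised values keeps threshold ties stable under a
    # global rescaling of the volume (scale equivariance of the index)
    rel = values / vmax
    t = np.asarray(config.threshold_fractions)
    return np.array([(rel >= ti).sum() for ti in t])


def fd_from_counts(threshold_fractions, counts) -> float:
    """Least-squares FD from per-stage suprathreshold counts.

    Stages whose region vanished (count 0) are dropped with a warning; at
    least three surviving stages are required for the log-log fit.
    """
    t = np.asarray(threshold_fractions, dtype=float)
    counts = np.asarray(counts, dtype=float)
    keep = counts > 0
    if keep.sum() < len(t):
        warnings.warn(
            f"suprathreshold region vanished at {int((~keep).sum())} stage(s); "
            "fitting the remaining stages",
            RuntimeWarning,
            stacklevel=2,
        )
    if keep.sum() < 3:
        raise ValueError("fewer than 3 non-empty threshold stages; FD undefined")
    slope = np.polyfit(np.log(t[keep]), np.log(counts[keep]), 1)[0]
    return float(-slope)


def fractal_dimension(volume: Volume, mask: np.ndarray, config: FDConfig | None = None) -> float:
    """FD = minus the least-squares slope of ln(count) against ln(threshold)."""
    if config is None:
        config = FDConfig()
    return fd_from_counts(config.threshold_fractions, threshold_counts(volume, mask, config))


def compute_panel(
    volume: Volume,
    fitted_vois: VOISet,
    pentagonal_vois: VOISet,
    config: IndexConfig | None = None,
    subject_id: str = "subject",
    label: str | None = None,
) -> IndexPanel:
    """All six indices for one volume (deterministic)."""
    if config is None:
        config = IndexConfig()
    ql, qr, qm = sbr_q(volume, fitted_vois)
    vl, vr, vm = sbr_v(
        volume,
        pentagonal_vois,
        v_str_ml=config.striatal_volume_ml,
        formulation=config.sbr_v_formulation,
    )
    _, _, pcr_mean = pcr(volume, fitted_vois)
    fd_sides = [
        fractal_dimension(volume, pentagonal_vois.masks[f"striatal_prism_{s}"], config.fd)
        for s in ("left", "right")
    ]
    return IndexPanel(
        subject_id=subject_id,
        label=label,
        sbr_q=qm,
        pcr_q=pcr_mean,
        ai_q=asymmetry_index(ql, qr, scale=config.ai_q_scale),
        sbr_v=vm,
        fd_v=float(np.mean(fd_sides)),
        ai_v=asymmetry_index(vl, vr, scale=config.ai_v_scale),
        sbr_q_left=ql,
        sbr_q_right=qr,
        sbr_v_left=vl,
        sbr_v_right=vr,
    )


class IndexPanelExtractor(BaseEstimator, TransformerMixin):
    """sklearn-style transformer mapping volumes to six-index feature rows.

    ``transform`` accepts a sequence of :class:`~datspect.volume.Volume` and
    returns an (n_subjects, 6) array ordered as
    (sbr_q, pcr_q, ai_q, sbr_v, fd_v, ai_v).  Stateless: ``fit`` is a no-op.
    """

    def __init__(self, fitted_vois=None, pentagonal_vois=None, config=None):
        self.fitted_vois = fitted_vois
        self.pentagonal_vois = pentagonal_vois
        self.config = config

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        from .voi import build_fitted_vois, build_pentagonal_vois

        fitted = self.fitted_vois if self.fitted_vois is not None else build_fitted_vois()
        pent = (
            self.pentagonal_vois if self.pentagonal_vois is not None else build_pentagonal_vois()
        )
        rows = []
        for i, vol in enumerate(X):
            p = compute_panel(vol, fitted, pent, self.config, subject_id=f"s{i}")
            rows.append(p.features("q").tolist() + p.features("v").tolist())
        return np.asarray(rows)
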