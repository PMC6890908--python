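"""Construction of the two VOI schemes and count statistics inside them.

Scheme ``fitted_q`` mimics template-fitted striatal sub-VOIs (caudate,
anterior and posterior putamen per hemisphere) with a bilateral occipital
reference.  Scheme ``pentagonal_v`` mimics the large-VOI approach: one
pentagonal prism per hemisphere sized to enclose the striatum with a wide
margin (so total counts are insensitive to partial-volume spill-out), with
the whole brain minus a box around the basal ganglia as reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import nibabel as nib
import numpy as np
from scipy import ndimage

from .geometry import (
    SIDES,
    STRIATAL_COMPARTMENTS,
    TemplateGeometry,
    brain_mask,
    compartment_masks,
    load_template,
    occipital_mask,
)
from .volume import Volume

FITTED_MASKS = [f"{c}_{s}" for s in SIDES for c in STRIATAL_COMPARTMENTS] + [
    "occipital_reference"
]
PENTAGONAL_MASKS = ["striatal_prism_left", "striatal_prism_right", "whole_brain_reference"]


@dataclass
class VOISet:
    """Named boolean voxel masks under one scheme tag."""

    scheme: str  # "fitted_q" | "pentagonal_v"
    masks: dict[str, np.ndarray]
    voxel_mm: float

    def __post_init__(self):
        expected = {"fitted_q": FITTED_MASKS, "pentagonal_v": PENTAGONAL_MASKS}.get(self.scheme)
        if expected is None:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        missing = [m for m in expected if m not in self.masks]
        if missing:
            raise ValueError(f"scheme {self.scheme} is missing mask(s): {missing}")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) != 1:
            raise ValueError("all masks must share one grid shape")
        for name, m in self.masks.items():
            if not m.any():
                raise ValueError(f"mask {name!r} is empty")
        ref = self.reference_mask()
        for name in self.target_mask_names():
            if (self.masks[name] & ref).any():
                raise ValueError(f"mask {name!r} overlaps the reference region")
        left = self.side_mask("left")
        right = self.side_mask("right")
        if (left & right).any():
            raise ValueError("left and right masks overlap")

    def target_mask_names(self) -> list[str]:
        if self.scheme == "fitted_q":
            return [f"{c}_{s}" for s in SIDES for c in STRIATAL_COMPARTMENTS]
        return ["striatal_prism_left", "striatal_prism_right"]

    def reference_mask(self) -> np.ndarray:
        name = "occipital_reference" if self.scheme == "fitted_q" else "whole_brain_reference"
        return self.masks[name]

    def side_mask(self, side: str) -> np.ndarray:
        if self.scheme == "fitted_q":
            out = np.zeros_like(self.reference_mask())
            for c in STRIATAL_COMPARTMENTS:
                out |= self.masks[f"{c}_{side}"]
            return out
        return self.masks[f"striatal_prism_{side}"]


@dataclass(frozen=True)
class VOIStats:
    """Count statistics of one mask: mean, total and physical volume."""

    mean_counts: float
    total_counts: float
    volume_ml: float
    n_voxels: int


def voi_stats(volume: Volume, mask: np.ndarray) -> VOIStats:
    if mask.shape != volume.data.shape:
        raise ValueError(f"mask shape {mask.shape} does not match volume {volume.data.shape}")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("mask is empty")
    total = float(volume.data[mask].sum())
    return VOIStats(
        mean_counts=total / n,
        total_counts=total,
        volume_ml=n * volume.voxel_volume_ml,
        n_voxels=n,
    )


def build_fitted_vois(template: TemplateGeometry | None = None) -> VOISet:
    """Template-fitted striatal sub-VOIs with a bilateral occipital reference."""
    if template is None:
        template = load_template()
    masks = compartment_masks(template)
    occ = occipital_mask(template)
    striatal_union = np.zeros(template.grid_shape, dtype=bool)
    for m in masks.values():
        striatal_union |= m
    if (occ & striatal_union).any():
        raise ValueError("occipital reference overlaps the striatal template")
    masks["occipital_reference"] = occ
    return VOISet(scheme="fitted_q", masks=masks, voxel_mm=template.voxel_mm)


def _pentagon_mask_2d(x_mm, y_mm, x0, x1, y0, y1, apex_height):
    """House-shaped pentagon: rectangle [x0,x1]x[y0,y1] plus an anterior apex."""
    xm = 0.5 * (x0 + x1)
    in_rect = (x_mm >= x0) & (x_mm <= x1) & (y_mm >= y0) & (y_mm <= y1)
    # two sloped roof edges from (x0,y1) and (x1,y1) up to (xm, y1+apex_height)
    with np.errstate(divide="ignore", invalid="ignore"):
        left_edge = y_mm <= y1 + apex_height * (x_mm - x0) / (xm - x0)
        right_edge = y_mm <= y1 + apex_height * (x1 - x_mm) / (x1 - xm)
    in_roof = (y_mm > y1) & (x_mm >= x0) & (x_mm <= x1) & left_edge & right_edge
    return in_rect | in_roof


def build_pentagonal_vois(template: TemplateGeometry | None = None) -> VOISet:
    """Large pentagonal prisms plus whole-brain reference.

    Each prism is the axial pentagon (apex anterior) circumscribing that
    hemisphere's striatal template dilated by ``pentagon_dilation_mm``,
    extruded over the dilated z-range and clipped at the midline so the two
    prisms stay disjoint.  The reference is the brain mask eroded away from
    its surface, minus the prism union dilated by one voxel.
    """
    if template is None:
        template = load_template()
    comp = compartment_masks(template)
    voxel = template.voxel_mm
    x_mm, y_mm, _ = template.voxel_centers_mm()
    x1d = x_mm[:, 0, 0]
    y1d = y_mm[0, :, 0]

    prisms: dict[str, np.ndarray] = {}
    for side in SIDES:
        side_mask = np.zeros(template.grid_shape, dtype=bool)
        for c in STRIATAL_COMPARTMENTS:
            side_mask |= comp[f"{c}_{side}"]
        dist = ndimage.distance_transform_edt(~side_mask, sampling=voxel)
        dilated = dist <= template.pentagon_dilation_mm
        xs = x1d[dilated.any(axis=(1, 2))]
        ys = y1d[dilated.any(axis=(0, 2))]
        zidx = np.where(dilated.any(axis=(0, 1)))[0]
        pent = _pentagon_mask_2d(
            x1d[:, None],
            y1d[None, :],
            xs.min(),
            xs.max(),
            ys.min(),
            ys.max(),
            template.pentagon_apex_height_mm,
        )
        prism = np.zeros(template.grid_shape, dtype=bool)
        prism[:, :, zidx.min() : zidx.max() + 1] = pent[:, :, None]
        hemisphere = x1d < 0 if side == "left" else x1d > 0
        prism &= hemisphere[:, None, None]
        if (side_mask & ~prism).any():
            raise ValueError(f"striatal template not fully contained in the {side} prism")
        prisms[f"striatal_prism_{side}"] = prism

    brain = brain_mask(template)
    interior = (
        ndimage.distance_transform_edt(brain, sampling=voxel)
        >= template.reference_brain_erosion_mm
    )
    union = prisms["striatal_prism_left"] | prisms["striatal_prism_right"]
    exclusion = ndimage.binary_dilation(
        union, iterations=template.reference_exclusion_dilation_voxels
    )
    reference = interior & ~exclusion
    if not reference.any():
        raise ValueError("whole-brain reference is empty; geometry parameters inconsistent")
    masks = {**prisms, "whole_brain_reference": reference}
    return VOISet(scheme="pentagonal_v", masks=masks, voxel_mm=template.voxel_mm)


# --- serialization: integer label map (NIfTI) + JSON legend -------------------


def save_voiset(voiset: VOISet, label_path: str | Path, legend_path: str | Path) -> None:
    names = sorted(voiset.masks)
    label = np.zeros(next(iter(voiset.masks.values())).shape, dtype=np.int16)
    legend = {}
    for i, name in enumerate(names, start=1):
        overlap = (label > 0) & voiset.masks[name]
        if overlap.any():
            raise ValueError(f"mask {name!r} overlaps another mask; cannot build a label map")
        label[voiset.masks[name]] = i
        legend[str(i)] = name
    vol = Volume(label.astype(float), voiset.voxel_mm)
    img = nib.Nifti1Image(label, vol.affine())
    img.header.set_zooms((voiset.voxel_mm,) * 3)
    nib.save(img, str(label_path))
    Path(legend_path).write_text(
        json.dumps({"scheme": voiset.scheme, "labels": legend}, indent=2)
    )


def load_voiset(label_path: str | Path, legend_path: str | Path) -> VOISet:
    img = nib.load(str(label_path))
    label = np.asarray(img.dataobj).astype(int)
    meta = json.loads(Path(legend_path).read_text())
    masks = {name: label == int(i) for i, name in meta["labels"].items()}
    return VOISet(
        scheme=meta["scheme"], masks=masks, voxel_mm=float(img.header.get_zooms()[0])
    )
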