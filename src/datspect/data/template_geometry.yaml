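# Striatal phantom template geometry, version 1.
# Coordinates are mm offsets from the grid centre; x runs left->right,
# y posterior->anterior, z inferior->superior.  "left" structures sit at
# negative x.  Semi-axes are ellipsoid half-widths in mm.
version: 1
grid_shape: [128, 128, 64]
voxel_mm: 4.4
structures:
  brain:              {center: [0.0, 0.0, 0.0],      semi_axes: [72.0, 88.0, 66.0]}
  caudate_left:       {center: [-13.0, 13.0, 4.0],   semi_axes: [6.5, 12.5, 11.0]}
  caudate_right:      {center: [13.0, 13.0, 4.0],    semi_axes: [6.5, 12.5, 11.0]}
  anterior_putamen_left:   {center: [-25.0, 10.5, 0.0],  semi_axes: [7.0, 10.0, 12.6]}
  anterior_putamen_right:  {center: [25.0, 10.5, 0.0],   semi_axes: [7.0, 10.0, 12.6]}
  posterior_putamen_left:  {center: [-27.0, -10.5, 0.0], semi_axes: [7.0, 10.0, 12.6]}
  posterior_putamen_right: {center: [27.0, -10.5, 0.0],  semi_axes: [7.0, 10.0, 12.6]}
  occipital_left:     {center: [-20.0, -52.0, -2.0], semi_axes: [12.0, 11.0, 10.0]}
  occipital_right:    {center: [20.0, -52.0, -2.0],  semi_axes: [12.0, 11.0, 10.0]}
pentagon:
  dilation_mm: 12.0       # striatal template dilated by one PSF FWHM before fitting the prism
  apex_height_mm: 15.0    # anterior apex of the pentagonal cross-section
reference:
  brain_erosion_mm: 18.0        # keeps the whole-brain reference away from edge partial volume
  exclusion_dilation_voxels: 1  # basal-ganglia box = prism union dilated this many voxels
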