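# Initial contour: a closed polygon drawn on one slice.
#   slice_index: 0-based slice number (the z index of the DICOM series
#                after sorting along the slice normal, or the NIfTI k index)
#   vertices:    ordered [x, y] pixel coordinates, 0-based, fractional
#                allowed; x = column (first array index), y = row. The
#                polygon closes itself (last vertex connects to the first).
# Draw the contour well inside the tumor component you want to segment —
# the surface grows outward from it.
slice_index: 24
vertices:
  - [52.5, 44.5]
  - [58.5, 45.5]
  - [58.0, 51.0]
  - [52.0, 50.5]
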