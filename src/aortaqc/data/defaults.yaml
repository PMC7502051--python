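# Default run configuration. Every key mirrors a field of
# aortaqc.config.RunConfig; values here are the package defaults, including
# the published parameters of the method (existence_threshold, offset_mm,
# top_k, path_length, cost_threshold, radius_reduction_px,
# category_boundaries).

# slice detection
existence_threshold: 0.6
offset_mm: 230.0
search_fraction: 0.6666666666666666
templates_per_soi: 3

# aortic ROI: circle Hough + dynamic programming
radius_range_mm: [8.0, 25.0]
edge_threshold: 100.0
top_k: 6
hough_min_score: 0.1
path_length: 5
cost_threshold: 200.0
variance_norm_v0: 100.0
radius_reduction_px: 4

# femoral ROI: vesselness
vessel_scales_mm: [1.0, 2.0, 3.0, 4.0]
bone_threshold_hu: 600.0
bone_dilation_px: 2
min_response: 0.1
search_band_px: 30
search_band_min_medial_px: 6

# classification
category_boundaries: [180.0, 240.0, 300.0, 360.0]
total_coverage: false
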