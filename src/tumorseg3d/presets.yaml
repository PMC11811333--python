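# Per-component segmentation presets.
#
# weights: [alpha, beta, gamma] = edge, region, smoothing weights of the
# hybrid speed F = alpha*S_e + beta*S_r + gamma*S_s (normalized to sum to 1).
# Rules encoded by check_weight_recommendations: edema needs beta >= 0.5
# (large, low-contrast halo is region-driven); gamma <= 0.3 for every
# component (stronger smoothing cannot hold irregular tumor boundaries).
#
# edge_scale: Gaussian sigma (mm) used to pre-smooth the image before the
# edge-stopping function. iterations: default evolution budget.
contrast_enhancing:
  weights: [0.3, 0.5, 0.2]
  edge_scale: 1.0
  iterations: 300
necrotic:
  weights: [0.3, 0.5, 0.2]
  edge_scale: 1.0
  iterations: 300
edema:
  weights: [0.2, 0.5, 0.3]
  edge_scale: 1.0
  iterations: 300
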