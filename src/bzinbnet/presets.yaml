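# Simulation scenario presets.
#
# lognormal: bivariate lognormal pair designs (n = 300, unit log-scale
# variance).  Zeros are introduced per margin either by the rank-based
# probability rule (metabolite margins: low counts are likelier to drop
# out) or by zeroing an exact number of randomly chosen positions
# (species margins: structural absences).  "zeros" are the target zero
# counts per margin, "means" the log-scale means before zeroing.
#
# bzinb/masking: the four zero-inflation regimes (pi1..pi4 = both
# observed / only first / only second / neither) with the implied
# expected masked-zero counts at n = 300.
#
# bzinb/shapes: shared-component shape/scale sets hitting each target
# latent correlation exactly: with alpha1 = alpha2 = 2 and beta1 =
# beta2 = 3, rho = alpha0 * (beta/(beta+1)) / (alpha0 + 2) so
# alpha0 = 2 rho / (0.75 - rho).

lognormal:
  met_sp_a:
    label: "Metabolite-species, balanced low"
    means: [14, 11]
    zeros: [30, 60]
    mechanisms: [rank_based, random_exact]
  met_sp_b:
    label: "Metabolite-species, balanced high"
    means: [12, 9]
    zeros: [150, 200]
    mechanisms: [rank_based, random_exact]
  met_sp_c:
    label: "Metabolite-species, unbalanced case 1"
    means: [14, 9]
    zeros: [30, 200]
    mechanisms: [rank_based, random_exact]
  met_sp_d:
    label: "Metabolite-species, unbalanced case 2"
    means: [12, 11]
    zeros: [150, 60]
    mechanisms: [rank_based, random_exact]
  sp_sp_a:
    label: "Species-species, balanced low"
    means: [11, 11]
    zeros: [60, 60]
    mechanisms: [random_exact, random_exact]
  sp_sp_b:
    label: "Species-species, balanced high"
    means: [9, 9]
    zeros: [200, 200]
    mechanisms: [random_exact, random_exact]
  sp_sp_c:
    label: "Species-species, unbalanced"
    means: [11, 9]
    zeros: [60, 200]
    mechanisms: [random_exact, random_exact]

bzinb:
  masking:
    bzinb_a:
      label: "Balanced, low"
      pi: [0.75, 0.15, 0.05, 0.05]
      expected_zeros: [30, 60]
    bzinb_b:
      label: "Balanced, high"
      pi: [0.1, 0.2, 0.1, 0.6]
      expected_zeros: [210, 240]
    bzinb_c:
      label: "Unbalanced, fewer zeros in first margin"
      pi: [0.2, 0.6, 0.05, 0.15]
      expected_zeros: [60, 225]
    bzinb_d:
      label: "Unbalanced, fewer zeros in second margin"
      pi: [0.2, 0.05, 0.6, 0.15]
      expected_zeros: [225, 60]
  shapes:
    alpha1: 2.0
    alpha2: 2.0
    beta1: 3.0
    beta2: 3.0
    rho_targets: [0.05, 0.1, 0.3, 0.5]
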