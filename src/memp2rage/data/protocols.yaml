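# Reference acquisition protocols (0.6 mm isotropic, 7 T).
# Units: seconds, degrees, Hz/pixel.  Flip angles are nominal; scale them
# with flip_accuracy to model the measured B1+ efficiency.
# The ME-MP2RAGE block timing only fits the period with the k-space center
# at the 6/8 partial-Fourier position, hence center_fraction = 1/3.
me_mp2rage:
  sequence_kind: me_mp2rage
  tr_seq: 6.0
  ti_1: 0.75
  ti_2: 2.90
  alpha_1: 4.0
  alpha_2: 6.0
  tr_gre: 0.0181
  n_lines: 114
  n_echoes: 4
  te_first: 0.00235
  delta_te: 0.00414
  bandwidth: 280.0
  inv_efficiency: 1.0
  flip_accuracy: 1.0
  center_fraction: 0.3333333333333333
mp2rage:
  sequence_kind: mp2rage
  tr_seq: 5.0
  ti_1: 0.80
  ti_2: 2.40
  alpha_1: 4.0
  alpha_2: 4.0
  tr_gre: 0.0059
  n_lines: 105
  n_echoes: 1
  te_first: 0.00235
  delta_te: 0.0
  bandwidth: 280.0
  inv_efficiency: 1.0
  flip_accuracy: 1.0
  center_fraction: 0.5
# Inversion-time variant used in the precision simulations.
mp2rage_sim:
  sequence_kind: mp2rage
  tr_seq: 5.0
  ti_1: 0.75
  ti_2: 2.90
  alpha_1: 4.0
  alpha_2: 4.0
  tr_gre: 0.0059
  n_lines: 105
  n_echoes: 1
  te_first: 0.00235
  delta_te: 0.0
  bandwidth: 280.0
  inv_efficiency: 1.0
  flip_accuracy: 1.0
  center_fraction: 0.5
me_flash:
  sequence_kind: me_flash
  alpha_1: 11.0
  alpha_2: 11.0
  tr_gre: 0.031
  n_lines: 0
  n_echoes: 5
  te_first: 0.003
  delta_te: 0.006
  bandwidth: 200.0
  inv_efficiency: 0.0
  flip_accuracy: 1.0
  center_fraction: 0.5
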