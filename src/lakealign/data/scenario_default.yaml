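lakes:
- lake_id: lake01
  n_observations: 46
  chla_median: 40.0
  chla_sigma_log: 0.7
  turbidity_median: 15.0
  turbidity_sigma_log: 1.4
  owt: 1
- lake_id: lake02
  n_observations: 60
  chla_median: 32.74186922827611
  chla_sigma_log: 0.7
  turbidity_median: 15.0
  turbidity_sigma_log: 1.4
  owt: 6
- lake_id: lake03
  n_observations: 80
  chla_median: 26.80075001403834
  chla_sigma_log: 0.7
  turbidity_median: 15.0
  turbidity_sigma_log: 1.4
  owt: 11
- lake_id: lake04
  n_observations: 100
  chla_median: 21.937666304484065
  chla_sigma_log: 0.7
  turbidity_median: 15.0
  turbidity_sigma_log: 1.4
  owt: 3
- lake_id: lake05
  n_observations: 140
  chla_median: 17.957005032874417
  chla_sigma_log: 0.7
  turbidity_median: 15.0
  turbidity_sigma_log: 1.4
  owt: 8
- lake_id: lake06
  n_observations: 160
  chla_median: 14.698647762946756
  chla_sigma_log: 0.7
  turbidity_median: 15.0
  turbidity_sigma_log: 1.4
  owt: 13
- lake_id: lake07
  n_observations: 200
  chla_median: 12.031530072172398
  chla_sigma_log: 0.7
  turbidity_median: 15.0
  turbidity_sigma_log: 1.4
  owt: 5
- lake_id: lake08
  n_observations: 250
  chla_median: 9.8483696059785
  chla_sigma_log: 0.7
  turbidity_median: 14.10263969432168
  turbidity_sigma_log: 1.4
  owt: 10
- lake_id: lake09
  n_observations: 300
  chla_median: 8.06135074376693
  chla_sigma_log: 0.7
  turbidity_median: 11.777131947188455
  turbidity_sigma_log: 1.4
  owt: 2
- lake_id: lake10
  n_observations: 400
  chla_median: 6.598592296392081
  chla_sigma_log: 0.7
  turbidity_median: 9.835097535487188
  turbidity_sigma_log: 1.4
  owt: 7
- lake_id: lake11
  n_observations: 500
  chla_median: 5.401256151479491
  chla_sigma_log: 0.7
  turbidity_median: 8.213302183103943
  turbidity_sigma_log: 1.4
  owt: 12
- lake_id: lake12
  n_observations: 700
  chla_median: 4.421180564504085
  chla_sigma_log: 0.7
  turbidity_median: 6.858938867415961
  turbidity_sigma_log: 1.4
  owt: 4
- lake_id: lake13
  n_observations: 900
  chla_median: 3.618942896939718
  chla_sigma_log: 0.7
  turbidity_median: 5.727908378158594
  turbidity_sigma_log: 1.4
  owt: 9
- lake_id: lake14
  n_observations: 1200
  chla_median: 2.9622738769049746
  chla_sigma_log: 0.7
  turbidity_median: 4.783383409996753
  turbidity_sigma_log: 1.4
  owt: 1
- lake_id: lake15
  n_observations: 1600
  chla_median: 2.4247595973990284
  chla_sigma_log: 0.7
  turbidity_median: 3.994609434445571
  turbidity_sigma_log: 1.4
  owt: 6
- lake_id: lake16
  n_observations: 2100
  chla_median: 1.9847790412011608
  chla_sigma_log: 0.7
  turbidity_median: 3.3359033065201027
  turbidity_sigma_log: 1.4
  owt: 11
- lake_id: lake17
  n_observations: 2800
  chla_median: 1.6246343953507916
  chla_sigma_log: 0.7
  turbidity_median: 2.7858169999030937
  turbidity_sigma_log: 1.4
  owt: 3
- lake_id: lake18
  n_observations: 3700
  chla_median: 1.3298391729083763
  chla_sigma_log: 0.7
  turbidity_median: 2.326439241143606
  turbidity_sigma_log: 1.4
  owt: 8
- lake_id: lake19
  n_observations: 4900
  chla_median: 1.0885355073501233
  chla_sigma_log: 0.7
  turbidity_median: 1.942812303507771
  turbidity_sigma_log: 1.4
  owt: 13
- lake_id: lake20
  n_observations: 6500
  chla_median: 0.8910171807998227
  chla_sigma_log: 0.7
  turbidity_median: 1.622444970798262
  turbidity_sigma_log: 1.4
  owt: 5
- lake_id: lake21
  n_observations: 8600
  chla_median: 0.7293392003473763
  chla_sigma_log: 0.7
  turbidity_median: 1.3549058128342486
  turbidity_sigma_log: 1.4
  owt: 10
- lake_id: lake22
  n_observations: 11000
  chla_median: 0.5969982180207318
  chla_sigma_log: 0.7
  turbidity_median: 1.13148352929888
  turbidity_sigma_log: 1.4
  owt: 2
- lake_id: lake23
  n_observations: 15000
  chla_median: 0.4886709395987166
  chla_sigma_log: 0.7
  turbidity_median: 0.944903302463924
  turbidity_sigma_log: 1.4
  owt: 7
- lake_id: lake24
  n_observations: 20000
  chla_median: 0.4
  chla_sigma_log: 0.7
  turbidity_median: 0.7890899229973565
  turbidity_sigma_log: 1.4
  owt: 12
seed: 0
bluegreen_distortion:
- 0.6934812760055479
- 0.3536754507628294
bluegreen_noise_sd: 0.03
nirred_distortion:
- 0.93
- -0.02
nirred_noise_sd: 0.02
nir_amplitude_gain:
  b665: 1.1337868480725624
  b778: 1.1862396204033214
  b865: 1.0101010101010102
bluegreen_skew_mu: 0.05
bluegreen_skew_sigma: 0.1
reflectance_noise_sd: 0.01
adjacency_amplitude: 0.002
adjacency_efold_km: 5.0
adjacency_band_weights:
  b443: 1.0
  b490: 1.0
  b560: 1.0
  b665: 1.0
  b708: 1.0
  b778: 1.0
  b865: 1.0
flag_probabilities:
  cloud: 0.01
  cloud_sure: 0.005
  cloud_buffer: 0.01
  cloud_ambiguous: 0.005
  cirrus_sure: 0.002
  cirrus_ambiguous: 0.002
  potential_shadow: 0.005
  land: 0.002
  out_of_bounds_msi: 0.002
  out_of_bounds_olci: 0.002
  snow_ice_olci: 0.002
clear_water_probability: 0.98
neighbour_probabilities:
- 0.0
- 0.0
- 0.005
- 0.005
- 0.01
- 0.02
- 0.06
- 0.2
- 0.7
distance_range_km:
- 0.1
- 100.0
rw560_median: 0.01
rw560_sigma_log: 0.25
b443_factor: 0.9
nir_red_inversion: gilerson
ocx_out_of_branch: clamp
ocx_branch:
- -0.35
- 1.5
resample_budget: 100
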