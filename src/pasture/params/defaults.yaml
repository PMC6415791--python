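# Packaged default configuration; overridable by a user config file (--config)
# and by CLI flags, in that order of increasing precedence.
growth:
  rue: 0.9                 # g above-ground DM per MJ intercepted PAR (0.8-1.2 typical)
  k_ext: 0.6               # canopy light extinction coefficient
  par_fraction: 0.48       # PAR fraction of global solar radiation
  sla: 25.0                # m2 leaf per kg DM
  leaf_partition: 0.6
  t_base: 4.0              # deg C
  t_opt: [16.0, 25.0]
planner:
  pre_grazing_target: 2700.0    # kg DM/ha
  post_grazing_target: 1300.0   # kg DM/ha
  min_farm_cover: 1800.0        # kg DM/ha
scene:
  n_paddocks: 16
  paddock_dims: [200.0, 50.0]
  pixel_size: 2.0
  biomass_mean: 1800.0
  correlation_length: 30.0
  biomass_cv: 0.45
  true_alpha: 66.5
  true_beta: 5.32
  noise_cv: 0.0
map_bands:                      # biomass map class edges, kg DM/ha
  - 500.0
  - 1700.0
  - 2800.0
ndvi_saturation: 0.8
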