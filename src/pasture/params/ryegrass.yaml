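# Perennial ryegrass: derived from the fescue defaults by the four standard
# adjustments for the species' faster leaf turnover and better feed quality:
#   leaf lifespan 630 -> 330 degree days,
#   leaf appearance and elongation rates two-fold fescue's,
#   minimum NDF 5 percentage units lower,
#   maximum NDFD 20 percentage units higher.
species: ryegrass
phyllochron_cd: 105.0            # fescue 210 / 2 (two-fold appearance rate)
leaf_elongation_rate_cm_per_cd: 0.30   # fescue 0.15 x 2
leaf_lifespan_cd: 330.0
ndf_min_pct: 40.0                # fescue 45 - 5
ndf_max_pct: 65.0
ndfd_max_pct: 90.0               # fescue 70 + 20
ndfd_min_pct: 35.0
metabolic_factor_g_kg: 119
elongation_fraction: 0.33
residual_ref_cm: 6.0
residual_length_exponent: 0.5
ndf_length_coeff_pct_per_cm: 0.15
ndfd_length_coeff_pct_per_cm: 0.30
initial_leaf_age_fraction: 0.9
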