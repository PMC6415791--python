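# Tall fescue morphogenetic and nutritive defaults.
# Numeric values are literature-plausible defaults for temperate tall fescue
# swards and are user-replaceable; the leaf lifespan of 630 degree days is the
# species' standard parameterization.
species: fescue
phyllochron_cd: 210.0            # ~3 live leaves maintained (lifespan/phyllochron)
leaf_elongation_rate_cm_per_cd: 0.15
leaf_lifespan_cd: 630.0
ndf_min_pct: 45.0                # youngest sward NDF
ndf_max_pct: 65.0                # fully aged sward NDF
ndfd_max_pct: 70.0               # youngest sward NDF digestibility
ndfd_min_pct: 35.0
metabolic_factor_g_kg: 119       # in-vitro apparent-DMD correction (g/kg = 11.9 % points)
elongation_fraction: 0.33        # elongation duration / leaf lifespan
residual_ref_cm: 6.0             # residual height with unit length scaling
residual_length_exponent: 0.5    # sheath-tube proxy: leaf length ~ (residual/ref)^exp
ndf_length_coeff_pct_per_cm: 0.15
ndfd_length_coeff_pct_per_cm: 0.30
initial_leaf_age_fraction: 0.9   # stubble leaf is old tissue
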