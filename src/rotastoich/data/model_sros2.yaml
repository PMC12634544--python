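# Six-latent structural model of the rotation-system remediation pathways.
# Two cascades: a biological pathway
#   treatment -> soil_properties -> microbial_community -> enzyme_ratios
# and a physicochemical pathway
#   treatment -> micronutrients -> enzyme_activity -> enzyme_ratios
# Indicator names match the columns of the pipeline's merged table.
latents:
  - treatment
  - soil_properties
  - micronutrients
  - microbial_community
  - enzyme_activity
  - enzyme_ratios
blocks:
  treatment: [treatment_ordinal]
  soil_properties: [SOC, TN, AP, pH]
  micronutrients: [Mg, Fe, Mn, Cu, Zn]
  microbial_community:
    [bacterial_chao1, bacterial_simpson, fungal_chao1, fungal_simpson]
  enzyme_activity: [BG, NAG, PPO]
  enzyme_ratios: [ratio_cn, ratio_cppo, ratio_cp, ratio_nagl]
inner:
  - [soil_properties, treatment]
  - [micronutrients, treatment]
  - [microbial_community, soil_properties]
  - [enzyme_activity, micronutrients]
  - [enzyme_ratios, microbial_community]
  - [enzyme_ratios, enzyme_activity]
scheme: path
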