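# Default 84-analyte scheduled-MRM panel configuration.
#
# RECONSTRUCTED: the assay monitors 84 molecular species across 14
# classes, but the exact per-class ceramide roster is instrument-method
# metadata that is not public.  This default assigns six
# ceramide species per class (14 x 6 = 84): {d34:1, d36:1, d38:1, d40:1,
# d41:1, d42:1}; note every purchased calibration standard falls in this
# set (d18:1/16:0 = d34:1, d18:1/18:0 = d36:1, d18:1/24:0 = d42:1).
# The config is data, not code: replace the rosters with the instrument
# method's true list to override.
#
# Charges default to [M-H]- for mono-sialo classes, [M-2H]2- for di/tri/
# quadri-sialo classes and [M+H]+ for neutral classes; per-species
# "charge" overrides are honoured.  RT model parameters reproduce the
# observed elution ordering only (more sialic acids elute earlier; longer
# chains elute later); absolute retention times are nominal.

gradient_min: 15.0
rt_window_min: 1.0

rt_model:
  chain_slope_per_carbon: 0.05   # min per ceramide carbon beyond C36
  unsat_slope: 0.05              # min earlier per double bond
  class_base_rt:                 # min, at d36:1
    GQ1: 3.0
    GT1: 3.8
    GT2: 4.0
    GT3: 4.2
    GD1: 5.0
    GD2: 5.2
    GD3: 5.4
    GM1: 6.5
    GM2: 6.7
    GM3: 6.9
    GA2: 8.0
    LacCer: 8.3
    Gb3: 8.6
    GlcCer: 9.0

classes:
  GM3:    {species: ["d34:1", "d36:1", "d38:1", "d40:1", "d41:1", "d42:1"]}
  GM2:    {species: ["d34:1", "d36:1", "d38:1", "d40:1", "d41:1", "d42:1"]}
  GM1:    {species: ["d34:1", "d36:1", "d38:1", "d40:1", "d41:1", "d42:1"]}
  GD3:    {species: ["d34:1", "d36:1", "d38:1", "d40:1", "d41:1", "d42:1"]}
  GD2:    {species: ["d34:1", "d36:1", "d38:1", "d40:1", "d41:1", "d42:1"]}
  GD1:    {species: ["d34:1", "d36:1", "d38:1", "d40:1", "d41:1", "d42:1"]}
  GT3:    {species: ["d34:1", "d36:1", "d38:1", "d40:1", "d41:1", "d42:1"]}
  GT2:    {species: ["d34:1", "d36:1", "d38:1", "d40:1", "d41:1", "d42:1"]}
  GT1:    {species: ["d34:1", "d36:1", "d38:1", "d40:1", "d41:1", "d42:1"]}
  GQ1:    {species: ["d34:1", "d36:1", "d38:1", "d40:1", "d41:1", "d42:1"]}
  GlcCer: {species: ["d34:1", "d36:1", "d38:1", "d40:1", "d41:1", "d42:1"]}
  LacCer: {species: ["d34:1", "d36:1", "d38:1", "d40:1", "d41:1", "d42:1"]}
  Gb3:    {species: ["d34:1", "d36:1", "d38:1", "d40:1", "d41:1", "d42:1"]}
  GA2:    {species: ["d34:1", "d36:1", "d38:1", "d40:1", "d41:1", "d42:1"]}

# Internal standards: deuterated or odd-acyl analogues spiked at fixed
# amount; each analyte class is quantified against the structurally
# closest IS.
internal_standards:
  - {class: GM3, ceramide: "d18:1/18:0-d5"}
  - {class: GM1, ceramide: "d18:1/17:0"}
  - {class: GlcCer, ceramide: "d18:1/16:0-d3"}
  - {class: Gb3, ceramide: "d18:1/18:0-d3"}

# analyte class -> IS species id
is_map:
  GM3: "GM3 d18:1/18:0-d5"
  GD3: "GM3 d18:1/18:0-d5"
  GT3: "GM3 d18:1/18:0-d5"
  GM1: "GM1 d18:1/17:0"
  GM2: "GM1 d18:1/17:0"
  GD1: "GM1 d18:1/17:0"
  GD2: "GM1 d18:1/17:0"
  GT1: "GM1 d18:1/17:0"
  GT2: "GM1 d18:1/17:0"
  GQ1: "GM1 d18:1/17:0"
  GA2: "GM1 d18:1/17:0"
  GlcCer: "GlcCer d18:1/16:0-d3"
  LacCer: "GlcCer d18:1/16:0-d3"
  Gb3: "Gb3 d18:1/18:0-d3"
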