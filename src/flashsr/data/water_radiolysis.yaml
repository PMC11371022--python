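# Nine-species cellular water-radiolysis network.
#
# Primary radiolytic yields (G-values, umol/J) are the standard low-LET
# photon values from the pulse-radiolysis literature (Buxton et al. 1988
# compilation); second-order rate constants are the recommended aqueous
# values from the same compilation.  The biology-facing channels
# (H-abstraction from biomolecules RH, superoxide dismutase, catalase,
# antioxidant reduction of peroxyl radicals) are pseudo-first-order
# contractions of enzyme/substrate reactions at typical intracellular
# concentrations, on the scale used in kinetic models of the FLASH
# sparing effect.  Edit freely: the file is the model definition.
name: water-radiolysis-9
readout: ROO
species:
  - name: e_aq
    description: "hydrated electron e_aq-, primary water-radiolysis product"
    initial: 0.0
    g_value: 0.28
  - name: O2
    description: "molecular oxygen, physioxic tissue level"
    initial: 5.0e-05
    g_value: 0.0
  - name: H2O2
    description: "hydrogen peroxide"
    initial: 0.0
    g_value: 0.073
  - name: OH
    description: "hydroxyl radical OH*"
    initial: 0.0
    g_value: 0.28
  - name: H
    description: "hydrogen atom H*"
    initial: 0.0
    g_value: 0.062
  - name: H2
    description: "molecular hydrogen"
    initial: 0.0
    g_value: 0.047
  - name: O2m
    description: "superoxide anion O2*- (HO2* lumped in)"
    initial: 0.0
    g_value: 0.0
  - name: R
    description: "carbon-centred biomolecule radical R* (from RH)"
    initial: 0.0
    g_value: 0.0
  - name: ROO
    description: "peroxyl radical ROO*, damage proxy for lipids and DNA"
    initial: 0.0
    g_value: 0.0
reactions:
  - equation: "e_aq + O2 -> O2m"
    k: 1.9e+10
    source: "Buxton et al. 1988"
  - equation: "H + O2 -> O2m"
    k: 2.1e+10
    source: "Buxton et al. 1988 (HO2 lumped with superoxide)"
  - equation: "2 OH -> H2O2"
    k: 5.5e+09
    source: "Buxton et al. 1988"
  - equation: "e_aq + OH ->"
    k: 3.0e+10
    source: "Buxton et al. 1988 (product OH-, outside the nine species)"
  - equation: "e_aq + H2O2 -> OH"
    k: 1.1e+10
    source: "Buxton et al. 1988"
  - equation: "OH + H2 -> H"
    k: 4.2e+07
    source: "Buxton et al. 1988"
  - equation: "OH + H2O2 -> O2m"
    k: 2.7e+07
    source: "Buxton et al. 1988"
  - equation: "2 e_aq -> H2"
    k: 5.5e+09
    source: "Buxton et al. 1988"
  - equation: "2 H -> H2"
    k: 7.8e+09
    source: "Buxton et al. 1988"
  - equation: "e_aq + H -> H2"
    k: 2.5e+10
    source: "Buxton et al. 1988"
  - equation: "OH -> R"
    k: 4.0e+08
    source: "pseudo-first-order H-abstraction from biomolecules RH at cellular scavenging capacity"
  - equation: "H -> R"
    k: 1.0e+08
    source: "pseudo-first-order H-abstraction from biomolecules RH"
  - equation: "R + O2 -> ROO"
    k: 4.9e+08
    source: "oxygen capture by carbon-centred radicals"
  - equation: "2 R -> "
    k: 7.8e+08
    source: "radical-radical recombination to non-radical products"
  - equation: "2 ROO -> "
    k: 1.0e+08
    source: "bimolecular peroxyl termination (Russell mechanism)"
  - equation: "ROO -> "
    k: 10.0
    source: "pseudo-first-order reduction by cellular antioxidants"
  - equation: "O2m -> 0.5 H2O2 + 0.5 O2"
    k: 2.0e+04
    source: "superoxide dismutase, pseudo-first-order at cellular SOD level"
  - equation: "H2O2 -> 0.5 O2"
    k: 1.0
    source: "catalase / peroxidase clearance, pseudo-first-order"
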