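"""Physical constants shared by all model variants.

These are fixed by convention, not estimated: the gas constant, the leaf
absorptance of photosynthetic pigments, the assumed equal partitioning of
absorbed light between the photosystems, and the atmospheric O2 fraction.
"""

#: Universal gas constant (J K^-1 mol^-1).
R_GAS = 8.314

#: Absorptance of leaf photosynthetic pigments (unitless).
ALPHA_LEAF = 0.85

#: Fraction of absorbed light reaching photosystem II (unitless).
F_PSII = 0.5

#: Mole fraction of O2 in air, used when O2 partial pressure is auto-derived.
O2_FRACTION = 0.21

#: Reference temperature of the Arrhenius response, in Kelvin.  Kept at the
#: integer value used in the temperature-response formulation (not 298.15).
T_REF_K = 298.0

#: Celsius -> Kelvin offset.
KELVIN_OFFSET = 273.15

#: Ratio of diffusivities of H2O and CO2 in air, used to convert stomatal
#: conductance to water vapour into conductance to CO2.
H2O_CO2_DIFFUSIVITY_RATIO = 1.6
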