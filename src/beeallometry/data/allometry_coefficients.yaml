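# Published six-family allometric power-function coefficients for bee
# mouthpart length on intertegular distance (IT, mm).  Natural-log scale:
# ln(length_mm) = intercept_family + slope * ln(IT_mm).
# Proboscis and glossa: common slope across families (additive best model);
# prementum: family-specific slopes (interaction best model).
proboscis:
  intercepts:
    Andrenidae: 1.06
    Apidae: 2.15
    Colletidae: 0.86
    Halictidae: 1.37
    Megachilidae: 1.87
    Melittidae: 1.10
  slope: 0.96
glossa:
  intercepts:
    Andrenidae: 0.23
    Apidae: 1.28
    Colletidae: 0.21
    Halictidae: 0.42
    Megachilidae: 1.17
    Melittidae: 0.29
  slope: 1.04
prementum:
  intercepts:
    Andrenidae: 0.88
    Apidae: 0.91
    Colletidae: 0.56
    Halictidae: 0.89
    Megachilidae: 0.76
    Melittidae: 1.26
  slopes:
    Andrenidae: 0.83
    Apidae: 0.75
    Colletidae: 1.14
    Halictidae: 1.05
    Megachilidae: 0.70
    Melittidae: 0.45
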