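# Indicator catalog for the western-Jilin case study (9 districts/counties,
# 10 indicators).  All ten indicators are vulnerability-driving (cost-type),
# hence orientation: contrarian throughout.  The source index list skips the
# name of the 9th indicator; it is kept positionally with a placeholder label.
indicators:
  - {id: "1", label: "average water shortage", category: water, orientation: contrarian}
  - {id: "2", label: "change rate of dry index", category: climate, orientation: contrarian}
  - {id: "3", label: "change rate of water", category: water, orientation: contrarian}
  - {id: "4", label: "spring drought frequency", category: climate, orientation: contrarian}
  - {id: "5", label: "summer drought frequency", category: climate, orientation: contrarian}
  - {id: "6", label: "flood frequency", category: water, orientation: contrarian}
  - {id: "7", label: "degree of grassland degradation", category: soil, orientation: contrarian}
  - {id: "8", label: "degree of sand salinization", category: soil, orientation: contrarian}
  - {id: "9", label: "indicator 9 (unnamed)", category: soil, orientation: contrarian}
  - {id: "10", label: "degree of desertification rate", category: soil, orientation: contrarian}
amplitude: 2.2
aggregation_mode: weighted_complement
zero_variance_policy: error
report_decimals: 4
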