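{
  "description": "Disease-associated subsets of the 15 shared AD/PD miRNAs (upregulation analysis), as printed.",
  "AD": ["hsa-miR-181a", "hsa-miR-29a", "hsa-miR-29b", "hsa-miR-29c", "hsa-miR-146a", "hsa-miR-148b"],
  "PD": ["hsa-miR-181a", "hsa-miR-16", "hsa-miR-29a", "hsa-miR-29b", "hsa-miR-29c"]
}
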