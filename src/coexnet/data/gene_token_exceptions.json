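{
  "description": "Hyphen handling exceptions for GWAS locus tokenization. A hyphen-minus normally separates two fused gene symbols; it is kept when the left part is a protected family prefix, when the right part matches a protected suffix pattern (antisense transcripts), or when the full token is a listed official hyphenated symbol.",
  "protected_prefixes": ["HLA"],
  "protected_suffix_patterns": ["AS\\d+", "B\\d+"],
  "hyphenated_symbols": []
}
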