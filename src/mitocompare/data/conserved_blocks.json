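{
  "comment": "Approximate vertebrate control-region consensus motifs (IUPAC). ETAS1 core GYRCAT and the CSB-1 3'-terminal GGACATA are the classical diagnostic cores; the central-domain blocks (CSB-F..B) and CSB-2/3 are loose mammalian-style consensuses and are expected to be edited per taxon. max_mismatch is the default per-block allowance.",
  "blocks": [
    {"name": "ETAS1", "consensus": "GYRCAT", "max_mismatch": 0},
    {"name": "CSB-F", "consensus": "ATGYAYTTYRTACATTA", "max_mismatch": 4},
    {"name": "CSB-E", "consensus": "AGGGGGTGRYTAYGG", "max_mismatch": 4},
    {"name": "CSB-D", "consensus": "TATTYAGTCAATGGTYT", "max_mismatch": 4},
    {"name": "CSB-C", "consensus": "TGCYYRGCATYYGGTAT", "max_mismatch": 4},
    {"name": "CSB-B", "consensus": "AAACCYCYYYACCAAAA", "max_mismatch": 4},
    {"name": "CSB-1", "consensus": "TTAATGCTTGWWGGACATA", "max_mismatch": 4},
    {"name": "CSB-2", "consensus": "CAAACCCCCCYTCCCCC", "max_mismatch": 3},
    {"name": "CSB-3", "consensus": "TGCCAAACCCCAAAAMCAA", "max_mismatch": 4}
  ]
}
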