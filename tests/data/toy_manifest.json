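{
  "comment": "hand-counted expectations for toy_clonotypes.tsv (min_reads=3)",
  "n_input_rows": 8,
  "n_surviving_records": 4,
  "surviving": [
    {"read_count": 12, "cdr3_aa": "CASSF", "trav_primary": "TRAV6-7"},
    {"read_count": 5, "cdr3_aa": "CAVSNCNTGKLIF", "trav_primary": "TRAV1"},
    {"read_count": 3, "cdr3_aa": "CALSGGSNYKLTF", "trav_primary": "TRAV3"},
    {"read_count": 3, "cdr3_aa": "CASSF", "trav_primary": "TRAV6-7"}
  ],
  "excluded": [
    {"cdr3_aa": "CALSGGGNYKLTF", "reason": "read_count 2 < 3"},
    {"cdr3_aa": "CAV*NLNTGKLIF", "reason": "stop-codon sentinel"},
    {"cdr3_aa": "CAVRF", "reason": "read_count 1 < 3"},
    {"cdr3_aa": "CAVS_LNTGKLIF", "reason": "frameshift sentinel"}
  ],
  "clonotypes_first_listed": [
    ["TRAV1", "CAVSNCNTGKLIF"],
    ["TRAV3", "CALSGGSNYKLTF"],
    ["TRAV6-7", "CASSF"]
  ]
}
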