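{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "genenets analysis report",
  "type": "object",
  "required": ["config", "networks"],
  "properties": {
    "config": {
      "type": "object",
      "required": ["seed"],
      "properties": {
        "seed": {"type": "integer"},
        "max_depth": {"type": "integer"},
        "min_list_genes": {"type": "integer"},
        "n_simulations": {"type": "integer"},
        "universe_size": {"type": ["integer", "null"]}
      }
    },
    "networks": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["rank", "members", "linkers", "edges", "stats"],
        "properties": {
          "rank": {"type": "integer"},
          "members": {"type": "array", "items": {"type": "string"}},
          "linkers": {"type": "array", "items": {"type": "string"}},
          "start_gene": {"type": ["string", "null"]},
          "depth": {"type": ["integer", "null"]},
          "edges": {"type": "array"},
          "stats": {
            "type": "object",
            "required": [
              "score",
              "score_pvalue",
              "n_simulations_used",
              "induced_neighbourhood_size",
              "list_overlap",
              "list_pvalue",
              "list_pvalue_bh"
            ],
            "properties": {
              "score": {"type": "number"},
              "score_pvalue": {"type": ["number", "null"]},
              "n_simulations_used": {"type": "integer"},
              "induced_neighbourhood_size": {"type": "integer"},
              "list_overlap": {"type": "integer"},
              "list_pvalue": {"type": "number"},
              "list_pvalue_bh": {"type": "number"}
            }
          }
        }
      }
    }
  }
}
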