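{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "metastab report",
  "oneOf": [
    {
      "properties": {
        "kind": {"const": "stability_report", "type": "string"},
        "seed": {"type": "integer"},
        "labels": {"type": "object"},
        "comparisons": {"type": "array"}
      },
      "required": ["kind", "seed", "labels", "comparisons"]
    },
    {
      "properties": {
        "kind": {"const": "conservation_report", "type": "string"},
        "query_id": {"type": "string"},
        "positions": {"type": "object"},
        "residue_set": {"type": "string"}
      },
      "required": ["kind", "query_id", "positions"]
    }
  ]
}
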