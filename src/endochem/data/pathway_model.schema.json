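{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/endochem/pathway_model.schema.json",
  "title": "Alkaloid pathway dependency model",
  "description": "A named DAG of metabolites. Each step produces one metabolite and is gated by an all-of set of gene markers plus an optional pathway precursor. This schema documents the on-disk YAML/JSON layout; endochem.models performs the equivalent structural validation in code.",
  "type": "object",
  "required": ["name", "steps"],
  "additionalProperties": false,
  "properties": {
    "name": {"enum": ["PPZ", "EAS", "IDT", "LOL"]},
    "steps": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["product", "required_genes"],
        "additionalProperties": false,
        "properties": {
          "product": {"type": "string", "minLength": 1},
          "precursor": {"type": ["string", "null"]},
          "required_genes": {
            "type": "array",
            "items": {"type": "string", "minLength": 1},
            "uniqueItems": true
          },
          "notes": {"type": "string"}
        }
      }
    },
    "terminal_products": {"type": "array", "items": {"type": "string"}},
    "toxic_products": {"type": "array", "items": {"type": "string"}}
  }
}
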