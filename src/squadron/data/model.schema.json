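{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "squadron network model",
  "type": "object",
  "required": [
    "nodes",
    "edges"
  ],
  "properties": {
    "nodes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "name"
        ],
        "properties": {
          "name": {
            "type": "string",
            "minLength": 1
          },
          "category": {
            "enum": [
              "receptor_total",
              "receptor_active",
              "signaling",
              "phenotype",
              "drug",
              "mutation",
              "auxiliary"
            ]
          },
          "gain": {
            "type": "number",
            "exclusiveMinimum": 0
          },
          "decay": {
            "type": "number",
            "exclusiveMinimum": 0
          }
        },
        "additionalProperties": false
      }
    },
    "edges": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "source",
          "target"
        ],
        "properties": {
          "source": {
            "type": "string"
          },
          "target": {
            "type": "string"
          },
          "sign": {
            "enum": [
              "activation",
              "inhibition"
            ]
          },
          "weight": {
            "type": "number",
            "exclusiveMinimum": 0
          }
        },
        "additionalProperties": false
      }
    },
    "metadata": {
      "type": "object"
    }
  },
  "additionalProperties": false
}
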