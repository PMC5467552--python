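{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Codon usage table",
  "type": "object",
  "required": [
    "total_codons",
    "counts",
    "frequencies",
    "per_aa_usage"
  ],
  "properties": {
    "total_codons": {
      "type": "integer",
      "minimum": 0
    },
    "counts": {
      "type": "object",
      "patternProperties": {
        "^[ACGT]{3}$": {
          "type": "integer",
          "minimum": 0
        }
      },
      "additionalProperties": false
    },
    "frequencies": {
      "type": "object",
      "patternProperties": {
        "^[ACGT]{3}$": {
          "type": "number",
          "minimum": 0,
          "maximum": 1
        }
      },
      "additionalProperties": false
    },
    "per_aa_usage": {
      "type": "object",
      "patternProperties": {
        "^[ACGT]{3}$": {
          "type": "number",
          "minimum": 0,
          "maximum": 1
        }
      },
      "additionalProperties": false
    }
  }
}
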