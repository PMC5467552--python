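{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Assembly summary statistics",
  "type": "object",
  "required": [
    "scaffold_count",
    "total_span",
    "longest",
    "N50",
    "N90",
    "GC_fraction",
    "N_fraction",
    "lengths"
  ],
  "properties": {
    "scaffold_count": {
      "type": "integer",
      "minimum": 1
    },
    "total_span": {
      "type": "integer",
      "minimum": 1
    },
    "longest": {
      "type": "integer",
      "minimum": 1
    },
    "N50": {
      "type": "integer",
      "minimum": 1
    },
    "N90": {
      "type": "integer",
      "minimum": 1
    },
    "GC_fraction": {
      "type": "number",
      "minimum": 0,
      "maximum": 1
    },
    "N_fraction": {
      "type": "number",
      "minimum": 0,
      "maximum": 1
    },
    "lengths": {
      "type": "array",
      "items": {
        "type": "integer",
        "minimum": 0
      }
    }
  }
}
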