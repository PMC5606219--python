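{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "genecontext session",
  "description": "Self-contained analysis snapshot written by genecontext.session_io.save_session. Canonical form: sorted keys, compact separators, shortest round-tripping floats, trailing newline.",
  "type": "object",
  "required": ["format_version", "genome_label", "settings", "panels", "filter_chain", "file_manifest"],
  "properties": {
    "format_version": {"type": "string", "description": "semver; readers accept matching major version only"},
    "genome_label": {"type": "string"},
    "settings": {
      "type": "object",
      "required": ["flank_up", "flank_down", "min_peak_score", "min_peak_size", "max_peak_size", "expr_scale_lo", "expr_scale_hi"],
      "properties": {
        "flank_up": {"type": "integer", "minimum": 0},
        "flank_down": {"type": "integer", "minimum": 0},
        "min_peak_score": {"type": "number"},
        "min_peak_size": {"type": "integer", "minimum": 0},
        "max_peak_size": {"type": ["number", "null"], "description": "null = no upper size cutoff"},
        "expr_scale_lo": {"type": ["number", "null"]},
        "expr_scale_hi": {"type": ["number", "null"], "description": "null bounds are recomputed from the 5th-95th percentile of loaded expression"}
      }
    },
    "panels": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["gene", "flank_up", "flank_down", "tracks", "expression", "neighbors", "exons_rel", "show"],
        "properties": {
          "gene": {
            "type": "object",
            "required": ["gene_id", "aliases", "chrom", "strand", "span_start", "span_end", "exons", "description"],
            "properties": {
              "gene_id": {"type": "string"},
              "aliases": {"type": "array", "items": {"type": "string"}},
              "chrom": {"type": "string"},
              "strand": {"enum": ["+", "-"]},
              "span_start": {"type": "integer", "minimum": 0},
              "span_end": {"type": "integer"},
              "exons": {"type": "array", "items": {"type": "array", "items": {"type": "integer"}, "minItems": 2, "maxItems": 2}},
              "description": {"type": "string"}
            }
          },
          "flank_up": {"type": "integer", "minimum": 0},
          "flank_down": {"type": "integer", "minimum": 0},
          "tracks": {
            "type": "array",
            "description": "sorted by (cell_type, mark); intervals sorted by (rel_start, rel_end)",
            "items": {
              "type": "object",
              "required": ["cell_type", "mark", "intervals"],
              "properties": {
                "cell_type": {"type": "string"},
                "mark": {"type": "string"},
                "intervals": {"type": "array", "items": {"$ref": "#/definitions/interval"}}
              }
            }
          },
          "expression": {"type": "object", "additionalProperties": {"type": "number"}, "description": "cell type -> value; absent key = no data (never zero-filled)"},
          "neighbors": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["interval", "orientation"],
              "properties": {
                "interval": {"$ref": "#/definitions/interval"},
                "orientation": {"enum": ["same", "opposite"]}
              }
            }
          },
          "exons_rel": {"type": "array", "items": {"$ref": "#/definitions/interval"}},
          "show": {"type": "boolean"}
        }
      }
    },
    "filter_chain": {
      "type": "object",
      "required": ["filters", "trace"],
      "properties": {
        "filters": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["type"],
            "properties": {
              "type": {"enum": ["name", "gene_size", "chrom", "expression", "feature_count", "feature_overlap"]}
            }
          }
        },
        "trace": {"type": "array", "items": {"type": "integer", "minimum": 0}}
      }
    },
    "file_manifest": {
      "type": "array",
      "description": "provenance only; a session never needs these files",
      "items": {"type": "object"}
    }
  },
  "definitions": {
    "interval": {
      "type": "object",
      "required": ["rel_start", "rel_end", "score", "name"],
      "properties": {
        "rel_start": {"type": "integer", "description": "bp relative to TSS, half-open; negative = upstream after orientation correction"},
        "rel_end": {"type": "integer"},
        "score": {"type": "number"},
        "name": {"type": "string"}
      }
    }
  }
}
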