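{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "umsched knowledge-base bundle",
  "type": "object",
  "required": ["products", "ingredients", "mtcod", "mtcmd", "ddi"],
  "properties": {
    "products": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["product_id", "name", "otc", "category", "origin", "ingredient_ids"],
        "properties": {
          "product_id": {"type": "string"},
          "name": {"type": "string"},
          "otc": {"type": ["boolean", "string"]},
          "category": {"enum": ["western", "chinese_patent"]},
          "origin": {"enum": ["domestic", "imported"]},
          "ingredient_ids": {"type": "string", "description": "semicolon-separated ingredient ids"}
        }
      }
    },
    "ingredients": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["ingredient_id", "name", "ingredient_class"],
        "properties": {
          "ingredient_id": {"type": "string"},
          "name": {"type": "string"},
          "ingredient_class": {"enum": ["chemical", "tcm_extract", "natural_product"]}
        }
      }
    },
    "mtcod": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["product_id", "doses_per_day", "min_isd", "max_isd"],
        "properties": {
          "product_id": {"type": "string"},
          "doses_per_day": {"type": "integer", "minimum": 1},
          "min_isd": {"type": "number", "exclusiveMinimum": 0, "maximum": 24},
          "max_isd": {"type": "number", "maximum": 24},
          "meal_constraint": {"type": "string", "description": "symbolic constraint DSL, empty for none"},
          "chrono_windows": {"type": "string", "description": "start~end;start~end in hours"},
          "prn": {"type": ["boolean", "string"]}
        }
      }
    },
    "mtcmd": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["first_product_id", "second_product_id", "min_itd", "max_itd"],
        "properties": {
          "first_product_id": {"type": "string"},
          "second_product_id": {"type": "string"},
          "min_itd": {"type": "number", "minimum": 0, "maximum": 24},
          "max_itd": {"type": "number", "minimum": 0, "maximum": 24}
        }
      }
    },
    "ddi": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["ingredient_a", "ingredient_b", "severity"],
        "properties": {
          "ingredient_a": {"type": "string"},
          "ingredient_b": {"type": "string"},
          "severity": {"enum": ["major", "moderate", "minor", "unknown"]},
          "mechanism_note": {"type": "string"},
          "source": {"enum": ["A", "B"]}
        }
      }
    }
  }
}
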