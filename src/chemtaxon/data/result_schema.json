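{
  "$defs": {
    "CategoryRef": {
      "properties": {
        "id": {
          "title": "Id",
          "type": "string"
        },
        "name": {
          "title": "Name",
          "type": "string"
        }
      },
      "required": [
        "id",
        "name"
      ],
      "title": "CategoryRef",
      "type": "object"
    },
    "ExternalDescriptor": {
      "properties": {
        "category_id": {
          "title": "Category Id",
          "type": "string"
        },
        "foreign_id": {
          "title": "Foreign Id",
          "type": "string"
        },
        "source": {
          "title": "Source",
          "type": "string"
        }
      },
      "required": [
        "source",
        "foreign_id",
        "category_id"
      ],
      "title": "ExternalDescriptor",
      "type": "object"
    }
  },
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "description": "One classification result as serialized to JSON.",
  "properties": {
    "alternative_parents": {
      "default": [],
      "items": {
        "$ref": "#/$defs/CategoryRef"
      },
      "title": "Alternative Parents",
      "type": "array"
    },
    "class": {
      "anyOf": [
        {
          "$ref": "#/$defs/CategoryRef"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "description": {
      "default": "",
      "title": "Description",
      "type": "string"
    },
    "direct_parent": {
      "$ref": "#/$defs/CategoryRef"
    },
    "external_descriptors": {
      "default": [],
      "items": {
        "$ref": "#/$defs/ExternalDescriptor"
      },
      "title": "External Descriptors",
      "type": "array"
    },
    "input": {
      "title": "Input",
      "type": "string"
    },
    "intermediate_nodes": {
      "default": [],
      "items": {
        "$ref": "#/$defs/CategoryRef"
      },
      "title": "Intermediate Nodes",
      "type": "array"
    },
    "is_mixture": {
      "default": false,
      "title": "Is Mixture",
      "type": "boolean"
    },
    "kingdom": {
      "$ref": "#/$defs/CategoryRef"
    },
    "molecular_framework": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Molecular Framework"
    },
    "record_id": {
      "default": "",
      "title": "Record Id",
      "type": "string"
    },
    "shallow_classification": {
      "default": false,
      "title": "Shallow Classification",
      "type": "boolean"
    },
    "smiles": {
      "title": "Smiles",
      "type": "string"
    },
    "subclass": {
      "anyOf": [
        {
          "$ref": "#/$defs/CategoryRef"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "substituents": {
      "default": [],
      "items": {
        "type": "string"
      },
      "title": "Substituents",
      "type": "array"
    },
    "superclass": {
      "anyOf": [
        {
          "$ref": "#/$defs/CategoryRef"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    }
  },
  "required": [
    "input",
    "smiles",
    "kingdom",
    "direct_parent"
  ],
  "title": "chemtaxon classification result",
  "type": "object"
}
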