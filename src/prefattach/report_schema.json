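{
  "description": "A replayable record of one CLI run.",
  "properties": {
    "command": {
      "description": "CLI subcommand that produced the report",
      "title": "Command",
      "type": "string"
    },
    "version": {
      "description": "prefattach package version",
      "title": "Version",
      "type": "string"
    },
    "seed": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "description": "master RNG seed of the run",
      "title": "Seed"
    },
    "config": {
      "additionalProperties": true,
      "description": "fully resolved options",
      "title": "Config",
      "type": "object"
    },
    "result": {
      "additionalProperties": true,
      "description": "command-specific outputs",
      "title": "Result",
      "type": "object"
    }
  },
  "required": [
    "command",
    "version",
    "seed",
    "config",
    "result"
  ],
  "title": "RunReport",
  "type": "object"
}
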