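{
 "type": "object",
 "required": ["config_hash", "seed", "participants", "classification", "group_stats"],
 "properties": {
  "config_hash": {"type": "string"},
  "seed": {"type": "integer"},
  "participants": {
   "type": "array",
   "items": {"type": "object", "required": ["id", "group", "sessions"]}
  },
  "classification": {"type": "array"},
  "group_stats": {"type": "object"}
 }
}
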