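[
  {"name": "AQ", "kind": "numeric"},
  {"name": "WS", "kind": "numeric"},
  {"name": "HM", "kind": "numeric"},
  {"name": "WM", "kind": "numeric"}
]
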