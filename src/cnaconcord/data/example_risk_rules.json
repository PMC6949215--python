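{
  "description": "Illustrative CNA-profile rule set for demonstrations and synthetic cohorts. This is NOT the published UKALL-CNA rule content, which is defined elsewhere and should be transcribed into this format before clinical-style use.",
  "rules": [
    {"if": {"IKZF1": "loss_deletion", "CDKN2A": "loss_deletion"}, "then": "PR"},
    {"if": {"IKZF1": "abnormal"}, "then": "IR"},
    {"if": {"EBF1": "loss_deletion"}, "then": "IR"},
    {"if": {"RB1": "abnormal"}, "then": "IR"},
    {"if": {"PAR1": "abnormal"}, "then": "IR"},
    {"if": {"CDKN2A": "abnormal"}, "then": "IR"},
    {"if": {"CDKN2B": "abnormal"}, "then": "IR"},
    {"if": {"PAX5": "abnormal"}, "then": "IR"},
    {"if": {"ETV6": "loss_deletion"}, "then": "GR"},
    {"if": {"BTG1": "abnormal"}, "then": "IR"}
  ],
  "default": "GR"
}
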