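# Default rule set: the drug-disease interaction "PPI use with
# osteoporosis/osteopenia" as a relative contraindication. Any mention
# subsumed under the trigger concept fires the rule; the condition holds
# when another eligible mention is subsumed under either bone condition.
rules:
  - id: ppi-osteoporosis-ddi
    description: >-
      Proton-pump inhibitor prescribed for a patient with osteoporosis or
      osteopenia (relative contraindication).
    trigger: E003230
    condition:
      any:
        - has_index: M0006E0
        - has_index: M002BF8
    action: emit_event
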