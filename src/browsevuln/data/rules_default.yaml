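# Default integration rules assigning species to vulnerability groups A-F.
#
# Evidence fields available to rules:
#   coverage : decline | no_decline | unknown
#   timing   : early | late | none      (browse-selection timing)
#   has_damage, has_dna : true | false  (evidence-stream presence)
#
# Rules are evaluated in order; the first whose conditions all hold fires.
# A condition lists the accepted values for one field. Species matching no
# rule are reported as unclassified, never dropped.
rules:
  - id: no-evidence
    when: {has_damage: [false], has_dna: [false]}
    group: unclassified
  - id: tolerant-dna
    when: {coverage: [no_decline], has_dna: [true]}
    group: E
  - id: tolerant-damage
    when: {coverage: [no_decline], has_damage: [true]}
    group: F
  - id: early-decline
    when: {coverage: [decline], timing: [early]}
    group: A
  - id: late-decline
    when: {coverage: [decline], timing: [late]}
    group: C
  - id: early-unknown
    when: {coverage: [unknown], timing: [early]}
    group: B
  - id: late-unknown
    when: {coverage: [unknown], timing: [late]}
    group: D
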