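# Problem 1 scoring rubric: RET-driven cancer pro-/anti-target panel.
# A starred target means binding/avoiding it is a requirement for
# target-based points (see star_mode in the scoring engine).
problem: "1"
thresholds:
  pro_bind_nM: 10000
  anti_avoid_nM: 30000
bind_criteria:
  - name: "Binds RET(M918T)"
    targets: [RET_M918T]
    starred: []
    schedule: {1: 5}
  - name: "Binds BRAF, SRC, S6K"
    targets: [BRAF, SRC, S6K]
    starred: []
    schedule: {1: 1, 2: 3, 3: 9}
avoid_criteria:
  - name: "Avoids MKNK1"
    targets: [MKNK1]
    starred: [MKNK1]
    schedule: {1: 3}
  - name: "Avoids TTK, ERK8, PDK1, PAK3"
    targets: [TTK, ERK8, PDK1, PAK3]
    starred: []
    schedule: {1: 1, 2: 2, 3: 3, 4: 4}
bonus:
  novelty: 2
  patent: 2
  druglike: 3
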