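# Problem 2 scoring rubric: Tauopathy pro-/anti-target panel.
# LKB1 is scored via its gene name STK11.
problem: "2"
thresholds:
  pro_bind_nM: 10000
  anti_avoid_nM: 30000
bind_criteria:
  - name: "Binds AURKA"
    targets: [AURKA]
    starred: [AURKA]
    schedule: {1: 5}
  - name: "Binds PAK1"
    targets: [PAK1]
    starred: [PAK1]
    schedule: {1: 5}
  - name: "Binds FGFR1, STK11"
    targets: [FGFR1, STK11]
    starred: []
    schedule: {1: 1, 2: 3}
avoid_criteria:
  - name: "Avoids PAK3"
    targets: [PAK3]
    starred: [PAK3]
    schedule: {1: 3}
  - name: "Avoids MAP3K7"
    targets: [MAP3K7]
    starred: [MAP3K7]
    schedule: {1: 3}
  - name: "Avoids PIK3CA"
    targets: [PIK3CA]
    starred: []
    schedule: {1: 1}
bonus:
  novelty: 2
  patent: 2
  druglike: 3
  cns: 3
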