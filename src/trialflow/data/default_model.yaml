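subprocesses:
- name: Initial Preparation
  activities:
  - name: OCR sends documents
    family: uniform
    params:
    - 0.5
    - 1.0
  - name: P&L reviews
    family: triangular
    params:
    - 1.0
    - 8.0
    - 21.0
  - name: PI prepares documents
    family: triangular
    params:
    - 1.0
    - 2.0
    - 3.0
  - name: P&L reviews (2)
    family: uniform
    params:
    - 0.5
    - 1.0
  capacity: 8
- name: Contract Negotiation
  duration:
    family: exponential
    params:
    - 28.5
  capacity: 12
- name: Budget Negotiation
  duration:
    family: exponential
    params:
    - 25.0
  capacity: 10
- name: PI Approval
  duration:
    family: lognormal
    params:
    - 5.0
    - 8.3
  capacity: 4
- name: DSR Approval
  duration:
    family: lognormal
    params:
    - 2.5
    - 2.8
  capacity: 3
- name: Sponsor Approval
  duration:
    family: lognormal
    params:
    - 6.5
    - 15.9
  capacity: 6
routing:
  Initial Preparation:
  - Contract Negotiation
  - Budget Negotiation
  Contract Negotiation:
  - PI Approval
  Budget Negotiation:
  - PI Approval
  PI Approval:
  - DSR Approval
  DSR Approval:
  - Sponsor Approval
  Sponsor Approval: []
semantics:
  Initial Preparation: and_split
  PI Approval: and_join
  Contract Negotiation: sequence
  Budget Negotiation: sequence
  DSR Approval: sequence
  Sponsor Approval: sequence
arrival:
  base_rate: 0.40273972602739727
  scale_factor: 1.0
source: Initial Preparation
sink: Sponsor Approval
branch_probability: {}
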