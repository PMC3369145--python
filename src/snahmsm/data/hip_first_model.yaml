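# Shipped 10-state model for hip-first arthroplasty cohorts.
# States 2-9 are transient; state 10 (dead) is absorbing.
states:
  - {id: 1, label: "1st arthroplasty hip"}
  - {id: 2, label: "Revision of 1st arthroplasty"}
  - {id: 3, label: "2nd arthroplasty hip"}
  - {id: 4, label: "2nd arthroplasty knee"}
  - {id: 5, label: "2nd arthroplasty hip / revision of 1st hip"}
  - {id: 6, label: "2nd arthroplasty knee / revision of 1st hip"}
  - {id: 7, label: "Revision of 2nd arthroplasty hip"}
  - {id: 8, label: "Revision of 2nd arthroplasty knee"}
  - {id: 9, label: "Revision of 1st or 2nd arthroplasty"}
  - {id: 10, label: "Dead"}
transitions:
  - [1, 2]
  - [1, 3]
  - [1, 4]
  - [1, 10]
  - [2, 5]
  - [2, 6]
  - [2, 10]
  - [3, 5]
  - [3, 7]
  - [3, 10]
  - [4, 6]
  - [4, 8]
  - [4, 10]
  - [5, 9]
  - [5, 10]
  - [6, 9]
  - [6, 10]
  - [7, 9]
  - [7, 10]
  - [8, 9]
  - [8, 10]
  - [9, 10]
absorbing: [10]
initial_state: 1
eligibility: first arthroplasty is a primary total hip
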