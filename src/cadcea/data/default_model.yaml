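# Default model configuration: three starting arms (OMT, stent PCI, CABG)
# over a shared nine-state structure with post-procedure maintenance and
# stable states, one absorbing death state, and mean/SD-parameterised cost
# and utility distributions (currency: SGD; costs per 6-month cycle unless
# one-time).
#
# The transition probabilities below are the shipped synthetic ground truth:
# the entries into the stable states come from published 5-year event-free
# fractions (64/70 after bypass, 43/72 after angioplasty) rescaled to the
# 6-month cycle by cumulative incidence; the remaining entries are plausible
# values chosen for the synthetic cohort, not estimates from any repository.

parameters:
  cost_omt:            {kind: gamma, mean: 129.86, sd: 36.06}
  cost_omt_post_stent: {kind: gamma, mean: 147.68, sd: 14.29}
  cost_omt_post_cabg:  {kind: gamma, mean: 96.65, sd: 30.03}
  cost_pci:            {kind: gamma, mean: 26261.18, sd: 4908.53}
  cost_cabg:           {kind: gamma, mean: 35756.64, sd: 4419.17}
  util_omt:            {kind: beta, mean: 0.69, sd: 0.12}
  util_pci:            {kind: beta, mean: 0.72, sd: 0.22}
  util_repci:          {kind: beta, mean: 0.70, sd: 0.16}
  util_stable_pci:     {kind: beta, mean: 0.87, sd: 0.03}
  util_cabg:           {kind: beta, mean: 0.82, sd: 0.03}
  util_stable_cabg:    {kind: beta, mean: 0.84, sd: 0.04}

states:
  - {name: OMT,        per_cycle_cost: cost_omt,            utility: util_omt}
  - {name: PCI,        per_cycle_cost: cost_omt_post_stent, entry_cost: cost_pci,  utility: util_pci}
  - {name: RePCI,      per_cycle_cost: cost_omt_post_stent, entry_cost: cost_pci,  utility: util_repci}
  - {name: PostPCI,    per_cycle_cost: cost_omt_post_stent, utility: util_pci}
  - {name: StablePCI,  per_cycle_cost: cost_omt_post_stent, utility: util_stable_pci}
  - {name: CABG,       per_cycle_cost: cost_omt_post_cabg,  entry_cost: cost_cabg, utility: util_cabg}
  - {name: PostCABG,   per_cycle_cost: cost_omt_post_cabg,  utility: util_cabg}
  - {name: StableCABG, per_cycle_cost: cost_omt_post_cabg,  utility: util_stable_cabg}
  - {name: Dead,       absorbing: true}

transitions:
  allowed:
    OMT:        [OMT, PCI, CABG, Dead]
    PCI:        [PostPCI, RePCI, StablePCI, CABG, Dead]
    RePCI:      [PostPCI, StablePCI, CABG, Dead]
    PostPCI:    [PostPCI, RePCI, StablePCI, CABG, Dead]
    StablePCI:  [StablePCI, Dead]
    CABG:       [PostCABG, StableCABG, RePCI, Dead]
    PostCABG:   [PostCABG, StableCABG, RePCI, Dead]
    StableCABG: [StableCABG, Dead]
    Dead:       [Dead]
  probabilities:
    OMT:        {OMT: 0.92, PCI: 0.04, CABG: 0.01, Dead: 0.03}
    PCI:        {PostPCI: 0.7931, RePCI: 0.06, StablePCI: 0.0869, CABG: 0.02, Dead: 0.04}
    RePCI:      {PostPCI: 0.80, StablePCI: 0.0869, CABG: 0.06, Dead: 0.0531}
    PostPCI:    {PostPCI: 0.85, RePCI: 0.05, StablePCI: 0.05, CABG: 0.02, Dead: 0.03}
    StablePCI:  {StablePCI: 0.985, Dead: 0.015}
    CABG:       {PostCABG: 0.6922, StableCABG: 0.2178, RePCI: 0.03, Dead: 0.06}
    PostCABG:   {PostCABG: 0.83, StableCABG: 0.12, RePCI: 0.02, Dead: 0.03}
    StableCABG: {StableCABG: 0.99, Dead: 0.01}

arms:
  OMT:  {start_state: OMT}
  PCI:  {start_state: PCI}
  CABG: {start_state: CABG}

# the five shipped policies: starting-arm mixes
strategies:
  current_practice: {OMT: 0.819, PCI: 0.135, CABG: 0.046}
  all_cabg:         {CABG: 1.0}
  all_omt:          {OMT: 1.0}
  all_pci:          {PCI: 1.0}
  recommended:      {OMT: 0.86, CABG: 0.14}

# settings for the synthetic-records generator (ground truth = the
# transition probabilities above plus these cohort/cost settings)
synthetic:
  n_patients: 10000
  n_cycles: 20
  start_distribution: {OMT: 0.819, PCI: 0.135, CABG: 0.046}
  administrative_censoring: false
  medication_groups:
    no-intervention: cost_omt
    post-stent: cost_omt_post_stent
    post-bypass: cost_omt_post_cabg
  procedure_cost_states:
    PCI: cost_pci
    RePCI: cost_pci
    CABG: cost_cabg
  stent_states: [PCI, RePCI, PostPCI, StablePCI]
  bypass_states: [CABG, PostCABG, StableCABG]

engine:
  cycle_length: 0.5
  n_cycles: 20
  cohort_size: 10000
  annual_discount_rate: 0.03
  half_cycle_correction: true
  mortality_increment: 0.01
  mortality_block: 10
  wtp_threshold: 80000
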