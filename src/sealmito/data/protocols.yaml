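# Default SUIT (substrate-uncoupler-inhibitor titration) protocol table.
#
# Four protocols (A, B, CI, CII) drive permeabilized muscle fibers through
# defined respiratory states.  Each step adds a set of agents and either
# establishes a named steady state or is a transitional titration ("none").
# Every protocol opens with a no-agent baseline step and contains an OXPHOS
# step and a cytochrome-c membrane-integrity check.
#
# States: Ln (leak, complex-I substrates, no adenylates), OXPHOS (coupled
# capacity, CI+CII substrates + ADP), LOmy (leak under oligomycin), ETS
# (uncoupled capacity after CCCP), CI / CII (uncoupled flux through a single
# complex after inhibiting the other).
agents:
  OC:   {name: octanoylcarnitine, target_conc: 0.5, unit: mM}
  P:    {name: pyruvate,          target_conc: 10,  unit: mM}
  M:    {name: malate,            target_conc: 0.5, unit: mM}
  G:    {name: glutamate,         target_conc: 10,  unit: mM}
  S:    {name: succinate,         target_conc: 10,  unit: mM}
  ADP:  {name: ADP,               target_conc: 5,   unit: mM}
  CytC: {name: cytochrome c,      target_conc: 10,  unit: uM}
  OM:   {name: oligomycin,        target_conc: 5,   unit: uM}
  CCCP: {name: CCCP,              target_conc: 0.5, unit: uM}
  Rot:  {name: rotenone,          target_conc: 1,   unit: uM}
  Mal:  {name: malonate,          target_conc: 10,  unit: mM}
protocols:
  A:
    steps:
      - {agents: [],           state: baseline}
      - {agents: [OC, M, P],   state: Ln}
      - {agents: [ADP],        state: none}
      - {agents: [G, S],       state: OXPHOS}
      - {agents: [CytC],       state: cytc_check}
      - {agents: [CCCP],       state: ETS}
  B:
    steps:
      - {agents: [],            state: baseline}
      - {agents: [OC, M, P, G], state: Ln}
      - {agents: [ADP, S],      state: OXPHOS}
      - {agents: [CytC],        state: cytc_check}
      - {agents: [OM],          state: LOmy}
      - {agents: [CCCP],        state: ETS}
  CI:
    steps:
      - {agents: [],          state: baseline}
      - {agents: [M, P, G],   state: none}
      - {agents: [ADP, S],    state: OXPHOS}
      - {agents: [CytC],      state: cytc_check}
      - {agents: [CCCP],      state: ETS}
      - {agents: [Mal],       state: CI}
  CII:
    steps:
      - {agents: [],          state: baseline}
      - {agents: [M, P, G],   state: none}
      - {agents: [ADP, S],    state: OXPHOS}
      - {agents: [CytC],      state: cytc_check}
      - {agents: [CCCP],      state: ETS}
      - {agents: [Rot],       state: CII}
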