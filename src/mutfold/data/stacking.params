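# Nearest-neighbour stacking energy model (kcal/mol, 37 C).
# Stack terms follow the style of the Turner 2004 nearest-neighbour
# free-energy set (Watson-Crick steps from the published table; steps
# involving GU wobble pairs are approximate). Key STACK_XY_WZ is the
# step with outer pair X.Y at (i,j) and inner pair W.Z at (i+1,j-1);
# the table is symmetric under strand reversal: STACK_XY_WZ = STACK_ZW_YX.
# Per-pair baselines destabilise AU/GU closings (terminal-AU-penalty style);
# dangling ends and coaxial stacking are not modelled.
model = stacking
RT = 0.6163
PAIR_AU = 0.45
PAIR_UA = 0.45
PAIR_CG = 0.0
PAIR_GC = 0.0
PAIR_GU = 0.45
PAIR_UG = 0.45
STACK_AU_AU = -0.93
STACK_AU_UA = -1.1
STACK_AU_CG = -2.24
STACK_AU_GC = -2.08
STACK_AU_GU = -0.55
STACK_AU_UG = -1.36
STACK_UA_AU = -1.33
STACK_UA_UA = -0.93
STACK_UA_CG = -2.35
STACK_UA_GC = -2.11
STACK_UA_GU = -1.27
STACK_UA_UG = -1.0
STACK_CG_AU = -2.11
STACK_CG_UA = -2.08
STACK_CG_CG = -3.26
STACK_CG_GC = -2.36
STACK_CG_GU = -1.41
STACK_CG_UG = -2.11
STACK_GC_AU = -2.35
STACK_GC_UA = -2.24
STACK_GC_CG = -3.42
STACK_GC_GC = -3.26
STACK_GC_GU = -1.53
STACK_GC_UG = -2.51
STACK_GU_AU = -1.0
STACK_GU_UA = -1.36
STACK_GU_CG = -2.51
STACK_GU_GC = -2.11
STACK_GU_GU = -0.25
STACK_GU_UG = -0.5
STACK_UG_AU = -1.27
STACK_UG_UA = -0.55
STACK_UG_CG = -1.53
STACK_UG_GC = -1.41
STACK_UG_GU = 0.47
STACK_UG_UG = -0.25
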