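# Toy pair-type energy model: a flat per-pair energy by pair type,
# no stacking. RT = 1.0 so Boltzmann weights have closed forms
# (e.g. a lone GC pair weighs e^3 against the open chain).
model = toy-pairtype
RT = 1.0
PAIR_AU = -2.0
PAIR_UA = -2.0
PAIR_CG = -3.0
PAIR_GC = -3.0
PAIR_GU = -1.0
PAIR_UG = -1.0
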