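# In-silico minimal salt medium with DEHP (di-(2-ethylhexyl) phthalate) as the
# sole carbon source. Keys are metabolite base ids (BiGG-style); values are
# maximum uptake rates in mmol gDW^-1 h^-1. The DEHP uptake bound is explicit
# and configurable rather than implied: edit it to match the scenario at hand.
# Inorganic components mirror an MSM salt base (phosphate, ammonium, sulfate,
# magnesium, trace metals) and are effectively non-limiting.
dehp: 10.0
o2: 1000.0
h2o: 1000.0
h: 1000.0
pi: 1000.0
nh4: 1000.0
so4: 1000.0
k: 1000.0
mg2: 1000.0
cl: 1000.0
ca2: 1000.0
mn2: 1000.0
fe2: 1000.0
mobd: 1000.0
na1: 1000.0
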