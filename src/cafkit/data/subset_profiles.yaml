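# Quartile-bin archetype profiles of the four CAF subsets.
# A range such as "Low-Hi" means the set of bins {Low, Med, Hi}.
CAF-S1: {cd29: Med, fap: Hi, fsp1: Low-Hi, sma: Hi, pdgfrb: Med-Hi}
CAF-S2: {cd29: Low, fap: Neg, fsp1: Neg-Low, sma: Neg, pdgfrb: Neg}
CAF-S3: {cd29: Med, fap: Neg, fsp1: Med-Hi, sma: Neg-Low, pdgfrb: Med}
CAF-S4: {cd29: Hi, fap: Neg-Low, fsp1: Low-Med, sma: Hi, pdgfrb: Low-Med}
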