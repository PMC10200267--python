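device_id,manufacturer,price,rate_minor_stroke,rate_major_stroke,rate_death
abbott,Abbott,530,2.35,0.16,0.07
cardinal,Cardinal Health,518,1.69,1.04,0.93
medtronic,Medtronic,408,0.89,3.12,1.78
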