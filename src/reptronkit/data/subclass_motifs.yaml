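# Subclass-level key-motif consensus patterns for TnpA_Y1 subclasses.
# Restricted regex syntax: literals, [..] alternatives, '.' wildcard.
# Several consensus strings are only partially legible in the source
# tabulation and are transcribed conservatively with wildcards.
"1.1": {huh: "DH[VI]H", w: "W[TS]", y: "Y[IV]E"}
"1.2": {huh: "DH[IV]H", w: "WQ", y: "YIK"}
"2.1": {huh: "NH[VYF]H", w: "W[EQ]", y: "Y[IV].[LH]NP"}
"2.2": {huh: "DHLH", w: "WE", y: "YIHYNP"}
"2.3": {huh: "NHYH", w: "WE", y: "YVDLNP"}
"2.4": {huh: "NH[IFV]H", w: "WQ", y: "YI.NNP"}
"2.5": {huh: "DH[LF]H", w: "WQ", y: "YI[VI]ANP"}
"2.6": {huh: "NH[LIV]H", w: "WQ", y: "YIH[QN]NP"}
"2.7": {huh: "[ND]HVH", w: "WQ", y: "YI[LR][NQ]NP"}
"2.8": {huh: "NHYH", w: "W[YH]", y: "YIHYNP"}
"3":   {huh: "NHVH", w: "W[TA]", y: "YV[VI].EQ"}
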