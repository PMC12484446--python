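# Thalamic nucleus -> territory lookup (editable).
# Territories follow the conventional grouping of the Morel parcellation
# into medial, lateral and posterior thalamus; nuclei not listed here are
# treated as "other".
medial: [MD, CM, CL, CeM, Pf]
lateral: [VA, VL, VM, VPL, VPM]
posterior: [PuA, PuM, PuL, PuI, LP, LGN, MGN]
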