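# Enzyme label -> KEGG orthology ids for the triterpene saponin
# biosynthesis backbone (MVA + MEP pathways and downstream steps).
# Editable; labels follow the common abbreviation scheme.
AACT: [K00626]
HMGS: [K01641]
HMGR: [K00021]
MK: [K00869]
PMK: [K00938]
MVD: [K01597]
IDI: [K01823]
DXS: [K01662]
DXR: [K00099]
MEP-CT: [K00991]
CDP-MEK: [K00919]
MECDPS: [K01770]
HMBPPS: [K03526]
HMBPPR: [K03527]
FPS: [K00787]
GPS: [K13789]
SS: [K00801]
SE: [K00511]
Beta-AS: [K15813]
DS: [K20666]
PPDS: [K20667]
PPTS: [K20668]
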