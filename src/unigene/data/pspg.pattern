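# PROSITE UDP-glycosyltransferase (PSPG) signature pattern, editable.
# Verify against the current PROSITE release before production use
# (entry PS00375); the pattern below is shipped as a convenience default.
[FVA]-[LIVMF]-[TS]-[HQ]-[SGAC]-G-x(2)-[STAG]-x(2)-[STAG]-[LIVMFA]-x-[LIVMSA]-x(4,6)-[LIVMFA]-[PQR]-[LIVMTA]-x(3)-[PA]-x(2,3)-[DES]-[QEHNR]
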