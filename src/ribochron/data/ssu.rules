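# Small-subunit (30S) assembly-map rule set: 15 universally conserved SSU
# proteins plus the bacterial-specific proteins S6, S16, S18 and S20 that
# other universal proteins depend on for binding.
#
# Transcription notes. Anchored on the classic Nomura 30S assembly map as
# refined by later kinetic studies, restricted to the proteins above with
# redundant weaker dependencies removed. S21 is terminal in assembly and
# absent outside Bacteria, so it is omitted from the map entirely.
# S6, S16, S18 and S20 are kept in the ordering model (universal proteins
# depend on them) but weighted zero in usage averaging, as they appear to
# have undergone non-orthologous gene displacement outside Bacteria.
# This rule set is deliberately less restrictive than the LSU one: it
# admits ~5.3e10 linear extensions, so chronologies are compiled from
# random samples rather than exhaustive enumeration.
@subunit SSU
@exclude S6 S16 S18 S20
S4:
S7:
S8:
S15:
S17:
S20:
S16: S4 S20
S12: S4 S17
S5: S8 S16
S6: S15
S18: S6 S15
S9: S7
S19: S7
S13: S7 S19
S10: S7 S9
S14: S19
S3: S5 S10
S2: S3
S11: S18
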