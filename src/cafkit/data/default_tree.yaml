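# Default CAF-subset decision tree (configuration, not code).
#
# Ordered rules, each comparing one marker's value against one of its
# named quantile thresholds (q1 | med | q3); the first rule whose
# comparison holds assigns its subset, otherwise evaluation falls
# through to `default`.
#
# This default is a profile-consistent derivation, chosen so that each
# subset's archetype marker-bin vector (CAF-S1: CD29^Med FAP^Hi
# FSP1^Low-Hi aSMA^Hi PDGFRb^Med-Hi, etc.) reaches its own leaf. It
# deliberately references only FAP, aSMA and CD29 so the same tree runs
# on tumor-level H-scores and on tile-level DAB optical densities
# (where only CD29/FAP/SMA/FSP1 are imaged). Replace this file to use a
# different transcription of the published tree.
provenance: profile-consistent-default
rules:
  - marker: fap
    threshold: q3
    op: ge
    subset: CAF-S1
  - marker: sma
    threshold: med
    op: ge
    subset: CAF-S4
  - marker: cd29
    threshold: med
    op: ge
    subset: CAF-S3
default: CAF-S2
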