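# Packaged P-type ATPase family definitions.
#
# Motifs are the published family-diagnostic patterns (X = single-residue
# wildcard, / = alternatives); the anchor DKTGT is shared by the whole
# superfamily.  Spacings are derived at load time from the reference
# alignments; the reference sets shipped here are SYNTHETIC stand-ins
# (see data/reference/) built to the family motifs and typical bait sizes.
# P4 members vary by one residue in inter-motif spacing, hence tolerance 1.
anchor: DKTGT
families:
  P1B:
    motif: CPC/SPC
    reference: reference/P1B_reference_synthetic.fasta
  P2A/B:
    motif: PEXL
    reference: reference/P2AB_reference_synthetic.fasta
  P3A:
    motif: PIA
    reference: reference/P3A_reference_synthetic.fasta
  P4:
    motif: PIS
    reference: reference/P4_reference_synthetic.fasta
    tolerance: 1
  P5:
    motif: PPXXP
    reference: reference/P5_reference_synthetic.fasta
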