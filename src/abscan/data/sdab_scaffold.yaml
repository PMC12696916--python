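# Example single-domain antibody (VHH-like) scaffold template.
# SYNTHETIC stand-in: a generic camelid framework composed for testing, NOT a
# published scaffold sequence.  Supply your own template via the same schema
# to use an exact scaffold.  The conserved framework cysteines sit at raw
# indices 23 and 97 (numbering_offset 0), and the CDR3 site spans the
# designed-loop region.
name: sdab_example
kind: sdab
sequence: QVQLVESGGGLVQPGGGSLRLSCAASGRTFSSYAMGWFRQAPGKEREFVAAISWSGGSTYYADSVKGRFTISRDNAKNTVYLQMNSLKPEDTAVYYCNAGSSRYGSSYEEEWGQGTQVTVSS
sites:
  CDR3: [100, 111]
numbered_residues:
  C23: 23
  C97: 97
numbering_offset: 0
n_terminal_region: [1, 8]
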