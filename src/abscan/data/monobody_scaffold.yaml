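# Monobody scaffold template on the tenth fibronectin type-III domain (10FN3)
# wild-type sequence (public domain knowledge); the BC and FG loop bounds are
# this package's fixture choice, marked synthetic in that sense.  Monobodies
# natively lack cysteines.
name: monobody_fn3
kind: monobody
sequence: VSDVPRDLEVVAATPTSLLISWDAPAVTVRYYRITYGETGGNSPVQEFTVPGSKSTATISGLKPGVDYTITVYAVTGRGDSPASSKPISINYRT
sites:
  BC: [23, 30]
  FG: [77, 85]
numbered_residues: {}
numbering_offset: 0
n_terminal_region: [1, 8]
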