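>IAPP mature human islet amyloid polypeptide (amylin), 37 aa, UniProt P10997 residues 34-70
KCNTATCATQRLANFLVHSSNNFGAILSSTNVGSNTY
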