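# Monoisotopic atomic masses (Da), CODATA/IUPAC. C = 12 exactly by definition.
symbol	mass
C	12.0
H	1.00782503207
N	14.0030740048
O	15.9949146196
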