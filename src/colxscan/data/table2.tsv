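# Biomolecule binding locations overlapping the favourable DOGDIC sites,
# as printed in the source table. Note: the table lists heparin (site D21)
# and Amyloid Precursor Protein (sites D19-D21) although the accompanying
# prose omits them for some sites; the fixture follows the table verbatim.
site	biomolecules
D4	Heat Shock Protein 47;Interleukin-2;α2β1 integrin
D11	Heat Shock Protein 47;Phosphophoryn;Keratan Sulfate PG
D18	Heat Shock Protein 47;α2β1 integrin;Matrix Metalloproteinase 1
D19	α2β1 integrin;Heat Shock Protein 47;Amyloid Precursor Protein;Interleukin-2;Dermatan Sulfate
D20	Dermatan Sulfate;Interleukin-2;Amyloid Precursor Protein
D21	Interleukin-2;heparin;Amyloid Precursor Protein
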