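>TRNA_LEU
TTATAAATTATTAAAAATTCAACATTTTTAATTGTTTAATCATTA
>P0
CAAAATATCTTATTTTATAATGAATAAGTAAGAAAAATACCATTGTTAAATTTGAAATAAGTGATTA
>P
CAAGATATCTCATTTTATAAAATACCATTGTTCGTTTTGAAATTAGTGATTA
>Q
TTATAAGAAATAATATAAATTCATTTTAACTAATATATTGTAATACTTTTAGACGGGTATTCTTATATCTTAATATTATGCTTAATAAAAAACTAAATAATTTAATATATAACTTTTAAAGGTCTTGTATTAAAAAAATATACTTTCATATATAAAATTGAAGATTTTATGAATCACTTGTAACAATATAAGCTGA
>COII
AAGGAAAAAAATCTTAATATAGAATTATTTAAAAGTTATAAAATTACAACACAATAAAAT
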