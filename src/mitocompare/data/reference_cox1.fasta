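>reference_cox1 synthetic basidiomycete-like cox1 CDS (generated stand-in, not a real gene)
ATGAAAAACTCGATAATTACCGTTAGATACTTTTTAATAGGACATTCTTCAGGTTTTTTTCCGTATGGTT
TAAAATCGTATATGTCATTTAAATACATTCATCTTTACCTTTTCCAATCTTGAGCTAGAAAAAACAATTT
AGCATTGTTTAAATATAATAATATACGGATTACTGAATATAATGGCTTCTATTCGTCTGAAAGACTACTC
TACTATATTCAAATATTTAATTATAGTTATTGAAAAATAATATTTGGTGCTTATGTATCATATAATGAAA
ATAATGATTTAATAATTAAAAATAGAATTTATCTATTCTTGAAAATTGAAGTGATTATCAATTTTAATAT
CAATAGAATTAGATTTGGTATTTTATTAAGCAATAATCAAAATTTATCAAAATTTCTATACGAAAAAGTT
TACACTATATTGTTTACCATATGTGATATAGGTTTTAGTATCAGTTATTTAACCTTTAAGTTGAAAAAAG
ATCTTTATCTAAACGGAACATACAAAATCATACTACTCATAATTATATTCAACATTTACCGTTTAGAAAA
TCCGTCACCCACGATTATTAGTATCCTTATCATTATTATATTAATAATAAGTTTACAAACTAGTTTGAAA
GAATGTTTTATTATCGTCTTTTTAAATTACCGTAGAGAATTTTTTCATAAGAGAGTTAACAATATCTTAC
ACTTAAAAAACTTATTTGTTATATTTAATATAAGTTCTTTTACGCATGTAGATAGAAAGTATTATTTTAA
AATAATAGGATACGCCCCAGCAATTAATCTAAAACATCAATCACTAATGGTTTTATATATAATTTGAATT
ATTTCAGATACTATAAATTCTTTTTTTAATGTTATGACATGTTTTATACTTTTTTCTGAATCACCAGGTA
TTTCACTTAAATTCGATATTCGTAAATTATATAACATCTTTGTCATATTATTGTTTTTAAGATTAAATCT
AAGACAATATATTATTAATATATACATAAATCATATGTTCGTTCATCACTTAAAGTGATTTTTGATATTA
TCAAATAGTAAGTTATTTTATATATTATGAAAGGTTAACTCGATGCGAATAAATTTTTATAAATTAATTA
GACTTATTAATAATTTAAGTGAATTGATATTTTGTCTGATAAAGGTCGTTATGTTTTATAAATTTATGTT
ACAAATTTATAATTGAGTATTTGCTACTAAAATTTTTAATTGATTTAATGTAAATCGAAAACAAAACAAT
ATCATAATTTTATGTAAGATACAGATTATACTAATCATTTATTCATTTCAATATTGCATTCATATTCTCC
CCCATTTTATTTCGATATTCCGGTTAACGGATATTATATCAGATATTATAAATATAACTATACAAATCTA
TAAATGTATACTTTCAGAGATGATATGCAATGGTATAAACGTACAATTTATAAAATGTAATTTAACTTAT
AAGCTACTCAAAATACAGAAGTTTTTTTTGCAATATATCAATAATCAAAAAATTGTAAAAGTCTCGAATA
AAATAACTATTTCGGATATAGTGATATATCTAAAATTACTATTCTGAAAATTTTTATATTAA
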