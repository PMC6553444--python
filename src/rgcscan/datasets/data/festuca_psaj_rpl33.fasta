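>Festuca_ovina_NC019649
AGG------------------------------------------------------------------------------AAAAAGAAATTC
>Festuca_ovina
AGGAAAAAGAAAGAA-----AAGATGGATTGGGTTGAACCTCAGAGTCATTAAAAATAGGGTA----AATTCTATTTTGGAAAAAAGAAATTC
>Festuca_altissima
AGGAAAAAGAAAGAA-----AAGATGGATTGGGTTGAACCTCAGAGTCATGAAAAATTTGGTA----AATTCTATTTTGGAAAAAAGAAATTC
>Festuca_arundinacea
AGGAAAAAGAAATAA-----AAGATGGATTGGGTTGAACCTCAGAGTCATGAAAAATTTGGTA----AATTATATTTTGGAAAAAAGAAATTC
>Festuca_pratensis
AGGAAAAAGAAATAA-----AAGATGGATTGGGTTGAACCTCAGAGTCATGAAAAATTTGGTA----AATTATATTTTGGAAAAAAGAAATTC
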