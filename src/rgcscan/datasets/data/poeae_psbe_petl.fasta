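>Amelichloa_brachychaeta
TAATCCAAAATAGAAATAAC---CTTTTTTTTTCTAATTCAATT----CTTTATTTATCTCTTATTCC-----AAAATTC
>Triplachne_nitens
TAATCCAAAATTCAATTGTTTA-TTTTTTTTTGCAAATTCAATTGTTTTGTTTATTTATCTCTTATTCC----AAAATTC
>Gastridium_ventricosum
TAATCCAAAATTCAATTGTTTA-TTTTTTTTTGCAAATTCAATTGTTTTGTTTATTTATCTCTTATTCC----AAAATTC
>Dichelachne_crinita
TAATCCAAAATAGAA---AGCATTTTTTTTTTTCAAATTCAATT-----GTTTATTTATCTCTTATTCC----AAAATTC
>Calamagrostis_breviligulata
TAATCCAAAATTCAATTGTTTATTTTTTTTTTTCAAATTCAATT-----GTTTATTTATCTCTTATTCC----AAAATTC
>Polypogon_fugax
TAA---------------------------------------------------------------TCC----AAAATTC
>Agrostis_gigantea
TAATCCAAAATTCAATT--------------------------------GTTTAGTTATCTCTTATTCC----AAAATTC
>Agrostis_stolonifera
TAATCCAAAATTCAATT--------------------------------GTTTATTTATCTCTTATTCC----AAAATTC
>Hierochloe_odorata
TAATCCAAAATAGAAAGCATT--TTTTTTTTTTCAAATTCAATT-----GTTTATTTATTTCTTATTCC----AAAATTC
>Torreyochloa_pallida
-------------------------------------------------GTTTATTTATCTCTTATTCC----AAAATTC
>Phalaris_arundinacea
TAATCCAAAATAGAAAGCA----TTTTTTTTTTCAAATGCAATT-----GTTTATTTATCTCTTATTCCAAAAAAAATTC
>Koeleria_nitidula
TAATCCAAAATAGAAAACA-T--TTTTTTTTTTCAAATTCAATT-----GTTTACTTATCTCTTATTCC----AAAATTC
>Trisetum_cernuum
TAATCCAAAATAGAAAACA-T--TTTTTTTTTTCAAATTCAATT-----GTTTATTTATCTCTTATTCC----AAAATTC
>Avena_sativa
TAATCCAAAATACAAAACATT--TTTTTTTTTTCAAATTCAATT-----GTTTATTTATCTCTTATTCC----AAAATTC
>Arrhenatherum_elatius
GAATCCAAAATAGAAAACA-------TTTTTTTTTAATTCAATT-----GTTTATTTATCTCTTATTCC----AAAATTC
>Anthoxanthum_odoratum
----------------------------TTTTTCAAATTCAATT-----GTTTATTTATCTCTTATTCC----AAAATTC
>Briza_maxima
-------------------------------------------------GTTTATTTATTTATTATTCC----AAAATTC
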