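#NEXUS

BEGIN DATA;
    DIMENSIONS NTAX=28 NCHAR=28;
    FORMAT DATATYPE=STANDARD SYMBOLS="012" MISSING=? GAP=-;
    MATRIX
        Permocupes_sojanensis         0?0000000?0000000100??000110
        Platycupes_dolichocerus       000000??0010100000011?000000
        Omma_delicata                 1110???-?11110?0111000001-10
        Omma_stanleyi                 1110111-01111010111000000110
        Omma_mastersii                1110111-01111010111000000110
        Omma_gobiense                 1?10???-?1111100111000001-10
        Pareuryomma_tylodes           1100???111000011001001010100
        Pareuryomma_ancistrodonta     110000?111000001001001010100
        Pareuryomma_cardiobasis       110000?111000011001001010100
        Cionocoleus_cervicalis        1110???101111100101000001-10
        Odontomma_trachylaena         11?0???101111000101000010100
        Brochocoleus_applanatus       1100???111111000001000110100
        Liassocupes_parvus            10?0?????11110000111??000100
        Tetraphalerus_decorosus       100????0111101?0011001001-10
        Tetraphalerus_bruchi          10012-1011111110011001000110
        Tetraphalerus_wagneri         10012-1011111110011101000110
        Tetraphalerus_brevicapits     1001???011111100011001001-10
        Tetraphalerus_glabratus       1001???011111100011001001-10
        Notocupoides_triassicus       0000000?01001000001110000001
        Rhabdocupes_longus            0000000?01101000001110100110
        Zygadenia_viridis             000000???1101000001110100110
        Notocupes_pingi               0000000?01101000001010100000
        Notocupes_nigrimonticola      0000000?01101000001010100000
        Eurydictyon_conspicuum        00000?0?01001000001110100001
        Amblomma_psilata              0000000101111000001111100000
        Amblomma_porrecta             0000000101111000001111100000
        Lithocupes_punctatus          10?0???1011110000011?0000100
        Tetraphalerites_oligocenicus  1??0?????11110000110??001-10
    ;
END;
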