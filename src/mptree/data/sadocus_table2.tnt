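xread
'Morphological matrix, 18 taxa x 64 characters'
64 18
Stygnus_polyacanthus 010001201010--01001101100100010-00-02000-10110000100010----00100
Acanthopachylus_aculeatus 1101000000010011010000000100100-01000100410110000001001040000010
Acanthoprocta_conica 1001012000010011010000000200101001202100-00000000100101041000000
Goniosoma_varium 101110111010--11000000000110100-00-10100-00110010001001150010011
Gonyleptes_horridus 101110100010--11000000001010110-01000011600110210001101101001110
Metagyndes_martensii 1101000000010001000010000100000-01000001310110000101001041000100
Nanophareus_polyhastatus 1001010000110011000000011100110-01110111000110000110001170001100
Neogonyleptes_docilis 1001001000011001000000001100001100-00101011000000110101121000100
Neogonyleptes_karschii 101100000010--11000000001110000101000100-11001000110001121000100
Pachyloides_thorellii 1010010000010011000000000100100-00-?0000-00110000010001131000000
Pachylus_chilensis 1101010000110111100000001100100-01102101510110000001101041000010
Roeweria_bittencourti 1010101000110011001101000112000-01000000-000000010010010--100010
Discocyrtus_catharinensis 1010100010110010101101001110111101100111610110001101001110100110
Sadocus_asperatus 1011101000110011000101001111101311001101210001100110001121000001
Sadocus_dilatatus 1011101000110010000101001111101301001001010001100110001121000001
Sadocus_funestus 1011101011110011000101000100111201010010-10000100110001121000001
Sadocus_ingens 1011101000110001000101001111101300-01101110001100110001121000000
Sadocus_polyacanthus 101110101010--10000101001111101301101010-10001100110001121000000
;
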