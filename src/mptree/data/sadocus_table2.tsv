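Stygnus polyacanthus	0	1	0	0	0	1	2	0	1	0	1	0	-	-	0	1	0	0	1	1	0	1	1	0	0	1	0	0	0	1	0	-	0	0	-	0	2	0	0	0	-	1	0	1	1	0	0	0	0	1	0	0	0	1	0	-	-	-	-	0	0	1	0	0
Acanthopachylus aculeatus	1	1	0	1	0	0	0	0	0	0	0	1	0	0	1	1	0	1	0	0	0	0	0	0	0	1	0	0	1	0	0	-	0	1	0	0	0	1	0	0	4	1	0	1	1	0	0	0	0	0	0	1	0	0	1	0	4	0	0	0	0	0	1	0
Acanthoprocta conica	1	0	0	1	0	1	2	0	0	0	0	1	0	0	1	1	0	1	0	0	0	0	0	0	0	2	0	0	1	0	1	0	0	1	2	0	2	1	0	0	-	0	0	0	0	0	0	0	0	1	0	0	1	0	1	0	4	1	0	0	0	0	0	0
Goniosoma varium	1	0	1	1	1	0	1	1	1	0	1	0	-	-	1	1	0	0	0	0	0	0	0	0	0	1	1	0	1	0	0	-	0	0	-	1	0	1	0	0	-	0	0	1	1	0	0	1	0	0	0	1	0	0	1	1	5	0	0	1	0	0	1	1
Gonyleptes horridus	1	0	1	1	1	0	1	0	0	0	1	0	-	-	1	1	0	0	0	0	0	0	0	0	1	0	1	0	1	1	0	-	0	1	0	0	0	0	1	1	6	0	0	1	1	0	2	1	0	0	0	1	1	0	1	1	0	1	0	0	1	1	1	0
Metagyndes martensii	1	1	0	1	0	0	0	0	0	0	0	1	0	0	0	1	0	0	0	0	1	0	0	0	0	1	0	0	0	0	0	-	0	1	0	0	0	0	0	1	3	1	0	1	1	0	0	0	0	1	0	1	0	0	1	0	4	1	0	0	0	1	0	0
Nanophareus polyhastatus	1	0	0	1	0	1	0	0	0	0	1	1	0	0	1	1	0	0	0	0	0	0	0	1	1	1	0	0	1	1	0	-	0	1	1	1	0	1	1	1	0	0	0	1	1	0	0	0	0	1	1	0	0	0	1	1	7	0	0	0	1	1	0	0
Neogonyleptes docilis	1	0	0	1	0	0	1	0	0	0	0	1	1	0	0	1	0	0	0	0	0	0	0	0	1	1	0	0	0	0	1	1	0	0	-	0	0	1	0	1	0	1	1	0	0	0	0	0	0	1	1	0	1	0	1	1	2	1	0	0	0	1	0	0
Neogonyleptes karschii	1	0	1	1	0	0	0	0	0	0	1	0	-	-	1	1	0	0	0	0	0	0	0	0	1	1	1	0	0	0	0	1	0	1	0	0	0	1	0	0	-	1	1	0	0	1	0	0	0	1	1	0	0	0	1	1	2	1	0	0	0	1	0	0
Pachyloides thorellii	1	0	1	0	0	1	0	0	0	0	0	1	0	0	1	1	0	0	0	0	0	0	0	0	0	1	0	0	1	0	0	-	0	0	-	?	0	0	0	0	-	0	0	1	1	0	0	0	0	0	1	0	0	0	1	1	3	1	0	0	0	0	0	0
Pachylus chilensis	1	1	0	1	0	1	0	0	0	0	1	1	0	1	1	1	1	0	0	0	0	0	0	0	1	1	0	0	1	0	0	-	0	1	1	0	2	1	0	1	5	1	0	1	1	0	0	0	0	0	0	1	1	0	1	0	4	1	0	0	0	0	1	0
Roeweria bittencourti	1	0	1	0	1	0	1	0	0	0	1	1	0	0	1	1	0	0	1	1	0	1	0	0	0	1	1	2	0	0	0	-	0	1	0	0	0	0	0	0	-	0	0	0	0	0	0	0	1	0	0	1	0	0	1	0	-	-	1	0	0	0	1	0
Discocyrtus catharinensis	1	0	1	0	1	0	0	0	1	0	1	1	0	0	1	0	1	0	1	1	0	1	0	0	1	1	1	0	1	1	1	1	0	1	1	0	0	1	1	1	6	1	0	1	1	0	0	0	1	1	0	1	0	0	1	1	1	0	1	0	0	1	1	0
Sadocus asperatus	1	0	1	1	1	0	1	0	0	0	1	1	0	0	1	1	0	0	0	1	0	1	0	0	1	1	1	1	1	0	1	3	1	1	0	0	1	1	0	1	2	1	0	0	0	1	1	0	0	1	1	0	0	0	1	1	2	1	0	0	0	0	0	1
Sadocus dilatatus	1	0	1	1	1	0	1	0	0	0	1	1	0	0	1	0	0	0	0	1	0	1	0	0	1	1	1	1	1	0	1	3	0	1	0	0	1	0	0	1	0	1	0	0	0	1	1	0	0	1	1	0	0	0	1	1	2	1	0	0	0	0	0	1
Sadocus funestus	1	0	1	1	1	0	1	0	1	1	1	1	0	0	1	1	0	0	0	1	0	1	0	0	0	1	0	0	1	1	1	2	0	1	0	1	0	0	1	0	-	1	0	0	0	0	1	0	0	1	1	0	0	0	1	1	2	1	0	0	0	0	0	1
Sadocus ingens	1	0	1	1	1	0	1	0	0	0	1	1	0	0	0	1	0	0	0	1	0	1	0	0	1	1	1	1	1	0	1	3	0	0	-	0	1	1	0	1	1	1	0	0	0	1	1	0	0	1	1	0	0	0	1	1	2	1	0	0	0	0	0	0
Sadocus polyacanthus	1	0	1	1	1	0	1	0	1	0	1	0	-	-	1	0	0	0	0	1	0	1	0	0	1	1	1	1	1	0	1	3	0	1	1	0	1	0	1	0	-	1	0	0	0	1	1	0	0	1	1	0	0	0	1	1	2	1	0	0	0	0	0	0
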