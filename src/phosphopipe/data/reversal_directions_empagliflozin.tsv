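gene_name	disease_direction	treatment_direction
CACNA1D	Down	Up
CACNA1A	Down	Up
CACNA1B	Down	Up
Ube2j1	Down	Up
Tjp2	Down	Up
Syngap1	Down	Up
Ssh2	Down	Up
Sh3kbp1	Down	Up
Rab10	Down	Up
Psd2	Down	Up
Prkce	Down	Up
Prkca	Down	Up
Pikfyve	Down	Up
Pak4	Down	Up
Ngfr	Down	Up
Nefl	Down	Up
Myh10	Down	Up
Iqsec1	Down	Up
Eef2	Down	Up
Dlg1	Down	Up
Dgkh	Down	Up
Dgkg	Down	Up
Csnk1a1	Down	Up
Cds2	Down	Up
Cdk5r1	Down	Up
Calm3	Down	Up
Cacnb4	Down	Up
Cacna1e	Down	Up
Atg2b	Down	Up
Apc2	Down	Up
Apc	Down	Up
Ablim3	Down	Up
Ablim1	Down	Up
Abl1	Down	Up
Prkg2	Up	Down
Pclo	Up	Down
Tiam1	Up	Down
Slc8a1	Up	Down
Shank3	Up	Down
Rims1	Up	Down
Rb1cc1	Up	Down
Rasgrf2	Up	Down
Plxna1	Up	Down
Nedd4l	Up	Down
Inpp5j	Up	Down
Htt	Up	Down
Gsk3a	Up	Down
Fgfr3	Up	Down
Epha7	Up	Down
Dnm1	Up	Down
Diaph1	Up	Down
Cxcr4	Up	Down
Cox6c	Up	Down
Cds1	Up	Down
Camkk2	Up	Down
Bmpr2	Up	Down
Atxn2l	Up	Down
Atp2b1	Up	Down
Atp1a2	Up	Down
Agap2	Up	Down
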