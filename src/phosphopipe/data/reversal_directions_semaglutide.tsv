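gene_name	disease_direction	treatment_direction
CACNA1D	Down	Up
CACNA1A	Down	Up
CACNA1B	Down	Up
Calm3	Down	Up
Atp2b1	Down	Up
Slc9a1	Down	Up
Atp1a3	Down	Up
Pak4	Down	Up
Slc12a2	Down	Up
Myh10	Down	Up
Abl1	Down	Up
Prkce	Down	Up
Ube2j1	Down	Up
Pikfyve	Down	Up
Pclo	Down	Up
Ngfr	Down	Up
Neo1	Down	Up
Nefl	Down	Up
Magi2	Down	Up
Eef2	Down	Up
Csnk1a1	Down	Up
Cltc	Down	Up
Cdk5r1	Down	Up
Atg2b	Down	Up
Camk2d	Up	Down
Ssh2	Up	Down
Cacnb2	Up	Down
Ca2	Up	Down
Zfyve1	Up	Down
Sipa1l1	Up	Down
Rb1cc1	Up	Down
Nefh	Up	Down
Map3k3	Up	Down
Htt	Up	Down
Farp2	Up	Down
Dnm1	Up	Down
Ctnnd1	Up	Down
Cox6c	Up	Down
Chrna4	Up	Down
Camkk2	Up	Down
Ablim3	Up/down	Down/up
Ablim1	Up/down	Down/up
Apc2	Up/down	Down/up
Gsk3a	Up/down	Down/up
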