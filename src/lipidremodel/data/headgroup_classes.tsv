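name	positions	compartment	membrane_diacyl
DGDG	2	plastidic	1
MGDG	2	plastidic	1
SQDG	2	plastidic	1
PG	2	plastidic	1
PC	2	extra-plastidic	1
PE	2	extra-plastidic	1
PE-N	2	extra-plastidic	0
PI	2	extra-plastidic	1
PS	2	extra-plastidic	1
PA	2	extra-plastidic	1
LPC	1	extra-plastidic	0
LPE	1	extra-plastidic	0
MGMG	1	plastidic	0
DGMG	1	plastidic	0
TrGDG	2	plastidic	0
acMGDG	3	plastidic	0
DG	2	neutral-storage	0
TG	3	neutral-storage	0
SE	1	sterol	0
SG	0	sterol	0
ASG	1	sterol	0
GSL	NA	sphingolipid	0
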