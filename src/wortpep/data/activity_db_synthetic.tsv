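# wortpep synthetic activity database v1 (50 entries).
# A small stand-in constructed for offline testing and examples;
# it does not reproduce any external database's coverage or counts.
sequence	activity
QG	dipeptidyl peptidase IV inhibitor
QQTTV	ACE inhibitor
SPHQG	antioxidative
QQG	calpain 1 inhibitor
QL	neprilysin 2 inhibitor
LA	stimulating
EL	xaa-pro inhibitor
PA	lactocepin inhibitor
QI	antiamnestic
QV	neuropeptide
SL	dipeptidyl peptidase IV inhibitor
SV	ACE inhibitor
TF	antioxidative
VA	calpain 1 inhibitor
PI	neprilysin 2 inhibitor
PL	stimulating
PQQPG	xaa-pro inhibitor
PV	lactocepin inhibitor
QQLG	antiamnestic
QQPG	neuropeptide
YV	dipeptidyl peptidase IV inhibitor
DA	ACE inhibitor
EG	antioxidative
ERG	calpain 1 inhibitor
FA	neprilysin 2 inhibitor
FG	stimulating
IA	xaa-pro inhibitor
IG	lactocepin inhibitor
NA	antiamnestic
NG	neuropeptide
RQQH	dipeptidyl peptidase IV inhibitor
FPLQ	ACE inhibitor
PQQ	antioxidative
DEL	calpain 1 inhibitor
NVPL	neprilysin 2 inhibitor
QPQQ	stimulating
NQ	xaa-pro inhibitor
YS	lactocepin inhibitor
TTS	antiamnestic
DDVL	neuropeptide
FEW	dipeptidyl peptidase IV inhibitor
HFN	ACE inhibitor
LQII	antioxidative
QR	calpain 1 inhibitor
RKDV	neprilysin 2 inhibitor
FITA	stimulating
MDEA	xaa-pro inhibitor
CNKQ	lactocepin inhibitor
KFVM	antiamnestic
CQVE	neuropeptide
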