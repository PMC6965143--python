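#% network: rvd_mv_rarefaction
targets, factors
#@ BF group=oxygenation_ischemia
#@ MildIschemia group=oxygenation_ischemia
#@ NADPHox group=oxidative_stress
#@ AngII group=endothelial_mv
#@ ROSscav group=oxidative_stress
#@ OxLDL group=oxidative_stress
#@ OxStress group=oxidative_stress
#@ NFkB group=inflammation
#@ NO group=endothelial_mv
#@ VEGF group=endothelial_mv
#@ Angiostatin group=endothelial_mv
#@ Vasoconstriction group=endothelial_mv
#@ MVrarefaction group=outcome
#@ Inflammation group=inflammation
#@ TGFbeta group=inflammation
#@ Sclerosis group=outcome
#@ TIMP_MMP group=outcome
#@ SevereIschemia group=oxygenation_ischemia
#@ Fibrosis group=outcome
#@ VEGFadmin role=intervention group=intervention
#@ Simvastatin role=intervention group=intervention
#@ RAS role=intervention group=intervention
#@ AntiOxidant role=intervention group=intervention
#@ ETAblockade role=intervention group=intervention
BF, !RAS & !MVrarefaction
MildIschemia, !BF
NADPHox, MildIschemia & AngII
AngII, !ETAblockade & (MildIschemia | SevereIschemia)
ROSscav, Simvastatin | !NADPHox
OxLDL, !Simvastatin & (!ROSscav | NADPHox | NFkB)
OxStress, !AntiOxidant & (!ROSscav | TGFbeta | !NO)
NFkB, !Simvastatin & (OxLDL & SevereIschemia)
NO, !OxStress | VEGF | Simvastatin
VEGF, !OxStress | VEGFadmin
Angiostatin, OxStress
Vasoconstriction, MAJ(AngII, !NO, Inflammation)
MVrarefaction, Angiostatin & Vasoconstriction
Inflammation, NFkB | AngII
TGFbeta, Inflammation
Sclerosis, TIMP_MMP
TIMP_MMP, MAJ(AngII, OxStress, TGFbeta)
SevereIschemia, MVrarefaction
Fibrosis, Sclerosis
VEGFadmin, VEGFadmin
Simvastatin, Simvastatin
RAS, RAS
AntiOxidant, AntiOxidant
ETAblockade, ETAblockade
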