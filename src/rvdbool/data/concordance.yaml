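# Qualitative expected steady-state outcomes per scenario, transcribed from
# the narrative outcome statements of the source model's simulation report
# (text statements only, never read off figure pixels). Variables not listed
# for a scenario are unstated and excluded from concordance scoring.
# basis: short note on which outcome statement the expectation comes from.

untreated:
  expected:
    BF: inactive
    MildIschemia: active
    NADPHox: active
    AngII: active
    ROSscav: inactive
    OxLDL: active
    OxStress: active
    NFkB: active
    "NO": inactive
    VEGF: inactive
    Angiostatin: active
    Vasoconstriction: active
    MVrarefaction: active
    Inflammation: active
    TGFbeta: active
    Sclerosis: active
    TIMP_MMP: active
    SevereIschemia: active
    Fibrosis: active
  basis:
    MildIschemia: untreated steady state activates ischemia and all deleterious processes
    Vasoconstriction: vasoconstriction reported active in the untreated steady state
    OxStress: oxidative-stress variables reported active untreated
    Inflammation: inflammation reported active untreated
    Fibrosis: fibrosis reported active untreated
    VEGF: protective VEGF reported inactivated untreated
    "NO": protective NO reported inactivated untreated
    ROSscav: ROS scavenging reported inactivated untreated
    BF: stenosis chronically inhibits blood flow

simvastatin:
  expected:
    ROSscav: active
    "NO": active
    VEGF: active
    MildIschemia: active
    AngII: active
    NADPHox: active
    OxStress: active
    OxLDL: inactive
    NFkB: inactive
    Vasoconstriction: inactive
    Angiostatin: inactive
    MVrarefaction: inactive
    Inflammation: inactive
    Sclerosis: inactive
    Fibrosis: inactive
  basis:
    ROSscav: statin arm reports ROS scavenging, NO and VEGF switched on vs untreated
    MildIschemia: ischemia, Ang II, NADPH oxidase and oxidative stress reported unchanged-active
    MVrarefaction: rarefaction, vasoconstriction, inflammation- and fibrosis-related outcomes reported halted
    OxLDL: statin described as inhibiting Ox-LDL and NFkB

antioxidant:
  expected:
    "NO": active
    VEGF: active
    MildIschemia: active
    NADPHox: active
    AngII: active
    OxLDL: active
    ROSscav: inactive
    OxStress: inactive
    MVrarefaction: inactive
    Sclerosis: inactive
    Fibrosis: inactive
  basis:
    OxLDL: anti-oxidant arm reports Ox-LDL unchanged-active, unlike the statin arm
    ROSscav: ROS scavenging reported inactivated under anti-oxidants
    OxStress: anti-oxidant administration inactivates oxidative stress directly
    MVrarefaction: rarefaction, fibrosis and glomerulosclerosis reported inactivated

eta_blockade:
  expected:
    MildIschemia: active
    BF: inactive
    ROSscav: active
    "NO": active
    VEGF: active
    AngII: inactive
    OxStress: inactive
    Vasoconstriction: inactive
    MVrarefaction: inactive
    Inflammation: inactive
    Sclerosis: inactive
    Fibrosis: inactive
  basis:
    MildIschemia: blood flow and mild ischemia reported unchanged (no flow restoration)
    AngII: receptor blockade interferes with the Ang II/ET-1 axis
    MVrarefaction: rarefaction, inflammation, oxidative stress and fibrosis reported improved
    VEGF: VEGF and NO reported preserved; end states reported to match expectations exactly

preventive_vegf:
  expected:
    VEGF: active
    "NO": active
    Sclerosis: active
    Fibrosis: active
    MVrarefaction: inactive
    Inflammation: inactive
    NFkB: inactive
    TGFbeta: inactive
    OxStress: inactive
  basis:
    VEGF: angiogenic and endothelial variables reported increased
    Sclerosis: sclerosis and fibrosis reported activated (unchanged vs untreated), noted as unexpected
    MVrarefaction: rarefaction and regression reported inactivated
    NFkB: TGF-beta, NFkB and inflammation reported inactivated

interventional_vegf:
  expected:
    VEGF: active
    "NO": active
    Sclerosis: active
    Fibrosis: active
    OxStress: active
    MVrarefaction: inactive
    Inflammation: inactive
    NFkB: inactive
    TGFbeta: inactive
  basis:
    VEGF: outcomes reported very similar to the preventive arm
    OxStress: oxidative stress, fibrosis and sclerosis reported to remain activated in this arm

angioplasty_vegf:
  expected:
    BF: active
    VEGF: active
    "NO": active
    ROSscav: active
    MildIschemia: inactive
    AngII: inactive
    NADPHox: inactive
    OxLDL: inactive
    OxStress: inactive
    NFkB: inactive
    Angiostatin: inactive
    Vasoconstriction: inactive
    MVrarefaction: inactive
    Inflammation: inactive
    TGFbeta: inactive
    Sclerosis: inactive
    TIMP_MMP: inactive
    SevereIschemia: inactive
    Fibrosis: inactive
  basis:
    BF: direct flow restoration reported to inactivate ischemia, Ang II and NADPH oxidase
    MVrarefaction: end state reported to mimic the healthy kidney; every variable switched
    ROSscav: angiogenesis and ROS scavenging reported recovered
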