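"""The packaged Boolean model of microvascular rarefaction in RVD.

Renovascular disease (RVD) is chronic kidney injury driven by renal artery
stenosis. The model encodes the qualitative feedback structure linking
reduced blood flow, ischemia, oxidative stress, inflammation, loss of
pro-angiogenic signaling (VEGF/NO) and microvascular (MV) rarefaction,
plus five intervention switches for previously tested therapies
(exogenous VEGF, simvastatin, angioplasty via stenosis release,
anti-oxidants, and endothelin-A receptor blockade).

Variables 1-19 are biological; 20-24 are intervention switches with
identity self-rules, so an intervention stays on (or off) once set.

The single documented model variant, ``"f7-nadph"``, swaps the TGF-beta
input (15) of the oxidative-stress rule F_7 for NADPH oxidase (3) — the
written description of that rule names NADPH oxidase while the formula
names TGF-beta; the formula is canonical and the variant preserves the
alternative reading for sensitivity analysis.
"""

from __future__ import annotations

from .expressions import And, BooleanExpression, Majority, Not, Or, Var
from .network import BooleanNetwork, VariableSpec

__all__ = ["build_rvd_model", "RVD_MODEL_NAME", "RVD_VARIANTS"]

RVD_MODEL_NAME = "rvd_mv_rarefaction"
RVD_VARIANTS = ("f7-nadph",)

# index, name, role, process group, annotation
_VARIABLES: list[tuple[int, str, str, str, str]] = [
    (1, "BF", "biological", "oxygenation_ischemia",
     "Chronic renal blood flow; normal in the healthy kidney, suppressed by stenosis "
     "and by microvascular loss (CT-derived renal blood flow)."),
    (2, "MildIschemia", "biological", "oxygenation_ischemia",
     "Mild renal ischemia: reduced tissue oxygen once chronic blood flow is lost "
     "(BOLD-MRI, HIF-1a expression)."),
    (3, "NADPHox", "biological", "oxidative_stress",
     "NADPH oxidase / xanthine oxidase, a superoxide source driven by ischemia plus "
     "Ang II/ET-1."),
    (4, "AngII", "biological", "endothelial_mv",
     "Ang II / ET-1 vasoconstrictor axis, stimulated by renal hypoxia; target of "
     "ET-A receptor blockade."),
    (5, "ROSscav", "biological", "oxidative_stress",
     "Scavenging of reactive oxygen species (superoxide dismutase activity); boosted "
     "by statins, depressed when NADPH oxidase is active."),
    (6, "OxLDL", "biological", "oxidative_stress",
     "Oxidized LDL, formed under oxidative stress; perpetuates renal inflammation; "
     "suppressed by simvastatin."),
    (7, "OxStress", "biological", "oxidative_stress",
     "ROS / oxidative stress burden (superoxide anion, nitrotyrosine); cleared by "
     "anti-oxidant administration."),
    (8, "NFkB", "biological", "inflammation",
     "NF-kB, transcription of pro-inflammatory cytokines; requires Ox-LDL plus "
     "severe ischemia, blocked by simvastatin."),
    (9, "NO", "biological", "endothelial_mv",
     "Nitric oxide (p-eNOS); vasodilator, lost with endothelial dysfunction under "
     "oxidative stress, supported by VEGF and statins."),
    (10, "VEGF", "biological", "endothelial_mv",
     "Endogenous VEGF; pro-angiogenic, maintains microvessel integrity; suppressed "
     "by oxidative stress, restored by VEGF administration."),
    (11, "Angiostatin", "biological", "endothelial_mv",
     "Angiostatin / endostatin / thrombospondin: anti-angiogenic factors elevated "
     "under oxidative stress."),
    (12, "Vasoconstriction", "biological", "endothelial_mv",
     "Intra-renal vasoconstriction: majority vote of Ang II/ET-1, absent NO, and "
     "inflammation."),
    (13, "MVrarefaction", "biological", "outcome",
     "Microvascular rarefaction/regression (loss of MV density), the central "
     "pathological outcome; needs angiostatin plus vasoconstriction."),
    (14, "Inflammation", "biological", "inflammation",
     "Renal inflammation (iNOS, MCP-1, inflammatory infiltrates); driven by NF-kB "
     "or Ang II/ET-1."),
    (15, "TGFbeta", "biological", "inflammation",
     "TGF-beta, pro-fibrotic and pro-inflammatory cytokine downstream of "
     "inflammation."),
    (16, "Sclerosis", "biological", "outcome",
     "Glomerulosclerosis (glomerular scarring); follows a TIMP-favouring "
     "TIMP/MMP balance."),
    (17, "TIMP_MMP", "biological", "outcome",
     "TIMP-over-MMP balance of extracellular-matrix turnover: majority vote of "
     "Ang II/ET-1, oxidative stress and TGF-beta."),
    (18, "SevereIschemia", "biological", "oxygenation_ischemia",
     "More severe renal ischemia once microvascular rarefaction is established."),
    (19, "Fibrosis", "biological", "outcome",
     "Tubule-interstitial injury and fibrosis; follows glomerulosclerosis."),
    (20, "VEGFadmin", "intervention", "intervention",
     "Exogenous VEGF administration; activates endogenous VEGF."),
    (21, "Simvastatin", "intervention", "intervention",
     "Simvastatin therapy; activates ROS scavenging, inhibits Ox-LDL and NF-kB, "
     "supports NO."),
    (22, "RAS", "intervention", "intervention",
     "Renal artery stenosis; chronically inhibits blood flow. Switching it off "
     "simulates renal angioplasty."),
    (23, "AntiOxidant", "intervention", "intervention",
     "Anti-oxidant administration (vitamins C and E); inactivates oxidative "
     "stress."),
    (24, "ETAblockade", "intervention", "intervention",
     "Endothelin-A receptor blockade; inactivates the Ang II/ET-1 axis."),
]


def _rules(variant: str | None) -> dict[int, BooleanExpression]:
    # F_7: canonical formula reads TGF-beta (15); the "f7-nadph" variant
    # follows the rule's written description and reads NADPH oxidase (3).
    f7_middle = Var(3) if variant == "f7-nadph" else Var(15)
    rules: dict[int, BooleanExpression] = {
        1: And(Not(Var(22)), Not(Var(13))),
        2: Not(Var(1)),
        3: And(Var(2), Var(4)),
        4: And(Not(Var(24)), Or(Var(2), Var(18))),
        5: Or(Var(21), Not(Var(3))),
        6: And(Not(Var(21)), Or(Not(Var(5)), Var(3), Var(8))),
        7: And(Not(Var(23)), Or(Not(Var(5)), f7_middle, Not(Var(9)))),
        8: And(Not(Var(21)), And(Var(6), Var(18))),
        9: Or(Not(Var(7)), Var(10), Var(21)),
        10: Or(Not(Var(7)), Var(20)),
        11: Var(7),
        12: Majority(Var(4), Not(Var(9)), Var(14)),
        13: And(Var(11), Var(12)),
        14: Or(Var(8), Var(4)),
        15: Var(14),
        16: Var(17),
        17: Majority(Var(4), Var(7), Var(15)),
        18: Var(13),
        19: Var(16),
    }
    for i in range(20, 25):
        rules[i] = Var(i)  # interventions hold their own state
    return rules


def build_rvd_model(variant: str | None = None) -> BooleanNetwork:
    """Construct the 24-variable RVD rarefaction network.

    Parameters
    ----------
    variant : str, optional
        ``None`` for the canonical rule set, ``"f7-nadph"`` for the
        documented alternative reading of the oxidative-stress rule.

    Returns
    -------
    BooleanNetwork
        A validated network: 19 biological variables plus 5 intervention
        switches with identity self-rules.
    """
    if variant not in (None,) + RVD_VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; known variants: {RVD_VARIANTS}"
        )
    name = RVD_MODEL_NAME if variant is None else f"{RVD_MODEL_NAME}_{variant}"
    net = BooleanNetwork(
        (VariableSpec(*row) for row in _VARIABLES),
        _rules(variant),
        name=name,
    )
    return net.require_valid()
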