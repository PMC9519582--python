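"""Concrete intracellular models: the cancer-cell and CAF signaling networks.

The cancer-cell model couples the TGFβ/SMAD pathway to the CXCL12→CXCR4→
PI3K/Akt→NFκB→MMP cascade (21 dynamical species; external inputs are
CAF-derived TGFβ ``xu3`` and CXCL12 ``xu4``).  The CAF model couples a
TGFβ/SMAD pathway to LIF→JAK/STAT signaling with pSMAD3–pSTAT crosstalk
driving SNAIL (26 dynamical species; external inputs are cancer-derived
TGFβ ``xu1`` and LIF ``xu2``).

Reactions taken from the published rate-law tables carry
``provenance: printed``; pathway segments that the tables only describe
(the CXCL12 downstream cascade, the CAF TGFβ-pathway mirror, SNAIL export)
are ``provenance: reconstructed`` and use the same mass-action/saturating
forms.  Default rate constants are placeholders meant to be re-estimated
from data; they are versioned in :data:`CANCER_DEFAULTS`/:data:`CAF_DEFAULTS`
and chosen so that the fate-determining observables (SMAD7, TGFβ, LIF,
CXCL12) rise above baseline over the first two days under constant
paracrine drive, matching the qualitative shape of measured time courses.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
import pandas as pd

from .reaction_network import (
    RateLaw,
    Reaction,
    ReactionNetwork,
    SpeciesSpec,
    Trajectory,
    simulate_network,
)

__all__ = [
    "CellModelSpec",
    "build_cancer_cell_network",
    "build_caf_network",
    "observables",
    "GENES",
    "OBS_TIMES",
]

GENES = ("SMAD7", "TGFb", "LIF", "CXCL12")
OBS_TIMES = (0.0, 24.0, 48.0, 72.0)

# default parameter magnitudes (a.u., hours); placeholders until estimated
_BASE = 0.1     # production / degradation turnover
_GAIN = 1.0     # association, enzymatic activation, nuclear import
_REV = 0.05     # dissociation, nuclear export
_INHIB = 0.01   # inhibitory removal fluxes
_K = 1.0        # half-saturation constants


@dataclass
class CellModelSpec:
    """A cell-type model: network plus the map from measured genes to species."""

    name: str
    network: ReactionNetwork
    observable_map: dict[str, str]
    input_names: list[str]
    default_inputs: dict[str, float] = field(default_factory=dict)

    def input_vector(self, overrides: dict[str, float] | None = None) -> np.ndarray:
        vals = dict(self.default_inputs)
        if overrides:
            vals.update(overrides)
        return np.array([vals.get(n, 0.0) for n in self.input_names])


def _mass(name, desc, k, orders, stoich, prov="printed"):
    return Reaction(
        name=name,
        description=desc,
        rate=RateLaw("mass_action", k, reactant_orders=orders),
        stoichiometry=stoich,
        provenance=prov,
    )


def _sat(name, desc, k, modifiers, sat_species, K, stoich, prov="printed"):
    return Reaction(
        name=name,
        description=desc,
        rate=RateLaw(
            "saturating",
            k,
            reactant_orders=modifiers,
            saturating_species=sat_species,
            half_constant=K,
        ),
        stoichiometry=stoich,
        provenance=prov,
    )


def _species(internal, secreted, inputs, complexes):
    specs = []
    for n in internal:
        specs.append(SpeciesSpec(n, "internal", 0.0 if n in complexes else 1.0))
    for n in secreted:
        specs.append(SpeciesSpec(n, "secreted-signal", 0.0 if n in complexes else 1.0))
    for n in inputs:
        specs.append(SpeciesSpec(n, "external-input", 0.0))
    return specs


def build_cancer_cell_network() -> CellModelSpec:
    """Cancer-cell model: TGFβ/SMAD pathway plus CXCL12→MMP cascade.

    21 dynamical species.  External inputs: ``xu3`` (CAF-derived TGFβ) and
    ``xu4`` (CXCL12).  Binding stoichiometry: the receptor-squared kinetics
    consume two receptors and one ligand per complex; all other steps are
    1:1.  Inhibitory rows act as extra first-order removal of the inhibited
    species.
    """
    internal = [
        "x1",  # TGFβ receptor
        "x2",  # TGFβ·TGFβR complex
        "x3",  # cytoplasmic SMAD3
        "x4",  # pSMAD3
        "x5",  # SMAD4
        "x6",  # pSMAD3-SMAD4 complex, cytoplasmic
        "x7",  # pSMAD3-SMAD4 complex, nuclear
        "x8",  # SMAD7
        "x9",  # CXCR4
        # reconstructed CXCL12 cascade
        "cx",     # CXCL12·CXCR4 complex
        "PI3K", "pPI3K", "Akt", "pAkt",
        "NFkBc", "NFkBn", "IkB",
        "MMPi",   # intracellular MMP
    ]
    secreted = ["xu1", "xu2", "MMPs"]  # cancer TGFβ, cancer LIF, secreted MMP
    inputs = ["xu3", "xu4"]            # CAF TGFβ, CXCL12
    complexes = {"x2", "x4", "x6", "x7", "cx", "pPI3K", "pAkt", "NFkBn", "MMPi", "MMPs"}

    rxns = [
        _mass("v1", "Production of TGFβ receptor", "k1p", {"x1": 1}, {"x1": +1}),
        _mass("v2", "Degradation of TGFβ receptor", "k1m", {"x1": 1}, {"x1": -1}),
        _mass("v3", "Association of TGFβ-TGFβR complex", "k2p",
              {"xu3": 1, "x1": 2}, {"x1": -2, "x2": +1}),
        _mass("v4", "Dissociation of TGFβ-receptor complex", "k2m",
              {"x2": 1}, {"x2": -1, "x1": +2}),
        _mass("v5", "Production of cytoplasmic SMAD3", "k3p", {"x3": 1}, {"x3": +1}),
        _mass("v6", "Degradation of cytoplasmic SMAD3", "k3m", {"x3": 1}, {"x3": -1}),
        _mass("v7", "Production of cytoplasmic SMAD4", "k4p", {"x5": 1}, {"x5": +1}),
        _mass("v8", "Degradation of cytoplasmic SMAD4", "k4m", {"x5": 1}, {"x5": -1}),
        _sat("v9", "Phosphorylation of SMAD3", "k5p", {"x2": 1}, "x3", "Ks1",
             {"x3": -1, "x4": +1}),
        _mass("v10", "Dephosphorylation of SMAD3", "k5m", {"x4": 1},
              {"x4": -1, "x3": +1}),
        _mass("v11", "Association of pSMAD3-4 Complex", "k6p", {"x4": 1, "x5": 1},
              {"x4": -1, "x5": -1, "x6": +1}),
        _mass("v12", "Dissociation of pSMAD3-4 Complex", "k6m", {"x6": 1},
              {"x6": -1, "x4": +1, "x5": +1}),
        _mass("v13", "Nuclear import of pSMAD3-4 Complex", "ki7", {"x6": 1},
              {"x6": -1, "x7": +1}),
        _mass("v14", "Nuclear export of pSMAD3-4 Complex", "ke7", {"x7": 1},
              {"x7": -1, "x6": +1}),
        _mass("v15", "Degradation of pSMAD3-4 Complex", "k7m", {"x7": 1}, {"x7": -1}),
        _mass("v16", "Production of SMAD7 in the pathway", "k8p", {"x7": 1}, {"x8": +1}),
        _mass("v17", "Degradation of SMAD7", "k8m", {"x8": 1}, {"x8": -1}),
        _mass("v18", "Inhibitory effect of SMAD7 on pSMAD3", "k8i", {"x8": 1},
              {"x4": -1}),
        _mass("v19", "Production of TGFβ in the pathway", "k9p", {"x7": 1}, {"xu1": +1}),
        _mass("v20", "Degradation of TGFβ", "k9m", {"xu1": 1}, {"xu1": -1}),
        _mass("v3p", "Association of TGFβ-TGFβR complex (autocrine)", "k2p",
              {"xu1": 1, "x1": 2}, {"x1": -2, "xu1": -1, "x2": +1}),
        _mass("v21", "Production of LIF in the pathway", "k10p", {"x7": 1}, {"xu2": +1}),
        _mass("v22", "Degradation of LIF", "k10m", {"xu2": 1}, {"xu2": -1}),
        _mass("v23", "Production of CXCR4 in the pathway", "k11p", {"x7": 1}, {"x9": +1}),
        _mass("v24", "Degradation of CXCR4", "k11m", {"x9": 1}, {"x9": -1}),
        # --- reconstructed CXCL12→PI3K/Akt→NFκB→MMP cascade ---
        _mass("c1", "Association of CXCL12-CXCR4 complex", "kc1p",
              {"xu4": 1, "x9": 1}, {"x9": -1, "cx": +1}, prov="reconstructed"),
        _mass("c2", "Dissociation of CXCL12-CXCR4 complex", "kc1m", {"cx": 1},
              {"cx": -1, "x9": +1}, prov="reconstructed"),
        _mass("c3", "Production of PI3K", "kc2p", {"PI3K": 1}, {"PI3K": +1},
              prov="reconstructed"),
        _mass("c4", "Degradation of PI3K", "kc2m", {"PI3K": 1}, {"PI3K": -1},
              prov="reconstructed"),
        _sat("c5", "Phosphorylation of PI3K by CXCL12-CXCR4 complex", "kc3p",
             {"cx": 1}, "PI3K", "Ksc1", {"PI3K": -1, "pPI3K": +1},
             prov="reconstructed"),
        _mass("c6", "Dephosphorylation of pPI3K", "kc3m", {"pPI3K": 1},
              {"pPI3K": -1, "PI3K": +1}, prov="reconstructed"),
        _mass("c7", "Production of Akt", "kc4p", {"Akt": 1}, {"Akt": +1},
              prov="reconstructed"),
        _mass("c8", "Degradation of Akt", "kc4m", {"Akt": 1}, {"Akt": -1},
              prov="reconstructed"),
        _sat("c9", "Phosphorylation of Akt by pPI3K", "kc5p", {"pPI3K": 1},
             "Akt", "Ksc2", {"Akt": -1, "pAkt": +1}, prov="reconstructed"),
        _mass("c10", "Dephosphorylation of pAkt", "kc5m", {"pAkt": 1},
              {"pAkt": -1, "Akt": +1}, prov="reconstructed"),
        _mass("c11", "Production of NFκB", "kc6p", {"NFkBc": 1}, {"NFkBc": +1},
              prov="reconstructed"),
        _mass("c12", "Degradation of NFκB", "kc6m", {"NFkBc": 1}, {"NFkBc": -1},
              prov="reconstructed"),
        _sat("c13", "Nuclear activation of NFκB by pAkt", "kc7p", {"pAkt": 1},
             "NFkBc", "Ksc3", {"NFkBc": -1, "NFkBn": +1}, prov="reconstructed"),
        _mass("c14", "Nuclear export of NFκB", "kc7m", {"NFkBn": 1},
              {"NFkBn": -1, "NFkBc": +1}, prov="reconstructed"),
        _mass("c15", "Production of IκB downstream of NFκB", "kc8p", {"NFkBn": 1},
              {"IkB": +1}, prov="reconstructed"),
        _mass("c16", "Degradation of IκB", "kc8m", {"IkB": 1}, {"IkB": -1},
              prov="reconstructed"),
        _mass("c17", "Inhibitory effect of IκB on NFκB", "kc8i", {"IkB": 1},
              {"NFkBn": -1}, prov="reconstructed"),
        _mass("c18", "Production of MMP downstream of NFκB", "kc9p", {"NFkBn": 1},
              {"MMPi": +1}, prov="reconstructed"),
        _mass("c19", "Degradation of intracellular MMP", "kc9m", {"MMPi": 1},
              {"MMPi": -1}, prov="reconstructed"),
        _mass("c20", "Secretion of MMP", "kc10p", {"MMPi": 1},
              {"MMPi": -1, "MMPs": +1}, prov="reconstructed"),
        _mass("c21", "Degradation of secreted MMP", "kc10m", {"MMPs": 1},
              {"MMPs": -1}, prov="reconstructed"),
    ]

    params = dict(CANCER_DEFAULTS)
    net = ReactionNetwork(_species(internal, secreted, inputs, complexes), rxns, params)
    return CellModelSpec(
        name="cancer",
        network=net,
        # CXCL12 expression in the cancer cell is read out through its
        # receptor axis (CXCR4, the pathway's CXCL12-axis target gene)
        observable_map={"SMAD7": "x8", "TGFb": "xu1", "LIF": "xu2", "CXCL12": "x9"},
        input_names=["xu3", "xu4"],
        default_inputs={"xu3": 1.0, "xu4": 1.0},
    )


def build_caf_network() -> CellModelSpec:
    """CAF model: TGFβ/SMAD mirror plus LIF→JAK/STAT with SMAD–STAT crosstalk.

    26 dynamical species.  External inputs: ``xu1`` (cancer TGFβ) and
    ``xu2`` (cancer LIF).  The TGFβ-pathway mirror (x1–x8) and two extra
    species — the autocrine TGFβ·receptor complex ``x23`` and the secreted
    SNAIL pool ``x24`` that feeds the microenvironment SNAIL field — are
    reconstructed; all LIF/STAT/crosstalk rows are the printed ones,
    including the two association routes that share the name ``w3``.
    """
    internal = [
        "x1", "x2", "x3", "x4", "x5", "x6", "x7", "x8",  # TGFβ mirror
        "x9",   # LIF produced by the CAF (autocrine ligand)
        "x10",  # LIF receptor
        "x11",  # LIF·LIFR complex
        "x12", "x13",          # JAK, pJAK
        "x14", "x15", "x16",   # STAT, pSTAT, nuclear pSTAT
        "x17",  # acetylated nuclear pSTAT
        "x18",  # SOCS3
        "x19",  # SHP1
        "x20", "x21",          # pSMAD3·pSTAT complex, cytoplasmic / nuclear
        "x22",  # SNAIL (nuclear)
        "x23",  # autocrine TGFβ·TGFβR complex (reconstructed)
    ]
    secreted = ["xu3", "xu4", "x24"]  # CAF TGFβ, CXCL12, secreted SNAIL
    inputs = ["xu1", "xu2"]           # cancer TGFβ, cancer LIF
    complexes = {"x2", "x4", "x6", "x7", "x11", "x13", "x15", "x16", "x17",
                 "x20", "x21", "x23", "x24"}

    mirror = [
        _mass("m1", "Production of TGFβ receptor", "m1p", {"x1": 1}, {"x1": +1},
              prov="reconstructed"),
        _mass("m2", "Degradation of TGFβ receptor", "m1m", {"x1": 1}, {"x1": -1},
              prov="reconstructed"),
        _mass("m3", "Association of TGFβ-TGFβR complex (paracrine)", "m2p",
              {"xu1": 1, "x1": 2}, {"x1": -2, "x2": +1}, prov="reconstructed"),
        _mass("m4", "Dissociation of TGFβ-receptor complex", "m2m", {"x2": 1},
              {"x2": -1, "x1": +2}, prov="reconstructed"),
        _mass("m3a", "Association of TGFβ-TGFβR complex (autocrine)", "m2p",
              {"xu3": 1, "x1": 2}, {"x1": -2, "xu3": -1, "x23": +1},
              prov="reconstructed"),
        _mass("m4a", "Dissociation of autocrine TGFβ-receptor complex", "m2m",
              {"x23": 1}, {"x23": -1, "x1": +2}, prov="reconstructed"),
        _mass("m5", "Production of cytoplasmic SMAD3", "m3p", {"x3": 1}, {"x3": +1},
              prov="reconstructed"),
        _mass("m6", "Degradation of cytoplasmic SMAD3", "m3m", {"x3": 1}, {"x3": -1},
              prov="reconstructed"),
        _mass("m7", "Production of cytoplasmic SMAD4", "m4p", {"x5": 1}, {"x5": +1},
              prov="reconstructed"),
        _mass("m8", "Degradation of cytoplasmic SMAD4", "m4m", {"x5": 1}, {"x5": -1},
              prov="reconstructed"),
        _sat("m9", "Phosphorylation of SMAD3", "m5p", {"x2": 1}, "x3", "Ksm1",
             {"x3": -1, "x4": +1}, prov="reconstructed"),
        _sat("m9a", "Phosphorylation of SMAD3 (autocrine complex)", "m5p",
             {"x23": 1}, "x3", "Ksm1", {"x3": -1, "x4": +1}, prov="reconstructed"),
        _mass("m10", "Dephosphorylation of SMAD3", "m5m", {"x4": 1},
              {"x4": -1, "x3": +1}, prov="reconstructed"),
        _mass("m11", "Association of pSMAD3-4 Complex", "m6p", {"x4": 1, "x5": 1},
              {"x4": -1, "x5": -1, "x6": +1}, prov="reconstructed"),
        _mass("m12", "Dissociation of pSMAD3-4 Complex", "m6m", {"x6": 1},
              {"x6": -1, "x4": +1, "x5": +1}, prov="reconstructed"),
        _mass("m13", "Nuclear import of pSMAD3-4 Complex", "mi7", {"x6": 1},
              {"x6": -1, "x7": +1}, prov="reconstructed"),
        _mass("m14", "Nuclear export of pSMAD3-4 Complex", "me7", {"x7": 1},
              {"x7": -1, "x6": +1}, prov="reconstructed"),
        _mass("m15", "Degradation of pSMAD3-4 Complex", "m7m", {"x7": 1}, {"x7": -1},
              prov="reconstructed"),
        _mass("m16", "Production of SMAD7 in the pathway", "m8p", {"x7": 1},
              {"x8": +1}, prov="reconstructed"),
        _mass("m17", "Degradation of SMAD7", "m8m", {"x8": 1}, {"x8": -1},
              prov="reconstructed"),
        _mass("m18", "Inhibitory effect of SMAD7 on pSMAD3", "m8i", {"x8": 1},
              {"x4": -1}, prov="reconstructed"),
        _mass("m19", "Production of TGFβ in the pathway", "m9p", {"x7": 1},
              {"xu3": +1}, prov="reconstructed"),
        _mass("m20", "Degradation of TGFβ", "m9m", {"xu3": 1}, {"xu3": -1},
              prov="reconstructed"),
        _mass("m21", "Production of LIF in the pathway", "m10p", {"x7": 1},
              {"x9": +1}, prov="reconstructed"),
        _mass("m22", "Degradation of LIF", "m10m", {"x9": 1}, {"x9": -1},
              prov="reconstructed"),
    ]
    printed = [
        _mass("v23", "Production of CXCL12 in the pathway", "k11p", {"x7": 1},
              {"xu4": +1}),
        _mass("v24", "Degradation of CXCL12", "k11m", {"xu4": 1}, {"xu4": -1}),
        _mass("w1", "Production of LIF receptor", "h1p", {"x10": 1}, {"x10": +1}),
        _mass("w2", "Degradation of LIF receptor", "h1m", {"x10": 1}, {"x10": -1}),
        _mass("w3", "Association of LIF-LIFreceptor complex", "h2p",
              {"x10": 1, "xu2": 1}, {"x10": -1, "x11": +1}),
        _mass("w3", "Association of LIFcaf-LIFreceptor complex", "h2p",
              {"x10": 1, "x9": 1}, {"x10": -1, "x9": -1, "x11": +1}),
        _mass("w4", "Dissociation of LIF-LIFreceptor complex", "h2m", {"x11": 1},
              {"x11": -1, "x10": +1}),
        _mass("w5", "Production of JAK", "h3p", {"x12": 1}, {"x12": +1}),
        _mass("w6", "Degradation of JAK", "h3m", {"x12": 1}, {"x12": -1}),
        _sat("w7", "Phosphorylation of JAK by LIF-receptor complex", "h4p",
             {"x11": 1}, "x12", "Ks2", {"x12": -1, "x13": +1}),
        _mass("w8", "Dephosphorylation of Pjak", "h4m", {"x13": 1},
              {"x13": -1, "x12": +1}),
        _mass("w9", "Production of STAT", "h5p", {"x14": 1}, {"x14": +1}),
        _mass("w10", "Degradation of STAT", "h5m", {"x14": 1}, {"x14": -1}),
        _sat("w11", "Phosphorylation of STAT by pJAK", "h6p", {}, "x14", "Ks3",
             {"x14": -1, "x15": +1}),
        _mass("w12", "Dephosphorylation of pSTAT", "h6m", {"x15": 1},
              {"x15": -1, "x14": +1}),
        _mass("w13", "Acetylation of pSTATn", "h7p", {"x16": 1},
              {"x16": -1, "x17": +1}),
        _mass("w14", "Deacetylation of pSTATn", "h7m", {"x17": 1},
              {"x17": -1, "x16": +1}),
        _mass("w15", "Inhibitory effect of pSTATnac on SHP1", "h7i", {"x17": 1},
              {"x19": -1}),
        _mass("w16", "Nuclear import of pSTAT", "hi8", {"x15": 1},
              {"x15": -1, "x16": +1}),
        _mass("w17", "Nuclear export of pSTAT", "he8", {"x16": 1},
              {"x16": -1, "x15": +1}),
        _mass("w18", "Production of SOCS3 downstream the pathway", "h9p", {"x16": 1},
              {"x18": +1}),
        _mass("w19", "Degradation of SOCS3", "h9m", {"x18": 1}, {"x18": -1}),
        _mass("w20", "Production of SMAD7 downstream the pathway", "h10p",
              {"x16": 1}, {"x8": +1}),
        _mass("w22", "Inhibitory effect of SOCS3 on STAT phosphorylation", "h10i",
              {"x18": 1}, {"x15": -1}),
        _mass("w23", "Production of SHP1", "h11p", {"x19": 1}, {"x19": +1}),
        _mass("w24", "Degradation of SHP1", "h11m", {"x19": 1}, {"x19": -1}),
        _mass("w25", "Inhibitory effect of SHP1 on STAT phosphorylation", "h11i",
              {"x19": 1}, {"x15": -1}),
        _mass("z1", "pSMAD3-pSTAT binding", "g1p", {"x4": 1, "x15": 1},
              {"x4": -1, "x15": -1, "x20": +1}),
        _mass("z2", "pSMAD3-pSTAT unbinding", "g1m", {"x20": 1},
              {"x20": -1, "x4": +1, "x15": +1}),
        _mass("z3", "Translocation of pSMAD3-pSTAT to nucleus", "gi", {"x20": 1},
              {"x20": -1, "x21": +1}),
        _mass("z4", "Translocation of pSMAD3-pSTAT to cytoplasm", "ge", {"x21": 1},
              {"x21": -1, "x20": +1}),
        _mass("z5", "Production of SNAIL in the pathway", "g2p", {"x21": 1},
              {"x22": +1}),
        _mass("z6", "Degradation of SNAIL", "g2m", {"x22": 1}, {"x22": -1}),
    ]
    extra = [
        _mass("s1", "Export of SNAIL to the microenvironment", "g3p", {"x22": 1},
              {"x24": +1}, prov="reconstructed"),
        _mass("s2", "Clearance of secreted SNAIL", "g3m", {"x24": 1}, {"x24": -1},
              prov="reconstructed"),
    ]

    params = dict(CAF_DEFAULTS)
    net = ReactionNetwork(
        _species(internal, secreted, inputs, complexes), mirror + printed + extra, params
    )
    return CellModelSpec(
        name="caf",
        network=net,
        observable_map={"SMAD7": "x8", "TGFb": "xu3", "LIF": "x9", "CXCL12": "xu4"},
        input_names=["xu1", "xu2"],
        default_inputs={"xu1": 1.0, "xu2": 1.0},
    )


# Placeholder kinetics, chosen once so the closed-loop shape is right:
# pool species (receptors, SMAD3/4, STAT, JAK, ...) get production slightly
# above degradation (0.13 vs 0.10 h^-1) so signaling can be sustained despite
# the absorbing degradation of nuclear complexes; enzymatic gains are 0.3,
# nuclear import 0.5, dissociation/export 0.05, inhibitory removals 0.01,
# target-gene synthesis 0.3 against 0.05 decay.  Half-constants 1 a.u.
_POOL = 0.13
_ENZ = 0.3
_IMP = 0.5
_SYN = 0.3
_DEC = 0.05

CANCER_DEFAULTS: dict[str, float] = {
    "k1p": _POOL, "k1m": _BASE, "k2p": 0.5, "k2m": _REV,
    "k3p": _POOL, "k3m": _BASE, "k4p": _POOL, "k4m": _BASE,
    "k5p": _ENZ, "Ks1": _K, "k5m": _BASE,
    "k6p": _ENZ, "k6m": _REV, "ki7": _IMP, "ke7": _REV, "k7m": 0.03,
    "k8p": _SYN, "k8m": _DEC, "k8i": _INHIB,
    "k9p": _SYN, "k9m": _DEC, "k10p": _SYN, "k10m": _DEC,
    "k11p": _SYN, "k11m": _DEC,
    "kc1p": 0.05, "kc1m": _REV, "kc2p": _POOL, "kc2m": _BASE,
    "kc3p": _ENZ, "Ksc1": _K, "kc3m": _BASE,
    "kc4p": _POOL, "kc4m": _BASE, "kc5p": _ENZ, "Ksc2": _K, "kc5m": _BASE,
    "kc6p": _POOL, "kc6m": _BASE, "kc7p": _ENZ, "Ksc3": _K, "kc7m": _REV,
    "kc8p": _BASE, "kc8m": _BASE, "kc8i": _INHIB,
    "kc9p": _SYN, "kc9m": _DEC, "kc10p": 0.2, "kc10m": _DEC,
}

CAF_DEFAULTS: dict[str, float] = {
    "m1p": _POOL, "m1m": _BASE, "m2p": 0.5, "m2m": _REV,
    "m3p": _POOL, "m3m": _BASE, "m4p": _POOL, "m4m": _BASE,
    "m5p": _ENZ, "Ksm1": _K, "m5m": _BASE,
    "m6p": _ENZ, "m6m": _REV, "mi7": _IMP, "me7": _REV, "m7m": 0.03,
    "m8p": _SYN, "m8m": _DEC, "m8i": _INHIB,
    "m9p": _SYN, "m9m": _DEC, "m10p": _SYN, "m10m": _DEC,
    "k11p": _SYN, "k11m": _DEC,
    "h1p": _POOL, "h1m": _BASE, "h2p": _ENZ, "h2m": _REV,
    "h3p": _POOL, "h3m": _BASE, "h4p": _ENZ, "Ks2": _K, "h4m": _BASE,
    "h5p": _POOL, "h5m": _BASE, "h6p": _ENZ, "Ks3": _K, "h6m": _BASE,
    "h7p": _BASE, "h7m": _BASE, "h7i": _INHIB,
    "hi8": _IMP, "he8": _REV,
    "h9p": _SYN, "h9m": _DEC, "h10p": _SYN, "h10i": _INHIB,
    "h11p": _POOL, "h11m": _BASE, "h11i": _INHIB,
    "g1p": _ENZ, "g1m": _REV, "gi": _IMP, "ge": _REV,
    "g2p": _SYN, "g2m": _DEC, "g3p": _SYN, "g3m": _DEC,
}


def observables(
    spec: CellModelSpec,
    traj: Trajectory,
    times: tuple[float, ...] = OBS_TIMES,
) -> pd.DataFrame:
    """Fold-change matrix (genes x times) of the mapped observables.

    Fold change is value(t)/value(0) per gene; the trajectory must cover
    the requested times and the baseline must be positive.
    """
    rows = {}
    for gene, species in spec.observable_map.items():
        series = traj[species]
        vals = np.array([series[np.searchsorted(traj.times, t)] for t in times])
        for t in times:
            idx = np.searchsorted(traj.times, t)
            if idx >= len(traj.times) or not np.isclose(traj.times[idx], t):
                raise ValueError(f"trajectory does not cover time {t}")
        baseline = vals[0] if times[0] == traj.times[0] else traj[species][0]
        if baseline <= 0:
            raise ZeroDivisionError(
                f"zero baseline for gene {gene} (species {species})"
            )
        rows[gene] = vals / baseline
    return pd.DataFrame(rows, index=list(times)).T


def simulate_cell(
    spec: CellModelSpec,
    parameters=None,
    inputs: dict[str, float] | None = None,
    times=OBS_TIMES,
    x0=None,
) -> Trajectory:
    """Convenience wrapper: simulate a cell model under constant inputs."""
    net = spec.network
    if x0 is None:
        x0 = net.initial_state()
    return simulate_network(
        net, x0, parameters=parameters, inputs=spec.input_vector(inputs), times=times
    )


def write_bundled_networks(directory) -> None:
    """Write both cell models as YAML definition files into *directory*."""
    from .reaction_network import save_network
    import os

    os.makedirs(directory, exist_ok=True)
    for spec in (build_cancer_cell_network(), build_caf_network()):
        save_network(spec.network, os.path.join(directory, f"{spec.name}.yaml"))
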