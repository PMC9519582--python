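"""Independent closed-form oracles for every published rate-law table row.

Each entry maps a reaction description to a lambda evaluating the printed
formula directly from concentrations ``c`` and parameters ``p``; tests
compare these against the package's structured rate-law evaluation on
random positive probe inputs.
"""

CANCER_PRINTED = {
    "Production of TGFβ receptor": lambda c, p: p["k1p"] * c["x1"],
    "Degradation of TGFβ receptor": lambda c, p: p["k1m"] * c["x1"],
    "Association of TGFβ-TGFβR complex": lambda c, p: p["k2p"] * c["xu3"] * c["x1"] ** 2,
    "Dissociation of TGFβ-receptor complex": lambda c, p: p["k2m"] * c["x2"],
    "Production of cytoplasmic SMAD3": lambda c, p: p["k3p"] * c["x3"],
    "Degradation of cytoplasmic SMAD3": lambda c, p: p["k3m"] * c["x3"],
    "Production of cytoplasmic SMAD4": lambda c, p: p["k4p"] * c["x5"],
    "Degradation of cytoplasmic SMAD4": lambda c, p: p["k4m"] * c["x5"],
    "Phosphorylation of SMAD3":
        lambda c, p: p["k5p"] * c["x2"] * c["x3"] / (c["x3"] + p["Ks1"]),
    "Dephosphorylation of SMAD3": lambda c, p: p["k5m"] * c["x4"],
    "Association of pSMAD3-4 Complex": lambda c, p: p["k6p"] * c["x4"] * c["x5"],
    "Dissociation of pSMAD3-4 Complex": lambda c, p: p["k6m"] * c["x6"],
    "Nuclear import of pSMAD3-4 Complex": lambda c, p: p["ki7"] * c["x6"],
    "Nuclear export of pSMAD3-4 Complex": lambda c, p: p["ke7"] * c["x7"],
    "Degradation of pSMAD3-4 Complex": lambda c, p: p["k7m"] * c["x7"],
    "Production of SMAD7 in the pathway": lambda c, p: p["k8p"] * c["x7"],
    "Degradation of SMAD7": lambda c, p: p["k8m"] * c["x8"],
    "Inhibitory effect of SMAD7 on pSMAD3": lambda c, p: p["k8i"] * c["x8"],
    "Production of TGFβ in the pathway": lambda c, p: p["k9p"] * c["x7"],
    "Degradation of TGFβ": lambda c, p: p["k9m"] * c["xu1"],
    "Association of TGFβ-TGFβR complex (autocrine)":
        lambda c, p: p["k2p"] * c["xu1"] * c["x1"] ** 2,
    "Production of LIF in the pathway": lambda c, p: p["k10p"] * c["x7"],
    "Degradation of LIF": lambda c, p: p["k10m"] * c["xu2"],
    "Production of CXCR4 in the pathway": lambda c, p: p["k11p"] * c["x7"],
    "Degradation of CXCR4": lambda c, p: p["k11m"] * c["x9"],
}

CAF_PRINTED = {
    "Production of CXCL12 in the pathway": lambda c, p: p["k11p"] * c["x7"],
    "Degradation of CXCL12": lambda c, p: p["k11m"] * c["xu4"],
    "Production of LIF receptor": lambda c, p: p["h1p"] * c["x10"],
    "Degradation of LIF receptor": lambda c, p: p["h1m"] * c["x10"],
    "Association of LIF-LIFreceptor complex":
        lambda c, p: p["h2p"] * c["x10"] * c["xu2"],
    "Association of LIFcaf-LIFreceptor complex":
        lambda c, p: p["h2p"] * c["x10"] * c["x9"],
    "Dissociation of LIF-LIFreceptor complex": lambda c, p: p["h2m"] * c["x11"],
    "Production of JAK": lambda c, p: p["h3p"] * c["x12"],
    "Degradation of JAK": lambda c, p: p["h3m"] * c["x12"],
    "Phosphorylation of JAK by LIF-receptor complex":
        lambda c, p: p["h4p"] * c["x11"] * c["x12"] / (c["x12"] + p["Ks2"]),
    "Dephosphorylation of Pjak": lambda c, p: p["h4m"] * c["x13"],
    "Production of STAT": lambda c, p: p["h5p"] * c["x14"],
    "Degradation of STAT": lambda c, p: p["h5m"] * c["x14"],
    "Phosphorylation of STAT by pJAK":
        lambda c, p: p["h6p"] * c["x14"] / (c["x14"] + p["Ks3"]),
    "Dephosphorylation of pSTAT": lambda c, p: p["h6m"] * c["x15"],
    "Acetylation of pSTATn": lambda c, p: p["h7p"] * c["x16"],
    "Deacetylation of pSTATn": lambda c, p: p["h7m"] * c["x17"],
    "Inhibitory effect of pSTATnac on SHP1": lambda c, p: p["h7i"] * c["x17"],
    "Nuclear import of pSTAT": lambda c, p: p["hi8"] * c["x15"],
    "Nuclear export of pSTAT": lambda c, p: p["he8"] * c["x16"],
    "Production of SOCS3 downstream the pathway": lambda c, p: p["h9p"] * c["x16"],
    "Degradation of SOCS3": lambda c, p: p["h9m"] * c["x18"],
    "Production of SMAD7 downstream the pathway": lambda c, p: p["h10p"] * c["x16"],
    "Inhibitory effect of SOCS3 on STAT phosphorylation":
        lambda c, p: p["h10i"] * c["x18"],
    "Production of SHP1": lambda c, p: p["h11p"] * c["x19"],
    "Degradation of SHP1": lambda c, p: p["h11m"] * c["x19"],
    "Inhibitory effect of SHP1 on STAT phosphorylation":
        lambda c, p: p["h11i"] * c["x19"],
    "pSMAD3-pSTAT binding": lambda c, p: p["g1p"] * c["x4"] * c["x15"],
    "pSMAD3-pSTAT unbinding": lambda c, p: p["g1m"] * c["x20"],
    "Translocation of pSMAD3-pSTAT to nucleus": lambda c, p: p["gi"] * c["x20"],
    "Translocation of pSMAD3-pSTAT to cytoplasm": lambda c, p: p["ge"] * c["x21"],
    "Production of SNAIL in the pathway": lambda c, p: p["g2p"] * c["x21"],
    "Degradation of SNAIL": lambda c, p: p["g2m"] * c["x22"],
}
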