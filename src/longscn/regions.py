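"""Desikan-Killiany cortical parcellation labels (34 per hemisphere)."""

_DK_BASE = [
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
]

#: The 68 bilateral Desikan-Killiany region labels used as network nodes.
DESIKAN_KILLIANY_68 = [f"{hemi}_{name}" for hemi in ("lh", "rh") for name in _DK_BASE]


def default_region_names(n_regions: int) -> list[str]:
    """Region labels for a network of ``n_regions`` nodes.

    Uses the 68 Desikan-Killiany names when ``n_regions == 68``, otherwise
    generic ``region_00 ...`` labels.
    """
    if n_regions == 68:
        return list(DESIKAN_KILLIANY_68)
    return [f"region_{i:02d}" for i in range(n_regions)]
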