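"""Packaged registry of metabolite spin-system moieties.

Chemical shifts (ppm) and scalar couplings (Hz) follow the standard
literature compilation of brain-metabolite NMR parameters
(Govindaraju, Young & Maudsley, NMR Biomed 2000, with the usual
corrigenda); each entry notes its source. Metabolites whose singlet and
multiplet parts relax differently in vivo are split into constituent
moieties (e.g. the N-acetylaspartate methyl singlet vs. its aspartyl
CH-CH2 multiplet), which also keeps every simulated system small.

``proton_count_scale`` carries the proton multiplicity of magnetically
equivalent groups that are simulated as a single spin (a methyl singlet
is one simulated spin weighted by 3).
"""

from __future__ import annotations

import numpy as np

from .spin_sim import SpinSystem

__all__ = ["build_spin_system", "available_moieties", "MOIETIES_OF", "SINGLET_COMPOUNDS"]


def _j(n: int, pairs: dict[tuple[int, int], float]) -> np.ndarray:
    m = np.zeros((n, n))
    for (i, k), v in pairs.items():
        m[i, k] = m[k, i] = v
    return m


# moiety -> (shifts ppm, J pairs Hz, parent compound, proton weight per spin)
# Sources: Govindaraju et al. 2000 unless noted.
_REGISTRY: dict[str, dict] = {
    # N-acetylaspartate acetyl CH3 singlet, 2.008 ppm
    "naa_ch3": dict(shifts=[2.008], j={}, parent="NAA", weight=3.0),
    # NAA aspartyl CH-CH2 (ABX): 4.382, 2.673, 2.486 ppm
    "naa_asp": dict(
        shifts=[4.382, 2.673, 2.486],
        j={(0, 1): 3.861, (0, 2): 9.821, (1, 2): -15.592},
        parent="NAA",
        weight=1.0,
    ),
    # creatine / phosphocreatine methyl and methylene singlets
    "cr_ch3": dict(shifts=[3.027], j={}, parent="Cr", weight=3.0),
    "cr_ch2": dict(shifts=[3.913], j={}, parent="Cr", weight=2.0),
    "pcr_ch3": dict(shifts=[3.029], j={}, parent="PCr", weight=3.0),
    "pcr_ch2": dict(shifts=[3.930], j={}, parent="PCr", weight=2.0),
    # choline head-group trimethyl singlets
    "pcho_n_ch3": dict(shifts=[3.208], j={}, parent="PCho", weight=9.0),
    "gpc_n_ch3": dict(shifts=[3.212], j={}, parent="GPC", weight=9.0),
    # glutamate CH + 2x CH2 (5 spins)
    "glu": dict(
        shifts=[3.743, 2.042, 2.120, 2.336, 2.352],
        j={
            (0, 1): 7.331,
            (0, 2): 4.651,
            (1, 2): -14.849,
            (1, 3): 6.413,
            (1, 4): 8.406,
            (2, 3): 8.478,
            (2, 4): 6.875,
            (3, 4): -15.915,
        },
        parent="Glu",
        weight=1.0,
    ),
    # glutamine CH + 2x CH2 (5 spins)
    "gln": dict(
        shifts=[3.753, 2.129, 2.109, 2.432, 2.454],
        j={
            (0, 1): 5.847,
            (0, 2): 6.500,
            (1, 2): -14.504,
            (1, 3): 9.165,
            (1, 4): 6.347,
            (2, 3): 6.324,
            (2, 4): 9.209,
            (3, 4): -15.371,
        },
        parent="Gln",
        weight=1.0,
    ),
    # myo-inositol ring, 6 coupled CH protons
    "mins": dict(
        shifts=[3.522, 4.054, 3.522, 3.614, 3.269, 3.614],
        j={
            (0, 1): 2.889,
            (1, 2): 3.006,
            (2, 3): 9.997,
            (3, 4): 9.485,
            (4, 5): 9.482,
            (0, 5): 9.998,
        },
        parent="mIns",
        weight=1.0,
    ),
}

#: compound label -> tuple of moiety keys composing it
MOIETIES_OF: dict[str, tuple[str, ...]] = {
    "NAA": ("naa_ch3", "naa_asp"),
    "Cr": ("cr_ch3", "cr_ch2"),
    "PCr": ("pcr_ch3", "pcr_ch2"),
    "PCho": ("pcho_n_ch3",),
    "GPC": ("gpc_n_ch3",),
    "Glu": ("glu",),
    "Gln": ("gln",),
    "mIns": ("mins",),
}

#: combined reporting channels built post-fit from singlet moieties
SINGLET_COMPOUNDS: dict[str, tuple[str, ...]] = {
    "NAA": ("naa_ch3",),
    "tCr": ("cr_ch3", "pcr_ch3"),
    "tCho": ("pcho_n_ch3", "gpc_n_ch3"),
}


def available_moieties() -> list[str]:
    return sorted(_REGISTRY)


def build_spin_system(registry_key: str) -> SpinSystem:
    """Look up a moiety and return its validated :class:`SpinSystem`.

    Raises ``KeyError`` listing the available keys for unknown names.
    """
    try:
        entry = _REGISTRY[registry_key]
    except KeyError:
        raise KeyError(
            f"unknown moiety {registry_key!r}; available: {', '.join(available_moieties())}"
        ) from None
    shifts = list(entry["shifts"])
    return SpinSystem(
        name=registry_key,
        shifts=tuple(shifts),
        j_matrix=_j(len(shifts), entry["j"]),
        moiety_of=entry["parent"],
        proton_count_scale=float(entry["weight"]),
    )
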