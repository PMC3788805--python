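"""Synthetic cohort generator: the study's raw-data stand-in.

Generates per-subject multi-TE STEAM metabolite spectra and twelve-TE
unsuppressed-water integral series with the statistical structure the
downstream analysis assumes: per-compound ground-truth T2s drawn from
group-specific truncated normals, mono-exponential amplitude decay of
every moiety of a compound with that compound's T2, a macromolecule
background with its own fast decay, ~12 Hz linewidth and additive
complex Gaussian noise in the frequency domain (equivalent to white
time-domain noise under the unitary transform).

Default group parameters are the study conditions: 18 young / 14
elderly subjects; young/elderly T2 means (SDs) of 208 (18) / 161 (19)
ms for NAA, 157 (14) / 132 (11) ms for tCr, 164 (29) / 147 (16) ms for
tCho and 52 (2) / 47 (4) ms for tissue water; CSF fractions 9 +/- 3 %
(young) and 25 +/- 11 % (elderly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from . import registry
from .spin_sim import (AcquisitionScheme, BasisSet, Spectrum, WATER_TE_LIST_MS)

__all__ = [
    "GroupParams",
    "CohortConfig",
    "SubjectRecord",
    "SpectrumSeries",
    "WaterSeries",
    "sample_cohort",
    "synthesize_metabolite_series",
    "synthesize_water_series",
]


#: compound concentrations, arbitrary units, typical occipital ratios
DEFAULT_CONCENTRATIONS: dict[str, float] = {
    "NAA": 12.0,
    "Cr": 5.0,
    "PCr": 4.5,
    "PCho": 0.6,
    "GPC": 1.0,
    "Glu": 9.0,
    "Gln": 3.0,
    "mIns": 6.0,
}

# (mean, sd) of T2 in ms per compound; tCr/tCho T2s are shared by their
# constituent compounds.  Glu/Gln/mIns T2s are not part of the study's
# reported values (those compounds fail quality control); plausible
# occipital values are used so their spectra decay realistically.
_YOUNG_T2 = {
    "NAA": (208.0, 18.0), "tCr": (157.0, 14.0), "tCho": (164.0, 29.0),
    "Glu": (135.0, 15.0), "Gln": (125.0, 15.0), "mIns": (110.0, 12.0),
}
_ELDERLY_T2 = {
    "NAA": (161.0, 19.0), "tCr": (132.0, 11.0), "tCho": (147.0, 16.0),
    "Glu": (122.0, 15.0), "Gln": (115.0, 15.0), "mIns": (100.0, 12.0),
}

#: compounds inheriting a shared T2 channel
T2_CHANNEL_OF: dict[str, str] = {
    "NAA": "NAA", "Cr": "tCr", "PCr": "tCr", "PCho": "tCho", "GPC": "tCho",
    "Glu": "Glu", "Gln": "Gln", "mIns": "mIns",
}


@dataclass(frozen=True)
class GroupParams:
    """One cohort's generative parameters."""

    n: int
    t2_ms: dict[str, tuple[float, float]]          # channel -> (mean, sd)
    csf_fraction: tuple[float, float]              # (mean, sd)
    water_t2_tissue: tuple[float, float]           # ms (mean, sd)


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; defaults are the study conditions."""

    young: GroupParams = GroupParams(
        n=18, t2_ms=_YOUNG_T2, csf_fraction=(0.09, 0.03), water_t2_tissue=(52.0, 2.0))
    elderly: GroupParams = GroupParams(
        n=14, t2_ms=_ELDERLY_T2, csf_fraction=(0.25, 0.11), water_t2_tissue=(47.0, 4.0))
    concentrations: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONCENTRATIONS))
    mm_scale: float = 1.0
    noise_sd: float = 120.0                # spectral units per real/imag bin
    water_te_list: tuple[float, ...] = WATER_TE_LIST_MS
    water_s0: float = 1000.0
    water_noise_frac: float = 0.002        # integral noise, fraction of S0
    t2_csf_fixed: float = 1500.0           # ms
    master_seed: int = 0

    def __post_init__(self):
        for grp in (self.young, self.elderly):
            if grp.n <= 0:
                raise ValueError("group size must be positive")
            for mean, sd in grp.t2_ms.values():
                if mean <= 0 or sd < 0:
                    raise ValueError("T2 means must be positive and SDs non-negative")
            if not (0 <= grp.csf_fraction[0] <= 1) or grp.csf_fraction[1] < 0:
                raise ValueError("CSF fraction mean must lie in [0,1] with sd >= 0")
        if self.noise_sd < 0 or self.water_noise_frac < 0:
            raise ValueError("noise levels must be non-negative")
        if self.t2_csf_fixed <= max(self.young.water_t2_tissue[0],
                                    self.elderly.water_t2_tissue[0]):
            raise ValueError("t2_csf_fixed must exceed tissue-water T2")


@dataclass(frozen=True)
class SubjectRecord:
    """Ground truth for one synthetic subject (stored so recovery can be scored)."""

    subject_id: str
    group: str                              # "young" | "elderly"
    true_t2: dict[str, float]               # channel -> ms
    true_csf_fraction: float
    true_water_t2_tissue: float
    seed: int


@dataclass
class SpectrumSeries:
    """Spectra indexed by TE (ms) with their acquisition scheme."""

    spectra: dict[float, Spectrum]
    scheme: AcquisitionScheme
    kind: str = "metabolite"
    subject_id: str = ""


@dataclass
class WaterSeries:
    """Unsuppressed-water integrals by TE (ms)."""

    te_ms: np.ndarray
    integrals: np.ndarray
    subject_id: str = ""


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float = -np.inf, hi: float = np.inf) -> float:
    """Normal truncated at +/-3 SD and at the [lo, hi] box."""
    if sd == 0:
        return mean
    a = max(mean - 3 * sd, lo)
    b = min(mean + 3 * sd, hi)
    return float(truncnorm.rvs((a - mean) / sd, (b - mean) / sd, loc=mean, scale=sd,
                               random_state=rng))


def sample_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Draw per-subject ground truth; deterministic given ``master_seed``."""
    ss = np.random.SeedSequence(config.master_seed)
    n_total = config.young.n + config.elderly.n
    child_seeds = ss.spawn(n_total)
    records = []
    i = 0
    for group, params in (("young", config.young), ("elderly", config.elderly)):
        for k in range(params.n):
            child = child_seeds[i]
            rng = np.random.default_rng(child)
            t2 = {ch: _trunc_normal(rng, m, s, lo=1.0) for ch, (m, s) in params.t2_ms.items()}
            csf = _trunc_normal(rng, *params.csf_fraction, lo=0.0, hi=1.0)
            wt2 = _trunc_normal(rng, *params.water_t2_tissue, lo=1.0)
            records.append(SubjectRecord(
                subject_id=f"{group[0].upper()}{k+1:03d}", group=group, true_t2=t2,
                true_csf_fraction=csf, true_water_t2_tissue=wt2,
                seed=int(child.generate_state(1)[0] % (2**31)),
            ))
            i += 1
    return records


def synthesize_metabolite_series(subject: SubjectRecord, basis: BasisSet,
                                 config: CohortConfig) -> SpectrumSeries:
    """Compose noisy multi-TE spectra from the basis and the subject's truth.

    At each TE the spectrum is ``sum_m c_m exp(-TE/T2_m) basis_m(TE)``
    plus the macromolecule component (its fast decay is already baked
    into the basis) and i.i.d. complex Gaussian noise per bin.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, subject.seed, 1]))
    scheme = basis.scheme
    synthesized = {basis.moiety_of.get(name, name) for name in basis.entries}
    missing = set(config.concentrations) - synthesized
    if missing:
        raise KeyError(f"basis lacks moieties for configured compounds {sorted(missing)}")
    spectra: dict[float, Spectrum] = {}
    for te in scheme.te_list:
        entries = basis.at_te(te)
        total = np.zeros(scheme.n_points, dtype=complex)
        for name, spec in entries.items():
            if name == "MM":
                total += config.mm_scale * spec.values
                continue
            compound = basis.moiety_of.get(name, name)
            if compound not in config.concentrations:
                continue  # compound not part of this synthesis
            channel = T2_CHANNEL_OF.get(compound, compound)
            if channel not in subject.true_t2:
                raise KeyError(f"subject truth lacks T2 channel {channel!r}")
            t2 = subject.true_t2[channel]
            total += config.concentrations[compound] * np.exp(-te / t2) * spec.values
        if config.noise_sd > 0:
            total = total + rng.normal(0.0, config.noise_sd, scheme.n_points) \
                + 1j * rng.normal(0.0, config.noise_sd, scheme.n_points)
        spectra[te] = Spectrum(values=total, ppm=scheme.ppm_axis(), hz=scheme.freq_axis_hz(),
                               te=te, linewidth=basis.linewidth, scheme=scheme)
    return SpectrumSeries(spectra=spectra, scheme=scheme, kind="metabolite",
                          subject_id=subject.subject_id)


def synthesize_water_series(subject: SubjectRecord, config: CohortConfig) -> WaterSeries:
    """Two-compartment water integral series with additive noise."""
    if config.t2_csf_fixed <= subject.true_water_t2_tissue:
        raise ValueError("t2_csf_fixed must exceed the tissue-water T2")
    rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, subject.seed, 2]))
    te = np.asarray(config.water_te_list, float)
    f = subject.true_csf_fraction
    s = config.water_s0 * ((1 - f) * np.exp(-te / subject.true_water_t2_tissue)
                           + f * np.exp(-te / config.t2_csf_fixed))
    if config.water_noise_frac > 0:
        s = s + rng.normal(0.0, config.water_noise_frac * config.water_s0, len(te))
    return WaterSeries(te_ms=te, integrals=s, subject_id=subject.subject_id)


def default_moieties() -> list:
    """Spin systems for every compound in the default concentration table."""
    keys = [k for compound in DEFAULT_CONCENTRATIONS
            for k in registry.MOIETIES_OF[compound]]
    return [registry.build_spin_system(k) for k in keys]
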