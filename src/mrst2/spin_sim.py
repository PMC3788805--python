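"""Ideal-pulse density-matrix simulation of STEAM basis spectra.

The stimulated-echo sequence is modelled as three instantaneous 90°
pulses, 90° – TE/2 – 90° – TM – 90° – TE/2 – acquire, with coherence
pathway selection applied as order masks in the Zeeman product basis
(the numerical analogue of the sequence's crusher gradients): order +1
is retained during the first TE/2 period, order 0 (populations and
zero-quantum coherence) during the mixing time, and order −1 during the
second TE/2 and acquisition.  The free-evolution Hamiltonian is

    H = sum_i Omega_i I_iz + sum_{i<j} 2*pi*J_ij I_i . I_j

with Omega_i the chemical-shift offset from the carrier in rad/s.  No
relaxation is applied inside the sequence; T2 weighting is injected
downstream as a per-moiety exp(-TE/T2) factor.

For an uncoupled spin this pathway retains exactly half of the
one-pulse magnetisation at every TE and TM, which is the textbook
stimulated-echo amplitude; FIDs are normalised so that a single proton
one-pulse FID would start at amplitude 1, hence a singlet moiety with
proton weight w yields a STEAM FID of initial amplitude w/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpinSystem",
    "AcquisitionScheme",
    "Spectrum",
    "BasisSet",
    "MacromoleculeModel",
    "simulate_steam_fid",
    "fid_to_spectrum",
    "build_basis_set",
    "WATER_TE_LIST_MS",
]

#: unsuppressed-water echo times (ms)
WATER_TE_LIST_MS: tuple[float, ...] = (5, 10, 20, 30, 50, 100, 200, 400, 800, 1500, 3000, 5000)

MAX_SPINS = 7


@dataclass(frozen=True)
class SpinSystem:
    """A metabolite moiety: proton shifts (ppm) and J-coupling matrix (Hz)."""

    name: str
    shifts: tuple[float, ...]
    j_matrix: np.ndarray
    moiety_of: str = ""
    proton_count_scale: float = 1.0

    def __post_init__(self):
        j = np.asarray(self.j_matrix, dtype=float)
        object.__setattr__(self, "j_matrix", j)
        n = len(self.shifts)
        if j.shape != (n, n):
            raise ValueError(f"{self.name}: j_matrix shape {j.shape} != ({n},{n})")
        if not np.allclose(j, j.T):
            raise ValueError(f"{self.name}: j_matrix must be symmetric")
        if np.any(np.diag(j) != 0):
            raise ValueError(f"{self.name}: j_matrix diagonal must be zero")
        if any(not (0.0 <= s <= 10.0) for s in self.shifts):
            raise ValueError(f"{self.name}: chemical shifts must lie in [0, 10] ppm")
        if self.proton_count_scale <= 0:
            raise ValueError("proton_count_scale must be positive")

    @property
    def n_spins(self) -> int:
        return len(self.shifts)


@dataclass(frozen=True)
class AcquisitionScheme:
    """STEAM acquisition parameters; defaults are the study's values."""

    te_list: tuple[float, ...] = (10, 20, 30, 40, 60, 80, 180)  # ms
    tm: float = 42.0  # ms
    tr: float = 4.5  # s
    sw: float = 6000.0  # Hz
    n_points: int = 6144
    f0: float = 169.0  # MHz
    carrier_ppm: float = 4.65

    def __post_init__(self):
        te = tuple(float(t) for t in self.te_list)
        object.__setattr__(self, "te_list", te)
        if len(te) == 0 or any(t <= 0 for t in te) or list(te) != sorted(te):
            raise ValueError("te_list must be strictly positive and sorted ascending")
        if self.n_points <= 0 or self.sw <= 0:
            raise ValueError("n_points and sw must be positive")

    @property
    def dwell(self) -> float:
        """Dwell time in seconds."""
        return 1.0 / self.sw

    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_points) * self.dwell

    def freq_axis_hz(self) -> np.ndarray:
        """Frequency axis (Hz, ascending) of the FFT-shifted spectrum."""
        return np.fft.fftshift(np.fft.fftfreq(self.n_points, d=self.dwell))

    def ppm_axis(self) -> np.ndarray:
        """ppm axis aligned with :meth:`freq_axis_hz` (ascending)."""
        return self.carrier_ppm + self.freq_axis_hz() / self.f0


@dataclass
class Spectrum:
    """A complex frequency-domain spectrum with its ppm/Hz axes."""

    values: np.ndarray
    ppm: np.ndarray
    hz: np.ndarray
    te: float | None = None
    linewidth: float | None = None
    scheme: AcquisitionScheme | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=complex)
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.hz = np.asarray(self.hz, dtype=float)
        if not (len(self.values) == len(self.ppm) == len(self.hz)):
            raise ValueError("values, ppm and hz must have equal length")

    def window(self, ppm_min: float, ppm_max: float) -> np.ndarray:
        """Boolean mask for bins with ppm_min <= ppm <= ppm_max."""
        return (self.ppm >= ppm_min) & (self.ppm <= ppm_max)


# ---------------------------------------------------------------------------
# spin operator machinery

def _spin_ops(n: int) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    sx = np.array([[0, 0.5], [0.5, 0]], dtype=complex)
    sy = np.array([[0, -0.5j], [0.5j, 0]], dtype=complex)
    sz = np.array([[0.5, 0], [0, -0.5]], dtype=complex)
    eye = np.eye(2, dtype=complex)
    ix, iy, iz = [], [], []
    for i in range(n):
        ox = oy = oz = np.array([[1.0 + 0j]])
        for k in range(n):
            a, b, c = (sx, sy, sz) if k == i else (eye, eye, eye)
            ox, oy, oz = np.kron(ox, a), np.kron(oy, b), np.kron(oz, c)
        ix.append(ox)
        iy.append(oy)
        iz.append(oz)
    return ix, iy, iz


def _hamiltonian(system: SpinSystem, scheme: AcquisitionScheme,
                 ops: tuple[list, list, list], weak_coupling: bool = False) -> np.ndarray:
    ix, iy, iz = ops
    n = system.n_spins
    h = np.zeros_like(ix[0])
    for i in range(n):
        omega = 2 * np.pi * (system.shifts[i] - scheme.carrier_ppm) * scheme.f0  # rad/s
        h = h + omega * iz[i]
    for i in range(n):
        for k in range(i + 1, n):
            j = system.j_matrix[i, k]
            if j != 0.0:
                if weak_coupling:
                    h = h + 2 * np.pi * j * (iz[i] @ iz[k])
                else:
                    h = h + 2 * np.pi * j * (ix[i] @ ix[k] + iy[i] @ iy[k] + iz[i] @ iz[k])
    return h


def _order_matrix(iz: list[np.ndarray]) -> np.ndarray:
    m = np.real(sum(np.diag(o) for o in iz))
    return m[:, None] - m[None, :]


def _evolve(rho: np.ndarray, evals: np.ndarray, vec: np.ndarray, t: float) -> np.ndarray:
    """Unitary free evolution exp(-iHt) rho exp(iHt) via the eigenbasis of H."""
    rt = vec.conj().T @ rho @ vec
    phase = np.exp(-1j * evals * t)
    rt = phase[:, None] * rt * phase.conj()[None, :]
    return vec @ rt @ vec.conj().T


def _acquire(rho: np.ndarray, evals: np.ndarray, vec: np.ndarray, detect: np.ndarray,
             t_ax: np.ndarray) -> np.ndarray:
    """s(t) = Tr(detect * rho(t)) expanded over eigen-transitions of H."""
    rt = vec.conj().T @ rho @ vec
    ot = vec.conj().T @ detect @ vec
    amp = (ot.T * rt).ravel()                         # O_rs * rho_sr
    freq = (evals[:, None] - evals[None, :]).ravel()  # rho_sr(t) ~ exp(-i(l_s-l_r)t)
    keep = np.abs(amp) > 1e-13 * max(1.0, np.abs(amp).max())
    amp, freq = amp[keep], freq[keep]
    return (amp[None, :] * np.exp(-1j * freq[None, :] * t_ax[:, None])).sum(axis=1)


def simulate_steam_fid(system: SpinSystem, scheme: AcquisitionScheme, te: float,
                       tm: float | None = None, weak_coupling: bool = False) -> np.ndarray:
    """Simulate the STEAM FID of one moiety at echo time ``te`` (ms).

    Returns a complex FID of length ``scheme.n_points`` sampled at
    ``1/scheme.sw`` starting at the stimulated-echo maximum.  Amplitude
    convention: a 1-proton singlet gives ``fid[0] == 0.5 *
    proton_count_scale`` (half the one-pulse signal).
    """
    if system.n_spins > MAX_SPINS:
        raise ValueError(
            f"{system.name}: {system.n_spins} spins exceeds the {MAX_SPINS}-spin cap; "
            "declare the system as split moieties"
        )
    if te <= 0:
        raise ValueError("te must be positive")
    tm_s = (scheme.tm if tm is None else tm) * 1e-3
    te2 = te * 1e-3 / 2.0

    n = system.n_spins
    ops = _spin_ops(n)
    ix, iy, iz = ops
    fz = sum(iz)
    fx = sum(ix)
    fplus = sum(ix[i] + 1j * iy[i] for i in range(n))
    order = _order_matrix(iz)

    h = _hamiltonian(system, scheme, ops, weak_coupling=weak_coupling)
    evals, vec = np.linalg.eigh(h)

    # instantaneous 90deg pulse about x
    px_evals, px_vec = np.linalg.eigh(fx)
    p90 = px_vec @ np.diag(np.exp(-1j * (np.pi / 2) * px_evals)) @ px_vec.conj().T

    rho = fz.astype(complex)
    rho = p90 @ rho @ p90.conj().T
    rho = np.where(np.isclose(order, 1.0), rho, 0.0)       # select p = +1
    rho = _evolve(rho, evals, vec, te2)
    rho = p90 @ rho @ p90.conj().T
    rho = np.where(np.isclose(order, 0.0), rho, 0.0)       # populations + ZQ during TM
    rho = _evolve(rho, evals, vec, tm_s)
    rho = p90 @ rho @ p90.conj().T
    rho = np.where(np.isclose(order, -1.0), rho, 0.0)      # echo pathway
    rho = _evolve(rho, evals, vec, te2)

    fid = _acquire(rho, evals, vec, fplus, scheme.time_axis())
    # one-pulse trace normalisation (2**(n-2) per proton) and zero-order phase so the
    # echo-top signal of a singlet is real positive (absorption-mode real spectra)
    return -1j * fid / 2.0 ** (n - 2) * system.proton_count_scale


def one_pulse_fid(system: SpinSystem, scheme: AcquisitionScheme) -> np.ndarray:
    """Reference pulse-acquire FID with the same normalisation convention."""
    n = system.n_spins
    ops = _spin_ops(n)
    ix, iy, iz = ops
    fz, fx = sum(iz), sum(ix)
    fplus = sum(ix[i] + 1j * iy[i] for i in range(n))
    h = _hamiltonian(system, scheme, ops)
    evals, vec = np.linalg.eigh(h)
    px_evals, px_vec = np.linalg.eigh(fx)
    p90 = px_vec @ np.diag(np.exp(-1j * (np.pi / 2) * px_evals)) @ px_vec.conj().T
    rho = p90 @ fz.astype(complex) @ p90.conj().T
    fid = _acquire(rho, evals, vec, fplus, scheme.time_axis())
    return 1j * fid / 2.0 ** (n - 2) * system.proton_count_scale


def fid_to_spectrum(fid: np.ndarray, scheme: AcquisitionScheme, linewidth: float = 0.0,
                    te: float | None = None) -> Spectrum:
    """Apodise (Lorentzian FWHM ``linewidth`` Hz), FFT, attach ppm/Hz axes."""
    if linewidth < 0:
        raise ValueError("linewidth must be >= 0")
    fid = np.asarray(fid, dtype=complex)
    if len(fid) != scheme.n_points:
        raise ValueError("fid length does not match scheme.n_points")
    t_ax = scheme.time_axis()
    apod = np.exp(-np.pi * linewidth * t_ax)
    vals = np.fft.fftshift(np.fft.fft(fid * apod))
    return Spectrum(values=vals, ppm=scheme.ppm_axis(), hz=scheme.freq_axis_hz(),
                    te=te, linewidth=linewidth, scheme=scheme)


# ---------------------------------------------------------------------------
# macromolecule background

@dataclass(frozen=True)
class MacromoleculeModel:
    """Broad Gaussian humps with one fast common T2 (default 25 ms).

    Emulates the short-T2 macromolecule background underlying the
    metabolite spectrum; positions follow the conventional M0.92 ...
    M3.75 resonance nomenclature.
    """

    ppm_positions: tuple[float, ...] = (0.92, 1.21, 1.43, 1.67, 2.08, 2.25, 3.00, 3.21, 3.75)
    amplitudes: tuple[float, ...] = (1.0, 1.2, 0.9, 0.7, 1.3, 1.0, 0.7, 0.5, 0.6)
    fwhm_hz: float = 40.0
    t2_mm: float = 25.0  # ms
    scale: float = 60.0

    def spectrum(self, scheme: AcquisitionScheme, te: float) -> Spectrum:
        ppm = scheme.ppm_axis()
        sigma_ppm = self.fwhm_hz / scheme.f0 / (2 * np.sqrt(2 * np.log(2)))
        vals = np.zeros_like(ppm)
        for pos, amp in zip(self.ppm_positions, self.amplitudes):
            vals += amp * np.exp(-((ppm - pos) ** 2) / (2 * sigma_ppm**2))
        vals = vals * self.scale * np.exp(-te / self.t2_mm)
        return Spectrum(values=vals.astype(complex), ppm=ppm, hz=scheme.freq_axis_hz(),
                        te=te, linewidth=self.fwhm_hz, scheme=scheme)


# ---------------------------------------------------------------------------
# basis set

@dataclass
class BasisSet:
    """Per-moiety, per-TE basis spectra plus the optional MM component."""

    entries: dict[str, dict[float, Spectrum]]
    scheme: AcquisitionScheme
    linewidth: float
    mm: dict[float, Spectrum] = field(default_factory=dict)
    moiety_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, per_te in self.entries.items():
            missing = [te for te in self.scheme.te_list if te not in per_te]
            if missing:
                raise ValueError(f"basis entry {name!r} missing TEs {missing}")

    @property
    def moiety_names(self) -> list[str]:
        return list(self.entries)

    def at_te(self, te: float) -> dict[str, Spectrum]:
        out = {name: per_te[te] for name, per_te in self.entries.items()}
        if te in self.mm:
            out["MM"] = self.mm[te]
        return out


def build_basis_set(moieties: list[SpinSystem], scheme: AcquisitionScheme,
                    linewidth: float = 12.0,
                    mm_model: MacromoleculeModel | None = MacromoleculeModel(),
                    mm_negligible_te: tuple[float, ...] = (180.0,)) -> BasisSet:
    """Simulate every moiety at every TE of ``scheme`` and assemble a basis.

    The macromolecule component is attached at every TE except those in
    ``mm_negligible_te`` (by default 180 ms, where its fast decay makes
    it unobservable).
    """
    if not moieties:
        raise ValueError("moieties must be non-empty")
    names = [m.name for m in moieties]
    if len(set(names)) != len(names):
        raise ValueError("duplicate moiety names in basis")
    entries: dict[str, dict[float, Spectrum]] = {}
    for system in moieties:
        per_te = {}
        for te in scheme.te_list:
            fid = simulate_steam_fid(system, scheme, te)
            per_te[te] = fid_to_spectrum(fid, scheme, linewidth=linewidth, te=te)
        entries[system.name] = per_te
    mm = {}
    if mm_model is not None:
        for te in scheme.te_list:
            if te not in mm_negligible_te:
                mm[te] = mm_model.spectrum(scheme, te)
    return BasisSet(entries=entries, scheme=scheme, linewidth=linewidth, mm=mm,
                    moiety_of={m.name: (m.moiety_of or m.name) for m in moieties})
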