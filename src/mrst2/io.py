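"""HDF5 containers and tidy-CSV interchange for pipeline artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .cohort import SpectrumSeries, SubjectRecord, WaterSeries
from .spin_sim import AcquisitionScheme, BasisSet, Spectrum

__all__ = [
    "save_basis",
    "load_basis",
    "write_basis_sidecars",
    "save_subject",
    "load_subject",
    "cohort_manifest",
]


def _scheme_attrs(grp: h5py.Group, scheme: AcquisitionScheme) -> None:
    grp.attrs["te_list"] = np.asarray(scheme.te_list)
    for key in ("tm", "tr", "sw", "n_points", "f0", "carrier_ppm"):
        grp.attrs[key] = getattr(scheme, key)


def _scheme_from_attrs(attrs) -> AcquisitionScheme:
    return AcquisitionScheme(
        te_list=tuple(attrs["te_list"]), tm=float(attrs["tm"]), tr=float(attrs["tr"]),
        sw=float(attrs["sw"]), n_points=int(attrs["n_points"]), f0=float(attrs["f0"]),
        carrier_ppm=float(attrs["carrier_ppm"]))


def save_basis(basis: BasisSet, path: str | Path) -> None:
    """Write a basis set to one hierarchical HDF5 container."""
    with h5py.File(path, "w") as f:
        _scheme_attrs(f, basis.scheme)
        f.attrs["linewidth"] = basis.linewidth
        for name, per_te in basis.entries.items():
            g = f.create_group(f"entries/{name}")
            g.attrs["moiety_of"] = basis.moiety_of.get(name, name)
            for te, spec in per_te.items():
                g.create_dataset(f"te_{te:g}", data=spec.values)
        for te, spec in basis.mm.items():
            f.create_dataset(f"mm/te_{te:g}", data=spec.values)


def load_basis(path: str | Path) -> BasisSet:
    with h5py.File(path, "r") as f:
        scheme = _scheme_from_attrs(f.attrs)
        linewidth = float(f.attrs["linewidth"])
        ppm, hz = scheme.ppm_axis(), scheme.freq_axis_hz()

        def spec(ds, te):
            return Spectrum(values=ds[()], ppm=ppm, hz=hz, te=te,
                            linewidth=linewidth, scheme=scheme)

        entries, moiety_of = {}, {}
        for name, g in f["entries"].items():
            moiety_of[name] = g.attrs["moiety_of"]
            entries[name] = {float(k[3:]): spec(d, float(k[3:])) for k, d in g.items()}
        mm = {}
        if "mm" in f:
            mm = {float(k[3:]): spec(d, float(k[3:])) for k, d in f["mm"].items()}
    return BasisSet(entries=entries, scheme=scheme, linewidth=linewidth, mm=mm,
                    moiety_of=moiety_of)


def write_basis_sidecars(basis: BasisSet, out_dir: str | Path) -> list[Path]:
    """Per-TE JSON sidecars describing the basis content."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for te in basis.scheme.te_list:
        meta = dict(te_ms=te, linewidth_hz=basis.linewidth,
                    moieties=sorted(basis.entries),
                    mm_included=te in basis.mm,
                    sw_hz=basis.scheme.sw, n_points=basis.scheme.n_points,
                    f0_mhz=basis.scheme.f0, carrier_ppm=basis.scheme.carrier_ppm)
        p = out_dir / f"basis_te{te:g}.json"
        p.write_text(json.dumps(meta, indent=2, sort_keys=True))
        paths.append(p)
    return paths


def save_subject(series: SpectrumSeries, water: WaterSeries, record: SubjectRecord,
                 path: str | Path) -> None:
    """One container per subject: metabolite spectra, water integrals, truth."""
    with h5py.File(path, "w") as f:
        _scheme_attrs(f, series.scheme)
        f.attrs["subject_id"] = record.subject_id
        f.attrs["group"] = record.group
        f.attrs["seed"] = record.seed
        f.attrs["true_csf_fraction"] = record.true_csf_fraction
        f.attrs["true_water_t2_tissue"] = record.true_water_t2_tissue
        tg = f.create_group("true_t2")
        for k, v in record.true_t2.items():
            tg.attrs[k] = v
        for te, spec in series.spectra.items():
            f.create_dataset(f"spectra/te_{te:g}", data=spec.values)
        f.create_dataset("water/te_ms", data=water.te_ms)
        f.create_dataset("water/integrals", data=water.integrals)


def load_subject(path: str | Path) -> tuple[SpectrumSeries, WaterSeries, SubjectRecord]:
    with h5py.File(path, "r") as f:
        scheme = _scheme_from_attrs(f.attrs)
        ppm, hz = scheme.ppm_axis(), scheme.freq_axis_hz()
        record = SubjectRecord(
            subject_id=str(f.attrs["subject_id"]), group=str(f.attrs["group"]),
            true_t2={k: float(v) for k, v in f["true_t2"].attrs.items()},
            true_csf_fraction=float(f.attrs["true_csf_fraction"]),
            true_water_t2_tissue=float(f.attrs["true_water_t2_tissue"]),
            seed=int(f.attrs["seed"]))
        spectra = {}
        for k, d in f["spectra"].items():
            te = float(k[3:])
            spectra[te] = Spectrum(values=d[()], ppm=ppm, hz=hz, te=te, scheme=scheme)
        water = WaterSeries(te_ms=f["water/te_ms"][()], integrals=f["water/integrals"][()],
                            subject_id=record.subject_id)
    series = SpectrumSeries(spectra=spectra, scheme=scheme, kind="metabolite",
                            subject_id=record.subject_id)
    return series, water, record


def cohort_manifest(records: list[SubjectRecord]) -> pd.DataFrame:
    """Tidy manifest of the generated cohort truth."""
    rows = []
    for r in records:
        row = dict(subject_id=r.subject_id, group=r.group, seed=r.seed,
                   true_csf_fraction=r.true_csf_fraction,
                   true_water_t2_tissue=r.true_water_t2_tissue)
        row.update({f"true_t2_{k}": v for k, v in r.true_t2.items()})
        rows.append(row)
    return pd.DataFrame(rows)
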