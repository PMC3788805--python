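"""End-to-end orchestration: simulate -> fit -> relaxometry -> stats -> MC.

One :func:`run_pipeline` call executes, under a single master seed:

1. STEAM basis simulation at the seven echo times;
2. synthetic cohort generation (metabolite spectra + water series);
3. per-TE linear-combination fitting with CRLB quality control;
4. per-subject mono-exponential metabolite T2 and biexponential
   tissue-water/CSF fits;
5. cohort summaries with Wilcoxon rank-sum tests;
6. the Monte Carlo TE-scheme assessment, with noise bounds taken from
   the maximum fractional T2-fit residual per compound and group.

Every stage output is a tidy DataFrame; with an output directory the
bundle is persisted as CSVs plus a JSON manifest (config hash, seed,
version) that makes the run reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (CohortConfig, SubjectRecord, default_moieties, sample_cohort,
                     synthesize_metabolite_series, synthesize_water_series)
from .group_stats import summarize_cohorts
from .lcfit import FitWindow, fit_series, qc_filter
from .monte_carlo import (EXTENSION_TES, TEScheme, compare_te_schemes,
                          extended_scheme)
from .relaxometry import (BiexponentialWaterModel, FitFailure, MonoExponentialT2)
from .spin_sim import AcquisitionScheme, build_basis_set

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("mrst2")

#: compounds carried into relaxometry when they pass quality control
T2_TARGET_COMPOUNDS = ("NAA", "tCr", "tCho")
WATER_LABEL = "tissue water"


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    scheme: AcquisitionScheme = field(default_factory=AcquisitionScheme)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    window: FitWindow = field(default_factory=FitWindow)
    linewidth: float = 12.0
    crlb_threshold_pct: float = 30.0
    mc_n_iter: int = 500
    mc_extensions: tuple[float, ...] = EXTENSION_TES
    run_monte_carlo: bool = True
    master_seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        # the master seed governs every stage
        self.cohort = dataclasses.replace(self.cohort, master_seed=self.master_seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "scheme" in raw:
            kwargs["scheme"] = AcquisitionScheme(**raw["scheme"])
        if "cohort" in raw:
            kwargs["cohort"] = CohortConfig(**raw["cohort"])
        if "window" in raw:
            kwargs["window"] = FitWindow(**raw["window"])
        for key in ("linewidth", "crlb_threshold_pct", "mc_n_iter", "run_monte_carlo",
                    "master_seed", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        if "mc_extensions" in raw:
            kwargs["mc_extensions"] = tuple(raw["mc_extensions"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.floating, np.integer)):
                return float(o)
            raise TypeError(type(o))
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    manifest: dict
    cohort_truth: pd.DataFrame
    amplitudes: pd.DataFrame
    fits: pd.DataFrame
    summary: pd.DataFrame
    mc_results: pd.DataFrame
    mc_comparisons: pd.DataFrame
    noise_bounds: pd.DataFrame


def _fit_subject_t2(subject: SubjectRecord, amp, retained) -> list[dict]:
    rows = []
    for compound in T2_TARGET_COMPOUNDS:
        if compound not in retained:
            log.info("subject %s: %s failed CRLB gate, excluded", subject.subject_id, compound)
            continue
        te, a = amp.amplitudes(compound)
        try:
            fit = MonoExponentialT2().fit(te, a)
        except FitFailure:
            log.warning("subject %s: %s T2 fit failed, excluded", subject.subject_id, compound)
            continue
        rows.append(dict(subject=subject.subject_id, group=subject.group,
                         compound=compound, s0=fit.s0_, t2=fit.t2_,
                         r_squared=fit.r_squared_,
                         max_frac_residual=float(np.max(np.abs(fit.residuals_)) / fit.s0_),
                         true_t2=subject.true_t2.get(compound, np.nan)))
    return rows


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None,
                 basis=None) -> PipelineResult:
    """Execute all stages; optionally persist the bundle under ``out_dir``.

    A pre-simulated ``basis`` (matching ``config.scheme``) may be passed
    to skip the basis stage; the basis is deterministic, so this does
    not affect the results.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    from .io import cohort_manifest  # local import to avoid cycle at module load

    if basis is None:
        log.info("stage basis: simulating %d-TE STEAM basis", len(config.scheme.te_list))
        basis = build_basis_set(default_moieties(), config.scheme,
                                linewidth=config.linewidth)

    log.info("stage cohort: sampling %d + %d subjects (seed %d)",
             config.cohort.young.n, config.cohort.elderly.n, config.master_seed)
    records = sample_cohort(config.cohort)
    truth = cohort_manifest(records)

    amp_frames, fit_rows = [], []
    for subject in records:
        series = synthesize_metabolite_series(subject, basis, config.cohort)
        amp = fit_series(series.spectra, basis, config.window,
                         subject_id=subject.subject_id)
        retained = qc_filter(amp, config.crlb_threshold_pct)
        log.info("subject %s: retained %s", subject.subject_id, ",".join(retained))
        frame = amp.frame.copy()
        frame.insert(0, "subject", subject.subject_id)
        frame.insert(1, "group", subject.group)
        amp_frames.append(frame)
        fit_rows.extend(_fit_subject_t2(subject, amp, retained))

        water = synthesize_water_series(subject, config.cohort)
        wfit = BiexponentialWaterModel(t2_csf=config.cohort.t2_csf_fixed).fit(
            water.te_ms, water.integrals)
        fit_rows.append(dict(subject=subject.subject_id, group=subject.group,
                             compound=WATER_LABEL, s0=wfit.s0_, t2=wfit.t2_tissue_,
                             r_squared=wfit.r_squared_,
                             max_frac_residual=float(
                                 np.max(np.abs(wfit.residuals_)) / wfit.s0_),
                             f_csf=wfit.f_csf_,
                             true_t2=subject.true_water_t2_tissue,
                             true_f_csf=subject.true_csf_fraction))

    amplitudes = pd.concat(amp_frames, ignore_index=True)
    fits = pd.DataFrame(fit_rows)
    summary = summarize_cohorts(fits)

    noise_bounds = (fits[fits["compound"] != WATER_LABEL]
                    .groupby(["compound", "group"])["max_frac_residual"].max()
                    .reset_index(name="noise_bound"))

    mc_results = pd.DataFrame()
    mc_comparisons = pd.DataFrame()
    if config.run_monte_carlo:
        mc_results, mc_comparisons = _run_monte_carlo(config, summary, noise_bounds)

    manifest = dict(version=__version__, master_seed=config.master_seed,
                    config_hash=config.config_hash(),
                    n_young=config.cohort.young.n, n_elderly=config.cohort.elderly.n)
    result = PipelineResult(manifest=manifest, cohort_truth=truth, amplitudes=amplitudes,
                            fits=fits, summary=summary, mc_results=mc_results,
                            mc_comparisons=mc_comparisons, noise_bounds=noise_bounds)
    if out_dir is not None:
        _persist(result, Path(out_dir))
    return result


def _run_monte_carlo(config: RunConfig, summary: pd.DataFrame,
                     noise_bounds: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    base = TEScheme(config.scheme.te_list, label="base7")
    schemes = [base] + [extended_scheme((t,), base) for t in config.mc_extensions]
    if len(config.mc_extensions) > 1:
        schemes.append(extended_scheme(tuple(config.mc_extensions), base))
    res_rows, cmp_frames = [], []
    mc_seed_root = np.random.SeedSequence([config.master_seed, 777])
    seeds = mc_seed_root.generate_state(len(noise_bounds) * 2)
    for i, rec in enumerate(noise_bounds.itertuples(index=False)):
        row = summary[summary["compound"] == rec.compound]
        if row.empty:
            continue
        true_t2 = float(row[f"{rec.group}_mean"].iloc[0])
        bound = float(min(max(rec.noise_bound, 1e-3), 0.5))
        log.info("stage MC: %s/%s T2=%.1f ms bound=%.3f", rec.compound, rec.group,
                 true_t2, bound)
        results, cmps = compare_te_schemes(true_t2, schemes, bound,
                                           n_iter=config.mc_n_iter,
                                           seed=int(seeds[i] % 2**31))
        for r in results:
            res_rows.append(dict(compound=rec.compound, group=rec.group,
                                 scheme=r.scheme.label, true_t2=r.true_t2,
                                 n_iter=r.n_iter, mean_t2=r.mean_t2, sd_t2=r.sd_t2,
                                 bias=r.bias, n_failed=r.n_failed))
        cmps.insert(0, "compound", rec.compound)
        cmps.insert(1, "group", rec.group)
        cmp_frames.append(cmps)
    return (pd.DataFrame(res_rows),
            pd.concat(cmp_frames, ignore_index=True) if cmp_frames else pd.DataFrame())


def _persist(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.cohort_truth.to_csv(out_dir / "cohort_truth.csv", index=False)
    result.amplitudes.to_csv(out_dir / "amplitudes.csv", index=False)
    result.fits.to_csv(out_dir / "t2_fits.csv", index=False)
    result.summary.to_csv(out_dir / "summary.csv", index=False)
    result.noise_bounds.to_csv(out_dir / "mc_noise_bounds.csv", index=False)
    if not result.mc_results.empty:
        result.mc_results.to_csv(out_dir / "mc_results.csv", index=False)
        result.mc_comparisons.to_csv(out_dir / "mc_comparisons.csv", index=False)
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=2,
                                                      sort_keys=True))
    log.info("result bundle written to %s", out_dir)
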