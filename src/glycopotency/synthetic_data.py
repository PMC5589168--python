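"""Synthetic inputs for exercising the pipeline end to end without external
data: glycopeptide peak lists with prescribed per-site species distributions,
and parallel-line assay datasets with a prescribed true relative potency.

All generators are deterministic given (config, seed); ground truth is
emitted alongside so every downstream stage can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bioassay_potency import AssayData
from .glycan_model import GlycanComposition, parse_glycan_name
from .ms_mapping import (
    GLYCOSITES,
    PeakList,
    Scan,
    SitePeptide,
    default_site_peptides,
    theoretical_mz,
)

__all__ = [
    "MSSimulationConfig",
    "AssaySimulationConfig",
    "simulate_peaklist",
    "simulate_assay",
    "DEFAULT_SITE_DISTRIBUTIONS",
]

#: Plausible per-site target distributions for demos and round-trip tests
#: (compositional shorthand species; percentages sum to 100 per site).
DEFAULT_SITE_DISTRIBUTIONS: dict[str, dict[str, float]] = {
    "alpha_Asn52": {
        "A2G2S1": 2.6, "A2G2S2": 81.8, "FA2G2S2": 2.2,
        "A3G3S2": 2.2, "A3G3S3": 10.3, "A4G4S3": 0.9,
    },
    "alpha_Asn78": {
        "A2G2S1": 28.0, "A2G2S2": 58.0, "A3G3S2": 7.0,
        "A3G3S3": 6.6, "A4G4S3": 0.4,
    },
    "beta_Asn7": {
        "FA2G2S2": 4.0, "FA3G3S2": 20.0, "FA3G3S3": 21.0,
        "FA4G4S3": 39.0, "FA4G4S3Lac1": 15.0, "FA4G4S4Lac2": 1.0,
    },
    "beta_Asn24": {
        "FA2G2S1": 12.0, "FA2G2S2": 59.0, "FA3G3S2": 15.0,
        "FA3G3S3": 13.0, "FA4G4S3": 1.0,
    },
}


@dataclass
class MSSimulationConfig:
    """Configuration of the glycopeptide peak-list generator."""

    site_distributions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            site: dict(entries) for site, entries in DEFAULT_SITE_DISTRIBUTIONS.items()
        }
    )
    peptides: Mapping[str, SitePeptide] | None = None  # default: chymotryptic sequon peptides
    charges: Sequence[int] = (2, 3, 4)
    intensity_scale: float = 1e5
    noise_sigma: float = 0.1  # log-normal multiplicative sd on ion counts
    decoy_rate: float = 0.0  # expected decoy peaks per scan
    mz_jitter_ppm: float = 0.0
    n_scans: int = 5
    rt_start: float = 10.0
    rt_step: float = 0.5
    scan_range: tuple[float, float] = (100.0, 2000.0)
    tolerance_ppm: float = 10.0  # decoys are kept > 3× this from any candidate
    seed: int = 0

    def __post_init__(self) -> None:
        for site, entries in self.site_distributions.items():
            if site not in GLYCOSITES:
                raise ValueError(f"unknown site {site!r}")
            if any(v < 0 for v in entries.values()):
                raise ValueError(f"negative percentage in {site} distribution")
            total = sum(entries.values())
            if abs(total - 100.0) > 0.5:
                raise ValueError(
                    f"{site} target distribution sums to {total:.2f}, expected 100"
                )
            for name in entries:
                parse_glycan_name(name)
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be ≥ 0")
        if self.decoy_rate < 0:
            raise ValueError("decoy_rate must be ≥ 0")


def _resolve_peptides(cfg: MSSimulationConfig) -> dict[str, SitePeptide]:
    if cfg.peptides is not None:
        return dict(cfg.peptides)
    return {site: peps[0] for site, peps in default_site_peptides().items()}


def simulate_peaklist(cfg: MSSimulationConfig) -> tuple[PeakList, pd.DataFrame]:
    """Generate a peak list plus a ground-truth table.

    For every site/species/charge whose theoretical m/z lies inside the scan
    range, peaks are emitted across ``n_scans`` scans with total intensity
    proportional to the species' target percentage, perturbed by
    multiplicative log-normal noise (σ = ``noise_sigma``) per scan and a
    Gaussian m/z jitter of ``mz_jitter_ppm``.  Decoy peaks are drawn at
    least 3× the matching tolerance away from every candidate m/z.

    Returns the peak list and a DataFrame with columns site_id, peptide,
    glycan, charge, mz, target_percent, true_ion_count.
    """
    rng = np.random.default_rng(cfg.seed)
    peptides = _resolve_peptides(cfg)
    lo, hi = cfg.scan_range

    # Candidate m/z grid and per-(site, species, charge) total intensities.
    truth_rows = []
    channels = []  # (mz per-scan centre, per-scan intensities)
    candidate_mzs = []
    for site in GLYCOSITES:
        if site not in cfg.site_distributions:
            continue
        peptide = peptides[site]
        for name, pct in cfg.site_distributions[site].items():
            glycan = parse_glycan_name(name)
            in_range = [
                z for z in cfg.charges
                if lo <= theoretical_mz(peptide, glycan, z) <= hi
            ]
            if not in_range:
                raise ValueError(
                    f"species {name} at {site} has no charge state inside the "
                    f"scan range {cfg.scan_range}; widen charges or range"
                )
            share = cfg.intensity_scale * pct / 100.0 / len(in_range)
            for z in in_range:
                mz = theoretical_mz(peptide, glycan, z)
                candidate_mzs.append(mz)
                if cfg.noise_sigma > 0:
                    factors = rng.lognormal(0.0, cfg.noise_sigma, cfg.n_scans)
                else:
                    factors = np.ones(cfg.n_scans)
                per_scan = share / cfg.n_scans * factors
                channels.append((mz, per_scan))
                truth_rows.append(
                    {
                        "site_id": site,
                        "peptide": peptide.sequence,
                        "glycan": glycan.canonical_name,
                        "charge": z,
                        "mz": mz,
                        "target_percent": pct,
                        "true_ion_count": float(per_scan.sum()),
                    }
                )

    candidate_arr = np.array(sorted(candidate_mzs))
    guard = 3.0 * cfg.tolerance_ppm  # ppm distance decoys must keep

    scans = []
    for i in range(cfg.n_scans):
        rt = cfg.rt_start + i * cfg.rt_step
        mzs, intens = [], []
        for mz, per_scan in channels:
            jitter = (
                rng.normal(0.0, cfg.mz_jitter_ppm * 1e-6 * mz)
                if cfg.mz_jitter_ppm > 0 else 0.0
            )
            mzs.append(mz + jitter)
            intens.append(per_scan[i])
        n_decoys = rng.poisson(cfg.decoy_rate) if cfg.decoy_rate > 0 else 0
        for _ in range(n_decoys):
            for _attempt in range(1000):
                decoy = rng.uniform(lo, hi)
                ppm_dist = np.abs(decoy - candidate_arr) / candidate_arr * 1e6
                if ppm_dist.min() > guard:
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError("could not place a decoy away from candidates")
            mzs.append(decoy)
            intens.append(rng.uniform(0.001, 0.05) * cfg.intensity_scale)
        order = np.argsort(mzs)
        scans.append(
            Scan(rt, np.asarray(mzs)[order], np.asarray(intens)[order])
        )

    peaklist = PeakList(scans=scans, scan_range=cfg.scan_range)
    return peaklist, pd.DataFrame(truth_rows)


@dataclass
class AssaySimulationConfig:
    """Configuration of the parallel-line assay generator.

    Defaults follow the compendial design used in practice — three
    geometric doses (2/4/8 IU) on five animals each — with response
    parameters tuned so batch CVs land in a realistic 5–9% range.
    """

    true_relative_potency: float = 1.0
    intercept: float = 50.0  # mg at ln(dose) = 0
    slope: float = 30.0  # mg per unit ln-dose
    residual_sd: float = 7.0
    doses: Sequence[float] = (2.0, 4.0, 8.0)
    rats_per_dose: int = 5
    n_assays: int = 1
    assumed_potency: float = 147.5
    standard_label: str = "standard"
    test_label: str = "test"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_relative_potency <= 0:
            raise ValueError("true relative potency must be positive")
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be positive")
        if self.rats_per_dose < 1:
            raise ValueError("rats_per_dose must be ≥ 1")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be ≥ 0")


def simulate_assay(cfg: AssaySimulationConfig) -> list[AssayData]:
    """Generate ``n_assays`` parallel-line datasets.

    Responses follow ``y = intercept + slope·ln(dose·ρ_prep) + N(0, sd)``
    with ρ = 1 for the standard and ρ = ``true_relative_potency`` for the
    test preparation.
    """
    rng = np.random.default_rng(cfg.seed)
    out = []
    preps = ((cfg.standard_label, 1.0), (cfg.test_label, cfg.true_relative_potency))
    for assay_idx in range(cfg.n_assays):
        rows = []
        for prep, rho in preps:
            for dose in cfg.doses:
                mean = cfg.intercept + cfg.slope * np.log(dose * rho)
                noise = (
                    rng.normal(0.0, cfg.residual_sd, cfg.rats_per_dose)
                    if cfg.residual_sd > 0 else np.zeros(cfg.rats_per_dose)
                )
                for rat, eps in enumerate(noise, start=1):
                    rows.append(
                        {
                            "assay_id": assay_idx + 1,
                            "preparation": prep,
                            "dose_iu": dose,
                            "animal_id": f"a{assay_idx + 1}-{prep}-{dose:g}-{rat}",
                            "response_mg": mean + eps,
                        }
                    )
        out.append(
            AssayData(
                records=pd.DataFrame(rows),
                standard=cfg.standard_label,
                assumed_potency=cfg.assumed_potency,
            )
        )
    return out
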