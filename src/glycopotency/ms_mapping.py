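"""Glycopeptide enumeration, ion matching, XIC integration and site quantitation.

The workflow mirrors a site-specific glycopeptide mapping experiment: digest
the subunit sequences in silico, enumerate (peptide, glycan, charge)
candidates, match them against an observed peak list within a ppm tolerance,
integrate extracted-ion-chromatogram (XIC) ion counts, and normalise per
glycosite into a relative distribution.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .glycan_model import (
    MONOISOTOPIC,
    GlycanComposition,
    MonosaccharideMassTable,
    parse_glycan_name,
)

__all__ = [
    "GLYCOSITES",
    "ALPHA_SUBUNIT",
    "BETA_SUBUNIT",
    "SitePeptide",
    "Scan",
    "PeakList",
    "GlycopeptideAssignment",
    "GlycanDistribution",
    "QuantificationError",
    "peptide_monoisotopic_mass",
    "chymotryptic_digest",
    "default_site_peptides",
    "theoretical_mz",
    "match_ions",
    "extract_xic",
    "quantify_site",
    "assignments_to_csv",
    "assignments_from_csv",
    "candidates_from_csv",
]

logger = logging.getLogger(__name__)

#: Canonical glycosite labels: (subunit sequence attribute, 1-based position).
GLYCOSITES = ("alpha_Asn52", "alpha_Asn78", "beta_Asn7", "beta_Asn24")

# Mature follitropin subunit sequences (92 aa alpha, 111 aa beta).
ALPHA_SUBUNIT = (
    "APDVQDCPECTLQENPFFSQPGAPILQCMGCCFSRAYPTPLRSKKTMLVQKNVTSESTCCVAKSYNRVTVMGGFKVENHTACHCSTCYYHKS"
)
BETA_SUBUNIT = (
    "NSCELTNITIAIEKEECRFCISINTTWCAGYCYTRDLVYKDPARPKIQKTCTFKELVYETVRVPGCAHHADSLYTYPVATQCHCGKCDSDSTDCTVRGLGPSYCSFGEMKE"
)

_SITE_POSITIONS = {
    "alpha_Asn52": (ALPHA_SUBUNIT, 52),
    "alpha_Asn78": (ALPHA_SUBUNIT, 78),
    "beta_Asn7": (BETA_SUBUNIT, 7),
    "beta_Asn24": (BETA_SUBUNIT, 24),
}

# Monoisotopic amino-acid residue masses, Da.
AMINO_ACID_MASSES = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

#: Carbamidomethylation of cysteine (iodoacetamide alkylation), fixed by default.
CARBAMIDOMETHYL = 57.02146

_SEQUON_RE = re.compile(r"N[^P][ST]")


class QuantificationError(ValueError):
    """Raised when a site has no quantifiable ion counts."""


def peptide_monoisotopic_mass(
    sequence: str,
    cam_cys: bool = True,
    table: MonosaccharideMassTable = MONOISOTOPIC,
) -> float:
    """Monoisotopic neutral mass of a peptide (residues + water).

    ``cam_cys`` applies fixed carbamidomethylation to every cysteine, matching
    an iodoacetamide-alkylated digest.
    """
    mass = table.water
    for i, residue in enumerate(sequence):
        try:
            mass += AMINO_ACID_MASSES[residue]
        except KeyError:
            raise ValueError(
                f"unknown residue {residue!r} at position {i + 1}"
            ) from None
        if cam_cys and residue == "C":
            mass += CARBAMIDOMETHYL
    return mass


@dataclass(frozen=True)
class SitePeptide:
    """A backbone peptide carrying exactly one N-glycosylation sequon."""

    site_id: str
    sequence: str
    glycosite_position: int  # 1-based index within sequence
    backbone_mass: float

    def __post_init__(self) -> None:
        if self.site_id not in GLYCOSITES:
            raise ValueError(f"unknown site_id {self.site_id!r}; expected one of {GLYCOSITES}")
        if self.backbone_mass <= 0:
            raise ValueError("backbone_mass must be positive")
        sequons = [m.start() + 1 for m in _SEQUON_RE.finditer(self.sequence)]
        if self.glycosite_position not in sequons:
            raise ValueError(
                f"sequence {self.sequence!r} has no N-X-S/T sequon starting at "
                f"position {self.glycosite_position} (sequons at {sequons})"
            )
        if len(sequons) != 1:
            raise ValueError(
                f"sequence {self.sequence!r} must contain exactly one sequon, "
                f"found {len(sequons)}"
            )

    @classmethod
    def from_sequence(
        cls, site_id: str, sequence: str, glycosite_position: int, cam_cys: bool = True
    ) -> "SitePeptide":
        return cls(
            site_id=site_id,
            sequence=sequence,
            glycosite_position=glycosite_position,
            backbone_mass=peptide_monoisotopic_mass(sequence, cam_cys=cam_cys),
        )


@dataclass(frozen=True)
class Scan:
    retention_time: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz", np.asarray(self.mz, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have the same length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class PeakList:
    """Centroided peaks grouped by scan, ordered by retention time."""

    scans: list[Scan] = field(default_factory=list)
    scan_range: tuple[float, float] = (100.0, 2000.0)

    def __post_init__(self) -> None:
        rts = [s.retention_time for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("scan retention times must be non-decreasing")
        lo, hi = self.scan_range
        for scan in self.scans:
            if scan.mz.size and (scan.mz.min() < lo or scan.mz.max() > hi):
                raise ValueError(
                    f"peak m/z outside configured scan range {self.scan_range}"
                )

    def __len__(self) -> int:
        return len(self.scans)

    @property
    def n_peaks(self) -> int:
        return int(sum(s.mz.size for s in self.scans))

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(["rt_min", "mz", "intensity"])
            for scan in self.scans:
                for mz, inten in zip(scan.mz, scan.intensity):
                    writer.writerow([f"{scan.retention_time:.4f}", f"{mz:.6f}", f"{inten:.4f}"])

    @classmethod
    def from_csv(cls, path, scan_range: tuple[float, float] = (100.0, 2000.0)) -> "PeakList":
        """Read a peak-list CSV with columns rt_min, mz, intensity."""
        by_rt: dict[float, list[tuple[float, float]]] = {}
        with open(path, newline="") as handle:
            for row in csv.DictReader(handle):
                by_rt.setdefault(float(row["rt_min"]), []).append(
                    (float(row["mz"]), float(row["intensity"]))
                )
        scans = [
            Scan(rt, np.array([p[0] for p in peaks]), np.array([p[1] for p in peaks]))
            for rt, peaks in sorted(by_rt.items())
        ]
        return cls(scans=scans, scan_range=scan_range)

    @classmethod
    def from_mzml(cls, path, scan_range: tuple[float, float] = (100.0, 2000.0)) -> "PeakList":
        """Read an mzML file (requires the optional pyteomics dependency)."""
        try:
            from pyteomics import mzml  # type: ignore[import-untyped]
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "mzML support requires pyteomics; install it or convert the "
                "file to the rt_min,mz,intensity CSV dialect"
            ) from exc
        scans = []
        with mzml.read(str(path)) as reader:  # pragma: no cover
            for spectrum in reader:
                if spectrum.get("ms level", 1) != 1:
                    continue
                rt = float(spectrum["scanList"]["scan"][0]["scan start time"])
                scans.append(Scan(rt, spectrum["m/z array"], spectrum["intensity array"]))
        scans.sort(key=lambda s: s.retention_time)
        return cls(scans=scans, scan_range=scan_range)


@dataclass
class GlycopeptideAssignment:
    """One candidate glycopeptide and the XIC evidence assigned to it."""

    site_id: str
    peptide: SitePeptide
    glycan: GlycanComposition
    charge: int
    theoretical_mz: float
    observed_mz: float  # nan when absent
    ppm_error: float  # nan when absent
    ion_count: float

    @property
    def observed(self) -> bool:
        return self.ion_count > 0


@dataclass
class GlycanDistribution:
    """Relative glycan-species distribution (%) at one glycosite."""

    site_id: str
    entries: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.entries.values()):
            raise ValueError("percentages must be non-negative")

    def total(self) -> float:
        return float(sum(self.entries.values()))

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        return {k: round(v, ndigits) for k, v in self.entries.items()}


# ---------------------------------------------------------------------------
# Digestion and candidate enumeration

_CHYMO_CLEAVE_AFTER = frozenset("FYWLM")


def chymotryptic_digest(
    sequence: str, missed_cleavages: int = 0
) -> list[tuple[str, int, int]]:
    """In-silico chymotryptic digest.

    Cleaves C-terminal to F, Y, W, L and M, except when the next residue is
    proline.  Returns ``(peptide, start, end)`` tuples with 1-based inclusive
    positions, for 0 up to ``missed_cleavages`` missed cleavage sites.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for i, residue in enumerate(sequence):
        if residue not in AMINO_ACID_MASSES:
            raise ValueError(f"unknown residue {residue!r} at position {i + 1}")
    # Fully cleaved fragments first.
    boundaries = [0]
    for i in range(len(sequence) - 1):
        if sequence[i] in _CHYMO_CLEAVE_AFTER and sequence[i + 1] != "P":
            boundaries.append(i + 1)
    boundaries.append(len(sequence))
    fragments = [
        (boundaries[i], boundaries[i + 1]) for i in range(len(boundaries) - 1)
    ]
    out: list[tuple[str, int, int]] = []
    for i in range(len(fragments)):
        for miss in range(missed_cleavages + 1):
            j = i + miss
            if j >= len(fragments):
                break
            start = fragments[i][0]
            end = fragments[j][1]
            out.append((sequence[start:end], start + 1, end))
    return out


def default_site_peptides(
    missed_cleavages: int = 0, cam_cys: bool = True
) -> dict[str, list[SitePeptide]]:
    """Chymotryptic sequon-bearing peptides for the four follitropin glycosites.

    Peptides carrying more than one sequon (possible with missed cleavages)
    are skipped, since they could not be attributed to a single site.
    """
    out: dict[str, list[SitePeptide]] = {site: [] for site in GLYCOSITES}
    for site, (subunit, position) in _SITE_POSITIONS.items():
        for peptide, start, end in chymotryptic_digest(subunit, missed_cleavages):
            if not (start <= position <= end):
                continue
            local = position - start + 1
            try:
                out[site].append(
                    SitePeptide.from_sequence(site, peptide, local, cam_cys=cam_cys)
                )
            except ValueError:
                continue
    return out


def theoretical_mz(
    peptide: SitePeptide,
    glycan: GlycanComposition,
    charge: int,
    table: MonosaccharideMassTable = MONOISOTOPIC,
) -> float:
    """m/z of the protonated glycopeptide at the given charge state."""
    if charge <= 0:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return (
        peptide.backbone_mass + glycan.residue_mass(table) + charge * table.proton
    ) / charge


# ---------------------------------------------------------------------------
# Matching and quantitation


def extract_xic(
    peaklist: PeakList,
    mz: float,
    tolerance_ppm: float = 10.0,
    rt_window: tuple[float, float] | None = None,
) -> float:
    """Summed XIC ion count for one m/z across scans in the retention window.

    The window defaults to the full run; the ion count is the plain sum of
    intensities of peaks within ±tolerance of the target m/z.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    if rt_window is not None and rt_window[0] > rt_window[1]:
        raise ValueError(f"invalid rt_window {rt_window}")
    half_width = mz * tolerance_ppm * 1e-6
    total = 0.0
    for scan in peaklist.scans:
        if rt_window is not None and not (
            rt_window[0] <= scan.retention_time <= rt_window[1]
        ):
            continue
        mask = np.abs(scan.mz - mz) <= half_width
        total += float(scan.intensity[mask].sum())
    return total


def match_ions(
    peaklist: PeakList,
    candidates: Sequence[tuple[SitePeptide, GlycanComposition, int]],
    tolerance_ppm: float = 10.0,
    table: MonosaccharideMassTable = MONOISOTOPIC,
    rt_window: tuple[float, float] | None = None,
) -> list[GlycopeptideAssignment]:
    """Assign observed peaks to the nearest candidate glycopeptide in ppm.

    Every candidate appears in the output; candidates with no peak within
    tolerance are reported absent with ``ion_count`` 0.  A peak within
    tolerance of several candidates goes to the nearest one in ppm, ties
    broken toward the lower theoretical m/z.  Candidates whose m/z falls
    outside the peak list's scan range are skipped.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    if not peaklist.scans or peaklist.n_peaks == 0:
        logger.warning("empty peak list: no assignments made")

    lo, hi = peaklist.scan_range
    entries = []  # (theo_mz, peptide, glycan, charge)
    for peptide, glycan, charge in candidates:
        theo = theoretical_mz(peptide, glycan, charge, table)
        if not (lo <= theo <= hi):
            logger.debug(
                "candidate %s/%s z=%d at m/z %.4f outside scan range, skipped",
                peptide.sequence, glycan.canonical_name, charge, theo,
            )
            continue
        entries.append((theo, peptide, glycan, charge))
    # Sort by theoretical m/z so ppm ties resolve toward the lower value.
    order = sorted(range(len(entries)), key=lambda i: entries[i][0])
    theo_sorted = np.array([entries[i][0] for i in order])

    sums = np.zeros(len(entries))
    weighted_mz = np.zeros(len(entries))
    for scan in peaklist.scans:
        if rt_window is not None and not (
            rt_window[0] <= scan.retention_time <= rt_window[1]
        ):
            continue
        if not scan.mz.size or not theo_sorted.size:
            continue
        ppm = (
            np.abs(scan.mz[:, None] - theo_sorted[None, :])
            / theo_sorted[None, :]
            * 1e6
        )
        # argmin returns the first (lowest-m/z) index on exact ppm ties
        nearest = np.argmin(ppm, axis=1)
        within = ppm[np.arange(scan.mz.size), nearest] <= tolerance_ppm
        for peak_idx in np.nonzero(within)[0]:
            cand = order[nearest[peak_idx]]
            sums[cand] += scan.intensity[peak_idx]
            weighted_mz[cand] += scan.intensity[peak_idx] * scan.mz[peak_idx]

    assignments = []
    for i, (theo, peptide, glycan, charge) in enumerate(entries):
        if sums[i] > 0:
            obs = weighted_mz[i] / sums[i]
            ppm_err = (obs - theo) / theo * 1e6
        else:
            obs, ppm_err = float("nan"), float("nan")
        assignments.append(
            GlycopeptideAssignment(
                site_id=peptide.site_id,
                peptide=peptide,
                glycan=glycan,
                charge=charge,
                theoretical_mz=theo,
                observed_mz=obs,
                ppm_error=ppm_err,
                ion_count=float(sums[i]),
            )
        )
    return assignments


def quantify_site(
    assignments: Iterable[GlycopeptideAssignment],
    site_id: str,
    pool_backbones: bool = False,
) -> GlycanDistribution:
    """Relative glycan distribution at one site from assigned ion counts.

    Charge states of the same (peptide, glycan) are pooled before
    normalisation.  By default only the backbone peptide with the highest
    total ion count is used — ionisation efficiency is comparable only within
    one peptide carrying various glycans — and other backbones are dropped
    with a warning; set ``pool_backbones=True`` to sum across backbones.
    """
    site_assignments = [a for a in assignments if a.site_id == site_id]
    if not site_assignments:
        raise QuantificationError(f"no assignments for site {site_id!r}")

    by_backbone: dict[str, dict[str, float]] = {}
    for a in site_assignments:
        by_backbone.setdefault(a.peptide.sequence, {}).setdefault(
            a.glycan.canonical_name, 0.0
        )
        by_backbone[a.peptide.sequence][a.glycan.canonical_name] += a.ion_count

    if pool_backbones or len(by_backbone) == 1:
        pooled: dict[str, float] = {}
        for species_counts in by_backbone.values():
            for name, count in species_counts.items():
                pooled[name] = pooled.get(name, 0.0) + count
    else:
        best = max(by_backbone, key=lambda seq: sum(by_backbone[seq].values()))
        logger.warning(
            "site %s observed on %d backbone peptides; quantifying on %r only "
            "(pool_backbones=False)", site_id, len(by_backbone), best,
        )
        pooled = by_backbone[best]

    total = sum(pooled.values())
    if total <= 0:
        raise QuantificationError(f"no quantifiable species at site {site_id!r}")
    return GlycanDistribution(
        site_id=site_id,
        entries={name: 100.0 * count / total for name, count in pooled.items()},
    )


# ---------------------------------------------------------------------------
# Tabular I/O

_ASSIGN_COLUMNS = (
    "site_id", "peptide", "glycosite_position", "glycan", "charge",
    "theoretical_mz", "observed_mz", "ppm_error", "ion_count",
)


def assignments_to_csv(assignments: Iterable[GlycopeptideAssignment], path) -> None:
    """Write an assignment report CSV (site, peptide, glycan, charge, m/z, ppm, XIC)."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(_ASSIGN_COLUMNS)
        for a in assignments:
            writer.writerow(
                [
                    a.site_id, a.peptide.sequence, a.peptide.glycosite_position,
                    a.glycan.canonical_name, a.charge,
                    f"{a.theoretical_mz:.6f}", f"{a.observed_mz:.6f}",
                    f"{a.ppm_error:.3f}", f"{a.ion_count:.4f}",
                ]
            )


def assignments_from_csv(path, cam_cys: bool = True) -> list[GlycopeptideAssignment]:
    out = []
    with open(path, newline="") as handle:
        lines = (line for line in handle if not line.startswith("#"))
        for row in csv.DictReader(lines):
            peptide = SitePeptide.from_sequence(
                row["site_id"], row["peptide"], int(row["glycosite_position"]),
                cam_cys=cam_cys,
            )
            out.append(
                GlycopeptideAssignment(
                    site_id=row["site_id"],
                    peptide=peptide,
                    glycan=parse_glycan_name(row["glycan"]),
                    charge=int(row["charge"]),
                    theoretical_mz=float(row["theoretical_mz"]),
                    observed_mz=float(row["observed_mz"]),
                    ppm_error=float(row["ppm_error"]),
                    ion_count=float(row["ion_count"]),
                )
            )
    return out


def candidates_from_csv(
    peptides_path, glycans_path, charges: Sequence[int] = (2, 3, 4), cam_cys: bool = True
) -> list[tuple[SitePeptide, GlycanComposition, int]]:
    """Build the candidate table from a peptide CSV and a glycan CSV.

    The peptide CSV needs columns site_id, sequence, glycosite_position; the
    glycan CSV needs a name column (optionally restricted per site with a
    site_id column).
    """
    peptides: list[SitePeptide] = []
    with open(peptides_path, newline="") as handle:
        for row in csv.DictReader(handle):
            peptides.append(
                SitePeptide.from_sequence(
                    row["site_id"], row["sequence"], int(row["glycosite_position"]),
                    cam_cys=cam_cys,
                )
            )
    glycans: list[tuple[str | None, GlycanComposition]] = []
    with open(glycans_path, newline="") as handle:
        for row in csv.DictReader(handle):
            glycans.append((row.get("site_id") or None, parse_glycan_name(row["name"])))
    out = []
    for peptide in peptides:
        for site, glycan in glycans:
            if site is not None and site != peptide.site_id:
                continue
            for charge in charges:
                out.append((peptide, glycan, charge))
    return out
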