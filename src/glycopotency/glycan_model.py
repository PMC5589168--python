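"""Compositional model of complex N-glycans in the [F]AxGySz[LacN] shorthand.

A glycan species is described by whether it carries a core fucose, how many
antennae branch from the trimannosyl core, how many of those antennae are
galactosylated, how many sialic acids cap the galactoses, and how many extra
N-acetyllactosamine ("lac") repeats extend the antennae.  Only composition is
modelled — no linkage or topology.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "GlycanComposition",
    "MonosaccharideMassTable",
    "MONOISOTOPIC",
    "AVERAGE",
    "GlycanError",
    "GlycanParseError",
    "GlycanValidityError",
    "DEFAULT_ALIASES",
    "parse_glycan_name",
    "render_glycan_name",
    "glycan_residue_mass",
    "compositions_to_csv",
    "compositions_from_csv",
]

logger = logging.getLogger(__name__)


class GlycanError(ValueError):
    """Base class for glycan model errors."""


class GlycanParseError(GlycanError):
    """A glycan name does not match the shorthand grammar."""


class GlycanValidityError(GlycanError):
    """A parsed composition violates a structural constraint."""


@dataclass(frozen=True)
class MonosaccharideMassTable:
    """Residue masses (Da) used when adding a glycan to a peptide backbone.

    Residue masses are the masses of the dehydrated monosaccharides, so a
    glycan attached to a peptide contributes the plain sum of its residue
    masses with no additional water term.
    """

    hexnac: float
    hex: float
    dhex: float
    neuac: float
    water: float = 18.0105646863
    proton: float = 1.00727646688

    def __post_init__(self) -> None:
        for name in ("hexnac", "hex", "dhex", "neuac", "water", "proton"):
            if getattr(self, name) <= 0:
                raise ValueError(f"mass table entry {name!r} must be positive")


#: Monoisotopic residue masses (default; appropriate for Q-TOF data).
MONOISOTOPIC = MonosaccharideMassTable(
    hexnac=203.0793725, hex=162.0528235, dhex=146.0579088, neuac=291.0954165
)

#: Average residue masses, selectable by configuration.
AVERAGE = MonosaccharideMassTable(
    hexnac=203.1950, hex=162.1424, dhex=146.1430, neuac=291.2579,
    water=18.01528, proton=1.00739,
)


@dataclass(frozen=True)
class GlycanComposition:
    """Counts of the structural features of one complex N-glycan species."""

    core_fucose: int = 0
    antennae: int = 0
    galactoses: int = 0
    sialic_acids: int = 0
    lac_repeats: int = 0

    def __post_init__(self) -> None:
        if self.core_fucose not in (0, 1):
            raise GlycanValidityError(
                f"core_fucose must be 0 or 1, got {self.core_fucose}"
            )
        for name in ("antennae", "galactoses", "sialic_acids", "lac_repeats"):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                raise GlycanValidityError(f"{name} must be a non-negative integer")
        if self.antennae > 4:
            raise GlycanValidityError(
                f"antennae must be at most 4, got {self.antennae}"
            )
        if self.sialic_acids > self.galactoses + self.lac_repeats:
            raise GlycanValidityError(
                f"sialic_acids ({self.sialic_acids}) exceeds galactoses + lac "
                f"repeats ({self.galactoses} + {self.lac_repeats})"
            )

    @property
    def canonical_name(self) -> str:
        return render_glycan_name(self)

    def residue_counts(self) -> dict[str, int]:
        """Monosaccharide residue counts implied by the feature counts."""
        return {
            "HexNAc": 2 + self.antennae + self.lac_repeats,
            "Hex": 3 + self.galactoses + self.lac_repeats,
            "dHex": self.core_fucose,
            "NeuAc": self.sialic_acids,
        }

    def residue_mass(self, table: MonosaccharideMassTable = MONOISOTOPIC) -> float:
        return glycan_residue_mass(self, table)


_NAME_RE = re.compile(
    r"^(?P<fuc>F)?"
    r"A(?P<ant>\d+)"
    r"G(?P<gal>\d+)"
    r"S(?P<sia>\d+)"
    r"(?:Lac(?P<lac>\d+))?$"
)

#: The species list in the source data once writes "F2A2G2S2"; the naming
#: convention defines only a single core fucose, so it is read as FA2G2S2.
DEFAULT_ALIASES: Mapping[str, str] = {"F2A2G2S2": "FA2G2S2"}


def parse_glycan_name(
    name: str, aliases: Mapping[str, str] | None = DEFAULT_ALIASES
) -> GlycanComposition:
    """Parse a shorthand glycan name such as ``FA2G2S1`` or ``A4G4S3Lac1``.

    Parameters
    ----------
    name:
        Glycan name in the ``[F]AxGySz[LacN]`` dialect.
    aliases:
        Optional irregular-spelling table applied before parsing.

    Raises
    ------
    GlycanParseError
        If the name does not match the grammar; the message names the
        offending token.
    GlycanValidityError
        If the name parses but the counts are structurally impossible.
    """
    if not isinstance(name, str) or not name:
        raise GlycanParseError("glycan name must be a non-empty string")
    stripped = name.strip()
    if aliases and stripped in aliases:
        logger.warning("glycan name %r read as alias of %r", stripped, aliases[stripped])
        stripped = aliases[stripped]
    match = _NAME_RE.match(stripped)
    if match is None:
        offender = _offending_token(stripped)
        raise GlycanParseError(
            f"cannot parse glycan name {name!r}: unexpected token {offender!r} "
            "(expected [F]AxGySz[LacN])"
        )
    return GlycanComposition(
        core_fucose=1 if match.group("fuc") else 0,
        antennae=int(match.group("ant")),
        galactoses=int(match.group("gal")),
        sialic_acids=int(match.group("sia")),
        lac_repeats=int(match.group("lac") or 0),
    )


def _offending_token(name: str) -> str:
    """Best-effort pointer to the first part of a name that breaks the grammar."""
    scan = re.match(r"(F?)(A\d+)?(G\d+)?(S\d+)?(Lac\d+)?", name)
    consumed = scan.end() if scan else 0
    return name[consumed:] or name


def render_glycan_name(comp: GlycanComposition) -> str:
    """Render the canonical shorthand name of a composition.

    ``parse_glycan_name(render_glycan_name(c)) == c`` for every valid ``c``.
    """
    parts = [
        "F" if comp.core_fucose else "",
        f"A{comp.antennae}",
        f"G{comp.galactoses}",
        f"S{comp.sialic_acids}",
        f"Lac{comp.lac_repeats}" if comp.lac_repeats else "",
    ]
    return "".join(parts)


def glycan_residue_mass(
    comp: GlycanComposition, table: MonosaccharideMassTable = MONOISOTOPIC
) -> float:
    """Mass (Da) the glycan adds to a peptide backbone.

    The glycan is treated as a residue addition: the sum of dehydrated
    monosaccharide masses with no extra water.
    """
    counts = comp.residue_counts()
    return (
        counts["HexNAc"] * table.hexnac
        + counts["Hex"] * table.hex
        + counts["dHex"] * table.dhex
        + counts["NeuAc"] * table.neuac
    )


_CSV_FIELDS = ("name", "fuc", "antennae", "gal", "sia", "lac", "residue_mass")


def compositions_to_csv(
    comps: Iterable[GlycanComposition],
    path,
    table: MonosaccharideMassTable = MONOISOTOPIC,
) -> None:
    """Write compositions to CSV with columns name,fuc,antennae,gal,sia,lac,residue_mass."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(_CSV_FIELDS)
        for comp in comps:
            writer.writerow(
                [
                    comp.canonical_name,
                    comp.core_fucose,
                    comp.antennae,
                    comp.galactoses,
                    comp.sialic_acids,
                    comp.lac_repeats,
                    f"{glycan_residue_mass(comp, table):.6f}",
                ]
            )


def compositions_from_csv(path) -> list[GlycanComposition]:
    """Read compositions written by :func:`compositions_to_csv`.

    The name column is authoritative; count columns, when present, are
    cross-checked against the parsed name.
    """
    out: list[GlycanComposition] = []
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle):
            comp = parse_glycan_name(row["name"])
            if "antennae" in row and row["antennae"] != "":
                declared = (
                    int(row["fuc"]),
                    int(row["antennae"]),
                    int(row["gal"]),
                    int(row["sia"]),
                    int(row["lac"]),
                )
                actual = (
                    comp.core_fucose,
                    comp.antennae,
                    comp.galactoses,
                    comp.sialic_acids,
                    comp.lac_repeats,
                )
                if declared != actual:
                    raise GlycanValidityError(
                        f"row {row['name']!r}: declared counts {declared} "
                        f"disagree with parsed name {actual}"
                    )
            out.append(comp)
    return out
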