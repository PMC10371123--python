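"""Data model and I/O for annotated germline NBN variants and the protein-domain map.

A variant catalog row is one rare, predicted-damaging coding variant with its
annotation scores (gnomAD allele fraction, CADD, REVEL) and the number of case
carriers.  Genomic coordinates (GRCh37, 1-based) are carried verbatim as opaque
``chrom-pos-ref-alt`` identifiers; they are never computed on.

The nibrin protein-domain map places residues into the N-terminal
FHA/BRCT-repeat region (the phosphoprotein-interaction module) or the
C-terminal region that carries the MRE11/RAD50 and ATM interaction sites.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import DomainError, FormatError, VariantTableError

__all__ = [
    "VariantClass",
    "VariantRecord",
    "DomainRegion",
    "DomainMap",
    "DEFAULT_DOMAIN_MAP",
    "parse_protein_change",
    "locate_residue",
    "load_variant_table",
    "write_variant_table",
    "records_to_frame",
    "load_vcf",
]


class VariantClass(str, Enum):
    """Coding consequence class."""

    MISSENSE = "missense"
    FRAMESHIFT = "frameshift"
    STOP_GAIN = "stop_gain"

    def is_truncating(self) -> bool:
        return self in (VariantClass.FRAMESHIFT, VariantClass.STOP_GAIN)


_PCHANGE_RE = re.compile(r"^p\.([A-Za-z])(\d+)(fs|X|\*|[A-Za-z])$")


def parse_protein_change(text: str) -> tuple[int, VariantClass]:
    """Parse a short-form protein change like ``p.K219fs`` or ``p.S706X``.

    Returns the affected residue position and the consequence class implied
    by the suffix: ``fs`` -> frameshift, ``X``/``*`` -> stop gain, any other
    single amino-acid letter -> missense.

    Raises
    ------
    FormatError
        If the string does not match the ``p.<ref><pos><alt|fs|X>`` shape.
    """
    m = _PCHANGE_RE.match(text.strip())
    if m is None:
        raise FormatError(f"unparseable protein change: {text!r}")
    ref, pos, alt = m.groups()
    residue = int(pos)
    if residue < 1:
        raise FormatError(f"residue position must be >= 1 in {text!r}")
    if alt == "fs":
        kind = VariantClass.FRAMESHIFT
    elif alt in ("X", "*"):
        kind = VariantClass.STOP_GAIN
    else:
        kind = VariantClass.MISSENSE
    return residue, kind


@dataclass(frozen=True)
class VariantRecord:
    """One annotated germline variant.

    ``af`` is the reference-population allele fraction (0 means absent from
    the reference cohort).  ``revel`` applies to missense variants only and is
    ``None`` for truncating variants — never 0, which would silently pass or
    fail numeric filters.  ``clinvar`` is carried as an annotation and never
    used in computation.
    """

    variant_id: str
    exon: int
    vclass: VariantClass
    genomic_location: str
    cdna_change: str
    af: float
    cadd: float
    revel: float | None = None
    clinvar: str | None = None
    case_count: int = 0

    def __post_init__(self) -> None:
        residue, kind = parse_protein_change(self.variant_id)
        if kind is not self.vclass:
            raise VariantTableError(
                f"{self.variant_id}: declared class {self.vclass.value!r} "
                f"inconsistent with protein change (implies {kind.value!r})"
            )
        if not 0.0 <= self.af <= 1.0:
            raise VariantTableError(f"{self.variant_id}: af {self.af} outside [0, 1]")
        if self.cadd < 0:
            raise VariantTableError(f"{self.variant_id}: negative CADD {self.cadd}")
        if self.exon < 1:
            raise VariantTableError(f"{self.variant_id}: exon must be >= 1")
        if self.case_count < 0:
            raise VariantTableError(f"{self.variant_id}: negative case_count")
        if self.revel is not None:
            if self.vclass is not VariantClass.MISSENSE:
                raise VariantTableError(
                    f"{self.variant_id}: REVEL given for non-missense variant"
                )
            if not 0.0 <= self.revel <= 1.0:
                raise VariantTableError(
                    f"{self.variant_id}: revel {self.revel} outside [0, 1]"
                )

    @property
    def residue(self) -> int:
        """Affected protein residue parsed from the variant id."""
        return parse_protein_change(self.variant_id)[0]


@dataclass(frozen=True)
class DomainRegion:
    name: str
    start: int  # first residue, inclusive
    end: int  # last residue, inclusive

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise DomainError(f"region {self.name}: need 1 <= start <= end")

    def contains(self, residue: int) -> bool:
        return self.start <= residue <= self.end


@dataclass(frozen=True)
class DomainMap:
    """Ordered protein-domain regions plus the N-terminal boundary residue.

    A residue is "N-terminal" when it lies at or before ``nterminal_boundary``;
    this delimits the FHA/BRCT-repeat module used for the domain-restricted
    burden test.
    """

    regions: tuple[DomainRegion, ...]
    nterminal_boundary: int = 330

    def __post_init__(self) -> None:
        if self.nterminal_boundary < 1:
            raise DomainError("nterminal_boundary must be >= 1")
        starts = [r.start for r in self.regions]
        if starts != sorted(starts):
            raise DomainError("regions must be sorted by start residue")


#: Residue bounds for the nibrin domains.  The FHA and tandem BRCT repeats
#: occupy the first ~330 residues; boundaries are literature-informed defaults
#: and configurable, since they vary a little between annotations.
DEFAULT_DOMAIN_MAP = DomainMap(
    regions=(
        DomainRegion("FHA", 24, 100),
        DomainRegion("BRCT-I", 111, 197),
        DomainRegion("BRCT-II", 221, 330),
        DomainRegion("C-terminal region", 331, 754),
    ),
    nterminal_boundary=330,
)


def locate_residue(
    residue: int, domain_map: DomainMap = DEFAULT_DOMAIN_MAP
) -> tuple[str | None, bool]:
    """Place a residue in the domain map.

    Returns ``(region_name, in_nterminal)`` where ``region_name`` is the first
    region containing the residue (``None`` if it falls between or after
    regions) and ``in_nterminal`` is true when the residue lies at or before
    the map's N-terminal boundary.
    """
    if residue < 1:
        raise DomainError(f"residue must be >= 1, got {residue}")
    name = next(
        (r.name for r in domain_map.regions if r.contains(residue)), None
    )
    return name, residue <= domain_map.nterminal_boundary


# ---------------------------------------------------------------------------
# Tabular I/O

REQUIRED_COLUMNS = (
    "variant_id",
    "exon",
    "class",
    "genomic_location",
    "cdna_change",
    "af",
    "cadd",
    "revel",
    "case_count",
)

_MISSING = ("", ".", "NA", "NaN", "nan", None)


def _parse_optional_float(value: object) -> float | None:
    if value in _MISSING or (isinstance(value, float) and pd.isna(value)):
        return None
    return float(value)  # type: ignore[arg-type]


def load_variant_table(path: str | Path) -> list[VariantRecord]:
    """Load a tab-separated variant catalog into validated records.

    The file must carry the columns ``variant_id, exon, class,
    genomic_location, cdna_change, af, cadd, revel, case_count`` (a
    ``clinvar`` column is optional); ``.`` or ``NA`` mark missing REVEL.
    Each row's declared class is cross-checked against the protein-change
    string and mismatches are rejected.

    Raises
    ------
    VariantTableError
        On a missing column or any invalid row, naming the row number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise VariantTableError(f"{path}: missing required column(s) {missing}")
    records: list[VariantRecord] = []
    for i, row in enumerate(df.to_dict("records"), start=2):  # header = line 1
        try:
            vclass = VariantClass(str(row["class"]).strip().replace(" ", "_"))
            rec = VariantRecord(
                variant_id=str(row["variant_id"]).strip(),
                exon=int(row["exon"]),
                vclass=vclass,
                genomic_location=str(row["genomic_location"]).strip(),
                cdna_change=str(row["cdna_change"]).strip(),
                af=float(row["af"]),
                cadd=float(row["cadd"]),
                revel=_parse_optional_float(row["revel"]),
                clinvar=(
                    None
                    if row.get("clinvar") in _MISSING
                    else str(row.get("clinvar"))
                ),
                case_count=int(row["case_count"]),
            )
        except (ValueError, KeyError, VariantTableError, FormatError) as exc:
            raise VariantTableError(f"{path}: line {i}: {exc}") from exc
        records.append(rec)
    return records


def records_to_frame(records: Iterable[VariantRecord]) -> pd.DataFrame:
    """Render records as a DataFrame in the catalog TSV dialect."""
    rows = []
    for r in records:
        rows.append(
            {
                "variant_id": r.variant_id,
                "exon": r.exon,
                "class": r.vclass.value,
                "genomic_location": r.genomic_location,
                "cdna_change": r.cdna_change,
                "af": r.af,
                "cadd": r.cadd,
                "revel": "NA" if r.revel is None else r.revel,
                "clinvar": r.clinvar or "NA",
                "case_count": r.case_count,
            }
        )
    return pd.DataFrame(
        rows, columns=list(REQUIRED_COLUMNS[:8]) + ["clinvar", "case_count"]
    )


def write_variant_table(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write records as a TSV that :func:`load_variant_table` round-trips."""
    records_to_frame(records).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Minimal VCF adapter

_VCF_CLASS_ALIASES = {
    "missense": VariantClass.MISSENSE,
    "missense_variant": VariantClass.MISSENSE,
    "frameshift": VariantClass.FRAMESHIFT,
    "frameshift_variant": VariantClass.FRAMESHIFT,
    "stop_gain": VariantClass.STOP_GAIN,
    "stop_gained": VariantClass.STOP_GAIN,
}


def load_vcf(path: str | Path) -> list[VariantRecord]:
    """Adapt a minimal annotated VCF onto variant records.

    Reads CHROM/POS/REF/ALT plus the INFO keys ``AF``, ``CADD``, ``REVEL``,
    ``CSQ_CLASS``, ``CASES``, ``PCHANGE`` (protein change), and optionally
    ``EXON`` and ``CDNA``.  Single-sample, unphased; no other VCF features are
    interpreted.  Requires cyvcf2.
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    records: list[VariantRecord] = []
    for v in VCF(str(path)):
        info = dict(v.INFO)
        try:
            vclass = _VCF_CLASS_ALIASES[str(info["CSQ_CLASS"]).lower()]
            rec = VariantRecord(
                variant_id=str(info["PCHANGE"]),
                exon=int(info.get("EXON", 1)),
                vclass=vclass,
                genomic_location=f"{v.CHROM}-{v.POS}-{v.REF}-{v.ALT[0]}",
                cdna_change=str(info.get("CDNA", ".")),
                af=float(info.get("AF", 0.0)),
                cadd=float(info["CADD"]),
                revel=_parse_optional_float(info.get("REVEL")),
                case_count=int(info.get("CASES", 0)),
            )
        except (KeyError, ValueError, VariantTableError, FormatError) as exc:
            raise VariantTableError(
                f"{path}: {v.CHROM}:{v.POS} {v.REF}>{v.ALT}: {exc}"
            ) from exc
        records.append(rec)
    return records
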