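"""Specimen-level morphometric records and species-level trait means.

A specimen is one measured bee: intertegular distance (IT, the span between
the wing tegulae, the standard proxy for bee body size) plus, for dissected
specimens, glossa and prementum lengths.  The functional proboscis length is
the sum of glossa and prementum.  Museum specimens are typically IT-only;
they contribute to species body-size means but not to mouthpart means.

All lengths are millimetres.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

FAMILIES = (
    "Andrenidae",
    "Apidae",
    "Colletidae",
    "Halictidae",
    "Megachilidae",
    "Melittidae",
)

#: Families whose glossa exceeds the prementum ("long-tongued" bees).
LONG_TONGUED_FAMILIES = frozenset({"Apidae", "Megachilidae"})

REGIONS = ("winter", "aseasonal", "early_summer", "late_summer")

SEXES = ("male", "female", "unknown")

#: Canonical column names; a schema mapping may rename any of them.
DEFAULT_COLUMNS = {
    "specimen_id": "specimen_id",
    "species": "species",
    "genus": "genus",
    "family": "family",
    "sex": "sex",
    "it_mm": "it_mm",
    "glossa_mm": "glossa_mm",
    "prementum_mm": "prementum_mm",
    "region": "region",
}

REQUIRED_COLUMNS = ("species", "genus", "family", "it_mm")


class SchemaError(ValueError):
    """A required column is absent from the input table."""


class ValidationError(ValueError):
    """One or more rows violate the specimen invariants."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__(
            "invalid specimen rows:\n" + "\n".join(problems)
        )


def tongue_group_for(family: str) -> str:
    """Tongue group implied by family: long iff Apidae or Megachilidae."""
    return "long" if family in LONG_TONGUED_FAMILIES else "short"


@dataclass(frozen=True)
class SpecimenRecord:
    """One measured bee specimen.

    ``proboscis_mm`` is derived (glossa + prementum) and present only when
    both mouthpart components were measured; ``tongue_group`` is derived
    from family.
    """

    specimen_id: str
    species: str
    genus: str
    family: str
    sex: str = "unknown"
    it_mm: float = float("nan")
    glossa_mm: float | None = None
    prementum_mm: float | None = None
    region: str | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not (self.it_mm > 0):
            raise ValueError(f"it_mm must be > 0, got {self.it_mm}")
        for name in ("glossa_mm", "prementum_mm"):
            v = getattr(self, name)
            if v is not None and not (v > 0):
                raise ValueError(f"{name} must be > 0 when present, got {v}")
        if self.region is not None and self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")

    @property
    def tongue_group(self) -> str:
        return tongue_group_for(self.family)

    @property
    def proboscis_mm(self) -> float | None:
        if self.glossa_mm is None or self.prementum_mm is None:
            return None
        return self.glossa_mm + self.prementum_mm


@dataclass
class SpeciesTraitMeans:
    """Arithmetic species-level means over the (possibly sex-filtered) specimens."""

    species: str
    genus: str
    family: str
    n_specimens: int
    mean_it_mm: float
    mean_glossa_mm: float | None = None
    mean_prementum_mm: float | None = None
    mean_proboscis_mm: float | None = None
    regions: frozenset[str] = field(default_factory=frozenset)

    @property
    def tongue_group(self) -> str:
        return tongue_group_for(self.family)


def _parse_optional_float(value) -> float | None:
    if value is None or (isinstance(value, str) and value.strip() == ""):
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"not numeric: {value!r}")
    if math.isnan(v):
        return None
    return v


def read_specimens(
    path,
    schema: dict[str, str] | None = None,
    strict: bool = True,
) -> list[SpecimenRecord]:
    """Read specimen records from a CSV file.

    Parameters
    ----------
    path
        CSV file with a header row, UTF-8.
    schema
        Mapping from canonical field names (keys of ``DEFAULT_COLUMNS``) to
        the column names used in this file.  Unmentioned fields keep their
        canonical names.
    strict
        If True (default), any invalid row aborts the read with a
        :class:`ValidationError` listing the offending rows by number.
        If False, invalid rows are skipped with a logged warning.

    Row numbers in error messages are 1-based data-row numbers (the header
    is row 0).
    """
    columns = dict(DEFAULT_COLUMNS)
    if schema:
        unknown = set(schema) - set(DEFAULT_COLUMNS)
        if unknown:
            raise SchemaError(f"schema maps unknown fields: {sorted(unknown)}")
        columns.update(schema)

    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [columns[f] for f in REQUIRED_COLUMNS if columns[f] not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    def cell(row, fieldname):
        col = columns[fieldname]
        if col not in frame.columns:
            return None
        value = row[col]
        return value if value != "" else None

    records: list[SpecimenRecord] = []
    problems: list[str] = []
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        try:
            it = _parse_optional_float(cell(row, "it_mm"))
            if it is None:
                raise ValueError("it_mm missing")
            records.append(
                SpecimenRecord(
                    specimen_id=cell(row, "specimen_id") or f"row{i}",
                    species=cell(row, "species") or "",
                    genus=cell(row, "genus") or "",
                    family=cell(row, "family") or "",
                    sex=cell(row, "sex") or "unknown",
                    it_mm=it,
                    glossa_mm=_parse_optional_float(cell(row, "glossa_mm")),
                    prementum_mm=_parse_optional_float(cell(row, "prementum_mm")),
                    region=cell(row, "region"),
                )
            )
        except ValueError as exc:
            problems.append(f"row {i}: {exc}")

    if problems:
        if strict:
            raise ValidationError(problems)
        for p in problems:
            logger.warning("skipping invalid specimen %s", p)
    return records


def _mean_or_none(values: list[float]) -> float | None:
    return sum(values) / len(values) if values else None


def aggregate_species_means(
    records: list[SpecimenRecord],
    sex_filter: str = "all",
) -> list[SpeciesTraitMeans]:
    """Collapse specimens to one row of arithmetic means per species.

    ``sex_filter`` is ``all`` (default; sexes pooled), ``male`` or
    ``female``.  Specimens are weighted equally.  Specimens missing glossa
    or prementum contribute to the IT mean but not to mouthpart means; the
    proboscis mean is the mean of per-specimen glossa+prementum sums.
    Species with no specimens left after filtering are omitted with a
    logged warning.
    """
    if sex_filter not in ("all", "male", "female"):
        raise ValueError(f"sex_filter must be all/male/female, got {sex_filter!r}")

    kept = [r for r in records if sex_filter == "all" or r.sex == sex_filter]
    if not kept:
        raise ValueError("no specimens remain after sex filtering")

    dropped = {r.species for r in records} - {r.species for r in kept}
    for sp in sorted(dropped):
        logger.warning("species %s has no %s specimens; omitted", sp, sex_filter)

    by_species: dict[str, list[SpecimenRecord]] = {}
    for r in kept:
        by_species.setdefault(r.species, []).append(r)

    out = []
    for species in sorted(by_species):
        group = by_species[species]
        out.append(
            SpeciesTraitMeans(
                species=species,
                genus=group[0].genus,
                family=group[0].family,
                n_specimens=len(group),
                mean_it_mm=_mean_or_none([r.it_mm for r in group]),
                mean_glossa_mm=_mean_or_none(
                    [r.glossa_mm for r in group if r.glossa_mm is not None]
                ),
                mean_prementum_mm=_mean_or_none(
                    [r.prementum_mm for r in group if r.prementum_mm is not None]
                ),
                mean_proboscis_mm=_mean_or_none(
                    [r.proboscis_mm for r in group if r.proboscis_mm is not None]
                ),
                regions=frozenset(r.region for r in group if r.region is not None),
            )
        )
    return out


def means_to_frame(means: list[SpeciesTraitMeans]) -> pd.DataFrame:
    """Tabular view of species means (regions serialized as ';'-joined labels)."""
    return pd.DataFrame(
        {
            "species": [m.species for m in means],
            "genus": [m.genus for m in means],
            "family": [m.family for m in means],
            "tongue_group": [m.tongue_group for m in means],
            "n_specimens": [m.n_specimens for m in means],
            "mean_it_mm": [m.mean_it_mm for m in means],
            "mean_glossa_mm": [m.mean_glossa_mm for m in means],
            "mean_prementum_mm": [m.mean_prementum_mm for m in means],
            "mean_proboscis_mm": [m.mean_proboscis_mm for m in means],
            "regions": [";".join(sorted(m.regions)) for m in means],
        }
    )


def means_from_frame(frame: pd.DataFrame) -> list[SpeciesTraitMeans]:
    """Inverse of :func:`means_to_frame` (also accepts a bare species CSV)."""
    out = []
    for _, row in frame.iterrows():
        regions = row.get("regions", "")
        if isinstance(regions, str):
            regions = frozenset(r for r in regions.split(";") if r)
        out.append(
            SpeciesTraitMeans(
                species=row["species"],
                genus=row.get("genus", ""),
                family=row["family"],
                n_specimens=int(row.get("n_specimens", 1)),
                mean_it_mm=float(row["mean_it_mm"]),
                mean_glossa_mm=_parse_optional_float(row.get("mean_glossa_mm")),
                mean_prementum_mm=_parse_optional_float(row.get("mean_prementum_mm")),
                mean_proboscis_mm=_parse_optional_float(row.get("mean_proboscis_mm")),
                regions=frozenset(regions),
            )
        )
    return out
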