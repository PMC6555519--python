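"""Trait prediction from body size: mouthpart lengths via the allometric
power function and foraging distances via published log10-log10 regressions.

Mouthpart prediction evaluates L = exp(a_f) * IT**b with family-specific
intercepts (and, for the prementum, family-specific exponents).  Foraging
distance uses regressions of the form log10(distance_km) = c0 + c1 *
log10(IT); the source regressions in the literature use IT in cm, so the
IT unit is declared explicitly in the coefficient config.  The published
foraging coefficients are not bundled: they must be supplied in a config
(transcribed from the source regression), and every example config in this
repository is synthetic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml

from .allometry import PowerFunctionParams
from .morphodata import REGIONS, SpeciesTraitMeans

logger = logging.getLogger(__name__)

_BUNDLED_COEFFS = "data/allometry_coefficients.yaml"


class PredictionError(ValueError):
    """Prediction is impossible with the given parameters/input."""


@dataclass(frozen=True)
class ForagingCoefficients:
    """One log10-log10 foraging-distance regression.

    ``kind`` distinguishes the typical from the maximum distance curve;
    ``it_unit`` declares the unit the source regression used for IT
    (body-size allometry literature mixes mm and cm); output is km.
    """

    kind: str
    c0: float
    c1: float
    it_unit: str = "cm"
    out_unit: str = "km"

    def __post_init__(self):
        if self.kind not in ("typical", "maximum"):
            raise ValueError("kind must be 'typical' or 'maximum'")
        if self.it_unit not in ("mm", "cm"):
            raise ValueError("it_unit must be 'mm' or 'cm'")
        if self.out_unit != "km":
            raise ValueError("only km output is supported")
        if not self.c1 > 0:
            raise ValueError("c1 must be > 0 for a meaningful size-distance allometry")


@dataclass
class TraitEstimates:
    """Per-species estimated traits from its mean IT."""

    species: str
    mean_it_mm: float
    est_proboscis_mm: float | None = None
    est_glossa_mm: float | None = None
    est_prementum_mm: float | None = None
    typical_km: float | None = None
    maximum_km: float | None = None
    regions: frozenset[str] = field(default_factory=frozenset)


def load_power_params(source=None) -> dict[str, PowerFunctionParams]:
    """Load power-function coefficients from a YAML file.

    Without ``source``, the bundled published six-family coefficient set
    (natural-log scale) is used.  The layout has one block per response
    with per-family ``intercepts`` and either a common ``slope`` or
    per-family ``slopes``.
    """
    if source is None:
        text = (resources.files("beeallometry") / _BUNDLED_COEFFS).read_text()
        raw = yaml.safe_load(text)
    else:
        with open(source, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    params = {}
    for response, block in raw.items():
        params[response] = PowerFunctionParams(
            response=response,
            intercepts=dict(block["intercepts"]),
            slope=block.get("slope"),
            slopes=dict(block["slopes"]) if "slopes" in block else None,
        )
    return params


def load_foraging_config(source) -> dict[str, ForagingCoefficients]:
    """Load typical/maximum foraging coefficients from a flat YAML config."""
    with open(source, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for kind in ("typical", "maximum"):
        if kind in raw:
            block = raw[kind]
            out[kind] = ForagingCoefficients(
                kind=kind,
                c0=float(block["c0"]),
                c1=float(block["c1"]),
                it_unit=block.get("it_unit", "cm"),
            )
    return out


def predict_length(params: PowerFunctionParams, family: str, it_mm: float) -> float:
    """Power-function evaluation exp(a_f) * IT**b (mm in, mm out)."""
    if it_mm <= 0:
        raise PredictionError(f"it_mm must be > 0, got {it_mm}")
    if family not in params.intercepts:
        raise PredictionError(
            f"family {family!r} not covered; available: {sorted(params.intercepts)}"
        )
    a = params.intercepts[family]
    b = params.slope_for(family)
    return math.exp(a + b * math.log(it_mm))


def estimate_foraging(coeffs: ForagingCoefficients | None, it_mm: float) -> float:
    """Distance in km from IT via 10**(c0 + c1*log10(IT in the declared unit))."""
    if coeffs is None:
        raise PredictionError(
            "foraging coefficients are not configured; supply c0/c1/it_unit "
            "transcribed from the published foraging-distance regressions"
        )
    if it_mm <= 0:
        raise PredictionError(f"it_mm must be > 0, got {it_mm}")
    it = it_mm / 10.0 if coeffs.it_unit == "cm" else it_mm
    return 10.0 ** (coeffs.c0 + coeffs.c1 * math.log10(it))


def batch_estimate(
    params: dict[str, PowerFunctionParams],
    typical_coeffs: ForagingCoefficients | None,
    max_coeffs: ForagingCoefficients | None,
    species_table: list[SpeciesTraitMeans],
) -> tuple[list[TraitEstimates], dict[str, str]]:
    """Apply the power functions (and foraging curves, if configured) to a
    species-means table.

    Returns estimates in input order plus a map of per-species failures
    (unknown family etc.); failures do not abort the batch.
    """
    estimates: list[TraitEstimates] = []
    failures: dict[str, str] = {}
    for m in species_table:
        try:
            est = TraitEstimates(
                species=m.species,
                mean_it_mm=m.mean_it_mm,
                regions=frozenset(m.regions),
            )
            for response in ("proboscis", "glossa", "prementum"):
                if response in params:
                    setattr(
                        est,
                        f"est_{response}_mm",
                        predict_length(params[response], m.family, m.mean_it_mm),
                    )
            if typical_coeffs is not None:
                est.typical_km = estimate_foraging(typical_coeffs, m.mean_it_mm)
            if max_coeffs is not None:
                est.maximum_km = estimate_foraging(max_coeffs, m.mean_it_mm)
            estimates.append(est)
        except PredictionError as exc:
            logger.warning("species %s: %s", m.species, exc)
            failures[m.species] = str(exc)
    return estimates, failures


_SUMMARY_FIELDS = (
    "mean_it_mm",
    "est_proboscis_mm",
    "est_glossa_mm",
    "est_prementum_mm",
    "typical_km",
    "maximum_km",
)


def summarize_by_region(estimates: list[TraitEstimates]) -> pd.DataFrame:
    """Per-region distribution summaries of the estimated traits.

    A species contributes to every rainfall region in its region set, so
    per-region species counts may sum to more than the number of species;
    species with an empty region set are reported under ``unassigned``.
    Quartiles are pandas linear-interpolation quantiles.
    """
    rows = []
    region_order = list(REGIONS) + ["unassigned"]
    for region in region_order:
        members = [
            e
            for e in estimates
            if (region in e.regions) or (region == "unassigned" and not e.regions)
        ]
        if not members:
            continue
        row = {"region": region, "n_species": len(members)}
        for fieldname in _SUMMARY_FIELDS:
            values = [getattr(e, fieldname) for e in members]
            values = [v for v in values if v is not None]
            if not values:
                continue
            s = pd.Series(values, dtype=float)
            row[f"{fieldname}_q25"] = s.quantile(0.25)
            row[f"{fieldname}_median"] = s.quantile(0.50)
            row[f"{fieldname}_q75"] = s.quantile(0.75)
        rows.append(row)
    return pd.DataFrame(rows)


def estimates_to_frame(estimates: list[TraitEstimates]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": [e.species for e in estimates],
            "mean_it_mm": [e.mean_it_mm for e in estimates],
            "est_proboscis_mm": [e.est_proboscis_mm for e in estimates],
            "est_glossa_mm": [e.est_glossa_mm for e in estimates],
            "est_prementum_mm": [e.est_prementum_mm for e in estimates],
            "typical_km": [e.typical_km for e in estimates],
            "maximum_km": [e.maximum_km for e in estimates],
            "regions": [";".join(sorted(e.regions)) for e in estimates],
        }
    )
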