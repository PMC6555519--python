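"""Interspecific log-log allometry: candidate OLS models, AIC selection,
and parameterization of the allometric power function.

The regression units are species-level trait means.  Both the response
(mean mouthpart length, mm) and the predictor (mean IT, mm) enter on the
natural-log scale, so a fitted line ln L = a + b ln IT is the power
function L = exp(a) * IT**b.  Seven candidate models per response cross a
grouping factor (family, tongue group, or none) with how IT enters
(absent, common slope, or group-specific slopes); the best-supported model
is the one with the lowest AIC.

AIC convention: Gaussian maximum-likelihood log-likelihood with the
residual variance counted as an estimated parameter,

    loglik = -(n/2) * (ln 2*pi + ln(rss/n) + 1)
    aic    = -2*loglik + 2*(k + 1)

where k is the number of regression coefficients.  A perfect fit (rss = 0)
is reported with an ``aic`` of -inf and a warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .morphodata import FAMILIES, SpecimenRecord, SpeciesTraitMeans

logger = logging.getLogger(__name__)

RESPONSES = ("proboscis", "glossa", "prementum")
GROUPINGS = ("family", "tongue_group", "none")
IT_TERMS = ("absent", "common_slope", "group_slope")

_RANK_TOL = 1e-10


class FitError(ValueError):
    """The requested model cannot be fitted on the given data."""


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response ~ grouping (+/x) ln(IT)."""

    response: str
    grouping: str
    it_term: str

    def __post_init__(self):
        if self.response not in RESPONSES:
            raise ValueError(f"response must be one of {RESPONSES}")
        if self.grouping not in GROUPINGS:
            raise ValueError(f"grouping must be one of {GROUPINGS}")
        if self.it_term not in IT_TERMS:
            raise ValueError(f"it_term must be one of {IT_TERMS}")
        if self.grouping == "none" and self.it_term != "common_slope":
            raise ValueError("without grouping the only admissible model is IT-only")

    @property
    def label(self) -> str:
        group = {"family": "Family", "tongue_group": "Short- vs. Long-Tongued"}.get(
            self.grouping
        )
        if self.grouping == "none":
            return "IT Only"
        if self.it_term == "absent":
            return f"{group} Only"
        op = "+" if self.it_term == "common_slope" else "x"
        return f"{group} {op} IT"


def candidate_specs(response: str) -> list[ModelSpec]:
    """The seven admissible candidate models, in fixed order (used for ties)."""
    specs = []
    for grouping in ("family", "tongue_group"):
        for it_term in ("common_slope", "group_slope", "absent"):
            specs.append(ModelSpec(response, grouping, it_term))
    specs.append(ModelSpec(response, "none", "common_slope"))
    return specs


@dataclass
class AllometryFit:
    """A fitted candidate model with its selection statistics."""

    spec: ModelSpec
    n: int
    k: int
    coefficients: dict[str, float]
    rss: float
    loglik: float
    aic: float
    r2: float
    adj_r2: float
    stderr: dict[str, float] = field(default_factory=dict)
    species: tuple[str, ...] = ()
    reference_group: str | None = None


@dataclass
class PowerFunctionParams:
    """Per-family power-function parameters L = exp(a_f) * IT**b.

    ``slope`` is set when the best model had a common IT slope, ``slopes``
    (per family) when it had family-specific slopes.  Intercepts are
    absolute per-family values on the natural-log scale.
    """

    response: str
    intercepts: dict[str, float]
    slope: float | None = None
    slopes: dict[str, float] | None = None

    def __post_init__(self):
        if (self.slope is None) == (self.slopes is None):
            raise ValueError("exactly one of slope/slopes must be set")

    def slope_for(self, family: str) -> float:
        if self.slope is not None:
            return self.slope
        return self.slopes[family]


def _response_mean(m: SpeciesTraitMeans, response: str) -> float | None:
    return getattr(m, f"mean_{response}_mm")


def _group_of(m: SpeciesTraitMeans, grouping: str) -> str:
    return m.family if grouping == "family" else m.tongue_group


def build_design(
    spec: ModelSpec, data: list[SpeciesTraitMeans]
) -> tuple[np.ndarray, np.ndarray, list[str], list[SpeciesTraitMeans]]:
    """Design matrix and ln-response vector for one candidate model.

    Categorical terms are treatment-coded against the alphabetically first
    group present (Andrenidae for family; "long" for tongue group).
    Species missing the response mean are excluded with a warning.
    Returns ``(X, y, coefficient_names, species_used)``.
    """
    usable = []
    for m in data:
        if _response_mean(m, spec.response) is None:
            logger.warning(
                "species %s lacks mean %s; excluded from design", m.species, spec.response
            )
            continue
        usable.append(m)
    if not usable:
        raise FitError(f"no species with a {spec.response} mean")

    y = np.log([_response_mean(m, spec.response) for m in usable])
    ln_it = np.log([m.mean_it_mm for m in usable])
    n = len(usable)

    cols = [np.ones(n)]
    names = ["intercept"]
    reference = None
    if spec.grouping != "none":
        groups = sorted({_group_of(m, spec.grouping) for m in usable})
        reference = groups[0]
        levels = np.array([_group_of(m, spec.grouping) for m in usable])
        if len(groups) < 2:
            raise FitError(
                f"grouping={spec.grouping} needs >=2 groups; data has only {groups}"
            )
        for g in groups[1:]:
            cols.append((levels == g).astype(float))
            names.append(f"{spec.grouping}[{g}]")
        if spec.it_term == "common_slope":
            cols.append(ln_it)
            names.append("ln_it")
        elif spec.it_term == "group_slope":
            cols.append(ln_it)
            names.append("ln_it")
            for g in groups[1:]:
                cols.append(ln_it * (levels == g))
                names.append(f"{spec.grouping}[{g}]:ln_it")
    else:
        cols.append(ln_it)
        names.append("ln_it")

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError(f"rank-deficient design for {spec.label}")
    return X, y, names, usable


def fit_ols(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    names: list[str] | None = None,
    species: list[SpeciesTraitMeans] | None = None,
    reference_group: str | None = None,
) -> AllometryFit:
    """Least-squares fit with the package AIC convention (see module docstring)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k:
        raise FitError(f"need n > k, got n={n}, k={k}")
    if np.linalg.matrix_rank(X) < k:
        raise FitError("singular design matrix")
    names = names or [f"b{i}" for i in range(k)]

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k)

    if rss <= _RANK_TOL * max(1.0, tss):
        logger.warning("perfect fit (rss ~ 0) for %s; AIC reported as -inf", spec.label)
        loglik = math.inf
        aic = -math.inf
        stderr = {nm: 0.0 for nm in names}
    else:
        loglik = -0.5 * n * (math.log(2 * math.pi) + math.log(rss / n) + 1.0)
        aic = -2.0 * loglik + 2.0 * (k + 1)
        sigma2 = rss / (n - k)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        stderr = {nm: math.sqrt(cov[i, i]) for i, nm in enumerate(names)}

    return AllometryFit(
        spec=spec,
        n=n,
        k=k,
        coefficients=dict(zip(names, beta)),
        rss=rss,
        loglik=loglik,
        aic=aic,
        r2=r2,
        adj_r2=adj_r2,
        stderr=stderr,
        species=tuple(m.species for m in species) if species else (),
        reference_group=reference_group,
    )


def fit_model(spec: ModelSpec, data: list[SpeciesTraitMeans]) -> AllometryFit:
    """Build the design for ``spec`` and fit it."""
    X, y, names, usable = build_design(spec, data)
    reference = None
    if spec.grouping != "none":
        reference = sorted({_group_of(m, spec.grouping) for m in usable})[0]
    return fit_ols(X, y, spec, names, usable, reference)


def candidate_fits(
    response: str, data: list[SpeciesTraitMeans]
) -> tuple[list[AllometryFit], dict[ModelSpec, str]]:
    """Fit all seven candidates on a common species set (listwise deletion).

    Species missing the response mean are dropped once, up front, so all
    AIC values are comparable.  Returns the successful fits and a map of
    failed specs to their error messages.
    """
    usable = [m for m in data if _response_mean(m, response) is not None]
    if not usable:
        raise FitError(f"no species with a {response} mean")

    fits: list[AllometryFit] = []
    failures: dict[ModelSpec, str] = {}
    for spec in candidate_specs(response):
        try:
            fits.append(fit_model(spec, usable))
        except FitError as exc:
            logger.warning("candidate %s failed: %s", spec.label, exc)
            failures[spec] = str(exc)
    return fits, failures


def select_best(fits: list[AllometryFit]) -> AllometryFit:
    """Lowest-AIC fit; ties broken by fewer coefficients, then candidate order."""
    if not fits:
        raise FitError("no successful candidate fits to select from")
    order = {spec: i for i, spec in enumerate(candidate_specs(fits[0].spec.response))}
    return min(fits, key=lambda f: (f.aic, f.k, order.get(f.spec, len(order))))


def parameterize(best: AllometryFit) -> PowerFunctionParams:
    """Absolute per-family power-function parameters from the best fit.

    Treatment-coded dummy offsets are folded into absolute per-family
    intercepts (reference intercept plus offset); the same is done for
    family-specific slopes under an interaction model.  Only defined when
    the best model includes an IT term and a family grouping (a tongue-group
    model is expanded to its member families).
    """
    spec = best.spec
    if spec.it_term == "absent":
        raise FitError(
            f"best model {best.spec.label!r} has no IT term; no power function defined"
        )
    coef = best.coefficients

    def family_key(family: str) -> str:
        if spec.grouping == "family":
            return family
        return "long" if family in ("Apidae", "Megachilidae") else "short"

    intercepts = {}
    slopes = {}
    for family in FAMILIES:
        key = family_key(family) if spec.grouping != "none" else None
        a = coef["intercept"]
        b = coef["ln_it"]
        if key is not None and key != best.reference_group:
            a += coef.get(f"{spec.grouping}[{key}]", 0.0)
            if spec.it_term == "group_slope":
                b += coef.get(f"{spec.grouping}[{key}]:ln_it", 0.0)
        intercepts[family] = a
        slopes[family] = b

    if spec.it_term == "group_slope":
        return PowerFunctionParams(spec.response, intercepts, slopes=slopes)
    return PowerFunctionParams(
        spec.response, intercepts, slope=coef["ln_it"]
    )


def test_common_slope_by_sex(
    records: list[SpecimenRecord],
    responses: tuple[str, ...] = RESPONSES,
    include_species_intercepts: bool = True,
) -> dict[str, dict[str, float]]:
    """F-test of a sex-specific IT slope, per mouthpart response.

    Specimen-level ln-ln regression: the full model adds a sex x ln(IT)
    interaction to the additive model (sex + ln IT, plus species intercepts
    by default to absorb species differences).  A small p-value would argue
    against pooling sexes in the interspecific fits.

    Returns ``{response: {"F": ..., "df1": ..., "df2": ..., "p": ...,
    "slope_diff": ...}}``.
    """
    out = {}
    for response in responses:
        rows = []
        for r in records:
            value = getattr(r, f"{response}_mm")
            if value is None or r.sex not in ("male", "female"):
                continue
            rows.append((math.log(value), math.log(r.it_mm), r.sex, r.species))
        sexes = {s for *_, s, _ in rows}
        if sexes != {"male", "female"}:
            raise FitError(
                f"both sexes required for {response}; present: {sorted(sexes)}"
            )

        y = np.array([t[0] for t in rows])
        ln_it = np.array([t[1] for t in rows])
        is_male = np.array([t[2] == "male" for t in rows], dtype=float)
        n = len(rows)

        cols = [np.ones(n), is_male, ln_it]
        if include_species_intercepts:
            species = sorted({t[3] for t in rows})
            labels = np.array([t[3] for t in rows])
            for sp in species[1:]:
                cols.append((labels == sp).astype(float))
        X0 = np.column_stack(cols)
        X1 = np.column_stack(cols + [is_male * ln_it])
        if np.linalg.matrix_rank(X1) < X1.shape[1]:
            raise FitError(f"rank-deficient sex-slope design for {response}")

        beta0, _, _, _ = np.linalg.lstsq(X0, y, rcond=None)
        beta1, _, _, _ = np.linalg.lstsq(X1, y, rcond=None)
        rss0 = float(np.sum((y - X0 @ beta0) ** 2))
        rss1 = float(np.sum((y - X1 @ beta1) ** 2))
        df1 = 1
        df2 = n - X1.shape[1]
        if df2 <= 0:
            raise FitError(f"not enough residual df for {response}")
        if rss1 <= 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat = max(0.0, (rss0 - rss1) / df1 / (rss1 / df2))
            p = float(stats.f.sf(f_stat, df1, df2))
        out[response] = {
            "F": f_stat,
            "df1": float(df1),
            "df2": float(df2),
            "p": p,
            "slope_diff": float(beta1[-1]),
        }
    return out
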