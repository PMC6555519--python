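"""Synthetic data with the statistical structure the analysis assumes.

Generators (all pure functions of a config/seed):

* specimen-level morphometrics — ln(mouthpart) linear in ln(IT) with
  family-specific intercepts/slopes plus Gaussian noise on the ln scale,
  proboscis recomputed as glossa + prementum after noising the parts;
* a museum-style species table — IT-only species means with a fixed
  multi-membership rainfall-region pattern (region totals 44/13/12/20 over
  56 species, memberships summing to 89);
* ultrametric pure-birth (Yule) genus backbones;
* Brownian-motion tip traits with optional additive region effects;
* nested-taxonomy traits (subfamily/tribe/genus random intercepts) for the
  LMM.

Defaults mirror the study conditions: the published six-family power
functions as generating coefficients, species mean IT log-uniform on
0.99-4.42 mm, ln-scale noise sd 0.1, 110 species across the six families,
10 specimens per species, 7 genera in the regional backbone.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .allometry import PowerFunctionParams
from .morphodata import FAMILIES, REGIONS, SpecimenRecord, SpeciesTraitMeans
from .phylocomp import brownian_covariance
from .traitpredict import load_power_params

#: Default species counts per family (110 interspecific regression units).
DEFAULT_N_SPECIES = {
    "Andrenidae": 19,
    "Apidae": 19,
    "Colletidae": 18,
    "Halictidae": 18,
    "Megachilidae": 18,
    "Melittidae": 18,
}

#: Museum-table shape: species per region with multi-membership (sum 89 > 56).
REGION_TOTALS = {"winter": 44, "aseasonal": 13, "early_summer": 12, "late_summer": 20}
#: Number of species by how many regions they occupy (56 species total).
MEMBERSHIP_SIZES = {1: 31, 2: 18, 3: 6, 4: 1}


@dataclass
class SynthConfig:
    """Generating parameters for the morphometric simulator."""

    seed: int = 0
    coefficients: dict[str, PowerFunctionParams] | None = None  # default: published set
    it_range: tuple[float, float] = (0.99, 4.42)  # mm, species means
    n_species: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_SPECIES))
    n_specimens: int = 10
    noise_sd: float = 0.1  # ln-scale sd on glossa and prementum
    sex_slope_shift: float = 0.0  # added to the male ln-ln slope (sex-effect sims)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 < self.it_range[0] <= self.it_range[1]):
            raise ValueError("it_range must be positive and ordered")
        if self.coefficients is None:
            self.coefficients = load_power_params()


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def gen_specimens(config: SynthConfig) -> list[SpecimenRecord]:
    """Specimen records from the family power functions plus ln-scale noise.

    Species mean IT is log-uniform on ``it_range``; all specimens of a
    species share its IT.  Glossa and prementum are noised independently
    and the proboscis is their per-specimen sum.  Sexes alternate
    female/male within each species; a non-zero ``sex_slope_shift`` tilts
    the male mouthpart slopes.
    """
    rng = _rng(config.seed)
    lo, hi = math.log(config.it_range[0]), math.log(config.it_range[1])
    records = []
    for family in FAMILIES:
        n_sp = config.n_species.get(family, 0)
        for i in range(n_sp):
            species = f"{family[:4]}_sp{i:02d}"
            genus = f"{family[:4]}G{i % 3}"
            ln_it = rng.uniform(lo, hi)
            it = math.exp(ln_it)
            for j in range(config.n_specimens):
                sex = "female" if j % 2 == 0 else "male"
                shift = config.sex_slope_shift * ln_it if sex == "male" else 0.0
                parts = {}
                for response in ("glossa", "prementum"):
                    p = config.coefficients[response]
                    mu = p.intercepts[family] + p.slope_for(family) * ln_it + shift
                    parts[response] = math.exp(mu + rng.normal(0.0, config.noise_sd))
                records.append(
                    SpecimenRecord(
                        specimen_id=f"{species}_{j:03d}",
                        species=species,
                        genus=genus,
                        family=family,
                        sex=sex,
                        it_mm=it,
                        glossa_mm=parts["glossa"],
                        prementum_mm=parts["prementum"],
                    )
                )
    return records


def region_membership_pattern() -> list[frozenset[str]]:
    """Deterministic 56-species rainfall-region membership pattern.

    Greedy quota-filling reproduces the study shape: per-region species
    totals (winter 44, aseasonal 13, early summer 12, late summer 20) with
    31 single-region, 18 two-region, 6 three-region and 1 four-region
    species.
    """
    quota = dict(REGION_TOTALS)
    order = {r: i for i, r in enumerate(REGIONS)}
    sizes = []
    for size in (4, 3, 2, 1):
        sizes.extend([size] * MEMBERSHIP_SIZES[size])
    pattern = []
    for size in sizes:
        ranked = sorted(quota, key=lambda r: (-quota[r], order[r]))
        chosen = [r for r in ranked if quota[r] > 0][:size]
        if len(chosen) < size:
            raise RuntimeError("region quotas exhausted; pattern infeasible")
        for r in chosen:
            quota[r] -= 1
        pattern.append(frozenset(chosen))
    assert all(v == 0 for v in quota.values())
    return pattern


#: Synthetic regional genera with a nested taxonomy (7 genera, 4 tribes,
#: 3 subfamilies), standing in for the regional melittid fauna.
GENERA_TAXONOMY = {
    "GenusA": ("Tribe1", "Subfam1"),
    "GenusB": ("Tribe1", "Subfam1"),
    "GenusC": ("Tribe2", "Subfam1"),
    "GenusD": ("Tribe3", "Subfam2"),
    "GenusE": ("Tribe3", "Subfam2"),
    "GenusF": ("Tribe4", "Subfam3"),
    "GenusG": ("Tribe4", "Subfam3"),
}


def gen_museum_species_table(
    seed: int = 0,
    n_species: int = 56,
    it_range: tuple[float, float] = (0.99, 4.42),
    family: str = "Melittidae",
) -> list[SpeciesTraitMeans]:
    """Museum-style IT-only species means with the fixed region pattern.

    Species are spread round-robin over the seven synthetic genera; mean IT
    is log-uniform on ``it_range``.  For the default 56 species the region
    sets follow :func:`region_membership_pattern`; extra species (if any)
    are single-region winter.
    """
    rng = _rng(seed)
    pattern = region_membership_pattern()
    genera = list(GENERA_TAXONOMY)
    lo, hi = math.log(it_range[0]), math.log(it_range[1])
    out = []
    for i in range(n_species):
        genus = genera[i % len(genera)]
        regions = pattern[i] if i < len(pattern) else frozenset({"winter"})
        out.append(
            SpeciesTraitMeans(
                species=f"{genus}_sp{i:02d}",
                genus=genus,
                family=family,
                n_specimens=int(rng.integers(1, 41)),
                mean_it_mm=math.exp(rng.uniform(lo, hi)),
                regions=regions,
            )
        )
    return out


def gen_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int = 0, label_prefix: str = "G"
) -> dendropy.Tree:
    """Ultrametric pure-birth (Yule) tree with relabelled tips.

    The process is run until the n-th split and then extended by the waiting
    time to the (unrealised) next split, Exp(n * birth_rate), so pendant
    edges are strictly positive and no two tips coincide.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    from dendropy.model import birthdeath

    rng = random.Random(seed)
    tree = birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    final_wait = rng.expovariate(n_tips * birth_rate)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"{label_prefix}{i + 1}"
        leaf.edge.length = (leaf.edge.length or 0.0) + final_wait
    return tree


def gen_brownian_traits(
    tree: dendropy.Tree,
    sigma2: float,
    root_state: float,
    region_effects: dict[str, float] | None,
    region_assignment: dict[str, str],
    seed: int = 0,
) -> pd.DataFrame:
    """Brownian tip values plus additive region shifts.

    Tip value ~ MVN(root_state, sigma2 * V) with V the Brownian covariance
    of the tree, then + region_effects[region of tip].  Returns a
    comparative dataset frame (species, region, ln_it).
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    cov = brownian_covariance(tree)
    missing = set(cov.tips) - set(region_assignment)
    if missing:
        raise ValueError(f"region assignment missing tips: {sorted(missing)}")
    rng = _rng(seed)
    n = len(cov.tips)
    if sigma2 == 0:
        values = np.full(n, root_state)
    else:
        L = np.linalg.cholesky(sigma2 * cov.V + 1e-12 * np.eye(n))
        values = root_state + L @ rng.standard_normal(n)
    effects = region_effects or {}
    shifts = np.array([effects.get(region_assignment[t], 0.0) for t in cov.tips])
    return pd.DataFrame(
        {
            "species": list(cov.tips),
            "region": [region_assignment[t] for t in cov.tips],
            "ln_it": values + shifts,
        }
    )


def gen_nested_traits(
    n_subfamilies: int = 5,
    tribes_per_subfamily: int = 2,
    genera_per_tribe: int = 5,
    species_per_genus: int = 10,
    vc: tuple[float, float, float] = (1.0, 0.5, 0.25),
    resid_sd: float = 1.0,
    region_effects: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Nested-taxonomy traits for the LMM: subfamily/tribe/genus random
    intercepts with variances ``vc`` plus N(0, resid_sd^2) residuals.

    Regions are assigned round-robin over species; ``region_effects`` adds
    fixed shifts (default none: the null).  Default shape gives n = 500.
    """
    rng = _rng(seed)
    effects = region_effects or {}
    rows = []
    s_sub, s_tri, s_gen = vc
    i = 0
    for a in range(n_subfamilies):
        u_sub = rng.normal(0.0, math.sqrt(s_sub))
        for b in range(tribes_per_subfamily):
            u_tri = rng.normal(0.0, math.sqrt(s_tri))
            for c in range(genera_per_tribe):
                u_gen = rng.normal(0.0, math.sqrt(s_gen))
                for d in range(species_per_genus):
                    region = REGIONS[i % len(REGIONS)]
                    i += 1
                    rows.append(
                        {
                            "species": f"sf{a}t{b}g{c}_sp{d}",
                            "genus": f"sf{a}t{b}g{c}",
                            "tribe": f"sf{a}t{b}",
                            "subfamily": f"sf{a}",
                            "region": region,
                            "ln_it": u_sub
                            + u_tri
                            + u_gen
                            + effects.get(region, 0.0)
                            + rng.normal(0.0, resid_sd),
                        }
                    )
    return pd.DataFrame(rows)
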