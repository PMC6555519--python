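"""Phylogenetically controlled comparison of body size across rainfall regions.

Builds the working phylogeny (prune a genus-level backbone to the study
taxa, then graft species onto their genus tips as equal-branch-length
polytomies), derives the Brownian-motion covariance matrix V (V_ij = shared
root-to-MRCA path length), and tests whether ln(IT) differs among rainfall
regions with two complementary models:

* PGLS — generalized least squares with Brownian error covariance,
  compared against the intercept-only null by an F test on whitened
  residuals;
* LMM — a linear mixed model with nested taxonomic random intercepts
  (genus within tribe within subfamily), fitted by maximum likelihood and
  compared against the null by AIC / likelihood ratio.

Trees are :class:`dendropy.Tree` objects throughout (Newick I/O via
dendropy).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .morphodata import REGIONS

logger = logging.getLogger(__name__)

#: Diagonal jitter added to a numerically singular Brownian covariance.
COV_JITTER = 1e-10


class PhyloError(ValueError):
    """Tree/data inconsistency that prevents the comparative analysis."""


# ---------------------------------------------------------------------------
# Tree utilities


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path lengths.

    A root stem edge, when present, is counted: it holds history shared by
    every tip, and pruning a backbone folds the path from the original root
    into exactly such a stem, so counting it keeps tip depths invariant
    under pruning.
    """
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    stem = tree.seed_node.edge.length or 0.0
    return {
        leaf.taxon.label: leaf.root_distance + stem
        for leaf in tree.leaf_node_iter()
    }


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-9) -> bool:
    depths = list(tip_depths(tree).values())
    return max(depths) - min(depths) < tol


def prune_to_taxa(tree: dendropy.Tree, keep: set[str]) -> dendropy.Tree:
    """Induced subtree on ``keep``, preserving root-to-tip distances.

    Collapsed degree-2 nodes have their branch lengths summed (dendropy's
    extract-tree machinery), so kept tips keep their original depths.
    """
    keep = set(keep)
    present = set(tip_labels(tree))
    unknown = keep - present
    if unknown:
        raise PhyloError(f"taxa not in tree: {sorted(unknown)}")
    if not keep:
        raise PhyloError("keep set is empty")
    pruned = tree.extract_tree_with_taxa_labels(labels=keep)
    pruned.taxon_namespace = dendropy.TaxonNamespace(
        [t.label for t in pruned.taxon_namespace if t.label in keep]
    )
    pruned.migrate_taxon_namespace(pruned.taxon_namespace)
    return pruned


def graft_species_polytomies(
    tree: dendropy.Tree, mapping: dict[str, list[str]]
) -> dendropy.Tree:
    """Replace each genus tip by a polytomy of its species.

    A genus tip with terminal edge length l becomes a stem of length l/2
    ending in a node whose species tips each subtend an edge of length l/2,
    so every species tip sits at the depth of its genus tip and an
    ultrametric backbone stays ultrametric.  A single-species genus keeps
    the same stem/tip split with the species label replacing the genus.
    """
    grafted = dendropy.Tree(tree)
    leaves = {leaf.taxon.label: leaf for leaf in grafted.leaf_node_iter()}

    all_species: list[str] = []
    for genus, species_list in mapping.items():
        if genus not in leaves:
            raise PhyloError(f"genus {genus!r} is not a tip of the backbone")
        if not species_list:
            raise PhyloError(f"genus {genus!r} has an empty species list")
        all_species.extend(species_list)
    dupes = {s for s in all_species if all_species.count(s) > 1}
    if dupes:
        raise PhyloError(f"species assigned to more than one genus: {sorted(dupes)}")

    ns = grafted.taxon_namespace
    for genus, species_list in mapping.items():
        node = leaves[genus]
        length = node.edge.length
        if length is None:
            raise PhyloError(f"genus tip {genus!r} has no branch length")
        node.edge.length = length / 2.0
        node.taxon = None
        for sp in species_list:
            taxon = ns.new_taxon(sp)
            node.new_child(taxon=taxon, edge_length=length / 2.0)
    return grafted


# ---------------------------------------------------------------------------
# Brownian covariance


@dataclass
class BrownianCov:
    """Brownian-motion trait covariance implied by a rooted tree.

    ``V[i, j]`` is the root-to-MRCA path length of tips i and j (the shared
    evolutionary history); the diagonal holds root-to-tip depths.
    """

    V: np.ndarray
    tips: tuple[str, ...]


def brownian_covariance(tree: dendropy.Tree) -> BrownianCov:
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise PhyloError(f"negative branch length {edge.length}")

    depths = tip_depths(tree)
    tips = tuple(sorted(depths))
    index = {t: i for i, t in enumerate(tips)}
    n = len(tips)
    V = np.zeros((n, n))

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in index}
    d = np.array([depths[t] for t in tips])
    V[np.diag_indices(n)] = d
    for i, ti in enumerate(tips):
        for j in range(i + 1, n):
            patristic = pdm.patristic_distance(taxa[ti], taxa[tips[j]])
            # shared path = (depth_i + depth_j - patristic_ij) / 2
            V[i, j] = V[j, i] = 0.5 * (d[i] + d[j] - patristic)
    return BrownianCov(V=V, tips=tips)


def _cholesky_with_jitter(V: np.ndarray) -> tuple[np.ndarray, float]:
    try:
        return np.linalg.cholesky(V), 0.0
    except np.linalg.LinAlgError:
        logger.warning("covariance numerically singular; adding %.0e jitter", COV_JITTER)
        try:
            return (
                np.linalg.cholesky(V + COV_JITTER * np.eye(V.shape[0])),
                COV_JITTER,
            )
        except np.linalg.LinAlgError as exc:
            raise PhyloError(
                "covariance matrix not positive definite even after jitter"
            ) from exc


# ---------------------------------------------------------------------------
# PGLS


@dataclass
class PGLSResult:
    """Generalized least-squares fit under a fixed (Brownian) correlation."""

    design: str
    n: int
    k: int
    coefficients: dict[str, float]
    rss: float  # on whitened scale
    loglik: float
    aic: float
    tips: tuple[str, ...] = ()
    _y_fingerprint: float = field(default=0.0, repr=False)


def majority_region(region_counts: dict[str, int]) -> str:
    """Single modeling region for a species: the region holding most of its
    specimen records; ties broken by the fixed region ordering."""
    if not region_counts:
        raise PhyloError("no region counts supplied")
    order = {r: i for i, r in enumerate(REGIONS)}
    return max(region_counts, key=lambda r: (region_counts[r], -order[r]))


def _region_design(dataset: pd.DataFrame, design: str) -> tuple[np.ndarray, list[str]]:
    n = len(dataset)
    cols = [np.ones(n)]
    names = ["intercept"]
    if design == "region":
        present = [r for r in REGIONS if (dataset["region"] == r).any()]
        if len(present) < 2:
            raise PhyloError(f"region design needs >=2 regions, found {present}")
        for r in present[1:]:
            cols.append((dataset["region"] == r).to_numpy(dtype=float))
            names.append(f"region[{r}]")
    elif design != "intercept":
        raise PhyloError(f"design must be 'region' or 'intercept', got {design!r}")
    return np.column_stack(cols), names


def pgls_fit(dataset: pd.DataFrame, design: str, cov: BrownianCov) -> PGLSResult:
    """GLS fit of ln(IT) on the region factor (or intercept only) under V.

    ``dataset`` needs columns ``species``, ``ln_it`` and (for the region
    design) ``region``; species must match ``cov.tips`` one-to-one.
    Estimation whitens X and y with the Cholesky factor of V and solves the
    whitened least-squares problem, which is algebraically
    beta = (X' V^-1 X)^-1 X' V^-1 y.
    """
    data_species = list(dataset["species"])
    missing_in_data = set(cov.tips) - set(data_species)
    missing_in_tree = set(data_species) - set(cov.tips)
    if missing_in_data or missing_in_tree:
        raise PhyloError(
            f"species/tip mismatch: not in data {sorted(missing_in_data)}; "
            f"not in tree {sorted(missing_in_tree)}"
        )
    ordered = dataset.set_index("species").loc[list(cov.tips)].reset_index()

    y = ordered["ln_it"].to_numpy(dtype=float)
    X, names = _region_design(ordered, design)
    n, k = X.shape
    if n <= k:
        raise PhyloError(f"need n > k, got n={n}, k={k}")

    L, _ = _cholesky_with_jitter(cov.V)
    from scipy.linalg import solve_triangular

    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < k:
        raise PhyloError("singular whitened design")
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(L))))
    sigma2 = rss / n
    loglik = -0.5 * n * (math.log(2 * math.pi) + math.log(sigma2) + 1.0) - 0.5 * logdet_v
    aic = -2.0 * loglik + 2.0 * (k + 1)

    return PGLSResult(
        design=design,
        n=n,
        k=k,
        coefficients=dict(zip(names, beta)),
        rss=rss,
        loglik=loglik,
        aic=aic,
        tips=cov.tips,
        _y_fingerprint=float(y @ y),
    )


def pgls_anova(full: PGLSResult, null: PGLSResult) -> dict[str, float]:
    """F test of the nested null against the full PGLS model.

    F = ((RSS_null - RSS_full)/dk) / (RSS_full/(n - k_full)) on whitened
    residuals, with df = (k_full - k_null, n - k_full); with a region
    factor of g levels this is the conventional (g - 1, n - g) ANOVA.
    """
    if full.tips != null.tips or full.n != null.n:
        raise PhyloError("models were fitted on different tip sets")
    if full._y_fingerprint != null._y_fingerprint:
        raise PhyloError("models were fitted to different responses")
    if full.k <= null.k:
        raise PhyloError("models are not nested (full must add coefficients)")
    df1 = full.k - null.k
    df2 = full.n - full.k
    if df2 <= 0:
        raise PhyloError("no residual degrees of freedom")
    num = max(0.0, null.rss - full.rss) / df1
    if full.rss <= 0:
        f_stat, p = 0.0, 1.0
    else:
        f_stat = num / (full.rss / df2)
        p = float(stats.f.sf(f_stat, df1, df2))
    return {"F": f_stat, "df1": float(df1), "df2": float(df2), "p": p}


# ---------------------------------------------------------------------------
# Nested-taxonomy linear mixed model (maximum likelihood)


@dataclass
class LMMResult:
    """ML fit of a Gaussian LMM with nested random intercepts."""

    fixed: str
    n: int
    k_fixed: int
    coefficients: dict[str, float]
    vcomp: dict[str, float]  # variance components, outermost..innermost
    sigma2_resid: float
    loglik: float
    aic: float
    npar: int
    converged: bool


_NESTING = ("subfamily", "tribe", "genus")


def _nested_group_codes(dataset: pd.DataFrame) -> list[np.ndarray]:
    """Integer group codes for subfamily, tribe-in-subfamily, genus-in-tribe."""
    codes = []
    key = None
    for level in _NESTING:
        if level not in dataset.columns or dataset[level].eq("").any():
            raise PhyloError(f"taxonomy level {level!r} missing or incomplete")
        key = dataset[level] if key is None else key + "/" + dataset[level]
        codes.append(pd.factorize(key)[0])
    return codes


def _profile_loglik(
    gammas: np.ndarray, X: np.ndarray, y: np.ndarray, masks: list[np.ndarray]
) -> tuple[float, np.ndarray, float]:
    """Profiled ML log-likelihood at variance ratios gamma_k = sigma_k^2/sigma^2.

    Returns (loglik, beta_hat, sigma2_hat).  V0 = I + sum_k gamma_k Z_k Z_k'
    with Z_k the indicator matrix of nesting level k (``masks`` holds the
    precomputed Z_k Z_k' same-group matrices).
    """
    n = len(y)
    V0 = np.eye(n)
    for gamma, mask in zip(gammas, masks):
        if gamma > 0:
            V0 += gamma * mask
    L = np.linalg.cholesky(V0)
    from scipy.linalg import solve_triangular

    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * n * (math.log(2 * math.pi) + math.log(sigma2) + 1.0) - 0.5 * logdet
    return ll, beta, sigma2


def lmm_fit(
    dataset: pd.DataFrame, fixed: str = "region", force_zero_variance: bool = False
) -> LMMResult:
    """ML fit of ln(IT) ~ fixed effects + nested taxonomic random intercepts.

    ``fixed`` is ``"region"`` or ``"intercept"``.  Random intercepts for
    subfamily, tribe within subfamily, and genus within tribe.  The
    likelihood is profiled over the fixed effects and the residual variance
    and maximised over the three variance ratios with a derivative-free
    optimiser; an exact zero-boundary candidate is always evaluated, so
    degenerate data (no group structure) collapse cleanly to the OLS
    likelihood.  ``force_zero_variance`` pins all variance components at the
    zero boundary (the model then coincides with OLS).  AIC counts fixed
    effects + variance components + residual variance.
    """
    y = dataset["ln_it"].to_numpy(dtype=float)
    X, names = _region_design(dataset, fixed)
    codes = _nested_group_codes(dataset)
    n, k = X.shape
    if n <= k:
        raise PhyloError(f"need n > k, got n={n}, k={k}")
    if all(len(np.unique(c)) < 2 for c in codes):
        raise PhyloError("all taxonomic grouping factors have a single level")
    masks = [(c[:, None] == c[None, :]).astype(float) for c in codes]

    def neg_ll(theta: np.ndarray) -> float:
        return -_profile_loglik(theta**2, X, y, masks)[0]

    candidates: list[tuple[float, np.ndarray, bool]] = []
    # exact boundary: all variance components zero (plain OLS)
    candidates.append((-neg_ll(np.zeros(3)), np.zeros(3), True))
    converged = True
    for start in () if force_zero_variance else (0.5, 0.05):
        res = optimize.minimize(
            neg_ll,
            np.full(3, math.sqrt(start)),
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 1000},
        )
        converged = converged and bool(res.success)
        theta = np.abs(res.x)
        candidates.append((-res.fun, theta, bool(res.success)))
        # clip tiny components to the boundary and re-evaluate
        clipped = np.where(theta**2 < 1e-7, 0.0, theta)
        if not np.array_equal(clipped, theta):
            candidates.append((-neg_ll(clipped), clipped, bool(res.success)))

    best_ll, best_theta, _ = max(candidates, key=lambda c: c[0])
    gammas = best_theta**2
    ll, beta, sigma2 = _profile_loglik(gammas, X, y, masks)
    npar = k + len(gammas) + 1
    return LMMResult(
        fixed=fixed,
        n=n,
        k_fixed=k,
        coefficients=dict(zip(names, beta)),
        vcomp={lvl: float(g * sigma2) for lvl, g in zip(_NESTING, gammas)},
        sigma2_resid=float(sigma2),
        loglik=float(ll),
        aic=float(-2.0 * ll + 2.0 * npar),
        npar=npar,
        converged=converged,
    )


def lmm_compare(null: LMMResult, full: LMMResult) -> dict[str, float | str]:
    """Likelihood-ratio test and AIC comparison of nested LMM fits."""
    if full.n != null.n:
        raise PhyloError("LMM fits use different sample sizes")
    if full.npar <= null.npar:
        raise PhyloError("models are not nested (full must add parameters)")
    df = full.npar - null.npar
    lrt = max(0.0, 2.0 * (full.loglik - null.loglik))
    p = float(stats.chi2.sf(lrt, df))
    best = "null" if null.aic <= full.aic else "full"
    return {
        "lrt": lrt,
        "df": float(df),
        "p": p,
        "aic_null": null.aic,
        "aic_full": full.aic,
        "best": best,
    }
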