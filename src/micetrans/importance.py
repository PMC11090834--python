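"""Leave-one-genus-out importance scores and phenotype regression.

For each genus, all its ASVs are dropped, the Jaccard response is
recomputed on the reduced ASV universe, the dyadic beta regression is
refit with an identical spec and seed, and the relative widening of each
effect's 95% credible interval is recorded:

    importance = ((CIw_excl - CIw_incl) / CIw_incl) / sqrt(n_ASV)

Raw scores are min-max scaled within each effect, then regressed on
genus phenotypes (aerotolerance, sporulation) with a
phylogenetically correlated genus-level random effect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import dyadic
from .mcmc import MarginalGaussianRegression, sample
from .similarity import jaccard_matrix

logger = logging.getLogger(__name__)

#: effect label -> model term
EFFECT_TERMS = {"social": "sri", "spatial": "spatial_overlap",
                "habitat": "habitat_similarity"}
PHENO_CELLS = ["AE-SF", "AE-NSF", "AN-SF", "AN-NSF"]


@dataclass
class ImportanceRecord:
    genus: str
    effect: str
    ciw_incl: float
    ciw_excl: float
    n_asv: int
    raw: float
    converged: bool = True
    scaled: float = None

    def __post_init__(self):
        if self.ciw_incl <= 0 or self.ciw_excl <= 0:
            raise ValueError("CI widths must be positive")
        if self.n_asv < 1:
            raise ValueError("n_asv must be >= 1")


def raw_importance(ciw_incl: float, ciw_excl: float, n_asv: int) -> float:
    """((CIw_excl - CIw_incl) / CIw_incl) / sqrt(n_ASV)."""
    if ciw_incl <= 0:
        raise ValueError("baseline CI width must be positive")
    if n_asv < 1:
        raise ValueError("n_asv must be >= 1")
    return ((ciw_excl - ciw_incl) / ciw_incl) / math.sqrt(n_asv)


@dataclass
class DyadContext:
    """Everything needed to (re)build dyads and refit the baseline model."""

    counts: pd.DataFrame        # samples x ASVs
    genus_map: pd.Series        # ASV -> genus
    metadata: pd.DataFrame
    sri: object
    overlap: object
    habitat: object
    spec: dyadic.ModelSpec
    _base_dyads: pd.DataFrame = field(default=None, repr=False)

    def dyads_for(self, counts: pd.DataFrame) -> pd.DataFrame:
        """Dyadic dataset with the response recomputed from ``counts``."""
        sim = jaccard_matrix(counts)
        if self._base_dyads is None:
            self._base_dyads = dyadic.build_dyads(
                self.metadata, sim, self.sri, self.overlap, self.habitat)
            return self._base_dyads
        d = self._base_dyads.copy()
        idx = {s: i for i, s in enumerate(sim.ids)}
        ia = d["sample_a"].map(idx).to_numpy()
        ib = d["sample_b"].map(idx).to_numpy()
        d["response"] = sim.values[ia, ib]
        return d

    def fit_counts(self, counts: pd.DataFrame) -> dyadic.PosteriorFit:
        return dyadic.fit(self.dyads_for(counts), self.spec)


def loo_importance(ctx: DyadContext, baseline: dyadic.PosteriorFit, genus: str):
    """Importance records (social, spatial, habitat) for one genus."""
    asvs = ctx.genus_map.index[ctx.genus_map == genus]
    if len(asvs) == 0:
        raise ValueError(f"genus {genus!r} not present in the table")
    reduced = ctx.counts.drop(columns=[a for a in asvs if a in ctx.counts.columns])
    if reduced.shape[1] == 0:
        raise ValueError(f"genus {genus!r} is the entire community")
    refit = ctx.fit_counts(reduced)
    if not refit.converged:
        logger.warning("refit without %s flagged non-converged", genus)
    records = []
    for effect, term in EFFECT_TERMS.items():
        ciw_incl = baseline.ci_width(term)
        ciw_excl = refit.ci_width(term)
        records.append(ImportanceRecord(
            genus=genus, effect=effect, ciw_incl=ciw_incl, ciw_excl=ciw_excl,
            n_asv=int(len(asvs)),
            raw=raw_importance(ciw_incl, ciw_excl, len(asvs)),
            converged=refit.converged))
    return records


def compute_importance(ctx: DyadContext, genera=None):
    """Baseline fit plus LOO importance records for each genus.

    Returns (records dataframe, baseline fit). Non-converged refits are
    kept in the table but flagged for exclusion downstream.
    """
    baseline = ctx.fit_counts(ctx.counts)
    if not baseline.converged:
        logger.warning("baseline fit flagged non-converged")
    if genera is None:
        genera = sorted(ctx.genus_map.unique())
    rows = []
    for genus in genera:
        for rec in loo_importance(ctx, baseline, genus):
            rows.append(rec.__dict__)
    return pd.DataFrame(rows), baseline


def scale_importance(records: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale raw importance to [0, 1] within each effect."""
    out = records.copy()
    out["scaled"] = np.nan
    for effect, grp in out.groupby("effect"):
        if len(grp) < 2:
            raise ValueError(f"need >= 2 genera per effect, got {len(grp)} for {effect}")
        lo, hi = grp["raw"].min(), grp["raw"].max()
        if hi == lo:
            logger.warning("constant raw importance for %s: scaled to 0", effect)
            out.loc[grp.index, "scaled"] = 0.0
        else:
            out.loc[grp.index, "scaled"] = (grp["raw"] - lo) / (hi - lo)
    return out


def phylo_cov(tree, genera=None) -> pd.DataFrame:
    """Shared-path-length correlation matrix from a newick tree over genera.

    ``tree`` is a newick string, a path, or a dendropy Tree whose tips
    cover the modelled genera. The covariance between two tips is the
    root-to-MRCA path length; the matrix is scaled to unit diagonal.
    """
    import dendropy

    if isinstance(tree, dendropy.Tree):
        t = tree
    else:
        text = str(tree)
        if "(" not in text:  # looks like a path
            t = dendropy.Tree.get(path=text, schema="newick")
        else:
            t = dendropy.Tree.get(data=text, schema="newick")
    t.calc_node_root_distances(return_leaf_distances_only=False)
    taxa = {leaf.taxon.label: leaf for leaf in t.leaf_node_iter()}
    if genera is None:
        genera = sorted(taxa)
    missing = [g for g in genera if g not in taxa]
    if missing:
        raise ValueError(f"tips missing from tree: {missing}")
    pdm = t.phylogenetic_distance_matrix()
    n = len(genera)
    cov = np.empty((n, n))
    for i, gi in enumerate(genera):
        di = taxa[gi].root_distance
        cov[i, i] = di
        for j in range(i + 1, n):
            gj = genera[j]
            dj = taxa[gj].root_distance
            patristic = pdm.patristic_distance(taxa[gi].taxon, taxa[gj].taxon)
            cov[i, j] = cov[j, i] = 0.5 * (di + dj - patristic)
    d = np.sqrt(np.maximum(np.diag(cov), 1e-12))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=genera, columns=genera)


def rank_cov(ranks: pd.DataFrame) -> pd.DataFrame:
    """Taxonomy-based fallback correlation: same family 0.5, same phylum
    0.25, otherwise 0.05, unit diagonal. ``ranks`` has family/phylum columns."""
    genera = list(ranks.index)
    n = len(genera)
    corr = np.full((n, n), 0.05)
    fam = ranks["family"].to_numpy()
    phy = ranks["phylum"].to_numpy()
    same_phy = phy[:, None] == phy[None, :]
    same_fam = fam[:, None] == fam[None, :]
    corr[same_phy] = 0.25
    corr[same_fam] = 0.5
    np.fill_diagonal(corr, 1.0)
    logger.warning("using taxonomy-rank fallback correlation (no tree supplied)")
    return pd.DataFrame(corr, index=genera, columns=genera)


@dataclass
class PhenoRegressionFit:
    fit: dyadic.PosteriorFit
    contrasts: pd.DataFrame = None  # four_level post hoc: cell vs pooled rest


def phenotype_regression(scores: pd.Series, phenotypes: pd.DataFrame,
                         cov: pd.DataFrame = None,
                         factorization: str = "two_binary_plus_interaction",
                         mcmc=None, seed: int = 0) -> PhenoRegressionFit:
    """Gaussian regression of importance scores on phenotypes.

    ``scores`` maps genus -> scaled importance for one effect;
    ``phenotypes`` carries 0/1 aerotolerant and spore_forming columns.
    A genus-level random effect with correlation ``cov`` (identity when
    None) absorbs phylogenetic structure. ``four_level`` uses cell-means
    coding over the four phenotype combinations and reports post hoc
    contrasts of each cell against the pooled rest.
    """
    genera = [g for g in scores.index if g in phenotypes.index]
    y = scores.loc[genera].to_numpy(float)
    aero = phenotypes.loc[genera, "aerotolerant"].to_numpy(float)
    spore = phenotypes.loc[genera, "spore_forming"].to_numpy(float)
    if factorization == "two_binary_plus_interaction":
        X = np.column_stack([np.ones_like(y), aero, spore, aero * spore])
        names = ["intercept", "aerotolerant", "spore_forming", "aero_x_spore"]
    elif factorization == "four_level":
        cells = np.where(aero == 1, np.where(spore == 1, "AE-SF", "AE-NSF"),
                         np.where(spore == 1, "AN-SF", "AN-NSF"))
        counts = pd.Series(cells).value_counts()
        thin = [c for c in PHENO_CELLS if counts.get(c, 0) < 2]
        if thin:
            raise ValueError(f"need >= 2 genera per phenotype cell; thin: {thin}")
        X = np.column_stack([(cells == c).astype(float) for c in PHENO_CELLS])
        names = [f"mu_{c}" for c in PHENO_CELLS]
    else:
        raise ValueError(f"unknown factorization {factorization!r}")

    if cov is None:
        C = np.eye(len(genera))
    else:
        C = cov.loc[genera, genera].to_numpy(float)
        try:
            np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            logger.warning("singular phylogenetic covariance: adding 1e-8 jitter")
            C = C + 1e-8 * np.eye(C.shape[0])
    model = MarginalGaussianRegression(y, X, C=C, term_names=names)
    mcmc = mcmc or replace(dyadic.REDUCED_MCMC)
    res = sample(model, mcmc, seed=seed)
    dataset = pd.DataFrame({"response": y}, index=genera)
    fit = dyadic._summarize(model, res, dataset,
                            dyadic.ModelSpec(likelihood="gaussian", mcmc=mcmc,
                                             seed=seed), X, names)
    contrasts = None
    if factorization == "four_level":
        rows = []
        for c in PHENO_CELLS:
            others = [f"mu_{o}" for o in PHENO_CELLS if o != c]
            delta = fit.term_draws[f"mu_{c}"] - sum(
                fit.term_draws[o] for o in others) / len(others)
            flat = delta.reshape(-1)
            rows.append({"cell": c, "mean": float(flat.mean()),
                         "ci_low": float(np.percentile(flat, 2.5)),
                         "ci_high": float(np.percentile(flat, 97.5))})
        contrasts = pd.DataFrame(rows).set_index("cell")
    return PhenoRegressionFit(fit=fit, contrasts=contrasts)


def importance_correlations(scores: pd.DataFrame, n_perm: int = 999,
                            seed=None) -> pd.DataFrame:
    """Pairwise Pearson r (and permutation p) among effect score vectors.

    ``scores`` is genus-indexed with one column per effect.
    """
    rng = np.random.default_rng(seed)
    effects = list(scores.columns)
    rows = []
    for i, e1 in enumerate(effects):
        for e2 in effects[i + 1:]:
            v1 = scores[e1].to_numpy(float)
            v2 = scores[e2].to_numpy(float)
            r = float(np.corrcoef(v1, v2)[0, 1])
            hits = 0
            for _ in range(n_perm):
                rp = np.corrcoef(v1, rng.permutation(v2))[0, 1]
                if abs(rp) >= abs(r) - 1e-12:
                    hits += 1
            rows.append({"effect_a": e1, "effect_b": e2, "r": r,
                         "p": (hits + 1) / (n_perm + 1)})
    return pd.DataFrame(rows)
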