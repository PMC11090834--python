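"""Dyadic Bayesian regression of microbiota similarity on transmission proxies.

One row per unordered pair of samples from two different individuals,
with social association (SRI), spatial (home range) overlap and habitat
similarity as predictors, technical/biological covariates, and
multi-membership random intercepts for samples and for individuals:

    eta = b0 + X b + u[sample_a] + u[sample_b] + v[indiv_a] + v[indiv_b]
    y ~ Beta(mu * phi, (1 - mu) * phi),  mu = inv-logit(eta)

(Poisson with log link for shared-taxon counts, Gaussian for general use.)
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .mcmc import GLMM, Group, SamplerConfig, sample
from .similarity import smithson_verkuilen

logger = logging.getLogger(__name__)

PREDICTORS = ["sri", "spatial_overlap", "habitat_similarity"]
COVARIATES = ["age_similarity", "sex_similarity", "time_interval_days",
              "extraction_distance", "read_depth_difference", "plate_similarity"]

#: Paper-scale MCMC profile.
FULL_MCMC = SamplerConfig(chains=4, warmup=1000, draws=4000)
#: Reduced profile for tests and desk-scale runs.
REDUCED_MCMC = SamplerConfig(chains=2, warmup=300, draws=700)


def _matrix_lookup(obj):
    """Accept AssociationMatrix/SimilarityMatrix/(ids, ndarray) uniformly."""
    if isinstance(obj, tuple):
        ids, m = obj
    else:
        ids, m = obj.ids, getattr(obj, "sri", None)
        if m is None:
            m = obj.values
    return {k: i for i, k in enumerate(ids)}, np.asarray(m, dtype=float)


def build_dyads(metadata: pd.DataFrame, response, sri, overlap, habitat) -> pd.DataFrame:
    """Assemble the dyadic dataset.

    ``metadata`` is indexed by sample id with columns: individual, date,
    sex, age_class, plate, extraction_row, extraction_col, read_depth.
    ``response`` is a sample-level similarity matrix; the three
    predictors are individual-level matrices. Samples whose individual
    is missing from any predictor matrix are dropped (logged).
    """
    resp_idx, resp_m = _matrix_lookup(response)
    sri_idx, sri_m = _matrix_lookup(sri)
    ovl_idx, ovl_m = _matrix_lookup(overlap)
    hab_idx, hab_m = _matrix_lookup(habitat)

    meta = metadata.copy()
    meta["date"] = pd.to_datetime(meta["date"])
    usable = [s for s in meta.index
              if s in resp_idx
              and meta.at[s, "individual"] in sri_idx
              and meta.at[s, "individual"] in ovl_idx
              and meta.at[s, "individual"] in hab_idx]
    dropped = len(meta) - len(usable)
    if dropped:
        logger.info("build_dyads: dropped %d samples lacking predictor coverage", dropped)
    rows = []
    for i, sa in enumerate(usable):
        ma = meta.loc[sa]
        for sb in usable[i + 1:]:
            mb = meta.loc[sb]
            ia, ib = ma["individual"], mb["individual"]
            if ia == ib:
                continue
            sexes = "".join(sorted([str(ma["sex"]), str(mb["sex"])]))
            rows.append({
                "sample_a": sa, "sample_b": sb, "indiv_a": ia, "indiv_b": ib,
                "response": resp_m[resp_idx[sa], resp_idx[sb]],
                "sri": sri_m[sri_idx[ia], sri_idx[ib]],
                "spatial_overlap": ovl_m[ovl_idx[ia], ovl_idx[ib]],
                "habitat_similarity": hab_m[hab_idx[ia], hab_idx[ib]],
                "age_similarity": float(ma["age_class"] == mb["age_class"]),
                "sex_similarity": float(ma["sex"] == mb["sex"]),
                "sex_combo": sexes,
                "time_interval_days": abs((ma["date"] - mb["date"]).days),
                "extraction_distance": float(np.hypot(
                    ma["extraction_row"] - mb["extraction_row"],
                    ma["extraction_col"] - mb["extraction_col"])),
                "read_depth_difference": abs(float(ma["read_depth"]) - float(mb["read_depth"])),
                "plate_similarity": float(ma["plate"] == mb["plate"]),
            })
    return pd.DataFrame(rows)


@dataclass
class ModelSpec:
    """Likelihood, fixed-effect terms, interaction switch and MCMC profile."""

    likelihood: str = "beta"
    terms: list = field(default_factory=lambda: PREDICTORS + COVARIATES)
    sex_interaction: bool = False
    mcmc: SamplerConfig = field(default_factory=lambda: replace(FULL_MCMC))
    seed: int = 0

    def __post_init__(self):
        if self.likelihood not in ("beta", "poisson", "gaussian"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if self.mcmc.chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")


@dataclass
class PosteriorFit:
    """Posterior draws, summaries and convergence diagnostics."""

    summary: pd.DataFrame          # term, mean, ci_low, ci_high, rhat, ess_bulk
    term_draws: dict               # name -> (chains, draws) constrained
    covariate_means: dict          # sample means of fixed-effect columns
    likelihood: str
    divergences: int
    max_rhat: float
    min_ess: float
    n_obs: int
    converged: bool
    spec: ModelSpec = None

    def coef(self, term) -> float:
        return float(self.summary.loc[term, "mean"])

    def ci(self, term):
        row = self.summary.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])

    def ci_width(self, term) -> float:
        lo, hi = self.ci(term)
        return hi - lo

    def ci_excludes_zero(self, term) -> bool:
        lo, hi = self.ci(term)
        return lo > 0 or hi < 0


#: nuisance covariates on unbounded scales, standardized to unit SD before
#: fitting (the three transmission predictors stay on their raw [0, 1] scale)
_STANDARDIZED = ("time_interval_days", "extraction_distance",
                 "read_depth_difference")


def _design(dataset: pd.DataFrame, spec: ModelSpec):
    terms = [t for t in spec.terms if t in dataset.columns]
    skipped = set(spec.terms) - set(terms)
    if skipped:
        logger.info("terms missing from dataset, skipped: %s", sorted(skipped))
    cols = [np.ones(len(dataset))]
    names = ["intercept"]
    for t in terms:
        x = dataset[t].to_numpy(float)
        if x.std() == 0:
            logger.info("dropping constant term %r (confounded with intercept)", t)
            continue
        if t in _STANDARDIZED:
            x = x / x.std()
        cols.append(x)
        names.append(t)
    if spec.sex_interaction:
        combos = sorted(dataset["sex_combo"].unique())
        expected = ["FF", "FM", "MM"]
        missing = [c for c in expected if c not in combos]
        if missing:
            raise ValueError(f"empty sex_combo level(s): {missing}")
        for combo in expected[1:]:  # FF is the reference level
            ind = (dataset["sex_combo"] == combo).to_numpy(float)
            cols.append(ind)
            names.append(f"sex_{combo}")
            cols.append(ind * dataset["sri"].to_numpy(float))
            names.append(f"sri:sex_{combo}")
    return np.column_stack(cols), names


def _membership(dataset, col_a, col_b, name):
    levels = sorted(set(dataset[col_a]) | set(dataset[col_b]))
    lookup = {k: i for i, k in enumerate(levels)}
    ia = dataset[col_a].map(lookup).to_numpy(np.int64)
    ib = dataset[col_b].map(lookup).to_numpy(np.int64)
    return Group(name=name, n_levels=len(levels), idx_a=ia, idx_b=ib)


def fit(dataset: pd.DataFrame, spec: ModelSpec) -> PosteriorFit:
    """Fit the multi-membership GLMM by HMC and summarize the posterior."""
    y = dataset["response"].to_numpy(float)
    if spec.likelihood == "beta" and ((y <= 0).any() or (y >= 1).any()):
        logger.info("boundary responses present: applying (y*(n-1)+0.5)/n")
        y = smithson_verkuilen(y, len(y))
    X, names = _design(dataset, spec)
    groups = [_membership(dataset, "sample_a", "sample_b", "samples"),
              _membership(dataset, "indiv_a", "indiv_b", "individuals")]
    model = GLMM(y, X, groups, likelihood=spec.likelihood, term_names=names)
    res = sample(model, spec.mcmc, seed=spec.seed)
    return _summarize(model, res, dataset, spec, X, names)


def _summarize(model, res, dataset, spec, X, names) -> PosteriorFit:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset({"theta": res.draws})
        rhat = az.rhat(ds)["theta"].to_numpy()
        ess = az.ess(ds, method="bulk")["theta"].to_numpy()
    constrained = model.constrain(res.draws)
    all_names = model.param_names()
    pos = {n: i for i, n in enumerate(all_names)}
    rows = []
    for name, draws in constrained.items():
        flat = draws.reshape(-1)
        rows.append({
            "term": name,
            "mean": float(flat.mean()),
            "ci_low": float(np.percentile(flat, 2.5)),
            "ci_high": float(np.percentile(flat, 97.5)),
            "rhat": float(rhat[pos[name]]),
            "ess_bulk": float(ess[pos[name]]),
        })
    summary = pd.DataFrame(rows).set_index("term")
    total_draws = res.draws.shape[0] * res.draws.shape[1]
    # gate convergence on the monitored (reported) parameters, i.e. fixed
    # effects, group SDs and the auxiliary scale -- the set a brms-style
    # summary prints -- not on the latent per-level intercepts
    monitored = [pos[n] for n in constrained]
    max_rhat = float(np.nanmax(rhat[monitored]))
    min_ess = float(np.nanmin(ess[monitored]))
    converged = (max_rhat < 1.05 and min_ess >= 0.1 * total_draws
                 and res.divergences <= 10)
    if not converged:
        logger.warning("fit flagged non-converged: max Rhat %.3f, min ESS %.0f, "
                       "%d divergences", max_rhat, min_ess, res.divergences)
    cov_means = {n: float(X[:, i].mean()) for i, n in enumerate(names) if n != "intercept"}
    return PosteriorFit(summary=summary, term_draws=constrained,
                        covariate_means=cov_means, likelihood=spec.likelihood,
                        divergences=res.divergences, max_rhat=max_rhat,
                        min_ess=min_ess, n_obs=len(dataset), converged=converged,
                        spec=spec)


def fit_interaction(dataset: pd.DataFrame, spec: ModelSpec) -> PosteriorFit:
    """Fit with a sex_combo x SRI interaction; adds per-category SRI slopes."""
    spec = replace(spec, sex_interaction=True)
    out = fit(dataset, spec)
    sri = out.term_draws["sri"]
    derived = {"sri_FF": sri,
               "sri_FM": sri + out.term_draws["sri:sex_FM"],
               "sri_MM": sri + out.term_draws["sri:sex_MM"]}
    rows = []
    for name, draws in derived.items():
        flat = draws.reshape(-1)
        rows.append({"term": name, "mean": float(flat.mean()),
                     "ci_low": float(np.percentile(flat, 2.5)),
                     "ci_high": float(np.percentile(flat, 97.5)),
                     "rhat": np.nan, "ess_bulk": np.nan})
        out.term_draws[name] = draws
    out.summary = pd.concat([out.summary, pd.DataFrame(rows).set_index("term")])
    return out


def predict_expected(fit_or_coefs, x: dict) -> float:
    """Expected response inv-logit(b0 + sum b_k x_k) at given predictor values.

    ``fit_or_coefs`` is a PosteriorFit (posterior-mean coefficients) or a
    plain mapping with an ``intercept`` entry; unspecified terms default
    to zero.
    """
    if isinstance(fit_or_coefs, PosteriorFit):
        coefs = {t: fit_or_coefs.coef(t) for t in fit_or_coefs.summary.index
                 if t not in ("phi", "sigma") and not t.startswith("sd_")}
    else:
        coefs = dict(fit_or_coefs)
    eta = coefs.get("intercept", 0.0)
    for k, v in x.items():
        eta += coefs.get(k, 0.0) * v
    return float(expit(eta))


def conditional_effect(fit: PosteriorFit, predictor: str, grid) -> pd.DataFrame:
    """Posterior mean and 95% band of mu over a predictor grid.

    Other covariates are held at their sample means and random effects
    at zero.
    """
    if predictor not in fit.term_draws:
        raise KeyError(f"unknown predictor {predictor!r}")
    grid = np.asarray(grid, dtype=float)
    b0 = fit.term_draws["intercept"].reshape(-1)
    eta = np.broadcast_to(b0, (len(grid), b0.size)).copy()
    for term, mean_x in fit.covariate_means.items():
        draws = fit.term_draws[term].reshape(-1)
        if term == predictor:
            eta += np.outer(grid, draws)
        else:
            eta += mean_x * draws
    mu = expit(eta) if fit.likelihood == "beta" else eta
    if fit.likelihood == "poisson":
        mu = np.exp(np.clip(eta, -30, 30))
    return pd.DataFrame({
        "grid": grid,
        "mean": mu.mean(axis=1),
        "ci_low": np.percentile(mu, 2.5, axis=1),
        "ci_high": np.percentile(mu, 97.5, axis=1),
    })


__all__ = ["PREDICTORS", "COVARIATES", "FULL_MCMC", "REDUCED_MCMC", "ModelSpec",
           "PosteriorFit", "build_dyads", "fit", "fit_interaction",
           "predict_expected", "conditional_effect", "logit", "expit"]
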