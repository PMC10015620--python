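"""Plant-pollinator network indices, visitation BLUPs, variable pruning
and ordinations for the ecological side of the analysis.

The visitation matrix has plant populations as rows and pollinator
functional categories as columns; all species-level indices treat the
population's visit distribution p over categories against the availability
distribution q (column totals over the grand total).

Index definitions (natural log throughout):

* normalized degree  — realized partner categories / possible categories
* species strength   — sum over categories of the population's share of
  that category's total visits (sum of dependencies)
* species specificity — coefficient of variation of the population's
  interaction counts, normalized to [0,1] (1 = all visits in one category)
* partner diversity  — Shannon H of p
* effective partners — exp(H)
* proportional similarity — 1 - 0.5 * sum |p - q|
* proportional generality — exp(H(p)) / exp(H(q))
* d-index (d') — Kullback-Leibler specialization d = sum p ln(p/q),
  normalized by the analytic maximum ln(1/q_min) reached when all visits
  concentrate on the rarest available partner; d' = 0 exactly when p = q.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "network_indices",
    "blup_visits",
    "spearman_prune",
    "env_pca",
    "genomic_pc",
]

log = logging.getLogger(__name__)

INDEX_COLUMNS = [
    "normalized_degree",
    "species_strength",
    "species_specificity",
    "partner_diversity",
    "effective_partners",
    "proportional_similarity",
    "proportional_generality",
    "d_index",
]


def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def network_indices(visits: pd.DataFrame) -> pd.DataFrame:
    """All eight species-level indices per population (row)."""
    m = visits.to_numpy(dtype=float)
    if np.any(m < 0):
        raise ValueError("visitation counts must be nonnegative")
    zero_rows = np.flatnonzero(m.sum(axis=1) == 0)
    if zero_rows.size:
        raise ValueError(
            f"population(s) with no visits: {list(visits.index[zero_rows])}"
        )
    n_pop, n_cat = m.shape
    col_tot = m.sum(axis=0)
    q = col_tot / col_tot.sum()
    h_q = _shannon(q)
    q_min = q[q > 0].min()
    d_max = np.log(1.0 / q_min)

    rows = []
    for i in range(n_pop):
        counts = m[i]
        tot = counts.sum()
        p = counts / tot
        h = _shannon(p)
        # dependencies: this population's share of each category's visits
        with np.errstate(invalid="ignore", divide="ignore"):
            dep = np.where(col_tot > 0, counts / col_tot, 0.0)
        cv = counts.std() / counts.mean()  # population sd (ddof=0)
        sel = (p > 0) & (q > 0)
        d = float((p[sel] * np.log(p[sel] / q[sel])).sum())
        rows.append(
            {
                "normalized_degree": float((counts > 0).sum() / n_cat),
                "species_strength": float(dep.sum()),
                "species_specificity": float(cv / np.sqrt(n_cat - 1)),
                "partner_diversity": h,
                "effective_partners": float(np.exp(h)),
                "proportional_similarity": float(1.0 - 0.5 * np.abs(p - q).sum()),
                "proportional_generality": float(np.exp(h) / np.exp(h_q)),
                "d_index": float(np.clip(d / d_max, 0.0, 1.0)) if d_max > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows, index=visits.index, columns=INDEX_COLUMNS)


def blup_visits(plant_level: pd.DataFrame, response: str = "visits") -> dict:
    """One-way random-effects model Y_i = mu + population + eps_i by REML.

    Returns the grand mean, REML variance components, shrinkage per
    population and the BLUP predictions mu + shrink_k * (ybar_k - mu).
    """
    pops = plant_level["population"]
    if pops.nunique() < 2:
        raise ValueError("variance components unidentifiable with one population")
    model = smf.mixedlm(f"{response} ~ 1", plant_level, groups=pops)
    with np.errstate(all="ignore"):
        fit = model.fit(reml=True, method="lbfgs")
    mu = float(fit.params["Intercept"])
    var_pop = float(fit.cov_re.iloc[0, 0])
    var_res = float(fit.scale)

    groups = plant_level.groupby("population")[response]
    n_k = groups.size()
    ybar = groups.mean()
    shrink = var_pop / (var_pop + var_res / n_k) if var_pop > 0 else n_k * 0.0
    preds = mu + shrink * (ybar - mu)
    return {
        "mu": mu,
        "var_pop": var_pop,
        "var_res": var_res,
        "shrinkage": shrink,
        "predictions": preds,
        "population_effects": preds - mu,
        "fit": fit,
    }


def spearman_prune(env: pd.DataFrame, rho_max: float = 0.8) -> list[str]:
    """Greedy pruning of rank-correlated variables (|rho| >= rho_max).

    Offending pairs are scanned by descending |rho| then lexical order and
    the later-in-input-order member is dropped unless the pair is already
    resolved.  Constant variables cannot enter the correlation and are
    flagged, excluded from pruning decisions, and retained.
    """
    if env.shape[1] < 2:
        raise ValueError("need at least two variables")
    cols = list(env.columns)
    constant = [c for c in cols if env[c].nunique() <= 1]
    if constant:
        log.warning("constant variables excluded from pruning: %s", constant)
    active = [c for c in cols if c not in constant]

    pairs = []
    for i, a in enumerate(active):
        for b in active[i + 1 :]:
            rho, _ = stats.spearmanr(env[a], env[b])
            if np.isnan(rho):
                continue
            if abs(rho) >= rho_max:
                pairs.append((abs(rho), tuple(sorted((a, b))), a, b))
    pairs.sort(key=lambda t: (-t[0], t[1]))

    dropped: set[str] = set()
    for rho_abs, _, a, b in pairs:
        if a in dropped or b in dropped:
            continue
        later = b if cols.index(b) > cols.index(a) else a
        dropped.add(later)
        log.info("dropping %s (|rho|=%.3f with %s)", later, rho_abs, a if later == b else b)
    return [c for c in cols if c not in dropped]


def env_pca(env: pd.DataFrame) -> dict:
    """PCA of standardized variables (eigendecomposition of the correlation
    matrix) with a deterministic sign convention."""
    if (env.std(ddof=0) == 0).any():
        bad = list(env.columns[env.std(ddof=0) == 0])
        raise ValueError(f"constant variables not allowed in PCA: {bad}")
    x = (env - env.mean()) / env.std(ddof=0)
    u, s, vt = np.linalg.svd(x.to_numpy(), full_matrices=False)
    # sign convention: largest-magnitude loading positive
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    var = s**2 / (s**2).sum()
    ncomp = s.shape[0]
    scores = pd.DataFrame(
        u * s, index=env.index, columns=[f"PC{i + 1}" for i in range(ncomp)]
    )
    loadings = pd.DataFrame(
        vt.T, index=env.columns, columns=[f"PC{i + 1}" for i in range(ncomp)]
    )
    return {"scores": scores, "loadings": loadings, "variance_explained": var}


def genomic_pc(
    env: pd.DataFrame,
    freqs,
    coords: pd.DataFrame | None = None,
) -> dict:
    """SVD of the raw (uncorrected) population x SNP frequency matrix.

    Returns PC scores, variance shares and the Pearson correlation of each
    environmental variable with PC1; with latitude/longitude coordinates,
    also the linear model score ~ latitude * longitude.
    """
    if freqs.n_pops < 3:
        raise ValueError("need at least three populations")
    x = freqs.imputed().T  # populations x SNPs
    x = x - x.mean(axis=0, keepdims=True)  # center SNP columns
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    for k in range(u.shape[1]):
        j = int(np.argmax(np.abs(u[:, k])))
        if u[j, k] < 0:
            u[:, k] *= -1
    var = s**2 / (s**2).sum()
    scores = pd.DataFrame(
        u * s,
        index=pd.Index(freqs.pop_labels, name="population"),
        columns=[f"PC{i + 1}_genomic" for i in range(s.shape[0])],
    )
    env = env.loc[freqs.pop_labels]
    pc1 = scores.iloc[:, 0]
    corr = {
        v: float(stats.pearsonr(env[v], pc1)[0]) for v in env.columns
    }
    out = {"scores": scores, "variance_explained": var, "env_pc1_correlation": corr}
    if coords is not None:
        coords = coords.loc[freqs.pop_labels]
        df = pd.DataFrame(
            {
                "score": pc1,
                "latitude": coords["latitude"],
                "longitude": coords["longitude"],
            }
        )
        fit = smf.ols("score ~ latitude * longitude", df).fit()
        out["geography_model"] = fit
    return out
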