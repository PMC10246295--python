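"""Independent oracles used by the test suite and the acceptance script.

Each oracle computes its quantity by a route independent of the
implementation it checks: brute-force enumeration, grid search, label
permutation, or direct Monte-Carlo simulation of the generating model.
"""

from __future__ import annotations

import math

import numpy as np

from burdenarch.architecture import LiabilityModel, genotype_liability_means
from burdenarch.association import burden_collapse, burden_test


def hypergeom_tail_exact(k: int, n_universe: int, n_set: int,
                         n_top: int) -> float:
    """P(overlap >= k) by exact combinatorial enumeration."""
    total = math.comb(n_universe, n_top)
    acc = 0
    for j in range(k, min(n_set, n_top) + 1):
        acc += math.comb(n_set, j) * math.comb(n_universe - n_set, n_top - j)
    return acc / total


def binomial_tail_exact(observed: int, n: int, p: float) -> float:
    """P(X >= observed) by direct enumeration."""
    return float(sum(math.comb(n, k) * p**k * (1 - p) ** (n - k)
                     for k in range(observed, n + 1)))


def winners_curse_grid(beta_hat: float, se: float, z_c: float,
                       n_grid: int = 400_001) -> float:
    """Conditional MLE by brute-force grid search over beta."""
    from scipy import stats

    beta = np.linspace(-abs(beta_hat), abs(beta_hat), n_grid)
    a = beta / se - z_c
    b = -beta / se - z_c
    denom = stats.norm.cdf(a) + stats.norm.cdf(b)
    loglik = stats.norm.logpdf((beta_hat - beta) / se) - np.log(denom)
    return float(beta[np.argmax(loglik)])


def lve_simulation(beta: float, freq: float, model: LiabilityModel,
                   n_draws: int, rng: np.random.Generator) -> float:
    """LVE by direct simulation of the liability-threshold model:
    draw HWE genotypes, map to liability means, measure the variance
    ratio of the genetic component to total liability."""
    mus = genotype_liability_means(beta, freq, model)[0]
    g = rng.binomial(2, freq, n_draws)
    gen = mus[g]
    liab = gen + rng.standard_normal(n_draws)
    return float(gen.var() / liab.var())


def permutation_min_p(dosages: np.ndarray, is_case: np.ndarray,
                      gene_sets: dict[str, np.ndarray], n_perm: int,
                      rng: np.random.Generator) -> float | None:
    """Empirical P of the observed min-P across masks under case-label
    permutation, using the same per-mask burden test as the pipeline.

    With no covariates and binary burdens, each mask's P depends only on
    its 2x2 table, so per-mask P values are precomputed per case-carrier
    count and permutations reduce to a matrix product.
    """
    y = np.asarray(is_case, dtype=np.int8)
    inds = [burden_collapse(dosages, cols) for cols in gene_sets.values()]
    inds = [b for b in inds if 0 < b.sum() < len(b)]
    if not inds:
        return None
    ind = np.column_stack(inds)
    k = int(y.sum())
    cache: dict[tuple[int, int], float] = {}

    def p_of(j: int, a: int) -> float:
        if (j, a) not in cache:
            yy = np.zeros(len(y))
            carr = np.where(ind[:, j] > 0)[0]
            non = np.where(ind[:, j] == 0)[0]
            yy[carr[:a]] = 1
            yy[non[: k - a]] = 1
            _, _, p = burden_test(ind[:, j], yy, None)
            cache[(j, a)] = p if np.isfinite(p) else 1.0
        return cache[(j, a)]

    a_obs = (ind * y[:, None]).sum(axis=0)
    minp_obs = min(p_of(j, int(a_obs[j])) for j in range(ind.shape[1]))
    perm = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
    A = perm @ ind
    minp = np.ones(n_perm)
    for j in range(ind.shape[1]):
        pj = {int(a): p_of(j, int(a)) for a in np.unique(A[:, j])}
        minp = np.minimum(minp, np.array([pj[int(a)] for a in A[:, j]]))
    return float((np.sum(minp <= minp_obs + 1e-12) + 1) / (n_perm + 1))


def draw_case_control_genotypes(beta: float, freq: float, prevalence: float,
                                n_cases: int, n_controls: int,
                                rng: np.random.Generator
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Sample genotypes for a case-control study directly from the
    per-genotype penetrance model (no liability machinery): an
    independent generating route for effect-recovery checks."""
    from scipy import special

    from burdenarch.architecture import _solve_baseline_logit

    b = np.array([beta])
    p = np.array([freq])
    x0 = _solve_baseline_logit(b, p, prevalence)[0]
    hwe = np.array([(1 - freq) ** 2, 2 * freq * (1 - freq), freq**2])
    f = special.expit(x0 + np.arange(3) * beta)
    p_case = hwe * f / (hwe * f).sum()
    p_ctrl = hwe * (1 - f) / (hwe * (1 - f)).sum()
    g_case = rng.choice(3, size=n_cases, p=p_case)
    g_ctrl = rng.choice(3, size=n_controls, p=p_ctrl)
    return g_case, g_ctrl
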