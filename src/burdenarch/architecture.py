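"""Liability-scale genetic architecture: variance explained, winner's
curse, and cross-study comparison with shared controls.

The disease is modelled with a liability threshold: a standard-normal
latent liability, disease iff liability exceeds ``t = Phi^-1(1 - K)``
for prevalence ``K``. A variant with odds ratio ``OR`` and risk-allele
frequency ``p`` is converted to the liability scale by solving for the
per-genotype penetrances ``f_g`` that satisfy

    odds(f_g) = OR^g * odds(f_0),   sum_g HWE(g) * f_g = K,

and mapping each genotype to the liability mean ``mu_g = t + Phi^-1(f_g)``
that reproduces its penetrance under a unit residual. The liability
variance explained (LVE) is then ``Var_g(mu_g) / (Var_g(mu_g) + 1)``.

Effect estimates that were selected for passing a significance threshold
are biased away from zero (winner's curse); they are de-biased by the
conditional maximum-likelihood estimator, maximizing the density of the
observed estimate under normal sampling truncated to the selection
region. Cross-study contrasts account for the correlation induced by
shared controls (and optionally shared cases).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = [
    "LiabilityModel",
    "AssociationSummary",
    "LVEEstimate",
    "winners_curse_correct",
    "variant_lve",
    "aggregate_lve",
    "lve_fold_change",
    "overlap_correlation",
    "simulate_overlap_correlation",
    "expected_exceedance_frequency",
    "binomial_enrichment_test",
    "effective_sample_size",
]


def effective_sample_size(n_cases: int, n_controls: int) -> int:
    """Case-control count equivalent ``4 / (1/n_cases + 1/n_controls)``.

    Equals the total sample size of the balanced design with the same
    power; rounded to the nearest integer.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    return int(round(4.0 / (1.0 / n_cases + 1.0 / n_controls)))


@dataclass(frozen=True)
class LiabilityModel:
    """Threshold model for one study's phenotype definition.

    Parameters
    ----------
    prevalence : population disease prevalence ``K`` in (0, 0.5).
    """

    prevalence: float

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 0.5:
            raise ValueError("prevalence must be in (0, 0.5)")

    @property
    def threshold(self) -> float:
        return float(stats.norm.isf(self.prevalence))


@dataclass
class AssociationSummary:
    """One variant- or gene-level association in one study."""

    unit_id: str
    beta: float  # log odds ratio
    se: float
    freq: float  # risk-allele or carrier frequency
    study: str = ""
    n_cases: int = 0
    n_controls: int = 0
    z_c: float = 0.0  # |z| selection threshold applied at discovery

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.unit_id}: SE must be positive")
        if not 0.0 < self.freq < 1.0:
            raise ValueError(f"{self.unit_id}: frequency must be in (0, 1)")


@dataclass
class LVEEstimate:
    point: float
    ci_low: float
    ci_high: float
    per_unit: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# winner's curse: conditional MLE under |beta_hat|/se > z_c
# ---------------------------------------------------------------------------

def _cmle_score(beta: np.ndarray, beta_hat: np.ndarray, se: np.ndarray,
                z_c: np.ndarray) -> np.ndarray:
    """Derivative of the truncated-normal log-likelihood in beta."""
    a = beta / se - z_c
    b = -beta / se - z_c
    log_d = np.logaddexp(special.log_ndtr(a), special.log_ndtr(b))
    log_phi_a = -0.5 * a * a - 0.5 * np.log(2.0 * np.pi)
    log_phi_b = -0.5 * b * b - 0.5 * np.log(2.0 * np.pi)
    ratio = np.exp(log_phi_a - log_d) - np.exp(log_phi_b - log_d)
    return (beta_hat - beta) / se**2 - ratio / se


def winners_curse_correct(
    beta_hat: float | np.ndarray,
    se: float | np.ndarray,
    z_c: float | np.ndarray,
    n_iter: int = 200,
) -> float | np.ndarray:
    """Conditional-MLE de-biasing of a selected effect estimate.

    Maximizes the likelihood of ``beta_hat ~ N(beta, se^2)`` conditioned
    on the selection event ``|beta_hat| / se > z_c``, by bisection on the
    score function over ``[0, |beta_hat|]`` (the conditional MLE never
    exceeds the naive estimate in magnitude and shares its sign). With
    ``z_c = 0`` the estimate is returned unchanged.
    """
    bh = np.atleast_1d(np.asarray(beta_hat, dtype=float))
    s = np.broadcast_to(np.asarray(se, dtype=float), bh.shape).copy()
    c = np.broadcast_to(np.asarray(z_c, dtype=float), bh.shape).copy()
    if np.any(s <= 0):
        raise ValueError("SE must be positive")
    if np.any(c < 0):
        raise ValueError("selection threshold z_c must be >= 0")
    below = np.abs(bh) / s < c - 1e-12
    if np.any(below):
        raise ValueError(
            "estimate below its own selection threshold; pass z_c=0 for "
            "units that were not subject to selection"
        )
    sign = np.where(bh < 0, -1.0, 1.0)
    mag = np.abs(bh)
    lo = np.zeros_like(mag)
    hi = mag.copy()
    # score at 0 is |beta_hat|/se^2 >= 0, score at |beta_hat| is <= 0;
    # bisect the sign change
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        g = _cmle_score(mid, mag, s, c)
        take_hi = g > 0
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    out = sign * 0.5 * (lo + hi)
    if np.isscalar(beta_hat) or np.ndim(beta_hat) == 0:
        return float(out[0])
    return out


# ---------------------------------------------------------------------------
# liability variance explained
# ---------------------------------------------------------------------------

def _hwe_freqs(p: float | np.ndarray) -> tuple[np.ndarray, ...]:
    p = np.asarray(p, dtype=float)
    return ((1 - p) ** 2, 2 * p * (1 - p), p**2)


def _solve_baseline_logit(beta: np.ndarray, p: np.ndarray, k: float,
                          n_iter: int = 200) -> np.ndarray:
    """Solve logit(f0) such that the HWE-weighted penetrance equals K."""
    g0, g1, g2 = _hwe_freqs(p)

    def mean_pen(x):
        return (g0 * special.expit(x)
                + g1 * special.expit(x + beta)
                + g2 * special.expit(x + 2 * beta))

    lo = np.full_like(beta, -60.0)
    hi = np.full_like(beta, 60.0)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        too_low = mean_pen(mid) < k
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def genotype_liability_means(
    beta: float | np.ndarray,
    freq: float | np.ndarray,
    model: LiabilityModel,
) -> np.ndarray:
    """Per-genotype liability means ``mu_g`` reproducing the variant's
    penetrances under a unit-variance residual.

    Returns an array of shape ``(..., 3)`` for genotypes 0/1/2. A variant
    with ``beta = 0`` maps to ``mu_g = 0`` for all genotypes.
    """
    b = np.atleast_1d(np.asarray(beta, dtype=float))
    p = np.broadcast_to(np.asarray(freq, dtype=float), b.shape).copy()
    x0 = _solve_baseline_logit(b, p, model.prevalence)
    t = model.threshold
    mus = []
    for g in range(3):
        f = special.expit(x0 + g * b)
        if np.any(f >= 1.0 - 1e-10):
            raise ValueError(
                f"penetrance saturates at genotype {g}: odds ratio too "
                f"large for prevalence {model.prevalence}"
            )
        mus.append(t + special.ndtri(f))
    return np.stack(mus, axis=-1)


def variant_lve(
    beta: float,
    freq: float,
    model: LiabilityModel,
) -> float:
    """Fraction of liability variance explained by one biallelic unit.

    ``beta`` is the log odds ratio of the risk allele (or of carrier
    status for a gene burden treated as a pseudo-variant at its combined
    MAF); ``freq`` is the risk-allele frequency.
    """
    return float(_lve_vec(np.array([beta]), np.array([freq]), model)[0])


def _lve_vec(beta: np.ndarray, freq: np.ndarray,
             model: LiabilityModel) -> np.ndarray:
    mu = genotype_liability_means(beta, freq, model)
    g0, g1, g2 = _hwe_freqs(freq)
    w = np.stack([g0, g1, g2], axis=-1)
    mean = np.sum(w * mu, axis=-1, keepdims=True)
    var = np.sum(w * (mu - mean) ** 2, axis=-1)
    return var / (var + 1.0)


def aggregate_lve(
    units: list[AssociationSummary],
    model: LiabilityModel,
    n_bootstrap: int = 1000,
    rng: np.random.Generator | None = None,
    corrected: bool = False,
) -> LVEEstimate:
    """Total LVE of a set of independent units with a bootstrap CI.

    Each unit's estimate is winner's-curse corrected at its own
    discovery threshold (skipped when ``corrected=True``, i.e. the caller
    already corrected). The CI is a percentile bootstrap: estimates are
    redrawn from ``N(beta_corrected, SE^2)``, re-corrected draw by draw
    (draws falling below the selection threshold are kept as-is, since
    the conditional correction is undefined for them), converted to LVE
    and summed.
    """
    if not units:
        return LVEEstimate(0.0, 0.0, 0.0, {})
    rng = np.random.default_rng() if rng is None else rng
    beta = np.array([u.beta for u in units])
    se = np.array([u.se for u in units])
    freq = np.array([u.freq for u in units])
    z_c = np.array([u.z_c for u in units])
    if corrected:
        bc = beta
    else:
        bc = np.asarray(winners_curse_correct(beta, se, z_c))
    per_lve = _lve_vec(bc, freq, model)
    per_unit = {u.unit_id: float(v) for u, v in zip(units, per_lve)}
    point = float(per_lve.sum())
    if n_bootstrap <= 0:
        return LVEEstimate(point, point, point, per_unit)
    draws = rng.normal(bc[None, :], se[None, :],
                       size=(n_bootstrap, len(units)))
    boot = _bootstrap_lve_totals(draws, se, z_c, freq, model)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return LVEEstimate(point, float(lo), float(hi), per_unit)


def _bootstrap_lve_totals(draws: np.ndarray, se: np.ndarray,
                          z_c: np.ndarray, freq: np.ndarray,
                          model: LiabilityModel) -> np.ndarray:
    """Re-correct and convert a (B, U) matrix of estimate draws."""
    b, u = draws.shape
    se_m = np.broadcast_to(se, draws.shape)
    zc_m = np.broadcast_to(z_c, draws.shape)
    passed = np.abs(draws) / se_m >= zc_m
    corr = draws.copy()
    if passed.any():
        corr[passed] = np.asarray(
            winners_curse_correct(draws[passed], se_m[passed], zc_m[passed])
        )
    freq_m = np.broadcast_to(freq, draws.shape)
    lve = _lve_vec(corr.ravel(), freq_m.ravel(), model).reshape(b, u)
    return lve.sum(axis=1)


def lve_fold_change(
    units_a: list[AssociationSummary],
    units_b: list[AssociationSummary],
    model_a: LiabilityModel,
    model_b: LiabilityModel,
    overlap_r: float = 0.0,
    n_bootstrap: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """LVE ratio (study A / study B) with a paired bootstrap CI.

    Units are paired positionally (the same variant or gene measured in
    two studies); estimate draws for a pair are bivariate normal with
    correlation ``overlap_r`` to reflect shared controls.
    """
    if len(units_a) != len(units_b):
        raise ValueError("unit lists must be paired")
    rng = np.random.default_rng() if rng is None else rng
    est_a = aggregate_lve(units_a, model_a, n_bootstrap=0)
    est_b = aggregate_lve(units_b, model_b, n_bootstrap=0)
    if est_b.point <= 0:
        raise ValueError("denominator study has zero aggregate LVE")
    point = est_a.point / est_b.point

    beta_a = np.asarray(winners_curse_correct(
        np.array([u.beta for u in units_a]),
        np.array([u.se for u in units_a]),
        np.array([u.z_c for u in units_a])))
    beta_b = np.asarray(winners_curse_correct(
        np.array([u.beta for u in units_b]),
        np.array([u.se for u in units_b]),
        np.array([u.z_c for u in units_b])))
    se_a = np.array([u.se for u in units_a])
    se_b = np.array([u.se for u in units_b])
    n = len(units_a)
    z1 = rng.standard_normal((n_bootstrap, n))
    z2 = rng.standard_normal((n_bootstrap, n))
    r = float(overlap_r)
    draws_a = beta_a + se_a * z1
    draws_b = beta_b + se_b * (r * z1 + np.sqrt(max(0.0, 1 - r * r)) * z2)
    tot_a = _bootstrap_lve_totals(
        draws_a, se_a, np.array([u.z_c for u in units_a]),
        np.array([u.freq for u in units_a]), model_a)
    tot_b = _bootstrap_lve_totals(
        draws_b, se_b, np.array([u.z_c for u in units_b]),
        np.array([u.freq for u in units_b]), model_b)
    ok = tot_b > 0
    ratios = tot_a[ok] / tot_b[ok]
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return point, float(lo), float(hi)


# ---------------------------------------------------------------------------
# shared-control correlation and cross-study exceedance
# ---------------------------------------------------------------------------

def overlap_correlation(
    n_cases_1: int,
    n_controls_1: int,
    n_cases_2: int,
    n_controls_2: int,
    n_shared_controls: int,
    n_shared_cases: int = 0,
) -> float:
    """Asymptotic correlation between two studies' log-OR estimates when
    the studies share controls (and optionally cases) and estimate the
    same true effect.

    From the delta method on the log odds difference of case and control
    allele frequencies: shared controls contribute
    ``n_s / (n_ctrl_1 * n_ctrl_2)`` to the covariance (shared cases
    analogously), and each study's variance is proportional to
    ``1/n_cases + 1/n_controls``, giving

        r = [ n_s0 * sqrt(c1 c2 / (d1 d2)) + n_s1 * sqrt(d1 d2 / (c1 c2)) ]
            / sqrt((c1 + d1) (c2 + d2))

    with c = cases, d = controls, n_s0/n_s1 shared controls/cases.
    """
    for v in (n_cases_1, n_controls_1, n_cases_2, n_controls_2):
        if v <= 0:
            raise ValueError("all study counts must be positive")
    if n_shared_controls < 0 or n_shared_controls > min(n_controls_1,
                                                        n_controls_2):
        raise ValueError("shared controls must be <= both control counts")
    if n_shared_cases < 0 or n_shared_cases > min(n_cases_1, n_cases_2):
        raise ValueError("shared cases must be <= both case counts")
    c1, d1, c2, d2 = map(float, (n_cases_1, n_controls_1,
                                 n_cases_2, n_controls_2))
    num = (n_shared_controls * np.sqrt(c1 * c2 / (d1 * d2))
           + n_shared_cases * np.sqrt(d1 * d2 / (c1 * c2)))
    return float(num / np.sqrt((c1 + d1) * (c2 + d2)))


def simulate_overlap_correlation(
    n_cases_1: int,
    n_controls_1: int,
    n_cases_2: int,
    n_controls_2: int,
    n_shared_controls: int,
    freq: float = 0.2,
    beta: float = 0.1,
    n_replicates: int = 500,
    rng: np.random.Generator | None = None,
) -> float:
    """Empirical correlation of log-OR estimates from two overlapping
    case-control studies, the simulation oracle for
    :func:`overlap_correlation`.

    Each replicate draws binomial allele counts for independent case
    pools, a shared control pool, and each study's private controls,
    then forms the two log odds ratios.
    """
    rng = np.random.default_rng() if rng is None else rng
    p0 = freq
    odds1 = p0 / (1 - p0) * np.exp(beta)
    p1 = odds1 / (1 + odds1)
    B = n_replicates
    a1 = rng.binomial(2 * n_cases_1, p1, B)
    a2 = rng.binomial(2 * n_cases_2, p1, B)
    sh = rng.binomial(2 * n_shared_controls, p0, B)
    pr1 = rng.binomial(2 * (n_controls_1 - n_shared_controls), p0, B)
    pr2 = rng.binomial(2 * (n_controls_2 - n_shared_controls), p0, B)

    def logor(case_alt, n_case, ctrl_alt, n_ctrl):
        ca = case_alt + 0.5
        cr = 2 * n_case - case_alt + 0.5
        da = ctrl_alt + 0.5
        dr = 2 * n_ctrl - ctrl_alt + 0.5
        return np.log(ca * dr / (cr * da))

    b1 = logor(a1, n_cases_1, sh + pr1, n_controls_1)
    b2 = logor(a2, n_cases_2, sh + pr2, n_controls_2)
    return float(np.corrcoef(b1, b2)[0, 1])


def overlap_correlation_checked(
    n_cases_1: int,
    n_controls_1: int,
    n_cases_2: int,
    n_controls_2: int,
    n_shared_controls: int,
    tol: float = 0.05,
    rng: np.random.Generator | None = None,
    n_replicates: int = 500,
) -> tuple[float, bool]:
    """Closed-form correlation, validated against the simulation oracle.

    Returns ``(r, used_closed_form)``; when the closed form disagrees
    with the simulated correlation by more than ``tol`` the simulated
    value is returned instead.
    """
    r = overlap_correlation(n_cases_1, n_controls_1, n_cases_2,
                            n_controls_2, n_shared_controls)
    r_sim = simulate_overlap_correlation(
        n_cases_1, n_controls_1, n_cases_2, n_controls_2,
        n_shared_controls, n_replicates=n_replicates, rng=rng)
    if abs(r - r_sim) > tol:
        return r_sim, False
    return r, True


def expected_exceedance_frequency(
    true_beta: float,
    se_1: float,
    se_2: float,
    overlap_r: float,
    z_c_2: float,
    n_sims: int = 100_000,
    z_c_1: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Expected cross-study agreement under a shared true effect.

    Draws bivariate-normal estimate pairs (correlation ``overlap_r``),
    conditions on study 2 passing its discovery threshold ``z_c_2``
    (and optionally study 1 passing ``z_c_1``), applies the winner's
    curse correction to the study-2 estimates (they are the discovery
    study's published effects), and returns

    ``(fraction same direction, fraction with |study 1| > |corrected
    study 2|)``.

    Study-1 estimates are left uncorrected: the question being
    calibrated is how often the raw replication-study estimate exceeds
    the de-biased discovery estimate when the true effects are equal.
    """
    if se_1 <= 0 or se_2 <= 0:
        raise ValueError("standard errors must be positive")
    import warnings
    if n_sims < 1000:
        warnings.warn("n_sims < 1000: exceedance fractions will be noisy")
    rng = np.random.default_rng() if rng is None else rng
    kept_1 = []
    kept_2 = []
    need = n_sims
    r = float(overlap_r)
    while need > 0:
        m = max(int(need * 1.5) + 1000, 2000)
        z1 = rng.standard_normal(m)
        z2 = rng.standard_normal(m)
        b1 = true_beta + se_1 * z1
        b2 = true_beta + se_2 * (r * z1 + np.sqrt(max(0.0, 1 - r * r)) * z2)
        keep = np.abs(b2) / se_2 >= z_c_2
        if z_c_1 > 0:
            keep &= np.abs(b1) / se_1 >= z_c_1
        kept_1.append(b1[keep])
        kept_2.append(b2[keep])
        need -= int(keep.sum())
    b1 = np.concatenate(kept_1)[:n_sims]
    b2 = np.concatenate(kept_2)[:n_sims]
    b2c = np.asarray(winners_curse_correct(b2, se_2, z_c_2))
    same_dir = float(np.mean(np.sign(b1) == np.sign(b2c)))
    larger_1 = float(np.mean(np.abs(b1) > np.abs(b2c)))
    return same_dir, larger_1


def binomial_enrichment_test(observed: int, n: int,
                             expected_fraction: float) -> float:
    """Exact one-sided binomial tail ``P(X >= observed)``."""
    if not 0 <= observed <= n:
        raise ValueError("observed must be in [0, n]")
    if not 0.0 < expected_fraction < 1.0:
        raise ValueError("expected fraction must be in (0, 1)")
    return float(stats.binom.sf(observed - 1, n, expected_fraction))
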