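"""Haseman-Elston regression for heritability and genetic correlations.

The estimator regresses a phenotypic-similarity score — the product of
z-normalized trait values for a pair of individuals, M_i x N_j — on the
pair's kinship r_ij:

    M_i x N_j = alpha + beta * r_ij + e

For a z-scored trait regressed against itself within one cohort the slope
relates to narrow-sense heritability as h2 = beta / 2; for two traits the
slope gives the genetic covariance rho = beta / 2, and the genetic
correlation follows as r_g = rho / (h_M * h_N).

Fisher's formula for the SE of a regression coefficient treats the pairwise
products as independent, which they are not: the miscalibration grows with
both h2 and cohort size.  The module therefore carries an empirically
derived multiplicative correction factor

    F = sqrt(n) * (0.020225 h2 + 0.004225) + (-0.2352 h2 + 0.9467)

applied as SE_corrected = SE * F, together with the split-half Delta_norm
machinery used to derive (and re-derive) those coefficients: the
standardized difference of two independent h2 estimates should have unit
standard deviation over replicates when SEs are calibrated.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .kinship import KinshipMatrix, kinship_from_genotypes
from .simdata import Population, SimSpec, simulate_genotypes, simulate_trait, split_half
from .pheno_prep import zscore

logger = logging.getLogger(__name__)

__all__ = [
    "HEFit",
    "HEEstimate",
    "RgEstimate",
    "CorrectionCoefficients",
    "DEFAULT_CORRECTION",
    "he_fit",
    "he_h2",
    "he_rg",
    "correction_factor",
    "delta_norm",
    "calibration_experiment",
    "derive_correction_coefficients",
    "filter_traits",
    "filter_rg",
    "H2_MIN",
]

#: Heritability threshold below which traits are excluded downstream.
H2_MIN = 0.10


@dataclasses.dataclass(frozen=True)
class CorrectionCoefficients:
    """Coefficients of the SE correction factor F.

    F(h2, n) = sqrt(n) * (slope_h2 * h2 + slope_const) + (int_h2 * h2 + int_const)
    """

    slope_h2: float
    slope_const: float
    int_h2: float
    int_const: float


#: Empirically derived coefficients used for all corrected SEs.
DEFAULT_CORRECTION = CorrectionCoefficients(
    slope_h2=0.020225, slope_const=0.004225, int_h2=-0.2352, int_const=0.9467
)


def correction_factor(
    h2: float, n: int, coeffs: CorrectionCoefficients = DEFAULT_CORRECTION
) -> float:
    """SE correction factor F at a given heritability and cohort size.

    h2 is clipped to [0, 1] before evaluation; n is the number of animals.
    """
    h2 = float(np.clip(h2, 0.0, 1.0))
    return float(
        np.sqrt(n) * (coeffs.slope_h2 * h2 + coeffs.slope_const)
        + (coeffs.int_h2 * h2 + coeffs.int_const)
    )


@dataclasses.dataclass
class HEFit:
    """Raw OLS fit of pairwise products on kinship."""

    beta: float
    intercept: float
    se_beta: float
    p: float
    n_pairs: int
    kinship_variance: float


@dataclasses.dataclass
class HEEstimate:
    """Heritability estimate from a same-cohort Haseman-Elston fit."""

    beta: float
    h2: float
    se_raw: float
    se_corrected: float
    p: float
    n_animals: int
    n_pairs: int
    trait: str | None = None


@dataclasses.dataclass
class RgEstimate:
    """Genetic correlation between two traits, with propagated SE."""

    rho: float
    rg: float
    se: float
    p: float
    h2_M: float
    h2_N: float
    n_M: int
    n_N: int
    rel_var_sum: float  # audit: sum of the three relative-variance terms
    valid: bool
    estimable: bool = True
    reason: str | None = None


def _moments_same_cohort(M: np.ndarray, N: np.ndarray, K: np.ndarray):
    """Pair-regression moments over unordered distinct pairs, closed form.

    Computes the sums over i < j of x, x^2, y, y^2 and xy (x = K_ij,
    y = M_i N_j symmetrized) from O(n^2) matrix quantities, without
    materializing the pair list; algebraically identical to enumerating
    pairs.
    """
    n = len(M)
    n_pairs = n * (n - 1) // 2
    dK = np.diagonal(K)
    S_x = (K.sum() - dK.sum()) / 2.0
    S_xx = ((K * K).sum() - (dK * dK).sum()) / 2.0
    sM, sN = M.sum(), N.sum()
    sMN = float(M @ N)
    if M is N:
        sM2 = float(M @ M)
        S_y = (sM * sM - sM2) / 2.0
        S_yy = (sM2 * sM2 - float((M**2) @ (M**2))) / 2.0
        KM = K @ M
        S_xy = (float(M @ KM) - float((M * M) @ dK)) / 2.0
    else:
        sM2, sN2 = float(M @ M), float(N @ N)
        S_y = (sM * sN - sMN) / 2.0
        full_sq = (sM2 * sN2 + sMN * sMN) / 2.0  # sum of symmetrized y^2
        S_yy = (full_sq - float(((M * N) ** 2).sum())) / 2.0
        S_xy = (float(M @ (K @ N)) - float((M * N) @ dK)) / 2.0
    return n_pairs, S_x, S_xx, S_y, S_yy, S_xy


def _ols_from_moments(n_pairs, S_x, S_xx, S_y, S_yy, S_xy):
    xbar, ybar = S_x / n_pairs, S_y / n_pairs
    sxx = S_xx - n_pairs * xbar * xbar
    if sxx <= 0:
        raise ValueError("kinship has zero variance across pairs")
    sxy = S_xy - n_pairs * xbar * ybar
    syy = S_yy - n_pairs * ybar * ybar
    beta = sxy / sxx
    alpha = ybar - beta * xbar
    rss = max(syy - sxy * sxy / sxx, 0.0)
    return beta, alpha, rss, sxx


def _pairs_general(M, N, K, idx_M, idx_N):
    """Cross-cohort pairs: self-pairs dropped, duplicate unordered pairs averaged."""
    gi = np.repeat(idx_M, len(idx_N))
    gj = np.tile(idx_N, len(idx_M))
    resp = np.repeat(M, len(idx_N)) * np.tile(N, len(idx_M))
    keep = gi != gj
    gi, gj, resp = gi[keep], gj[keep], resp[keep]
    a, b = np.minimum(gi, gj), np.maximum(gi, gj)
    key = a * (K.shape[0] + 1) + b
    uniq, inv = np.unique(key, return_inverse=True)
    sums = np.bincount(inv, weights=resp, minlength=len(uniq))
    counts = np.bincount(inv, minlength=len(uniq))
    y = sums / counts
    ua, ub = uniq // (K.shape[0] + 1), uniq % (K.shape[0] + 1)
    x = K[ua, ub]
    return x, y


def he_fit(
    M: np.ndarray,
    N: np.ndarray | None,
    K: KinshipMatrix | np.ndarray,
    idx_M: np.ndarray | None = None,
    idx_N: np.ndarray | None = None,
) -> HEFit:
    """OLS of pairwise trait products on pairwise kinship.

    ``M`` and ``N`` are z-normalized trait vectors; ``idx_M`` / ``idx_N``
    position each cohort's animals in the kinship matrix (defaults: the first
    len(M) rows, shared by both).  Pair construction:

    * same trait, same cohort: unordered distinct pairs i < j;
    * two traits on the same animals: each unordered pair contributes the
      symmetrized product (M_i N_j + M_j N_i) / 2;
    * distinct/overlapping cohorts: all cross products, self-pairs (the same
      animal on both sides) dropped, duplicated unordered pairs averaged.

    Missing values are dropped before pairing.  SE follows Fisher's
    regression-coefficient formula with the residual standard error
    S_eps = sqrt(RSS / (n_pairs - 2)); p is a two-sided slope t-test.
    """
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K)
    M = np.asarray(M, dtype=float)
    same_object = N is None
    N_arr = M if same_object else np.asarray(N, dtype=float)
    if idx_M is None:
        idx_M = np.arange(len(M))
    if idx_N is None:
        idx_N = idx_M
    idx_M, idx_N = np.asarray(idx_M), np.asarray(idx_N)

    mM = np.isfinite(M)
    mN = np.isfinite(N_arr)
    Mv, iMv = M[mM], idx_M[mM]
    Nv, iNv = N_arr[mN], idx_N[mN]

    same_cohort = len(iMv) == len(iNv) and np.array_equal(iMv, iNv)
    if same_cohort:
        sub = Kv[np.ix_(iMv, iMv)]
        n_pairs, *moments = _moments_same_cohort(Mv, Mv if same_object else Nv, sub)
        if n_pairs < 3:
            raise ValueError(f"need at least 3 usable pairs, got {n_pairs}")
        beta, alpha, rss, sxx = _ols_from_moments(n_pairs, *moments)
    else:
        x, y = _pairs_general(Mv, Nv, Kv, iMv, iNv)
        n_pairs = len(x)
        if n_pairs < 3:
            raise ValueError(f"need at least 3 usable pairs, got {n_pairs}")
        xbar = x.mean()
        sxx = float(np.sum((x - xbar) ** 2))
        if sxx <= 0:
            raise ValueError("kinship has zero variance across pairs")
        ybar = y.mean()
        beta = float(np.sum((x - xbar) * (y - ybar)) / sxx)
        alpha = float(ybar - beta * xbar)
        rss = float(np.sum((y - alpha - beta * x) ** 2))
    s_eps = np.sqrt(rss / (n_pairs - 2))
    se_beta = float(s_eps / np.sqrt(sxx))
    t_stat = beta / se_beta if se_beta > 0 else np.inf
    p = float(2.0 * stats.t.sf(abs(t_stat), df=n_pairs - 2))
    return HEFit(float(beta), float(alpha), se_beta, p, int(n_pairs), float(sxx / n_pairs))


def he_h2(
    M: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    idx: np.ndarray | None = None,
    trait: str | None = None,
    coeffs: CorrectionCoefficients = DEFAULT_CORRECTION,
) -> HEEstimate:
    """Estimate narrow-sense heritability of a z-scored trait: h2 = beta / 2.

    The raw SE is Fisher's slope SE divided by 2; the corrected SE multiplies
    it by F evaluated at the (clipped) point estimate and the number of
    animals with data.
    """
    M = np.asarray(M, dtype=float)
    n_animals = int(np.isfinite(M).sum())
    fit = he_fit(M, None, K, idx_M=idx)
    h2 = fit.beta / 2.0
    se_raw = fit.se_beta / 2.0
    F = correction_factor(h2, n_animals, coeffs)
    return HEEstimate(fit.beta, h2, se_raw, se_raw * F, fit.p, n_animals, fit.n_pairs, trait)


def he_rg(
    M: np.ndarray,
    N: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    est_M: HEEstimate,
    est_N: HEEstimate,
    idx_M: np.ndarray | None = None,
    idx_N: np.ndarray | None = None,
    coeffs: CorrectionCoefficients = DEFAULT_CORRECTION,
) -> RgEstimate:
    """Genetic correlation of two traits from the cross-trait HE slope.

    rho = beta_MN / 2 and r_g = rho / sqrt(h2_M * h2_N).  The SE propagates
    the relative variances of the three ingredients (delta method):

        SE(r_g) = |r_g| * sqrt( (SE(rho)/rho)^2
                              + (SE(h2_M)/(2 h2_M))^2
                              + (SE(h2_N)/(2 h2_N))^2 )

    using corrected SEs throughout; the raw relative-variance sum is kept for
    audit.  Requires positive h2 estimates for both traits; otherwise the
    result is flagged not estimable (never NaN by surprise).
    """
    if est_M.h2 <= 0 or est_N.h2 <= 0:
        return RgEstimate(
            rho=np.nan, rg=np.nan, se=np.nan, p=np.nan,
            h2_M=est_M.h2, h2_N=est_N.h2, n_M=est_M.n_animals, n_N=est_N.n_animals,
            rel_var_sum=np.nan, valid=False, estimable=False,
            reason="non-positive h2 for at least one trait",
        )
    fit = he_fit(M, N, K, idx_M=idx_M, idx_N=idx_N)
    rho = fit.beta / 2.0
    rg = rho / np.sqrt(est_M.h2 * est_N.h2)
    n_min = min(est_M.n_animals, est_N.n_animals)
    se_rho = (fit.se_beta / 2.0) * correction_factor(abs(rho), n_min, coeffs)
    terms = 0.0
    if rho != 0:
        terms += (se_rho / rho) ** 2
    terms += (est_M.se_corrected / (2.0 * est_M.h2)) ** 2
    terms += (est_N.se_corrected / (2.0 * est_N.h2)) ** 2
    se_rg = abs(rg) * np.sqrt(terms) if rg != 0 else se_rho / np.sqrt(est_M.h2 * est_N.h2)
    est = RgEstimate(
        rho=float(rho), rg=float(rg), se=float(se_rg), p=fit.p,
        h2_M=est_M.h2, h2_N=est_N.h2, n_M=est_M.n_animals, n_N=est_N.n_animals,
        rel_var_sum=float(terms), valid=True,
    )
    est.valid = filter_rg(est)
    return est


def delta_norm(est1: HEEstimate, est2: HEEstimate, corrected: bool = True) -> float:
    """Standardized difference of two independent h2 estimates.

    Delta_norm = (h2_1 - h2_2) / sqrt(sigma2_1 + sigma2_2).  Over many
    split-half replicates its SD should be approximately 1 when the SEs are
    calibrated.
    """
    s1 = est1.se_corrected if corrected else est1.se_raw
    s2 = est2.se_corrected if corrected else est2.se_raw
    denom = s1 ** 2 + s2 ** 2
    if not np.isfinite(denom) or denom <= 0:
        raise ValueError("total variance must be finite and positive")
    return float((est1.h2 - est2.h2) / np.sqrt(denom))


def calibration_experiment(
    h2_grid,
    n_grid,
    n_replicates: int,
    seed: int = 0,
    corrected: bool = True,
    n_markers: int = 1000,
    n_causal: int = 10,
    coeffs: CorrectionCoefficients = DEFAULT_CORRECTION,
) -> pd.DataFrame:
    """Split-half SE calibration: sigma_Delta_norm on an (h2, n) grid.

    Per replicate: simulate a cohort of 2n individuals at the given h2, split
    it randomly in half, estimate h2 in each half by HE regression (kinship
    from the half's own standardized genotypes), and form Delta_norm.  Each
    cell reports the SD of Delta_norm over replicates.
    """
    h2_grid = list(h2_grid)
    n_grid = list(n_grid)
    if not h2_grid or not n_grid:
        raise ValueError("grids must be non-empty")
    if n_replicates < 30:
        warnings.warn("fewer than 30 replicates: sigma_Delta_norm will be unstable")
    rng = np.random.default_rng(seed)
    rows = []
    for h2 in h2_grid:
        for n in n_grid:
            deltas = np.empty(n_replicates)
            for r in range(n_replicates):
                rep_seed = int(rng.integers(2**31 - 1))
                spec = SimSpec(n_individuals=2 * n, n_markers=n_markers,
                               n_causal=n_causal, h2=h2, seed=rep_seed)
                G = simulate_genotypes(spec)
                trait = simulate_trait(G, h2, n_causal, seed=rep_seed + 1)
                pop = Population(G, pd.DataFrame({"y": trait.values}))
                half1, half2 = split_half(pop, (n, n), seed=rep_seed + 2)
                ests = []
                for half in (half1, half2):
                    Kh = kinship_from_genotypes(half.genotypes)
                    y = zscore(half.phenotypes["y"].to_numpy())
                    ests.append(he_h2(y, Kh, coeffs=coeffs))
                deltas[r] = delta_norm(ests[0], ests[1], corrected=corrected)
            rows.append({"h2": h2, "n": n,
                         "sigma_delta_norm": float(np.std(deltas, ddof=1)),
                         "n_replicates": n_replicates})
            logger.info("calibration h2=%.2f n=%d sigma=%.3f", h2, n, rows[-1]["sigma_delta_norm"])
    return pd.DataFrame(rows)


def derive_correction_coefficients(sigma_table: pd.DataFrame) -> CorrectionCoefficients:
    """Re-derive F's coefficients from a sigma_Delta_norm table.

    Stage 1: per h2, OLS of sigma_Delta_norm on sqrt(n) giving an intercept
    and slope.  Stage 2: OLS of those intercepts and slopes on h2.  The four
    stage-2 coefficients parameterize F.
    """
    stage1 = []
    for h2, grp in sigma_table.groupby("h2"):
        if grp["n"].nunique() < 2:
            raise ValueError(f"need >=2 distinct n values at h2={h2}")
        X = np.column_stack([np.ones(len(grp)), np.sqrt(grp["n"].to_numpy(dtype=float))])
        coef, *_ = np.linalg.lstsq(X, grp["sigma_delta_norm"].to_numpy(dtype=float), rcond=None)
        stage1.append((float(h2), coef[0], coef[1]))
    if len(stage1) < 2:
        raise ValueError("need >=2 distinct h2 values")
    arr = np.asarray(stage1)
    X2 = np.column_stack([np.ones(len(arr)), arr[:, 0]])
    int_const, int_h2 = np.linalg.lstsq(X2, arr[:, 1], rcond=None)[0]
    slope_const, slope_h2 = np.linalg.lstsq(X2, arr[:, 2], rcond=None)[0]
    return CorrectionCoefficients(
        slope_h2=float(slope_h2), slope_const=float(slope_const),
        int_h2=float(int_h2), int_const=float(int_const),
    )


def filter_traits(estimates) -> tuple[list, list]:
    """Partition h2 estimates into kept and excluded, with reasons.

    A trait is kept iff h2 >= 0.10 and h2 <= 1 + SE (corrected).  Returns
    (kept, excluded) where excluded entries are (estimate, reason) pairs.
    """
    kept, excluded = [], []
    for est in estimates:
        if est.h2 < H2_MIN:
            excluded.append((est, f"h2={est.h2:.3f} below threshold {H2_MIN}"))
        elif est.h2 > 1.0 + est.se_corrected:
            excluded.append((est, f"h2={est.h2:.3f} exceeds 1 by more than SE={est.se_corrected:.3f}"))
        else:
            kept.append(est)
    return kept, excluded


def filter_rg(est: RgEstimate) -> bool:
    """A genetic correlation is valid iff -1 - SE <= r_g <= 1 + SE."""
    if not est.estimable or not np.isfinite(est.rg):
        return False
    return bool(-1.0 - est.se <= est.rg <= 1.0 + est.se)
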