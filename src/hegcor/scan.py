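"""Additive founder-haplotype genome scans with permutation calibration.

At each pseudomarker the (meta-)trait is regressed on the founder-probability
columns plus an intercept (Haley-Knott regression; the sum-to-one
collinearity is absorbed by a pseudo-inverse, to which the LOD is invariant):

    LOD = (n / 2) * log10(RSS_0 / RSS_1)

Genome-wide significance comes from unrestricted permutations: the phenotype
is shuffled across individuals, the genome rescanned, and the (1 - alpha)
quantile of the per-permutation maximum LOD used as the threshold.  The same
permuted scans drive a permutation FDR curve over a LOD grid.  Peaks are
called with qtl2-style drop/peakdrop rules and 2-LOD support intervals;
founder effects at a locus are shrunken BLUP-style under a single
variance-component model.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .kinship import FounderProbs, KinshipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ScanResult",
    "QTLPeak",
    "PermutationResult",
    "FounderEffects",
    "genome_scan",
    "permutation_scan",
    "permutation_threshold",
    "permutation_fdr",
    "find_peaks",
    "variance_explained",
    "founder_effects",
    "effect_correlation",
]

DROP_DEFAULT = 2.0
PEAKDROP_DEFAULT = 3.0


@dataclasses.dataclass
class ScanResult:
    """LOD profile over the pseudomarker grid."""

    lod: np.ndarray
    marker_map: pd.DataFrame
    n_used: int
    trait_name: str | None = None

    def to_frame(self) -> pd.DataFrame:
        out = self.marker_map.copy()
        out["lod"] = self.lod
        return out


@dataclasses.dataclass
class QTLPeak:
    chromosome: object
    position: float
    marker_index: int
    lod: float
    ci_lo: float
    ci_hi: float
    variance_explained: float


@dataclasses.dataclass
class PermutationResult:
    max_lods: np.ndarray
    alpha: float
    alpha_threshold: float
    fdr_curve: pd.DataFrame | None = None


@dataclasses.dataclass
class FounderEffects:
    founders: np.ndarray
    effects: np.ndarray
    se: np.ndarray
    shrinkage: float  # fitted variance ratio sigma_a^2 / sigma_e^2
    fixed_effects: np.ndarray


def _marker_bases(P: FounderProbs, mask: np.ndarray) -> np.ndarray:
    """Orthonormal column bases of [1 | probs_m] per marker, for fast RSS.

    Returns an array (markers, n_used, r) with r the design rank; RSS_1 at a
    marker is y'y - ||Q_m' y||^2, so a whole permutation scan is one
    tensordot.
    """
    n = int(mask.sum())
    nm = P.n_markers
    ones = np.ones((n, 1))
    bases = np.zeros((nm, n, P.n_founders + 1))
    for m in range(nm):
        X = np.concatenate([ones, P.probs[mask, m, :]], axis=1)
        Q, R = np.linalg.qr(X)
        keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(R[0, 0]))
        r = int(keep.sum())
        # re-orthonormalize the independent columns only
        Q2, _ = np.linalg.qr(X[:, keep])
        bases[m, :, :r] = Q2
    return bases


def _lod_from_bases(bases: np.ndarray, y: np.ndarray) -> np.ndarray:
    n = len(y)
    yc = y - y.mean()
    rss0 = float(yc @ yc)
    proj = np.einsum("mnr,n->mr", bases, y)
    rss1 = np.maximum(y @ y - np.einsum("mr,mr->m", proj, proj), 1e-300)
    return np.maximum((n / 2.0) * np.log10(rss0 / rss1), 0.0)


def genome_scan(
    y: np.ndarray,
    P: FounderProbs,
    trait_name: str | None = None,
    kinship: KinshipMatrix | None = None,
    _bases: np.ndarray | None = None,
    _mask: np.ndarray | None = None,
) -> ScanResult:
    """Haley-Knott LOD scan of a z-scored trait over all pseudomarkers.

    Individuals with missing phenotype are dropped.  If ``kinship`` is
    given, both phenotype and founder probabilities are pre-rotated by the
    kinship eigendecomposition (a GLS whitening) before the per-marker OLS —
    a kinship-corrected variant for parity checks on structured cohorts.
    """
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y) if _mask is None else _mask
    n = int(mask.sum())
    if n < P.n_founders + 2:
        raise ValueError(f"only {n} usable individuals for a {P.n_founders}-founder scan")
    yv = y[mask]
    if kinship is not None:
        # GLS whitening under V = K + I: slow path, used for parity checks
        w, U = np.linalg.eigh(kinship.values[np.ix_(mask, mask)])
        D = 1.0 / np.sqrt(np.maximum(w, 1e-8) + 1.0)
        rot = (U * D) @ U.T
        yw = rot @ yv
        ones_w = rot @ np.ones(n)
        lod = np.empty(P.n_markers)
        for m in range(P.n_markers):
            Xw = rot @ np.column_stack([np.ones(n), P.probs[mask, m, :]])
            rss1 = float(np.sum((yw - Xw @ (np.linalg.pinv(Xw) @ yw)) ** 2))
            b0 = float(ones_w @ yw) / float(ones_w @ ones_w)
            rss0 = float(np.sum((yw - b0 * ones_w) ** 2))
            lod[m] = max((n / 2.0) * np.log10(rss0 / max(rss1, 1e-300)), 0.0)
    else:
        bases = _bases if _bases is not None else _marker_bases(P, mask)
        lod = _lod_from_bases(bases, yv)
    return ScanResult(lod, P.marker_map, n, trait_name)


def permutation_scan(
    y: np.ndarray,
    P: FounderProbs,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Max-LOD null distribution from unrestricted phenotype permutations.

    Each permutation shuffles the phenotype across all individuals and
    rescans the genome; returns the per-permutation genome-wide maximum LOD.
    """
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y)
    bases = _marker_bases(P, mask)
    yv = y[mask]
    rng = np.random.default_rng(seed)
    max_lods = np.empty(n_perm)
    for p in range(n_perm):
        yp = rng.permutation(yv)
        max_lods[p] = _lod_from_bases(bases, yp).max()
    return max_lods


def permutation_threshold(
    y: np.ndarray,
    P: FounderProbs,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PermutationResult:
    """Genome-wide significance threshold: the (1 - alpha) quantile of the
    permutation max-LOD distribution (95th percentile at alpha = 0.05)."""
    max_lods = permutation_scan(y, P, n_perm=n_perm, seed=seed)
    thr = float(np.quantile(max_lods, 1.0 - alpha))
    return PermutationResult(max_lods, alpha, thr)


def find_peaks(
    scan: ScanResult,
    threshold: float,
    drop: float = DROP_DEFAULT,
    peakdrop: float = PEAKDROP_DEFAULT,
) -> list[QTLPeak]:
    """Call QTL peaks above a LOD threshold with support intervals.

    Per chromosome, local maxima above ``threshold`` are accepted in
    decreasing LOD order; a candidate is a distinct peak only if, between it
    and every accepted peak, the profile dips by at least ``peakdrop`` below
    the lower of the two.  The support interval is the contiguous span around
    the peak where LOD >= peak_lod - ``drop``, truncated at chromosome ends.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    peaks: list[QTLPeak] = []
    mm = scan.marker_map
    for c in mm["chromosome"].unique():
        sel = np.nonzero((mm["chromosome"] == c).to_numpy())[0]
        lod = scan.lod[sel]
        pos = mm["position"].to_numpy()[sel]
        order = np.argsort(pos)
        lod, pos, sel_sorted = lod[order], pos[order], sel[order]
        cand = [i for i in range(len(lod)) if lod[i] >= threshold
                and (i == 0 or lod[i] >= lod[i - 1])
                and (i == len(lod) - 1 or lod[i] >= lod[i + 1])]
        accepted: list[int] = []
        for i in sorted(cand, key=lambda i: -lod[i]):
            ok = True
            for j in accepted:
                lo, hi = min(i, j), max(i, j)
                valley = lod[lo:hi + 1].min()
                if valley > min(lod[i], lod[j]) - peakdrop:
                    ok = False
                    break
            if ok:
                accepted.append(i)
        for i in sorted(accepted):
            lo = i
            while lo > 0 and lod[lo - 1] >= lod[i] - drop:
                lo -= 1
            hi = i
            while hi < len(lod) - 1 and lod[hi + 1] >= lod[i] - drop:
                hi += 1
            peaks.append(QTLPeak(
                chromosome=c, position=float(pos[i]), marker_index=int(sel_sorted[i]),
                lod=float(lod[i]), ci_lo=float(pos[lo]), ci_hi=float(pos[hi]),
                variance_explained=variance_explained(float(lod[i]), scan.n_used),
            ))
    return peaks


def permutation_fdr(
    observed: ScanResult,
    perm_scans: list[ScanResult] | list[np.ndarray],
    lod_grid: np.ndarray,
    threshold_floor: float = 1.0,
    drop: float = DROP_DEFAULT,
    peakdrop: float = PEAKDROP_DEFAULT,
) -> pd.DataFrame:
    """Permutation FDR curve over a LOD grid.

    At each grid LOD t: T = number of peaks >= t in the observed scan,
    F_p = peaks >= t in permuted scan p (false discoveries);
    FDR(t) = mean_p[ F_p / (F_p + T) ] with 0/0 -> 0.  Reports both the
    expected number of false discoveries FDR * T and the expected number of
    true discoveries (1 - FDR) * T, plus a monotone (running-max over
    decreasing t) version of the raw curve.
    """
    lod_grid = np.asarray(lod_grid, dtype=float)
    if lod_grid.size == 0:
        raise ValueError("empty LOD grid")

    def peak_counts(scan: ScanResult) -> np.ndarray:
        pk = find_peaks(scan, threshold=threshold_floor, drop=drop, peakdrop=peakdrop)
        lods = np.array([p.lod for p in pk]) if pk else np.empty(0)
        return np.array([(lods >= t).sum() for t in lod_grid])

    T = peak_counts(observed)
    fdr = np.zeros(len(lod_grid))
    for p_scan in perm_scans:
        if isinstance(p_scan, ScanResult):
            F = peak_counts(p_scan)
        else:  # pre-computed peak LODs
            lods = np.asarray(p_scan, dtype=float)
            F = np.array([(lods >= t).sum() for t in lod_grid])
        denom = F + T
        with np.errstate(invalid="ignore"):
            contrib = np.where(denom > 0, F / np.where(denom == 0, 1, denom), 0.0)
        fdr += contrib
    fdr /= len(perm_scans)
    monotone = np.maximum.accumulate(fdr[::-1])[::-1]
    if not np.array_equal(monotone, fdr):
        logger.info("FDR curve regularized to be non-increasing in LOD")
    return pd.DataFrame({
        "lod": lod_grid,
        "fdr_raw": fdr,
        "fdr": monotone,
        "n_observed": T,
        "expected_false": monotone * T,
        "expected_true": (1.0 - monotone) * T,
    })


def variance_explained(lod: float, n: int) -> float:
    """Fraction of phenotypic variance explained: 1 - 10^(-(2/n) LOD)."""
    if n < 1 or lod < 0:
        raise ValueError("need n >= 1 and lod >= 0")
    return float(1.0 - 10.0 ** (-(2.0 / n) * lod))


def founder_effects(
    y: np.ndarray,
    P: FounderProbs,
    marker_index: int,
    shrinkage: float | None = None,
) -> FounderEffects:
    """Shrunken (BLUP-style) founder-allele effects at one marker.

    Model: y = mu + X a + e with a ~ N(0, sigma_a^2 I) over the founder
    columns X.  The variance ratio lambda = sigma_a^2 / sigma_e^2 is chosen
    by maximizing the single-locus marginal likelihood (1-D search) unless
    supplied.  Effects are reported as deviations (sum ~ 0 under the
    sum-to-one design); SEs come from the conditional posterior.  On
    optimizer failure the fixed-effect estimates are returned with a
    warning.
    """
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y)
    yv = y[mask]
    X = P.probs[mask, marker_index, :]
    n, f = X.shape
    ones = np.ones(n)
    # fixed-effect reference fit (pseudo-inverse for collinearity)
    Xi = np.column_stack([ones, X])
    fixed = np.linalg.pinv(Xi) @ yv
    fixed_eff = fixed[1:] - fixed[1:].mean()

    Xc = X - X.mean(axis=0)
    yc = yv - yv.mean()

    def neg_loglik(log_lam: float) -> float:
        lam = np.exp(log_lam)
        V = lam * (Xc @ Xc.T) + np.eye(n)
        sign, logdet = np.linalg.slogdet(V)
        if sign <= 0:
            return np.inf
        alpha = np.linalg.solve(V, yc)
        sigma2 = float(yc @ alpha) / n
        if sigma2 <= 0:
            return np.inf
        return 0.5 * (logdet + n * np.log(sigma2))

    try:
        if shrinkage is None:
            res = optimize.minimize_scalar(neg_loglik, bounds=(-10.0, 6.0), method="bounded")
            if not res.success:
                raise RuntimeError(res.message)
            lam = float(np.exp(res.x))
        else:
            lam = float(shrinkage)
        V = lam * (Xc @ Xc.T) + np.eye(n)
        Vinv_y = np.linalg.solve(V, yc)
        sigma2_e = float(yc @ Vinv_y) / n
        a = lam * (Xc.T @ Vinv_y)
        # conditional posterior variance of a
        Vinv_X = np.linalg.solve(V, Xc)
        post = sigma2_e * (lam * np.eye(f) - lam**2 * (Xc.T @ Vinv_X))
        se = np.sqrt(np.maximum(np.diag(post), 0.0))
        a = a - a.mean()
        return FounderEffects(np.asarray(P.founder_labels), a, se, lam, fixed_eff)
    except (RuntimeError, np.linalg.LinAlgError) as exc:
        logger.warning("BLUP optimizer failed (%s); using fixed effects", exc)
        se = np.full(f, np.nan)
        return FounderEffects(np.asarray(P.founder_labels), fixed_eff, se, np.nan, fixed_eff)


def effect_correlation(e1: FounderEffects, e2: FounderEffects) -> tuple[float, float]:
    """Pearson correlation of two founder-effect vectors, with a t-test p."""
    if len(e1.effects) != len(e2.effects):
        raise ValueError("founder sets differ in size")
    if not np.array_equal(e1.founders, e2.founders):
        raise ValueError("founder ordering differs")
    a, b = e1.effects, e2.effects
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance effect vector")
    r = float(np.corrcoef(a, b)[0, 1])
    df = len(a) - 2
    r_clip = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
    p = float(2.0 * stats.t.sf(abs(t), df=df))
    return r, p
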