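"""Per-site differential signals and 1D Ising energies.

For each CpG site two paired differential tests are computed between tumor
and matched-normal samples: a two-sided paired t-test on the mean and a
one-sided Pitman-Morgan test for inflated tumor variance. Each p-value below
0.05 becomes a signal s = -ln(p); otherwise s = 0. A site's energy for a
feature f in {mean, variance} couples its own signal with those of its
manifest neighbors:

    e_i^f = -sum_j J_ij * (s_i^f + s_j^f)

where J_ij is the Pearson correlation of sites i and j across the *normal*
samples (a property of the methylation landscape, held fixed under label
permutation). The two feature energies are combined through a per-site
convex weight lambda = e_mean / (e_mean + e_var):

    e_i = lambda * e_i^mean + (1 - lambda) * e_i^var

which equals (e_mean^2 + e_var^2) / (e_mean + e_var) and down-weights
whichever feature carries less energy, accommodating tumor heterogeneity.
Lower (more negative) energy means stronger evidence of differential
methylation at the site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import MethylationDataset, NORMAL

logger = logging.getLogger(__name__)

#: signals are zeroed at and above this p-value (the zero branch owns the
#: boundary).
SIGNAL_ALPHA = 0.05

#: p-values are floored here before taking logs, so signals stay finite.
P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# Scalar operations (the reference path; the engine below vectorizes them)
# ---------------------------------------------------------------------------

def paired_mean_pvalue(tumor, normal) -> float:
    """Two-sided paired t-test p-value on differences tumor - normal.

    Degenerate inputs (n < 3 or zero-variance differences) return p = 1 with
    a logged warning: no evidence rather than an error.
    """
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumor.shape != normal.shape:
        raise ValueError("tumor and normal vectors must have equal length")
    n = tumor.size
    if n < 3:
        logger.warning("paired t-test with n=%d < 3; returning p=1", n)
        return 1.0
    d = tumor - normal
    sd = d.std(ddof=1)
    if sd <= 0 or not np.isfinite(sd):
        logger.warning("zero-variance paired differences; returning p=1")
        return 1.0
    t = d.mean() / (sd / np.sqrt(n))
    return float(2.0 * stats.t.sf(abs(t), df=n - 1))


def pitman_morgan_pvalue(tumor, normal) -> float:
    """One-sided Pitman-Morgan p-value for Var(tumor) > Var(normal).

    With S = tumor + normal and D = tumor - normal, Cov(S, D) equals
    Var(tumor) - Var(normal), so the test reduces to the upper-tail t-test of
    the correlation r_SD: t = r * sqrt(n-2) / sqrt(1 - r^2), df = n - 2.
    """
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumor.shape != normal.shape:
        raise ValueError("tumor and normal vectors must have equal length")
    n = tumor.size
    if n < 4:
        logger.warning("Pitman-Morgan test with n=%d < 4; returning p=1", n)
        return 1.0
    s = tumor + normal
    d = tumor - normal
    ss = s.std(ddof=1)
    sd = d.std(ddof=1)
    if ss <= 0 or sd <= 0:
        logger.warning("zero variance in S or D; returning p=1")
        return 1.0
    r = float(np.corrcoef(s, d)[0, 1])
    r = min(max(r, -1.0), 1.0)
    denom = max(1.0 - r * r, P_FLOOR)
    t = r * np.sqrt(n - 2) / np.sqrt(denom)
    return float(stats.t.sf(t, df=n - 2))


def signal_from_pvalue(p) -> float:
    """Site signal s = -ln(p) when p < 0.05, else 0 (natural log).

    The boundary p = 0.05 maps to 0 (the conservative branch); p-values are
    floored at 1e-300 so signals stay finite.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError(f"p-value outside [0, 1]: {p!r}")
    out = np.where(arr < SIGNAL_ALPHA, -np.log(np.maximum(arr, P_FLOOR)), 0.0)
    return float(out) if arr.ndim == 0 else out


def _adjacent_correlations(values: np.ndarray, chrom_codes: np.ndarray,
                           offset: int = 1) -> np.ndarray:
    """Pearson correlation between rows i and i+offset of ``values``.

    Returns an array of length n_sites - offset; NaN where the two sites lie
    on different chromosomes, 0 (with a logged count) where either site has
    zero variance across samples.
    """
    n_sites = values.shape[0]
    if n_sites <= offset:
        return np.zeros(0)
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    num = (centered[:-offset] * centered[offset:]).sum(axis=1)
    den = norms[:-offset] * norms[offset:]
    with np.errstate(invalid="ignore", divide="ignore"):
        j = num / den
    degenerate = den <= 0
    if degenerate.any():
        logger.warning("%d neighbor pairs involve a zero-variance site; J=0",
                       int(degenerate.sum()))
        j[degenerate] = 0.0
    j = np.clip(j, -1.0, 1.0)
    cross = chrom_codes[:-offset] != chrom_codes[offset:]
    j[cross] = np.nan
    return j


def neighbor_coupling(dataset: MethylationDataset,
                      window: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (J_left, J_right) couplings from the normal samples.

    J is the Pearson correlation across normal samples between a site and its
    immediate manifest neighbor on the same chromosome. Chromosome-terminal
    sites get NaN on the missing side (treated as absent-neighbor, J = 0, in
    the energy sum). For ``window`` > 1 only the offset-1 couplings are
    returned here; the engine handles the extra offsets internally.
    """
    normals = dataset.condition_matrix(NORMAL)
    if normals.shape[1] < 3:
        raise ValueError("neighbor coupling requires >= 3 normal samples")
    j = _adjacent_correlations(normals, dataset.chrom_codes(), offset=1)
    n = dataset.n_sites
    j_right = np.full(n, np.nan)
    j_left = np.full(n, np.nan)
    if n > 1:
        j_right[:-1] = j
        j_left[1:] = j
    return j_left, j_right


def site_energy(s_i: float, s_left: float, s_right: float,
                J_left: float, J_right: float) -> float:
    """Ising energy of one site: -[J_l*(s_i+s_l) + J_r*(s_i+s_r)].

    An absent neighbor is encoded as (s=0, J=0); NaN couplings are treated
    the same way.
    """
    jl = 0.0 if J_left is None or not np.isfinite(J_left) else float(J_left)
    jr = 0.0 if J_right is None or not np.isfinite(J_right) else float(J_right)
    return -(jl * (s_i + s_left) + jr * (s_i + s_right))


def combine_energies(e_mean, e_var):
    """Combine feature energies via the per-site weight lambda.

    lambda = e_mean / (e_mean + e_var) and e = lambda*e_mean +
    (1-lambda)*e_var = (e_mean^2 + e_var^2) / (e_mean + e_var). The
    degenerate denominator (both energies zero, or exact cancellation under
    negative couplings) yields lambda = 0.5 and e = 0.

    Returns (lambda, e); vectorized over array inputs.
    """
    em = np.asarray(e_mean, dtype=float)
    ev = np.asarray(e_var, dtype=float)
    denom = em + ev
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(denom != 0, em / np.where(denom != 0, denom, 1.0), 0.5)
        e = np.where(denom != 0, (em ** 2 + ev ** 2) /
                     np.where(denom != 0, denom, 1.0), 0.0)
    if np.ndim(e_mean) == 0 and np.ndim(e_var) == 0:
        return float(lam), float(e)
    return lam, e


# ---------------------------------------------------------------------------
# Vectorized engine
# ---------------------------------------------------------------------------

class EnergyEngine:
    """Precomputed state for repeated site-energy evaluation with fixed J.

    A label permutation in a paired design is a vector of +/-1 signs, one per
    pair (+1 keeps the pair, -1 swaps tumor and normal). Swapping flips the
    difference D = T - N while leaving the sum S = T + N unchanged, so both
    test statistics for *all* permutations reduce to two matrix products:
    D @ signs for the paired t-test and (S_centered * D) @ signs for the
    Pitman-Morgan correlation. Couplings J come from the observed normal
    samples once and are never recomputed under permutation.
    """

    def __init__(self, dataset: MethylationDataset, window: int = 1):
        if window < 1:
            raise ValueError("window must be >= 1")
        dataset = dataset.to_m()
        self.dataset = dataset
        self.window = int(window)
        tumor, normal = dataset.paired_matrices()
        self.n_pairs = tumor.shape[1]
        if self.n_pairs < 4:
            raise ValueError("need >= 4 pairs for the paired tests")
        self.D = tumor - normal
        S = tumor + normal
        self._ssq_d = (self.D ** 2).sum(axis=1)
        self._S_c = S - S.mean(axis=1, keepdims=True)
        self._ss_S = (self._S_c ** 2).sum(axis=1)
        self._SD = self._S_c * self.D
        self.chrom_codes = dataset.chrom_codes()
        # couplings per offset d: array of length n_sites - d linking i, i+d
        normals = dataset.condition_matrix(NORMAL)
        self.couplings = [
            _adjacent_correlations(normals, self.chrom_codes, offset=d)
            for d in range(1, self.window + 1)
        ]
        n_negative = int(sum(np.nansum(j < 0) for j in self.couplings))
        if n_negative:
            logger.info("%d neighbor couplings are negative and used as-is",
                        n_negative)

    # -- p-values ----------------------------------------------------------

    def pvalues(self, signs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(p_mean, p_var) of shape (n_sites, n_perm) for a sign matrix.

        ``signs`` has shape (n_pairs,) or (n_pairs, n_perm) with entries
        in {-1, +1}. Column of ones reproduces the observed labels.
        """
        signs = np.asarray(signs, dtype=float)
        if signs.ndim == 1:
            signs = signs[:, None]
        if signs.shape[0] != self.n_pairs:
            raise ValueError("signs length must equal the number of pairs")
        n = self.n_pairs
        md = (self.D @ signs) / n
        var_d = (self._ssq_d[:, None] - n * md ** 2) / (n - 1)
        var_d = np.maximum(var_d, 0.0)
        # relative tolerance catches exact-constant differences that cancel
        # to rounding error instead of zero
        zero_d = var_d <= (self._ssq_d[:, None] / n) * 1e-12
        with np.errstate(invalid="ignore", divide="ignore"):
            t_mean = md / np.sqrt(var_d / n)
        p_mean = 2.0 * stats.t.sf(np.abs(t_mean), df=n - 1)
        p_mean[zero_d] = 1.0

        cross = self._SD @ signs
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cross / np.sqrt(self._ss_S[:, None] * (n - 1) * var_d)
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_var = r * np.sqrt(n - 2) / np.sqrt(np.maximum(1 - r ** 2, P_FLOOR))
        p_var = stats.t.sf(t_var, df=n - 2)
        zero_v = zero_d | (self._ss_S[:, None] <= 0)
        p_var[zero_v] = 1.0
        return p_mean, p_var

    # -- energies ----------------------------------------------------------

    def feature_energy(self, s: np.ndarray) -> np.ndarray:
        """Map a signal matrix (n_sites, n_perm) to feature energies."""
        e = np.zeros_like(s)
        for d, j in enumerate(self.couplings, start=1):
            if len(j) == 0:
                continue
            jv = np.where(np.isnan(j), 0.0, j)[:, None]
            contrib = -jv * (s[:-d] + s[d:])
            e[:-d] += contrib
            e[d:] += contrib
        return e

    def site_energies(self, signs: np.ndarray, full: bool = False):
        """Total site energies for each permutation column of ``signs``.

        With ``full=True`` returns a dict carrying all intermediates
        (p-values, signals, feature energies, lambda) alongside ``e``.
        """
        p_mean, p_var = self.pvalues(signs)
        s_mean = signal_from_pvalue(p_mean)
        s_var = signal_from_pvalue(p_var)
        e_mean = self.feature_energy(s_mean)
        e_var = self.feature_energy(s_var)
        lam, e = combine_energies(e_mean, e_var)
        if not full:
            return e
        return {
            "p_mean": p_mean, "p_var": p_var,
            "s_mean": s_mean, "s_var": s_var,
            "e_mean": e_mean, "e_var": e_var,
            "lambda": lam, "e": e,
        }

    def observed_signs(self) -> np.ndarray:
        return np.ones((self.n_pairs, 1))


def compute_energy_table(dataset: MethylationDataset,
                         window: int = 1) -> pd.DataFrame:
    """Full per-site energy table for the observed labels.

    Columns: site_id, chrom, pos, p_mean, p_var, s_mean, s_var, J_left,
    J_right, e_mean, e_var, lambda, e. Row order follows the (chrom, pos)-
    sorted manifest.
    """
    engine = EnergyEngine(dataset, window=window)
    return energy_table_from_engine(engine)


def energy_table_from_engine(engine: EnergyEngine) -> pd.DataFrame:
    parts = engine.site_energies(engine.observed_signs(), full=True)
    ds = engine.dataset
    n = ds.n_sites
    j1 = engine.couplings[0] if engine.couplings else np.zeros(0)
    j_left = np.full(n, np.nan)
    j_right = np.full(n, np.nan)
    if n > 1:
        j_right[:-1] = j1
        j_left[1:] = j1
    return pd.DataFrame({
        "site_id": ds.manifest["site_id"].to_numpy(),
        "chrom": ds.manifest["chrom"].to_numpy(),
        "pos": ds.manifest["pos"].to_numpy(),
        "p_mean": parts["p_mean"][:, 0],
        "p_var": parts["p_var"][:, 0],
        "s_mean": parts["s_mean"][:, 0],
        "s_var": parts["s_var"][:, 0],
        "J_left": j_left,
        "J_right": j_right,
        "e_mean": parts["e_mean"][:, 0],
        "e_var": parts["e_var"][:, 0],
        "lambda": parts["lambda"][:, 0],
        "e": parts["e"][:, 0],
    })
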