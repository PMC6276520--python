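"""Permutation p-values and multiplicity correction for candidate DMRs.

For each label permutation the entire region-calling step is repeated (same
tau, same couplings J, same minimum size), and the per-site energies E/size
of every permuted region are pooled into a null. A candidate's p-value is
the fraction of null values strictly below its own per-site energy; a
pseudocount correction (count+1)/(total+1) keeps p away from exactly zero,
and the raw count ratio is reported alongside. Bonferroni (default) or
Benjamini-Hochberg adjustment is applied across the observed candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from statsmodels.stats.multitest import multipletests

from .data import RegionRecord
from .energy import EnergyEngine
from .regions import _greedy_spans, sample_sign_matrix

logger = logging.getLogger(__name__)


@dataclass
class PermutationNull:
    """Pooled per-site energies of regions grown under label permutations."""

    per_site_energies: np.ndarray  # sorted ascending
    n_t: np.ndarray                # regions per permutation
    total_regions: int
    tau: float
    rng_seed: int | None = None

    @property
    def degenerate(self) -> bool:
        return self.total_regions == 0


def build_null(dataset_or_engine, tau: float, n_permutations: int = 1000,
               seed: int | None = None, min_sites: int = 2,
               signs: np.ndarray | None = None,
               cluster_blocks: np.ndarray | None = None) -> PermutationNull:
    """Regrow regions under each permutation and pool their E/size values.

    Must be run with the same ``tau``, couplings, and ``min_sites`` as the
    observed call; pass the threshold step's sign matrix via ``signs`` to
    share the identical permutation set.
    """
    engine = (dataset_or_engine if isinstance(dataset_or_engine, EnergyEngine)
              else EnergyEngine(dataset_or_engine))
    if signs is None:
        rng = np.random.default_rng(seed)
        signs = sample_sign_matrix(engine.n_pairs, n_permutations, rng)
    elif signs.shape != (engine.n_pairs, n_permutations):
        raise ValueError("signs shape must be (n_pairs, n_permutations)")
    e = engine.site_energies(signs)
    blocks = engine.chrom_codes if cluster_blocks is None else cluster_blocks
    values: list[float] = []
    n_t = np.zeros(n_permutations, dtype=int)
    for t in range(n_permutations):
        spans = _greedy_spans(e[:, t], blocks, tau)
        col = e[:, t]
        kept = 0
        for lo, hi in spans:
            size = hi - lo + 1
            if size < min_sites:
                continue
            values.append(float(col[lo:hi + 1].sum()) / size)
            kept += 1
        n_t[t] = kept
    total = int(n_t.sum())
    if total == 0:
        logger.warning("degenerate permutation null: no permuted regions; "
                       "all candidate p-values will be 1")
    return PermutationNull(
        per_site_energies=np.sort(np.asarray(values, dtype=float)),
        n_t=n_t, total_regions=total, tau=tau, rng_seed=seed,
    )


def region_pvalue(candidate: RegionRecord,
                  null: PermutationNull) -> tuple[float, float]:
    """(raw, corrected) permutation p-value of one candidate region.

    raw = #{null per-site energies strictly below the candidate's} / total
    (ties count as not-more-extreme); corrected = (count+1)/(total+1), the
    standard permutation pseudocount that keeps p > 0.
    """
    if null.degenerate:
        return 1.0, 1.0
    count = int(np.searchsorted(null.per_site_energies,
                                candidate.per_site_energy, side="left"))
    raw = count / null.total_regions
    corrected = (count + 1) / (null.total_regions + 1)
    return raw, corrected


def attach_pvalues(candidates: list[RegionRecord],
                   null: PermutationNull) -> list[RegionRecord]:
    """Return candidates with p_raw and p_value (corrected) populated."""
    out = []
    for cand in candidates:
        raw, corrected = region_pvalue(cand, null)
        out.append(dc_replace(cand, p_raw=raw, p_value=corrected))
    return out


def adjust_and_filter(regions: list[RegionRecord], alpha: float = 0.05,
                      method: str = "bonferroni") -> list[RegionRecord]:
    """Multiplicity-adjust candidate p-values and keep p_adjusted < alpha.

    The number of comparisons is the number of observed candidates. Output
    is sorted by (p_adjusted, per_site_energy). Supported methods:
    ``bonferroni`` (default, the conservative choice) and ``fdr_bh``.
    """
    if method not in ("bonferroni", "fdr_bh"):
        raise ValueError(f"unsupported correction method {method!r}")
    if not regions:
        return []
    pvals = np.array([r.p_value for r in regions], dtype=float)
    if np.any(np.isnan(pvals)):
        raise ValueError("all candidates must carry raw p-values")
    _, p_adj, _, _ = multipletests(pvals, alpha=alpha, method=method)
    out = [dc_replace(r, p_adjusted=float(p)) for r, p in zip(regions, p_adj)]
    out = [r for r in out if r.p_adjusted < alpha]
    out.sort(key=lambda r: (r.p_adjusted, r.per_site_energy))
    return out
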