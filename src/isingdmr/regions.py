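"""Permutation energy threshold and greedy candidate-region growth.

The energy threshold tau is the 5% lower tail of the permutation-null site
energy distribution: sample labels are swapped independently within each
tumor/normal pair, site energies are recomputed with the couplings J held
fixed, the 5th percentile of the pooled per-site energies is taken for each
permutation, and tau is the mean of those per-permutation quantiles.

Candidate regions are grown greedily: seed at the unassigned site with the
globally lowest energy (if below tau), then repeatedly absorb the lower-
energy of the region's two flanking manifest neighbors while that flank's
energy is below tau; ties go to the left flank. Regions never cross
chromosome (or, optionally, cluster) boundaries. For this two-flank rule the
closed regions coincide with maximal runs of consecutive sub-tau sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MethylationDataset, RegionRecord
from .energy import EnergyEngine

logger = logging.getLogger(__name__)


@dataclass
class ThresholdEstimate:
    """Permutation-derived energy threshold.

    ``tau`` is the mean over permutations of the per-permutation lower
    ``quantile`` of pooled site energies (ascending 5th percentile by
    default; informative energies are the most negative).
    """

    tau: float
    n_permutations: int
    quantile: float
    per_permutation_quantiles: np.ndarray
    rng_seed: int | None = None

    def __post_init__(self):
        self.per_permutation_quantiles = np.asarray(
            self.per_permutation_quantiles, dtype=float)
        if len(self.per_permutation_quantiles) != self.n_permutations:
            raise ValueError("quantile list length != n_permutations")
        if not np.isclose(self.tau,
                          float(self.per_permutation_quantiles.mean())):
            raise ValueError("tau must equal the mean per-permutation quantile")


@dataclass
class CandidateRegionSet:
    """Candidate DMRs (p-values unset) from one greedy pass."""

    regions: list[RegionRecord]
    tau: float
    n_discarded: int = 0
    trace: list | None = None


def sample_sign_matrix(n_pairs: int, n_permutations: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Within-pair label-swap permutations as a (n_pairs, n_perm) sign matrix."""
    return rng.integers(0, 2, size=(n_pairs, n_permutations)) * 2.0 - 1.0


def permutation_threshold(dataset_or_engine, n_permutations: int,
                          quantile: float = 0.05,
                          seed: int | None = None,
                          signs: np.ndarray | None = None) -> ThresholdEstimate:
    """Estimate tau from within-pair label-swap permutations.

    Accepts either a :class:`MethylationDataset` or a prebuilt
    :class:`EnergyEngine` (couplings J are fixed either way). A precomputed
    sign matrix may be passed to share permutations with the significance
    null.
    """
    if n_permutations < 2:
        raise ValueError("n_permutations must be >= 2")
    if not 0 <= quantile < 1:
        raise ValueError("quantile must lie in [0, 1)")
    engine = (dataset_or_engine if isinstance(dataset_or_engine, EnergyEngine)
              else EnergyEngine(dataset_or_engine))
    if signs is None:
        rng = np.random.default_rng(seed)
        signs = sample_sign_matrix(engine.n_pairs, n_permutations, rng)
    elif signs.shape != (engine.n_pairs, n_permutations):
        raise ValueError("signs shape must be (n_pairs, n_permutations)")
    e = engine.site_energies(signs)
    q = np.quantile(e, quantile, axis=0)
    tau = float(q.mean())
    if np.all(e == 0):
        logger.warning("all permuted energies are zero; tau=0, no regions "
                       "will be called")
        tau = 0.0
        q = np.zeros(n_permutations)
    return ThresholdEstimate(tau=tau, n_permutations=n_permutations,
                             quantile=quantile,
                             per_permutation_quantiles=q, rng_seed=seed)


# ---------------------------------------------------------------------------
# Greedy growth
# ---------------------------------------------------------------------------

def _greedy_spans(e: np.ndarray, blocks: np.ndarray, tau: float,
                  collect_trace: bool = False):
    """Greedy seed-and-extend over one energy vector.

    ``blocks`` gives the adjacency block (chromosome, optionally refined by
    cluster) of each site; growth never crosses a block change. Returns
    spans [(lo, hi)] in seed-discovery order and, optionally, a per-region
    trace of the site indices in the order they were absorbed.
    """
    sub = np.flatnonzero(e < tau)
    spans: list[tuple[int, int]] = []
    traces: list[list[int]] = []
    if len(sub) == 0:
        return (spans, traces) if collect_trace else spans
    order = sub[np.argsort(e[sub], kind="stable")]
    assigned = np.zeros(len(e), dtype=bool)
    n = len(e)
    for seed in order:
        if assigned[seed]:
            continue
        lo = hi = int(seed)
        assigned[seed] = True
        trace = [lo]
        while True:
            left = lo - 1
            right = hi + 1
            left_ok = (left >= 0 and not assigned[left]
                       and blocks[left] == blocks[seed] and e[left] < tau)
            right_ok = (right < n and not assigned[right]
                        and blocks[right] == blocks[seed] and e[right] < tau)
            if not left_ok and not right_ok:
                break
            # absorb the lower-energy flank; ties go left (lower index)
            if left_ok and (not right_ok or e[left] <= e[right]):
                lo = left
                assigned[left] = True
                trace.append(left)
            else:
                hi = right
                assigned[right] = True
                trace.append(right)
        spans.append((lo, hi))
        if collect_trace:
            traces.append(trace)
    return (spans, traces) if collect_trace else spans


def _assert_caller_invariants(e: np.ndarray, blocks: np.ndarray, tau: float,
                              spans: list[tuple[int, int]]) -> None:
    """Every member sub-tau; spans disjoint and maximal (cheap check)."""
    covered = np.zeros(len(e), dtype=bool)
    for lo, hi in spans:
        assert np.all(e[lo:hi + 1] < tau), "region member with e >= tau"
        assert not covered[lo:hi + 1].any(), "overlapping regions"
        covered[lo:hi + 1] = True
        if lo > 0 and blocks[lo - 1] == blocks[lo]:
            assert e[lo - 1] >= tau or covered[lo - 1], "non-maximal region"
        if hi + 1 < len(e) and blocks[hi + 1] == blocks[hi]:
            assert e[hi + 1] >= tau or covered[hi + 1], "non-maximal region"


def grow_regions(energy_table: pd.DataFrame, tau: float,
                 min_sites: int = 2,
                 cluster_ids: np.ndarray | None = None,
                 collect_trace: bool = False) -> CandidateRegionSet:
    """Grow candidate DMRs from a per-site energy table.

    ``energy_table`` is the frame produced by
    :func:`~isingdmr.energy.compute_energy_table` (sorted by chrom, pos).
    Regions with fewer than ``min_sites`` members are discarded after growth
    (logged count). Passing per-site ``cluster_ids`` additionally forbids
    growth across cluster boundaries.
    """
    if len(energy_table) == 0:
        return CandidateRegionSet(regions=[], tau=tau)
    e = energy_table["e"].to_numpy(dtype=float)
    chroms = energy_table["chrom"].to_numpy()
    codes, _ = pd.factorize(chroms, sort=False)
    blocks = codes.astype(np.int64)
    if cluster_ids is not None:
        cluster_ids = np.asarray(cluster_ids)
        if len(cluster_ids) != len(e):
            raise ValueError("cluster_ids length mismatch")
        _, cl = np.unique(cluster_ids, return_inverse=True)
        blocks = blocks * (cl.max() + 1) + cl
    result = _greedy_spans(e, blocks, tau, collect_trace=collect_trace)
    spans, traces = result if collect_trace else (result, None)
    _assert_caller_invariants(e, blocks, tau, spans)

    pos = energy_table["pos"].to_numpy()
    site_ids = energy_table["site_id"].to_numpy()
    regions = []
    n_discarded = 0
    for lo, hi in spans:
        if hi - lo + 1 < min_sites:
            n_discarded += 1
            continue
        total = float(e[lo:hi + 1].sum())
        regions.append(RegionRecord(
            chrom=str(chroms[lo]),
            start_pos=int(pos[lo]), end_pos=int(pos[hi]),
            site_ids=tuple(site_ids[lo:hi + 1]),
            n_sites=hi - lo + 1,
            energy=total, per_site_energy=total / (hi - lo + 1),
            start_idx=lo, end_idx=hi,
        ))
    if n_discarded:
        logger.info("discarded %d regions smaller than min_sites=%d",
                    n_discarded, min_sites)
    regions.sort(key=lambda r: (r.chrom, r.start_pos))
    return CandidateRegionSet(regions=regions, tau=tau,
                              n_discarded=n_discarded, trace=traces)


def region_energy(site_ids, energy_table: pd.DataFrame) -> tuple[float, float]:
    """Total and per-site energy of a run of consecutive manifest sites.

    Raises if the sites are not consecutive rows of the table.
    """
    site_ids = list(site_ids)
    index = pd.Index(energy_table["site_id"])
    locs = index.get_indexer(site_ids)
    if np.any(locs < 0):
        missing = site_ids[int(np.flatnonzero(locs < 0)[0])]
        raise ValueError(f"site {missing!r} not in energy table")
    if not np.array_equal(locs, np.arange(locs[0], locs[0] + len(locs))):
        raise ValueError("region sites must be consecutive in the manifest")
    e = energy_table["e"].to_numpy()[locs]
    total = float(e.sum())
    return total, total / len(site_ids)
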