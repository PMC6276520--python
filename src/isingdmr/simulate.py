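"""Synthetic paired tumor/normal methylation data with embedded truth DMRs.

The generator emulates a 100-pair, 10000-site methylation-array study on
M-values. Within each positional cluster of h consecutive sites, methylation
follows a scaled multivariate normal:

    X | control       = z * N(0, Sigma)
    X | tumor, DMR    = z * N(mu, D Sigma D),   D = diag(v_1..v_h)

with Sigma_ij = sigma * rho^|i-j| (AR(1)-correlated neighbors), z ~ Beta(1,1)
drawn once per sample (sample-level heterogeneity scaling the whole vector),
mu_i ~ unif(mu_a, mu_b) for mean-signal sites, and v_i = alpha + unif(0, 0.5)
for variance-signal sites. Tumor samples outside truth DMRs follow the
control law. Ten whole clusters (with at least 3 sites) are embedded as
truth DMRs: 3 mean-only, 3 variance-only, 4 with both signals.

Genomic positions are synthesized with 450k-like clumping (a mixture of
short and long inter-site gaps) and clusters are cut wherever the gap
exceeds ``max_gap`` (300 bp, the bump-hunter clusterMaker convention).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MethylationDataset

logger = logging.getLogger(__name__)

#: class labels for embedded truth DMRs
MEAN_ONLY = "mean"
VAR_ONLY = "variance"
BOTH = "both"


@dataclass
class SimulationConfig:
    """Parameters of the scaled-normal cluster simulation.

    Defaults are the study conditions: 100 pairs, 10000 sites, 10 embedded
    DMRs split 3 mean-only / 3 variance-only / 4 both, and parameter setting
    1 of the five-row grid (mu in unif(-2,2), variance base 1.5, sigma 0.3,
    rho 0.7). ``sigma`` is the marginal *variance* scale of the AR(1)
    covariance Sigma_ij = sigma * rho^|i-j|.
    """

    n_pairs: int = 100
    n_sites: int = 10000
    mu_a: float = -2.0
    mu_b: float = 2.0
    alpha_var: float = 1.5
    sigma: float = 0.3
    rho: float = 0.7
    n_true_dmrs: int = 10
    class_split: tuple = (3, 3, 4)  # (mean-only, variance-only, both)
    max_gap: int = 300
    min_cluster_sites: int = 3
    z_mode: str = "sample"  # "sample": one z scales the whole vector; "site"
    mu_mode: str = "uniform"  # "uniform": unif(mu_a, mu_b); "split": +/-unif
    seed: int | None = None

    def __post_init__(self):
        if self.mu_a > self.mu_b:
            raise ValueError("mu_a must be <= mu_b")
        if not 0 < self.rho < 1:
            raise ValueError("rho must lie in (0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if sum(self.class_split) != self.n_true_dmrs:
            raise ValueError("class_split must sum to n_true_dmrs")
        if self.z_mode not in ("sample", "site"):
            raise ValueError("z_mode must be 'sample' or 'site'")
        if self.mu_mode not in ("uniform", "split"):
            raise ValueError("mu_mode must be 'uniform' or 'split'")


@dataclass(frozen=True)
class TruthRegion:
    """One embedded truth DMR: a whole positional cluster."""

    cluster_id: int
    chrom: str
    start_pos: int
    end_pos: int
    start_idx: int
    end_idx: int
    n_sites: int
    signal_class: str
    mu: tuple
    v: tuple


@dataclass
class SimulationTruth:
    """Generated dataset plus ground truth."""

    dataset: MethylationDataset
    true_dmrs: list[TruthRegion]
    cluster_ids: np.ndarray
    config: SimulationConfig

    def truth_site_mask(self) -> np.ndarray:
        mask = np.zeros(self.dataset.n_sites, dtype=bool)
        for t in self.true_dmrs:
            mask[t.start_idx:t.end_idx + 1] = True
        return mask


def preset_config(setting: int, **overrides) -> SimulationConfig:
    """The five standard parameter settings of the simulation study."""
    grid = {
        1: (-2.0, 2.0, 1.5, 0.3, 0.7),
        2: (-2.0, 2.0, 2.5, 0.3, 0.7),
        3: (-3.0, 3.0, 1.5, 0.3, 0.7),
        4: (-3.0, 3.0, 2.5, 0.3, 0.7),
        5: (-2.0, 2.0, 1.5, 0.3, 0.4),
    }
    if setting not in grid:
        raise ValueError(f"unknown parameter setting {setting!r}; expected 1..5")
    mu_a, mu_b, alpha_var, sigma, rho = grid[setting]
    return SimulationConfig(mu_a=mu_a, mu_b=mu_b, alpha_var=alpha_var,
                            sigma=sigma, rho=rho, **overrides)


# ---------------------------------------------------------------------------
# Positions and clusters
# ---------------------------------------------------------------------------

def synth_positions(n_sites: int, seed=None,
                    chrom: str = "chr1") -> pd.DataFrame:
    """Synthesize a clumpy single-chromosome site manifest.

    Inter-site gaps are drawn from a mixture — 80% geometric with mean
    120 bp (within CpG-dense islands), 20% geometric with mean 5000 bp
    (between islands) — giving the heavy-tailed, clumped spacing typical of
    the first stretch of chromosome 1 on a 450k array.
    """
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    long_gap = rng.random(n_sites - 1) < 0.2
    gaps = np.where(long_gap,
                    rng.geometric(1.0 / 5000.0, size=n_sites - 1),
                    rng.geometric(1.0 / 120.0, size=n_sites - 1))
    pos = np.empty(n_sites, dtype=np.int64)
    pos[0] = 10_000
    pos[1:] = pos[0] + np.cumsum(gaps)
    return pd.DataFrame({
        "site_id": [f"cg{i:06d}" for i in range(n_sites)],
        "chrom": chrom,
        "pos": pos,
    })


def make_clusters(manifest: pd.DataFrame, max_gap: int = 300) -> np.ndarray:
    """Gap-based single-linkage clustering of manifest sites.

    A new cluster starts at each chromosome change or wherever the gap to
    the previous site exceeds ``max_gap`` (clusterMaker semantics). Ids are
    contiguous from 1 in manifest order.
    """
    pos = manifest["pos"].to_numpy()
    chrom = manifest["chrom"].to_numpy()
    n = len(manifest)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    new = np.ones(n, dtype=bool)
    if n > 1:
        new[1:] = (chrom[1:] != chrom[:-1]) | (np.diff(pos) > max_gap)
    return np.cumsum(new).astype(np.int64)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _ar1_noise(n_sites: int, n_cols: int, cluster_start: np.ndarray,
               sigma: float, rho: float,
               rng: np.random.Generator) -> np.ndarray:
    """Draw N(0, Sigma) vectors with Sigma_ij = sigma*rho^|i-j| per cluster.

    The AR(1) covariance admits an exact sequential construction:
    eta_1 = sqrt(sigma) g_1, eta_i = rho*eta_{i-1} + sqrt(sigma(1-rho^2)) g_i,
    restarted at every cluster boundary.
    """
    g = rng.standard_normal((n_sites, n_cols))
    eta = np.empty_like(g)
    sd0 = np.sqrt(sigma)
    sd_step = np.sqrt(sigma * (1.0 - rho * rho))
    for i in range(n_sites):
        if cluster_start[i]:
            eta[i] = sd0 * g[i]
        else:
            eta[i] = rho * eta[i - 1] + sd_step * g[i]
    return eta


def simulate_dataset(config: SimulationConfig,
                     seed: int | None = None) -> SimulationTruth:
    """Generate one paired dataset with embedded truth DMRs (M scale).

    ``seed`` overrides ``config.seed``; a fixed seed makes the full
    SimulationTruth (positions, cluster selection, drawn mu_i/v_i, data)
    reproducible.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    manifest = synth_positions(config.n_sites, seed=rng)
    clusters = make_clusters(manifest, max_gap=config.max_gap)

    # choose truth clusters among those with enough sites
    ids, counts = np.unique(clusters, return_counts=True)
    eligible = ids[counts >= config.min_cluster_sites]
    if len(eligible) < config.n_true_dmrs:
        raise ValueError(
            f"only {len(eligible)} clusters with >= "
            f"{config.min_cluster_sites} sites; cannot embed "
            f"{config.n_true_dmrs} truth DMRs")
    chosen = rng.choice(eligible, size=config.n_true_dmrs, replace=False)
    classes = ([MEAN_ONLY] * config.class_split[0]
               + [VAR_ONLY] * config.class_split[1]
               + [BOTH] * config.class_split[2])

    n_sites, n_pairs = config.n_sites, config.n_pairs
    cluster_start = np.ones(n_sites, dtype=bool)
    cluster_start[1:] = clusters[1:] != clusters[:-1]

    # per-site signal vectors, zero / one outside truth DMRs
    mu_site = np.zeros(n_sites)
    v_site = np.ones(n_sites)
    true_dmrs: list[TruthRegion] = []
    pos = manifest["pos"].to_numpy()
    for cid, cls in zip(chosen, classes):
        idx = np.flatnonzero(clusters == cid)
        h = len(idx)
        mu = np.zeros(h)
        v = np.ones(h)
        if cls in (MEAN_ONLY, BOTH):
            if config.mu_mode == "uniform":
                mu = rng.uniform(config.mu_a, config.mu_b, size=h)
            else:  # "split": fixed-sign draws away from zero
                signs = rng.integers(0, 2, size=h) * 2 - 1
                mu = signs * rng.uniform(abs(config.mu_a) / 2,
                                         abs(config.mu_b), size=h)
        if cls in (VAR_ONLY, BOTH):
            v = config.alpha_var + rng.uniform(0.0, 0.5, size=h)
        mu_site[idx] = mu
        v_site[idx] = v
        true_dmrs.append(TruthRegion(
            cluster_id=int(cid), chrom=str(manifest["chrom"].iloc[idx[0]]),
            start_pos=int(pos[idx[0]]), end_pos=int(pos[idx[-1]]),
            start_idx=int(idx[0]), end_idx=int(idx[-1]), n_sites=h,
            signal_class=cls, mu=tuple(mu), v=tuple(v)))
    true_dmrs.sort(key=lambda t: t.start_idx)

    # controls and tumors: X = z * eta, with tumor truth clusters remapped to
    # z * (mu + v*eta) — i.e. mean mu and covariance D Sigma D before scaling
    eta_t = _ar1_noise(n_sites, n_pairs, cluster_start, config.sigma,
                       config.rho, rng)
    eta_n = _ar1_noise(n_sites, n_pairs, cluster_start, config.sigma,
                       config.rho, rng)
    if config.z_mode == "sample":
        z_t = rng.beta(1.0, 1.0, size=n_pairs)[None, :]
        z_n = rng.beta(1.0, 1.0, size=n_pairs)[None, :]
    else:
        z_t = rng.beta(1.0, 1.0, size=(n_sites, n_pairs))
        z_n = rng.beta(1.0, 1.0, size=(n_sites, n_pairs))
    x_tumor = z_t * (mu_site[:, None] + v_site[:, None] * eta_t)
    x_normal = z_n * eta_n

    width = len(str(n_pairs))
    samples = pd.DataFrame({
        "sample_id": [f"T{i + 1:0{width}d}" for i in range(n_pairs)]
                     + [f"N{i + 1:0{width}d}" for i in range(n_pairs)],
        "condition": ["tumor"] * n_pairs + ["normal"] * n_pairs,
        "pair_id": [f"P{i + 1:0{width}d}" for i in range(n_pairs)] * 2,
    })
    values = np.hstack([x_tumor, x_normal])
    dataset = MethylationDataset(manifest=manifest, samples=samples,
                                 values=values, scale="M")
    return SimulationTruth(dataset=dataset, true_dmrs=true_dmrs,
                           cluster_ids=clusters, config=config)


def write_truth_bed(truth: SimulationTruth, path) -> None:
    """Write embedded truth DMRs as BED6+ with a signal_class column."""
    rows = sorted(truth.true_dmrs, key=lambda t: (t.chrom, t.start_pos))
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tn_sites\t"
                 "signal_class\n")
        for t in rows:
            fh.write(f"{t.chrom}\t{t.start_pos - 1}\t{t.end_pos}\t"
                     f"cluster_{t.cluster_id}\t0\t.\t{t.n_sites}\t"
                     f"{t.signal_class}\n")


def read_truth_bed(path, manifest: pd.DataFrame) -> list[TruthRegion]:
    """Read a truth BED back into TruthRegion records (indices via manifest)."""
    out: list[TruthRegion] = []
    chrom_arr = manifest["chrom"].to_numpy()
    pos_arr = manifest["pos"].to_numpy()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
            cls = parts[7] if len(parts) > 7 else BOTH
            idx = np.flatnonzero((chrom_arr == chrom) & (pos_arr >= start0 + 1)
                                 & (pos_arr <= end))
            if len(idx) == 0:
                logger.warning("truth interval %s:%d-%d matches no manifest "
                               "site; skipped", chrom, start0 + 1, end)
                continue
            h = len(idx)
            out.append(TruthRegion(
                cluster_id=len(out) + 1, chrom=chrom,
                start_pos=start0 + 1, end_pos=end,
                start_idx=int(idx[0]), end_idx=int(idx[-1]), n_sites=h,
                signal_class=cls, mu=(0.0,) * h, v=(1.0,) * h))
    return out
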