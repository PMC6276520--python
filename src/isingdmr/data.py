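"""Data containers and I/O for paired methylation-array experiments.

The universal input is a :class:`MethylationDataset`: a site-by-sample matrix of
methylation measures (beta-values in (0,1) or M-values on the real line)
together with a site manifest (site id, chromosome, 1-based position) and a
paired sample sheet (one tumor and one matched normal per pair id).

Coordinates are 1-based inclusive internally, matching array-manifest
convention; BED output converts to 0-based half-open.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TUMOR = "tumor"
NORMAL = "normal"

#: beta-values exactly at 0 or 1 are clipped to [EPS, 1-EPS] before the logit
#: transform, which diverges at the boundary.
BETA_EPS = 1e-6

MANIFEST_COLUMNS = ("site_id", "chrom", "pos")
SAMPLE_COLUMNS = ("sample_id", "condition", "pair_id")


# ---------------------------------------------------------------------------
# beta <-> M conversion
# ---------------------------------------------------------------------------

def beta_to_m(beta):
    """Convert beta-values (methylated proportion) to M-values.

    M = log2(beta / (1 - beta)), the log2 ratio of methylated to unmethylated
    intensity. Strictly increasing on (0, 1); M(0.5) = 0.

    Parameters
    ----------
    beta : float or array-like
        Values strictly inside (0, 1).

    Raises
    ------
    ValueError
        If any value lies outside the open interval (0, 1).
    """
    arr = np.asarray(beta, dtype=float)
    bad = ~((arr > 0.0) & (arr < 1.0))
    if np.any(bad):
        offender = arr.ravel()[np.flatnonzero(bad.ravel())[0]]
        raise ValueError(
            f"beta_to_m requires values in the open interval (0, 1); got {offender!r}"
        )
    out = np.log2(arr / (1.0 - arr))
    return float(out) if np.isscalar(beta) or arr.ndim == 0 else out


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2**M / (1 + 2**M)."""
    arr = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("m_to_beta requires finite M-values")
    # numerically stable logistic in base 2
    out = np.where(arr >= 0, 1.0 / (1.0 + 2.0 ** (-arr)),
                   2.0 ** arr / (1.0 + 2.0 ** arr))
    return float(out) if np.isscalar(m) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionRecord:
    """A run of consecutive manifest sites called as a candidate/final DMR.

    ``start_pos``/``end_pos`` are 1-based inclusive genomic coordinates of the
    first and last member site. ``energy`` is the total Ising energy
    E(R) = sum of member site energies; ``per_site_energy`` is E / n_sites,
    the scale on which permutation p-values compare regions of unequal size.
    ``p_value`` carries the pseudocount-corrected permutation p-value,
    ``p_raw`` the uncorrected count ratio, ``p_adjusted`` the multiplicity-
    adjusted value (Bonferroni by default).
    """

    chrom: str
    start_pos: int
    end_pos: int
    site_ids: tuple
    n_sites: int
    energy: float
    per_site_energy: float
    start_idx: int | None = None
    end_idx: int | None = None
    p_value: float | None = None
    p_raw: float | None = None
    p_adjusted: float | None = None
    name: str | None = None

    def __post_init__(self):
        if self.n_sites != len(self.site_ids):
            raise ValueError("n_sites must equal len(site_ids)")
        if self.end_pos < self.start_pos:
            raise ValueError("end_pos < start_pos")

    @property
    def site_index_range(self) -> range:
        """Manifest row indices of member sites (requires start_idx/end_idx)."""
        if self.start_idx is None or self.end_idx is None:
            raise ValueError("region carries no manifest indices")
        return range(self.start_idx, self.end_idx + 1)


def _validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    for col in MANIFEST_COLUMNS:
        if col not in manifest.columns:
            raise ValueError(f"manifest missing required column {col!r}")
    manifest = manifest.loc[:, list(MANIFEST_COLUMNS)].copy()
    manifest["site_id"] = manifest["site_id"].astype(str)
    manifest["chrom"] = manifest["chrom"].astype(str)
    manifest["pos"] = manifest["pos"].astype(int)
    dup = manifest["site_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate site_id in manifest: {manifest.loc[dup, 'site_id'].iloc[0]!r}"
        )
    # stable sort keeps first-appearance chromosome order deterministic
    order = np.lexsort((manifest["pos"].to_numpy(),
                        manifest["chrom"].to_numpy()))
    manifest = manifest.iloc[order].reset_index(drop=True)
    same_chrom = manifest["chrom"].to_numpy()[1:] == manifest["chrom"].to_numpy()[:-1]
    nondecr = np.diff(manifest["pos"].to_numpy()) > 0
    bad = same_chrom & ~nondecr
    if bad.any():
        i = int(np.flatnonzero(bad)[0]) + 1
        raise ValueError(
            "manifest positions not strictly increasing within chromosome at "
            f"site {manifest['site_id'].iloc[i]!r}"
        )
    return manifest


def _validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    for col in SAMPLE_COLUMNS:
        if col not in samples.columns:
            raise ValueError(f"sample sheet missing required column {col!r}")
    samples = samples.loc[:, list(SAMPLE_COLUMNS)].copy()
    for col in SAMPLE_COLUMNS:
        samples[col] = samples[col].astype(str)
    bad_cond = ~samples["condition"].isin([TUMOR, NORMAL])
    if bad_cond.any():
        raise ValueError(
            f"unknown condition {samples.loc[bad_cond, 'condition'].iloc[0]!r}; "
            f"expected {TUMOR!r} or {NORMAL!r}"
        )
    dup = samples["sample_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate sample_id: {samples.loc[dup, 'sample_id'].iloc[0]!r}"
        )
    for pair_id, grp in samples.groupby("pair_id", sort=False):
        conditions = sorted(grp["condition"])
        if conditions != [NORMAL, TUMOR]:
            raise ValueError(
                f"pair_id {pair_id!r} must contain exactly one tumor and one "
                f"normal sample; found conditions {list(grp['condition'])}"
            )
    return samples.reset_index(drop=True)


@dataclass
class MethylationDataset:
    """Validated site-by-sample methylation matrix with manifest and pairing.

    ``values`` rows align with ``manifest`` rows (sorted by chrom, pos) and
    columns align with ``samples`` rows. ``scale`` is ``"beta"`` or ``"M"``.
    """

    manifest: pd.DataFrame
    samples: pd.DataFrame
    values: np.ndarray
    scale: str = "M"

    def __post_init__(self):
        self.manifest = _validate_manifest(self.manifest)
        self.samples = _validate_samples(self.samples)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.manifest), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.manifest)} manifest sites x {len(self.samples)} samples"
            )
        if np.isnan(self.values).any():
            raise ValueError(
                "dataset contains missing values; impute or filter before loading"
            )
        if self.scale not in ("beta", "M"):
            raise ValueError(f"scale must be 'beta' or 'M', got {self.scale!r}")
        if self.scale == "beta":
            if not np.all((self.values > 0) & (self.values < 1)):
                raise ValueError("beta-scale values must lie strictly in (0, 1)")
        elif not np.all(np.isfinite(self.values)):
            raise ValueError("M-scale values must be finite")

    # -- basic geometry -----------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.manifest)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_pairs(self) -> int:
        return self.samples["pair_id"].nunique()

    @property
    def pair_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for pid in self.samples["pair_id"]:
            seen.setdefault(pid, None)
        return sorted(seen)

    def column_of(self, sample_id: str) -> int:
        idx = self.samples.index[self.samples["sample_id"] == sample_id]
        if len(idx) == 0:
            raise KeyError(sample_id)
        return int(idx[0])

    def condition_matrix(self, condition: str) -> np.ndarray:
        cols = self.samples.index[self.samples["condition"] == condition].to_numpy()
        return self.values[:, cols]

    def paired_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (tumor, normal) matrices with columns aligned by pair_id.

        Pairs are ordered by sorted pair_id so the pairing is deterministic
        regardless of sample-sheet row order.
        """
        tumor_cols, normal_cols = [], []
        by_pair = self.samples.groupby("pair_id", sort=True)
        for _, grp in by_pair:
            tumor_cols.append(grp.index[grp["condition"] == TUMOR][0])
            normal_cols.append(grp.index[grp["condition"] == NORMAL][0])
        return self.values[:, tumor_cols], self.values[:, normal_cols]

    # -- transforms ---------------------------------------------------------

    def to_m(self, eps: float = BETA_EPS) -> "MethylationDataset":
        """Return an M-scale view of the dataset (no-op when already M-scale).

        Beta-values exactly at the boundary would map to +/-infinity; they are
        clipped into [eps, 1-eps] first, with a logged warning.
        """
        if self.scale == "M":
            return self
        vals = self.values
        n_clip = int(np.sum((vals <= eps) | (vals >= 1 - eps)))
        if n_clip:
            logger.warning("clipping %d beta-values into [%g, %g] before logit",
                           n_clip, eps, 1 - eps)
            vals = np.clip(vals, eps, 1 - eps)
        return MethylationDataset(
            manifest=self.manifest.copy(),
            samples=self.samples.copy(),
            values=beta_to_m(vals),
            scale="M",
        )

    def chrom_codes(self) -> np.ndarray:
        """Integer chromosome code per manifest row (adjacency blocks)."""
        codes, _ = pd.factorize(self.manifest["chrom"], sort=False)
        return codes.astype(np.int64)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def load_dataset(values_path, manifest_path, samples_path, scale: str,
                 target_scale: str | None = None,
                 impute: bool = False) -> MethylationDataset:
    """Load a dataset from three delimited text files.

    ``values_path``: matrix with site ids in the first column and sample ids
    as remaining headers. ``manifest_path``: columns site_id, chrom, pos.
    ``samples_path``: columns sample_id, condition, pair_id.

    Rows are reordered to the (chrom, pos)-sorted manifest; columns to the
    sample-sheet order. Missing values are rejected unless ``impute`` is set,
    in which case each missing cell is replaced by the site mean within its
    condition.
    """
    values = pd.read_csv(values_path, sep=None, engine="python", index_col=0)
    manifest = _validate_manifest(_read_table(manifest_path))
    samples = _validate_samples(_read_table(samples_path))

    missing_sites = set(manifest["site_id"]) - set(values.index.astype(str))
    if missing_sites:
        raise ValueError(
            f"values matrix missing manifest site {sorted(missing_sites)[0]!r}"
        )
    missing_samples = set(samples["sample_id"]) - set(values.columns.astype(str))
    if missing_samples:
        raise ValueError(
            f"values matrix missing sample {sorted(missing_samples)[0]!r}"
        )
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    mat = values.loc[manifest["site_id"], samples["sample_id"]].to_numpy(dtype=float)

    if np.isnan(mat).any():
        if not impute:
            i, j = np.argwhere(np.isnan(mat))[0]
            raise ValueError(
                f"missing value at site {manifest['site_id'].iloc[i]!r}, "
                f"sample {samples['sample_id'].iloc[j]!r}; pass impute=True "
                "to fill with within-condition site means"
            )
        for cond in (TUMOR, NORMAL):
            cols = samples.index[samples["condition"] == cond].to_numpy()
            block = mat[:, cols]
            means = np.nanmean(block, axis=1, keepdims=True)
            mask = np.isnan(block)
            block[mask] = np.broadcast_to(means, block.shape)[mask]
            mat[:, cols] = block
        logger.warning("imputed missing values with within-condition site means")

    ds = MethylationDataset(manifest=manifest, samples=samples,
                            values=mat, scale=scale)
    if target_scale == "M" and scale == "beta":
        ds = ds.to_m()
    elif target_scale == "beta" and scale == "M":
        raise ValueError("M-to-beta dataset conversion is not supported on load")
    return ds


def write_dataset(dataset: MethylationDataset, out_dir,
                  prefix: str = "") -> dict[str, str]:
    """Write values/manifest/samples TSVs; returns the paths written."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "values": os.path.join(out_dir, f"{prefix}values.tsv"),
        "manifest": os.path.join(out_dir, f"{prefix}manifest.tsv"),
        "samples": os.path.join(out_dir, f"{prefix}samples.tsv"),
    }
    vf = pd.DataFrame(dataset.values,
                      index=pd.Index(dataset.manifest["site_id"], name="site_id"),
                      columns=dataset.samples["sample_id"])
    vf.to_csv(paths["values"], sep="\t", float_format="%.10g")
    dataset.manifest.to_csv(paths["manifest"], sep="\t", index=False)
    dataset.samples.to_csv(paths["samples"], sep="\t", index=False)
    return paths


BED_HEADER = ("#chrom", "start", "end", "name", "score", "strand",
              "n_sites", "energy", "p_value", "p_adjusted")


def write_regions_bed(regions: Sequence[RegionRecord], path) -> None:
    """Write regions as BED6+ (0-based half-open; score = per-site energy).

    Columns beyond BED6: n_sites, total energy, permutation p-value and
    adjusted p-value. Rows are ordered by (chrom, start) for determinism.
    """
    rows = sorted(regions, key=lambda r: (r.chrom, r.start_pos, r.end_pos))
    with open(path, "w") as fh:
        fh.write("\t".join(BED_HEADER) + "\n")
        for k, r in enumerate(rows):
            name = r.name if r.name is not None else f"dmr_{k + 1}"
            fields = [
                r.chrom,
                str(r.start_pos - 1),
                str(r.end_pos),
                name,
                f"{r.per_site_energy:.6g}",
                ".",
                str(r.n_sites),
                f"{r.energy:.6g}",
                "NA" if r.p_value is None else f"{r.p_value:.6g}",
                "NA" if r.p_adjusted is None else f"{r.p_adjusted:.6g}",
            ]
            fh.write("\t".join(fields) + "\n")


def read_regions_bed(path, manifest: pd.DataFrame | None = None) -> list[RegionRecord]:
    """Read a BED file written by :func:`write_regions_bed`.

    With a manifest, member site_ids and manifest indices are reconstructed
    from the genomic span; without one, only the spans are recovered.
    """
    regions: list[RegionRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else None
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            n_sites = int(parts[6]) if len(parts) > 6 else 0
            energy = float(parts[7]) if len(parts) > 7 else score * max(n_sites, 1)
            pv = None
            padj = None
            if len(parts) > 8 and parts[8] != "NA":
                pv = float(parts[8])
            if len(parts) > 9 and parts[9] != "NA":
                padj = float(parts[9])
            start_pos, end_pos = start0 + 1, end
            site_ids: tuple = ()
            start_idx = end_idx = None
            if manifest is not None:
                hit = (manifest["chrom"].to_numpy() == chrom) & \
                      (manifest["pos"].to_numpy() >= start_pos) & \
                      (manifest["pos"].to_numpy() <= end_pos)
                idx = np.flatnonzero(hit)
                if len(idx) == 0:
                    logger.warning("BED interval %s:%d-%d matches no manifest "
                                   "site; skipped", chrom, start_pos, end_pos)
                    continue
                site_ids = tuple(manifest["site_id"].to_numpy()[idx])
                start_idx, end_idx = int(idx[0]), int(idx[-1])
                n_sites = len(site_ids)
            elif n_sites == 0:
                n_sites = 1
                site_ids = (name or f"{chrom}:{start_pos}-{end_pos}",)
            else:
                site_ids = tuple(f"{name}_{i}" for i in range(n_sites))
            regions.append(RegionRecord(
                chrom=chrom, start_pos=start_pos, end_pos=end_pos,
                site_ids=site_ids, n_sites=n_sites,
                energy=energy,
                per_site_energy=energy / n_sites if n_sites else 0.0,
                start_idx=start_idx, end_idx=end_idx,
                p_value=pv, p_adjusted=padj, name=name,
            ))
    return regions
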