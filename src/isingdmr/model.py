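"""Model/Results interface tying the pipeline together.

:class:`IsingDMRModel` is built from a :class:`~isingdmr.data.MethylationDataset`
and runs the three-step procedure on ``fit()``:

1. per-site energies from the paired mean and variance tests coupled through
   neighbor correlation (couplings J fixed from the normal samples);
2. permutation threshold tau and greedy candidate-region growth;
3. permutation p-values per candidate with multiplicity correction.

``fit`` returns an :class:`IsingDMRResults` carrying the energy table, the
threshold estimate, candidate and significant regions, a ``summary()``
table, and writers for BED/TSV/JSON artifacts.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .data import MethylationDataset, RegionRecord, load_dataset, \
    write_regions_bed
from .energy import EnergyEngine, energy_table_from_engine
from .regions import CandidateRegionSet, ThresholdEstimate, grow_regions, \
    permutation_threshold, sample_sign_matrix
from .significance import PermutationNull, adjust_and_filter, attach_pvalues, \
    build_null
from .evaluate import EvaluationReport, evaluate_calls

logger = logging.getLogger(__name__)


class IsingDMRModel:
    """Ising-energy DMR detector for a paired tumor/normal dataset.

    Parameters
    ----------
    dataset : MethylationDataset
        Paired methylation data; beta-scale input is converted to M-values.
    n_permutations_threshold : int
        Label permutations for the energy threshold tau (default 500).
    n_permutations_null : int
        Label permutations for the region-significance null (default 1000).
        When equal to ``n_permutations_threshold`` the identical permutation
        set is shared between the two steps.
    quantile : float
        Lower tail of the permuted site-energy distribution defining tau.
    alpha : float
        Significance level on the adjusted region p-values.
    correction : str
        ``"bonferroni"`` (default) or ``"fdr_bh"``.
    min_sites : int
        Minimum region size in CpG sites (default 2).
    window : int
        Neighbor window for the Ising coupling (default 1: the two adjacent
        sites).
    """

    def __init__(self, dataset: MethylationDataset, *,
                 n_permutations_threshold: int = 500,
                 n_permutations_null: int = 1000,
                 quantile: float = 0.05,
                 alpha: float = 0.05,
                 correction: str = "bonferroni",
                 min_sites: int = 2,
                 window: int = 1):
        if not 0 < quantile < 1 or not 0 < alpha < 1:
            raise ValueError("quantile and alpha must lie in (0, 1)")
        if n_permutations_threshold < 2 or n_permutations_null < 1:
            raise ValueError("permutation counts too small")
        self.dataset = dataset
        self.n_permutations_threshold = n_permutations_threshold
        self.n_permutations_null = n_permutations_null
        self.quantile = quantile
        self.alpha = alpha
        self.correction = correction
        self.min_sites = min_sites
        self.window = window
        self.engine = EnergyEngine(dataset, window=window)

    @classmethod
    def from_files(cls, values_path, manifest_path, samples_path,
                   scale: str = "M", **kwargs) -> "IsingDMRModel":
        ds = load_dataset(values_path, manifest_path, samples_path,
                          scale=scale, target_scale="M")
        return cls(ds, **kwargs)

    def fit(self, seed: int | None = None) -> "IsingDMRResults":
        """Run energy -> threshold -> call -> significance and collect results."""
        ss = np.random.SeedSequence(seed)
        seed_thr, seed_null = (int(s.generate_state(1)[0] % (2 ** 31))
                               for s in ss.spawn(2))
        engine = self.engine
        energy_table = energy_table_from_engine(engine)

        rng_thr = np.random.default_rng(seed_thr)
        signs_thr = sample_sign_matrix(engine.n_pairs,
                                       self.n_permutations_threshold, rng_thr)
        threshold = permutation_threshold(
            engine, self.n_permutations_threshold, quantile=self.quantile,
            seed=seed_thr, signs=signs_thr)

        candidates = grow_regions(energy_table, threshold.tau,
                                  min_sites=self.min_sites)

        if self.n_permutations_null == self.n_permutations_threshold:
            signs_null, seed_null = signs_thr, seed_thr
        else:
            rng_null = np.random.default_rng(seed_null)
            signs_null = sample_sign_matrix(engine.n_pairs,
                                            self.n_permutations_null, rng_null)
        null = build_null(engine, threshold.tau,
                          n_permutations=self.n_permutations_null,
                          seed=seed_null, min_sites=self.min_sites,
                          signs=signs_null)
        with_p = attach_pvalues(candidates.regions, null)
        significant = adjust_and_filter(with_p, alpha=self.alpha,
                                        method=self.correction)
        return IsingDMRResults(
            model=self, energy_table=energy_table, threshold=threshold,
            candidates=CandidateRegionSet(regions=with_p, tau=threshold.tau,
                                          n_discarded=candidates.n_discarded),
            null=null, significant_regions=significant,
            seed=seed, seeds={"threshold": seed_thr, "null": seed_null})


@dataclass
class IsingDMRResults:
    """Fitted results: energies, threshold, candidate and significant DMRs."""

    model: IsingDMRModel
    energy_table: pd.DataFrame
    threshold: ThresholdEstimate
    candidates: CandidateRegionSet
    null: PermutationNull
    significant_regions: list[RegionRecord]
    seed: int | None = None
    seeds: dict = field(default_factory=dict)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        """statsmodels-style text summary of the run and significant regions."""
        from statsmodels.iolib.table import SimpleTable

        ds = self.model.dataset
        info = [
            ("No. sites:", f"{ds.n_sites}"),
            ("No. pairs:", f"{ds.n_pairs}"),
            ("Energy threshold tau:", f"{self.threshold.tau:.4f}"),
            ("Permutations (tau / null):",
             f"{self.threshold.n_permutations} / "
             f"{int(len(self.null.n_t))}"),
            ("Candidate regions:", f"{len(self.candidates.regions)}"),
            ("Permuted null regions:", f"{self.null.total_regions}"),
            ("Significant regions:", f"{len(self.significant_regions)}"),
            ("Correction:",
             f"{self.model.correction} (alpha={self.model.alpha:g})"),
        ]
        top = SimpleTable([[k, v] for k, v in info],
                          title="Ising DMR detection results")
        lines = [str(top)]
        if self.significant_regions:
            rows = [[r.chrom, r.start_pos, r.end_pos, r.n_sites,
                     f"{r.energy:.3f}", f"{r.per_site_energy:.3f}",
                     f"{r.p_value:.4g}", f"{r.p_adjusted:.4g}"]
                    for r in self.significant_regions]
            tab = SimpleTable(rows, headers=["chrom", "start", "end",
                                             "n_sites", "E", "E/size",
                                             "p", "p_adj"],
                              title="Significant DMRs")
            lines.append(str(tab))
        return "\n".join(lines)

    def regions_frame(self, which: str = "significant") -> pd.DataFrame:
        regs = (self.significant_regions if which == "significant"
                else self.candidates.regions)
        return pd.DataFrame([{
            "chrom": r.chrom, "start_pos": r.start_pos, "end_pos": r.end_pos,
            "n_sites": r.n_sites, "energy": r.energy,
            "per_site_energy": r.per_site_energy, "p_raw": r.p_raw,
            "p_value": r.p_value, "p_adjusted": r.p_adjusted,
        } for r in regs])

    # -- evaluation ----------------------------------------------------------

    def evaluate(self, truth, theta: float = 0.2,
                 which: str = "significant") -> EvaluationReport:
        """Score the called regions against truth intervals at one theta."""
        called = (self.significant_regions if which == "significant"
                  else self.candidates.regions)
        return evaluate_calls(called, truth, self.model.dataset.n_sites,
                              theta=theta)

    # -- artifacts -----------------------------------------------------------

    def to_bed(self, path, which: str = "significant") -> None:
        regs = (self.significant_regions if which == "significant"
                else self.candidates.regions)
        write_regions_bed(regs, path)

    def save(self, out_dir, prefix: str = "") -> dict:
        """Write energy table, BEDs, and a machine-readable run manifest."""
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "energy": os.path.join(out_dir, f"{prefix}energy.tsv"),
            "candidates": os.path.join(out_dir, f"{prefix}candidates.bed"),
            "significant": os.path.join(out_dir, f"{prefix}significant.bed"),
            "manifest": os.path.join(out_dir, f"{prefix}run_manifest.json"),
        }
        self.energy_table.to_csv(paths["energy"], sep="\t", index=False,
                                 float_format="%.10g")
        self.to_bed(paths["candidates"], which="candidates")
        self.to_bed(paths["significant"], which="significant")
        manifest = {
            "version": __version__,
            "seed": self.seed,
            "stage_seeds": self.seeds,
            "tau": self.threshold.tau,
            "quantile": self.threshold.quantile,
            "n_permutations_threshold": self.threshold.n_permutations,
            "n_permutations_null": int(len(self.null.n_t)),
            "permutation_scheme": "within-pair label swap",
            "tau_rule": "mean over permutations of the ascending "
                        f"{self.threshold.quantile:g} site-energy quantile",
            "min_sites": self.model.min_sites,
            "window": self.model.window,
            "correction": self.model.correction,
            "alpha": self.model.alpha,
            "n_candidates": len(self.candidates.regions),
            "n_significant": len(self.significant_regions),
            "null_total_regions": self.null.total_regions,
        }
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths
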