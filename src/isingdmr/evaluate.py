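"""Scoring called DMRs against simulation truth.

Site level: the confusion matrix over manifest sites — d (true positive:
differential site inside a call), c (false negative), b (false positive),
a (true negative) — with sensitivity SE = d/(c+d) and specificity
SP = a/(a+b).

Region level: a called region is a true positive when its site overlap with
some truth DMR reaches theta times the truth region's length in sites
(overlap >= ceil(theta * len) by default; the literal strict ">" rule is
available by flag).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    """Confusion counts, SE/SP, and region TP/FP at one overlap theta."""

    theta: float
    a: int
    b: int
    c: int
    d: int
    se: float
    sp: float
    tp_regions: int
    fp_regions: int
    matches: list  # (called index, truth index, overlap site count)

    @property
    def n_sites(self) -> int:
        return self.a + self.b + self.c + self.d


def _site_mask(regions, n_sites: int) -> np.ndarray:
    """Boolean site mask from records carrying start_idx/end_idx."""
    mask = np.zeros(n_sites, dtype=bool)
    for r in regions:
        lo, hi = r.start_idx, r.end_idx
        if lo is None or hi is None:
            raise ValueError("region carries no manifest indices")
        if lo < 0 or hi >= n_sites:
            raise ValueError(f"site index span [{lo}, {hi}] outside manifest "
                             f"of {n_sites} sites")
        mask[lo:hi + 1] = True
    return mask


def site_confusion(called, truth, n_sites: int) -> tuple[int, int, int, int]:
    """(a, b, c, d) over manifest sites.

    d = called AND truth, c = truth only, b = called only, a = neither.
    """
    called_mask = _site_mask(called, n_sites)
    truth_mask = _site_mask(truth, n_sites)
    d = int(np.sum(called_mask & truth_mask))
    c = int(np.sum(truth_mask & ~called_mask))
    b = int(np.sum(called_mask & ~truth_mask))
    a = n_sites - b - c - d
    return a, b, c, d


def sensitivity_specificity(a: int, b: int, c: int,
                            d: int) -> tuple[float, float]:
    """SE = d/(c+d), SP = a/(a+b); an empty margin reports NaN with warning."""
    if c + d > 0:
        se = d / (c + d)
    else:
        logger.warning("no truth sites; sensitivity undefined")
        se = float("nan")
    if a + b > 0:
        sp = a / (a + b)
    else:
        logger.warning("no non-truth sites; specificity undefined")
        sp = float("nan")
    return se, sp


def _overlap_sites(called_region, truth_region) -> int:
    if called_region.chrom != truth_region.chrom:
        return 0
    lo = max(called_region.start_idx, truth_region.start_idx)
    hi = min(called_region.end_idx, truth_region.end_idx)
    return max(0, hi - lo + 1)


def region_tp_fp(called, truth, theta: float,
                 strict: bool = False) -> tuple[int, int, list]:
    """Classify called regions as TP/FP by the theta-overlap rule.

    A call is TP when its site overlap with some truth region reaches
    L = theta * (truth length in sites): overlap >= ceil(L) by default, or
    the literal overlap > L with ``strict=True``. A call overlapping several
    truth regions counts once; all (called, truth, overlap) matches are
    returned for de-duplication analyses.
    """
    if not 0 < theta <= 1:
        raise ValueError("theta must lie in (0, 1]")
    matches = []
    tp = 0
    for i, cr in enumerate(called):
        hit = False
        for j, tr in enumerate(truth):
            ov = _overlap_sites(cr, tr)
            if ov == 0:
                continue
            L = theta * tr.n_sites
            if (ov > L) if strict else (ov >= math.ceil(L)):
                matches.append((i, j, ov))
                hit = True
        if hit:
            tp += 1
    return tp, len(called) - tp, matches


def evaluate_calls(called, truth, n_sites: int, theta: float = 0.2,
                   strict: bool = False) -> EvaluationReport:
    """Full site- and region-level report for one theta."""
    a, b, c, d = site_confusion(called, truth, n_sites)
    se, sp = sensitivity_specificity(a, b, c, d)
    tp, fp, matches = region_tp_fp(called, truth, theta, strict=strict)
    return EvaluationReport(theta=theta, a=a, b=b, c=c, d=d, se=se, sp=sp,
                            tp_regions=tp, fp_regions=fp, matches=matches)
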