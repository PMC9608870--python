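"""Critical-region extraction and clinical-score correlation.

The aggregate vertex-relevance map defines the "critical" cortex: the top
fraction (default 3%) of vertices by relevance.  Selected vertices are
grouped by their source-space region labels, each region's per-subject mean
current density (over retained trials, selected vertices, and the analysis
window) is computed for the patient group, and Spearman rank correlations
against the seven clinical scores are tabulated.  Cells are flagged at
p < 0.05 without multiple-testing correction — a deliberate caveat: with 42
cells, chance flags are expected under the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from cortexlrp.preprocess import WindowedTrialSet
from cortexlrp.sourcespace import CorticalSourceSpace
from cortexlrp.synthdata import CLINICAL_SCORES, ClinicalTable

__all__ = [
    "CriticalRegionSet",
    "CorrelationTable",
    "top_fraction_mask",
    "region_activity",
    "spearman",
    "build_correlation_table",
]


@dataclass
class CriticalRegionSet:
    """Vertices in the top relevance fraction of the aggregate map."""

    selected: np.ndarray  # vertex ids, relevance-descending order
    fraction: float
    n_scored: int

    def mask(self) -> np.ndarray:
        m = np.zeros(self.n_scored, dtype=bool)
        m[self.selected] = True
        return m

    def region_masks(self, space: CorticalSourceSpace) -> dict[str, np.ndarray]:
        """Selected vertices grouped by source-space region label.

        Keys are "{hemisphere} {region}"; only labels with at least one
        selected vertex appear.
        """
        sel = self.mask()
        out: dict[str, np.ndarray] = {}
        for hemi in ("left", "right"):
            for name in (*space.region_names(), "background"):
                m = sel & space.region_mask(name, hemi)
                if np.any(m):
                    out[f"{hemi} {name}"] = m
        return out


def top_fraction_mask(vertex_relevance: np.ndarray, fraction: float = 0.03) -> CriticalRegionSet:
    """Select the top round(fraction * n) vertices by relevance.

    Ties at the cutoff are broken by ascending vertex id; an all-equal map
    degenerates to the first round(fraction * n) ids (with a warning).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    r = np.asarray(vertex_relevance, dtype=np.float64)
    n = len(r)
    k = int(np.floor(fraction * n + 0.5))
    if np.ptp(r) == 0:
        warnings.warn("all relevance values equal; selection is arbitrary (first ids)")
    order = np.lexsort((np.arange(n), -r))  # relevance desc, ties by id asc
    return CriticalRegionSet(selected=order[:k], fraction=fraction, n_scored=n)


def region_activity(windowed: WindowedTrialSet, region_mask: np.ndarray) -> pd.Series:
    """Per-subject mean current density over a vertex mask.

    For each subject: the mean over that subject's retained trials and the
    masked vertices of the window-averaged current density.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if not np.any(region_mask):
        raise ValueError("empty region mask")
    values = {}
    for sid in np.unique(windowed.subject_id):
        rows = windowed.subject_id == sid
        if not np.any(rows):  # pragma: no cover - unique() precludes this
            warnings.warn(f"subject {sid} has no retained trials; excluded")
            continue
        values[int(sid)] = float(windowed.data[np.ix_(rows, region_mask)].mean())
    return pd.Series(values, name="activity")


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Spearman rank correlation with mid-rank ties and a two-sided
    t-approximation p-value; |rho| = 1 maps to p = 0.

    Returns (rho, p, n).  Zero variance in either input leaves rho
    undefined (NaN, flagged by a warning).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance; Spearman rho undefined")
        return float("nan"), float("nan"), n
    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    if abs(rho) >= 1.0 - 1e-12:
        return float(np.sign(rho)), 0.0, n
    return rho, float(res.pvalue), n


@dataclass
class CorrelationTable:
    """Regions x clinical-scores Spearman table with per-cell flags."""

    rho: pd.DataFrame
    p: pd.DataFrame
    n: int
    alpha: float = 0.05

    @property
    def flagged(self) -> pd.DataFrame:
        return self.p < self.alpha

    def to_csv(self, path) -> None:
        out = self.rho.round(3).astype(str)
        out = out.where(~self.flagged, out + " *")
        out.to_csv(path)


def build_correlation_table(
    region_activities: dict[str, pd.Series],
    clinical: ClinicalTable,
    alpha: float = 0.05,
) -> CorrelationTable:
    """One Spearman test per (region, score) pair over patient subjects.

    ``region_activities`` maps region names to per-subject activity Series
    (patient subjects only; subjects are matched to the clinical table by
    id).  No multiple-testing correction is applied; cells are flagged at
    p < alpha.
    """
    clinical.validate()
    ct = clinical.table.set_index("subject_id")
    if len(ct) < 3:
        raise ValueError("need at least 3 patient subjects")

    rho = pd.DataFrame(index=list(region_activities), columns=list(CLINICAL_SCORES), dtype=float)
    pval = pd.DataFrame(index=list(region_activities), columns=list(CLINICAL_SCORES), dtype=float)
    n_used = len(ct)
    for region, activity in region_activities.items():
        common = [s for s in ct.index if s in activity.index]
        if len(common) < 3:
            raise ValueError(f"region {region!r}: fewer than 3 patients with activity")
        x = activity.loc[common].to_numpy()
        for score in CLINICAL_SCORES:
            r, p, n_used = spearman(x, ct.loc[common, score].to_numpy())
            rho.loc[region, score] = r
            pval.loc[region, score] = p
    return CorrelationTable(rho=rho, p=pval, n=n_used, alpha=alpha)
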