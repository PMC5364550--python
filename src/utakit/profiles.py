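"""Small-RNA count-profile computations.

Covers the expression side of the analysis: median-of-ratios size factors
(the DESeq normalisation formula), log2 quartile ranking of normalised means,
RPM/RPKM, cytoplasm/nucleus compartment ratios, and the Kruskal–Wallis +
Dunn's post-hoc comparison of expression across functional groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "median_of_ratios_size_factors",
    "normalize_median_of_ratios",
    "log2_quartile_rank",
    "rpm_normalize",
    "rpkm_normalize",
    "compartment_ratio",
    "kruskal_dunn",
    "KruskalDunnResult",
]


@dataclass
class CountMatrix:
    """miRNA x sample read counts with optional lengths and compartment tags."""

    counts: pd.DataFrame  # index: miRNA ids, columns: sample labels, int >= 0
    feature_length: pd.Series | None = None
    compartments: pd.Series | None = None  # index: sample label -> compartment

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates or c.columns.has_duplicates:
            raise ValueError("feature and sample labels must be unique")
        values = c.to_numpy()
        if np.any(values < 0) or not np.allclose(values, np.round(values)):
            raise ValueError("counts must be non-negative integers")
        if self.feature_length is not None:
            self.feature_length = self.feature_length.reindex(c.index)
            if self.feature_length.isna().any() or (self.feature_length <= 0).any():
                raise ValueError("feature lengths must be positive for every feature")

    @classmethod
    def read_tsv(cls, path, sample_sheet=None) -> "CountMatrix":
        """TSV with first column ``mirna``, optional ``length`` column, one
        column per sample; ``sample_sheet`` is a two-column TSV
        ``sample_id<TAB>compartment``."""
        frame = pd.read_csv(path, sep="\t")
        frame = frame.set_index(frame.columns[0])
        length = None
        if "length" in frame.columns:
            length = frame.pop("length")
        compartments = None
        if sample_sheet is not None:
            sheet = pd.read_csv(
                sample_sheet, sep="\t", header=None, names=["sample_id", "compartment"]
            )
            compartments = sheet.set_index("sample_id")["compartment"]
        return cls(frame.astype(np.int64), feature_length=length, compartments=compartments)


def _counts_df(m) -> pd.DataFrame:
    return m.counts if isinstance(m, CountMatrix) else pd.DataFrame(m)


def median_of_ratios_size_factors(m) -> pd.Series:
    """Per-sample size factors by the median-of-ratios formula.

    The pseudo-reference is the per-feature geometric mean over samples,
    computed only for features with all-positive counts; each sample's factor
    is the median of its count-to-reference ratios over those features.
    """
    counts = _counts_df(m).astype(float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no feature has positive counts in every sample")
    logs = np.log(counts.loc[positive])
    log_geomean = logs.mean(axis=1)
    factors = np.exp((logs.sub(log_geomean, axis=0)).median(axis=0))
    factors.name = "size_factor"
    return factors


def normalize_median_of_ratios(m) -> pd.DataFrame:
    """Counts divided by their median-of-ratios size factors."""
    counts = _counts_df(m).astype(float)
    return counts.div(median_of_ratios_size_factors(counts), axis=1)


def log2_quartile_rank(values, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(x + pseudocount) plus empirical quartile labels Q1–Q4.

    Quartile edges use linear interpolation; boundary ties go to the lower
    quartile.
    """
    series = pd.Series(values, dtype=float)
    if series.empty:
        raise ValueError("empty input")
    if (series < 0).any():
        raise ValueError("values must be >= 0")
    y = np.log2(series + pseudocount)
    q1, q2, q3 = np.quantile(y, [0.25, 0.5, 0.75])
    labels = np.select([y <= q1, y <= q2, y <= q3], ["Q1", "Q2", "Q3"], default="Q4")
    return pd.DataFrame({"log2": y, "quartile": labels}, index=series.index)


def rpm_normalize(m) -> pd.DataFrame:
    """Reads per million mapped reads, per sample."""
    counts = _counts_df(m).astype(float)
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero library size for sample(s) {bad}")
    return counts.div(totals, axis=1) * 1e6


def rpkm_normalize(m, feature_length=None) -> pd.DataFrame:
    """RPM additionally scaled per kilobase of feature length."""
    if feature_length is None:
        if not (isinstance(m, CountMatrix) and m.feature_length is not None):
            raise ValueError("feature lengths are required for RPKM")
        feature_length = m.feature_length
    rpm = rpm_normalize(m)
    lengths = pd.Series(feature_length, dtype=float).reindex(rpm.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("feature lengths must be positive for every feature")
    return rpm.div(lengths / 1000.0, axis=0)


def compartment_ratio(
    m: CountMatrix,
    num: str = "cytoplasm",
    den: str = "nucleus",
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-feature RPM ratio between two subcellular compartments.

    Samples are RPM-normalised, averaged within each compartment, and the
    ratio (RPM_num + pc) / (RPM_den + pc) is returned per miRNA.
    """
    if m.compartments is None:
        raise ValueError("CountMatrix has no compartment labels")
    rpm = rpm_normalize(m)
    comp = m.compartments.reindex(rpm.columns)
    out = {}
    for label in (num, den):
        cols = comp.index[comp == label]
        if len(cols) == 0:
            raise ValueError(f"no samples labelled compartment {label!r}")
        out[label] = rpm[cols].mean(axis=1)
    ratio = (out[num] + pseudocount) / (out[den] + pseudocount)
    ratio.name = f"{num}/{den}"
    return ratio


@dataclass
class KruskalDunnResult:
    """Kruskal–Wallis H with Dunn's pairwise post-hoc comparisons."""

    h_statistic: float
    pvalue: float
    pairwise: pd.DataFrame  # group_a, group_b, z, pvalue, pvalue_adj


def kruskal_dunn(groups: Mapping[str, object], adjust: str = "bonferroni") -> KruskalDunnResult:
    """Nonparametric k-group comparison with tie correction.

    H and its chi-square p-value (k-1 df) come from the rank-sum statistic;
    Dunn's pairwise z uses the pooled mean ranks with tie-corrected standard
    error SE = sqrt((N(N+1)/12 - T/(12(N-1))) * (1/n_a + 1/n_b)) where
    T = sum(t^3 - t) over tie groups.  ``adjust`` is ``"bonferroni"`` over all
    pairs (default) or ``"none"``.
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    names = list(groups)
    samples = [np.asarray(groups[name], float) for name in names]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")

    pooled = np.concatenate(samples)
    n_total = len(pooled)
    if np.ptp(pooled) == 0.0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)

    ranks = stats.rankdata(pooled)
    sizes = [len(s) for s in samples]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = {
        name: float(np.mean(ranks[bounds[i] : bounds[i + 1]])) for i, name in enumerate(names)
    }
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        base_var -= tie_term / (12.0 * (n_total - 1))

    rows = []
    pairs = list(combinations(range(len(names)), 2))
    for i, j in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0.0:
            z, pz = 0.0, 1.0
        else:
            z = (mean_ranks[names[i]] - mean_ranks[names[j]]) / se
            pz = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, pz * len(pairs)) if adjust == "bonferroni" else pz
        rows.append((names[i], names[j], z, pz, p_adj))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "pvalue", "pvalue_adj"])
    return KruskalDunnResult(h_statistic=float(h), pvalue=float(p), pairwise=pairwise)
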