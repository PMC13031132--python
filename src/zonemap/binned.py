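"""Discrete (binned) comparator for the continuous gradient analysis.

Cells are sorted into 20 equal-width bins of the spatial ratio S — bin b
covers [(b-1)/20, b/20), the last bin right-closed — and per-(protein, bin)
mean expression is computed.  Z-scoring along the bin axis, heatmap ordering
by expression difference, a per-protein one-way ANOVA across bins (with BH
correction) and pathway median-Z profiles complete the binned toolkit, plus
a protein-level comparison of the continuous and binned Q values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gradient import bh_adjust
from .qc import IntensityMatrix

__all__ = [
    "BinnedMatrix",
    "bin_by_spatial_ratio",
    "zscore_bins",
    "order_by_gradient",
    "anova_bins",
    "anova_all_proteins",
    "pathway_profile",
    "method_comparison",
]


@dataclass
class BinnedMatrix:
    """Proteins x bins mean expression with bin bookkeeping."""

    means: pd.DataFrame  # proteins x n_bins, NaN where a (protein, bin) is empty
    edges: np.ndarray  # n_bins + 1 edges on [0, 1]
    cell_counts: np.ndarray  # cells per bin (sums to n cells)

    @property
    def n_bins(self) -> int:
        return self.means.shape[1]


def _bin_index(S: np.ndarray, n_bins: int) -> np.ndarray:
    """Half-open equal-width bins on [0, 1]; S = 1 falls in the last bin."""
    S = np.asarray(S, dtype=float)
    if S.min() < 0 or S.max() > 1:
        raise ValueError("S values must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.digitize(S, edges[1:-1], right=False)
    return idx


def bin_by_spatial_ratio(matrix: IntensityMatrix, n_bins: int = 20) -> BinnedMatrix:
    """Mean observed expression per (protein, bin) along the S axis."""
    idx = _bin_index(matrix.meta["S"].to_numpy(dtype=float), n_bins)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    cols = [f"bin_{b + 1:02d}" for b in range(n_bins)]
    means = pd.DataFrame(index=matrix.values.index, columns=cols, dtype=float)
    counts = np.zeros(n_bins, dtype=int)
    vals = matrix.values.to_numpy(dtype=float)
    for b in range(n_bins):
        in_bin = idx == b
        counts[b] = int(in_bin.sum())
        if counts[b]:
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)
                means.iloc[:, b] = np.nanmean(vals[:, in_bin], axis=1)
    return BinnedMatrix(means=means, edges=edges, cell_counts=counts)


def zscore_bins(binned: BinnedMatrix) -> BinnedMatrix:
    """Z-score each protein across its non-missing bins (n-1 s.d.).

    Proteins with fewer than 2 non-missing bins, or zero variance, become
    all-missing rows; missing bins stay missing.
    """
    m = binned.means
    mean = m.mean(axis=1)
    sd = m.std(axis=1, ddof=1)
    n_obs = m.notna().sum(axis=1)
    z = m.sub(mean, axis=0).div(sd, axis=0)
    z[(n_obs < 2) | (sd == 0) | sd.isna()] = np.nan
    return BinnedMatrix(means=z, edges=binned.edges.copy(),
                        cell_counts=binned.cell_counts.copy())


def order_by_gradient(binned: BinnedMatrix, n_edge_bins: int = 3) -> list[str]:
    """Order proteins by expression difference along the trajectory.

    Sort key: (mean of the last ``n_edge_bins`` bins) - (mean of the first
    ``n_edge_bins``), descending — portal-enriched proteins first, central-
    enriched last.  Ties break by protein id (ascending), stably.
    """
    m = binned.means
    first = m.iloc[:, :n_edge_bins].mean(axis=1)
    last = m.iloc[:, -n_edge_bins:].mean(axis=1)
    key = (last - first).fillna(-np.inf)
    order = sorted(m.index, key=lambda p: (-key[p], p))
    return order


def anova_bins(values: np.ndarray, bin_labels: np.ndarray) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of a protein's values across spatial bins.

    For a single factor the Type II decomposition coincides with the
    standard one-way sum of squares.  Missing values are dropped.  Groups
    need >= 2 bins with >= 2 cells.  All-equal input returns (0, 1).
    """
    y = np.asarray(values, dtype=float)
    b = np.asarray(bin_labels)
    ok = np.isfinite(y)
    y, b = y[ok], b[ok]
    groups = [y[b == lab] for lab in np.unique(b)]
    groups = [g for g in groups if len(g) > 0]
    if sum(len(g) >= 2 for g in groups) < 2:
        raise ValueError("need at least 2 bins with at least 2 cells")
    if np.ptp(y) == 0:
        return 0.0, 1.0
    F, p = stats.f_oneway(*groups)
    return float(F), float(p)


def anova_all_proteins(matrix: IntensityMatrix, n_bins: int = 20) -> pd.DataFrame:
    """Per-protein binned ANOVA with BH correction across proteins."""
    idx = _bin_index(matrix.meta["S"].to_numpy(dtype=float), n_bins)
    rows = []
    for pid, row in matrix.values.iterrows():
        try:
            F, p = anova_bins(row.to_numpy(dtype=float), idx)
        except ValueError:
            F, p = np.nan, np.nan
        rows.append({"protein_id": pid, "F": F, "p": p})
    out = pd.DataFrame(rows).set_index("protein_id")
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out


def pathway_profile(
    binned_z: BinnedMatrix, membership: dict[str, list[str]]
) -> pd.DataFrame:
    """Median member-protein Z per (pathway, bin); missing values omitted.

    Pathways without any available member yield an all-missing row (with a
    warning).
    """
    import warnings as _warnings

    rows = {}
    for pathway, members in membership.items():
        present = [m for m in members if m in binned_z.means.index]
        if not present:
            _warnings.warn(f"pathway {pathway!r}: no member proteins available")
            rows[pathway] = pd.Series(np.nan, index=binned_z.means.columns)
            continue
        rows[pathway] = binned_z.means.loc[present].median(axis=0, skipna=True)
    return pd.DataFrame(rows).T


def method_comparison(
    continuous_q: pd.Series, anova_q: pd.Series, q_threshold: float = 0.05
) -> dict:
    """Protein-level comparison of the continuous and 20-bin analyses.

    Pairs -log10(Q) of both methods over the shared proteins and reports
    Spearman rho, plus counts of proteins significant in both and in either
    method at the threshold.
    """
    shared = continuous_q.index.intersection(anova_q.index)
    qc = continuous_q.loc[shared].astype(float)
    qa = anova_q.loc[shared].astype(float)
    ok = qc.notna() & qa.notna()
    qc, qa = qc[ok], qa[ok]
    table = pd.DataFrame({
        "q_continuous": qc,
        "q_anova": qa,
        "neglog10_q_continuous": -np.log10(qc.clip(lower=1e-300)),
        "neglog10_q_anova": -np.log10(qa.clip(lower=1e-300)),
    })
    both = int(((qc < q_threshold) & (qa < q_threshold)).sum())
    either = int(((qc < q_threshold) | (qa < q_threshold)).sum())
    if len(qc) >= 2 and qc.nunique() > 1 and qa.nunique() > 1:
        rho = float(stats.spearmanr(qc, qa).statistic)
    else:
        rho = 1.0 if len(qc) and (qc == qa).all() else float("nan")
    return {"table": table, "spearman_rho": rho,
            "significant_both": both, "significant_either": either}
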