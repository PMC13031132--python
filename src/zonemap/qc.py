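"""Intensity-matrix I/O, quality-control filters and contamination scoring.

The container is a proteins x samples matrix (``IntensityMatrix``) carrying
per-sample metadata (patient, condition, spatial ratio S).  "Detected" means
a finite, positive intensity: zeros and empty fields in DIA-NN/directLFQ
style exports are both read as missing.

Filters implement the cohort's QC rules:

* samples are dropped when their protein-identification count falls below
  median - 1.5 s.d. or above median + 3 s.d. of all samples (one pass,
  sample s.d. with n-1);
* proteins must be detected in at least 70% of samples;
* optional per-patient z-scoring centres every protein within each patient.

``contamination_score`` ranks each sample's proteins by intensity (ties
averaged, undetected markers rank 0) and reports the median rank of each
cell-type marker panel, a monotone-transform-invariant purity readout.
``pca_space_association`` checks that position along the porto-central axis
drives the first principal component.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

__all__ = [
    "IntensityMatrix",
    "SampleQCReport",
    "MarkerPanel",
    "read_intensity_table",
    "write_intensity_table",
    "filter_samples_by_id_count",
    "filter_protein_completeness",
    "zscore_within_patient",
    "build_marker_panel",
    "contamination_score",
    "pca_space_association",
]

META_COLUMNS = ("patient_id", "condition", "S")


@dataclass
class IntensityMatrix:
    """Proteins x samples intensities plus per-sample metadata.

    ``values``: DataFrame indexed by protein id, columns = sample ids, NaN
    for missing entries.  ``meta``: DataFrame indexed by sample_id with
    columns patient_id, condition, S.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate protein ids: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        missing = [s for s in self.values.columns if s not in self.meta.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        self.meta = self.meta.loc[self.values.columns]
        S = self.meta["S"].to_numpy(dtype=float)
        if np.nanmin(S) < 0 or np.nanmax(S) > 1:
            raise ValueError("S values must lie in [0, 1]")
        if (self.meta["patient_id"].astype(str).str.len() == 0).any():
            raise ValueError("patient_id must be non-empty")

    @property
    def detected(self) -> pd.DataFrame:
        """Boolean mask of detected (finite, positive) entries."""
        return self.values.notna() & (self.values > 0)

    def subset_samples(self, sample_ids) -> "IntensityMatrix":
        return IntensityMatrix(values=self.values[list(sample_ids)],
                               meta=self.meta.loc[list(sample_ids)])

    def subset_proteins(self, protein_ids) -> "IntensityMatrix":
        return IntensityMatrix(values=self.values.loc[list(protein_ids)],
                               meta=self.meta)


@dataclass
class SampleQCReport:
    """Outcome of the identification-count sample filter."""

    counts: pd.Series  # per-sample protein-ID counts (before filtering)
    median: float
    sd: float
    kept: list[str]
    excluded: dict[str, str]  # sample_id -> "low" | "high"


@dataclass(frozen=True)
class MarkerPanel:
    """Cell-type marker proteins with their reference intensities."""

    cell_type: str
    markers: tuple[str, ...]
    reference_intensity: tuple[float, ...]


def read_intensity_table(matrix_path: str | Path, meta_path: str | Path) -> IntensityMatrix:
    """Read a proteins x samples TSV plus its sample-metadata TSV.

    Zeros and empty fields are parsed as missing.  Raises when matrix and
    metadata sample sets disagree, naming the offenders.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values = values.apply(pd.to_numeric, errors="coerce")
    values = values.where(values > 0)  # zeros -> missing
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    extra = [s for s in meta.index if s not in values.columns]
    if extra:
        raise ValueError(f"metadata samples absent from matrix: {extra}")
    return IntensityMatrix(values=values, meta=meta)


def write_intensity_table(
    matrix: IntensityMatrix, matrix_path: str | Path, meta_path: str | Path
) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="protein_id")
    matrix.meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def filter_samples_by_id_count(
    matrix: IntensityMatrix, low_sd: float = 1.5, high_sd: float = 3.0
) -> tuple[IntensityMatrix, SampleQCReport]:
    """Drop samples with ID counts below median - 1.5 s.d. or above median + 3 s.d.

    Median and (n-1) standard deviation are computed once over all samples
    before any exclusion.
    """
    if matrix.values.shape[1] < 3:
        raise ValueError("need at least 3 samples for the ID-count filter")
    counts = matrix.detected.sum(axis=0)
    med = float(counts.median())
    sd = float(counts.std(ddof=1))
    excluded: dict[str, str] = {}
    for sid, c in counts.items():
        if c < med - low_sd * sd:
            excluded[sid] = "low"
        elif c > med + high_sd * sd:
            excluded[sid] = "high"
    kept = [s for s in matrix.values.columns if s not in excluded]
    report = SampleQCReport(counts=counts, median=med, sd=sd, kept=kept, excluded=excluded)
    return matrix.subset_samples(kept), report


def filter_protein_completeness(
    matrix: IntensityMatrix, min_fraction: float = 0.70
) -> IntensityMatrix:
    """Keep proteins detected in at least ``min_fraction`` of samples (>=)."""
    frac = matrix.detected.mean(axis=1)
    keep = frac.index[frac >= min_fraction]
    return matrix.subset_proteins(keep)


def zscore_within_patient(matrix: IntensityMatrix) -> IntensityMatrix:
    """Per protein and per patient: centre and scale to unit variance.

    Groups with fewer than 2 observed values or zero variance become
    missing.  Missing entries stay missing.
    """
    values = matrix.values.copy()
    patients = matrix.meta["patient_id"]
    for pid, cols in patients.groupby(patients).groups.items():
        block = values[list(cols)]
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        n_obs = block.notna().sum(axis=1)
        z = block.sub(mean, axis=0).div(sd, axis=0)
        z[(n_obs < 2) | (sd == 0) | sd.isna()] = np.nan
        values[list(cols)] = z
    return IntensityMatrix(values=values, meta=matrix.meta.copy())


def build_marker_panel(
    reference: pd.DataFrame,
    min_intensity: float = 1e8,
    fold: float = 5.0,
    top_n: int = 20,
) -> dict[str, MarkerPanel]:
    """Derive cell-type marker panels from a reference intensity table.

    ``reference``: proteins x cell types.  A protein is a marker for a cell
    type when its intensity there exceeds ``min_intensity`` and is at least
    ``fold`` times its intensity in every other cell type; the ``top_n``
    qualifying proteins by intensity form the panel.
    """
    if reference.shape[1] < 2:
        raise ValueError("reference table needs at least 2 cell types")
    ref = reference.fillna(0.0)
    panels: dict[str, MarkerPanel] = {}
    for ct in ref.columns:
        own = ref[ct]
        others = ref.drop(columns=ct).max(axis=1)
        ok = (own > min_intensity) & (own >= fold * others)
        qualifying = own[ok].sort_values(ascending=False).head(top_n)
        if len(qualifying) > 0:
            panels[ct] = MarkerPanel(
                cell_type=ct,
                markers=tuple(qualifying.index),
                reference_intensity=tuple(float(v) for v in qualifying.values),
            )
    return panels


def contamination_score(
    matrix: IntensityMatrix, panels: dict[str, MarkerPanel]
) -> pd.DataFrame:
    """Median within-sample intensity rank of each marker panel, per sample.

    Within each sample, detected proteins are ranked ascending by intensity
    (highest = number of detected proteins; ties averaged).  Markers that
    are undetected in the sample get rank 0.  Returns samples x cell types.
    """
    out = pd.DataFrame(index=matrix.values.columns,
                       columns=list(panels), dtype=float)
    detected = matrix.detected
    for sid in matrix.values.columns:
        col = matrix.values[sid]
        obs = col[detected[sid]]
        ranks = pd.Series(stats.rankdata(obs.to_numpy()), index=obs.index)
        for ct, panel in panels.items():
            marker_ranks = [float(ranks.get(m, 0.0)) for m in panel.markers]
            out.loc[sid, ct] = float(np.median(marker_ranks))
    return out


def pca_space_association(
    matrix: IntensityMatrix,
    n_components: int = 2,
    z_cutoff: float = 3.0,
) -> dict:
    """PCA of complete proteins with outlier removal and a PC1-vs-S check.

    Only proteins without any missing value enter (no imputation).
    Features are standardized; samples with any absolute feature z-score
    above ``z_cutoff`` are excluded.  The sign of every component is fixed
    by forcing its first nonzero loading positive.  Returns the PC
    coordinates, explained-variance ratios, Spearman rho and two-sided p of
    PC1 against the spatial ratio S, and the excluded sample ids.
    """
    complete = matrix.values.dropna(axis=0, how="any")
    if complete.shape[0] < 2:
        raise ValueError("need at least 2 complete proteins for PCA")
    X = complete.to_numpy().T  # samples x proteins
    Z = StandardScaler().fit_transform(X)
    keep = (np.abs(Z) <= z_cutoff).all(axis=1)
    excluded = [s for s, k in zip(complete.columns, keep) if not k]
    if keep.sum() < 3:
        raise ValueError("fewer than 3 samples remain after outlier exclusion")
    Zk = StandardScaler().fit_transform(X[keep])
    n_components = min(n_components, Zk.shape[0] - 1, Zk.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(Zk)
    for c in range(n_components):
        loadings = pca.components_[c]
        nz = np.flatnonzero(loadings)
        if len(nz) and loadings[nz[0]] < 0:
            pca.components_[c] *= -1
            coords[:, c] *= -1
    kept_samples = [s for s, k in zip(complete.columns, keep) if k]
    S = matrix.meta.loc[kept_samples, "S"].to_numpy(dtype=float)
    rho, p = stats.spearmanr(coords[:, 0], S)
    return {
        "coordinates": pd.DataFrame(
            coords, index=kept_samples,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        "explained_variance_ratio": pca.explained_variance_ratio_.copy(),
        "spearman_rho": float(rho),
        "spearman_p": float(p),
        "excluded_samples": excluded,
    }
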