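"""Continuous protein-gradient inference with a random-intercept mixed model.

Each protein's expression y_ij (cell j of patient i) is modelled as

    y_ij = beta0 + beta1 * S_ij + u_i + eps_ij,
    u_i ~ N(0, sigma_u^2),  eps_ij ~ N(0, sigma^2),

where S is the cell's normalized position along the porto-central axis
(0 = central vein, 1 = portal vein).  beta1 — the *zonation coefficient* —
quantifies the expression gradient: negative values mean enrichment toward
the central vein, positive toward the portal vein.  The null beta1 = 0 is
tested with a Wald z = beta1 / SE(beta1) against the standard normal, and
Benjamini-Hochberg Q values control the FDR across proteins.  A protein is
*strongly zonated* when |beta1| > 1 and Q < 0.05.

Per-protein preprocessing follows the acquisition pipeline: Tukey's-fences
outlier removal, then robust scaling ((x - median) / IQR), then the fit.
Quartiles use linear interpolation throughout.

``contrast_conditions`` compares a protein's zonation coefficients between
two cohorts (e.g. healthy vs desmoplasia) with a Wald test on
Delta_beta1 = beta1_A - beta1_B, SE = sqrt(SE_A^2 + SE_B^2); zonation *loss*
is called at |Delta_beta1| > 1 and Q < 0.05 over the scoped protein set
(by default the proteins strongly zonated in cohort A).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qc import IntensityMatrix

__all__ = [
    "GradientFit",
    "ZonationCall",
    "ConditionContrast",
    "tukey_fence_filter",
    "robust_scale",
    "fit_lmm",
    "bh_adjust",
    "classify_zonation",
    "fit_gradients",
    "contrast_conditions",
    "zonation_summary",
]


@dataclass
class GradientFit:
    """Per-protein random-intercept fit and Wald inference."""

    protein_id: str
    beta0: float
    beta1: float
    se_beta1: float
    sigma_u2: float  # patient random-intercept variance
    sigma2: float  # residual variance
    n_cells: int
    n_patients: int
    z: float
    p: float
    q: float = float("nan")
    converged: bool = True
    skip_reason: str | None = None


@dataclass(frozen=True)
class ZonationCall:
    """Direction and significance flags derived from a GradientFit."""

    protein_id: str
    direction: str  # "central" | "portal" | "none"
    significant: bool  # Q < 0.05
    strong: bool  # |beta1| > 1 and Q < 0.05


@dataclass
class ConditionContrast:
    """Wald contrast of zonation coefficients between two conditions."""

    protein_id: str
    delta_beta1: float
    se: float
    z: float
    p: float
    q: float = float("nan")
    loss: bool = False


def tukey_fence_filter(values: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Drop values outside [Q1 - k*IQR, Q3 + k*IQR] (linear-interp quartiles)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 4:
        raise ValueError("Tukey fences need at least 4 finite values")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return x[(x >= q1 - k * iqr) & (x <= q3 + k * iqr)]


def _tukey_mask(x: np.ndarray, k: float = 1.5) -> np.ndarray:
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return (x >= q1 - k * iqr) & (x <= q3 + k * iqr)


def robust_scale(values: np.ndarray) -> np.ndarray:
    """(x - median) / IQR; invariant to affine transforms of the input."""
    x = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(x[np.isfinite(x)], [25, 50, 75])
    iqr = q3 - q1
    if iqr == 0:
        raise ValueError("IQR is zero; cannot robust-scale")
    return (x - med) / iqr


def fit_lmm(
    values: np.ndarray,
    S: np.ndarray,
    patient_ids: np.ndarray,
    protein_id: str = "",
    reml: bool = True,
) -> GradientFit:
    """Fit the random-intercept model for one protein.

    Missing values are dropped pairwise.  With a single patient the model
    degenerates to ordinary least squares (sigma_u^2 = 0).  Degenerate S
    (all cells at the same position) yields a non-converged fit with a
    skip reason rather than an exception.
    """
    y = np.asarray(values, dtype=float)
    S = np.asarray(S, dtype=float)
    groups = np.asarray(patient_ids)
    ok = np.isfinite(y)
    y, S, groups = y[ok], S[ok], groups[ok]
    n = len(y)
    uniq = np.unique(groups)

    def _skipped(reason: str) -> GradientFit:
        return GradientFit(protein_id, np.nan, np.nan, np.nan, np.nan, np.nan,
                           n, len(uniq), np.nan, np.nan,
                           converged=False, skip_reason=reason)

    if n < 3:
        return _skipped("fewer than 3 observations")
    if np.ptp(S) == 0:
        return _skipped("degenerate S (no spatial spread)")

    X = sm.add_constant(S)
    if len(uniq) < 2:
        res = sm.OLS(y, X).fit()
        beta0, beta1 = res.params
        se = float(res.bse[1])
        z = beta1 / se
        p = 2 * stats.norm.sf(abs(z))
        return GradientFit(protein_id, float(beta0), float(beta1), se,
                           0.0, float(res.scale), n, 1, float(z), float(p))

    model = sm.MixedLM(y, X, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=reml)
            converged = bool(res.converged)
        except Exception:
            res, converged = None, False
        if res is not None and not converged and reml:
            try:
                res = model.fit(reml=False)
                converged = bool(res.converged)
            except Exception:
                res, converged = None, False
    if res is None or not converged or not np.isfinite(res.bse[1]) or res.bse[1] <= 0:
        return _skipped("mixed-model fit did not converge")
    beta0, beta1 = float(res.params[0]), float(res.params[1])
    se = float(res.bse[1])
    sigma_u2 = float(np.asarray(res.cov_re)[0, 0])
    sigma2 = float(res.scale)
    z = beta1 / se
    p = 2 * stats.norm.sf(abs(z))
    return GradientFit(protein_id, beta0, beta1, se, sigma_u2, sigma2,
                       n, len(uniq), float(z), float(p))


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up Q values (order-preserving over sorted p)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_zonation(
    fit: GradientFit,
    q_threshold: float = 0.05,
    strong_beta: float = 1.0,
) -> ZonationCall:
    """Direction (sign of beta1) and significance/strength flags."""
    if not fit.converged or not np.isfinite(fit.q):
        return ZonationCall(fit.protein_id, "none", False, False)
    significant = fit.q < q_threshold
    direction = "none"
    if significant:
        direction = "central" if fit.beta1 < 0 else "portal"
    strong = significant and abs(fit.beta1) > strong_beta
    return ZonationCall(fit.protein_id, direction, significant, strong)


def fit_gradients(
    matrix: IntensityMatrix,
    preprocess: bool = True,
    tukey_k: float = 1.5,
    reml: bool = True,
) -> pd.DataFrame:
    """Fit the gradient model for every protein of a matrix.

    Per protein (over the analyzed cohort's cells): optional Tukey-fences
    outlier removal and robust scaling, then the mixed-model fit.  Q values
    are BH-adjusted over the converged fits; skipped proteins keep Q = NaN.
    Returns a tidy DataFrame with one row per protein, including direction
    and strength calls.
    """
    S_all = matrix.meta["S"].to_numpy(dtype=float)
    patients_all = matrix.meta["patient_id"].to_numpy()
    fits: list[GradientFit] = []
    for pid, row in matrix.values.iterrows():
        y = row.to_numpy(dtype=float)
        keep = np.isfinite(y)
        if preprocess and keep.sum() >= 4:
            obs = y[keep]
            fence = _tukey_mask(obs, tukey_k)
            q1, med, q3 = np.percentile(obs[fence], [25, 50, 75])
            if q3 - q1 == 0:
                fits.append(GradientFit(pid, np.nan, np.nan, np.nan, np.nan,
                                        np.nan, 0, 0, np.nan, np.nan,
                                        converged=False,
                                        skip_reason="zero IQR after outlier removal"))
                continue
            scaled = np.full_like(y, np.nan)
            scaled[keep] = np.where(fence, (obs - med) / (q3 - q1), np.nan)
            y = scaled
        fits.append(fit_lmm(y, S_all, patients_all, protein_id=pid, reml=reml))

    ok = [f for f in fits if f.converged]
    if ok:
        q = bh_adjust(np.array([f.p for f in ok]))
        for f, qi in zip(ok, q):
            f.q = float(qi)
    rows = []
    for f in fits:
        call = classify_zonation(f)
        rows.append({
            "protein_id": f.protein_id, "beta0": f.beta0, "beta1": f.beta1,
            "se_beta1": f.se_beta1, "sigma_u2": f.sigma_u2, "sigma2": f.sigma2,
            "n_cells": f.n_cells, "n_patients": f.n_patients,
            "z": f.z, "p": f.p, "q": f.q, "converged": f.converged,
            "direction": call.direction, "significant": call.significant,
            "strong": call.strong, "skip_reason": f.skip_reason,
        })
    return pd.DataFrame(rows).set_index("protein_id")


def contrast_conditions(
    fits_a: pd.DataFrame,
    fits_b: pd.DataFrame,
    scope: list[str] | None = None,
    delta_threshold: float = 1.0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Wald contrast of zonation coefficients between two fitted cohorts.

    ``scope`` defaults to the proteins called *strong* in cohort A that are
    present and converged in both cohorts.  Delta_beta1 = beta1_A - beta1_B;
    SE = sqrt(SE_A^2 + SE_B^2); two-sided normal p; BH over the scoped set.
    Zonation loss: |Delta_beta1| > 1 and Q < 0.05.
    """
    if scope is None:
        scope = list(fits_a.index[fits_a["strong"].fillna(False)])
    usable = [
        p for p in scope
        if p in fits_a.index and p in fits_b.index
        and bool(fits_a.loc[p, "converged"]) and bool(fits_b.loc[p, "converged"])
    ]
    rows = []
    for p in usable:
        d = float(fits_a.loc[p, "beta1"]) - float(fits_b.loc[p, "beta1"])
        se = float(np.hypot(fits_a.loc[p, "se_beta1"], fits_b.loc[p, "se_beta1"]))
        z = d / se
        pv = 2 * stats.norm.sf(abs(z))
        rows.append({"protein_id": p, "delta_beta1": d, "se": se, "z": z, "p": pv})
    out = pd.DataFrame(rows, columns=["protein_id", "delta_beta1", "se", "z", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["loss"] = (out["delta_beta1"].abs() > delta_threshold) & (out["q"] < q_threshold)
    else:
        out["q"] = pd.Series(dtype=float)
        out["loss"] = pd.Series(dtype=bool)
    return out.set_index("protein_id")


def zonation_summary(
    contrasts: pd.DataFrame,
    fits_a: pd.DataFrame,
    fits_b: pd.DataFrame,
    scope: list[str] | None = None,
) -> pd.DataFrame:
    """Per-direction summary of zonation change between two conditions.

    For the scoped proteins (default: strong in cohort A), grouped by their
    healthy-cohort direction: median |Delta_beta1|, the two-sided unpaired
    rank-sum p comparing |Delta_beta1| between the central and portal
    groups, and the fractions of proteins whose zonation was *lost*
    (|beta1_B| < 1), *maintained* (|beta1_B| > 1 and Q_B < 0.05) or *not
    detected* in cohort B.
    """
    if scope is None:
        scope = list(fits_a.index[fits_a["strong"].fillna(False)])
    groups: dict[str, dict] = {}
    abs_delta: dict[str, list[float]] = {"central": [], "portal": []}
    for direction in ("central", "portal"):
        members = [p for p in scope if fits_a.loc[p, "direction"] == direction]
        n = len(members)
        lost = maintained = not_detected = 0
        for p in members:
            if p not in fits_b.index or not bool(fits_b.loc[p, "converged"]):
                not_detected += 1
                continue
            b1 = abs(float(fits_b.loc[p, "beta1"]))
            qb = float(fits_b.loc[p, "q"])
            if b1 > 1 and qb < 0.05:
                maintained += 1
            elif b1 < 1:
                lost += 1
            if p in contrasts.index:
                abs_delta[direction].append(abs(float(contrasts.loc[p, "delta_beta1"])))
        groups[direction] = {
            "n": n,
            "median_abs_delta": float(np.median(abs_delta[direction]))
            if abs_delta[direction] else float("nan"),
            "frac_lost": lost / n if n else float("nan"),
            "frac_maintained": maintained / n if n else float("nan"),
            "frac_not_detected": not_detected / n if n else float("nan"),
        }
    if abs_delta["central"] and abs_delta["portal"]:
        if (np.ptp(abs_delta["central"]) == 0 and np.ptp(abs_delta["portal"]) == 0
                and np.median(abs_delta["central"]) == np.median(abs_delta["portal"])):
            p_ranksum = 1.0  # both groups identical constants
        else:
            p_ranksum = float(stats.mannwhitneyu(
                abs_delta["central"], abs_delta["portal"],
                alternative="two-sided").pvalue)
    else:
        p_ranksum = float("nan")
    summary = pd.DataFrame(groups).T
    summary["ranksum_p"] = p_ranksum
    summary.index.name = "direction"
    return summary
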