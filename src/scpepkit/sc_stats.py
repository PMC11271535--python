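"""QC metrics, housekeeping fraction, PCA, and differential expression.

Testing follows the study conventions: equal-variance two-sample Student's
t on observed values only (no imputation for testing), Benjamini-Hochberg
adjustment over the tested family, and call thresholds |fold-change| > 2
with adjusted p < 0.01 on proteins quantified in at least 25% of samples.
PCA retains features observed in >= 70% of samples, imputes remaining
gaps with the feature's minimum observed value, centers features, and
decomposes by SVD with a deterministic sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .matrix import QuantMatrix
from .report_ingest import PrecursorObservation


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def cv_percent(values) -> float:
    """Coefficient of variation in percent: 100 * sd / mean.

    Sample (ddof=1) standard deviation; undefined (NaN) with fewer than
    two observed values or zero mean.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        return float("nan")
    mean = arr.mean()
    if mean == 0:
        return float("nan")
    return float(100.0 * arr.std(ddof=1) / mean)


@dataclass
class QCSummary:
    """Reproducibility and depth metrics of a precursor report."""

    peptide_rt_cv: pd.Series      # % CV of retention time per peptide
    peptide_im_cv: pd.Series      # % CV of ion mobility per peptide
    median_rt_cv: float
    median_im_cv: float
    per_sample_counts: pd.DataFrame  # n_peptides / n_proteins per sample


def qc_summary(
    observations: list[PrecursorObservation], min_samples: int = 5
) -> QCSummary:
    """Per-peptide RT/IM coefficients of variation and per-sample depth.

    CVs are computed across the samples in which a peptide was observed;
    the medians are taken over peptides observed in at least
    ``min_samples`` samples.
    """
    from .report_ingest import detected_proteins_per_sample

    if not observations:
        empty = pd.Series(dtype=float)
        return QCSummary(empty, empty, float("nan"), float("nan"), pd.DataFrame())
    df = pd.DataFrame(
        {
            "peptide": [o.modified_sequence for o in observations],
            "sample": [o.run_id for o in observations],
            "rt": [o.rt for o in observations],
            "im": [o.ion_mobility for o in observations],
        }
    )
    # one RT/IM per peptide per sample (first precursor wins)
    df = df.drop_duplicates(["peptide", "sample"])
    grouped = df.groupby("peptide")
    rt_cv = grouped["rt"].apply(cv_percent)
    im_cv = grouped["im"].apply(cv_percent)
    eligible = grouped.size() >= min_samples
    return QCSummary(
        peptide_rt_cv=rt_cv,
        peptide_im_cv=im_cv,
        median_rt_cv=float(rt_cv[eligible].median()),
        median_im_cv=float(im_cv[eligible].median()),
        per_sample_counts=detected_proteins_per_sample(observations),
    )


def housekeeping_fraction(
    detected_genes, housekeeping_list, per_sample_detected=None
):
    """Fraction of detected genes on a housekeeping list.

    Gene symbols are compared case-insensitively.  Returns
    ``(fraction, per_sample)`` where ``per_sample`` (when per-sample
    detected gene sets are given) counts housekeeping vs non-housekeeping
    detections per sample.  The fraction is NaN for an empty detected set.
    """
    detected = {g.upper() for g in detected_genes if g}
    housekeeping = {g.upper() for g in housekeeping_list if g}
    fraction = (
        len(detected & housekeeping) / len(detected)
        if detected
        else float("nan")
    )
    per_sample = None
    if per_sample_detected is not None:
        rows = []
        for sample, genes in per_sample_detected.items():
            genes = {g.upper() for g in genes if g}
            hk = len(genes & housekeeping)
            rows.append(
                {
                    "sample": sample,
                    "housekeeping": hk,
                    "non_housekeeping": len(genes) - hk,
                }
            )
        per_sample = pd.DataFrame(rows).set_index("sample")
    return fraction, per_sample


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def student_t_test(x, y) -> tuple[float, float]:
    """Equal-variance two-sample Student's t-test (two-sided).

    Pooled variance with df = n1 + n2 - 2.  Returns ``(nan, nan)`` when
    either group has fewer than two observed values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        return float("nan"), float("nan")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResult:
    """Per-feature differential-expression outcome."""

    feature_id: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    log2_fc: float
    t: float
    p: float
    adj_p: float
    status: str  # up / down / ns / filtered


def differential_expression(
    matrix: QuantMatrix,
    group_a: str | list[str],
    group_b: str | list[str],
    min_fraction: float = 0.25,
    fc_threshold: float = 2.0,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Two-group differential expression on a log2 matrix.

    Features observed in fewer than ``min_fraction`` of *all* samples are
    marked ``filtered`` and excluded from testing and from the BH family.
    The remaining features are tested on observed values only; the
    fold-change is ``2 ** (mean_a - mean_b)``; features pass as up/down
    when ``|fold-change| > fc_threshold`` and adjusted p < alpha.
    """
    groups_a = [group_a] if isinstance(group_a, str) else list(group_a)
    groups_b = [group_b] if isinstance(group_b, str) else list(group_b)
    samples_a = [
        s for g in groups_a for s in matrix.samples_in(g)
    ]
    samples_b = [
        s for g in groups_b for s in matrix.samples_in(g)
    ]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValidationError("each group needs at least 2 samples")
    values = matrix.values
    observed = values[samples_a + samples_b].notna().mean(axis=1)
    log2_fc_cut = np.log2(fc_threshold)

    rows = []
    tested = []
    for feature in values.index:
        if observed[feature] < min_fraction:
            rows.append(
                DEResult(feature, 0, 0, np.nan, np.nan, np.nan, np.nan,
                         np.nan, np.nan, "filtered")
            )
            continue
        a = values.loc[feature, samples_a].to_numpy(dtype=float)
        b = values.loc[feature, samples_b].to_numpy(dtype=float)
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        t, p = student_t_test(a, b)
        mean_a = a.mean() if a.size else np.nan
        mean_b = b.mean() if b.size else np.nan
        res = DEResult(
            feature, a.size, b.size, mean_a, mean_b,
            mean_a - mean_b, t, p, np.nan, "ns",
        )
        rows.append(res)
        if not np.isnan(p):
            tested.append(res)

    if tested:
        adj = bh_adjust([r.p for r in tested])
        for res, q in zip(tested, adj):
            res.adj_p = float(q)
            if abs(res.log2_fc) > log2_fc_cut and q < alpha:
                res.status = "up" if res.log2_fc > 0 else "down"

    out = pd.DataFrame([vars(r) for r in rows]).set_index("feature_id")
    return out


def pca_scores(
    matrix: QuantMatrix,
    n_components: int = 2,
    min_observed: float = 0.70,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores and explained-variance fractions by SVD.

    Features observed in >= ``min_observed`` of samples are retained;
    remaining missing values are imputed with the feature's minimum
    observed value; features are centered; scores come from the singular
    value decomposition.  The sign of each component is fixed by making
    its largest-magnitude feature loading positive, so results are
    deterministic.
    """
    if n_components > matrix.n_samples:
        raise ValidationError(
            f"{n_components} components requested from "
            f"{matrix.n_samples} samples"
        )
    values = matrix.values
    keep = values.notna().mean(axis=1) >= min_observed
    sub = values.loc[keep]
    filled = sub.apply(lambda row: row.fillna(row.min()), axis=1)
    x = filled.to_numpy(dtype=float).T  # samples x features
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic signs: largest-|loading| entry of each component > 0
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores = u[:, :n_components] * s[:n_components]
    total_var = np.sum(s**2)
    explained = (
        (s[:n_components] ** 2) / total_var
        if total_var > 0
        else np.zeros(n_components)
    )
    if total_var == 0:
        scores = np.zeros_like(scores)
    frame = pd.DataFrame(
        scores,
        index=values.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    frame["group"] = matrix.sample_groups.values
    return frame, explained


def treatment_site_comparison(
    site_matrix: QuantMatrix,
    protein_matrix: QuantMatrix,
    control: str,
    treated: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-site and per-protein control-vs-treated t-tests.

    Runs Student's t for every site and every protein between the two
    conditions and flags sites significant at ``alpha`` whose parent
    protein is not — the signature of a site-specific drug effect (e.g.
    H3K27me3 loss under an EZH2 inhibitor with total H3 unchanged).
    """
    for mat, name in ((site_matrix, "site"), (protein_matrix, "protein")):
        for grp in (control, treated):
            if len(mat.samples_in(grp)) < 2:
                raise ValidationError(
                    f"{name} matrix: group {grp!r} has < 2 samples"
                )

    def _tests(matrix: QuantMatrix, level: str) -> list[dict]:
        a = matrix.values[matrix.samples_in(treated)]
        b = matrix.values[matrix.samples_in(control)]
        out = []
        for feature in matrix.values.index:
            t, p = student_t_test(a.loc[feature], b.loc[feature])
            delta = float(
                np.nanmean(a.loc[feature]) - np.nanmean(b.loc[feature])
            ) if a.loc[feature].notna().any() and b.loc[feature].notna().any() else np.nan
            meta = matrix.feature_meta
            out.append(
                {
                    "feature_id": feature,
                    "level": level,
                    "accession": meta.at[feature, "accession"]
                    if "accession" in meta.columns
                    else feature,
                    "log2_fc": delta,
                    "t": t,
                    "p": p,
                    "significant": bool(p < alpha) if not np.isnan(p) else False,
                }
            )
        return out

    rows = _tests(site_matrix, "site") + _tests(protein_matrix, "protein")
    df = pd.DataFrame(rows).set_index("feature_id")
    protein_sig = {
        r["accession"]: r["significant"]
        for r in rows
        if r["level"] == "protein"
    }
    df["site_specific"] = [
        bool(
            r["level"] == "site"
            and r["significant"]
            and not protein_sig.get(r["accession"], False)
        )
        for r in rows
    ]
    return df
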