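"""Batch correction, normalisation, family profiles and multivariate statistics.

The abundance container is a peptide x run matrix of positive peak areas
plus run metadata (accession, replicate, batch, injection order).  Batch
correction is a per-peptide least-squares fit on the log10 scale with
sum-to-zero batch coding and injection order retained as a linear
covariate; only the fitted batch terms are subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

LONG_COLUMNS = ["peptide", "accession", "replicate", "batch", "injection_order", "area"]


@dataclass
class AbundanceMatrix:
    """Peak areas (peptide x run) with per-run metadata.

    ``runs`` is indexed by run id and carries columns ``accession``,
    ``replicate``, ``batch`` and ``injection_order``.
    """

    areas: pd.DataFrame
    runs: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.areas.columns) != list(self.runs.index):
            raise ValueError("areas columns must equal runs index")
        vals = self.areas.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValueError("observed areas must be positive")
        if self.runs["injection_order"].duplicated().any():
            raise ValueError("injection orders must be unique")
        counts = self.runs.groupby("accession").size()
        if counts.nunique() > 1:
            raise ValueError("every accession must have the same replicate count")

    @property
    def accessions(self) -> list[str]:
        return list(dict.fromkeys(self.runs["accession"]))

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "AbundanceMatrix":
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"long table missing columns: {missing}")
        df = df.copy()
        df["run"] = df["accession"].astype(str) + ".r" + df["replicate"].astype(str)
        areas = df.pivot_table(index="peptide", columns="run", values="area", aggfunc="first")
        runs = (
            df.drop_duplicates("run")
            .set_index("run")[["accession", "replicate", "batch", "injection_order"]]
        )
        return cls(areas[runs.index], runs)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for run in self.areas.columns:
            meta = self.runs.loc[run]
            for pep, area in self.areas[run].items():
                if pd.isna(area):
                    continue
                rows.append(
                    {
                        "peptide": pep,
                        "accession": meta["accession"],
                        "replicate": meta["replicate"],
                        "batch": meta["batch"],
                        "injection_order": meta["injection_order"],
                        "area": area,
                    }
                )
        return pd.DataFrame(rows, columns=LONG_COLUMNS)

    def accession_means(self) -> pd.DataFrame:
        """Peptide x accession mean of linear areas over replicates."""
        return self.areas.T.groupby(self.runs["accession"]).mean().T


# ---------------------------------------------------------------------------
# batch correction
# ---------------------------------------------------------------------------


@dataclass
class BatchCorrectionResult:
    log10: pd.DataFrame           # corrected log10 areas, peptide x run
    batch_effects: pd.DataFrame   # peptide x batch fitted effects (sum to 0)
    covariate_slope: pd.Series    # per-peptide injection-order slope


def remove_batch_effect(matrix: AbundanceMatrix) -> BatchCorrectionResult:
    """Subtract fitted batch effects from log10 areas.

    Model per peptide: log10(area) ~ intercept + injection_order + batch
    (sum-to-zero coding).  Only the batch terms are removed; the covariate
    and residual structure are retained.
    """
    batches = list(dict.fromkeys(matrix.runs["batch"]))
    if len(batches) < 2:
        raise ValueError("batch correction requires >= 2 batches")
    sizes = matrix.runs.groupby("batch").size()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"batches with < 2 runs: {list(small.index)}")

    y = np.log10(matrix.areas.to_numpy(dtype=float))
    order = matrix.runs["injection_order"].to_numpy(dtype=float)
    b_idx = matrix.runs["batch"].map({b: i for i, b in enumerate(batches)}).to_numpy()
    nb = len(batches)
    # sum-to-zero coding: one column per non-reference batch
    coding = np.zeros((len(order), nb - 1))
    for j in range(nb - 1):
        coding[b_idx == j, j] = 1.0
        coding[b_idx == nb - 1, j] = -1.0
    X = np.column_stack([np.ones_like(order), order, coding])
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)  # (2 + nb-1) x peptides
    batch_beta = beta[2:, :]
    batch_term = coding @ batch_beta  # runs x peptides
    corrected = y - batch_term.T
    effects = np.vstack([batch_beta, -batch_beta.sum(axis=0)])  # nb x peptides
    return BatchCorrectionResult(
        pd.DataFrame(corrected, index=matrix.areas.index, columns=matrix.areas.columns),
        pd.DataFrame(effects.T, index=matrix.areas.index, columns=batches),
        pd.Series(beta[1, :], index=matrix.areas.index, name="injection_order_slope"),
    )


# ---------------------------------------------------------------------------
# replicate CV, normalisation, family profiles
# ---------------------------------------------------------------------------


def replicate_cv(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Per-peptide, per-accession CV%% (sample sd / mean) on linear areas."""
    grouped = matrix.areas.T.groupby(matrix.runs["accession"])
    mean = grouped.mean().T
    sd = grouped.std(ddof=1).T
    cv = 100.0 * sd / mean
    return cv.where(mean != 0)


def percent_of_average(values: pd.Series) -> pd.Series:
    """Percent relative to the panel average; the outputs average to 100."""
    v = values.astype(float)
    m = v.mean()
    if m == 0:
        raise ValueError("all-zero value vector")
    return 100.0 * v / m


@dataclass
class ConglutinProfile:
    """Relative abundance per accession: subfamily/group level and family totals."""

    subfamily_percent: pd.DataFrame  # accession x subfamily/group label
    family_percent: pd.DataFrame     # accession x family
    family_raw: pd.DataFrame         # summed accession-mean areas per family


def _family_of_label(label: str) -> str:
    for fam in ("alpha", "beta", "delta", "gamma"):
        if label.startswith(fam):
            return fam
    raise ValueError(f"cannot derive family from marker target {label!r}")


def family_abundance(
    matrix: AbundanceMatrix, marker_map: dict[str, str]
) -> ConglutinProfile:
    """Summed family abundance, expressed as percent of the panel average.

    ``marker_map`` assigns each peptide to a subfamily or protein-group
    label (e.g. ``beta2`` or ``beta4+6``); group-assigned peptides
    contribute to their group's family.
    """
    unmapped = [p for p in matrix.areas.index if p not in marker_map]
    if unmapped:
        raise ValueError(f"unmapped marker peptides: {unmapped}")
    means = matrix.accession_means()  # peptide x accession
    labels = pd.Series({p: marker_map[p] for p in means.index})
    families = labels.map(_family_of_label)

    sub_sum = means.groupby(labels).sum().T       # accession x label
    fam_sum = means.groupby(families).sum().T     # accession x family
    sub_pct = sub_sum.apply(percent_of_average, axis=0)
    fam_pct = fam_sum.apply(percent_of_average, axis=0)
    return ConglutinProfile(sub_pct, fam_pct, fam_sum)


# ---------------------------------------------------------------------------
# multivariate views
# ---------------------------------------------------------------------------


def prepare_multivariate(
    matrix: AbundanceMatrix, max_missing_frac: float = 0.5
) -> pd.DataFrame:
    """Runs x peptides log10 matrix with the missing-value policy applied:
    peptides missing in more than ``max_missing_frac`` of runs are dropped,
    the remainder imputed with half the peptide's minimum observed area."""
    areas = matrix.areas.copy()
    frac_missing = areas.isna().mean(axis=1)
    areas = areas.loc[frac_missing <= max_missing_frac]
    fill = areas.min(axis=1) / 2.0
    areas = areas.T.fillna(fill).T
    return np.log10(areas).T


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_pct: np.ndarray

    def cumulative_pct(self, n_components: int) -> float:
        """Cumulative percent variance over the first ``n_components``."""
        return cumulative_variance(self.explained_pct, n_components)


def cumulative_variance(explained_pct, n_components: int) -> float:
    pcts = np.asarray(explained_pct, dtype=float)
    if not 1 <= n_components <= len(pcts):
        raise ValueError("n_components out of range")
    return float(pcts[:n_components].sum())


def pca(X: pd.DataFrame, scaling: str = "unit-variance") -> PCAResult:
    """Principal component analysis by SVD of the scaled sample x feature
    matrix.  Columns are mean-centred and, with the default scaling,
    divided by their standard deviation.  Component signs are fixed by
    making the largest-magnitude loading element positive."""
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    if X.isna().any().any():
        raise ValueError("PCA input contains missing values; impute first")
    Z = X.to_numpy(dtype=float)
    Z = Z - Z.mean(axis=0)
    if scaling == "unit-variance":
        sd = Z.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if len(zero):
            raise ValueError(f"zero-variance features: {list(X.columns[zero])}")
        Z = Z / sd
    elif scaling != "center":
        raise ValueError("scaling must be 'unit-variance' or 'center'")
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    # fix signs: largest-|.| element of each loading vector made positive
    for k in range(len(s)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U * s
    var = s**2
    pct = 100.0 * var / var.sum() if var.sum() > 0 else var
    comp = [f"PC{k + 1}" for k in range(len(s))]
    return PCAResult(
        pd.DataFrame(scores, index=X.index, columns=comp),
        pd.DataFrame(Vt.T, index=X.columns, columns=comp),
        pct,
    )


@dataclass
class HCAResult:
    linkage_matrix: np.ndarray
    labels: list[str]
    distance: pd.DataFrame

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in leaves_list(self.linkage_matrix)]

    def cut(self, k: int) -> pd.Series:
        flat = fcluster(self.linkage_matrix, k, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")


def correlation_distance(X: pd.DataFrame) -> pd.DataFrame:
    """One-minus-Pearson distance between samples (rows); range [0, 2]."""
    sd = X.std(axis=1, ddof=0)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance samples: {list(zero.index)}")
    corr = np.corrcoef(X.to_numpy(dtype=float))
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return pd.DataFrame(d, index=X.index, columns=X.index)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a newick string (branch lengths are
    half the merge-height increments, dendrogram style)."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    frags = {i: labels[i] for i in range(n)}
    for step, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        node = n + step
        la = h / 2.0 - heights[a] / 2.0
        lb = h / 2.0 - heights[b] / 2.0
        frags[node] = f"({frags[a]}:{la:.6f},{frags[b]}:{lb:.6f})"
        heights[node] = h
    return frags[n + len(Z) - 1] + ";"


def hca(X: pd.DataFrame, method: str = "average") -> HCAResult:
    """Hierarchical clustering of samples on the one-minus-Pearson metric."""
    if X.shape[0] < 2:
        raise ValueError("HCA requires at least 2 samples")
    dist = correlation_distance(X)
    condensed = squareform(dist.to_numpy(), checks=False)
    Z = linkage(condensed, method=method)
    return HCAResult(Z, list(X.index), dist)


# ---------------------------------------------------------------------------
# ANOVA + Dunnett many-to-one comparisons
# ---------------------------------------------------------------------------

_NULL_CACHE: dict[tuple, np.ndarray] = {}


def _dunnett_null_max_abs_t(
    n_treat: tuple[int, ...], n_control: int, df: int, mc_draws: int, seed: int
) -> np.ndarray:
    """Sorted Monte-Carlo sample of max_j |T_j| under the joint null, where
    T follows the multivariate t with the Dunnett correlation structure."""
    key = (n_treat, n_control, df, mc_draws, seed)
    if key not in _NULL_CACHE:
        lam = np.sqrt(np.array(n_treat, dtype=float) / (np.array(n_treat) + n_control))
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        rng = np.random.default_rng(seed)
        L = np.linalg.cholesky(R)
        z = rng.standard_normal((mc_draws, len(n_treat))) @ L.T
        scale = np.sqrt(rng.chisquare(df, mc_draws) / df)
        maxabs = np.abs(z / scale[:, None]).max(axis=1)
        maxabs.sort()
        _NULL_CACHE[key] = maxabs
    return _NULL_CACHE[key]


@dataclass
class DunnettResult:
    f_statistic: float
    anova_p: float
    comparisons: pd.DataFrame  # group, diff, tstat, p_adj, significant
    alpha: float = 0.05


def anova_dunnett(
    groups: dict[str, np.ndarray],
    control: str,
    alpha: float = 0.05,
    mc_draws: int = 100_000,
    seed: int = 0,
) -> DunnettResult:
    """One-way ANOVA followed by Dunnett many-to-one comparisons.

    Adjusted p-values come from the multivariate t distribution evaluated
    by Monte-Carlo integration with a fixed seed (>= 100,000 draws by
    default; tolerance on the adjusted p is about 0.002).
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} not among groups")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    f_stat, anova_p = stats.f_oneway(*arrays.values())

    treat = [g for g in arrays if g != control]
    xc = arrays[control]
    n_c = len(xc)
    df = sum(len(v) for v in arrays.values()) - len(arrays)
    s2 = sum((len(v) - 1) * np.var(v, ddof=1) for v in arrays.values()) / df
    n_treat = tuple(len(arrays[g]) for g in treat)
    null = _dunnett_null_max_abs_t(n_treat, n_c, df, mc_draws, seed)

    rows = []
    for g, n_g in zip(treat, n_treat):
        diff = arrays[g].mean() - xc.mean()
        t = diff / np.sqrt(s2 * (1.0 / n_g + 1.0 / n_c))
        # P(max |T| >= |t|) from the sorted null sample
        p = 1.0 - np.searchsorted(null, abs(t), side="left") / len(null)
        rows.append(
            {"group": g, "diff": diff, "tstat": t, "p_adj": p, "significant": p < alpha}
        )
    return DunnettResult(
        float(f_stat), float(anova_p), pd.DataFrame(rows), alpha
    )
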