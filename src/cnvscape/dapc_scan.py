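"""From-scratch DAPC on the CNV dosage matrix and upper-tail outlier scan.

The pipeline is: mean-impute and encode dosages, PCA by SVD on the centered
matrix, retain PCs up to a cumulative-variance target, fit a two-group
linear discriminant on the retained PC scores via the closed form
W^-1 (mu_1 - mu_2) (one axis exists for two groups), fold the discriminant
back to locus space as composite loadings, and rank loci by their squared,
sum-to-one contributions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from cnvscape.sv_io import MISSING, CNVTable

logger = logging.getLogger(__name__)


@dataclass
class DosageMatrix:
    """samples x loci dosage matrix restricted to group-labeled samples.

    Missing entries are mean-imputed per locus; zero-variance loci are
    dropped at construction.
    """

    values: np.ndarray  # float, n_samples x n_loci, imputed
    sample_ids: tuple[str, ...]
    locus_ids: tuple[str, ...]
    groups: dict[str, str]
    dropped_locus_ids: tuple[str, ...] = ()

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    def group_vector(self) -> np.ndarray:
        return np.array([self.groups[s] for s in self.sample_ids])


@dataclass
class PCAResult:
    column_means: np.ndarray
    column_scales: np.ndarray | None
    rotation: np.ndarray  # loci x n_components (orthonormal columns)
    variance_fractions: np.ndarray
    scores: np.ndarray  # samples x n_components


@dataclass
class DAPCModel:
    column_means: np.ndarray
    n_pcs: int
    pc_rotation: np.ndarray  # loci x n_pcs
    pc_variance_fraction: np.ndarray
    cumulative_variance: float
    discriminant_coefficients: np.ndarray  # length n_pcs
    individual_scores: np.ndarray  # per discriminated sample
    sample_ids: tuple[str, ...]
    locus_ids: tuple[str, ...]
    loadings: np.ndarray  # signed composite per-locus loading
    contributions: np.ndarray  # squared loadings, normalized to sum 1
    group_labels: tuple[str, str]


@dataclass(frozen=True)
class DivergenceHits:
    selected_locus_ids: tuple[str, ...]
    threshold_value: float
    q: float


def encode_dosage(
    table: CNVTable,
    groups: dict[str, str],
    binarize: bool = False,
) -> DosageMatrix:
    """Build the dosage matrix for the group-labeled samples.

    Samples without a group label are excluded from discrimination (and
    logged).  Missing dosages are imputed with the locus mean over
    non-missing discriminated samples; loci monomorphic after imputation
    are dropped with a warning.  ``binarize`` collapses dosage to
    presence/absence.
    """
    keep_idx = [i for i, s in enumerate(table.samples) if s in groups]
    excluded = [s for s in table.samples if s not in groups]
    if excluded:
        logger.info("samples without group label excluded: %s", ", ".join(excluded))
    if not keep_idx:
        raise ValueError("no sample has a group label")
    sample_ids = tuple(table.samples[i] for i in keep_idx)

    raw = table.dosage_matrix()[keep_idx, :].astype(float)  # samples x loci
    raw[raw == MISSING] = np.nan
    if binarize:
        raw = np.where(np.isnan(raw), np.nan, (raw > 0).astype(float))
    col_means = np.nanmean(np.where(np.isnan(raw), np.nan, raw), axis=0)
    # loci never called get mean nan -> dropped below as zero-variance
    inds = np.where(np.isnan(raw))
    raw[inds] = np.take(col_means, inds[1])

    variances = np.nanvar(raw, axis=0)
    keep_loci = np.flatnonzero(np.nan_to_num(variances, nan=0.0) > 0)
    kept_set = set(keep_loci.tolist())
    dropped = [
        table.records[j].locus_id for j in range(raw.shape[1]) if j not in kept_set
    ]
    if dropped:
        logger.warning("%d zero-variance loci dropped", len(dropped))
    return DosageMatrix(
        values=raw[:, keep_loci],
        sample_ids=sample_ids,
        locus_ids=tuple(table.records[j].locus_id for j in keep_loci),
        groups={s: groups[s] for s in sample_ids},
        dropped_locus_ids=tuple(dropped),
    )


def fit_pca(m: DosageMatrix, center: bool = True, scale: bool = False) -> PCAResult:
    """PCA of the (optionally centered/scaled) dosage matrix by SVD.

    Variance fractions sum to 1 over the nonzero components; rotation
    columns are orthonormal.
    """
    x = m.values.astype(float).copy()
    means = x.mean(axis=0) if center else np.zeros(x.shape[1])
    x -= means
    scales = None
    if scale:
        scales = x.std(axis=0, ddof=0)
        scales[scales == 0] = 1.0
        x /= scales
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    nz = s > tol
    u, s, vt = u[:, nz], s[nz], vt[nz, :]
    var = s**2
    return PCAResult(
        column_means=means,
        column_scales=scales,
        rotation=vt.T,
        variance_fractions=var / var.sum() if var.size else var,
        scores=u * s,
    )


def choose_n_pcs(
    variance_fractions: np.ndarray,
    target_cumulative: float = 0.875,
    cap: int | None = None,
    n_pcs: int | None = None,
) -> int:
    """Smallest number of leading PCs whose cumulative variance reaches the
    target, clipped to [1, cap].  An explicit ``n_pcs`` overrides the rule."""
    n_avail = len(variance_fractions)
    if n_avail == 0:
        raise ValueError("no principal components available")
    if cap is None:
        cap = n_avail
    cap = max(1, min(cap, n_avail))
    if n_pcs is not None:
        return max(1, min(n_pcs, cap))
    cum = np.cumsum(variance_fractions)
    above = np.flatnonzero(cum >= target_cumulative - 1e-12)
    n = int(above[0]) + 1 if above.size else n_avail
    return max(1, min(n, cap))


def fit_dapc(
    m: DosageMatrix,
    n_pcs: int,
    center: bool = True,
    scale: bool = False,
    ridge: float = 1e-8,
    _pca: PCAResult | None = None,
    _group_vector: np.ndarray | None = None,
) -> DAPCModel:
    """Two-group discriminant analysis on the retained PC scores.

    The discriminant coefficients are W^-1 (mu_1 - mu_2) with W the pooled
    within-group covariance of the PC scores, regularized by
    ``ridge * trace(W)/n_pcs`` on the diagonal.  Per-locus composite
    loadings are ``rotation @ coefficients``; contributions are squared
    loadings normalized to sum to 1.
    """
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    pca = _pca if _pca is not None else fit_pca(m, center=center, scale=scale)
    g = _group_vector if _group_vector is not None else m.group_vector()
    labels = sorted(set(g.tolist()))
    if len(labels) != 2:
        raise ValueError(f"exactly 2 group labels required, got {len(labels)}")
    for lab in labels:
        if int(np.sum(g == lab)) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")

    p = min(n_pcs, pca.scores.shape[1])
    if p < n_pcs:
        logger.warning("only %d nonzero PCs available (requested %d)", p, n_pcs)
    t = pca.scores[:, :p]
    rot = pca.rotation[:, :p]

    mask_a = g == labels[0]
    mask_b = g == labels[1]
    mu_a = t[mask_a].mean(axis=0)
    mu_b = t[mask_b].mean(axis=0)
    da = t[mask_a] - mu_a
    db = t[mask_b] - mu_b
    n = t.shape[0]
    w = (da.T @ da + db.T @ db) / (n - 2)
    w_r = w + np.eye(p) * ridge * (np.trace(w) / p if np.trace(w) > 0 else 1.0)
    coef = np.linalg.solve(w_r, mu_a - mu_b)

    scores = t @ coef
    loadings = rot @ coef
    sq = loadings**2
    total = sq.sum()
    if total == 0:
        raise ValueError("degenerate discriminant: all loadings zero")
    contributions = sq / total
    return DAPCModel(
        column_means=pca.column_means,
        n_pcs=p,
        pc_rotation=rot,
        pc_variance_fraction=pca.variance_fractions[:p],
        cumulative_variance=float(np.sum(pca.variance_fractions[:p])),
        discriminant_coefficients=coef,
        individual_scores=scores,
        sample_ids=m.sample_ids,
        locus_ids=m.locus_ids,
        loadings=loadings,
        contributions=contributions,
        group_labels=(labels[0], labels[1]),
    )


def select_divergent(model: DAPCModel, q: float = 0.025) -> DivergenceHits:
    """Select the ceil(q * n_loci) loci with the largest contributions.

    Ties at the threshold are broken by locus order with a warning; the
    reported threshold is the smallest selected contribution.
    """
    if not (0.0 < q <= 1.0):
        raise ValueError("q must be in (0, 1]")
    n = len(model.locus_ids)
    k = math.ceil(q * n)
    # stable sort on (-contribution, locus order): ties resolve to earlier loci
    order = np.argsort(-model.contributions, kind="stable")
    selected = order[:k]
    threshold = float(model.contributions[selected].min())
    n_at_threshold = int(np.sum(model.contributions == threshold))
    n_selected_at = int(np.sum(model.contributions[selected] == threshold))
    if n_at_threshold > n_selected_at:
        logger.warning(
            "%d loci tie at the selection threshold; broken by locus order",
            n_at_threshold,
        )
    selected_sorted = np.sort(selected)  # report in locus order
    return DivergenceHits(
        selected_locus_ids=tuple(model.locus_ids[i] for i in selected_sorted),
        threshold_value=threshold,
        q=q,
    )


def permutation_null(
    m: DosageMatrix,
    n_pcs: int,
    q: float = 0.025,
    n_perm: int = 99,
    seed: int = 0,
    center: bool = True,
    scale: bool = False,
) -> np.ndarray:
    """Null distribution of the maximum locus contribution under group-label
    permutation.

    The PCA is label-free and fitted once; only the discriminant step is
    refitted per permutation.  Deterministic given ``seed``.
    """
    del q  # selection quantile does not affect the max statistic
    if n_perm < 0:
        raise ValueError("n_perm must be >= 0")
    if n_perm == 0:
        return np.zeros(0, dtype=float)
    pca = fit_pca(m, center=center, scale=scale)
    g = m.group_vector()
    rng = np.random.default_rng(seed)
    out = np.empty(n_perm, dtype=float)
    for i in range(n_perm):
        perm = rng.permutation(len(g))
        model = fit_dapc(
            m, n_pcs, center=center, scale=scale, _pca=pca, _group_vector=g[perm]
        )
        out[i] = float(model.contributions.max())
    return out
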