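"""Differential gene activity (DGA): a variance-regularized two-sample t.

For each gene in each disease the DGA score is a regularized t-statistic
contrasting the disease arm against the control arm.  The per-arm variance
is shrunk toward a *background* variance estimated from genes of similar
mean expression (a sliding window over the expression-rank order), which
stabilizes the denominator at the small sample sizes typical of disease
expression studies:

    sigma~^2 = (v0 * sigma_bg^2 + (n - 1) * s^2) / (v0 + n - 1)
    t = (m_disease - m_control) / sqrt(sigma~_d^2/n_d + sigma~_c^2/n_c)

where m, s are the arm mean and sample standard deviation, and the prior
weight is v0 = max(c - n_arm, 0) for a pseudo-observation count c.  With
v0 = 0 the statistic reduces exactly to Welch's t.  Positive scores mean
up-regulation in disease.  No t-distribution p-values are attached: all
downstream significance is permutation-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .preprocessing import ARM_CONTROL, ARM_DISEASE, ExpressionStudy


@dataclass(frozen=True)
class RegTParams:
    """Hyperparameters of the regularized t-test.

    Parameters
    ----------
    window : int
        Odd number of genes in the background-variance window (default 101).
    confidence : float
        Pseudo-observation count ``c``; the prior weight per arm is
        ``v0 = max(c - n_arm, 0)`` (default 10).
    """

    window: int = 101
    confidence: float = 10.0

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")
        if self.confidence < 0:
            raise ValueError("confidence must be >= 0")

    def v0(self, n_arm: int) -> float:
        return max(self.confidence - n_arm, 0.0)


@dataclass
class DGAMatrix:
    """Genes x diseases matrix of DGA scores (regularized t-statistics)."""

    gene_ids: list
    disease_ids: list
    scores: np.ndarray
    degenerate: np.ndarray | None = None  # mask of zero-denominator entries

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.gene_ids), len(self.disease_ids)):
            raise ValueError("scores shape does not match labels")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("DGA scores must be finite")

    def column(self, disease_id) -> np.ndarray:
        return self.scores[:, self.disease_ids.index(disease_id)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.scores, index=self.gene_ids, columns=self.disease_ids)


def background_sd(arm_matrix: np.ndarray, w: int, gene_ids=None) -> np.ndarray:
    """Background sd per gene: window-mean of sds over the arm-mean rank.

    Genes are ranked by their mean in the arm (ties broken by gene id);
    the background sd of a gene is the arithmetic mean of the per-gene
    sample sds of the ``w`` genes centered on its rank, with the window
    clamped at the ends so it always spans exactly ``w`` genes.
    """
    arm_matrix = np.asarray(arm_matrix, dtype=float)
    n_genes = arm_matrix.shape[0]
    if arm_matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples in the arm")
    if w > n_genes:
        raise ValueError(f"window {w} larger than gene count {n_genes}")
    means = arm_matrix.mean(axis=1)
    sds = arm_matrix.std(axis=1, ddof=1)
    if gene_ids is None:
        gene_ids = np.arange(n_genes)
    order = np.lexsort((np.asarray(gene_ids), means))  # mean, then id
    sds_sorted = sds[order]
    half = (w - 1) // 2
    lo = np.clip(np.arange(n_genes) - half, 0, n_genes - w)
    csum = np.concatenate([[0.0], np.cumsum(sds_sorted)])
    window_mean = (csum[lo + w] - csum[lo]) / w
    out = np.empty(n_genes)
    out[order] = window_mean
    return out


def _regularized_var(s: np.ndarray, n: int, sigma_bg: np.ndarray, v0: float) -> np.ndarray:
    return (v0 * sigma_bg**2 + (n - 1) * s**2) / (v0 + n - 1)


def regularized_t(
    g1, g2, sigma_bg1: float, sigma_bg2: float, params: RegTParams,
    return_flag: bool = False,
):
    """Regularized t-statistic for one gene, arm 1 minus arm 2.

    With ``v0 = 0`` this is exactly Welch's t.  If both regularized
    variances are zero the statistic is defined as 0 and flagged.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    n1, n2 = g1.size, g2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each arm needs at least 2 samples")
    m1, m2 = g1.mean(), g2.mean()
    s1, s2 = g1.std(ddof=1), g2.std(ddof=1)
    var1 = _regularized_var(s1, n1, np.asarray(sigma_bg1), params.v0(n1))
    var2 = _regularized_var(s2, n2, np.asarray(sigma_bg2), params.v0(n2))
    den = math.sqrt(var1 / n1 + var2 / n2)
    if den == 0.0:
        return (0.0, True) if return_flag else 0.0
    t = (m1 - m2) / den
    return (t, False) if return_flag else t


def study_dga(study: ExpressionStudy, params: RegTParams) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized DGA column for one study: disease arm vs. control arm.

    Returns (scores, degenerate-mask)."""
    study.check_arms()
    Xd = study.arm_matrix(ARM_DISEASE)
    Xc = study.arm_matrix(ARM_CONTROL)
    gene_ids = np.asarray(study.gene_ids)
    out = []
    for X in (Xd, Xc):
        n = X.shape[1]
        m = X.mean(axis=1)
        s = X.std(axis=1, ddof=1)
        sbg = background_sd(X, params.window, gene_ids)
        out.append((m, _regularized_var(s, n, sbg, params.v0(n)), n))
    (md, vard, nd), (mc, varc, nc) = out
    den = np.sqrt(vard / nd + varc / nc)
    degenerate = den == 0.0
    t = np.where(degenerate, 0.0, (md - mc) / np.where(degenerate, 1.0, den))
    return t, degenerate


def dga_matrix(studies: list, params: RegTParams | None = None) -> DGAMatrix:
    """Assemble the genes x diseases DGA matrix from intersected studies."""
    if params is None:
        params = RegTParams()
    if not studies:
        raise ValueError("no studies given")
    universe = list(studies[0].gene_ids)
    for s in studies[1:]:
        if list(s.gene_ids) != universe:
            raise ValueError(
                f"study {s.disease_id!r} is not on the shared gene universe; "
                "run intersect_genes first"
            )
    cols, masks = zip(*(study_dga(s, params) for s in studies))
    return DGAMatrix(
        gene_ids=universe,
        disease_ids=[s.disease_id for s in studies],
        scores=np.column_stack(cols),
        degenerate=np.column_stack(masks),
    )
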