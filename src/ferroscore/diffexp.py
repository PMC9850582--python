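"""Two-group moderated differential expression and signature derivation.

The engine is the empirical-Bayes moderated t: per-gene pooled variances
are shrunk toward a prior variance s0^2 with prior degrees of freedom d0,
both estimated by moment-matching the log pooled variances against the
scaled-F distribution they follow under normality (digamma/trigamma
moments, Newton inversion of the trigamma function). The moderated
statistic is

    t_g = logFC_g / sqrt(s~_g^2 (1/n1 + 1/n2)),
    s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g),

with two-sided p-values on d0 + d_g degrees of freedom. With fewer than
10 genes the prior cannot be estimated and the engine falls back to the
ordinary pooled t (d0 = 0).

Signatures: genes up in the case-enriched cluster past the logFC and FDR
thresholds form signature A, genes down form signature B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

_MIN_GENES_FOR_PRIOR = 10
_PRIOR_DF_CAP = 1e6


@dataclass
class DifferentialResult:
    """Per-gene moderated-t table plus the fitted prior.

    ``table`` columns: gene, log_fc, t_mod, p, p_adj, s2_g. ``log_fc`` is
    mean(case) - mean(other), so positive means up in ``case_group``.
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float
    case_group: object
    other_group: object
    n_case: int
    n_other: int


@dataclass
class SignaturePair:
    """Up (A) and down (B) gene lists with the thresholds that made them."""

    signature_A: list[str]
    signature_B: list[str]
    lfc_threshold: float
    fdr_threshold: float

    def __post_init__(self) -> None:
        if set(self.signature_A) & set(self.signature_B):
            raise ValidationError("signatures A and B overlap")


def trigamma_inverse(y: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the standard initialisation x = 0.5 + 1/y and the multiplicative
    update on x (trigamma is convex decreasing); converges in a handful of
    steps for any positive y.
    """
    y = np.asarray(y, dtype=float)
    scalar = y.ndim == 0
    y = np.atleast_1d(y).copy()
    if (y <= 0).any():
        raise ValueError("trigamma_inverse requires positive input")
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if np.max(np.abs(dif / x)) < 1e-10:
            break
    return float(x[0]) if scalar else x


def _fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from log pooled variances.

    Under normality, log s2_g = log s0^2 + log chi^2 terms whose mean and
    variance involve digamma/trigamma at df/2 and d0/2; subtracting the
    known residual-df part leaves a location estimate for log s0^2 and an
    excess variance solved for d0 by trigamma inversion.
    """
    ok = (df > 0) & (s2 > 0)
    s2, df = s2[ok], df[ok]
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    n = len(e)
    excess = float(np.mean((e - e_mean) ** 2) * n / (n - 1) - np.mean(polygamma(1, df / 2.0)))
    if excess > 0:
        d0 = 2.0 * float(trigamma_inverse(excess))
        s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # variances more concordant than chi^2 sampling alone: infinite
        # shrinkage, represented by a large finite prior df
        d0 = _PRIOR_DF_CAP
        s0_sq = float(np.exp(e_mean))
    return d0, s0_sq


def moderated_t_test(
    matrix: ExpressionMatrix,
    group_labels: pd.Series | dict,
    case_group: object | None = None,
    prior_df: float | str = "auto",
) -> DifferentialResult:
    """Moderated two-group contrast on every gene of ``matrix``.

    ``group_labels`` maps sample_id to one of exactly two group labels;
    ``case_group`` names the group whose mean enters log_fc positively
    (default: the lexically larger label). ``prior_df=0`` disables
    shrinkage and reproduces the classical pooled t.
    """
    labels = pd.Series(group_labels)
    labels = labels.loc[[s for s in matrix.sample_ids if s in labels.index]]
    if set(labels.index) != set(matrix.sample_ids):
        raise ValidationError("group label missing for some samples")
    groups = sorted(labels.unique(), key=str)
    if len(groups) != 2:
        raise ValidationError(f"exactly two groups required, got {groups}")
    if case_group is None:
        case_group = groups[1]
    if case_group not in groups:
        raise ValidationError(f"case_group {case_group!r} not among {groups}")
    other_group = groups[0] if case_group == groups[1] else groups[1]

    frame = matrix.to_frame()
    case_cols = [s for s in matrix.sample_ids if labels[s] == case_group]
    other_cols = [s for s in matrix.sample_ids if labels[s] == other_group]
    n1, n2 = len(case_cols), len(other_cols)
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs >= 2 samples")

    case_vals = frame[case_cols].to_numpy()
    other_vals = frame[other_cols].to_numpy()
    log_fc = case_vals.mean(axis=1) - other_vals.mean(axis=1)
    dg = float(n1 + n2 - 2)
    ss = (case_vals.var(axis=1, ddof=1) * (n1 - 1)
          + other_vals.var(axis=1, ddof=1) * (n2 - 1))
    s2_g = ss / dg

    if prior_df == "auto":
        if matrix.n_genes >= _MIN_GENES_FOR_PRIOR and (s2_g > 0).sum() >= _MIN_GENES_FOR_PRIOR:
            d0, s0_sq = _fit_variance_prior(s2_g, np.full(matrix.n_genes, dg))
        else:
            logger.info("too few genes for a variance prior; using ordinary t")
            d0, s0_sq = 0.0, 0.0
    else:
        d0 = float(prior_df)
        s0_sq = 0.0 if d0 == 0 else float(np.median(s2_g))
    d0 = min(d0, _PRIOR_DF_CAP)

    s2_post = (d0 * s0_sq + dg * s2_g) / (d0 + dg)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log_fc / np.where(se > 0, se, 1.0),
                         np.where(log_fc == 0, 0.0, np.inf * np.sign(log_fc)))
    df_total = d0 + dg
    p = 2.0 * t_dist.sf(np.abs(t_mod), df_total)
    # a gene flat in both groups with no shift carries no evidence
    degenerate = (se == 0) & (log_fc == 0)
    t_mod = np.where(degenerate, 0.0, t_mod)
    p = np.where(degenerate, 1.0, p)

    table = pd.DataFrame({
        "gene": matrix.gene_ids,
        "log_fc": log_fc,
        "t_mod": t_mod,
        "p": p,
        "p_adj": bh_adjust(p),
        "s2_g": s2_g,
    })
    return DifferentialResult(table=table, d0=d0, s0_sq=s0_sq,
                              case_group=case_group, other_group=other_group,
                              n_case=n1, n_other=n2)


def bh_adjust(p_values: np.ndarray | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, monotone and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def derive_signatures(
    result: DifferentialResult,
    lfc_threshold: float = 0.5,
    fdr_threshold: float = 0.05,
    case_cluster: object | None = None,
) -> SignaturePair:
    """Threshold the moderated-t table into up (A) / down (B) signatures.

    Strict inequalities on both axes; ``case_cluster`` may re-orient the
    table if it names the group the contrast treated as reference.
    """
    if lfc_threshold <= 0:
        raise ValidationError("lfc_threshold must be positive")
    if not (0 < fdr_threshold <= 1):
        raise ValidationError("fdr_threshold must lie in (0, 1]")
    table = result.table
    sign = 1.0
    if case_cluster is not None and case_cluster != result.case_group:
        if case_cluster != result.other_group:
            raise ValidationError(
                f"case_cluster {case_cluster!r} matches neither contrast group"
            )
        sign = -1.0
    lfc = sign * table["log_fc"]
    significant = table["p_adj"] < fdr_threshold
    up = table.loc[significant & (lfc > lfc_threshold), "gene"].tolist()
    down = table.loc[significant & (lfc < -lfc_threshold), "gene"].tolist()
    if not up or not down:
        raise ValidationError(
            f"empty signature (A: {len(up)}, B: {len(down)}); relax thresholds "
            f"(current lfc > {lfc_threshold}, FDR < {fdr_threshold})"
        )
    return SignaturePair(up, down, lfc_threshold, fdr_threshold)
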