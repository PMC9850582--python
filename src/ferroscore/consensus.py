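"""Resampling-based consensus clustering over the ferroptosis-panel subspace.

For each candidate number of clusters k, samples are repeatedly subsampled
without replacement, the subsample is partitioned by a base clusterer, and
for every pair of samples two tallies accumulate: how often the pair was
drawn together (co-sampling) and how often it then landed in the same
cluster (co-occurrence). The consensus matrix is their ratio — the empirical
probability that two samples cluster together when both are observed.

k is selected quantitatively, by default with the PAC criterion (proportion
of consensus values in an ambiguity window, lower = crisper partition),
replacing the visual "flattest CDF" reading; the relative increase in area
under the consensus CDF (delta-area) is the configurable alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import AgglomerativeClustering, KMeans

from .exceptions import ValidationError
from .io_formats import ExpressionMatrix, FerroptosisGeneSet

logger = logging.getLogger(__name__)

DEFAULT_K_RANGE = tuple(range(2, 10))
DEFAULT_N_RESAMPLES = 200
DEFAULT_SUBSAMPLE_FRACTION = 0.8
PAC_WINDOW = (0.1, 0.9)
DELTA_AREA_THRESHOLD = 0.05
_MAX_REDRAWS = 10


@dataclass
class ConsensusResult:
    """Per-k consensus matrices with their tallies and k-selection
    diagnostics; ``labels`` hold the final partition at ``chosen_k``."""

    sample_ids: list[str]
    k_range: tuple[int, ...]
    consensus: dict[int, np.ndarray]
    cooccurrence_counts: dict[int, np.ndarray]
    cosample_counts: dict[int, np.ndarray]
    cdf: dict[int, tuple[np.ndarray, np.ndarray]]  # (sorted values, ECDF at values)
    area: dict[int, float]
    delta_area: dict[int, float]
    pac: dict[int, float]
    chosen_k: int | None = None
    labels: dict[str, int] | None = None

    def consensus_frame(self, k: int):
        import pandas as pd

        return pd.DataFrame(self.consensus[k], index=self.sample_ids,
                            columns=self.sample_ids)


def subset_to_panel(
    matrix: ExpressionMatrix, panel: FerroptosisGeneSet
) -> ExpressionMatrix:
    """Restrict rows to panel genes (panel order); drop zero-variance rows.

    Absent panel genes and dropped constant rows are reported by warning;
    zero overlap is an error because clustering has no subspace to work in.
    """
    present = [g for g in panel.symbols if g in set(matrix.gene_ids)]
    absent = [g for g in panel.symbols if g not in set(matrix.gene_ids)]
    if not present:
        raise ValidationError("no panel genes present in expression matrix")
    if absent:
        logger.warning("%d panel gene(s) absent from matrix: %s",
                       len(absent), ", ".join(absent[:10]))
    sub = matrix.subset_genes(present)
    variances = sub.values.var(axis=1)
    constant = [g for g, v in zip(sub.gene_ids, variances) if v == 0.0]
    if constant:
        logger.warning("dropping %d zero-variance panel row(s): %s",
                       len(constant), ", ".join(constant[:10]))
        keep = [g for g in sub.gene_ids if g not in set(constant)]
        if not keep:
            raise ValidationError("all panel rows have zero variance")
        sub = sub.subset_genes(keep)
    return sub


def prepare_values(values: np.ndarray, center_genes: bool = True,
                   z_score: bool = False) -> np.ndarray:
    """Preprocess gene rows before sample-space distance computation.

    ``center_genes`` removes each gene's median. Correlation between
    *samples* is taken across genes, so the shared per-gene baseline acts
    as a common signal that swamps group structure unless removed —
    median-centering gene rows is the standard preprocessing for
    correlation-based consensus clustering of samples. ``z_score``
    additionally scales each row to unit SD.
    """
    if z_score:
        sd = values.std(axis=1, keepdims=True)
        if (sd == 0).any():
            raise ValidationError("zero-variance gene row under z-scoring")
        return (values - values.mean(axis=1, keepdims=True)) / sd
    if center_genes:
        return values - np.median(values, axis=1, keepdims=True)
    return values


def correlation_distance(values: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between sample columns; undefined
    correlations (constant columns) count as distance 1."""
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(values.T)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0)


def _cluster_subsample(values: np.ndarray, k: int, base: str,
                       rng: np.random.Generator) -> np.ndarray:
    """Partition the sample columns of ``values`` into k groups."""
    if base == "hierarchical":
        dist = correlation_distance(values)
        model = AgglomerativeClustering(n_clusters=k, metric="precomputed",
                                        linkage="average")
        return model.fit_predict(dist)
    if base == "kmeans":
        model = KMeans(n_clusters=k, n_init=10,
                       random_state=int(rng.integers(2**31 - 1)))
        return model.fit_predict(values.T)
    raise ValueError(f"unknown base clusterer {base!r}")


def resample_indices(
    n_samples: int,
    subsample_fraction: float,
    n_resamples: int,
    seed: int,
) -> list[np.ndarray]:
    """The deterministic subsample stream used for one value of k.

    Exposed so that independent tally implementations can consume the same
    stream; each draw takes ceil(fraction * n) samples without replacement.
    """
    rng = np.random.default_rng(seed)
    size = int(np.ceil(subsample_fraction * n_samples))
    return [np.sort(rng.choice(n_samples, size=size, replace=False))
            for _ in range(n_resamples)]


def _tally_for_k(
    values: np.ndarray,
    k: int,
    draws: list[np.ndarray],
    base: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    n = values.shape[1]
    cooccur = np.zeros((n, n), dtype=np.int64)
    cosample = np.zeros((n, n), dtype=np.int64)
    for idx in draws:
        sub = values[:, idx]
        attempts = 0
        while np.unique(sub.T, axis=0).shape[0] < k:
            attempts += 1
            if attempts > _MAX_REDRAWS:
                raise ValidationError(
                    f"could not draw {len(idx)} samples with >= {k} distinct "
                    f"profiles after {_MAX_REDRAWS} redraws"
                )
            idx = np.sort(rng.choice(n, size=len(idx), replace=False))
            sub = values[:, idx]
        assignment = _cluster_subsample(sub, k, base, rng)
        cosample[np.ix_(idx, idx)] += 1
        for cluster in range(k):
            members = idx[assignment == cluster]
            cooccur[np.ix_(members, members)] += 1
    return cooccur, cosample


def _consensus_from_tallies(cooccur: np.ndarray, cosample: np.ndarray) -> np.ndarray:
    consensus = np.zeros_like(cooccur, dtype=float)
    observed = cosample > 0
    consensus[observed] = cooccur[observed] / cosample[observed]
    if not observed[np.triu_indices_from(observed, k=1)].all():
        n_missing = int((~observed[np.triu_indices_from(observed, k=1)]).sum())
        logger.warning("%d sample pair(s) never co-sampled; consensus set to 0",
                       n_missing)
    np.fill_diagonal(consensus, 1.0)
    return consensus


def _cdf_and_area(consensus: np.ndarray) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    values = np.sort(consensus[np.triu_indices_from(consensus, k=1)])
    m = len(values)
    ecdf = np.arange(1, m + 1) / m
    # area under the ECDF over [min, max] of observed consensus values
    area = float(np.sum(np.diff(values) * ecdf[:-1])) if m > 1 else 0.0
    return (values, ecdf), area


def pac_score(consensus: np.ndarray, window: tuple[float, float] = PAC_WINDOW) -> float:
    """Fraction of off-diagonal consensus values strictly inside the
    ambiguity window."""
    values = consensus[np.triu_indices_from(consensus, k=1)]
    lo, hi = window
    return float(np.mean((values > lo) & (values < hi))) if len(values) else 0.0


def consensus_cluster(
    matrix: ExpressionMatrix,
    k_range: Iterable[int] = DEFAULT_K_RANGE,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    subsample_fraction: float = DEFAULT_SUBSAMPLE_FRACTION,
    seed: int = 0,
    base: str = "hierarchical",
    center_genes: bool = True,
    z_score: bool = False,
    select: str = "pac",
) -> ConsensusResult:
    """Run the full consensus procedure over ``k_range`` and pick k.

    Gene rows are median-centered by default (see :func:`prepare_values`);
    ``z_score`` standardizes them fully instead. Deterministic given
    ``seed``: the subsample stream for k uses the derived seed
    ``seed + k``.
    """
    k_range = tuple(sorted(set(int(k) for k in k_range)))
    if n_resamples < 2:
        raise ValidationError("n_resamples must be >= 2")
    if not (0.0 < subsample_fraction <= 1.0):
        raise ValidationError("subsample_fraction must lie in (0, 1]")
    if matrix.n_samples < max(k_range) + 1:
        raise ValidationError(
            f"{matrix.n_samples} samples cannot support k up to {max(k_range)}"
        )
    values = prepare_values(matrix.values, center_genes=center_genes,
                            z_score=z_score)

    consensus: dict[int, np.ndarray] = {}
    cooccur_all: dict[int, np.ndarray] = {}
    cosample_all: dict[int, np.ndarray] = {}
    cdf: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    area: dict[int, float] = {}
    pac: dict[int, float] = {}
    for k in k_range:
        draws = resample_indices(matrix.n_samples, subsample_fraction,
                                 n_resamples, seed + k)
        redraw_rng = np.random.default_rng((seed + k) * 2654435761 % (2**31))
        cooccur, cosample = _tally_for_k(values, k, draws, base, redraw_rng)
        cons = _consensus_from_tallies(cooccur, cosample)
        consensus[k] = cons
        cooccur_all[k] = cooccur
        cosample_all[k] = cosample
        cdf[k], area[k] = _cdf_and_area(cons)
        pac[k] = pac_score(cons)

    delta_area: dict[int, float] = {}
    for i, k in enumerate(k_range):
        if i == 0:
            delta_area[k] = area[k]
        else:
            prev = area[k_range[i - 1]]
            delta_area[k] = (area[k] - prev) / prev if prev > 0 else area[k]

    result = ConsensusResult(
        sample_ids=list(matrix.sample_ids), k_range=k_range,
        consensus=consensus, cooccurrence_counts=cooccur_all,
        cosample_counts=cosample_all, cdf=cdf, area=area,
        delta_area=delta_area, pac=pac,
    )
    result.chosen_k = select_k(result, method=select)
    result.labels = final_labels(result, result.chosen_k)
    return result


def select_k(result: ConsensusResult, method: str = "pac") -> int:
    """Quantitative k selection.

    ``pac`` takes the k minimizing PAC; ties at a nonzero minimum break
    toward smaller k. Ties at PAC exactly 0 mean several partitions are
    perfectly crisp — there PAC carries no information (a deterministic
    base clusterer merges true groups crisply when k is too small), so the
    tied candidates are adjudicated by the delta-area rule, which still
    sees the extra separation structure in the consensus CDF.
    """
    if method == "pac":
        if all(result.pac[k] == 0.0 for k in result.k_range):
            logger.warning("PAC is 0 for all k; deciding by delta-area")
        min_pac = min(result.pac[k] for k in result.k_range)
        candidates = [k for k in result.k_range if result.pac[k] == min_pac]
        if len(candidates) == 1 or min_pac > 0.0:
            return min(candidates)
        chosen = candidates[0]
        for k in candidates[1:]:
            if result.delta_area[k] > DELTA_AREA_THRESHOLD:
                chosen = k
        return chosen
    if method == "delta_area":
        chosen = result.k_range[0]
        for k in result.k_range[1:]:
            if result.delta_area[k] > DELTA_AREA_THRESHOLD:
                chosen = k
        return chosen
    raise ValueError(f"unknown k-selection method {method!r}")


def final_labels(result: ConsensusResult, k: int) -> dict[str, int]:
    """Cut an average-linkage tree of (1 - consensus) at k; cluster ids are
    1..k in decreasing cluster size (first appearance breaks size ties)."""
    if k not in result.k_range:
        raise ValidationError(f"k={k} was not evaluated (range {result.k_range})")
    dissimilarity = 1.0 - result.consensus[k]
    np.fill_diagonal(dissimilarity, 0.0)
    condensed = squareform(dissimilarity, checks=False)
    tree = linkage(condensed, method="average")
    raw = fcluster(tree, t=k, criterion="maxclust")
    order = sorted(set(raw), key=lambda c: (-(raw == c).sum(),
                                            int(np.argmax(raw == c))))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    return {s: relabel[c] for s, c in zip(result.sample_ids, raw)}
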