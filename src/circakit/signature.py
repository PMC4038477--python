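"""Strong/weak-oscillator gene-signature discovery.

Empirical-Bayes moderated two-group t-testing, leave-one-cell-line-out
cross-validation, hierarchical-clustering fold validation (Pearson
distance, Ward linkage), list intersection, sample classification and
the exact binomial test on classification outcomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import digamma, polygamma, stdtr
from scipy.optimize import brentq

__all__ = [
    "ExpressionStudy",
    "ModeratedStats",
    "FoldResult",
    "moderated_t_test",
    "loocv_discriminative_lists",
    "validate_fold_by_clustering",
    "intersect_lists",
    "classify_sample",
    "binomial_classification_test",
    "collapse_probes_to_genes",
    "DesignError",
]


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class ExpressionStudy:
    """Log-scale genes x samples matrix with per-sample annotations.

    ``annotations`` columns: sample, cell_line, phenotype
    (strong/weak/test), timepoint. Each cell line contributes its two
    timepoints as biological replicates.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self):
        ann = self.annotations
        required = {"sample", "cell_line", "phenotype", "timepoint"}
        if not required.issubset(ann.columns):
            raise DesignError(f"annotations need columns {sorted(required)}")
        if set(ann["sample"]) != set(self.values.columns):
            raise DesignError("annotation samples do not match matrix columns")
        bad = set(ann["phenotype"]) - {"strong", "weak", "test"}
        if bad:
            raise DesignError(f"unknown phenotypes {sorted(bad)}")

    def samples_of(self, phenotype=None, cell_line=None) -> list:
        ann = self.annotations
        mask = np.ones(len(ann), dtype=bool)
        if phenotype is not None:
            mask &= (ann["phenotype"] == phenotype).to_numpy()
        if cell_line is not None:
            mask &= (ann["cell_line"] == cell_line).to_numpy()
        return list(ann.loc[mask, "sample"])

    def cell_lines(self, phenotypes=("strong", "weak")) -> list:
        ann = self.annotations
        return sorted(ann.loc[ann["phenotype"].isin(phenotypes), "cell_line"].unique())

    def phenotype_of_line(self, cell_line) -> str:
        vals = self.annotations.loc[self.annotations["cell_line"] == cell_line, "phenotype"]
        return vals.iloc[0]

    def subset_samples(self, samples) -> "ExpressionStudy":
        ann = self.annotations[self.annotations["sample"].isin(samples)].reset_index(drop=True)
        return ExpressionStudy(self.values[list(ann["sample"])], ann)


@dataclass(frozen=True)
class ModeratedStats:
    """Per-gene moderated two-group statistics plus shared hyperparameters."""

    table: pd.DataFrame  # columns: beta, s2, t, p (index: gene)
    d_g: float
    d0: float
    s0_sq: float


def _fit_f_dist_moments(s2: np.ndarray, d_g: float) -> tuple[float, float]:
    """Hyperparameters (d0, s0^2) by moment matching on log variances.

    e_g = log s2_g - digamma(d_g/2) + log(d_g/2); the excess spread of
    e_g over trigamma(d_g/2) identifies trigamma(d0/2), inverted
    monotonically; non-positive excess means no spread to shrink and
    d0 = +inf.
    """
    G = s2.size
    e = np.log(s2) - digamma(d_g / 2) + np.log(d_g / 2)
    ebar = float(np.mean(e))
    rhs = float(np.mean((e - ebar) ** 2 * G / (G - 1) - polygamma(1, d_g / 2)))
    if rhs <= 0:
        return np.inf, float(np.exp(ebar))

    def f(d0):
        return polygamma(1, d0 / 2) - rhs

    lo, hi = 1e-6, 1e-6
    while f(hi) > 0:
        hi *= 2
        if hi > 1e12:
            return np.inf, float(np.exp(ebar))
    d0 = brentq(f, lo, hi) if f(lo) > 0 else lo
    s0_sq = float(np.exp(ebar + digamma(d0 / 2) - np.log(d0 / 2)))
    return float(d0), s0_sq


def moderated_t_test(study: ExpressionStudy, group_a: str = "strong",
                     group_b: str = "weak") -> ModeratedStats:
    """Two-group moderated t with empirical-Bayes variance shrinkage.

    Pooled per-gene variance on d_g = n_a + n_b - 2 df is shrunk to the
    posterior (d0 s0^2 + d_g s2_g)/(d0 + d_g); the moderated statistic is
    referred to a Student t on d0 + d_g degrees of freedom.
    """
    a = study.samples_of(group_a)
    b = study.samples_of(group_b)
    if len(a) < 2 or len(b) < 2:
        raise DesignError(f"need >= 2 samples per group (got {len(a)}, {len(b)})")
    xa = study.values[a].to_numpy(dtype=float)
    xb = study.values[b].to_numpy(dtype=float)
    na, nb = xa.shape[1], xb.shape[1]
    d_g = na + nb - 2
    beta = xa.mean(axis=1) - xb.mean(axis=1)
    ss = ((xa - xa.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (xb - xb.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / d_g

    positive = s2 > 0
    if positive.sum() < 30:
        raise DesignError("need >= 30 genes with positive variance for hyperparameter fit")
    d0, s0_sq = _fit_f_dist_moments(s2[positive], d_g)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
        df_total = d0 + d_g
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, 0.0)
    if np.isinf(df_total):
        from scipy.special import ndtr
        p = 2 * (1 - ndtr(np.abs(tstat)))
    else:
        p = 2 * stdtr(df_total, -np.abs(tstat))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    table = pd.DataFrame(
        {"beta": beta, "s2": s2, "s2_post": s2_post, "t": tstat, "p": p},
        index=study.values.index,
    )
    return ModeratedStats(table, float(d_g), float(d0), float(s0_sq))


@dataclass
class FoldResult:
    excluded_cell_line: str
    genes: list
    pvalues: dict
    retained: bool | None = None


def rank_top_genes(stats: ModeratedStats, top_k: int) -> list:
    """Top-k by ascending p; ties by descending |t|, then gene name."""
    tbl = stats.table.copy()
    tbl["abs_t"] = -np.abs(tbl["t"])
    tbl["gene"] = tbl.index.astype(str)
    tbl = tbl.sort_values(["p", "abs_t", "gene"], kind="mergesort")
    return list(tbl.index[:top_k])


def loocv_discriminative_lists(study: ExpressionStudy, top_k: int = 100) -> list[FoldResult]:
    """One fold per labeled cell line, excluding both its replicates."""
    if top_k > study.values.shape[0]:
        raise ValueError(f"top_k={top_k} exceeds gene count {study.values.shape[0]}")
    lines = study.cell_lines()
    folds = []
    for line in lines:
        keep = [
            s for s in study.samples_of()
            if study.annotations.set_index("sample").loc[s, "cell_line"] != line
            and study.annotations.set_index("sample").loc[s, "phenotype"] in ("strong", "weak")
        ]
        sub = study.subset_samples(keep)
        if len(sub.cell_lines(("strong",))) < 2 or len(sub.cell_lines(("weak",))) < 2:
            raise DesignError(
                f"excluding {line!r} leaves < 2 cell lines in a phenotype"
            )
        stats = moderated_t_test(sub)
        genes = rank_top_genes(stats, top_k)
        folds.append(FoldResult(line, genes, {g: float(stats.table.loc[g, "p"]) for g in genes}))
    return folds


def _pearson_distance_matrix(x: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between columns; constant columns dropped upstream."""
    r = np.corrcoef(x, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def _two_way_cluster(values: pd.DataFrame, ward_squared: bool = True) -> pd.Series:
    """Cut a Ward tree over 1-Pearson sample distances into 2 clusters."""
    x = values.to_numpy(dtype=float)
    keep = x.std(axis=0) > 0
    if not keep.all():
        warnings.warn("dropping constant sample columns (undefined correlation)")
    cols = values.columns[keep]
    d = _pearson_distance_matrix(x[:, keep])
    if ward_squared:
        # Ward.D2-style: recurrence on squared dissimilarities
        condensed = squareform(d, checks=False)
        Z = linkage(condensed, method="ward")
    else:
        condensed = squareform(d ** 2, checks=False)
        Z = linkage(condensed, method="ward")
    labels = fcluster(Z, t=2, criterion="maxclust")
    return pd.Series(labels, index=cols)


def validate_fold_by_clustering(study: ExpressionStudy, fold: FoldResult,
                                ward_squared: bool = True) -> FoldResult:
    """Retain a fold iff the excluded line co-clusters with its phenotype.

    The matrix is restricted to the fold's genes and all strong/weak
    samples (excluded line included); both excluded samples must land in
    the cluster whose majority phenotype matches theirs.
    """
    samples = study.samples_of("strong") + study.samples_of("weak")
    sub = study.subset_samples(samples)
    values = sub.values.loc[[g for g in fold.genes if g in sub.values.index]]
    labels = _two_way_cluster(values, ward_squared)
    ann = sub.annotations.set_index("sample")
    excluded = [s for s in samples if ann.loc[s, "cell_line"] == fold.excluded_cell_line]
    truth = study.phenotype_of_line(fold.excluded_cell_line)

    retained = True
    for s in excluded:
        cluster = labels.get(s)
        if cluster is None:
            retained = False
            break
        members = [m for m in labels.index if labels[m] == cluster and m not in excluded]
        phenos = [ann.loc[m, "phenotype"] for m in members]
        if not phenos:
            retained = False
            break
        majority = max(set(phenos), key=phenos.count)
        if phenos.count(majority) * 2 == len(phenos):  # tie -> not a clean call
            retained = False
            break
        if majority != truth:
            retained = False
            break
    fold.retained = retained
    return fold


def intersect_lists(folds: list[FoldResult], retained_only: bool = True) -> list:
    """Set intersection over retained folds, ordered by best fold p-value."""
    used = [f for f in folds if (f.retained or not retained_only)]
    if not used:
        raise DesignError("no retained folds to intersect")
    common = set(used[0].genes)
    for f in used[1:]:
        common &= set(f.genes)
    best_p = {g: min(f.pvalues[g] for f in used if g in f.pvalues) for g in common}
    return sorted(common, key=lambda g: (best_p[g], str(g)))


def classify_sample(
    study: ExpressionStudy,
    signature: list,
    sample_or_line: str,
    mode: str = "cocluster",
    min_coverage: float = 0.8,
) -> str:
    """Assign strong/weak to a held-out sample or cell line.

    ``cocluster`` reclusters the labeled samples plus the query and
    reads the joined cluster's majority phenotype; ``centroid`` picks
    the phenotype centroid with the higher Pearson correlation. Returns
    "unclassified" on ties.
    """
    present = [g for g in signature if g in study.values.index]
    if len(present) < min_coverage * len(signature):
        raise KeyError(
            f"only {len(present)}/{len(signature)} signature genes present "
            f"(need >= {min_coverage:.0%})"
        )
    ann = study.annotations.set_index("sample")
    if sample_or_line in ann.index:
        query_samples = [sample_or_line]
    else:
        query_samples = study.samples_of(cell_line=sample_or_line)
        if not query_samples:
            raise KeyError(f"unknown sample or cell line {sample_or_line!r}")
    labeled = [s for s in study.samples_of("strong") + study.samples_of("weak")
               if s not in query_samples]
    values = study.values.loc[present]

    if mode == "centroid":
        votes = []
        for q in query_samples:
            x = values[q].to_numpy(dtype=float)
            cors = {}
            for ph in ("strong", "weak"):
                cent = values[[s for s in labeled if ann.loc[s, "phenotype"] == ph]].mean(axis=1)
                cors[ph] = np.corrcoef(x, cent.to_numpy())[0, 1]
            if np.isclose(cors["strong"], cors["weak"]):
                votes.append("unclassified")
            else:
                votes.append(max(cors, key=cors.get))
    elif mode == "cocluster":
        labels = _two_way_cluster(values[labeled + query_samples])
        votes = []
        for q in query_samples:
            cluster = labels.get(q)
            members = [m for m in labeled if labels.get(m) == cluster]
            phenos = [ann.loc[m, "phenotype"] for m in members]
            if not phenos:
                votes.append("unclassified")
                continue
            n_strong = phenos.count("strong")
            if 2 * n_strong == len(phenos):
                votes.append("unclassified")
            else:
                votes.append("strong" if 2 * n_strong > len(phenos) else "weak")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    counts = {v: votes.count(v) for v in set(votes)}
    top = max(counts.values())
    winners = [v for v, c in counts.items() if c == top]
    return winners[0] if len(winners) == 1 else "unclassified"


def binomial_classification_test(correct: int, total: int, chance_p: float = 0.5) -> float:
    """Exact one-sided upper-tail binomial probability P(X >= correct)."""
    if not (0 < chance_p < 1):
        raise ValueError("chance_p must lie in (0, 1)")
    if not (0 <= correct <= total):
        raise ValueError("need 0 <= correct <= total")
    pf = Fraction(chance_p).limit_denominator(10 ** 12)
    tail = sum(
        comb(total, k) * pf ** k * (1 - pf) ** (total - k) for k in range(correct, total + 1)
    )
    return float(tail)


def collapse_probes_to_genes(values: pd.DataFrame, probe_to_gene: dict) -> pd.DataFrame:
    """Collapse probe-level rows to genes, keeping the max-mean probe per gene."""
    means = values.mean(axis=1)
    best = {}
    for probe in values.index:
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        if gene not in best or means[probe] > means[best[gene]]:
            best[gene] = probe
    out = values.loc[list(best.values())].copy()
    out.index = list(best.keys())
    return out.sort_index()
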