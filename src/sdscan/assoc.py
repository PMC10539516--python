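"""Codominant genotype-sex association with FDR control.

A relatedness/structure prefilter flags clusters of highly related
samples (standardized allele sharing, connected components above a
z-score threshold).  The association test itself is a per-marker
likelihood-ratio chi-square on the sex x genotype contingency table
(genotype as an unordered factor, df = classes - 1), with
Benjamini-Hochberg correction across tested markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, MISSING

logger = logging.getLogger(__name__)

__all__ = [
    "RelatednessReport",
    "prefilter_structure",
    "codominant_association",
    "fdr_adjust",
    "qq_observed_expected",
]


@dataclass
class RelatednessReport:
    relatedness: pd.DataFrame  # symmetric allele-sharing matrix
    zscores: pd.DataFrame      # standardized (off-diagonal) relatedness
    ordination: pd.DataFrame   # first k principal axes
    flagged: set[str] = field(default_factory=set)


def _allele_sharing(matrix: GenotypeMatrix) -> np.ndarray:
    """Pairwise similarity 1 - mean(|dosage_i - dosage_j|)/2 over joint calls."""
    n = matrix.n_samples
    d = matrix.genotypes.astype(float)
    d[matrix.genotypes == MISSING] = np.nan
    s = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.abs(d[:, i] - d[:, j])
            ok = ~np.isnan(diff)
            s[i, j] = s[j, i] = 1.0 - np.nanmean(diff[ok]) / 2.0 if ok.any() else np.nan
    return s


def prefilter_structure(
    matrix: GenotypeMatrix,
    relatedness_threshold: float = 4.0,
    k_axes: int = 2,
    mode: str = "all",
) -> tuple[list[str], RelatednessReport]:
    """Flag clusters of highly related samples before association testing.

    Pairs whose standardized allele sharing exceeds ``relatedness_threshold``
    (z-score against the off-diagonal distribution) form edges; connected
    components of size >= 2 are clusters.  ``mode='all'`` flags every
    cluster member (mirrors removing whole related clusters);
    ``mode='keep_one'`` keeps the least-missing member of each cluster.
    Returns (retained sample ids, report).
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if mode not in ("all", "keep_one"):
        raise ValueError(f"bad mode {mode!r}")
    ids = matrix.sample_ids
    s = _allele_sharing(matrix)
    off = s[~np.eye(len(ids), dtype=bool)]
    mu, sd = np.nanmean(off), np.nanstd(off)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (s - mu) / sd if sd > 0 else np.zeros_like(s)
    np.fill_diagonal(z, 0.0)

    g = nx.Graph()
    g.add_nodes_from(ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if np.isfinite(z[i, j]) and z[i, j] > relatedness_threshold:
                g.add_edge(ids[i], ids[j])
    flagged: set[str] = set()
    missing_frac = dict(zip(ids, matrix.missing_fraction_per_sample()))
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        if mode == "all":
            flagged |= comp
        else:
            keep = min(comp, key=lambda x: (missing_frac[x], x))
            flagged |= comp - {keep}

    # PCA ordination on the mean-imputed centered dosage matrix for QC
    d = matrix.genotypes.astype(float).T  # samples x markers
    d[d == MISSING] = np.nan
    col_mean = np.nanmean(d, axis=0)
    col_mean = np.nan_to_num(col_mean)
    d = np.where(np.isnan(d), col_mean, d) - col_mean
    k = min(k_axes, min(d.shape))
    u, sv, _ = np.linalg.svd(d, full_matrices=False)
    coords = u[:, :k] * sv[:k]
    report = RelatednessReport(
        relatedness=pd.DataFrame(s, index=ids, columns=ids),
        zscores=pd.DataFrame(z, index=ids, columns=ids),
        ordination=pd.DataFrame(
            coords, index=ids, columns=[f"PC{a + 1}" for a in range(k)]
        ),
        flagged=flagged,
    )
    retained = [sid for sid in ids if sid not in flagged]
    return retained, report


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0,1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0, 1)
    return q


def _lr_chi2(table: np.ndarray) -> float:
    """Likelihood-ratio (G) statistic for an r x c contingency table."""
    n = table.sum()
    exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = table * np.log(table / exp)
    return 2.0 * float(np.nansum(np.where(table > 0, terms, 0.0)))


def codominant_association(
    matrix: GenotypeMatrix,
    min_call_rate: float = 0.8,
    alpha: float = 0.05,
    statistic: str = "lrt",
) -> pd.DataFrame:
    """Per-marker sex x genotype contingency test with BH correction.

    Only bi-allelic markers genotyped in at least ``min_call_rate`` of the
    sexed cohort are tested; markers with a single observed genotype class
    are skipped (logged).  ``statistic`` is ``lrt`` (likelihood-ratio
    chi-square, default) or ``pearson``.
    """
    if statistic not in ("lrt", "pearson"):
        raise ValueError(f"bad statistic {statistic!r}")
    sex = matrix.sexes
    use = np.flatnonzero((sex == "M") | (sex == "F"))
    if use.size == 0 or len(set(sex[use])) < 2:
        raise ValueError("cohort must contain both sexes")
    sub = matrix.take_samples(use)
    male = sub.sexes == "M"
    rows = []
    skipped = 0
    for i, m in enumerate(sub.markers):
        if m.monomorphic:
            continue
        g = sub.genotypes[i]
        called = g != MISSING
        if called.mean() < min_call_rate:
            continue
        classes = np.unique(g[called])
        if len(classes) < 2:
            skipped += 1
            continue
        table = np.array(
            [
                [int(((g == c) & male).sum()) for c in classes],
                [int(((g == c) & ~male).sum()) for c in classes],
            ],
            dtype=float,
        )
        df = len(classes) - 1
        if statistic == "lrt":
            stat = _lr_chi2(table)
        else:
            stat = float(stats.chi2_contingency(table, correction=False)[0])
        p = float(stats.chi2.sf(stat, df))
        rows.append(
            {"marker_id": m.marker_id, "radtag_id": m.radtag_id,
             "statistic": stat, "df": df, "p": p}
        )
    if skipped:
        logger.info("skipped %d markers with a single observed genotype class", skipped)
    res = pd.DataFrame(rows, columns=["marker_id", "radtag_id", "statistic", "df", "p"])
    if len(res):
        res["q"] = fdr_adjust(res["p"].to_numpy())
        res["significant"] = res["q"] < alpha
    else:
        res["q"] = pd.Series(dtype=float)
        res["significant"] = pd.Series(dtype=bool)
    return res


def qq_observed_expected(p_values) -> pd.DataFrame:
    """Observed vs expected -log10 p under a uniform null.

    Expected quantiles are at (i - 0.5)/n for the i-th smallest p.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    if p.size == 0:
        raise ValueError("empty p-value vector")
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    with np.errstate(divide="ignore"):
        return pd.DataFrame(
            {
                "expected_neglog10": -np.log10(expected),
                "observed_neglog10": -np.log10(p),
            }
        )
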