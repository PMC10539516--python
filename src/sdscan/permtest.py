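"""Permutation null for the sex-linkage detection methods.

Sex labels of the cohort are shuffled (sex counts preserved exactly) and
the scan re-run on each permutation; per-sex call-rate gates are
recomputed inside every permutation because they depend on the labels.
Observed counts are compared to the empirical upper 95%/99% quantiles of
the null and given an add-one empirical p-value
``(1 + #{null >= observed}) / (n_perm + 1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .sexlink import ALL_METHODS, SYSTEMS, MethodThresholds, count_hits, prepare_scan_arrays

logger = logging.getLogger(__name__)

__all__ = ["PermutationSummary", "permute_sexes", "run_permutation_test", "summaries_to_frame"]


@dataclass
class PermutationSummary:
    method_id: int
    system: str
    observed_count: int
    n_perm: int
    null_mean: float
    q95: int
    q99: int
    empirical_p: float
    seed: int
    significant_05: bool = False
    significant_01: bool = False
    null_counts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int), repr=False)


def permute_sexes(
    sexes: Sequence[str] | np.ndarray,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Uniform random permutation of the sex-label multiset."""
    labels = np.asarray(sexes)
    if not set(np.unique(labels)) <= {"M", "F"}:
        raise ValueError("labels must be M/F")
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.permutation(labels)


def _upper_quantile(sorted_null: np.ndarray, q: float) -> int:
    """Order statistic at position ceil(q * n) of the ascending null counts."""
    n = len(sorted_null)
    k = int(np.ceil(q * n))
    return int(sorted_null[max(k - 1, 0)])


def run_permutation_test(
    matrix: GenotypeMatrix,
    methods: Sequence[int] = ALL_METHODS,
    systems: Sequence[str] = SYSTEMS,
    n_perm: int = 10_000,
    seed: int = 0,
    thresholds: MethodThresholds | None = None,
) -> list[PermutationSummary]:
    """Label-permutation null for each requested (method, system)."""
    if n_perm < 100:
        logger.warning("n_perm=%d is small; quantiles will be unstable", n_perm)
    arrays = prepare_scan_arrays(matrix)
    male = arrays["male_mask"]
    rng = np.random.default_rng(seed)

    observed = count_hits(arrays, male, methods, systems, thresholds)
    keys = list(observed)
    null = {k: np.empty(n_perm, dtype=int) for k in keys}
    for r in range(n_perm):
        perm = rng.permutation(male)
        counts = count_hits(arrays, perm, methods, systems, thresholds)
        for k in keys:
            null[k][r] = counts[k]

    out = []
    for (method, system) in keys:
        nc = np.sort(null[(method, system)])
        obs = int(observed[(method, system)])
        p = (1 + int((nc >= obs).sum())) / (n_perm + 1)
        q95 = _upper_quantile(nc, 0.95)
        q99 = _upper_quantile(nc, 0.99)
        out.append(
            PermutationSummary(
                method_id=method,
                system=system,
                observed_count=obs,
                n_perm=n_perm,
                null_mean=float(nc.mean()),
                q95=q95,
                q99=q99,
                empirical_p=p,
                seed=seed,
                significant_05=obs > q95,
                significant_01=obs > q99,
                null_counts=null[(method, system)],
            )
        )
    return out


def summaries_to_frame(summaries: list[PermutationSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "method": s.method_id,
                "system": s.system,
                "observed": s.observed_count,
                "n_perm": s.n_perm,
                "null_mean": s.null_mean,
                "q95": s.q95,
                "q99": s.q99,
                "empirical_p": s.empirical_p,
                "significant_05": s.significant_05,
                "significant_01": s.significant_01,
                "seed": s.seed,
            }
            for s in summaries
        ]
    )
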