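"""Seven-model Mendelian segregation filter for an F1 mapping family.

Every marker is tested against the seven possible bi-allelic segregation
models (AAxAA, BBxBB, AAxBB, AAxAB, BBxAB, ABxAB and ABxMissing, the last
being a heterozygous-by-unsequenced cross yielding AA and BB offspring
1:1).  A model passes when at most ``max_error`` of called offspring fall
outside its expected genotype classes and, for multi-class models, a
goodness-of-fit chi-square on the in-class counts is not rejected at
``alpha``.  Among passing models, parent compatibility (order-agnostic,
with missing parents imputable) decides the assignment; markers with no
passing model are removed as distorted, those with no parent-compatible
passing model as parent mismatches, and those with several as ambiguous.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genotypes import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING

logger = logging.getLogger(__name__)

__all__ = [
    "SegregationType",
    "SegregationAssessment",
    "SEGREGATION_TYPES",
    "classify_offspring",
    "test_segregation",
    "assign_segregation",
    "apply_segregation_filter",
]


@dataclass(frozen=True)
class SegregationType:
    name: str
    parent_pair: tuple[int | None, int | None]  # unordered; None = must be missing
    expected_classes: dict[int, int]  # genotype code -> ratio
    informative: bool

    @property
    def single_class(self) -> bool:
        return len(self.expected_classes) == 1


SEGREGATION_TYPES: dict[str, SegregationType] = {
    t.name: t
    for t in (
        SegregationType("AAxAA", (HOM_REF, HOM_REF), {HOM_REF: 1}, False),
        SegregationType("BBxBB", (HOM_ALT, HOM_ALT), {HOM_ALT: 1}, False),
        SegregationType("AAxBB", (HOM_REF, HOM_ALT), {HET: 1}, False),
        SegregationType("AAxAB", (HOM_REF, HET), {HOM_REF: 1, HET: 1}, True),
        SegregationType("BBxAB", (HOM_ALT, HET), {HOM_ALT: 1, HET: 1}, True),
        SegregationType("ABxAB", (HET, HET), {HOM_REF: 1, HET: 2, HOM_ALT: 1}, True),
        SegregationType("ABxMissing", (HET, None), {HOM_REF: 1, HOM_ALT: 1}, True),
    )
}


@dataclass
class TypeTestResult:
    chi2: float
    df: int
    p: float
    error_fraction: float
    passed: bool
    reason: str = ""


@dataclass
class SegregationAssessment:
    marker_id: str
    per_type: dict[str, TypeTestResult] = field(default_factory=dict)
    assigned_type: str | None = None
    action: str = "remove_distorted"
    corrected_parents: list[tuple[str, int]] = field(default_factory=list)
    silenced: list[str] = field(default_factory=list)


def classify_offspring(
    offspring_genotypes: np.ndarray, seg_type: SegregationType
) -> tuple[Counter, int]:
    """Count offspring genotypes per expected class plus incompatibles.

    Missing genotypes are excluded from both tallies.
    """
    g = np.asarray(offspring_genotypes)
    counts = Counter()
    incompatible = 0
    for code in (HOM_REF, HET, HOM_ALT):
        n = int((g == code).sum())
        if code in seg_type.expected_classes:
            counts[code] = n
        else:
            incompatible += n
    return counts, incompatible


def test_segregation(
    class_counts: Counter,
    incompatible_count: int,
    seg_type: SegregationType,
    max_error: float = 0.02,
    alpha: float = 0.005,
) -> TypeTestResult:
    """Goodness-of-fit test of one segregation model.

    ``error_fraction`` is incompatible / total-called.  Single-class models
    pass on the error criterion alone (chi-square undefined, df 0);
    multi-class models additionally require the chi-square p-value on the
    in-class counts (no continuity correction) to be >= ``alpha``.
    """
    n_in = sum(class_counts.values())
    total = n_in + incompatible_count
    if total == 0:
        return TypeTestResult(np.nan, 0, np.nan, np.nan, False, "no called offspring")
    err = incompatible_count / total
    err_ok = err <= max_error
    if seg_type.single_class:
        return TypeTestResult(np.nan, 0, np.nan, err, err_ok,
                              "" if err_ok else "error fraction")
    if n_in == 0:
        return TypeTestResult(np.nan, 0, np.nan, err, False, "no in-class offspring")
    ratios = np.array([seg_type.expected_classes[c] for c in sorted(seg_type.expected_classes)],
                      dtype=float)
    obs = np.array([class_counts.get(c, 0) for c in sorted(seg_type.expected_classes)],
                   dtype=float)
    exp = ratios / ratios.sum() * n_in
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(ratios) - 1
    p = float(stats.chi2.sf(chi2, df))
    passed = err_ok and p >= alpha
    reason = "" if passed else ("error fraction" if not err_ok else "chi2 rejected")
    return TypeTestResult(chi2, df, p, err, passed, reason)


def _parent_compatibility(
    gm: int, gf: int, seg_type: SegregationType
) -> tuple[bool, list[tuple[str, int]]]:
    """Check whether observed parent genotypes fit a model's parental pair.

    The pair is order-agnostic.  A missing parent can be imputed to the
    required genotype (recorded); ABxMissing instead *requires* exactly one
    called heterozygous parent and one missing parent.
    """
    a, b = seg_type.parent_pair
    if b is None:  # ABxMissing
        ok = (gm == HET and gf == MISSING) or (gf == HET and gm == MISSING)
        return ok, []
    best: list[tuple[str, int]] | None = None
    for x, y in ((a, b), (b, a)):
        if (gm == x or gm == MISSING) and (gf == y or gf == MISSING):
            imput = []
            if gm == MISSING:
                imput.append(("mother", x))
            if gf == MISSING:
                imput.append(("father", y))
            if best is None or len(imput) < len(best):
                best = imput
    return (best is not None), (best or [])


def assign_segregation(
    marker_id: str,
    mother_gt: int,
    father_gt: int,
    offspring_genotypes: np.ndarray,
    offspring_ids: list[str] | None = None,
    max_error: float = 0.02,
    alpha: float = 0.005,
) -> SegregationAssessment:
    """Test all seven models and produce a per-marker verdict."""
    g = np.asarray(offspring_genotypes)
    if offspring_ids is None:
        offspring_ids = [f"off{i}" for i in range(len(g))]
    a = SegregationAssessment(marker_id=marker_id)
    passing: list[str] = []
    for name, t in SEGREGATION_TYPES.items():
        counts, inc = classify_offspring(g, t)
        res = test_segregation(counts, inc, t, max_error, alpha)
        a.per_type[name] = res
        if res.passed:
            passing.append(name)
    if not passing:
        a.action = "remove_distorted"
        return a
    compatible: list[tuple[str, list[tuple[str, int]]]] = []
    for name in passing:
        ok, imput = _parent_compatibility(mother_gt, father_gt, SEGREGATION_TYPES[name])
        if ok:
            compatible.append((name, imput))
    if not compatible:
        a.action = "remove_parent_mismatch"
        return a
    if len(compatible) > 1:
        a.action = "remove_ambiguous"
        return a
    name, imput = compatible[0]
    t = SEGREGATION_TYPES[name]
    a.assigned_type = name
    a.corrected_parents = imput
    a.action = "retain" if t.informative else "remove_uninformative"
    bad = (g != MISSING) & ~np.isin(g, list(t.expected_classes))
    a.silenced = [offspring_ids[i] for i in np.flatnonzero(bad)]
    return a


def apply_segregation_filter(
    matrix: GenotypeMatrix,
    max_error: float = 0.02,
    alpha: float = 0.005,
) -> tuple[GenotypeMatrix, list[SegregationAssessment], dict]:
    """Run the segregation filter over a family matrix.

    Retained (informative, parent-compatible) markers have their
    incompatible offspring genotypes silenced and any imputed parent
    genotype written back; all other markers are removed.  The report
    counts markers per action class plus total silenced genotypes.
    """
    mothers = matrix.role_indices("mother")
    fathers = matrix.role_indices("father")
    off = matrix.role_indices("offspring")
    if len(off) == 0:
        raise ValueError("family matrix contains no offspring")
    if len(mothers) > 1 or len(fathers) > 1:
        raise ValueError("more than one mother or father in family")
    mi = int(mothers[0]) if len(mothers) else None
    fi = int(fathers[0]) if len(fathers) else None
    off_ids = [matrix.samples[j].sample_id for j in off]

    out = matrix.copy()
    assessments: list[SegregationAssessment] = []
    keep_rows: list[int] = []
    report = Counter()
    n_silenced = 0
    for i in range(matrix.n_markers):
        gm = int(matrix.genotypes[i, mi]) if mi is not None else MISSING
        gf = int(matrix.genotypes[i, fi]) if fi is not None else MISSING
        a = assign_segregation(
            matrix.markers[i].marker_id, gm, gf,
            matrix.genotypes[i, off], off_ids, max_error, alpha,
        )
        assessments.append(a)
        report[a.action] += 1
        if a.action == "retain":
            keep_rows.append(i)
            t = SEGREGATION_TYPES[a.assigned_type]
            bad = (out.genotypes[i, off] != MISSING) & ~np.isin(
                out.genotypes[i, off], list(t.expected_classes)
            )
            out.genotypes[i, off[bad]] = MISSING
            if out.depth is not None:
                out.depth[i, off[bad]] = 0
            n_silenced += int(bad.sum())
            for who, code in a.corrected_parents:
                j = mi if who == "mother" else fi
                if j is not None:
                    out.genotypes[i, j] = code
    summary = dict(report)
    summary["input"] = matrix.n_markers
    summary["n_silenced"] = n_silenced
    return out.take_markers(keep_rows), assessments, summary


def assessments_to_frame(assessments: list[SegregationAssessment]):
    """Flatten assessments into a tidy table (one row per marker)."""
    import pandas as pd

    rows = []
    for a in assessments:
        res = a.per_type.get(a.assigned_type) if a.assigned_type else None
        rows.append(
            {
                "marker_id": a.marker_id,
                "assigned_type": a.assigned_type or "",
                "chi2": res.chi2 if res else np.nan,
                "p": res.p if res else np.nan,
                "error_fraction": res.error_fraction if res else np.nan,
                "action": a.action,
                "corrected_parent": ";".join(
                    f"{w}={g}" for w, g in a.corrected_parents
                ),
                "n_silenced": len(a.silenced),
            }
        )
    return pd.DataFrame(rows)
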