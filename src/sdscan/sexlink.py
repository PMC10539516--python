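"""Five detection criteria for sex-linked markers, in XY and ZW orientation.

Methods 1, 2, 4 and 5 are genotype-frequency thresholds on SNPs; Method 3
is a presence/absence screen on whole RADtags.  For an XY scan the X
allele (the "reference allele" of Methods 4-5) is the major allele among
called female genotypes; ties are evaluated under both orientations and
hit if either passes.  A ZW scan applies the same criteria with the sexes
swapped.  All heterozygosity-based methods require a per-sex call rate of
at least ``min_sex_call_rate`` (default 60%).

The module exposes both a scalar per-marker API (``method1`` ..
``method5`` on :class:`GenotypeFreqs`) and a vectorized counting core
(:func:`count_hits`) reused by the permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING

__all__ = [
    "MethodThresholds",
    "GenotypeFreqs",
    "SexLinkCall",
    "compute_sex_genotype_freqs",
    "method1",
    "method2",
    "method3",
    "method4",
    "method5",
    "scan_sex_linkage",
    "count_hits",
    "prepare_scan_arrays",
]

SYSTEMS = ("XY", "ZW")
ALL_METHODS = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class MethodThresholds:
    """Cutoffs for Methods 1-5 (XY wording; ZW swaps sexes)."""

    min_sex_call_rate: float = 0.6  # inclusive, per sex, Methods 1/2/4/5
    m1_hom_sex_freq: float = 0.95   # X-allele frequency in females, strict >
    m1_het_sex_low: float = 0.4     # X-allele frequency band in males, inclusive
    m1_het_sex_high: float = 0.6
    m2_het_frac: float = 0.5        # fraction of males heterozygous, inclusive >=
    m3_presence_frac: float = 0.5   # fraction of males with the tag, inclusive >=
    m4_het_frac: float = 0.75       # strict >
    m4_hom_x_frac: float = 0.80     # females hom for X allele, strict >
    m4_het_hom_sex_frac: float = 0.20  # females het, strict <
    m4_hom_y_frac: float = 0.10     # females hom for Y allele, strict <
    m5_het_frac: float = 0.55       # strict >
    m5_hom_x_frac: float = 0.80     # strict >
    m5_het_hom_sex_frac: float = 0.20  # strict <


@dataclass
class GenotypeFreqs:
    """Per-sex genotype counts for one marker."""

    marker_id: str
    counts_m: tuple[int, int, int]  # (hom_ref, het, hom_alt) among called males
    counts_f: tuple[int, int, int]
    n_males: int  # total males in cohort
    n_females: int

    @property
    def n_called_m(self) -> int:
        return sum(self.counts_m)

    @property
    def n_called_f(self) -> int:
        return sum(self.counts_f)


@dataclass
class SexLinkCall:
    marker_id: str | None
    radtag_id: str
    system: str
    methods_hit: tuple[int, ...]


# ------------------------------------------------------------- vector core


def prepare_scan_arrays(matrix: GenotypeMatrix) -> dict:
    """Precompute indicator stacks for repeated (permuted) scans.

    Only samples with known sex are used.  Returns arrays keyed for
    :func:`count_hits`: a (3, m, s) genotype indicator stack, a (t, s) tag
    presence matrix, the boolean male mask and marker/tag bookkeeping.
    """
    sex = matrix.sexes
    use = np.flatnonzero((sex == "M") | (sex == "F"))
    if use.size == 0:
        raise ValueError("no sexed samples in matrix")
    sub = matrix.take_samples(use)
    if not ((sub.sexes == "M").any() and (sub.sexes == "F").any()):
        raise ValueError("cohort must contain both sexes")
    G = sub.genotypes
    ind = np.stack([(G == c) for c in (HOM_REF, HET, HOM_ALT)]).astype(np.float32)
    tags, pres = sub.tag_presence()
    return {
        "indicators": ind,                      # (3, m, s)
        "ind_flat": ind.reshape(3 * G.shape[0], G.shape[1]),
        "tag_presence": pres.astype(np.float32),
        "tag_ids": tags,
        "male_mask": sub.sexes == "M",
        "marker_ids": sub.marker_ids,
        "radtag_ids": [m.radtag_id for m in sub.markers],
        "matrix": sub,
    }


def _counts_for_mask(arrays: dict, male_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(3, m) genotype counts for males and females given a label mask."""
    m = male_mask.astype(np.float32)
    n_mark = arrays["indicators"].shape[1]
    cM = (arrays["ind_flat"] @ m).reshape(3, n_mark)
    total = arrays["indicators"].sum(axis=2) if "totals" not in arrays else arrays["totals"]
    arrays.setdefault("totals", total)
    cF = total - cM
    return cM, cF


def _xy_marker_hits(
    c_het_sex: np.ndarray,   # (3, m) genotype counts in the heterogametic-candidate sex
    c_hom_sex: np.ndarray,
    n_het_total: int,
    n_hom_total: int,
    thr: MethodThresholds,
    methods: Iterable[int],
) -> dict[int, np.ndarray]:
    """Boolean hit arrays for Methods 1/2/4/5 in one orientation of sexes."""
    nM = c_het_sex.sum(axis=0)
    nF = c_hom_sex.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        gate = (
            (nM / n_het_total >= thr.min_sex_call_rate)
            & (nF / n_hom_total >= thr.min_sex_call_rate)
            & (nM > 0)
            & (nF > 0)
        )
        het_m = np.where(nM > 0, c_het_sex[1] / nM, np.nan)
        het_f = np.where(nF > 0, c_hom_sex[1] / nF, np.nan)
        ref_f = 2 * c_hom_sex[0] + c_hom_sex[1]
        alt_f = c_hom_sex[1] + 2 * c_hom_sex[2]

        out: dict[int, np.ndarray] = {}
        if 2 in set(methods):
            out[2] = gate & (c_hom_sex[1] == 0) & (het_m >= thr.m2_het_frac)

        def oriented(x_is_ref: bool) -> dict[int, np.ndarray]:
            hx, hy = (0, 2) if x_is_ref else (2, 0)
            res: dict[int, np.ndarray] = {}
            xf_f = np.where(nF > 0, (2 * c_hom_sex[hx] + c_hom_sex[1]) / (2 * nF), np.nan)
            xf_m = np.where(nM > 0, (2 * c_het_sex[hx] + c_het_sex[1]) / (2 * nM), np.nan)
            homx_f = np.where(nF > 0, c_hom_sex[hx] / nF, np.nan)
            homy_f = np.where(nF > 0, c_hom_sex[hy] / nF, np.nan)
            if 1 in set(methods):
                res[1] = (
                    (xf_f > thr.m1_hom_sex_freq)
                    & (xf_m >= thr.m1_het_sex_low)
                    & (xf_m <= thr.m1_het_sex_high)
                )
            if 4 in set(methods):
                res[4] = (
                    (het_m > thr.m4_het_frac)
                    & (homx_f > thr.m4_hom_x_frac)
                    & (het_f < thr.m4_het_hom_sex_frac)
                    & (homy_f < thr.m4_hom_y_frac)
                )
            if 5 in set(methods):
                res[5] = (
                    (het_m > thr.m5_het_frac)
                    & (homx_f > thr.m5_hom_x_frac)
                    & (het_f < thr.m5_het_hom_sex_frac)
                    & (c_hom_sex[hy] == 0)
                )
            return res

        need_orient = {1, 4, 5} & set(methods)
        if need_orient:
            h_ref = oriented(True)
            h_alt = oriented(False)
            major_ref = ref_f > alt_f
            tie = ref_f == alt_f
            for k in need_orient:
                hit = np.where(major_ref, h_ref[k], h_alt[k])
                hit = hit | (tie & (h_ref[k] | h_alt[k]))
                out[k] = gate & np.nan_to_num(hit).astype(bool)
    return {k: np.nan_to_num(v).astype(bool) for k, v in out.items()}


def _tag_hits(
    pres_het: np.ndarray,  # per-tag presence count in the heterogametic-candidate sex
    pres_hom: np.ndarray,
    n_het_total: int,
    n_hom_total: int,
    thr: MethodThresholds,
) -> np.ndarray:
    return (pres_hom == 0) & (pres_het / n_het_total >= thr.m3_presence_frac)


def count_hits(
    arrays: dict,
    male_mask: np.ndarray,
    methods: Sequence[int] = ALL_METHODS,
    systems: Sequence[str] = SYSTEMS,
    thresholds: MethodThresholds | None = None,
    return_arrays: bool = False,
):
    """Hit counts (or boolean hit arrays) per (method, system) for a label mask."""
    thr = thresholds or MethodThresholds()
    cM, cF = _counts_for_mask(arrays, male_mask)
    n_m = int(male_mask.sum())
    n_f = int((~male_mask).sum())
    tagM = arrays["tag_presence"] @ male_mask.astype(np.float32)
    tagF = arrays["tag_presence"].sum(axis=1) - tagM
    out: dict[tuple[int, str], np.ndarray | int] = {}
    for system in systems:
        if system == "XY":
            het, hom, nh, no = cM, cF, n_m, n_f
            tag_h, tag_o, tnh = tagM, tagF, n_m
        else:
            het, hom, nh, no = cF, cM, n_f, n_m
            tag_h, tag_o, tnh = tagF, tagM, n_f
        snp_methods = [k for k in methods if k != 3]
        hits = _xy_marker_hits(het, hom, nh, no, thr, snp_methods)
        for k in snp_methods:
            out[(k, system)] = hits[k] if return_arrays else int(hits[k].sum())
        if 3 in methods:
            th = _tag_hits(tag_h, tag_o, tnh, no, thr)
            out[(3, system)] = th if return_arrays else int(th.sum())
    return out


# ------------------------------------------------------------- scalar API


def compute_sex_genotype_freqs(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker, per-sex genotype counts, frequencies and gate flag."""
    arrays = prepare_scan_arrays(matrix)
    male = arrays["male_mask"]
    cM, cF = _counts_for_mask(arrays, male)
    n_m, n_f = int(male.sum()), int((~male).sum())
    nM, nF = cM.sum(axis=0), cF.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = pd.DataFrame(
            {
                "marker_id": arrays["marker_ids"],
                "radtag_id": arrays["radtag_ids"],
                "n_called_m": nM.astype(int),
                "n_called_f": nF.astype(int),
                "call_rate_m": nM / n_m,
                "call_rate_f": nF / n_f,
                "freq_hom_ref_m": cM[0] / nM,
                "freq_het_m": cM[1] / nM,
                "freq_hom_alt_m": cM[2] / nM,
                "freq_hom_ref_f": cF[0] / nF,
                "freq_het_f": cF[1] / nF,
                "freq_hom_alt_f": cF[2] / nF,
            }
        )
    thr = MethodThresholds()
    df["passes_call_gate"] = (df.call_rate_m >= thr.min_sex_call_rate) & (
        df.call_rate_f >= thr.min_sex_call_rate
    )
    return df


def _freqs_to_arrays(freqs: GenotypeFreqs) -> dict:
    cM = np.array(freqs.counts_m, dtype=float).reshape(3, 1)
    cF = np.array(freqs.counts_f, dtype=float).reshape(3, 1)
    return {"cM": cM, "cF": cF}


def _scalar_hit(freqs: GenotypeFreqs, system: str, method: int,
                thresholds: MethodThresholds | None = None) -> bool:
    thr = thresholds or MethodThresholds()
    a = _freqs_to_arrays(freqs)
    if system == "XY":
        het, hom, nh, no = a["cM"], a["cF"], freqs.n_males, freqs.n_females
    else:
        het, hom, nh, no = a["cF"], a["cM"], freqs.n_females, freqs.n_males
    hits = _xy_marker_hits(het, hom, nh, no, thr, [method])
    return bool(hits[method][0])


def method1(freqs: GenotypeFreqs, system: str = "XY",
            thresholds: MethodThresholds | None = None) -> bool:
    """X (or Z) allele nearly fixed in the homogametic sex, balanced in the other."""
    return _scalar_hit(freqs, system, 1, thresholds)


def method2(freqs: GenotypeFreqs, system: str = "XY",
            thresholds: MethodThresholds | None = None) -> bool:
    """All homogametic-sex calls homozygous; >=50% heterogametic-sex calls het."""
    return _scalar_hit(freqs, system, 2, thresholds)


def method3(
    tag_presence: np.ndarray,
    sexes: np.ndarray,
    system: str = "XY",
    tag_ids: Sequence[str] | None = None,
    thresholds: MethodThresholds | None = None,
) -> list:
    """RADtags absent from every homogametic-sex sample yet present in >=50%
    of the heterogametic sex.  ``tag_presence`` is tags x samples boolean."""
    thr = thresholds or MethodThresholds()
    sexes = np.asarray(sexes)
    male = sexes == "M"
    female = sexes == "F"
    pres = np.asarray(tag_presence, dtype=float)
    pM = pres[:, male].sum(axis=1)
    pF = pres[:, female].sum(axis=1)
    if system == "XY":
        hit = _tag_hits(pM, pF, int(male.sum()), int(female.sum()), thr)
    else:
        hit = _tag_hits(pF, pM, int(female.sum()), int(male.sum()), thr)
    idx = np.flatnonzero(hit)
    if tag_ids is not None:
        return [tag_ids[i] for i in idx]
    return idx.tolist()


def method4(freqs: GenotypeFreqs, system: str = "XY",
            thresholds: MethodThresholds | None = None) -> bool:
    """Strong heterozygote excess in the heterogametic sex with tight
    homogametic-sex composition limits."""
    return _scalar_hit(freqs, system, 4, thresholds)


def method5(freqs: GenotypeFreqs, system: str = "XY",
            thresholds: MethodThresholds | None = None) -> bool:
    """Relaxed heterozygote excess but zero Y/W-homozygotes allowed in the
    homogametic sex."""
    return _scalar_hit(freqs, system, 5, thresholds)


# ---------------------------------------------------------------- full scan


def scan_sex_linkage(
    matrix: GenotypeMatrix,
    methods: Sequence[int] = ALL_METHODS,
    systems: Sequence[str] = SYSTEMS,
    thresholds: MethodThresholds | None = None,
) -> tuple[list[SexLinkCall], pd.DataFrame]:
    """Evaluate every marker/tag under both systems and all methods.

    Returns the individual calls plus a summary table with per
    (method, system) hit counts and deduplicated unique-marker and
    unique-RADtag totals per system.
    """
    arrays = prepare_scan_arrays(matrix)
    male = arrays["male_mask"]
    res = count_hits(arrays, male, methods, systems, thresholds, return_arrays=True)
    calls: list[SexLinkCall] = []
    summary_rows = []
    for system in systems:
        marker_methods: dict[int, tuple[int, ...]] = {}
        for k in methods:
            if k == 3:
                continue
            hit = res[(k, system)]
            for i in np.flatnonzero(hit):
                marker_methods.setdefault(i, ())
                marker_methods[i] += (k,)
            summary_rows.append({"method": k, "system": system, "n_hits": int(hit.sum())})
        for i, ms in sorted(marker_methods.items()):
            calls.append(
                SexLinkCall(
                    marker_id=arrays["marker_ids"][i],
                    radtag_id=arrays["radtag_ids"][i],
                    system=system,
                    methods_hit=tuple(sorted(ms)),
                )
            )
        tag_hit_ids: list[str] = []
        if 3 in methods:
            hit3 = res[(3, system)]
            tag_hit_ids = [arrays["tag_ids"][i] for i in np.flatnonzero(hit3)]
            for t in tag_hit_ids:
                calls.append(SexLinkCall(None, t, system, (3,)))
            summary_rows.append(
                {"method": 3, "system": system, "n_hits": len(tag_hit_ids)}
            )
        uniq_markers = len(marker_methods)
        uniq_tags = len(
            {arrays["radtag_ids"][i] for i in marker_methods} | set(tag_hit_ids)
        )
        summary_rows.append(
            {"method": "unique_markers", "system": system, "n_hits": uniq_markers}
        )
        summary_rows.append(
            {"method": "unique_radtags", "system": system, "n_hits": uniq_tags}
        )
    return calls, pd.DataFrame(summary_rows)


def calls_to_frame(calls: list[SexLinkCall]) -> pd.DataFrame:
    rows = [
        {
            "marker_id": c.marker_id or "",
            "radtag_id": c.radtag_id,
            "system": c.system,
            "methods_hit": ",".join(map(str, c.methods_hit)),
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=["marker_id", "radtag_id", "system", "methods_hit"])
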