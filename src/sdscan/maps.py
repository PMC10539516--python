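"""Linkage-map utilities: cleanup, sex-averaged merging, summaries,
genome coverage and marker placement.

Maps are exchanged as TSV tables with columns ``lg``, ``marker_id``,
``radtag_id``, ``pos_cM``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LinkageMap",
    "read_map",
    "write_map",
    "clean_map",
    "merge_sex_maps",
    "summarize_map",
    "genome_coverage",
    "locate_markers",
]

MAP_COLUMNS = ["lg", "marker_id", "radtag_id", "pos_cM"]


@dataclass
class LinkageMap:
    """Per-linkage-group ordered marker positions in centiMorgans."""

    sex_label: str  # male | female | averaged
    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        missing = set(MAP_COLUMNS) - set(t.columns)
        if missing:
            raise ValueError(f"map table lacks columns {sorted(missing)}")
        t["pos_cM"] = t["pos_cM"].astype(float)
        if (t["pos_cM"] < 0).any():
            raise ValueError("negative map positions")
        if t["marker_id"].duplicated().any():
            raise ValueError("duplicate marker ids in map")
        t = t.sort_values(["lg", "pos_cM", "marker_id"], kind="mergesort")
        self.table = t.reset_index(drop=True)[MAP_COLUMNS]

    @property
    def groups(self) -> dict[str, pd.DataFrame]:
        return {str(lg): sub.reset_index(drop=True) for lg, sub in self.table.groupby("lg", sort=True)}

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def lg_ids(self) -> list[str]:
        return sorted(self.table["lg"].astype(str).unique())


def read_map(path: str | Path, sex_label: str = "averaged") -> LinkageMap:
    return LinkageMap(sex_label=sex_label, table=pd.read_csv(path, sep="\t", dtype={"lg": str}))


def write_map(lmap: LinkageMap, path: str | Path) -> None:
    lmap.table.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ cleanup


def clean_map(lmap: LinkageMap, gap_threshold_cM: float = 10.0) -> tuple[LinkageMap, list[dict]]:
    """Remove impossible and dangling RADtags.

    (a) RADtags whose markers span more than one linkage group are removed
    entirely.  (b) Iteratively, a RADtag whose markers occupy a terminal
    segment of a group separated from the remainder by a gap larger than
    ``gap_threshold_cM`` is removed; positions are re-anchored to start at
    zero after each removal.
    """
    t = lmap.table.copy()
    removals: list[dict] = []

    span = t.groupby("radtag_id")["lg"].nunique()
    multi = set(span[span > 1].index)
    if multi:
        for tag in sorted(multi):
            removals.append({"radtag_id": tag, "reason": "multi_lg"})
        t = t[~t["radtag_id"].isin(multi)]

    changed = True
    while changed:
        changed = False
        parts = []
        for lg, sub in t.groupby("lg", sort=True):
            sub = sub.sort_values(["pos_cM", "marker_id"], kind="mergesort").reset_index(drop=True)
            for end in ("high", "low"):
                if len(sub) < 2:
                    break
                order = sub if end == "low" else sub.iloc[::-1].reset_index(drop=True)
                tag = order.loc[0, "radtag_id"]
                k = 0
                while k < len(order) and order.loc[k, "radtag_id"] == tag:
                    k += 1
                if k >= len(order):
                    continue  # whole group is one tag
                gap = abs(order.loc[k, "pos_cM"] - order.loc[k - 1, "pos_cM"])
                if gap > gap_threshold_cM:
                    removals.append(
                        {"radtag_id": tag, "reason": f"terminal_gap_{end}", "lg": lg,
                         "gap_cM": float(gap)}
                    )
                    sub = sub[sub["radtag_id"] != tag].reset_index(drop=True)
                    changed = True
            if len(sub):
                sub["pos_cM"] = sub["pos_cM"] - sub["pos_cM"].min()
            parts.append(sub)
        t = pd.concat(parts, ignore_index=True) if parts else t.iloc[0:0]
    return LinkageMap(sex_label=lmap.sex_label, table=t), removals


# -------------------------------------------------------------------- merge


def _interp_extrap(p: np.ndarray, s: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Piecewise-linear map of positions ``p`` through anchors (s -> t),
    with linear extrapolation from the two nearest anchors outside."""
    order = np.argsort(s, kind="mergesort")
    s, t = s[order], t[order]
    # merge duplicate source positions (average targets)
    su, inv = np.unique(s, return_inverse=True)
    tu = np.zeros_like(su, dtype=float)
    cnt = np.zeros_like(su, dtype=float)
    np.add.at(tu, inv, t)
    np.add.at(cnt, inv, 1)
    tu /= cnt
    if len(su) == 1:
        return np.full_like(p, tu[0], dtype=float)
    out = np.interp(p, su, tu)
    lo = p < su[0]
    hi = p > su[-1]
    slope_lo = (tu[1] - tu[0]) / (su[1] - su[0])
    slope_hi = (tu[-1] - tu[-2]) / (su[-1] - su[-2])
    out[lo] = tu[0] + (p[lo] - su[0]) * slope_lo
    out[hi] = tu[-1] + (p[hi] - su[-1]) * slope_hi
    return out


def merge_sex_maps(male_map: LinkageMap, female_map: LinkageMap) -> LinkageMap:
    """Sex-averaged map: shared markers at the mean of their two positions.

    Markers present on only one map are placed by piecewise-linear
    interpolation between flanking shared anchors in their source map's
    coordinates (terminal markers by extrapolation from the two nearest
    anchors, clipped at zero).  Linkage groups with fewer than two shared
    anchors pass through from the female map with a warning.
    """
    rows = []
    m_groups = male_map.groups
    f_groups = female_map.groups
    for lg in sorted(set(m_groups) | set(f_groups)):
        msub = m_groups.get(lg)
        fsub = f_groups.get(lg)
        if msub is None or fsub is None:
            src = fsub if fsub is not None else msub
            logger.warning("LG %s present on one map only; passed through", lg)
            rows.append(src.assign(lg=lg))
            continue
        mpos = dict(zip(msub["marker_id"], msub["pos_cM"]))
        fpos = dict(zip(fsub["marker_id"], fsub["pos_cM"]))
        shared = sorted(set(mpos) & set(fpos))
        if len(shared) < 2:
            logger.warning(
                "LG %s has %d shared markers; female map passed through", lg, len(shared)
            )
            rows.append(fsub.assign(lg=lg))
            continue
        s_m = np.array([mpos[k] for k in shared])
        s_f = np.array([fpos[k] for k in shared])
        avg = (s_m + s_f) / 2.0
        placed = {k: a for k, a in zip(shared, avg)}
        male_only = [k for k in mpos if k not in fpos]
        if male_only:
            p = np.array([mpos[k] for k in male_only])
            for k, v in zip(male_only, _interp_extrap(p, s_m, avg)):
                placed[k] = v
        female_only = [k for k in fpos if k not in mpos]
        if female_only:
            p = np.array([fpos[k] for k in female_only])
            for k, v in zip(female_only, _interp_extrap(p, s_f, avg)):
                placed[k] = v
        tag_of = dict(zip(msub["marker_id"], msub["radtag_id"]))
        tag_of.update(zip(fsub["marker_id"], fsub["radtag_id"]))
        rows.append(
            pd.DataFrame(
                {
                    "lg": lg,
                    "marker_id": list(placed),
                    "radtag_id": [tag_of[k] for k in placed],
                    "pos_cM": np.maximum(0.0, np.array(list(placed.values()))),
                }
            )
        )
    return LinkageMap(sex_label="averaged", table=pd.concat(rows, ignore_index=True))


# ----------------------------------------------------------------- summary


def _lg_metrics(sub: pd.DataFrame) -> dict:
    pos = np.sort(sub["pos_cM"].to_numpy())
    uniq = np.unique(pos)
    length = float(pos.max() - pos.min()) if len(pos) else 0.0
    gaps = np.diff(uniq)
    return {
        "n_snps": len(pos),
        "n_unique_positions": len(uniq),
        "length_cM": length,
        "nonzero_interval_cM": float(gaps.mean()) if len(gaps) else np.nan,
    }


def summarize_map(
    male: LinkageMap | None = None,
    female: LinkageMap | None = None,
    averaged: LinkageMap | None = None,
) -> pd.DataFrame:
    """Per-LG and map-level summary metrics.

    Rows are linkage groups plus ``MapAvg`` (unweighted per-LG means) and
    ``Total`` (sums; the F:M ratio on the Total row is the ratio of total
    lengths, on MapAvg the mean of per-LG ratios).  The two map-level F:M
    variants are also exposed as ``DataFrame.attrs['fm_ratio_total']`` and
    ``attrs['fm_ratio_mean']``.
    """
    maps = {"male": male, "female": female, "averaged": averaged}
    maps = {k: v for k, v in maps.items() if v is not None}
    if not maps:
        raise ValueError("provide at least one map")
    lgs = sorted({lg for m in maps.values() for lg in m.lg_ids()})
    rows = {}
    for lg in lgs:
        row: dict[str, float] = {}
        for label, m in maps.items():
            sub = m.table[m.table["lg"].astype(str) == lg]
            if len(sub) == 0:
                continue
            for k, v in _lg_metrics(sub).items():
                row[f"{label}_{k}"] = v
        rows[lg] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "lg"

    if male is not None and female is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            df["fm_ratio"] = df["female_length_cM"] / df["male_length_cM"]

    mapavg = df.mean(axis=0, skipna=True)
    total = pd.Series(dtype=float)
    for c in df.columns:
        if c.endswith(("n_snps", "n_unique_positions", "length_cM")):
            total[c] = df[c].sum(skipna=True)
    fm_total = np.nan
    if male is not None and female is not None:
        fm_total = float(total["female_length_cM"] / total["male_length_cM"])
        total["fm_ratio"] = fm_total
    out = pd.concat(
        [df, mapavg.to_frame("MapAvg").T, total.to_frame("Total").T]
    )
    out.index.name = "lg"
    if male is not None and female is not None:
        out.attrs["fm_ratio_total"] = fm_total
        out.attrs["fm_ratio_mean"] = float(df["fm_ratio"].mean(skipna=True))
    return out


def genome_coverage(d: float, n: int, L: float) -> float:
    """Expected genome fraction within ``d`` cM of a marker: 1 - e^(-2dn/L)."""
    if L <= 0:
        raise ValueError("map length L must be positive")
    if d < 0 or n < 0:
        raise ValueError("d and n must be non-negative")
    return float(1.0 - np.exp(-2.0 * d * n / L))


def locate_markers(lmap: LinkageMap, marker_ids) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resolve query markers to (LG, position); unplaced ids are flagged.

    The second return value summarizes per-LG hit counts and the cM span
    of hits.
    """
    pos = lmap.table.set_index("marker_id")
    rows = []
    for mid in marker_ids:
        if mid in pos.index:
            r = pos.loc[mid]
            rows.append({"marker_id": mid, "lg": r["lg"], "pos_cM": float(r["pos_cM"]),
                         "placed": True})
        else:
            rows.append({"marker_id": mid, "lg": "", "pos_cM": np.nan, "placed": False})
    table = pd.DataFrame(rows, columns=["marker_id", "lg", "pos_cM", "placed"])
    hits = table[table["placed"]]
    if len(hits):
        summary = (
            hits.groupby("lg")["pos_cM"]
            .agg(n_hits="count", span_min="min", span_max="max")
            .reset_index()
        )
        summary["span_cM"] = summary["span_max"] - summary["span_min"]
    else:
        summary = pd.DataFrame(columns=["lg", "n_hits", "span_min", "span_max", "span_cM"])
    return table, summary
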