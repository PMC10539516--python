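"""Synthetic genotype data with known truth.

Two generators mirror the study designs the pipeline targets:

* an F1 mapping family (two parents, many offspring) with markers on a
  fixed number of linkage groups, sex-specific recombination (male
  crossovers depleted from the centre of each group, female crossovers
  even) and injected genotyping error/missingness;
* an independent cohort of sexed adults segregating an XY or ZW
  sex-determining locus with distance-decaying linkage and optional
  heterogametic-sex-specific RADtags.

Everything is driven by one ``numpy`` generator seeded from
``SimConfig.seed``: same seed, same bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, Marker, SampleMeta, MISSING

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_parent_haplotypes",
    "simulate_f1_family",
    "simulate_sexed_cohort",
    "inject_errors",
]


@dataclass
class SimConfig:
    # map architecture
    n_lgs: int = 13
    markers_per_lg: int = 100
    markers_per_tag: int = 2
    female_lg_length_cM: float | Sequence[float] = 137.0
    male_lg_length_cM: float | Sequence[float] = 106.2
    male_central_weight: float = 0.1  # crossover mass on the central 50% of a LG

    # sex system (cohort)
    sex_system: str = "XY"  # XY | ZW | none
    sd_lg: int = 6
    sd_position_cM: float = 60.0
    sd_region_markers: int = 20
    linkage_decay_per_cM: float = 0.005
    n_sex_specific_tags: int = 0

    # cohort / family sizes
    n_offspring: int = 315
    n_males: int = 19
    n_females: int = 19

    # population allele frequencies (Beta draw per marker)
    allele_freq_beta: tuple[float, float] = (1.0, 1.0)

    # noise
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0
    depth_mean: float | None = None  # None -> no depth matrix
    depth_dispersion: float = 5.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.sex_system not in ("XY", "ZW", "none"):
            raise ValueError(f"bad sex_system {self.sex_system!r}")
        if self.sex_system != "none" and not (1 <= self.sd_lg <= self.n_lgs):
            raise ValueError("sd_lg must be in [1, n_lgs]")
        for r in (self.genotype_error_rate, self.missing_rate,
                  self.linkage_decay_per_cM, self.male_central_weight):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0,1]")
        for L in np.atleast_1d(self.female_lg_length_cM):
            if L <= 0:
                raise ValueError("map lengths must be positive")

    def female_lengths(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.female_lg_length_cM, dtype=float), (self.n_lgs,)
        ).copy()

    def male_lengths(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.male_lg_length_cM, dtype=float), (self.n_lgs,)
        ).copy()


@dataclass
class SimTruth:
    """Ground truth attached to a simulated matrix."""

    marker_map: pd.DataFrame
    true_sex: dict[str, str] = field(default_factory=dict)
    sd_lg: int | None = None
    sd_position_cM: float | None = None
    seg_types: pd.Series | None = None
    error_coords: set[tuple[int, int]] = field(default_factory=set)
    missing_coords: set[tuple[int, int]] = field(default_factory=set)
    crossovers: list[dict] | None = None
    sex_specific_tags: list[str] = field(default_factory=list)

    def linkage_map(self, sex: str):
        """Build a true LinkageMap (``male``/``female``) from the marker map."""
        from .maps import LinkageMap

        col = {"male": "male_cM", "female": "female_cM"}[sex]
        rows = []
        for _, r in self.marker_map.iterrows():
            rows.append(
                {
                    "lg": f"LG{int(r.lg)}",
                    "marker_id": r.marker_id,
                    "radtag_id": r.radtag_id,
                    "pos_cM": float(r[col]),
                }
            )
        return LinkageMap(sex_label=sex, table=pd.DataFrame(rows))


# ------------------------------------------------------------------ map


def _male_position_cdf(u: np.ndarray, central_weight: float) -> np.ndarray:
    """CDF of the male crossover-position density on the unit interval.

    Mass ``central_weight`` sits on the central 50% [0.25, 0.75]; the rest
    is split evenly between the two terminal quarters.
    """
    w = central_weight
    tail = (1.0 - w) / 2.0
    out = np.empty_like(u, dtype=float)
    lo = u < 0.25
    mid = (u >= 0.25) & (u <= 0.75)
    hi = u > 0.75
    out[lo] = u[lo] / 0.25 * tail
    out[mid] = tail + (u[mid] - 0.25) / 0.5 * w
    out[hi] = tail + w + (u[hi] - 0.75) / 0.25 * tail
    return out


def _sample_male_positions(rng: np.random.Generator, k: int, central_weight: float) -> np.ndarray:
    """Inverse-CDF draws from the male crossover density (unit coordinates)."""
    w = central_weight
    tail = (1.0 - w) / 2.0
    r = rng.random(k)
    out = np.empty(k)
    lo = r < tail
    mid = (r >= tail) & (r <= tail + w)
    hi = r > tail + w
    out[lo] = r[lo] / tail * 0.25 if tail > 0 else 0.0
    out[mid] = 0.25 + (r[mid] - tail) / w * 0.5 if w > 0 else 0.25
    out[hi] = 0.75 + (r[hi] - tail - w) / tail * 0.25 if tail > 0 else 0.75
    return out


def _build_marker_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    Lf, Lm = config.female_lengths(), config.male_lengths()
    a, b = config.allele_freq_beta
    rows = []
    tag_counter = 0
    for lg in range(1, config.n_lgs + 1):
        n = config.markers_per_lg
        u = np.sort(rng.random(n))
        female = u * Lf[lg - 1]
        male = _male_position_cdf(u, config.male_central_weight) * Lm[lg - 1]
        p_alt = rng.beta(a, b, size=n)
        for i in range(n):
            if i % config.markers_per_tag == 0:
                tag_counter += 1
            tag = f"tag{tag_counter:05d}"
            offset = i % config.markers_per_tag
            rows.append(
                {
                    "marker_id": f"{tag}_{offset}",
                    "radtag_id": tag,
                    "snp_offset": offset,
                    "lg": lg,
                    "u": u[i],
                    "female_cM": female[i],
                    "male_cM": male[i],
                    "p_alt": p_alt[i],
                    "is_sd_region": False,
                    "sd_distance_cM": np.nan,
                }
            )
    columns = [
        "marker_id", "radtag_id", "snp_offset", "lg", "u",
        "female_cM", "male_cM", "p_alt", "is_sd_region", "sd_distance_cM",
    ]
    df = pd.DataFrame(rows, columns=columns)
    if config.sex_system != "none" and len(df):
        on_lg = df.index[df.lg == config.sd_lg]
        dist = (df.loc[on_lg, "female_cM"] - config.sd_position_cM).abs()
        region = dist.nsmallest(min(config.sd_region_markers, len(on_lg))).index
        df.loc[region, "is_sd_region"] = True
        df.loc[on_lg, "sd_distance_cM"] = dist
        # the sex-specific allele exists only on the Y/W haplotype
        df.loc[region, "p_alt"] = 0.0
    return df


def _markers_from_map(map_df: pd.DataFrame) -> list[Marker]:
    mono = (
        map_df["monomorphic"].fillna(False).astype(bool)
        if "monomorphic" in map_df.columns
        else pd.Series(False, index=map_df.index)
    )
    return [
        Marker(
            marker_id=r.marker_id,
            radtag_id=r.radtag_id,
            snp_offset=int(r.snp_offset),
            ref_allele="A",
            alt_allele=None if mono.loc[i] else "C",
            chrom=f"LG{int(r.lg)}",
        )
        for i, r in zip(map_df.index, map_df.itertuples())
    ]


def simulate_parent_haplotypes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw the marker map and four phased parental haplotypes.

    Returns ``(marker_map, haplotypes)`` where ``haplotypes`` has shape
    (4, n_markers): rows 0-1 are the maternal pair, 2-3 the paternal pair,
    entries are alternate-allele indicators.
    """
    rng = rng or np.random.default_rng(config.seed)
    map_df = _build_marker_map(config, rng)
    n = len(map_df)
    haps = (rng.random((4, n)) < map_df["p_alt"].to_numpy()).astype(np.int8)
    return map_df, haps


def _gamete(
    rng: np.random.Generator,
    haps: np.ndarray,  # (2, n_markers) for this parent
    map_df: pd.DataFrame,
    lengths: np.ndarray,
    male: bool,
    central_weight: float,
    xover_log: list | None = None,
    meiosis_label: tuple | None = None,
) -> np.ndarray:
    out = np.empty(haps.shape[1], dtype=np.int8)
    for lg in map_df["lg"].unique():
        idx = np.flatnonzero((map_df["lg"] == lg).to_numpy())
        u = map_df["u"].to_numpy()[idx]
        L = lengths[int(lg) - 1]
        k = rng.poisson(L / 100.0)
        if k > 0:
            if male:
                xs = np.sort(_sample_male_positions(rng, k, central_weight))
            else:
                xs = np.sort(rng.random(k))
        else:
            xs = np.empty(0)
        start = rng.integers(2)
        hap_idx = (start + np.searchsorted(xs, u)) % 2
        out[idx] = haps[hap_idx, idx]
        if xover_log is not None and meiosis_label is not None:
            xover_log.append(
                {
                    "offspring": meiosis_label[0],
                    "parent": meiosis_label[1],
                    "lg": int(lg),
                    "positions_u": xs.tolist(),
                }
            )
    return out


def simulate_f1_family(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate two parents and ``n_offspring`` F1 progeny."""
    rng = np.random.default_rng(config.seed)
    map_df, haps = simulate_parent_haplotypes(config, rng)
    n = len(map_df)
    Lf, Lm = config.female_lengths(), config.male_lengths()

    samples = [
        SampleMeta("mother", role="mother", sex="F"),
        SampleMeta("father", role="father", sex="M"),
    ]
    genos = np.empty((n, 2 + config.n_offspring), dtype=np.int8)
    genos[:, 0] = haps[0] + haps[1]
    genos[:, 1] = haps[2] + haps[3]
    xovers: list[dict] = []
    for o in range(config.n_offspring):
        sid = f"off{o + 1:04d}"
        samples.append(SampleMeta(sid, role="offspring", sex="unknown"))
        mat = _gamete(rng, haps[0:2], map_df, Lf, False, config.male_central_weight,
                      xovers, (sid, "mother"))
        pat = _gamete(rng, haps[2:4], map_df, Lm, True, config.male_central_weight,
                      xovers, (sid, "father"))
        genos[:, 2 + o] = mat + pat

    seg = _true_segregation_types(genos[:, 0], genos[:, 1])
    matrix = GenotypeMatrix(
        markers=_markers_from_map(map_df), samples=samples, genotypes=genos
    )
    matrix, err, miss = inject_errors(
        matrix, config.genotype_error_rate, config.missing_rate, rng=rng
    )
    miss |= _attach_depth(matrix, config, rng)
    truth = SimTruth(
        marker_map=map_df,
        true_sex={"mother": "F", "father": "M"},
        seg_types=pd.Series(seg, index=matrix.marker_ids, name="seg_type"),
        error_coords=err - miss,
        missing_coords=miss,
        crossovers=xovers,
    )
    return matrix, truth


def _true_segregation_types(gm: np.ndarray, gf: np.ndarray) -> list[str]:
    names = []
    for a, b in zip(gm, gf):
        pair = tuple(sorted((int(a), int(b))))
        names.append(
            {
                (0, 0): "AAxAA",
                (2, 2): "BBxBB",
                (0, 2): "AAxBB",
                (0, 1): "AAxAB",
                (1, 2): "BBxAB",
                (1, 1): "ABxAB",
            }[pair]
        )
    return names


def simulate_sexed_cohort(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate an adult cohort of ``n_males`` + ``n_females``.

    Under ``XY`` each male carries one population X haplotype plus a Y
    haplotype holding the alternate allele across the sex-determining
    region; each region allele independently reverts to a population draw
    with probability ``min(1, linkage_decay_per_cM * distance)``.  ``ZW``
    swaps the sexes.  ``none`` draws everyone from population frequencies.
    """
    rng = np.random.default_rng(config.seed)
    map_df = _build_marker_map(config, rng)
    n = len(map_df)
    p_alt = map_df["p_alt"].to_numpy()
    region = map_df["is_sd_region"].to_numpy()
    dist = np.nan_to_num(map_df["sd_distance_cM"].to_numpy(), nan=0.0)
    revert_p = np.minimum(1.0, config.linkage_decay_per_cM * dist)

    sex_of = ["M"] * config.n_males + ["F"] * config.n_females
    samples = [
        SampleMeta(f"adult{i + 1:03d}", role="adult", sex=s)
        for i, s in enumerate(sex_of)
    ]
    het_sex = {"XY": "M", "ZW": "F"}.get(config.sex_system)

    genos = np.empty((n, len(samples)), dtype=np.int8)
    for j, s in enumerate(samples):
        h1 = (rng.random(n) < p_alt).astype(np.int8)
        h2 = (rng.random(n) < p_alt).astype(np.int8)
        if het_sex is not None and s.sex == het_sex:
            # h2 becomes the Y (or W) haplotype
            y = np.ones(region.sum(), dtype=np.int8)
            revert = rng.random(region.sum()) < revert_p[region]
            y[revert] = (rng.random(int(revert.sum())) < p_alt[region][revert]).astype(np.int8)
            h2[region] = y
        genos[:, j] = h1 + h2

    markers = _markers_from_map(map_df)
    full_map = map_df

    # heterogametic-sex-specific RADtags: monomorphic markers present
    # (called) only in the heterogametic sex
    sex_tags: list[str] = []
    if het_sex is not None and config.n_sex_specific_tags > 0:
        extra_rows = []
        extra_geno = []
        is_het_sex = np.array([s.sex == het_sex for s in samples])
        for t in range(config.n_sex_specific_tags):
            tag = f"sextag{t + 1:03d}"
            sex_tags.append(tag)
            extra_rows.append(
                {
                    "marker_id": f"{tag}_0",
                    "radtag_id": tag,
                    "snp_offset": 0,
                    "lg": config.sd_lg,
                    "u": np.nan,
                    "female_cM": config.sd_position_cM,
                    "male_cM": np.nan,
                    "p_alt": 0.0,
                    "is_sd_region": True,
                    "sd_distance_cM": 0.0,
                    "monomorphic": True,
                }
            )
            row = np.where(is_het_sex, 0, MISSING).astype(np.int8)
            extra_geno.append(row)
        extra_df = pd.DataFrame(extra_rows)
        full_map = pd.concat([map_df, extra_df], ignore_index=True)
        markers += _markers_from_map(extra_df)
        genos = np.vstack([genos, np.array(extra_geno, dtype=np.int8)])

    matrix = GenotypeMatrix(markers=markers, samples=samples, genotypes=genos)
    matrix, err, miss = inject_errors(
        matrix, config.genotype_error_rate, config.missing_rate, rng=rng
    )
    miss |= _attach_depth(matrix, config, rng)
    truth = SimTruth(
        marker_map=full_map,
        true_sex={s.sample_id: s.sex for s in samples},
        sd_lg=config.sd_lg if config.sex_system != "none" else None,
        sd_position_cM=config.sd_position_cM if config.sex_system != "none" else None,
        error_coords=err - miss,
        missing_coords=miss,
        sex_specific_tags=sex_tags,
    )
    return matrix, truth


def inject_errors(
    matrix: GenotypeMatrix,
    genotype_error_rate: float,
    missing_rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, set[tuple[int, int]], set[tuple[int, int]]]:
    """Flip called genotypes at random, then mask calls at random.

    Each called genotype is independently flipped to a uniformly chosen
    *different* code with probability ``genotype_error_rate``, then set
    missing with probability ``missing_rate``.  Returns the new matrix and
    the (disjoint) sets of surviving error coordinates and newly missing
    coordinates, both as (marker_index, sample_index).
    """
    if not (0 <= genotype_error_rate <= 1 and 0 <= missing_rate <= 1):
        raise ValueError("rates must be in [0,1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = matrix.copy()
    called = out.genotypes != MISSING
    flip = called & (rng.random(out.genotypes.shape) < genotype_error_rate)
    if flip.any():
        shift = rng.integers(1, 3, size=int(flip.sum()))
        out.genotypes[flip] = (out.genotypes[flip] + shift) % 3
    mask = called & (rng.random(out.genotypes.shape) < missing_rate)
    out.genotypes[mask] = MISSING
    if out.depth is not None:
        out.depth[mask] = 0
    err = set(map(tuple, np.argwhere(flip & ~mask)))
    miss = set(map(tuple, np.argwhere(mask)))
    return out, err, miss


def _attach_depth(
    matrix: GenotypeMatrix, config: SimConfig, rng: np.random.Generator
) -> set[tuple[int, int]]:
    """Draw per-call negative-binomial depth in place; depth 0 forces missing.

    Returns coordinates newly set missing because of zero depth.
    """
    if config.depth_mean is None:
        return set()
    r = config.depth_dispersion
    p = r / (r + config.depth_mean)
    depth = rng.negative_binomial(r, p, size=matrix.genotypes.shape).astype(np.int32)
    depth[matrix.genotypes == MISSING] = 0
    zero = (depth == 0) & (matrix.genotypes != MISSING)
    matrix.genotypes[zero] = MISSING
    matrix.depth = depth
    return set(map(tuple, np.argwhere(zero)))
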