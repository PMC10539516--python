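"""Genotype matrices: VCF/TSV input-output and generic marker/sample filters.

Genotypes are coded on a bi-allelic A/B alphabet as small integers:
``0`` = homozygous reference (AA), ``1`` = heterozygous (AB), ``2`` =
homozygous alternate (BB) and ``-1`` = missing.  Depth, when present, is a
parallel non-negative integer matrix with the invariant *missing genotype
iff depth 0*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

CODE_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}

ROLES = ("mother", "father", "offspring", "adult")
SEXES = ("M", "F", "unknown")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sample."""

    sample_id: str
    role: str = "adult"
    sex: str = "unknown"
    replicate_group: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for sample {self.sample_id}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r} for sample {self.sample_id}")


@dataclass(frozen=True)
class Marker:
    """One SNP (or monomorphic site) within a RADtag.

    ``alt_allele`` is ``None`` for monomorphic markers, which are retained in
    the pipeline because they can represent Y- or W-specific tags.
    """

    marker_id: str
    radtag_id: str
    snp_offset: int = 0
    ref_allele: str = "A"
    alt_allele: str | None = "C"
    chrom: str = "UN"

    @property
    def monomorphic(self) -> bool:
        return self.alt_allele is None


@dataclass
class GenotypeMatrix:
    """Markers x samples genotype codes with optional per-call depth."""

    markers: list[Marker]
    samples: list[SampleMeta]
    genotypes: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.markers), len(self.samples)):
            raise ValueError(
                f"genotype shape {self.genotypes.shape} does not match "
                f"{len(self.markers)} markers x {len(self.samples)} samples"
            )
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=np.int32)
            if self.depth.shape != self.genotypes.shape:
                raise ValueError("depth shape does not match genotype shape")
            if (self.depth < 0).any():
                raise ValueError("negative depth")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        mids = [m.marker_id for m in self.markers]
        if len(set(mids)) != len(mids):
            raise ValueError("duplicate marker ids")

    # ---------------------------------------------------------------- basics
    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def sexes(self) -> np.ndarray:
        return np.array([s.sex for s in self.samples])

    @property
    def roles(self) -> np.ndarray:
        return np.array([s.role for s in self.samples])

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            markers=list(self.markers),
            samples=list(self.samples),
            genotypes=self.genotypes.copy(),
            depth=None if self.depth is None else self.depth.copy(),
        )

    def take_markers(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            markers=[self.markers[i] for i in idx],
            samples=list(self.samples),
            genotypes=self.genotypes[idx, :],
            depth=None if self.depth is None else self.depth[idx, :],
        )

    def take_samples(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            markers=list(self.markers),
            samples=[self.samples[i] for i in idx],
            genotypes=self.genotypes[:, idx],
            depth=None if self.depth is None else self.depth[:, idx],
        )

    # ------------------------------------------------------------- summaries
    def call_rate(self) -> np.ndarray:
        """Per-marker fraction of non-missing genotypes."""
        if self.n_samples == 0:
            return np.zeros(self.n_markers)
        return (self.genotypes != MISSING).mean(axis=1)

    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency over called genotypes only.

        Monomorphic markers have MAF 0 by definition.
        """
        called = self.genotypes != MISSING
        n_called = called.sum(axis=1)
        alt = np.where(called, self.genotypes, 0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_alt = alt / (2.0 * n_called)
        f_alt = np.where(n_called > 0, f_alt, 0.0)
        return np.minimum(f_alt, 1.0 - f_alt)

    def missing_fraction_per_sample(self) -> np.ndarray:
        if self.n_markers == 0:
            return np.zeros(self.n_samples)
        return (self.genotypes == MISSING).mean(axis=0)

    # ------------------------------------------------------------------ tags
    @property
    def tag_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.markers:
            seen.setdefault(m.radtag_id, None)
        return list(seen)

    def tag_presence(self) -> tuple[list[str], np.ndarray]:
        """Return (tag ids, tags x samples boolean presence matrix).

        A tag is present in a sample iff any of its markers has a
        non-missing genotype for that sample.
        """
        tags = self.tag_ids
        tag_index = {t: i for i, t in enumerate(tags)}
        pres = np.zeros((len(tags), self.n_samples), dtype=bool)
        called = self.genotypes != MISSING
        for row, m in enumerate(self.markers):
            pres[tag_index[m.radtag_id]] |= called[row]
        return tags, pres

    def sample_index(self, sample_id: str) -> int:
        for i, s in enumerate(self.samples):
            if s.sample_id == sample_id:
                return i
        raise KeyError(sample_id)

    def role_indices(self, role: str) -> np.ndarray:
        return np.flatnonzero(self.roles == role)


# ============================================================ I/O


def read_sample_metadata(meta_path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(meta_path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "role", "sex"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        rg = row.get("replicate_group", "") or None
        out.append(SampleMeta(row["sample_id"], row["role"], row["sex"], rg))
    return out


def write_sample_metadata(samples: Iterable[SampleMeta], meta_path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "role": s.role,
            "sex": s.sex,
            "replicate_group": s.replicate_group or "",
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)


def _code_from_gt(gt: tuple) -> int:
    if gt is None or len(gt) == 0 or any(a is None for a in gt):
        return MISSING
    return int(sum(1 for a in gt if a != 0))


def read_genotypes(
    vcf_path: str | Path,
    meta_path: str | Path,
    on_multiallelic: str = "error",
) -> GenotypeMatrix:
    """Read a VCF plus a sample-metadata TSV into a :class:`GenotypeMatrix`.

    ``on_multiallelic`` is one of ``error`` (fatal), ``drop`` (skip record)
    or ``split`` (one bi-allelic marker per alternate allele; genotypes
    involving other alternates become missing).
    """
    if on_multiallelic not in ("error", "drop", "split"):
        raise ValueError(f"bad on_multiallelic mode {on_multiallelic!r}")
    meta = read_sample_metadata(meta_path)
    by_id = {s.sample_id: s for s in meta}
    vf = pysam.VariantFile(str(vcf_path))
    vcf_samples = list(vf.header.samples)
    for sid in vcf_samples:
        if sid not in by_id:
            raise ValueError(f"sample {sid!r} present in VCF but absent from metadata")
    samples = [by_id[sid] for sid in vcf_samples]

    markers: list[Marker] = []
    geno_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    any_depth = False
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) > 1 and on_multiallelic == "error":
            raise ValueError(
                f"multi-allelic record at {rec.chrom}:{rec.pos} "
                f"({rec.ref}->{','.join(alts)})"
            )
        if len(alts) > 1 and on_multiallelic == "drop":
            continue
        mid = rec.id or f"{rec.chrom}_{rec.pos}"
        radtag = str(rec.info.get("RT", mid))
        offset = int(rec.info.get("SO", 0))
        dp = np.zeros(len(vcf_samples), dtype=np.int32)
        has_dp = False
        raw_gts = []
        for j, sid in enumerate(vcf_samples):
            call = rec.samples[sid]
            raw_gts.append(call.get("GT"))
            d = call.get("DP")
            if d is not None:
                dp[j] = int(d)
                has_dp = True
        any_depth = any_depth or has_dp

        alt_list = list(alts) if alts else [None]
        split = len(alts) > 1
        for k, alt in enumerate(alt_list, start=1):
            codes = np.full(len(vcf_samples), MISSING, dtype=np.int8)
            for j, gt in enumerate(raw_gts):
                if gt is None or any(a is None for a in gt):
                    continue
                if split:
                    if any(a not in (0, k) for a in gt):
                        continue  # genotype involves a different alternate
                    codes[j] = sum(1 for a in gt if a == k)
                else:
                    codes[j] = _code_from_gt(gt)
            this_id = mid if not split else f"{mid}_alt{k}"
            markers.append(
                Marker(
                    marker_id=this_id,
                    radtag_id=radtag,
                    snp_offset=offset,
                    ref_allele=rec.ref or "N",
                    alt_allele=alt,
                    chrom=rec.chrom,
                )
            )
            geno_rows.append(codes)
            depth_rows.append(dp.copy())
    vf.close()

    genotypes = (
        np.array(geno_rows, dtype=np.int8)
        if geno_rows
        else np.zeros((0, len(samples)), dtype=np.int8)
    )
    depth = None
    if any_depth and geno_rows:
        depth = np.array(depth_rows, dtype=np.int32)
    return GenotypeMatrix(markers=markers, samples=samples, genotypes=genotypes, depth=depth)


_VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=RT,Number=1,Type=String,Description="RADtag identifier">',
    '##INFO=<ID=SO,Number=1,Type=Integer,Description="SNP offset within RADtag">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
]

_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_genotypes(
    matrix: GenotypeMatrix,
    vcf_path: str | Path,
    meta_path: str | Path | None = None,
) -> None:
    """Write an uncompressed VCFv4.2 file (and optional metadata sidecar).

    Coordinates are synthetic: the marker ``chrom`` attribute is the contig
    and the position is a running 1-based index within the contig.
    """
    vcf_path = Path(vcf_path)
    contigs: dict[str, int] = {}
    for m in matrix.markers:
        contigs.setdefault(m.chrom, 0)
    lines = list(_VCF_HEADER_LINES)
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    cols += matrix.sample_ids
    lines.append("\t".join(cols))

    fmt = "GT:DP" if matrix.depth is not None else "GT"
    for i, m in enumerate(matrix.markers):
        contigs[m.chrom] += 1
        pos = contigs[m.chrom]
        alt = m.alt_allele if m.alt_allele is not None else "."
        info = f"RT={m.radtag_id};SO={m.snp_offset}"
        fields = [m.chrom, str(pos), m.marker_id, m.ref_allele, alt, ".", ".", info, fmt]
        for j in range(matrix.n_samples):
            gt = _GT_STRINGS[int(matrix.genotypes[i, j])]
            if matrix.depth is not None:
                gt = f"{gt}:{int(matrix.depth[i, j])}"
            fields.append(gt)
        lines.append("\t".join(fields))
    try:
        vcf_path.write_text("\n".join(lines) + "\n")
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"cannot write VCF to {vcf_path}: {exc}") from exc
    if meta_path is not None:
        write_sample_metadata(matrix.samples, meta_path)


# ============================================================ filters


def filter_markers(
    matrix: GenotypeMatrix,
    min_call_rate: float = 0.6,
    min_maf: float = 0.02,
    depth_min: int = 5,
    depth_max: int = 50,
    biallelic_only: bool = True,
    keep_monomorphic: bool = False,
) -> tuple[GenotypeMatrix, dict]:
    """Apply generic marker filters, returning (filtered matrix, report).

    Per-call depth masking happens first: calls with depth outside
    ``[depth_min, depth_max]`` are silenced (set missing, depth zeroed)
    before call-rate and MAF evaluation.  Criteria are then applied in
    order: allele-count class, call rate (inclusive >=), MAF (inclusive >=,
    bypassed by monomorphic markers when they are kept).
    """
    if not (0 <= min_call_rate <= 1 and 0 <= min_maf <= 1):
        raise ValueError("rate thresholds must be in [0,1]")
    if depth_min > depth_max:
        raise ValueError("depth_min must be <= depth_max")
    work = matrix.copy()
    n_masked = 0
    if work.depth is not None:
        bad = (work.genotypes != MISSING) & (
            (work.depth < depth_min) | (work.depth > depth_max)
        )
        n_masked = int(bad.sum())
        work.genotypes[bad] = MISSING
        work.depth[bad] = 0

    mono = np.array([m.monomorphic for m in work.markers])
    keep = np.ones(work.n_markers, dtype=bool)
    report: dict[str, int] = {"input": work.n_markers, "depth_masked_calls": n_masked}

    drop_allelic = mono if not keep_monomorphic else np.zeros_like(mono)
    report["removed_not_biallelic"] = int((keep & drop_allelic).sum())
    keep &= ~drop_allelic

    cr = work.call_rate()
    fail_cr = cr < min_call_rate
    report["removed_call_rate"] = int((keep & fail_cr).sum())
    keep &= ~fail_cr

    maf = work.maf()
    fail_maf = maf < min_maf
    if keep_monomorphic:
        fail_maf &= ~mono  # monomorphic markers bypass the MAF filter
    report["removed_maf"] = int((keep & fail_maf).sum())
    keep &= ~fail_maf

    report["retained"] = int(keep.sum())
    if report["retained"] == 0:
        logger.warning("filter_markers removed every marker")
    return work.take_markers(np.flatnonzero(keep)), report


def filter_samples(matrix: GenotypeMatrix, max_missing: float = 0.4) -> GenotypeMatrix:
    """Drop samples whose missing-data fraction strictly exceeds ``max_missing``.

    Parents are never auto-dropped; a warning is logged instead.
    """
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0,1]")
    frac = matrix.missing_fraction_per_sample()
    keep = []
    for j, s in enumerate(matrix.samples):
        if frac[j] > max_missing:
            if s.role in ("mother", "father"):
                logger.warning(
                    "parent %s has %.1f%% missing data (> %.0f%%) but is retained",
                    s.sample_id, 100 * frac[j], 100 * max_missing,
                )
                keep.append(j)
            continue
        keep.append(j)
    return matrix.take_samples(keep)


def dedupe_replicates(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Keep one sample per replicate group: the least-missing member.

    Ties are broken lexicographically by sample id.  Samples without a
    replicate group are always kept.
    """
    frac = matrix.missing_fraction_per_sample()
    groups: dict[str, list[int]] = {}
    keep = []
    for j, s in enumerate(matrix.samples):
        if s.replicate_group:
            groups.setdefault(s.replicate_group, []).append(j)
        else:
            keep.append(j)
    for members in groups.values():
        best = min(members, key=lambda j: (frac[j], matrix.samples[j].sample_id))
        keep.append(best)
    keep.sort()
    return matrix.take_samples(keep)


def replicate_mismatch_rate(
    matrix: GenotypeMatrix,
    depth_bins: Sequence[int] = (5, 10, 20),
) -> pd.DataFrame:
    """Genotype-mismatch rates between technical replicates.

    For every replicate pair and every marker called in both members, a
    mismatch is a genotype-code disagreement.  Rates are reported per depth
    bin (binned on the minimum of the two call depths, with ``depth_bins``
    as the interior bin edges) and separately for the class of comparisons
    where either call is heterozygous.
    """
    groups: dict[str, list[int]] = {}
    for j, s in enumerate(matrix.samples):
        if s.replicate_group:
            groups.setdefault(s.replicate_group, []).append(j)
    pairs = [
        (a, b)
        for members in groups.values()
        for i, a in enumerate(members)
        for b in members[i + 1:]
    ]
    cols = ["depth_bin", "genotype_class", "n_comparisons", "n_mismatch", "mismatch_rate"]
    if not pairs:
        logger.warning("no replicate pairs found")
        return pd.DataFrame(columns=cols)

    edges = np.asarray(sorted(depth_bins), dtype=int)

    def bin_label(k: int) -> str:
        if len(edges) == 0:
            return "all"
        if k == 0:
            return f"<{edges[0]}"
        if k == len(edges):
            return f">={edges[-1]}"
        return f"{edges[k-1]}-{edges[k]-1}"

    records: dict[tuple[str, str], list[int]] = {}
    for a, b in pairs:
        ga, gb = matrix.genotypes[:, a], matrix.genotypes[:, b]
        both = (ga != MISSING) & (gb != MISSING)
        mism = both & (ga != gb)
        het = both & ((ga == HET) | (gb == HET))
        if matrix.depth is not None and len(edges) > 0:
            mind = np.minimum(matrix.depth[:, a], matrix.depth[:, b])
            bins = np.digitize(mind, edges)
        else:
            bins = np.zeros(matrix.n_markers, dtype=int)
        for k in np.unique(bins[both]):
            sel = both & (bins == k)
            for cls, cls_mask in (("all", sel), ("het", sel & het)):
                key = (bin_label(int(k)), cls)
                cur = records.setdefault(key, [0, 0])
                cur[0] += int(cls_mask.sum())
                cur[1] += int((cls_mask & mism).sum())
    rows = []
    for (label, cls), (n, nm) in sorted(records.items()):
        rows.append(
            {
                "depth_bin": label,
                "genotype_class": cls,
                "n_comparisons": n,
                "n_mismatch": nm,
                "mismatch_rate": nm / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=cols)
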