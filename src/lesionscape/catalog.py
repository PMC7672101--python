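"""Somatic mutation catalogs: records, filters, tracks, and VCF I/O.

Internal coordinates are 0-based half-open everywhere; the VCF boundary
(1-based) converts on read and write. Multi-allelic VCF records are split
into biallelic records before anything else sees them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MutClass",
    "MutationRecord",
    "FilterPolicy",
    "FILTER_PRESETS",
    "GenomicTrack",
    "GeneModel",
    "read_catalog",
    "write_vcf",
    "apply_filters",
    "merge_adjacent_sbs",
    "read_genes",
    "read_expression",
]

PYRIMIDINES = {"C", "T"}
PURINES = {"A", "G"}
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class MutClass(str, enum.Enum):
    SBS = "SBS"
    DBS = "DBS"
    ID = "ID"


def _classify_alleles(ref: str, alt: str) -> MutClass:
    if len(ref) == 1 and len(alt) == 1:
        return MutClass.SBS
    if len(ref) == 2 and len(alt) == 2:
        return MutClass.DBS
    if len(ref) != len(alt):
        return MutClass.ID
    raise ValueError(f"unsupported allele pair {ref}>{alt}")


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant. ``pos`` is the 0-based position of the first
    reference base (VCF POS - 1)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    fwd_support: int = 0   # F1R2-like alt read count
    rev_support: int = 0   # F2R1-like alt read count
    info: Mapping[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"VAF {self.vaf} outside [0, 1]")
        if self.fwd_support < 0 or self.rev_support < 0:
            raise ValueError("negative strand support")
        _classify_alleles(self.ref, self.alt)  # validates shape

    @property
    def mut_class(self) -> MutClass:
        return _classify_alleles(self.ref, self.alt)


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds applied to a somatic catalog after variant calling."""

    min_reads_per_strand: int = 1
    min_vaf: float = 0.05
    mappability_min: float = 1.0

    def __post_init__(self):
        if self.min_reads_per_strand < 0:
            raise ValueError("min_reads_per_strand must be >= 0")
        if not (0.0 <= self.min_vaf <= 1.0):
            raise ValueError("min_vaf must lie in [0, 1]")


# The three filtering regimes used for the cohort: bone-marrow leukemia
# biopsies, FFPE breast sarcoma, and FFPE rhabdomyosarcoma.
FILTER_PRESETS: dict[str, FilterPolicy] = {
    "leukemia": FilterPolicy(min_reads_per_strand=1, min_vaf=0.05),
    "ffpe_sarcoma": FilterPolicy(min_reads_per_strand=2, min_vaf=0.3),
    "ffpe_rms": FilterPolicy(min_reads_per_strand=1, min_vaf=0.4),
}


class GenomicTrack:
    """Interval -> value map with non-overlapping, sorted intervals per
    chromosome (0-based half-open)."""

    def __init__(self, intervals: Iterable[tuple[str, int, int, float]]):
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in intervals:
            if end <= start:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            starts = np.array([i[0] for i in ivals])
            ends = np.array([i[1] for i in ivals])
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping intervals on {chrom}")
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._values[chrom] = np.array([i[2] for i in ivals])

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "GenomicTrack":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        return cls(df.itertuples(index=False, name=None))

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._starts):
                for s, e, v in zip(self._starts[chrom], self._ends[chrom], self._values[chrom]):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._starts[chrom], self._ends[chrom], self._values[chrom]

    def value_at(self, chrom: str, pos: int) -> float | None:
        """Track value covering ``pos``; None where uncovered."""
        starts = self._starts.get(chrom)
        if starts is None:
            return None
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos >= self._ends[chrom][i]:
            return None
        return float(self._values[chrom][i])

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized lookup; NaN where uncovered."""
        out = np.full(len(positions), np.nan)
        starts = self._starts.get(chrom)
        if starts is None:
            return out
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = (idx >= 0) & (positions < self._ends[chrom][np.clip(idx, 0, None)])
        out[ok] = self._values[chrom][idx[ok]]
        return out

    def covers(self, chrom: str, pos: int) -> bool:
        return self.value_at(chrom, pos) is not None

    def total_length(self) -> int:
        return int(sum((self._ends[c] - self._starts[c]).sum() for c in self._starts))


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand, TSS and a scalar expression level (RPKM/FPKM)."""

    gene_id: str
    chrom: str
    start: int   # 0-based half-open
    end: int
    strand: str  # '+' or '-'
    expression: float = 0.0

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError("gene end must exceed start")
        if self.expression < 0:
            raise ValueError("expression must be >= 0")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


def read_genes(bed_path: str | Path, expression: Mapping[str, float] | None = None) -> list[GeneModel]:
    """Read gene models from a 6-column BED (name in col 4, strand in col 6),
    attaching expression values when provided (missing genes get 0)."""
    df = pd.read_csv(
        bed_path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    expression = expression or {}
    return [
        GeneModel(r.name, r.chrom, int(r.start), int(r.end), r.strand,
                  float(expression.get(r.name, 0.0)))
        for r in df.itertuples(index=False)
    ]


def read_expression(tsv_path: str | Path) -> dict[str, float]:
    df = pd.read_csv(tsv_path, sep="\t")
    if not {"gene_id", "expression"} <= set(df.columns):
        raise ValueError("expression TSV needs gene_id and expression columns")
    return dict(zip(df["gene_id"].astype(str), df["expression"].astype(float)))


# ---------------------------------------------------------------------------
# VCF I/O

def read_catalog(vcf_path: str | Path, sample_id: str | None = None) -> list[MutationRecord]:
    """Read PASS variants for one tumor sample into MutationRecords.

    VAF comes from the AD field (alt depth / total depth) unless a VAF
    FORMAT field is present. F1R2/F2R1 FORMAT fields supply per-orientation
    alt support when available. Multi-allelic records are split.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = vcf.samples
    if sample_id is None:
        if len(samples) != 1:
            raise ValueError("sample_id required for multi-sample VCF")
        sample_id = samples[0]
    if sample_id not in samples:
        raise ValueError(f"sample {sample_id!r} not in VCF ({samples})")
    si = samples.index(sample_id)

    def _fmt(variant, key):
        try:
            return variant.format(key)
        except KeyError:
            return None

    records: list[MutationRecord] = []
    for v in vcf:
        if v.FILTER is not None:  # None == PASS in cyvcf2
            continue
        if v.POS < 1:
            raise ValueError(f"malformed coordinate at {v.CHROM}:{v.POS}")
        ad = _fmt(v, "AD")
        vaf_fmt = _fmt(v, "VAF")
        f1r2 = _fmt(v, "F1R2")
        f2r1 = _fmt(v, "F2R1")
        info = {k: str(val) for k, val in dict(v.INFO).items()}
        for ai, alt in enumerate(v.ALT):
            if vaf_fmt is not None:
                vaf = float(vaf_fmt[si][min(ai, vaf_fmt.shape[1] - 1)])
            elif ad is not None:
                depth = float(ad[si].sum())
                if depth <= 0:
                    raise ValueError(f"zero depth in AD at {v.CHROM}:{v.POS}")
                vaf = float(ad[si][ai + 1]) / depth
            else:
                raise ValueError(
                    f"missing required field AD (or VAF) at {v.CHROM}:{v.POS}"
                )
            fwd = int(f1r2[si][ai + 1]) if f1r2 is not None else 0
            rev = int(f2r1[si][ai + 1]) if f2r1 is not None else 0
            records.append(
                MutationRecord(
                    sample_id=sample_id, chrom=v.CHROM, pos=v.POS - 1,
                    ref=v.REF, alt=str(alt), vaf=vaf,
                    fwd_support=fwd, rev_support=rev, info=info,
                )
            )
    return records


def write_vcf(
    records: Sequence[MutationRecord],
    path: str | Path,
    contigs: Mapping[str, int],
    depth: int = 100,
) -> None:
    """Write records as a minimal single-sample VCF 4.2 with AD, F1R2 and
    F2R1 FORMAT fields (alt depths derived from VAF when supports are 0).

    INFO keys present on records are carried through verbatim."""
    if records:
        sample_ids = {r.sample_id for r in records}
        if len(sample_ids) > 1:
            raise ValueError("write_vcf writes one sample per file")
        sample = next(iter(sample_ids))
    else:
        sample = "SAMPLE"
    info_keys = sorted({k for r in records for k in r.info})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        for k in info_keys:
            fh.write(f'##INFO=<ID={k},Number=1,Type=String,Description="simulation truth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=F1R2,Number=R,Type=Integer,Description="F1R2 orientation support">\n')
        fh.write('##FORMAT=<ID=F2R1,Number=R,Type=Integer,Description="F2R1 orientation support">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        key = lambda r: (r.chrom, r.pos)
        for r in sorted(records, key=key):
            alt_depth = max(r.fwd_support + r.rev_support, int(round(r.vaf * depth)))
            total = max(depth, alt_depth)
            ref_depth = total - alt_depth
            f1, f2 = r.fwd_support, r.rev_support
            if f1 + f2 == 0 and alt_depth > 0:
                f1 = alt_depth // 2
                f2 = alt_depth - f1
            info = ";".join(f"{k}={r.info[k]}" for k in sorted(r.info)) or "."
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\t"
                f"AD:F1R2:F2R1\t{ref_depth},{alt_depth}:0,{f1}:0,{f2}\n"
            )


# ---------------------------------------------------------------------------
# Filtering

def _passes(
    rec: MutationRecord,
    policy: FilterPolicy,
    mappability: GenomicTrack | None,
    blacklist: GenomicTrack | None,
) -> bool:
    if rec.fwd_support < policy.min_reads_per_strand:
        return False
    if rec.rev_support < policy.min_reads_per_strand:
        return False
    if rec.vaf < policy.min_vaf:
        return False
    if mappability is not None:
        v = mappability.value_at(rec.chrom, rec.pos)
        # uncovered positions fail mappability
        if v is None or v < policy.mappability_min:
            return False
    if blacklist is not None and blacklist.covers(rec.chrom, rec.pos):
        return False
    return True


def apply_filters(
    records: Sequence[MutationRecord],
    policy: FilterPolicy,
    mappability: GenomicTrack | None = None,
    blacklist: GenomicTrack | None = None,
) -> list[MutationRecord]:
    """Keep records passing all per-record predicates (strand support, VAF,
    mappability, blacklist); input order preserved."""
    return [r for r in records if _passes(r, policy, mappability, blacklist)]


def merge_adjacent_sbs(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    """Merge same-sample adjacent SBS pairs (distance 1 on one chromosome)
    into DBS records, flagged with info MERGED_DBS=1. Non-SBS records and
    unpaired SBS pass through; output sorted by (sample, chrom, pos)."""
    sbs = sorted(
        (r for r in records if r.mut_class is MutClass.SBS),
        key=lambda r: (r.sample_id, r.chrom, r.pos),
    )
    other = [r for r in records if r.mut_class is not MutClass.SBS]
    out: list[MutationRecord] = []
    i = 0
    while i < len(sbs):
        cur = sbs[i]
        if (
            i + 1 < len(sbs)
            and sbs[i + 1].sample_id == cur.sample_id
            and sbs[i + 1].chrom == cur.chrom
            and sbs[i + 1].pos == cur.pos + 1
        ):
            nxt = sbs[i + 1]
            info = dict(cur.info)
            info["MERGED_DBS"] = "1"
            out.append(
                MutationRecord(
                    sample_id=cur.sample_id, chrom=cur.chrom, pos=cur.pos,
                    ref=cur.ref + nxt.ref, alt=cur.alt + nxt.alt,
                    vaf=(cur.vaf + nxt.vaf) / 2.0,
                    fwd_support=min(cur.fwd_support, nxt.fwd_support),
                    rev_support=min(cur.rev_support, nxt.rev_support),
                    info=info,
                )
            )
            i += 2
        else:
            out.append(cur)
            i += 1
    out.extend(other)
    out.sort(key=lambda r: (r.sample_id, r.chrom, r.pos))
    return out
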