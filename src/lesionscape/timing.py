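"""Timing mutations relative to copy-number events from allele frequencies.

In a region where one allele was duplicated (copy gain or copy-neutral LOH),
a mutation present on both copies of the duplicated allele (multiplicity 2)
must predate the duplication, while multiplicity-1 mutations arose after it
(or on the other allele). The expected VAF of a clonal mutation with
multiplicity m at tumor purity p and total copy number T is

    VAF = p * m / (2 * (1 - p) + p * T)

Mutations are classified as pre- or post-event by conservative thresholds
around the two expected VAFs; a symmetric exclusion margin leaves ambiguous
mutations unclassified. Per-segment fractions are copy-normalized: the
pre-event count is divided by the single duplicated lineage copy on which
such mutations could arise, the post-event count by the T copies present
afterwards.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import MutationRecord
from .exactstats import wilcoxon_signed_rank_exact

__all__ = [
    "SCNAType",
    "SCNASegment",
    "Epoch",
    "TimedMutation",
    "expected_vaf",
    "classify_epoch",
    "fraction_before",
    "cohort_timing_test",
    "read_segments",
]


class SCNAType(str, enum.Enum):
    GAIN = "gain"
    CNLOH = "cnLOH"


class Epoch(str, enum.Enum):
    BEFORE = "before"
    AFTER = "after"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class SCNASegment:
    chrom: str
    start: int  # 0-based half-open
    end: int
    total_cn: int
    minor_cn: int
    purity: float
    scna_type: SCNAType

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("purity must lie in (0, 1]")
        if self.total_cn < 2 or self.minor_cn < 0:
            raise ValueError("need total_cn >= 2 and minor_cn >= 0")
        t = SCNAType(self.scna_type)
        if t is SCNAType.CNLOH and not (self.total_cn == 2 and self.minor_cn == 0):
            raise ValueError("cnLOH requires total_cn == 2, minor_cn == 0")
        if t is SCNAType.GAIN and self.total_cn < 3:
            raise ValueError("gain requires total_cn >= 3")
        if self.major_cn < 2:
            raise ValueError("segment not eligible: major copy number < 2")

    @property
    def major_cn(self) -> int:
        return self.total_cn - self.minor_cn

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class TimedMutation:
    record: MutationRecord
    multiplicity: int  # 1 or 2
    epoch: Epoch


def expected_vaf(purity: float, total_cn: int, multiplicity: int) -> float:
    """Expected clonal VAF at the given purity, total copy number and
    mutation multiplicity (normal cells contribute 2 reference copies)."""
    if not (0.0 < purity <= 1.0):
        raise ValueError("purity must lie in (0, 1]")
    if total_cn < 1:
        raise ValueError("total_cn must be >= 1")
    if not (1 <= multiplicity <= total_cn):
        raise ValueError("multiplicity must lie in [1, total_cn]")
    return purity * multiplicity / (2.0 * (1.0 - purity) + purity * total_cn)


def classify_epoch(
    records: Sequence[MutationRecord],
    segment: SCNASegment,
    margin: float = 0.25,
) -> list[TimedMutation]:
    """Assign each mutation in the segment to before/after the copy-number
    event by its VAF.

    With v1, v2 the expected VAFs at multiplicity 1 and 2, a mutation is
    ``before`` when vaf >= v2 - margin*(v2-v1), ``after`` when
    vaf <= v1 + margin*(v2-v1), else ``ambiguous``. margin=0 reduces to the
    midpoint rule (no ambiguous class); margin=0.25 is the conservative
    default.
    """
    if not (0.0 <= margin <= 0.5):
        raise ValueError("margin must lie in [0, 0.5]")
    v1 = expected_vaf(segment.purity, segment.total_cn, 1)
    v2 = expected_vaf(segment.purity, segment.total_cn, 2)
    if v2 <= v1:
        raise RuntimeError("expected VAF not increasing in multiplicity")
    width = v2 - v1
    hi = v2 - margin * width
    lo = v1 + margin * width
    out: list[TimedMutation] = []
    for r in records:
        if not segment.contains(r.chrom, r.pos):
            raise ValueError(f"record at {r.chrom}:{r.pos} outside segment")
        if r.vaf >= hi:
            out.append(TimedMutation(r, 2, Epoch.BEFORE))
        elif r.vaf <= lo:
            out.append(TimedMutation(r, 1, Epoch.AFTER))
        elif margin == 0.0:  # exact midpoint under the midpoint rule
            out.append(TimedMutation(r, 2, Epoch.BEFORE))
        else:
            out.append(TimedMutation(r, 2 if r.vaf >= (v1 + v2) / 2 else 1, Epoch.AMBIGUOUS))
    return out


def fraction_before(timed: Sequence[TimedMutation], segment: SCNASegment) -> dict:
    """Copy-normalized fraction of mutations predating the event.

    ``before`` mutations are normalized by the 1 duplicated pre-event lineage
    copy, ``after`` mutations by the T copies present post-event."""
    n_before = sum(1 for t in timed if t.epoch is Epoch.BEFORE)
    n_after = sum(1 for t in timed if t.epoch is Epoch.AFTER)
    n_amb = sum(1 for t in timed if t.epoch is Epoch.AMBIGUOUS)
    if n_before + n_after == 0:
        return {"n_before": 0, "n_after": 0, "n_ambiguous": n_amb,
                "before_per_copy": np.nan, "after_per_copy": np.nan,
                "fraction_before": np.nan}
    before_per_copy = n_before / 1.0
    after_per_copy = n_after / float(segment.total_cn)
    frac = before_per_copy / (before_per_copy + after_per_copy)
    return {"n_before": n_before, "n_after": n_after, "n_ambiguous": n_amb,
            "before_per_copy": before_per_copy, "after_per_copy": after_per_copy,
            "fraction_before": frac}


def cohort_timing_test(fractions: Sequence[float]) -> float:
    """Two-sided exact Wilcoxon signed-rank test of per-segment pre-event
    fractions against 0.5."""
    fr = [f for f in fractions if np.isfinite(f)]
    if len(fr) < 5:
        raise ValueError("need at least 5 segments")
    return wilcoxon_signed_rank_exact([f - 0.5 for f in fr])


def read_segments(tsv_path) -> list[SCNASegment]:
    df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str})
    return [
        SCNASegment(r.chrom, int(r.start), int(r.end), int(r.total_cn),
                    int(r.minor_cn), float(r.purity), SCNAType(r.type))
        for r in df.itertuples(index=False)
    ]
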