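"""Mutation channel classification: SBS96, DBS78 and ID83 schemes.

SBS channels are pyrimidine-centric trinucleotide contexts; DBS channels
canonicalize doublet substitutions by reverse complement; ID channels encode
indel length, affected base (1-bp events), repeat context and microhomology.
Indels are left-aligned before classification so the channel does not depend
on the VCF dialect used to express them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import MutClass, MutationRecord, revcomp, PURINES, PYRIMIDINES

logger = logging.getLogger(__name__)

__all__ = [
    "SBS96_LABELS",
    "DBS78_LABELS",
    "ID83_LABELS",
    "ChannelMatrix",
    "fetch",
    "classify_sbs96",
    "classify_dbs78",
    "classify_id83",
    "classify_record",
    "build_matrix",
    "profile_from_counts",
]

_BASES = "ACGT"
_SUBS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]

SBS96_LABELS: list[str] = [
    f"{five}[{sub}]{three}" for sub in _SUBS for five in _BASES for three in _BASES
]


def _dbs78_labels() -> list[str]:
    """Enumerate the 78 canonical doublet channels.

    Canonical reference doublets are the ten whose reverse complement is not
    lexicographically smaller; for palindromic references, equivalent alts
    under reverse complement collapse to the lexicographically smaller one.
    """
    labels = []
    for r1 in _BASES:
        for r2 in _BASES:
            ref = r1 + r2
            if revcomp(ref) < ref:
                continue
            seen = set()
            for a1 in _BASES:
                for a2 in _BASES:
                    alt = a1 + a2
                    if a1 == r1 or a2 == r2:
                        continue
                    if ref == revcomp(ref):
                        alt = min(alt, revcomp(alt))
                    if alt not in seen:
                        seen.add(alt)
            for alt in sorted(seen):
                labels.append(f"{ref}>{alt}")
    return labels


DBS78_LABELS: list[str] = _dbs78_labels()
assert len(DBS78_LABELS) == 78

def _id83_labels() -> list[str]:
    labels = []
    for base in "CT":
        labels += [f"1:Del:{base}:{i}" for i in range(6)]
    for base in "CT":
        labels += [f"1:Ins:{base}:{i}" for i in range(6)]
    for size in range(2, 6):
        labels += [f"{size}:Del:R:{i}" for i in range(6)]
    for size in range(2, 6):
        labels += [f"{size}:Ins:R:{i}" for i in range(6)]
    for size, max_mh in ((2, 1), (3, 2), (4, 3), (5, 5)):
        labels += [f"{size}:Del:M:{i}" for i in range(1, max_mh + 1)]
    return labels


ID83_LABELS: list[str] = _id83_labels()
assert len(ID83_LABELS) == 83

# COSMIC-style display names for the ID83 dialect above: deletion repeat
# digits are copies-1 (display shows homopolymer/repeat length including the
# deleted unit); insertion digits are copies of the unit already present.
ID83_DISPLAY = {
    lab: (
        lab.replace(":Del:C:", "bp del C, homopolymer len ")
        .replace(":Del:T:", "bp del T, homopolymer len ")
        .replace(":Ins:C:", "bp ins C, repeat count ")
        .replace(":Ins:T:", "bp ins T, repeat count ")
        .replace(":Del:R:", "bp del at repeat, copies-1 ")
        .replace(":Ins:R:", "bp ins at repeat, copies ")
        .replace(":Del:M:", "bp del with microhomology len ")
    )
    for lab in ID83_LABELS
}

SCHEMES = {"SBS96": SBS96_LABELS, "DBS78": DBS78_LABELS, "ID83": ID83_LABELS}


def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Uppercase reference slice [start, end); supports plain dicts of
    strings and pyfaidx.Fasta objects."""
    if start < 0:
        raise IndexError("negative start")
    if isinstance(genome, dict):
        seq = genome[chrom][start:end]
    else:
        seq = str(genome[chrom][start:end])
    if len(seq) != end - start:
        raise IndexError(f"{chrom}:{start}-{end} beyond contig end")
    return seq.upper()


def classify_sbs96(record: MutationRecord, genome) -> str | None:
    """Pyrimidine-centric 5'[REF>ALT]3' channel, or None when a flanking
    base is ambiguous."""
    if record.mut_class is not MutClass.SBS:
        raise ValueError("classify_sbs96 requires an SBS record")
    try:
        tri = fetch(genome, record.chrom, record.pos - 1, record.pos + 2)
    except (IndexError, KeyError):
        logger.warning("SBS at contig edge excluded: %s:%d", record.chrom, record.pos)
        return None
    if tri[1] != record.ref.upper():
        raise ValueError(
            f"reference mismatch at {record.chrom}:{record.pos}: "
            f"genome {tri[1]} vs record {record.ref}"
        )
    ref, alt = record.ref.upper(), record.alt.upper()
    if ref in PURINES:
        tri = revcomp(tri)
        ref, alt = revcomp(ref), revcomp(alt)
    if "N" in tri or alt == "N":
        logger.warning("ambiguous base near %s:%d excluded", record.chrom, record.pos)
        return None
    return f"{tri[0]}[{ref}>{alt}]{tri[2]}"


def classify_dbs78(record: MutationRecord, genome=None) -> str | None:
    """Canonical doublet-substitution channel (reverse complement applied to
    reach a canonical reference doublet)."""
    if record.mut_class is not MutClass.DBS:
        raise ValueError("classify_dbs78 requires a DBS record")
    ref, alt = record.ref.upper(), record.alt.upper()
    if "N" in ref + alt:
        logger.warning("ambiguous base in DBS at %s:%d excluded", record.chrom, record.pos)
        return None
    if revcomp(ref) < ref:
        ref, alt = revcomp(ref), revcomp(alt)
    if ref == revcomp(ref):
        alt = min(alt, revcomp(alt))
    label = f"{ref}>{alt}"
    if label not in _DBS78_SET:
        # same-base positions (e.g. AC>AT) are not doublet substitutions
        logger.warning("non-canonical doublet %s at %s:%d excluded",
                       label, record.chrom, record.pos)
        return None
    return label


_DBS78_SET = set(DBS78_LABELS)


def _left_align(genome, chrom: str, start: int, unit: str) -> tuple[int, str]:
    """Shift an indel's unit left through identical context (0-based start of
    the deleted unit / insertion point)."""
    while start > 0:
        prev = fetch(genome, chrom, start - 1, start)
        if prev != unit[-1]:
            break
        unit = prev + unit[:-1]
        start -= 1
    return start, unit


def _count_copies_forward(genome, chrom: str, pos: int, unit: str, limit: int = 8) -> int:
    k = len(unit)
    n = 0
    while n < limit:
        try:
            if fetch(genome, chrom, pos + n * k, pos + (n + 1) * k) != unit:
                break
        except (IndexError, KeyError):
            break
        n += 1
    return n


def _count_copies_backward(genome, chrom: str, pos: int, unit: str, limit: int = 8) -> int:
    k = len(unit)
    n = 0
    while n < limit:
        s = pos - (n + 1) * k
        if s < 0:
            break
        try:
            if fetch(genome, chrom, s, s + k) != unit:
                break
        except (IndexError, KeyError):
            break
        n += 1
    return n


def _microhomology(genome, chrom: str, start: int, deleted: str) -> int:
    """Longest partial match of the deleted sequence with its flanks:
    3' flank against a prefix, 5' flank against a suffix."""
    k = len(deleted)
    fwd = 0
    for i in range(k - 1):
        try:
            if fetch(genome, chrom, start + k + i, start + k + i + 1) != deleted[i]:
                break
        except (IndexError, KeyError):
            break
        fwd += 1
    bwd = 0
    for i in range(k - 1):
        s = start - 1 - i
        if s < 0:
            break
        if fetch(genome, chrom, s, s + 1) != deleted[k - 1 - i]:
            break
        bwd += 1
    return max(fwd, bwd)


def classify_id83(record: MutationRecord, genome) -> str | None:
    """ID83 channel of a small indel (anchored VCF representation)."""
    if record.mut_class is not MutClass.ID:
        raise ValueError("classify_id83 requires an indel record")
    ref, alt = record.ref.upper(), record.alt.upper()
    if "N" in ref + alt:
        logger.warning("ambiguous indel at %s:%d excluded", record.chrom, record.pos)
        return None
    if len(ref) > len(alt):  # deletion
        if not ref.startswith(alt):
            logger.warning("non-left-anchored deletion at %s:%d excluded",
                           record.chrom, record.pos)
            return None
        unit = ref[len(alt):]
        start = record.pos + len(alt)
        try:
            start, unit = _left_align(genome, record.chrom, start, unit)
            k = len(unit)
            copies = (
                1
                + _count_copies_forward(genome, record.chrom, start + k, unit)
                + _count_copies_backward(genome, record.chrom, start, unit)
            )
            if k == 1:
                base = unit if unit in PYRIMIDINES else revcomp(unit)
                return f"1:Del:{base}:{min(copies - 1, 5)}"
            size = min(k, 5)
            if copies == 1:
                mh = _microhomology(genome, record.chrom, start, unit)
                if mh > 0:
                    max_mh = 5 if size == 5 else size - 1
                    return f"{size}:Del:M:{min(mh, max_mh)}"
            return f"{size}:Del:R:{min(copies - 1, 5)}"
        except (IndexError, KeyError):
            logger.warning("indel at contig edge excluded: %s:%d", record.chrom, record.pos)
            return None
    else:  # insertion
        if not alt.startswith(ref):
            logger.warning("non-left-anchored insertion at %s:%d excluded",
                           record.chrom, record.pos)
            return None
        unit = alt[len(ref):]
        start = record.pos + len(ref)  # reference point the unit is inserted before
        try:
            start, unit = _left_align(genome, record.chrom, start, unit)
            k = len(unit)
            copies = (
                _count_copies_forward(genome, record.chrom, start, unit)
                + _count_copies_backward(genome, record.chrom, start, unit)
            )
            if k == 1:
                base = unit if unit in PYRIMIDINES else revcomp(unit)
                return f"1:Ins:{base}:{min(copies, 5)}"
            return f"{min(k, 5)}:Ins:R:{min(copies, 5)}"
        except (IndexError, KeyError):
            logger.warning("indel at contig edge excluded: %s:%d", record.chrom, record.pos)
            return None


_CLASSIFIERS = {
    "SBS96": (MutClass.SBS, classify_sbs96),
    "DBS78": (MutClass.DBS, classify_dbs78),
    "ID83": (MutClass.ID, classify_id83),
}


def classify_record(record: MutationRecord, genome, scheme: str) -> str | None:
    cls, fn = _CLASSIFIERS[scheme]
    if record.mut_class is not cls:
        raise ValueError(f"record class {record.mut_class} does not fit scheme {scheme}")
    return fn(record, genome)


@dataclass
class ChannelMatrix:
    """Per-sample mutation counts over the channels of one scheme."""

    scheme: str
    counts: pd.DataFrame  # samples x channels
    n_excluded: int = 0

    @property
    def channel_labels(self) -> list[str]:
        return list(self.counts.columns)

    def profile(self, sample: str) -> pd.Series:
        return profile_from_counts(self.counts.loc[sample])

    def to_tsv(self, path) -> None:
        # conventional orientation: channels x samples
        self.counts.T.to_csv(path, sep="\t", index_label="channel")

    @classmethod
    def from_tsv(cls, path, scheme: str) -> "ChannelMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0).T
        df = df[SCHEMES[scheme]].astype(int)
        df.index.name = None
        df.columns.name = None
        return cls(scheme=scheme, counts=df)


def profile_from_counts(counts: pd.Series | np.ndarray) -> pd.Series:
    total = float(np.sum(counts))
    if total <= 0:
        raise ValueError("cannot normalize an empty channel vector")
    return counts / total


def build_matrix(
    records: Sequence[MutationRecord],
    scheme: str,
    genome,
    samples: Sequence[str] | None = None,
) -> ChannelMatrix:
    """Count classified mutations per sample and channel; records that fail
    classification (ambiguous bases, contig edges) are excluded and tallied."""
    labels = SCHEMES[scheme]
    cls, fn = _CLASSIFIERS[scheme]
    wanted = [r for r in records if r.mut_class is cls]
    if samples is None:
        samples = sorted({r.sample_id for r in wanted})
    counts = pd.DataFrame(0, index=list(samples), columns=labels, dtype=int)
    excluded = 0
    for r in wanted:
        ch = fn(r, genome)
        if ch is None:
            excluded += 1
            continue
        counts.loc[r.sample_id, ch] += 1
    return ChannelMatrix(scheme=scheme, counts=counts, n_excluded=excluded)
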