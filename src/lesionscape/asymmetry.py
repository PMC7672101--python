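"""Strand asymmetries and genomic covariates of mutation density.

Strand convention: SBS are represented pyrimidine-centrically. A genic
mutation is labeled "untranscribed" when the pyrimidine of the mutated base
pair lies on the gene's coding strand and "transcribed" when it lies on the
template strand; under purine-lesion mutagenesis with transcription-coupled
repair, lesions on the template strand (pyrimidine on coding strand) are
repaired, depleting the "untranscribed" label. Mutations in regions covered
by genes on both strands are excluded as ambiguous.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import GeneModel, GenomicTrack, MutationRecord, PYRIMIDINES
from .channels import ChannelMatrix, SBS96_LABELS, classify_sbs96, SCHEMES
from .exactstats import poisson_pair_test
from .signatures import SignatureSet, refit_exposures

__all__ = [
    "StrandLabel",
    "StrandAnnotatedMutation",
    "ExpressionBins",
    "ReplicationTimingConsensus",
    "ForkDirectionBins",
    "annotate_strand",
    "trb_by_class",
    "trb_by_context",
    "trb_overall",
    "trb_by_expression",
    "tss_profiles",
    "build_timing_consensus",
    "density_by_timing",
    "fork_direction_bins",
    "replication_strand_bias",
    "estimate_replication_factor",
    "mark_quantile_density",
    "chromatin_state_density",
    "strandwise_signature_contrast",
]

SBS_CLASSES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]


class StrandLabel(str, enum.Enum):
    TRANSCRIBED = "transcribed"
    UNTRANSCRIBED = "untranscribed"
    INTERGENIC = "intergenic"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class StrandAnnotatedMutation:
    record: MutationRecord
    strand_label: StrandLabel
    gene_id: str | None = None
    gene_strand: str | None = None
    expression: float = float("nan")

    @property
    def sbs_class(self) -> str:
        ref, alt = self.record.ref.upper(), self.record.alt.upper()
        if ref not in PYRIMIDINES:
            comp = {"A": "T", "G": "C", "C": "G", "T": "A"}
            ref, alt = comp[ref], comp[alt]
        return f"{ref}>{alt}"


# ---------------------------------------------------------------------------
# interval helpers (0-based half-open, per chromosome)

def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def _overlap_len(ivals: list[tuple[int, int]], s: int, e: int) -> int:
    return sum(max(0, min(e, ie) - max(s, is_)) for is_, ie in ivals)


class GeneTerritory:
    """Per-chromosome partition into single-strand genic intervals,
    both-strand (ambiguous) intervals, and intergenic remainder."""

    def __init__(self, genes: Sequence[GeneModel], chrom_lengths: Mapping[str, int]):
        self.chrom_lengths = dict(chrom_lengths)
        self.plus: dict[str, list[tuple[int, int]]] = {}
        self.minus: dict[str, list[tuple[int, int]]] = {}
        self.ambiguous: dict[str, list[tuple[int, int]]] = {}
        self.genic: dict[str, list[tuple[int, int]]] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gl in by_chrom.items():
            plus = _merge([(g.start, g.end) for g in gl if g.strand == "+"])
            minus = _merge([(g.start, g.end) for g in gl if g.strand == "-"])
            amb = _intersect(plus, minus)
            self.plus[chrom] = _subtract(plus, amb)
            self.minus[chrom] = _subtract(minus, amb)
            self.ambiguous[chrom] = amb
            self.genic[chrom] = _merge(plus + minus)

    def genic_length(self, chrom: str, s: int, e: int) -> int:
        return _overlap_len(self.genic.get(chrom, []), s, e)

    def ambiguous_length(self, chrom: str, s: int, e: int) -> int:
        return _overlap_len(self.ambiguous.get(chrom, []), s, e)

    def intergenic_length(self, chrom: str, s: int, e: int) -> int:
        return (e - s) - self.genic_length(chrom, s, e)

    def single_strand_genic_length(self, chrom: str, s: int, e: int) -> int:
        return self.genic_length(chrom, s, e) - self.ambiguous_length(chrom, s, e)


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _subtract(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for s, e in a:
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
        if cur < e:
            out.append((cur, e))
    return out


# ---------------------------------------------------------------------------
# strand annotation and transcriptional bias

def annotate_strand(
    records: Sequence[MutationRecord],
    genes: Sequence[GeneModel],
    genome=None,
) -> list[StrandAnnotatedMutation]:
    """Label each SBS as transcribed / untranscribed / intergenic / excluded
    under the pyrimidine-centric convention described in the module
    docstring."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for gl in by_chrom.values():
        gl.sort(key=lambda g: g.start)
    out: list[StrandAnnotatedMutation] = []
    for r in records:
        hits = [
            g for g in by_chrom.get(r.chrom, [])
            if g.start <= r.pos < g.end
        ]
        strands = {g.strand for g in hits}
        if not hits:
            out.append(StrandAnnotatedMutation(r, StrandLabel.INTERGENIC))
            continue
        if len(strands) > 1:
            out.append(StrandAnnotatedMutation(r, StrandLabel.EXCLUDED))
            continue
        g = hits[0]
        pyr_strand = "+" if r.ref.upper() in PYRIMIDINES else "-"
        label = (
            StrandLabel.UNTRANSCRIBED if pyr_strand == g.strand
            else StrandLabel.TRANSCRIBED
        )
        out.append(StrandAnnotatedMutation(r, label, g.gene_id, g.strand, g.expression))
    return out


def _strand_counts(annotated, key_fn) -> pd.DataFrame:
    rows: dict[str, list[int]] = {}
    for a in annotated:
        if a.strand_label not in (StrandLabel.TRANSCRIBED, StrandLabel.UNTRANSCRIBED):
            continue
        k = key_fn(a)
        if k is None:
            continue
        n = rows.setdefault(k, [0, 0])
        n[0 if a.strand_label is StrandLabel.TRANSCRIBED else 1] += 1
    return rows


def _trb_table(counts: dict, keys: Sequence[str]) -> pd.DataFrame:
    rows = []
    for k in keys:
        t, u = counts.get(k, [0, 0])
        if t + u == 0:
            rows.append({"key": k, "n_transcribed": 0, "n_untranscribed": 0,
                         "ratio": np.nan, "p": np.nan})
            continue
        ratio = t / u if u > 0 else np.nan
        rows.append({
            "key": k, "n_transcribed": t, "n_untranscribed": u,
            "ratio": ratio, "p": poisson_pair_test(t, u),
        })
    return pd.DataFrame(rows).set_index("key")


def trb_by_class(annotated: Sequence[StrandAnnotatedMutation]) -> pd.DataFrame:
    """Per-substitution-class strand counts, transcribed/untranscribed ratio
    and exact two-sided conditional Poisson test."""
    counts = _strand_counts(annotated, lambda a: a.sbs_class)
    return _trb_table(counts, SBS_CLASSES)


def trb_by_context(annotated: Sequence[StrandAnnotatedMutation], genome) -> pd.DataFrame:
    """As trb_by_class at trinucleotide-context (96-channel) resolution."""
    def key(a):
        return classify_sbs96(a.record, genome)
    counts = _strand_counts(annotated, key)
    return _trb_table(counts, SBS96_LABELS)


def trb_overall(annotated: Sequence[StrandAnnotatedMutation]) -> dict:
    """Pooled transcribed/untranscribed counts, ratio and p across classes."""
    t = sum(1 for a in annotated if a.strand_label is StrandLabel.TRANSCRIBED)
    u = sum(1 for a in annotated if a.strand_label is StrandLabel.UNTRANSCRIBED)
    ratio = t / u if u > 0 else np.nan
    p = poisson_pair_test(t, u) if t + u > 0 else np.nan
    return {"n_transcribed": t, "n_untranscribed": u, "ratio": ratio, "p": p}


def strand_context_opportunity(
    genes: Sequence[GeneModel], genome
) -> pd.DataFrame:
    """Strand-resolved trinucleotide opportunity of a genic territory: for
    each pyrimidine-centric context, the number of sites whose pyrimidine
    lies on the coding vs the template strand of its gene."""
    from .clusters import _encode, _COMP_CODE, _chrom_seq

    counts: dict[str, np.ndarray] = {}
    bases = "ACGT"
    seqs: dict[str, np.ndarray] = {}
    for g in genes:
        if g.chrom not in seqs:
            seqs[g.chrom] = _encode(_chrom_seq(genome, g.chrom))
        codes = seqs[g.chrom]
        lo = max(g.start, 1)
        hi = min(g.end, codes.size - 1)
        if hi <= lo:
            continue
        tri = np.stack([codes[lo - 1 : hi - 1], codes[lo:hi], codes[lo + 1 : hi + 1]])
        ok = (tri < 4).all(axis=0)
        center = tri[1]
        pyr_plus = (center == 1) | (center == 3)
        canon = np.where(pyr_plus[None, :], tri, _COMP_CODE[tri][::-1, :])
        key = canon[0].astype(np.int64) * 16 + canon[1] * 4 + canon[2]
        key[~ok] = -1
        coding = pyr_plus == (g.strand == "+")
        for code in np.unique(key[key >= 0]):
            m = key == code
            s, c = "", int(code)
            for _ in range(3):
                s = bases[c % 4] + s
                c //= 4
            row = counts.setdefault(s, np.zeros(2))
            row[0] += int((m & coding).sum())
            row[1] += int((m & ~coding).sum())
    return pd.DataFrame(
        {k: v for k, v in counts.items()}, index=["n_coding_pyr", "n_template_pyr"]
    ).T.sort_index()


def _corrected_strand_sums(
    annotated, genes, genome, fork, replication_factor
) -> tuple[float, float]:
    """Opportunity- and replication-corrected (transcribed, untranscribed)
    pseudo-counts over the given genes."""
    sel_ids = {g.gene_id for g in genes}
    opp = strand_context_opportunity(genes, genome)
    ratio = (opp["n_coding_pyr"] / opp["n_template_pyr"]).to_dict()
    from .catalog import revcomp
    from .clusters import _chrom_seq

    seqs: dict[str, str] = {}
    num = den = 0.0
    for a in annotated:
        if a.gene_id not in sel_ids:
            continue
        r = a.record
        if r.chrom not in seqs:
            seqs[r.chrom] = _chrom_seq(genome, r.chrom)
        seq = seqs[r.chrom]
        if r.pos < 1 or r.pos + 1 >= len(seq):
            continue
        ctx = seq[r.pos - 1 : r.pos + 2]
        if any(b not in "ACGT" for b in ctx):
            continue
        if ctx[1] in "AG":
            ctx = revcomp(ctx)
        if ctx not in ratio:
            continue
        w = 1.0
        if fork is not None and replication_factor != 1.0:
            f = fork.track.value_at(r.chrom, r.pos)
            if f is not None:
                # lesion strand is the purine strand, opposite the pyrimidine
                lag_prob = (1.0 + f) / 2.0 if r.ref.upper() in PYRIMIDINES \
                    else (1.0 - f) / 2.0
                w = 1.0 + (replication_factor - 1.0) * lag_prob
        if a.strand_label is StrandLabel.TRANSCRIBED:
            num += ratio[ctx] / w
        elif a.strand_label is StrandLabel.UNTRANSCRIBED:
            den += 1.0 / w
    return num, den


def estimate_trb_factor(
    annotated: Sequence[StrandAnnotatedMutation],
    genes: Sequence[GeneModel],
    genome,
    fork: "ForkDirectionBins | None" = None,
    replication_factor: float = 1.0,
    bins: "ExpressionBins | None" = None,
    coupling: Sequence[float] = (0.0, 0.25, 0.6, 1.0),
) -> float:
    """Transcription-coupled repair factor estimated from the strand bias in
    every expression bin.

    Per bin, the transcribed/untranscribed count ratio is computed with
    opportunity normalization (per-context coding/template site availability)
    and, when a fork-direction consensus plus replication-factor estimate are
    supplied, a per-mutation replication-weight correction (a gene usually
    lies within one replication domain, so lagging-strand mutagenesis
    perturbs its strand ratio coherently). Each bin's ratio maps to a factor
    estimate through its repair coupling, 1 + (ratio - 1)/coupling, and bins
    are pooled by inverse variance; bins with zero coupling carry no
    information and are skipped."""
    if bins is None:
        bins = ExpressionBins()
    estimates, weights = [], []
    for b in range(bins.n_bins):
        c = coupling[b] if b < len(coupling) else coupling[-1]
        if c <= 0:
            continue
        sel = [g for g in genes if bins.assign(g.expression) == b]
        if not sel:
            continue
        t, u = _corrected_strand_sums(annotated, sel, genome, fork,
                                      replication_factor)
        if t < 10 or u < 10:
            continue
        ratio = t / u
        est = 1.0 + (ratio - 1.0) / c
        var = (ratio / c) ** 2 * (1.0 / t + 1.0 / u)
        estimates.append(est)
        weights.append(1.0 / var)
    if not estimates:
        return float("nan")
    return float(np.average(estimates, weights=weights))


@dataclass(frozen=True)
class ExpressionBins:
    """Expression breakpoints; genes fall in [edge_i, edge_{i+1}), with the
    last bin closed on the right."""

    edges: tuple[float, ...] = (0.0, 0.1, 1.0, 10.0, 20_000.0)

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def labels(self) -> list[str]:
        return [f"{a:g}-{b:g}" for a, b in zip(self.edges, self.edges[1:])]

    def assign(self, expression: float) -> int | None:
        if expression < self.edges[0] or expression > self.edges[-1]:
            return None
        i = int(np.searchsorted(self.edges, expression, side="right")) - 1
        return min(i, self.n_bins - 1)


def trb_by_expression(
    annotated: Sequence[StrandAnnotatedMutation],
    genes: Sequence[GeneModel],
    bins: ExpressionBins = ExpressionBins(),
) -> pd.DataFrame:
    """Strand-specific mutation densities (per Mb of summed gene length) and
    bias per expression bin."""
    gene_bin = {}
    bin_length = np.zeros(bins.n_bins)
    for g in genes:
        b = bins.assign(g.expression)
        if b is None:
            continue
        gene_bin[g.gene_id] = b
        bin_length[b] += g.length
    counts = np.zeros((bins.n_bins, 2))
    for a in annotated:
        if a.strand_label not in (StrandLabel.TRANSCRIBED, StrandLabel.UNTRANSCRIBED):
            continue
        b = gene_bin.get(a.gene_id)
        if b is None:
            continue
        counts[b, 0 if a.strand_label is StrandLabel.TRANSCRIBED else 1] += 1
    rows = []
    for b, lab in enumerate(bins.labels()):
        t, u = counts[b]
        L = bin_length[b]
        if L == 0 or t + u == 0:
            rows.append({"bin": lab, "n_transcribed": int(t), "n_untranscribed": int(u),
                         "length_bp": int(L), "density_transcribed": np.nan,
                         "density_untranscribed": np.nan, "ratio": np.nan, "p": np.nan})
            continue
        rows.append({
            "bin": lab, "n_transcribed": int(t), "n_untranscribed": int(u),
            "length_bp": int(L),
            "density_transcribed": t / L * 1e6,
            "density_untranscribed": u / L * 1e6,
            "ratio": t / u if u > 0 else np.nan,
            "p": poisson_pair_test(int(t), int(u)),
        })
    return pd.DataFrame(rows).set_index("bin")


# ---------------------------------------------------------------------------
# TSS-anchored strand-specific density profiles

def tss_profiles(
    annotated: Sequence[StrandAnnotatedMutation],
    genes: Sequence[GeneModel],
    chrom_lengths: Mapping[str, int],
    flank: int = 50_000,
    bin_size: int = 1_000,
) -> pd.DataFrame:
    """Strand-resolved mutation density as a function of distance from the
    TSS, in gene-relative orientation (negative offsets upstream/intergenic,
    nonnegative offsets inside the gene body).

    1-kb intervals overlapping any other gene, or overlapping intervals
    anchored at another TSS, are removed. Densities are reported separately
    for mutations whose pyrimidine lies on the gene's coding strand
    ("coding_pyr": depleted downstream of the TSS under template-strand
    purine repair) and on the template strand ("template_pyr")."""
    n_bins = flank // bin_size
    # candidate intervals: (chrom, start, end, gene_idx, offset_bin)
    candidates = []
    for gi, g in enumerate(genes):
        tss = g.tss
        for k in range(-n_bins, n_bins):
            if g.strand == "+":
                s = tss + k * bin_size
                e = s + bin_size
            else:
                e = tss + 1 - k * bin_size
                s = e - bin_size
            if s < 0 or e > chrom_lengths.get(g.chrom, 0):
                continue
            if k >= 0:
                # genic side must stay inside the gene body
                if g.strand == "+" and e > g.end:
                    continue
                if g.strand == "-" and s < g.start:
                    continue
            else:
                # intergenic side must stay outside the own gene
                if g.strand == "+" and e > g.start:
                    continue
                if g.strand == "-" and s < g.end:
                    continue
            candidates.append((g.chrom, s, e, gi, k))

    # remove intervals overlapping other genes or other TSS intervals
    gene_ivals: dict[str, list[tuple[int, int, int]]] = {}
    for gi, g in enumerate(genes):
        gene_ivals.setdefault(g.chrom, []).append((g.start, g.end, gi))
    kept = []
    by_chrom: dict[str, list[tuple[int, int, int, int]]] = {}
    for chrom, s, e, gi, k in candidates:
        if any(s < ge and e > gs for gs, ge, ogi in gene_ivals.get(chrom, []) if ogi != gi):
            continue
        by_chrom.setdefault(chrom, []).append((s, e, gi, k))
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        n = len(ivals)
        drop = [False] * n
        for i in range(n):
            for j in range(i + 1, n):
                if ivals[j][0] >= ivals[i][1]:
                    break
                if ivals[j][2] != ivals[i][2]:  # cross-gene overlap
                    drop[i] = drop[j] = True
        kept.extend(
            (chrom, s, e, gi, k)
            for flag, (s, e, gi, k) in zip(drop, ivals) if not flag
        )

    interval_count = np.zeros(2 * n_bins)
    counts = np.zeros((2 * n_bins, 2))  # columns: coding_pyr, template_pyr
    per_chrom: dict[str, list[tuple[int, int, int, int]]] = {}
    for chrom, s, e, gi, k in kept:
        interval_count[k + n_bins] += 1
        per_chrom.setdefault(chrom, []).append((s, e, gi, k))
    lookup = {}
    for chrom, lst in per_chrom.items():
        lst.sort()
        lookup[chrom] = (
            np.array([i[0] for i in lst]),
            np.array([i[1] for i in lst]),
            [(i[2], i[3]) for i in lst],
        )
    for a in annotated:
        r = a.record
        entry = lookup.get(r.chrom)
        if entry is None:
            continue
        starts, ends, meta = entry
        i = int(np.searchsorted(starts, r.pos, side="right")) - 1
        if i >= 0 and r.pos < ends[i]:
            gi, k = meta[i]
            g = genes[gi]
            pyr_strand = "+" if r.ref.upper() in PYRIMIDINES else "-"
            col = 0 if pyr_strand == g.strand else 1
            counts[k + n_bins, col] += 1

    offsets = np.arange(-n_bins, n_bins)
    length = interval_count * bin_size
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = np.where(length[:, None] > 0, counts / length[:, None] * 1e6, np.nan)
    return pd.DataFrame({
        "offset_kb": offsets * (bin_size / 1000.0),
        "side": np.where(offsets < 0, "upstream", "genic"),
        "n_intervals": interval_count.astype(int),
        "n_coding_pyr": counts[:, 0].astype(int),
        "n_template_pyr": counts[:, 1].astype(int),
        "density_coding_pyr": dens[:, 0],
        "density_template_pyr": dens[:, 1],
    })


# ---------------------------------------------------------------------------
# replication timing

TIMING_BIN_EDGES = (10.0, 25.0, 40.0, 55.0, 70.0, 85.0)


@dataclass
class ReplicationTimingConsensus:
    """Mean replication timing per 1-kb region across cell lines, restricted
    to regions consistent between lines (sd <= sd_max)."""

    track: GenomicTrack
    bin_edges: tuple[float, ...] = TIMING_BIN_EDGES
    n_dropped: int = 0

    def bin_of(self, value: float) -> int | None:
        e = self.bin_edges
        if value < e[0] or value > e[-1]:
            return None
        return min(int(np.searchsorted(e, value, side="right")) - 1, len(e) - 2)

    def bin_labels(self) -> list[str]:
        e = self.bin_edges
        return [f"{a:g}-{b:g}" for a, b in zip(e, e[1:])]


def _check_same_grid(tracks: Sequence[GenomicTrack]):
    ref = tracks[0]
    for t in tracks[1:]:
        if t.chroms != ref.chroms:
            raise ValueError("tracks cover different chromosomes")
        for chrom in ref.chroms:
            s0, e0, _ = ref.intervals(chrom)
            s1, e1, _ = t.intervals(chrom)
            if len(s0) != len(s1) or np.any(s0 != s1) or np.any(e0 != e1):
                raise ValueError(f"grid mismatch on {chrom}")


def build_timing_consensus(
    tracks: Sequence[GenomicTrack],
    sd_max: float = 15.0,
    bin_edges: tuple[float, ...] = TIMING_BIN_EDGES,
) -> ReplicationTimingConsensus:
    """Per-region mean timing across cell lines where the cross-line standard
    deviation is <= sd_max; discordant regions are dropped."""
    if len(tracks) < 2:
        raise ValueError("need at least 2 cell-line tracks")
    _check_same_grid(tracks)
    intervals = []
    dropped = 0
    for chrom in tracks[0].chroms:
        starts, ends, _ = tracks[0].intervals(chrom)
        vals = np.stack([t.intervals(chrom)[2] for t in tracks])
        sd = vals.std(axis=0, ddof=0)
        mean = vals.mean(axis=0)
        keep = sd <= sd_max
        dropped += int((~keep).sum())
        for s, e, v in zip(starts[keep], ends[keep], mean[keep]):
            intervals.append((chrom, int(s), int(e), float(v)))
    return ReplicationTimingConsensus(GenomicTrack(intervals), bin_edges, dropped)


def density_by_timing(
    annotated: Sequence[StrandAnnotatedMutation],
    consensus: ReplicationTimingConsensus,
    territory: GeneTerritory,
) -> pd.DataFrame:
    """Length-adjusted mutation density (per Mb) per replication-timing bin
    for the transcribed strand, untranscribed strand and intergenic
    regions."""
    n_bins = len(consensus.bin_edges) - 1
    cats = [StrandLabel.TRANSCRIBED, StrandLabel.UNTRANSCRIBED, StrandLabel.INTERGENIC]
    counts = np.zeros((n_bins, 3))
    lengths = np.zeros((n_bins, 3))
    track = consensus.track
    for chrom in track.chroms:
        starts, ends, vals = track.intervals(chrom)
        for s, e, v in zip(starts, ends, vals):
            b = consensus.bin_of(float(v))
            if b is None:
                continue
            genic = territory.single_strand_genic_length(chrom, int(s), int(e))
            lengths[b, 0] += genic  # each genic bp offers one template strand
            lengths[b, 1] += genic
            lengths[b, 2] += territory.intergenic_length(chrom, int(s), int(e))
    for a in annotated:
        if a.strand_label is StrandLabel.EXCLUDED:
            continue
        v = track.value_at(a.record.chrom, a.record.pos)
        if v is None:
            continue
        b = consensus.bin_of(v)
        if b is None:
            continue
        counts[b, cats.index(a.strand_label)] += 1
    rows = []
    labels = consensus.bin_labels()
    for b in range(n_bins):
        for c, cat in enumerate(cats):
            L = lengths[b, c]
            rows.append({
                "timing_bin": labels[b], "category": cat.value,
                "count": int(counts[b, c]), "length_bp": int(L),
                "density_per_mb": counts[b, c] / L * 1e6 if L > 0 else np.nan,
            })
    return pd.DataFrame(rows)


def estimate_timing_gradient(
    density: pd.DataFrame,
    consensus: ReplicationTimingConsensus,
    category: str = "intergenic",
) -> float:
    """Late/early mutation-density ratio implied by per-bin densities: a
    linear fit of density against the length-weighted mean timing per bin,
    evaluated at the ends of the timing scale."""
    e = consensus.bin_edges
    n_bins = len(e) - 1
    sums = np.zeros(n_bins)
    lens = np.zeros(n_bins)
    track = consensus.track
    for chrom in track.chroms:
        starts, ends, vals = track.intervals(chrom)
        for s, en, v in zip(starts, ends, vals):
            b = consensus.bin_of(float(v))
            if b is None:
                continue
            sums[b] += v * (en - s)
            lens[b] += en - s
    mean_t = np.where(lens > 0, sums / np.maximum(lens, 1), np.nan)
    sub = density[density.category == category].set_index("timing_bin")
    y = sub.loc[consensus.bin_labels(), "density_per_mb"].to_numpy()
    ok = np.isfinite(y) & np.isfinite(mean_t)
    slope, intercept = np.polyfit(mean_t[ok], y[ok], 1)
    return float((intercept + slope * e[-1]) / (intercept + slope * e[0]))


# ---------------------------------------------------------------------------
# replication strand bias

FORK_BIN_EDGES = (-1.0, -0.5, 0.0, 0.5, 1.0)


@dataclass
class ForkDirectionBins:
    """Consensus replication-fork direction per 1-kb region, in [-1, 1];
    negative values mean the reference strand is preferentially replicated
    as the lagging strand."""

    track: GenomicTrack
    bin_edges: tuple[float, ...] = FORK_BIN_EDGES
    n_dropped: int = 0

    def bin_of(self, value: float) -> int | None:
        e = self.bin_edges
        if value < e[0] or value > e[-1]:
            return None
        return min(int(np.searchsorted(e, value, side="right")) - 1, len(e) - 2)

    def bin_labels(self) -> list[str]:
        e = self.bin_edges
        return [f"({a:g},{b:g})" for a, b in zip(e, e[1:])]


def fork_direction_bins(
    tracks: Sequence[GenomicTrack],
    max_diff: float = 0.4,
) -> ForkDirectionBins:
    """Consensus fork direction; with >= 2 tracks, regions where the lines
    differ by more than ``max_diff`` are removed."""
    if not tracks:
        raise ValueError("need at least 1 fork-direction track")
    if len(tracks) > 1:
        _check_same_grid(tracks)
    intervals = []
    dropped = 0
    for chrom in tracks[0].chroms:
        starts, ends, _ = tracks[0].intervals(chrom)
        vals = np.stack([t.intervals(chrom)[2] for t in tracks])
        spread = vals.max(axis=0) - vals.min(axis=0)
        keep = spread <= max_diff
        dropped += int((~keep).sum())
        mean = vals.mean(axis=0)
        for s, e, v in zip(starts[keep], ends[keep], mean[keep]):
            intervals.append((chrom, int(s), int(e), float(v)))
    return ForkDirectionBins(GenomicTrack(intervals), n_dropped=dropped)


def replication_strand_bias(
    records: Sequence[MutationRecord],
    bins: ForkDirectionBins,
) -> pd.DataFrame:
    """Pyrimidine/purine mutation-count ratio per fork-direction bin and
    substitution class (reference-strand base identity; the covered
    territory is identical for both, so the count ratio is the density
    ratio)."""
    n_bins = len(bins.bin_edges) - 1
    comp = {"A": "T", "G": "C", "C": "G", "T": "A"}
    counts: dict[tuple[int, str], list[int]] = {}
    for r in records:
        v = bins.track.value_at(r.chrom, r.pos)
        if v is None:
            continue
        b = bins.bin_of(v)
        if b is None:
            continue
        ref, alt = r.ref.upper(), r.alt.upper()
        if ref in PYRIMIDINES:
            cls, is_pyr = f"{ref}>{alt}", True
        else:
            cls, is_pyr = f"{comp[ref]}>{comp[alt]}", False
        c = counts.setdefault((b, cls), [0, 0])
        c[0 if is_pyr else 1] += 1
    rows = []
    labels = bins.bin_labels()
    for b in range(n_bins):
        for cls in SBS_CLASSES:
            pyr, pur = counts.get((b, cls), [0, 0])
            rows.append({
                "fork_bin": labels[b], "bin_index": b, "class": cls,
                "n_pyrimidine": pyr, "n_purine": pur,
                "ratio": pyr / pur if pur > 0 else np.nan,
            })
    return pd.DataFrame(rows)


def estimate_replication_factor(bias: pd.DataFrame) -> float:
    """Lagging/leading conversion factor implied by the pyr/pur ratios in the
    two extreme fork-direction bins: sqrt(ratio_leading / ratio_lagging),
    using class-pooled counts."""
    pooled = bias.groupby("bin_index")[["n_pyrimidine", "n_purine"]].sum()
    lo = pooled.iloc[0]   # most lagging reference strand
    hi = pooled.iloc[-1]  # most leading reference strand
    r_lag = lo["n_pyrimidine"] / lo["n_purine"]
    r_lead = hi["n_pyrimidine"] / hi["n_purine"]
    return float(np.sqrt(r_lead / r_lag))


# ---------------------------------------------------------------------------
# epigenetic marks and chromatin states

def _alignable_windows(
    alignability: GenomicTrack,
    chrom_lengths: Mapping[str, int],
    window: int = 1_000,
    min_fraction: float = 0.9,
) -> dict[str, np.ndarray]:
    """Start coordinates of non-overlapping windows with alignability == 1
    over at least ``min_fraction`` of the window."""
    out = {}
    for chrom, L in chrom_lengths.items():
        starts = np.arange(0, L - window + 1, window)
        keep = []
        for s in starts:
            cov = 0
            st, en, vals = (alignability.intervals(chrom)
                            if chrom in alignability.chroms else (np.array([]),) * 3)
            for is_, ie, v in zip(st, en, vals):
                if v >= 1.0:
                    cov += max(0, min(s + window, ie) - max(s, is_))
            if cov >= min_fraction * window:
                keep.append(s)
        out[chrom] = np.asarray(keep, dtype=int)
    return out


def mark_quantile_density(
    records: Sequence[MutationRecord],
    mark: GenomicTrack,
    alignability: GenomicTrack,
    chrom_lengths: Mapping[str, int],
    annotated: Sequence[StrandAnnotatedMutation] | None = None,
    territory: GeneTerritory | None = None,
    n_quantiles: int = 5,
    window: int = 1_000,
) -> pd.DataFrame:
    """Relative mutation density per mark-intensity quantile group.

    Window mean intensities are normalized to the 1-100 range and cut into
    ``n_quantiles`` near-equal-size groups (ties broken by window order).
    Densities are normalized so the across-group weighted mean is 1. When
    ``annotated`` and ``territory`` are given, densities are additionally
    resolved by strand category."""
    wins = _alignable_windows(alignability, chrom_lengths, window)
    rows_w = []
    for chrom, starts in wins.items():
        if len(starts) == 0:
            continue
        mids = starts + window // 2
        vals = mark.values_at(chrom, mids)
        for s, v in zip(starts, vals):
            if np.isfinite(v):
                rows_w.append((chrom, int(s), float(v)))
    if not rows_w:
        raise ValueError("no alignable windows with mark coverage")
    wdf = pd.DataFrame(rows_w, columns=["chrom", "start", "value"])
    vmin, vmax = wdf["value"].min(), wdf["value"].max()
    if vmax == vmin:
        warnings.warn("all-equal mark intensities; quantile groups degenerate")
        wdf["intensity"] = 50.0
        wdf["group"] = 0
    else:
        wdf["intensity"] = 1.0 + 99.0 * (wdf["value"] - vmin) / (vmax - vmin)
        order = np.lexsort((np.arange(len(wdf)), wdf["intensity"].to_numpy()))
        group = np.empty(len(wdf), dtype=int)
        group[order] = (np.arange(len(wdf)) * n_quantiles) // len(wdf)
        wdf["group"] = group

    win_group = {
        (r.chrom, r.start): r.group for r in wdf.itertuples(index=False)
    }

    def group_of(chrom, pos):
        return win_group.get((chrom, (pos // window) * window))

    cat_of: dict[tuple[str, int], str] = {}
    if annotated is not None:
        for a in annotated:
            cat_of[(a.record.chrom, a.record.pos)] = a.strand_label.value

    counts: dict[tuple[int, str], int] = {}
    for r in records:
        g = group_of(r.chrom, r.pos)
        if g is None:
            continue
        cat = cat_of.get((r.chrom, r.pos), "all")
        counts[(g, cat)] = counts.get((g, cat), 0) + 1
        if cat != "all":
            counts[(g, "all")] = counts.get((g, "all"), 0) + 1

    group_len = wdf.groupby("group").size() * window
    cats = sorted({c for _, c in counts} | {"all"})
    rows = []
    for cat in cats:
        dens = {}
        for g in group_len.index:
            n = counts.get((g, cat), 0)
            dens[g] = n / group_len[g]
        total_n = sum(counts.get((g, cat), 0) for g in group_len.index)
        total_l = group_len.sum()
        mean_d = total_n / total_l if total_l else np.nan
        for g in group_len.index:
            rows.append({
                "quantile": int(g), "category": cat,
                "n_windows": int(group_len[g] // window),
                "count": counts.get((g, cat), 0),
                "relative_density": dens[g] / mean_d if mean_d else np.nan,
            })
    return pd.DataFrame(rows)


def chromatin_state_density(
    records: Sequence[MutationRecord],
    states: Sequence[tuple[str, int, int, str]],
    alignability: GenomicTrack | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
    window: int = 1_000,
) -> pd.DataFrame:
    """Relative mutation density per chromatin state, normalized so the
    length-weighted mean over states equals 1. ``states`` are BED-like
    (chrom, start, end, state_label) intervals; low-alignability windows are
    removed when an alignability track is supplied."""
    allowed: dict[str, set[int]] | None = None
    if alignability is not None:
        if chrom_lengths is None:
            raise ValueError("chrom_lengths required with alignability filtering")
        allowed = {
            c: set(arr.tolist())
            for c, arr in _alignable_windows(alignability, chrom_lengths, window).items()
        }

    def win_ok(chrom, pos):
        if allowed is None:
            return True
        return (pos // window) * window in allowed.get(chrom, ())

    state_len: dict[str, float] = {}
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, s, e, lab in states:
        by_chrom.setdefault(chrom, []).append((int(s), int(e), lab))
        if allowed is None:
            state_len[lab] = state_len.get(lab, 0) + (e - s)
        else:
            for w in allowed.get(chrom, ()):
                ov = max(0, min(e, w + window) - max(s, w))
                state_len[lab] = state_len.get(lab, 0) + ov
    lookup: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom, lst in by_chrom.items():
        lst.sort()
        lookup[chrom] = (
            np.array([i[0] for i in lst]),
            np.array([i[1] for i in lst]),
            [i[2] for i in lst],
        )

    counts: dict[str, int] = {}
    for r in records:
        if not win_ok(r.chrom, r.pos):
            continue
        entry = lookup.get(r.chrom)
        if entry is None:
            continue
        starts, ends, labs = entry
        i = int(np.searchsorted(starts, r.pos, side="right")) - 1
        if i >= 0 and r.pos < ends[i]:
            counts[labs[i]] = counts.get(labs[i], 0) + 1

    total_n = sum(counts.values())
    total_l = sum(state_len.values())
    mean_d = total_n / total_l if total_l else np.nan
    rows = []
    for lab in sorted(state_len):
        L = state_len[lab]
        n = counts.get(lab, 0)
        rows.append({
            "state": lab, "count": n, "length_bp": int(L),
            "relative_density": (n / L) / mean_d if L > 0 and mean_d else np.nan,
        })
    return pd.DataFrame(rows).set_index("state")


# ---------------------------------------------------------------------------
# strand-resolved signature contrast

def strandwise_signature_contrast(
    annotated: Sequence[StrandAnnotatedMutation],
    genome,
    signatures: SignatureSet,
    active_min: float = 2.0,
    silent_max: float = 0.05,
    min_mutations: int = 50,
) -> pd.DataFrame:
    """Refit signature exposures separately for the four sub-catalogs
    strand x transcriptional activity (active: expression > active_min;
    silent: expression < silent_max); sub-catalogs below ``min_mutations``
    return NA fractions."""
    from .channels import build_matrix

    subsets: dict[tuple[str, str], list[MutationRecord]] = {}
    for a in annotated:
        if a.strand_label not in (StrandLabel.TRANSCRIBED, StrandLabel.UNTRANSCRIBED):
            continue
        if a.expression > active_min:
            act = "active"
        elif a.expression < silent_max:
            act = "silent"
        else:
            continue
        subsets.setdefault((a.strand_label.value, act), []).append(a.record)

    rows = []
    for (strand, act), recs in sorted(subsets.items()):
        n = len(recs)
        if n < min_mutations:
            warnings.warn(f"sub-catalog {strand}/{act} has only {n} mutations; NA")
            for sig in signatures.profiles.columns:
                rows.append({"strand": strand, "activity": act, "signature": sig,
                             "n_mutations": n, "fraction": np.nan})
            continue
        pooled = [  # pool samples: contrast is about strands, not samples
            MutationRecord(sample_id="pooled", chrom=r.chrom, pos=r.pos,
                           ref=r.ref, alt=r.alt, vaf=r.vaf,
                           fwd_support=r.fwd_support, rev_support=r.rev_support)
            for r in recs
        ]
        mat = build_matrix(pooled, signatures.scheme, genome)
        expo, _ = refit_exposures(mat, signatures)
        frac = expo.fractions().iloc[0]
        for sig in signatures.profiles.columns:
            rows.append({"strand": strand, "activity": act, "signature": sig,
                         "n_mutations": n, "fraction": float(frac[sig])})
    return pd.DataFrame(rows)
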