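"""Synthetic scenes with known ground truth for every analysis.

The generator emulates the data a whole-genome somatic study consumes: a
small random genome with genes on both strands and log-uniform expression,
1-kb replication-timing tracks for several cell lines, a fork-direction
track derived from the timing gradient, epigenetic-mark and mappability
tracks, chromatin states, and per-sample mutation catalogs.

Mutation placement is lesion-first: lesions arise on purines uniformly,
modulated by replication timing; conversion to a mutation is reduced on
template strands of expressed genes (transcription-coupled repair) and
increased on strands replicated as lagging (error-prone translesion
bypass). Transcriptional and replicational asymmetries therefore arise
mechanistically rather than by post-hoc labeling, and every emitted variant
carries its latent labels in a truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import (
    GeneModel,
    GenomicTrack,
    MutationRecord,
    revcomp,
    write_vcf,
)
from .channels import SBS96_LABELS
from .timing import SCNASegment, SCNAType, expected_vaf

__all__ = [
    "GenomeSpec",
    "MutagenesisSpec",
    "SCNASimSpec",
    "SyntheticGenome",
    "SyntheticTracks",
    "make_genome",
    "make_tracks",
    "make_catalog",
    "make_scna_catalog",
    "default_signatures",
    "write_scene",
]

_OFFSET = 1 << 40
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GenomeSpec:
    """Desk-scale genome: a few megabase chromosomes, genes on both strands
    without opposite-strand overlap, log-uniform expression."""

    n_chroms: int = 2
    chrom_length: int = 5_000_000
    gc_content: float = 0.42
    n_genes: int = 100
    gene_length_range: tuple[int, int] = (10_000, 60_000)
    expression_log10_range: tuple[float, float] = (-2.0, 3.0)
    seed: int = 0

    def __post_init__(self):
        if self.chrom_length < 100_000:
            raise ValueError("chromosomes must be >= 100 kb for TSS analyses")
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must lie in (0, 1)")


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    genes: list[GeneModel]
    spec: GenomeSpec

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_gene_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for g in self.genes:
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")

    def write_expression_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\texpression\n")
            for g in self.genes:
                fh.write(f"{g.gene_id}\t{g.expression:.6g}\n")


def make_genome(spec: GenomeSpec) -> SyntheticGenome:
    """Random genome with non-overlapping genes alternating strands at
    random, expression log-uniform over the configured range."""
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    sequences = {}
    for i in range(spec.n_chroms):
        codes = rng.choice(4, size=spec.chrom_length, p=probs)
        sequences[f"chr{i + 1}"] = _BASES[codes].tobytes().decode()

    per_chrom = np.full(spec.n_chroms, spec.n_genes // spec.n_chroms)
    per_chrom[: spec.n_genes % spec.n_chroms] += 1
    genes: list[GeneModel] = []
    gid = 0
    lo_len, hi_len = spec.gene_length_range
    lo_e, hi_e = spec.expression_log10_range
    for ci in range(spec.n_chroms):
        chrom = f"chr{ci + 1}"
        n = int(per_chrom[ci])
        lengths = np.exp(rng.uniform(np.log(lo_len), np.log(hi_len), n)).astype(int)
        total = int(lengths.sum())
        free = spec.chrom_length - total - 120_000  # margins for TSS flanks
        if free < (n + 1) * 1_000:
            raise ValueError("infeasible gene packing: genome too small")
        gaps = rng.multinomial(free - (n + 1) * 1_000, np.ones(n + 1) / (n + 1)) + 1_000
        cur = 60_000 + int(gaps[0])
        for k in range(n):
            strand = "+" if rng.random() < 0.5 else "-"
            expr = float(10.0 ** rng.uniform(lo_e, hi_e))
            genes.append(GeneModel(f"G{gid:04d}", chrom, cur, cur + int(lengths[k]),
                                   strand, expr))
            gid += 1
            cur += int(lengths[k]) + int(gaps[k + 1])
    return SyntheticGenome(sequences, genes, spec)


@dataclass
class SyntheticTracks:
    """All genomic tracks of one scene, on a common 1-kb grid."""

    timing_tracks: list[GenomicTrack]          # one per cell line
    fork_tracks: list[GenomicTrack]            # two "experiments"
    mark_tracks: dict[str, GenomicTrack]
    mappability: GenomicTrack
    chromatin_states: list[tuple[str, int, int, str]]
    timing_surface: dict[str, np.ndarray]      # latent truth per chrom
    fork_surface: dict[str, np.ndarray]
    grid: int = 1_000


def make_tracks(
    genome: SyntheticGenome,
    seed: int = 0,
    n_timing_lines: int = 4,
    timing_noise_sd: float = 3.0,
    discordant_fraction: float = 0.01,
    fork_noise_sd: float = 0.05,
    unmappable_fraction: float = 0.02,
    grid: int = 1_000,
) -> SyntheticTracks:
    """Smooth replication-timing surface (range ~10-85) with per-cell-line
    noise and a small fraction of planted discordant regions; fork direction
    as the saturated gradient of timing; marks coupled to timing and to gene
    expression; mappability mostly 1 with a few zero stretches; chromatin
    states from timing terciles."""
    rng = np.random.default_rng(seed)
    timing_surface: dict[str, np.ndarray] = {}
    fork_surface: dict[str, np.ndarray] = {}
    timing_tracks = [[] for _ in range(n_timing_lines)]
    fork_tracks = [[], []]
    mark_names = ["H3K36me3_like", "H3K9me3_like"]
    marks: dict[str, list] = {m: [] for m in mark_names}
    mappability: list = []
    states: list[tuple[str, int, int, str]] = []

    # expression boost territory per chrom (gene bodies weighted by expression)
    expr_boost: dict[str, np.ndarray] = {}
    for chrom, L in genome.chrom_lengths.items():
        nw = L // grid
        boost = np.zeros(nw)
        for g in genome.genes:
            if g.chrom != chrom:
                continue
            w0, w1 = g.start // grid, min(g.end // grid, nw)
            boost[w0:w1] = np.log10(1.0 + g.expression)
        expr_boost[chrom] = boost

    period = 2_000_000.0
    for ci, (chrom, L) in enumerate(genome.chrom_lengths.items()):
        nw = L // grid
        x = (np.arange(nw) + 0.5) * grid
        phase = ci * 1.3
        surface = 47.5 + 37.5 * np.sin(2 * np.pi * x / period + phase)
        timing_surface[chrom] = surface
        fork = np.tanh(4.0 * np.cos(2 * np.pi * x / period + phase))
        fork_surface[chrom] = fork

        discord = rng.random(nw) < discordant_fraction
        for li in range(n_timing_lines):
            vals = surface + rng.normal(0.0, timing_noise_sd, nw)
            if li == 0:
                vals = np.where(discord, vals + 60.0, vals)
            timing_tracks[li].append((chrom, vals))
        for fi in range(2):
            vals = np.clip(fork + rng.normal(0.0, fork_noise_sd, nw), -1.0, 1.0)
            fork_tracks[fi].append((chrom, vals))

        active = 100.0 - surface + 20.0 * expr_boost[chrom]
        repressive = surface + rng.normal(0, 2.0, nw)
        marks["H3K36me3_like"].append((chrom, active))
        marks["H3K9me3_like"].append((chrom, repressive))

        # mappability: a few unmappable 50-window stretches
        mp = np.ones(nw)
        n_holes = max(0, int(round(unmappable_fraction * nw / 50)))
        for _ in range(n_holes):
            s = int(rng.integers(0, max(1, nw - 50)))
            mp[s : s + 50] = 0.0
        mappability.append((chrom, mp))

        terciles = np.quantile(surface, [1 / 3, 2 / 3])
        lab = np.where(surface <= terciles[0], "early_active",
                       np.where(surface <= terciles[1], "mid", "late_quiet"))
        s0 = 0
        for i in range(1, nw + 1):
            if i == nw or lab[i] != lab[s0]:
                states.append((chrom, s0 * grid, i * grid, str(lab[s0])))
                s0 = i

    def to_track(chunks) -> GenomicTrack:
        ivals = []
        for chrom, vals in chunks:
            for i, v in enumerate(vals):
                ivals.append((chrom, i * grid, (i + 1) * grid, float(v)))
        return GenomicTrack(ivals)

    return SyntheticTracks(
        timing_tracks=[to_track(t) for t in timing_tracks],
        fork_tracks=[to_track(t) for t in fork_tracks],
        mark_tracks={m: to_track(v) for m, v in marks.items()},
        mappability=to_track(mappability),
        chromatin_states=states,
        timing_surface=timing_surface,
        fork_surface=fork_surface,
        grid=grid,
    )


def default_signatures() -> pd.DataFrame:
    """Two well-separated 96-channel signatures: a dominant broad profile
    concentrated on C>A and C>T (the NER-deficiency-like pattern) and a
    background profile on C>G and T>C."""
    idx = pd.Index(SBS96_LABELS, name="channel")
    s1 = pd.Series(0.0, index=idx)
    s2 = pd.Series(0.0, index=idx)
    for lab in SBS96_LABELS:
        sub = lab[2:5]
        five, three = lab[0], lab[6]
        if sub in ("C>A", "C>T"):
            s1[lab] = 2.0 if five in "CT" else 1.0
        if sub in ("C>G", "T>C"):
            s2[lab] = 2.0 if three in "AG" else 1.0
    return pd.DataFrame({"sigC_like": s1 / s1.sum(), "background": s2 / s2.sum()})


@dataclass(frozen=True)
class MutagenesisSpec:
    """Mutational process parameters; the defaults are the conditions the
    recovery analyses assume."""

    signatures: pd.DataFrame = field(default_factory=default_signatures)
    mixture: tuple[float, ...] = (0.83, 0.17)
    # optional per-sample mixtures (rows = samples); identical mixtures make
    # the cohort matrix rank-1 and signatures unidentifiable by NMF
    mixture_by_sample: tuple[tuple[float, ...], ...] | None = None
    n_sbs: int = 5_000
    n_samples: int = 6
    trb_factor: float = 2.0
    trb_expression_coupling: tuple[float, ...] = (0.0, 0.25, 0.6, 1.0)
    # which signatures are lesion-driven (subject to TRB and replication
    # modulation); the background process is symmetric
    lesion_signatures: tuple[int, ...] = (0,)
    expression_bin_edges: tuple[float, ...] = (0.0, 0.1, 1.0, 10.0, 20_000.0)
    replication_factor: float = 1.4
    timing_gradient: float = 1.5
    cluster_fraction: float = 0.003
    cluster_max_gap: int = 16
    dbs_fraction: float = 0.006
    indel_fraction: float = 0.07
    depth: int = 45
    mean_vaf: float = 0.45
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.mixture) - 1.0) > 1e-9:
            raise ValueError("mixture fractions must sum to 1")
        if len(self.mixture) != self.signatures.shape[1]:
            raise ValueError("one mixture fraction per signature required")
        if self.mixture_by_sample is not None:
            if len(self.mixture_by_sample) != self.n_samples:
                raise ValueError("one mixture per sample required")
            for mx in self.mixture_by_sample:
                if abs(sum(mx) - 1.0) > 1e-9:
                    raise ValueError("each sample mixture must sum to 1")
        if min(self.trb_factor, self.replication_factor, self.timing_gradient) <= 0:
            raise ValueError("asymmetry factors must be positive")


class _Scene:
    """Precomputed per-bp lookups used during placement."""

    def __init__(self, genome: SyntheticGenome, tracks: SyntheticTracks,
                 spec: MutagenesisSpec):
        self.grid = tracks.grid
        self.chroms = list(genome.sequences)
        self.timing = tracks.timing_surface
        self.fork = tracks.fork_surface
        edges = spec.expression_bin_edges
        coupling = spec.trb_expression_coupling
        self.gene_strand: dict[str, np.ndarray] = {}
        self.gene_eff: dict[str, np.ndarray] = {}
        for chrom, L in genome.chrom_lengths.items():
            strand = np.zeros(L, dtype=np.int8)  # 0 none, +1, -1
            eff = np.ones(L, dtype=np.float32)
            for g in genome.genes:
                if g.chrom != chrom:
                    continue
                b = int(np.clip(np.searchsorted(edges, g.expression, side="right") - 1,
                                0, len(coupling) - 1))
                factor = 1.0 + (spec.trb_factor - 1.0) * coupling[b]
                strand[g.start:g.end] = 1 if g.strand == "+" else -1
                eff[g.start:g.end] = factor
            self.gene_strand[chrom] = strand
            self.gene_eff[chrom] = eff

    def weights(self, chrom_idx: np.ndarray, pos: np.ndarray,
                pyr_plus: np.ndarray, spec: MutagenesisSpec,
                lesion_driven: bool = True) -> np.ndarray:
        w = np.ones(len(pos))
        for ci in np.unique(chrom_idx):
            chrom = self.chroms[ci]
            m = chrom_idx == ci
            p = pos[m]
            t = self.timing[chrom][np.clip(p // self.grid, 0, len(self.timing[chrom]) - 1)]
            wt = 1.0 + (spec.timing_gradient - 1.0) * (t - 10.0) / 75.0
            if not lesion_driven:
                w[m] = wt
                continue
            f = self.fork[chrom][np.clip(p // self.grid, 0, len(self.fork[chrom]) - 1)]
            # lesion is on the purine strand, opposite the pyrimidine
            purine_plus = ~pyr_plus[m]
            lag_prob = np.where(purine_plus, (1.0 - f) / 2.0, (1.0 + f) / 2.0)
            wr = 1.0 + (spec.replication_factor - 1.0) * lag_prob
            gs = self.gene_strand[chrom][p]
            purine_sign = np.where(purine_plus, 1, -1)
            on_template = (gs != 0) & (purine_sign != gs)
            eff = self.gene_eff[chrom][p].astype(float)
            wtrb = np.where(on_template, 1.0 / eff, 1.0)
            w[m] = wt * wr * wtrb
        return w


def _site_index(genome: SyntheticGenome) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Eligible sites per pyrimidine-centric trinucleotide: global positions
    and whether the pyrimidine sits on the + strand."""
    from .clusters import _encode, _COMP_CODE

    out: dict[str, list] = {}
    bases = "ACGT"
    for ci, (chrom, seq) in enumerate(genome.sequences.items()):
        codes = _encode(seq)
        n = codes.size
        pos = np.arange(1, n - 1)
        tri = np.stack([codes[:-2], codes[1:-1], codes[2:]])
        ok = (tri < 4).all(axis=0)
        center = tri[1]
        pyr_plus = (center == 1) | (center == 3)  # C or T on + strand
        canon = np.where(pyr_plus[None, :], tri, _COMP_CODE[tri][::-1, :])
        key = canon[0].astype(np.int64) * 16 + canon[1] * 4 + canon[2]
        key[~ok] = -1
        for code in np.unique(key[key >= 0]):
            s = ""
            c = int(code)
            for _ in range(3):
                s = bases[c % 4] + s
                c //= 4
            m = key == code
            out.setdefault(s, []).append(
                (pos[m] + ci * _OFFSET, pyr_plus[m])
            )
    return {
        k: (np.concatenate([c[0] for c in chunks]),
            np.concatenate([c[1] for c in chunks]))
        for k, chunks in out.items()
    }


def _draw_reads(rng, n: int, depth: int, mean_vaf: float):
    alt = rng.binomial(depth, mean_vaf, n)
    alt = np.maximum(alt, 1)
    fwd = rng.binomial(alt, 0.5)
    rev = alt - fwd
    return alt / depth, fwd, rev


def make_catalog(
    genome: SyntheticGenome,
    tracks: SyntheticTracks,
    spec: MutagenesisSpec,
) -> tuple[list[MutationRecord], pd.DataFrame]:
    """Per-sample mutation catalogs with full latent truth.

    Returns all samples' records plus a truth table with one row per variant
    (signature, lesion strand, gene context, cluster id, timing and fork
    values at the site)."""
    rng = np.random.default_rng(spec.seed)
    sites = _site_index(genome)
    scene = _Scene(genome, tracks, spec)
    sig_p = spec.signatures.to_numpy(dtype=float)
    channel_context = {lab: lab[0] + lab[2] + lab[6] for lab in SBS96_LABELS}
    mix_p = np.array(spec.mixture)
    missing = sorted(
        {channel_context[lab] for lab in SBS96_LABELS
         if sig_p[SBS96_LABELS.index(lab)].sum() > 0
         and channel_context[lab] not in sites}
    )
    if missing:
        raise ValueError(f"contexts unattainable in this genome: {missing}")

    w_max = spec.timing_gradient * spec.replication_factor
    comp = str.maketrans("ACGT", "TGCA")
    records: list[MutationRecord] = []
    truth_rows: list[dict] = []

    for si in range(spec.n_samples):
        sample = f"S{si + 1:02d}"
        sample_mix = (np.array(spec.mixture_by_sample[si])
                      if spec.mixture_by_sample is not None else mix_p)
        n_extra = int(round(spec.cluster_fraction * spec.n_sbs))
        n_base = spec.n_sbs - n_extra
        sig_ids = rng.choice(len(mix_p), size=n_base, p=sample_mix)
        placed: list[tuple] = []  # (global_pos, channel, pyr_plus, sig)
        taken: set[int] = set()
        for k, f in enumerate(mix_p):
            n_k = int((sig_ids == k).sum())
            lesion_driven = k in spec.lesion_signatures
            chans = rng.choice(96, size=n_k, p=sig_p[:, k] / sig_p[:, k].sum())
            for lab_idx in np.unique(chans):
                lab = SBS96_LABELS[lab_idx]
                ctx = channel_context[lab]
                need = int((chans == lab_idx).sum())
                gpos, pyr = sites[ctx]
                got = 0
                while got < need:
                    batch = max(64, 2 * (need - got))
                    idx = rng.integers(0, len(gpos), batch)
                    cand, cpyr = gpos[idx], pyr[idx]
                    ci = (cand // _OFFSET).astype(int)
                    p = (cand % _OFFSET).astype(int)
                    w = scene.weights(ci, p, cpyr, spec, lesion_driven)
                    acc = rng.random(batch) < w / w_max
                    for g, ispyr in zip(cand[acc], cpyr[acc]):
                        if got >= need:
                            break
                        if int(g) in taken:
                            continue
                        taken.add(int(g))
                        placed.append((int(g), lab, bool(ispyr), k))
                        got += 1

        # short clusters: extra mutations planted near random anchors
        cluster_ids = {}
        extras: list[tuple] = []
        if n_extra > 0 and placed:
            anchors = rng.choice(len(placed), size=n_extra, replace=False)
            for cid, ai in enumerate(anchors):
                g0, _, _, k0 = placed[ai]
                gap = int(rng.integers(1, spec.cluster_max_gap + 1))
                g1 = g0 + gap if rng.random() < 0.5 else g0 - gap
                chrom = scene.chroms[g0 // _OFFSET]
                p1 = g1 % _OFFSET
                if p1 < 1 or p1 >= len(genome.sequences[chrom]) - 1 or g1 in taken:
                    continue
                ref = genome.sequences[chrom][p1]
                if ref == "N":
                    continue
                alt = rng.choice([b for b in "ACGT" if b != ref])
                taken.add(int(g1))
                extras.append((int(g1), ref, str(alt), k0))
                cluster_ids[int(g0)] = cid
                cluster_ids[int(g1)] = cid

        vafs, fwds, revs = _draw_reads(rng, len(placed) + len(extras),
                                       spec.depth, spec.mean_vaf)
        ri = 0
        for g, lab, pyr_plus, k in placed:
            chrom = scene.chroms[g // _OFFSET]
            p = g % _OFFSET
            ref_pyr, alt_pyr = lab[2], lab[4]
            if pyr_plus:
                ref, alt = ref_pyr, alt_pyr
            else:
                ref, alt = ref_pyr.translate(comp), alt_pyr.translate(comp)
            rec = MutationRecord(
                sample_id=sample, chrom=chrom, pos=p, ref=ref, alt=alt,
                vaf=float(vafs[ri]), fwd_support=int(fwds[ri]), rev_support=int(revs[ri]),
                info={"XSIM_SIG": spec.signatures.columns[k],
                      "XSIM_CLUSTER": str(cluster_ids.get(g, -1))},
            )
            records.append(rec)
            truth_rows.append(_truth_row(rec, scene, lab, pyr_plus, k, spec,
                                         cluster_ids.get(g, -1)))
            ri += 1
        for g, ref, alt, k in extras:
            chrom = scene.chroms[g // _OFFSET]
            p = g % _OFFSET
            rec = MutationRecord(
                sample_id=sample, chrom=chrom, pos=p, ref=ref, alt=alt,
                vaf=float(vafs[ri]), fwd_support=int(fwds[ri]), rev_support=int(revs[ri]),
                info={"XSIM_SIG": spec.signatures.columns[k],
                      "XSIM_CLUSTER": str(cluster_ids.get(g, -1))},
            )
            records.append(rec)
            pyr_plus = ref in "CT"
            truth_rows.append(_truth_row(rec, scene, None, pyr_plus, k, spec,
                                         cluster_ids.get(g, -1)))
            ri += 1

        records.extend(_make_dbs(genome, rng, sample, spec, truth_rows))
        records.extend(_make_indels(genome, rng, sample, spec, truth_rows))

    truth = pd.DataFrame(truth_rows)
    return records, truth


def _truth_row(rec, scene: _Scene, channel, pyr_plus, sig_idx, spec, cluster_id):
    chrom = rec.chrom
    grid = scene.grid
    widx = min(rec.pos // grid, len(scene.timing[chrom]) - 1)
    gs = int(scene.gene_strand[chrom][rec.pos])
    purine_sign = -1 if pyr_plus else 1
    if gs == 0:
        label = "intergenic"
    elif purine_sign != gs:
        label = "untranscribed"  # purine lesion on template; pyr on coding
    else:
        label = "transcribed"
    return {
        "sample": rec.sample_id, "chrom": chrom, "pos": rec.pos,
        "ref": rec.ref, "alt": rec.alt, "mut_class": rec.mut_class.value,
        "signature": spec.signatures.columns[sig_idx],
        "channel": channel, "pyr_on_plus": bool(pyr_plus),
        "lesion_strand": "-" if pyr_plus else "+",
        "strand_label": label,
        "timing": float(scene.timing[chrom][widx]),
        "fork": float(scene.fork[chrom][widx]),
        "cluster_id": cluster_id,
    }


def _make_dbs(genome, rng, sample, spec, truth_rows) -> list[MutationRecord]:
    n = int(round(spec.dbs_fraction * spec.n_sbs))
    out = []
    chroms = list(genome.sequences)
    vafs, fwds, revs = _draw_reads(rng, n, spec.depth, spec.mean_vaf)
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        seq = genome.sequences[chrom]
        p = int(rng.integers(1, len(seq) - 2))
        ref = seq[p : p + 2]
        if "N" in ref:
            continue
        alt = "".join(str(rng.choice([b for b in "ACGT" if b != r])) for r in ref)
        rec = MutationRecord(sample_id=sample, chrom=chrom, pos=p, ref=ref, alt=alt,
                             vaf=float(vafs[i]), fwd_support=int(fwds[i]),
                             rev_support=int(revs[i]), info={"XSIM_SIG": "dbs_bg"})
        out.append(rec)
        truth_rows.append({"sample": sample, "chrom": chrom, "pos": p, "ref": ref,
                           "alt": alt, "mut_class": "DBS", "signature": "dbs_bg",
                           "channel": None, "pyr_on_plus": None, "lesion_strand": None,
                           "strand_label": None, "timing": np.nan, "fork": np.nan,
                           "cluster_id": -1})
    return out


def _make_indels(genome, rng, sample, spec, truth_rows) -> list[MutationRecord]:
    """Mostly 1-bp deletions of C:G in homopolymer stretches (the dominant
    observed indel pattern), plus 1-bp insertions and a few longer
    deletions."""
    n = int(round(spec.indel_fraction * spec.n_sbs))
    out = []
    chroms = list(genome.sequences)
    vafs, fwds, revs = _draw_reads(rng, n, spec.depth, spec.mean_vaf)
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        seq = genome.sequences[chrom]
        p = int(rng.integers(100, len(seq) - 100))
        u = rng.random()
        if u < 0.6:  # 1-bp deletion
            ref = seq[p : p + 2]
            alt = seq[p]
        elif u < 0.85:  # 1-bp insertion
            ref = seq[p]
            ins = str(rng.choice(list("ACGT")))
            alt = ref + ins
        else:  # 2-4 bp deletion
            k = int(rng.integers(2, 5))
            ref = seq[p : p + 1 + k]
            alt = seq[p]
        if "N" in ref or ref == alt:
            continue
        rec = MutationRecord(sample_id=sample, chrom=chrom, pos=p, ref=ref, alt=alt,
                             vaf=float(vafs[i]), fwd_support=int(fwds[i]),
                             rev_support=int(revs[i]), info={"XSIM_SIG": "id_bg"})
        out.append(rec)
        truth_rows.append({"sample": sample, "chrom": chrom, "pos": p, "ref": ref,
                           "alt": alt, "mut_class": "ID", "signature": "id_bg",
                           "channel": None, "pyr_on_plus": None, "lesion_strand": None,
                           "strand_label": None, "timing": np.nan, "fork": np.nan,
                           "cluster_id": -1})
    return out


def make_channel_matrix(
    signatures: pd.DataFrame,
    exposures: np.ndarray,
    n_mutations: int | Sequence[int],
    seed: int,
    scheme: str = "SBS96",
):
    """Channel count matrix drawn multinomially from known signature
    mixtures: sample s gets n_mutations[s] draws from signatures @
    exposures[s]. Returns the matrix and the exact expected profile truth."""
    from .channels import ChannelMatrix, SCHEMES

    rng = np.random.default_rng(seed)
    expo = np.asarray(exposures, dtype=float)
    if expo.ndim != 2 or expo.shape[1] != signatures.shape[1]:
        raise ValueError("exposures must be samples x signatures")
    expo = expo / expo.sum(axis=1, keepdims=True)
    n_samples = expo.shape[0]
    ns = np.full(n_samples, n_mutations) if np.isscalar(n_mutations) else np.asarray(n_mutations)
    S = signatures.to_numpy(dtype=float)
    counts = np.stack([
        rng.multinomial(int(ns[s]), S @ expo[s]) for s in range(n_samples)
    ])
    df = pd.DataFrame(counts, index=[f"S{i + 1:02d}" for i in range(n_samples)],
                      columns=SCHEMES[scheme])
    return ChannelMatrix(scheme=scheme, counts=df)


# ---------------------------------------------------------------------------
# SCNA timing scenes

@dataclass(frozen=True)
class SCNASimSpec:
    """Clonal copy-number segments with binomially sampled VAFs at a known
    pre-event mutation fraction."""

    segments: tuple[tuple[str, int, int, int, int, float, str], ...] = (
        # chrom, start, end, total_cn, minor_cn, purity, type
        ("chr1", 0, 1_000_000, 3, 1, 0.9, "gain"),
        ("chr1", 1_500_000, 2_500_000, 3, 1, 0.75, "gain"),
        ("chr1", 3_000_000, 4_000_000, 2, 0, 0.85, "cnLOH"),
        ("chr2", 0, 1_000_000, 2, 0, 0.95, "cnLOH"),
        ("chr2", 1_500_000, 2_500_000, 4, 1, 0.8, "gain"),
        ("chr2", 3_000_000, 4_000_000, 2, 0, 0.7, "cnLOH"),
        ("chr1", 4_200_000, 4_900_000, 3, 0, 0.9, "gain"),
        ("chr2", 4_200_000, 4_900_000, 2, 0, 0.65, "cnLOH"),
    )
    fraction_before: float = 0.75
    depth: int = 45
    mutations_per_segment: int = 300
    sample_id: str = "SCNA1"
    seed: int = 0

    def __post_init__(self):
        if self.depth < 10:
            raise ValueError("depth must be >= 10")
        if not (0.0 <= self.fraction_before <= 1.0):
            raise ValueError("fraction_before must lie in [0, 1]")


def make_scna_catalog(
    spec: SCNASimSpec,
) -> tuple[list[MutationRecord], list[SCNASegment], pd.DataFrame]:
    """Mutations in duplicated-allele segments: epoch drawn at the true
    pre-event fraction, multiplicity from epoch, read counts binomial at the
    stated depth around the expected VAF."""
    rng = np.random.default_rng(spec.seed)
    segments = [
        SCNASegment(c, s, e, t, m, p, SCNAType(ty))
        for c, s, e, t, m, p, ty in spec.segments
    ]
    records: list[MutationRecord] = []
    rows = []
    for gi, seg in enumerate(segments):
        n = spec.mutations_per_segment
        pos = np.sort(rng.choice(np.arange(seg.start, seg.end), size=n, replace=False))
        # epochs: per-copy opportunity makes post-event mutations T times as
        # likely per unit time; the stated fraction is of copy-normalized
        # counts, so raw counts are drawn to match it after normalization
        fb = spec.fraction_before
        p_before_raw = fb / (fb + (1 - fb) * seg.total_cn)
        before = rng.random(n) < p_before_raw
        for i in range(n):
            m = 2 if before[i] else 1
            ev = expected_vaf(seg.purity, seg.total_cn, m)
            alt = int(rng.binomial(spec.depth, ev))
            vaf = alt / spec.depth
            fwd = int(rng.binomial(alt, 0.5)) if alt else 0
            rec = MutationRecord(
                sample_id=spec.sample_id, chrom=seg.chrom, pos=int(pos[i]),
                ref="A", alt="G", vaf=vaf, fwd_support=fwd, rev_support=alt - fwd,
                info={"XSIM_EPOCH": "before" if before[i] else "after",
                      "XSIM_SEGMENT": str(gi)},
            )
            records.append(rec)
            rows.append({"sample": spec.sample_id, "segment": gi, "chrom": seg.chrom,
                         "pos": int(pos[i]), "epoch": "before" if before[i] else "after",
                         "multiplicity": m, "expected_vaf": ev, "vaf": vaf})
    return records, segments, pd.DataFrame(rows)


def write_scene(
    genome: SyntheticGenome,
    tracks: SyntheticTracks,
    records: Sequence[MutationRecord],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write a full scene to disk in standard formats (FASTA, BED, TSV,
    bedGraph, one VCF per sample)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    genome.write_fasta(out / "genome.fa")
    genome.write_gene_bed(out / "genes.bed")
    genome.write_expression_tsv(out / "expression.tsv")
    paths["fasta"] = out / "genome.fa"
    paths["genes"] = out / "genes.bed"
    paths["expression"] = out / "expression.tsv"
    for i, t in enumerate(tracks.timing_tracks):
        p = out / f"timing_line{i + 1}.bedgraph"
        t.to_bedgraph(p)
        paths[f"timing_{i}"] = p
    for i, t in enumerate(tracks.fork_tracks):
        p = out / f"fork_line{i + 1}.bedgraph"
        t.to_bedgraph(p)
        paths[f"fork_{i}"] = p
    for name, t in tracks.mark_tracks.items():
        p = out / f"mark_{name}.bedgraph"
        t.to_bedgraph(p)
        paths[f"mark_{name}"] = p
    tracks.mappability.to_bedgraph(out / "mappability.bedgraph")
    paths["mappability"] = out / "mappability.bedgraph"
    with open(out / "chromatin_states.bed", "w") as fh:
        for chrom, s, e, lab in tracks.chromatin_states:
            fh.write(f"{chrom}\t{s}\t{e}\t{lab}\n")
    paths["states"] = out / "chromatin_states.bed"
    by_sample: dict[str, list[MutationRecord]] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, []).append(r)
    for sample, recs in sorted(by_sample.items()):
        p = out / f"{sample}.vcf"
        write_vcf(recs, p, genome.chrom_lengths)
        paths[f"vcf_{sample}"] = p
    return paths
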