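"""Monte Carlo test for clustered somatic mutations.

Random catalogs are drawn uniformly over the mappable genome, constrained to
reproduce each sample's nucleotide-context spectrum exactly (a discrete
homogeneous Poisson point process conditioned on context counts). Observed
intermutation distances are then compared with the simulated null in 5-bp
sliding windows across 2..10,000 bp, with a Wilcoxon signed-rank test across
samples per window and Bonferroni correction over windows.

Two samplers are provided. The literal sampler follows the published
rejection loop verbatim: draw a uniform position, accept it while its
context quota is unfilled. The default stratified sampler draws, for each
context, the quota of positions uniformly from that context's eligible
sites; because uniform draws conditioned on a context are uniform over that
context's sites, the two samplers generate the same distribution, and the
stratified one is orders of magnitude faster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import GenomicTrack, MutationRecord, revcomp
from .exactstats import bonferroni, wilcoxon_signed_rank_exact

__all__ = [
    "SimConfig",
    "SimResult",
    "ContextIndex",
    "simulate_random_catalog",
    "observed_distances",
    "observed_spectrum",
    "cluster_scan",
    "cluster_membership",
]

_CHROM_OFFSET = 1 << 40  # separates chromosomes in a single coordinate axis


@dataclass(frozen=True)
class SimConfig:
    """Monte Carlo configuration: number of replicates, maximal recorded
    intermutation distance, context width (0 = context-free, 3 or 5) and
    the RNG seed."""

    n_sim: int = 1000
    max_distance: int = 10_000
    context_size: int = 3
    seed: int = 0
    keep_positions: bool = False

    def __post_init__(self):
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        if self.max_distance < 2:
            raise ValueError("max_distance must be >= 2")
        if self.context_size not in (0, 3, 5):
            raise ValueError("context_size must be 0, 3 or 5")


@dataclass
class SimResult:
    """Per-replicate distances (and optionally positions) from one sample's
    simulation."""

    distances: list[np.ndarray]
    positions: list[np.ndarray] | None = None  # global sortable coordinates
    context_labels: list[str] = field(default_factory=list)


class ContextIndex:
    """Eligible positions per pyrimidine-centric context within mappable
    regions of a genome."""

    def __init__(self, genome, regions: GenomicTrack, context_size: int = 3):
        if context_size not in (0, 3, 5):
            raise ValueError("context_size must be 0, 3 or 5")
        self.context_size = context_size
        self.chroms: list[str] = list(regions.chroms)
        self.chrom_index: dict[str, int] = {}
        pos_by_ctx: dict[str, list[np.ndarray]] = {}
        for ci, chrom in enumerate(regions.chroms):
            self.chrom_index[chrom] = ci
            seq = _chrom_seq(genome, chrom)
            codes = _encode(seq)
            starts, ends, _ = regions.intervals(chrom)
            sel = np.concatenate(
                [np.arange(s, e) for s, e in zip(starts, ends)]
            ) if len(starts) else np.array([], dtype=int)
            if context_size == 0:
                labels = np.zeros(sel.size, dtype=int)
                lut = ["*"]
            else:
                labels, lut = _context_codes(codes, sel, context_size)
            for k, lab in enumerate(lut):
                mask = labels == k
                if not mask.any():
                    continue
                pos_by_ctx.setdefault(lab, []).append(
                    sel[mask] + ci * _CHROM_OFFSET
                )
        self.positions: dict[str, np.ndarray] = {
            lab: np.concatenate(chunks) for lab, chunks in pos_by_ctx.items()
        }

    def total_sites(self) -> int:
        return int(sum(len(v) for v in self.positions.values()))


def _chrom_seq(genome, chrom: str) -> str:
    if isinstance(genome, dict):
        return genome[chrom].upper()
    return str(genome[chrom][:]).upper()


_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _BASE_CODE[ord(b)] = i
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _context_codes(codes: np.ndarray, sel: np.ndarray, width: int):
    """Pyrimidine-centric context label index for each selected position;
    positions with out-of-range or ambiguous bases get label -1."""
    half = width // 2
    n = codes.size
    ok = (sel >= half) & (sel < n - half)
    cols = np.stack([codes[np.clip(sel + d, 0, n - 1)] for d in range(-half, half + 1)])
    ok &= (cols < 4).all(axis=0)
    center = cols[half]
    # reverse complement purine-centered contexts
    is_purine = (center == 0) | (center == 2)  # A or G
    canon = np.where(is_purine[None, :], _COMP_CODE[cols][::-1, :], cols)
    idx = np.zeros(sel.size, dtype=np.int64)
    for row in canon:
        idx = idx * 4 + row
    idx[~ok] = -1
    bases = "ACGT"
    lut_size = 4**width
    lut = []
    remap = np.full(lut_size, -1, dtype=np.int64)
    labels = np.full(sel.size, -1, dtype=np.int64)
    uniq = np.unique(idx[idx >= 0])
    for k, code in enumerate(uniq):
        s = ""
        c = int(code)
        for _ in range(width):
            s = bases[c % 4] + s
            c //= 4
        lut.append(s)
        remap[code] = k
    valid = idx >= 0
    labels[valid] = remap[idx[valid]]
    return labels, lut


def context_of(genome, chrom: str, pos: int, width: int) -> str | None:
    """Pyrimidine-centric reference context of width 3 or 5 around pos
    (0-based); None near contig edges or ambiguous bases."""
    if width == 0:
        return "*"
    half = width // 2
    seq = _chrom_seq(genome, chrom)
    if pos < half or pos + half >= len(seq):
        return None
    ctx = seq[pos - half : pos + half + 1]
    if any(b not in "ACGT" for b in ctx):
        return None
    if ctx[half] in "AG":
        ctx = revcomp(ctx)
    return ctx


def observed_spectrum(
    records: Sequence[MutationRecord], genome, context_size: int = 3
) -> dict[str, int]:
    """Context spectrum S of a sample's SBS catalog (input to the simulator)."""
    spec: dict[str, int] = {}
    if context_size == 0:
        return {"*": len(records)}
    half = context_size // 2
    by_chrom: dict[str, list[int]] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r.pos)
    for chrom, positions in by_chrom.items():
        seq = _chrom_seq(genome, chrom)
        for pos in positions:
            if pos < half or pos + half >= len(seq):
                continue
            ctx = seq[pos - half : pos + half + 1]
            if any(b not in "ACGT" for b in ctx):
                continue
            if ctx[half] in "AG":
                ctx = revcomp(ctx)
            spec[ctx] = spec.get(ctx, 0) + 1
    return spec


def simulate_random_catalog(
    index: ContextIndex,
    spectrum: Mapping[str, int],
    config: SimConfig,
    literal: bool = False,
) -> SimResult:
    """Generate ``config.n_sim`` random catalogs matching ``spectrum`` and
    record intermutation distances <= ``config.max_distance``.

    ``literal=True`` runs the published rejection loop verbatim (slow;
    distributionally identical to the default stratified sampler)."""
    for ctx, n in spectrum.items():
        if n > 0 and ctx not in index.positions:
            raise ValueError(f"context {ctx!r} unattainable in the mappable regions")
    if not index.positions:
        raise ValueError("mappable region set is empty")
    rng = np.random.default_rng(config.seed)
    dists: list[np.ndarray] = []
    positions: list[np.ndarray] | None = [] if config.keep_positions else None
    for _ in range(config.n_sim):
        if literal:
            M = _draw_literal(index, spectrum, rng)
        else:
            M = _draw_stratified(index, spectrum, rng)
        M.sort()
        d = np.diff(M)
        same_chrom = (M[1:] // _CHROM_OFFSET) == (M[:-1] // _CHROM_OFFSET)
        d = d[same_chrom & (d <= config.max_distance)]
        dists.append(d.astype(np.int64))
        if positions is not None:
            positions.append(M)
    return SimResult(distances=dists, positions=positions)


def _draw_stratified(index: ContextIndex, spectrum, rng) -> np.ndarray:
    chunks = []
    for ctx, n in spectrum.items():
        if n <= 0:
            continue
        sites = index.positions[ctx]
        chunks.append(sites[rng.integers(0, len(sites), n)])
    return np.concatenate(chunks) if chunks else np.array([], dtype=np.int64)


def _draw_literal(index: ContextIndex, spectrum, rng) -> np.ndarray:
    """Verbatim rejection loop: uniform positions over the mappable space,
    accepted while the position's context quota is unfilled."""
    all_pos = np.concatenate(list(index.positions.values()))
    ctx_of_site: dict[int, str] = {}
    for ctx, sites in index.positions.items():
        for s in sites:
            ctx_of_site[int(s)] = ctx
    target = {c: n for c, n in spectrum.items() if n > 0}
    need = sum(target.values())
    have: dict[str, int] = {c: 0 for c in target}
    M = np.empty(need, dtype=np.int64)
    k = 0
    guard = 0
    limit = max(10_000, 10_000 * need) * max(1, len(target))
    while k < need:
        p = int(all_pos[rng.integers(0, len(all_pos))])
        guard += 1
        if guard > limit:
            raise RuntimeError("rejection sampling failed to fill the spectrum")
        x = ctx_of_site[p]
        if x in target and have[x] < target[x]:
            M[k] = p
            have[x] += 1
            k += 1
    return M


def observed_distances(
    records: Sequence[MutationRecord], max_distance: int
) -> np.ndarray:
    """Successive intra-chromosome distances <= max_distance of one sample's
    sorted catalog."""
    by_chrom: dict[str, list[int]] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r.pos)
    out = []
    for chrom, pos in by_chrom.items():
        p = np.sort(np.asarray(pos))
        d = np.diff(p)
        out.append(d[d <= max_distance])
    return np.concatenate(out) if out else np.array([], dtype=np.int64)


def _window_counts(dists: np.ndarray, d_min: int, d_max: int, window: int) -> np.ndarray:
    """Counts of distances in [d, d+window-1] for d = d_min..d_max-window+1."""
    hist = np.bincount(
        np.clip(dists, 0, d_max + 1), minlength=d_max + 2
    )[d_min : d_max + 1].astype(float)
    c = np.cumsum(np.concatenate([[0.0], hist]))
    return c[window:] - c[:-window]


def cluster_scan(
    observed: Mapping[str, np.ndarray],
    sims: Mapping[str, SimResult],
    window: int = 5,
    step: int = 1,
    d_range: tuple[int, int] = (2, 10_000),
) -> pd.DataFrame:
    """Sliding-window comparison of observed vs simulated intermutation
    distances.

    Per window [d, d+window-1], each sample contributes its observed pair
    count and the empirical tail probability of that count under its own
    simulation null; the per-window p-value combines the per-sample
    two-sided Monte Carlo p-values with Fisher's method (a single sample
    uses its Monte Carlo p directly). Per-sample empirical p-values use the
    add-one estimator and are therefore valid (conservative) at any number
    of replicates. A two-sided Wilcoxon signed-rank test across samples on
    (observed - simulated mean) is reported alongside; with few samples its
    resolution (2/2^n) cannot clear a genome-wide Bonferroni bar, so the
    Monte Carlo p is the primary statistic. Bonferroni corrects over
    windows. The pooled effect size is observed/simulated-mean with a
    percentile interval over replicates.
    """
    from scipy import stats as _st

    if step != 1:
        raise ValueError("windows advance by 1 bp in this scan")
    d_min, d_max = d_range
    samples = sorted(observed)
    if set(samples) != set(sims):
        raise ValueError("observed and simulated sample sets differ")
    n_windows = (d_max - d_min + 1) - window + 1
    obs_counts = np.zeros((len(samples), n_windows))
    sim_means = np.zeros((len(samples), n_windows))
    pooled_reps: np.ndarray | None = None
    log_p_hi = np.zeros((len(samples), n_windows))  # log upper-tail MC p
    log_p_lo = np.zeros((len(samples), n_windows))
    for i, s in enumerate(samples):
        obs_counts[i] = _window_counts(np.asarray(observed[s]), d_min, d_max, window)
        reps = np.stack([
            _window_counts(d, d_min, d_max, window) for d in sims[s].distances
        ])
        n_rep = reps.shape[0]
        sim_means[i] = reps.mean(axis=0)
        ge = (reps >= obs_counts[i][None, :]).sum(axis=0)
        le = (reps <= obs_counts[i][None, :]).sum(axis=0)
        log_p_hi[i] = np.log((ge + 1.0) / (n_rep + 1.0))
        log_p_lo[i] = np.log((le + 1.0) / (n_rep + 1.0))
        if pooled_reps is None:
            pooled_reps = reps
        elif reps.shape != pooled_reps.shape:
            raise ValueError("all samples must use the same n_sim")
        else:
            pooled_reps = pooled_reps + reps

    obs_pool = obs_counts.sum(axis=0)
    sim_pool_mean = sim_means.sum(axis=0)
    import warnings as _warnings
    with np.errstate(divide="ignore", invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        effect = np.where(sim_pool_mean > 0, obs_pool / sim_pool_mean, np.nan)
        ratios = np.where(pooled_reps > 0, obs_pool / pooled_reps, np.nan)
        lo = np.nanquantile(ratios, 0.025, axis=0)
        hi = np.nanquantile(ratios, 0.975, axis=0)

    # Fisher combination of per-sample two-sided Monte Carlo p-values
    log_two_sided = np.minimum(
        np.log(2.0) + np.minimum(log_p_hi, log_p_lo), 0.0
    )
    stat = -2.0 * log_two_sided.sum(axis=0)
    p_mc = _st.chi2.sf(stat, df=2 * len(samples))
    empty = (obs_pool == 0) & (sim_pool_mean == 0)
    p_mc = np.where(empty, np.nan, np.minimum(p_mc, 1.0))

    p_wsr = np.full(n_windows, np.nan)
    if len(samples) >= 2:
        diffs = obs_counts - sim_means
        for w in range(n_windows):
            d = diffs[:, w]
            if np.allclose(d, 0.0):
                continue
            p_wsr[w] = wilcoxon_signed_rank_exact(d)

    return pd.DataFrame({
        "d": np.arange(d_min, d_min + n_windows),
        "observed": obs_pool,
        "simulated_mean": sim_pool_mean,
        "effect_size": effect,
        "effect_ci_low": lo,
        "effect_ci_high": hi,
        "p": p_mc,
        "p_bonferroni": bonferroni(p_mc),
        "p_wilcoxon": p_wsr,
        "p_wilcoxon_bonferroni": bonferroni(p_wsr),
    })


def cluster_membership(
    records: Sequence[MutationRecord], max_gap: int = 16
) -> pd.DataFrame:
    """Single-linkage chaining of mutations <= max_gap apart; returns clusters
    of size >= 2 with spans and mean gaps."""
    by_chrom: dict[str, list[int]] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r.pos)
    rows = []
    cid = 0
    for chrom in sorted(by_chrom):
        pos = sorted(by_chrom[chrom])
        run = [pos[0]]
        for p in pos[1:]:
            if p - run[-1] <= max_gap:
                run.append(p)
            else:
                if len(run) >= 2:
                    rows.append(_cluster_row(cid, chrom, run))
                    cid += 1
                run = [p]
        if len(run) >= 2:
            rows.append(_cluster_row(cid, chrom, run))
            cid += 1
    return pd.DataFrame(
        rows, columns=["cluster_id", "chrom", "start", "end", "size", "mean_gap"]
    )


def _cluster_row(cid: int, chrom: str, run: list[int]) -> dict:
    gaps = np.diff(run)
    return {"cluster_id": cid, "chrom": chrom, "start": run[0], "end": run[-1] + 1,
            "size": len(run), "mean_gap": float(gaps.mean())}
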