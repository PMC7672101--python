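"""Shared study scene for the analysis scripts.

One synthetic cohort mirroring the study design: six high-burden tumors
dominated by the lesion signature (GG-NER-deficient-like) and six sporadic
tumors with ~24-fold fewer mutations dominated by the background signature.
Scene files (FASTA, VCFs, tracks) go under scratch/, tables under results/.
"""

from dataclasses import replace as _replace
from pathlib import Path

import numpy as np

from lesionscape import synthetic as syn

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "scene"
RESULTS = ROOT / "results"

SCENE_SEED = 2024
XPC_SAMPLES = [f"XPC{i+1:02d}" for i in range(6)]
SPORADIC_SAMPLES = [f"SPO{i+1:02d}" for i in range(6)]
XPC_SBS_PER_SAMPLE = 5_000
LOAD_FOLD = 24  # burden ratio between the two cohorts


def build_scene():
    genome = syn.make_genome(syn.GenomeSpec(seed=SCENE_SEED))
    tracks = syn.make_tracks(genome, seed=SCENE_SEED + 1)

    rng = np.random.default_rng(SCENE_SEED + 2)
    xpc_mix = tuple(
        (float(f), float(1 - f)) for f in rng.uniform(0.82, 0.9, 6)
    )
    spec_xpc = syn.MutagenesisSpec(
        seed=SCENE_SEED + 3, n_samples=6, n_sbs=XPC_SBS_PER_SAMPLE,
        mixture=(0.83, 0.17), mixture_by_sample=xpc_mix,
    )
    xpc_records, xpc_truth = syn.make_catalog(genome, tracks, spec_xpc)

    spo_mix = tuple(
        (float(f), float(1 - f)) for f in rng.uniform(0.0, 0.2, 6)
    )
    spec_spo = syn.MutagenesisSpec(
        seed=SCENE_SEED + 4, n_samples=6,
        n_sbs=XPC_SBS_PER_SAMPLE // LOAD_FOLD,
        mixture=(0.1, 0.9), mixture_by_sample=spo_mix,
        # sporadic tumors lack the lesion-driven asymmetries
        trb_factor=1.0, replication_factor=1.0,
    )
    spo_records, spo_truth = syn.make_catalog(genome, tracks, spec_spo)

    def rename(records, names):
        out = []
        for r in records:
            idx = int(r.sample_id[1:]) - 1
            out.append(_replace(r, sample_id=names[idx]))
        return out

    xpc_records = rename(xpc_records, XPC_SAMPLES)
    spo_records = rename(spo_records, SPORADIC_SAMPLES)
    xpc_truth["sample"] = xpc_truth["sample"].map(
        lambda s: XPC_SAMPLES[int(s[1:]) - 1])
    spo_truth["sample"] = spo_truth["sample"].map(
        lambda s: SPORADIC_SAMPLES[int(s[1:]) - 1])
    return genome, tracks, xpc_records, spo_records, xpc_truth, spo_truth


def load_or_build_scene():
    """Build the scene and persist it under scratch/ if not already there."""
    import pandas as pd

    marker = SCRATCH / "genes.bed"
    genome, tracks, xpc, spo, xt, st_ = build_scene()
    if not marker.exists():
        SCRATCH.mkdir(parents=True, exist_ok=True)
        syn.write_scene(genome, tracks, xpc + spo, SCRATCH)
        pd.concat([xt, st_]).to_csv(SCRATCH / "truth.tsv", sep="\t", index=False)
    RESULTS.mkdir(exist_ok=True)
    return genome, tracks, xpc, spo
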