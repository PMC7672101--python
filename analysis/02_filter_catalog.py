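#!/usr/bin/env python
"""Read the scene VCFs back, apply the somatic filter policies, and report
retention per sample.

High-burden bone-marrow samples use the lenient policy (1 read per strand,
VAF >= 0.05); the stricter FFPE policies are shown on the same catalogs for
comparison. Mutations in unmappable territory are removed.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from _scene import RESULTS, SCRATCH, XPC_SAMPLES, SPORADIC_SAMPLES, load_or_build_scene
from lesionscape.catalog import FILTER_PRESETS, GenomicTrack, apply_filters, read_catalog


def main():
    load_or_build_scene()
    mappability = GenomicTrack.from_bedgraph(SCRATCH / "mappability.bedgraph")
    rows = []
    for sample in XPC_SAMPLES + SPORADIC_SAMPLES:
        records = read_catalog(SCRATCH / f"{sample}.vcf", sample)
        for policy_name in ("leukemia", "ffpe_sarcoma", "ffpe_rms"):
            kept = apply_filters(records, FILTER_PRESETS[policy_name],
                                 mappability=mappability)
            rows.append({"sample": sample, "policy": policy_name,
                         "n_input": len(records), "n_kept": len(kept),
                         "retention": len(kept) / len(records)})
    df = pd.DataFrame(rows)
    out = RESULTS / "filter_retention.tsv"
    df.to_csv(out, sep="\t", index=False)
    lenient = df[df.policy == "leukemia"]
    print(f"lenient policy keeps {lenient.retention.mean():.1%} of calls "
          f"(losses are almost entirely the ~2% unmappable territory)")
    strict = df[df.policy == "ffpe_rms"]
    print(f"the VAF>=0.4 FFPE policy keeps {strict.retention.mean():.1%} "
          f"(binomial VAF sampling at depth 45, mean 0.45)")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
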