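#!/usr/bin/env python
"""Read-origin QC at desk scale: two-reference k-mer classification.

Simulates reads from two toy references sharing an rRNA-like conserved
segment (30% of reads from the shared segment, 1% substitution error),
classifies every read by exact canonical k-mer membership, and estimates the
rRNA fraction — the diagnosis pattern where a high "both" fraction is
explained by rRNA carry-over rather than cross-species contamination.

Writes the category summary under results/read_origin/.
"""

import json
from pathlib import Path

import numpy as np

from cellpair.read_origin import build_kmer_index, classify_reads, estimate_rrna_fraction
from cellpair.simulate import make_read_origin_refs, simulate_reads

OUT = Path(__file__).resolve().parent.parent / "results" / "read_origin"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ref_a, ref_b, shared = make_read_origin_refs(SEED)
    index = build_kmer_index(ref_a, ref_b, k=25)
    reads = simulate_reads(
        {"a": {"u": ref_a["refA_unique"]},
         "b": {"u": ref_b["refB_unique"]},
         "shared": shared},
        {"a": 400, "b": 300, "shared": 300},
        read_len=100, error_rate=0.01, seed=SEED + 10,
    )
    df, summary = classify_reads(reads, index)
    summary.to_frame().to_csv(OUT / "categories.tsv", sep="\t", index=False)
    truth_map = {"a": "A_only", "b": "B_only", "shared": "both"}
    truth = [truth_map[n.split("source=")[1]] for n, _ in reads]
    agree = np.mean([t == c for t, c in zip(truth, df["category"])])
    frac = estimate_rrna_fraction(reads, shared, k=15)
    (OUT / "summary.json").write_text(json.dumps(
        {"percent": summary.percentages, "truth_agreement": float(agree),
         "rrna_fraction": frac}, indent=2))
    for cat, pct in summary.percentages.items():
        print(f"{cat:10s} {pct:6.2f}%")
    print(f"truth agreement {agree:.1%}; estimated rRNA fraction {frac:.3f} "
          f"(designed 0.300)")


if __name__ == "__main__":
    main()
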