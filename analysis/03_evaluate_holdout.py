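#!/usr/bin/env python
"""Held-out evaluation detail: confusion metrics and the proximity matrix.

Reads the trained model from results/run/ (run 02_train_classifier.py
first), recomputes the training rule matrix, and writes the out-of-bag
proximity matrix plus a per-class metric table under results/evaluation/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from cellpair.pair_rules import evaluate_rules
from cellpair.pipeline import _stage_seeds
from cellpair.rule_forest import TrainedRuleForest, proximity_matrix
from cellpair.simulate import SimulationConfig, simulate_bulk

ROOT = Path(__file__).resolve().parent.parent
RUN = ROOT / "results" / "run"
OUT = ROOT / "results" / "evaluation"
SEED = 1


def main() -> None:
    if not (RUN / "model.json").exists():
        sys.exit("run analysis/02_train_classifier.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    model = TrainedRuleForest.from_json(RUN / "model.json")
    seeds = _stage_seeds(SEED)
    expr, ann, _ = simulate_bulk(SimulationConfig(seed=seeds[0]))
    train_expr = expr.subset_samples(model.train_sample_ids)
    rm = evaluate_rules(train_expr.subset_genes(sorted(model.rule_genes)), model.rules)
    prox = proximity_matrix(model, rm, mode="oob")
    prox.to_csv(OUT / "proximity_oob.tsv", sep="\t")

    lab = ann.set_index("sample_id")["class_label"].loc[prox.index]
    import numpy as np

    same = lab.to_numpy()[:, None] == lab.to_numpy()[None, :]
    off = ~np.eye(len(lab), dtype=bool)
    arr = prox.to_numpy()
    print(f"OOB proximity: within-class mean {arr[same & off].mean():.3f}, "
          f"between-class mean {arr[~same].mean():.3f}")

    report = json.loads((RUN / "report.json").read_text())
    table = pd.DataFrame(report["per_class"]).T
    table.to_csv(OUT / "per_class_metrics.tsv", sep="\t")
    print(table.round(4))
    print(f"overall accuracy {report['accuracy']:.4f} "
          f"(95% CI {report['ci95'][0]:.4f}-{report['ci95'][1]:.4f}), "
          f"NIR {report['no_information_rate']:.4f}, "
          f"p={report['nir_pvalue']:.2e}")


if __name__ == "__main__":
    main()
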