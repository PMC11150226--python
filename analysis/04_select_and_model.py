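"""Run the selection cascade and train/evaluate the SVM model roster.

For each source (each habitat, the whole tumor, the deep features, and every
fusion with the deep features) the ICC → z-score → Pearson → t-test → LASSO
cascade is re-run on that source's training columns, an RBF SVM is tuned by
stratified 5-fold CV and evaluated on the held-out split at the training
Youden cutoff.  Prints the metric table (the study's Table-2/3 layout) and
writes metrics.csv plus per-model selection/eval JSON.

Usage: python analysis/04_select_and_model.py [--seed 1]
"""

import argparse
import importlib.util
from pathlib import Path

import pandas as pd

from habitatpipe.pipeline_cli import run_all

_here = Path(__file__).resolve().parent
spec = importlib.util.spec_from_file_location("sim", _here / "01_simulate_cohort.py")
sim = importlib.util.module_from_spec(spec); spec.loader.exec_module(sim)


def main(seed: int = 1) -> None:
    cfg = sim.demo_config(seed)
    run_all(cfg, sim.RESULTS, stages=("simulate", "habitats", "features", "models"))
    metrics = pd.read_csv(sim.RESULTS / "metrics.csv")
    cols = ["model", "accuracy", "precision", "recall", "f1", "auc",
            "auc_ci_low", "auc_ci_high", "mcc", "plr", "nlr"]
    print("held-out test performance (training-Youden cutoff):")
    print(metrics[cols].round(3).to_string(index=False))
    best = metrics.loc[metrics["auc"].idxmax()]
    print(f"\nbest model by test AUC: {best['model']} "
          f"(AUC {best['auc']:.3f} [{best['auc_ci_low']:.3f}-{best['auc_ci_high']:.3f}])")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
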