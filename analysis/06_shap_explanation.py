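"""Kernel-SHAP explanation of the best fused SVM.

Explains the held-out predictions of the top fused model against a
training-table background (medoid-capped), prints the top-10 features by
mean |phi|, and writes shap_summary.csv / shap_values.csv (beeswarm-ready).

Usage: python analysis/06_shap_explanation.py [--seed 1]
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
    run_all(cfg, sim.RESULTS)  # all stages incl. explain
    summary = pd.read_csv(sim.RESULTS / "shap_summary.csv")
    print(f"SHAP explanation of model '{summary['model'].iloc[0]}' "
          f"(positive phi pushes toward non-response):")
    top = summary.head(10)[["rank", "feature", "mean_abs_phi", "mean_phi"]]
    print(top.round(4).to_string(index=False))


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
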