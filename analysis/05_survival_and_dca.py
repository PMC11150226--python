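"""Survival stratification and decision-curve analysis of the fused model.

Patients in the held-out split are divided into high/low-risk groups at the
training Youden cutoff of the best fused model; Kaplan-Meier curves and
log-rank tests for PFS and OS, plus the decision curve, are read from the
model's evaluation report and summarized here.  Curve tables are exported as
CSV for plotting.

Usage: python analysis/05_survival_and_dca.py [--seed 1]
"""

import argparse
import importlib.util
import json
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
    fused = metrics[metrics["model"].str.contains("\\+DL")]
    best = fused.loc[fused["auc"].idxmax(), "model"]
    rep = json.loads(
        (sim.RESULTS / f"eval_{best.replace('+', '_')}.json").read_text()
    )
    print(f"risk stratification by '{best}' at cutoff {rep['cutoff']:.3f}")
    surv = rep.get("survival", {})
    if "logrank" in surv:
        for ep in ("pfs", "os"):
            lr = surv["logrank"][ep]
            print(f"  {ep.upper()}: log-rank chi2 = {lr['chi2']:.2f}, p = {lr['p']:.4g}")
        for ep in ("pfs", "os"):
            rows = []
            for grp, curve in surv["curves"][ep].items():
                for t, s in zip(curve["times"], curve["survival"]):
                    rows.append({"group": grp, "time_months": t, "survival": s})
            out = sim.RESULTS / f"km_{ep}.csv"
            pd.DataFrame(rows).to_csv(out, index=False)
            print(f"  KM table written: {out.name}")
    else:
        print("  all test patients fell in one risk group; KM skipped")
    dca = pd.DataFrame(rep["dca"])
    dca.to_csv(sim.RESULTS / "dca.csv", index=False)
    useful = dca[dca["net_benefit"] > dca[["treat_all", "treat_none"]].max(axis=1)]
    if len(useful):
        print(f"  DCA: model beats treat-all/none for thresholds "
              f"{useful['threshold'].min():.2f}-{useful['threshold'].max():.2f} "
              f"(table: dca.csv)")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
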