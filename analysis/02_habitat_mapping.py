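"""Choose the habitat count by consensus clustering and report diagnostics.

Runs the Monti consensus scan (k = 2..10) on pooled training voxels of the
demo cohort, prints the CDF-area / delta-area / PAC table and the selected k,
and writes consensus.json under results/run_demo/.

Usage: python analysis/02_habitat_mapping.py [--seed 1]
"""

import argparse
import importlib.util
import json
import sys
from pathlib import Path

from habitatpipe.pipeline_cli import run_all

_here = Path(__file__).resolve().parent
spec = importlib.util.spec_from_file_location("sim", _here / "01_simulate_cohort.py")
sim = importlib.util.module_from_spec(spec); spec.loader.exec_module(sim)


def main(seed: int = 1) -> None:
    cfg = sim.demo_config(seed)
    run_all(cfg, sim.RESULTS, stages=("simulate", "habitats"))
    cons = json.loads((sim.RESULTS / "consensus.json").read_text())
    print(f"consensus mode: {cons['mode']}")
    if cons["mode"] == "consensus":
        print("  k   area    delta   PAC")
        for k in sorted(cons["cdf_areas"], key=int):
            print(f"  {k}  {cons['cdf_areas'][k]:.3f}  {cons['delta_areas'][k]:.3f}  "
                  f"{cons['pac_scores'][k]:.3f}")
    print(f"selected number of habitats: k = {cons['k_selected']}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
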