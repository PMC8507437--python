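"""All-in-one alignment experiment: simulate -> filter -> tune -> evaluate.

Runs the orchestrated pipeline on a scaled-down campaign with the default
planted distortions and prints the before/after agreement per algorithm.
Equivalent to `lakealign run experiment.yaml --out out/` on the shell.
"""

import json
import tempfile
from pathlib import Path

from lakealign import run_experiment
from lakealign.simulate import study_scenario

config = {
    "synthetic": study_scenario(total_scale=0.5, seed=11).to_dict(),
    "algorithms": ["oc2", "gilerson", "turbidity_b665"],
    "tuning": {"n_replicates": 50, "seed": 2, "min_unique_per_lake": 140,
               "objective_space": "log10"},
}

with tempfile.TemporaryDirectory() as out:
    manifest = run_experiment(config, out)
    for algorithm in config["algorithms"]:
        payload = json.loads(Path(out, algorithm, "metrics.json").read_text())
        b, a = payload["before"], payload["after"]
        print(f"{algorithm:15s} n={b['n']:6d}  "
              f"MAD {b['mad']:.3f} -> {a['mad']:.3f}   "
              f"bias {b['bias']:+.3f} -> {a['bias']:+.3f}   "
              f"R {b['r']:.3f} -> {a['r']:.3f}")
    print(f"\nstage row counts: {manifest.stage_rows}")
    print("tuning reduces the mean absolute difference for every algorithm "
          "because the generator planted a recoverable inter-sensor distortion.")
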