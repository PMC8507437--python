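"""Run the quality-filter cascade and read its survivor accounting.

The cascade removes flagged pixels, implausible reflectances, heterogeneous
macro-pixels, the extreme 0.1% of products, 2-sigma outliers and finally the
records outside each algorithm's validity range.  The report telescopes:
each step's output count is the next step's input.
"""

from lakealign import default_registry, generate_dataset, run_filter_cascade
from lakealign.simulate import study_scenario

registry = default_registry()
table, _ = generate_dataset(study_scenario(total_scale=0.2, seed=3), registry)

for algorithm in ("oc2", "gilerson", "turbidity_b665"):
    filtered, report = run_filter_cascade(table, algorithm, registry)
    print(f"\n{algorithm}: {report.n_initial} -> {report.n_final} rows")
    for step in report.steps:
        print(f"  {step.name:18s} kept {step.n_out:6d}  removed {step.n_removed}")
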