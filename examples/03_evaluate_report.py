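"""Produce a full per-case evaluation report (gamma maps, DVH, metrics).

Uses the identity conversion (converted = PB) so it runs in seconds; swap in a
trained model's output to evaluate a real conversion. Writes report.json,
metrics.csv, gamma volumes and a DVH plot under ./example_report/.

Run:  python examples/03_evaluate_report.py
"""

import json

import numpy as np

from protondl import evaluate_case, generate_case

rng = np.random.default_rng(3)
case = generate_case("headneck_like", "example_hn", rng)

report = evaluate_case(case, case.pb_composite, out_dir="example_report")

print(json.dumps(
    {
        "case": report["case_id"],
        "site": report["site"],
        "pb_vs_mc_gamma_pct": round(report["pb_vs_mc"]["gamma_passing_rate_pct"], 2),
        "pb_vs_mc_mse_gy2": round(report["pb_vs_mc"]["mse_gy2"], 5),
        "qualifying_diff_voxels": report["pb_vs_mc"][
            "diff_histogram_qualifying_voxels"
        ],
    },
    indent=2,
))
print("full report written to example_report/")
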