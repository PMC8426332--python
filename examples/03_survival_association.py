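"""Associate neoantigen load with overall survival on a synthetic cohort.

Runs the full pipeline (detection through loads), splits the cohort at the
median load, and reports Kaplan-Meier / log-rank / Cox results. The
simulated hazard doubles in the high-load group, so the fitted hazard ratio
should sit near 2.
"""

import json
import tempfile
from pathlib import Path

from irneo import SimConfig, simulate_study

with tempfile.TemporaryDirectory() as tmp:
    cfg = SimConfig(seed=1)  # 20 genes, 50 tumor + 5 normal samples, HR 2
    ref, counts, clinical, loads, manifest = simulate_study(cfg, tmp)
    print("stage row counts:", json.dumps(manifest["stages"]))
    stats = json.loads((Path(tmp) / "pipeline" / "stats.json").read_text())

    for tag in ("count", "weighted"):
        s = stats[tag]
        hr = s["cox_univariate"]["hazard_ratio"]
        lo, hi = s["cox_univariate"]["ci95_low"], s["cox_univariate"]["ci95_high"]
        print(
            f"{tag:8s} load: log-rank p = {s['logrank_p']:.3f}, "
            f"HR = {hr:.2f} (95% CI {lo:.2f}-{hi:.2f})"
        )
    multi = stats["cox_multivariate"]["load_group[high]"]
    print(f"multivariate (adjusting age, sex): HR = {multi['hazard_ratio']:.2f}, "
          f"p = {multi['wald_p']:.3f}")
# HR > 1 means higher-than-median load carries a higher death hazard; at
# n = 50 the log-rank test is underpowered, so p-values vary across seeds
# while the HR estimate stays near the planted value.
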