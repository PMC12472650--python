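#!/usr/bin/env python
"""Step 6 — survival analysis.

Kaplan–Meier tables for EFS and OS, a log-rank comparison of the cohort
split at the median neoantigen load, and a Cox proportional-hazards fit of
standardized load on each endpoint.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from allneo import io as aio
from allneo.survival import (
    SurvivalRecord,
    cox_fit,
    km_estimate,
    logrank_test,
    median_split_labels,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    summaries = aio.read_summaries_tsv(ROOT / "results" / "summaries.tsv")
    res_dir = ROOT / "results"
    load = np.array([s.load for s in summaries], dtype=float)
    labels = median_split_labels(load)
    out = {}
    for endpoint in ("EFS", "OS"):
        recs = [
            SurvivalRecord(
                s.patient_id,
                s.efs_time if endpoint == "EFS" else s.os_time,
                s.efs_event if endpoint == "EFS" else s.os_event,
                endpoint,
            )
            for s in summaries
        ]
        km = km_estimate(recs)
        pd.DataFrame(
            {
                "time": km.times,
                "n_at_risk": km.at_risk,
                "n_events": km.n_events,
                "survival": km.survival,
            }
        ).to_csv(res_dir / f"km_{endpoint.lower()}.tsv", sep="\t", index=False)
        lo = [r for r, lab in zip(recs, labels) if lab == "low"]
        hi = [r for r, lab in zip(recs, labels) if lab == "high"]
        chi2, p = logrank_test(lo, hi)
        fit = cox_fit(
            np.array([r.time for r in recs]),
            np.array([r.event for r in recs]),
            pd.DataFrame({"load_sd": (load - load.mean()) / load.std()}),
        )
        out[endpoint] = {
            "events": int(sum(r.event for r in recs)),
            "logrank_chi2": round(chi2, 4),
            "logrank_p": round(p, 4),
            "cox_hr_per_sd_load": round(fit.hazard_ratios.get("load_sd", float("nan")), 4),
            "cox_converged": fit.converged,
        }
        print(
            f"{endpoint}: {out[endpoint]['events']} events; median-load split "
            f"log-rank p = {p:.3f}; Cox HR per SD load = "
            f"{out[endpoint]['cox_hr_per_sd_load']}"
        )
    (res_dir / "survival.json").write_text(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
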