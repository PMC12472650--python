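#!/usr/bin/env python
"""Step 5 — cohort statistics.

HLA carrier/allelic frequency tables, the TMB–neoantigen-load correlation,
and two-group comparisons of burden and load across clinical strata (sex,
age, WBC, blast %, immunophenotype, NCI risk, MMR status, median splits),
each with a Wilcoxon–Mann–Whitney p and an adaptive permutation p.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from allneo import io as aio
from allneo.stats import GROUP_VARIABLES, compare_groups, correlate_tmb_load, hla_frequencies

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    summaries = aio.read_summaries_tsv(ROOT / "results" / "summaries.tsv")
    genotypes = aio.read_hla_tsv(ROOT / "scratch" / "cohort" / "hla.tsv")
    res_dir = ROOT / "results"

    for mode in ("carrier", "allelic"):
        hla_frequencies(genotypes, mode=mode).to_csv(
            res_dir / f"hla_{mode}.tsv", sep="\t", index=False
        )

    corr = correlate_tmb_load(summaries)
    (res_dir / "correlation.json").write_text(
        json.dumps(corr.__dict__, indent=2)
    )

    rng = np.random.default_rng(SEED)
    rows = []
    for var in GROUP_VARIABLES:
        try:
            for gc in compare_groups(summaries, var, rng=rng):
                rows.append(
                    {
                        "variable": gc.variable,
                        "outcome": gc.outcome,
                        "groups": f"{gc.labels[0]}({gc.n[0]}) vs {gc.labels[1]}({gc.n[1]})",
                        "mean1": round(gc.means[0], 1),
                        "mean2": round(gc.means[1], 1),
                        "wilcoxon_p": round(gc.wilcoxon_p, 4),
                        "permutation_p": round(gc.permutation_p, 4),
                        "perm_iters": gc.permutation_iterations,
                    }
                )
        except ValueError as exc:
            print(f"  [skip] {var}: {exc}")
    df = pd.DataFrame(rows)
    df.to_csv(res_dir / "group_comparisons.tsv", sep="\t", index=False)

    print(
        f"TMB–load correlation: Pearson R = {corr.pearson_r:.3f}, "
        f"Spearman rho = {corr.spearman_rho:.3f}"
    )
    mmr = df[(df.variable == "mmr_status") & (df.outcome == "tmb")]
    if len(mmr):
        r = mmr.iloc[0]
        print(
            f"MMR stratification (TMB): {r.groups}, means {r.mean1} vs {r.mean2}, "
            f"Wilcoxon p = {r.wilcoxon_p}, permutation p = {r.permutation_p}"
        )


if __name__ == "__main__":
    main()
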