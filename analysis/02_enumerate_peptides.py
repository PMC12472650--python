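#!/usr/bin/env python
"""Step 2 — enumerate tiling mutant/wild-type nonamer pairs.

Every somatic missense mutation is expanded into the (up to nine) 9-mer
windows that contain it, each paired with the wild-type window from the
reference proteome.  Internal mutations yield exactly nine pairs; mutations
near a protein terminus yield fewer.
"""

import json
from collections import Counter
from pathlib import Path

from allneo import io as aio
from allneo.peptides import dedupe_mutations, enumerate_nonamer_pairs

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort_dir = ROOT / "scratch" / "cohort"
    proteome = {p.protein_id: p for p in aio.read_proteome_fasta(cohort_dir / "proteome.fasta")}
    mutations = dedupe_mutations(aio.read_mutations_tsv(cohort_dir / "mutations.tsv"))
    pairs = []
    for m in mutations:
        pairs.extend(enumerate_nonamer_pairs(proteome[m.protein_id], m))
    out_dir = ROOT / "scratch" / "pipeline"
    out_dir.mkdir(parents=True, exist_ok=True)
    aio.write_pairs_tsv(pairs, out_dir / "pairs.tsv")

    per_mut = Counter()
    for p in pairs:
        per_mut[(p.mutation.patient_id, p.mutation.protein_id, p.mutation.position)] += 1
    hist = Counter(per_mut.values())
    summary = {
        "mutations": len(mutations),
        "peptide_pairs": len(pairs),
        "pairs_per_mutation_histogram": {str(k): v for k, v in sorted(hist.items())},
    }
    (ROOT / "results" / "peptide_summary.json").write_text(json.dumps(summary, indent=2))
    print(
        f"{len(mutations)} mutations -> {len(pairs)} nonamer pairs "
        f"({hist.get(9, 0)} mutations with the full nine windows)"
    )


if __name__ == "__main__":
    main()
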