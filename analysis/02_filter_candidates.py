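"""Step 02 — run the four-stage candidate filter cascade.

Applies flanking conservation, genotype quality, unique mapping and KASP
design feasibility to the simulated candidate table, reporting how many
loci each stage retains — the same shape of cascade that narrows tens of
millions of raw GBS variants to a few thousand designable assays.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1]))

from analysis import common
from kaspfp import run_filter_cascade
from kaspfp.filtering import read_candidate_table, write_candidate_table


def main() -> None:
    common.ensure_inputs()
    candidates = read_candidate_table(common.CANDIDATES_TSV)
    positions = {
        chrom: np.array(pos)
        for chrom, pos in json.loads(
            (common.SCRATCH / "variant_positions.json").read_text()
        ).items()
    }
    retained, report = run_filter_cascade(
        candidates, common.REFERENCE_FASTA, all_variant_positions=positions
    )

    report.to_json(common.RESULTS / "02_filter_report.json")
    write_candidate_table(retained, common.SCRATCH / "candidates_retained.tsv")

    print(report.to_text())
    first, last = report.stages[0].n_in, report.stages[-1].n_retained
    print(f"\nretained {last}/{first} candidates "
          f"({100 * last / first:.1f}%) across {len(report.stages)} stages")


if __name__ == "__main__":
    main()
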