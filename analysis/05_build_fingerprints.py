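"""Step 05 — DNA fingerprints over the selected core marker set.

Builds every accession's multilocus genotype string, color-coded heatmap
row and QR payload from the core set chosen in step 04, and verifies that
distinct fingerprint strings match the multilocus-genotype classes.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1]))

from analysis import common
from kaspfp import build_fingerprints, mlg_groups, render_heatmap_matrix
from kaspfp.fingerprint import profiles_table, write_heatmap_grid
from kaspfp.genotypes import read_genotypes


def main() -> None:
    common.ensure_inputs()
    core_path = common.RESULTS / "04_core_set.json"
    if not core_path.exists():
        import runpy

        runpy.run_path(str(common.ROOT / "analysis" / "04_select_core_markers.py"),
                       run_name="__main__")
    core = json.loads(core_path.read_text())

    matrix = read_genotypes(common.SCRATCH / "panel.tsv")
    profiles = build_fingerprints(matrix, core["loci"])
    profiles_table(profiles).to_csv(common.RESULTS / "05_fingerprints.tsv", sep="\t", index=False)
    write_heatmap_grid(render_heatmap_matrix(profiles), common.RESULTS / "05_heatmap_grid.tsv")

    n_strings = len({p.genotype_string for p in profiles})
    n_classes = len(mlg_groups(matrix, core["loci"]))
    print(f"built {len(profiles)} fingerprint profiles over {len(core['loci'])} loci")
    print(f"distinct genotype strings: {n_strings} (MLG classes: {n_classes})")
    print(f"example code: {profiles[0].code}")
    print(f"example QR payload: {profiles[0].qr_payload}")


if __name__ == "__main__":
    main()
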