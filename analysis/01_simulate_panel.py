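"""Step 01 — simulate the study panel and the candidate-SNP table.

Generates the seeded 77-accession x 30-locus genotype panel (two groups
at target Fst 0.099, two clonal duplicate pairs, 0.3% missing calls) and
a 150-candidate SNP table with planted design defects, then writes them
in the pipeline's interchange formats (VCF, genotype table, candidate
table, reference FASTA, group map).
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1]))

from analysis import common
from kaspfp import simulate_candidate_table, simulate_genotypes
from kaspfp.filtering import write_candidate_table
from kaspfp.simulate import write_fasta


def main() -> None:
    common.SCRATCH.mkdir(parents=True, exist_ok=True)
    common.RESULTS.mkdir(parents=True, exist_ok=True)

    matrix, truth = simulate_genotypes(common.PANEL)
    matrix.write_vcf(common.SCRATCH / "panel.vcf")
    matrix.write_table(common.SCRATCH / "panel.tsv")
    common.GROUPS_TSV.write_text(
        "".join(f"{acc}\t{grp}\n" for acc, grp in truth.group_of.items())
    )

    candidates, fasta, cand_truth = simulate_candidate_table(
        common.N_CANDIDATES,
        secondary_poly_rate=common.SECONDARY_POLY_RATE,
        duplicate_region_rate=common.DUPLICATE_REGION_RATE,
        seed=common.SEED,
    )
    write_candidate_table(candidates, common.CANDIDATES_TSV)
    write_fasta(fasta, common.REFERENCE_FASTA)
    # full variant-site list (candidates + their neighbouring polymorphisms),
    # needed by the flanking-conservation filter
    (common.SCRATCH / "variant_positions.json").write_text(json.dumps(
        {chrom: pos.tolist() for chrom, pos in cand_truth.variant_positions.items()}
    ) + "\n")

    summary = {
        "n_accessions": matrix.n_accessions,
        "n_loci": matrix.n_loci,
        "clone_pairs": truth.clone_pairs,
        "groups": {g: sum(1 for v in truth.group_of.values() if v == g)
                   for g in sorted(set(truth.group_of.values()))},
        "n_candidates": len(candidates),
        "planted_secondary": sum(cand_truth.has_secondary.values()),
        "planted_duplicates": sum(cand_truth.has_duplicate.values()),
        "seed": common.SEED,
    }
    (common.RESULTS / "01_panel_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"simulated {matrix.n_accessions} accessions x {matrix.n_loci} loci; "
          f"clone pairs {truth.clone_pairs}")
    print(f"candidate table: {len(candidates)} loci "
          f"({summary['planted_secondary']} with secondary polymorphisms, "
          f"{summary['planted_duplicates']} with duplicated regions)")


if __name__ == "__main__":
    main()
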