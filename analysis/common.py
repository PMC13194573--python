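"""Shared study conditions for the analysis scripts.

One seeded scenario is threaded through all numbered steps: a 77-accession
garlic-like germplasm panel genotyped at 30 validated KASP loci (two
groups at moderate differentiation, two clonal duplicate pairs), plus a
candidate-SNP table with planted design defects for the filter cascade.
Bulky intermediates land in scratch/analysis/; result tables in results/.
"""

from pathlib import Path

from kaspfp import SimulationConfig, core_panel_mafs

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

SEED = 42

#: 77 accessions x 30 KASP-validated loci; the first 13 loci follow the
#: validated core-panel He spectrum, the rest draw from a uniform MAF range
PANEL = SimulationConfig(
    n_accessions=77,
    n_loci=30,
    allele_freq_spectrum=core_panel_mafs() + [0.05 + 0.45 * (i / 16) for i in range(17)],
    missing_rate=0.003,
    n_groups=2,
    target_fst=0.099,
    n_clone_pairs=2,
    seed=SEED,
)

N_CANDIDATES = 150
SECONDARY_POLY_RATE = 0.25
DUPLICATE_REGION_RATE = 0.15

PANEL_PREFIX = SCRATCH / "panel"
CANDIDATES_TSV = SCRATCH / "candidates.tsv"
REFERENCE_FASTA = SCRATCH / "reference.fasta"
GROUPS_TSV = SCRATCH / "groups.tsv"


def ensure_inputs() -> None:
    """Regenerate the seeded inputs if step 01 has not been run yet."""
    if not CANDIDATES_TSV.exists() or not (SCRATCH / "panel.tsv").exists():
        import runpy

        runpy.run_path(str(ROOT / "analysis" / "01_simulate_panel.py"), run_name="__main__")
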