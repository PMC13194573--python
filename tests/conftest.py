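import numpy as np
import pytest

from kaspfp import GenotypeMatrix, SimulationConfig, core_panel_mafs, simulate_genotypes


def make_matrix(rows: dict[str, list[str]], loci: list[str] | None = None) -> GenotypeMatrix:
    """Small literal genotype matrix: {accession: [calls...]}."""
    accessions = list(rows)
    calls = np.array([rows[a] for a in accessions], dtype="<U2")
    if loci is None:
        loci = [f"chr1_{j + 1}" for j in range(calls.shape[1])]
    return GenotypeMatrix(accessions=accessions, loci=loci, calls=calls)


@pytest.fixture
def panel_77() -> tuple:
    """77-accession, 13-locus panel with 2 injected clone pairs.

    Mirrors the structure of a validated garlic core panel: two groups at
    moderate differentiation, sub-percent missing rate, and exactly two
    deliberately duplicated multilocus genotypes.
    """
    config = SimulationConfig(
        n_accessions=77,
        n_loci=13,
        allele_freq_spectrum=core_panel_mafs(),
        missing_rate=0.003,
        n_groups=2,
        target_fst=0.099,
        n_clone_pairs=2,
        seed=23,
    )
    return simulate_genotypes(config)
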