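"""Seeded synthetic genotype panels, candidate-SNP tables and references.

The generator emulates the structure of a KASP-validated garlic germplasm
panel: a few dozen diploid accessions genotyped at a handful of biallelic
SNP loci, with very low missing rates, an allele-frequency spectrum
spanning nearly-fixed to maximally polymorphic loci, optional two-group
population structure at a chosen differentiation level, and deliberately
duplicated multilocus genotypes standing in for clonal accessions.

Two-group structure uses Balding–Nichols dispersion: each group's allele
frequency is drawn from Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral
frequency p.  For Nei's Gst over two equally weighted groups the expected
value is (F/2)/(1 - F/2), so the dispersion parameter is set to
F = 2t/(1+t) to realize a target Gst of t.

Genotypes are Hardy–Weinberg draws; clonality appears only through the
explicit clone pairs, whose rows are byte-identical (including the missing
pattern).  By default accidental multilocus-genotype collisions among
non-clone accessions are resampled away so that the clone-pair list is the
exact ground truth for indistinguishability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .diversity import invert_he
from .filtering import CandidateSNP
from .genotypes import MISSING, GenotypeMatrix

NUCLEOTIDES = np.array(list("ACGT"))

# He spectrum of a validated 13-marker garlic core panel (KASP genotyping
# of 77 accessions); inverted to minor allele frequencies this is the
# default spectrum for core-panel-sized simulations.
CORE_PANEL_HE: tuple[float, ...] = (
    0.485, 0.497, 0.483, 0.36, 0.463, 0.145, 0.169,
    0.178, 0.051, 0.304, 0.185, 0.026, 0.5,
)


def core_panel_mafs() -> list[float]:
    """Minor allele frequencies implied by the core-panel He spectrum."""
    return [invert_he(he)[1] for he in CORE_PANEL_HE]


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic genotype panel.

    ``allele_freq_spectrum`` is either a ``(low, high)`` range for a
    uniform draw of per-locus minor allele frequencies or an explicit
    sequence of MAFs (used cyclically when shorter than ``n_loci``).
    """

    n_accessions: int = 77
    n_loci: int = 13
    allele_freq_spectrum: tuple[float, float] | Sequence[float] = (0.05, 0.5)
    missing_rate: float = 0.003
    n_groups: int = 1
    target_fst: float = 0.0
    n_clone_pairs: int = 0
    seed: int = 0
    ensure_unique: bool = True

    def __post_init__(self) -> None:
        if self.n_accessions < 1 or self.n_loci < 1:
            raise ValueError("n_accessions and n_loci must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.target_fst < 1.0:
            raise ValueError("target_fst must lie in [0, 1)")
        if self.n_groups not in (1, 2):
            raise ValueError("n_groups must be 1 or 2")
        if self.n_clone_pairs > self.n_accessions // 2:
            raise ValueError(
                f"{self.n_clone_pairs} clone pairs impossible with "
                f"{self.n_accessions} accessions"
            )
        mafs = self._spectrum_values()
        if any(not 0.0 <= m <= 0.5 for m in mafs):
            raise ValueError("minor allele frequencies must lie in [0, 0.5]")

    def _spectrum_values(self) -> list[float]:
        if (
            isinstance(self.allele_freq_spectrum, tuple)
            and len(self.allele_freq_spectrum) == 2
            and all(isinstance(x, (int, float)) for x in self.allele_freq_spectrum)
            and self.allele_freq_spectrum[0] <= self.allele_freq_spectrum[1]
        ):
            return list(self.allele_freq_spectrum)
        return [float(x) for x in self.allele_freq_spectrum]

    def locus_mafs(self, rng: np.random.Generator) -> np.ndarray:
        spec = self.allele_freq_spectrum
        if isinstance(spec, tuple) and len(spec) == 2 and spec[0] <= spec[1] and not isinstance(spec[0], str):
            low, high = float(spec[0]), float(spec[1])
            return rng.uniform(low, high, size=self.n_loci)
        values = np.array([float(x) for x in spec])
        reps = int(np.ceil(self.n_loci / len(values)))
        return np.tile(values, reps)[: self.n_loci]


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated panel, for recovery tests."""

    group_of: dict[str, str]
    group_freqs: np.ndarray       # (n_groups, n_loci) frequency of the REF allele
    ancestral_freqs: np.ndarray   # (n_loci,) REF-allele frequency
    clone_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.group_freqs < 0) or np.any(self.group_freqs > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")
        for a, b in self.clone_pairs:
            if a == b:
                raise ValueError("a clone pair must reference two distinct accessions")


def _sample_rows(
    rng: np.random.Generator,
    freqs_of_row: np.ndarray,
    ref: np.ndarray,
    alt: np.ndarray,
    rows: np.ndarray,
    which: Sequence[int],
) -> None:
    """Draw HW genotypes for the given accession rows, REF/ALT oriented."""
    n_loci = ref.shape[0]
    for i in which:
        draws = rng.random((n_loci, 2)) < freqs_of_row[i][:, None]
        n_ref = draws.sum(axis=1)
        for j in range(n_loci):
            if n_ref[j] == 2:
                rows[i, j] = ref[j] + ref[j]
            elif n_ref[j] == 1:
                rows[i, j] = ref[j] + alt[j]
            else:
                rows[i, j] = alt[j] + alt[j]


def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Generate a seeded synthetic genotype panel with known ground truth.

    Returns the genotype matrix plus the truth record (per-group allele
    frequencies, group assignments, clone-pair list).  Identical config +
    seed gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n_acc, n_loci = config.n_accessions, config.n_loci

    mafs = config.locus_mafs(rng)
    p_ref = 1.0 - mafs  # REF allele is the major allele at simulation time
    alleles = np.array([rng.choice(4, size=2, replace=False) for _ in range(n_loci)])
    ref = NUCLEOTIDES[alleles[:, 0]]
    alt = NUCLEOTIDES[alleles[:, 1]]

    accessions = [f"acc{i+1:03d}" for i in range(n_acc)]
    loci = [f"chr{j % 8 + 1}_{(j // 8 + 1) * 1_000_000 + j + 1}" for j in range(n_loci)]

    # group structure with Balding-Nichols dispersion calibrated to Gst
    if config.n_groups == 2:
        half = n_acc // 2
        group_idx = np.array([0] * half + [1] * (n_acc - half))
        t = config.target_fst
        if t > 0:
            f_bn = 2.0 * t / (1.0 + t)
            c = (1.0 - f_bn) / f_bn
            group_freqs = np.empty((2, n_loci))
            for g in range(2):
                group_freqs[g] = rng.beta(np.maximum(p_ref * c, 1e-6),
                                          np.maximum((1.0 - p_ref) * c, 1e-6))
        else:
            group_freqs = np.vstack([p_ref, p_ref])
    else:
        group_idx = np.zeros(n_acc, dtype=int)
        group_freqs = p_ref[None, :]

    freqs_of_row = group_freqs[group_idx]  # (n_acc, n_loci)
    calls = np.empty((n_acc, n_loci), dtype="<U2")
    _sample_rows(rng, freqs_of_row, ref, alt, calls, range(n_acc))

    # clone pairs: disjoint accession pairs drawn within a group
    clone_pairs: list[tuple[int, int]] = []
    if config.n_clone_pairs:
        available = list(range(n_acc))
        for k in range(config.n_clone_pairs):
            g = k % int(group_idx.max() + 1)
            pool = [i for i in available if group_idx[i] == g]
            if len(pool) < 2:
                pool = available
            pair = rng.choice(len(pool), size=2, replace=False)
            a, b = pool[pair[0]], pool[pair[1]]
            clone_pairs.append((min(a, b), max(a, b)))
            available = [i for i in available if i not in (a, b)]

    clone_targets = {b for _, b in clone_pairs}
    if config.ensure_unique:
        # resample accidental multilocus-genotype collisions so the clone
        # list is the exact indistinguishability ground truth
        for _ in range(200):
            keys: dict[tuple, int] = {}
            dupes: list[int] = []
            for i in range(n_acc):
                if i in clone_targets:
                    continue
                key = tuple(calls[i])
                if key in keys:
                    dupes.append(i)
                else:
                    keys[key] = i
            if not dupes:
                break
            _sample_rows(rng, freqs_of_row, ref, alt, calls, dupes)

    if config.missing_rate > 0:
        mask = rng.random((n_acc, n_loci)) < config.missing_rate
        calls[mask] = MISSING

    for a, b in clone_pairs:  # byte-identical rows, incl. missing pattern
        calls[b] = calls[a]

    matrix = GenotypeMatrix(
        accessions=accessions,
        loci=loci,
        calls=calls,
        ref=list(ref),
        alt=list(alt),
    )
    truth = SyntheticTruth(
        group_of={accessions[i]: f"G{group_idx[i] + 1}" for i in range(n_acc)},
        group_freqs=group_freqs,
        ancestral_freqs=p_ref,
        clone_pairs=[(accessions[a], accessions[b]) for a, b in clone_pairs],
    )
    return matrix, truth


# ---------------------------------------------------------------------- #
# candidate-SNP tables with planted filter defects
# ---------------------------------------------------------------------- #


@dataclass
class CandidateTruth:
    """Planted-defect labels for a simulated candidate table."""

    has_secondary: dict[str, bool]
    has_duplicate: dict[str, bool]
    variant_positions: dict[str, np.ndarray]   # all variant sites per chromosome

    def defect_free(self) -> set[str]:
        return {
            cid
            for cid in self.has_secondary
            if not self.has_secondary[cid] and not self.has_duplicate[cid]
        }


def _random_feasible_seq(rng: np.random.Generator, length: int,
                         max_homopolymer: int = 4) -> str:
    """Random sequence with homopolymer runs capped (KASP-designable)."""
    out = []
    run = 0
    last = None
    for _ in range(length):
        if run >= max_homopolymer:
            choices = [b for b in "ACGT" if b != last]
            base = choices[rng.integers(len(choices))]
        else:
            base = "ACGT"[rng.integers(4)]
        run = run + 1 if base == last else 1
        last = base
        out.append(base)
    return "".join(out)


def _feasible_flank(rng: np.random.Generator, length: int) -> str:
    """Flank whose proximal 50-bp window is GC-balanced and run-capped."""
    for _ in range(200):
        seq = _random_feasible_seq(rng, length)
        win = seq[:50] if length >= 50 else seq
        gc = sum(b in "GC" for b in win) / len(win)
        if 0.35 <= gc <= 0.65:
            return seq
    return seq  # pragma: no cover - practically unreachable


def simulate_candidate_table(
    n_candidates: int,
    flank_len: int = 60,
    secondary_poly_rate: float = 0.0,
    duplicate_region_rate: float = 0.0,
    seed: int = 0,
    *,
    n_accessions: int = 40,
    maf_range: tuple[float, float] = (0.2, 0.5),
    depth_range: tuple[int, int] = (10, 30),
    gq_range: tuple[int, int] = (30, 60),
) -> tuple[list[CandidateSNP], str, CandidateTruth]:
    """Candidate SNPs with flanks drawn from a synthetic reference.

    Defects are planted independently: with probability
    ``secondary_poly_rate`` a second variant position lands within 50 bp
    of the target; with probability ``duplicate_region_rate`` the flanking
    context is copied elsewhere in the reference so the uniqueness check
    fails.  Returns ``(candidates, reference FASTA text, truth)``.

    Flanks are generated KASP-designable (bounded homopolymers, balanced
    GC) so the planted defects are the only filter failures; per-accession
    calls are drawn HW at a MAF from ``maf_range`` with depth/GQ in the
    given ranges.
    """
    if flank_len < 50:
        raise ValueError("flank_len must be >= 50 to express the 50-bp flanking rule")
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    spacer = 150  # keeps ±50-bp windows of neighbouring candidates disjoint

    segments: list[str] = []
    candidates: list[CandidateSNP] = []
    has_secondary: dict[str, bool] = {}
    has_duplicate: dict[str, bool] = {}
    positions: list[int] = []
    duplicate_contexts: list[str] = []
    cursor = 0

    for _ in range(n_candidates):
        gap = _random_feasible_seq(rng, spacer)
        flank5 = _feasible_flank(rng, flank_len)[::-1]  # proximal window at the 3' end
        flank3 = _feasible_flank(rng, flank_len)
        ref_allele, alt_allele = NUCLEOTIDES[rng.choice(4, size=2, replace=False)]
        segment = gap + flank5 + ref_allele + flank3
        pos = cursor + spacer + flank_len + 1  # 1-based SNP coordinate
        cursor += len(segment)
        segments.append(segment)

        cid = f"{chrom}_{pos}"
        positions.append(pos)

        secondary = bool(rng.random() < secondary_poly_rate)
        has_secondary[cid] = secondary
        if secondary:
            offset = int(rng.integers(1, 51)) * (1 if rng.random() < 0.5 else -1)
            positions.append(pos + offset)

        duplicate = bool(rng.random() < duplicate_region_rate)
        has_duplicate[cid] = duplicate
        if duplicate:
            duplicate_contexts.append(flank5 + ref_allele + flank3)

        maf = rng.uniform(*maf_range)
        draws = rng.random((n_accessions, 2)) >= maf  # True = ref allele
        genotypes = np.array(
            [
                ref_allele * 2 if d.sum() == 2 else (ref_allele + alt_allele if d.sum() == 1 else alt_allele * 2)
                for d in draws
            ],
            dtype="<U2",
        )
        depths = rng.integers(depth_range[0], depth_range[1] + 1, size=n_accessions)
        gqs = rng.integers(gq_range[0], gq_range[1] + 1, size=n_accessions)
        candidates.append(
            CandidateSNP(
                id=cid,
                chrom=chrom,
                pos=pos,
                ref_allele=str(ref_allele),
                alt_allele=str(alt_allele),
                flank5=flank5,
                flank3=flank3,
                genotypes=genotypes,
                depths=depths,
                gqs=gqs,
            )
        )

    for context in duplicate_contexts:
        segments.append(_random_feasible_seq(rng, spacer) + context)
    sequence = "".join(segments) + _random_feasible_seq(rng, spacer)

    fasta_lines = [f">{chrom}"]
    fasta_lines += [sequence[i : i + 70] for i in range(0, len(sequence), 70)]
    fasta = "\n".join(fasta_lines) + "\n"

    truth = CandidateTruth(
        has_secondary=has_secondary,
        has_duplicate=has_duplicate,
        variant_positions={chrom: np.array(sorted(positions))},
    )
    return candidates, fasta, truth


def write_fasta(text: str, path) -> None:
    from pathlib import Path

    Path(path).write_text(text)
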