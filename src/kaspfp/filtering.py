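"""Candidate-SNP filter cascade for KASP assay design.

Four stages, applied in fixed order:

1. flanking conservation — no other variant within ±50 bp of the target;
2. genotype quality — calls failing depth/GQ become missing, then the
   locus must satisfy missing-rate, MAF and biallelic thresholds;
3. unique mapping — the ~100 bp probe centred on the SNP occurs exactly
   once in the reference (exact substring search on either strand; a
   deliberate, fully testable proxy for BLAST uniqueness);
4. KASP design feasibility — proximal 50-bp flanks GC-balanced, bounded
   homopolymer runs, no ambiguous bases.

Each stage annotates candidates and the cascade emits a stage-by-stage
count report.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .genotypes import MISSING
from . import diversity


@dataclass
class CandidateSNP:
    """A biallelic variant with flanking sequence and per-accession calls."""

    id: str
    chrom: str
    pos: int                     # 1-based
    ref_allele: str
    alt_allele: str
    flank5: str = ""
    flank3: str = ""
    genotypes: np.ndarray | None = None   # "<U2" calls, REF/ALT oriented
    depths: np.ndarray | None = None
    gqs: np.ndarray | None = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.id != f"{self.chrom}_{self.pos}":
            raise ValueError(f"id {self.id!r} must equal chrom_pos {self.chrom}_{self.pos}")
        for allele in (self.ref_allele, self.alt_allele):
            if allele not in "ACGT" or len(allele) != 1:
                raise ValueError(f"alleles must be single nucleotides, got {allele!r}")

    def masked_genotypes(self, min_depth: int, min_gq: int) -> np.ndarray:
        """Calls with sub-threshold depth or GQ converted to missing."""
        if self.genotypes is None:
            raise ValueError(f"candidate {self.id} carries no calls")
        calls = self.genotypes.copy()
        if self.depths is not None:
            calls[self.depths < min_depth] = MISSING
        if self.gqs is not None:
            calls[self.gqs < min_gq] = MISSING
        return calls


@dataclass
class FilterStage:
    name: str
    n_in: int
    n_retained: int
    params: dict


@dataclass
class FilterReport:
    """Ordered per-stage input/retained counts of a filter cascade."""

    stages: list[FilterStage] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_retained: int, params: dict) -> None:
        if n_retained > n_in:
            raise ValueError("retained count cannot exceed input count")
        if self.stages and n_in != self.stages[-1].n_retained:
            raise ValueError("stage input must equal previous stage's retained count")
        self.stages.append(FilterStage(name, n_in, n_retained, dict(params)))

    def to_dict(self) -> dict:
        return {
            "stages": [
                {"name": s.name, "input": s.n_in, "retained": s.n_retained, "params": s.params}
                for s in self.stages
            ]
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_text(self) -> str:
        lines = [f"{'stage':<24}{'input':>10}{'retained':>10}"]
        for s in self.stages:
            lines.append(f"{s.name:<24}{s.n_in:>10}{s.n_retained:>10}")
        return "\n".join(lines)


def filter_flanking_conservation(
    candidates: Sequence[CandidateSNP],
    all_variant_positions: Mapping[str, np.ndarray],
    window: int = 50,
) -> list[CandidateSNP]:
    """Retain candidates with no other variant within ±``window`` bp.

    The interval [pos - window, pos + window] is inclusive on both ends;
    the candidate's own position is not counted against it.  Position
    arrays must be sorted per chromosome.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    positions = {c: np.asarray(p) for c, p in all_variant_positions.items()}
    for chrom, p in positions.items():
        if np.any(np.diff(p) < 0):
            raise ValueError(f"variant positions for {chrom} are not sorted")
    retained = []
    for cand in candidates:
        p = positions.get(cand.chrom, np.empty(0, dtype=int))
        lo = np.searchsorted(p, cand.pos - window, side="left")
        hi = np.searchsorted(p, cand.pos + window, side="right")
        n_in_window = hi - lo
        n_self = np.count_nonzero(p[lo:hi] == cand.pos)
        ok = (n_in_window - n_self) == 0
        cand.annotations["flanking_conserved"] = bool(ok)
        if ok:
            retained.append(cand)
    return retained


def filter_genotype_quality(
    candidates: Sequence[CandidateSNP],
    min_depth: int = 8,
    min_gq: int = 20,
    max_missing: float = 0.1,
    min_maf: float = 0.05,
    require_biallelic: bool = True,
) -> list[CandidateSNP]:
    """Depth/GQ/missing-rate/MAF/biallelic screen over per-locus calls.

    A call failing depth or GQ is treated as missing before the locus
    missing rate and MAF are computed, so the missing-rate threshold is
    the single gatekeeper for low-quality data.
    """
    if min_depth < 0 or min_gq < 0:
        raise ValueError("depth/GQ thresholds must be non-negative")
    if not (0.0 <= max_missing <= 1.0 and 0.0 <= min_maf <= 1.0):
        raise ValueError("max_missing and min_maf must lie in [0, 1]")
    retained = []
    for cand in candidates:
        calls = cand.masked_genotypes(min_depth, min_gq)
        missing = np.count_nonzero(calls == MISSING)
        missing_rate = missing / len(calls)
        reasons = []
        if missing_rate > max_missing:
            reasons.append("missing_rate")
        maf = 0.0
        n_alleles = 0
        if missing_rate < 1.0:
            freqs = diversity.allele_frequencies(calls)
            n_alleles = len(freqs)
            maf = min(freqs.values()) if n_alleles >= 2 else 0.0
        if maf < min_maf:
            reasons.append("maf")
        if require_biallelic and n_alleles != 2:
            reasons.append("not_biallelic")
        cand.annotations["quality"] = {
            "pass": not reasons,
            "missing_rate": missing_rate,
            "maf": maf,
            "n_alleles": n_alleles,
            "reasons": reasons,
        }
        if not reasons:
            retained.append(cand)
    return retained


def _parse_reference(reference: str | Path | Mapping[str, str]) -> dict[str, str]:
    if isinstance(reference, Mapping):
        return {k: str(v).upper() for k, v in reference.items()}
    text = str(reference)
    if not text.lstrip().startswith(">"):
        text = Path(reference).read_text()
    records = SeqIO.parse(io.StringIO(text), "fasta")
    return {rec.id: str(rec.seq).upper() for rec in records}


def _count_overlapping(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        start = haystack.find(needle, start)
        if start < 0:
            return count
        count += 1
        start += 1


def build_probe(candidate: CandidateSNP, probe_len: int = 100) -> str:
    """Probe of ``probe_len`` bases centred on the SNP (ref base included)."""
    left = probe_len // 2
    right = probe_len - left - 1
    if len(candidate.flank5) < left or len(candidate.flank3) < right:
        raise ValueError(
            f"candidate {candidate.id}: flanks shorter than probe halves "
            f"({left}/{right} bp required)"
        )
    return candidate.flank5[-left:] + candidate.ref_allele + candidate.flank3[:right]


def filter_unique_mapping(
    candidates: Sequence[CandidateSNP],
    reference: str | Path | Mapping[str, str],
    probe_len: int = 100,
) -> list[CandidateSNP]:
    """Retain candidates whose probe maps to exactly one reference site.

    The probe (5' tail + reference base + 3' head) or its reverse
    complement must occur exactly once by exact substring match across all
    reference sequences — a self-contained stand-in for BLAST uniqueness.
    """
    seqs = _parse_reference(reference)
    retained = []
    for cand in candidates:
        probe = build_probe(cand, probe_len).upper()
        rc = str(Seq(probe).reverse_complement())
        hits = sum(_count_overlapping(s, probe) for s in seqs.values())
        if rc != probe:
            hits += sum(_count_overlapping(s, rc) for s in seqs.values())
        cand.annotations["unique_mapping"] = {"pass": hits == 1, "hits": hits}
        if hits == 1:
            retained.append(cand)
    return retained


def _max_run(seq: str) -> int:
    best = run = 0
    last = None
    for base in seq:
        run = run + 1 if base == last else 1
        last = base
        best = max(best, run)
    return best


def assess_kasp_feasibility(
    candidate: CandidateSNP,
    gc_range: tuple[float, float] = (0.3, 0.7),
    max_homopolymer: int = 4,
) -> tuple[bool, list[str]]:
    """Simplified primer-design screen on the proximal 50-bp flanks.

    Feasible iff both windows have GC content within ``gc_range``, no
    homopolymer run longer than ``max_homopolymer``, and no ambiguous
    bases.  Returns the verdict plus every violated rule.
    """
    reasons = []
    for window in (candidate.flank5[-50:], candidate.flank3[:50]):
        if not window:
            reasons.append("missing_flank")
            continue
        if any(b not in "ACGT" for b in window):
            reasons.append("ambiguous_base")
        gc = sum(b in "GC" for b in window) / len(window)
        if not gc_range[0] <= gc <= gc_range[1]:
            reasons.append("gc_out_of_range")
        if _max_run(window) > max_homopolymer:
            reasons.append("homopolymer")
    reasons = sorted(set(reasons))
    return (not reasons, reasons)


def run_filter_cascade(
    candidates: Sequence[CandidateSNP],
    reference: str | Path | Mapping[str, str],
    all_variant_positions: Mapping[str, np.ndarray] | None = None,
    window: int = 50,
    min_depth: int = 8,
    min_gq: int = 20,
    max_missing: float = 0.1,
    min_maf: float = 0.05,
    require_biallelic: bool = True,
    probe_len: int = 100,
    gc_range: tuple[float, float] = (0.3, 0.7),
    max_homopolymer: int = 4,
) -> tuple[list[CandidateSNP], FilterReport]:
    """Apply all four stages in order and report per-stage counts.

    When ``all_variant_positions`` is omitted it is derived from the
    candidates themselves.
    """
    if all_variant_positions is None:
        by_chrom: dict[str, list[int]] = {}
        for cand in candidates:
            by_chrom.setdefault(cand.chrom, []).append(cand.pos)
        all_variant_positions = {c: np.array(sorted(p)) for c, p in by_chrom.items()}

    report = FilterReport()
    current = list(candidates)

    out = filter_flanking_conservation(current, all_variant_positions, window)
    report.add("flanking_conservation", len(current), len(out), {"window_bp": window})
    current = out

    out = filter_genotype_quality(current, min_depth, min_gq, max_missing, min_maf, require_biallelic)
    report.add(
        "genotype_quality",
        len(current),
        len(out),
        {
            "min_depth": min_depth,
            "min_gq": min_gq,
            "max_missing": max_missing,
            "min_maf": min_maf,
            "require_biallelic": require_biallelic,
        },
    )
    current = out

    out = filter_unique_mapping(current, reference, probe_len)
    report.add("unique_mapping", len(current), len(out), {"probe_len_bp": probe_len})
    current = out

    out = []
    for cand in current:
        feasible, reasons = assess_kasp_feasibility(cand, gc_range, max_homopolymer)
        cand.annotations["kasp_feasibility"] = {"pass": feasible, "reasons": reasons}
        if feasible:
            out.append(cand)
    report.add(
        "kasp_design_feasibility",
        len(current),
        len(out),
        {"gc_range": list(gc_range), "max_homopolymer": max_homopolymer},
    )
    return out, report


# ---------------------------------------------------------------------- #
# candidate table I/O
# ---------------------------------------------------------------------- #

CANDIDATE_COLUMNS = ["id", "chrom", "pos", "ref_allele", "alt_allele", "flank5", "flank3"]


def write_candidate_table(candidates: Sequence[CandidateSNP], path: str | Path) -> None:
    """Delimited candidate table; per-accession calls, when present, are
    stored as comma-joined ``genotypes``/``depths``/``gqs`` columns."""
    rows = []
    with_calls = any(c.genotypes is not None for c in candidates)
    for c in candidates:
        row = [c.id, c.chrom, c.pos, c.ref_allele, c.alt_allele, c.flank5, c.flank3]
        if with_calls:
            row += [
                ",".join(c.genotypes) if c.genotypes is not None else "",
                ",".join(map(str, c.depths)) if c.depths is not None else "",
                ",".join(map(str, c.gqs)) if c.gqs is not None else "",
            ]
        rows.append(row)
    columns = CANDIDATE_COLUMNS + (["genotypes", "depths", "gqs"] if with_calls else [])
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_candidate_table(path: str | Path) -> list[CandidateSNP]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for row in df.itertuples():
        kwargs = {}
        if getattr(row, "genotypes", "") and isinstance(row.genotypes, str):
            kwargs["genotypes"] = np.array(row.genotypes.split(","), dtype="<U2")
        if getattr(row, "depths", "") and isinstance(row.depths, str):
            kwargs["depths"] = np.array(row.depths.split(","), dtype=int)
        if getattr(row, "gqs", "") and isinstance(row.gqs, str):
            kwargs["gqs"] = np.array(row.gqs.split(","), dtype=int)
        out.append(
            CandidateSNP(
                id=row.id,
                chrom=row.chrom,
                pos=int(row.pos),
                ref_allele=row.ref_allele,
                alt_allele=row.alt_allele,
                flank5=row.flank5,
                flank3=row.flank3,
                **kwargs,
            )
        )
    return out
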