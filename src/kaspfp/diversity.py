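"""Per-locus diversity statistics and between-group differentiation.

All statistics are the classical plug-in estimators over allele
frequencies p_i computed from the non-missing diploid calls at a locus:

* expected heterozygosity  He = 1 - sum(p_i^2)  (no small-sample correction;
  this keeps the identity Ne = 1/(1-He) exact for biallelic loci)
* effective number of alleles  Ne = 1 / sum(p_i^2)
* Shannon's information index  I = -sum(p_i ln p_i)  (natural log)
* observed heterozygosity  Ho = fraction of heterozygous non-missing calls
* polymorphism information content (Botstein)
  PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2
* minor allele frequency  MAF = min(p, q) for a biallelic locus

Between-group differentiation uses Nei's Gst with two equally weighted
groups: per locus Hs is the mean within-group He and Ht the He of the mean
of the group allele-frequency vectors; Fst = (mean Ht - mean Hs) / mean Ht
over polymorphic loci.  The island-model gene-flow estimate is
Nm = (1 - Fst) / (4 Fst).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genotypes import MISSING, GenotypeMatrix


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round half away from zero, as diversity tables conventionally do.

    Values are kept at full precision internally; this applies only at
    serialization (e.g. Ne = 1.5625 prints as 1.563, not banker's 1.562).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class LocusStats:
    """All per-locus summary statistics reported by the pipeline."""

    locus: str | None
    n: int                 # accessions with a non-missing call
    na: int                # observed number of alleles
    ne: float              # effective number of alleles
    shannon_i: float       # Shannon's information index (nats)
    ho: float              # observed heterozygosity
    he: float              # expected heterozygosity
    maf: float
    pic: float
    missing_rate: float

    def rounded(self, ndigits: int = 3) -> dict:
        """Serialization form; rounding (half away from zero) only here."""
        return {
            "locus": self.locus,
            "N": self.n,
            "Na": self.na,
            "Ne": round_half_up(self.ne, ndigits),
            "I": round_half_up(self.shannon_i, ndigits),
            "Ho": round_half_up(self.ho, ndigits),
            "He": round_half_up(self.he, ndigits),
            "MAF": round_half_up(self.maf, ndigits),
            "PIC": round_half_up(self.pic, ndigits),
            "missing_rate": round_half_up(self.missing_rate, ndigits),
        }


@dataclass
class GroupDifferentiation:
    """Pairwise Fst and gene flow between two accession groups."""

    groups: tuple[str, str]
    fst: float
    nm: float | None       # None when Fst == 0 (gene flow unbounded)
    n_loci_used: int

    @property
    def nm_label(self) -> str:
        return "unbounded" if self.nm is None else f"{self.nm:.3f}"


def allele_frequencies(calls: Iterable[str]) -> dict[str, float]:
    """Allele frequencies at one locus, missing calls excluded.

    Counts both alleles of every non-missing diploid call and divides by
    2N.  Returns alleles in decreasing frequency order (ties broken
    alphabetically).  Raises ``ValueError`` on an all-missing column.
    """
    counts: Counter[str] = Counter()
    for call in calls:
        if call == MISSING or "N" in call:
            continue
        counts[call[0]] += 1
        counts[call[1]] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no non-missing calls at locus")
    return {
        a: c / total
        for a, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    }


def _pic(freqs: Sequence[float]) -> float:
    s2 = sum(p * p for p in freqs)
    cross = 0.0
    for i in range(len(freqs)):
        for j in range(i + 1, len(freqs)):
            cross += 2.0 * freqs[i] ** 2 * freqs[j] ** 2
    return 1.0 - s2 - cross


def locus_summary(calls: Iterable[str], locus: str | None = None) -> LocusStats:
    """Compute every per-locus statistic from one genotype column."""
    calls = list(calls)
    n_total = len(calls)
    present = [c for c in calls if c != MISSING and "N" not in c]
    if not present:
        raise ValueError("no non-missing calls at locus")
    freqs = allele_frequencies(present)
    p = list(freqs.values())
    s2 = sum(x * x for x in p)
    he = 1.0 - s2
    ne = 1.0 / s2
    shannon = -sum(x * math.log(x) for x in p if x > 0)
    ho = sum(1 for c in present if c[0] != c[1]) / len(present)
    maf = min(p) if len(p) >= 2 else 0.0
    return LocusStats(
        locus=locus,
        n=len(present),
        na=len(p),
        ne=ne,
        shannon_i=shannon,
        ho=ho,
        he=he,
        maf=maf,
        pic=_pic(p),
        missing_rate=(n_total - len(present)) / n_total,
    )


def stats_from_frequencies(
    freqs: Mapping[str, float] | Sequence[float],
    locus: str | None = None,
    n: int = 0,
) -> LocusStats:
    """Frequency-based statistics (He, Ne, I, MAF, PIC) from allele frequencies.

    Useful when a table prints He but not genotypes: combined with
    :func:`invert_he` it reconstructs every frequency-derived column.
    Genotype-derived fields (Ho, missing rate) are not computable from
    frequencies and are reported as 0.
    """
    p = list(freqs.values()) if isinstance(freqs, Mapping) else [float(x) for x in freqs]
    if not math.isclose(sum(p), 1.0, abs_tol=1e-9):
        raise ValueError("allele frequencies must sum to 1")
    s2 = sum(x * x for x in p)
    return LocusStats(
        locus=locus,
        n=n,
        na=sum(1 for x in p if x > 0),
        ne=1.0 / s2,
        shannon_i=-sum(x * math.log(x) for x in p if x > 0),
        ho=0.0,
        he=1.0 - s2,
        maf=min(p) if len(p) >= 2 else 0.0,
        pic=_pic(p),
        missing_rate=0.0,
    )


def matrix_summary(matrix: GenotypeMatrix) -> list[LocusStats]:
    """Per-locus statistics for every locus of a genotype matrix."""
    return [locus_summary(matrix.calls[:, j], locus) for j, locus in enumerate(matrix.loci)]


def invert_he(he: float) -> tuple[float, float]:
    """Allele frequencies (p >= q) of a biallelic locus with given He.

    Solves 2pq = He with p + q = 1: p = (1 + sqrt(1 - 2 He)) / 2.  Only
    He <= 0.5 is attainable for two alleles.
    """
    if not 0.0 <= he <= 0.5:
        raise ValueError(f"biallelic He must lie in [0, 0.5], got {he}")
    p = (1.0 + math.sqrt(1.0 - 2.0 * he)) / 2.0
    return p, 1.0 - p


def nm_from_fst(fst: float) -> float:
    """Wright island-model gene flow Nm = (1 - Fst) / (4 Fst)."""
    if fst <= 0:
        raise ValueError("Nm is unbounded (undefined) when Fst <= 0")
    return (1.0 - fst) / (4.0 * fst)


def fst(matrix: GenotypeMatrix, groups: Mapping[str, str]) -> GroupDifferentiation:
    """Nei's Gst between exactly two accession groups.

    Per locus the two groups are weighted equally; loci monomorphic in the
    pooled sample, or with no data in either group, are skipped.  The
    global value is the ratio of locus-averaged (Ht - Hs) to locus-averaged
    Ht.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    members = {
        g: [i for i, a in enumerate(matrix.accessions) if groups.get(a) == g]
        for g in labels
    }
    for g, idx in members.items():
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 accessions")

    hs_vals: list[float] = []
    ht_vals: list[float] = []
    for j in range(matrix.n_loci):
        col = matrix.calls[:, j]
        per_group: list[dict[str, float]] = []
        usable = True
        for g in labels:
            sub = col[members[g]]
            try:
                per_group.append(allele_frequencies(sub))
            except ValueError:
                usable = False
                break
        if not usable:
            continue
        alleles = sorted(set().union(*per_group))
        vecs = np.array([[f.get(a, 0.0) for a in alleles] for f in per_group])
        pooled = vecs.mean(axis=0)
        ht = 1.0 - float(np.sum(pooled**2))
        if ht <= 0:  # monomorphic across both groups
            continue
        hs = float(np.mean([1.0 - np.sum(v**2) for v in vecs]))
        hs_vals.append(hs)
        ht_vals.append(ht)

    if not ht_vals:
        raise ValueError("no polymorphic loci usable for Fst")
    mean_ht = float(np.mean(ht_vals))
    mean_hs = float(np.mean(hs_vals))
    value = max(0.0, (mean_ht - mean_hs) / mean_ht)
    nm = nm_from_fst(value) if value > 0 else None
    return GroupDifferentiation(
        groups=(labels[0], labels[1]),
        fst=value,
        nm=nm,
        n_loci_used=len(ht_vals),
    )


def panel_summary(stats: Sequence[LocusStats]) -> dict:
    """Panel-level means and the missing-rate range over a marker set."""
    if not stats:
        raise ValueError("empty panel")
    return {
        "n_loci": len(stats),
        "mean_maf": float(np.mean([s.maf for s in stats])),
        "mean_he": float(np.mean([s.he for s in stats])),
        "mean_pic": float(np.mean([s.pic for s in stats])),
        "missing_rate_range": (
            min(s.missing_rate for s in stats),
            max(s.missing_rate for s in stats),
        ),
    }
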