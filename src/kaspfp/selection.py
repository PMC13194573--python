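"""Core-marker screening and the minimal discriminating marker-set search.

An accession pair is *distinguished* by a locus subset iff some locus in
the subset has non-missing calls for both accessions whose unordered
allele pairs differ — a missing ("NN") call never serves as a
discriminating site.  Finding a smallest marker subset that distinguishes
as many pairs as possible is a set-cover problem over accession pairs;
the production path is greedy set cover with a redundancy-pruning
post-pass, and an exhaustive enumerator serves as the optimality oracle
on small instances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .diversity import LocusStats
from .genotypes import MISSING, GenotypeMatrix, unordered


class InstanceTooLargeError(ValueError):
    """Raised when exhaustive enumeration would be intractable."""


@dataclass
class ScreeningCriteria:
    """Thresholds for the stepwise marker screen (boundaries inclusive)."""

    max_missing_rate: float = 0.1
    min_maf: float = 0.0
    min_pic: float = 0.0
    require_stable: bool = True

    def __post_init__(self) -> None:
        for name in ("max_missing_rate", "min_maf", "min_pic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class SelectionStep:
    locus: str
    new_pairs: int           # accession pairs newly separated by this locus
    distinguished: int       # accessions uniquely identified so far


@dataclass
class CoreSet:
    """Ordered selected marker subset with its selection trace."""

    loci: list[str]
    trace: list[SelectionStep]
    unresolved_groups: list[list[str]]
    distinguished_pairs: int
    total_pairs: int
    n_accessions: int
    pruned: list[str] = field(default_factory=list)

    @property
    def n_distinguished_accessions(self) -> int:
        return self.n_accessions - sum(len(g) for g in self.unresolved_groups)

    def to_dict(self) -> dict:
        return {
            "loci": self.loci,
            "trace": [
                {"locus": s.locus, "new_pairs": s.new_pairs, "distinguished": s.distinguished}
                for s in self.trace
            ],
            "unresolved_groups": self.unresolved_groups,
            "distinguished_pairs": self.distinguished_pairs,
            "total_pairs": self.total_pairs,
            "n_accessions": self.n_accessions,
            "n_distinguished_accessions": self.n_distinguished_accessions,
            "pruned": self.pruned,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def screen_markers(
    stats: Sequence[LocusStats],
    qc: Mapping[str, bool] | None,
    criteria: ScreeningCriteria,
) -> list[str]:
    """Loci passing all screening criteria, ordered by PIC then ID.

    ``qc`` holds external genotyping-QC verdicts (amplification stability,
    cluster clarity) per locus; when ``None``, all loci are treated as
    stable.  Thresholds are inclusive: a locus at exactly the maximum
    missing rate is retained.
    """
    qc = qc or {}
    unknown = set(qc) - {s.locus for s in stats}
    if unknown:
        raise ValueError(f"QC annotations reference unknown loci: {sorted(unknown)}")
    passed = []
    for s in stats:
        if criteria.require_stable and not qc.get(s.locus, True):
            continue
        if s.missing_rate > criteria.max_missing_rate:
            continue
        if s.maf < criteria.min_maf or s.pic < criteria.min_pic:
            continue
        passed.append(s)
    passed.sort(key=lambda s: (-s.pic, s.locus))
    return [s.locus for s in passed]


def pair_distinguished(a: Sequence[str], b: Sequence[str], loci_idx: Sequence[int] | None = None) -> bool:
    """True iff some locus separates the two accessions.

    Both calls must be non-missing and their unordered allele pairs must
    differ (heterozygote orientation never matters).
    """
    idx = range(len(a)) if loci_idx is None else loci_idx
    for j in idx:
        ca, cb = a[j], b[j]
        if ca == MISSING or cb == MISSING or "N" in ca or "N" in cb:
            continue
        if unordered(ca) != unordered(cb):
            return True
    return False


def _pair_separation_masks(matrix: GenotypeMatrix, candidates: Sequence[str]) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Boolean (locus x pair) matrix: which candidate separates which pair."""
    n = matrix.n_accessions
    pairs = list(combinations(range(n), 2))
    masks = np.zeros((len(candidates), len(pairs)), dtype=bool)
    for k, locus in enumerate(candidates):
        col = matrix.column(locus)
        keys = np.array(["".join(sorted(c)) if "N" not in c else "NN" for c in col])
        for p, (i, j) in enumerate(pairs):
            if keys[i] != "NN" and keys[j] != "NN" and keys[i] != keys[j]:
                masks[k, p] = True
    return masks, pairs


def mlg_groups(matrix: GenotypeMatrix, loci: Sequence[str]) -> list[list[str]]:
    """Partition accessions by multilocus-genotype indistinguishability.

    With missing data the pairwise not-distinguished relation need not be
    transitive; classes are its transitive closure (union-find), so an
    accession bridging two genotypes through missing calls merges them.
    Singleton classes are the uniquely identified accessions.
    """
    if not loci:
        raise ValueError("loci subset must be non-empty")
    sub = matrix.subset_loci(list(loci))
    n = sub.n_accessions
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in combinations(range(n), 2):
        if not pair_distinguished(sub.calls[i], sub.calls[j]):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri

    classes: dict[int, list[str]] = {}
    for i in range(n):
        classes.setdefault(find(i), []).append(matrix.accessions[i])
    return sorted(classes.values(), key=lambda g: g[0])


def _build_core_set(
    matrix: GenotypeMatrix,
    selected: list[str],
    masks: np.ndarray,
    candidates: Sequence[str],
    pruned: list[str],
    total_pairs: int,
) -> CoreSet:
    """Replay the final locus list to produce the trace and bookkeeping."""
    cand_idx = {l: k for k, l in enumerate(candidates)}
    covered = np.zeros(total_pairs, dtype=bool)
    trace = []
    for locus in selected:
        new = int(np.count_nonzero(masks[cand_idx[locus]] & ~covered))
        covered |= masks[cand_idx[locus]]
        groups = mlg_groups(matrix, selected[: len(trace) + 1])
        distinguished = sum(1 for g in groups if len(g) == 1)
        trace.append(SelectionStep(locus, new, distinguished))
    groups = mlg_groups(matrix, selected) if selected else [[a] for a in matrix.accessions]
    return CoreSet(
        loci=selected,
        trace=trace,
        unresolved_groups=[g for g in groups if len(g) > 1],
        distinguished_pairs=int(np.count_nonzero(covered)),
        total_pairs=total_pairs,
        n_accessions=matrix.n_accessions,
        pruned=pruned,
    )


def greedy_min_set(
    matrix: GenotypeMatrix,
    candidates: Sequence[str],
    tie_break: Mapping[str, float] | None = None,
) -> CoreSet:
    """Greedy set cover over accession pairs, with redundancy pruning.

    At each step the locus separating the most not-yet-separated pairs is
    added (ties: higher PIC per ``tie_break``, then lexicographic ID);
    iteration stops when no candidate separates a new pair.  A post-pass
    removes loci made redundant by later picks, so removing any single
    locus from the result strictly decreases the distinguished-pair count.
    """
    if matrix.n_accessions < 2:
        raise ValueError("need at least two accessions")
    if not candidates:
        raise ValueError("empty candidate list")
    tie_break = tie_break or {}
    masks, pairs = _pair_separation_masks(matrix, candidates)
    covered = np.zeros(len(pairs), dtype=bool)
    remaining = list(range(len(candidates)))
    selected: list[str] = []

    while remaining:
        # best = largest gain, then higher PIC, then lexicographic ID
        best_k = min(
            remaining,
            key=lambda k: (
                -int(np.count_nonzero(masks[k] & ~covered)),
                -tie_break.get(candidates[k], 0.0),
                candidates[k],
            ),
        )
        gain = int(np.count_nonzero(masks[best_k] & ~covered))
        if gain == 0:
            break
        covered |= masks[best_k]
        selected.append(candidates[best_k])
        remaining.remove(best_k)

    # prune loci whose pairs are fully covered by the rest
    pruned: list[str] = []
    changed = True
    while changed:
        changed = False
        for locus in list(selected):
            others = [l for l in selected if l != locus]
            if not others:
                continue
            cand_idx = {l: k for k, l in enumerate(candidates)}
            cover_without = np.zeros(len(pairs), dtype=bool)
            for l in others:
                cover_without |= masks[cand_idx[l]]
            if np.array_equal(cover_without, covered):
                selected = others
                pruned.append(locus)
                changed = True
                break

    return _build_core_set(matrix, selected, masks, candidates, pruned, len(pairs))


def exhaustive_min_set(
    matrix: GenotypeMatrix,
    candidates: Sequence[str],
    tie_break: Mapping[str, float] | None = None,
    max_loci: int = 15,
    max_combinations: int = 2_000_000,
) -> CoreSet:
    """Smallest subset attaining the maximum achievable pair coverage.

    Enumerates subsets by increasing size; ties broken by higher PIC sum,
    then lexicographic locus list.  Raises
    :class:`InstanceTooLargeError` when enumeration would exceed the
    budget (use :func:`greedy_min_set` instead).
    """
    if not candidates:
        raise ValueError("empty candidate list")
    tie_break = tie_break or {}
    masks, pairs = _pair_separation_masks(matrix, candidates)
    target = int(np.count_nonzero(masks.any(axis=0)))

    n = len(candidates)
    limit = min(max_loci, n)
    total = sum(comb(n, k) for k in range(1, limit + 1))
    if total > max_combinations:
        raise InstanceTooLargeError(
            f"{total} subsets to enumerate exceeds budget {max_combinations}; "
            "use greedy_min_set"
        )

    for k in range(1, limit + 1):
        best: tuple | None = None
        for combo in combinations(range(n), k):
            cover = np.zeros(len(pairs), dtype=bool)
            for idx in combo:
                cover |= masks[idx]
            if int(np.count_nonzero(cover)) == target:
                loci = [candidates[i] for i in combo]
                key = (-sum(tie_break.get(l, 0.0) for l in loci), sorted(loci))
                if best is None or key < best[0]:
                    best = (key, loci)
        if best is not None:
            return _build_core_set(matrix, best[1], masks, candidates, [], len(pairs))
    raise AssertionError("unreachable: full candidate set attains the target")
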