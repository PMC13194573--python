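"""Diploid genotype matrices and their on-disk formats.

The central object of the pipeline is a small dense matrix of diploid
biallelic calls: rows are germplasm accessions, columns are SNP loci, and
each cell is a two-letter nucleotide pair such as ``"AG"`` or the missing
marker ``"NN"``.  Heterozygous calls are stored in REF/ALT orientation (the
orientation matters for fingerprint color coding); comparisons that should
ignore orientation go through :func:`unordered`.

Supported formats: a minimal VCF 4.2 (GT only, ``./.`` for missing) and a
delimited genotype table (rows = accessions, columns = locus IDs).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

MISSING = "NN"
_LOCUS_ID_RE = re.compile(r"^(?P<chrom>.+)_(?P<pos>\d+)$")


def unordered(call: str) -> tuple[str, str]:
    """Orientation-free representation of a diploid call (AG == GA)."""
    return tuple(sorted(call))


@dataclass
class GenotypeMatrix:
    """Accessions x loci grid of diploid biallelic calls.

    Parameters
    ----------
    accessions : list of str
        Row labels (germplasm accession IDs).
    loci : list of str
        Column labels, conventionally ``"<chrom>_<pos>"`` with a 1-based
        position.
    calls : ndarray of shape (n_accessions, n_loci), dtype ``<U2``
        Two-letter genotype strings over {A, C, G, T}, or ``"NN"``.
    ref, alt : list of str, optional
        Per-locus allele orientation.  When absent it is derived from
        observed allele frequencies (major allele as REF) on demand.
    """

    accessions: list[str]
    loci: list[str]
    calls: np.ndarray
    ref: list[str] | None = None
    alt: list[str] | None = None
    _locus_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="<U2")
        if self.calls.shape != (len(self.accessions), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.loci)} loci"
            )
        if self.ref is not None and len(self.ref) != len(self.loci):
            raise ValueError("ref length must match loci")
        if self.alt is not None and len(self.alt) != len(self.loci):
            raise ValueError("alt length must match loci")
        self._locus_index = {l: j for j, l in enumerate(self.loci)}

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, locus: str) -> int:
        return self._locus_index[locus]

    def column(self, locus: str) -> np.ndarray:
        return self.calls[:, self._locus_index[locus]]

    def row(self, accession: str) -> np.ndarray:
        return self.calls[self.accessions.index(accession)]

    def subset_loci(self, loci: list[str]) -> "GenotypeMatrix":
        idx = [self._locus_index[l] for l in loci]
        return GenotypeMatrix(
            accessions=list(self.accessions),
            loci=list(loci),
            calls=self.calls[:, idx].copy(),
            ref=[self.ref[i] for i in idx] if self.ref else None,
            alt=[self.alt[i] for i in idx] if self.alt else None,
        )

    def orientation(self) -> tuple[list[str], list[str]]:
        """REF/ALT per locus; derived from major/minor allele if unset."""
        if self.ref is not None and self.alt is not None:
            return self.ref, self.alt
        ref, alt = [], []
        for j in range(self.n_loci):
            counts: Counter[str] = Counter()
            for call in self.calls[:, j]:
                if call != MISSING:
                    counts[call[0]] += 1
                    counts[call[1]] += 1
            ordered = [a for a, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
            ordered += ["N"] * (2 - len(ordered))
            ref.append(ordered[0])
            alt.append(ordered[1])
        return ref, alt

    # ------------------------------------------------------------------ #
    # delimited genotype table
    # ------------------------------------------------------------------ #

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.accessions, columns=self.loci)

    def write_table(self, path: str | Path, sep: str = "\t") -> None:
        df = self.to_dataframe()
        df.index.name = "accession"
        df.to_csv(path, sep=sep)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        return cls(
            accessions=[str(a) for a in df.index],
            loci=[str(l) for l in df.columns],
            calls=df.to_numpy(dtype="<U2"),
        )

    @classmethod
    def read_table(cls, path: str | Path, sep: str = "\t") -> "GenotypeMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
        return cls.from_dataframe(df)

    # ------------------------------------------------------------------ #
    # VCF
    # ------------------------------------------------------------------ #

    def _locus_coords(self) -> list[tuple[str, int]]:
        coords = []
        for j, locus in enumerate(self.loci):
            m = _LOCUS_ID_RE.match(locus)
            if m:
                coords.append((m.group("chrom"), int(m.group("pos"))))
            else:
                coords.append(("chrUn", j + 1))
        return coords

    def write_vcf(self, path: str | Path) -> None:
        """Write a minimal VCF 4.2 (GT format field, ``./.`` missing)."""
        ref, alt = self.orientation()
        coords = self._locus_coords()
        chroms: list[str] = []
        for chrom, _ in coords:
            if chrom not in chroms:
                chroms.append(chrom)
        lines = ["##fileformat=VCFv4.2"]
        lines += [f"##contig=<ID={c},length=2000000000>" for c in chroms]
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        lines.append(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(self.accessions)
        )
        # VCF requires records grouped by contig and sorted by position
        order = sorted(range(self.n_loci), key=lambda j: (chroms.index(coords[j][0]), coords[j][1]))
        for j in order:
            chrom, pos = coords[j]
            r, a = ref[j], alt[j]
            alt_field = a if a not in ("N", r) else "."
            gts = []
            for call in self.calls[:, j]:
                if call == MISSING:
                    gts.append("./.")
                else:
                    codes = sorted("0" if allele == r else "1" for allele in call)
                    gts.append("/".join(codes))
            lines.append(
                f"{chrom}\t{pos}\t{self.loci[j]}\t{r}\t{alt_field}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_vcf(cls, path: str | Path) -> "GenotypeMatrix":
        with pysam.VariantFile(str(path)) as vf:
            accessions = list(vf.header.samples)
            loci, ref, alt, rows = [], [], [], []
            for rec in vf:
                r = rec.ref
                a = rec.alts[0] if rec.alts else "N"
                loci.append(rec.id or f"{rec.chrom}_{rec.pos}")
                ref.append(r)
                alt.append(a)
                col = []
                for sample in accessions:
                    gt = rec.samples[sample]["GT"]
                    if gt is None or any(g is None for g in gt):
                        col.append(MISSING)
                    else:
                        alleles = [r if g == 0 else a for g in sorted(gt)]
                        col.append("".join(alleles))
                rows.append(col)
        calls = np.asarray(rows, dtype="<U2").T if rows else np.empty((len(accessions), 0), dtype="<U2")
        return cls(accessions=accessions, loci=loci, calls=calls, ref=ref, alt=alt)


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Dispatch on extension: ``.vcf`` vs delimited table."""
    p = Path(path)
    if p.suffix == ".vcf":
        return GenotypeMatrix.read_vcf(p)
    sep = "," if p.suffix == ".csv" else "\t"
    return GenotypeMatrix.read_table(p, sep=sep)


def read_group_map(path: str | Path) -> dict[str, str]:
    """Two-column delimited text: accession, group label."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str, comment="#")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
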