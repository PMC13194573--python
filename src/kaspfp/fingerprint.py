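"""DNA fingerprints: multilocus genotype strings, color rows, codes, QR payloads.

Each accession's fingerprint over the core marker panel is its ordered
multilocus genotype string (e.g. ``"AA-AG-TT"``), a color-coded row for
heatmap rendering, and a compact text code suitable for QR encoding.

The genotype→color legend distinguishes some heterozygote orientations
(C/T is Gray but T/C is Dark Green; G/T Deep Red vs T/G Brown): the label
is decided by the call's stored REF/ALT orientation.  Orientations absent
from the legend (e.g. T/A) fall back to their listed mirror (A/T).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

FORMAT_VERSION = "1"

#: genotype (as written, first/second allele) -> color label
COLOR_LEGEND: dict[str, str] = {
    "CC": "Yellow",
    "AA": "Green",
    "TT": "Blue",
    "GG": "Purple",
    "AT": "Orange",
    "AG": "Pink",
    "AC": "Dark Pink",
    "TG": "Brown",
    "TC": "Dark Green",
    "CG": "Light Blue",
    "CT": "Gray",
    "GT": "Deep Red",
    "NN": "White",
}

#: default rendering colors for the 13 labels
COLOR_HEX: dict[str, str] = {
    "Yellow": "#f5e636",
    "Green": "#3cb44b",
    "Blue": "#4363d8",
    "Purple": "#911eb4",
    "Orange": "#f58231",
    "Pink": "#fabed4",
    "Dark Pink": "#d9488c",
    "Brown": "#9a6324",
    "Dark Green": "#1e6e3c",
    "Light Blue": "#42d4f4",
    "Gray": "#a9a9a9",
    "Deep Red": "#800000",
    "White": "#ffffff",
}


def genotype_color(call: str) -> str:
    """Color label for a diploid call (orientation-sensitive).

    Calls are looked up as written; an orientation missing from the
    legend (TA, GA, CA, GC) maps to its reversed, listed form.
    """
    if len(call) != 2 or any(b not in "ACGTN" for b in call):
        raise ValueError(f"invalid genotype call {call!r}")
    if "N" in call:
        return COLOR_LEGEND["NN"]
    if call in COLOR_LEGEND:
        return COLOR_LEGEND[call]
    return COLOR_LEGEND[call[::-1]]


def panel_hash(loci: Sequence[str]) -> str:
    """Short stable digest identifying a marker panel and its order."""
    return hashlib.sha256(",".join(loci).encode()).hexdigest()[:8]


@dataclass
class FingerprintProfile:
    """One accession's fingerprint over an ordered core marker panel."""

    accession: str
    loci: list[str]
    genotype_string: str       # "AA-AG-TT-..."
    colors: list[str]
    code: str                  # accession|panel hash|genotype string
    qr_payload: str

    def to_dict(self) -> dict:
        return {
            "accession": self.accession,
            "loci": self.loci,
            "genotype_string": self.genotype_string,
            "colors": self.colors,
            "code": self.code,
            "qr_payload": self.qr_payload,
        }


def build_fingerprints(
    matrix: GenotypeMatrix, core_loci: Sequence[str]
) -> list[FingerprintProfile]:
    """One fingerprint profile per accession, in core-panel locus order."""
    core_loci = list(core_loci)
    if not core_loci:
        raise ValueError("empty core marker set")
    sub = matrix.subset_loci(core_loci)
    digest = panel_hash(core_loci)
    profiles = []
    for i, accession in enumerate(sub.accessions):
        calls = list(sub.calls[i])
        geno = "-".join(calls)
        code = f"{accession}|{digest}|{geno}"
        profiles.append(
            FingerprintProfile(
                accession=accession,
                loci=core_loci,
                genotype_string=geno,
                colors=[genotype_color(c) for c in calls],
                code=code,
                qr_payload=f"KASPFP{FORMAT_VERSION}|{code}",
            )
        )
    return profiles


def render_heatmap_matrix(profiles: Sequence[FingerprintProfile]) -> pd.DataFrame:
    """Color-label grid with loci as rows and accessions as columns."""
    if not profiles:
        raise ValueError("no profiles")
    loci = profiles[0].loci
    for p in profiles:
        if p.loci != loci:
            raise ValueError("profiles do not share a locus order")
    data = {p.accession: p.colors for p in profiles}
    return pd.DataFrame(data, index=loci)


def write_heatmap_grid(grid: pd.DataFrame, path: str | Path) -> None:
    grid.to_csv(path, sep="\t", index_label="locus")


def read_heatmap_grid(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="locus")


def write_profiles(profiles: Sequence[FingerprintProfile], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([p.to_dict() for p in profiles], indent=2) + "\n"
    )


def profiles_table(profiles: Sequence[FingerprintProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "accession": [p.accession for p in profiles],
            "genotype_string": [p.genotype_string for p in profiles],
            "code": [p.code for p in profiles],
            "qr_payload": [p.qr_payload for p in profiles],
        }
    )


def plot_heatmap(grid: pd.DataFrame, path: str | Path) -> None:
    """Optional PNG rendering of the color grid (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    labels = sorted(COLOR_HEX)
    index = {label: i for i, label in enumerate(labels)}
    coded = grid.map(lambda label: index[label])
    fig, ax = plt.subplots(figsize=(max(6, grid.shape[1] / 4), max(3, grid.shape[0] / 2)))
    ax.imshow(coded.to_numpy(), cmap=ListedColormap([COLOR_HEX[l] for l in labels]),
              vmin=0, vmax=len(labels) - 1, aspect="auto")
    ax.set_yticks(range(grid.shape[0]), grid.index, fontsize=6)
    ax.set_xticks(range(grid.shape[1]), grid.columns, rotation=90, fontsize=5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
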