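"""Pairwise linkage disequilibrium r² between SNPs from phased haplotypes.

With alternate-allele frequencies ``pA``, ``pB`` and joint frequency ``pAB``
across phased haplotypes, the disequilibrium is ``D = pAB - pA*pB`` and

    r² = D² / (pA (1-pA) pB (1-pB)),

ranging from 0 (no correlation) to 1 (perfect correlation). r² is undefined
at monomorphic sites; such cells are reported as not-a-value (``NA`` in TSV
exports), never as 0, to avoid fabricating "no linkage".
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import HaplotypePanel


@dataclass(frozen=True)
class LDResult:
    snp_a: str
    snp_b: str
    r2: float            # nan when undefined
    d: float             # signed disequilibrium D, nan when undefined
    n_haplotypes: int
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r2)


def r_squared(hap_a: Sequence[int] | np.ndarray,
              hap_b: Sequence[int] | np.ndarray,
              snp_a: str = "a", snp_b: str = "b") -> LDResult:
    """LD between two SNPs given their binary phased haplotype vectors."""
    a = np.asarray(hap_a)
    b = np.asarray(hap_b)
    if a.shape != b.shape:
        raise ValueError(f"haplotype vectors differ in length "
                         f"({a.shape} vs {b.shape})")
    n = a.size
    if n < 4:
        raise ValueError("need >= 4 haplotypes")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("allele codes must be 0 or 1")
    p_a = float(a.mean())
    p_b = float(b.mean())
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return LDResult(snp_a=snp_a, snp_b=snp_b, r2=math.nan, d=math.nan,
                        n_haplotypes=n, reason="monomorphic")
    p_ab = float((a & b).mean())
    d = p_ab - p_a * p_b
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LDResult(snp_a=snp_a, snp_b=snp_b, r2=r2, d=d, n_haplotypes=n)


def minor_allele_frequency(column: np.ndarray) -> float:
    p = float(np.asarray(column).mean())
    return min(p, 1.0 - p)


@dataclass
class LDMatrix:
    """r² between two SNP sets, with undefined/filtered cells flagged."""

    r2: pd.DataFrame                  # rows snps_a, columns snps_b; NaN = undefined
    d: pd.DataFrame
    monomorphic: list[str]
    below_maf_floor: list[str]

    def to_tsv(self, path: str | Path, metadata: dict | None = None) -> None:
        """Write the r² matrix; not-a-value cells become the sentinel "NA"."""
        from .io import write_table

        out = self.r2.reset_index().rename(columns={"index": "snp"})
        meta = dict(metadata or {})
        if self.monomorphic:
            meta["monomorphic_snps"] = ",".join(self.monomorphic)
        if self.below_maf_floor:
            meta["below_maf_floor"] = ",".join(self.below_maf_floor)
        out = out.fillna("NA")
        write_table(path, out, metadata=meta)


def ld_matrix(panel: HaplotypePanel, snps_a: Sequence[str] | None = None,
              snps_b: Sequence[str] | None = None,
              maf_floor: float = 0.0) -> LDMatrix:
    """Pairwise r² between ``snps_a`` (rows) and ``snps_b`` (columns).

    Row/column order follows the input SNP order (positional, matching a locus
    heatmap layout); both default to every SNP in the panel. SNPs that are
    monomorphic or fall below ``maf_floor`` yield NaN cells and are flagged,
    not silently dropped. Unknown ids raise KeyError.
    """
    snps_a = list(panel.snp_ids) if snps_a is None else list(snps_a)
    snps_b = list(panel.snp_ids) if snps_b is None else list(snps_b)
    columns = {snp: panel.column(snp) for snp in dict.fromkeys(snps_a + snps_b)}
    monomorphic = sorted({s for s, c in columns.items()
                          if c.min() == c.max()})
    below_floor = sorted({s for s, c in columns.items()
                          if s not in monomorphic
                          and minor_allele_frequency(c) < maf_floor})
    skip = set(monomorphic) | set(below_floor)
    r2 = pd.DataFrame(np.nan, index=snps_a, columns=snps_b)
    d = pd.DataFrame(np.nan, index=snps_a, columns=snps_b)
    for sa in snps_a:
        for sb in snps_b:
            if sa in skip or sb in skip:
                continue
            res = r_squared(columns[sa], columns[sb], snp_a=sa, snp_b=sb)
            r2.loc[sa, sb] = res.r2
            d.loc[sa, sb] = res.d
    return LDMatrix(r2=r2, d=d, monomorphic=monomorphic,
                    below_maf_floor=below_floor)


def plot_ld_heatmap(matrix: LDMatrix, path: str | Path,
                    title: str = "Linkage disequilibrium (r²)") -> None:
    """Render the r² matrix as a heatmap image (undefined cells hatched grey)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.3 * matrix.r2.shape[1]),
                                    max(3, 0.3 * matrix.r2.shape[0])))
    data = np.ma.masked_invalid(matrix.r2.to_numpy(dtype=float))
    cmap = plt.get_cmap("Reds").copy()
    cmap.set_bad("lightgrey")
    im = ax.imshow(data, vmin=0, vmax=1, cmap=cmap, aspect="auto")
    ax.set_xticks(range(matrix.r2.shape[1]), matrix.r2.columns,
                  rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.r2.shape[0]), matrix.r2.index, fontsize=6)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="r²")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
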