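"""Diversity-panel container: inbred accessions x multi-allelic loci.

Accessions are haploid-coded (fully inbred elite lines): each call is a
single allele index per locus, ``-1`` for missing. Loci are either
multi-allelic SSR-like markers or dominant presence/absence DArT-like
markers (two states). Optional metadata: subpopulation labels and a Q
matrix of ancestry fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ValidationError

MISSING = -1

__all__ = ["PanelData", "allele_frequencies", "MISSING"]


@dataclass(frozen=True)
class PanelData:
    accessions: tuple[str, ...]
    loci: tuple[str, ...]
    calls: np.ndarray  # (n_accessions, n_loci) int16, allele index or -1
    locus_types: tuple[str, ...]  # "SSR" | "DArT" per locus
    subpops: pd.Series | None = None  # accession -> subpopulation label
    q_matrix: pd.DataFrame | None = None  # accession x subpopulation ancestry

    def __post_init__(self):
        calls = np.asarray(self.calls, dtype=np.int16)
        object.__setattr__(self, "calls", calls)
        object.__setattr__(self, "accessions", tuple(self.accessions))
        object.__setattr__(self, "loci", tuple(self.loci))
        object.__setattr__(self, "locus_types", tuple(self.locus_types))
        if calls.shape != (len(self.accessions), len(self.loci)):
            raise ValidationError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.loci)} loci"
            )
        if len(set(self.loci)) != len(self.loci):
            raise ValidationError("duplicate locus names")
        if len(self.locus_types) != len(self.loci):
            raise ValidationError("locus_types length mismatch")
        if any(t not in ("SSR", "DArT") for t in self.locus_types):
            raise ValidationError("locus types must be 'SSR' or 'DArT'")
        if self.subpops is not None and set(self.subpops.index) != set(self.accessions):
            raise ValidationError("subpop labels must cover every accession exactly")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, name: str) -> int:
        try:
            return self.loci.index(name)
        except ValueError:
            raise ValidationError(f"locus {name!r} not in panel") from None

    def locus_calls(self, name: str) -> np.ndarray:
        return self.calls[:, self.locus_index(name)]

    def subset_loci(self, loci: list[str]) -> "PanelData":
        idx = [self.locus_index(l) for l in loci]
        return replace(
            self,
            loci=tuple(loci),
            calls=self.calls[:, idx],
            locus_types=tuple(self.locus_types[i] for i in idx),
        )

    def subset_accessions(self, accessions: list[str]) -> "PanelData":
        pos = {a: i for i, a in enumerate(self.accessions)}
        idx = [pos[a] for a in accessions]
        return replace(
            self,
            accessions=tuple(accessions),
            calls=self.calls[idx],
            subpops=self.subpops.loc[list(accessions)] if self.subpops is not None else None,
            q_matrix=self.q_matrix.loc[list(accessions)] if self.q_matrix is not None else None,
        )


def allele_frequencies(calls: np.ndarray) -> dict[int, float]:
    """Allele frequencies of one locus' haploid calls, ignoring missing."""
    ok = calls[calls != MISSING]
    if ok.size == 0:
        return {}
    vals, counts = np.unique(ok, return_counts=True)
    return {int(v): float(c) / ok.size for v, c in zip(vals, counts)}
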