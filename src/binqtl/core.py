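"""Shared genotype-call containers and codes.

Genotype calls are stored as a compact ``int8`` matrix (markers x individuals)
with a four-symbol alphabet: the two parental homozygotes, the heterozygote,
and missing.  Parent 1 of the biparental cross contributes the ``AA`` allele
(written as the REF allele in VCF output), parent 2 the ``BB`` allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# genotype codes
AA: int = 0
AB: int = 1
BB: int = 2
MISSING: int = -1

CODE_TO_LABEL = {AA: "AA", AB: "AB", BB: "BB", MISSING: "NA"}
LABEL_TO_CODE = {v: k for k, v in CODE_TO_LABEL.items()}
VALID_CODES = frozenset((AA, AB, BB, MISSING))


@dataclass
class SnpCallMatrix:
    """Coded SNP calls with physical coordinates for one population.

    Parameters
    ----------
    chrom : array of str, shape (m,)
        Chromosome id per marker.  Markers of one chromosome are contiguous.
    pos : array of int, shape (m,)
        1-based physical coordinate per marker (VCF convention), strictly
        increasing within a chromosome.
    calls : array of int8, shape (m, n)
        Genotype code per marker x individual.
    samples : list of str
        Individual / accession ids (columns of ``calls``).
    population : str
        ``"ril"`` or ``"panel"``.
    """

    chrom: np.ndarray
    pos: np.ndarray
    calls: np.ndarray
    samples: list[str] = field(default_factory=list)
    population: str = "ril"

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2 or self.calls.shape[0] != self.pos.shape[0]:
            raise ValueError("calls must be (n_markers, n_individuals)")
        if self.chrom.shape[0] != self.pos.shape[0]:
            raise ValueError("chrom and pos length mismatch")
        if not self.samples:
            self.samples = [f"ind{i + 1}" for i in range(self.calls.shape[1])]
        if len(self.samples) != self.calls.shape[1]:
            raise ValueError("samples length mismatch")
        bad = ~np.isin(self.calls, (AA, AB, BB, MISSING))
        if bad.any():
            raise ValueError("calls contain codes outside {AA, AB, BB, missing}")
        for c in self.chromosomes:
            p = self.pos[self.chrom == c]
            if p.size > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_markers(self) -> int:
        return self.calls.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[1]

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome ids in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_index(self, chrom_id: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == chrom_id)

    def copy(self) -> "SnpCallMatrix":
        return SnpCallMatrix(
            self.chrom.copy(),
            self.pos.copy(),
            self.calls.copy(),
            list(self.samples),
            self.population,
        )

    def dosage(self) -> np.ndarray:
        """Alternate-allele (parent-2) dosage in {0, 1, 2}; missing -> NaN."""
        d = np.full(self.calls.shape, np.nan)
        d[self.calls == AA] = 0.0
        d[self.calls == AB] = 1.0
        d[self.calls == BB] = 2.0
        return d

    def signed_dosage(self) -> np.ndarray:
        """Parent-1 signed coding: AA -> +1, AB -> 0, BB -> -1, missing NaN."""
        d = np.full(self.calls.shape, np.nan)
        d[self.calls == AA] = 1.0
        d[self.calls == AB] = 0.0
        d[self.calls == BB] = -1.0
        return d
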