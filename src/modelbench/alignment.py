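"""Nucleotide alignments as compact integer-coded matrices.

States are coded A=0, C=1, G=2, T=3; anything else (gaps, N, ambiguity
codes) is coded 4 and treated as missing data by the likelihood layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError

ALPHABET = "ACGT"
MISSING = 4
_DECODE = np.array(list("ACGTN"))

_ENCODE = np.full(256, MISSING, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i
_ENCODE[ord("U")] = 3  # RNA input
_ENCODE[ord("u")] = 3


@dataclass
class Alignment:
    """A taxa-by-sites nucleotide matrix.

    Attributes
    ----------
    taxa : list of str
        Unique sequence names, order preserved.
    codes : np.ndarray
        uint8 matrix of shape (n_taxa, n_sites) with values in 0..4.
    provenance : dict
        Optional record of how the alignment was produced (generating
        model, parameters, seed, tree).
    """

    taxa: list[str]
    codes: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise InvalidInputError("codes must be (n_taxa, n_sites)")
        if len(set(self.taxa)) != len(self.taxa):
            raise InvalidInputError("taxa names must be unique")
        if self.codes.size and self.codes.max() > MISSING:
            raise InvalidInputError("invalid state code in alignment")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_strings(cls, taxa, sequences, provenance=None) -> "Alignment":
        """Build from per-taxon sequence strings (case-insensitive;
        U mapped to T; gaps/ambiguity mapped to missing)."""
        taxa = list(taxa)
        sequences = list(sequences)
        if len(taxa) != len(sequences):
            raise InvalidInputError("one sequence per taxon required")
        lengths = {len(s) for s in sequences}
        if len(lengths) > 1:
            raise InvalidInputError("sequences have unequal lengths (ragged alignment)")
        if sequences:
            buf = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
            codes = _ENCODE[buf].reshape(len(taxa), -1)
        else:
            codes = np.zeros((0, 0), dtype=np.uint8)
        return cls(taxa, codes, provenance or {})

    def sequence(self, i: int) -> str:
        return "".join(_DECODE[self.codes[i]])

    def sequences(self) -> list[str]:
        return [self.sequence(i) for i in range(self.n_taxa)]

    def base_frequencies(self, pseudocount: float = 0.0) -> np.ndarray:
        """Empirical A,C,G,T frequencies over non-missing cells."""
        counts = np.bincount(self.codes.ravel(), minlength=5)[:4].astype(float)
        counts += pseudocount
        total = counts.sum()
        if total == 0:
            raise InvalidInputError("alignment contains no unambiguous bases")
        return counts / total
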