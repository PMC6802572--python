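"""Alignment input, site-pattern compression, and tip encoding.

The engine never sees raw alignments: identical alignment columns within
a partition-defined subset carry identical likelihood contributions, so
columns are collapsed to unique *site patterns* with integer weights.
For most real data the number of unique patterns is substantially
smaller than the alignment length, which is where the compression pays.

Tips enter the engine either as *compact* state codes (one integer per
pattern; ambiguity collapses to a "missing" sentinel) or as *tip
partials* (a 0/1 indicator vector over states per pattern, which
represents IUPAC ambiguity codes exactly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import AlignIO, SeqIO

from .errors import ParseError, ValidationError
from .model import NUCLEOTIDES

__all__ = [
    "Alignment",
    "PatternSet",
    "read_alignment",
    "compress_patterns",
    "encode_tip",
    "IUPAC_PARTIALS",
    "MISSING_STATE",
]

# IUPAC nucleotide codes -> compatible states (indices into "ACGT")
IUPAC_PARTIALS: dict[str, tuple[int, ...]] = {
    "A": (0,), "C": (1,), "G": (2,), "T": (3,),
    "R": (0, 2), "Y": (1, 3), "S": (1, 2), "W": (0, 3),
    "K": (2, 3), "M": (0, 1),
    "B": (1, 2, 3), "D": (0, 2, 3), "H": (0, 1, 3), "V": (0, 1, 2),
    "N": (0, 1, 2, 3), "-": (0, 1, 2, 3), "?": (0, 1, 2, 3),
}

#: sentinel compact state meaning "no information at this tip/site"
MISSING_STATE = 4


@dataclass(frozen=True)
class Alignment:
    """A validated multiple sequence alignment (nucleotide)."""

    taxon_names: tuple[str, ...]
    sequences: tuple[str, ...]

    @property
    def taxon_count(self) -> int:
        return len(self.taxon_names)

    @property
    def site_count(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def column(self, site: int) -> str:
        return "".join(seq[site] for seq in self.sequences)


@dataclass(frozen=True)
class PatternSet:
    """Unique weighted site patterns, laid out contiguously by subset.

    ``patterns`` is (n_patterns, n_taxa) of IUPAC characters (stored as
    single-byte strings); ``weights[p]`` counts the original sites the
    pattern represents.  ``subset_ranges`` are half-open [start, end)
    pattern-index ranges, one per partition-defined subset, disjoint and
    covering the whole pattern axis in order.
    """

    patterns: np.ndarray
    weights: np.ndarray
    subset_ranges: tuple[tuple[int, int], ...]
    subset_of_site: np.ndarray
    taxon_names: tuple[str, ...]

    @property
    def pattern_count(self) -> int:
        return self.patterns.shape[0]

    @property
    def subset_count(self) -> int:
        return len(self.subset_ranges)

    def taxon_column(self, taxon: int) -> str:
        """The taxon's character at every pattern, in pattern order."""
        return "".join(self.patterns[:, taxon].astype(str))


def _validate(names: list[str], seqs: list[str]) -> Alignment:
    if len(names) != len(set(names)):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ParseError(f"duplicate taxon names: {dup}")
    if not seqs:
        raise ParseError("alignment contains no sequences")
    length = len(seqs[0])
    cleaned = []
    for name, seq in zip(names, seqs):
        s = seq.upper().replace("U", "T")
        if len(s) != length:
            raise ParseError(
                f"ragged alignment: taxon {name!r} has {len(s)} sites, expected {length}"
            )
        for i, ch in enumerate(s):
            if ch not in IUPAC_PARTIALS:
                raise ParseError(
                    f"illegal character {ch!r} for taxon {name!r} at site {i + 1}"
                )
        cleaned.append(s)
    return Alignment(tuple(names), tuple(cleaned))


def read_alignment(path, fmt: str = "fasta") -> Alignment:
    """Read a FASTA or relaxed PHYLIP alignment into a validated Alignment.

    Lowercase is uppercased and RNA 'U' is mapped to 'T'.  Ragged rows,
    duplicate taxon names, and characters outside the IUPAC nucleotide
    alphabet raise :class:`ParseError`.
    """
    fmt = fmt.lower()
    if fmt == "fasta":
        try:
            records = list(SeqIO.parse(str(path), "fasta"))
        except Exception as exc:  # Bio raises various ValueErrors
            raise ParseError(f"cannot parse FASTA {path}: {exc}") from exc
        if not records:
            raise ParseError(f"no FASTA records in {path}")
        names = [r.id for r in records]
        seqs = [str(r.seq) for r in records]
    elif fmt == "phylip":
        try:
            aln = AlignIO.read(str(path), "phylip-relaxed")
        except Exception as exc:
            raise ParseError(f"cannot parse PHYLIP {path}: {exc}") from exc
        names = [r.id for r in aln]
        seqs = [str(r.seq) for r in aln]
    else:
        raise ValidationError(f"unknown alignment format {fmt!r}")
    return _validate(names, seqs)


def compress_patterns(aln: Alignment, subset_of_site=None) -> PatternSet:
    """Collapse identical columns within each subset into weighted patterns.

    Parameters
    ----------
    aln : Alignment
    subset_of_site : array-like of int, optional
        Subset index for every site; defaults to a single subset.
        Subsets must be 0..K-1 with every subset nonempty.

    Within each subset patterns are ordered by first occurrence; subsets
    are laid out contiguously in subset order.
    """
    n_sites = aln.site_count
    if subset_of_site is None:
        subset_of_site = np.zeros(n_sites, dtype=int)
    sub = np.asarray(subset_of_site, dtype=int)
    if sub.shape != (n_sites,):
        raise ValidationError(
            f"subset map covers {sub.shape[0] if sub.ndim else 0} sites, "
            f"alignment has {n_sites}"
        )
    n_subsets = int(sub.max()) + 1 if n_sites else 0
    counts = np.bincount(sub, minlength=n_subsets)
    if np.any(counts == 0):
        empty = np.where(counts == 0)[0].tolist()
        raise ValidationError(f"empty subsets: {empty}")

    # column matrix (site, taxon) of single characters
    cols = np.array([list(s) for s in aln.sequences], dtype="U1").T

    pattern_rows: list[np.ndarray] = []
    weights: list[int] = []
    ranges: list[tuple[int, int]] = []
    for k in range(n_subsets):
        start = len(weights)
        seen: dict[tuple, int] = {}
        for site in np.where(sub == k)[0]:
            key = tuple(cols[site])
            idx = seen.get(key)
            if idx is None:
                seen[key] = len(weights)
                pattern_rows.append(cols[site])
                weights.append(1)
            else:
                weights[idx] += 1
        ranges.append((start, len(weights)))

    return PatternSet(
        patterns=np.array(pattern_rows, dtype="U1"),
        weights=np.array(weights, dtype=np.int64),
        subset_ranges=tuple(ranges),
        subset_of_site=sub,
        taxon_names=aln.taxon_names,
    )


def encode_tip(sequence: str, mode: str = "compact") -> np.ndarray:
    """Encode one tip's characters for the engine.

    compact mode returns int codes: A,C,G,T -> 0..3, anything ambiguous
    (including gaps) -> the MISSING_STATE sentinel, which contributes a
    likelihood factor of one.  partial mode returns a (sites, 4) 0/1
    matrix with ones at the states compatible with each IUPAC code,
    representing partial ambiguity exactly.
    """
    seq = sequence.upper().replace("U", "T")
    if mode == "compact":
        out = np.empty(len(seq), dtype=np.int8)
        for i, ch in enumerate(seq):
            if ch not in IUPAC_PARTIALS:
                raise ValidationError(f"illegal character {ch!r} at position {i}")
            j = NUCLEOTIDES.find(ch)
            out[i] = j if j >= 0 else MISSING_STATE
        return out
    if mode == "partial":
        out = np.zeros((len(seq), 4))
        for i, ch in enumerate(seq):
            states = IUPAC_PARTIALS.get(ch)
            if states is None:
                raise ValidationError(f"illegal character {ch!r} at position {i}")
            out[i, list(states)] = 1.0
        return out
    raise ValidationError(f"unknown tip encoding mode {mode!r}")


def has_partial_ambiguity(sequence: str) -> bool:
    """True if any character is ambiguous but not fully missing.

    Such tips lose information under compact encoding (the sentinel
    treats them as fully missing), so the engine auto-upgrades them to
    tip partials.
    """
    seq = sequence.upper().replace("U", "T")
    for ch in seq:
        states = IUPAC_PARTIALS.get(ch)
        if states is not None and 1 < len(states) < 4:
            return True
    return False
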