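"""Site-pattern extraction for ordered quartets.

An alignment column restricted to an ordered quartet (outgroup, parent 1,
putative hybrid, parent 2) is one of 4^4 = 256 site patterns
``X = X_O X_P1 X_H X_P2``.  Under the Jukes-Cantor symmetry the 256
patterns collapse into classes; the six two-state classes with a single
base change (``iijj``, ``ijij``, ``ijji``, ``ijii``, ``iiji``, ``iiij``
with ``i != j``) carry all the information the invariants-based
hybridization test uses.

Patterns are indexed in base 4 with A=0, C=1, G=2, T=3 and the outgroup
as the most significant digit, so serialized count vectors are
comparable across runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import AlignIO

__all__ = [
    "Alignment",
    "QuartetAssignment",
    "SitePatternCounts",
    "CumulativeFrequencies",
    "BASES",
    "CLASS_NAMES",
    "CLASS_INDICES",
    "pattern_index",
    "pattern_string",
    "read_alignment",
    "write_alignment",
    "count_site_patterns",
    "cumulative_frequencies",
]

BASES = "ACGT"

#: byte -> base code lookup; 255 marks gaps/ambiguity (column excluded)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("U")] = _CODE[ord("u")] = 3  # RNA


def pattern_index(pattern: str) -> int:
    """Base-4 index of a 4-character pattern such as ``"AACC"``."""
    if len(pattern) != 4:
        raise ValueError(f"pattern must have 4 bases, got {pattern!r}")
    idx = 0
    for ch in pattern.upper():
        code = _CODE[ord(ch)]
        if code == 255:
            raise ValueError(f"invalid base {ch!r} in pattern {pattern!r}")
        idx = idx * 4 + int(code)
    return idx


def pattern_string(index: int) -> str:
    """Inverse of :func:`pattern_index`."""
    if not 0 <= index < 256:
        raise ValueError("pattern index out of range")
    return "".join(BASES[(index >> s) & 3] for s in (6, 4, 2, 0))


def _build_class_indices() -> dict[str, np.ndarray]:
    classes: dict[str, list[int]] = {k: [] for k in
                                     ("iijj", "ijij", "ijji", "ijii", "iiji", "iiij")}
    for i, j in itertools.permutations(range(4), 2):
        classes["iijj"].append(64 * i + 16 * i + 4 * j + j)
        classes["ijij"].append(64 * i + 16 * j + 4 * i + j)
        classes["ijji"].append(64 * i + 16 * j + 4 * j + i)
        classes["ijii"].append(64 * i + 16 * j + 4 * i + i)
        classes["iiji"].append(64 * i + 16 * i + 4 * j + i)
        classes["iiij"].append(64 * i + 16 * i + 4 * i + j)
    return {k: np.array(sorted(v), dtype=np.intp) for k, v in classes.items()}


CLASS_INDICES: dict[str, np.ndarray] = _build_class_indices()
CLASS_NAMES = tuple(CLASS_INDICES)


class AlignmentError(ValueError):
    """Raised for malformed alignments or unknown taxa."""


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment held as uppercase strings.

    Sequences must be of equal length with unique labels; U is mapped to
    T on construction.
    """

    labels: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequences):
            raise AlignmentError("labels and sequences differ in number")
        if len(set(self.labels)) != len(self.labels):
            raise AlignmentError("duplicate taxon labels")
        if not self.sequences:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"sequences of unequal length: {sorted(lengths)}")
        if self.length < 1:
            raise AlignmentError("alignment has no columns")
        object.__setattr__(
            self, "sequences",
            tuple(s.upper().replace("U", "T") for s in self.sequences),
        )

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    def sequence(self, label: str) -> str:
        try:
            return self.sequences[self.labels.index(label)]
        except ValueError:
            raise AlignmentError(f"unknown taxon {label!r}") from None

    def encoded(self, labels: Iterable[str] | None = None) -> np.ndarray:
        """Return a (taxa, sites) uint8 matrix; 255 marks gap/ambiguity."""
        labels = tuple(labels) if labels is not None else self.labels
        rows = [
            _CODE[np.frombuffer(self.sequence(lb).encode("ascii"), dtype=np.uint8)]
            for lb in labels
        ]
        return np.vstack(rows)

    @classmethod
    def from_matrix(cls, labels: Iterable[str], matrix: np.ndarray) -> "Alignment":
        """Build from a (taxa, sites) matrix of base codes 0..3."""
        lut = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)
        seqs = tuple(lut[row].tobytes().decode("ascii") for row in np.asarray(matrix))
        return cls(tuple(labels), seqs)


@dataclass(frozen=True)
class QuartetAssignment:
    """An ordered quartet (outgroup, parent1, hybrid, parent2)."""

    outgroup: str
    parent1: str
    hybrid: str
    parent2: str

    def __post_init__(self) -> None:
        if len({self.outgroup, self.parent1, self.hybrid, self.parent2}) != 4:
            raise ValueError("quartet assignment requires four distinct taxa")

    @property
    def taxa(self) -> tuple[str, str, str, str]:
        return (self.outgroup, self.parent1, self.hybrid, self.parent2)

    def swap_parents(self) -> "QuartetAssignment":
        return QuartetAssignment(self.outgroup, self.parent2, self.hybrid, self.parent1)


@dataclass
class SitePatternCounts:
    """Counts of the 256 ordered site patterns for one quartet.

    ``counts[k]`` is the (possibly pseudocounted) count of the pattern with
    base-4 index ``k``; ``N`` is the effective number of sites (the total of
    ``counts``) and ``n_skipped`` the excluded columns.
    """

    counts: np.ndarray
    N: float
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (256,):
            raise ValueError("counts must have shape (256,)")
        if np.any(self.counts < 0):
            raise ValueError("negative pattern count")
        if self.N <= 0:
            raise ValueError("effective sample size must be positive")
        if not np.isclose(self.counts.sum(), self.N):
            raise ValueError("counts do not sum to N")

    def class_totals(self) -> dict[str, float]:
        return {k: float(self.counts[idx].sum()) for k, idx in CLASS_INDICES.items()}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"pattern": [pattern_string(i) for i in range(256)],
             "count": self.counts}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CumulativeFrequencies:
    """The six JC69-collapsed class frequencies plus the effective N."""

    p_iijj: float
    p_ijij: float
    p_ijji: float
    p_ijii: float
    p_iiji: float
    p_iiij: float
    N: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, f"p_{k}") for k in CLASS_NAMES}


_FORMAT_MAP = {
    "fasta": "fasta",
    "phylip": "phylip-relaxed",
    "nexus": "nexus",
}

_EXT_FORMATS = {
    ".fa": "fasta", ".fasta": "fasta", ".fna": "fasta",
    ".phy": "phylip", ".phylip": "phylip",
    ".nex": "nexus", ".nexus": "nexus",
}


def read_alignment(path: str | Path, format: str | None = None) -> Alignment:
    """Read an alignment in FASTA, relaxed PHYLIP, or NEXUS format.

    When ``format`` is None it is inferred from the file extension.
    """
    path = Path(path)
    if format is None:
        format = _EXT_FORMATS.get(path.suffix.lower())
        if format is None:
            raise AlignmentError(
                f"cannot infer format from extension {path.suffix!r}; pass format="
            )
    if format not in _FORMAT_MAP:
        raise AlignmentError(
            f"unsupported format {format!r}; expected one of {sorted(_FORMAT_MAP)}"
        )
    try:
        msa = AlignIO.read(str(path), _FORMAT_MAP[format])
    except Exception as exc:  # Bio raises bare ValueError on ragged input
        raise AlignmentError(f"failed to parse {path} as {format}: {exc}") from exc
    return Alignment(
        tuple(rec.id for rec in msa),
        tuple(str(rec.seq) for rec in msa),
    )


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write an alignment in FASTA, relaxed PHYLIP, or NEXUS format."""
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if format not in _FORMAT_MAP:
        raise AlignmentError(f"unsupported format {format!r}")
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(s), id=lb, description="",
                  annotations={"molecule_type": "DNA"})
        for lb, s in zip(aln.labels, aln.sequences)
    )
    AlignIO.write(msa, str(path), _FORMAT_MAP[format])


def count_site_patterns(aln: Alignment, q: QuartetAssignment) -> SitePatternCounts:
    """Tally the 256 ordered site patterns for a quartet assignment.

    Columns in which any of the four sequences has a gap or an IUPAC
    ambiguity code are excluded entirely and reported via ``n_skipped``.
    """
    mat = aln.encoded(q.taxa)  # raises AlignmentError on unknown taxa
    valid = (mat != 255).all(axis=0)
    n_used = int(valid.sum())
    if n_used == 0:
        raise AlignmentError("no usable columns for this quartet")
    sub = mat[:, valid].astype(np.intp)
    idx = ((sub[0] * 4 + sub[1]) * 4 + sub[2]) * 4 + sub[3]
    counts = np.bincount(idx, minlength=256).astype(float)
    return SitePatternCounts(counts, float(n_used), int(aln.length - n_used))


def cumulative_frequencies(
    counts: SitePatternCounts,
    pseudocount: float = 0.005,
    pseudocount_mode: str = "off",
) -> CumulativeFrequencies:
    """Collapse raw pattern counts into the six class frequencies.

    ``pseudocount_mode``:

    * ``"off"`` — frequencies are raw class totals over ``counts.N``;
    * ``"always"`` — ``pseudocount`` is added to each of the 256 raw counts
      and N is recomputed as the new total before frequencies are formed;
    * ``"on_zero"`` — as ``"always"``, but only when at least one of the
      six class totals is zero (the situation the correction addresses).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount_mode not in ("off", "always", "on_zero"):
        raise ValueError(f"unknown pseudocount_mode {pseudocount_mode!r}")
    raw = counts.counts
    totals = {k: float(raw[idx].sum()) for k, idx in CLASS_INDICES.items()}
    apply = pseudocount_mode == "always" or (
        pseudocount_mode == "on_zero" and any(v == 0.0 for v in totals.values())
    )
    if apply and pseudocount > 0:
        n_eff = counts.N + 256 * pseudocount
        freqs = {k: (v + 12 * pseudocount) / n_eff for k, v in totals.items()}
    else:
        n_eff = counts.N
        freqs = {k: v / n_eff for k, v in totals.items()}
    return CumulativeFrequencies(
        p_iijj=freqs["iijj"], p_ijij=freqs["ijij"], p_ijji=freqs["ijji"],
        p_ijii=freqs["ijii"], p_iiji=freqs["iiji"], p_iiij=freqs["iiij"],
        N=float(n_eff),
    )
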