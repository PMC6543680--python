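"""Genome-scale scans for hybrid taxa over many sequences.

Given n ingroup sequences and an outgroup, every 3-subset of ingroup
taxa is tested for hybridization under each hybrid designation.  The
designation whose parents-share pattern frequency strictly dominates
(p_ijij > max{p_iijj, p_ijji}) is eliminated — it implies the two
designated parents are sisters — leaving a nominal C(n,3) x 2 tests,
which sets the Bonferroni denominator M.  A row is flagged significant
when its one-sided p-value falls below alpha / M.

When several alleles are sampled per group (e.g. per subspecies), a
grouping restricts enumeration to one allele from each of three
distinct groups, with M the product-of-group-sizes count times two.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .hilstest import (
    DegenerateStatisticError,
    HilsResult,
    UndefinedStatisticError,
    hils_test,
    invariants,
    is_eliminated,
)
from .patterns import (
    Alignment,
    CLASS_INDICES,
    QuartetAssignment,
    SitePatternCounts,
    cumulative_frequencies,
)

__all__ = [
    "TaxonGrouping",
    "ScanConfig",
    "ScanResult",
    "enumerate_triples",
    "enumerate_assignments",
    "nominal_comparisons",
    "apply_elimination",
    "scan_alignment",
    "scan_matrix",
    "classify_detection",
]


@dataclass(frozen=True)
class TaxonGrouping:
    """Maps scanned taxa to allele groups and groups to species.

    ``group_of`` assigns every scanned ingroup taxon to exactly one
    group; ``species_of`` (optional, keyed by group) supports the
    cross-species constraint; ``outgroups`` are excluded from grouping.
    """

    group_of: Mapping[str, str]
    species_of: Mapping[str, str] = field(default_factory=dict)
    outgroups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        overlap = set(self.group_of) & set(self.outgroups)
        if overlap:
            raise ValueError(f"outgroup taxa also grouped: {sorted(overlap)}")

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for taxon, grp in self.group_of.items():
            out.setdefault(grp, []).append(taxon)
        return {g: sorted(v) for g, v in sorted(out.items())}

    @classmethod
    def from_tsv(cls, path: str | Path, outgroups: Iterable[str] = ()) -> "TaxonGrouping":
        """Read a two- or three-column TSV: taxon, group[, species]."""
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] < 2:
            raise ValueError("grouping TSV needs at least two columns")
        group_of = dict(zip(df[0], df[1]))
        species_of = {}
        if df.shape[1] >= 3:
            species_of = {g: s for g, s in zip(df[1], df[2]) if isinstance(s, str)}
        return cls(group_of, species_of, tuple(outgroups))


@dataclass(frozen=True)
class ScanConfig:
    """Options controlling one scan family."""

    alpha: float = 0.05
    ratio: str = "f1/f2"
    pseudocount: float = 0.005
    pseudocount_mode: str = "always"
    constraint: str = "none"  # none | one_per_group | cross_species

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.constraint not in ("none", "one_per_group", "cross_species"):
            raise ValueError(f"unknown constraint {self.constraint!r}")


def enumerate_triples(
    taxa: Sequence[str],
    outgroup: str,
    grouping: TaxonGrouping | None = None,
    constraint: str = "none",
) -> list[tuple[str, str, str]]:
    """All ingroup triples to be tested, in deterministic sorted order."""
    ingroup = sorted(t for t in taxa if t != outgroup)
    if grouping is not None:
        ingroup = [t for t in ingroup
                   if t in grouping.group_of and t not in grouping.outgroups]
    if len(ingroup) < 3:
        raise ValueError("need at least three ingroup taxa")
    if grouping is None or constraint == "none":
        return list(itertools.combinations(ingroup, 3))
    groups = grouping.groups
    triples: list[tuple[str, str, str]] = []
    for g1, g2, g3 in itertools.combinations(sorted(groups), 3):
        if constraint == "cross_species" and grouping.species_of:
            species = {grouping.species_of.get(g) for g in (g1, g2, g3)}
            if len(species) < 2:
                continue
        for combo in itertools.product(groups[g1], groups[g2], groups[g3]):
            triples.append(tuple(sorted(combo)))
    return sorted(triples)


def enumerate_assignments(
    taxa: Sequence[str],
    outgroup: str,
    grouping: TaxonGrouping | None = None,
    constraint: str = "none",
) -> list[QuartetAssignment]:
    """All hybrid/parental assignments for a scan.

    Three hybrid designations are produced per triple (parents in
    sorted order); the elimination rule discards one of them at test
    time, so the nominal comparison count is two per triple (see
    :func:`nominal_comparisons`).
    """
    out = []
    for triple in enumerate_triples(taxa, outgroup, grouping, constraint):
        for hybrid in triple:
            p1, p2 = sorted(set(triple) - {hybrid})
            out.append(QuartetAssignment(outgroup, p1, hybrid, p2))
    return out


def nominal_comparisons(
    taxa: Sequence[str],
    outgroup: str,
    grouping: TaxonGrouping | None = None,
    constraint: str = "none",
) -> int:
    """The Bonferroni denominator M: two retained designations per triple."""
    return 2 * len(enumerate_triples(taxa, outgroup, grouping, constraint))


def apply_elimination(
    counts: SitePatternCounts,
    pseudocount: float = 0.005,
    pseudocount_mode: str = "off",
) -> bool:
    """True when this hybrid designation is eliminated (parents are sisters)."""
    return is_eliminated(cumulative_frequencies(counts, pseudocount, pseudocount_mode))


# -- fast pattern-count reordering ------------------------------------------


@lru_cache(maxsize=None)
def _permutation_map(perm: tuple[int, int, int, int]) -> np.ndarray:
    """Index map sending counts in one taxon order to a permuted order.

    ``perm[k]`` gives, for position k of the new order, the position in
    the old order holding that taxon.
    """
    idx = np.arange(256)
    digits = [(idx >> s) & 3 for s in (6, 4, 2, 0)]
    new = np.zeros(256, dtype=np.intp)
    for k, p in enumerate(perm):
        new = new * 4 + digits[p]
    return new


def _reorder_counts(counts: SitePatternCounts,
                    perm: tuple[int, int, int, int]) -> SitePatternCounts:
    new = np.empty(256)
    new[_permutation_map(perm)] = counts.counts
    return SitePatternCounts(new, counts.N, counts.n_skipped)


def _counts_for_quartet(mat: np.ndarray, rows: Sequence[int]) -> SitePatternCounts:
    sub = mat[list(rows)]
    valid = (sub != 255).all(axis=0)
    n_used = int(valid.sum())
    if n_used == 0:
        raise ValueError("no usable columns for quartet")
    sub = sub[:, valid].astype(np.intp)
    pat = ((sub[0] * 4 + sub[1]) * 4 + sub[2]) * 4 + sub[3]
    return SitePatternCounts(
        np.bincount(pat, minlength=256).astype(float),
        float(n_used), int(mat.shape[1] - n_used),
    )


# -- results ----------------------------------------------------------------


@dataclass
class ScanResult:
    """All tested assignments of one scan family plus the correction."""

    rows: list[HilsResult]
    M: int
    alpha: float

    @property
    def per_test_alpha(self) -> float:
        return self.alpha / self.M

    @property
    def significant_rows(self) -> list[HilsResult]:
        return [r for r in self.rows if r.significant]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([r.to_dict() for r in self.rows])
        df["significant"] = [r.significant for r in self.rows]
        return df

    def summary(self) -> pd.DataFrame:
        """Significant hybrid/parental triples ranked by p-value."""
        df = self.to_frame()
        return df[df["significant"]].reset_index(drop=True)


def scan_matrix(
    mat: np.ndarray,
    taxa: Sequence[str],
    outgroup: str,
    grouping: TaxonGrouping | None = None,
    config: ScanConfig | None = None,
) -> ScanResult:
    """Scan an encoded (taxa, sites) matrix; see :func:`scan_alignment`."""
    config = config or ScanConfig()
    taxa = list(taxa)
    if outgroup not in taxa:
        raise ValueError(f"outgroup {outgroup!r} not in alignment")
    constraint = config.constraint
    if grouping is not None and constraint == "none":
        constraint = "one_per_group"
    triples = enumerate_triples(taxa, outgroup, grouping, constraint)
    M = 2 * len(triples)
    per_test = config.alpha / M
    row_of = {t: i for i, t in enumerate(taxa)}
    rows: list[HilsResult] = []
    for triple in triples:
        base = _counts_for_quartet(
            mat, [row_of[outgroup]] + [row_of[t] for t in triple]
        )
        for h_pos, hybrid in enumerate(triple):
            p_pos = [k for k in range(3) if k != h_pos]
            parents = [triple[k] for k in p_pos]
            # order parents so the hybrid shares more states with P1
            # (p_ijji >= p_iijj), putting the non-vanishing invariant
            # in the denominator as the null derivation assumes
            perm = (0, p_pos[0] + 1, h_pos + 1, p_pos[1] + 1)
            counts = _reorder_counts(base, perm)
            freqs = cumulative_frequencies(
                counts, config.pseudocount, config.pseudocount_mode
            )
            if freqs.p_iijj > freqs.p_ijji:
                parents = parents[::-1]
                counts = _reorder_counts(
                    base, (0, p_pos[1] + 1, h_pos + 1, p_pos[0] + 1)
                )
            assignment = QuartetAssignment(outgroup, parents[0], hybrid, parents[1])
            try:
                res = hils_test(
                    counts, ratio=config.ratio, alpha=per_test,
                    pseudocount=config.pseudocount,
                    pseudocount_mode=config.pseudocount_mode,
                    assignment=assignment,
                )
            except (UndefinedStatisticError, DegenerateStatisticError):
                res = HilsResult(assignment, invariants(freqs), None,
                                 config.ratio, None, None, False,
                                 freqs.N, per_test)
            rows.append(res)
    rows.sort(key=lambda r: (r.p_value if r.p_value is not None else np.inf,
                             r.assignment.taxa))
    return ScanResult(rows, M, config.alpha)


def scan_alignment(
    aln: Alignment,
    outgroup: str,
    grouping: TaxonGrouping | None = None,
    config: ScanConfig | None = None,
) -> ScanResult:
    """Test every hybrid/parental assignment in an alignment.

    Runs the invariants-based test for each enumerated assignment with
    pattern counts shared across the three designations of a triple,
    applies the elimination rule, and flags rows significant at the
    Bonferroni-corrected level alpha/M, where M is the nominal
    enumeration count (two designations per triple).  Output is
    deterministic given identical input.
    """
    return scan_matrix(aln.encoded(), aln.labels, outgroup, grouping, config)


def classify_detection(
    scan: ScanResult,
    hybrid_taxa: Iterable[str],
    parent1_taxa: Iterable[str],
    parent2_taxa: Iterable[str],
) -> dict[str, bool]:
    """Score a scan against a known hybridization event.

    Returns flags following the simulation-study convention:
    ``true_positive`` — some significant row names the correct triple
    (one taxon from the hybrid clade and one from each donor clade) with
    the hybrid correctly designated; ``true_set`` — a significant row
    names a correct triple but mis-designates the hybrid;
    ``false_positive`` — a significant row names any other triple.
    """
    hybrid_taxa = frozenset(hybrid_taxa)
    parent1_taxa = frozenset(parent1_taxa)
    parent2_taxa = frozenset(parent2_taxa)
    out = {"true_positive": False, "true_set": False, "false_positive": False}
    for row in scan.significant_rows:
        a = row.assignment
        members = (a.hybrid, a.parent1, a.parent2)
        correct_triple = any(
            h in hybrid_taxa and p in parent1_taxa and q in parent2_taxa
            for h, p, q in itertools.permutations(members)
        )
        if not correct_triple:
            out["false_positive"] = True
        elif a.hybrid in hybrid_taxa:
            out["true_positive"] = True
        else:
            out["true_set"] = True
    return out
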