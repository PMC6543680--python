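"""Simulation under the coalescent-with-hybridization model.

A hybrid species network is represented as a mixture of two parental
species trees S1 (hybrid lineage attached to the P2-side donor) and S2
(hybrid attached to the P1-side donor), sharing all non-hybrid
relationships, with mixing weight ``gamma`` = probability that a site's
gene tree comes from S1.  Data are generated in three stages: choose a
parental tree, draw a gene tree from the multispecies coalescent along
it, then evolve one site (or one locus) along the gene tree under a
Markov substitution model (JC69 or GTR+I+Gamma).

All times and branch lengths are in coalescent units with tips at time
0; gene-tree lengths are multiplied by the substitution model's
``scale`` factor (default 1.0, i.e. coalescent units are fed to the
substitution process directly) before sequence simulation.

The gene-tree sampler and the site simulator are vectorized across
sites, which makes the "coalescent independent sites" design (a fresh
gene tree for every site) practical at 10^5-10^6 sites per replicate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .patterns import Alignment, QuartetAssignment, SitePatternCounts

__all__ = [
    "ClockTree",
    "SpeciesNetwork",
    "SubstitutionModel",
    "SimulationConfig",
    "jc69",
    "benchmark_gtr",
    "PRESETS",
    "four_taxon_network",
    "general_network",
    "example_network",
    "stretch_tip",
    "sample_parental_tree",
    "simulate_gene_trees",
    "simulate_gene_tree_newick",
    "simulate_sites",
    "simulate_site_matrix",
    "simulate_dataset",
    "run_power_study",
    "run_scan_study",
    "parse_extended_newick",
]


# ---------------------------------------------------------------------------
# clock species trees


@dataclass(frozen=True)
class ClockTree:
    """A rooted ultrametric species tree in coalescent units.

    Node ids: tips are 0..n-1 in the order of ``taxa`` (all at time 0);
    internal nodes are n..2n-2 sorted by increasing speciation time, so
    the root is always node 2n-2.  ``tip_extra`` holds optional extra
    pendant branch length per tip (in coalescent units) applied only at
    the substitution stage, used to model molecular-clock violations.
    """

    taxa: tuple[str, ...]
    node_time: tuple[float, ...]
    children: tuple[tuple[int, int], ...]
    tip_extra: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if len(set(self.taxa)) != n:
            raise ValueError("duplicate taxon names")
        if len(self.node_time) != 2 * n - 1 or len(self.children) != max(n - 1, 0):
            raise ValueError("inconsistent node arrays")
        times = self.node_time
        for v in range(n, 2 * n - 1):
            if v > n and times[v] < times[v - 1]:
                raise ValueError("internal nodes must be sorted by time")
            for c in self.children[v - n]:
                if not (0 <= c < v):
                    raise ValueError("children must precede parents")
                if times[c] > times[v]:
                    raise ValueError("child older than parent")
        if self.tip_extra is not None and len(self.tip_extra) != n:
            raise ValueError("tip_extra must have one entry per tip")

    # -- basic structure ---------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    @cached_property
    def parent(self) -> np.ndarray:
        """Parent node id per node; -1 for the root."""
        par = np.full(2 * self.n_tips - 1, -1, dtype=np.int64)
        for v, (c1, c2) in enumerate(self.children, start=self.n_tips):
            par[c1] = v
            par[c2] = v
        return par

    @cached_property
    def clades(self) -> tuple[frozenset[int], ...]:
        out: list[frozenset[int]] = [frozenset([i]) for i in range(self.n_tips)]
        for c1, c2 in self.children:
            out.append(out[c1] | out[c2])
        return tuple(out)

    def mrca(self, taxa: Iterable[str]) -> int:
        want = {self.taxa.index(t) for t in taxa}
        for v, clade in enumerate(self.clades):
            if want <= clade:
                return v
        raise ValueError("no containing clade found")  # pragma: no cover

    def pendant_length(self, taxon: str) -> float:
        tip = self.taxa.index(taxon)
        return self.node_time[self.parent[tip]]

    def joins(self) -> list[tuple[float, str, str]]:
        """The tree as a merge schedule (time, taxon-in-A, taxon-in-B)."""
        out = []
        for v, (c1, c2) in enumerate(self.children, start=self.n_tips):
            rep = lambda c: self.taxa[min(self.clades[c])]
            out.append((self.node_time[v], rep(c1), rep(c2)))
        return out

    # -- construction ------------------------------------------------------

    @classmethod
    def leaf(cls, taxon: str) -> "ClockTree":
        return cls((taxon,), (0.0,), ())

    @classmethod
    def from_joins(
        cls,
        taxa: Sequence[str],
        joins: Iterable[tuple[float, str, str]],
        tip_extra: Sequence[float] | None = None,
    ) -> "ClockTree":
        """Build from a merge schedule.

        Each join ``(time, a, b)`` merges the current clades containing
        taxa ``a`` and ``b``; joins are applied in order of time (stable
        for ties).
        """
        taxa = tuple(taxa)
        n = len(taxa)
        root_of = {t: i for i, t in enumerate(taxa)}
        members: dict[int, list[str]] = {i: [t] for i, t in enumerate(taxa)}
        times = [0.0] * n
        children: list[tuple[int, int]] = []
        for time, a, b in sorted(joins, key=lambda j: j[0]):
            ra, rb = root_of[a], root_of[b]
            if ra == rb:
                raise ValueError(f"taxa {a!r} and {b!r} already joined")
            new = n + len(children)
            children.append((ra, rb))
            times.append(float(time))
            members[new] = members.pop(ra) + members.pop(rb)
            for t in members[new]:
                root_of[t] = new
        if len(members) != 1:
            raise ValueError("joins do not connect all taxa")
        return cls(taxa, tuple(times), tuple(children),
                   tuple(tip_extra) if tip_extra is not None else None)

    @classmethod
    def from_newick(cls, newick: str, rtol: float = 1e-6) -> "ClockTree":
        """Parse a clock (ultrametric) tree from a Newick string."""
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        depth = {tree.seed_node: 0.0}
        tips: list = []
        for node in tree.preorder_node_iter():
            if node is not tree.seed_node:
                bl = node.edge.length
                if bl is None:
                    raise ValueError("Newick tree must have branch lengths")
                depth[node] = depth[node.parent_node] + bl
            if node.is_leaf():
                tips.append(node)
        height = max(depth[t] for t in tips)
        for t in tips:
            if abs(depth[t] - height) > rtol * max(height, 1.0):
                raise ValueError("tree is not ultrametric (clock required)")
        taxa = tuple(t.taxon.label for t in tips)
        joins: list[tuple[float, str, str]] = []
        rep: dict = {t: t.taxon.label for t in tips}
        for node in tree.postorder_internal_node_iter():
            kids = node.child_nodes()
            t = height - depth[node]
            for other in kids[1:]:
                joins.append((t, rep[kids[0]], rep[other]))
            rep[node] = rep[kids[0]]
        return cls.from_joins(taxa, joins)

    def to_newick(self) -> str:
        n = self.n_tips

        def render(v: int) -> str:
            if v < n:
                return self.taxa[v]
            c1, c2 = self.children[v - n]
            bl = lambda c: self.node_time[v] - self.node_time[c]
            return f"({render(c1)}:{bl(c1):.6g},{render(c2)}:{bl(c2):.6g})"

        return render(2 * n - 2) + ";"

    # -- surgery -----------------------------------------------------------

    def attach(
        self,
        subtree: "ClockTree | str",
        donor: str | Iterable[str],
        time: float,
    ) -> "ClockTree":
        """Attach a subtree (or a new tip) onto a donor edge at ``time``.

        The donor edge is the edge above the MRCA of the given taxa; it
        must span ``time``, and the subtree's root must not be younger
        than its attachment point.
        """
        if isinstance(subtree, str):
            subtree = ClockTree.leaf(subtree)
        donor_taxa = (donor,) if isinstance(donor, str) else tuple(donor)
        d = self.mrca(donor_taxa)
        parent = self.parent[d]
        top = np.inf if parent < 0 else self.node_time[parent]
        if not (self.node_time[d] <= time < top):
            raise ValueError(
                f"attachment time {time} outside donor edge span "
                f"[{self.node_time[d]}, {top})"
            )
        sub_root_time = max(subtree.node_time)
        if sub_root_time > time:
            raise ValueError("subtree root is younger than the attachment time")
        if set(subtree.taxa) & set(self.taxa):
            raise ValueError("subtree shares taxa with the base tree")
        taxa = self.taxa + subtree.taxa
        joins = (
            self.joins()
            + subtree.joins()
            + [(float(time), self.taxa[min(self.clades[d])], subtree.taxa[0])]
        )
        return ClockTree.from_joins(taxa, joins)

    def with_tip_extra(self, extra: dict[str, float]) -> "ClockTree":
        cur = list(self.tip_extra) if self.tip_extra else [0.0] * self.n_tips
        for taxon, value in extra.items():
            cur[self.taxa.index(taxon)] += value
        return replace(self, tip_extra=tuple(cur))


# ---------------------------------------------------------------------------
# species networks


@dataclass(frozen=True)
class SpeciesNetwork:
    """Two parental species trees plus the mixing weight ``gamma``.

    ``gamma`` is the probability that a gene tree is drawn from S1 (the
    tree with the hybrid lineage attached to the P2-side donor).
    ``hybrid_taxa``/``parent*_taxa`` record the true hybrid and donor
    clades when known (used to score detections in simulation studies).
    """

    s1: ClockTree
    s2: ClockTree
    gamma: float
    hybrid: str
    outgroup: str
    hybrid_taxa: frozenset[str] = field(default_factory=frozenset)
    parent1_taxa: frozenset[str] = field(default_factory=frozenset)
    parent2_taxa: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if set(self.s1.taxa) != set(self.s2.taxa):
            raise ValueError("parental trees must share the same taxa")
        if self.outgroup not in self.s1.taxa:
            raise ValueError("outgroup not in taxa")
        if not self.hybrid_taxa:
            object.__setattr__(self, "hybrid_taxa", frozenset([self.hybrid]))

    @property
    def taxa(self) -> tuple[str, ...]:
        return self.s1.taxa

    def quartet_assignment(self) -> QuartetAssignment:
        """The (O, P1, H, P2) assignment for a four-taxon network."""
        if len(self.taxa) != 4:
            raise ValueError("quartet assignment defined for 4-taxon networks only")

        def sibling(tree: ClockTree) -> str:
            tip = tree.taxa.index(self.hybrid)
            par = tree.parent[tip]
            c1, c2 = tree.children[par - tree.n_tips]
            other = c2 if c1 == tip else c1
            if other >= tree.n_tips:
                raise ValueError("hybrid sibling is not a tip")
            return tree.taxa[other]

        return QuartetAssignment(self.outgroup, sibling(self.s2),
                                 self.hybrid, sibling(self.s1))

    @classmethod
    def from_newicks(
        cls, newick_s1: str, newick_s2: str, gamma: float,
        hybrid: str, outgroup: str, **kw,
    ) -> "SpeciesNetwork":
        return cls(ClockTree.from_newick(newick_s1),
                   ClockTree.from_newick(newick_s2),
                   gamma, hybrid, outgroup, **kw)


def four_taxon_network(
    tau1: float, tau2: float, tau3: float, gamma: float,
    taxa: tuple[str, str, str, str] = ("O", "P1", "H", "P2"),
) -> SpeciesNetwork:
    """The four-taxon hybrid network with speciation times tau1<tau2<tau3.

    S1 = (((H,P2):tau1,P1):tau2,O):tau3 and S2 = (((P1,H):tau1,P2):tau2,
    O):tau3.  ``(0.25, 0.5, 1.0)`` and ``(0.5, 1.0, 2.0)`` are the
    benchmark "short" and "long" settings used throughout the package's
    calibration studies.
    """
    if not 0 < tau1 < tau2 < tau3:
        raise ValueError("speciation times must satisfy 0 < tau1 < tau2 < tau3")
    O, P1, H, P2 = taxa
    s1 = ClockTree.from_joins(taxa, [(tau1, H, P2), (tau2, H, P1), (tau3, H, O)])
    s2 = ClockTree.from_joins(taxa, [(tau1, P1, H), (tau2, P1, P2), (tau3, P1, O)])
    return SpeciesNetwork(s1, s2, gamma, hybrid=H, outgroup=O,
                          parent1_taxa=frozenset([P1]),
                          parent2_taxa=frozenset([P2]))


def general_network(
    base_tree: ClockTree,
    hybrid: "ClockTree | str",
    donor1: str | Iterable[str],
    donor2: str | Iterable[str],
    attach_time: float,
    gamma: float,
    outgroup: str,
) -> SpeciesNetwork:
    """Attach a hybrid tip or clade to two donor edges of a clock tree.

    S1 attaches the hybrid to ``donor1`` (the P2-side lineage), S2 to
    ``donor2``; ``gamma`` is the S1 weight.  Deep hybridization events
    are expressed by passing a ClockTree subtree as ``hybrid``, making
    the hybrid lineage ancestral to a clade.
    """
    sub = ClockTree.leaf(hybrid) if isinstance(hybrid, str) else hybrid
    s1 = base_tree.attach(sub, donor1, attach_time)
    s2 = base_tree.attach(sub, donor2, attach_time)
    d1 = (donor1,) if isinstance(donor1, str) else tuple(donor1)
    d2 = (donor2,) if isinstance(donor2, str) else tuple(donor2)
    clade = lambda tree, taxa_: frozenset(
        tree.taxa[i] for i in tree.clades[tree.mrca(taxa_)]
    )
    hybrid_label = sub.taxa[0]
    return SpeciesNetwork(
        s1, s2, gamma, hybrid=hybrid_label, outgroup=outgroup,
        hybrid_taxa=frozenset(sub.taxa),
        parent1_taxa=clade(base_tree, d2),
        parent2_taxa=clade(base_tree, d1),
    )


def stretch_tip(network: SpeciesNetwork, taxon: str, factor: float) -> SpeciesNetwork:
    """Lengthen the pendant branch of one tip, violating the clock.

    Within each parental tree the tip's gene-tree pendant edges gain
    ``(factor - 1) * pendant species-branch length`` of extra
    substitution length; coalescent times are unchanged.
    """
    if taxon not in network.taxa:
        raise ValueError(f"unknown taxon {taxon!r}")
    if factor < 0:
        raise ValueError("factor must be non-negative")

    def stretched(tree: ClockTree) -> ClockTree:
        return tree.with_tip_extra({taxon: (factor - 1.0) * tree.pendant_length(taxon)})

    return replace(network, s1=stretched(network.s1), s2=stretched(network.s2))


def example_network(n_taxa: int = 9, event: str = "shallow",
                    gamma: float = 0.0) -> SpeciesNetwork:
    """Synthetic 9- or 20-taxon one-hybrid-edge benchmark networks.

    These are reconstructions built for the large-network simulation
    studies; no published branch lengths are reproduced.  Depths follow
    the "long" four-taxon benchmark setting (speciation intervals of
    0.5 coalescent units, root-to-outgroup split at 2.0 or less), and
    the two donor lineages of the hybrid are sisters, so that the
    hybridization signal is confined to triples containing the hybrid
    and one taxon from each donor clade.  ``event`` selects a recent tip
    hybrid ("shallow": hybrid of two sister tips) or an ancestral hybrid
    lineage subtending a two-taxon clade ("deep": donors are two sister
    clades).
    """
    if n_taxa == 9 and event == "shallow":
        taxa = ("O", "t1", "t2", "t3", "t4", "t5", "t6", "t7")
        base = ClockTree.from_joins(taxa, [
            (0.5, "t1", "t2"), (1.0, "t1", "t3"),
            (1.0, "t4", "t5"), (0.5, "t6", "t7"), (1.25, "t4", "t6"),
            (1.5, "t1", "t4"), (1.75, "t1", "O"),
        ])
        return general_network(base, "h", "t4", "t5", 0.5, gamma, "O")
    if n_taxa == 9 and event == "deep":
        taxa = ("O", "t1", "t2", "t3", "t4", "t5", "t6")
        base = ClockTree.from_joins(taxa, [
            (0.5, "t1", "t2"),
            (0.5, "t3", "t4"), (0.5, "t5", "t6"), (1.25, "t3", "t5"),
            (1.5, "t1", "t3"), (1.75, "t1", "O"),
        ])
        hyb = ClockTree.from_joins(("h1", "h2"), [(0.5, "h1", "h2")])
        return general_network(base, hyb, ("t3", "t4"), ("t5", "t6"),
                               0.75, gamma, "O")
    if n_taxa == 20 and event == "shallow":
        taxa = ["O"] + [f"u{i}" for i in range(1, 19)]
        joins = []
        for c in range(4):  # four clades of four
            a = 4 * c + 1
            joins += [(0.5, f"u{a}", f"u{a+1}"), (0.5, f"u{a+2}", f"u{a+3}"),
                      (1.0, f"u{a}", f"u{a+2}")]
        joins += [(1.5, "u1", "u5"), (1.6, "u9", "u13"), (2.0, "u1", "u9"),
                  (0.5, "u17", "u18"), (2.25, "u1", "u17"), (2.75, "u1", "O")]
        base = ClockTree.from_joins(taxa, joins)
        return general_network(base, "h", "u3", "u4", 0.25, gamma, "O")
    if n_taxa == 20 and event == "deep":
        taxa = ["O"] + [f"u{i}" for i in range(1, 18)]
        joins = []
        for c in range(4):
            a = 4 * c + 1
            joins += [(0.5, f"u{a}", f"u{a+1}"), (0.5, f"u{a+2}", f"u{a+3}"),
                      (1.0, f"u{a}", f"u{a+2}")]
        joins += [(1.5, "u1", "u5"), (1.6, "u9", "u13"), (2.0, "u1", "u9"),
                  (2.25, "u1", "u17"), (2.75, "u1", "O")]
        base = ClockTree.from_joins(taxa, joins)
        hyb = ClockTree.from_joins(("h1", "h2"), [(0.5, "h1", "h2")])
        return general_network(base, hyb, ("u1", "u2", "u3", "u4"),
                               ("u5", "u6", "u7", "u8"), 1.25, gamma, "O")
    raise ValueError("supported example networks: n_taxa in {9, 20}, "
                     "event in {'shallow', 'deep'}")


# ---------------------------------------------------------------------------
# substitution models


@dataclass(frozen=True)
class SubstitutionModel:
    """A GTR-family model with optional invariable sites and discrete gamma.

    ``exchangeabilities`` are the six symmetric rate factors in the
    order (AC, AG, AT, CG, CT, GT); ``base_freqs`` are the stationary
    frequencies (A, C, G, T).  The rate matrix is normalized so the mean
    substitution rate at stationarity is 1, making branch lengths
    expected substitutions per site at rate 1.  Among-site variation
    uses a proportion ``p_inv`` of invariable sites plus a
    ``gamma_categories``-category discrete gamma (equal-probability
    categories, category-mean rates).  Following the convention of
    classic sequence simulators, the discrete-gamma rates have mean 1
    over the gamma distribution and invariable sites simply do not
    evolve, so with ``p_inv`` > 0 the mean rate over all sites is
    ``1 - p_inv``.  ``scale`` converts coalescent-unit branch lengths to
    substitution units.
    """

    exchangeabilities: tuple[float, ...] = (1.0,) * 6
    base_freqs: tuple[float, ...] = (0.25,) * 4
    p_inv: float = 0.0
    gamma_shape: float | None = None
    gamma_categories: int = 1
    scale: float = 1.0
    name: str = "GTR"

    def __post_init__(self) -> None:
        if len(self.exchangeabilities) != 6 or any(r <= 0 for r in self.exchangeabilities):
            raise ValueError("six positive exchangeabilities required")
        freqs = np.asarray(self.base_freqs, dtype=float)
        if freqs.shape != (4,) or np.any(freqs <= 0) or abs(freqs.sum() - 1) > 1e-8:
            raise ValueError("base_freqs must be 4 positive values summing to 1")
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError("p_inv must be in [0, 1)")
        if self.gamma_categories < 1:
            raise ValueError("gamma_categories must be >= 1")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @cached_property
    def rate_matrix(self) -> np.ndarray:
        pi = np.asarray(self.base_freqs)
        r = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for (i, j), x in zip(pairs, self.exchangeabilities):
            r[i, j] = r[j, i] = x
        q = r * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(pi @ np.diag(q))
        return q / mu

    @cached_property
    def _eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # reversible Q: symmetrize with sqrt(pi) and use a symmetric solver
        pi = np.asarray(self.base_freqs)
        s = np.sqrt(pi)
        b = (s[:, None] * self.rate_matrix) / s[None, :]
        eigs, v = np.linalg.eigh((b + b.T) / 2.0)
        u = v / s[:, None]
        w = v.T * s[None, :]
        return eigs, u, w

    def transition_matrix(self, t: float) -> np.ndarray:
        eigs, u, w = self._eigen
        p = (u * np.exp(eigs * t)[None, :]) @ w
        np.clip(p, 0.0, None, out=p)
        return p / p.sum(axis=1, keepdims=True)

    @cached_property
    def rate_categories(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, probabilities) of the site-rate mixture.

        The variable-site rates are the discrete-gamma category means
        (mean 1); an invariable site has rate 0, so the mean rate over
        all sites is 1 - p_inv.
        """
        k = self.gamma_categories
        if self.gamma_shape is None or k == 1:
            var_rates = np.array([1.0])
        else:
            a = self.gamma_shape
            edges = np.concatenate([
                [0.0], gamma_dist.ppf(np.arange(1, k) / k, a=a, scale=1.0 / a),
                [np.inf],
            ])
            cdf1 = gammainc(a + 1.0, a * edges)
            cdf1[-1] = 1.0
            var_rates = k * np.diff(cdf1)  # category means, mean 1 overall
        if self.p_inv > 0:
            rates = np.concatenate([[0.0], var_rates])
            probs = np.concatenate([
                [self.p_inv],
                np.full(var_rates.size, (1.0 - self.p_inv) / var_rates.size),
            ])
        else:
            rates = var_rates
            probs = np.full(var_rates.size, 1.0 / var_rates.size)
        return rates, probs

    def draw_site_rates(self, n: int, rng: np.random.Generator) -> np.ndarray:
        rates, probs = self.rate_categories
        if rates.size == 1:
            return np.full(n, rates[0])
        idx = rng.choice(rates.size, size=n, p=probs)
        return rates[idx]


def jc69(scale: float = 1.0) -> SubstitutionModel:
    """The Jukes-Cantor model (equal rates and frequencies)."""
    return SubstitutionModel(scale=scale, name="JC69")


def benchmark_gtr(scale: float = 1.0) -> SubstitutionModel:
    """The GTR+I+Gamma parameter set used for all calibration studies.

    Seq-Gen-style parameters: -mGTR -r 1.0 0.2 10.0 0.75 3.2 1.6
    -f 0.15 0.35 0.15 0.35 -i 0.2 -a 5.0 -g 3.
    """
    return SubstitutionModel(
        exchangeabilities=(1.0, 0.2, 10.0, 0.75, 3.2, 1.6),
        base_freqs=(0.15, 0.35, 0.15, 0.35),
        p_inv=0.2, gamma_shape=5.0, gamma_categories=3,
        scale=scale, name="GTR+I+G",
    )


PRESETS = {"jc69": jc69, "benchmark-gtr": benchmark_gtr}


# ---------------------------------------------------------------------------
# gene tree simulation (vectorized multispecies coalescent)


def _coalesce_population(
    lin: np.ndarray, k: np.ndarray, t0: float, t1: float,
    P: np.ndarray, heights: np.ndarray, cnt: np.ndarray,
    n_tips: int, rng: np.random.Generator,
) -> None:
    """Run the coalescent in one population across all sites in place.

    ``lin[s, :k[s]]`` are the active gene-lineage ids of site ``s``;
    pairs coalesce at rate k(k-1)/2 between times t0 and t1.
    """
    S = k.shape[0]
    t = np.full(S, float(t0))
    alive = np.nonzero(k >= 2)[0]
    while alive.size:
        kk = k[alive]
        t[alive] += rng.exponential(1.0, alive.size) / (kk * (kk - 1) / 2.0)
        ev = alive[t[alive] < t1]
        if ev.size == 0:
            break
        kk = k[ev]
        i = (rng.random(ev.size) * kk).astype(np.int64)
        j = (rng.random(ev.size) * (kk - 1)).astype(np.int64)
        j += (j >= i).astype(np.int64)
        new = n_tips + cnt[ev]
        ci = lin[ev, i]
        cj = lin[ev, j]
        P[ev, ci] = new
        P[ev, cj] = new
        heights[ev, new] = t[ev]
        lin[ev, i] = new
        lin[ev, j] = lin[ev, kk - 1]
        cnt[ev] += 1
        k[ev] = kk - 1
        alive = ev[k[ev] >= 2]


def simulate_gene_trees(
    tree: ClockTree, n_sites: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw independent multispecies-coalescent gene trees, one per site.

    Returns ``(parent, height)`` arrays of shape (n_sites, 2n-1): tips
    are gene nodes 0..n-1 at height 0, coalescences are numbered in time
    order so node 2n-2 is always the root; ``parent`` is -1 at the root.
    One lineage is sampled per species.
    """
    n = tree.n_tips
    if n < 2:
        raise ValueError("need at least two tips")
    S = int(n_sites)
    M = 2 * n - 1
    P = np.full((S, M), -1, dtype=np.int64)
    heights = np.zeros((S, M))
    cnt = np.zeros(S, dtype=np.int64)
    parent = tree.parent
    buf: dict[int, tuple[np.ndarray, np.ndarray]] = {
        tip: (np.full((S, 1), tip, dtype=np.int64), np.ones(S, dtype=np.int64))
        for tip in range(n)
    }
    for v in range(n, M):
        c1, c2 = tree.children[v - n]
        l1, k1 = buf.pop(c1)
        l2, k2 = buf.pop(c2)
        w1, w2 = l1.shape[1], l2.shape[1]
        lin = np.zeros((S, w1 + w2), dtype=np.int64)
        lin[:, :w1] = l1
        mask = np.arange(w2)[None, :] < k2[:, None]
        rws, cs = np.nonzero(mask)
        lin[rws, k1[rws] + cs] = l2[rws, cs]
        k = k1 + k2
        t1 = np.inf if parent[v] < 0 else tree.node_time[parent[v]]
        _coalesce_population(lin, k, tree.node_time[v], t1, P, heights, cnt, n, rng)
        buf[v] = (lin, k)
    return P, heights


def simulate_gene_tree_newick(
    tree: ClockTree, rng: np.random.Generator
) -> str:
    """Draw a single gene tree and return it as a Newick string."""
    P, heights = simulate_gene_trees(tree, 1, rng)
    par, h = P[0], heights[0]
    n = tree.n_tips
    kids: dict[int, list[int]] = {}
    for v in range(2 * n - 2):
        kids.setdefault(int(par[v]), []).append(v)

    def render(v: int) -> str:
        if v < n:
            return tree.taxa[v]
        inner = ",".join(
            f"{render(c)}:{h[v] - h[c]:.6g}" for c in kids[v]
        )
        return f"({inner})"

    return render(2 * n - 2) + ";"


def _sample_categorical(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cdf = np.cumsum(probs, axis=1)
    cdf[:, -1] = 1.0
    u = rng.random(probs.shape[0])
    return np.minimum((u[:, None] > cdf).sum(axis=1), probs.shape[1] - 1)


def simulate_sites(
    P: np.ndarray,
    heights: np.ndarray,
    model: SubstitutionModel,
    rng: np.random.Generator,
    site_rates: np.ndarray | None = None,
    tip_extra: Sequence[float] | None = None,
) -> np.ndarray:
    """Evolve one site down each gene tree; returns (sites, tips) base codes.

    The root state is drawn from the stationary frequencies, and each
    branch applies the model's transition probabilities for length
    ``(height difference + pendant extra) * site rate * scale``.
    """
    S, M = P.shape
    n_tips = (M + 1) // 2
    eigs, u_mat, w_mat = model._eigen
    if site_rates is None:
        site_rates = model.draw_site_rates(S, rng)
    eff = site_rates * model.scale
    pi = np.asarray(model.base_freqs)
    states = np.empty((S, M), dtype=np.int64)
    states[:, M - 1] = _sample_categorical(np.broadcast_to(pi, (S, 4)), rng)
    rows = np.arange(S)
    for v in range(M - 2, -1, -1):
        par = P[:, v]
        t = heights[rows, par] - heights[:, v]
        if tip_extra is not None and v < n_tips and tip_extra[v]:
            t = t + tip_extra[v]
        bl = t * eff
        a = u_mat[states[rows, par]] * np.exp(eigs[None, :] * bl[:, None])
        probs = a @ w_mat
        np.clip(probs, 0.0, None, out=probs)
        probs /= probs.sum(axis=1, keepdims=True)
        states[:, v] = _sample_categorical(probs, rng)
    return states[:, :n_tips].astype(np.uint8)


# ---------------------------------------------------------------------------
# datasets


@dataclass(frozen=True)
class SimulationConfig:
    """Shape of one simulated dataset.

    ``mode`` is "cis" (coalescent independent sites: a fresh gene tree
    per site) or "multilocus" (one gene tree per locus of
    ``locus_length`` sites).  ``allocation`` fixes the number of
    S1-derived sites/loci at round(total * gamma) ("fixed") or draws it
    binomially ("bernoulli").
    """

    mode: str = "cis"
    n_sites: int = 100_000
    n_loci: int = 1000
    locus_length: int = 100
    allocation: str = "fixed"

    def __post_init__(self) -> None:
        if self.mode not in ("cis", "multilocus"):
            raise ValueError("mode must be 'cis' or 'multilocus'")
        if self.allocation not in ("fixed", "bernoulli"):
            raise ValueError("allocation must be 'fixed' or 'bernoulli'")
        if min(self.n_sites, self.n_loci, self.locus_length) < 1:
            raise ValueError("sizes must be positive")

    @property
    def n_units(self) -> int:
        """Gene trees per dataset (sites in cis mode, loci otherwise)."""
        return self.n_sites if self.mode == "cis" else self.n_loci

    @property
    def total_sites(self) -> int:
        return self.n_sites if self.mode == "cis" else self.n_loci * self.locus_length


def sample_parental_tree(
    network: SpeciesNetwork, rng: np.random.Generator, n: int | None = None
):
    """Bernoulli(gamma) choice of parental tree: 1 selects S1, 0 selects S2."""
    if n is None:
        return int(rng.random() < network.gamma)
    return (rng.random(n) < network.gamma).astype(np.int64)


def _rng_of(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def simulate_site_matrix(
    network: SpeciesNetwork,
    model: SubstitutionModel,
    config: SimulationConfig,
    rng_or_seed=None,
) -> np.ndarray:
    """Simulate a dataset; returns a (taxa, sites) base-code matrix.

    Rows follow ``network.taxa``.  The S1-derived block comes first;
    site patterns are exchangeable across positions so no shuffling is
    applied.
    """
    rng = _rng_of(rng_or_seed)
    total = config.n_units
    if config.allocation == "fixed":
        n1 = int(round(total * network.gamma))
    else:
        n1 = int(rng.binomial(total, network.gamma))
    blocks = []
    for tree, n_units in ((network.s1, n1), (network.s2, total - n1)):
        if n_units == 0:
            continue
        P, heights = simulate_gene_trees(tree, n_units, rng)
        if config.mode == "multilocus":
            P = np.repeat(P, config.locus_length, axis=0)
            heights = np.repeat(heights, config.locus_length, axis=0)
        states = simulate_sites(P, heights, model, rng,
                                tip_extra=tree.tip_extra)
        order = [tree.taxa.index(t) for t in network.taxa]
        blocks.append(states[:, order])
    return np.concatenate(blocks, axis=0).T


def simulate_dataset(
    network: SpeciesNetwork,
    model: SubstitutionModel,
    config: SimulationConfig,
    rng_or_seed=None,
) -> Alignment:
    """Simulate an alignment under the coalescent-with-hybridization model."""
    mat = simulate_site_matrix(network, model, config, rng_or_seed)
    return Alignment.from_matrix(network.taxa, mat)


def _quartet_counts_from_matrix(
    mat: np.ndarray, taxa: Sequence[str], q: QuartetAssignment
) -> SitePatternCounts:
    idx_taxa = [list(taxa).index(t) for t in q.taxa]
    sub = mat[idx_taxa].astype(np.intp)
    pat = ((sub[0] * 4 + sub[1]) * 4 + sub[2]) * 4 + sub[3]
    counts = np.bincount(pat, minlength=256).astype(float)
    return SitePatternCounts(counts, float(pat.size), 0)


# ---------------------------------------------------------------------------
# study harnesses


def run_power_study(
    cells: Sequence[dict],
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run replicated four-taxon power/estimation studies.

    Each cell is a dict with keys ``network``, ``model``, ``config``,
    ``n_replicates`` and optionally ``test`` ("f1/f2", "f3/f4",
    "pooled", or "abba") and ``label``.  Per cell the table reports the
    rejection proportion at ``alpha`` and the mean, SD and MSE of the
    gamma estimate (from the f1/f2 ratio unless another invariant ratio
    is the test).  Replicate random streams are spawned deterministically
    from ``seed``, so any cell is reproducible in isolation.
    """
    from .hilstest import abba_baba, hils_test

    root_ss = np.random.SeedSequence(seed)
    cell_seeds = root_ss.spawn(len(cells))
    rows = []
    for cell, cell_ss in zip(cells, cell_seeds):
        network: SpeciesNetwork = cell["network"]
        model: SubstitutionModel = cell["model"]
        config: SimulationConfig = cell["config"]
        reps: int = cell["n_replicates"]
        test = cell.get("test", "f1/f2")
        assignment = network.quartet_assignment()
        gamma_ratio = test if test in ("f1/f2", "f3/f4", "pooled") else "f1/f2"
        rejected = 0
        estimates = []
        for rep_ss in cell_ss.spawn(reps):
            rng = np.random.default_rng(rep_ss)
            mat = simulate_site_matrix(network, model, config, rng)
            counts = _quartet_counts_from_matrix(mat, network.taxa, assignment)
            if test == "abba":
                res = abba_baba(counts)
                rejected += res.p_value < alpha
            else:
                res = hils_test(counts, ratio=test, alpha=alpha,
                                assignment=assignment)
                rejected += res.significant
            try:
                from .hilstest import estimate_gamma
                from .patterns import cumulative_frequencies

                estimates.append(
                    estimate_gamma(cumulative_frequencies(counts), gamma_ratio)
                )
            except ZeroDivisionError:
                estimates.append(np.nan)
        est = np.asarray(estimates, dtype=float)
        ok = est[np.isfinite(est)]
        rows.append({
            "label": cell.get("label", ""),
            "gamma": network.gamma,
            "mode": config.mode,
            "n_sites": config.total_sites,
            "test": test,
            "n_replicates": reps,
            "power": rejected / reps,
            "mean_gamma_hat": ok.mean() if ok.size else np.nan,
            "sd_gamma_hat": ok.std(ddof=1) if ok.size > 1 else np.nan,
            "mse_gamma_hat": (
                ((ok - network.gamma) ** 2).mean() if ok.size else np.nan
            ),
        })
    return pd.DataFrame(rows)


def run_scan_study(
    network: SpeciesNetwork,
    model: SubstitutionModel,
    config: SimulationConfig,
    n_replicates: int,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicated whole-network scans scored against the true hybrid.

    Per replicate an alignment is simulated, every hybrid/parental
    assignment is tested with the Bonferroni-corrected Hils test, and
    the outcome is tallied as false positive / true positive / true set
    following the simulation-study convention: a true positive flags the
    correct triple with the hybrid correctly designated, a true set
    flags the correct triple with the hybrid mis-designated, and a false
    positive flags any other triple.
    """
    from .scan import ScanConfig, classify_detection, scan_matrix

    scan_cfg = ScanConfig(alpha=alpha, pseudocount_mode="always")
    tallies = {"false_positive": 0, "true_positive": 0, "true_set": 0}
    for rep_ss in np.random.SeedSequence(seed).spawn(n_replicates):
        rng = np.random.default_rng(rep_ss)
        mat = simulate_site_matrix(network, model, config, rng)
        result = scan_matrix(mat, network.taxa, network.outgroup, config=scan_cfg)
        hit = classify_detection(
            result, network.hybrid_taxa,
            network.parent1_taxa, network.parent2_taxa,
        )
        for key in tallies:
            tallies[key] += bool(hit[key])
    return pd.DataFrame([{
        "gamma": network.gamma,
        "mode": config.mode,
        "n_sites": config.total_sites,
        "n_replicates": n_replicates,
        **{k: v / n_replicates for k, v in tallies.items()},
    }])


# ---------------------------------------------------------------------------
# extended Newick (one reticulation)


def parse_extended_newick(text: str, outgroup: str | None = None) -> SpeciesNetwork:
    """Parse a one-reticulation extended Newick string into a network.

    The hybrid node is tagged ``#H<id>`` and appears twice, once with
    its child subtree and once as a bare reference; inheritance
    probabilities use the ``:length::gamma`` convention.  S1 is the tree
    that keeps the first ``#H`` attachment in the string (by the
    package's convention, the P2-side donor) and ``gamma`` is its
    inheritance probability (or one minus the other edge's annotation).
    When ``outgroup`` is not given, the root child that is a tip (or the
    smaller root clade) is taken as the outgroup.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    pos = 0

    def parse_node():
        nonlocal pos
        node = {"children": [], "label": "", "length": None, "gamma": None}
        if text[pos] == "(":
            pos += 1
            while True:
                node["children"].append(parse_node())
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                raise ValueError(f"unexpected character {text[pos]!r} at {pos}")
        m = re.match(r"[^(),;:]*", text[pos:])
        node["label"] = m.group(0)
        pos += m.end()
        if pos < len(text) and text[pos] == ":":
            m = re.match(r":([^:,();]*)(?::([^:,();]*))?(?::([^:,();]*))?", text[pos:])
            fields = m.groups()
            pos += m.end()
            if fields[0]:
                node["length"] = float(fields[0])
            if fields[2]:
                node["gamma"] = float(fields[2])
        return node

    root = parse_node()
    if pos >= len(text) or text[pos] != ";":
        raise ValueError("trailing characters in Newick string")

    hybrids: list[dict] = []

    def collect(node):
        if "#" in node["label"]:
            hybrids.append(node)
        for c in node["children"]:
            collect(c)

    collect(root)
    if len(hybrids) != 2 or len({h["label"] for h in hybrids}) != 1:
        raise ValueError("expected exactly one hybrid node appearing twice")
    definition = next((h for h in hybrids if h["children"]), None)
    if definition is None:
        raise ValueError("hybrid node has no child subtree")
    first, second = hybrids
    if first["gamma"] is not None:
        gamma = first["gamma"]
    elif second["gamma"] is not None:
        gamma = 1.0 - second["gamma"]
    else:
        raise ValueError("no inheritance probability annotated on the hybrid edges")

    hybrid_children = definition["children"]
    hybrid_tail = definition["label"].split("#")[0]

    def build_tree(keep) -> ClockTree:
        # depth-first: compute tip depths and joins, dropping the other edge
        joins: list[tuple[float, str, str]] = []
        depths: dict[str, float] = {}

        def walk(node, depth, pending):
            """Returns (representative taxon, subtree height) or None."""
            length = node["length"] or 0.0
            if node in hybrids:
                if node is not keep:
                    return None
                node = {"children": hybrid_children, "label": hybrid_tail,
                        "length": length, "gamma": None}
            if not node["children"]:
                name = node["label"]
                if not name:
                    raise ValueError("unnamed tip")
                depths[name] = depth + length
                return name
            reps = [walk(c, depth + length, pending)
                    for c in node["children"]]
            reps = [r for r in reps if r is not None]
            if not reps:
                return None
            if len(reps) == 1:
                return reps[0]
            pending.append((depth + length, reps))
            return reps[0]

        pending: list[tuple[float, list[str]]] = []
        walk(root, 0.0, pending)
        height = max(depths.values())
        for tip, d in depths.items():
            if abs(d - height) > 1e-6 * max(height, 1.0):
                raise ValueError("network tips are not contemporaneous")
        for node_depth, reps in pending:
            t = height - node_depth
            for other in reps[1:]:
                joins.append((t, reps[0], other))
        return ClockTree.from_joins(sorted(depths), joins)

    s1 = build_tree(first)
    s2 = build_tree(second)
    hybrid_taxa: set[str] = set()

    def tips_of(node):
        if not node["children"]:
            hybrid_taxa.add(node["label"])
        for c in node["children"]:
            tips_of(c)

    for c in hybrid_children:
        tips_of(c)
    if outgroup is None:
        c1, c2 = s1.children[-1]
        n = s1.n_tips
        if c2 < n:
            outgroup = s1.taxa[c2]
        elif c1 < n:
            outgroup = s1.taxa[c1]
        else:
            smaller = min((c1, c2), key=lambda c: len(s1.clades[c]))
            outgroup = s1.taxa[min(s1.clades[smaller])]
    hybrid_label = sorted(hybrid_taxa)[0]
    return SpeciesNetwork(s1, s2, gamma, hybrid=hybrid_label,
                          outgroup=outgroup, hybrid_taxa=frozenset(hybrid_taxa))
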