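"""Filter NMF modules for robustness/recurrence and cluster them into consensus programs.

A module is kept when it (i) reappears at another factorisation rank of
the same sample (robustness), (ii) survives a within-sample redundancy
collapse, and (iii) recurs in at least one other sample (recurrence).
Retained modules are clustered by Jaccard similarity into consensus ITH
programs; each program's signature is the set of genes present in at
least a quarter of its member modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .nmf import GeneModule
from .preprocessing import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Overlap gates of the module filter.

    Overlaps here are shared-gene fractions |A n B| / top_n (modules are
    equal-sized), distinct from the Jaccard index used for clustering.
    """

    intra_min_overlap: float = 0.7
    cross_min_overlap: float = 0.2
    redundancy_max_overlap: float = 0.8

    def validate(self) -> None:
        for name in ("intra_min_overlap", "cross_min_overlap", "redundancy_max_overlap"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        if self.redundancy_max_overlap < self.cross_min_overlap:
            raise ValidationError("redundancy_max_overlap must be >= cross_min_overlap")


@dataclass
class ITHProgram:
    """A consensus cluster of modules and its derived signature genes."""

    program_id: str
    member_modules: list[GeneModule]
    signature_genes: list[str] = field(default_factory=list)
    annotation: str | None = None

    @property
    def n_members(self) -> int:
        return len(self.member_modules)

    @property
    def samples(self) -> list[str]:
        return sorted({m.sample_id for m in self.member_modules})


def jaccard(set_a, set_b) -> float:
    """|A n B| / |A u B| for two non-empty gene sets."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValidationError("jaccard requires non-empty sets")
    return len(a & b) / len(a | b)


def _shared_fraction(a: GeneModule, b: GeneModule) -> float:
    # modules are equal-sized (top_n genes); use |A n B| / max size for safety
    denom = max(len(a.genes), len(b.genes))
    return len(a.gene_set & b.gene_set) / denom


def filter_modules(modules: list[GeneModule], cfg: FilterConfig | None = None) -> list[GeneModule]:
    """Apply the robustness / redundancy / recurrence gates.

    (i)  intra: keep a module only if some module of the same sample at a
         *different* rank shares >= intra_min_overlap of its genes.  A
         module's recorded ``rank_supporters`` (from a previous pass)
         counts as evidence, so filtering is idempotent.
    (ii) redundancy: within a sample, greedily keep the module with more
         rank supporters and drop others overlapping it beyond
         redundancy_max_overlap.
    (iii) cross: iterate to a fixpoint keeping modules that share >=
         cross_min_overlap with a surviving module of another sample.

    Output order is deterministic: (sample id, rank, factor index).
    With modules from a single sample the cross step is skipped with a warning.
    """
    cfg = cfg or FilterConfig()
    cfg.validate()
    modules = sorted(modules, key=lambda m: m.sort_key)

    # (i) robustness across ranks within each sample
    survivors: list[GeneModule] = []
    for m in modules:
        same_sample = [
            o for o in modules
            if o.sample_id == m.sample_id and o.rank != m.rank
        ]
        supporters = {
            o.rank for o in same_sample
            if _shared_fraction(m, o) >= cfg.intra_min_overlap
        }
        n_sup = len(supporters)
        if m.rank_supporters is not None:
            n_sup = max(n_sup, m.rank_supporters)
        if n_sup >= 1:
            m.rank_supporters = n_sup
            survivors.append(m)
        else:
            logger.debug("module %s dropped: no intra-sample support", m.name)

    # (ii) within-sample redundancy collapse, greedy by supporter count
    collapsed: list[GeneModule] = []
    for sid in dict.fromkeys(m.sample_id for m in survivors):
        sample_mods = sorted(
            (m for m in survivors if m.sample_id == sid),
            key=lambda m: (-(m.rank_supporters or 0), m.sort_key),
        )
        kept: list[GeneModule] = []
        for m in sample_mods:
            if any(_shared_fraction(m, k) > cfg.redundancy_max_overlap for k in kept):
                logger.debug("module %s dropped: redundant within sample", m.name)
                continue
            kept.append(m)
        collapsed.extend(kept)

    # (iii) cross-sample recurrence, to a fixpoint
    n_samples = len({m.sample_id for m in collapsed})
    if n_samples < 2:
        logger.warning("modules from <2 samples: cross-sample recurrence step skipped")
        return sorted(collapsed, key=lambda m: m.sort_key)

    current = list(collapsed)
    while True:
        nxt = [
            m for m in current
            if any(
                o.sample_id != m.sample_id
                and _shared_fraction(m, o) >= cfg.cross_min_overlap
                for o in current
            )
        ]
        if len(nxt) == len(current):
            break
        current = nxt
    return sorted(current, key=lambda m: m.sort_key)


def cluster_modules(
    modules: list[GeneModule],
    method: str = "average",
    distance_cut: float = 0.9,
    n_clusters: int | None = None,
    min_cluster_size: int = 2,
    signature_min_frac: float = 0.25,
) -> list[ITHProgram]:
    """Hierarchically cluster modules on 1 - Jaccard into consensus programs.

    The tree is cut at ``distance_cut`` unless an explicit ``n_clusters``
    is requested.  Clusters smaller than ``min_cluster_size`` are
    discarded (logged); surviving programs are numbered by descending
    size (ties by the members' deterministic sort keys) and given
    signatures via :func:`derive_signature`.
    """
    if len(modules) < 2:
        raise ValidationError("need at least 2 retained modules to cluster")
    modules = sorted(modules, key=lambda m: m.sort_key)
    n = len(modules)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - jaccard(modules[i].gene_set, modules[j].gene_set)
            dist[i, j] = dist[j, i] = d

    Z = linkage(squareform(dist, checks=False), method=method)
    if n_clusters is not None:
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        labels = fcluster(Z, t=distance_cut, criterion="distance")

    clusters: dict[int, list[GeneModule]] = {}
    for lab, m in zip(labels, modules):
        clusters.setdefault(int(lab), []).append(m)

    kept = []
    for lab, members in clusters.items():
        if len(members) < min_cluster_size:
            logger.info(
                "discarding cluster of %d module(s) below min size %d: %s",
                len(members), min_cluster_size,
                [m.name for m in members],
            )
            continue
        kept.append(members)
    if not kept:
        raise ValidationError("no consensus programs: every cluster fell below the minimum size")

    kept.sort(key=lambda ms: (-len(ms), ms[0].sort_key))
    programs = []
    for i, members in enumerate(kept, start=1):
        prog = ITHProgram(program_id=f"ITH{i}", member_modules=members)
        prog.signature_genes = derive_signature(prog, min_frac=signature_min_frac)
        programs.append(prog)
    return programs


def derive_signature(program: ITHProgram, min_frac: float = 0.25) -> list[str]:
    """Genes present in at least ``min_frac`` of the program's member modules.

    The threshold is inclusive (a gene in exactly 25% of members is kept
    at the default).  Order: descending occurrence count, then gene id.
    """
    if not program.member_modules:
        raise ValidationError("program has no member modules")
    counts: dict[str, int] = {}
    for m in program.member_modules:
        for g in m.gene_set:
            counts[g] = counts.get(g, 0) + 1
    n = len(program.member_modules)
    sig = [g for g, c in counts.items() if c / n >= min_frac]
    if not sig:
        raise ValidationError(f"empty signature at min_frac={min_frac}")
    return sorted(sig, key=lambda g: (-counts[g], g))
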