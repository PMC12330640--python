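"""Module filtering, Jaccard clustering into consensus programs, signatures."""

import numpy as np
import pytest

from ithkit import (
    FilterConfig,
    ITHProgram,
    ValidationError,
    cluster_modules,
    derive_signature,
    filter_modules,
    jaccard,
)
from ithkit.nmf import GeneModule


def _module(sample, rank, factor, genes):
    genes = list(genes)
    return GeneModule(sample, rank, factor, genes, np.linspace(1, 0.5, len(genes)))


def _genes(lo, hi):
    return [f"g{i:03d}" for i in range(lo, hi)]


class TestJaccard:
    def test_identical(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint(self):
        assert jaccard({"a"}, {"b"}) == 0.0

    def test_partial(self):
        assert jaccard({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            jaccard(set(), {"a"})


class TestFilterModules:
    def test_recurrent_module_retained(self):
        genes = _genes(0, 10)
        mods = [_module("A", k, 0, genes) for k in (6, 7, 8, 9)]
        mods.append(_module("B", 6, 0, genes[:9] + ["g999"]))  # 0.9 overlap with A's
        mods.append(_module("B", 7, 0, genes[:9] + ["g999"]))
        kept = filter_modules(mods)
        assert any(m.sample_id == "A" for m in kept)
        assert any(m.sample_id == "B" for m in kept)

    def test_unsupported_module_dropped_at_intra_step(self):
        base = _genes(0, 10)
        mods = [_module("A", k, 0, base) for k in (6, 7)]
        # ~0.3 overlap with everything in the sample, present at a single K
        loner = _module("A", 8, 1, base[:3] + _genes(50, 57))
        # another sample so the cross step runs
        mods += [_module("B", 6, 0, base), _module("B", 7, 0, base), loner]
        kept = filter_modules(mods)
        assert loner.name not in {m.name for m in kept}

    def test_redundancy_keeps_better_supported_module(self):
        """Of two near-duplicate same-sample modules, the one recurring at
        3 ranks survives; the 1-rank one is collapsed away."""
        strong = _genes(0, 10)
        weak = strong[:9] + ["g999"]  # 0.9 overlap with strong
        mods = [_module("A", k, 0, strong) for k in (6, 7, 8)]
        mods += [_module("A", 9, 0, weak), _module("A", 6, 1, weak)]
        mods += [_module("B", 6, 0, strong), _module("B", 7, 0, strong)]
        kept = filter_modules(mods)
        kept_a = [m for m in kept if m.sample_id == "A"]
        assert all(m.gene_set == frozenset(strong) for m in kept_a)
        assert len(kept_a) >= 1

    def test_cross_sample_recurrence_required(self):
        shared = _genes(0, 10)
        private = _genes(100, 110)
        mods = [_module("A", k, 0, shared) for k in (6, 7)]
        mods += [_module("B", k, 0, shared) for k in (6, 7)]
        mods += [_module("C", k, 0, private) for k in (6, 7)]  # recurs only within C
        kept = filter_modules(mods)
        assert {m.sample_id for m in kept} == {"A", "B"}

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        universe = _genes(0, 120)
        mods = []
        for s in "ABC":
            for k in (6, 7, 8):
                for f in range(3):
                    start = rng.integers(0, 40)
                    mods.append(_module(s, k, f, universe[start:start + 10]))
        once = filter_modules(mods)
        twice = filter_modules(list(once))
        assert [m.name for m in twice] == [m.name for m in once]

    def test_single_sample_skips_cross_step(self):
        mods = [_module("A", k, 0, _genes(0, 10)) for k in (6, 7)]
        kept = filter_modules(mods)
        assert len(kept) >= 1


class TestClusterModules:
    def test_two_block_structure_gives_two_programs(self):
        group1 = [_module("A", 6, i, _genes(0, 10)[: 8] + _genes(20 + i, 22 + i))
                  for i in range(5)]
        group2 = [_module("B", 6, i, _genes(100, 110)[: 8] + _genes(130 + i, 132 + i))
                  for i in range(5)]
        programs = cluster_modules(group1 + group2, distance_cut=0.9)
        assert len(programs) == 2
        sizes = sorted(p.n_members for p in programs)
        assert sizes == [5, 5]

    def test_identical_modules_form_one_program(self):
        mods = [_module("A", 6, i, _genes(0, 10)) for i in range(10)]
        programs = cluster_modules(mods)
        assert len(programs) == 1
        assert programs[0].n_members == 10
        assert set(programs[0].signature_genes) == set(_genes(0, 10))

    def test_all_singletons_is_an_error(self):
        mods = [_module("A", 6, i, _genes(20 * i, 20 * i + 10)) for i in range(4)]
        with pytest.raises(ValidationError, match="no consensus programs"):
            cluster_modules(mods, n_clusters=4)

    def test_partition_no_module_in_two_programs(self):
        rng = np.random.default_rng(3)
        mods = []
        for s in "AB":
            for i in range(6):
                block = 0 if i < 3 else 100
                mods.append(_module(s, 6, i, _genes(block, block + 8)
                                    + _genes(200 + rng.integers(40), 202 + rng.integers(40, 44))))
        programs = cluster_modules(mods, distance_cut=0.9)
        names = [m.name for p in programs for m in p.member_modules]
        assert len(names) == len(set(names))


class TestDeriveSignature:
    def test_quarter_occurrence_is_inclusive(self):
        members = [_module("A", 6, i, _genes(0, 8)) for i in range(3)]
        members.append(_module("A", 7, 0, _genes(0, 7) + ["g999"]))
        prog = ITHProgram("p", members)
        sig = derive_signature(prog, min_frac=0.25)
        assert "g999" in sig  # 1 of 4 members = 25%, kept

    def test_below_threshold_excluded(self):
        members = [_module("A", 6, i, _genes(0, 8)) for i in range(4)]
        members.append(_module("A", 7, 0, _genes(0, 7) + ["g999"]))
        sig = derive_signature(ITHProgram("p", members), min_frac=0.25)
        assert "g999" not in sig  # 1 of 5 = 20%

    def test_single_member_signature_is_module(self):
        m = _module("A", 6, 0, _genes(0, 10))
        sig = derive_signature(ITHProgram("p", [m]))
        assert set(sig) == m.gene_set

    def test_raising_min_frac_never_adds_genes(self):
        rng = np.random.default_rng(7)
        # shared 8-gene core plus 2 variable genes, so every threshold is attainable
        members = [
            _module("A", 6, i,
                    _genes(0, 8) + list(rng.choice(_genes(20, 30), size=2, replace=False)))
            for i in range(6)
        ]
        prog = ITHProgram("p", members)
        prev = set(derive_signature(prog, min_frac=0.01))
        for f in (0.25, 0.5, 0.75, 1.0):
            cur = set(derive_signature(prog, min_frac=f))
            assert cur <= prev
            prev = cur
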