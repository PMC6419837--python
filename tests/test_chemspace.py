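"""Canonicalization, skeletons, toy enumeration and filter checks."""

import itertools

import pytest
from rdkit import Chem

from chemcover import chemspace as cs


class TestCanonicalize:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("C1CCCCC1", "C1CCCCC1"),  # already canonical cyclohexane
            ("OCC", "CCO"),  # ethanol written backwards
            ("c1ccccc1", "c1ccccc1"),
        ],
    )
    def test_known_forms(self, raw, expected):
        assert cs.canonicalize(raw) == expected

    @pytest.mark.parametrize("bad", ["C1CC", "QXZ", "", "C(("])
    def test_unparseable_returns_none(self, bad):
        assert cs.canonicalize(bad) is None

    def test_idempotent_on_toy_corpus(self, toy_space):
        for s in itertools.islice(iter(toy_space), 200):
            assert cs.canonicalize(s) == s


class TestLoadSpace:
    def test_dedup_and_failures(self, tmp_path):
        p = tmp_path / "space.smi"
        p.write_text("CCO\nOCC\nC1CC\n")
        space, stats = cs.load_space(p)
        assert space.n == 1
        assert stats == {"n": 1, "parse_failures": 1, "duplicates_removed": 1}

    def test_ten_distinct(self, tmp_path):
        mols = ["C", "N", "O", "CC", "CN", "CO", "CCC", "CCN", "CCO", "C=O"]
        p = tmp_path / "ten.smi"
        p.write_text("\n".join(mols))
        space, _ = cs.load_space(p)
        assert space.n == 10
        assert space.p == pytest.approx(0.1)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.smi"
        p.write_text("")
        with pytest.raises(ValueError):
            cs.load_space(p)

    def test_mostly_garbage_errors(self, tmp_path):
        p = tmp_path / "bad.smi"
        p.write_text("CCO\nXX1\nYY2\nZZ3\n")
        with pytest.raises(ValueError, match="wrong file"):
            cs.load_space(p)

    def test_roundtrip_save_load(self, tmp_path, toy_space):
        p = tmp_path / "toy.smi"
        cs.save_space(toy_space, p)
        reloaded, _ = cs.load_space(p)
        assert reloaded.molecules == toy_space.molecules


class TestCarbonSkeleton:
    @pytest.mark.parametrize(
        "smiles, skeleton_of",
        [
            ("CCO", "CCC"),  # ethanol -> propane
            ("c1ccncc1", "C1CCCCC1"),  # pyridine -> cyclohexane
            ("CCC", "CCC"),  # saturated all-carbon is its own skeleton
            ("CC(=O)N", "CC(C)C"),
        ],
    )
    def test_examples(self, smiles, skeleton_of):
        assert cs.carbon_skeleton(smiles) == cs.canonicalize(skeleton_of)

    def test_heteroatom_substitution_invariance(self):
        # swapping one heteroatom for another must not change the skeleton
        for a, b in [("O", "N"), ("N", "O")]:
            assert cs.carbon_skeleton(f"CC{a}C=C") == cs.carbon_skeleton(f"CC{b}C=C")
        assert cs.carbon_skeleton("C1COCCN1") == cs.carbon_skeleton("C1CNCCO1")

    def test_invalid_raises(self):
        with pytest.raises(ValueError):
            cs.carbon_skeleton("C1CC")


def _bare_filters(**kw):
    defaults = dict(
        max_heteroatom_ratio=None,
        disallowed_group_patterns={},
        disallowed_heteroatom_neighbor_patterns={},
        bond_rules={},
    )
    defaults.update(kw)
    return cs.EnumerationFilters(**defaults)


class TestEnumerateToySpace:
    def test_saturated_carbon_max3(self):
        filters = _bare_filters(
            max_heavy_atoms=3,
            allowed_elements=frozenset({"C"}),
            bond_rules={"double": "*=*", "triple": "*#*"},
        )
        space = cs.enumerate_toy_space(filters, max_rings=0)
        assert space.molecules == {"C", "CC", "CCC"}

    def test_single_atoms(self):
        filters = _bare_filters(max_heavy_atoms=1)
        space = cs.enumerate_toy_space(filters)
        assert space.molecules == {"C", "N", "O"}

    def test_deterministic(self):
        f = cs.default_filters(4)
        a = cs.enumerate_toy_space(f)
        b = cs.enumerate_toy_space(f)
        assert sorted(a.molecules) == sorted(b.molecules)
        assert a.skeletons == b.skeletons

    def test_completeness_micro_scale(self):
        """Acyclic <=3-atom C/N/O space equals an independent brute force.

        The oracle builds every connected graph directly: single atoms,
        bonded pairs, and 3-atom paths (the only connected acyclic shape on
        three nodes), over all element and bond-order assignments, keeping
        whatever RDKit sanitization accepts as a neutral molecule (the toy
        space is neutral-only; sanitize-cleanup otherwise charge-separates
        hypervalent nitrogen, e.g. diazo species).
        """

        def neutral(m):
            return all(a.GetFormalCharge() == 0 for a in m.GetAtoms())

        elements = ["C", "N", "O"]
        orders = [
            Chem.BondType.SINGLE,
            Chem.BondType.DOUBLE,
            Chem.BondType.TRIPLE,
        ]
        expected = set()
        for e in elements:
            expected.add(Chem.CanonSmiles(e))
        for e1, e2 in itertools.product(elements, repeat=2):
            for o in orders:
                rw = Chem.RWMol()
                a = rw.AddAtom(Chem.Atom(e1))
                b = rw.AddAtom(Chem.Atom(e2))
                rw.AddBond(a, b, o)
                try:
                    m = rw.GetMol()
                    Chem.SanitizeMol(m)
                    if neutral(m):
                        expected.add(Chem.MolToSmiles(m))
                except Exception:
                    pass
        for e1, e2, e3 in itertools.product(elements, repeat=3):
            for o1, o2 in itertools.product(orders, repeat=2):
                rw = Chem.RWMol()
                a = rw.AddAtom(Chem.Atom(e1))
                b = rw.AddAtom(Chem.Atom(e2))
                c = rw.AddAtom(Chem.Atom(e3))
                rw.AddBond(a, b, o1)
                rw.AddBond(b, c, o2)
                try:
                    m = rw.GetMol()
                    Chem.SanitizeMol(m)
                    if neutral(m):
                        expected.add(Chem.MolToSmiles(m))
                except Exception:
                    pass
        filters = _bare_filters(max_heavy_atoms=3)
        space = cs.enumerate_toy_space(filters, max_rings=0)
        assert space.molecules == expected

    def test_guard_refuses_large_enumeration(self):
        with pytest.raises(ValueError, match="refusing"):
            cs.enumerate_toy_space(cs.default_filters(10))


class TestCheckFilters:
    def test_members_pass_their_own_filters(self, toy_space, toy_filters):
        for s in itertools.islice(iter(toy_space), 300):
            assert cs.check_filters(s, toy_filters, toy_space) == []

    def test_heavy_atom_count(self, toy_filters):
        assert "heavy_atom_count" in cs.check_filters("CCCCCC", toy_filters)

    def test_element_set(self, toy_filters):
        assert "element_set" in cs.check_filters("CCF", toy_filters)

    def test_single_functional_group_label(self, toy_filters):
        # peroxide motif and nothing else
        labels = cs.check_filters("CCOOCC", toy_filters)
        assert labels == ["heavy_atom_count", "functional_group:peroxide"]
        labels = cs.check_filters("COOC", toy_filters)
        assert labels == ["functional_group:peroxide"]

    def test_heteroatom_ratio(self, toy_filters):
        assert "heteroatom_ratio" in cs.check_filters("OCO", toy_filters)

    def test_invalid_raises(self, toy_filters):
        with pytest.raises(ValueError):
            cs.check_filters("C1CC", toy_filters)
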