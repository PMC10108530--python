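"""Module-definition grammar and pathwise completeness."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mindep.errors import ValidationError
from mindep.moddef import (
    Alternatives,
    Atom,
    Complex,
    CompletenessPolicy,
    Gap,
    GenomeAnnotations,
    ModuleCycleError,
    ModuleParseError,
    NestedModule,
    PathCapacityError,
    completeness_matrix,
    count_paths,
    enumerate_paths,
    parse_definition,
    pathwise_completeness,
    render,
    step_completeness,
)

from conftest import definition_ko_pool, oracle_pathwise, random_parsed_definitions


class TestParsing:
    def test_sequential_atoms(self):
        d = parse_definition("M00001", "K00001 K00002")
        assert d.steps == (Atom("K00001"), Atom("K00002"))

    def test_alternatives_then_atom(self):
        d = parse_definition("M00002", "(K00001,K00002) K00003")
        assert d.steps == (
            Alternatives(((Atom("K00001"),), (Atom("K00002"),))),
            Atom("K00003"),
        )

    def test_complex_with_nonessential(self):
        d = parse_definition("M00003", "K00001+K00002-K00003 K00004")
        assert d.steps == (
            Complex((("K00001", True), ("K00002", True), ("K00003", False))),
            Atom("K00004"),
        )

    def test_gap_and_nested_module(self):
        d = parse_definition("M00004", "K00001 -- M00002")
        assert d.steps == (Atom("K00001"), Gap(), NestedModule("M00002"))

    def test_lowercase_is_normalized(self):
        d = parse_definition("M00005", "k00001 k00002")
        assert d.steps == (Atom("K00001"), Atom("K00002"))

    @pytest.mark.parametrize(
        "text",
        ["(K00001 K00002", "K00001)", "K00001 + ", "K0001", "foo", "K00001+(K00002,K00003)"],
    )
    def test_parse_errors_carry_position(self, text):
        with pytest.raises(ModuleParseError) as err:
            parse_definition("M00001", text)
        assert err.value.position is not None

    def test_empty_definition_rejected(self):
        with pytest.raises(ModuleParseError):
            parse_definition("M00001", "   ")


# hypothesis strategy over definition structures -----------------------------

_KOS = [f"K{i:05d}" for i in range(1, 21)]
_atoms = st.sampled_from(_KOS).map(Atom)
_complexes = st.lists(
    st.tuples(st.sampled_from(_KOS), st.booleans()), min_size=2, max_size=4
).map(lambda comps: Complex(tuple([(comps[0][0], True)] + list(comps[1:]))))
_atomic = st.one_of(_atoms, _complexes, st.just(Gap()))


def _alternatives(children):
    return st.lists(
        st.lists(children, min_size=1, max_size=3).map(tuple),
        min_size=2,
        max_size=3,
    ).map(lambda bs: Alternatives(tuple(bs)))


_steps = st.recursive(_atomic, _alternatives, max_leaves=12)
_definitions = st.lists(_steps, min_size=1, max_size=4).map(tuple)


@given(_definitions)
def test_parse_render_roundtrip(steps):
    """Rendering a parsed structure and re-parsing reproduces it exactly."""
    text = render(steps)
    assert parse_definition("M00001", text).steps == steps


@given(_definitions, st.sets(st.sampled_from(_KOS)), st.sets(st.sampled_from(_KOS)))
def test_completeness_monotone_in_ko_set(steps, kos, extra):
    """Adding annotations never lowers pathwise completeness."""
    defn = parse_definition("M00001", render(steps))
    assert pathwise_completeness(defn, kos) <= pathwise_completeness(
        defn, kos | extra
    ) + 1e-12


@given(
    st.lists(st.sampled_from(_KOS), min_size=3, max_size=5, unique=True),
    st.sets(st.sampled_from(_KOS)),
)
def test_extra_alternative_branch_never_decreases(branch_kos, kos):
    base = Alternatives(tuple((Atom(k),) for k in branch_kos[:-1]))
    widened = Alternatives(tuple((Atom(k),) for k in branch_kos))
    d1 = parse_definition("M00001", render((base,)))
    d2 = parse_definition("M00001", render((widened,)))
    assert pathwise_completeness(d1, kos) <= pathwise_completeness(d2, kos) + 1e-12


class TestPathEnumeration:
    def test_single_route(self):
        d = parse_definition("M00001", "K00001 K00002")
        paths = enumerate_paths(d)
        assert paths == [(Atom("K00001"), Atom("K00002"))]

    def test_branch_product(self):
        d = parse_definition("M00001", "(K00001,K00002) (K00003,K00004)")
        assert len(enumerate_paths(d)) == 4

    def test_routes_of_different_length(self):
        d = parse_definition("M00001", "(K00001,(K00002 K00003))")
        paths = enumerate_paths(d)
        assert sorted(len(p) for p in paths) == [1, 2]

    def test_capacity_error_not_truncation(self):
        d = parse_definition("M00001", "(K00001,K00002) (K00003,K00004)")
        with pytest.raises(PathCapacityError):
            enumerate_paths(d, path_cap=3)

    def test_nested_expansion(self):
        registry = {
            "M00001": parse_definition("M00001", "K00001 K00002"),
        }
        d = parse_definition("M00002", "M00001 K00003")
        paths = enumerate_paths(d, registry)
        assert paths == [(Atom("K00001"), Atom("K00002"), Atom("K00003"))]

    def test_cycle_detected(self):
        registry = {
            "M00001": parse_definition("M00001", "M00002"),
            "M00002": parse_definition("M00002", "M00001"),
        }
        with pytest.raises(ModuleCycleError):
            enumerate_paths(registry["M00001"], registry)

    def test_missing_nested_module(self):
        d = parse_definition("M00002", "M00099")
        with pytest.raises(ValidationError):
            enumerate_paths(d, registry={})


class TestStepCompleteness:
    def test_atom(self):
        assert step_completeness(Atom("K00001"), {"K00001"}) == 1.0
        assert step_completeness(Atom("K00001"), {"K00002"}) == 0.0

    def test_complex_fractional_and_strict(self):
        cplx = Complex((("K00001", True), ("K00002", True)))
        assert step_completeness(cplx, {"K00001"}) == 0.5
        strict = CompletenessPolicy(complex_all_or_none=True)
        assert step_completeness(cplx, {"K00001"}, strict) == 0.0
        assert step_completeness(cplx, {"K00001", "K00002"}, strict) == 1.0

    def test_nonessential_components_ignored(self):
        cplx = Complex((("K00001", True), ("K00002", False)))
        assert step_completeness(cplx, {"K00001"}) == 1.0

    def test_gap_scores_zero(self):
        assert step_completeness(Gap(), {"K00001"}) == 0.0


class TestPathwiseCompleteness:
    @pytest.mark.parametrize(
        "text,kos,expected",
        [
            ("(K00001,K00002) K00003", {"K00002"}, 0.5),
            ("K00001+K00002 K00003", {"K00001", "K00003"}, 0.75),
            ("(K00001,K00002) K00003", set(), 0.0),
            ("(K00001,K00002) K00003", {"K00002", "K00003"}, 1.0),
        ],
    )
    def test_examples(self, text, kos, expected):
        d = parse_definition("M00001", text)
        assert pathwise_completeness(d, kos) == pytest.approx(expected)

    def test_gap_policy(self):
        d = parse_definition("M00001", "K00001 --")
        assert pathwise_completeness(d, {"K00001"}) == pytest.approx(0.5)
        excl = CompletenessPolicy(exclude_gap_steps=True)
        assert pathwise_completeness(d, {"K00001"}, policy=excl) == 1.0

    def test_matches_bruteforce_oracle_on_random_definitions(self):
        defs = random_parsed_definitions(seed=21, n=120, max_paths=64)
        rng = np.random.default_rng(21)
        assert len(defs) > 60
        for defn, registry in defs:
            pool = definition_ko_pool(defn, registry)
            kos = {k for k in pool if rng.random() < 0.5}
            got = pathwise_completeness(defn, kos, registry)
            assert got == pytest.approx(oracle_pathwise(defn, kos, registry))


class TestCompletenessMatrix:
    def test_disjoint_modules(self):
        mods = [
            parse_definition("M00001", "K00001 K00002"),
            parse_definition("M00002", "K00003 K00004"),
        ]
        genomes = [
            GenomeAnnotations("g1", frozenset({"K00001", "K00002"})),
            GenomeAnnotations("g2", frozenset({"K00003", "K00004"})),
        ]
        m = completeness_matrix(genomes, mods)
        assert m.loc["g1", "M00001"] == 1.0 and m.loc["g1", "M00002"] == 0.0
        assert m.loc["g2", "M00001"] == 0.0 and m.loc["g2", "M00002"] == 1.0

    def test_empty_module_list(self):
        genomes = [GenomeAnnotations("g1", frozenset({"K00001"}))]
        m = completeness_matrix(genomes, [])
        assert m.shape == (1, 0)

    def test_duplicate_ids_rejected(self):
        mods = [parse_definition("M00001", "K00001")]
        genomes = [
            GenomeAnnotations("g1", frozenset()),
            GenomeAnnotations("g1", frozenset()),
        ]
        with pytest.raises(ValidationError):
            completeness_matrix(genomes, mods)

    def test_values_in_unit_interval(self):
        defs = random_parsed_definitions(seed=5, n=30)
        registry = defs[0][1]
        mods = [d for d, _ in defs]
        rng = np.random.default_rng(5)
        genomes = []
        for i in range(5):
            pool = sorted({k for d, _ in defs for k in definition_ko_pool(d, registry)})
            kos = frozenset(k for k in pool if rng.random() < 0.3)
            genomes.append(GenomeAnnotations(f"g{i}", kos))
        m = completeness_matrix(genomes, mods, registry=registry)
        assert ((m >= 0) & (m <= 1)).all().all()
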