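import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mindep import moddef
from mindep.synthetic_data import SimConfig, gen_module_definitions, simulate

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


SMALL_CFG = SimConfig(
    seed=11,
    n_modules=80,
    n_planted=10,
    n_genomes_per_group=8,
    n_cohort_genomes=20,
    colonizer_fractions=(0.3, 0.3, 0.4),
    n_reference_samples=12,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SMALL_CFG


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """One coherent synthetic dataset shared across read-only tests."""
    definitions, annotations, groups, cohort, truth = simulate(small_cfg)
    return {
        "definitions": definitions,
        "annotations": annotations,
        "groups": groups,
        "cohort": cohort,
        "truth": truth,
    }


def random_parsed_definitions(seed: int, n: int, max_paths=None):
    """Random parsed definitions (with registry) for property tests."""
    cfg = SimConfig(seed=seed, n_modules=n, n_planted=min(10, n))
    frame = gen_module_definitions(cfg)
    registry = {
        row.module_id: moddef.parse_definition(row.module_id, row.definition)
        for row in frame.itertuples()
    }
    out = []
    for defn in registry.values():
        if max_paths is not None:
            if moddef.count_paths(defn, registry) > max_paths:
                continue
        out.append((defn, registry))
    return out


def definition_ko_pool(defn, registry):
    """All KO accessions reachable in a definition (nested modules included)."""
    kos = set()

    def _walk(steps):
        for step in steps:
            if isinstance(step, moddef.Atom):
                kos.add(step.ko)
            elif isinstance(step, moddef.Complex):
                kos.update(ko for ko, _ in step.components)
            elif isinstance(step, moddef.Alternatives):
                for branch in step.branches:
                    _walk(branch)
            elif isinstance(step, moddef.NestedModule):
                _walk(registry[step.module_id].steps)

    _walk(defn.steps)
    return sorted(kos)


def oracle_pathwise(defn, kos, registry=None):
    """Independent brute-force evaluator: expand every route recursively,
    score each step, return the best route mean."""
    koset = set(kos)

    def routes(steps):
        if not steps:
            return [[]]
        head, tail = steps[0], steps[1:]
        tails = routes(tail)
        if isinstance(head, moddef.Alternatives):
            heads = [r for b in head.branches for r in routes(list(b))]
        elif isinstance(head, moddef.NestedModule):
            heads = routes(list(registry[head.module_id].steps))
        else:
            heads = [[head]]
        return [h + t for h in heads for t in tails]

    def score(step):
        if isinstance(step, moddef.Atom):
            return 1.0 if step.ko in koset else 0.0
        if isinstance(step, moddef.Gap):
            return 0.0
        essential = [ko for ko, ess in step.components if ess]
        return sum(1 for ko in essential if ko in koset) / len(essential)

    best = 0.0
    for route in routes(list(defn.steps)):
        if route:
            best = max(best, sum(score(s) for s in route) / len(route))
    return best
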