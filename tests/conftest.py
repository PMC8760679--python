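import numpy as np
import pandas as pd
import pytest

import metacap as mc


@pytest.fixture
def tiny_catalog():
    """Hand-built catalog exercising all three ranks and shared taxa.

    GenusA has two models differing in rxn2; SpX has one model; FamB has
    one model with a private reaction. rxn9 has no subsystem entry.
    """
    models = [
        mc.Model("m1", "genus", "GenusA", frozenset({"rxn1", "rxn2"})),
        mc.Model("m2", "genus", "GenusA", frozenset({"rxn1"})),
        mc.Model("m3", "species", "GenusA spX", frozenset({"rxn1", "rxn3"})),
        mc.Model("m4", "family", "FamB", frozenset({"rxn1", "rxn4", "rxn9"})),
    ]
    subsystems = {
        "rxn1": ("Core",),
        "rxn2": ("SugarPath",),
        "rxn3": ("SugarPath", "AminoPath"),
        "rxn4": ("AminoPath",),
    }
    return mc.ModelCatalog(models=models, subsystems=subsystems)


@pytest.fixture
def tiny_taxonomy():
    rows = {
        # species-resolved, matches m3 at species rank
        "asv_sp": ["Bacteria", "P1", "C1", "O1", "FamA", "GenusA", "GenusA spX"],
        # species name matches nothing -> falls back to genus (m1, m2)
        "asv_ge": ["Bacteria", "P1", "C1", "O1", "FamA", "GenusA", "GenusA spZ"],
        # family-resolved, matches m4
        "asv_fa": ["Bacteria", "P1", "C1", "O2", "FamB", None, None],
        # resolved only to order -> unmappable
        "asv_or": ["Bacteria", "P1", "C1", "O3", None, None, None],
        # resolved to an unknown family -> no match anywhere
        "asv_un": ["Bacteria", "P1", "C1", "O4", "FamZ", None, None],
    }
    return mc.TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index", columns=list(mc.containers.RANKS)))


@pytest.fixture
def tiny_table(tiny_taxonomy):
    counts = pd.DataFrame(
        [[3, 1, 2, 5, 0], [1, 1, 0, 2, 4], [2, 0, 4, 1, 1]],
        index=["s1", "s2", "s3"],
        columns=list(tiny_taxonomy.asv_ids),
    )
    return mc.AsvCountTable(counts)


@pytest.fixture
def tiny_tree():
    return mc.parse_tree("((asv_sp:1,asv_ge:1):1,(asv_fa:2,(asv_or:1,asv_un:1):1):1);")


@pytest.fixture(scope="session")
def sim_config():
    return mc.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def sim_catalog(sim_config):
    return mc.generate_model_catalog(sim_config)


@pytest.fixture(scope="session")
def sim_null(sim_config, sim_catalog):
    """A full null study (no planted shift) at the default design."""
    return mc.generate_community(sim_config, sim_catalog)


@pytest.fixture(scope="session")
def sim_shifted(sim_catalog, sim_null):
    """The same study replanted with a 10x shift on the most abundant
    mapped ASV (same seed reproduces the base composition exactly)."""
    _, _, _, _, truth0 = sim_null
    mapped = list(truth0.expectation.columns)
    target = truth0.group_mean_proportions.loc["CD", mapped].idxmax()
    cfg = mc.SimulationConfig(seed=1, planted_shift={target: 10.0})
    out = mc.generate_community(cfg, sim_catalog)
    return cfg, target, out


def random_instance(rng):
    """A random small (table, E) pair for oracle cross-checks."""
    n_samples = int(rng.integers(2, 21))
    n_asvs = int(rng.integers(1, 51))
    n_rxn = int(rng.integers(1, 101))
    counts = rng.integers(0, 200, size=(n_samples, n_asvs))
    counts[:, 0] += 1  # keep every sample's mapped total positive
    table = mc.AsvCountTable(
        pd.DataFrame(counts, index=[f"s{i}" for i in range(n_samples)],
                     columns=[f"a{j}" for j in range(n_asvs)])
    )
    E = pd.DataFrame(
        rng.random(size=(n_rxn, n_asvs)),
        index=[f"r{i}" for i in range(n_rxn)],
        columns=[f"a{j}" for j in range(n_asvs)],
    )
    return table, E


def brute_force_reaction_abundance(table, E):
    """Independent double-loop evaluation of the weighted-mean formula.

    Plain Python loops over plain Python lists — no shared linear-algebra
    path with the implementation under test.
    """
    counts = [[int(table.counts.loc[s, a]) for a in E.columns] for s in table.sample_ids]
    evals = [[float(E.loc[r, a]) for a in E.columns] for r in E.index]
    out = np.zeros((len(counts), len(evals)))
    for si, row in enumerate(counts):
        denom = sum(row)
        for ri, erow in enumerate(evals):
            num = 0.0
            for w, e in zip(row, erow):
                num += w * e
            out[si, ri] = num / denom
    return out
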