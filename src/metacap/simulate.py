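"""Synthetic study generator with an analytic ground-truth oracle.

Emulates the shape of a diet-comparison amplicon study: a GSMM catalog
whose taxa share genera and families (so reaction expectations are
non-trivial), a taxonomy with mixed resolution (species / genus / family /
above family), a random coalescent tree, and grouped ASV count tables
drawn from a Dirichlet-multinomial: per sample, proportions are drawn from
a Dirichlet centred on the group's mean composition (overdispersion set by
the concentration parameter) and counts from a multinomial at the sample's
sequencing depth. One group's mean composition carries a planted
multiplicative shift on chosen ASVs; every other group equals the
reference, so between-unshifted-group comparisons are null.

The :class:`GroundTruth` object carries the true mean proportions, the
true expectation matrix, per-group expected reaction abundances computed
by an explicit double summation (a code path independent of the vectorized
pipeline), and the set of reactions whose expected between-group
difference exceeds a threshold delta — the recoverable effects.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import (
    MODEL_RANKS,
    RANKS,
    AsvCountTable,
    Model,
    ModelCatalog,
    PhyloTree,
    SampleMetadata,
    TaxonomyTable,
    normalize_taxon_name,
)
from .errors import ContractError

#: Dietary group labels, following the six-diet design (control, full-fat
#: insect meal, defatted, de-chitinized, insect oil, exoskeleton).
DIET_LABELS = ("CD", "IM", "DFIM", "DCIM", "IO", "EX")

_FAM_RE = re.compile(r"^(Fam\d+)")


@dataclass
class SimulationConfig:
    """Study-design knobs for the generator.

    Defaults mirror the emulated study: 6 dietary groups of 13 digesta
    samples, a mean depth of 50,000 reads, moderate gut-amplicon
    overdispersion (Dirichlet concentration 200), and a taxonomy in which
    10% of ASVs are resolved to species, 50% to genus, 25% to family, and
    15% only above family (and therefore unmappable).
    """

    n_groups: int = 6
    samples_per_group: int = 13
    n_asvs: int = 60
    n_models: int = 80
    n_reactions: int = 150
    n_subsystems: int = 12
    frac_species: float = 0.10
    frac_genus: float = 0.50
    frac_family: float = 0.25
    frac_above_family: float = 0.15
    concentration: float = 200.0
    depth_mean: int = 50_000
    depth_dispersion: float = 0.3  # coefficient of variation of depth; 0 = fixed
    core_reaction_fraction: float = 0.6
    planted_shift: dict = field(default_factory=dict)  # asv_id -> fold change > 0
    shift_group_index: int = 1  # group receiving the shift; group 0 is the reference
    delta: float = 0.02  # |expected a_r difference| above which a reaction is truly shifted
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_groups", "samples_per_group", "n_asvs", "n_models",
                     "n_reactions", "n_subsystems", "depth_mean"):
            if getattr(self, name) < 1:
                raise ContractError(f"{name} must be positive")
        fr = self.frac_species + self.frac_genus + self.frac_family + self.frac_above_family
        if abs(fr - 1.0) > 1e-9:
            raise ContractError(f"resolution fractions must sum to 1, got {fr}")
        if self.n_reactions < self.n_subsystems:
            raise ContractError("n_reactions must be >= n_subsystems")
        if any(f <= 0 for f in self.planted_shift.values()):
            raise ContractError("fold changes must be > 0")
        if self.concentration <= 0:
            raise ContractError("concentration must be > 0")
        if not (0 <= self.shift_group_index < self.n_groups):
            raise ContractError("shift_group_index out of range")

    @property
    def group_labels(self) -> list:
        labels = list(DIET_LABELS[: self.n_groups])
        labels += [f"G{i + 1}" for i in range(len(labels), self.n_groups)]
        return labels


@dataclass
class GroundTruth:
    """Analytic expectations behind one simulated study."""

    group_mean_proportions: pd.DataFrame  # groups x ASVs, rows sum to 1
    expectation: pd.DataFrame  # reactions x mapped ASVs, true E(i, j)
    expected_reaction_abundance: pd.DataFrame  # groups x reactions
    shifted_reactions: dict  # (group1, group2) -> frozenset of reactions
    delta: float

    def __post_init__(self) -> None:
        sums = self.group_mean_proportions.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ContractError("group mean proportions must sum to 1")
        a = self.expected_reaction_abundance.to_numpy()
        if a.size and (a.min() < -1e-12 or a.max() > 1 + 1e-12):
            raise ContractError("expected reaction abundances must lie in [0, 1]")

    def shifted_between(self, g1: str, g2: str) -> frozenset:
        return self.shifted_reactions.get((g1, g2)) or self.shifted_reactions.get((g2, g1), frozenset())


# ---------------------------------------------------------------------------
# catalog generation

def _family_name(i: int) -> str:
    return f"Fam{i:02d}aceae"


def _genus_name(fam: int, j: int) -> str:
    return f"Fam{fam:02d}gen{j}"


def _species_name(fam: int, j: int, k: int) -> str:
    return f"Fam{fam:02d}gen{j} sp{k}"


def _family_of(name: str, rank: str) -> str:
    """Recover the family from a synthetic genus/species name.

    Names outside the generator's own convention (hand-built catalogs) get
    a deterministic placeholder family derived from the genus token; the
    upper ranks never participate in matching, which stops at the lowest
    resolved rank.
    """
    if rank == "family":
        return name
    m = _FAM_RE.match(name)
    if m:
        return m.group(1) + "aceae"
    return name.split(" ")[0] + "_family"


def generate_model_catalog(config: SimulationConfig, seed: int | None = None) -> ModelCatalog:
    """Generate a GSMM catalog over a synthetic taxonomy hierarchy.

    Families host several genera and species, and model ranks are mixed,
    so that multiple models share a genus or family and the expectation
    matrix takes values strictly between 0 and 1. A configurable core
    fraction of reactions is present in every model (the ubiquitous
    backbone); the rest have per-family inclusion probabilities, making
    reaction prevalence vary across taxa. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_fam = max(3, config.n_models // 8)
    genera = {}  # family index -> list of genus indices
    species = {}  # (fam, genus) -> list of species indices
    for f in range(1, n_fam + 1):
        genera[f] = list(range(1, int(rng.integers(2, 5)) + 1))
        for g in genera[f]:
            species[(f, g)] = list(range(1, int(rng.integers(1, 4)) + 1))
    reactions = [f"rxn{i + 1:04d}" for i in range(config.n_reactions)]
    subsystem_names = [f"Subsystem{i + 1:02d}" for i in range(config.n_subsystems)]
    # pathways are contiguous reaction blocks, mirroring how reactions of
    # one subsystem tend to be gained or lost together
    sub_of = [i * config.n_subsystems // config.n_reactions for i in range(config.n_reactions)]
    subsystems = {}
    for i, rxn in enumerate(reactions):
        subs = [subsystem_names[sub_of[i]]]
        if rng.random() < 0.1:  # some reactions sit in two pathways
            extra = subsystem_names[int(rng.integers(config.n_subsystems))]
            if extra not in subs:
                subs.append(extra)
        subsystems[rxn] = tuple(subs)
    # inclusion probabilities act at the (pathway, family) level: the first
    # subsystems form a near-ubiquitous core backbone, the rest are
    # accessory pathways present or absent largely as a unit per family;
    # per-reaction jitter keeps the content imperfectly modular
    n_core_subs = int(round(config.core_reaction_fraction * config.n_subsystems))
    n_acc = config.n_subsystems - n_core_subs
    # accessory pathway prevalence is mostly shared across families, with
    # sparse family-specific deviations — so a compositional shift of one
    # taxon stands out in the few pathways where its family is distinctive
    acc = np.tile(rng.uniform(0.05, 0.95, size=(n_acc, 1)), (1, n_fam))
    dev = rng.random((n_acc, n_fam)) < 0.2
    acc[dev] = rng.uniform(0.05, 0.95, size=int(dev.sum()))
    base = np.vstack([rng.uniform(0.85, 1.0, size=(n_core_subs, n_fam)), acc])
    q = np.clip(base[sub_of, :] + rng.normal(0, 0.05, size=(config.n_reactions, n_fam)),
                0.02, 1.0)
    models = []
    for m in range(config.n_models):
        rank = ("species", "genus", "family")[rng.choice(3, p=[0.2, 0.45, 0.35])]
        f = int(rng.integers(1, n_fam + 1))
        if rank == "family":
            name = _family_name(f)
        elif rank == "genus":
            name = _genus_name(f, int(rng.choice(genera[f])))
        else:
            g = int(rng.choice(genera[f]))
            name = _species_name(f, g, int(rng.choice(species[(f, g)])))
        keep = rng.random(config.n_reactions) < q[:, f - 1]
        content = {r for r, k in zip(reactions, keep) if k}
        if not content:
            content.add(reactions[int(rng.integers(config.n_reactions))])
        models.append(Model(model_id=f"model{m + 1:03d}", rank=rank, name=name,
                            reactions=frozenset(content)))
    # guarantee at least one genus shared by two models when possible
    genus_models = [m for m in models if m.rank == "genus"]
    if len(genus_models) >= 2 and len({m.name for m in genus_models}) == len(genus_models):
        i = models.index(genus_models[1])
        models[i] = Model(model_id=genus_models[1].model_id, rank="genus",
                          name=genus_models[0].name, reactions=genus_models[1].reactions)
    return ModelCatalog(models=models, subsystems=subsystems)


# ---------------------------------------------------------------------------
# community generation

def _catalog_names(catalog: ModelCatalog) -> dict:
    out = {r: sorted({m.name for m in catalog.models if m.rank == r}) for r in MODEL_RANKS}
    return out


def _lineage_for(rank: str, name: str) -> dict:
    """Build a full lineage dict for a synthetic taxon, truncated at ``rank``."""
    fam = _family_of(name, rank) if rank in MODEL_RANKS else None
    if fam is not None:
        m = _FAM_RE.match(fam)
        fam_idx = int(m.group(1)[3:]) if m else 1 + sum(fam.encode()) % 20
    else:
        fam_idx = None
    lineage = dict.fromkeys(RANKS)
    lineage["domain"] = "Bacteria"
    if rank == "above_family":
        idx = int(name[5:]) if name.startswith("Order") else 1
        lineage.update(phylum=f"Phylum{(idx - 1) % 4 + 1}", **{"class": f"Class{(idx - 1) % 4 + 1}"})
        lineage["order"] = name
        return lineage
    lineage.update(
        phylum=f"Phylum{(fam_idx - 1) % 4 + 1}",
        **{"class": f"Class{(fam_idx - 1) % 4 + 1}"},
        order=f"Order{fam_idx:02d}",
        family=fam,
    )
    if rank in ("genus", "species"):
        lineage["genus"] = name.split(" ")[0]
    if rank == "species":
        lineage["species"] = name
    return lineage


def _coalescent_tree(asv_ids: list, rng: np.random.Generator) -> PhyloTree:
    """Random binary coalescent-style tree with exponential branch lengths."""
    nodes = [TreeNode(name=a, length=float(rng.exponential(0.5))) for a in asv_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(0.5)), children=[a, b])
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return PhyloTree(root)


def _brute_force_expectation(taxonomy: TaxonomyTable, catalog: ModelCatalog) -> pd.DataFrame:
    """True E(i, j) by exhaustive per-rank scan over the raw model list.

    Deliberately loop-based and independent of the mapping module: for
    each ASV the catalog is scanned rank by rank (species, genus, family)
    for name-equal models, and occurrence frequencies are counted by hand.
    """
    matched: dict = {}
    for asv in taxonomy.asv_ids:
        row = taxonomy.assignments.loc[asv]
        for rank in ("species", "genus", "family"):
            if row[rank] is None:
                continue
            hits = []
            for m in catalog.models:
                if m.rank == rank and normalize_taxon_name(m.name) == normalize_taxon_name(row[rank]):
                    hits.append(m)
            if hits:
                matched[asv] = hits
                break
    reactions = sorted({r for hits in matched.values() for m in hits for r in m.reactions})
    data = {}
    for asv, hits in matched.items():
        col = []
        for rxn in reactions:
            col.append(sum(1 for m in hits if rxn in m.reactions) / len(hits))
        data[asv] = col
    return pd.DataFrame(data, index=reactions)


def ground_truth_reaction_means(
    group_mean_proportions, expectation: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Expected per-group reaction abundances by direct double summation.

    For each group, a_r(i) = sum_j w_j E(i,j) / sum_j w_j over the mapped
    ASVs with true mean proportions w. Written as explicit loops — the
    brute-force oracle kept separate from the vectorized pipeline path.
    Accepts either a :class:`GroundTruth` or the two frames directly.
    """
    if isinstance(group_mean_proportions, GroundTruth):
        truth = group_mean_proportions
        group_mean_proportions = truth.group_mean_proportions
        expectation = truth.expectation
    mapped = [a for a in expectation.columns if a in group_mean_proportions.columns]
    rows = {}
    for g in group_mean_proportions.index:
        denom = 0.0
        for a in mapped:
            denom += group_mean_proportions.loc[g, a]
        vals = []
        for rxn in expectation.index:
            num = 0.0
            for a in mapped:
                num += group_mean_proportions.loc[g, a] * expectation.loc[rxn, a]
            vals.append(num / denom if denom > 0 else 0.0)
        rows[g] = vals
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(expectation.index))


def _draw_counts(
    config: SimulationConfig,
    mean_props: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dirichlet-multinomial draw of counts for every group and sample."""
    rows, meta_rows, ids = [], [], []
    for g in mean_props.index:
        alpha = config.concentration * mean_props.loc[g].to_numpy()
        for k in range(config.samples_per_group):
            if config.depth_dispersion > 0:
                cv = config.depth_dispersion
                sigma = np.sqrt(np.log(1 + cv**2))
                mu = np.log(config.depth_mean) - sigma**2 / 2
                depth = max(1, int(round(rng.lognormal(mu, sigma))))
            else:
                depth = config.depth_mean
            p = rng.dirichlet(alpha)
            rows.append(rng.multinomial(depth, p))
            ids.append(f"{g}_{k + 1:02d}")
            meta_rows.append((g, "digesta"))
    counts = pd.DataFrame(rows, index=ids, columns=list(mean_props.columns))
    meta = pd.DataFrame(meta_rows, index=ids, columns=["group", "sample_type"])
    return counts, meta


def generate_community(
    config: SimulationConfig, catalog: ModelCatalog, seed: int | None = None
) -> tuple[AsvCountTable, TaxonomyTable, SampleMetadata, PhyloTree, GroundTruth]:
    """Generate one full synthetic study around a catalog.

    Taxonomic resolution is assigned per ASV by truncating a lineage drawn
    from the catalog's hierarchy at the configured rank, so a known
    fraction is unmappable. Group 0 is the reference composition; the
    group at ``shift_group_index`` has the planted fold changes applied to
    its mean proportions and renormalized; all other groups equal the
    reference (null comparisons). Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    names = _catalog_names(catalog)
    n = config.n_asvs
    n_sp = int(round(config.frac_species * n))
    n_ge = int(round(config.frac_genus * n))
    n_fa = int(round(config.frac_family * n))
    n_ab = n - n_sp - n_ge - n_fa
    ranks = ["species"] * n_sp + ["genus"] * n_ge + ["family"] * n_fa + ["above_family"] * n_ab
    rng.shuffle(ranks)
    asv_ids = [f"ASV_{i + 1:04d}" for i in range(n)]
    lineages = []
    for rank in ranks:
        r = rank
        # fall back to a coarser rank when the catalog has no names at r
        while r in MODEL_RANKS and not names[r]:
            r = {"species": "genus", "genus": "family", "family": "above_family"}[r]
        if r == "above_family":
            name = f"Order{int(rng.integers(1, 30)):02d}"
        else:
            name = str(rng.choice(names[r]))
        lineages.append(_lineage_for(r if r in MODEL_RANKS else "above_family", name))
    taxonomy = TaxonomyTable(pd.DataFrame(lineages, index=asv_ids)[list(RANKS)])

    base = rng.lognormal(0.0, 1.5, size=n)
    base /= base.sum()
    labels = config.group_labels
    props = {g: base.copy() for g in labels}
    bad = [a for a in config.planted_shift if a not in set(asv_ids)]
    if bad:
        raise ContractError(f"planted ASVs not in the table: {bad}")
    if config.planted_shift and config.n_groups > 1:
        shifted = props[labels[config.shift_group_index]]
        for a, fold in config.planted_shift.items():
            shifted[asv_ids.index(a)] *= fold
        shifted /= shifted.sum()
    mean_props = pd.DataFrame(props, index=asv_ids).T.loc[labels]

    counts, meta = _draw_counts(config, mean_props, rng)
    table = AsvCountTable(counts)
    metadata = SampleMetadata(meta)
    tree = _coalescent_tree(asv_ids, rng)

    expectation = _brute_force_expectation(taxonomy, catalog)
    expected = ground_truth_reaction_means(mean_props, expectation)
    shifted_reactions = {}
    for i, g1 in enumerate(labels):
        for g2 in labels[i + 1:]:
            diff = (expected.loc[g1] - expected.loc[g2]).abs()
            shifted_reactions[(g1, g2)] = frozenset(diff.index[diff >= config.delta])
    truth = GroundTruth(
        group_mean_proportions=mean_props,
        expectation=expectation,
        expected_reaction_abundance=expected,
        shifted_reactions=shifted_reactions,
        delta=config.delta,
    )
    return table, taxonomy, metadata, tree, truth


def resample_counts(
    config: SimulationConfig, truth: GroundTruth, seed: int
) -> tuple[AsvCountTable, SampleMetadata]:
    """Redraw only the count table from an existing ground truth.

    The catalog, taxonomy, and mean compositions stay fixed; counts are a
    fresh Dirichlet-multinomial draw. This is the cheap path for
    replicated simulations (null calibration, power studies).
    """
    rng = np.random.default_rng(seed)
    counts, meta = _draw_counts(config, truth.group_mean_proportions, rng)
    return AsvCountTable(counts), SampleMetadata(meta)


def ground_truth_to_json(truth: GroundTruth, path) -> None:
    """Serialize a GroundTruth to JSON (CLI `simulate` output)."""
    data = {
        "delta": truth.delta,
        "group_mean_proportions": {
            g: truth.group_mean_proportions.loc[g].to_dict()
            for g in truth.group_mean_proportions.index
        },
        "expectation": {
            a: truth.expectation[a].to_dict() for a in truth.expectation.columns
        },
        "expected_reaction_abundance": {
            g: truth.expected_reaction_abundance.loc[g].to_dict()
            for g in truth.expected_reaction_abundance.index
        },
        "shifted_reactions": {
            f"{g1}|{g2}": sorted(v) for (g1, g2), v in truth.shifted_reactions.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(data, fh)
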