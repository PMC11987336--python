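"""Synthetic reaction datasets for desk-scale testing and experiments.

Records are built by template joins of a small fragment library so each
reactant's core fragment literally appears as a substructure of the
product. That gives contrastive training recoverable structure: the product
graph is a deterministic composition of the reactant cores. Fragments are
written attachment-atom-first so plain string composition yields valid
SMILES. Records carry 1-5 reactants, exactly one product, optional reagents
and optional yield/temperature attributes, mirroring the shape of large
patent-derived reaction sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .reaction_io import ReactionRecord, canonicalize_smiles
from .search import QuerySpec

__all__ = [
    "FixtureConfig",
    "FragmentLibrary",
    "generate_fragment_library",
    "generate_reactions",
    "generate_query_set",
    "generate_splits",
]

# attachment-atom-first cores; halogen-bearing subset tagged below
_PLAIN_CORES = [
    "C",
    "CC",
    "CCC",
    "CCCC",
    "C(C)C",
    "CCOC",
    "CC(C)C",
    "CCN(C)C",
    "c1ccccc1",
    "Cc1ccccc1",
    "c1ccc(C)cc1",
    "c1ccco1",
    "c1ccncc1",
    "C1CCCCC1",
    "CC#N",
    "CCCCCC",
    "CCCCCCCC",
    "CCCCCCCCCC",
    "CCc1ccccc1",
    "CCCCc1ccccc1",
]
_HALO_CORES = [
    "CCF",
    "CCCl",
    "CCBr",
    "CCI",
    "C(F)(F)F",
    "c1ccc(F)cc1",
    "c1ccc(Cl)cc1",
    "c1ccc(Br)cc1",
    "c1ccc(I)cc1",
    "Cc1ccc(Cl)cc1",
    "CCCCCCCl",
    "CCCCCCCCBr",
    "CCc1ccc(Cl)cc1",
    "CCCCc1ccc(F)cc1",
]
_REAGENTS = ["O", "CO", "CS(C)=O", "c1ccncc1", "CCN(CC)CC", "[Na+]", "[Pd]"]


@dataclass
class FragmentLibrary:
    plain: list[str]
    halogenated: list[str]
    reagents: list[str]

    @property
    def all_cores(self) -> list[str]:
        return self.plain + self.halogenated


def generate_fragment_library(seed: int = 0) -> FragmentLibrary:
    """Deterministic fragment library; the seed shuffles presentation order."""
    rng = np.random.default_rng(seed)
    plain = [s for s in _PLAIN_CORES if Chem.MolFromSmiles(s) is not None]
    halo = [s for s in _HALO_CORES if Chem.MolFromSmiles(s) is not None]
    rng.shuffle(plain)
    rng.shuffle(halo)
    return FragmentLibrary(plain=plain, halogenated=halo, reagents=list(_REAGENTS))


@dataclass
class FixtureConfig:
    n_reactions: int = 2000
    seed: int = 0
    reactant_count_range: tuple[int, int] = (1, 5)
    halogen_rate: float = 0.4
    reagent_rate: float = 0.3
    attribute_spec: dict = field(
        default_factory=lambda: {
            "yield": {"dist": "uniform", "lo": 30.0, "hi": 100.0, "rate": 0.8},
            "temperature": {"dist": "normal", "mean": 80.0, "sd": 20.0, "rate": 0.7},
        }
    )

    def __post_init__(self):
        if self.n_reactions <= 0:
            raise ValueError("n_reactions must be positive")
        lo, hi = self.reactant_count_range
        if not 1 <= lo <= hi <= 5:
            raise ValueError("reactant counts must stay within [1, 5]")
        for rate in (self.halogen_rate, self.reagent_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def _compose(cores: list[str], kind: str) -> tuple[list[str], str]:
    """Return (reactant SMILES list, product SMILES) for a template join."""
    if kind == "dehalogenation":
        (s,) = cores
        return [f"Cl{s}"], s
    if kind == "ester":
        s1, s2 = cores
        return [f"OC(=O){s1}", f"O{s2}"], f"O=C({s1})O{s2}"
    if kind == "amide":
        s1, s2 = cores
        return [f"OC(=O){s1}", f"N{s2}"], f"O=C({s1})N{s2}"
    if kind == "ether":
        s1, s2 = cores
        return [f"O{s1}", f"Cl{s2}"], f"O({s1}){s2}"
    if kind == "amine":
        s1, s2, s3 = cores
        return [f"N{s1}", f"Cl{s2}", f"Cl{s3}"], f"N({s1})({s2}){s3}"
    if kind == "quaternary":
        head, *rest = cores
        reactants = ["C"] + [f"Cl{s}" for s in rest]
        branches = "".join(f"({s})" for s in rest[:-1])
        return reactants, f"C{branches}{rest[-1]}"
    raise ValueError(kind)


_TWO_REACTANT_KINDS = ["ester", "amide", "ether"]
_COUNT_WEIGHTS = {1: 0.15, 2: 0.5, 3: 0.2, 4: 0.1, 5: 0.05}


def generate_reactions(config: FixtureConfig) -> list[ReactionRecord]:
    """Generate valid single-product records from template couplings.

    Every record's meta carries ``cores`` (the "."-joined canonical core
    fragments) and ``template``. The generated set is guaranteed to contain
    both satisfying and violating records for each preference scenario
    (halogen presence, reactant count of two, high/low product-reactant
    similarity); curated records are substituted into the tail if a class
    is missing at small n.
    """
    from .evaluation import halogen_set, max_tanimoto  # local import: no cycle at load

    library = generate_fragment_library(config.seed)
    rng = np.random.default_rng(config.seed)
    lo, hi = config.reactant_count_range
    counts = [c for c in range(lo, hi + 1)]
    weights = np.array([_COUNT_WEIGHTS[c] for c in counts])
    weights = weights / weights.sum()

    def pick_core() -> str:
        pool = (
            library.halogenated
            if rng.random() < config.halogen_rate
            else library.plain
        )
        return pool[rng.integers(len(pool))]

    records: list[ReactionRecord] = []
    for i in range(config.n_reactions):
        n_react = int(rng.choice(counts, p=weights))
        if n_react == 1:
            kind, n_cores = "dehalogenation", 1
        elif n_react == 2:
            kind, n_cores = _TWO_REACTANT_KINDS[rng.integers(3)], 2
        elif n_react == 3:
            kind, n_cores = "amine", 3
        else:
            kind, n_cores = "quaternary", n_react - 1
        cores = [pick_core() for _ in range(n_cores)]
        if kind == "quaternary":
            cores = ["C"] + cores
        reactants, product = _compose(cores, kind)
        reagents = []
        if rng.random() < config.reagent_rate:
            n_reagents = int(rng.integers(1, 3))
            reagents = list(
                rng.choice(library.reagents, size=n_reagents, replace=False)
            )
        attributes = {}
        for name, spec in config.attribute_spec.items():
            if rng.random() >= spec.get("rate", 1.0):
                continue
            if spec["dist"] == "uniform":
                attributes[name] = round(float(rng.uniform(spec["lo"], spec["hi"])), 1)
            else:
                attributes[name] = round(float(rng.normal(spec["mean"], spec["sd"])), 1)
        core_list = (
            cores[1:] if kind == "quaternary" else cores
        )  # drop the methane head; its core is trivially present
        records.append(
            ReactionRecord(
                record_id=f"fx{config.seed}_{i}",
                product=canonicalize_smiles(product),
                reactants=[canonicalize_smiles(s) for s in reactants],
                reagents=[canonicalize_smiles(s) for s in reagents],
                attributes=attributes,
                meta={
                    "template": kind,
                    "cores": ".".join(canonicalize_smiles(s) for s in core_list),
                },
            )
        )

    _ensure_scenario_diversity(records, config.seed)
    return records


def _curated(seed: int, tag: str, kind: str, cores: list[str]) -> ReactionRecord:
    reactants, product = _compose(cores, kind)
    return ReactionRecord(
        record_id=f"fx{seed}_{tag}",
        product=canonicalize_smiles(product),
        reactants=[canonicalize_smiles(s) for s in reactants],
        meta={"template": kind, "cores": ".".join(canonicalize_smiles(s) for s in cores)},
    )


def _ensure_scenario_diversity(records: list[ReactionRecord], seed: int) -> None:
    """Guarantee both +1 and -1 records for every preference scenario.

    Each scenario predicate (product halogen set, reactant count of two,
    product-reactant Tanimoto above 0.5) needs satisfying and violating
    records. When a side is missing (possible at very small n), tail records
    are replaced with curated template records covering it.
    """
    from .evaluation import halogen_set, max_tanimoto  # local import: no cycle at load

    checks = {
        "halogen": lambda r: bool(halogen_set(r.product)),
        "two-reactants": lambda r: len(r.reactants) == 2,
        "tanimoto": lambda r: max_tanimoto(r.product, r.reactants) > 0.5,
    }
    fixes = {
        # (record making the predicate True, record making it False)
        "halogen": (
            _curated(seed, "haloT", "ester", ["CCCl", "CC"]),
            _curated(seed, "haloF", "ester", ["CC", "CCC"]),
        ),
        "two-reactants": (
            _curated(seed, "twoT", "ether", ["CC", "CCC"]),
            _curated(seed, "twoF", "amine", ["CC", "CCC", "C"]),
        ),
        "tanimoto": (
            _curated(seed, "simT", "dehalogenation", ["CCCCCCCCCC"]),
            _curated(seed, "simF", "ester", ["C", "CC"]),
        ),
    }
    slot = len(records) - 1
    for name, pred in checks.items():
        flags = [pred(r) for r in records]
        for want, fix in ((True, fixes[name][0]), (False, fixes[name][1])):
            if want not in flags:
                if slot < 0:
                    raise RuntimeError("dataset too small to cover all scenarios")
                records[slot] = fix
                slot -= 1
    for name, pred in checks.items():
        flags = [pred(r) for r in records]
        if not (any(flags) and not all(flags)):
            raise RuntimeError(f"could not establish {name} diversity")


def generate_query_set(
    dataset: list[ReactionRecord],
    n: int,
    query_type: str = "product_only",
    seed: int = 0,
    K: int = 30,
) -> list[QuerySpec]:
    """Sample n queries from held-out records (product-only or full)."""
    if query_type not in {"product_only", "product_and_reactants"}:
        raise ValueError(f"unknown query type {query_type!r}")
    if n > len(dataset):
        raise ValueError("cannot sample more queries than records")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(dataset), size=n, replace=False)
    queries = []
    for i in picks:
        record = dataset[i]
        queries.append(
            QuerySpec(
                product=record.product,
                reactants=(
                    list(record.reactants)
                    if query_type == "product_and_reactants"
                    else None
                ),
                match_mode="similarity",
                K=K,
            )
        )
    return queries


def generate_splits(
    config: FixtureConfig, n_val: int = 200, n_test: int = 200
) -> tuple[list[ReactionRecord], list[ReactionRecord], list[ReactionRecord]]:
    """Train/val/test fixture splits from disjoint seeds."""
    make = lambda n, seed_offset: generate_reactions(
        FixtureConfig(
            n_reactions=n,
            seed=config.seed + seed_offset,
            reactant_count_range=config.reactant_count_range,
            halogen_rate=config.halogen_rate,
            reagent_rate=config.reagent_rate,
            attribute_spec=config.attribute_spec,
        )
    )
    return make(config.n_reactions, 0), make(n_val, 1), make(n_test, 2)
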