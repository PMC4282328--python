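"""Synthetic taxonomies, reference sets, and query sets.

The generator grows a ranked taxonomy (orders → families → genera →
species) under a fixed kingdom/phylum/class spine and evolves sequences
down it: a root ancestor is drawn uniformly over {A,C,G,T} and every child
taxon's ancestor derives from its parent's by independent per-site
substitution (to a uniformly chosen different base — a Jukes–Cantor-like
model with no indels, which suits an alignment-free k-mer classifier).
Leaf sequences derive from species ancestors at the within-species rate.

Query sets are *new* draws from existing species — never copies of training
sequences — optionally mixed with queries from novel taxa that are simulated
but withheld from the reference, emulating the common field situation where
a whole group is absent from public databases.  Novel taxa live in their own
withheld orders, so they are unrepresented at every rank below class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .reference import TrainingSet
from .taxonomy import Lineage, ReferenceRecord, build_tree

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Fixed spine above the simulated orders.
_SPINE = (("kingdom", "Animalia"), ("phylum", "Arthropoda"), ("class", "Insecta"))


@dataclass(frozen=True)
class SimParams:
    """Shape and divergence of the simulated reference database.

    Defaults give a 5x2x3x3x2 taxonomy (180 sequences) of 650 nt barcodes —
    full-length COI scale — with 12% per-site divergence between genera and
    2% within genera, a regime where genus assignment should be easy at full
    length and degrade for short fragments.
    """

    n_orders: int = 5
    families_per_order: int = 2
    genera_per_family: int = 3
    species_per_genus: int = 3
    sequences_per_species: int = 2
    seq_length: int = 650
    inter_genus_divergence: float = 0.12
    intra_genus_divergence: float = 0.02
    intra_species_divergence: float = 0.005
    inter_order_divergence: float | None = None  # default: inter-genus rate
    inter_family_divergence: float | None = None  # default: inter-genus rate
    novel_taxon_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (
            "n_orders",
            "families_per_order",
            "genera_per_family",
            "species_per_genus",
            "sequences_per_species",
            "seq_length",
        ):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")
        for f in (
            "inter_genus_divergence",
            "intra_genus_divergence",
            "intra_species_divergence",
        ):
            if not (0 <= getattr(self, f) < 1):
                raise ValueError(f"{f} must be in [0, 1)")
        if not (0 <= self.novel_taxon_fraction <= 1):
            raise ValueError("novel_taxon_fraction must be in [0, 1]")

    @property
    def order_rate(self) -> float:
        return (
            self.inter_order_divergence
            if self.inter_order_divergence is not None
            else self.inter_genus_divergence
        )

    @property
    def family_rate(self) -> float:
        return (
            self.inter_family_divergence
            if self.inter_family_divergence is not None
            else self.inter_genus_divergence
        )


@dataclass(frozen=True)
class LabeledQuery:
    id: str
    sequence: str
    lineage: Lineage  # truth, down to species
    novel: bool  # true taxon absent from the paired reference


@dataclass(frozen=True)
class LabeledQuerySet:
    queries: tuple[LabeledQuery, ...]

    def __len__(self) -> int:
        return len(self.queries)

    def __iter__(self):
        return iter(self.queries)


def _random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(parent: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution at `rate`, always to a *different* base."""
    child = parent.copy()
    mask = rng.random(parent.size) < rate
    n_mut = int(mask.sum())
    if n_mut:
        # shift by 1..3 positions in base order: uniform over the other three
        shift = rng.integers(1, 4, size=n_mut)
        idx = np.searchsorted(_BASES, child[mask])
        child[mask] = _BASES[(idx + shift) % 4]
    return child


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


class Simulator:
    """Deterministic world of ancestors: reference taxa plus a withheld
    novel clade, all derived from ``params.seed``."""

    def __init__(self, params: SimParams):
        self.params = params
        rng = np.random.default_rng(params.seed)
        p = params
        self.root_seq = _random_sequence(p.seq_length, rng)
        # species ancestors keyed by lineage (order, family, genus, species)
        self.species_anc: dict[tuple[str, str, str, str], np.ndarray] = {}
        self.novel_species_anc: dict[tuple[str, str, str, str], np.ndarray] = {}

        def grow(order_name: str, store: dict) -> None:
            order_anc = _mutate(self.root_seq, p.order_rate, rng)
            for fi in range(p.families_per_order):
                fam = f"Fam_{order_name}_{fi + 1:02d}"
                fam_anc = _mutate(order_anc, p.family_rate, rng)
                for gi in range(p.genera_per_family):
                    gen = f"Gen_{order_name}_{fi + 1:02d}_{gi + 1:02d}"
                    gen_anc = _mutate(fam_anc, p.inter_genus_divergence, rng)
                    for si in range(p.species_per_genus):
                        sp = f"{gen}_s{si + 1:02d}"
                        store[(order_name, fam, gen, sp)] = _mutate(
                            gen_anc, p.intra_genus_divergence, rng
                        )

        for oi in range(p.n_orders):
            grow(f"Ord{oi + 1:02d}", self.species_anc)
        # withheld clade, generated unconditionally so the world is the same
        # whether or not novel queries are requested
        for oi in range(p.n_orders):
            grow(f"NovOrd{oi + 1:02d}", self.novel_species_anc)

    def _lineage(self, key: tuple[str, str, str, str]) -> Lineage:
        order, fam, gen, sp = key
        return Lineage(
            _SPINE
            + (("order", order), ("family", fam), ("genus", gen), ("species", sp))
        )

    def training_set(self) -> TrainingSet:
        """Leaf sequences for every reference species; genus-trained."""
        p = self.params
        rng = np.random.default_rng(np.random.SeedSequence([p.seed, 2]))
        records: list[ReferenceRecord] = []
        for key in sorted(self.species_anc):
            anc = self.species_anc[key]
            for i in range(p.sequences_per_species):
                seq = _to_str(_mutate(anc, p.intra_species_divergence, rng))
                records.append(
                    ReferenceRecord(f"ref_{key[3]}_{i + 1:02d}", seq, self._lineage(key))
                )
        return TrainingSet(tuple(records), build_tree(records), "genus")

    def make_queries(
        self,
        n_queries: int,
        novel_fraction: float | None = None,
        fragment_length: int | None = None,
        seed: int | None = None,
    ) -> LabeledQuerySet:
        """Fresh query draws: known species plus a novel-taxon fraction.

        Known queries are new sequences evolved from reference species
        ancestors at the within-species rate; novel queries come from the
        withheld clade.  Fragments are sampled as uniform contiguous windows.
        """
        p = self.params
        if novel_fraction is None:
            novel_fraction = p.novel_taxon_fraction
        rng = np.random.default_rng(
            np.random.SeedSequence([p.seed if seed is None else seed, 3])
        )
        n_novel = round(n_queries * novel_fraction)
        known_keys = sorted(self.species_anc)
        novel_keys = sorted(self.novel_species_anc)
        queries: list[LabeledQuery] = []
        for i in range(n_queries):
            novel = i < n_novel
            pool, store = (
                (novel_keys, self.novel_species_anc)
                if novel
                else (known_keys, self.species_anc)
            )
            key = pool[int(rng.integers(0, len(pool)))]
            seq = _to_str(_mutate(store[key], p.intra_species_divergence, rng))
            if fragment_length is not None:
                seq = sample_fragment(seq, fragment_length, rng)
            queries.append(
                LabeledQuery(f"q{i + 1:04d}_{key[3]}", seq, self._lineage(key), novel)
            )
        return LabeledQuerySet(tuple(queries))


def simulate_reference(params: SimParams) -> TrainingSet:
    """Simulated genus-trained reference database (see :class:`Simulator`)."""
    return Simulator(params).training_set()


def make_queries(
    params: SimParams,
    n_queries: int,
    novel_fraction: float | None = None,
    fragment_length: int | None = None,
) -> LabeledQuerySet:
    """Query set paired with ``simulate_reference(params)``."""
    return Simulator(params).make_queries(
        n_queries, novel_fraction=novel_fraction, fragment_length=fragment_length
    )


def sample_fragment(sequence: str, length: int, rng: np.random.Generator) -> str:
    """Contiguous window of `length` nt with a uniform random start."""
    L = len(sequence)
    if length > L:
        raise ValueError(f"fragment length {length} exceeds sequence length {L}")
    start = int(rng.integers(0, L - length + 1))
    return sequence[start : start + length]
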