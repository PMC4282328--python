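"""Reference-database curation: record screening and training-set assembly.

Candidate annotated sequences are screened with the filters used to build
curated COI training sets: minimum length 500 nt, no missing data (N), no
nucleotide ambiguity codes, optionally a fully identified species name
(names containing tokens such as "sp." or "cf." mark insufficiently
identified records), and a named taxon at the trained rank.  Duplicate
sequences for the same taxon are retained to preserve within-species
variation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .taxonomy import (
    DEFAULT_RANKS,
    Lineage,
    ReferenceRecord,
    TaxonomyError,
    TaxonomyTree,
    build_tree,
    is_placeholder,
    normalize_sequence,
    placeholder_for,
)

#: Name tokens that mark a record as not fully identified to species rank.
DEFAULT_NAME_EXCLUSION_TERMS: tuple[str, ...] = ("sp.", "nr.", "aff.", "cf.")

#: Reject reason codes, in the order the rules are applied.
REASONS: tuple[str, ...] = (
    "too_short",
    "has_N",
    "has_ambiguity",
    "insufficient_name",
    "missing_rank",
)

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class FilterPolicy:
    """Screening rules for candidate reference sequences.

    ``require_full_species_name`` mirrors the genus-trained curation, which
    drops insufficiently identified names; a family-trained set permits them
    to retain as many records as possible.
    """

    min_length: int = 500
    forbid_N: bool = True
    forbid_ambiguity: bool = True
    require_full_species_name: bool = True
    trained_rank: str = "genus"
    name_exclusion_terms: tuple[str, ...] = DEFAULT_NAME_EXCLUSION_TERMS

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.trained_rank not in ("genus", "family"):
            raise ValueError("trained_rank must be 'genus' or 'family'")

    @classmethod
    def genus_trained(cls, **kw) -> "FilterPolicy":
        return cls(trained_rank="genus", require_full_species_name=True, **kw)

    @classmethod
    def family_trained(cls, **kw) -> "FilterPolicy":
        return cls(trained_rank="family", require_full_species_name=False, **kw)


@dataclass(frozen=True)
class Candidate:
    """Raw annotated sequence before screening.

    ``lineage`` maps rank name → taxon name and may be partial; ``name`` is
    the organism name as annotated (e.g. ``"Aedes aegypti"`` or
    ``"Aedes sp. BOLD-1"``).
    """

    id: str
    name: str
    lineage: Mapping[str, str]
    sequence: str


@dataclass
class FilterReport:
    kept: int = 0
    rejected: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return self.kept + sum(self.rejected.values())


@dataclass(frozen=True)
class TrainingSet:
    """Curated records plus their taxonomy; the classifier's reference."""

    records: tuple[ReferenceRecord, ...]
    tree: TaxonomyTree
    trained_rank: str

    def __len__(self) -> int:
        return len(self.records)

    def taxa_at(self, rank: str) -> set[str]:
        return {
            r.lineage.name_at(rank)
            for r in self.records
            if r.lineage.name_at(rank) is not None
        }


def _name_insufficient(name: str, terms: Sequence[str]) -> bool:
    # token equality, not substring match: "Crispa" must not trip on "sp."
    tokens = name.split()
    return any(tok in terms for tok in tokens)


def complete_lineage(
    lineage: Mapping[str, str],
    ranks: Sequence[str] = DEFAULT_RANKS,
    down_to: str | None = None,
) -> Lineage:
    """Fill missing intermediate ranks with ``undef_<parentName>`` placeholders.

    The path runs from the root rank to the deepest named rank (or `down_to`
    if given).  Missing ranks inherit a placeholder named after the
    immediate parent taxon.
    """
    named = {r: n for r, n in lineage.items() if n}
    if not named:
        raise TaxonomyError("candidate lineage has no named ranks")
    if down_to is None:
        down_to = max(named, key=lambda r: ranks.index(r))
    entries: list[tuple[str, str]] = []
    for rank in ranks:
        name = named.get(rank)
        if name is None:
            if not entries:
                raise TaxonomyError("candidate lineage lacks a root-rank name")
            name = placeholder_for(entries[-1][1])
        entries.append((rank, name))
        if rank == down_to:
            break
    return Lineage(tuple(entries))


def enforce_rank_completeness(
    candidate: Candidate,
    trained_rank: str,
    ranks: Sequence[str] = DEFAULT_RANKS,
) -> str | None:
    """Return ``"missing_rank"`` if the trained rank is unnamed, else None.

    A placeholder at the trained rank counts as missing; gaps at more
    inclusive ranks are tolerated (filled with placeholders downstream).
    """
    name = candidate.lineage.get(trained_rank) or None
    if name is None or is_placeholder(name):
        return "missing_rank"
    return None


def screen_record(candidate: Candidate, policy: FilterPolicy) -> str | None:
    """Return None to keep, or the single reject reason code.

    Rules apply in a fixed order (length, N, ambiguity, name terms, rank
    completeness); the first failure wins, making reports deterministic.
    """
    seq = normalize_sequence(candidate.sequence)
    if len(seq) < policy.min_length:
        return "too_short"
    if policy.forbid_N and "N" in seq:
        return "has_N"
    if policy.forbid_ambiguity and (set(seq) - _ACGT - {"N"}):
        return "has_ambiguity"
    if policy.require_full_species_name and _name_insufficient(
        candidate.name, policy.name_exclusion_terms
    ):
        return "insufficient_name"
    return enforce_rank_completeness(candidate, policy.trained_rank)


def build_training_set(
    candidates: Sequence[Candidate],
    policy: FilterPolicy,
    ranks: Sequence[str] = DEFAULT_RANKS,
) -> tuple[TrainingSet, FilterReport]:
    """Screen candidates and assemble a genus- or family-trained set.

    Duplicate sequences for the same taxon are retained (they improve the
    representation of within-species variation).  Kept lineages are
    truncated at the trained rank.
    """
    if not candidates:
        raise TaxonomyError("empty training set")
    report = FilterReport()
    kept: list[ReferenceRecord] = []
    for cand in candidates:
        reason = screen_record(cand, policy)
        if reason is not None:
            report.rejected[reason] += 1
            continue
        report.kept += 1
        lineage = complete_lineage(cand.lineage, ranks, down_to=policy.trained_rank)
        kept.append(
            ReferenceRecord(cand.id, normalize_sequence(cand.sequence), lineage)
        )
    if not kept:
        raise TaxonomyError("empty training set: every candidate was rejected")
    tree = build_tree(kept)
    return TrainingSet(tuple(kept), tree, policy.trained_rank), report


def singleton_census(training_set: TrainingSet, rank: str) -> float:
    """Proportion of taxa at `rank` represented by exactly one sequence."""
    counts = Counter(
        rec.lineage.name_at(rank)
        for rec in training_set.records
        if rec.lineage.name_at(rank) is not None
    )
    if not counts:
        raise ValueError(f"no taxa at rank {rank!r}")
    return sum(1 for c in counts.values() if c == 1) / len(counts)


# ---------------------------------------------------------------------------
# Candidate readers


def candidates_from_tsv(path: str | Path, ranks: Sequence[str] = DEFAULT_RANKS) -> list[Candidate]:
    """Read candidates from a TSV of (id, name, lineage, sequence).

    The lineage column is semicolon-delimited root→leaf with empty slots for
    missing ranks, e.g. ``Metazoa;Arthropoda;Insecta;;Culicidae;Aedes``.
    """
    out: list[Candidate] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise TaxonomyError(f"{path}:{lineno}: expected 4 tab-separated fields")
            ident, name, lineage_text, seq = fields
            names = lineage_text.split(";")
            if len(names) > len(ranks):
                raise TaxonomyError(f"{path}:{lineno}: more lineage names than ranks")
            lineage = {r: n.strip() for r, n in zip(ranks, names) if n.strip()}
            out.append(Candidate(ident, name, lineage, seq))
    return out


def write_filter_report(report: FilterReport, path: str | Path) -> None:
    with open(path, "w", newline="\n") as handle:
        handle.write("outcome\tcount\n")
        handle.write(f"kept\t{report.kept}\n")
        for reason in REASONS:
            handle.write(f"{reason}\t{report.rejected.get(reason, 0)}\n")
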