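"""Reference-based haplotype calling, naming, and tabulation.

Haplotype identity is exact string equality over the full marker window:
a sample sequence either matches a reference haplotype (and inherits its
published name, e.g. ``H1`` for COI or ``h1`` for COII) or is a novel
haplotype and receives a minted name (``N<i>`` / ``n<i>``) in first-
encounter order. No mismatch tolerance and no reverse-complement search
are applied; sequences of differing length are never equated. Per-
individual calls at the two loci are concatenated into combined
haplotype names such as ``H1h1``.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from .seq_io import COI, COII, VALID_BASES, LocusSpec, PopulationMap, SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CatalogConflictError",
    "HaplotypeCatalog",
    "HaplotypeCall",
    "Individual",
    "FrequencyTable",
    "build_catalog",
    "assemble_individuals",
    "combine_calls",
    "tabulate",
    "default_prefixes",
]

#: known/novel name prefixes by locus name.
_PREFIXES = {"COI": ("H", "N"), "COII": ("h", "n")}


def default_prefixes(locus: LocusSpec) -> tuple[str, str]:
    """Return the field's conventional (known, novel) prefixes for a locus."""
    try:
        return _PREFIXES[locus.name]
    except KeyError:
        raise ValueError(f"no default naming prefixes for locus {locus.name!r}")


class CatalogConflictError(ValueError):
    """Two reference entries violate name<->sequence injectivity."""


@dataclass(frozen=True)
class HaplotypeCall:
    individual_id: str
    locus: str
    haplotype_name: str
    status: Literal["known", "novel"]


class HaplotypeCatalog:
    """Bidirectional sequence<->name dictionary for one locus.

    The catalog starts from reference haplotypes (known names) and grows
    as novel haplotypes are minted during calling. Both directions of the
    mapping are injective at all times.
    """

    def __init__(
        self,
        locus: LocusSpec,
        known_prefix: str | None = None,
        novel_prefix: str | None = None,
        next_novel_index: int = 1,
    ):
        if known_prefix is None or novel_prefix is None:
            known_prefix, novel_prefix = default_prefixes(locus)
        self.locus = locus
        self.known_prefix = known_prefix
        self.novel_prefix = novel_prefix
        self.next_novel_index = next_novel_index
        self._by_seq: dict[str, str] = {}
        self._by_name: dict[str, str] = {}
        self._minted: set[str] = set()

    def __len__(self) -> int:
        return len(self._by_seq)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._by_name)

    def sequence(self, name: str) -> str:
        return self._by_name[name]

    def sequences(self) -> Mapping[str, str]:
        """name -> sequence view of the current catalog."""
        return dict(self._by_name)

    def _validate(self, record: SequenceRecord) -> None:
        if record.locus != self.locus.name:
            raise ValueError(
                f"locus mismatch: record is {record.locus}, catalog is {self.locus.name}"
            )
        if len(record.bases) != self.locus.window_length or (
            set(record.bases) - VALID_BASES
        ):
            raise ValueError(
                f"{record.individual_id}: sequence must be QC-accepted "
                f"({self.locus.window_length} bp, A/C/G/T only)"
            )

    def add_reference(self, name: str, sequence: str) -> None:
        """Register a reference haplotype; conflicts are fatal."""
        if name in self._by_name and self._by_name[name] != sequence:
            raise CatalogConflictError(
                f"name {name!r} maps to two distinct sequences"
            )
        if sequence in self._by_seq and self._by_seq[sequence] != name:
            raise CatalogConflictError(
                f"sequence of {name!r} already named {self._by_seq[sequence]!r}"
            )
        self._by_name[name] = sequence
        self._by_seq[sequence] = name

    def call(self, record: SequenceRecord) -> HaplotypeCall:
        """Assign a haplotype name to one QC-accepted sequence.

        Exact full-window identity with a catalog entry returns that name;
        otherwise a new ``novel_prefix + index`` name is minted, stored,
        and reused for every later identical sequence. Deterministic for a
        fixed input order.
        """
        self._validate(record)
        name = self._by_seq.get(record.bases)
        if name is None:
            name = f"{self.novel_prefix}{self.next_novel_index}"
            self.next_novel_index += 1
            self._by_name[name] = record.bases
            self._by_seq[record.bases] = name
            self._minted.add(name)
        status: Literal["known", "novel"] = (
            "novel" if name in self._minted else "known"
        )
        return HaplotypeCall(record.individual_id, self.locus.name, name, status)


def build_catalog(
    reference_records: Sequence[SequenceRecord],
    locus: LocusSpec,
    next_novel_index: int | None = None,
) -> HaplotypeCatalog:
    """Build a catalog from reference haplotypes (names in the headers).

    Exact duplicates (same name, same sequence) collapse; any genuine
    name/sequence conflict raises :class:`CatalogConflictError`. Reference
    sequences shorter than the window, or containing ambiguity codes, are
    excluded with a logged warning — a shorter record of the same gene
    cannot safely be equated with a full-window haplotype. The novel-name
    counter starts past the largest novel index seen among the reference
    names unless ``next_novel_index`` overrides it.
    """
    catalog = HaplotypeCatalog(locus)
    novel_pat = re.compile(rf"^{re.escape(catalog.novel_prefix)}(\d+)$")
    max_novel = 0
    for rec in reference_records:
        seq = rec.bases.upper()
        if len(seq) != locus.window_length or set(seq) - VALID_BASES:
            logger.warning(
                "reference %s excluded from %s catalog (length %d or ambiguity)",
                rec.individual_id,
                locus.name,
                len(seq),
            )
            continue
        catalog.add_reference(rec.individual_id, seq)
        m = novel_pat.match(rec.individual_id)
        if m:
            max_novel = max(max_novel, int(m.group(1)))
    catalog.next_novel_index = (
        next_novel_index if next_novel_index is not None else max_novel + 1
    )
    return catalog


@dataclass
class Individual:
    """Per-individual metadata plus per-locus and combined haplotype names."""

    individual_id: str
    country: str
    region: str
    coi_name: str | None = None
    coii_name: str | None = None
    status_coi: str | None = None
    status_coii: str | None = None
    combined_name: str | None = field(default=None)


class UnknownIndividualError(KeyError):
    pass


def assemble_individuals(
    coi_calls: Iterable[HaplotypeCall],
    coii_calls: Iterable[HaplotypeCall],
    popmap: PopulationMap,
) -> list[Individual]:
    """Join per-locus calls with population metadata.

    Every called individual must appear in the population map. An
    individual may legitimately be called at only one locus; the other
    slot stays ``None``. Output order follows first appearance (COI file
    order, then COII-only individuals).
    """
    by_id: dict[str, Individual] = {}

    def get(ind_id: str) -> Individual:
        if ind_id not in popmap:
            raise UnknownIndividualError(
                f"{ind_id} has sequence data but no population-map entry"
            )
        if ind_id not in by_id:
            by_id[ind_id] = Individual(
                ind_id, popmap.country(ind_id), popmap.region(ind_id)
            )
        return by_id[ind_id]

    for call in coi_calls:
        ind = get(call.individual_id)
        ind.coi_name, ind.status_coi = call.haplotype_name, call.status
    for call in coii_calls:
        ind = get(call.individual_id)
        ind.coii_name, ind.status_coii = call.haplotype_name, call.status
    return list(by_id.values())


def combine_calls(individuals: Sequence[Individual]) -> int:
    """Set combined names (COI name + COII name) where both loci were called.

    Mutates the individuals in place and returns the number of combinable
    individuals (those with both loci present).
    """
    n = 0
    for ind in individuals:
        if ind.coi_name is not None and ind.coii_name is not None:
            ind.combined_name = ind.coi_name + ind.coii_name
            n += 1
        else:
            ind.combined_name = None
    return n


@dataclass(frozen=True)
class FrequencyTable:
    """Haplotype counts per population at one grouping level."""

    counts: Mapping[str, Mapping[str, int]]
    level: Literal["country", "region"]

    def totals(self) -> dict[str, int]:
        return {pop: sum(c.values()) for pop, c in self.counts.items()}

    def percentages(self, ndigits: int = 1) -> dict[str, dict[str, float]]:
        """count / population total x 100, rounded to reporting precision."""
        out: dict[str, dict[str, float]] = {}
        for pop, hap_counts in self.counts.items():
            total = sum(hap_counts.values())
            out[pop] = {
                hap: round(100.0 * c / total, ndigits)
                for hap, c in hap_counts.items()
            }
        return out


def tabulate(
    individuals: Sequence[Individual],
    level: Literal["country", "region"] = "country",
    which: Literal["combined", "coi", "coii"] = "combined",
) -> FrequencyTable:
    """Count haplotypes per population (individuals lacking the name skipped)."""
    if level not in ("country", "region"):
        raise ValueError(f"level must be 'country' or 'region', got {level!r}")
    attr = {"combined": "combined_name", "coi": "coi_name", "coii": "coii_name"}[which]
    counts: dict[str, Counter[str]] = {}
    for ind in individuals:
        name = getattr(ind, attr)
        if name is None:
            continue
        pop = getattr(ind, level)
        counts.setdefault(pop, Counter())[name] += 1
    return FrequencyTable({p: dict(c) for p, c in counts.items()}, level)
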