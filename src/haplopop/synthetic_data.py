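"""Synthetic two-locus haplotype worlds for end-to-end pipeline testing.

A *world* is a designed set of combined (COI+COII) haplotypes laid out
on a mutation tree, a set of populations with fixed haplotype frequency
spectra, and the file artefacts the pipeline consumes: per-locus
reference FASTA (the "previously reported" haplotypes), per-locus
sample FASTA, a population map, and a truth table.

Design choices that make expectations exactly computable:

* every mutation on the tree strikes a globally distinct site, so the
  Hamming distance between any two designed haplotypes is exactly the
  number of steps on the tree path between them (additivity);
* base composition is uniform over A/C/G/T with no substitution model —
  haplotype calling is exact-identity, so the model is irrelevant;
* individuals are assigned to haplotypes deterministically from the
  configured spectra (identity is noiseless, so calling plus tabulation
  must reproduce the spectra exactly).

The default preset (:func:`preset_paper_world`) emulates the structure
of a global invasion survey of the brown marmorated stink bug: three
ancestral combined-haplotype lineages; two native countries (China- and
Japan-like) each sampled in two provinces, with many star-like derived
haplotypes and high haplotype diversity (~0.85-0.95) and no haplotype
sharing between them; seven invaded "group A" countries nearly fixed
for the globally dominant haplotype; and three invaded "group B"
countries segregating 2-3 haplotypes at intermediate frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from .seq_io import (
    COI,
    COII,
    PopulationMap,
    SequenceRecord,
    write_fasta,
    write_popmap,
)

__all__ = [
    "PopulationSpec",
    "SimConfig",
    "SimWorld",
    "generate_world",
    "preset_paper_world",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PopulationSpec:
    """One sampled population: a named site within a country.

    ``spectrum`` maps designed haplotype labels to individual counts;
    its values sum to the population sample size.
    """

    name: str
    country: str
    kind: Literal["native", "invadedA", "invadedB"]
    spectrum: Mapping[str, int]

    @property
    def sample_size(self) -> int:
        return sum(self.spectrum.values())


@dataclass(frozen=True)
class SimConfig:
    """Recipe for a synthetic world.

    ``tree`` lists ``(parent, child, steps)`` edges defining the designed
    haplotypes; the first entry must have ``parent=None`` (the random
    root, steps ignored). ``known`` labels go into the reference FASTA
    (previously reported haplotypes); all others will be called novel.
    """

    seed: int
    tree: tuple[tuple[str | None, str, int], ...]
    populations: tuple[PopulationSpec, ...]
    known: frozenset[str] = frozenset()
    l_coi: int = COI.window_length
    l_coii: int = COII.window_length

    def __post_init__(self) -> None:
        labels = [child for _, child, _ in self.tree]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate haplotype labels in tree")
        if not self.tree or self.tree[0][0] is not None:
            raise ValueError("first tree entry must be the root (parent=None)")
        defined = set(labels)
        for parent, child, steps in self.tree[1:]:
            if parent not in defined:
                raise ValueError(f"edge to {child!r}: undefined parent {parent!r}")
            if steps < 1:
                raise ValueError(f"edge to {child!r}: steps must be >= 1")
        total_steps = sum(s for p, _, s in self.tree if p is not None)
        if total_steps > self.l_coi + self.l_coii:
            raise ValueError("total mutations exceed sequence length")
        unknown = self.known - defined
        if unknown:
            raise ValueError(f"known labels not in tree: {sorted(unknown)}")
        for pop in self.populations:
            missing = set(pop.spectrum) - defined
            if missing:
                raise ValueError(f"{pop.name}: undefined haplotypes {sorted(missing)}")
            if any(c < 1 for c in pop.spectrum.values()):
                raise ValueError(f"{pop.name}: spectrum counts must be positive")


@dataclass(frozen=True)
class SimWorld:
    """A generated world plus its ground truth."""

    config: SimConfig
    haplotype_seqs: Mapping[str, str]  # label -> combined 1175 bp sequence
    coi_reference: Sequence[SequenceRecord]
    coii_reference: Sequence[SequenceRecord]
    coi_samples: Sequence[SequenceRecord]
    coii_samples: Sequence[SequenceRecord]
    popmap: PopulationMap
    truth_assignments: Mapping[str, str]  # individual -> haplotype label
    truth_spectra: Mapping[str, Mapping[str, int]]  # population -> spectrum
    reference_names: Mapping[str, tuple[str, str]] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit all world files into a directory; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "coi_ref": out / "coi_reference.fasta",
            "coii_ref": out / "coii_reference.fasta",
            "coi_seqs": out / "coi_samples.fasta",
            "coii_seqs": out / "coii_samples.fasta",
            "popmap": out / "popmap.tsv",
            "truth": out / "truth.tsv",
        }
        write_fasta(self.coi_reference, paths["coi_ref"])
        write_fasta(self.coii_reference, paths["coii_ref"])
        write_fasta(self.coi_samples, paths["coi_seqs"])
        write_fasta(self.coii_samples, paths["coii_seqs"])
        write_popmap(self.popmap, paths["popmap"])
        with open(paths["truth"], "w") as fh:
            fh.write("individual_id\ttrue_haplotype\n")
            for ind, label in self.truth_assignments.items():
                fh.write(f"{ind}\t{label}\n")
        return paths


def _design_sequences(config: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    total_len = config.l_coi + config.l_coii
    root_label = config.tree[0][1]
    root = rng.choice(_BASES, size=total_len)
    seqs: dict[str, np.ndarray] = {root_label: root}
    site_pool = list(rng.permutation(total_len))
    for parent, child, steps in config.tree[1:]:
        seq = seqs[parent].copy()
        for _ in range(steps):
            site = site_pool.pop()
            alternatives = [b for b in "ACGT" if b != seq[site]]
            seq[site] = alternatives[rng.integers(0, 3)]
        seqs[child] = seq
    return {label: "".join(s) for label, s in seqs.items()}


def generate_world(config: SimConfig) -> SimWorld:
    """Generate a fully reproducible world from a config.

    Identical configs (including seed) yield byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    seqs = _design_sequences(config, rng)
    l_coi = config.l_coi

    # reference FASTA: unique per-locus sequences of the known haplotypes,
    # named H1, H2, ... (COI) / h1, h2, ... (COII) in first-appearance order
    coi_names: dict[str, str] = {}
    coii_names: dict[str, str] = {}
    reference_names: dict[str, tuple[str, str]] = {}
    for label in (child for _, child, _ in config.tree if child in config.known):
        coi_seq, coii_seq = seqs[label][:l_coi], seqs[label][l_coi:]
        if coi_seq not in coi_names:
            coi_names[coi_seq] = f"H{len(coi_names) + 1}"
        if coii_seq not in coii_names:
            coii_names[coii_seq] = f"h{len(coii_names) + 1}"
        reference_names[label] = (coi_names[coi_seq], coii_names[coii_seq])
    coi_reference = [
        SequenceRecord(name, COI.name, seq) for seq, name in coi_names.items()
    ]
    coii_reference = [
        SequenceRecord(name, COII.name, seq) for seq, name in coii_names.items()
    ]

    coi_samples: list[SequenceRecord] = []
    coii_samples: list[SequenceRecord] = []
    popmap_entries: dict[str, tuple[str, str]] = {}
    assignments: dict[str, str] = {}
    spectra: dict[str, dict[str, int]] = {}
    for pop in config.populations:
        spectra[pop.name] = dict(pop.spectrum)
        i = 0
        for label, count in pop.spectrum.items():
            for _ in range(count):
                i += 1
                ind = f"{pop.name}_{i:03d}"
                popmap_entries[ind] = (pop.country, pop.name)
                assignments[ind] = label
                coi_samples.append(SequenceRecord(ind, COI.name, seqs[label][:l_coi]))
                coii_samples.append(
                    SequenceRecord(ind, COII.name, seqs[label][l_coi:])
                )

    return SimWorld(
        config=config,
        haplotype_seqs=seqs,
        coi_reference=coi_reference,
        coii_reference=coii_reference,
        coi_samples=coi_samples,
        coii_samples=coii_samples,
        popmap=PopulationMap(popmap_entries),
        truth_assignments=assignments,
        truth_spectra=spectra,
        reference_names=reference_names,
    )


def _star(parent: str, prefix: str, n: int) -> list[tuple[str, str, int]]:
    # n derived haplotypes, each one step from the shared ancestor
    return [(parent, f"{prefix}{i}", 1) for i in range(1, n + 1)]


def preset_paper_world(seed: int) -> SimWorld:
    """Twelve-country world emulating a global BMSB-style invasion survey.

    Three ancestral combined haplotypes (``anc1`` — the globally dominant
    one, ``anc2`` four steps away, ``anc3`` six further steps) carry
    star-like one-step derivatives. Native countries: China-like
    (provinces Beijing/Hainan, lineages 1 and 2, 26 haplotypes, n=90)
    and Japan-like (provinces Akita/Kyoto, lineage 3, 33 haplotypes,
    n=65), sharing no haplotype. Seven invaded group-A countries are
    (nearly) fixed for ``anc1``; three invaded group-B countries
    segregate 2-3 haplotypes at intermediate frequencies, each with
    haplotype diversity >= 0.5 and nucleotide diversity >= 0.001.
    Total sample size 428 combinable individuals.
    """
    tree: list[tuple[str | None, str, int]] = [
        (None, "anc1", 0),
        ("anc1", "anc2", 4),
        ("anc2", "anc3", 6),
    ]
    tree += _star("anc1", "anc1.b", 9)  # Beijing derivatives
    tree += _star("anc2", "anc2.h", 15)  # Hainan derivatives
    tree += _star("anc3", "anc3.a", 12)  # Akita derivatives
    tree += _star("anc3", "anc3.k", 20)  # Kyoto derivatives
    tree += [("anc2", "aut1", 1), ("anc2", "slo1", 1)]
    # minor group-A haplotypes sit one step off the dominant one, keeping
    # those populations star-like (expansion signature, Fs <= 0)
    tree += [("anc1", "hun1", 1), ("anc1", "hun2", 1), ("anc1", "ita1", 1),
             ("anc1", "chi1", 1)]

    def spec(counts: Sequence[tuple[str, int]]) -> dict[str, int]:
        return dict(counts)

    beijing = spec(
        [("anc1", 25), ("anc1.b1", 6), ("anc1.b2", 4), ("anc1.b3", 3), ("anc1.b4", 2)]
        + [(f"anc1.b{i}", 1) for i in range(5, 10)]
    )
    hainan = spec(
        [("anc2", 13), ("anc2.h1", 10), ("anc2.h2", 5), ("anc2.h3", 3),
         ("anc2.h4", 2), ("anc2.h5", 2)]
        + [(f"anc2.h{i}", 1) for i in range(6, 16)]
    )
    akita = spec(
        [("anc3", 12), ("anc3.a1", 5), ("anc3.a2", 3), ("anc3.a3", 2), ("anc3.a4", 2)]
        + [(f"anc3.a{i}", 1) for i in range(5, 13)]
    )
    kyoto = spec(
        [("anc3.k1", 8), ("anc3.k2", 4), ("anc3.k3", 3), ("anc3.k4", 2)]
        + [(f"anc3.k{i}", 1) for i in range(5, 21)]
    )

    populations = (
        PopulationSpec("Beijing", "China", "native", beijing),
        PopulationSpec("Hainan", "China", "native", hainan),
        PopulationSpec("Akita", "Japan", "native", akita),
        PopulationSpec("Kyoto", "Japan", "native", kyoto),
        PopulationSpec("Maryland", "USA", "invadedA", {"anc1": 24}),
        PopulationSpec("Eki", "Georgia", "invadedA", {"anc1": 31}),
        PopulationSpec("Arhavi", "Turkey", "invadedA", {"anc1": 11}),
        PopulationSpec("Bucharest", "Romania", "invadedA", {"anc1": 23}),
        PopulationSpec(
            "Budapest", "Hungary", "invadedA", {"anc1": 85, "hun1": 4, "hun2": 1}
        ),
        PopulationSpec("Udine", "Italy", "invadedA", {"anc1": 23, "ita1": 1}),
        PopulationSpec("Santiago", "Chile", "invadedA", {"anc1": 30, "chi1": 1}),
        PopulationSpec(
            "Vienna", "Austria", "invadedB", {"anc1": 8, "anc2": 4, "aut1": 3}
        ),
        PopulationSpec("Senta", "Serbia", "invadedB", {"anc1": 5, "anc2": 4}),
        PopulationSpec(
            "Ljubljana", "Slovenia", "invadedB", {"anc1": 10, "anc2": 4, "slo1": 1}
        ),
    )

    known = frozenset(
        {"anc1", "anc2", "anc3", "aut1", "hun1", "hun2", "ita1", "chi1",
         "anc1.b1", "anc1.b2", "anc2.h1", "anc2.h2", "anc3.a1", "anc3.a2"}
    )
    config = SimConfig(
        seed=seed, tree=tuple(tree), populations=populations, known=known
    )
    return generate_world(config)
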