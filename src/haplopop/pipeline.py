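"""End-to-end orchestration: call -> tabulate -> diversity -> AMOVA/F_ST
-> PCoA -> parsimony network, with table-shaped artefacts.

Stages write: ``table1.tsv`` (country-level haplotype percentages, plus
per-locus variants), ``table2.tsv`` (per-region/country/group diversity
and neutrality), ``amova.tsv``, ``fst_matrix.tsv`` / ``fst_pvalues.tsv``,
``pcoa.tsv``, ``network.nex`` (+ edge/node tables) and ``summary.json``.
Identical config and seed give identical artefacts. Any stage failure
aborts the run with a stage-tagged error and removes partial artefacts.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd

from . import differentiation, diversity, ordination, parsimony_network
from .haplotype_catalog import (
    HaplotypeCatalog,
    Individual,
    assemble_individuals,
    build_catalog,
    combine_calls,
    tabulate,
)
from .seq_io import COI, COII, COMBINED, read_fasta, read_popmap, qc_filter

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "RunSummary",
    "PipelineError",
    "run_all",
    "call_and_combine",
    "combined_sequences",
    "assign_genetic_groups",
]


class PipelineError(RuntimeError):
    """A stage failed; the message is tagged with the stage name."""


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs; ``seed`` is mandatory for reproducibility."""

    coi_ref: str | Path
    coii_ref: str | Path
    coi_seqs: str | Path
    coii_seqs: str | Path
    popmap: str | Path
    out_dir: str | Path
    seed: int
    level: Literal["country", "region"] = "country"
    permutations: int = 1000
    fst_permutations: int = 100
    alpha: float = 0.95
    fixed_limit: int | None = None
    hd_threshold: float = 0.5
    pi_threshold: float = 0.001
    native_countries: tuple[str, ...] = ()
    coi_window_start: int = 0
    coii_window_start: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.hd_threshold < 1.0):
            raise ValueError("hd_threshold must be in (0, 1)")
        if not (0.0 < self.pi_threshold < 1.0):
            raise ValueError("pi_threshold must be in (0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class RunSummary:
    """Counts, stage timings and headline results of one pipeline run."""

    n_individuals: int
    n_coi_called: int
    n_coii_called: int
    n_combinable: int
    n_coi_rejected: int
    n_coii_rejected: int
    haplotypes: dict[str, dict[str, int]]  # locus -> {known, novel, total}
    genetic_groups: dict[str, str]
    amova: dict[str, float | None]
    pcoa_percent_variance: list[float]
    connection_limit: int
    n_network_components: int
    timings: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    config: dict[str, object] = field(default_factory=dict)

    def to_json(self) -> str:
        def clean(x):
            if isinstance(x, float) and (math.isnan(x) or math.isinf(x)):
                return None
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [clean(v) for v in x]
            return x

        return json.dumps(clean(self.__dict__), indent=2, default=str)


def assign_genetic_groups(
    stats: Mapping[str, diversity.DiversityStats],
    native: set[str] | frozenset[str],
    hd_threshold: float = 0.5,
    pi_threshold: float = 0.001,
) -> dict[str, str]:
    """Classify populations: native, or invaded group A / group B.

    Invaded populations with haplotype diversity >= ``hd_threshold`` AND
    nucleotide diversity >= ``pi_threshold`` (both boundaries inclusive)
    form group B (multi-haplotype, bottlenecked); the rest form group A
    (near-monomorphic, expanding). Undefined (NaN) diversity counts as
    below threshold.
    """
    out: dict[str, str] = {}
    for pop, st in stats.items():
        if pop in native:
            out[pop] = "native"
        elif (
            not math.isnan(st.hd)
            and not math.isnan(st.pi)
            and st.hd >= hd_threshold
            and st.pi >= pi_threshold
        ):
            out[pop] = "B"
        else:
            out[pop] = "A"
    return out


def call_and_combine(
    coi_reference: Sequence,
    coii_reference: Sequence,
    coi_records: Sequence,
    coii_records: Sequence,
    popmap,
) -> tuple[list[Individual], HaplotypeCatalog, HaplotypeCatalog]:
    """In-memory core of the calling stage.

    Builds both per-locus catalogs from reference records, calls every
    QC-accepted sample record, joins with the population map and sets
    combined names. Returns the individuals and the (grown) catalogs.
    """
    coi_cat = build_catalog(list(coi_reference), COI)
    coii_cat = build_catalog(list(coii_reference), COII)
    coi_calls = [coi_cat.call(r) for r in coi_records]
    coii_calls = [coii_cat.call(r) for r in coii_records]
    individuals = assemble_individuals(coi_calls, coii_calls, popmap)
    combine_calls(individuals)
    return individuals, coi_cat, coii_cat


def combined_sequences(
    individuals: Sequence[Individual],
    coi_cat: HaplotypeCatalog,
    coii_cat: HaplotypeCatalog,
) -> dict[str, str]:
    """combined-name -> concatenated COI+COII sequence for called individuals."""
    return {
        ind.coi_name + ind.coii_name: coi_cat.sequence(ind.coi_name)
        + coii_cat.sequence(ind.coii_name)
        for ind in individuals
        if ind.combined_name is not None
    }


def _hap_counts(individuals: Sequence[Individual]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for ind in individuals:
        if ind.combined_name is not None:
            counts[ind.combined_name] = counts.get(ind.combined_name, 0) + 1
    return counts


def _members(
    individuals: Sequence[Individual], level: str
) -> dict[str, list[str]]:
    members: dict[str, list[str]] = {}
    for ind in individuals:
        if ind.combined_name is None:
            continue
        members.setdefault(getattr(ind, level), []).append(ind.combined_name)
    return members


def _write_wide_percentages(table, path: Path) -> None:
    pct = table.percentages()
    df = pd.DataFrame(pct).T.sort_index()
    df = df[sorted(df.columns)]
    df.index.name = table.level
    df.to_csv(path, sep="\t", float_format="%.1f")


def run_all(config: RunConfig) -> RunSummary:
    """Execute the full analysis; returns the run summary.

    See the module docstring for the artefact list. Raises
    :class:`PipelineError` (partial artefacts removed) on any failure.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    timings: dict[str, float] = {}
    current_stage = {"name": "call"}

    def emit(name: str, text: str) -> Path:
        path = out_dir / name
        path.write_text(text)
        written.append(path)
        return path

    def stage(name: str):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                current_stage["name"] = name
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 4)
                if exc is None:
                    logger.info("stage %s: done in %.3fs", name, timings[name])
                return False

        return _Timer()

    try:
        with stage("call"):
            popmap = read_popmap(config.popmap)
            coi_cat = build_catalog(read_fasta(config.coi_ref, COI), COI)
            coii_cat = build_catalog(read_fasta(config.coii_ref, COII), COII)
            coi_raw = read_fasta(config.coi_seqs, COI)
            coii_raw = read_fasta(config.coii_seqs, COII)
            coi_ok, coi_rej = qc_filter(coi_raw, COI, config.coi_window_start)
            coii_ok, coii_rej = qc_filter(coii_raw, COII, config.coii_window_start)
            coi_calls = [coi_cat.call(r) for r in coi_ok]
            coii_calls = [coii_cat.call(r) for r in coii_ok]
            individuals = assemble_individuals(coi_calls, coii_calls, popmap)
            n_combinable = combine_calls(individuals)
            calls_df = pd.DataFrame(
                {
                    "individual_id": [i.individual_id for i in individuals],
                    "country": [i.country for i in individuals],
                    "region": [i.region for i in individuals],
                    "coi": [i.coi_name for i in individuals],
                    "coii": [i.coii_name for i in individuals],
                    "combined": [i.combined_name for i in individuals],
                    "status_coi": [i.status_coi for i in individuals],
                    "status_coii": [i.status_coii for i in individuals],
                }
            )
            path = out_dir / "calls.tsv"
            calls_df.to_csv(path, sep="\t", index=False)
            written.append(path)

        with stage("tabulate"):
            for which, fname in (
                ("combined", "table1.tsv"),
                ("coi", "table1_coi.tsv"),
                ("coii", "table1_coii.tsv"),
            ):
                table = tabulate(individuals, level="country", which=which)
                p = out_dir / fname
                _write_wide_percentages(table, p)
                written.append(p)

        with stage("diversity"):
            combined_seqs = combined_sequences(individuals, coi_cat, coii_cat)
            region_stats = diversity.population_stats(
                _members(individuals, "region"), combined_seqs, COMBINED.window_length
            )
            country_stats = diversity.population_stats(
                _members(individuals, "country"), combined_seqs, COMBINED.window_length
            )
            by_country = {s.population: s for s in country_stats}
            groups = assign_genetic_groups(
                by_country,
                set(config.native_countries),
                config.hd_threshold,
                config.pi_threshold,
            )
            group_members: dict[str, list[str]] = {}
            for ind in individuals:
                if ind.combined_name is None:
                    continue
                g = groups.get(ind.country)
                if g in ("A", "B"):
                    group_members.setdefault(f"Group {g}", []).append(
                        ind.combined_name
                    )
            group_stats = diversity.population_stats(
                group_members, combined_seqs, COMBINED.window_length
            )
            rows = [
                {"level": lvl, **st.rounded()}
                for lvl, stats in (
                    ("region", region_stats),
                    ("country", country_stats),
                    ("group", group_stats),
                )
                for st in stats
            ]
            p = out_dir / "table2.tsv"
            pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
            written.append(p)

        with stage("amova"):
            hap_seqs = combined_seqs
            dist = differentiation.hamming_matrix(hap_seqs)
            members = _members(individuals, config.level)
            amova_res = differentiation.amova(
                members, dist, n_permutations=config.permutations, seed=config.seed
            )
            amova_df = pd.DataFrame(
                [
                    {
                        "source": "among populations",
                        "df": amova_res.df_among,
                        "SSD": round(amova_res.ssd_among, 4),
                        "variance": round(amova_res.sigma2_a, 5),
                        "pct": round(amova_res.pct_among, 2),
                    },
                    {
                        "source": "within populations",
                        "df": amova_res.df_within,
                        "SSD": round(amova_res.ssd_within, 4),
                        "variance": round(amova_res.sigma2_w, 5),
                        "pct": round(amova_res.pct_within, 2),
                    },
                ]
            )
            p = out_dir / "amova.tsv"
            amova_df.to_csv(p, sep="\t", index=False)
            written.append(p)

            fst = differentiation.pairwise_fst(
                members,
                dist,
                n_permutations=config.fst_permutations,
                seed=config.seed,
            )
            fst_df = pd.DataFrame(
                fst.values, index=fst.populations, columns=fst.populations
            )
            p = out_dir / "fst_matrix.tsv"
            fst_df.round(5).to_csv(p, sep="\t")
            written.append(p)
            pv_df = pd.DataFrame(
                fst.p_values, index=fst.populations, columns=fst.populations
            )
            p = out_dir / "fst_pvalues.tsv"
            pv_df.round(5).to_csv(p, sep="\t")
            written.append(p)

        with stage("pcoa"):
            pcoa_res = ordination.pcoa(fst)
            coord_cols = {
                f"coord{a + 1}": pcoa_res.coordinates[:, a].round(6)
                for a in range(pcoa_res.n_axes)
            }
            pcoa_df = pd.DataFrame({"population": pcoa_res.labels, **coord_cols})
            p = out_dir / "pcoa.tsv"
            pcoa_df.to_csv(p, sep="\t", index=False)
            written.append(p)
            p = out_dir / "pcoa_variance.tsv"
            pd.DataFrame(
                {
                    "axis": [f"coord{a + 1}" for a in range(pcoa_res.n_axes)],
                    "percent_variance": pcoa_res.percent_variance.round(2),
                }
            ).to_csv(p, sep="\t", index=False)
            written.append(p)

        with stage("network"):
            counts = _hap_counts(individuals)
            limit = parsimony_network.connection_limit(
                COMBINED.window_length, config.alpha, config.fixed_limit
            )
            comp_table = tabulate(individuals, level=config.level, which="combined")
            per_hap_pops: dict[str, dict[str, int]] = {}
            for pop, hap_counts in comp_table.counts.items():
                for hap, c in hap_counts.items():
                    per_hap_pops.setdefault(hap, {})[pop] = c
            network = parsimony_network.build_network(
                {h: hap_seqs[h] for h in counts}, counts, limit, per_hap_pops
            )
            emit("network.nex", parsimony_network.to_nexus(network))
            edge_lines = ["node1\tnode2"] + [
                f"{u}\t{v}" for u, v in parsimony_network.to_edge_table(network)
            ]
            emit("network_edges.tsv", "\n".join(edge_lines) + "\n")
            node_rows = parsimony_network.to_node_table(network)
            emit(
                "network_nodes.tsv",
                "\n".join(
                    ["node\tkind\tfrequency\tpopulations"]
                    + [
                        f"{r['node']}\t{r['kind']}\t{r['frequency']}\t{r['populations']}"
                        for r in node_rows
                    ]
                )
                + "\n",
            )

        with stage("summary"):
            hap_summary = {}
            for locus, calls in (("COI", coi_calls), ("COII", coii_calls)):
                names = {c.haplotype_name: c.status for c in calls}
                hap_summary[locus] = {
                    "total": len(names),
                    "known": sum(1 for s in names.values() if s == "known"),
                    "novel": sum(1 for s in names.values() if s == "novel"),
                }
            combined_names = {
                i.combined_name: (i.status_coi == "known" and i.status_coii == "known")
                for i in individuals
                if i.combined_name is not None
            }
            hap_summary["COMBINED"] = {
                "total": len(combined_names),
                "known": sum(1 for known in combined_names.values() if known),
                "novel": sum(1 for known in combined_names.values() if not known),
            }
            summary = RunSummary(
                n_individuals=len(individuals),
                n_coi_called=len(coi_calls),
                n_coii_called=len(coii_calls),
                n_combinable=n_combinable,
                n_coi_rejected=len(coi_rej),
                n_coii_rejected=len(coii_rej),
                haplotypes=hap_summary,
                genetic_groups=groups,
                amova={
                    "phi_st": amova_res.phi_st,
                    "pct_among": amova_res.pct_among,
                    "pct_within": amova_res.pct_within,
                    "p_value": amova_res.p_value,
                },
                pcoa_percent_variance=[
                    float(x) for x in pcoa_res.percent_variance
                ],
                connection_limit=limit.j_max,
                n_network_components=len(network.components),
                timings=timings,
                seed=config.seed,
                config={
                    k: str(v) if isinstance(v, Path) else v
                    for k, v in config.__dict__.items()
                },
            )
            emit("summary.json", summary.to_json())
        return summary
    except Exception as exc:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise PipelineError(
            f"stage {current_stage['name']!r} failed: {exc}"
        ) from exc
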