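"""Self-contained synthetic fixtures: toy annotations, two-condition
replicate FPKM tables with planted DE features, and term maps with
planted enriched terms (including lncGene-only terms).

All generators are deterministic for a fixed seed. Gene placements are
spaced far enough apart (>= 8 windows) that each lncRNA can only ever be
within the window of its single designated target gene, so ground-truth
association distances are exact by construction.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from lncora.annotations import GenomicFeature, OntologyDag, TermMap, write_gtf
from lncora.enrichment import hypergeom_tail
from lncora.errors import ConfigError

import networkx as nx

logger = logging.getLogger(__name__)

ROOT_TERM = "GO:0000001"


@dataclass(frozen=True)
class PlantedTerm:
    """One deliberately enriched term: fractions of its members drawn from
    the true DE genes and from the true lncGene pool."""

    term_id: str
    fraction_from_de: float
    fraction_from_lncgenes: float
    size: int = 10

    def __post_init__(self) -> None:
        for frac in (self.fraction_from_de, self.fraction_from_lncgenes):
            if not (0 <= frac <= 1):
                raise ConfigError("planted fractions must be in [0, 1]")
        if self.size <= 0:
            raise ConfigError("planted term size must be > 0")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 300
    n_lncrnas: int = 40
    n_chroms: int = 3
    # fractions of lncRNAs placed (overlapping, within_window, beyond_window)
    placement_mix: tuple[float, float, float] = (0.25, 0.5, 0.25)
    window_bp: int = 5000
    n_de_genes: int = 30
    n_de_lncrnas: int = 20
    de_fold: float = 2.0
    replicate_cv: float = 0.0
    n_terms: int = 20
    term_size_range: tuple[int, int] = (5, 15)
    planted_terms: list[PlantedTerm] = field(
        default_factory=lambda: [
            PlantedTerm("GO:9100001", fraction_from_de=0.8, fraction_from_lncgenes=0.0),
            PlantedTerm("GO:9100002", fraction_from_de=0.0, fraction_from_lncgenes=0.8),
        ]
    )

    def __post_init__(self) -> None:
        if abs(sum(self.placement_mix) - 1.0) > 1e-9:
            raise ConfigError("placement_mix fractions must sum to 1")
        if self.n_lncrnas > self.n_genes:
            raise ConfigError("need n_lncrnas <= n_genes (one target gene each)")
        if self.n_de_genes > self.n_genes or self.n_de_lncrnas > self.n_lncrnas:
            raise ConfigError("planted DE counts exceed feature counts")
        if self.de_fold <= 1:
            raise ConfigError("de_fold must be > 1")
        if self.window_bp <= 0:
            raise ConfigError("window_bp must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_terms"] = [dataclasses.asdict(p) for p in self.planted_terms]
        return d


@dataclass
class GroundTruth:
    """What was planted, recorded at generation time."""

    de_genes: set[str] = field(default_factory=set)
    de_lncrnas: set[str] = field(default_factory=set)
    # (lncrna_id, gene_id, relation, distance) for DE lncRNAs within window
    lncgene_records: list[tuple[str, str, str, int]] = field(default_factory=list)
    lncgenes: set[str] = field(default_factory=set)
    # planted term -> sorted member gene ids
    planted_members: dict[str, list[str]] = field(default_factory=dict)
    # planted term -> {"p_eq1": ..., "p_eq2_combined": ..., ...}
    expected_detection: dict[str, dict] = field(default_factory=dict)


def _placement_categories(config: SimulationConfig, rng: np.random.Generator):
    n = config.n_lncrnas
    n_overlap = int(round(config.placement_mix[0] * n))
    n_within = int(round(config.placement_mix[1] * n))
    n_beyond = n - n_overlap - n_within
    if n_beyond < 0:  # rounding overshoot
        n_within += n_beyond
        n_beyond = 0
    cats = ["overlapping"] * n_overlap + ["within_window"] * n_within + [
        "beyond_window"
    ] * n_beyond
    return list(rng.permutation(cats))


def simulate_annotations(
    config: SimulationConfig,
) -> tuple[list[GenomicFeature], list[GenomicFeature], GroundTruth]:
    """Place non-overlapping genes on toy chromosomes and one lncRNA per
    target gene at a controlled distance (0 for overlapping; uniform in
    [1, window] for within_window; uniform in (window, 3*window] for
    beyond_window)."""
    rng = np.random.default_rng(config.seed)
    w = config.window_bp
    spacing = 8 * w + 4000  # guarantees a lncRNA is near only its target
    origin = 10 * w

    genes: list[GenomicFeature] = []
    positions: dict[str, tuple[str, int, int]] = {}
    cursor = {f"chr{c + 1}": origin for c in range(config.n_chroms)}
    for i in range(config.n_genes):
        chrom = f"chr{(i % config.n_chroms) + 1}"
        length = int(rng.integers(800, 3000))
        start = cursor[chrom]
        end = start + length - 1
        cursor[chrom] = end + spacing
        gid = f"gene{i + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GenomicFeature(gid, chrom, start, end, strand, "protein_coding"))
        positions[gid] = (chrom, start, end)

    truth = GroundTruth()
    gene_ids = [g.feature_id for g in genes]
    truth.de_genes = set(
        rng.choice(gene_ids, size=config.n_de_genes, replace=False).tolist()
    )

    target_ids = rng.choice(gene_ids, size=config.n_lncrnas, replace=False)
    categories = _placement_categories(config, rng)
    gene_by_id = {g.feature_id: g for g in genes}
    lncrnas: list[GenomicFeature] = []
    lnc_meta: list[tuple[str, str, str, int]] = []  # lnc, target, category, distance
    for j, (target_id, category) in enumerate(zip(target_ids, categories)):
        gene = gene_by_id[target_id]
        length = int(rng.integers(300, 1500))
        lid = f"lnc{j + 1:05d}"
        if category == "overlapping":
            start = int(rng.integers(gene.start, gene.end + 1))
            distance = 0
        else:
            if category == "within_window":
                distance = int(rng.integers(1, w + 1))
            else:
                distance = int(rng.integers(w + 1, 3 * w + 1))
            if rng.random() < 0.5:  # left of gene
                end = gene.start - distance
                start = end - length + 1
                if start < 1:
                    raise ConfigError("chromosome too small for requested features")
                lncrnas.append(
                    GenomicFeature(lid, gene.chrom, start, end, "+", "lncRNA")
                )
                lnc_meta.append((lid, target_id, category, distance))
                continue
            start = gene.end + distance
        end = start + length - 1
        lncrnas.append(GenomicFeature(lid, gene.chrom, start, end, "+", "lncRNA"))
        lnc_meta.append((lid, target_id, category, distance))

    lnc_ids = [l.feature_id for l in lncrnas]
    truth.de_lncrnas = set(
        rng.choice(lnc_ids, size=config.n_de_lncrnas, replace=False).tolist()
    )

    lnc_by_id = {l.feature_id: l for l in lncrnas}
    for lid, target_id, category, distance in lnc_meta:
        if lid not in truth.de_lncrnas or category == "beyond_window":
            continue
        gene = gene_by_id[target_id]
        lnc = lnc_by_id[lid]
        if distance == 0:
            relation = "overlap"
        else:
            lnc_is_left = lnc.end < gene.start
            if gene.strand == "-":
                relation = "downstream" if lnc_is_left else "upstream"
            else:
                relation = "upstream" if lnc_is_left else "downstream"
        truth.lncgene_records.append((lid, target_id, relation, distance))
        truth.lncgenes.add(target_id)

    logger.info(
        "simulate_annotations: %d genes, %d lncRNAs, %d true lncGenes",
        len(genes), len(lncrnas), len(truth.lncgenes),
    )
    return genes, lncrnas, truth


def simulate_expression(
    config: SimulationConfig,
    truth: GroundTruth,
    genes: list[GenomicFeature],
    lncrnas: list[GenomicFeature],
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Two-condition, two-replicate FPKM matrix over all features.

    Baseline means are log-normal (median ~10, floored above the default
    expression cutoff); DE features get case = control * fold (up) or
    control / fold (down), split half and half; replicate noise is
    multiplicative with the configured CV (exact means at CV = 0).
    """
    rng = np.random.default_rng(config.seed + 1)
    samples = ["case_rep1", "case_rep2", "control_rep1", "control_rep2"]
    conditions = {
        "case_rep1": "case", "case_rep2": "case",
        "control_rep1": "control", "control_rep2": "control",
    }
    feature_ids = [f.feature_id for f in genes] + [f.feature_id for f in lncrnas]
    de_features = truth.de_genes | truth.de_lncrnas

    de_sorted = sorted(de_features)
    up = set(de_sorted[0::2])  # alternate so genes and lncRNAs both split

    rows = np.empty((len(feature_ids), 4))
    for idx, fid in enumerate(feature_ids):
        control_mean = float(rng.lognormal(math.log(10.0), 0.6)) + 1.5
        if fid in de_features:
            case_mean = (
                control_mean * config.de_fold
                if fid in up
                else control_mean / config.de_fold
            )
        else:
            case_mean = control_mean
        for col, mean in enumerate((case_mean, case_mean, control_mean, control_mean)):
            noise = 1.0
            if config.replicate_cv > 0:
                noise = max(1e-6, 1.0 + rng.normal(0.0, config.replicate_cv))
            rows[idx, col] = mean * noise
    values = pd.DataFrame(rows, index=feature_ids, columns=samples)
    values.index.name = "feature_id"
    return values, conditions


def simulate_term_maps(
    config: SimulationConfig,
    truth: GroundTruth,
    genes: list[GenomicFeature],
) -> tuple[TermMap, TermMap, OntologyDag]:
    """Background terms filled with random universe genes; planted terms
    drawn from the true DE genes and true lncGenes per their fractions,
    padded to size from unaffected genes. Each planted term also gets a
    significant parent term (superset) so parent pruning is exercised.

    Fills ``truth.planted_members`` and ``truth.expected_detection`` with
    analytically computed tail probabilities for both test modes.
    """
    rng = np.random.default_rng(config.seed + 2)
    universe = sorted(g.feature_id for g in genes)
    de_pool = sorted(truth.de_genes)
    lnc_pool = sorted(truth.lncgenes - truth.de_genes)  # subtract_de policy
    quiet_pool = sorted(set(universe) - truth.de_genes - truth.lncgenes)

    lo, hi = config.term_size_range
    terms: dict[str, frozenset[str]] = {}
    for t in range(config.n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        terms[f"GO:{1000001 + t}"] = frozenset(members.tolist())

    N = len(universe)
    n = len(de_pool)
    r = len(lnc_pool)
    graph = nx.DiGraph()
    graph.add_node(ROOT_TERM)
    for term_id in terms:
        graph.add_edge(term_id, ROOT_TERM, relation="is_a")

    for planted in config.planted_terms:
        n_de = int(round(planted.fraction_from_de * planted.size))
        n_lnc = int(round(planted.fraction_from_lncgenes * planted.size))
        if n_de + n_lnc > planted.size:
            n_lnc = planted.size - n_de
        if n_de > len(de_pool) or n_lnc > len(lnc_pool):
            raise ConfigError(
                f"planted term {planted.term_id}: requested members exceed "
                f"available pools (de {n_de}/{len(de_pool)}, "
                f"lnc {n_lnc}/{len(lnc_pool)})"
            )
        members = set(rng.choice(de_pool, size=n_de, replace=False).tolist())
        members |= set(rng.choice(lnc_pool, size=n_lnc, replace=False).tolist())
        pad = planted.size - len(members)
        if pad > len(quiet_pool):
            raise ConfigError(f"planted term {planted.term_id}: universe too small")
        members |= set(rng.choice(quiet_pool, size=pad, replace=False).tolist())
        terms[planted.term_id] = frozenset(members)
        truth.planted_members[planted.term_id] = sorted(members)

        parent_id = planted.term_id + "_parent"
        extra = rng.choice(quiet_pool, size=min(3, len(quiet_pool)), replace=False)
        terms[parent_id] = frozenset(members | set(extra.tolist()))
        graph.add_edge(planted.term_id, parent_id, relation="is_a")
        graph.add_edge(parent_id, ROOT_TERM, relation="is_a")

        K = planted.size
        k_de = n_de
        k_lnc = n_lnc
        p_eq1 = hypergeom_tail(N, n, K, k_de)
        p_eq2 = hypergeom_tail(N, n + r, K, k_de + k_lnc)
        truth.expected_detection[planted.term_id] = {
            "K": K, "k_de": k_de, "k_lnc": k_lnc,
            "p_eq1": p_eq1, "p_eq2_combined": p_eq2,
            "detect_eq1": p_eq1 <= 0.05,
            "detect_eq2_combined": p_eq2 <= 0.05,
        }

    go_map = TermMap(terms=dict(sorted(terms.items())), namespace="GO")

    kegg_terms: dict[str, frozenset[str]] = {}
    for t in range(max(1, config.n_terms // 2)):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        kegg_terms[f"path:ko{10 + t}"] = frozenset(members.tolist())
    kegg_map = TermMap(terms=dict(sorted(kegg_terms.items())), namespace="KEGG")

    dag = OntologyDag(graph)
    return go_map, kegg_map, dag


def write_obo(dag: OntologyDag, path) -> None:
    """Minimal OBO 1.2 serialization of a toy DAG."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {term}\n")
            label = dag.labels.get(term)
            if label:
                fh.write(f"name: {label}\n")
            for parent in sorted(dag.parents(term)):
                fh.write(f"is_a: {parent}\n")


def write_term_map_tsv(term_map: TermMap, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(term_map.terms):
            for gene in sorted(term_map.terms[term]):
                fh.write(f"{term}\t{gene}\n")


def write_fixture(config: SimulationConfig, outdir) -> GroundTruth:
    """Generate a complete fixture directory:

    genes.gtf, lncrnas.gtf, expression.tsv, conditions.tsv, go_map.tsv,
    kegg_map.tsv, ontology.obo, truth/*.tsv, manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)

    genes, lncrnas, truth = simulate_annotations(config)
    write_gtf(genes, outdir / "genes.gtf")
    write_gtf(lncrnas, outdir / "lncrnas.gtf")

    values, conditions = simulate_expression(config, truth, genes, lncrnas)
    values.to_csv(outdir / "expression.tsv", sep="\t", float_format="%.6f")
    with open(outdir / "conditions.tsv", "w") as fh:
        for sample in values.columns:
            fh.write(f"{sample}\t{conditions[sample]}\n")

    go_map, kegg_map, dag = simulate_term_maps(config, truth, genes)
    write_term_map_tsv(go_map, outdir / "go_map.tsv")
    write_term_map_tsv(kegg_map, outdir / "kegg_map.tsv")
    write_obo(dag, outdir / "ontology.obo")

    with open(truth_dir / "de_genes.tsv", "w") as fh:
        fh.writelines(f"{g}\n" for g in sorted(truth.de_genes))
    with open(truth_dir / "de_lncrnas.tsv", "w") as fh:
        fh.writelines(f"{l}\n" for l in sorted(truth.de_lncrnas))
    with open(truth_dir / "lncgenes.tsv", "w") as fh:
        fh.write("lncrna_id\tgene_id\trelation\tdistance\n")
        for rec in sorted(truth.lncgene_records):
            fh.write("\t".join(map(str, rec)) + "\n")
    with open(truth_dir / "planted_terms.tsv", "w") as fh:
        fh.write(
            "term_id\tK\tk_de\tk_lnc\tp_eq1\tp_eq2_combined"
            "\tdetect_eq1\tdetect_eq2_combined\n"
        )
        for term_id in sorted(truth.expected_detection):
            e = truth.expected_detection[term_id]
            fh.write(
                f"{term_id}\t{e['K']}\t{e['k_de']}\t{e['k_lnc']}"
                f"\t{e['p_eq1']:.6e}\t{e['p_eq2_combined']:.6e}"
                f"\t{e['detect_eq1']}\t{e['detect_eq2_combined']}\n"
            )

    manifest = {"config": config.to_dict(), "seed": config.seed}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth
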