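"""End-to-end orchestration: filter -> associate -> enrich -> prune ->
compare, with deterministic outputs that embed the config hash."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from lncora.annotations import parse_gtf, parse_obo, parse_term_map
from lncora.association import (
    associations_to_rows,
    derive_lncgenes,
    find_associations,
    lncgene_ids_for_enrichment,
)
from lncora.diffexp import (
    DEConfig,
    ExpressionTable,
    de_feature_ids,
    filter_de,
    results_to_frame,
)
from lncora.enrichment import (
    MODES,
    EnrichmentInput,
    EnrichmentResult,
    enrich_all,
    prune_go_parents,
    results_to_rows,
)
from lncora.errors import ConfigError, LncOraError, ParseError, StageError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genes_gtf: str
    lncrnas_gtf: str
    expression: str
    conditions: str
    go_map: str
    outdir: str
    kegg_map: str | None = None
    obo: str | None = None
    window_bp: int = 5000
    modes: tuple[str, ...] = ("eq1", "eq2_combined")
    alpha: float = 0.05
    universe_policy: str = "annotated"  # annotated | expressed
    dedup: str = "subtract_de"
    gene_de: DEConfig = field(default_factory=DEConfig)
    lncrna_de: DEConfig = field(default_factory=DEConfig)
    bh_adjust: bool = False
    prune_transitive: bool = True

    def __post_init__(self) -> None:
        bad = set(self.modes) - set(MODES)
        if bad:
            raise ConfigError(f"unknown modes: {sorted(bad)}")
        if self.universe_policy not in {"annotated", "expressed"}:
            raise ConfigError(f"unknown universe policy: {self.universe_policy!r}")
        for path_attr in ("genes_gtf", "lncrnas_gtf", "expression", "conditions", "go_map"):
            path = getattr(self, path_attr)
            if not Path(path).exists():
                raise ConfigError(f"{path_attr}: file not found: {path}")
        for path_attr in ("kegg_map", "obo"):
            path = getattr(self, path_attr)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{path_attr}: file not found: {path}")

    def hash(self) -> str:
        """Digest of the analysis parameters (paths excluded, so runs on
        identical inputs in different locations hash the same)."""

        def _default(obj):
            if isinstance(obj, (set, frozenset)):
                return sorted(obj)
            return str(obj)

        payload = dataclasses.asdict(self)
        for key in ("genes_gtf", "lncrnas_gtf", "expression", "conditions",
                    "go_map", "kegg_map", "obo", "outdir"):
            payload.pop(key, None)
        blob = json.dumps(payload, sort_keys=True, default=_default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_tsv(frame: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def compare_modes(
    results_by_mode: dict[str, list[EnrichmentResult]],
    baseline: str = "eq1",
) -> dict:
    """Per-mode significant counts and set differences against the
    baseline mode; post-pruning counts where pruning flags are set."""
    if len(results_by_mode) < 2:
        raise ConfigError("compare_modes needs results from >= 2 modes")
    term_sets = {m: {res.term_id for res in rs} for m, rs in results_by_mode.items()}
    reference = next(iter(term_sets.values()))
    if any(ts != reference for ts in term_sets.values()):
        raise ConfigError("modes were run over different term universes")
    if baseline not in results_by_mode:
        baseline = sorted(results_by_mode)[0]
    sig = {
        m: {res.term_id for res in rs if res.significant}
        for m, rs in results_by_mode.items()
    }
    kept = {
        m: {res.term_id for res in rs if res.significant and not res.pruned}
        for m, rs in results_by_mode.items()
    }
    out: dict = {"baseline": baseline, "modes": {}}
    for mode, rs in results_by_mode.items():
        out["modes"][mode] = {
            "n_significant": len(sig[mode]),
            "n_significant_after_pruning": len(kept[mode]),
            "gained": sorted(sig[mode] - sig[baseline]),
            "lost": sorted(sig[baseline] - sig[mode]),
            "n_gained": len(sig[mode] - sig[baseline]),
            "n_lost": len(sig[baseline] - sig[mode]),
        }
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, writing TSV artifacts under ``config.outdir``.

    Returns a summary dict (also written as summary.json). Any stage
    error is re-raised as :class:`StageError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    summary: dict = {"config_hash": chash, "stages": {}}

    # --- annotations -----------------------------------------------------
    try:
        genes = parse_gtf(config.genes_gtf, biotype="protein_coding")
        lncrnas = parse_gtf(config.lncrnas_gtf, biotype="lncRNA")
    except (ParseError, OSError) as exc:
        raise StageError("annotations", str(exc)) from exc
    gene_ids = {g.feature_id for g in genes}
    lnc_ids = {l.feature_id for l in lncrnas}
    summary["stages"]["annotations"] = {"n_genes": len(genes), "n_lncrnas": len(lncrnas)}

    # --- diffexp ---------------------------------------------------------
    try:
        table = ExpressionTable.from_files(config.expression, config.conditions)
        gene_rows = [f for f in table.feature_ids if f in gene_ids]
        lnc_rows = [f for f in table.feature_ids if f in lnc_ids]
        gene_table = ExpressionTable(table.values.loc[gene_rows], table.conditions)
        lnc_table = ExpressionTable(table.values.loc[lnc_rows], table.conditions)
        gene_results = filter_de(gene_table, config.gene_de)
        lnc_results = filter_de(lnc_table, config.lncrna_de)
    except (ConfigError, ParseError):
        raise
    except (OSError, KeyError, ValueError) as exc:
        raise StageError("diffexp", str(exc)) from exc
    de_genes = de_feature_ids(gene_results)
    de_lncrnas = de_feature_ids(lnc_results)
    _write_tsv(results_to_frame(gene_results), outdir / "de_genes.tsv", chash)
    _write_tsv(results_to_frame(lnc_results), outdir / "de_lncrnas.tsv", chash)
    summary["stages"]["diffexp"] = {
        "n_features_genes": len(gene_rows),
        "n_features_lncrnas": len(lnc_rows),
        "n_de_genes": len(de_genes),
        "n_de_genes_up": sum(1 for r in gene_results if r.status == "de_up"),
        "n_de_genes_down": sum(1 for r in gene_results if r.status == "de_down"),
        "n_de_lncrnas": len(de_lncrnas),
        "n_de_lncrnas_up": sum(1 for r in lnc_results if r.status == "de_up"),
        "n_de_lncrnas_down": sum(1 for r in lnc_results if r.status == "de_down"),
    }

    # --- associate -------------------------------------------------------
    needs_lncgenes = any(m.startswith("eq2") for m in config.modes)
    lncgenes: set[str] = set()
    if needs_lncgenes:
        de_lnc_features = [l for l in lncrnas if l.feature_id in de_lncrnas]
        associations = find_associations(de_lnc_features, genes, config.window_bp)
        lncgene_set = derive_lncgenes(associations, de_genes, config.dedup)
        lncgenes = lncgene_ids_for_enrichment(lncgene_set, de_genes)
        assoc_frame = pd.DataFrame(
            associations_to_rows(associations),
            columns=["lncrna_id", "gene_id", "relation", "distance"],
        ).sort_values(["lncrna_id", "gene_id"], kind="stable")
        _write_tsv(assoc_frame, outdir / "associations.tsv", chash)
        summary["stages"]["associate"] = {
            "n_associations": len(associations),
            "n_lncgenes": len(lncgene_set.gene_ids),
            "r": lncgene_set.r,
        }

    # --- enrich + prune --------------------------------------------------
    dag = None
    if config.obo:
        try:
            dag = parse_obo(config.obo)
        except ParseError:
            raise
        except OSError as exc:
            raise StageError("prune", str(exc)) from exc

    namespaces = {"GO": (config.go_map, "tsv")}
    if config.kegg_map:
        namespaces["KEGG"] = (config.kegg_map, "tsv")

    expressed = set(table.feature_ids)
    results_by_ns: dict[str, dict[str, list[EnrichmentResult]]] = {}
    for ns, (map_path, fmt) in namespaces.items():
        try:
            term_map = parse_term_map(map_path, format=fmt, namespace=ns)
        except ParseError:
            raise
        except OSError as exc:
            raise StageError("enrich", str(exc)) from exc
        universe = term_map.genes() & gene_ids
        if config.universe_policy == "expressed":
            universe &= expressed
        results_by_mode: dict[str, list[EnrichmentResult]] = {}
        for mode in config.modes:
            enr_input = EnrichmentInput(
                universe=frozenset(universe),
                de_genes=frozenset(de_genes),
                lncgenes=frozenset(lncgenes if mode.startswith("eq2") else set()),
                term_map=term_map,
                alpha=config.alpha,
                mode=mode,
            )
            results = enrich_all(enr_input, bh_adjust=config.bh_adjust)
            if dag is not None and ns == "GO":
                results = prune_go_parents(results, dag, transitive=config.prune_transitive)
            results_by_mode[mode] = results
            frame = pd.DataFrame(
                results_to_rows(results, enr_input.N, enr_input.n, enr_input.r)
            )
            _write_tsv(frame, outdir / f"enrichment_{ns}_{mode}.tsv", chash)
            kept = frame[frame["significant"] & ~frame["pruned"]]
            _write_tsv(kept, outdir / f"significant_{ns}_{mode}.tsv", chash)
        results_by_ns[ns] = results_by_mode
        summary["stages"].setdefault("enrich", {})[ns] = {
            mode: {
                "n_terms": len(rs),
                "n_significant": sum(r.significant for r in rs),
                "n_significant_after_pruning": sum(
                    r.significant and not r.pruned for r in rs
                ),
            }
            for mode, rs in results_by_mode.items()
        }

    # --- compare ---------------------------------------------------------
    if len(config.modes) >= 2:
        comparison = {
            ns: compare_modes(by_mode) for ns, by_mode in results_by_ns.items()
        }
        summary["comparison"] = comparison
        rows = []
        for ns, comp in comparison.items():
            for mode, stats in comp["modes"].items():
                rows.append(
                    {
                        "namespace": ns,
                        "mode": mode,
                        "n_significant": stats["n_significant"],
                        "n_significant_after_pruning": stats[
                            "n_significant_after_pruning"
                        ],
                        "n_gained_vs_baseline": stats["n_gained"],
                        "n_lost_vs_baseline": stats["n_lost"],
                        "gained_terms": ",".join(stats["gained"]),
                    }
                )
        _write_tsv(pd.DataFrame(rows), outdir / "comparison.tsv", chash)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
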