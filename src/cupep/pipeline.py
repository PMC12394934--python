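"""End-to-end orchestration: ingest → filter → properties → composition →
positions → motifs → stats → report bundle, under a single config.

Every output table begins with ``#`` metadata lines naming the parameters
sufficient to regenerate it (seed, thresholds, pKa set), and a JSON run
manifest records versions, parameters, and record counts at each stage.
Identical config and inputs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .core import PeptidePopulation
from .io import filter_by_probability, read_peptide_report, write_peptide_report
from .motifs import build_catalog, cross_condition_compare
from .physchem import EMBOSS_PKA, KYTE_DOOLITTLE, PkaSet, properties_table
from .profiles import (BackgroundProfile, enrichment_ratio, global_composition,
                       load_background, positional_matrix_by_condition,
                       rice_bran_background)
from .simulate import (calibrate_his_n1, simulate_enrichment, study_populations)
from .stats import compare_all_properties

__all__ = ["RunConfig", "run_profile", "run_synthetic", "write_table"]

log = logging.getLogger("cupep")

PKA_SETS: dict[str, PkaSet] = {"emboss": EMBOSS_PKA}


@dataclass
class RunConfig:
    """Parameters of one pipeline run (JSON-serialisable)."""

    inputs: list[str] = field(default_factory=list)
    output_dir: str = "cupep_out"
    probability_threshold: float = 0.99
    pka_set: str = "emboss"
    background_path: Optional[str] = None
    motif_n: list[int] = field(default_factory=lambda: [5, 6, 7])
    min_count: int = 2
    top_k: int = 50
    max_distance: float = 0.4
    seed: int = 0
    # synthetic-run parameters
    n_proteins: int = 100
    max_missed: int = 2
    target_his_n1: float = 0.32

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))

    def metadata(self) -> dict[str, object]:
        return {"cupep_version": __version__, **asdict(self)}


def write_table(df: pd.DataFrame, path, metadata: Mapping[str, object]) -> None:
    """Write a TSV with ``#`` metadata header lines (UTF-8, '.' decimal)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for k in sorted(metadata):
            fh.write(f"# {k}={metadata[k]}\n")
        df.to_csv(fh, sep="\t", index=False)


def _load_inputs(config: RunConfig) -> PeptidePopulation:
    peptides = []
    for p in config.inputs:
        pop = read_peptide_report(p)
        log.info("ingest: %s -> %d peptides", p, len(pop))
        peptides.extend(pop.peptides)
    return PeptidePopulation(peptides, "ingest")


def run_profile(config: RunConfig) -> dict:
    """Run the full profiling pipeline and write the report bundle.

    Returns the manifest (also written as ``manifest.json``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "probability_threshold": config.probability_threshold,
            "pka_set": config.pka_set}
    pka = PKA_SETS[config.pka_set]
    manifest: dict = {"version": __version__, "parameters": config.metadata(),
                      "stages": {}}

    pop = _load_inputs(config)
    manifest["stages"]["ingest"] = {"n": len(pop)}

    fr = filter_by_probability(pop, config.probability_threshold)
    pop = fr.population
    manifest["stages"]["probability_filter"] = {
        "n": fr.n_retained, "n_below": fr.n_below, "n_missing": fr.n_missing}
    log.info("filter: %d retained, %d below threshold, %d missing probability",
             fr.n_retained, fr.n_below, fr.n_missing)
    if len(pop) == 0:
        raise ValueError("probability filter removed every peptide; nothing to profile")

    props = properties_table(pop, KYTE_DOOLITTLE, pka)
    write_table(props.round(6), out / "properties.tsv", meta)
    manifest["stages"]["properties"] = {"n": len(props)}

    comp = global_composition(pop)
    comp_df = comp.percent.rename("percent").rename_axis("residue").reset_index()
    write_table(comp_df.round(6), out / "composition.tsv",
                {**meta, "total_residues": comp.total_residues})
    if config.background_path:
        bg = load_background(config.background_path)
    else:
        bg = rice_bran_background()
    ratio = enrichment_ratio(comp, bg).rename("ratio").rename_axis("residue").reset_index()
    write_table(ratio.round(6), out / "enrichment_ratio.tsv",
                {**meta, "background": bg.name})
    manifest["stages"]["composition"] = {"n_residues": comp.total_residues}

    matrices = positional_matrix_by_condition(pop)
    for name, pm in sorted(matrices.items()):
        df = pm.matrix.round(6).rename_axis("residue").reset_index()
        write_table(df, out / f"positions_{name}.tsv",
                    {**meta, "n_peptides": pm.n_peptides,
                     "n_excluded_short": pm.n_excluded,
                     "length5_middle_residue": "counted in both N3 and C3"})
    manifest["stages"]["positions"] = {
        name: {"n": pm.n_peptides, "excluded": pm.n_excluded}
        for name, pm in sorted(matrices.items())}

    motif_counts = {}
    for n in config.motif_n:
        cat = build_catalog(pop, n, config.min_count)
        rows = []
        for cond in cat.conditions():
            for motif, count in sorted(cat.counts[cond].items()):
                rows.append({"condition": cond, "motif": motif, "count": count})
        write_table(pd.DataFrame(rows, columns=["condition", "motif", "count"]),
                    out / f"motifs_n{n}.tsv",
                    {**meta, "n": n, "min_count": config.min_count})
        motif_counts[n] = sum(len(c) for c in cat.counts.values())
        if len(cat.conditions()) >= 2:
            pairs = cross_condition_compare(cat, config.top_k, config.max_distance)
            pdf = pd.DataFrame(
                [{"condition_a": p.condition_a, "motif_a": p.motif_a,
                  "condition_b": p.condition_b, "motif_b": p.motif_b,
                  "distance": round(p.distance, 6)} for p in pairs],
                columns=["condition_a", "motif_a", "condition_b", "motif_b", "distance"])
            write_table(pdf, out / f"motif_pairs_n{n}.tsv",
                        {**meta, "n": n, "top_k": config.top_k,
                         "max_distance": config.max_distance})
    manifest["stages"]["motifs"] = {str(n): c for n, c in motif_counts.items()}

    conds = sorted(pop.conditions())
    if len(conds) >= 2:
        a = pop.subset(lambda p: p.condition == conds[0], conds[0])
        b = pop.subset(lambda p: p.condition == conds[1], conds[1])
        stats_df = compare_all_properties(a, b, pka=pka)
        write_table(stats_df.round(8), out / "stats.tsv",
                    {**meta, "group_a": conds[0], "group_b": conds[1]})
        manifest["stages"]["stats"] = {"group_a": conds[0], "group_b": conds[1],
                                       "n_tests": len(stats_df)}

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def run_synthetic(config: RunConfig) -> dict:
    """Generate the synthetic study populations and their enrichment splits.

    Writes, per digestion scheme, the full digest report plus the
    retained (eluent) and flow-through reports, with generating
    parameters in the manifest.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "parameters": config.metadata(),
                      "stages": {}}
    pops = study_populations(config.n_proteins, config.seed, config.max_missed)
    for scheme, pop in sorted(pops.items()):
        if len(pop) == 0:
            raise ValueError(f"digestion produced no peptides for scheme {scheme}")
        model = calibrate_his_n1(pop, config.target_his_n1, seed=config.seed)
        retained, flow = simulate_enrichment(pop, model)
        meta = {"seed": config.seed, "scheme": scheme,
                "target_his_n1": config.target_his_n1,
                "w_his_n1": round(model.w_his_n1, 6),
                "intercept": round(model.intercept, 6)}
        write_peptide_report(pop, out / f"{scheme}_digest.tsv", meta)
        write_peptide_report(retained, out / f"{scheme}_retained.tsv", meta)
        write_peptide_report(flow, out / f"{scheme}_flow_through.tsv", meta)
        manifest["stages"][scheme] = {
            "n_digest": len(pop), "n_retained": len(retained),
            "n_flow_through": len(flow),
            "model": {"w_his_n1": model.w_his_n1, "intercept": model.intercept,
                      "seed": model.seed},
        }
        log.info("synthetic %s: %d peptides, %d retained, %d flow-through",
                 scheme, len(pop), len(retained), len(flow))
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
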