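"""End-to-end orchestration from a single YAML config.

Runs: simulation (or file loading) -> host genetics (IBS, clone pruning,
cluster assignment, FST, UPGMA) -> community processing per community ->
marginal PERMANOVA + dispersion + forest importance -> text summary, and
writes a manifest recording every threshold, seed and output checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

import holo
from holo import synthetic_data
from holo.asv_processing import AsvTable, FilterConfig, process_community
from holo.community_stats import dispersion_test, pcoa, permanova_marginal
from holo.distance import DistanceMatrix
from holo.host_genetics import (
    GenotypeMatrix,
    assign_clusters,
    ibs_distance,
    pairwise_fst,
    prune_clones,
    upgma,
)
from holo.rda_forest import (
    RdaForestConfig,
    aggregate_importance,
    dummy_code,
    fit_rda_forest,
    relative_importance,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "holo_run",
    "simulation": {},
    "filters": {},
    "permanova": {"n_perm": 999, "model": "cluster + site + size_class"},
    "genetics_permanova": {"n_perm": 999, "model": "site * size_class"},
    "rda_forest": {"n_axes": 15, "n_trees": 1500},
    "predictors": ["cluster", "site", "size_class"],
    "communities": {
        "its2": {"mode": "its2", "n_variant_sets": 3, "stream": 0},
        "16s": {"mode": "16s", "stream": 1},
    },
    "clone_threshold": None,
    "n_clusters": None,  # default: simulation's n_clusters
    "dispersion": {"n_perm": 999},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute every stage and write all outputs plus a manifest.

    ``config`` is a dict (or a YAML path) layered over
    :data:`DEFAULT_CONFIG`. Returns a dict of in-memory results keyed by
    stage. All randomness derives from ``config['seed']``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = _merge(DEFAULT_CONFIG, config)
    out = Path(out_dir or config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    results: dict = {"config": config}

    # --- stage: data ------------------------------------------------------
    stage = "simulate"
    try:
        sim_cfg = synthetic_data.SimulationConfig(**{**config["simulation"], "seed": seed})
        genotypes = synthetic_data.simulate_genotypes(sim_cfg)
        metadata = synthetic_data.simulate_metadata(sim_cfg, genotypes.clusters)
        tables: dict[str, AsvTable] = {}
        truths: dict[str, dict] = {}
        for name, spec in config["communities"].items():
            com_cfg = sim_cfg.replace(
                n_variant_sets=int(spec.get("n_variant_sets", 0)),
                **{k: v for k, v in spec.items() if k.startswith("effect_")},
            )
            tables[name], truths[name] = synthetic_data.simulate_community(
                metadata, com_cfg, stream=int(spec.get("stream", 0))
            )
        synthetic_data.write_outputs(out, genotypes, metadata, tables)

        # --- stage: host genetics ----------------------------------------
        stage = "host_genetics"
        ibs = ibs_distance(genotypes)
        ibs.to_tsv(out / "ibs_distances.tsv")
        retained, clone_groups = prune_clones(
            ibs, clone_threshold=config["clone_threshold"], quality=genotypes.call_rate()
        )
        pruned = genotypes.subset(retained)
        ibs_pruned = ibs.subset(retained)
        k = int(config["n_clusters"] or sim_cfg.n_clusters)
        clusters = assign_clusters(ibs_pruned, k).map(lambda c: f"cluster{c}")
        fst = pairwise_fst(pruned, clusters)
        fst.matrix.to_tsv(out / "fst.tsv")
        tree = upgma(fst)
        (out / "fst_upgma.nwk").write_text(tree.newick + "\n")
        results["host_genetics"] = {
            "retained": retained,
            "clone_groups": clone_groups,
            "clusters": clusters,
            "fst": fst,
            "tree": tree,
        }

        # genetics PERMANOVA on individual-level metadata
        stage = "genetics_permanova"
        ind_meta = metadata.drop_duplicates("individual_id").set_index("individual_id")
        ind_meta = ind_meta.loc[[i for i in ibs_pruned.labels if i in ind_meta.index]]
        d_gen = ibs_pruned.subset(list(ind_meta.index))
        gen_perm = permanova_marginal(
            d_gen,
            ind_meta,
            config["genetics_permanova"]["model"],
            n_perm=int(config["genetics_permanova"]["n_perm"]),
            seed=seed,
        )
        gen_perm.table.to_csv(out / "permanova_genetics.tsv", sep="\t")
        results["genetics_permanova"] = gen_perm

        # --- stage: communities ------------------------------------------
        filters = FilterConfig(**config["filters"])
        genotyped_colonies = set(
            metadata.loc[metadata["individual_id"].isin(retained), "colony_id"]
        )
        rf_cfg_base = config["rda_forest"]
        for name, spec in config["communities"].items():
            stage = f"community:{name}"
            proc = process_community(
                tables[name],
                mode=spec.get("mode", "16s"),
                cfg=filters,
                genotyped=genotyped_colonies,
            )
            proc.colony_table.to_tsv(out / f"colony_counts_{name}.tsv")
            proc.distances.to_tsv(out / f"braycurtis_{name}.tsv")

            colony_meta = (
                metadata.drop_duplicates("colony_id")
                .set_index("colony_id")
                .loc[proc.distances.labels, ["site", "size_class", "cluster"]]
            )
            perm = permanova_marginal(
                proc.distances,
                colony_meta,
                config["permanova"]["model"],
                n_perm=int(config["permanova"]["n_perm"]),
                seed=seed,
            )
            perm.table.to_csv(out / f"permanova_{name}.tsv", sep="\t")

            disp = dispersion_test(
                proc.distances,
                colony_meta["cluster"],
                n_perm=int(config["dispersion"]["n_perm"]),
                seed=seed,
            )

            ord_res = pcoa(proc.distances)
            predictors = dummy_code(colony_meta, list(config["predictors"]))
            rf_cfg = RdaForestConfig(
                n_axes=int(rf_cfg_base["n_axes"]),
                n_trees=int(rf_cfg_base["n_trees"]),
                seed=seed,
            )
            report = aggregate_importance(fit_rda_forest(ord_res, predictors, rf_cfg))
            shares = relative_importance(report.importance)
            imp_table = pd.DataFrame(
                {
                    "weighted_importance": report.importance,
                    "share": shares.fractions,
                    "percent": shares.percents,
                }
            )
            imp_table.to_csv(out / f"importance_{name}.tsv", sep="\t", index_label="predictor")
            results[name] = {
                "processing": proc,
                "permanova": perm,
                "dispersion": disp,
                "importance": report,
                "shares": shares,
            }
    except Exception as exc:  # pragma: no cover - error path formatting
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- summary + manifest ----------------------------------------------
    summary = _summarize(results, config)
    (out / "summary.txt").write_text(summary)
    manifest = {
        "software_version": holo.__version__,
        "seed": seed,
        "config": _jsonable(config),
        "thresholds": asdict(filters),
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def _summarize(results: dict, config: dict) -> str:
    lines = [f"holo v{holo.__version__} run summary", ""]
    hg = results["host_genetics"]
    lines.append(f"retained individuals after clone pruning: {len(hg['retained'])}")
    lines.append(f"assigned clusters: {hg['clusters'].nunique()}")
    lines.append(f"UPGMA tree: {hg['tree'].newick}")
    for name in config["communities"]:
        if name not in results:
            continue
        shares = results[name]["shares"]
        top = shares.fractions.idxmax()
        lines.append("")
        lines.append(f"[{name}] top predictor by weighted importance: {top}")
        for pred, pct in shares.percents.items():
            lines.append(f"  {pred}: {pct}% (importance {results[name]['importance'].importance[pred]:.4f})")
        ptab = results[name]["permanova"].table
        for term in ptab.index[:-2]:
            lines.append(
                f"  PERMANOVA {term}: R2={ptab.loc[term, 'R2']:.3f} "
                f"F={ptab.loc[term, 'F']:.2f} p={ptab.loc[term, 'p']:.4g}"
            )
    return "\n".join(lines) + "\n"
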