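"""Synthetic holobiont data with known ground truth.

Generates host genotypes under the Balding-Nichols model, colony metadata
with replicate structure (3 samples per large colony, 1 per small), ASV
count tables with planted cluster/site/size effects under a
Dirichlet-multinomial count model, and toy BLAST hit tables — everything a
downstream analysis stage needs, with the generating parameters returned
alongside so tests can assert against truth.

All randomness flows from ``SimulationConfig.seed`` through named
sub-streams (one per operation), so each operation is a pure function of
its config and outputs are bit-identical across calls.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from holo.asv_processing import AsvTable
from holo.host_genetics import GenotypeMatrix

# sub-stream indices of the seed tree; never renumber, only append
_STREAMS = {"genotypes": 0, "metadata": 1, "community": 2, "blast": 3}


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream], extra))
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters for the full holobiont simulation.

    Effects are log-scale standard deviations: each factor level draws a
    per-ASV offset ~ Normal(0, effect), so larger values plant stronger
    community structure for that factor.
    """

    n_clusters: int = 5
    fst_target: float = 0.25
    n_individuals: int = 100
    n_snps: int = 1000
    sites: tuple[str, ...] = ("NE_Pelorus", "SE_Pelorus", "Pioneer_Bay", "S_Orpheus")
    size_classes: tuple[str, ...] = ("small", "large")
    cluster_site_concentration: float = 1.0
    n_asvs: int = 50
    effect_cluster: float = 2.0
    effect_site: float = 0.5
    effect_size: float = 0.2
    replicate_noise_sd: float = 0.2
    library_size_log_mean: float = 9.0
    library_size_log_sd: float = 0.4
    overdispersion: float = 200.0
    n_variant_sets: int = 0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_clusters", "n_individuals", "n_snps", "n_asvs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.fst_target < 1.0:
            raise ValueError(f"fst_target must lie in (0, 1), got {self.fst_target}")
        for name in ("effect_cluster", "effect_site", "effect_size", "replicate_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive")
        if self.cluster_site_concentration <= 0:
            raise ValueError("cluster_site_concentration must be positive")
        if self.n_variant_sets < 0:
            raise ValueError("n_variant_sets must be nonnegative")
        object.__setattr__(self, "sites", tuple(self.sites))
        object.__setattr__(self, "size_classes", tuple(self.size_classes))

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw biallelic dosage genotypes under the Balding-Nichols model.

    Per SNP the ancestral allele frequency is Uniform(0.1, 0.9); each
    cluster's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) with
    F = ``fst_target``; individual dosages are Binomial(2, p_cluster).
    Individuals are split as evenly as possible across clusters and the
    true cluster labels are attached to the returned matrix.
    """
    if config.n_snps < 50:
        raise ValueError("need at least 50 SNPs for a meaningful simulation")
    if config.n_individuals < config.n_clusters:
        raise ValueError("need at least one individual per cluster")
    rng = _rng(config.seed, "genotypes")
    n, k, m = config.n_individuals, config.n_clusters, config.n_snps
    f = config.fst_target

    cluster_idx = rng.permutation(np.arange(n) % k)
    p_anc = rng.uniform(0.1, 0.9, size=m)
    shape = (1.0 - f) / f
    p_cluster = rng.beta(p_anc * shape, (1.0 - p_anc) * shape, size=(k, m))
    dosages = rng.binomial(2, p_cluster[cluster_idx, :]).astype(float)

    ids = [f"ind{i:03d}" for i in range(n)]
    clusters = pd.Series([f"cluster{c + 1}" for c in cluster_idx], index=ids, name="cluster")
    return GenotypeMatrix(
        pd.DataFrame(dosages, index=ids, columns=[f"snp{j:05d}" for j in range(m)]),
        clusters=clusters,
    )


def simulate_metadata(config: SimulationConfig, labels: pd.Series) -> pd.DataFrame:
    """Assign each individual a site and size class, expand to sample rows.

    Sites are drawn from a per-cluster site distribution sampled from a
    symmetric Dirichlet with concentration ``cluster_site_concentration``
    (low concentration concentrates each cluster on few sites, high
    concentration makes site independent of cluster). Large colonies
    produce 3 replicate sample rows sharing one colony id; small colonies
    one row.

    Returns a table with columns sample_id, colony_id, site, size_class,
    cluster, indexed by sample_id.
    """
    if len(labels) != config.n_individuals:
        raise ValueError("labels length must equal n_individuals")
    rng = _rng(config.seed, "metadata")
    sites = list(config.sites)
    conc = config.cluster_site_concentration

    site_probs = {}
    for cl in sorted(labels.unique()):
        # gamma draws rather than rng.dirichlet: stable for tiny concentration
        g = rng.gamma(max(conc, 1e-12), 1.0, size=len(sites))
        if g.sum() <= 0 or not np.all(np.isfinite(g)):
            probs = np.zeros(len(sites))
            probs[rng.integers(len(sites))] = 1.0
        else:
            probs = g / g.sum()
        site_probs[cl] = probs

    rows = []
    for i, (ind, cl) in enumerate(labels.items()):
        site = sites[rng.choice(len(sites), p=site_probs[cl])]
        size = config.size_classes[rng.integers(len(config.size_classes))]
        colony = f"colony{i:03d}"
        n_rep = 3 if size == "large" else 1
        for r in range(n_rep):
            rows.append(
                {
                    "sample_id": f"{colony}-r{r + 1}",
                    "colony_id": colony,
                    "individual_id": str(ind),
                    "site": site,
                    "size_class": size,
                    "cluster": str(cl),
                }
            )
    meta = pd.DataFrame(rows).set_index("sample_id", drop=False)
    meta.index.name = None
    return meta


def simulate_community(
    metadata: pd.DataFrame, config: SimulationConfig, stream: int = 0
) -> tuple[AsvTable, dict]:
    """Generate an ASV count table with additive planted effects.

    Colony expected log-abundance per ASV = baseline + cluster effect +
    site effect + size effect (each per-(level, ASV) effect drawn
    Normal(0, effect_*)); each replicate sample adds Normal(0,
    replicate_noise_sd); proportions are the softmax over ASVs; counts are
    Dirichlet-multinomial with concentration ``overdispersion`` x
    proportions and a log-normal library size.

    For each of ``n_variant_sets``, one base ASV becomes a "parent" whose
    presence pattern is copied exactly onto 2-4 appended variant ASVs
    (variant count = ceil(parent x Uniform(0.2, 1))), mimicking
    intragenomic rDNA variants that always co-occur with their parent.
    Variant reads are added on top of the parent's library, so per-sample
    totals equal the drawn library size plus variant reads.

    ``stream`` selects an independent sub-stream, letting one metadata
    table drive several community tables (e.g. a symbiont-like and a
    microbe-like community) from one seed.

    Returns the sample-level table plus a ground-truth dict with the
    effect tables, library sizes and variant map.
    """
    for col in ("cluster", "site", "size_class"):
        if col not in metadata.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    rng = _rng(config.seed, "community", extra=stream)
    n_asv = config.n_asvs
    asv_ids = [f"asv{j + 1:04d}" for j in range(n_asv)]

    baseline = rng.normal(0.0, 1.0, size=n_asv)
    effects = {}
    for factor, sd in (
        ("cluster", config.effect_cluster),
        ("site", config.effect_site),
        ("size_class", config.effect_size),
    ):
        levels = sorted(metadata[factor].unique())
        effects[factor] = pd.DataFrame(
            rng.normal(0.0, sd, size=(len(levels), n_asv)), index=levels, columns=asv_ids
        )

    colony_log = {}
    counts = np.zeros((len(metadata), n_asv), dtype=np.int64)
    lib_sizes = np.zeros(len(metadata), dtype=np.int64)
    for i, (sid, row) in enumerate(metadata.iterrows()):
        key = row["colony_id"]
        if key not in colony_log:
            colony_log[key] = (
                baseline
                + effects["cluster"].loc[row["cluster"]].to_numpy()
                + effects["site"].loc[row["site"]].to_numpy()
                + effects["size_class"].loc[row["size_class"]].to_numpy()
            )
        log_ab = colony_log[key] + rng.normal(0.0, config.replicate_noise_sd, size=n_asv)
        log_ab -= log_ab.max()
        props = np.exp(log_ab)
        props /= props.sum()
        lib = max(1, int(np.round(rng.lognormal(config.library_size_log_mean, config.library_size_log_sd))))
        alpha = config.overdispersion * props
        p = rng.dirichlet(np.clip(alpha, 1e-9, None))
        counts[i] = rng.multinomial(lib, p)
        lib_sizes[i] = lib

    table = pd.DataFrame(counts, index=metadata.index, columns=asv_ids)

    variant_map: dict[str, list[str]] = {}
    if config.n_variant_sets > 0:
        parents = rng.choice(n_asv, size=min(config.n_variant_sets, n_asv), replace=False)
        for p_idx in parents:
            parent = asv_ids[p_idx]
            members = []
            for v in range(rng.integers(2, 5)):
                vid = f"{parent}v{v + 1}"
                frac = rng.uniform(0.2, 1.0, size=len(table))
                vcounts = np.ceil(table[parent].to_numpy() * frac).astype(np.int64)
                table[vid] = vcounts
                members.append(vid)
            variant_map[parent] = members

    truth = {
        "baseline": pd.Series(baseline, index=asv_ids, name="baseline"),
        "effects": effects,
        "library_sizes": pd.Series(lib_sizes, index=metadata.index, name="library_size"),
        "variant_map": variant_map,
    }
    colony_map = metadata["colony_id"].astype(str)
    return AsvTable(table, colony_map), truth


_BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def simulate_blast_hits(
    true_subtype: str,
    n_hits: int,
    noise_fraction: float = 0.0,
    seed: int = 0,
    query_id: str = "ASV_1",
    decoy_subtype: str | None = None,
) -> pd.DataFrame:
    """Emit a toy BLAST tabular (outfmt 6) hit table for one query.

    Each hit is independently a decoy with probability ``noise_fraction``;
    otherwise its subject is a strain of ``true_subtype`` (random
    lowercase suffix, e.g. C15au-like labels). E-values are log-uniform in
    [1e-180, 1e-110); identities Uniform(96, 100).
    """
    if n_hits < 1:
        raise ValueError("n_hits must be >= 1")
    if not 0.0 <= noise_fraction <= 1.0:
        raise ValueError("noise_fraction must lie in [0, 1]")
    if decoy_subtype is None:
        decoy_subtype = "D1" if true_subtype != "D1" else "C3"
    rng = _rng(seed, "blast")

    suffixes = "abcdefghijklmnopqrstuvwxyz"
    rows = []
    bitscores = np.sort(rng.uniform(250.0, 450.0, size=n_hits))[::-1]
    for h in range(n_hits):
        subtype = decoy_subtype if rng.random() < noise_fraction else true_subtype
        strain = subtype + "".join(rng.choice(list(suffixes), size=rng.integers(1, 3)))
        evalue = 10.0 ** rng.uniform(-180.0, -110.0)
        rows.append(
            {
                "qseqid": query_id,
                "sseqid": strain,
                "pident": round(rng.uniform(96.0, 100.0), 3),
                "length": int(rng.integers(200, 320)),
                "mismatch": int(rng.integers(0, 10)),
                "gapopen": 0,
                "qstart": 1,
                "qend": 260,
                "sstart": 1,
                "send": 260,
                "evalue": evalue,
                "bitscore": round(bitscores[h], 1),
            }
        )
    return pd.DataFrame(rows, columns=_BLAST_COLUMNS)


def write_outputs(
    out_dir,
    genotypes: GenotypeMatrix,
    metadata: pd.DataFrame,
    tables: dict[str, AsvTable],
) -> list[Path]:
    """Write genotypes, metadata and count tables as tab-separated files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    path = out / "genotypes.tsv"
    genotypes.to_tsv(path)
    written.append(path)

    path = out / "metadata.tsv"
    metadata.reset_index(drop=True).to_csv(path, sep="\t", index=False)
    written.append(path)

    for name, table in tables.items():
        path = out / f"counts_{name}.tsv"
        table.to_tsv(path)
        written.append(path)
    return written
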