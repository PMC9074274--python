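"""Strategy pipelines: individual, co-assembly, and mix catalogues.

``build_catalogue`` turns a strategy's gene records into a nonredundant
catalogue:

* *individual* — greedy clustering of the pooled per-sample genes (the
  cross-sample redundancy removal step);
* *coassembly* — the co-assembly genes taken as-is (contigs derived from all
  reads already yield a nonredundant set);
* *mix* — two-stage cascade: cluster the individual-assembly proteins, then
  cluster the stage-1 representatives together with the co-assembly
  proteins; each representative keeps its provenance.

``run_benchmark`` wires the synthetic community through all three
strategies plus the read-mapping evaluation, and is the basis of the
shipped end-to-end scenario.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Literal

from .catalogue import Catalogue, CatalogueSummary, summarize
from .cluster import ClusterParams, cascade_cluster, greedy_cluster
from .mapping import (
    CoverageEstimate,
    MappingConfig,
    MappingResult,
    assign_and_count,
    estimate_coverage,
    subsample_reads,
)
from .records import GeneRecord
from .simulate import SimCommunity, SimConfig, emulate_assembly, simulate_community

logger = logging.getLogger(__name__)

Strategy = Literal["individual", "coassembly", "mix"]


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of a pipeline run (serialized into the manifest)."""

    strategy: Strategy = "mix"
    cluster_params: ClusterParams = ClusterParams()
    mapping_config: MappingConfig = MappingConfig()
    sim_config: SimConfig = SimConfig()
    seed: int = 0

    def manifest(self) -> dict:
        payload = {
            "strategy": self.strategy,
            "cluster_params": self.cluster_params.__dict__,
            "mapping_config": self.mapping_config.__dict__,
            "sim_config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.sim_config.__dict__.items()
            },
            "seed": self.seed,
        }
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]
        payload["config_hash"] = digest
        return payload


def _records_by_id(records: list[GeneRecord]) -> dict[str, GeneRecord]:
    out: dict[str, GeneRecord] = {}
    for rec in records:
        if rec.gene_id in out:
            raise ValueError(f"duplicate gene record id: {rec.gene_id}")
        out[rec.gene_id] = rec
    return out


def build_catalogue(
    strategy: Strategy,
    individual_records: list[GeneRecord] | None = None,
    coassembly_records: list[GeneRecord] | None = None,
    params: ClusterParams = ClusterParams(),
) -> Catalogue:
    """Build the nonredundant catalogue for one assembly strategy."""
    if strategy == "individual":
        if not individual_records:
            raise ValueError("individual strategy requires individual-assembly genes")
        by_id = _records_by_id(individual_records)
        clusters = greedy_cluster(
            {gid: rec.aa_seq for gid, rec in by_id.items()}, params
        )
        return Catalogue(
            name="individual",
            representatives=[by_id[c.representative_id] for c in clusters],
            provenance={c.representative_id: "from_individual" for c in clusters},
            membership={c.representative_id: list(c.member_ids) for c in clusters},
        )
    if strategy == "coassembly":
        if coassembly_records is None:
            raise ValueError("coassembly strategy requires co-assembly genes")
        by_id = _records_by_id(coassembly_records)
        return Catalogue(
            name="coassembly",
            representatives=list(by_id.values()),
            provenance={gid: "from_coassembly" for gid in by_id},
            membership={gid: [gid] for gid in by_id},
        )
    if strategy == "mix":
        if not individual_records:
            raise ValueError("mix strategy requires individual-assembly genes")
        if coassembly_records is None:
            raise ValueError("mix strategy requires co-assembly genes")
        ind_by_id = _records_by_id(individual_records)
        co_by_id = _records_by_id(coassembly_records)
        by_sample: dict[str, dict[str, str]] = {}
        for gid, rec in ind_by_id.items():
            by_sample.setdefault(rec.sample_id or "pooled", {})[gid] = rec.aa_seq
        cascade = cascade_cluster(
            by_sample, {gid: rec.aa_seq for gid, rec in co_by_id.items()}, params
        )
        all_records = {**ind_by_id, **co_by_id}
        return Catalogue(
            name="mix",
            representatives=[
                all_records[rid] for rid in cascade.representative_ids
            ],
            provenance=dict(cascade.provenance),
            membership=dict(cascade.final_members),
        )
    raise ValueError(f"unknown strategy {strategy!r}")


@dataclass
class BenchmarkResult:
    """Everything the end-to-end benchmark computes."""

    community: SimCommunity
    catalogues: dict[str, Catalogue]
    summaries: dict[str, CatalogueSummary]
    # per catalogue: per-sample mapping results
    mapping: dict[str, list[MappingResult]] = field(default_factory=dict)
    # per catalogue: pooled per-gene coverage estimates
    coverage: dict[str, dict[str, CoverageEstimate]] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def rates(self, catalogue_name: str) -> list[float]:
        return [m.mapped_fraction for m in self.mapping[catalogue_name]]


def run_benchmark(
    sim_config: SimConfig | None = None,
    cluster_params: ClusterParams = ClusterParams(),
    mapping_config: MappingConfig | None = None,
    *,
    with_mapping: bool = True,
) -> BenchmarkResult:
    """Simulate a community and evaluate all three assembly strategies.

    The mapping stage subsamples each sample's forward reads, counts reads
    per gene for every catalogue, and pools the counts into per-gene
    coverage estimates on the total-metagenome scale.
    """
    sim_config = sim_config or SimConfig()
    if mapping_config is None:
        # benchmark-sized subsample (a quarter of each sample's reads)
        mapping_config = MappingConfig(
            n_subsample=max(1, sim_config.reads_per_sample // 4),
            seed=100,
        )
    community = simulate_community(sim_config)
    ind_records = emulate_assembly(community, "individual")
    co_records = emulate_assembly(community, "coassembly")
    logger.info(
        "emulated assembly: %d individual records, %d co-assembly records",
        len(ind_records),
        len(co_records),
    )

    catalogues = {
        "individual": build_catalogue(
            "individual", individual_records=ind_records, params=cluster_params
        ),
        "coassembly": build_catalogue(
            "coassembly", coassembly_records=co_records, params=cluster_params
        ),
        "mix": build_catalogue(
            "mix",
            individual_records=ind_records,
            coassembly_records=co_records,
            params=cluster_params,
        ),
    }
    summaries = {name: summarize(cat) for name, cat in catalogues.items()}
    result = BenchmarkResult(
        community=community,
        catalogues=catalogues,
        summaries=summaries,
        manifest=RunConfig(
            strategy="mix",
            cluster_params=cluster_params,
            mapping_config=mapping_config,
            sim_config=sim_config,
            seed=sim_config.seed,
        ).manifest(),
    )
    if not with_mapping:
        return result

    from .simulate import simulate_reads

    all_readsets = []
    for j in range(sim_config.n_samples):
        readset, _ = simulate_reads(community, j)
        all_readsets.append(subsample_reads(readset, mapping_config))

    n_sampled_total = sum(len(rs) for rs in all_readsets)
    total_pairs = community.total_read_pairs()
    avg_pair_len = 2.0 * sim_config.read_length
    for name, cat in catalogues.items():
        per_sample = [
            assign_and_count(rs, cat, mapping_config) for rs in all_readsets
        ]
        result.mapping[name] = per_sample
        pooled_counts: dict[str, int] = {}
        for m in per_sample:
            for gid, c in m.counts.items():
                pooled_counts[gid] = pooled_counts.get(gid, 0) + c
        gene_lengths = {r.gene_id: r.nt_length for r in cat.representatives}
        result.coverage[name] = estimate_coverage(
            pooled_counts, gene_lengths, avg_pair_len, total_pairs, n_sampled_total
        )
    return result


def provenance_read_shares(
    result: BenchmarkResult, catalogue_name: str = "mix"
) -> dict[str, dict[str, int]]:
    """Reads mapped to each coverage bin, split by representative provenance
    (the contribution analysis of individual- vs co-assembly genes)."""
    cat = result.catalogues[catalogue_name]
    cov = result.coverage[catalogue_name]
    pooled: dict[str, int] = {}
    for m in result.mapping[catalogue_name]:
        for gid, c in m.counts.items():
            pooled[gid] = pooled.get(gid, 0) + c
    out: dict[str, dict[str, int]] = {}
    for gid, count in pooled.items():
        bin_label = cov[gid].bin
        prov = cat.provenance.get(gid, "unknown")
        out.setdefault(bin_label, {}).setdefault(prov, 0)
        out[bin_label][prov] += count
    return out
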