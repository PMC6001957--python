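"""Pipeline orchestration: mine -> consensus -> date -> cophylo -> network.

Stages communicate only through documented on-disk formats (FASTA, newick,
tabular hits, TSV), so any stage's input can be swapped for genuine external
tool output (a real translated-search table, a real tree).  A run is driven
by one YAML config with a section per stage and produces a machine-readable
JSON report carrying per-stage input/output counts, parameters, seeds and
output checksums; identical config + seeds give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

from . import consensus as cns
from . import cophylogeny as cph
from . import dating as dat
from . import mining as mng
from . import transmission as tns
from .core_io import (load_config, read_association_table, read_fasta,
                      read_group_table, read_hits_table, write_fasta)
from .core_io import SequenceRecord
from .phylo import parse_newick

logger = logging.getLogger("ervpipe.pipeline")

STAGES = ("mine", "consensus", "dating", "cophylogeny", "transmission")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_config(config: dict) -> list[str]:
    """Empty list iff the config is runnable; each problem names its field."""
    problems: list[str] = []
    if "output_dir" not in config:
        problems.append("output_dir is required")
    for stage in STAGES:
        if stage not in config:
            problems.append(f"missing stage section: {stage}")
    if problems:
        return problems

    def need_paths(stage: str, keys: list[str]) -> None:
        for key in keys:
            val = config[stage].get(key)
            if val is None:
                problems.append(f"{stage}.{key} is required")
            elif not Path(val).exists():
                problems.append(f"{stage}.{key}: no such file {val}")

    need_paths("mine", ["genome", "hits", "tree", "labels"])
    if config["mine"].get("evalue_max", 1e-5) <= 0:
        problems.append("mine.evalue_max must be > 0")
    for key in ("max_genomic_gap", "max_query_gap"):
        if config["mine"].get(key, 0) < 0:
            problems.append(f"mine.{key} must be >= 0")
    need_paths("consensus", ["clusters", "paralog_hits"])
    if config["consensus"].get("flank", 5000) < 0:
        problems.append("consensus.flank must be >= 0")
    need_paths("dating", ["alignment"])
    mu_low = config["dating"].get("mu_low", dat.MU_LOW)
    mu_high = config["dating"].get("mu_high", dat.MU_HIGH)
    if mu_low <= 0 or mu_high <= 0:
        problems.append("dating.mu bounds must be positive")
    elif mu_low > mu_high:
        problems.append("dating.mu_low must be <= dating.mu_high")
    need_paths("cophylogeny", ["host", "virus", "associations"])
    if config["cophylogeny"].get("n_random", 500) < 1:
        problems.append("cophylogeny.n_random must be >= 1")
    if not config["cophylogeny"].get("schemes"):
        problems.append("cophylogeny.schemes must list at least one scheme")
    need_paths("transmission", ["tree", "groups"])
    return problems


def run_pipeline(config: dict, config_path: Optional[str] = None) -> dict:
    """Execute all stages in order; returns (and writes) the run report."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out_dir = Path(config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config_path, "stages": {}}

    def record(stage: str, params: dict, counts: dict, outputs: list[Path]) -> None:
        report["stages"][stage] = {
            "params": params,
            "counts": counts,
            "outputs": {str(p): _sha256(p) for p in outputs},
        }
        logger.info("stage %s: %s", stage, counts)

    # ---- mine ----------------------------------------------------------
    c = config["mine"]
    try:
        genome = read_fasta(c["genome"])
        hits = read_hits_table(c["hits"])
        tree = parse_newick(Path(c["tree"]).read_text())
        groups, _ = read_group_table(c["labels"])
        labels = mng.ReferenceLabelSet(groups)
        params = {
            "evalue_max": float(c.get("evalue_max", mng.DEFAULT_EVALUE_MAX)),
            "max_genomic_gap": int(c.get("max_genomic_gap",
                                         mng.DEFAULT_MAX_GENOMIC_GAP)),
            "max_query_gap": int(c.get("max_query_gap",
                                       mng.DEFAULT_MAX_QUERY_GAP)),
            "species": c.get("species", ""),
        }
        prefix = str(out_dir / "mine")
        loci = mng.mine(genome, hits, tree, labels, out_prefix=prefix, **params)
    except Exception as exc:
        raise RuntimeError(f"stage mine failed: {exc}") from exc
    record("mine", params,
           {"hits_in": len(hits), "loci_out": len(loci),
            "erv": sum(l.status == "erv" for l in loci)},
           [Path(prefix + ".loci.tsv"), Path(prefix + ".loci.fasta")])

    # ---- consensus -----------------------------------------------------
    c = config["consensus"]
    try:
        genome_map = {r.id: r.residues for r in genome}
        loci_by_id = {l.locus_id: l for l in loci}
        clusters: dict[str, list[str]] = {}
        for line in Path(c["clusters"]).read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            cid, lid = line.split("\t")[:2]
            clusters.setdefault(cid, []).append(lid)
        paralog_hits = read_hits_table(c["paralog_hits"])
        flank = int(c.get("flank", cns.DEFAULT_FLANK))
        evmax = float(c.get("evalue_max", cns.PARALOG_EVALUE_MAX))
        pol = c.get("pol_interval")
        pol = tuple(pol) if pol else None
        records = []
        for cid, lids in sorted(clusters.items()):
            members = [loci_by_id[x] for x in lids if x in loci_by_id]
            if not members:
                raise ValueError(f"cluster {cid} references no mined locus")
            cluster = cns.ErvCluster(cid, members)
            rec = cns.consensus_for_cluster(
                cluster, genome_map,
                [h for h in paralog_hits if h.query_id == cid
                 or h.query_id == cns.select_representative(cluster).locus_id],
                pol_interval=pol, flank=flank, evalue_max=evmax)
            records.append(SequenceRecord(
                f"{rec.cluster_id}|{rec.species}|depth_max={max(rec.depth_profile)}",
                rec.residues))
        consensus_path = out_dir / "consensus.fasta"
        write_fasta(records, consensus_path)
    except Exception as exc:
        raise RuntimeError(f"stage consensus failed: {exc}") from exc
    record("consensus", {"flank": flank, "evalue_max": evmax},
           {"clusters_in": len(clusters), "consensus_out": len(records)},
           [consensus_path])

    # ---- dating --------------------------------------------------------
    c = config["dating"]
    try:
        aln = read_fasta(c["alignment"])
        mu_low = float(c.get("mu_low", dat.MU_LOW))
        mu_high = float(c.get("mu_high", dat.MU_HIGH))
        d_max, pair = dat.max_pairwise_distance(
            [r.residues for r in aln], [r.id for r in aln])
        res = dat.invasion_time(d_max, (mu_low, mu_high))
        dating_path = out_dir / "dating.tsv"
        with open(dating_path, "w") as fh:
            fh.write("d_max\tpair\tt_low_my\tt_high_my\n")
            fh.write(f"{res.d_max:.6f}\t{pair[0]},{pair[1]}\t"
                     f"{res.t_low / 1e6:.2f}\t{res.t_high / 1e6:.2f}\n")
    except Exception as exc:
        raise RuntimeError(f"stage dating failed: {exc}") from exc
    record("dating", {"mu_low": mu_low, "mu_high": mu_high},
           {"sequences_in": len(aln)}, [dating_path])

    # ---- cophylogeny ---------------------------------------------------
    c = config["cophylogeny"]
    try:
        host = parse_newick(Path(c["host"]).read_text())
        virus = parse_newick(Path(c["virus"]).read_text())
        assoc = read_association_table(c["associations"], virus_tree=virus)
        problem = cph.CophylogenyProblem(host, virus, assoc)
        schemes = [cph.CostScheme.from_string(s) for s in c["schemes"]]
        n_random = int(c.get("n_random", 500))
        seed = int(c.get("seed", config.get("seed", 0)))
        table = cph.summarize_table({"lineage": problem}, schemes,
                                    n_random=n_random, seed=seed)
        cophylo_path = out_dir / "cophylogeny.tsv"
        table.to_csv(cophylo_path, sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage cophylogeny failed: {exc}") from exc
    record("cophylogeny",
           {"schemes": c["schemes"], "n_random": n_random, "seed": seed},
           {"virus_tips": virus.n_tips(), "host_tips": host.n_tips(),
            "rows_out": len(table)}, [cophylo_path])

    # ---- transmission --------------------------------------------------
    c = config["transmission"]
    try:
        vtree = parse_newick(Path(c["tree"]).read_text())
        groups, habitats = read_group_table(c["groups"])
        gmap = tns.HostGroupMap(groups, habitats)
        collapsed = tns.collapse_by_group(vtree, gmap)
        net = tns.count_terminal_transmissions(collapsed)
        edges_path = out_dir / "network.edges.tsv"
        tns.write_network(net, str(edges_path))
        n_waterland = (tns.annotate_habitat_transitions(collapsed, gmap)
                       if habitats else None)
    except Exception as exc:
        raise RuntimeError(f"stage transmission failed: {exc}") from exc
    record("transmission", {"habitats": bool(habitats)},
           {"tips_in": vtree.n_tips(), "groups_out": collapsed.n_tips(),
            "edges_out": net.number_of_edges(),
            "water_land_cherries": n_waterland}, [edges_path])

    report_path = out_dir / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def run_from_file(config_path: str) -> dict:
    return run_pipeline(load_config(config_path), config_path=config_path)
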