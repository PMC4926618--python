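"""End-to-end survey analysis: conditioning, grouping, trees, assignment,
delimitation, richness and morphospecies comparison, with a checksummed
artifact manifest.

The identification track runs prep (orient, trim, dereplicate), threshold
clustering, reference recruitment, per-group alignment + bootstrapped tree +
midpoint rooting, and strict/liberal taxonomic assignment.  The delimitation
track aligns all dereplicated queries, builds an ultrametric (UPGMA) tree or
a midpoint-rooted NJ tree, delimits species (GMYC or PTP), expands entities
back over collapsed haplotypes, and feeds the entity-by-event incidence into
accumulation curves and richness extrapolation; morphospecies labels, when
present in the input metadata, are compared against the molecular partition.

All stage outputs are plain text; the manifest records a SHA-256 checksum of
every artifact so that two same-seed runs can be compared byte for byte.
Stage failures keep whatever was written, renamed with a ``.partial``
suffix.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import pandas as pd

from .compare import compare_partitions
from .delimit import gmyc_fit, gmyc_lr_test, ptp_fit
from .errors import DataError
from .io import read_fasta, read_lineage_table, write_fasta
from .records import IncidenceMatrix, ReferenceLibrary, check_unique_ids
from .richness import accumulation_curve, completeness, richness_report
from .seqprep import (anchor_align, cluster_by_threshold, dereplicate,
                      distance_matrix, orient_sequences, progressive_align,
                      recruit_references, trim_to_marker)
from .taxassign import assign_all, assignments_table
from .trees import bootstrap_support, build_tree, check_ultrametric, polarise

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    queries: str
    reference_fasta: str
    lineage_tsv: str
    out_dir: str
    seed: int
    d_max: float = 0.05           # query grouping threshold (p-distance)
    recruit_d_max: float = 0.10   # reference recruitment threshold
    s_min: float = 0.70           # support bar for strict assignment
    bootstrap_B: int = 100
    l_min: int = 100              # minimum post-trim length
    tree_method: str = "nj"       # group trees: nj | upgma
    delimit_method: str = "gmyc"  # gmyc | ptp
    skip_orient: bool = False
    skip_trim: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        missing = {"queries", "reference_fasta", "lineage_tsv", "out_dir",
                   "seed"} - set(data)
        if missing:
            raise DataError(f"missing config keys: {sorted(missing)}")
        return cls(**data)

    def validate(self) -> None:
        for key in ("queries", "reference_fasta", "lineage_tsv"):
            path = Path(getattr(self, key))
            if not path.exists():
                raise DataError(f"{key} file not found: {path}")
        if self.d_max < 0 or self.recruit_d_max < 0:
            raise DataError("divergence thresholds must be nonnegative")
        if not 0 <= self.s_min <= 1.01:
            raise DataError("s_min must be in [0, 1]")
        if self.bootstrap_B < 1:
            raise DataError("bootstrap_B must be >= 1")
        if self.tree_method not in ("nj", "upgma"):
            raise DataError(f"unknown tree method {self.tree_method!r}")
        if self.delimit_method not in ("gmyc", "ptp"):
            raise DataError(f"unknown delimit method {self.delimit_method!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full survey analysis; returns the manifest dictionary."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit_df(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)

    try:
        # ---------------------------------------------------------- stage: load
        queries = read_fasta(cfg.queries)
        refs = read_fasta(cfg.reference_fasta)
        lineages = read_lineage_table(cfg.lineage_tsv)
        lib = ReferenceLibrary(
            records=refs,
            lineages={r.id: lineages.get(r.id) for r in refs
                      if lineages.get(r.id) is not None})
        lib.check_disjoint(queries)
        check_unique_ids(queries)
        logger.info("loaded %d queries, %d references", len(queries),
                    len(lib))

        # ---------------------------------------------------------- stage: prep
        if not cfg.skip_orient:
            queries, orient_report = orient_sequences(queries, lib.records)
            emit_df(orient_report, "orient_report.tsv")
        anchor = max(lib.records, key=lambda r: (len(r), r.id))
        if not cfg.skip_trim:
            queries, trim_report = trim_to_marker(queries, anchor,
                                                 l_min=cfg.l_min)
            emit_df(trim_report, "trim_report.tsv")
        reps, derep_map = dereplicate(queries)
        emit_df(pd.DataFrame(sorted(derep_map.items()),
                             columns=["id", "representative"]),
                "dereplication.tsv")
        logger.info("%d unique haplotypes from %d queries", len(reps),
                    len(queries))

        # ------------------------------------------------------- stage: cluster
        dm = distance_matrix(reps, model="p", screen_k=8)
        groups = cluster_by_threshold(dm, cfg.d_max)
        emit_df(pd.DataFrame([{"group": g.group_id, "member": m}
                              for g in groups for m in g.members]),
                "groups.tsv")

        # ------------------------------------- stage: per-group trees + assign
        rep_by_id = {r.id: r for r in reps}
        group_trees = {}
        group_queries = {}
        recruit_logs = []
        for group in groups:
            group, rlog = recruit_references(
                group, reps, lib, d_max=cfg.recruit_d_max)
            recruit_logs.append(rlog)
            if group.flagged:
                continue
            members = [rep_by_id[m] for m in group.members]
            ref_recs = [r for r in lib.records if r.id in group.refs]
            seqs = members + ref_recs
            if len(seqs) < 2:
                continue
            aln = progressive_align(seqs)
            if len(aln) >= 4:
                tree = bootstrap_support(aln, method=cfg.tree_method,
                                         B=cfg.bootstrap_B, seed=cfg.seed)
            else:
                tree = build_tree(distance_matrix(aln),
                                  method=cfg.tree_method)
            rooted = polarise(tree, "midpoint") if not tree.rooted else tree
            rooted.write_newick(out / f"group_{group.group_id}.nwk")
            written.append(out / f"group_{group.group_id}.nwk")
            group_trees[group.group_id] = rooted
            group_queries[group.group_id] = list(group.members)
        emit_df(pd.concat(recruit_logs, ignore_index=True)
                if recruit_logs else pd.DataFrame(), "recruitment.tsv")

        assignments, rank_summary = assign_all(
            group_trees, group_queries, lib.lineages, s_min=cfg.s_min)
        # expand assignments over collapsed duplicates
        by_rep = {a.query: a for a in assignments}
        rows = []
        for qid, rep in sorted(derep_map.items()):
            a = by_rep.get(rep)
            if a is None:
                rows.append({"query": qid, "strict": "", "liberal": "",
                             "support": 0.0, "n_refs": 0, "clade_size": 0,
                             "flag": "unidentifiable group"})
            else:
                row = assignments_table([a]).iloc[0].to_dict()
                row["query"] = qid
                rows.append(row)
        emit_df(pd.DataFrame(rows), "assignments.tsv")
        emit_df(rank_summary, "assignment_rank_summary.tsv")

        # --------------------------------------------- stage: delimit + richness
        # the all-query alignment spans divergence levels far beyond what
        # de-novo progressive alignment handles reliably, so it is pinned to
        # the marker exemplar's coordinate system instead
        results: dict = {}
        aln_all = anchor_align(reps, anchor)
        write_fasta(aln_all, out / "query_alignment.fasta")
        written.append(out / "query_alignment.fasta")
        if cfg.delimit_method == "gmyc":
            from .trees import upgma_from_alignment
            gtree = upgma_from_alignment(aln_all)
            ok, _ = check_ultrametric(gtree)
            if not ok:
                raise DataError("UPGMA tree failed ultrametricity check")
            fit = gmyc_fit(gtree, seed=cfg.seed)
            lr, p_value = gmyc_lr_test(fit)
            partition_reps = fit.partition
            results["delimitation"] = {
                "method": "gmyc", "n_entities": fit.n_entities,
                "n_clusters": fit.n_clusters,
                "ci_entities": list(fit.ci_entities),
                "logL": round(fit.logL, 6),
                "logL_null": round(fit.logL_null, 6),
                "LR": round(lr, 6), "p_value": round(p_value, 8),
            }
            gtree.write_newick(out / "delimitation_tree.nwk")
            written.append(out / "delimitation_tree.nwk")
        else:
            ntree = build_tree(distance_matrix(aln_all), method="nj")
            rooted = polarise(ntree, "midpoint")
            fit = ptp_fit(rooted, mode="greedy")
            partition_reps = fit.partition
            results["delimitation"] = {
                "method": "ptp", "n_species": fit.n_species,
                "logL": round(fit.logL, 6),
            }
            rooted.write_newick(out / "delimitation_tree.nwk")
            written.append(out / "delimitation_tree.nwk")

        partition = {qid: partition_reps[rep]
                     for qid, rep in derep_map.items()}
        emit_df(pd.DataFrame(sorted(partition.items()),
                             columns=["tip", "entity"]),
                "delimitation.tsv")

        q_by_id = {q.id: q for q in queries}
        with_events = [qid for qid in partition
                       if q_by_id[qid].event_id is not None]
        if len(with_events) < len(partition):
            logger.warning("%d queries lack event metadata; excluded from "
                           "incidence", len(partition) - len(with_events))
        if with_events:
            inc = IncidenceMatrix.from_observations(
                [partition[q] for q in with_events],
                [q_by_id[q].event_id for q in with_events])
            inc.to_csv(out / "incidence.csv")
            written.append(out / "incidence.csv")
            curve = accumulation_curve(inc, "analytic")
            emit_df(pd.DataFrame({"events": range(1, inc.n_events + 1),
                                  "expected_species": curve.round(6)}),
                    "accumulation.tsv")
            if inc.n_events >= 2:
                report = richness_report(inc)
                results["richness"] = {
                    name: {"S_obs": est.S_obs,
                           "S_hat": round(est.S_hat, 4),
                           "completeness": round(
                               completeness(est.S_obs, est), 4)}
                    for name, est in sorted(report.items())
                }

        morph = {qid: q_by_id[qid].morphospecies for qid in partition
                 if q_by_id[qid].morphospecies is not None}
        if morph:
            cmpres = compare_partitions(
                {q: partition[q] for q in morph}, morph)
            results["morphospecies_comparison"] = {
                "adjusted_rand": round(cmpres.adjusted_rand, 6),
                "class_counts": cmpres.class_counts,
            }

        summary_path = out / "summary.json"
        summary_path.write_text(json.dumps(results, indent=2,
                                           sort_keys=True) + "\n")
        written.append(summary_path)

        manifest = {
            "config": asdict(cfg),
            "artifacts": {p.name: _sha256(p) for p in sorted(written)},
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return manifest
    except Exception:
        for path in written:
            if path.exists():
                path.rename(path.with_suffix(path.suffix + ".partial"))
        raise
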