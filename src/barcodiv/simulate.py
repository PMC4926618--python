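"""Synthetic barcode-survey generator.

Provides ground truth for every other stage of the toolkit: a Yule species
tree, within-species gene genealogies under the censored multispecies
coalescent, sequence evolution (Jukes-Cantor or Kimura 2-parameter, optional
indels), ranked taxonomies obtained by cutting the species tree at fixed
depths, sampling-event structure with imperfect detection, and morphospecies
labels with controlled lumping/splitting error.

All times are measured in expected substitutions per site, so gene-tree
branch lengths feed the sequence simulator directly; the coalescent scale
``theta`` is in the same unit (a random pair within a species coalesces
``theta/2`` back in time on average).

Every operation takes a seed (or an already-spawned numpy Generator) and is
fully deterministic for a given seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .errors import DataError
from .phylo import PhyloTree, parse_newick, tip_label
from .records import IncidenceMatrix, Lineage, SequenceRecord

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated multi-species barcode survey.

    Defaults emulate a tropical leaf-beetle style survey at desk scale:
    10 well-separated species (species-tree height a few tenths of a
    substitution/site, within-species depth two orders of magnitude
    shallower), 5 individuals per species, an ~830 bp mitochondrial barcode
    with transition bias, 10 sampling events with imperfect detection, and a
    small morphospecies error rate.
    """

    n_species: int = 10
    yule_rate: float = 5.0
    theta: float = 0.01
    samples_per_species: int = 5
    abundance: str = "fixed"  # "fixed" | "geometric" (mean = samples_per_species)
    seq_length: int = 830
    subst_model: str = "k2p"  # "jc" | "k2p"
    kappa: float = 4.0
    indel_rate: float = 0.0  # events per site per unit branch length
    n_events: int = 10
    detection: float = 0.5
    morph_lump: float = 0.05
    morph_split: float = 0.05
    genus_cut: float = 0.5   # fraction of species-tree height
    family_cut: float = 0.85
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 1:
            raise DataError("n_species must be >= 1")
        if self.yule_rate <= 0 or self.theta <= 0:
            raise DataError("yule_rate and theta must be positive")
        if self.samples_per_species < 1:
            raise DataError("samples_per_species must be >= 1")
        if self.abundance not in ("fixed", "geometric"):
            raise DataError(f"unknown abundance model {self.abundance!r}")
        if self.seq_length < 1:
            raise DataError("seq_length must be positive")
        if self.subst_model not in ("jc", "k2p"):
            raise DataError(f"unknown substitution model {self.subst_model!r}")
        if self.indel_rate < 0:
            raise DataError("indel_rate must be nonnegative")
        if self.n_events < 1:
            raise DataError("n_events must be >= 1")
        if not 0 < self.detection <= 1:
            raise DataError("detection must be in (0, 1]")
        if not (0 <= self.morph_lump < 1 and 0 <= self.morph_split < 1):
            raise DataError("morphospecies error rates must be in [0, 1)")
        if not 0 < self.genus_cut < self.family_cut < 1:
            raise DataError("need 0 < genus_cut < family_cut < 1")


@dataclass
class SyntheticSurvey:
    """A simulated survey with complete ground truth."""

    config: SimConfig
    species_tree: PhyloTree
    gene_tree: PhyloTree
    records: list[SequenceRecord]            # unaligned (degapped)
    aligned_records: list[SequenceRecord]    # true alignment
    true_partition: dict[str, str]           # tip id -> species id
    lineages: dict[str, Lineage]             # tip id -> ranked taxonomy
    species_lineages: dict[str, Lineage]     # species id -> ranked taxonomy
    incidence: IncidenceMatrix
    morphospecies: dict[str, str]            # tip id -> morphospecies label


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ------------------------------------------------------------- species tree
def sim_species_tree(n: int, rate: float, seed=0) -> PhyloTree:
    """Yule pure-birth tree conditioned on ``n`` tips.

    Simulated backwards: with k lineages the next (older) join is an
    exponential ``rate * k`` waiting time and merges a uniformly chosen pair,
    which reproduces the Yule labelled-history distribution; the expected
    root age is ``sum_{k=2..n} 1/(rate*k)``.
    """
    if n < 1:
        raise DataError("n must be >= 1")
    rng = _rng(seed)
    labels = [f"sp{i + 1:02d}" for i in range(n)]
    if n == 1:
        return parse_newick(f"{labels[0]};")
    frags = {lab: (lab, 0.0) for lab in labels}
    active = list(labels)
    age = 0.0
    for k in range(n, 1, -1):
        age += rng.exponential(1.0 / (rate * k))
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        (sa, ta), (sb, tb) = frags.pop(a), frags.pop(b)
        merged = f"({sa}:{age - ta:.12g},{sb}:{age - tb:.12g})"
        key = f"__{k}"
        frags[key] = (merged, age)
        active = [x for x in active if x not in (a, b)] + [key]
    newick = next(iter(frags.values()))[0] + ";"
    return parse_newick(newick)


# ---------------------------------------------------------------- gene tree
def sim_gene_tree(sp_tree: PhyloTree, samples: Mapping[str, int] | int,
                  theta: float, seed=0) -> PhyloTree:
    """Censored multispecies coalescent within a species tree.

    Within each species-tree branch, the lineages present coalesce at rate
    ``pairs * 2/theta``, truncated at the top of the branch; survivors enter
    the ancestral population.  At the root population coalescence runs to a
    single lineage.  Gene-tree tips are labelled ``<species>_i<k>``.
    """
    rng = _rng(seed)
    if isinstance(samples, int):
        samples = {lab: samples for lab in sp_tree.tip_labels}
    ages = sp_tree.node_ages()
    # lineage = (newick fragment, age of its most recent end)
    pending: dict = {}

    def coalesce(lineages, t0, t1):
        lineages = list(lineages)
        t = t0
        while len(lineages) >= 2:
            k = len(lineages)
            t += rng.exponential(theta / (k * (k - 1)))  # pairs * 2/theta
            if t >= t1:
                break
            i, j = sorted(rng.choice(k, size=2, replace=False))
            (sa, ta) = lineages[i]
            (sb, tb) = lineages[j]
            merged = (f"({sa}:{t - ta:.12g},{sb}:{t - tb:.12g})", t)
            lineages = [x for idx, x in enumerate(lineages)
                        if idx not in (i, j)] + [merged]
        return lineages

    for node in sp_tree.dt.postorder_node_iter():
        if node.is_leaf():
            sp = tip_label(node)
            n_s = samples[sp]
            if n_s < 1:
                raise DataError(f"species {sp} needs >= 1 sample")
            entering = [(f"{sp}_i{k + 1}", 0.0) for k in range(n_s)]
            bottom = ages[node]
        else:
            entering = []
            for child in node.child_nodes():
                entering.extend(pending.pop(child))
            bottom = ages[node]
        top = ages[node.parent_node] if node.parent_node is not None \
            else np.inf
        pending[node] = coalesce(entering, bottom, top)

    survivors = pending.pop(sp_tree.root)
    if len(survivors) != 1:
        survivors = coalesce(survivors, max(t for _, t in survivors), np.inf)
    frag, _ = survivors[0]
    if not frag.startswith("("):
        frag = f"({frag}:0)"
    return parse_newick(frag + ";")


# ----------------------------------------------------------------- sequences
def _rate_matrix(model: str, kappa: float) -> np.ndarray:
    """GTR-style rate matrix (ACGT order) scaled to one expected
    substitution per unit branch length."""
    if model == "jc":
        kappa = 1.0
    q = np.ones((4, 4))
    # transitions: A<->G (0,2), C<->T (1,3)
    q[0, 2] = q[2, 0] = q[1, 3] = q[3, 1] = kappa
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -0.25 * np.trace(q)
    return q / mean_rate


def sim_sequences(tree: PhyloTree, seq_length: int = 830,
                  subst_model: str = "jc", kappa: float = 4.0,
                  indel_rate: float = 0.0, seed=0
                  ) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Evolve sequences down a tree.

    Returns ``(unaligned, aligned)`` record lists; with ``indel_rate`` 0 the
    two coincide (no gaps).  Substitutions follow the scaled rate matrix of
    the chosen model; indels occur as Poisson events per branch with
    geometric lengths (mean 3), insertions and deletions equally likely.
    """
    rng = _rng(seed)
    q = _rate_matrix(subst_model, kappa)
    trans_cache: dict[float, np.ndarray] = {}

    def pmatrix(t: float) -> np.ndarray:
        if t not in trans_cache:
            trans_cache[t] = expm(q * t)
        return trans_cache[t]

    # column registry for the true alignment
    order: list[int] = list(range(seq_length))
    next_col = seq_length

    root_bases = rng.integers(0, 4, size=seq_length)
    # node sequence: list of (column id, base index), 5' -> 3'
    root_seq = list(zip(order, root_bases))
    seqs: dict = {tree.root: root_seq}
    tip_seqs: dict[str, list] = {}

    for node in tree.dt.preorder_node_iter():
        if node is tree.root:
            pass
        else:
            parent_seq = seqs[node.parent_node]
            t = node.edge.length
            cols = np.array([c for c, _ in parent_seq], dtype=int)
            bases = np.array([b for _, b in parent_seq], dtype=int)
            if t > 0 and len(bases):
                p = pmatrix(t)
                new = np.empty_like(bases)
                for parent_base in range(4):
                    mask = bases == parent_base
                    if mask.any():
                        new[mask] = rng.choice(4, size=int(mask.sum()),
                                               p=p[parent_base])
                bases = new
            seq = list(zip(cols.tolist(), bases.tolist()))
            if indel_rate > 0 and len(seq):
                n_events = rng.poisson(indel_rate * len(seq) * t)
                for _ in range(n_events):
                    length = rng.geometric(1.0 / 3.0)
                    pos = int(rng.integers(0, len(seq)))
                    if rng.random() < 0.5:  # deletion
                        del seq[pos:pos + length]
                    else:  # insertion after pos
                        anchor_col = seq[pos][0]
                        new_cols = list(range(next_col, next_col + length))
                        next_col += length
                        at = order.index(anchor_col) + 1
                        order[at:at] = new_cols
                        ins = [(c, int(rng.integers(0, 4)))
                               for c in new_cols]
                        seq[pos + 1:pos + 1] = ins
            seqs[node] = seq
        if node.is_leaf():
            tip_seqs[tip_label(node)] = seqs[node]

    col_rank = {c: i for i, c in enumerate(order)}
    used = sorted({c for s in tip_seqs.values() for c, _ in s},
                  key=col_rank.get)
    col_pos = {c: i for i, c in enumerate(used)}
    unaligned, aligned = [], []
    for label in sorted(tip_seqs):
        seq = tip_seqs[label]
        row = np.full(len(used), "-", dtype="<U1")
        for c, b in seq:
            row[col_pos[c]] = _BASES[b]
        gapped = "".join(row)
        aligned.append(SequenceRecord(id=label, bases=gapped, marker="sim"))
        unaligned.append(SequenceRecord(id=label,
                                        bases=gapped.replace("-", ""),
                                        marker="sim"))
    return unaligned, aligned


# -------------------------------------------------------------------- survey
def _taxon_groups(sp_tree: PhyloTree, cut_age: float) -> list[set[str]]:
    """Clades of species subtended by edges crossing the given age."""
    if sp_tree.n_tips == 1:
        return [set(sp_tree.tip_labels)]
    ages = sp_tree.node_ages()
    groups = []
    for node in sp_tree.dt.preorder_node_iter():
        if node.parent_node is None:
            if ages[node] <= cut_age:
                groups.append({tip_label(lf) for lf in node.leaf_iter()})
            continue
        if ages[node] <= cut_age < ages[node.parent_node]:
            groups.append({tip_label(lf) for lf in node.leaf_iter()})
    return groups


def sim_survey(cfg: SimConfig) -> SyntheticSurvey:
    """Compose species tree, gene tree, sequences, taxonomy, sampling events
    and noisy morphospecies labels into one fully scored survey."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(6)]
    r_sptree, r_samples, r_genetree, r_seq, r_events, r_morph = rngs

    sp_tree = sim_species_tree(cfg.n_species, cfg.yule_rate, r_sptree)
    species = sorted(sp_tree.tip_labels)

    if cfg.abundance == "fixed":
        samples = {sp: cfg.samples_per_species for sp in species}
    else:
        samples = {sp: int(r_samples.geometric(1.0 / cfg.samples_per_species))
                   for sp in species}

    gene_tree = sim_gene_tree(sp_tree, samples, cfg.theta, r_genetree)
    unaligned, aligned = sim_sequences(
        gene_tree, seq_length=cfg.seq_length, subst_model=cfg.subst_model,
        kappa=cfg.kappa, indel_rate=cfg.indel_rate, seed=r_seq)

    true_partition = {rec.id: rec.id.rsplit("_i", 1)[0] for rec in unaligned}

    # ranked taxonomy from tree-depth cuts
    height = sp_tree.height()
    genus_groups = _taxon_groups(sp_tree, cfg.genus_cut * height)
    family_groups = _taxon_groups(sp_tree, cfg.family_cut * height)
    genus_of = {}
    for k, grp in enumerate(sorted(genus_groups, key=min)):
        for sp in grp:
            genus_of[sp] = f"gen{k + 1:02d}"
    family_of = {}
    for k, grp in enumerate(sorted(family_groups, key=min)):
        for sp in grp:
            family_of[sp] = f"fam{k + 1:02d}"
    species_lineages = {
        sp: Lineage((("family", family_of[sp]), ("genus", genus_of[sp]),
                     ("species", sp)))
        for sp in species
    }

    # sampling events with imperfect detection
    event_ids = [f"ev{k + 1:02d}" for k in range(cfg.n_events)]
    occupied = {}
    for sp in species:
        occ = [e for e in event_ids if r_events.random() < cfg.detection]
        if not occ:
            occ = [event_ids[int(r_events.integers(0, cfg.n_events))]]
        occupied[sp] = occ
    event_of = {}
    for rec in unaligned:
        sp = true_partition[rec.id]
        occ = occupied[sp]
        event_of[rec.id] = occ[int(r_events.integers(0, len(occ)))]

    # morphospecies labels with lump/split noise
    label_of_species = {sp: f"m_{sp}" for sp in species}
    for sp in species:
        congeners = [o for o in species
                     if o != sp and genus_of[o] == genus_of[sp]]
        if congeners and r_morph.random() < cfg.morph_lump:
            partner = congeners[int(r_morph.integers(0, len(congeners)))]
            label_of_species[sp] = label_of_species[partner]
    split_species = {sp for sp in species
                     if r_morph.random() < cfg.morph_split}
    morphospecies = {}
    for rec in unaligned:
        sp = true_partition[rec.id]
        label = label_of_species[sp]
        if sp in split_species:
            label = f"{label}{'ab'[int(r_morph.integers(0, 2))]}"
        morphospecies[rec.id] = label

    records = [
        SequenceRecord(id=rec.id, bases=rec.bases, marker=rec.marker,
                       event_id=event_of[rec.id],
                       morphospecies=morphospecies[rec.id])
        for rec in unaligned
    ]
    aligned_records = [
        SequenceRecord(id=rec.id, bases=rec.bases, marker=rec.marker,
                       event_id=event_of[rec.id],
                       morphospecies=morphospecies[rec.id])
        for rec in aligned
    ]
    incidence = IncidenceMatrix.from_observations(
        [true_partition[r.id] for r in records],
        [event_of[r.id] for r in records])
    lineages = {rec.id: species_lineages[true_partition[rec.id]]
                for rec in records}
    return SyntheticSurvey(
        config=cfg, species_tree=sp_tree, gene_tree=gene_tree,
        records=records, aligned_records=aligned_records,
        true_partition=true_partition, lineages=lineages,
        species_lineages=species_lineages, incidence=incidence,
        morphospecies=morphospecies)


def split_reference_library(survey: SyntheticSurvey,
                            refs_per_species: int = 1):
    """Partition a survey into queries and a taxonomically tagged reference
    library (the first ``refs_per_species`` individuals of each species, in
    id order, become references)."""
    from .records import ReferenceLibrary

    by_species: dict[str, list[SequenceRecord]] = {}
    for rec in survey.records:
        by_species.setdefault(survey.true_partition[rec.id], []).append(rec)
    ref_ids = set()
    for sp in sorted(by_species):
        for rec in sorted(by_species[sp], key=lambda r: r.id)[:refs_per_species]:
            ref_ids.add(rec.id)
    refs = [r for r in survey.records if r.id in ref_ids]
    queries = [r for r in survey.records if r.id not in ref_ids]
    lib = ReferenceLibrary(
        records=refs,
        lineages={r.id: survey.lineages[r.id] for r in refs})
    return queries, lib


def write_survey(survey: SyntheticSurvey, out_dir) -> dict[str, str]:
    """Write a survey to plain-text files; returns a name -> path mapping."""
    from pathlib import Path

    from .io import write_fasta, write_lineage_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sequences": out / "survey.fasta",
        "alignment": out / "survey_true_alignment.fasta",
        "species_tree": out / "species_tree.nwk",
        "gene_tree": out / "gene_tree.nwk",
        "lineages": out / "lineages.tsv",
        "incidence": out / "incidence.csv",
        "truth": out / "truth.tsv",
    }
    write_fasta(survey.records, paths["sequences"])
    write_fasta(survey.aligned_records, paths["alignment"])
    survey.species_tree.write_newick(paths["species_tree"])
    survey.gene_tree.write_newick(paths["gene_tree"])
    write_lineage_table(survey.lineages, paths["lineages"])
    survey.incidence.to_csv(paths["incidence"])
    with open(paths["truth"], "w") as fh:
        fh.write("tip\tspecies\tevent\tmorphospecies\n")
        for rec in survey.records:
            fh.write(f"{rec.id}\t{survey.true_partition[rec.id]}\t"
                     f"{rec.event_id}\t{survey.morphospecies[rec.id]}\n")
    return {k: str(v) for k, v in paths.items()}
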