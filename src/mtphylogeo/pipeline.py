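"""Orchestration: run the full analysis from a config and write report bundles.

The bundle mirrors the study's result tables: a per-group diversity and
neutrality table, the pairwise Phi-ST / p matrix, AMOVA results per
candidate grouping, a dating table, Newick trees and a haplotype network,
plus a run log with seeds and package versions.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .demography import (DatingConvention, dating_table, fit_expansion,
                         mismatch_distribution)
from .distances import distance_matrix
from .diversity import diversity_summary
from .haplotypes import collapse_haplotypes, shared_haplotype_report, site_statistics
from .neutrality import neutrality_test
from .seqio import (Alignment, Dataset, concatenate_loci, load_population_map,
                    read_fasta)
from .structure import (amova, geographic_distance_matrix, grouping_search,
                        mantel_test, pairwise_phist_matrix, upgma)
from .trees_networks import (bootstrap_support, network_from_table, nj_tree,
                             split_support, tree_bipartitions,
                             write_network_edgelist, write_network_graphml)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs, seeds and knobs for a full pipeline run."""

    loci: dict[str, str]                 # locus name -> FASTA path (analysis order)
    popmap: str = ""
    outdir: str = "mtphylogeo_out"
    metric: str = "raw"                  # AMOVA / Phi-ST distance metric
    tree_metric: str = "k2p"
    lineages: dict[str, list[str]] | str = "tree"  # explicit lists or "tree"
    min_lineage_n: int = 5               # suppress per-lineage stats below this n
    groupings: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    n_perm_amova: int = 10_000
    n_perm_fst: int = 10_000
    n_perm_mantel: int = 1_000
    neutrality_reps: int = 1_000
    bootstrap_reps: int = 1_000
    dating: dict = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def seed(self, stage: str, default: int = 0) -> int:
        return int(self.seeds.get(stage, default))

    def convention(self, L: int) -> DatingConvention:
        d = dict(self.dating)
        d.setdefault("L", L)
        if "rate_range" in d:
            d["rate_range"] = tuple(d["rate_range"])
        return DatingConvention(**d)


def load_dataset(config: RunConfig) -> Dataset:
    """Read and concatenate the configured loci and join the population map."""
    alignments = [read_fasta(path, partition_name=name) for name, path in config.loci.items()]
    combined = alignments[0]
    for aln in alignments[1:]:
        combined = concatenate_loci(combined, aln)
    popmap = load_population_map(config.popmap)
    return Dataset(combined, popmap)


def assign_lineages(dataset: Dataset, rule: dict[str, list[str]] | str = "tree",
                    tree_metric: str = "k2p") -> tuple[Dataset, object | None]:
    """Attach lineage labels to every specimen.

    ``rule`` is either explicit ``{label: [specimen ids]}`` lists or
    ``"tree"``: the two clades flanking the midpoint root of the NJ tree of
    haplotypes, the clade with higher nucleotide diversity labelled "A"
    (the older lineage preserves more variation).
    """
    if isinstance(rule, dict):
        labels: dict[str, str] = {}
        for lab, ids in rule.items():
            for sid in ids:
                if sid in labels:
                    raise ValueError(f"specimen {sid!r} listed in two lineages")
                labels[sid] = lab
        missing = [i for i in dataset.alignment.ids if i not in labels]
        if missing:
            raise ValueError(f"lineage lists do not cover: {missing}")
        return Dataset(dataset.alignment, dataset.popmap, labels), None

    table = collapse_haplotypes(dataset)
    hap_aln = Alignment(tuple(table.counts.index), table.sequences)
    tree = nj_tree(distance_matrix(hap_aln, tree_metric))
    rooted = tree.root_at_midpoint()
    clades = rooted.children
    if len(clades) != 2:
        raise ValueError("midpoint rooting did not yield a bipartition")
    sides = [frozenset(t.name for t in c.tips()) | ({c.name} if c.is_tip() else set())
             for c in clades]
    hap_of = {sid: f"H{idx + 1}" for sid, idx in table.assignments.items()}

    def side_pi(side: frozenset[str]) -> float:
        ids = [sid for sid in dataset.alignment.ids if hap_of[sid] in side]
        if len(ids) < 2:
            return 0.0
        return diversity_summary(dataset.alignment.subset(ids)).pi

    order = sorted(range(2), key=lambda i: -side_pi(sides[i]))
    label_of_side = {sides[order[0]]: "A", sides[order[1]]: "B"}
    labels = {}
    for sid in dataset.alignment.ids:
        for side, lab in label_of_side.items():
            if hap_of[sid] in side:
                labels[sid] = lab
    return Dataset(dataset.alignment, dataset.popmap, labels), rooted


def _group_row(name: str, aln: Alignment, reps: int, seed: int,
               lineage_counts: dict[str, int] | None = None) -> dict:
    row: dict = {"group": name, "n": aln.n}
    if lineage_counts:
        for lab, c in sorted(lineage_counts.items()):
            row[f"n_{lab}"] = c
    if aln.n >= 2:
        div = diversity_summary(aln)
        row.update(n_h=div.n_haplotypes, h=round(div.h, 3), h_sd=round(div.h_sd, 3),
                   pi=round(div.pi, 5), pi_sd=round(div.pi_sd, 5), k_bar=round(div.k_bar, 3))
    if aln.n >= 4:
        neut = neutrality_test(aln, reps=reps, seed=seed)
        row.update(tajimas_D=round(neut.D, 3) if np.isfinite(neut.D) else None,
                   fus_Fs=round(neut.Fs, 3) if np.isfinite(neut.Fs) else None,
                   p_D=neut.p_D, p_Fs=neut.p_Fs)
    return row


def run_all(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns a name -> path map of outputs."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "setup"
    try:
        stage = "seqio"
        dataset = load_dataset(config)

        stage = "haplotypes"
        table = collapse_haplotypes(dataset)
        table.write_tsv(out / "haplotypes.tsv")
        table.write_fasta(out / "haplotypes.fasta")
        shared_haplotype_report(table).to_csv(out / "shared_haplotypes.tsv", sep="\t")
        outputs["haplotypes"] = out / "haplotypes.tsv"
        site_rows = []
        for name, path in config.loci.items():
            stats = site_statistics(read_fasta(path, partition_name=name))
            site_rows.append({"locus": name, "sites": stats.n_sites, "S": stats.S,
                              "parsimony_informative": stats.parsimony_informative,
                              "GC_percent": round(100 * stats.gc, 1)})
        pd.DataFrame(site_rows).to_csv(out / "site_statistics.tsv", sep="\t", index=False)
        outputs["site_statistics"] = out / "site_statistics.tsv"

        stage = "lineages"
        dataset, rooted = assign_lineages(dataset, config.lineages, config.tree_metric)
        lineage_labels = sorted(set(dataset.lineages.values()))

        stage = "diversity"
        reps = config.neutrality_reps
        rows = []
        for pop in dataset.popmap.populations:
            sub = dataset.subset_by_population([pop])
            counts = {lab: sum(1 for i in sub.alignment.ids if dataset.lineages[i] == lab)
                      for lab in lineage_labels}
            rows.append(_group_row(pop, sub.alignment, reps, config.seed("neutrality"), counts))
            for lab in lineage_labels:
                ids = [i for i in sub.alignment.ids if dataset.lineages[i] == lab]
                if len(ids) >= config.min_lineage_n:
                    rows.append(_group_row(f"{pop}/{lab}", sub.alignment.subset(ids),
                                           reps, config.seed("neutrality")))
        for lab in lineage_labels:
            sub = dataset.subset_by_lineage(lab)
            rows.append(_group_row(f"Lineage {lab}", sub.alignment, reps, config.seed("neutrality")))
        rows.append(_group_row("Total", dataset.alignment, reps, config.seed("neutrality")))
        pd.DataFrame(rows).to_csv(out / "diversity_neutrality.tsv", sep="\t", index=False)
        outputs["diversity_neutrality"] = out / "diversity_neutrality.tsv"

        stage = "demography"
        taus: dict[str, float] = {}
        mm_rows = []
        for lab in lineage_labels:
            sub = dataset.subset_by_lineage(lab)
            if sub.alignment.n < 3:
                continue
            spec = mismatch_distribution(sub.alignment, label=lab)
            fit = fit_expansion(spec)
            taus[lab] = fit.tau
            for i, (fo, fe) in enumerate(zip(spec.freqs, fit.expected)):
                mm_rows.append({"group": lab, "differences": i, "observed": fo,
                                "expected": round(float(fe), 6), "tau": round(fit.tau, 3),
                                "theta0": round(fit.theta0, 3), "theta1": round(fit.theta1, 3),
                                "ssd": fit.ssd})
        pd.DataFrame(mm_rows).to_csv(out / "mismatch.tsv", sep="\t", index=False)
        outputs["mismatch"] = out / "mismatch.tsv"
        conv = config.convention(dataset.alignment.masked().length)
        dating_table(taus, conv).to_csv(out / "dating.tsv", sep="\t", index=False)
        outputs["dating"] = out / "dating.tsv"

        stage = "structure"
        fst = pairwise_phist_matrix(dataset, config.metric, config.n_perm_fst,
                                    config.seed("fst"))
        fst.write_tsv(out / "pairwise_phist.tsv")
        outputs["pairwise_phist"] = out / "pairwise_phist.tsv"
        newick = upgma(fst.distance_matrix())
        (out / "upgma.nwk").write_text(newick + "\n")
        outputs["upgma"] = out / "upgma.nwk"
        amova_rows = []
        one_group = amova(dataset, None, config.metric, config.n_perm_amova,
                          config.seed("amova"))
        amova_rows.append({"grouping": "one group", "phi_st": round(one_group.phi_st, 5),
                           "p_st": one_group.p_values.get("phi_st"),
                           **{f"pct_{k}": round(v, 2) for k, v in one_group.percent.items()}})
        if config.groupings:
            candidates = {name: {g: tuple(ps) for g, ps in grp.items()}
                          for name, grp in config.groupings.items()}
            for name, res in grouping_search(dataset, candidates, config.metric,
                                             config.n_perm_amova, config.seed("amova")):
                amova_rows.append({
                    "grouping": name,
                    "phi_ct": round(res.phi.get("phi_ct", float("nan")), 5),
                    "phi_sc": round(res.phi.get("phi_sc", float("nan")), 5),
                    "phi_st": round(res.phi_st, 5),
                    "p_ct": res.p_values.get("phi_ct"),
                    **{f"pct_{k}": round(v, 2) for k, v in res.percent.items()},
                })
        pd.DataFrame(amova_rows).to_csv(out / "amova.tsv", sep="\t", index=False)
        outputs["amova"] = out / "amova.tsv"
        coords = dataset.popmap.coordinates()
        if all(p in coords for p in fst.labels) and len(fst.labels) >= 3:
            geo = geographic_distance_matrix(dataset.popmap, fst.labels)
            r, p = mantel_test(fst.distance_matrix(), geo, config.n_perm_mantel,
                               config.seed("mantel"))
            pd.DataFrame([{"r": r, "p": p, "n_perm": config.n_perm_mantel}]).to_csv(
                out / "mantel.tsv", sep="\t", index=False)
            outputs["mantel"] = out / "mantel.tsv"

        stage = "trees_networks"
        hap_aln = Alignment(tuple(table.counts.index), table.sequences)
        tree = nj_tree(distance_matrix(hap_aln, config.tree_metric))
        support = bootstrap_support(hap_aln, reps=config.bootstrap_reps,
                                    seed=config.seed("bootstrap"), metric=config.tree_metric)
        hap_of = {sid: f"H{idx + 1}" for sid, idx in table.assignments.items()}
        a_haps = {hap_of[sid] for sid in dataset.alignment.ids if dataset.lineages[sid] == lineage_labels[0]}
        ab_split = split_support(support, a_haps, set(hap_aln.ids)) if len(lineage_labels) == 2 else None
        (out / "nj.nwk").write_text(str(tree))
        outputs["nj"] = out / "nj.nwk"
        net = network_from_table(table)
        write_network_graphml(net, out / "network.graphml")
        write_network_edgelist(net, out / "network_edges.tsv")
        outputs["network"] = out / "network.graphml"

        stage = "log"
        log = {
            "version": __version__,
            "seeds": {k: config.seed(k) for k in
                      ("neutrality", "fst", "amova", "mantel", "bootstrap")},
            "n_specimens": dataset.alignment.n,
            "L": dataset.alignment.length,
            "L_retained": int(dataset.alignment.masked().length),
            "n_haplotypes": table.n_haplotypes,
            "lineage_sizes": {lab: sum(1 for v in dataset.lineages.values() if v == lab)
                              for lab in lineage_labels},
            "lineage_split_bootstrap": ab_split,
            "taus": {k: float(v) for k, v in taus.items()},
            "metric": config.metric,
        }
        with open(out / "run_log.yaml", "w") as fh:
            yaml.safe_dump(log, fh, sort_keys=False)
        outputs["run_log"] = out / "run_log.yaml"
    except Exception as exc:  # noqa: BLE001 - annotate stage, keep partial outputs
        raise StageError(stage, exc) from exc
    return outputs
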