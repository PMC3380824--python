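"""Configuration-driven orchestration of the full multi-locus analysis.

A run config lists per-locus FASTA alignments, a specimen metadata table,
two focal populations defined by metadata predicates, and which analyses
to run.  ``run_all`` produces the study's summary tables: per-locus AMOVA
percentages by phenotype/species/geography, the per-locus gene-flow (x)
table, bootstrapped neighbour-joining trees, and optional
Shimodaira-Hasegawa comparisons — all reproducible from (config, seed).
"""

from __future__ import annotations

import json
import logging
import math
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from ._version import __version__ as _version
from .seqdata import HaplotypeAlignment, InputError, read_fasta_alignment, read_metadata
from .ldstats import geneflow_test, infer_direction
from .amova import amova_permutation_test, pairwise_difference_matrix
from .phylo import SubstitutionModel, bootstrap_support, sh_test, tree_from_newick, tree_to_newick

__all__ = ["RunConfig", "LocusConfig", "ReportBundle", "run_all", "table_significance_tiers"]

logger = logging.getLogger("introgrescan")

DEFAULT_FACTORS = {"phenotype": "phenotype", "species": "species", "geography": "region"}


def table_significance_tiers(p: float) -> str:
    """Star tier for a permutation/simulation p-value as printed in the
    study tables: '*' p<0.05, '**' p<0.001, '***' at the permutation
    floor (p <= 1e-6)."""
    if not (isinstance(p, (int, float)) and 0 < p <= 1):
        raise InputError(f"p must be in (0, 1], got {p!r}")
    if p <= 1e-6:
        return "***"
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class LocusConfig:
    name: str
    fasta: str
    linkage: str = "unlinked"  # linked/unlinked to the colour-pattern locus

    def __post_init__(self) -> None:
        if self.linkage not in {"linked", "unlinked"}:
            raise InputError(f"linkage must be linked/unlinked, got {self.linkage!r}")


@dataclass
class RunConfig:
    """Analysis configuration. Replicate-count defaults are the study's:
    1000 AMOVA permutations, 1000 bootstrap replicates, 30000 gene-flow
    simulations."""

    loci: list[LocusConfig]
    metadata: str
    pop1: str = "species=melpomene"
    pop2: str = "species=timareta,heurippa"
    outgroup_species: str = "numata_outgroup"
    factors: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_FACTORS))
    analyses: dict[str, bool] = field(
        default_factory=lambda: {"amova": True, "ldflow": True, "nj": True, "sh": False}
    )
    sh_topologies: dict[str, list[str]] = field(default_factory=dict)
    n_perm: int = 1000
    n_boot: int = 1000
    n_sims: int = 30_000
    recombination_rate: float = 0.0  # rho for the gene-flow null
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text())
        loci = [LocusConfig(**l) for l in raw.pop("loci")]
        return cls(loci=loci, **raw)

    def validate_paths(self) -> None:
        missing = [l.fasta for l in self.loci if not Path(l.fasta).exists()]
        if not Path(self.metadata).exists():
            missing.append(self.metadata)
        for paths in self.sh_topologies.values():
            missing += [p for p in paths if not Path(p).exists()]
        if missing:
            raise InputError(f"missing input file(s): {missing}")


@dataclass
class ReportBundle:
    amova_table: pd.DataFrame | None = None
    geneflow_table: pd.DataFrame | None = None
    trees: dict[str, str] = field(default_factory=dict)  # locus -> newick
    sh_table: pd.DataFrame | None = None
    log: dict[str, Any] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if self.amova_table is not None:
            self.amova_table.to_csv(out / "amova.tsv", sep="\t", index=False)
        if self.geneflow_table is not None:
            self.geneflow_table.to_csv(out / "geneflow.tsv", sep="\t", index=False)
        if self.sh_table is not None:
            self.sh_table.to_csv(out / "sh_test.tsv", sep="\t", index=False)
        for locus, newick in self.trees.items():
            (out / f"{locus}.nwk").write_text(newick + "\n")
        (out / "run_log.json").write_text(json.dumps(self.log, indent=2, default=str))


def _fmt_p(p: float) -> str:
    if math.isnan(p):
        return "NA"
    return f"{p:.6g}{table_significance_tiers(p)}"


def run_all(config: RunConfig) -> ReportBundle:
    """Run every enabled analysis over every locus.

    Per-locus, per-stage failures are logged and collected in
    ``bundle.failures`` (partial results are still returned); the CLI
    maps a non-empty failure set to a non-zero exit status.
    """
    bundle = ReportBundle()
    bundle.log = {
        "version": _version,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "n_boot": config.n_boot,
        "n_sims": config.n_sims,
        "pop1": config.pop1,
        "pop2": config.pop2,
        "n_tests_note": (
            "loci are analysed independently; no multiple-testing "
            f"correction is applied across the {len(config.loci)} loci"
        ),
    }
    try:
        config.validate_paths()
        meta = read_metadata(config.metadata)
    except Exception as exc:  # noqa: BLE001 - reported per bundle contract
        bundle.failures["config"] = str(exc)
        logger.error("config stage failed: %s", exc)
        return bundle

    seeds = np.random.SeedSequence(config.seed).spawn(len(config.loci))
    amova_rows, flow_rows, sh_rows = [], [], []
    for locus, seed_seq in zip(config.loci, seeds):
        locus_seed = int(seed_seq.generate_state(1)[0] % (2**31))
        try:
            aln = read_fasta_alignment(locus.fasta, locus_name=locus.name)
            read_metadata(config.metadata, aln)
        except Exception as exc:  # noqa: BLE001
            bundle.failures[f"{locus.name}:read"] = str(exc)
            logger.error("locus %s read failed: %s", locus.name, exc)
            continue
        outgroup_ids = set(meta.ids_where(f"species={config.outgroup_species}"))
        ingroup = [h for h in aln.ids if h not in outgroup_ids]
        pop1 = [h for h in meta.ids_where(config.pop1) if h in set(aln.ids)]
        pop2 = [h for h in meta.ids_where(config.pop2) if h in set(aln.ids)]

        if config.analyses.get("amova"):
            try:
                sub = aln.subset(ingroup)
                dist = pairwise_difference_matrix(sub)
                row: dict[str, Any] = {"locus": locus.name, "linkage": locus.linkage,
                                       "n_perm": config.n_perm, "seed": locus_seed}
                for factor, column in config.factors.items():
                    groups = meta.table.loc[ingroup, column].to_dict()
                    res = amova_permutation_test(
                        dist, sub.ids, groups, n_perm=config.n_perm,
                        seed=locus_seed, factor=factor,
                    )
                    row[f"pct_{factor}"] = round(res.pct_among, 2)
                    row[f"p_{factor}"] = _fmt_p(res.p_perm)
                amova_rows.append(row)
            except Exception as exc:  # noqa: BLE001
                bundle.failures[f"{locus.name}:amova"] = str(exc)
                logger.error("locus %s AMOVA failed: %s", locus.name, exc)

        if config.analyses.get("ldflow"):
            try:
                res = geneflow_test(
                    aln, pop1, pop2, n_sims=config.n_sims, seed=locus_seed,
                    recombination_rate=config.recombination_rate,
                )
                recipient = (
                    infer_direction(res, labels=(config.pop1, config.pop2))
                    if not (math.isnan(res.x_pop1) and math.isnan(res.x_pop2))
                    else "NA"
                )
                for pop_label, x, sim, p in (
                    (config.pop1, res.x_pop1, res.sim_mean_x_pop1, res.p_pop1),
                    (config.pop2, res.x_pop2, res.sim_mean_x_pop2, res.p_pop2),
                ):
                    flow_rows.append(
                        {
                            "locus": locus.name,
                            "population": pop_label,
                            "observed_x": "NA" if math.isnan(x) else round(x, 4),
                            "simulated_x": "NA" if math.isnan(sim) else round(sim, 4),
                            "p": _fmt_p(p),
                            "recipient": recipient,
                            "n_sims": config.n_sims,
                            "seed": locus_seed,
                        }
                    )
            except Exception as exc:  # noqa: BLE001
                bundle.failures[f"{locus.name}:ldflow"] = str(exc)
                logger.error("locus %s gene-flow test failed: %s", locus.name, exc)

        if config.analyses.get("nj"):
            try:
                tree = bootstrap_support(aln, n_reps=config.n_boot, seed=locus_seed)
                bundle.trees[locus.name] = tree_to_newick(tree)
            except Exception as exc:  # noqa: BLE001
                bundle.failures[f"{locus.name}:nj"] = str(exc)
                logger.error("locus %s NJ failed: %s", locus.name, exc)

        if config.analyses.get("sh") and locus.name in config.sh_topologies:
            try:
                from .phylo import nj_tree

                tops = [nj_tree(aln)] + [
                    tree_from_newick(Path(p).read_text())
                    for p in config.sh_topologies[locus.name]
                ]
                res = sh_test(
                    aln, tops, SubstitutionModel.jc(alpha=1.0),
                    n_resamples=config.n_boot, seed=locus_seed,
                )
                for i, (lnl, d, p) in enumerate(
                    zip(res.log_likelihoods, res.deltas, res.p_values)
                ):
                    sh_rows.append(
                        {
                            "locus": locus.name,
                            "topology": "nj" if i == 0 else f"alternative_{i}",
                            "lnL": round(float(lnl), 4),
                            "delta": round(float(d), 4),
                            "p": _fmt_p(float(p)),
                            "seed": locus_seed,
                        }
                    )
            except Exception as exc:  # noqa: BLE001
                bundle.failures[f"{locus.name}:sh"] = str(exc)
                logger.error("locus %s SH test failed: %s", locus.name, exc)

    if amova_rows:
        bundle.amova_table = pd.DataFrame(amova_rows)
    if flow_rows:
        bundle.geneflow_table = pd.DataFrame(flow_rows)
    if sh_rows:
        bundle.sh_table = pd.DataFrame(sh_rows)
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle
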