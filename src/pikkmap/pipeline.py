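"""End-to-end orchestration: catalog -> conservation -> structure -> stats.

The :func:`run` entry point executes the whole analysis from a
:class:`RunConfig` and writes, per stage, the summary tables the analysis
is read from:

a. per-gene mutation-frequency table with consequence-class counts;
b. per-cancer-type conserved-residue table (total / conserved / %);
c. burial-surface table and a spatial cluster report (when a structure is
   configured — structure stages are optional so the pipeline runs without
   any PDB download);
d. domain-enrichment and overlap reports.

A machine-readable JSON summary mirrors every number that appears in a TSV.
Re-running an identical config reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import catalog as cat
from . import conservation as cons
from . import sasa as sasa_mod
from . import stats as stats_mod
from . import structure as struct_mod

__all__ = ["RunConfig", "PipelineError", "run"]

log = logging.getLogger("pikkmap")


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs, thresholds and output location for a full pipeline run."""

    catalog_path: str
    cohort_size: int
    out_dir: str
    genes: list[str] = field(default_factory=list)
    # gene -> list of 2-row aligned FASTA files, human sequence first
    alignments: dict[str, list[str]] = field(default_factory=dict)
    # gene -> PDB coordinate file (optional; structure stages skipped if absent)
    structures: dict[str, str] = field(default_factory=dict)
    chains: dict[str, list[str]] = field(default_factory=dict)
    offsets: dict[str, int] = field(default_factory=dict)
    # gene -> domain-map TSV, or a bundled gene name (ATM/ATR/MEC1)
    domain_maps: dict[str, str] = field(default_factory=dict)
    burial_threshold: float = sasa_mod.DEFAULT_BURIAL_THRESHOLD
    cluster_cutoff: float = 24.0
    distance_mode: str = "ca"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.burial_threshold <= 1.0):
            raise ValueError("burial_threshold must lie in [0, 1]")
        if self.cluster_cutoff <= 0:
            raise ValueError("cluster_cutoff must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _load_domain_map(spec: str) -> struct_mod.DomainMap:
    if Path(spec).is_file():
        return struct_mod.read_domain_map(spec)
    return struct_mod.default_domain_map(spec)


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns the JSON-ready summary dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"genes": {}}

    # -- stage a: catalog ---------------------------------------------------
    try:
        catalog = cat.load_catalog(
            config.catalog_path, config.cohort_size, genes=config.genes or None
        )
        genes = config.genes or catalog.genes()
        freq_df = cat.write_gene_summary(catalog, genes, out / "frequency_summary.tsv")
        for _, row in freq_df.iterrows():
            summary["genes"][row["gene"]] = {
                "mutated_samples": int(row["mutated_samples"]),
                "frequency_pct": float(row["frequency_pct"]),
                "consequence_counts": {
                    c: int(row[f"n_{c}"]) for c in cat.CONSEQUENCES
                },
            }
        log.info("catalog: %d records, %d genes", len(catalog.records), len(genes))
    except Exception as exc:
        raise PipelineError("catalog", str(exc)) from exc

    for gene in genes:
        gene_summary = summary["genes"].setdefault(gene, {})

        # -- stage b: conservation ------------------------------------------
        conserved_all: Optional[set[int]] = None
        human_len: Optional[int] = None
        per_type_conserved: dict[str, set[int]] = {}
        if gene in config.alignments:
            try:
                pairs = {}
                human_seq = None
                for path in config.alignments[gene]:
                    pair = cons.read_alignment(path)
                    if not isinstance(pair, cons.AlignedPair):
                        raise ValueError(f"{path}: expected a 2-row alignment")
                    if human_seq is None:
                        human_seq = pair.seq_a
                    elif pair.seq_a != human_seq:
                        raise ValueError(
                            f"{path}: human row disagrees with earlier alignments"
                        )
                    pairs[pair.id_b] = pair
                assert human_seq is not None
                human_len = len(human_seq)

                all_res = cat.mutated_residues(catalog, gene)
                calls = cons.call_conserved(all_res, human_seq, pairs)
                conserved_all = {c.human_pos for c in calls if c.conserved}

                rows = []
                for ctype in sorted(set(catalog.cancer_types())):
                    rs = cat.mutated_residues(catalog, gene, cancer_type=ctype)
                    csub = {p for p in rs.positions() if p in conserved_all}
                    per_type_conserved[ctype] = csub
                    rows.append(
                        {
                            "gene": gene,
                            "cancer_type": ctype,
                            "total_mutated_residues": len(rs),
                            "conserved_residues": len(csub),
                            "conserved_pct": cat.round_half_up(
                                100.0 * len(csub) / len(rs), 1
                            )
                            if len(rs)
                            else 0.0,
                        }
                    )
                ctable = pd.DataFrame(rows)
                ctable.to_csv(out / f"conservation_{gene}.tsv", sep="\t", index=False)
                detail = pd.DataFrame(
                    [
                        {
                            "gene": gene,
                            "position": c.human_pos,
                            "human_aa": c.human_aa,
                            **{f"status_{k}": v for k, v in sorted(c.status.items())},
                            "conserved": c.conserved,
                        }
                        for c in calls
                    ]
                )
                detail.to_csv(
                    out / f"conserved_residues_{gene}.tsv", sep="\t", index=False
                )
                gene_summary["conservation"] = {
                    "n_mutated_residues": len(all_res),
                    "n_conserved": len(conserved_all),
                    "per_cancer_type": {
                        r["cancer_type"]: {
                            "total": r["total_mutated_residues"],
                            "conserved": r["conserved_residues"],
                            "pct": r["conserved_pct"],
                        }
                        for r in rows
                    },
                }
                log.info(
                    "conservation %s: %d/%d residues conserved",
                    gene, len(conserved_all), len(all_res),
                )
            except Exception as exc:
                raise PipelineError("conservation", str(exc)) from exc

        # -- stage c: structure ---------------------------------------------
        profile = None
        if gene in config.structures:
            try:
                model = struct_mod.read_pdb(config.structures[gene])
                profile = sasa_mod.shrake_rupley(model)
                burial = sasa_mod.classify_burial(profile, config.burial_threshold)
                sasa_mod.write_sasa_table(profile, out / f"burial_{gene}.tsv")

                chains = config.chains.get(gene, model.chains)
                offset = config.offsets.get(gene, 0)
                positions = sorted(conserved_all) if conserved_all else sorted(
                    cat.mutated_residues(catalog, gene).positions()
                )
                mapped, unresolved = [], []
                for pos in positions:
                    for chain in chains:
                        try:
                            res = struct_mod.map_position(model, chain, pos, offset)
                        except (IndexError, KeyError):
                            continue
                        if res is None:
                            unresolved.append((chain, pos))
                        else:
                            mapped.append((chain, res.number))
                surf = stats_mod.surface_fraction(profile, mapped)
                surface_keys = [
                    key
                    for key in mapped
                    if profile.residues.get(key)
                    and profile.residues[key].burial == "surface"
                ]
                clusters = struct_mod.cluster_residues(
                    model, surface_keys, config.cluster_cutoff, config.distance_mode
                )
                struct_mod.write_clusters(clusters, out / f"clusters_{gene}.tsv")
                pd.DataFrame(
                    [
                        {
                            "gene": gene,
                            "n_residues_resolved_model": burial.n_resolved,
                            "model_surface_fraction": round(burial.surface_fraction, 4),
                            "mapped_n_surface": surf["n_surface"],
                            "mapped_n_resolved": surf["n_resolved"],
                            "mapped_n_unresolved": surf["n_unresolved"],
                            "mapped_surface_fraction": round(surf["fraction"], 4)
                            if surf["fraction"] is not None
                            else "",
                            "n_clusters": len(clusters),
                        }
                    ]
                ).to_csv(out / f"structure_summary_{gene}.tsv", sep="\t", index=False)
                gene_summary["structure"] = {
                    "n_residues_resolved_model": burial.n_resolved,
                    "model_surface_fraction": round(burial.surface_fraction, 4),
                    "mapped_subset": {
                        **{k: v for k, v in surf.items() if k != "fraction"},
                        "fraction": round(surf["fraction"], 4)
                        if surf["fraction"] is not None
                        else None,
                    },
                    "n_unresolved_mapped": len(unresolved),
                    "n_clusters": len(clusters),
                    "cluster_sizes": sorted(
                        (len(c) for c in clusters), reverse=True
                    ),
                }
                log.info(
                    "structure %s: %d mapped, %d surface, %d clusters",
                    gene, len(mapped), surf["n_surface"], len(clusters),
                )
            except Exception as exc:
                raise PipelineError("structure", str(exc)) from exc
        elif config.structures:
            log.warning("structure: no model configured for %s; stage skipped", gene)

        # -- stage d: stats --------------------------------------------------
        try:
            if gene in config.domain_maps and conserved_all:
                dmap = _load_domain_map(config.domain_maps[gene])
                plen = human_len or max(
                    (e for _, _, e in dmap.intervals), default=0
                )
                enr = stats_mod.enrich_domains(conserved_all, dmap, plen)
                pd.DataFrame(
                    [
                        {
                            "gene": gene,
                            "domain": e.domain,
                            "k": e.k,
                            "n": e.n,
                            "f_dom": round(e.f_dom, 4),
                            "fold": round(e.fold, 3),
                            "p_binomial": f"{e.p_value:.3e}",
                            "p_hypergeom": f"{e.p_hypergeom:.3e}",
                        }
                        for e in enr
                    ]
                ).to_csv(out / f"enrichment_{gene}.tsv", sep="\t", index=False)
                gene_summary["enrichment"] = {
                    e.domain: {"k": e.k, "n": e.n, "fold": round(e.fold, 3)}
                    for e in enr
                }
            if len(per_type_conserved) >= 2:
                ov = stats_mod.overlap_analysis(
                    sorted(per_type_conserved.items())
                )
                rows = [
                    {"kind": "set", "labels": label, "size": n}
                    for label, n in sorted(ov.sizes.items())
                ]
                rows += [
                    {"kind": "pair", "labels": f"{a}&{b}", "size": n}
                    for (a, b), n in sorted(ov.pairwise.items())
                ]
                rows.append(
                    {"kind": "k_way", "labels": "&".join(sorted(ov.sizes)),
                     "size": ov.k_way_intersection}
                )
                rows.append({"kind": "union", "labels": "all", "size": ov.union})
                pd.DataFrame(rows).to_csv(
                    out / f"overlap_{gene}.tsv", sep="\t", index=False
                )
                gene_summary["overlap"] = {
                    "sizes": ov.sizes,
                    "pairwise": {f"{a}&{b}": n for (a, b), n in sorted(ov.pairwise.items())},
                    "k_way_intersection": ov.k_way_intersection,
                    "union": ov.union,
                }
        except Exception as exc:
            raise PipelineError("stats", str(exc)) from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
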