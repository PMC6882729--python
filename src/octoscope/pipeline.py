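"""End-to-end orchestration: simulate → subgenome calls → chromosome/HE
assignment → expression bias → fractionation → TE statistics, with a run
manifest (config snapshot, digests, row counts) that makes a run exactly
reproducible from its seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from octoscope import chromassign, fractionation, hebstats, phyds, testats
from octoscope import io as oio
from octoscope.simdata import SimConfig, simulate_genome, write_simulation

log = logging.getLogger("octoscope")

__version__ = "0.1.0"


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _row_count(path: Path) -> int:
    if path.suffix in {".tsv", ".bed", ".nwk", ".gff3"}:
        return sum(1 for _ in open(path))
    return 0


def placements_from_calls(calls: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Join subgenome calls onto GFF3 gene order.

    Gene ordinals are the rank of each gene's start along its sequence.
    Genes without an assigned call get a null species.
    """
    g = genes.copy()
    g["ordinal"] = g.groupby("seqid")["start"].rank(method="first").astype(int) - 1
    assigned = calls[calls["status"] == "assigned"][["focal_leaf", "species"]]
    merged = g.merge(assigned, left_on="gene_id", right_on="focal_leaf", how="left")
    out = merged[["gene_id", "seqid", "ordinal", "species"]].rename(
        columns={"seqid": "chromosome", "species": "called_species"}
    )
    return out.sort_values(["chromosome", "ordinal"]).reset_index(drop=True)


def _finalize(partials: dict[Path, Path]) -> None:
    for tmp, final in partials.items():
        tmp.rename(final)


def run_all(
    config: SimConfig,
    outdir: str | Path,
    min_bootstrap: int = 80,
    alpha: float = 0.01,
    min_run: int = 3,
    max_gap: int = 1,
    window: int = 100,
    step: int = 1,
    tandem_max_gap: int = 10,
    flank_bp: int | None = None,
) -> dict:
    """Run every stage on a fresh simulation and write a consolidated report.

    Stage outputs are written with a ``.partial`` suffix and renamed on stage
    success, so an aborted run leaves its partial products identifiable. A
    stage failure raises :class:`StageError` naming the stage. Returns the
    manifest dictionary (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    flank_bp = config.flank_bp if flank_bp is None else flank_bp
    log.info(
        "run-all seed=%s min_bootstrap=%s alpha=%s min_run=%s max_gap=%s window=%s flank=%s",
        config.seed, min_bootstrap, alpha, min_run, max_gap, window, flank_bp,
    )
    report: dict = {}
    paths: dict[str, Path] = {}

    # --- simulate ---------------------------------------------------------
    try:
        genome = simulate_genome(config)
        paths.update(write_simulation(outdir, genome))
    except Exception as exc:
        raise StageError(f"stage 'simulate' failed: {exc}") from exc

    # --- phyds ------------------------------------------------------------
    try:
        role_map = oio.read_role_map(paths["roles.tsv"])
        trees = oio.read_gene_trees(paths["trees.nwk"], role_map)
        params = phyds.PhyDSParams(min_bootstrap=min_bootstrap)
        calls = phyds.phyds_batch(trees, role_map, params)
        tmp = outdir / "calls.tsv.partial"
        oio.write_tsv(calls, tmp)
        _finalize({tmp: outdir / "calls.tsv"})
        paths["calls.tsv"] = outdir / "calls.tsv"
    except Exception as exc:
        raise StageError(f"stage 'phyds' failed: {exc}") from exc

    # --- assign -----------------------------------------------------------
    try:
        genes = oio.read_genes_gff3(paths["genes.gff3"])
        placements = placements_from_calls(calls, genes)
        assignments, blocks = chromassign.assign_and_segment(
            placements, min_run=min_run, max_gap=max_gap
        )
        bias_mat, ratios = chromassign.he_bias_matrix(blocks, assignments, unit="genes")
        assign_df = pd.DataFrame(
            [
                (a.chromosome, a.assigned_species, round(a.consensus_fraction, 6),
                 json.dumps(a.counts, sort_keys=True))
                for a in assignments
            ],
            columns=["chromosome", "assigned_species", "consensus_fraction", "counts"],
        )
        block_df = pd.DataFrame(
            [
                (b.chromosome, b.start, b.end, b.donor, b.gene_count,
                 b.donor_gene_count, b.single_gene)
                for b in blocks
            ],
            columns=["chromosome", "start", "end", "donor", "gene_count",
                     "donor_gene_count", "single_gene"],
        )
        tmp1, tmp2 = outdir / "assignments.tsv.partial", outdir / "he_blocks.tsv.partial"
        oio.write_tsv(assign_df, tmp1)
        oio.write_tsv(block_df, tmp2)
        _finalize({tmp1: outdir / "assignments.tsv", tmp2: outdir / "he_blocks.tsv"})
        paths["assignments.tsv"] = outdir / "assignments.tsv"
        paths["he_blocks.tsv"] = outdir / "he_blocks.tsv"
        dom = config.dominant
        report["chromosomes"] = {
            a.chromosome: a.assigned_species for a in assignments
        }
        report["he_bias_ratios_toward_dominant"] = {
            other: (None if not np.isfinite(ratios.get((dom, other), float("nan")))
                    else round(ratios[(dom, other)], 3))
            for other in config.subgenomes if other != dom
        }
        report["n_he_blocks"] = int(len(blocks))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage 'assign' failed: {exc}") from exc

    # --- heb --------------------------------------------------------------
    try:
        if not paths["pairs.tsv"].exists() or not paths["counts.tsv"].exists():
            raise FileNotFoundError("pairs/counts tables missing")
        pairs = oio.read_tsv(paths["pairs.tsv"])
        counts = pd.read_csv(paths["counts.tsv"], sep="\t", index_col="gene_id")
        x_a = counts.loc[pairs["gene_a"]].to_numpy()
        x_b = counts.loc[pairs["gene_b"]].to_numpy()
        classed = hebstats.heb_analysis(pairs, x_a, x_b, alpha=alpha)
        summary = hebstats.heb_summary(classed, dominant=config.dominant)
        tmp = outdir / "heb_results.tsv.partial"
        oio.write_tsv(classed.drop(columns=["ll0", "ll1", "ll2"]), tmp)
        _finalize({tmp: outdir / "heb_results.tsv"})
        paths["heb_results.tsv"] = outdir / "heb_results.tsv"
        report["heb_class_counts"] = classed["class"].value_counts().to_dict()
        report["heb_pairings"] = {
            k: {"n_pairs": v["n_pairs"],
                "n_biased_dominant": v["n_biased_dominant"],
                "n_biased_other": v["n_biased_other"]}
            for k, v in summary.items()
        }
        bias_counts = (
            classed.loc[classed["class"] == "consistent-bias", "direction"]
            .value_counts().reindex(list(config.subgenomes), fill_value=0)
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage 'heb' failed: {exc}") from exc

    # --- fractionation ----------------------------------------------------
    try:
        anchors = oio.read_tsv(paths["anchors.tsv"])
        retention_means = {}
        n_windows = {}
        for sg, grp in anchors.groupby("subgenome"):
            fracs = []
            for _, chrom_grp in grp.groupby("ref_chrom"):
                vec = chrom_grp.sort_values("ref_ordinal")["present"].to_numpy()
                if len(vec) >= window:
                    fracs.append(fractionation.retention_windows(vec, window=window, step=step))
            all_f = np.concatenate(fracs) if fracs else np.array([])
            retention_means[sg] = float(all_f.mean()) if len(all_f) else float("nan")
            n_windows[sg] = int(len(all_f))
        content = anchors.groupby("subgenome")["present"].sum().astype(int).to_dict()
        content_df = fractionation.subgenome_content_summary(content)
        gene_table = genome.genes[["chromosome", "ordinal", "family_id"]]
        arrays = fractionation.tandem_arrays(gene_table, max_gap=tandem_max_gap)
        tmp = outdir / "content_summary.tsv.partial"
        oio.write_tsv(content_df, tmp)
        _finalize({tmp: outdir / "content_summary.tsv"})
        paths["content_summary.tsv"] = outdir / "content_summary.tsv"
        report["retention_window_means"] = {k: round(v, 4) for k, v in retention_means.items()}
        report["subgenome_gene_content"] = content
        report["n_tandem_arrays"] = int(len(arrays))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage 'fract' failed: {exc}") from exc

    # --- te statistics ----------------------------------------------------
    try:
        tes = oio.read_bed(paths["tes.bed"])
        dens = testats.te_density(genes, tes, flank_bp=flank_bp)
        dens = dens.merge(
            placements[["gene_id", "called_species"]], on="gene_id", how="left"
        )
        lib_sizes = counts.sum(axis=0)
        lengths = (genes.set_index("gene_id")["end"] - genes.set_index("gene_id")["start"])
        common = counts.index.intersection(lengths.index)
        fpkm_vals = pd.DataFrame(
            {
                t: [hebstats.fpkm(c, lib_sizes[t], lengths[g])
                    for g, c in counts.loc[common, t].items()]
                for t in counts.columns
            },
            index=common,
        ).mean(axis=1)
        dd = dens.set_index("gene_id").loc[common]
        rho, p_rho = testats.spearman_expr_te(dd["density"].to_numpy(), fpkm_vals.to_numpy())
        samples = {
            sg: grp["density"].to_numpy()
            for sg, grp in dens.dropna(subset=["called_species"]).groupby("called_species")
        }
        ks_table, lowest, supported = testats.ks_subgenomes(samples, alpha=alpha)
        content_weights = np.array([content[sg] for sg in config.subgenomes], dtype=float)
        chi2_stat, df, p_chi = testats.chisq_subgenome_bias(
            bias_counts.to_numpy(), weights=content_weights / content_weights.sum()
        )
        tmp = outdir / "te_density.tsv.partial"
        oio.write_tsv(dens, tmp)
        _finalize({tmp: outdir / "te_density.tsv"})
        paths["te_density.tsv"] = outdir / "te_density.tsv"
        report["te_spearman"] = {"rho": round(rho, 4), "p": float(f"{p_rho:.3e}")}
        report["te_density_means"] = {
            sg: round(float(np.mean(v)), 4) for sg, v in sorted(samples.items())
        }
        report["te_lowest_density_subgenome"] = lowest
        report["te_lowest_supported"] = supported
        report["bias_chisq"] = {"stat": round(chi2_stat, 3), "df": df, "p": float(f"{p_chi:.3e}")}
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage 'tedens' failed: {exc}") from exc

    # --- report + manifest --------------------------------------------------
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    paths["report.json"] = report_path

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "parameters": {
            "min_bootstrap": min_bootstrap, "alpha": alpha, "min_run": min_run,
            "max_gap": max_gap, "window": window, "step": step,
            "tandem_max_gap": tandem_max_gap, "flank_bp": flank_bp,
        },
        "files": {
            name: {"sha256": _sha256(p), "rows": _row_count(p)}
            for name, p in sorted(paths.items())
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def roundtrip_check(path: str | Path, fmt: str) -> bool:
    """Read → write → read a file; True when the representation is unchanged."""
    path = Path(path)
    with tempfile.TemporaryDirectory() as td:
        tmp = Path(td) / path.name
        if fmt == "newick":
            import dendropy

            def load(p):
                return dendropy.TreeList.get(
                    path=str(p), schema="newick",
                    suppress_internal_node_taxa=True, preserve_underscores=True,
                )

            def dump(trees, p):
                with open(p, "w") as fh:
                    for t in trees:
                        fh.write(
                            t.as_string(schema="newick", suppress_rooting=True,
                                        unquoted_underscores=True,
                                        suppress_edge_lengths=True).strip() + "\n"
                        )

            first = load(path)
            dump(first, tmp)
            second = load(tmp)
            key = lambda ts: [
                t.as_string(schema="newick", suppress_rooting=True).strip() for t in ts
            ]
            return key(first) == key(second)
        if fmt == "gff3":
            first = oio.read_genes_gff3(path)
            oio.write_genes_gff3(first, tmp)
            return first.equals(oio.read_genes_gff3(tmp))
        if fmt == "bed":
            first = oio.read_bed(path)
            oio.write_bed(first, tmp)
            return first.equals(oio.read_bed(tmp))
        if fmt == "tsv":
            first = oio.read_tsv(path)
            oio.write_tsv(first, tmp)
            return first.equals(oio.read_tsv(tmp))
    raise ValueError(f"unsupported format: {fmt!r}")
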