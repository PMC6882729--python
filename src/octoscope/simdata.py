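"""Seeded simulator for allopolyploid subgenome-dominance analyses.

Emulates the data structures of a four-subgenome allopolyploid (an octoploid
formed by the merger of four diploid progenitor species) together with full
ground truth, so every analysis stage can be exercised and scored without
external data:

* a genome: each subgenome chromosome is an ancestral gene order thinned by
  a subgenome-specific retention probability, with adjacent tandem
  duplicates and donor-biased homoeologous-exchange (HE) blocks that
  overwrite the origin of recipient genes;
* TE intervals drawn per subgenome (the dominant subgenome carries fewer
  TEs near genes), written as BED;
* gene trees: per retained homoeolog, a small tree in which the focal leaf
  is sister to its true origin's diploid relative with probability
  ``tree_signal`` (for HE genes, the donor's relative), with bootstrap
  supports drawn from concordant/discordant distributions;
* homoeolog pair count matrices over T tissues under the nested H0/H1/H2
  expression models, with pair abundance log-linear in TE density
  (negative coefficient).

Trees are generated topology-first with parametric supports rather than by
sequence simulation and bootstrapping: that preserves exactly the structure
the clade search decides on (sister identity and node support) at a tiny
fraction of the cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from octoscope.io import LeafRoleMap, write_bed, write_genes_gff3, write_role_map, write_tsv


def _default_retention() -> dict[str, float]:
    # emulates a dominant subgenome with ~20/19.5/14% more retained genes
    return {"vesca": 0.95, "iinumae": 0.79, "viridis": 0.80, "nipponica": 0.83}


def _default_donor_weights() -> dict[str, float]:
    return {"vesca": 9.0, "iinumae": 1.0, "viridis": 1.0, "nipponica": 1.0}


def _default_te_beta() -> dict[str, tuple[float, float]]:
    return {
        "vesca": (2.0, 8.0),      # mean density 0.2 near genes
        "iinumae": (4.0, 6.0),    # mean density 0.4
        "viridis": (4.0, 6.0),
        "nipponica": (4.0, 6.0),
    }


@dataclass
class SimConfig:
    """All tunable study conditions; a fixed seed gives byte-identical output."""

    seed: int = 0
    subgenomes: tuple[str, ...] = ("vesca", "iinumae", "viridis", "nipponica")
    dominant: str = "vesca"
    focal_species: str = "xananassa"
    outgroups: tuple[str, ...] = ("athaliana", "mdomestica")
    n_chromosomes: int = 2
    genes_per_chromosome: int = 500
    retention: dict = field(default_factory=_default_retention)
    tandem_rate: float = 0.02
    he_count: int = 30
    he_donor_weights: dict = field(default_factory=_default_donor_weights)
    he_block_genes: tuple[int, int] = (5, 25)
    tree_signal: float = 0.9
    concordant_support: tuple[int, int] = (85, 100)
    discordant_support: tuple[int, int] = (40, 90)
    tissues: tuple[str, ...] = ("anther", "root", "leaf")
    depth_per_pair: float = 500.0
    mixture: tuple[float, float, float] = (0.7, 0.2, 0.1)
    log2_scale_range: tuple[float, float] = (0.5, 2.5)
    dominant_bias_fraction: float = 0.7
    te_density_beta: dict = field(default_factory=_default_te_beta)
    te_effect: float = 2.0  # magnitude of the negative log-linear TE effect
    expression_sigma: float = 0.4
    overdispersion: float = 0.0  # beta-binomial intra-class correlation; 0 = binomial
    pair_support_range: tuple[int, int] = (81, 100)
    gene_length_range: tuple[int, int] = (900, 3000)
    gene_spacing: int = 8000
    flank_bp: int = 2000

    def validate(self) -> None:
        for sg in self.subgenomes:
            r = self.retention.get(sg)
            if r is None or not 0 < r <= 1:
                raise ValueError(f"retention[{sg!r}] must be in (0, 1]")
            if sg not in self.he_donor_weights or self.he_donor_weights[sg] <= 0:
                raise ValueError(f"he_donor_weights[{sg!r}] must be positive")
            if sg not in self.te_density_beta:
                raise ValueError(f"te_density_beta[{sg!r}] missing")
        if self.dominant not in self.subgenomes:
            raise ValueError("dominant must be one of subgenomes")
        if not 0 <= self.tree_signal <= 1:
            raise ValueError("tree_signal must be in [0, 1]")
        if abs(sum(self.mixture) - 1.0) > 1e-9 or any(m < 0 for m in self.mixture):
            raise ValueError("mixture fractions must be nonnegative and sum to 1")
        if not 0 <= self.overdispersion < 1:
            raise ValueError("overdispersion must be in [0, 1)")
        if len(self.tissues) < 2:
            raise ValueError("tissues must list at least 2 tissues")
        if self.he_block_genes[0] < 1 or self.he_block_genes[0] > self.he_block_genes[1]:
            raise ValueError("he_block_genes must be a nonempty (lo, hi) range")
        if not 0 <= self.tandem_rate < 1:
            raise ValueError("tandem_rate must be in [0, 1)")


GENE_TABLE_COLUMNS = [
    "gene_id", "subgenome", "chromosome", "ordinal", "seqid", "start", "end",
    "strand", "ancestral_chrom", "ancestral_ordinal", "family_id", "origin",
    "is_tandem", "te_density",
]

HE_TRUTH_COLUMNS = ["chromosome", "start", "end", "donor", "gene_count"]


@dataclass
class SimGenome:
    """Simulated genome plus ground truth (gene origins, HE blocks, TE truth)."""

    config: SimConfig
    genes: pd.DataFrame       # GENE_TABLE_COLUMNS
    tes: pd.DataFrame         # seqid, start, end
    anchors: pd.DataFrame     # ref_chrom, ref_ordinal, subgenome, present, family_id
    he_blocks: pd.DataFrame   # HE_TRUTH_COLUMNS


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def simulate_genome(config: SimConfig) -> SimGenome:
    """Draw the four-subgenome gene order, TEs, anchors and HE ground truth."""
    config.validate()
    rng = _rng(config, 1)
    gene_rows: list[tuple] = []
    anchor_rows: list[tuple] = []

    for sg in config.subgenomes:
        for c in range(config.n_chromosomes):
            chrom = f"{sg}_chr{c + 1}"
            present = rng.random(config.genes_per_chromosome) < config.retention[sg]
            ordinal = 0
            for i in range(config.genes_per_chromosome):
                anc_id = f"anc{c + 1}_{i:04d}"
                anchor_rows.append((f"anc_chr{c + 1}", i, sg, int(present[i]), anc_id))
                if not present[i]:
                    continue
                n_copies = 1 + int(rng.random() < config.tandem_rate)
                for copy in range(n_copies):
                    length = int(rng.integers(*config.gene_length_range))
                    start = ordinal * config.gene_spacing + config.flank_bp
                    gene_id = f"{sg}_c{c + 1}_g{ordinal:04d}"
                    gene_rows.append(
                        (
                            gene_id, sg, chrom, ordinal, chrom, start, start + length,
                            "+" if rng.random() < 0.5 else "-",
                            f"anc_chr{c + 1}", i, anc_id, sg, copy > 0, np.nan,
                        )
                    )
                    ordinal += 1

    genes = pd.DataFrame(gene_rows, columns=GENE_TABLE_COLUMNS)

    # homoeologous exchanges: donor drawn by biased weights, recipient uniform
    donor_w = np.array([config.he_donor_weights[sg] for sg in config.subgenomes], dtype=float)
    donor_w /= donor_w.sum()
    chrom_sizes = genes.groupby("chromosome")["ordinal"].max().to_dict()
    chrom_of = {sg: [f"{sg}_chr{c + 1}" for c in range(config.n_chromosomes)] for sg in config.subgenomes}
    occupied: dict[str, list[tuple[int, int]]] = {ch: [] for ch in chrom_sizes}
    he_rows = []
    genes_by_chrom = {ch: grp.index.to_numpy() for ch, grp in genes.groupby("chromosome")}
    for _ in range(config.he_count):
        placed = False
        for _attempt in range(1000):
            donor = str(rng.choice(np.asarray(config.subgenomes), p=donor_w))
            others = [sg for sg in config.subgenomes if sg != donor]
            recipient = str(rng.choice(np.asarray(others)))
            chrom = str(rng.choice(np.asarray(chrom_of[recipient])))
            n = chrom_sizes[chrom] + 1
            size = int(rng.integers(config.he_block_genes[0], min(config.he_block_genes[1], n - 2) + 1))
            start = int(rng.integers(0, n - size + 1))
            end = start + size - 1
            # keep >= 1 consensus gene between blocks so truth blocks are unambiguous
            if any(start <= e + 1 and end >= s - 1 for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((start, end))
            idx = genes_by_chrom[chrom]
            sel = genes.loc[idx]
            mask = idx[(sel["ordinal"] >= start) & (sel["ordinal"] <= end)]
            genes.loc[mask, "origin"] = donor
            he_rows.append((chrom, start, end, donor, size))
            placed = True
            break
        if not placed:
            raise ValueError(
                "he_count/he_block_genes too large for this genome: could not "
                "place all HE blocks without overlap"
            )
    he_blocks = pd.DataFrame(he_rows, columns=HE_TRUTH_COLUMNS).sort_values(
        ["chromosome", "start"]
    ).reset_index(drop=True)

    # TE intervals: one interval per gene window at the drawn target density
    te_rows = []
    densities = np.zeros(len(genes))
    for j, r in enumerate(genes.itertuples()):
        a, b = config.te_density_beta[r.origin]
        d = float(rng.beta(a, b))
        ws = r.start - config.flank_bp
        we = r.end + config.flank_bp
        te_len = int(round(d * (we - ws)))
        if te_len > 0:
            off = int(rng.integers(0, we - ws - te_len + 1))
            te_rows.append((r.seqid, ws + off, ws + off + te_len))
        densities[j] = te_len / (we - ws)
    genes["te_density"] = densities
    tes = pd.DataFrame(te_rows, columns=["seqid", "start", "end"])

    anchors = pd.DataFrame(
        anchor_rows, columns=["ref_chrom", "ref_ordinal", "subgenome", "present", "family_id"]
    )
    return SimGenome(config=config, genes=genes, tes=tes, anchors=anchors, he_blocks=he_blocks)


# ---------------------------------------------------------------------------
# gene trees


def simulate_gene_trees(genome: SimGenome, config: SimConfig | None = None) -> tuple[str, LeafRoleMap]:
    """Emit one Newick tree per gene plus the matching leaf role map.

    With probability ``tree_signal`` the focal leaf is sister to its true
    origin's diploid relative; otherwise to a uniformly chosen other diploid.
    The sister node's support is drawn from the concordant distribution when
    the sister matches the truth, the discordant one otherwise; deeper nodes
    draw concordant supports.
    """
    config = config or genome.config
    rng = _rng(config, 2)
    subg = list(config.subgenomes)
    outgroup_sp = config.outgroups[0]
    lines: list[str] = []
    entries: dict[str, tuple[str, str]] = {}
    for r in genome.genes.itertuples():
        anc = r.family_id
        concordant = rng.random() < config.tree_signal
        if concordant:
            sister_sp = r.origin
        else:
            others = [sg for sg in subg if sg != r.origin]
            sister_sp = str(rng.choice(np.asarray(others)))
        support_dist = config.concordant_support if sister_sp == r.origin else config.discordant_support
        s1 = int(rng.integers(support_dist[0], support_dist[1] + 1))
        deeper = [int(rng.integers(config.concordant_support[0], config.concordant_support[1] + 1))
                  for _ in range(3)]
        rest = [sg for sg in subg if sg != sister_sp]
        leaf = {sg: f"{sg}|{anc}" for sg in subg}
        og = f"{outgroup_sp}|{anc}"
        newick = (
            f"((((({r.gene_id},{leaf[sister_sp]}){s1},{leaf[rest[0]]}){deeper[0]},"
            f"{leaf[rest[1]]}){deeper[1]},{leaf[rest[2]]}){deeper[2]},{og});"
        )
        lines.append(newick)
        entries[r.gene_id] = (config.focal_species, "focal")
        for sg in subg:
            entries[leaf[sg]] = (sg, "diploid")
        entries[og] = (outgroup_sp, "outgroup")
    return "\n".join(lines) + "\n", LeafRoleMap(entries)


# ---------------------------------------------------------------------------
# expression


def simulate_pair_counts(
    n_pairs: int,
    rng: np.random.Generator,
    n_tissues: int = 3,
    depth: float = 500.0,
    mixture: tuple[float, float, float] = (1.0, 0.0, 0.0),
    log2_scale_range: tuple[float, float] = (0.5, 2.5),
    bias_toward_a: float = 0.7,
    lengths: tuple[np.ndarray, np.ndarray] | None = None,
    scale: float | None = None,
    overdispersion: float = 0.0,
    gene_length_range: tuple[int, int] = (900, 3000),
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, pd.DataFrame]:
    """Low-level generator of homoeolog-pair count matrices.

    Each pair draws a model from ``mixture`` (H0 equal, H1 one scaling
    factor, H2 per-tissue factors); H1/H2 log2 factors are uniform in
    ``log2_scale_range`` (or fixed to ``scale`` when given), directed toward
    copy A with probability ``bias_toward_a``. Per-tissue totals are
    Poisson(``depth``); copy-A counts are binomial (beta-binomial when
    ``overdispersion`` > 0). Returns (pairs, x_a, x_b, truth).
    """
    if lengths is None:
        la = rng.integers(*gene_length_range, size=n_pairs).astype(float)
        lb = rng.integers(*gene_length_range, size=n_pairs).astype(float)
    else:
        la, lb = (np.asarray(v, dtype=float) for v in lengths)
    q = la / (la + lb)
    model = rng.choice(3, size=n_pairs, p=np.asarray(mixture, dtype=float))
    if scale is None:
        mag = rng.uniform(*log2_scale_range, size=(n_pairs, n_tissues))
    else:
        mag = np.full((n_pairs, n_tissues), np.log2(scale))
    sign = np.where(rng.random((n_pairs, n_tissues)) < bias_toward_a, 1.0, -1.0)
    # H1 uses one factor across tissues (first column); H2 one per tissue
    log2s = mag * sign
    log2s_h1 = np.repeat(log2s[:, :1], n_tissues, axis=1)
    logit_q = np.log(q / (1 - q))[:, None]
    log_s = np.where(model[:, None] == 1, log2s_h1, log2s) * np.log(2.0)
    log_s = np.where(model[:, None] == 0, 0.0, log_s)
    p = 1.0 / (1.0 + np.exp(-(logit_q + log_s)))
    n = rng.poisson(depth, size=(n_pairs, n_tissues))
    if overdispersion > 0:
        c = (1.0 - overdispersion) / overdispersion
        p = rng.beta(np.maximum(p * c, 1e-9), np.maximum((1 - p) * c, 1e-9))
    x_a = rng.binomial(n, p)
    x_b = n - x_a
    pairs = pd.DataFrame(
        {
            "pair_id": [f"pair{i:05d}" for i in range(n_pairs)],
            "gene_a": [f"pair{i:05d}_A" for i in range(n_pairs)],
            "gene_b": [f"pair{i:05d}_B" for i in range(n_pairs)],
            "subgenome_a": "A",
            "subgenome_b": "B",
            "length_a": la,
            "length_b": lb,
            "support": 100,
        }
    )
    true_s = np.where(model == 0, 1.0, 2.0 ** log2s_h1[:, 0])
    true_s = np.where(model == 2, np.nan, true_s)
    truth = pd.DataFrame(
        {
            "pair_id": pairs["pair_id"],
            "model": np.array(["H0", "H1", "H2"])[model],
            "true_s": true_s,
        }
    )
    return pairs, x_a, x_b, truth


def simulate_expression(
    genome: SimGenome, config: SimConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Homoeolog pair table, gene × tissue count matrix and expression truth.

    Pairs join the dominant-subgenome copy of each ancestral gene with one
    other-subgenome copy chosen at random (tandem extras excluded), so every
    gene appears in at most one pair and the count matrix is consistent with
    the per-pair truth; subgenome labels are the true origins (an HE gene
    pairs as its donor). Pair read totals are
    log-linear in mean TE density with coefficient −``te_effect``, embedding
    the negative TE–expression relationship; unpaired genes receive their own
    TE-modulated Poisson counts so genome-wide correlations are measurable.
    """
    config = config or genome.config
    rng = _rng(config, 3)
    genes = genome.genes
    core = genes[~genes["is_tandem"]]
    t_names = list(config.tissues)
    n_t = len(t_names)
    mean_density = float(genes["te_density"].mean())

    pair_rows = []
    counts: dict[str, np.ndarray] = {}
    truth_rows = []
    k = 0
    for _, grp in core.groupby(["ancestral_chrom", "family_id"], sort=True):
        dom_rows = grp[grp["subgenome"] == config.dominant]
        other_rows = grp[grp["subgenome"] != config.dominant].sort_values("gene_id")
        if dom_rows.empty or other_rows.empty:
            continue
        d = dom_rows.iloc[0]
        r = other_rows.iloc[int(rng.integers(len(other_rows)))]
        pair_id = f"pair{k:05d}"
        k += 1
        la = float(d["end"] - d["start"])
        lb = float(r["end"] - r["start"])
        q = la / (la + lb)
        model = int(rng.choice(3, p=np.asarray(config.mixture, dtype=float)))
        toward_a = rng.random() < config.dominant_bias_fraction
        mag = rng.uniform(*config.log2_scale_range, size=n_t)
        sign = 1.0 if toward_a else -1.0
        if model == 0:
            log_s = np.zeros(n_t)
            true_s = 1.0
        elif model == 1:
            log_s = np.full(n_t, sign * mag[0] * np.log(2.0))
            true_s = float(2.0 ** (sign * mag[0]))
        else:
            signs = np.where(rng.random(n_t) < 0.5, 1.0, -1.0)
            log_s = signs * mag * np.log(2.0)
            true_s = np.nan
        p = 1.0 / (1.0 + np.exp(-(np.log(q / (1 - q)) + log_s)))
        dens = 0.5 * (float(d["te_density"]) + float(r["te_density"]))
        lam = config.depth_per_pair * np.exp(
            -config.te_effect * (dens - mean_density)
            + rng.normal(0.0, config.expression_sigma, size=n_t)
        )
        n = rng.poisson(lam)
        if config.overdispersion > 0:
            c = (1.0 - config.overdispersion) / config.overdispersion
            p = rng.beta(np.maximum(p * c, 1e-9), np.maximum((1 - p) * c, 1e-9))
        x_a = rng.binomial(n, p)
        x_b = n - x_a
        counts[str(d["gene_id"])] = x_a
        counts[str(r["gene_id"])] = x_b
        pair_rows.append(
            (pair_id, d["gene_id"], r["gene_id"], d["origin"], r["origin"], la, lb,
             int(rng.integers(config.pair_support_range[0], config.pair_support_range[1] + 1)))
        )
        truth_rows.append((pair_id, ["H0", "H1", "H2"][model], true_s))

    # unpaired genes: TE-modulated counts of their own
    for r in genes.itertuples():
        if r.gene_id in counts:
            continue
        lam = 0.5 * config.depth_per_pair * np.exp(
            -config.te_effect * (r.te_density - mean_density)
            + rng.normal(0.0, config.expression_sigma, size=n_t)
        )
        counts[r.gene_id] = rng.poisson(lam)

    pairs = pd.DataFrame(
        pair_rows,
        columns=["pair_id", "gene_a", "gene_b", "subgenome_a", "subgenome_b",
                 "length_a", "length_b", "support"],
    )
    count_df = pd.DataFrame.from_dict(counts, orient="index", columns=t_names)
    count_df.index.name = "gene_id"
    count_df = count_df.loc[genes["gene_id"]]
    truth = pd.DataFrame(truth_rows, columns=["pair_id", "model", "true_s"])
    return pairs, count_df, truth


# ---------------------------------------------------------------------------
# file emission


def write_simulation(outdir: str | Path, genome: SimGenome) -> dict[str, Path]:
    """Write every simulated input + truth table under ``outdir``.

    Emits genes.gff3, tes.bed, anchors.tsv, trees.nwk, roles.tsv, pairs.tsv,
    counts.tsv and truth/*.tsv; returns a name → path map.
    """
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    config = genome.config
    paths: dict[str, Path] = {}

    paths["genes.gff3"] = outdir / "genes.gff3"
    write_genes_gff3(genome.genes, paths["genes.gff3"])
    paths["tes.bed"] = outdir / "tes.bed"
    write_bed(genome.tes, paths["tes.bed"])
    paths["anchors.tsv"] = outdir / "anchors.tsv"
    write_tsv(genome.anchors, paths["anchors.tsv"])

    trees_text, role_map = simulate_gene_trees(genome, config)
    paths["trees.nwk"] = outdir / "trees.nwk"
    paths["trees.nwk"].write_text(trees_text)
    paths["roles.tsv"] = outdir / "roles.tsv"
    write_role_map(role_map, paths["roles.tsv"])

    pairs, count_df, expr_truth = simulate_expression(genome, config)
    paths["pairs.tsv"] = outdir / "pairs.tsv"
    write_tsv(pairs, paths["pairs.tsv"])
    paths["counts.tsv"] = outdir / "counts.tsv"
    count_df.to_csv(paths["counts.tsv"], sep="\t")

    paths["truth/genes.tsv"] = outdir / "truth" / "genes.tsv"
    write_tsv(
        genome.genes[["gene_id", "chromosome", "ordinal", "subgenome", "origin", "te_density"]],
        paths["truth/genes.tsv"],
    )
    paths["truth/he_blocks.tsv"] = outdir / "truth" / "he_blocks.tsv"
    write_tsv(genome.he_blocks, paths["truth/he_blocks.tsv"])
    paths["truth/expression.tsv"] = outdir / "truth" / "expression.tsv"
    write_tsv(expr_truth, paths["truth/expression.tsv"])
    return paths
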