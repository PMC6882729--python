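"""Chromosome-level aggregation of subgenome calls and homoeologous-exchange
(HE) segmentation.

Each chromosome is assigned to the diploid progenitor whose calls dominate
among its genes. Runs of genes called to a single *other* progenitor are
segmented as putative HE blocks; real HEs range from single genes (hard to
distinguish from gene conversion, so single-gene blocks are flagged) to
regions covering much of a chromosome. Because a very large HE can flip the
naive majority, the consensus is re-estimated once with candidate blocks
excluded before final segmentation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

PLACEMENT_COLUMNS = ["gene_id", "chromosome", "ordinal", "called_species"]


@dataclass(frozen=True)
class ChromosomeAssignment:
    chromosome: str
    counts: dict
    assigned_species: str | None
    consensus_fraction: float


@dataclass(frozen=True)
class HEBlock:
    """A run of genes discordant with the chromosome consensus.

    ``gene_count`` is the ordinal span end−start+1 (it may include up to
    ``max_gap`` interleaved uncalled/consensus genes); ``donor_gene_count``
    counts only genes actually called to the donor.
    """

    chromosome: str
    start: int
    end: int
    donor: str
    gene_count: int
    donor_gene_count: int
    single_gene: bool


def _consensus(counts: dict) -> tuple[str | None, float]:
    total = sum(counts.values())
    if total == 0:
        return None, 0.0
    top = max(counts.values())
    winners = [sp for sp, n in counts.items() if n == top]
    if len(winners) > 1:
        return None, 0.0
    return winners[0], top / total


def assign_chromosomes(placements: pd.DataFrame) -> list[ChromosomeAssignment]:
    """Assign each chromosome to the progenitor with the most calls.

    Ties and all-uncalled chromosomes are left unassigned (fraction 0).
    """
    out = []
    for chrom, grp in placements.groupby("chromosome", sort=True):
        called = grp["called_species"].dropna()
        counts = called.value_counts().to_dict()
        species, frac = _consensus(counts)
        out.append(ChromosomeAssignment(chrom, counts, species, frac))
    return out


def call_he_segments(
    placements: pd.DataFrame,
    consensus_species: str,
    min_run: int = 3,
    max_gap: int = 1,
) -> list[HEBlock]:
    """Segment maximal single-donor runs on one chromosome.

    ``placements`` must be sorted by ordinal and belong to one chromosome.
    A run of genes called to one non-consensus donor may bridge up to
    ``max_gap`` consecutive uncalled/consensus genes; a call to a different
    donor always closes the run. Runs with fewer than ``min_run``
    donor-called genes are discarded.
    """
    if min_run < 1 or max_gap < 0:
        raise ValueError("min_run must be >= 1 and max_gap >= 0")
    ordinals = placements["ordinal"].to_numpy()
    if len(ordinals) and (ordinals != sorted(ordinals)).any():
        raise ValueError("placements must be sorted by ordinal")
    chroms = placements["chromosome"].unique()
    if len(chroms) > 1:
        raise ValueError("call_he_segments expects a single chromosome")
    chrom = chroms[0] if len(chroms) else ""

    blocks: list[HEBlock] = []
    donor = None
    start = end = None
    n_donor = 0
    gap = 0

    def close() -> None:
        nonlocal donor, start, end, n_donor, gap
        if donor is not None and n_donor >= min_run:
            span = end - start + 1
            blocks.append(
                HEBlock(chrom, start, end, donor, span, n_donor, single_gene=span == 1)
            )
        donor, start, end, n_donor, gap = None, None, None, 0, 0

    for row in placements.itertuples():
        call = row.called_species
        if pd.isna(call):
            call = None
        if call is not None and call != consensus_species:
            if donor is None:
                donor, start, end, n_donor, gap = call, row.ordinal, row.ordinal, 1, 0
            elif call == donor:
                end, n_donor, gap = row.ordinal, n_donor + 1, 0
            else:  # a different donor closes and opens
                close()
                donor, start, end, n_donor, gap = call, row.ordinal, row.ordinal, 1, 0
        else:  # uncalled or consensus gene
            if donor is not None:
                gap += 1
                if gap > max_gap:
                    close()
    close()
    return blocks


def assign_and_segment(
    placements: pd.DataFrame, min_run: int = 3, max_gap: int = 1
) -> tuple[list[ChromosomeAssignment], list[HEBlock]]:
    """Assign chromosomes and segment HE blocks, robust to very large HEs.

    The naive majority flips when a single exchange replaces most of a
    chromosome, so the consensus is chosen by parsimony: among called
    species, the one whose choice as consensus leaves the fewest discordant
    runs (ties broken by call count, then left unassigned). The reported
    consensus_fraction is count(assigned)/total called — identical to the
    majority fraction except in the mostly-replaced case.
    """
    assignments: list[ChromosomeAssignment] = []
    blocks: list[HEBlock] = []
    for chrom, grp in placements.groupby("chromosome", sort=True):
        grp = grp.sort_values("ordinal")
        called = grp["called_species"].dropna()
        counts = called.value_counts().to_dict()
        if not counts:
            assignments.append(ChromosomeAssignment(chrom, counts, None, 0.0))
            continue
        runs = {
            sp: len(call_he_segments(grp, sp, min_run=1, max_gap=0)) for sp in counts
        }
        best = min(runs.values())
        finalists = [sp for sp in counts if runs[sp] == best]
        species, _ = _consensus({sp: counts[sp] for sp in finalists})
        if species is None:  # tie in both run count and call count
            assignments.append(ChromosomeAssignment(chrom, counts, None, 0.0))
            continue
        total = sum(counts.values())
        assignments.append(
            ChromosomeAssignment(chrom, counts, species, counts[species] / total)
        )
        blocks.extend(call_he_segments(grp, species, min_run=min_run, max_gap=max_gap))
    return assignments, blocks


def he_bias_matrix(
    blocks: Iterable[HEBlock],
    assignments: Sequence[ChromosomeAssignment],
    unit: str = "genes",
) -> tuple[pd.DataFrame, dict]:
    """Donor × recipient exchange counts and pairwise bias ratios.

    The recipient of a block is its chromosome's assigned progenitor. With
    ``unit='genes'`` each block contributes its donor-called gene count;
    with ``unit='blocks'`` each block counts once. ``ratio[(d, r)]`` is
    count(d→r) / count(r→d); an undefined ratio (zero denominator) is
    reported as ``inf`` when the numerator is positive, ``nan`` otherwise.
    """
    if unit not in {"genes", "blocks"}:
        raise ValueError("unit must be 'genes' or 'blocks'")
    recipient_of = {a.chromosome: a.assigned_species for a in assignments}
    species = sorted(
        {a.assigned_species for a in assignments if a.assigned_species}
        | {b.donor for b in blocks}
    )
    mat = pd.DataFrame(0, index=species, columns=species, dtype=int)
    mat.index.name = "donor"
    mat.columns.name = "recipient"
    for b in blocks:
        recipient = recipient_of.get(b.chromosome)
        if recipient is None or recipient == b.donor:
            continue
        mat.loc[b.donor, recipient] += b.donor_gene_count if unit == "genes" else 1
    ratios: dict[tuple[str, str], float] = {}
    for d, r in itertools.permutations(species, 2):
        num, den = mat.loc[d, r], mat.loc[r, d]
        if den == 0:
            ratios[(d, r)] = float("inf") if num > 0 else float("nan")
        else:
            ratios[(d, r)] = num / den
    return mat, ratios
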