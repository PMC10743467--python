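"""Gene-tree branch-length quality control and supermatrix concatenation.

Single-copy gene trees from shallow-genome datasets frequently contain
mis-orthologous or contaminated sequences, which show up as abnormally
long branches.  The filter implemented here flags a taxon as
*problematic* when its terminal branch length exceeds the tree-wide mean
branch length by more than twice the standard deviation, and drops a gene
entirely when more than 40% of its taxa are problematic.  Both the branch
set entering the statistics (``all`` branches or ``terminal`` only) and
the sidedness of the deviation test are configurable; the defaults (all
branches, one-sided upper) target the long-branch signal.

Kept genes are concatenated into a supermatrix with a 1-based inclusive
partition table (RAxML-style ``DNA, gene = start-end`` lines); taxa
missing a gene are gap-filled.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import dendropy

from .seq_io import LabeledAlignment, LabeledSequence

logger = logging.getLogger("skimtax")

__all__ = [
    "GeneTree",
    "GeneQCReport",
    "Supermatrix",
    "MissingBranchLengthError",
    "DEFAULT_MAX_PROBLEMATIC_FRACTION",
    "read_gene_tree",
    "read_gene_trees",
    "branch_length_stats",
    "problematic_taxa",
    "filter_genes",
    "concatenate",
]

DEFAULT_MAX_PROBLEMATIC_FRACTION = 0.40
SD_MULTIPLIER = 2.0


class MissingBranchLengthError(ValueError):
    """A non-root edge lacks a branch length."""


@dataclass
class GeneTree:
    """A per-gene tree with branch lengths, used as given (no re-rooting)."""

    gene_id: str
    tree: dendropy.Tree

    @property
    def taxa(self) -> set[str]:
        return {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}

    def _edges(self, branches: str) -> list[tuple[str, float]]:
        """(description, length) for the selected branch set.

        The root edge is not a branch of the unrooted shape and is
        excluded; every other edge must carry a length.
        """
        out = []
        for edge in self.tree.preorder_edge_iter():
            if edge.tail_node is None:  # root edge
                continue
            node = edge.head_node
            is_terminal = node.is_leaf()
            if branches == "terminal" and not is_terminal:
                continue
            desc = (
                node.taxon.label if is_terminal
                else f"internal[{node.bipartition or id(node)}]"
            )
            if edge.length is None:
                raise MissingBranchLengthError(
                    f"gene {self.gene_id!r}: branch to {desc} has no length"
                )
            out.append((desc, float(edge.length)))
        return out

    def terminal_lengths(self) -> dict[str, float]:
        return dict(self._edges("terminal"))


@dataclass
class GeneQCReport:
    gene_id: str
    mean_bl: float
    sd_bl: float
    problematic: set[str]
    n_taxa: int
    keep: bool

    @property
    def fraction(self) -> float:
        return len(self.problematic) / self.n_taxa if self.n_taxa else 0.0


def read_gene_tree(
    path: Union[str, Path], gene_id: Union[str, None] = None
) -> GeneTree:
    """Read a single Newick tree; gene id defaults to the file stem."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    return GeneTree(gene_id or Path(path).stem, tree)


def read_gene_trees(path: Union[str, Path]) -> list[GeneTree]:
    """Read a multi-tree Newick file; genes are numbered by position."""
    trees = dendropy.TreeList.get(path=str(path), schema="newick")
    stem = Path(path).stem
    return [GeneTree(f"{stem}_{i + 1}", t) for i, t in enumerate(trees)]


def branch_length_stats(
    gt: GeneTree, branches: str = "all"
) -> tuple[float, float]:
    """Mean and sample SD (n-1) of branch lengths.

    ``branches`` selects the distribution: ``all`` edges of the tree or
    ``terminal`` edges only.
    """
    if branches not in ("all", "terminal"):
        raise ValueError("branches must be 'all' or 'terminal'")
    lengths = [bl for _, bl in gt._edges(branches)]
    if len(lengths) < 2:
        raise ValueError(
            f"gene {gt.gene_id!r}: need >= 2 branches with lengths"
        )
    return statistics.mean(lengths), statistics.stdev(lengths)


def pooled_branch_length_stats(
    trees: Sequence[GeneTree], branches: str = "all"
) -> tuple[float, float]:
    """Mean and sample SD over the branches of *all* trees pooled.

    Used by :func:`filter_genes`: a cross-gene reference distribution is
    the only threshold under which a large fraction of one gene's taxa
    can be problematic (no more than ~1/5 of any sample can exceed its
    own mean + 2 SD, by the one-sided Chebyshev bound, so per-tree
    thresholds can never trip a 40% cap).
    """
    lengths = [bl for gt in trees for _, bl in gt._edges(branches)]
    if len(lengths) < 2:
        raise ValueError("need >= 2 branches with lengths across the gene set")
    return statistics.mean(lengths), statistics.stdev(lengths)


def problematic_taxa(
    gt: GeneTree,
    branches: str = "all",
    sided: str = "one",
    threshold_stats: Union[tuple[float, float], None] = None,
) -> set[str]:
    """Taxa whose terminal branch deviates from the mean by > 2 SD.

    One-sided (default): terminal length strictly greater than
    ``mean + 2*sd``.  Two-sided additionally flags terminals shorter than
    ``mean - 2*sd``.  Equality at a threshold is never flagged.
    ``threshold_stats`` substitutes an externally computed ``(mean, sd)``
    (e.g. pooled across genes); by default the tree's own branches set
    the threshold.
    """
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    mean, sd = threshold_stats or branch_length_stats(gt, branches)
    upper = mean + SD_MULTIPLIER * sd
    lower = mean - SD_MULTIPLIER * sd
    flagged = set()
    for taxon, bl in gt.terminal_lengths().items():
        if bl > upper or (sided == "two" and bl < lower):
            flagged.add(taxon)
    return flagged


def filter_genes(
    trees: Sequence[GeneTree],
    max_fraction: float = DEFAULT_MAX_PROBLEMATIC_FRACTION,
    branches: str = "all",
    sided: str = "one",
    stats: str = "pooled",
) -> tuple[list[str], list[GeneQCReport]]:
    """Drop genes whose problematic-taxon fraction strictly exceeds the cap.

    ``stats="pooled"`` (default) flags taxa against the mean/SD of
    branch lengths pooled over the whole gene set — the reading under
    which the 40% cap is actually reachable (see
    :func:`pooled_branch_length_stats`).  ``stats="per-tree"`` thresholds
    each gene against its own branches.  Returns the kept gene ids
    (input order) and a report for every gene.
    """
    if not 0 <= max_fraction <= 1:
        raise ValueError("max_fraction must be in [0, 1]")
    if stats not in ("pooled", "per-tree"):
        raise ValueError("stats must be 'pooled' or 'per-tree'")
    pooled = (
        pooled_branch_length_stats(trees, branches)
        if stats == "pooled" else None
    )
    kept, reports = [], []
    for gt in trees:
        mean, sd = pooled if pooled else branch_length_stats(gt, branches)
        flagged = problematic_taxa(gt, branches, sided, threshold_stats=pooled)
        n_taxa = len(gt.taxa)
        keep = (len(flagged) / n_taxa) <= max_fraction
        reports.append(
            GeneQCReport(
                gene_id=gt.gene_id, mean_bl=mean, sd_bl=sd,
                problematic=flagged, n_taxa=n_taxa, keep=keep,
            )
        )
        if keep:
            kept.append(gt.gene_id)
        else:
            logger.info(
                "gene %s dropped: %d/%d taxa problematic (%.0f%%)",
                gt.gene_id, len(flagged), n_taxa,
                100 * len(flagged) / n_taxa,
            )
    return kept, reports


def write_qc_report(
    reports: Sequence[GeneQCReport], path: Union[str, Path]
) -> None:
    lines = ["gene_id\tn_taxa\tmean_bl\tsd_bl\tn_problematic\tfraction\tkeep"]
    for r in reports:
        lines.append(
            f"{r.gene_id}\t{r.n_taxa}\t{r.mean_bl:.6g}\t{r.sd_bl:.6g}\t"
            f"{len(r.problematic)}\t{r.fraction:.4f}\t{int(r.keep)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class Supermatrix:
    """Concatenated per-gene alignments with a partition table."""

    alignment: LabeledAlignment
    #: (gene_id, start, end) with 1-based inclusive column spans
    partitions: list[tuple[str, int, int]]

    @property
    def n_columns(self) -> int:
        return self.alignment.n_columns

    def partition_text(self) -> str:
        """RAxML-style ``DNA, gene = start-end`` lines."""
        return "\n".join(
            f"DNA, {gene} = {start}-{end}"
            for gene, start, end in self.partitions
        ) + "\n"

    def write(
        self, fasta_path: Union[str, Path], partition_path: Union[str, Path]
    ) -> None:
        from .seq_io import write_labeled_alignment

        write_labeled_alignment(self.alignment, fasta_path)
        Path(partition_path).write_text(self.partition_text())


def concatenate(
    gene_alignments: Sequence[tuple[str, LabeledAlignment]],
    taxa: Union[Sequence[str], None] = None,
) -> Supermatrix:
    """Concatenate per-gene alignments taxon-wise into a supermatrix.

    ``gene_alignments`` is an ordered list of ``(gene_id, alignment)``;
    sequences are matched across genes by ``sample_id``.  ``taxa`` fixes
    the row universe and order; by default it is the union of taxa in
    first-appearance order.  A taxon absent from a gene receives a gap
    block of that gene's width.
    """
    if not gene_alignments:
        raise ValueError("no gene alignments supplied")
    if taxa is None:
        seen: dict[str, None] = {}
        for _, aln in gene_alignments:
            for s in aln:
                seen.setdefault(s.sample_id, None)
        taxa = list(seen)
    rows: dict[str, list[str]] = {t: [] for t in taxa}
    species: dict[str, str] = {t: t for t in taxa}
    partitions = []
    start = 1
    for gene_id, aln in gene_alignments:
        width = aln.n_columns
        per_taxon: dict[str, str] = {}
        for s in aln:
            if s.sample_id in per_taxon:
                raise ValueError(
                    f"gene {gene_id!r}: duplicate taxon {s.sample_id!r}"
                )
            per_taxon[s.sample_id] = s.residues
            species[s.sample_id] = s.species_label
        for t in taxa:
            rows[t].append(per_taxon.get(t, "-" * width))
        partitions.append((gene_id, start, start + width - 1))
        start += width
    sequences = [
        LabeledSequence(t, species[t], "".join(rows[t])) for t in taxa
    ]
    return Supermatrix(LabeledAlignment(sequences), partitions)
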