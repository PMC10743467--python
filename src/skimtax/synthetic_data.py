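"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators, all pure functions of their spec (which carries the
seed):

* :func:`simulate_barcode_alignment` — a COI-like multi-species alignment
  with a plantable barcode gap.  A random ancestral sequence is drawn;
  each species ancestor diverges from it by independent per-site
  substitution at ``p_inter`` (substitution = jump to a uniformly chosen
  *different* base, i.e. an equal-rates, Jukes–Cantor-like step without
  rate heterogeneity); each sample then diverges from its species
  ancestor at ``p_intra``.  Named test groups get their own ancestors and
  emulate taxa of unresolved status (e.g. subspecies probed for cryptic
  species).
* :func:`simulate_rogue_gene_trees` — balanced gene trees whose branch
  lengths are uniform draws, with planted rogue taxa whose terminal
  branches are scaled by a large factor, and a known subset of "bad"
  genes in which half the taxa are rogue.
* :func:`make_mock_mitogenome` / :func:`simulate_mito_records` — small
  annotated mitogenomes with the full 37-gene feature table (typical
  insect gene lengths and strands, random spacers), plus mutated copies
  with an exact planted SNP count for identity benchmarking.

Default parameter values are the conditions the downstream analyses are
validated under: 8 training species x 10 samples, 621-column alignments,
p_intra = 0.005, p_inter = 0.08, three planted test groups; 20 gene trees
of 20 taxa with 3 bad genes; mitogenome pairs separated by 80 SNPs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence, Union

import dendropy
import numpy as np

from .mito_concat import AnnotatedRecord, Feature
from .seq_io import LabeledAlignment, LabeledSequence
from .tree_qc import GeneTree

__all__ = [
    "TestGroupSpec",
    "RogueSpec",
    "MitoSpec",
    "SimulationSpec",
    "simulate_barcode_alignment",
    "simulate_rogue_gene_trees",
    "make_mock_mitogenome",
    "simulate_mito_records",
    "mutate_sequence",
    "write_genbank",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class TestGroupSpec:
    """A planted test group: its own ancestor at ``divergence`` from the
    root ancestor, samples at the within-species rate."""

    __test__ = False  # not a test class, despite the Test* name

    name: str
    n_samples: int = 10
    divergence: float = 0.08


@dataclass(frozen=True)
class RogueSpec:
    n_genes: int = 20
    n_taxa: int = 20
    n_rogue_genes: int = 3
    rogue_taxon_fraction: float = 0.5   # within a rogue gene
    scale: float = 10.0                 # terminal-branch multiplier, >= 5
    bl_low: float = 0.05                # uniform branch-length range
    bl_high: float = 0.15


@dataclass(frozen=True)
class MitoSpec:
    n_taxa: int = 3
    n_snps: int = 80        # planted substitutions per derived genome
    spacer_max: int = 20    # intergenic spacer length range [0, max]


def _default_test_groups() -> tuple[TestGroupSpec, ...]:
    return (
        TestGroupSpec("TestGroupA"),
        TestGroupSpec("TestGroupB"),
        TestGroupSpec("TestGroupC"),
    )


@dataclass(frozen=True)
class SimulationSpec:
    """All knobs for the generators; reproducible from ``seed`` alone."""

    seed: int = 0
    n_species: int = 8
    samples_per_species: int = 10
    seq_length: int = 621
    p_intra: float = 0.005
    p_inter: float = 0.08
    test_group_spec: tuple[TestGroupSpec, ...] = field(
        default_factory=_default_test_groups
    )
    rogue_spec: RogueSpec = field(default_factory=RogueSpec)
    mito_spec: MitoSpec = field(default_factory=MitoSpec)

    def __post_init__(self) -> None:
        if not 0 <= self.p_intra < self.p_inter <= 0.75:
            raise ValueError(
                "require 0 <= p_intra < p_inter <= 0.75, got "
                f"{self.p_intra} / {self.p_inter}"
            )
        for name, v in (
            ("n_species", self.n_species),
            ("samples_per_species", self.samples_per_species),
            ("seq_length", self.seq_length),
        ):
            if v <= 0:
                raise ValueError(f"{name} must be positive")


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution at probability ``p`` to a different base."""
    out = seq.copy()
    hit = rng.random(seq.size) < p
    n = int(hit.sum())
    if n:
        # offset 1..3 from the current base index guarantees a change
        offsets = rng.integers(1, 4, size=n)
        idx = np.searchsorted(_BASES, out[hit])
        out[hit] = _BASES[(idx + offsets) % 4]
    return out


def _to_str(seq: np.ndarray) -> str:
    return seq.tobytes().decode("ascii")


def simulate_barcode_alignment(
    spec: SimulationSpec,
) -> tuple[LabeledAlignment, dict]:
    """Generate the training + test-group alignment and its ground truth.

    Returns ``(alignment, truth)``; ``truth`` records species and group
    memberships, which labels are training species, and the expected
    p-distance levels implied by the substitution rates.
    """
    rng = np.random.default_rng(spec.seed)
    root = rng.choice(_BASES, size=spec.seq_length)
    sequences: list[LabeledSequence] = []
    training_species = []
    test_groups: dict[str, list[str]] = {}

    for s in range(spec.n_species):
        species = f"TrainSp{s + 1:02d}"
        training_species.append(species)
        ancestor = _mutate(root, spec.p_inter, rng)
        for k in range(spec.samples_per_species):
            sid = f"{species}_s{k + 1:02d}"
            sequences.append(
                LabeledSequence(
                    sid, species, _to_str(_mutate(ancestor, spec.p_intra, rng))
                )
            )

    for group in spec.test_group_spec:
        ancestor = _mutate(root, group.divergence, rng)
        members = []
        for k in range(group.n_samples):
            sid = f"{group.name}_s{k + 1:02d}"
            members.append(sid)
            sequences.append(
                LabeledSequence(
                    sid, group.name,
                    _to_str(_mutate(ancestor, spec.p_intra, rng)),
                )
            )
        test_groups[group.name] = members

    aln = LabeledAlignment(sequences)
    # expected p-distance between two lineages that each underwent one
    # substitution pass at rate p from a common ancestor:
    # 2p(1-p) + (2/3)p^2  (two independent hits agree with prob 1/3)
    def pair_dist(p: float) -> float:
        return 2 * p * (1 - p) + (2 / 3) * p * p

    truth = {
        "training_species": training_species,
        "test_groups": test_groups,
        "labels": aln.labels,
        "expected_intra_distance": pair_dist(spec.p_intra),
        "expected_inter_distance_ancestors": pair_dist(spec.p_inter),
        "p_intra": spec.p_intra,
        "p_inter": spec.p_inter,
    }
    return aln, truth


def _balanced_newick(
    labels: Sequence[str], bl: dict[str, float], rng_lengths: list[float]
) -> str:
    """Balanced binary newick over ``labels``; internal branch lengths are
    popped from ``rng_lengths``."""
    if len(labels) == 1:
        lab = labels[0]
        return f"{lab}:{bl[lab]:.6f}"
    mid = len(labels) // 2
    left = _balanced_newick(labels[:mid], bl, rng_lengths)
    right = _balanced_newick(labels[mid:], bl, rng_lengths)
    return f"({left},{right}):{rng_lengths.pop():.6f}"


def simulate_rogue_gene_trees(
    spec: SimulationSpec,
) -> tuple[list[GeneTree], dict]:
    """Gene trees with planted long-branch (rogue) taxa.

    The first ``n_rogue_genes`` genes (after a seeded shuffle of gene
    order) carry ``rogue_taxon_fraction`` of their taxa with terminal
    branches scaled by ``scale``; the remaining genes are clean.  The
    truth record lists per-gene rogue taxa and which genes exceed the
    40% problematic-taxon cap.
    """
    rs = spec.rogue_spec
    rng = np.random.default_rng(spec.seed + 1)
    taxa = [f"T{i + 1:02d}" for i in range(rs.n_taxa)]
    gene_ids = [f"gene{i + 1:03d}" for i in range(rs.n_genes)]
    rogue_genes = sorted(
        rng.choice(rs.n_genes, size=rs.n_rogue_genes, replace=False).tolist()
    )
    n_rogue_taxa = int(round(rs.rogue_taxon_fraction * rs.n_taxa))
    trees, rogues_per_gene = [], {}
    for g, gene_id in enumerate(gene_ids):
        term_bl = {
            t: float(rng.uniform(rs.bl_low, rs.bl_high)) for t in taxa
        }
        rogues: set[str] = set()
        if g in rogue_genes:
            rogues = set(
                np.array(taxa)[
                    rng.choice(rs.n_taxa, size=n_rogue_taxa, replace=False)
                ].tolist()
            )
            for t in rogues:
                term_bl[t] *= rs.scale
        n_internal = rs.n_taxa - 1  # balanced rooted tree
        internal = [
            float(rng.uniform(rs.bl_low, rs.bl_high))
            for _ in range(n_internal)
        ]
        newick = _balanced_newick(list(taxa), term_bl, internal) + ";"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        trees.append(GeneTree(gene_id, tree))
        rogues_per_gene[gene_id] = sorted(rogues)
    truth = {
        "rogue_genes": [gene_ids[g] for g in rogue_genes],
        "rogues_per_gene": rogues_per_gene,
        "expected_dropped": [
            gene_ids[g] for g in rogue_genes
            if n_rogue_taxa / rs.n_taxa > 0.40
        ],
    }
    return trees, truth


# approximate gene lengths (nt) of an insect mitogenome; minus-strand
# genes follow the typical culicid arrangement
_MITO_GENES: tuple[tuple[str, int, str], ...] = (
    ("trnI", 69, "+"), ("trnQ", 69, "-"), ("trnM", 69, "+"),
    ("ND2", 1023, "+"), ("trnW", 68, "+"), ("trnC", 66, "-"),
    ("trnY", 66, "-"), ("COX1", 1536, "+"), ("trnL2", 71, "+"),
    ("COX2", 684, "+"), ("trnK", 71, "+"), ("trnD", 68, "+"),
    ("ATP8", 159, "+"), ("ATP6", 678, "+"), ("COX3", 789, "+"),
    ("trnG", 66, "+"), ("ND3", 354, "+"), ("trnA", 66, "+"),
    ("trnR", 65, "+"), ("trnN", 66, "+"), ("trnS1", 68, "+"),
    ("trnE", 66, "+"), ("trnF", 67, "-"), ("ND5", 1719, "-"),
    ("trnH", 66, "-"), ("ND4", 1338, "-"), ("ND4L", 297, "-"),
    ("trnT", 66, "+"), ("trnP", 66, "-"), ("ND6", 525, "+"),
    ("CYTB", 1137, "+"), ("trnS2", 68, "+"), ("ND1", 942, "-"),
    ("trnL1", 71, "-"), ("rrnL", 1325, "-"), ("trnV", 72, "-"),
    ("rrnS", 789, "-"),
)

# a few features are annotated under synonym spellings to exercise the
# canonical-name table the way real GenBank records do
_SYNONYM_SPELLINGS = {
    "COX1": "COI", "CYTB": "cob", "trnF": "tRNA-Phe",
    "rrnL": "16S ribosomal RNA", "trnL1": "tRNA-Leu(CUN)",
}


def _revcomp(seq: np.ndarray) -> np.ndarray:
    comp = {65: 84, 84: 65, 67: 71, 71: 67}  # A<->T, C<->G
    return np.array([comp[int(b)] for b in seq[::-1]], dtype=np.uint8)


def make_mock_mitogenome(
    spec: SimulationSpec,
    taxon: str = "MockTaxon",
    accession: str = "MOCK000001",
    rng: Union[np.random.Generator, None] = None,
) -> tuple[AnnotatedRecord, dict]:
    """A mock annotated mitogenome with the full 37-gene feature table.

    Gene blocks are random sequence of typical lengths separated by
    random spacers; the truth record maps each canonical gene name to
    the exact residues :func:`skimtax.mito_concat.extract_genes` must
    recover (minus-strand genes reverse-complemented).
    """
    ms = spec.mito_spec
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    chunks: list[np.ndarray] = []
    features: list[Feature] = []
    truth_genes: dict[str, str] = {}
    pos = 0
    for gene, length, strand in _MITO_GENES:
        spacer = int(rng.integers(0, ms.spacer_max + 1))
        if spacer:
            chunks.append(rng.choice(_BASES, size=spacer))
            pos += spacer
        block = rng.choice(_BASES, size=length)
        chunks.append(block)
        start, end = pos + 1, pos + length
        pos = end
        ftype = (
            "tRNA" if gene.startswith("trn")
            else "rRNA" if gene.startswith("rrn")
            else "CDS"
        )
        name = _SYNONYM_SPELLINGS.get(gene, gene)
        features.append(Feature(ftype, name, ((start, end),), strand))
        truth_genes[gene] = _to_str(
            _revcomp(block) if strand == "-" else block
        )
    record = AnnotatedRecord(
        taxon=taxon, accession=accession,
        sequence=_to_str(np.concatenate(chunks)), features=features,
    )
    truth = {"genes": truth_genes, "genome_length": len(record.sequence)}
    return record, truth


def mutate_sequence(
    sequence: str, n_snps: int, rng: np.random.Generator
) -> tuple[str, list[int]]:
    """Plant exactly ``n_snps`` substitutions at distinct positions.

    Returns the mutated sequence and the 0-based positions changed.
    """
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    positions = sorted(
        rng.choice(arr.size, size=n_snps, replace=False).tolist()
    )
    for p in positions:
        idx = int(np.searchsorted(_BASES, arr[p]))
        arr[p] = _BASES[(idx + int(rng.integers(1, 4))) % 4]
    return _to_str(arr), positions


def simulate_mito_records(
    spec: SimulationSpec,
) -> tuple[list[AnnotatedRecord], dict]:
    """A reference mock mitogenome plus derived taxa with planted SNPs.

    Every derived record reuses the reference feature table (lengths are
    preserved: substitutions only), so per-gene extraction is comparable
    across taxa; the truth record carries the per-taxon SNP positions.
    """
    ms = spec.mito_spec
    rng = np.random.default_rng(spec.seed + 2)
    ref, ref_truth = make_mock_mitogenome(
        spec, taxon="Taxon01", accession="MOCK000001", rng=rng
    )
    records = [ref]
    snps: dict[str, list[int]] = {"Taxon01": []}
    for t in range(1, ms.n_taxa):
        taxon = f"Taxon{t + 1:02d}"
        seq, positions = mutate_sequence(ref.sequence, ms.n_snps, rng)
        records.append(
            AnnotatedRecord(
                taxon=taxon, accession=f"MOCK{t + 1:06d}",
                sequence=seq, features=list(ref.features),
            )
        )
        snps[taxon] = positions
    truth = {
        "reference": ref_truth,
        "n_snps": ms.n_snps,
        "snp_positions": snps,
    }
    return records, truth


def write_genbank(records: Sequence[AnnotatedRecord], path) -> None:
    """Write :class:`AnnotatedRecord` objects as a GenBank flat file."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import SeqFeature, SimpleLocation, CompoundLocation
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    out = []
    for rec in records:
        seqrec = SeqRecord(
            Seq(rec.sequence), id=rec.accession, name=rec.accession[:16],
            description=f"{rec.taxon} mitochondrion, mock record",
            annotations={"molecule_type": "DNA", "organism": rec.taxon},
        )
        for ft in rec.features:
            strand = -1 if ft.strand == "-" else 1
            locs = [
                SimpleLocation(start - 1, end, strand)
                for start, end in ft.spans
            ]
            loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
            qualifiers = {"gene": [ft.name]}
            if ft.type == "CDS":
                qualifiers["product"] = [ft.name]
            seqrec.features.append(
                SeqFeature(loc, type=ft.type, qualifiers=qualifiers)
            )
        out.append(seqrec)
    SeqIO.write(out, str(path), "genbank")
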