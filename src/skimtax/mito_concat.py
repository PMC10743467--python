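"""Mitogenome gene extraction, per-gene grouping, and identity/SNP counts.

Annotated mitogenome records (GenBank flat files) are sliced into their
CDS/tRNA/rRNA features; gene names are canonicalised through an editable
synonym table covering the 37-gene animal mitochondrial vocabulary
(13 protein-coding genes, 22 tRNAs, 2 rRNAs).  Per-gene per-taxon
sequences are written as unaligned FASTA — alignment is an external step
— after which :func:`skimtax.tree_qc.concatenate` builds the supermatrix.
The control region (D-loop) is not part of the gene vocabulary and is
never extracted.

Whole-mitogenome comparison: identity is the fraction of pairwise-aligned
columns where both genomes carry a base and it is identical; SNPs are the
both-base mismatching columns; indel columns are tallied separately.  The
default aligner is edlib (deterministic global Needleman–Wunsch path);
mafft can be used instead, and a precomputed alignment is accepted.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("skimtax")

__all__ = [
    "Feature",
    "AnnotatedRecord",
    "GeneSet",
    "MitoIdentity",
    "MITO_GENE_NAMES",
    "load_synonym_table",
    "canonical_gene_name",
    "read_genbank",
    "extract_genes",
    "build_gene_sets",
    "write_gene_fastas",
    "mito_identity",
]

FEATURE_TYPES = ("CDS", "tRNA", "rRNA")

#: the 37 canonical animal mitochondrial genes
MITO_GENE_NAMES = (
    "ATP6", "ATP8", "COX1", "COX2", "COX3", "CYTB",
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
    "rrnL", "rrnS",
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)


def _normalise(name: str) -> str:
    return name.strip().upper().replace(" ", " ").strip()


def load_synonym_table(path: Union[str, Path, None] = None) -> dict[str, str]:
    """Load the synonym -> canonical-name table (tab-separated)."""
    if path is None:
        text = (
            resources.files("skimtax.data")
            .joinpath("mito_gene_synonyms.tsv")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    table: dict[str, str] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        syn, canon = line.rstrip("\n").split("\t")
        table[_normalise(syn)] = canon
    return table


_DEFAULT_TABLE: dict[str, str] | None = None


def canonical_gene_name(
    name: str, table: Union[dict[str, str], None] = None
) -> Union[str, None]:
    """Canonical gene name, or None when the name is unrecognized."""
    global _DEFAULT_TABLE
    if table is None:
        if _DEFAULT_TABLE is None:
            _DEFAULT_TABLE = load_synonym_table()
        table = _DEFAULT_TABLE
    return table.get(_normalise(name))


@dataclass(frozen=True)
class Feature:
    """One annotated gene feature, GenBank convention: 1-based inclusive
    spans, in annotation order; minus-strand features are
    reverse-complemented after slicing."""

    type: str
    name: str
    spans: tuple[tuple[int, int], ...]
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.type not in FEATURE_TYPES:
            raise ValueError(f"feature type must be one of {FEATURE_TYPES}")
        if not self.name:
            raise ValueError("feature name must be non-empty")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        for start, end in self.spans:
            if not 1 <= start <= end:
                raise ValueError(f"bad span {start}..{end}")


@dataclass
class AnnotatedRecord:
    taxon: str
    accession: str
    sequence: str
    features: list[Feature]

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        L = len(self.sequence)
        for f in self.features:
            for start, end in f.spans:
                if end > L:
                    raise ValueError(
                        f"{self.accession}: feature {f.name!r} span "
                        f"{start}..{end} exceeds sequence length {L}"
                    )


def read_genbank(path: Union[str, Path]) -> list[AnnotatedRecord]:
    """Read GenBank flat-file record(s) into :class:`AnnotatedRecord`."""
    records = []
    for rec in SeqIO.parse(str(path), "genbank"):
        feats = []
        for ft in rec.features:
            if ft.type not in FEATURE_TYPES:
                continue
            name = (
                ft.qualifiers.get("gene", [None])[0]
                or ft.qualifiers.get("product", [None])[0]
                or ft.qualifiers.get("note", [None])[0]
            )
            if not name:
                logger.warning(
                    "%s: %s feature without a name qualifier skipped",
                    rec.id, ft.type,
                )
                continue
            spans = tuple(
                (int(part.start) + 1, int(part.end))
                for part in ft.location.parts
            )
            strand = "-" if ft.location.strand == -1 else "+"
            feats.append(Feature(ft.type, name, spans, strand))
        taxon = rec.annotations.get("organism") or rec.id
        records.append(
            AnnotatedRecord(
                taxon=taxon, accession=rec.id,
                sequence=str(rec.seq), features=feats,
            )
        )
    if not records:
        raise ValueError(f"{path}: no GenBank records found")
    return records


def _slice_feature(sequence: str, feature: Feature) -> str:
    parts = [sequence[start - 1:end] for start, end in feature.spans]
    joined = "".join(parts)
    if feature.strand == "-":
        return str(Seq(joined).reverse_complement())
    return joined


def _spans_overlap(a: Feature, b: Feature) -> bool:
    for s1, e1 in a.spans:
        for s2, e2 in b.spans:
            if s1 <= e2 and s2 <= e1:
                return True
    return False


def extract_genes(
    record: AnnotatedRecord,
    synonyms: Union[dict[str, str], None] = None,
) -> dict[str, str]:
    """Slice every CDS/tRNA/rRNA feature, keyed by canonical gene name.

    Unrecognized names are kept under their raw name with a warning
    (the run degrades gracefully rather than failing).  Two features
    mapping to the same canonical name are an error when their spans
    overlap; non-overlapping duplicates keep the first and warn.
    """
    if not record.features:
        raise ValueError(f"{record.accession}: record has no features")
    out: dict[str, str] = {}
    first_feature: dict[str, Feature] = {}
    for ft in record.features:
        canon = canonical_gene_name(ft.name, synonyms)
        if canon is None:
            logger.warning(
                "%s: unrecognized gene name %r kept under its raw name",
                record.accession, ft.name,
            )
            canon = ft.name
        if canon in out:
            if _spans_overlap(first_feature[canon], ft):
                raise ValueError(
                    f"{record.accession}: overlapping duplicate "
                    f"annotations for {canon!r}"
                )
            logger.warning(
                "%s: duplicate non-overlapping annotation for %r; "
                "keeping the first", record.accession, canon,
            )
            continue
        out[canon] = _slice_feature(record.sequence, ft)
        first_feature[canon] = ft
    return out


#: map canonical gene name -> taxon -> unaligned residues
GeneSet = dict[str, dict[str, str]]


def build_gene_sets(
    records: Sequence[AnnotatedRecord],
    synonyms: Union[dict[str, str], None] = None,
) -> GeneSet:
    """Group extracted genes across taxa; missing genes are recorded."""
    if len(records) < 2:
        raise ValueError("need >= 2 records to build gene sets")
    gene_sets: GeneSet = {}
    for rec in records:
        for gene, seq in extract_genes(rec, synonyms).items():
            gene_sets.setdefault(gene, {})[rec.taxon] = seq
    all_taxa = {r.taxon for r in records}
    for gene, per_taxon in gene_sets.items():
        missing = all_taxa - set(per_taxon)
        if missing:
            logger.info(
                "gene %s missing from %d taxa (%s); concatenation will "
                "gap-fill", gene, len(missing), ", ".join(sorted(missing)),
            )
    return gene_sets


def write_gene_fastas(
    gene_sets: GeneSet, out_dir: Union[str, Path]
) -> list[Path]:
    """One unaligned FASTA per gene, ready for external alignment."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for gene in sorted(gene_sets):
        path = out_dir / f"{gene}.fasta"
        with open(path, "w") as fh:
            for taxon in sorted(gene_sets[gene]):
                fh.write(f">{taxon}\n{gene_sets[gene][taxon]}\n")
        paths.append(path)
    return paths


@dataclass
class MitoIdentity:
    """Pairwise whole-genome comparison on an alignment."""

    identity: float       # identical-base columns / both-base columns
    snp_count: int        # both-base columns that differ
    n_compared: int       # both-base columns
    indel_columns: int    # columns where exactly one genome has a base
    aligner: str

    @property
    def identity_percent(self) -> float:
        return 100.0 * self.identity


def _align_edlib(a: str, b: str) -> tuple[str, str]:
    import edlib

    result = edlib.align(a, b, task="path")
    nice = edlib.getNiceAlignment(result, a, b)
    return nice["query_aligned"], nice["target_aligned"]


def _align_mafft(a: str, b: str) -> tuple[str, str]:
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "pair.fasta"
        inp.write_text(f">a\n{a}\n>b\n{b}\n")
        proc = subprocess.run(
            ["mafft", "--auto", "--quiet", str(inp)],
            capture_output=True, text=True, check=True,
        )
        recs = list(SeqIO.parse(
            __import__("io").StringIO(proc.stdout), "fasta"
        ))
    return str(recs[0].seq).upper(), str(recs[1].seq).upper()


def mito_identity(
    a: str,
    b: str,
    alignment: Union[tuple[str, str], None] = None,
    aligner: str = "edlib",
) -> MitoIdentity:
    """Identity fraction and SNP count between two genome sequences.

    Supply ``alignment`` (the two gapped rows of a precomputed pairwise
    alignment) or let the named aligner produce one.  Symmetric in its
    arguments.
    """
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    if alignment is not None:
        row_a, row_b = (r.upper() for r in alignment)
        aligner = "precomputed"
    elif aligner == "edlib":
        row_a, row_b = _align_edlib(a.upper(), b.upper())
    elif aligner == "mafft":
        row_a, row_b = _align_mafft(a.upper(), b.upper())
    else:
        raise ValueError(f"unknown aligner {aligner!r}")
    if len(row_a) != len(row_b) or not row_a:
        raise ValueError("alignment rows must be equal-length and non-empty")
    identical = snps = indels = 0
    for ca, cb in zip(row_a, row_b):
        a_base = ca != "-"
        b_base = cb != "-"
        if a_base and b_base:
            if ca == cb:
                identical += 1
            else:
                snps += 1
        elif a_base or b_base:
            indels += 1
    n_compared = identical + snps
    if n_compared == 0:
        raise ValueError("alignment has no columns where both carry a base")
    return MitoIdentity(
        identity=identical / n_compared,
        snp_count=snps,
        n_compared=n_compared,
        indel_columns=indels,
        aligner=aligner,
    )
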