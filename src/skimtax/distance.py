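"""Pairwise identity-based (p-) distance matrices for barcoding.

Two column-handling dialects are exposed:

``strict-columns`` (default)
    Every alignment column is scored.  A column counts as identical when
    both sequences carry the same character and that character is not
    ``N`` (gap pairs ``-``/``-`` *are* identical); the distance is
    ``1 - identical / n_columns``.  This mirrors the behaviour of the
    classical "identity" scoring of full columns, with the conservative
    refinement that an ambiguous base is never credited as a match.

``pairwise-deletion``
    Columns where either sequence has a gap or ``N`` are excluded; the
    distance is ``mismatches / compared_columns`` — the conventional
    barcoding p-distance.  When no column survives, the distance is
    undefined and reported as ``nan``.

Any IUPAC ambiguity letter (R, Y, S, W, ...) is treated exactly like ``N``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .seq_io import AlignmentShapeError, LabeledAlignment

logger = logging.getLogger("skimtax")

__all__ = [
    "DIALECTS",
    "UNDEFINED_DISTANCE",
    "DistanceMatrix",
    "pairwise_distance",
    "distance_matrix",
]

DIALECTS = ("strict-columns", "pairwise-deletion")

#: sentinel for a pairwise-deletion distance with zero comparable columns
UNDEFINED_DISTANCE = float("nan")

# integer codes: A,C,G,T are 0..3; N (and any ambiguity letter) 4; gap 5
_N_CODE = 4
_GAP_CODE = 5
_ENCODE = np.full(128, _N_CODE, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i
_ENCODE[ord("-")] = _GAP_CODE


def encode(residues: str) -> np.ndarray:
    """Map residues to the internal integer code (ambiguity letters -> N)."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def _check_dialect(dialect: str) -> None:
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}, got {dialect!r}")


def pairwise_distance(
    a: str, b: str, dialect: str = "strict-columns"
) -> float:
    """Identity-based distance between two aligned residue strings."""
    _check_dialect(dialect)
    if len(a) != len(b):
        raise AlignmentShapeError(
            f"sequence lengths differ: {len(a)} vs {len(b)}"
        )
    if not a:
        raise AlignmentShapeError("empty sequences")
    ca, cb = encode(a), encode(b)
    if dialect == "strict-columns":
        identical = np.count_nonzero((ca == cb) & (ca != _N_CODE))
        return 1.0 - identical / len(a)
    valid = (ca < _N_CODE) & (cb < _N_CODE)
    n_valid = int(np.count_nonzero(valid))
    if n_valid == 0:
        return UNDEFINED_DISTANCE
    mismatches = int(np.count_nonzero(valid & (ca != cb)))
    return mismatches / n_valid


@dataclass
class DistanceMatrix:
    """Symmetric pairwise-distance table keyed by sample id."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("sample ids must be unique")
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("distances must lie in [0, 1]")
        if not np.allclose(np.diag(self.values), 0, equal_nan=False):
            raise ValueError("diagonal must be zero")
        if not np.array_equal(
            np.isnan(self.values), np.isnan(self.values.T)
        ) or not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T)
        ):
            raise ValueError("matrix must be symmetric")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.values[i, j])

    @property
    def n_undefined(self) -> int:
        """Number of undefined (nan) off-diagonal pairs, unordered."""
        return int(np.count_nonzero(np.isnan(self.values)) // 2)

    def to_tsv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", float_format="%.8g"
        )

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))

    def to_long_tsv(self, path: Union[str, Path]) -> None:
        """Long format ``id_a  id_b  distance`` over unordered pairs."""
        rows = []
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                rows.append((self.ids[i], self.ids[j], self.values[i, j]))
        pd.DataFrame(rows, columns=["id_a", "id_b", "distance"]).to_csv(
            path, sep="\t", index=False, float_format="%.8g"
        )


def distance_matrix(
    aln: LabeledAlignment, dialect: str = "strict-columns"
) -> DistanceMatrix:
    """All-against-all :func:`pairwise_distance` over an alignment.

    Undefined pairwise-deletion distances are recorded as ``nan``,
    reported via a log warning, and excluded from downstream
    distributions by the gap-analysis code.
    """
    _check_dialect(dialect)
    if len(aln) < 2:
        raise AlignmentShapeError("distance matrix needs >= 2 sequences")
    codes = np.stack([encode(s.residues) for s in aln])
    n, L = codes.shape
    values = np.zeros((n, n), dtype=float)
    if dialect == "strict-columns":
        for i in range(n):
            eq = (codes[i + 1:] == codes[i]) & (codes[i + 1:] != _N_CODE)
            d = 1.0 - eq.sum(axis=1) / L
            values[i, i + 1:] = d
            values[i + 1:, i] = d
    else:
        base = codes < _N_CODE
        for i in range(n):
            valid = base[i + 1:] & base[i]
            n_valid = valid.sum(axis=1)
            mism = (valid & (codes[i + 1:] != codes[i])).sum(axis=1)
            with np.errstate(invalid="ignore"):
                d = np.where(n_valid > 0, mism / np.maximum(n_valid, 1), np.nan)
            values[i, i + 1:] = d
            values[i + 1:, i] = d
    dm = DistanceMatrix(list(aln.sample_ids), values)
    if dm.n_undefined:
        logger.warning(
            "%d sequence pairs share no comparable columns; their distances "
            "are undefined and excluded from distributions", dm.n_undefined,
        )
    return dm
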